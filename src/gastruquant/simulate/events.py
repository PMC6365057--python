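"""Protrusion-event stream simulator.

Protrusion formation is modelled as a homogeneous Poisson process per cell
and per protrusion type, with orientations drawn from a von Mises
distribution centred on the animal pole (0°). Default rates mirror the
wild-type-like (0.33 events/cell/min for lamellipodia/pseudopodia) and
mutant-like (0.14) regimes of the study system.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["PROTRUSION_TYPES", "WT_LIKE_RATES", "MUTANT_LIKE_RATES", "simulate_protrusion_events"]

PROTRUSION_TYPES = ("lamellipodium_pseudopodium", "filopodium", "bleb")

# events/cell/min; lamellipodium rates are the wt/mutant emulation targets,
# filopodium and bleb rates are plausible fill-ins of the same order.
WT_LIKE_RATES = {"lamellipodium_pseudopodium": 0.33, "filopodium": 0.2, "bleb": 0.1}
MUTANT_LIKE_RATES = {"lamellipodium_pseudopodium": 0.14, "filopodium": 0.2, "bleb": 0.2}


def simulate_protrusion_events(
    rates: dict,
    n_cells: int,
    duration: float,
    orientation_concentration: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw Poisson protrusion events with von Mises orientations.

    Parameters
    ----------
    rates : dict
        Mapping protrusion type -> rate (events/cell/min). Types must come
        from :data:`PROTRUSION_TYPES`; rates must be non-negative.
    n_cells : int
        Number of observed cells (ids ``cell_0000`` ...).
    duration : float
        Observation window per cell, minutes.
    orientation_concentration : float
        von Mises κ; ``np.inf`` collapses all angles onto 0° (animal pole).
    seed : int
        Random seed; identical seeds give identical streams.

    Returns
    -------
    pandas.DataFrame
        Columns ``cell_id, t_min, type, angle_deg``; angles in [0, 360).
        ``df.attrs`` records the ground-truth rates and κ.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    for t, r in rates.items():
        if t not in PROTRUSION_TYPES:
            raise ValueError(f"unknown protrusion type {t!r}")
        if r < 0:
            raise ValueError(f"rate for {t!r} must be non-negative")

    rng = np.random.default_rng(seed)
    rows = []
    for cell in range(n_cells):
        cid = f"cell_{cell:04d}"
        for ptype in PROTRUSION_TYPES:
            rate = rates.get(ptype, 0.0)
            count = rng.poisson(rate * duration)
            if count == 0:
                continue
            times = np.sort(rng.uniform(0.0, duration, size=count))
            if np.isinf(orientation_concentration):
                angles = np.zeros(count)
            else:
                angles = np.degrees(
                    rng.vonmises(0.0, orientation_concentration, size=count)
                )
            angles = np.mod(angles, 360.0)
            for t_ev, a in zip(times, angles):
                rows.append((cid, float(t_ev), ptype, float(a)))
    df = pd.DataFrame(rows, columns=["cell_id", "t_min", "type", "angle_deg"])
    df.attrs["rates"] = dict(rates)
    df.attrs["duration"] = duration
    df.attrs["n_cells"] = n_cells
    df.attrs["orientation_concentration"] = orientation_concentration
    return df


def observation_windows(n_cells: int, duration: float) -> pd.DataFrame:
    """Uniform observation windows matching a simulated event stream."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return pd.DataFrame(
        {
            "cell_id": [f"cell_{c:04d}" for c in range(n_cells)],
            "minutes": [duration] * n_cells,
        }
    )
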