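"""Protrusion rates, orientation rose histograms, and circular statistics.

Events are manual annotations of cell protrusions (lamellipodia/pseudopodia,
filopodia, blebs) with an orientation angle measured from the animal pole
(0°, counterclockwise positive, range [0, 360)). Rates are normalised per
cell and per minute of observation; cohort dispersion is the SD over cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gastruquant.simulate.events import PROTRUSION_TYPES

__all__ = [
    "RateResult",
    "read_events",
    "read_windows",
    "protrusion_rate",
    "orientation_histogram",
    "circular_summary",
    "marginal_cell_fraction",
]


@dataclass
class RateResult:
    """Cohort protrusion rate: mean ± SD over per-cell rates."""

    mean: float
    sd: float
    sem: float
    per_cell: pd.DataFrame  # cell_id, count, minutes, rate
    protrusion_type: str | None


def read_events(path) -> pd.DataFrame:
    """Read an event CSV (``cell_id,t_min,type,angle_deg``) and validate it."""
    df = pd.read_csv(path)
    required = ["cell_id", "t_min", "type", "angle_deg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_type = set(df["type"].unique()) - set(PROTRUSION_TYPES)
    if bad_type:
        raise ValueError(f"{path}: unknown protrusion types {sorted(bad_type)}")
    ang = df["angle_deg"].to_numpy(dtype=float)
    if ((ang < 0) | (ang >= 360)).any():
        raise ValueError(f"{path}: angles must lie in [0, 360)")
    return df


def read_windows(path) -> pd.DataFrame:
    """Read an observation-window CSV (``cell_id,minutes``)."""
    df = pd.read_csv(path)
    if not {"cell_id", "minutes"}.issubset(df.columns):
        raise ValueError(f"{path}: needs columns cell_id, minutes")
    if (df["minutes"] <= 0).any():
        raise ValueError(f"{path}: observation minutes must be positive")
    return df


def protrusion_rate(
    events: pd.DataFrame,
    windows: pd.DataFrame,
    protrusion_type: str | None = None,
) -> RateResult:
    """Events per cell per minute, for one type or all types pooled.

    Every cell in ``windows`` contributes (zero-event cells included); an
    event whose cell has no observation window is an error. Per-cell rate =
    count / observed minutes; the cohort value is the mean ± SD over cells.
    """
    if (windows["minutes"] <= 0).any():
        raise ValueError("observation windows must have positive minutes")
    ev = events
    if protrusion_type is not None:
        ev = ev[ev["type"] == protrusion_type]
    known = set(windows["cell_id"])
    unknown = set(ev["cell_id"]) - known
    if unknown:
        raise ValueError(f"events reference cells without windows: {sorted(unknown)[:5]}")
    counts = ev.groupby("cell_id").size()
    per_cell = windows.copy()
    per_cell["count"] = per_cell["cell_id"].map(counts).fillna(0).astype(int)
    per_cell["rate"] = per_cell["count"] / per_cell["minutes"]
    rates = per_cell["rate"].to_numpy(dtype=float)
    sd = float(rates.std(ddof=1)) if len(rates) > 1 else 0.0
    return RateResult(
        mean=float(rates.mean()),
        sd=sd,
        sem=sd / np.sqrt(len(rates)),
        per_cell=per_cell[["cell_id", "count", "minutes", "rate"]],
        protrusion_type=protrusion_type,
    )


def orientation_histogram(events: pd.DataFrame, bin_deg: float = 30.0) -> pd.DataFrame:
    """Rose-plot counts in half-open angular bins ``[k·w, (k+1)·w)``.

    ``bin_deg`` must divide 360. An angle exactly on a boundary falls in the
    higher bin. Returns ``bin_low_deg, bin_high_deg, count``; counts sum to
    the number of events.
    """
    if bin_deg <= 0 or not np.isclose(360.0 % bin_deg, 0.0):
        raise ValueError(f"bin width {bin_deg} does not divide 360")
    n_bins = int(round(360.0 / bin_deg))
    ang = np.mod(events["angle_deg"].to_numpy(dtype=float), 360.0)
    idx = np.floor(ang / bin_deg).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # guard float edge at 360-eps
    counts = np.bincount(idx, minlength=n_bins)
    lows = np.arange(n_bins) * bin_deg
    return pd.DataFrame(
        {"bin_low_deg": lows, "bin_high_deg": lows + bin_deg, "count": counts}
    )


def circular_summary(angles_deg) -> tuple[float, float]:
    """Mean direction (degrees in [0, 360)) and resultant length R ∈ [0, 1].

    Vector-sum statistics: R = 1 iff all angles coincide, R = 0 for a
    balanced (e.g. antipodal) sample. Empty input is an error.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one angle")
    rad = np.radians(a)
    c, s = np.cos(rad).mean(), np.sin(rad).mean()
    r = float(np.hypot(c, s))
    mean_dir = float(np.mod(np.degrees(np.arctan2(s, c)), 360.0))
    return mean_dir, r


def marginal_cell_fraction(n_with: int, n_total: int) -> float:
    """Fraction of cells displaying a protrusion phenotype."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_with <= n_total:
        raise ValueError("need 0 <= n_with <= n_total")
    return n_with / n_total
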