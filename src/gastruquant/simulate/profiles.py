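"""Synthetic membrane/cytosol line profiles.

A line drawn across ``n_cells`` adjacent cells crosses ``n_cells + 1``
membranes; each membrane appears as an intensity peak over the cytosolic
plateau. Peaks are raised-cosine bumps whose support is exactly
``peak_width`` px wide, so every sample farther than ``peak_width / 2`` from
a peak center sits exactly on the plateau — the noise-free cytosol/membrane
ratio is therefore recovered exactly by the profile analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gastruquant.morphometry import IntensityProfile

__all__ = ["ProfileSimConfig", "make_membrane_profile"]


@dataclass
class ProfileSimConfig:
    n_cells: int = 4
    membrane_peak: float = 200.0
    cytosol_level: float = 50.0
    peak_width: float = 10.0  # full support width of one membrane bump, px
    noise_sigma: float = 0.0
    length: int = 200  # samples (1 px spacing)
    seed: int = 0

    def __post_init__(self):
        if not self.membrane_peak > self.cytosol_level >= 0:
            raise ValueError("need membrane_peak > cytosol_level >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.peak_width <= 0 or self.length < 3:
            raise ValueError("invalid peak_width or length")
        if self.n_cells > 0:
            spacing = self.length / (self.n_cells + 1)
            if spacing < self.peak_width:
                raise ValueError(
                    f"peak spacing {spacing:.1f} px is smaller than peak_width "
                    f"{self.peak_width} px"
                )


def make_membrane_profile(config: ProfileSimConfig) -> IntensityProfile:
    """1D profile with ``n_cells + 1`` membrane peaks at known positions.

    ``n_cells = 0`` yields a flat cytosolic profile flagged as degenerate in
    the provenance (no membrane pair to quantify). The ground-truth
    cytosol/membrane ratio, peak positions and spacing are stored in the
    provenance dict.
    """
    pos = np.arange(config.length, dtype=float)
    intensity = np.full(config.length, config.cytosol_level, dtype=float)
    if config.n_cells > 0:
        spacing = config.length / (config.n_cells + 1)
        centers = spacing * (np.arange(config.n_cells + 1) + 0.5)
        amp = config.membrane_peak - config.cytosol_level
        h = config.peak_width / 2.0
        for c in centers:
            u = (pos - c) / h
            sel = np.abs(u) <= 1.0
            intensity[sel] += amp * 0.5 * (1.0 + np.cos(np.pi * u[sel]))
        degenerate = False
        centers = centers.tolist()
        spacing_out = spacing
    else:
        degenerate = True
        centers = []
        spacing_out = None

    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        intensity = intensity + rng.normal(0.0, config.noise_sigma, size=config.length)
        intensity = np.clip(intensity, 0.0, None)

    return IntensityProfile(
        position_px=pos,
        intensity=intensity,
        provenance={
            "generator": "make_membrane_profile",
            "degenerate": degenerate,
            "true_ratio": config.cytosol_level / config.membrane_peak,
            "peak_centers_px": centers,
            "peak_spacing_px": spacing_out,
            "peak_width_px": config.peak_width,
            "membrane_peak": config.membrane_peak,
            "cytosol_level": config.cytosol_level,
            "noise_sigma": config.noise_sigma,
            "seed": config.seed,
        },
    )
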