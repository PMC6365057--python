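"""Synthetic expression-domain images.

Produces a label image with a rotated elliptical prechordal-plate (ppl)
domain and a rectangular notochord (nc) bar separated by a configured gap
along the ppl's major axis, plus a scale-bar record — the geometry the
domain-morphometry measurements (length-to-width ratio, inter-domain
distance, scale-bar calibration) must recover.

Masks are built by testing pixel-center membership against the analytic
shapes, so with integer semi-axes and zero rotation the extreme pixel
centers land exactly on the shape boundary and the ground-truth LWR and gap
are recovered exactly; rotated variants carry up to ~1 px quantization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gastruquant.morphometry import BACKGROUND, NC, PPL, LabelImage

__all__ = ["DomainSimConfig", "make_domain_image"]


@dataclass
class DomainSimConfig:
    """Geometry of the synthetic two-domain image (all lengths in μm)."""

    ppl_axes: tuple = (100.0, 50.0)  # (major, minor) full axis lengths
    nc_width: float = 30.0  # bar width perpendicular to the major axis
    nc_length: float = 150.0  # bar length along the major axis
    gap: float = 60.0  # boundary gap between ppl and nc along the major axis
    rotation: float = 0.0  # degrees, counterclockwise
    pixel_size: float = 1.0  # μm per pixel
    scalebar: tuple | None = None  # (px length, μm value); default 100 px
    seed: int = 0

    def __post_init__(self):
        major, minor = self.ppl_axes
        if not major >= minor > 0:
            raise ValueError("need major >= minor > 0")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.nc_width <= 0 or self.nc_length <= 0:
            raise ValueError("nc dimensions must be positive")
        if self.scalebar is None:
            self.scalebar = (100.0, 100.0 * self.pixel_size)


def make_domain_image(config: DomainSimConfig) -> LabelImage:
    """Render the ppl ellipse and nc bar into a label image.

    Labels: 0 background, 1 ppl, 2 nc. Metadata stores the ground truths
    (``lwr``, ``gap_um``, ``um_per_px``, scale-bar record) each downstream
    estimator must recover. Overlapping domains with ``gap > 0`` raise.
    """
    major, minor = config.ppl_axes
    a = major / 2.0 / config.pixel_size  # semi-axes in px
    b = minor / 2.0 / config.pixel_size
    g = config.gap / config.pixel_size
    w = config.nc_width / 2.0 / config.pixel_size
    length = config.nc_length / config.pixel_size

    extent = a + g + length + 2 * max(b, w)
    half = int(np.ceil(extent)) + 4
    cy = cx = half
    size = 2 * half + 1

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    theta = np.radians(config.rotation)
    # rotate pixel centers into the unrotated domain frame
    dx, dy = xx - cx, yy - cy
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy

    ppl_mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    nc_mask = (u >= a + g) & (u <= a + g + length) & (np.abs(v) <= w)

    if config.gap > 0 and (ppl_mask & nc_mask).any():
        raise RuntimeError("construction failure: domains overlap despite gap > 0")
    if not ppl_mask.any() or not nc_mask.any():
        raise RuntimeError("construction failure: empty domain mask")

    pixels = np.zeros((size, size), dtype=np.uint8)
    pixels[ppl_mask] = PPL
    pixels[nc_mask] = NC

    bar_px, bar_um = config.scalebar
    meta = {
        "generator": "make_domain_image",
        "um_per_px": config.pixel_size,
        "scalebar_px": bar_px,
        "scalebar_um": bar_um,
        "lwr": major / minor,
        "gap_um": config.gap,
        "rotation_deg": config.rotation,
        "ppl_axes_um": (major, minor),
        "labels": {"background": BACKGROUND, "ppl": PPL, "nc": NC},
    }
    return LabelImage(pixels=pixels, metadata=meta)
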