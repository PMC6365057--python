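"""Expression-domain morphometry and intensity quantification.

Reimplements, as plain functions, the measurements done interactively in
Fiji on in-situ-hybridised embryo images and on fluorescence line profiles:

* length-to-width ratio (LWR) of an expression domain — longest axis is the
  maximum Feret diameter of the mask, width the maximal extent perpendicular
  to it;
* minimum boundary distance between two expression domains, converted to μm
  with a scale-bar calibration;
* membrane/cytosol intensity ratio from a line profile drawn across several
  cells, with membrane peaks found by prominence-based peak detection;
* per-nucleus mean intensity under a label mask.

Pixel model: pixel centers sit at integer coordinates (row-major, origin
top-left, 0-based); a boundary pixel is a mask pixel 4-adjacent to
background.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull, QhullError, cKDTree

__all__ = [
    "LabelImage",
    "Calibration",
    "IntensityProfile",
    "ProfileRatioResult",
    "calibrate",
    "segment_domain",
    "lwr",
    "domain_distance",
    "membrane_cytosol_ratio",
    "nuclear_mean_intensity",
    "save_label_image",
    "load_label_image",
    "read_profile",
    "write_profile",
]

# label semantics for domain masks
BACKGROUND, PPL, NC = 0, 1, 2


@dataclass
class LabelImage:
    """2D pixel array with label or intensity semantics plus metadata."""

    pixels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("LabelImage expects a 2D array")
        if np.issubdtype(self.pixels.dtype, np.floating) and (self.pixels < 0).any():
            raise ValueError("negative intensities")

    def mask(self, label: int) -> np.ndarray:
        return self.pixels == label


@dataclass(frozen=True)
class Calibration:
    """Isotropic image calibration in μm per pixel."""

    um_per_px: float

    def __post_init__(self):
        if self.um_per_px <= 0:
            raise ValueError("μm/px must be positive")


@dataclass
class IntensityProfile:
    """Ordered 1D intensity samples along a line (positions in px)."""

    position_px: np.ndarray
    intensity: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.position_px = np.asarray(self.position_px, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position_px.size < 3:
            raise ValueError("profile needs at least 3 samples")
        if self.position_px.size != self.intensity.size:
            raise ValueError("position/intensity length mismatch")
        if not np.all(np.diff(self.position_px) > 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class ProfileRatioResult:
    """Outcome of membrane/cytosol quantification on one profile."""

    ratio: float  # cytosol / membrane
    membrane_mean: float
    cytosol_mean: float
    peak_positions: np.ndarray
    peak_heights: np.ndarray
    n_cytosol_samples: int


def calibrate(bar_px: float, bar_um: float) -> Calibration:
    """Calibration from an annotated scale bar: μm/px = bar_um / bar_px."""
    if bar_px <= 0 or bar_um <= 0:
        raise ValueError("scale-bar length and value must be positive")
    return Calibration(um_per_px=bar_um / bar_px)


def segment_domain(
    image: np.ndarray | LabelImage,
    threshold: float,
    dark_stain: bool = False,
) -> np.ndarray:
    """Largest 8-connected component above (or below) a threshold.

    Replaces interactive ROI selection: thresholds the intensity image
    (``dark_stain=True`` selects pixels *below* the threshold, for
    chromogenic stains darker than background) and keeps the largest
    8-connected component. An empty segmentation is an error.
    """
    px = image.pixels if isinstance(image, LabelImage) else np.asarray(image)
    fg = (px < threshold) if dark_stain else (px > threshold)
    labeled, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("segmentation is empty: no pixels pass the threshold")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return labeled == keep


def _hull_points(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if len(xs) == 0:
        raise ValueError("empty mask")
    pts = np.column_stack([xs, ys]).astype(float)
    if len(pts) < 3:
        return pts
    try:
        hull = ConvexHull(pts)
        return pts[hull.vertices]
    except QhullError:
        return pts  # collinear pixels


def lwr(mask: np.ndarray) -> float:
    """Length-to-width ratio of a mask.

    Length = maximum Feret diameter (largest pixel-center pairwise
    distance); width = maximal extent of the mask projected perpendicular to
    that axis. The ratio is ≥ 1 by construction. Degenerate masks (single
    pixel, or zero perpendicular extent) are an error.
    """
    pts = _hull_points(mask)
    if len(pts) < 2:
        raise ValueError("mask is degenerate (fewer than 2 pixels)")
    d = pts[:, None, :] - pts[None, :, :]
    dist2 = np.einsum("ijk,ijk->ij", d, d)
    i, j = np.unravel_index(np.argmax(dist2), dist2.shape)
    length = float(np.sqrt(dist2[i, j]))
    axis = (pts[j] - pts[i]) / length
    perp = np.array([-axis[1], axis[0]])
    proj = pts @ perp
    width = float(proj.max() - proj.min())
    if width == 0:
        raise ValueError("mask is degenerate (zero width)")
    return length / width


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Centers (x, y) of mask pixels 4-adjacent to background."""
    m = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    ys, xs = np.nonzero(m & ~eroded)
    return np.column_stack([xs, ys]).astype(float)


def domain_distance(
    mask_ppl: np.ndarray, mask_nc: np.ndarray, calibration: Calibration
) -> float:
    """Minimum boundary-to-boundary distance between two domains, in μm.

    Euclidean distance between the closest boundary pixel centers of the
    two masks, scaled by the calibration. Overlapping masks return 0 with a
    warning. Symmetric in its arguments.
    """
    a = np.asarray(mask_ppl, dtype=bool)
    b = np.asarray(mask_nc, dtype=bool)
    if not a.any() or not b.any():
        raise ValueError("both masks must be non-empty")
    if (a & b).any():
        warnings.warn("domains overlap; distance is 0", stacklevel=2)
        return 0.0
    pa = _boundary_pixels(a)
    pb = _boundary_pixels(b)
    tree = cKDTree(pb)
    dmin, _ = tree.query(pa, k=1)
    return float(dmin.min()) * calibration.um_per_px


def membrane_cytosol_ratio(
    profile: IntensityProfile,
    prominence: float = 10.0,
    min_spacing: float = 8.0,
    peak_halfwidth: float | None = None,
) -> ProfileRatioResult:
    """Cytosol-to-membrane intensity ratio from a line profile.

    Membrane peaks are local maxima with at least ``prominence`` prominence
    and ``min_spacing`` px separation (at least two peaks are required — a
    cell contributes two membranes to the line). Membrane intensity is the
    mean of the peak values; cytosol intensity is the mean of all samples
    strictly farther than ``peak_halfwidth`` (default ``min_spacing / 2``)
    from every peak; the reported ratio is cytosol / membrane.

    The ratio is invariant under multiplicative rescaling of the whole
    profile (gain) but not under an additive offset; no external-background
    subtraction is applied. To use an extracellular background reference
    instead of the cytosolic plateau, divide ``membrane_mean`` by that
    reference yourself.
    """
    pos = profile.position_px
    inten = profile.intensity
    step = float(np.median(np.diff(pos)))
    idx, props = find_peaks(
        inten, prominence=prominence, distance=max(1, int(round(min_spacing / step)))
    )
    if len(idx) < 2:
        raise ValueError("no membrane pair found (fewer than 2 peaks)")
    if peak_halfwidth is None:
        peak_halfwidth = min_spacing / 2.0
    peak_pos = pos[idx]
    peak_heights = inten[idx]
    dist_to_peak = np.min(np.abs(pos[:, None] - peak_pos[None, :]), axis=1)
    cyt_sel = dist_to_peak > peak_halfwidth
    if not cyt_sel.any():
        raise ValueError("no cytosolic samples outside the membrane peaks")
    membrane = float(peak_heights.mean())
    cytosol = float(inten[cyt_sel].mean())
    if membrane == 0:
        raise ValueError("membrane intensity is zero")
    return ProfileRatioResult(
        ratio=cytosol / membrane,
        membrane_mean=membrane,
        cytosol_mean=cytosol,
        peak_positions=peak_pos,
        peak_heights=peak_heights,
        n_cytosol_samples=int(cyt_sel.sum()),
    )


def nuclear_mean_intensity(
    signal_image: np.ndarray, nuclear_mask: np.ndarray
) -> pd.DataFrame:
    """Mean signal intensity per labelled nucleus.

    ``nuclear_mask`` is an integer label image (0 = background, one label
    per nucleus, e.g. from a DAPI channel); an empty mask is an error.
    Returns a frame with columns ``label, mean_intensity, n_px``.
    """
    sig = np.asarray(signal_image, dtype=float)
    lab = np.asarray(nuclear_mask)
    if sig.shape != lab.shape:
        raise ValueError("signal and mask shapes differ")
    labels = np.unique(lab)
    labels = labels[labels > 0]
    if len(labels) == 0:
        raise ValueError("nuclear mask is empty")
    means = ndimage.mean(sig, labels=lab, index=labels)
    npx = ndimage.sum_labels(np.ones_like(lab), labels=lab, index=labels)
    return pd.DataFrame(
        {"label": labels, "mean_intensity": means, "n_px": npx.astype(int)}
    )


# ---------------------------------------------------------------------------
# file I/O: PNG/TIFF images with JSON sidecars, profile CSVs


def save_label_image(img: LabelImage, path) -> Path:
    """Write a label/intensity image plus a JSON metadata sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img.pixels.astype(np.uint16))
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img.pixels.astype(np.uint8))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(img.metadata, indent=1, default=float))
    return sidecar


def load_label_image(path) -> LabelImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        px = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        px = iio.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return LabelImage(pixels=px, metadata=meta)


def read_profile(path) -> IntensityProfile:
    """Read a line-profile CSV (``position_px,intensity``)."""
    df = pd.read_csv(path)
    if not {"position_px", "intensity"}.issubset(df.columns):
        raise ValueError(f"{path}: needs columns position_px, intensity")
    return IntensityProfile(
        position_px=df["position_px"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        provenance={"path": str(path)},
    )


def write_profile(profile: IntensityProfile, path) -> None:
    pd.DataFrame(
        {"position_px": profile.position_px, "intensity": profile.intensity}
    ).to_csv(path, index=False)
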