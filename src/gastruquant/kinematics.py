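"""Track kinematics and the tissue–tissue movement-correlation order parameter.

The central quantity is the *order parameter of local correlation* between
two cell populations (e.g. prechordal plate and overlying neuroectoderm):
3D velocity vectors are computed per cell from consecutive track positions,
averaged within 50 × 50 μm sectors of an xy grid centred on the leading edge
of the reference population (z is collapsed), and for every sector occupied
by both populations the cosine between the two sector-mean velocity vectors
is taken. The unweighted mean of these cosines over sectors is the order
parameter: +1 when the tissues co-move, −1 when they move in opposition.

Conventions: after :func:`orient_axes` the animal pole is +y, so positive
y-velocity means animal-ward migration; sectors are half-open intervals
``[low, high)``; the leading edge is the centroid of the animal-most
quantile of the reference population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "TrackSet",
    "SectorField",
    "CorrelationResult",
    "read_tracks",
    "write_tracks",
    "orient_axes",
    "compute_velocities",
    "leading_edge",
    "bin_to_grid",
    "directional_correlation",
    "order_parameter",
    "ap_velocity",
]

TRACK_COLUMNS = ["track_id", "population", "frame", "t_min", "x_um", "y_um", "z_um"]

# Animal pole direction after orientation: +y.
ANIMAL_AXIS = np.array([0.0, 1.0, 0.0])


@dataclass
class TrackSet:
    """Time-stamped 3D cell positions tagged with a population label.

    ``data`` holds one row per (track, frame) with columns
    ``track_id, population, frame, t_min, x_um, y_um, z_um``. Positions are
    in μm, time in minutes. Frames must be strictly increasing within each
    track and (track, frame) pairs unique.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("track table is empty")
        pos = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite positions in track table")
        dup = df.duplicated(subset=["track_id", "frame"])
        if dup.any():
            row = df.index[dup][0]
            raise ValueError(f"duplicate (track_id, frame) pair at row {row}")
        # strictly increasing frames per track (sorted check)
        by = df.sort_values(["track_id", "frame"])
        diffs = by.groupby("track_id", sort=False)["frame"].diff().dropna()
        if (diffs <= 0).any():
            raise ValueError("frames must be strictly increasing within each track")
        self.data = by.reset_index(drop=True)

    @property
    def populations(self) -> list:
        return sorted(self.data["population"].unique())

    def positions(self, population: str, t: float) -> np.ndarray:
        sel = self.data[
            (self.data["population"] == population) & (self.data["t_min"] == t)
        ]
        return sel[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    def times(self) -> np.ndarray:
        return np.sort(self.data["t_min"].unique())


@dataclass
class SectorField:
    """Sector-averaged velocity field at one time point.

    ``table`` has one row per (sector, population) with columns
    ``ix, iy`` (integer sector indices relative to the grid origin),
    ``population``, ``vx, vy, vz`` (mean velocity, μm/min) and ``n``
    (occupancy). Sectors with zero occupancy are simply absent.
    """

    table: pd.DataFrame
    center: np.ndarray
    sector_um: float
    t: float


@dataclass
class CorrelationResult:
    """Order-parameter time series with dispersion.

    ``per_time`` has columns ``t_min, value, sd, sem, n`` where ``n`` is the
    number of sectors (single embryo) or embryos (pooled) behind each mean.
    """

    per_time: pd.DataFrame
    per_sector: pd.DataFrame | None = None


def read_tracks(path) -> TrackSet:
    """Read a track CSV (``track_id,population,frame,t_min,x_um,y_um,z_um``)."""
    df = pd.read_csv(path)
    try:
        return TrackSet(df)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def write_tracks(tracks: TrackSet, path) -> None:
    tracks.data.to_csv(path, index=False)


def orient_axes(tracks: TrackSet, animal_direction, lateral_direction=None) -> TrackSet:
    """Rotate coordinates so ``animal_direction`` becomes +y.

    A proper rigid rotation (no reflection, no scaling) about the origin;
    pairwise distances are preserved. With only the animal direction the
    rotation about the resulting +y axis is chosen by least squares and the
    lateral axes are arbitrary; pass ``lateral_direction`` (mapped to +x
    after projecting out the animal component) to pin the full frame — the
    sector grid is axis-aligned, so reproducible lateral axes matter when
    comparing sector-level output across re-orientations. Raises on a zero
    vector.
    """
    a = np.asarray(animal_direction, dtype=float)
    norm = np.linalg.norm(a)
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("animal_direction must be a non-zero finite vector")
    a = a / norm
    if lateral_direction is None:
        rot = Rotation.align_vectors([ANIMAL_AXIS], [a])[0].as_matrix()
    else:
        lat = np.asarray(lateral_direction, dtype=float)
        lat = lat - (lat @ a) * a
        n = np.linalg.norm(lat)
        if n == 0 or not np.isfinite(n):
            raise ValueError("lateral_direction is zero or parallel to the animal axis")
        x_hat = lat / n
        z_hat = np.cross(x_hat, a)
        rot = np.vstack([x_hat, a, z_hat])  # rows: new x, y, z axes
    df = tracks.data.copy()
    pos = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    df[["x_um", "y_um", "z_um"]] = pos @ rot.T
    meta = dict(tracks.metadata)
    meta["oriented"] = True
    return TrackSet(df, metadata=meta)


def compute_velocities(tracks: TrackSet) -> pd.DataFrame:
    """Forward-difference velocities over consecutive observed frames.

    One sample per consecutive pair of observations within a track:
    v = Δposition / Δt, with Δt the actual time difference, so gaps in a
    track are handled without interpolation. Single-frame tracks yield no
    samples. Returns a tidy frame with columns ``track_id, population,
    t_min`` (interval start), ``t_mid``, ``x_um, y_um, z_um`` (interval
    start position) and ``vx, vy, vz`` (μm/min).
    """
    df = tracks.data
    g = df.groupby("track_id", sort=False)
    dt = g["t_min"].diff().shift(-1)
    dpos = g[["x_um", "y_um", "z_um"]].diff().shift(-1)
    valid = dt.notna() & (dt > 0)
    out = df.loc[valid, ["track_id", "population", "t_min", "x_um", "y_um", "z_um"]].copy()
    v = dpos.loc[valid].to_numpy(dtype=float) / dt.loc[valid].to_numpy(dtype=float)[:, None]
    out[["vx", "vy", "vz"]] = v
    out["t_mid"] = out["t_min"] + dt.loc[valid].to_numpy(dtype=float) / 2.0
    bad = dt.notna() & (dt <= 0)
    if bad.any():
        raise ValueError("non-positive time step within a track")
    return out.reset_index(drop=True)


def leading_edge(
    tracks: TrackSet, t: float, population: str = "ppl", quantile: float = 0.95
) -> np.ndarray:
    """Centroid of the animal-most cells of a population at time ``t``.

    Cells at or beyond the given quantile of the animal-axis (y) coordinate
    are averaged. ``quantile=0.95`` keeps the leading 5%.
    """
    pos = tracks.positions(population, t)
    if len(pos) == 0:
        raise ValueError(f"population {population!r} absent at t={t}")
    cut = np.quantile(pos[:, 1], quantile)
    lead = pos[pos[:, 1] >= cut]
    return lead.mean(axis=0)


def bin_to_grid(
    samples: pd.DataFrame, t: float, center, sector_um: float = 50.0
) -> SectorField:
    """Average velocity vectors in xy sectors of ``sector_um`` μm.

    The grid is anchored at ``center`` (sector boundaries at
    ``center + k·sector_um``), sectors are half-open ``[low, high)`` in both
    x and y, and the z direction is collapsed (full z per sector). Within
    each sector the per-population arithmetic mean of the 3D velocity
    vectors is taken.
    """
    if sector_um <= 0:
        raise ValueError("sector size must be positive")
    center = np.asarray(center, dtype=float)
    at_t = samples[samples["t_min"] == t]
    if len(at_t) == 0:
        raise ValueError(f"no velocity samples at t={t}")
    ix = np.floor((at_t["x_um"].to_numpy() - center[0]) / sector_um).astype(int)
    iy = np.floor((at_t["y_um"].to_numpy() - center[1]) / sector_um).astype(int)
    binned = at_t.assign(ix=ix, iy=iy)
    agg = (
        binned.groupby(["ix", "iy", "population"], sort=True)
        .agg(
            vx=("vx", "mean"),
            vy=("vy", "mean"),
            vz=("vz", "mean"),
            n=("vx", "size"),
        )
        .reset_index()
    )
    return SectorField(table=agg, center=center, sector_um=sector_um, t=t)


def directional_correlation(
    field: SectorField, pop_a: str, pop_b: str
) -> pd.DataFrame:
    """Per-sector cosine between the two populations' mean velocities.

    Only sectors where both populations are present with non-zero mean
    vectors contribute; others are excluded. Returns columns
    ``ix, iy, correlation, n_a, n_b``.
    """
    t = field.table
    a = t[t["population"] == pop_a].set_index(["ix", "iy"])
    b = t[t["population"] == pop_b].set_index(["ix", "iy"])
    common = a.index.intersection(b.index)
    rows = []
    for key in common:
        va = a.loc[key, ["vx", "vy", "vz"]].to_numpy(dtype=float)
        vb = b.loc[key, ["vx", "vy", "vz"]].to_numpy(dtype=float)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            continue  # zero-length mean vector: sector excluded
        c = float(np.dot(va, vb) / (na * nb))
        rows.append((key[0], key[1], np.clip(c, -1.0, 1.0), int(a.loc[key, "n"]), int(b.loc[key, "n"])))
    return pd.DataFrame(rows, columns=["ix", "iy", "correlation", "n_a", "n_b"])


def order_parameter(
    tracks_or_list,
    pop_a: str = "ppl",
    pop_b: str = "neuroectoderm",
    sector_um: float = 50.0,
    edge_population: str | None = None,
    edge_quantile: float = 0.95,
    weighted: bool = False,
    min_occupancy: int = 3,
) -> CorrelationResult:
    """Order-parameter time series for one embryo or a list of embryos.

    Per embryo and time point: velocities → leading-edge-centred sector
    grid → per-sector directional correlation → unweighted mean over
    sectors (occupancy-weighted when ``weighted=True``). Sectors where
    either population has fewer than ``min_occupancy`` cells are dropped: a
    "sector-averaged velocity" estimated from one or two cells is dominated
    by single-cell noise rather than tissue flow, and including such sectors
    makes the order parameter depend on tracking density. When several
    embryos are supplied, the across-embryo mean ± SEM per time point is
    reported (``n`` = embryos); for a single embryo the SD/SEM are across
    sectors (``n`` = sectors). Time points with no valid sector are absent
    from the output.
    """
    if isinstance(tracks_or_list, TrackSet):
        embryos = [tracks_or_list]
        pooled = False
    else:
        embryos = list(tracks_or_list)
        pooled = len(embryos) > 1
    edge_population = edge_population or pop_a

    per_embryo = []
    all_sectors = []
    for e_idx, tr in enumerate(embryos):
        vel = compute_velocities(tr)
        rows = []
        for t in np.sort(vel["t_min"].unique()):
            try:
                center = leading_edge(tr, t, population=edge_population, quantile=edge_quantile)
            except ValueError:
                continue
            fld = bin_to_grid(vel, t, center[:2], sector_um=sector_um)
            corr = directional_correlation(fld, pop_a, pop_b)
            corr = corr[(corr["n_a"] >= min_occupancy) & (corr["n_b"] >= min_occupancy)]
            if len(corr) == 0:
                continue
            vals = corr["correlation"].to_numpy()
            if weighted:
                w = (corr["n_a"] + corr["n_b"]).to_numpy(dtype=float)
                mean = float(np.average(vals, weights=w))
            else:
                mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append((t, mean, sd, sd / np.sqrt(len(vals)), len(vals)))
            corr = corr.assign(t_min=t, embryo=e_idx)
            all_sectors.append(corr)
        per_embryo.append(pd.DataFrame(rows, columns=["t_min", "value", "sd", "sem", "n"]))

    per_sector = pd.concat(all_sectors, ignore_index=True) if all_sectors else None
    if not pooled:
        return CorrelationResult(per_time=per_embryo[0], per_sector=per_sector)
    stacked = pd.concat(
        [d.assign(embryo=i) for i, d in enumerate(per_embryo)], ignore_index=True
    )
    g = stacked.groupby("t_min")["value"]
    out = g.agg(value="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="size")
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out = out.reset_index()[["t_min", "value", "sd", "sem", "n"]]
    return CorrelationResult(per_time=out, per_sector=per_sector)


def ap_velocity(
    tracks: TrackSet,
    population: str = "ppl",
    edge_quantile: float = 0.95,
) -> pd.DataFrame:
    """Animal-pole-directed velocity of leading-edge cells over time.

    Per time point with velocity samples: mean projection of the velocity
    onto the animal axis (+y) over cells at or beyond ``edge_quantile`` of
    the population's y coordinates. Positive values mean animal-ward
    movement. Returns ``t_min, value, sd, sem, n``.
    """
    vel = compute_velocities(tracks)
    vel = vel[vel["population"] == population]
    rows = []
    for t in np.sort(vel["t_min"].unique()):
        at_t = vel[vel["t_min"] == t]
        cut = np.quantile(at_t["y_um"].to_numpy(), edge_quantile)
        lead = at_t[at_t["y_um"] >= cut]
        if len(lead) == 0:
            continue
        vy = lead["vy"].to_numpy(dtype=float)
        sd = float(vy.std(ddof=1)) if len(vy) > 1 else 0.0
        rows.append((t, float(vy.mean()), sd, sd / np.sqrt(len(vy)), len(vy)))
    return pd.DataFrame(rows, columns=["t_min", "value", "sd", "sem", "n"])
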