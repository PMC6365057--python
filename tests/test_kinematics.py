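"""Kinematics: velocities, sector binning, directional correlation, order
parameter, and their invariances."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from gastruquant import kinematics as k
from gastruquant.simulate import TrackSimConfig, simulate_correlated_tracks


def make_tracks(rows):
    return k.TrackSet(
        pd.DataFrame(
            rows,
            columns=["track_id", "population", "frame", "t_min", "x_um", "y_um", "z_um"],
        )
    )


class TestReadTracks:
    def test_well_formed_file(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "track_id,population,frame,t_min,x_um,y_um,z_um\n"
            "a,ppl,0,0.0,0,0,0\na,ppl,1,1.0,1,0,0\n"
            "b,neuroectoderm,0,0.0,5,5,5\nb,neuroectoderm,1,1.0,5,6,5\n"
        )
        ts = k.read_tracks(p)
        assert ts.data["track_id"].nunique() == 2
        assert ts.populations == ["neuroectoderm", "ppl"]

    def test_duplicate_track_frame_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "track_id,population,frame,t_min,x_um,y_um,z_um\n"
            "a,ppl,0,0.0,0,0,0\na,ppl,0,0.0,1,0,0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            k.read_tracks(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("track_id,population,frame\n" "a,ppl,0\n")
        with pytest.raises(ValueError, match="missing"):
            k.read_tracks(p)


class TestOrientAxes:
    def test_already_oriented_is_identity(self):
        ts = make_tracks([("a", "ppl", 0, 0.0, 1.0, 2.0, 3.0)])
        out = k.orient_axes(ts, (0, 1, 0))
        assert np.allclose(
            out.data[["x_um", "y_um", "z_um"]], ts.data[["x_um", "y_um", "z_um"]]
        )

    def test_x_axis_rotation_is_isometry(self):
        rng = np.random.default_rng(4)
        rows = [
            (f"t{i}", "ppl", 0, 0.0, *rng.uniform(0, 10, 3)) for i in range(6)
        ]
        ts = make_tracks(rows)
        out = k.orient_axes(ts, (1, 0, 0))
        a = ts.data[["x_um", "y_um", "z_um"]].to_numpy()
        b = out.data[["x_um", "y_um", "z_um"]].to_numpy()
        # +x must map to +y
        ts2 = make_tracks([("a", "ppl", 0, 0.0, 1.0, 0.0, 0.0)])
        assert np.allclose(
            k.orient_axes(ts2, (1, 0, 0)).data[["x_um", "y_um", "z_um"]], [[0, 1, 0]],
            atol=1e-12,
        )
        # pairwise distances preserved
        da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
        assert np.allclose(da, db)

    def test_zero_vector_rejected(self):
        ts = make_tracks([("a", "ppl", 0, 0.0, 0, 0, 0)])
        with pytest.raises(ValueError):
            k.orient_axes(ts, (0, 0, 0))

    def test_joint_rotation_leaves_order_parameter_invariant(self):
        cfg = TrackSimConfig(
            n_cells_per_population=60, n_frames=10, coupling=0.7, noise_sigma=0.8, seed=2
        )
        ts = simulate_correlated_tracks(cfg)
        base = k.order_parameter(ts).per_time["value"].to_numpy()
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True)
        df = ts.data.copy()
        df[["x_um", "y_um", "z_um"]] = rot.apply(
            df[["x_um", "y_um", "z_um"]].to_numpy()
        )
        rotated = k.TrackSet(df)
        # re-orient with the full frame (animal + lateral) so the sector
        # grid is restored exactly
        back = k.orient_axes(
            rotated, rot.apply([0, 1, 0]), lateral_direction=rot.apply([1, 0, 0])
        )
        again = k.order_parameter(back).per_time["value"].to_numpy()
        assert np.allclose(base, again, atol=1e-8)


class TestVelocities:
    def test_forward_difference_arithmetic(self):
        ts = make_tracks(
            [
                ("a", "ppl", 0, 0.0, 0.0, 0.0, 0.0),
                ("a", "ppl", 1, 1.0, 2.0, 0.0, 0.0),
                ("s", "ppl", 0, 0.0, 5.0, 5.0, 5.0),
                ("s", "ppl", 1, 1.0, 5.0, 5.0, 5.0),
            ]
        )
        vel = k.compute_velocities(ts)
        va = vel[vel["track_id"] == "a"][["vx", "vy", "vz"]].to_numpy()[0]
        vs = vel[vel["track_id"] == "s"][["vx", "vy", "vz"]].to_numpy()[0]
        assert np.allclose(va, [2.0, 0.0, 0.0])
        assert np.allclose(vs, 0.0)

    def test_gap_uses_actual_dt(self):
        ts = make_tracks(
            [
                ("a", "ppl", 3, 3.0, 0.0, 0.0, 0.0),
                ("a", "ppl", 7, 7.0, 4.0, 0.0, 0.0),
            ]
        )
        vel = k.compute_velocities(ts)
        assert len(vel) == 1
        assert np.allclose(vel[["vx", "vy", "vz"]].to_numpy()[0], [1.0, 0.0, 0.0])

    def test_single_frame_track_yields_no_samples(self):
        ts = make_tracks([("a", "ppl", 0, 0.0, 1.0, 1.0, 1.0)])
        assert len(k.compute_velocities(ts)) == 0


class TestLeadingEdge:
    def test_single_cell_is_its_position(self):
        ts = make_tracks([("a", "ppl", 0, 0.0, 1.0, 2.0, 3.0)])
        assert np.allclose(k.leading_edge(ts, 0.0), [1.0, 2.0, 3.0])

    def test_quantile_selection_matches_explicit_sort(self):
        rows = [
            (f"t{i}", "ppl", 0, 0.0, 0.0, float(i), 0.0) for i in range(101)
        ]  # y = 0..100
        ts = make_tracks(rows)
        got = k.leading_edge(ts, 0.0, quantile=0.95)
        ys = np.arange(101.0)
        cut = np.quantile(ys, 0.95)
        oracle = ys[ys >= cut].mean()
        assert got[1] == pytest.approx(oracle)

    def test_coincident_cells(self):
        rows = [(f"t{i}", "ppl", 0, 0.0, 2.0, 2.0, 2.0) for i in range(5)]
        assert np.allclose(k.leading_edge(make_tracks(rows), 0.0), [2, 2, 2])

    def test_absent_population_is_error(self):
        ts = make_tracks([("a", "ppl", 0, 0.0, 0, 0, 0)])
        with pytest.raises(ValueError):
            k.leading_edge(ts, 0.0, population="neuroectoderm")


def velocity_frame(entries):
    """entries: (population, x, y, vx, vy, vz)"""
    return pd.DataFrame(
        [
            dict(
                track_id=f"t{i}", population=p, t_min=0.0, t_mid=0.5,
                x_um=x, y_um=y, z_um=0.0, vx=vx, vy=vy, vz=vz,
            )
            for i, (p, x, y, vx, vy, vz) in enumerate(entries)
        ]
    )


class TestGridAndCorrelation:
    def test_single_cell_sector_mean_is_cell_velocity(self):
        vel = velocity_frame([("ppl", 10.0, 10.0, 1.0, 2.0, 3.0)])
        fld = k.bin_to_grid(vel, 0.0, (0.0, 0.0), sector_um=50.0)
        assert len(fld.table) == 1
        assert np.allclose(fld.table[["vx", "vy", "vz"]].to_numpy()[0], [1, 2, 3])

    def test_opposite_velocities_cancel(self):
        vel = velocity_frame(
            [("ppl", 10.0, 10.0, 1.0, 0.0, 0.0), ("ppl", 20.0, 20.0, -1.0, 0.0, 0.0)]
        )
        fld = k.bin_to_grid(vel, 0.0, (0.0, 0.0))
        assert np.allclose(fld.table[["vx", "vy", "vz"]].to_numpy()[0], 0.0)

    def test_half_open_sector_assignment_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = rng.integers(2, 12)
            xy = rng.uniform(-100, 100, size=(n, 2))
            center = rng.uniform(-20, 20, size=2)
            sector = float(rng.uniform(20, 60))
            vel = velocity_frame(
                [("ppl", x, y, 1.0, 0.0, 0.0) for x, y in xy]
            )
            fld = k.bin_to_grid(vel, 0.0, center, sector_um=sector)
            # brute force: per-cell loop
            from collections import defaultdict

            cnt = defaultdict(int)
            for x, y in xy:
                ix = int(np.floor((x - center[0]) / sector))
                iy = int(np.floor((y - center[1]) / sector))
                cnt[(ix, iy)] += 1
            got = {
                (r.ix, r.iy): r.n for r in fld.table.itertuples()
            }
            assert got == dict(cnt)

    def test_non_positive_sector_rejected(self):
        vel = velocity_frame([("ppl", 0.0, 0.0, 1.0, 0.0, 0.0)])
        with pytest.raises(ValueError):
            k.bin_to_grid(vel, 0.0, (0, 0), sector_um=0.0)

    @pytest.mark.parametrize(
        "va,vb,expected",
        [((1, 0, 0), (2, 0, 0), 1.0), ((1, 0, 0), (-3, 0, 0), -1.0)],
    )
    def test_parallel_antiparallel(self, va, vb, expected):
        vel = velocity_frame([("ppl", 1.0, 1.0, *va), ("ne", 2.0, 2.0, *vb)])
        fld = k.bin_to_grid(vel, 0.0, (0, 0))
        corr = k.directional_correlation(fld, "ppl", "ne")
        assert corr["correlation"].to_numpy() == pytest.approx([expected])

    def test_cosine_matches_dot_product_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            va = rng.normal(size=3)
            vb = rng.normal(size=3)
            vel = velocity_frame([("ppl", 1.0, 1.0, *va), ("ne", 2.0, 2.0, *vb)])
            fld = k.bin_to_grid(vel, 0.0, (0, 0))
            got = k.directional_correlation(fld, "ppl", "ne")["correlation"].iloc[0]
            oracle = float(
                np.dot(va / np.linalg.norm(va), vb / np.linalg.norm(vb))
            )
            assert got == pytest.approx(oracle, abs=1e-12)

    def test_zero_mean_vector_sector_excluded(self):
        vel = velocity_frame(
            [
                ("ppl", 1.0, 1.0, 1.0, 0.0, 0.0),
                ("ppl", 2.0, 2.0, -1.0, 0.0, 0.0),
                ("ne", 3.0, 3.0, 1.0, 0.0, 0.0),
            ]
        )
        fld = k.bin_to_grid(vel, 0.0, (0, 0))
        assert len(k.directional_correlation(fld, "ppl", "ne")) == 0


class TestOrderParameter:
    def test_sector_mean_trivials(self):
        cfg = TrackSimConfig(
            n_cells_per_population=40, n_frames=6, coupling=1.0, noise_sigma=0.0, seed=3
        )
        res = k.order_parameter(simulate_correlated_tracks(cfg))
        assert np.allclose(res.per_time["value"], 1.0)

    def test_population_swap_symmetry(self):
        cfg = TrackSimConfig(
            n_cells_per_population=60, n_frames=8, coupling=0.6, noise_sigma=1.0, seed=9
        )
        ts = simulate_correlated_tracks(cfg)
        ab = k.order_parameter(ts, pop_a="ppl", pop_b="neuroectoderm").per_time
        ba = k.order_parameter(
            ts, pop_a="neuroectoderm", pop_b="ppl", edge_population="ppl"
        ).per_time
        assert np.allclose(ab["value"], ba["value"])

    def test_uniform_speed_rescale_invariance(self):
        cfg = TrackSimConfig(
            n_cells_per_population=50, n_frames=8, coupling=0.5, noise_sigma=1.0, seed=13
        )
        ts = simulate_correlated_tracks(cfg)
        base = k.order_parameter(ts).per_time["value"].to_numpy()
        df = ts.data.copy()
        df["t_min"] /= 3.0  # triples every speed, positions unchanged
        rescaled = k.order_parameter(k.TrackSet(df)).per_time["value"].to_numpy()
        assert np.allclose(base, rescaled, atol=1e-9)

    def test_values_bounded(self):
        cfg = TrackSimConfig(
            n_cells_per_population=50, n_frames=10, coupling=0.3, noise_sigma=2.0, seed=21
        )
        res = k.order_parameter(simulate_correlated_tracks(cfg))
        assert res.per_time["value"].between(-1, 1).all()
        assert res.per_sector["correlation"].between(-1, 1).all()

    def test_monotone_in_coupling(self):
        values = []
        for c in [0.0, 0.25, 0.5, 0.75, 1.0]:
            cfg = TrackSimConfig(
                n_cells_per_population=100,
                n_frames=20,
                coupling=c,
                noise_sigma=1.0,
                population_directions=((0, 1, 0), (0, -1, 0)),
                seed=11,
            )
            res = k.order_parameter(simulate_correlated_tracks(cfg))
            values.append(res.per_time["value"].mean())
        assert all(np.diff(values) > 0)

    def test_multi_embryo_pooling_reports_sem_over_embryos(self):
        embryos = [
            simulate_correlated_tracks(
                TrackSimConfig(
                    n_cells_per_population=40, n_frames=6, coupling=0.9,
                    noise_sigma=0.5, seed=s,
                )
            )
            for s in (1, 2, 3)
        ]
        res = k.order_parameter(embryos)
        assert (res.per_time["n"] == 3).all()
        assert np.allclose(
            res.per_time["sem"], res.per_time["sd"] / np.sqrt(3)
        )


class TestApVelocity:
    def test_pure_drift_recovered_exactly(self):
        cfg = TrackSimConfig(
            n_cells_per_population=30, n_frames=6, drift_speed=2.5,
            coupling=1.0, noise_sigma=0.0, seed=1,
        )
        series = k.ap_velocity(simulate_correlated_tracks(cfg))
        assert np.allclose(series["value"], 2.5)

    def test_default_drift_recovered_within_3_sem(self):
        # drift in the 2-3 μm/min range typical of animal-ward migration
        cfg = TrackSimConfig(
            n_cells_per_population=200, n_frames=30, drift_speed=2.5,
            coupling=0.8, noise_sigma=1.0, seed=17,
        )
        series = k.ap_velocity(simulate_correlated_tracks(cfg))
        pooled = series["value"].to_numpy()
        sem = pooled.std(ddof=1) / np.sqrt(len(pooled))
        assert abs(pooled.mean() - 2.5) < 3 * max(sem, series["sem"].mean())

    def test_reversed_drift_gives_negative_values(self):
        cfg = TrackSimConfig(
            n_cells_per_population=30, n_frames=6, drift_speed=2.0,
            drift_direction=(0, -1, 0), coupling=1.0, noise_sigma=0.0, seed=1,
        )
        series = k.ap_velocity(simulate_correlated_tracks(cfg))
        assert (series["value"] < 0).all()
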