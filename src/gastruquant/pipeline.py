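"""Config-driven pipeline runner with provenance logging.

A pipeline config (YAML or dict) names an ordered list of stages; each
stage reads files written by earlier stages (or simulator stages generate
them), and every run writes a JSON provenance record — package and library
versions, the seed, per-stage parameters, and SHA-256 hashes of all outputs
— so that identical configs and seeds give byte-identical results.

Stage failures (e.g. a missing input file) are recorded per stage and do
not abort independent later stages; the run report carries the error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gastruquant import __version__, kinematics, morphometry, protrusions
from gastruquant.simulate import (
    ProfileSimConfig,
    TrackSimConfig,
    make_membrane_profile,
    simulate_correlated_tracks,
    simulate_protrusion_events,
)
from gastruquant.simulate.events import observation_windows
from gastruquant.stats import compare_groups

log = logging.getLogger("gastruquant")

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_simulate_tracks(params: dict, outdir: Path, seed: int) -> list:
    cfg = TrackSimConfig(**{**params.get("config", {}), "seed": params.get("seed", seed)})
    ts = simulate_correlated_tracks(cfg)
    out = outdir / params.get("out", "tracks.csv")
    kinematics.write_tracks(ts, out)
    return [out]


def _stage_correlate(params: dict, outdir: Path, seed: int) -> list:
    ts = kinematics.read_tracks(outdir / params["tracks"])
    res = kinematics.order_parameter(
        ts,
        pop_a=params.get("pop_a", "ppl"),
        pop_b=params.get("pop_b", "neuroectoderm"),
        sector_um=params.get("sector_um", 50.0),
    )
    out = outdir / params.get("out", "correlation.csv")
    res.per_time.to_csv(out, index=False)
    return [out]


def _stage_ap_velocity(params: dict, outdir: Path, seed: int) -> list:
    ts = kinematics.read_tracks(outdir / params["tracks"])
    series = kinematics.ap_velocity(
        ts,
        population=params.get("population", "ppl"),
        edge_quantile=params.get("edge_quantile", 0.95),
    )
    out = outdir / params.get("out", "ap_velocity.csv")
    series.to_csv(out, index=False)
    return [out]


def _stage_simulate_protrusions(params: dict, outdir: Path, seed: int) -> list:
    ev = simulate_protrusion_events(
        rates=params["rates"],
        n_cells=params.get("n_cells", 15),
        duration=params.get("duration", 60.0),
        orientation_concentration=params.get("orientation_concentration", 2.0),
        seed=params.get("seed", seed),
    )
    out_e = outdir / params.get("out_events", "events.csv")
    out_w = outdir / params.get("out_windows", "windows.csv")
    ev.to_csv(out_e, index=False)
    observation_windows(params.get("n_cells", 15), params.get("duration", 60.0)).to_csv(
        out_w, index=False
    )
    return [out_e, out_w]


def _stage_protrusions(params: dict, outdir: Path, seed: int) -> list:
    ev = protrusions.read_events(outdir / params["events"])
    win = protrusions.read_windows(outdir / params["windows"])
    rows = []
    types = params.get("types") or sorted(ev["type"].unique())
    for ptype in types:
        r = protrusions.protrusion_rate(ev, win, ptype)
        rows.append((ptype, r.mean, r.sd, r.sem, len(r.per_cell)))
    out = outdir / params.get("out", "rates.csv")
    pd.DataFrame(rows, columns=["type", "rate", "sd", "sem", "n_cells"]).to_csv(
        out, index=False
    )
    written = [out]
    if params.get("rose"):
        rose = protrusions.orientation_histogram(ev, bin_deg=params.get("bin_deg", 30.0))
        rose_out = outdir / params["rose"]
        rose.to_csv(rose_out, index=False)
        written.append(rose_out)
    return written


def _stage_simulate_profile(params: dict, outdir: Path, seed: int) -> list:
    cfg = ProfileSimConfig(**{**params.get("config", {}), "seed": params.get("seed", seed)})
    prof = make_membrane_profile(cfg)
    out = outdir / params.get("out", "profile.csv")
    morphometry.write_profile(prof, out)
    return [out]


def _stage_profile_ratio(params: dict, outdir: Path, seed: int) -> list:
    prof = morphometry.read_profile(outdir / params["profile"])
    res = morphometry.membrane_cytosol_ratio(
        prof,
        prominence=params.get("prominence", 10.0),
        min_spacing=params.get("min_spacing", 8.0),
    )
    out = outdir / params.get("out", "profile_ratio.csv")
    pd.DataFrame(
        [
            {
                "ratio": res.ratio,
                "membrane_mean": res.membrane_mean,
                "cytosol_mean": res.cytosol_mean,
                "n_peaks": len(res.peak_positions),
            }
        ]
    ).to_csv(out, index=False)
    return [out]


def _stage_compare(params: dict, outdir: Path, seed: int) -> list:
    table = pd.read_csv(outdir / params["table"])
    group_col = params.get("group_column", "group")
    value_col = params.get("value_column", "value")
    samples = {
        str(g): sub[value_col].to_numpy() for g, sub in table.groupby(group_col)
    }
    res = compare_groups(samples, alpha=params.get("alpha", 0.05))
    out = outdir / params.get("out", "comparison.json")
    payload = {
        "test": res.test_name,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "normality": res.normality,
        "notes": res.notes,
    }
    if res.posthoc is not None:
        payload["posthoc"] = res.posthoc.to_dict(orient="records")
    out.write_text(json.dumps(payload, indent=1, default=float))
    return [out]


_STAGES = {
    "simulate-tracks": _stage_simulate_tracks,
    "correlate": _stage_correlate,
    "ap-velocity": _stage_ap_velocity,
    "simulate-protrusions": _stage_simulate_protrusions,
    "protrusions": _stage_protrusions,
    "simulate-profile": _stage_simulate_profile,
    "profile-ratio": _stage_profile_ratio,
    "compare": _stage_compare,
}


def run_pipeline(config) -> dict:
    """Execute the stages named in ``config`` and write a provenance log.

    ``config`` is a dict or a path to a YAML file with keys ``outdir``,
    ``seed`` and ``stages`` (a list of ``{stage: <name>, ...params}``
    mappings). Returns the run report (also written to
    ``<outdir>/provenance.json``); ``report["ok"]`` is False when any stage
    failed.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    outdir = Path(config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    import scipy
    import skimage

    report = {
        "package": "gastruquant",
        "version": __version__,
        "python": platform.python_version(),
        "libraries": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-image": skimage.__version__,
        },
        "seed": seed,
        "stages": [],
        "ok": True,
    }
    for entry in config.get("stages", []):
        entry = dict(entry)
        name = entry.pop("stage")
        record = {"stage": name, "params": entry}
        if name not in _STAGES:
            record["status"] = "error"
            record["error"] = f"unknown stage {name!r}"
            report["ok"] = False
            report["stages"].append(record)
            log.error("stage %s: unknown", name)
            continue
        try:
            outputs = _STAGES[name](entry, outdir, seed)
            record["status"] = "ok"
            record["outputs"] = {
                str(p.relative_to(outdir)): _sha256(p) for p in outputs
            }
            log.info("stage %s: ok (%d outputs)", name, len(outputs))
        except Exception as e:  # stage isolation: later stages still run
            record["status"] = "error"
            record["error"] = f"{type(e).__name__}: {e}"
            report["ok"] = False
            log.error("stage %s failed: %s", name, e)
        report["stages"].append(record)

    prov = outdir / "provenance.json"
    prov.write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    return report
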