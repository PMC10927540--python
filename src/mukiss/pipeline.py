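"""Config-driven scenario runner.

A scenario is a YAML document naming an ordered list of stages with
parameter blocks; ``run_scenario`` executes them, writes every artifact
under the output directory, and records a manifest (parameter hashes,
per-stage seeds, output paths) so that every reported number is
traceable to a command.  Identical config + seed reproduce byte
identical CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures, io as mio
from .flow import axial_velocity_profile, build_field, compute_envelope, shear_report
from .geometry import DeviceGeometry, FlowConfig
from .tracers import TipPath, simulate_deposition, simulate_tracers, stroke_width
from .transport import BindingParameters, regime_report
from .quant import cluster_timecourse


def _device(params) -> tuple[DeviceGeometry, FlowConfig]:
    if "device" in params:
        return fixtures.load_device(params["device"])
    return DeviceGeometry(**params["geometry"]), FlowConfig(**params["flow"])


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# -- stages ---------------------------------------------------------------

def stage_envelope(params, seed, out_dir: Path) -> dict:
    g, c = _device(params)
    env = compute_envelope(
        g, c,
        n_streamlines=params.get("n_streamlines", 2000),
        raster_resolution=params.get("raster_resolution"),
        seed=seed,
    )
    csv = out_dir / "envelope_boundary.csv"
    mio.save_envelope(env, csv)
    return {
        "volume_fl": env.volume,
        "extent_um": env.extent,
        "n_voxels": env.n_voxels,
        "files": [str(csv)],
    }


def stage_regime(params, seed, out_dir: Path) -> dict:
    g, c = _device(params)
    env = compute_envelope(
        g, c, n_streamlines=params.get("n_streamlines", 500), seed=seed
    )
    binding = BindingParameters(**params.get("binding", {}))
    grid = params.get("diffusivity_grid", [1e-9, 1e-10, 1e-11, 1e-12])
    report = regime_report(g, c, env, binding, grid)
    path = out_dir / "regime.json"
    report.to_json(path)
    return {"Pe": report.Pe, "Da": report.Da, "Re": report.Re,
            "files": [str(path)]}


def stage_synth(params, seed, out_dir: Path) -> dict:
    rec = fixtures.load_recipe(params["recipe"])
    out = fixtures.realize(rec, seed)
    files = []
    if rec["kind"] == "coloc":
        (series_a, series_b), _design = out
        for s, tag in ((series_a, "a"), (series_b, "b")):
            p = out_dir / f"{params['recipe']}_{tag}.tiff"
            mio.save_series(s, p)
            files.append(str(p))
    else:
        p = out_dir / f"{params['recipe']}.tiff"
        mio.save_series(out, p)
        files.append(str(p))
    return {"files": files}


def stage_diffusion_ensemble(params, seed, out_dir: Path) -> dict:
    rec = fixtures.load_recipe(params["recipe"])
    n = params.get("replicates", rec.get("replicates", 8))
    seeds = [seed + i for i in range(n)]
    fits, stats = fixtures.diffusion_ensemble(rec, seeds)
    table = pd.DataFrame(
        {
            "seed": seeds,
            "D_hat": [f.D_hat for f in fits],
            "stderr": [f.stderr for f in fits],
            "method": [f.method for f in fits],
        }
    )
    csv = out_dir / f"{params['recipe']}_fits.csv"
    table.to_csv(csv, index=False)
    return {
        "n": stats.n,
        "mean_D": stats.mean_D,
        "sd_D": stats.sd_D,
        "files": [str(csv)],
    }


def stage_kymograph_speed(params, seed, out_dir: Path) -> dict:
    speed = fixtures.kymograph_speed(params["recipe"], seed)
    return {"speed_nm_s": speed, "files": []}


def stage_coloc(params, seed, out_dir: Path) -> dict:
    res = fixtures.coloc_measurement(params["recipe"], seed)
    path = out_dir / "coloc.json"
    path.write_text(json.dumps({"M1": res.M1, "M2": res.M2,
                                "threshold_a": res.threshold_a,
                                "threshold_b": res.threshold_b,
                                "threshold_method": res.threshold_method},
                               indent=2))
    return {"M1": res.M1, "M2": res.M2, "files": [str(path)]}


def stage_tracers(params, seed, out_dir: Path) -> dict:
    g, c = _device(params)
    fld = build_field(g, c)
    traj = simulate_tracers(
        n=params.get("n", 100),
        fld=fld,
        D=params.get("D", 5.7e-12),
        dt=params.get("dt", 1e-5),
        duration=params.get("duration", 0.05),
        seed=seed,
    )
    csv = out_dir / "trajectories.csv"
    traj.to_csv(csv)
    return {"n_particles": len(traj.particle_ids), "files": [str(csv)]}


def stage_deposition(params, seed, out_dir: Path) -> dict:
    g, c = _device(params)
    if not g.substrate_present:
        g = dataclasses.replace(g, substrate_present=True)
    path = TipPath(
        waypoints=np.asarray(params.get("waypoints", [[0, 0], [40, 0]]), float),
        speed=params.get("tip_speed", 2.0),
    )
    result = simulate_deposition(
        g, c,
        n=params.get("n", 800),
        D=params.get("D", 2.26e-12),
        sticking_probability=params.get("sticking_probability", 1.0),
        tip_path=path,
        dt=params.get("dt", 2e-5),
        seed=seed,
    )
    csv = out_dir / "deposits.csv"
    result.to_csv(csv)
    out = {"n_deposited": len(result.positions), "files": [str(csv)]}
    if len(result.positions) >= 50:
        out["mean_fwhm_um"] = stroke_width(
            result, n_cross_sections=params.get("n_cross_sections", 10)
        )
    return out


def stage_cluster_timecourse(params, seed, out_dir: Path) -> dict:
    rec = fixtures.load_recipe(params["recipe"])
    series = fixtures.realize(rec, seed)
    table = cluster_timecourse(
        series,
        threshold_method=params.get("threshold_method", "otsu"),
        min_area=params.get("min_area", 0.0),
        unit_intensity=params.get("unit_intensity"),
    )
    csv = out_dir / "clusters.csv"
    table.to_csv(csv, index=False)
    counts = table.groupby("frame").size()
    return {
        "n_initial": int(counts.iloc[0]) if len(counts) else 0,
        "n_final": int(counts.iloc[-1]) if len(counts) else 0,
        "files": [str(csv)],
    }


STAGES = {
    "envelope": stage_envelope,
    "regime": stage_regime,
    "synth": stage_synth,
    "diffusion_ensemble": stage_diffusion_ensemble,
    "kymograph_speed": stage_kymograph_speed,
    "coloc": stage_coloc,
    "tracers": stage_tracers,
    "deposition": stage_deposition,
    "cluster_timecourse": stage_cluster_timecourse,
}


class ScenarioError(ValueError):
    pass


def validate_scenario(config: dict) -> None:
    """Schema check; raises before any stage executes."""
    if "stages" not in config or not isinstance(config["stages"], list):
        raise ScenarioError("scenario must contain a 'stages' list")
    for i, st in enumerate(config["stages"]):
        if not isinstance(st, dict) or "stage" not in st:
            raise ScenarioError(f"stage {i}: missing 'stage' key")
        if st["stage"] not in STAGES:
            raise ScenarioError(
                f"stage {i}: unknown stage {st['stage']!r}; "
                f"known: {sorted(STAGES)}"
            )
        if "recipe" in st.get("params", {}):
            name = st["params"]["recipe"]
            if name not in fixtures.available_recipes():
                raise ScenarioError(f"stage {i}: unknown recipe {name!r}")


def run_scenario(config, out_dir, seed: int | None = None) -> dict:
    """Execute a scenario config (path or dict); returns the manifest."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    validate_scenario(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base_seed = int(config.get("seed", 0) if seed is None else seed)
    manifest = {
        "name": config.get("name", "scenario"),
        "seed": base_seed,
        "config_hash": _hash(config),
        "stages": [],
    }
    for i, st in enumerate(config["stages"]):
        params = st.get("params", {})
        stage_seed = base_seed + 1000 * i
        entry = {
            "stage": st["stage"],
            "params_hash": _hash(params),
            "seed": stage_seed,
        }
        try:
            entry["outputs"] = STAGES[st["stage"]](params, stage_seed, out_dir)
            entry["status"] = "ok"
        except Exception as exc:  # record the failure, keep the manifest
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            manifest["stages"].append(entry)
            break
        manifest["stages"].append(entry)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
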