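"""Packaged fixture recipes: named generator parameter sets.

Each recipe is a YAML file under ``mukiss/recipes`` describing one
study condition (device geometry, a labeling/FRAP series, the extended
band, the colocalization design, ...).  Fixtures ship as parameters,
never as rendered binaries: ``realize(recipe, seed)`` renders the
synthetic data at run time and ``analyze`` runs the matching
quantification stage.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from . import geometry as geo
from .diffusion import (
    DiffusionResults,
    EnsembleStats,
    ensemble_stats,
    estimate_diffusivity_frap,
    estimate_diffusivity_punctual,
)
from .imaging import (
    ColocDesign,
    DriftingCluster,
    LabelingBand,
    NoiseModel,
    PSFModel,
    SpotModel,
    generate_cluster_timelapse,
    generate_extended_series,
    generate_frap_series,
    generate_punctual_series,
    generate_two_channel,
)
from .quant import build_kymograph, kymograph_feature_speed, manders_coefficients


def available_recipes() -> list[str]:
    root = resources.files("mukiss") / "recipes"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_recipe(name: str) -> dict:
    """Load a packaged recipe by name (or a dict passthrough)."""
    if isinstance(name, dict):
        return name
    path = resources.files("mukiss") / "recipes" / f"{name}.yaml"
    if not path.is_file():
        raise KeyError(f"unknown recipe {name!r}; have {available_recipes()}")
    return yaml.safe_load(path.read_text())


def load_device(name: str):
    """(DeviceGeometry, FlowConfig) from a packaged device recipe."""
    rec = load_recipe(name)
    g = {k: v for k, v in rec["geometry"].items()}
    return geo.DeviceGeometry(**g), geo.FlowConfig(**rec["flow"])


def _psf(rec) -> PSFModel:
    return PSFModel.from_optics(**rec["psf"])


def _noise(rec) -> NoiseModel:
    return NoiseModel(**rec["noise"])


def realize(recipe, seed: int):
    """Render the synthetic data described by a recipe at a given seed."""
    rec = load_recipe(recipe)
    kind = rec["kind"]
    if kind == "punctual":
        spot = SpotModel(**{**rec["spot"], "center": tuple(rec["spot"]["center"])})
        return generate_punctual_series(
            spot, _psf(rec), _noise(rec),
            pixel_size=rec["pixel_size"], frame_interval=rec["frame_interval"],
            n_frames=rec["n_frames"], n_pixels=rec["n_pixels"], seed=seed,
        )
    if kind == "frap":
        bleach = SpotModel(
            **{**rec["bleach"], "center": tuple(rec["bleach"]["center"])}, sign=-1
        )
        return generate_frap_series(
            rec["prebleach_level"], bleach, _psf(rec), _noise(rec),
            pixel_size=rec["pixel_size"], frame_interval=rec["frame_interval"],
            n_frames=rec["n_frames"], n_prebleach=rec["n_prebleach"],
            n_pixels=rec["n_pixels"], seed=seed,
        )
    if kind == "extended":
        band = LabelingBand(**rec["band"])
        clusters = [
            DriftingCluster(
                position=tuple(c["position"]),
                speed=c["speed"],
                direction=tuple(c.get("direction", (1.0, 0.0))),
                amplitude=c.get("amplitude", 100.0),
                sigma=c.get("sigma", 0.25),
            )
            for c in rec["clusters"]
        ]
        return generate_extended_series(
            band, clusters, _psf(rec), _noise(rec),
            pixel_size=rec["pixel_size"], frame_interval=rec["frame_interval"],
            n_frames=rec["n_frames"], n_pixels=tuple(rec["n_pixels"]), seed=seed,
        )
    if kind == "coloc":
        design = ColocDesign(**rec["design"])
        return generate_two_channel(
            design, _psf(rec), _noise(rec),
            pixel_size=rec["pixel_size"], n_pixels=rec["n_pixels"], seed=seed,
        ), design
    if kind == "clusters":
        return generate_cluster_timelapse(
            n0=rec["n0"], D_cluster=rec["D_cluster"],
            coalescence_radius=rec["coalescence_radius"],
            field_size=rec["field_size"], duration=rec["duration"],
            frame_interval=rec["frame_interval"], noise=_noise(rec),
            pixel_size=rec["pixel_size"],
            initial_intensity=rec["initial_intensity"],
            initial_sigma=rec["initial_sigma"], seed=seed,
        )
    raise ValueError(f"recipe kind {kind!r} has no generator")


def fit_series(recipe, series) -> DiffusionResults:
    """Run the diffusion estimator matching the recipe kind."""
    rec = load_recipe(recipe)
    if rec["kind"] == "punctual":
        return estimate_diffusivity_punctual(series)
    if rec["kind"] == "frap":
        return estimate_diffusivity_frap(series, n_prebleach=rec["n_prebleach"])
    raise ValueError(f"recipe kind {rec['kind']!r} is not a diffusion fixture")


def diffusion_ensemble(recipe, seeds) -> tuple[list[DiffusionResults], EnsembleStats]:
    """Generate + fit one series per seed and summarize the ensemble."""
    rec = load_recipe(recipe)
    fits = [fit_series(rec, realize(rec, int(s))) for s in seeds]
    return fits, ensemble_stats(fits)


def kymograph_speed(recipe, seed: int) -> float:
    """Extended-labeling fixture → kymograph ridge speed, nm/s."""
    rec = load_recipe(recipe)
    series = realize(rec, seed)
    kcfg = rec["kymograph"]
    kymo = build_kymograph(
        series, np.asarray(kcfg["path"], dtype=float), kcfg["line_width"]
    )
    speed, _ = kymograph_feature_speed(kymo, tuple(kcfg["feature_window"]))
    return speed


def coloc_measurement(recipe, seed: int):
    """Two-channel fixture → measured ColocResult under its convention."""
    rec = load_recipe(recipe)
    (series_a, series_b), design = realize(rec, seed)
    b_sub = design.background_subtraction
    return manders_coefficients(
        series_a.frames[0],
        series_b.frames[0],
        thresholds=(design.threshold, design.threshold),
        background=(b_sub, b_sub),
    )
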