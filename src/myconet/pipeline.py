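"""End-to-end pipeline orchestration with manifest tracking.

A run is described by a single YAML/JSON config with per-stage sections;
stages execute in dependency order (generate -> morphometry / radii /
fluxes / calibrate, plus the standalone simulate and pareto stages), each
writing its artifacts into the run directory.  A JSON manifest records the
config hash, seed, per-stage status/duration and a checksum for every
output file; rerunning with an unchanged config skips up-to-date stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exchange_fluxes import (
    CarbonParams,
    TransportParams,
    calibrate_J,
    compute_flux_series,
    media_phosphorus,
)
from .morphometry import compute_series, read_timelapse_csv, wave_speed, write_timelapse_csv
from .pareto_analysis import isoexchange_curve, strategy_sweep
from .radius_estimator import evaluate, resample_test_to_train, split_dataset, train_estimator
from .synthetic_data import (
    SyntheticRunConfig,
    generate_depletion_assay,
    generate_timelapse,
    generate_transect_dataset,
)
from .wave_model import default_params, run_simulation

__all__ = ["RunManifest", "run_pipeline", "STAGES"]

logger = logging.getLogger("myconet.pipeline")

STAGES = ("generate", "morphometry", "radii", "fluxes", "calibrate", "simulate", "pareto")
_DEPENDENCIES = {
    "morphometry": ("generate",),
    "radii": ("generate",),
    "fluxes": ("generate",),
    "calibrate": ("generate",),
}
_TOP_LEVEL_KEYS = {"seed", "out_dir", "stages", *STAGES}


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    created: str
    out_dir: str
    stages: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @staticmethod
    def from_json(path: str) -> "RunManifest":
        with open(path) as fh:
            return RunManifest(**json.load(fh))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh) or {}


def _validate(config: dict) -> None:
    unknown = sorted(set(config) - _TOP_LEVEL_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    stages = config.get("stages", ["generate", "morphometry", "fluxes", "calibrate"])
    bad = sorted(set(stages) - set(STAGES))
    if bad:
        raise ValueError(f"unknown stages: {bad}")


def run_pipeline(config, out_dir: str | None = None) -> RunManifest:
    """Execute the configured stages and return the manifest.

    ``config`` is a path to a YAML file or an equivalent dict.  Stage
    failure marks downstream dependents as skipped; the manifest is always
    written.
    """
    config = load_config(config)
    _validate(config)
    seed = int(config.get("seed", 0))
    out_dir = out_dir or config.get("out_dir", "myconet_run")
    os.makedirs(out_dir, exist_ok=True)
    requested = list(config.get("stages", ["generate", "morphometry", "fluxes", "calibrate"]))
    # dependency closure, in canonical order
    selected = set(requested)
    for stage in requested:
        selected.update(_DEPENDENCIES.get(stage, ()))
    ordered = [s for s in STAGES if s in selected]

    cfg_hash = _config_hash(config)
    manifest_path = os.path.join(out_dir, "manifest.json")
    previous = None
    if os.path.exists(manifest_path):
        try:
            previous = RunManifest.from_json(manifest_path)
        except Exception:
            previous = None

    manifest = RunManifest(
        config_hash=cfg_hash,
        seed=seed,
        version=__version__,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        out_dir=out_dir,
    )
    context: dict = {"seed": seed, "out_dir": out_dir, "config": config}
    failed: set[str] = set()

    for stage in ordered:
        deps_failed = [d for d in _DEPENDENCIES.get(stage, ()) if d in failed]
        if deps_failed:
            manifest.stages[stage] = {"status": "skipped", "reason": f"dependency failed: {deps_failed}"}
            logger.warning("stage %s skipped (failed deps %s)", stage, deps_failed)
            continue
        if _is_cached(stage, previous, cfg_hash, out_dir):
            manifest.stages[stage] = dict(previous.stages[stage], status="cached")
            logger.info("stage %s cached", stage)
            _reload_cached(stage, context)
            continue
        start = time.time()
        try:
            outputs = _STAGE_RUNNERS[stage](context)
            manifest.stages[stage] = {
                "status": "done",
                "duration_s": round(time.time() - start, 3),
                "outputs": {p: _sha256(p) for p in outputs},
            }
            logger.info("stage %s done (%.1fs)", stage, time.time() - start)
        except Exception as exc:  # noqa: BLE001 - recorded, downstream skipped
            failed.add(stage)
            manifest.stages[stage] = {
                "status": "failed",
                "duration_s": round(time.time() - start, 3),
                "error": f"{type(exc).__name__}: {exc}",
            }
            logger.error("stage %s failed: %s", stage, exc)

    manifest.to_json(manifest_path)
    if failed:
        raise RuntimeError(f"pipeline stages failed: {sorted(failed)} (see {manifest_path})")
    return manifest


def _is_cached(stage, previous, cfg_hash, out_dir) -> bool:
    if previous is None or previous.config_hash != cfg_hash:
        return False
    record = previous.stages.get(stage)
    if not record or record.get("status") not in ("done", "cached"):
        return False
    outputs = record.get("outputs", {})
    return bool(outputs) and all(
        os.path.exists(p) and _sha256(p) == digest for p, digest in outputs.items()
    )


def _reload_cached(stage: str, context: dict) -> None:
    """Re-hydrate the in-memory context a later stage needs."""
    out_dir = context["out_dir"]
    if stage == "generate":
        context["timelapse_dir"] = os.path.join(out_dir, "timelapse")


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_generate(context: dict) -> list[str]:
    config = context["config"]
    out_dir = context["out_dir"]
    section = dict(config.get("generate", {}))
    harvest = section.pop("harvest_times_h", None)
    n_transects = section.pop("n_transects", 1200)
    J_true = section.pop("J_true_ng_per_mm2_h", 3.0)
    run_cfg = SyntheticRunConfig(seed=context["seed"], **section)
    timelapse = generate_timelapse(run_cfg)
    tl_dir = os.path.join(out_dir, "timelapse")
    index_path = write_timelapse_csv(tl_dir, timelapse.snapshots)
    truth_path = os.path.join(out_dir, "truth.csv")
    timelapse.truth.to_csv(truth_path, index=False)
    if harvest is None:
        harvest = list(
            np.linspace(run_cfg.duration_h / 4, run_cfg.duration_h, 8)
        )
    assay = generate_depletion_assay(run_cfg, J_true, harvest, timelapse=timelapse)
    assay_path = os.path.join(out_dir, "assay.csv")
    assay.to_csv(assay_path, index=False)
    transects = generate_transect_dataset(run_cfg, n_transects)
    transects_path = os.path.join(out_dir, "transects.csv")
    transects.to_csv(transects_path, index=False)
    context.update(timelapse=timelapse, timelapse_dir=tl_dir, assay=assay, transects=transects,
                   run_cfg=run_cfg)
    snapshot_files = [
        os.path.join(tl_dir, f) for f in sorted(os.listdir(tl_dir))
    ]
    return [index_path, truth_path, assay_path, transects_path, *snapshot_files]


def _require_timelapse(context: dict):
    if "timelapse" in context:
        return context["timelapse"].snapshots
    return read_timelapse_csv(context["timelapse_dir"])


def _stage_morphometry(context: dict) -> list[str]:
    snapshots = _require_timelapse(context)
    series = compute_series(snapshots)
    v_wave, diag = wave_speed(series, window_h=context["config"].get("morphometry", {}).get(
        "speed_window_h", 100.0))
    path = os.path.join(context["out_dir"], "morphometry.csv")
    series.to_csv(path, index=False)
    speed_path = os.path.join(context["out_dir"], "wave_speed.json")
    with open(speed_path, "w") as fh:
        json.dump({"v_wave_um_per_h": v_wave, **diag}, fh, indent=2)
    context["morphometry"] = series
    return [path, speed_path]


def _stage_radii(context: dict) -> list[str]:
    config = context["config"].get("radii", {})
    out_dir = context["out_dir"]
    transects = context.get("transects")
    if transects is None:
        transects = pd.read_csv(os.path.join(out_dir, "transects.csv"))
    train, test = split_dataset(transects, config.get("train_fraction", 0.9),
                                seed=context["seed"])
    test_rs = resample_test_to_train(train, test, config.get("n_bins", 20),
                                     seed=context["seed"])
    model = train_estimator(train, config.get("model"), seed=context["seed"])
    report = evaluate(model, test_rs)
    model_path = os.path.join(out_dir, "radius_model.joblib")
    model.save(model_path)
    report_path = os.path.join(out_dir, "estimator_report.json")
    with open(report_path, "w") as fh:
        json.dump(
            {
                "rmse_um": report.rmse_um,
                "r_squared": report.r_squared,
                "n_train": report.n_train,
                "n_test": report.n_test,
                "config_hash": model.config_hash,
            },
            fh,
            indent=2,
        )
    return [model_path, report_path]


def _carbon_params(config: dict) -> CarbonParams:
    return CarbonParams(**config.get("carbon", {}))


def _transport_params(config: dict) -> TransportParams:
    return TransportParams(**config.get("transport", {}))


def _stage_fluxes(context: dict) -> list[str]:
    config = context["config"]
    snapshots = _require_timelapse(context)
    section = config.get("fluxes", {})
    carbon = _carbon_params(section)
    transport = _transport_params(section)
    media = media_phosphorus(volume_ml=transport.gel_volume_ml)
    budget = section.get("P_budget_ug", media.accessible_mass_ug)
    fluxes = compute_flux_series(snapshots, carbon, transport, budget,
                                 section.get("smoothing_window_h", 10.0))
    path = os.path.join(context["out_dir"], "fluxes.csv")
    fluxes.to_csv(path, index=False)
    context["fluxes"] = fluxes
    return [path]


def _stage_calibrate(context: dict) -> list[str]:
    out_dir = context["out_dir"]
    assay = context.get("assay")
    if assay is None:
        assay = pd.read_csv(os.path.join(out_dir, "assay.csv"))
    result = calibrate_J(assay, seed=context["seed"])
    path = os.path.join(out_dir, "calibration.json")
    with open(path, "w") as fh:
        json.dump(
            {
                "J_ng_per_mm2_h": result.J_ng_per_mm2_h,
                "ci_ng_per_mm2_h": list(result.ci_ng_per_mm2_h),
                "r_squared": result.r_squared,
                "Pf0_ug": result.Pf0_ug,
                "n_points": result.n_points,
            },
            fh,
            indent=2,
        )
    return [path]


def _stage_simulate(context: dict) -> list[str]:
    section = context["config"].get("simulate", {})
    params = default_params(
        section.get("v_wave_um_per_h", 150.0), **section.get("params", {})
    )
    result = run_simulation(params, section.get("T_h", 900.0),
                            save_interval_h=section.get("save_interval_h", 2.0))
    path = os.path.join(context["out_dir"], "simulation.csv")
    result.saves.to_csv(path, index=False)
    summary_path = os.path.join(context["out_dir"], "simulation_summary.json")
    with open(summary_path, "w") as fh:
        json.dump(
            {
                "v_wave_um_per_h": result.v_wave_um_per_h,
                "v_wave_r_squared": result.v_wave_r_squared,
                "t0_h": result.t0_h,
                "t1_h": result.t1_h,
            },
            fh,
            indent=2,
        )
    return [path, summary_path]


def _stage_pareto(context: dict) -> list[str]:
    section = context["config"].get("pareto", {})
    out_dir = context["out_dir"]
    outputs = []
    for kappa0 in section.get("kappa0_values", [2.0, 3.0, 4.0]):
        curve = isoexchange_curve(kappa0)
        path = os.path.join(out_dir, f"isoexchange_kappa{kappa0:g}.csv")
        pd.DataFrame(
            {"v_wave_um_per_h": curve.v_wave_um_per_h, "rho_s": curve.rho_s}
        ).to_csv(path, index=False)
        outputs.append(path)
    if section.get("sweep", False):
        sweep = strategy_sweep(
            section.get("v_wave_values", [150, 200, 250, 300]),
            section.get("P0_values", [0.35, 1.4, 30.0, 60.0]),
            T_h=section.get("T_h", 900.0),
        )
        path = os.path.join(out_dir, "strategy_sweep.csv")
        sweep.to_csv(path, index=False)
        outputs.append(path)
    return outputs


_STAGE_RUNNERS = {
    "generate": _stage_generate,
    "morphometry": _stage_morphometry,
    "radii": _stage_radii,
    "fluxes": _stage_fluxes,
    "calibrate": _stage_calibrate,
    "simulate": _stage_simulate,
    "pareto": _stage_pareto,
}
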