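"""End-to-end pipeline orchestration with a run manifest.

Stages run in a fixed order — simulate, build-layers, calibrate, exposure,
inequality, classify, regress, report — each reading the previous stage's
files from the output directory and recording its outputs (with row/cell
counts) in ``manifest.json``.  A stage is skipped when its outputs exist
and were produced under the same config hash and seed, so reruns are
idempotent and deleting one stage's outputs reproduces exactly them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from infraccess import __version__
from infraccess.admin import AdminPartition
from infraccess.config import config_hash, default_config
from infraccess.grid import GridLayer, read_layer, write_layer
from infraccess import layers as L
from infraccess import exposure as E
from infraccess import inequality as Q
from infraccess import classify as C
from infraccess import health as H
from infraccess import report as R
from infraccess.synthetic import WorldConfig, generate_world

__all__ = ["STAGES", "run_pipeline", "load_manifest"]

log = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "build-layers",
    "calibrate",
    "exposure",
    "inequality",
    "classify",
    "regress",
    "report",
]

_CSV_FLOAT = "%.12g"  # fixed float formatting keeps reruns byte-identical


def _write_csv(df: pd.DataFrame, path: Path) -> int:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_CSV_FLOAT)
    return len(df)


def load_manifest(out: Path) -> dict:
    path = Path(out) / "manifest.json"
    if path.exists():
        return json.loads(path.read_text())
    return {"stages": {}}


def _save_manifest(out: Path, manifest: dict) -> None:
    (Path(out) / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage_current(manifest: dict, stage: str, chash: str, out: Path) -> bool:
    rec = manifest.get("stages", {}).get(stage)
    if not rec or rec.get("config_hash") != chash:
        return False
    return all((out / f).exists() for f in rec.get("outputs", {}))


def _record(manifest: dict, stage: str, chash: str, outputs: dict[str, int], dt: float) -> None:
    manifest.setdefault("stages", {})[stage] = {
        "config_hash": chash,
        "outputs": outputs,
        "seconds": round(dt, 3),
    }


def _world_config(config: dict, seed: int) -> WorldConfig:
    fields = {f.name for f in dataclasses.fields(WorldConfig)}
    overrides = {k: v for k, v in config.get("world", {}).items() if k in fields}
    unknown = set(config.get("world", {})) - fields
    if unknown:
        raise ValueError(f"unknown world config keys: {sorted(unknown)}")
    if "grid_shape" in overrides:
        overrides["grid_shape"] = tuple(overrides["grid_shape"])
    overrides["seed"] = seed
    return WorldConfig(**overrides)


def _catalog(config: dict) -> dict[str, str]:
    if config["catalog"]["sensitivity_remap"]:
        catalog = L.sensitivity_catalog()
    else:
        catalog = dict(L.DEFAULT_TYPE_CATALOG)
    catalog.update(config["catalog"].get("overrides", {}))
    L.validate_catalog(catalog)
    return catalog


def run_pipeline(
    config: dict | None = None,
    out: str | Path = "runs/default",
    seed: int | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Execute the requested stages (all by default) and return the manifest."""
    config = config if config is not None else default_config()
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    config = dict(config, seed=seed)
    chash = config_hash(config)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    requested = stages or STAGES
    bad = set(requested) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")

    manifest = load_manifest(out)
    manifest.update({"config_hash": chash, "seed": seed, "version": __version__})

    runners = {
        "simulate": _stage_simulate,
        "build-layers": _stage_build_layers,
        "calibrate": _stage_calibrate,
        "exposure": _stage_exposure,
        "inequality": _stage_inequality,
        "classify": _stage_classify,
        "regress": _stage_regress,
        "report": _stage_report,
    }
    for stage in STAGES:
        if stage not in requested:
            continue
        if _stage_current(manifest, stage, chash, out):
            log.info("stage %s is current; skipping", stage)
            continue
        t0 = time.perf_counter()
        outputs = runners[stage](config, out, seed)
        dt = time.perf_counter() - t0
        log.info("stage %s finished in %.2fs (%d outputs)", stage, dt, len(outputs))
        _record(manifest, stage, chash, outputs, dt)
        _save_manifest(out, manifest)
    _save_manifest(out, manifest)
    return manifest


# --------------------------------------------------------------------- stages


def _layer_path(out: Path, name: str) -> Path:
    return out / "layers" / f"{name}.asc"


def _stage_simulate(config: dict, out: Path, seed: int) -> dict[str, int]:
    world = _world_config(config, seed)
    layers, partition, covariates = generate_world(world)
    outputs: dict[str, int] = {}
    for name, layer in layers.items():
        path = _layer_path(out, name)
        write_layer(layer, path)
        outputs[str(path.relative_to(out))] = layer.n_valid
    partition.write(out / "partition.asc", out / "units.csv")
    outputs["partition.asc"] = int(partition.unit_ids.size)
    outputs["units.csv"] = len(partition.units)
    outputs["covariates.csv"] = _write_csv(covariates, out / "covariates.csv")
    return outputs


def _stage_build_layers(config: dict, out: Path, seed: int) -> dict[str, int]:
    catalog = _catalog(config)
    normalized = {
        t: L.normalize_type_layer(read_layer(_layer_path(out, f"type_{t}")))
        for t in catalog
    }
    outputs: dict[str, int] = {}
    by_cat: dict[str, list[GridLayer]] = {}
    for t, cat in catalog.items():
        by_cat.setdefault(cat, []).append(normalized[t])

    for cat in ("economic", "social"):
        layer = L.aggregate_category(by_cat[cat])
        path = _layer_path(out, f"initial_{cat}")
        write_layer(layer, path)
        outputs[str(path.relative_to(out))] = layer.n_valid

    green = read_layer(_layer_path(out, "green"))
    air = read_layer(_layer_path(out, "air"))
    heat = read_layer(_layer_path(out, "heat"))
    if by_cat.get("environmental"):
        ci_env = L.aggregate_category(by_cat["environmental"])
    else:
        # sensitivity remap leaves no count layers in the environmental
        # category; the composite then rests on green/air/heat alone
        ci_env = green.copy_with(np.zeros(green.shape), green.mask)
    env = L.environmental_composite(
        L.EnvInputs(ci_env=ci_env, green=green, air=air, heat=heat),
        epsilon=float(config["env"]["epsilon"]),
    )
    path = _layer_path(out, "final_environmental")
    write_layer(env, path)
    outputs[str(path.relative_to(out))] = env.n_valid
    return outputs


def _stage_calibrate(config: dict, out: Path, seed: int) -> dict[str, int]:
    outputs: dict[str, int] = {}
    ntl = read_layer(_layer_path(out, "ntl"))
    urban = read_layer(_layer_path(out, "urban_mask"))
    urban_mask = urban.mask & (urban.values > 0)
    fits = []
    for cat in ("economic", "social"):
        initial = read_layer(_layer_path(out, f"initial_{cat}"))
        if not config["calibration"]["enabled"]:
            final = initial
            fit = None
        else:
            if config["calibration"]["per_category"] or not fits:
                fit = L.fit_calibration(initial, ntl, urban_mask)
                fits.append((cat, fit))
            else:
                fit = fits[0][1]  # shared economic fit applied to both layers
            final = L.apply_calibration(initial, fit)
        path = _layer_path(out, f"final_{cat}")
        write_layer(final, path)
        outputs[str(path.relative_to(out))] = final.n_valid
    fit_rows = [
        {"category": cat, "slope": f.slope, "intercept": f.intercept, "r": f.r, "n": f.n}
        for cat, f in fits
    ]
    outputs["calibration.csv"] = _write_csv(pd.DataFrame(fit_rows), out / "calibration.csv")
    return outputs


def _load_final(out: Path) -> dict[str, GridLayer]:
    return {
        cat: read_layer(_layer_path(out, f"final_{cat}"))
        for cat in ("economic", "social", "environmental")
    }


def _partition(out: Path) -> AdminPartition:
    return AdminPartition.read(out / "partition.asc", out / "units.csv")


def _stage_exposure(config: dict, out: Path, seed: int) -> dict[str, int]:
    pop = read_layer(_layer_path(out, "population"))
    partition = _partition(out)
    finals = _load_final(out)
    pct = float(config["exposure"]["percentile"])
    tmz = bool(config["exposure"]["treat_missing_as_zero"])
    frames, bias_frames = [], []
    for level in config["exposure"]["levels"]:
        for cat, layer in finals.items():
            raw = E.population_weighted_access(pop, layer, partition, level, tmz)
            frames.append(E.normalize_access(raw, level, cat, pct))
            b = E.access_bias(pop, layer, partition, level)
            b.insert(1, "level", level)
            b.insert(2, "category", cat)
            bias_frames.append(b)
    outputs = {
        "access.csv": _write_csv(pd.concat(frames, ignore_index=True), out / "access.csv"),
        "access_bias.csv": _write_csv(
            pd.concat(bias_frames, ignore_index=True), out / "access_bias.csv"
        ),
    }
    return outputs


def _stage_inequality(config: dict, out: Path, seed: int) -> dict[str, int]:
    pop = read_layer(_layer_path(out, "population"))
    partition = _partition(out)
    finals = _load_final(out)
    frames = [
        Q.unit_inequality(pop, layer, partition, "country", cat)
        for cat, layer in finals.items()
    ]
    table = pd.concat(frames, ignore_index=True).drop(columns=["degenerate"])
    return {"inequality.csv": _write_csv(table, out / "inequality.csv")}


def _stage_classify(config: dict, out: Path, seed: int) -> dict[str, int]:
    access = pd.read_csv(out / "access.csv")
    frames = [
        C.classify_units(access, level) for level in config["exposure"]["levels"]
    ]
    table = pd.concat(frames, ignore_index=True)
    return {"classification.csv": _write_csv(table, out / "classification.csv")}


def _health_table(out: Path) -> pd.DataFrame:
    covariates = pd.read_csv(out / "covariates.csv")
    access = pd.read_csv(out / "access.csv")
    ineq = pd.read_csv(out / "inequality.csv")
    acc = (
        access[access["level"] == "country"]
        .pivot(index="unit_id", columns="category", values="ie_norm")
        .rename(columns={"economic": "ExpEco", "social": "ExpSoc"})
    )
    gin = (
        ineq.pivot(index="unit_id", columns="category", values="gini")
        .rename(columns={"economic": "GiniEco", "social": "GiniSoc"})
    )
    data = covariates[["unit_id", "group", "region", "LnPop", "LnGDP", "Health", "DALYs"]]
    data = data.merge(
        acc[["ExpEco", "ExpSoc"]], left_on="unit_id", right_index=True
    ).merge(gin[["GiniEco", "GiniSoc"]], left_on="unit_id", right_index=True)
    return data


def _stage_regress(config: dict, out: Path, seed: int) -> dict[str, int]:
    data = _health_table(out)
    results = []
    for response in ("Health", "DALYs"):
        for model_id in ("I", "II", "III"):
            res = H.fit_health_model(
                data,
                model_id,
                response=response,
                log_transform=config["health"]["log_transform"],
                group_as_fixed=config["health"]["group_as_fixed"],
            )
            res.meta["response"] = response
            results.append(res)
    summary = R.model_summary_table(results)
    summary.insert(0, "response", np.repeat([r.meta["response"] for r in results],
                                            [len(r.summary) for r in results]))
    diagnostics = pd.concat([r.diagnostics_frame() for r in results], ignore_index=True)
    diagnostics.insert(0, "response", [r.meta["response"] for r in results])
    return {
        "model_summaries.csv": _write_csv(summary, out / "model_summaries.csv"),
        "model_diagnostics.csv": _write_csv(diagnostics, out / "model_diagnostics.csv"),
        "health_table.csv": _write_csv(data, out / "health_table.csv"),
    }


def _stage_report(config: dict, out: Path, seed: int) -> dict[str, int]:
    data = _health_table(out)
    access = pd.read_csv(out / "access.csv")
    ineq = pd.read_csv(out / "inequality.csv")
    units = pd.read_csv(out / "units.csv")
    stats_table = R.group_stats_table(
        data, ["ExpEco", "ExpSoc", "GiniEco", "GiniSoc", "Health"]
    )
    means = R.computed_group_means(
        access[access["level"] == "country"], ineq, units
    )
    ratio_series = R.north_south_ratios(means)
    ratios = pd.DataFrame({"quantity": ratio_series.index, "ratio": ratio_series.to_numpy()})
    return {
        "report_group_stats.csv": _write_csv(stats_table, out / "report_group_stats.csv"),
        "report_group_means.csv": _write_csv(
            means.reset_index(), out / "report_group_means.csv"
        ),
        "report_ratios.csv": _write_csv(ratios, out / "report_ratios.csv"),
    }
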