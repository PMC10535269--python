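"""End-to-end orchestration: synth -> separability -> classification -> NPP -> SDM.

Stages communicate through declared file artifacts under the run directory;
the manifest records a deterministic content hash, the seed, and the config
hash for every artifact, so re-running an unchanged config reproduces an
identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accuracy, casa, classify, sdm, separability, synthdata
from .errors import ConfigurationError
from .features import build_feature_table, model_registry, registry_to_yaml, \
    screening_combinations
from .raster import Raster, points_to_geojson, write_raster
from .synthdata import FIELD_SAMPLE_COUNTS, TARGET_CLASS, CLASS_NAMES

log = logging.getLogger(__name__)

STAGES = ("synth", "separability", "classify", "casa", "sdm")


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results/run"
    stages: tuple[str, ...] = STAGES
    preset: str = "default"               # or "well_separated"
    shape: tuple[int, int] = (160, 160)
    n_per_class: dict = dataclasses.field(default_factory=lambda: dict(FIELD_SAMPLE_COUNTS))
    min_distance: float = 20.0
    n_trees: int = 500
    sdm_n_occurrences: int = 60
    sdm_n_background: int = 2000
    sdm_replicates: int = 10
    npp_reference_noise_sd: float = 50.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if "shape" in raw:
            cfg.shape = tuple(raw["shape"])
        if "stages" in raw:
            cfg.stages = tuple(raw["stages"])
        if "n_per_class" in raw:
            cfg.n_per_class = {int(k): int(v) for k, v in raw["n_per_class"].items()}
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["shape"] = list(self.shape)
        return d

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()

    def truth(self) -> synthdata.SyntheticTruth:
        maker = {"default": synthdata.default_truth,
                 "well_separated": synthdata.well_separated_truth}.get(self.preset)
        if maker is None:
            raise ConfigurationError(f"unknown preset {self.preset!r}")
        return maker(seed=self.seed, shape=self.shape)


def _hash_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _hash_df(df: pd.DataFrame) -> str:
    return _hash_text(df.to_csv(index=False))


class Manifest:
    def __init__(self, config: RunConfig):
        self.doc = {"config": config.to_dict(), "config_hash": config.hash(),
                    "seed": config.seed, "artifacts": {}, "stages": []}

    def add(self, name: str, path: Path | None, content_hash: str) -> None:
        self.doc["artifacts"][name] = {
            "path": str(path) if path else None, "hash": content_hash}

    def write(self, out_dir: Path) -> Path:
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(self.doc, indent=1, sort_keys=True))
        return p


# ---------------------------------------------------------------------------
# stage drivers (pure library calls + artifact writing)

def stage_synth(cfg: RunConfig, out: Path, manifest: Manifest) -> dict:
    truth = cfg.truth()
    scenes = {}
    labels = None
    for date in truth.dates:
        scene, labels = synthdata.generate_scene(truth, date)
        scenes[date] = scene
        p = write_raster(out / f"scene_{date}.tif", scene)
        manifest.add(f"scene_{date}", p, scene.content_hash())
    p = write_raster(out / "labels.tif", labels)
    (out / "labels.classes.json").write_text(json.dumps(CLASS_NAMES, indent=1))
    manifest.add("labels", p, labels.content_hash())
    samples = synthdata.sample_points(labels, cfg.n_per_class, cfg.min_distance, cfg.seed)
    samples.to_csv(out / "samples.csv", index=False)
    (out / "samples.geojson").write_text(json.dumps(points_to_geojson(
        samples["x"], samples["y"],
        samples[["sample_id", "class_id", "class_name", "partition"]].to_dict("records"),
        truth.grid.crs)))
    manifest.add("samples", out / "samples.csv", _hash_df(samples))
    climate = synthdata.generate_climate(truth)
    for var in ("sol", "temp", "precip"):
        r = climate.raster(var)
        p = write_raster(out / f"climate_{var}.tif", r)
        manifest.add(f"climate_{var}", p, r.content_hash())
    ndvi = synthdata.generate_ndvi_series(truth, labels)
    p = write_raster(out / "ndvi_monthly.tif", ndvi)
    manifest.add("ndvi_monthly", p, ndvi.content_hash())
    occ, bioclim, true_p = synthdata.generate_sdm_inputs(
        truth, cfg.sdm_n_occurrences, cfg.sdm_n_background)
    occ.presence.to_csv(out / "occurrences.csv", index=False)
    occ.background.to_csv(out / "background.csv", index=False)
    manifest.add("occurrences", out / "occurrences.csv", _hash_df(occ.presence))
    manifest.add("background", out / "background.csv", _hash_df(occ.background))
    p = write_raster(out / "bioclim.tif", bioclim)
    manifest.add("bioclim", p, bioclim.content_hash())
    return {"truth": truth, "scenes": scenes, "labels": labels, "samples": samples,
            "climate": climate, "ndvi": ndvi, "occ": occ, "bioclim": bioclim,
            "true_p": true_p}


def stage_separability(state: dict, out: Path, manifest: Manifest) -> dict:
    combos = screening_combinations()
    tables = {date: {cid: build_feature_table(scene, state["samples"], combo)[0]
                     for cid, combo in combos.items()}
              for date, scene in state["scenes"].items()}
    report = separability.separability_report(tables)
    best = separability.select_optimal_window(report)
    report.to_csv(out / "separability.csv", index=False)
    (out / "separability.txt").write_text(separability.render_report(report))
    manifest.add("separability", out / "separability.csv", _hash_df(report))
    return {"separability": report, "best_date": best}


def stage_classify(state: dict, cfg: RunConfig, out: Path, manifest: Manifest) -> dict:
    registry = model_registry()
    (out / "registry.yaml").write_text(registry_to_yaml(registry))
    scene = state["scenes"][state["best_date"]]
    rf_cfg = classify.ClassifierConfig(n_trees=cfg.n_trees, seed=cfg.seed)
    comparison = classify.evaluate_combinations(scene, state["samples"], registry, rf_cfg)
    comparison.table.to_csv(out / "model_comparison.csv", index=False)
    manifest.add("model_comparison", out / "model_comparison.csv",
                 _hash_df(comparison.table))
    winner = registry[comparison.winner]
    table, _ = build_feature_table(scene, state["samples"], winner)
    model = classify.train(table, config=rf_cfg, combo=winner)
    class_map = classify.classify_raster(model, scene)
    p = write_raster(out / "class_map.tif", class_map)
    (out / "class_map.legend.json").write_text(json.dumps(
        {"classes": CLASS_NAMES, "winner": comparison.winner,
         "partition_hash": comparison.partition_hash,
         "split": "single fixed 3:1 train/test partition"}, indent=1))
    manifest.add("class_map", p, class_map.content_hash())
    test = table[table["partition"] == "test"]
    rows, cols = class_map.grid.index(
        state["samples"].loc[test.index, "x"].to_numpy(),
        state["samples"].loc[test.index, "y"].to_numpy())
    cm = accuracy.build(test["class"].to_numpy(), class_map.data[rows, cols],
                        classes=sorted(CLASS_NAMES))
    cm.to_frame().to_csv(out / "confusion.csv")
    (out / "confusion.json").write_text(cm.to_json())
    manifest.add("confusion", out / "confusion.json", _hash_text(cm.to_json()))
    return {"comparison": comparison, "class_map": class_map, "confusion": cm}


def stage_casa(state: dict, cfg: RunConfig, out: Path, manifest: Manifest) -> dict:
    labels, ndvi, climate = state["labels"], state["ndvi"], state["climate"]
    eps = {cid: casa.EPS_MAX_DEFAULTS.get(name, casa.EPS_MAX_DEFAULTS["default"])
           for cid, name in CLASS_NAMES.items()}
    params = casa.auto_configure(ndvi, labels, eps)
    model = casa.CasaModel(labels, params)
    grid = model.run(ndvi, climate)
    p = write_raster(out / "npp_annual.tif", grid.annual_raster())
    manifest.add("npp_annual", p, grid.annual_raster().content_hash())
    grades, breaks = casa.classify_npp(grid.annual_raster())
    write_raster(out / "npp_grades.tif", grades)
    manifest.add("npp_grades", out / "npp_grades.tif", grades.content_hash())
    mask_src = state.get("class_map", labels)
    mask = mask_src.data == TARGET_CLASS
    pixel_area = labels.grid.pixel_size ** 2
    total_t = casa.total_carbon(grid.annual_raster(), mask, pixel_area)
    # synthetic stand-in for an independent reference NPP product
    rng = np.random.default_rng([cfg.seed, 910])
    ref = Raster(grid.annual + rng.standard_normal(grid.annual.shape)
                 * cfg.npp_reference_noise_sd, labels.grid)
    val = casa.validate(grid.annual_raster(), ref, n_points=30, seed=cfg.seed)
    summary = {"breaks": breaks,
               "grade_labels": casa.NPP_GRADE_LABELS,
               "target_total_tC_per_year": total_t,
               "target_pixels": int(mask.sum()),
               "validation": {"rmse": val.rmse, "r": val.r, "r2": val.r2,
                              "n_points": 30, "seed": cfg.seed},
               "eps_max": eps}
    (out / "npp_summary.json").write_text(json.dumps(summary, indent=1))
    val.points.to_csv(out / "npp_validation_points.csv", index=False)
    manifest.add("npp_summary", out / "npp_summary.json",
                 _hash_text(json.dumps(summary, sort_keys=True)))
    return {"npp": grid, "npp_breaks": breaks, "carbon_total_t": total_t,
            "validation": val}


def stage_sdm(state: dict, cfg: RunConfig, out: Path, manifest: Manifest) -> dict:
    occ, bioclim = state["occ"], state["bioclim"]
    reps = sdm.bootstrap_replicates(occ, n_replicates=cfg.sdm_replicates, seed=cfg.seed)
    auc_table = pd.DataFrame({"replicate": range(len(reps)),
                              "auc_test": [r.auc_test for r in reps],
                              "auc_train": [r.auc_train for r in reps]})
    auc_table.to_csv(out / "sdm_auc.csv", index=False)
    manifest.add("sdm_auc", out / "sdm_auc.csv", _hash_df(auc_table))
    full = sdm.fit(occ)
    importance = sdm.variable_importance(full, occ, "percent_contribution").merge(
        sdm.variable_importance(full, occ, "permutation", seed=cfg.seed), on="variable")
    importance.to_csv(out / "sdm_importance.csv", index=False)
    manifest.add("sdm_importance", out / "sdm_importance.csv", _hash_df(importance))
    prob = sdm.predict_logistic(full, bioclim)
    write_raster(out / "suitability.tif", prob)
    manifest.add("suitability", out / "suitability.tif", prob.content_hash())
    grades, breaks = sdm.classify_suitability(prob, "fixed_breaks")
    write_raster(out / "suitability_grades.tif", grades)
    manifest.add("suitability_grades", out / "suitability_grades.tif",
                 grades.content_hash())
    areas = sdm.area_by_class(grades, resolution_km=bioclim.grid.pixel_size / 1000.0)
    summary = {"mean_auc_test": float(np.nanmean(auc_table["auc_test"])),
               "breaks": breaks,
               "areas_km2": {sdm.SUITABILITY_LABELS.get(k, k): v
                             for k, v in sorted(areas.items())},
               "weights_nonzero": int((full.lam != 0).sum())}
    (out / "sdm_summary.json").write_text(json.dumps(summary, indent=1))
    manifest.add("sdm_summary", out / "sdm_summary.json",
                 _hash_text(json.dumps(summary, sort_keys=True)))
    return {"sdm_replicates": reps, "sdm_model": full, "sdm_importance": importance,
            "suitability": prob, "suitability_areas": areas}


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest document."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)
    state: dict = {}
    order = [s for s in STAGES if s in config.stages]
    analysis_stages = set(order) - {"synth"}
    if analysis_stages and "synth" not in order:
        raise ConfigurationError("analysis stages need the synth stage (or on-disk inputs)")
    drivers = {"synth": lambda: stage_synth(config, out, manifest),
               "separability": lambda: stage_separability(state, out, manifest),
               "classify": lambda: stage_classify(state, config, out, manifest),
               "casa": lambda: stage_casa(state, config, out, manifest),
               "sdm": lambda: stage_sdm(state, config, out, manifest)}
    for stage in order:
        if stage == "classify" and "best_date" not in state:
            state.update(stage_separability(state, out, manifest))
        try:
            state.update(drivers[stage]())
        except Exception as exc:  # annotate which stage died
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        manifest.doc["stages"].append(stage)
    manifest.write(out)
    return manifest.doc
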