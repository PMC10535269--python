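"""Random-forest training/evaluation over the band-combination registry.

The learner itself is scikit-learn's RandomForestClassifier (500 trees,
floor(sqrt(p)) features per split by default, fixed seed); the bespoke
surface here is schema control, the shared-split model comparison, and
full-raster map production.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import accuracy
from .errors import EumapError, SchemaError
from .features import BandCombination, build_feature_table, feature_matrix
from .raster import Raster
from .synthdata import TARGET_CLASS


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 500
    max_features: int | str = "sqrt"   # "sqrt" -> floor(sqrt(p)), minimum 1
    seed: int = 0

    def resolve_max_features(self, p: int) -> int:
        if self.max_features == "sqrt":
            return max(1, int(math.floor(math.sqrt(p))))
        m = int(self.max_features)
        if not 1 <= m <= p:
            raise EumapError(f"max_features {m} outside [1, {p}]")
        return m


@dataclasses.dataclass
class FittedModel:
    estimator: RandomForestClassifier
    combo: BandCombination
    config: ClassifierConfig

    def vote_proportions(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(X)


def train(table_or_X, labels=None, config: ClassifierConfig = ClassifierConfig(),
          combo: BandCombination | None = None) -> FittedModel:
    """Fit the forest on a feature table (train partition) or an (X, y) pair."""
    if isinstance(table_or_X, pd.DataFrame):
        if combo is None:
            raise EumapError("combo is required when training from a feature table")
        X, y = feature_matrix(table_or_X, combo, partition="train")
    else:
        X = np.asarray(table_or_X, dtype=float)
        y = np.asarray(labels)
        if combo is None:
            combo = BandCombination("adhoc", ())
    if X.size and not np.isfinite(X).all():
        raise EumapError("training features contain missing values")
    if len(np.unique(y)) < 2:
        raise EumapError("training requires at least 2 classes")
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.resolve_max_features(X.shape[1]) if X.shape[1] else None,
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return FittedModel(est, combo, config)


def partition_hash(samples: pd.DataFrame) -> str:
    """Hash of the (sample_id, partition) assignment shared by all compared models."""
    blob = samples.sort_values("sample_id")[["sample_id", "partition"]].to_csv(index=False)
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclasses.dataclass
class ModelComparison:
    table: pd.DataFrame          # model, n_features, oa, kappa, pa, ua
    winner: str
    partition_hash: str
    target_class: int


def evaluate_combinations(scene: Raster, samples: pd.DataFrame,
                          registry: dict[str, BandCombination],
                          config: ClassifierConfig = ClassifierConfig(),
                          target_class: int = TARGET_CLASS) -> ModelComparison:
    """Fit every registry model on the shared 3:1 split and score the common test set.

    Winner = highest overall accuracy, ties broken by target-class producer's
    accuracy, then by lowest model id.
    """
    phash = partition_hash(samples)
    rows = []
    fitted: dict[str, FittedModel] = {}
    for model_id in sorted(registry):
        combo = registry[model_id]
        table, _ = build_feature_table(scene, samples, combo)
        n_test_target = ((table["partition"] == "test") & (table["class"] == target_class)).sum()
        if n_test_target == 0:
            raise EumapError(f"{model_id}: no test samples of the target class; "
                             "comparison aborted")
        model = train(table, config=config, combo=combo)
        X_test, y_test = feature_matrix(table, combo, partition="test")
        y_hat = model.estimator.predict(X_test)
        cm = accuracy.build(y_test, y_hat, classes=sorted(set(samples["class_id"])))
        rows.append({
            "model": model_id,
            "bands": "+".join(combo.feature_names),
            "n_features": combo.n_features,
            "oa": cm.overall_accuracy(),
            "kappa": cm.kappa(),
            "pa": cm.producer_accuracy(target_class),
            "ua": cm.user_accuracy(target_class),
        })
        fitted[model_id] = model
    table = pd.DataFrame(rows)
    ranked = table.sort_values(by=["oa", "pa", "model"],
                               ascending=[False, False, True], kind="mergesort")
    winner = str(ranked.iloc[0]["model"])
    return ModelComparison(table=table, winner=winner, partition_hash=phash,
                           target_class=target_class)


def classify_raster(model: FittedModel, scene: Raster,
                    combo: BandCombination | None = None,
                    nodata: int = 0) -> Raster:
    """Apply a fitted model to every pixel; nodata in any feature propagates."""
    combo = combo or model.combo
    if combo.feature_names != model.combo.feature_names:
        raise SchemaError(f"feature order mismatch: model trained on "
                          f"{model.combo.feature_names}, asked to apply {combo.feature_names}")
    from .features import scene_features

    cube = scene_features(scene, combo)
    h, w = cube.shape
    X = cube.data.reshape(cube.n_bands, -1).T
    valid = np.isfinite(X).all(axis=1)
    out = np.full(h * w, nodata, dtype=np.uint8)
    if valid.any():
        out[valid] = model.estimator.predict(X[valid])
    return Raster(out.reshape(h, w), scene.grid, nodata=nodata)
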