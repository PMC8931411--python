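"""Random-forest training and scene classification.

Classifier input rows are fitted-curve evaluations on a fixed DOY grid
(by default DOY 140..290 step 10 for NIR, NDVI and NDWI: 48 columns), so
train and predict stay comparable even when the underlying observation
dates differ.  The forest follows the reference configuration: 150
trees, sqrt(p) candidate features per split, per-tree bootstrap the size
of the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ContractError
from .feature_curves import (
    MIN_FIT_POINTS,
    feature_cube,
    fit_pixel_curves,
)
from .raster_io import SceneStack

DEFAULT_DOY_GRID = tuple(range(140, 291, 10))  # 16 evaluation dates


@dataclass
class ForestConfig:
    n_trees: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ContractError("n_trees must be >= 1")


@dataclass
class FeatureMatrix:
    X: np.ndarray
    column_spec: tuple  # ordered (feature, doy) pairs
    valid: np.ndarray  # row eligibility flags
    labels: np.ndarray | None = None
    pixel_index: np.ndarray | None = None  # (row, col) per matrix row


def _column_spec(feature_models: dict, doy_grid) -> tuple:
    return tuple((f, int(d)) for f in feature_models for d in doy_grid)


def build_feature_matrix(
    points: pd.DataFrame | None,
    stack: SceneStack,
    feature_models: dict,
    doy_grid=DEFAULT_DOY_GRID,
    min_valid: int = MIN_FIT_POINTS,
) -> FeatureMatrix:
    """Curve-evaluation features for sample points or the whole grid.

    ``points`` is a sample table (rows used: row, col and, if present,
    class); pass None to build one row per pixel of the stack.  Rows
    whose pixel is ineligible (too few valid dates, or every curve fit
    failed) are flagged invalid and zero-filled.
    """
    doy_grid = np.asarray(doy_grid, dtype=float)
    if doy_grid.size == 0:
        raise ContractError("doy_grid must be non-empty")
    if points is None:
        rows, cols = stack.shape
        rc = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=int)
        labels = None
    else:
        rc = points[["row", "col"]].to_numpy(dtype=int)
        labels = points["class"].to_numpy() if "class" in points.columns else None
    cube = feature_cube(stack, tuple(feature_models))
    spec = _column_spec(feature_models, doy_grid)
    X = np.zeros((len(rc), len(spec)))
    valid = np.zeros(len(rc), dtype=bool)
    n_per_feature = len(doy_grid)
    for i, (r, c) in enumerate(rc):
        curves = fit_pixel_curves(cube, stack.dates, int(r), int(c), feature_models, min_valid)
        if curves is None or set(curves) != set(feature_models):
            continue
        row = np.empty(len(spec))
        for j, f in enumerate(feature_models):
            row[j * n_per_feature: (j + 1) * n_per_feature] = curves[f](doy_grid)
        if np.all(np.isfinite(row)):
            X[i] = row
            valid[i] = True
    return FeatureMatrix(X=X, column_spec=spec, valid=valid, labels=labels, pixel_index=rc)


@dataclass
class ForestModel:
    estimator: RandomForestClassifier
    column_spec: tuple
    classes: tuple

    def predict(self, matrix: FeatureMatrix) -> np.ndarray:
        if tuple(matrix.column_spec) != tuple(self.column_spec):
            raise ContractError("train/predict column_spec mismatch")
        out = np.full(len(matrix.X), None, dtype=object)
        if matrix.valid.any():
            out[matrix.valid] = self.estimator.predict(matrix.X[matrix.valid])
        return out

    def save(self, path) -> None:
        joblib.dump(
            {"estimator": self.estimator, "column_spec": self.column_spec, "classes": self.classes},
            path,
        )

    @classmethod
    def load(cls, path) -> "ForestModel":
        blob = joblib.load(path)
        return cls(
            estimator=blob["estimator"],
            column_spec=tuple(map(tuple, blob["column_spec"])),
            classes=tuple(blob["classes"]),
        )


def train_forest(matrix: FeatureMatrix, config: ForestConfig | None = None) -> ForestModel:
    """Train the bagged decision-tree ensemble on the valid matrix rows."""
    config = config or ForestConfig()
    if matrix.labels is None:
        raise ContractError("training matrix needs labels")
    X = matrix.X[matrix.valid]
    y = np.asarray(matrix.labels)[matrix.valid]
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ContractError("training needs at least 2 classes")
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features="sqrt",
        bootstrap=True,  # per-tree sample size equals the training size
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return ForestModel(estimator=est, column_spec=matrix.column_spec, classes=classes)


def classify_scene(
    model: ForestModel,
    stack: SceneStack,
    feature_models: dict,
    doy_grid=DEFAULT_DOY_GRID,
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Classify every eligible pixel of a scene.

    Returns (label_raster, unclassifiable_mask, class_order); the label
    raster holds indices into class_order, -1 where unclassifiable.
    """
    matrix = build_feature_matrix(None, stack, feature_models, doy_grid)
    preds = model.predict(matrix)
    rows, cols = stack.shape
    class_index = {c: i for i, c in enumerate(model.classes)}
    labels = np.full((rows, cols), -1, dtype=int)
    unclassifiable = np.ones((rows, cols), dtype=bool)
    for (r, c), ok, p in zip(matrix.pixel_index, matrix.valid, preds):
        if ok:
            labels[r, c] = class_index[p]
            unclassifiable[r, c] = False
    return labels, unclassifiable, model.classes
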