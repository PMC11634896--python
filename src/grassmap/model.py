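"""Per-class probability modelling.

Training data is assembled by spacetime overlay: each point sample receives
the 84 seasonal features of its year (7 composite bands + 7 spectral
indices, each over 6 bi-monthly periods) plus the static covariates at its
location. Two binary tasks are modelled independently -- cultivated
grassland vs everything else, and natural/semi-natural grassland vs
everything else.

Evaluation uses tile-blocked 5-fold cross-validation (all samples of one
1x1 km interpretation tile share a fold, limiting spatial leakage); a 10%
per-tile calibration split feeds hyperparameter search by successive
halving; recursive feature elimination targets a fixed feature count by
repeatedly dropping the least important features of a forest fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier

from .core import BAND_NAMES, NODATA, GeoTransform, ProbabilityCube
from .indices import INDEX_NAMES, IndexCube
from .sampling import CovariateStack, PointSample

#: Binary modelling tasks and the class code each one targets.
TASKS: dict[str, int] = {"cultivated": 1, "natural": 2}

META_COLUMNS = ("sample_id", "tile_id", "year", "class_code", "complete")


def seasonal_feature_names() -> list[str]:
    """The 84 seasonal feature names: band/index x bi-monthly period."""
    names = []
    for period in range(1, 7):
        for band in BAND_NAMES:
            names.append(f"{band}_p{period}")
        for index in INDEX_NAMES:
            names.append(f"{index.lower()}_p{period}")
    return names


def pixel_feature_table(
    year: int,
    composites: dict,
    index_cube: IndexCube,
    static: CovariateStack,
) -> pd.DataFrame:
    """Feature values of every pixel of the grid for one year.

    Composite bands enter on their 8-bit scale, indices on their analytic
    scale, statics as-is. Rows are pixels in row-major order.
    """
    shape = static.data.shape[1:]
    n = shape[0] * shape[1]
    cols: dict[str, np.ndarray] = {}
    for period in range(1, 7):
        comp = composites[(year, period)]
        decoded = comp.bands.astype(np.float64)
        decoded[:, comp.gap_mask] = np.nan
        for bi, band in enumerate(BAND_NAMES):
            cols[f"{band}_p{period}"] = decoded[bi].ravel()
        idx_slice = index_cube.slices[(year, period)]
        for index in INDEX_NAMES:
            cols[f"{index.lower()}_p{period}"] = idx_slice[index].ravel()
    for li, name in enumerate(static.names):
        cols[f"static_{name}"] = static.data[li].ravel().astype(np.float64)
    table = pd.DataFrame(cols, copy=False)
    assert len(table) == n
    return table


def spacetime_overlay(
    points: list[PointSample],
    composites: dict,
    index_cube: IndexCube,
    static: CovariateStack,
) -> tuple[pd.DataFrame, list[str]]:
    """Feature matrix for point samples by spacetime overlay.

    Each sample row carries its year's 84 seasonal features sampled at its
    location plus the static covariates. Rows with any missing feature are
    kept but flagged ``complete=False``. Points outside the raster extent
    are excluded and their ids returned.
    """
    shape = static.data.shape[1:]
    years = sorted({p.year for p in points})
    missing_years = [y for y in years if (y, 1) not in composites]
    if missing_years:
        raise ValueError(f"years missing from the composite archive: {missing_years}")

    tables = {y: pixel_feature_table(y, composites, index_cube, static)
              for y in years}
    rows = []
    excluded: list[str] = []
    for p in points:
        r = int(round(p.location[0]))
        c = int(round(p.location[1]))
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            excluded.append(p.sample_id)
            continue
        feats = tables[p.year].iloc[r * shape[1] + c]
        row = {
            "sample_id": p.sample_id, "tile_id": p.tile_id, "year": p.year,
            "class_code": p.class_code,
        }
        row.update(feats.to_dict())
        row["complete"] = not feats.isna().any()
        rows.append(row)
    matrix = pd.DataFrame(rows)
    return matrix, excluded


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in META_COLUMNS]


def binarize_labels(matrix: pd.DataFrame, task: str) -> np.ndarray:
    """0/1 labels for one binary task (the task's class code vs the rest)."""
    return (matrix["class_code"].to_numpy() == TASKS[task]).astype(int)


def split_calibration(
    matrix: pd.DataFrame, fraction: float = 0.10, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tile random split into training and calibration sets.

    Per tile, ``round(fraction * n)`` samples (half-up) go to calibration,
    except that a tile is never emptied of training samples. The two parts
    partition the input.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    cal_idx: list[np.ndarray] = []
    for _tile, group in matrix.groupby("tile_id"):
        n = len(group)
        n_cal = int(math.floor(fraction * n + 0.5))
        if n_cal >= n:
            n_cal = n - 1
        if n_cal > 0:
            cal_idx.append(rng.choice(group.index.to_numpy(), n_cal, replace=False))
    cal_index = np.concatenate(cal_idx) if cal_idx else np.array([], dtype=int)
    cal_mask = matrix.index.isin(cal_index)
    return matrix.loc[~cal_mask], matrix.loc[cal_mask]


@dataclass
class FoldAssignment:
    """Tile-blocked fold assignment: every sample of a tile shares its fold."""

    n_folds: int
    tile_fold: dict  # tile_id -> fold (1-based)
    sample_fold: dict  # sample_id -> fold

    def fold_of(self, matrix: pd.DataFrame) -> np.ndarray:
        return matrix["tile_id"].map(self.tile_fold).to_numpy()


def make_spatial_folds(
    matrix: pd.DataFrame, k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Assign tiles (and thereby samples) to ``k`` folds, balanced by tile count."""
    tiles = sorted(matrix["tile_id"].unique())
    if len(tiles) < k:
        raise ValueError(f"need at least {k} tiles, got {len(tiles)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tiles))
    tile_fold = {tiles[int(t)]: (i % k) + 1 for i, t in enumerate(order)}
    sample_fold = {
        sid: tile_fold[tid]
        for sid, tid in zip(matrix["sample_id"], matrix["tile_id"])
    }
    return FoldAssignment(n_folds=k, tile_fold=tile_fold, sample_fold=sample_fold)


@dataclass
class ModelSpec:
    """Learner choice and configuration for one binary task."""

    task: str = "natural"
    learner: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    selected_features: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {sorted(TASKS)}")


def make_learner(spec: ModelSpec):
    """Instantiate the configured scikit-learn estimator."""
    params = dict(spec.hyperparameters)
    if spec.learner == "random_forest":
        params.setdefault("n_estimators", 60)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.learner == "gradient_boosting":
        return GradientBoostingClassifier(random_state=spec.seed, **params)
    if spec.learner == "neural_network":
        params.setdefault("max_iter", 500)
        return MLPClassifier(random_state=spec.seed, **params)
    raise ValueError(f"unknown learner {spec.learner!r}")


def _clean(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop rows flagged incomplete (missing features) before fitting."""
    if "complete" in matrix.columns:
        return matrix[matrix["complete"]]
    return matrix


def rfe_select(
    matrix: pd.DataFrame,
    task: str,
    target: int = 75,
    step: int = 4,
    spec: ModelSpec | None = None,
) -> list[str]:
    """Recursive feature elimination down to exactly ``target`` features.

    Repeatedly fits the learner, ranks features by impurity importance, and
    drops the ``step`` least important (fewer on the last iteration).
    Returns the input unchanged when it already has at most ``target``
    features.
    """
    spec = spec or ModelSpec(task=task)
    matrix = _clean(matrix)
    features = feature_columns(matrix)
    if target >= len(features):
        return features
    y = binarize_labels(matrix, task)
    while len(features) > target:
        est = make_learner(spec)
        est.fit(matrix[features].to_numpy(), y)
        importances = est.feature_importances_
        drop = min(step, len(features) - target)
        worst = np.argsort(importances, kind="stable")[:drop]
        features = [f for i, f in enumerate(features) if i not in set(worst)]
    return features


def _blocked_logloss(
    matrix: pd.DataFrame, task: str, spec: ModelSpec, k: int, seed: int
) -> float:
    """Tile-blocked CV log-loss of one candidate on one subsample."""
    k = min(k, matrix["tile_id"].nunique())
    if k < 2:
        raise ValueError("need at least 2 tiles for blocked evaluation")
    folds = make_spatial_folds(matrix, k=k, seed=seed)
    oof = cross_val_predict_oof(matrix, folds, spec)
    merged = matrix.merge(oof, on="sample_id")
    y = (merged["class_code"] == TASKS[task]).astype(int)
    return log_loss(y, merged["probability"], labels=[0, 1])


def successive_halving(
    calibration: pd.DataFrame,
    task: str,
    candidates: list[dict],
    start_n: int = 500,
    seed: int = 0,
    learner: str = "random_forest",
    cv_folds: int = 5,
) -> dict:
    """Hyperparameter search by successive halving on the calibration set.

    Each round scores the surviving candidates by tile-blocked CV log-loss
    on the current subsample, drops the worse half (rounding survivors up),
    and doubles the subsample (capped at the full calibration set). A
    single candidate is returned without any evaluation round.
    """
    if not candidates:
        raise ValueError("candidate set must not be empty")
    survivors = list(candidates)
    if len(survivors) == 1:
        return survivors[0]
    calibration = _clean(calibration)
    rng = np.random.default_rng(seed)
    n = min(start_n, len(calibration))
    while len(survivors) > 1:
        sub_idx = rng.choice(len(calibration), size=n, replace=False)
        subsample = calibration.iloc[sub_idx]
        scores = []
        for params in survivors:
            spec = ModelSpec(task=task, learner=learner,
                             hyperparameters=params, seed=seed)
            scores.append(_blocked_logloss(subsample, task, spec, cv_folds, seed))
        keep = int(math.ceil(len(survivors) / 2))
        order = np.argsort(scores, kind="stable")[:keep]
        survivors = [survivors[int(i)] for i in order]
        n = min(2 * n, len(calibration))
    return survivors[0]


def cross_val_predict_oof(
    matrix: pd.DataFrame, folds: FoldAssignment, spec: ModelSpec
) -> pd.DataFrame:
    """Out-of-fold probabilities under tile-blocked cross-validation.

    For each fold the learner is fitted on every other fold and predicts
    the held-out samples, so each sample gets exactly one probability from
    a model that never saw its tile. Returns a table with columns
    (sample_id, fold, probability, label).
    """
    matrix = _clean(matrix)
    features = spec.selected_features or feature_columns(matrix)
    y = binarize_labels(matrix, spec.task)
    fold_of = matrix["tile_id"].map(folds.tile_fold).to_numpy()
    out = []
    for fold in sorted(set(fold_of)):
        train = fold_of != fold
        test = ~train
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"fold {fold}: training side has a single class")
        est = make_learner(spec)
        est.fit(matrix.loc[train, features].to_numpy(), y_train)
        proba = est.predict_proba(matrix.loc[test, features].to_numpy())[:, 1]
        out.append(pd.DataFrame({
            "sample_id": matrix.loc[test, "sample_id"].to_numpy(),
            "fold": fold,
            "probability": proba,
            "label": y[test],
        }))
    return pd.concat(out, ignore_index=True)


def fit_predict_full(
    matrix: pd.DataFrame,
    spec: ModelSpec,
    composites: dict,
    index_cube: IndexCube,
    static: CovariateStack,
    years: list[int],
    exclusion_mask: np.ndarray | None = None,
    transform: GeoTransform = GeoTransform(),
) -> ProbabilityCube:
    """Fit on all samples and predict the per-pixel probability cube.

    Probabilities are stored as integers 0-100; pixels under the exclusion
    mask (or with missing features) are set to 255.
    """
    for year in years:
        if (year, 1) not in composites:
            raise ValueError(f"year {year} missing from the composite archive")
    matrix = _clean(matrix)
    features = spec.selected_features or feature_columns(matrix)
    y = binarize_labels(matrix, spec.task)
    est = make_learner(spec)
    est.fit(matrix[features].to_numpy(), y)

    shape = static.data.shape[1:]
    cube = np.full((len(years),) + shape, NODATA, dtype=np.uint8)
    for yi, year in enumerate(years):
        table = pixel_feature_table(year, composites, index_cube, static)
        X = table[features].to_numpy()
        ok = np.isfinite(X).all(axis=1)
        proba = np.full(len(table), np.nan)
        if ok.any():
            proba[ok] = est.predict_proba(X[ok])[:, 1]
        plane = np.full(len(table), NODATA, dtype=np.uint8)
        plane[ok] = np.rint(proba[ok] * 100.0).astype(np.uint8)
        plane = plane.reshape(shape)
        if exclusion_mask is not None:
            plane[exclusion_mask] = NODATA
        cube[yi] = plane
    return ProbabilityCube(
        class_name=spec.task, years=list(years), data=cube,
        transform=transform, smoothed=False,
    )
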