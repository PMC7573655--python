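"""Single-image harmonization for unseen scanners.

Learns the mapping from per-image quality metrics (plus age, sex, and
the raw relative volumes) to the per-ROI corrections prescribed by the
batch harmonizer, so a single image from a scanner never seen by the
harmonizer can be corrected without a representative sample. One
regressor is trained per ROI on a shared standardized principal
component basis retaining a configured fraction (default 99%) of the
explained variance. Inputs outside the training envelope are flagged
but still predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor

from .tables import CohortTable

logger = logging.getLogger(__name__)

DEFAULT_GRID: tuple[dict, ...] = (
    {"n_estimators": 100, "max_depth": None, "min_samples_leaf": 1},
    {"n_estimators": 100, "max_depth": None, "min_samples_leaf": 5},
    {"n_estimators": 100, "max_depth": 10, "min_samples_leaf": 1},
    {"n_estimators": 100, "max_depth": 10, "min_samples_leaf": 5},
    {"n_estimators": 500, "max_depth": None, "min_samples_leaf": 1},
    {"n_estimators": 500, "max_depth": None, "min_samples_leaf": 5},
    {"n_estimators": 500, "max_depth": 10, "min_samples_leaf": 1},
    {"n_estimators": 500, "max_depth": 10, "min_samples_leaf": 5},
)


def _complexity_key(params: dict) -> tuple:
    depth = params.get("max_depth")
    return (
        params.get("n_estimators", 0),
        np.inf if depth is None else depth,
        -params.get("min_samples_leaf", 1),
    )


@dataclass
class ComponentBasis:
    """Standardization + orthonormal loadings retaining >= threshold variance."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray            # (k, p)
    explained_variance_ratio: np.ndarray
    n_components: int
    variance_threshold: float

    def project(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.mean) / self.scale
        return Z @ self.components.T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        return (scores @ self.components) * self.scale + self.mean


@dataclass
class RangeFlag:
    subject_id: str
    out_of_range_features: list[tuple[str, float, float, float]] = field(default_factory=list)


@dataclass
class HarmonyModel:
    feature_names: list[str]
    roi_names: list[str]
    basis: ComponentBasis
    regressors: dict[str, Any]
    hyperparameters: dict[str, dict]
    training_ranges: dict[str, tuple[float, float]]
    cv_report: pd.DataFrame | None = None
    seed: int = 0


class _ConstantPredictor:
    """Stand-in regressor for targets with zero variance."""

    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.value)


def assemble_features(
    table: CohortTable, rois: str | Sequence[str] | None = None
) -> pd.DataFrame:
    """Ordered numeric feature matrix: IQMs, age, sex, relative volume(s).

    ``rois`` may be a single target ROI, a list, or ``None`` for every
    ROI in the table (the shared-basis training layout).
    """
    if rois is None:
        rois = list(table.roi_cols)
    elif isinstance(rois, str):
        rois = [rois]
    missing = [c for c in table.iqm_cols if c not in table.data.columns]
    missing += [r for r in rois if table.rel_col(r) not in table.data.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {', '.join(missing)}")
    d = table.data.set_index("subject_id")
    out = pd.DataFrame(index=d.index)
    for c in table.iqm_cols:
        out[c] = d[c].astype(float)
    out["age"] = d["age"].astype(float)
    out["sex"] = d["sex"].astype(float)
    for r in rois:
        out[f"vol:{r}"] = d[table.rel_col(r)].astype(float)
    const = [c for c in out.columns if out[c].nunique() <= 1]
    if const:
        logger.warning("constant feature column(s): %s", ", ".join(const))
    return out


def fit_component_basis(
    features: pd.DataFrame | np.ndarray, threshold: float = 0.99
) -> ComponentBasis:
    """Smallest number of standardized principal components whose
    cumulative explained variance reaches ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"variance threshold {threshold} outside (0, 1]")
    X = features.to_numpy(float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    mean = X.mean(axis=0)
    scale = np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    Z = (X - mean) / scale
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, len(cum))
    return ComponentBasis(
        mean=mean,
        scale=scale,
        components=pca.components_[:k],
        explained_variance_ratio=pca.explained_variance_ratio_[:k],
        n_components=k,
        variance_threshold=threshold,
    )


def _fit_forest(X: np.ndarray, y: np.ndarray, params: dict, seed: int) -> Any:
    if np.ptp(y) == 0:
        return _ConstantPredictor(y[0] if len(y) else 0.0)
    rf = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    rf.fit(X, y)
    return rf


def _roi_seed(seed: int, roi_index: int) -> int:
    return int(np.random.SeedSequence([seed, roi_index]).generate_state(1)[0] % (2**31 - 1))


def loso_search(
    table: CohortTable,
    corrections: pd.DataFrame,
    grid: Sequence[dict] = DEFAULT_GRID,
    merge_below: int = 30,
    cap_to_second_largest: bool = True,
    seed: int = 0,
    variance_threshold: float = 0.99,
) -> tuple[dict[str, dict], pd.DataFrame]:
    """Leave-one-scanner-out hyperparameter search.

    For the cross-validation split only, scanners with fewer than
    ``merge_below`` subjects are pooled into one pseudo-scanner, and the
    largest scanner is randomly under-sampled to the size of the second
    largest. Each fold leaves one (pseudo-)scanner out and scores the
    mean absolute error of predicted corrections on it. Per ROI, the
    grid point with the smallest mean fold MAE wins; ties go to the
    least complex point (fewest trees, then shallowest).
    """
    if len(table.scanners()) < 3:
        raise ValueError("leave-one-scanner-out search requires at least 3 scanners")
    if not grid:
        raise ValueError("empty hyperparameter grid")
    grid = sorted(grid, key=_complexity_key)

    rng = np.random.default_rng(seed)
    sizes = pd.Series(table.scanner_sizes()).sort_values(ascending=False)
    d = table.data.reset_index(drop=True)
    keep = np.ones(len(d), dtype=bool)
    if cap_to_second_largest and len(sizes) >= 2 and sizes.iloc[0] > sizes.iloc[1]:
        largest = sizes.index[0]
        idx = np.flatnonzero((d["scanner"] == largest).to_numpy())
        drop = rng.choice(idx, size=len(idx) - int(sizes.iloc[1]), replace=False)
        keep[drop] = False
    sub = table.subset(keep)

    pseudo = sub.data["scanner"].map(
        lambda s: "MERGED" if sub.scanner_sizes()[s] < merge_below else s
    )
    folds = sorted(pseudo.unique())
    feats = assemble_features(sub)
    y_all = corrections.loc[feats.index]
    rois = list(y_all.columns)

    records = []
    for fold in folds:
        test_mask = (pseudo == fold).to_numpy()
        train_feats, test_feats = feats.loc[~test_mask], feats.loc[test_mask]
        basis = fit_component_basis(train_feats, variance_threshold)
        Xtr = basis.project(train_feats.to_numpy(float))
        Xte = basis.project(test_feats.to_numpy(float))
        for gi, params in enumerate(grid):
            for ri, roi in enumerate(rois):
                est = _fit_forest(Xtr, y_all.loc[~test_mask, roi].to_numpy(), params, _roi_seed(seed, ri))
                mae = float(np.abs(est.predict(Xte) - y_all.loc[test_mask, roi].to_numpy()).mean())
                records.append({"fold": fold, "grid_index": gi, "roi": roi, "mae": mae})
    report = pd.DataFrame(records)
    chosen: dict[str, dict] = {}
    for roi in rois:
        mean_mae = report[report["roi"] == roi].groupby("grid_index")["mae"].mean()
        best = int(mean_mae.index[np.argmin(mean_mae.to_numpy())])  # stable: first minimum
        chosen[roi] = dict(grid[best])
    return chosen, report


def train(
    table: CohortTable,
    corrections: pd.DataFrame,
    hyperparameters: dict[str, dict] | dict | None = None,
    variance_threshold: float = 0.99,
    seed: int = 0,
) -> HarmonyModel:
    """Fit one forest regressor per ROI on the shared component basis.

    ``corrections`` is a subject-indexed frame of per-ROI correction
    targets (harmonized minus raw relative volume). ``hyperparameters``
    is either one parameter dict for every ROI or a per-ROI map (e.g.
    from :func:`loso_search`); default 100 trees.
    """
    feats = assemble_features(table)
    y_all = corrections.loc[feats.index]
    rois = list(y_all.columns)
    basis = fit_component_basis(feats, variance_threshold)
    X = basis.project(feats.to_numpy(float))

    if hyperparameters is None:
        per_roi = {r: {"n_estimators": 100, "max_depth": None, "min_samples_leaf": 1} for r in rois}
    elif rois and all(r in hyperparameters for r in rois):
        per_roi = {r: dict(hyperparameters[r]) for r in rois}
    else:
        per_roi = {r: dict(hyperparameters) for r in rois}

    regressors: dict[str, Any] = {}
    for ri, roi in enumerate(rois):
        y = y_all[roi].to_numpy(float)
        est = _fit_forest(X, y, per_roi[roi], _roi_seed(seed, ri))
        if isinstance(est, _ConstantPredictor):
            logger.warning("ROI %s has zero-variance corrections; constant predictor used", roi)
        regressors[roi] = est

    ranges = {c: (float(feats[c].min()), float(feats[c].max())) for c in feats.columns}
    return HarmonyModel(
        feature_names=list(feats.columns),
        roi_names=rois,
        basis=basis,
        regressors=regressors,
        hyperparameters=per_roi,
        training_ranges=ranges,
        seed=seed,
    )


def range_check(model: HarmonyModel, feats: pd.DataFrame) -> list[RangeFlag]:
    """Flag subjects with any feature outside the training envelope."""
    flags = []
    for sid, row in feats.iterrows():
        out = []
        for f in model.feature_names:
            lo, hi = model.training_ranges[f]
            v = float(row[f])
            if v < lo or v > hi:
                out.append((f, v, lo, hi))
        if out:
            flags.append(RangeFlag(subject_id=str(sid), out_of_range_features=out))
    return flags


def predict_corrections(
    model: HarmonyModel, table: CohortTable
) -> tuple[pd.DataFrame, list[RangeFlag]]:
    """Predict per subject x ROI corrections; no batch statistics are
    consulted, so a single subject from an unknown scanner is valid input."""
    rois = [f.split("vol:", 1)[1] for f in model.feature_names if f.startswith("vol:")]
    feats = assemble_features(table, rois)
    missing = [f for f in model.feature_names if f not in feats.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {', '.join(missing)}")
    feats = feats[model.feature_names]
    flags = range_check(model, feats)
    if flags:
        logger.warning("%d subject(s) outside the training range", len(flags))
    X = model.basis.project(feats.to_numpy(float))
    out = pd.DataFrame(index=feats.index)
    for roi in model.roi_names:
        out[roi] = model.regressors[roi].predict(X)
    return out, flags


def apply(
    model: HarmonyModel, table: CohortTable
) -> tuple[CohortTable, pd.DataFrame, list[RangeFlag]]:
    """harmonized relative volume = raw relative volume + predicted correction."""
    corr, flags = predict_corrections(model, table)
    rel = table.relative_volumes()
    harmonized = rel + corr.loc[rel.index, rel.columns]
    return table.with_relative_volumes(harmonized), corr, flags
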