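"""Brain-age prediction with kernel support-vector regression.

The global model regresses chronological age on region-mean GMV across all
atlas regions; one regional model per region uses that region's voxel-level
GMV only.  Hyperparameters C and gamma of the RBF kernel are selected by
grid search over seven values each (0.001 ... 1000) in an inner 5-fold
cross-validation loop; an outer 5-fold loop reports out-of-sample MAE and
R².  The final model is refit on the whole training set with parameters
chosen by a 5-fold CV over all of it.  The brain-age gap (BAG) of an
application subject is predicted age minus chronological age, so positive
BAG means an older-looking brain.

Features are z-scored with training-fold statistics inside the estimation
pipeline, since RBF kernels need commensurate feature scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .atlas import AtlasSpec
from .features import FeatureSet

__all__ = [
    "ModelSpec",
    "CVResult",
    "BrainAgeModel",
    "BagResult",
    "nested_cv_fit",
    "fit_model",
    "fit_regional_models",
    "predict_and_bag",
    "mae",
    "r_squared",
]

SEVEN_VALUES: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


@dataclass
class ModelSpec:
    """SVR configuration: RBF kernel, C/gamma grids, epsilon, CV layout."""

    c_grid: tuple[float, ...] = SEVEN_VALUES
    gamma_grid: tuple[float, ...] = SEVEN_VALUES
    epsilon: float = 0.1  # insensitive-loss half-width, years
    k_outer: int = 5
    k_inner: int = 5
    seed: int = 0
    scale_features: bool = True
    max_iter: int = 2_000_000  # caps pathological solver cases

    def validate(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("C and gamma grids must be non-empty")
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("k_outer and k_inner must be >= 2")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class CVResult:
    """Nested-CV evaluation: per-outer-fold and pooled out-of-fold metrics."""

    fold_mae: np.ndarray
    fold_r2: np.ndarray
    fold_params: list[dict]
    pooled_mae: float
    pooled_r2: float
    pooled_r: float
    final_params: dict
    oof_pred: np.ndarray
    fold_id: np.ndarray  # outer-fold membership per subject


@dataclass
class BrainAgeModel:
    """A fitted brain-age predictor with its feature schema."""

    estimator: Pipeline
    feature_names: list[str]
    spec: ModelSpec
    cv: CVResult | None = None

    def predict(self, X) -> np.ndarray:
        """Predict ages; ``X`` may be an array or a DataFrame keyed by name."""
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            extra = [c for c in X.columns if c not in set(self.feature_names)]
            if missing or extra:
                raise ValueError(
                    f"feature schema mismatch: missing={missing}, extra={extra}"
                )
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns, "
                f"got {X.shape[1]}"
            )
        return self.estimator.predict(X)


# ----------------------------------------------------------------- metrics

def mae(pred, true) -> float:
    """Mean absolute error, in the target's units (years here)."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size < 1:
        raise ValueError("pred and true must have equal length >= 1")
    return float(np.mean(np.abs(pred - true)))


def r_squared(pred, true) -> float:
    """Coefficient of determination, 1 - SSE/SST about the mean of ``true``.

    Returns NaN (with a warning) when ``true`` has zero variance.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size < 2:
        raise ValueError("pred and true must have equal length >= 2")
    sst = float(np.sum((true - true.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("R² undefined: zero variance in true values",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    sse = float(np.sum((true - pred) ** 2))
    return 1.0 - sse / sst


# ------------------------------------------------------------------- folds

def age_stratified_folds(ages, k: int, seed: int):
    """Shuffled k-fold assignment stratified by age decile.

    Falls back to coarser bins (then to a plain shuffled split) when bins
    are too small to stratify; always returns ``k`` (train, test) pairs.
    """
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    if np.ptp(ages) == 0:
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros(n)))
    for n_bins in (10, 5, 3, 2):
        try:
            labels = pd.qcut(ages, q=n_bins, labels=False, duplicates="drop")
        except ValueError:
            continue
        counts = np.bincount(labels.astype(int))
        if counts.min() >= k:
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            return list(skf.split(np.zeros(n), labels))
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(n)))


def _pipeline(spec: ModelSpec) -> Pipeline:
    steps = []
    if spec.scale_features:
        steps.append(("scaler", StandardScaler()))
    steps.append(("svr", SVR(kernel="rbf", epsilon=spec.epsilon,
                             max_iter=spec.max_iter)))
    return Pipeline(steps)


def select_params(X, y, spec: ModelSpec) -> dict:
    """Grid-search (C, gamma) minimising k_inner-fold CV mean absolute error.

    Ties break to the smallest C, then the smallest gamma (the first best
    candidate in ascending grid order).
    """
    grid = {
        "svr__C": sorted(spec.c_grid),
        "svr__gamma": sorted(spec.gamma_grid),
    }
    inner = KFold(n_splits=spec.k_inner, shuffle=True, random_state=spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gs = GridSearchCV(_pipeline(spec), grid, cv=inner,
                          scoring="neg_mean_absolute_error", refit=False)
        gs.fit(X, y)
    best = gs.best_params_
    return {"C": best["svr__C"], "gamma": best["svr__gamma"]}


def _check_xy(X, y, spec: ModelSpec):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if len(X) != len(y):
        raise ValueError(f"features ({len(X)}) and ages ({len(y)}) misaligned")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in features or ages")
    if len(y) < spec.k_outer:
        raise ValueError(f"need n >= k_outer={spec.k_outer}, got n={len(y)}")
    const = np.where(np.ptp(X, axis=0) == 0)[0]
    if const.size:
        warnings.warn(
            f"{const.size} constant feature column(s); scaling guards them",
            RuntimeWarning, stacklevel=3,
        )
    return X, y


def fit_model(X, y, spec: ModelSpec | None = None,
              feature_names: list[str] | None = None) -> BrainAgeModel:
    """Fit the final model: whole-set k_inner-fold CV selection, then refit."""
    spec = spec or ModelSpec()
    spec.validate()
    X, y = _check_xy(X, y, spec)
    params = select_params(X, y, spec)
    est = _pipeline(spec)
    est.set_params(svr__C=params["C"], svr__gamma=params["gamma"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    return BrainAgeModel(estimator=est, feature_names=list(names), spec=spec)


def nested_cv_fit(X, y, spec: ModelSpec | None = None,
                  feature_names: list[str] | None = None) -> BrainAgeModel:
    """Nested cross-validation evaluation plus final whole-set refit.

    The inner loop selects (C, gamma) per outer fold; the outer loop's
    out-of-fold predictions give unbiased MAE/R².  The returned model is
    refit on all data with parameters selected by a k_inner-fold CV over
    the whole training set, and carries the :class:`CVResult`.
    """
    spec = spec or ModelSpec()
    spec.validate()
    X, y = _check_xy(X, y, spec)
    n = len(y)
    if np.ptp(y) == 0:
        warnings.warn("constant target ages: R² will be undefined",
                      RuntimeWarning, stacklevel=2)

    folds = age_stratified_folds(y, spec.k_outer, spec.seed)
    oof = np.full(n, np.nan)
    fold_id = np.full(n, -1, dtype=int)
    fold_mae, fold_r2, fold_params = [], [], []
    for i, (tr, te) in enumerate(folds):
        params = select_params(X[tr], y[tr], spec)
        est = _pipeline(spec)
        est.set_params(svr__C=params["C"], svr__gamma=params["gamma"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        oof[te] = pred
        fold_id[te] = i
        fold_mae.append(mae(pred, y[te]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fold_r2.append(r_squared(pred, y[te]) if len(te) >= 2 else np.nan)
        fold_params.append(params)

    pooled_mae = mae(oof, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pooled_r2 = r_squared(oof, y)
        pooled_r = (float(stats.pearsonr(oof, y).statistic)
                    if np.ptp(y) > 0 and np.ptp(oof) > 0 else float("nan"))

    model = fit_model(X, y, spec, feature_names)
    model.cv = CVResult(
        fold_mae=np.array(fold_mae),
        fold_r2=np.array(fold_r2),
        fold_params=fold_params,
        pooled_mae=pooled_mae,
        pooled_r2=pooled_r2,
        pooled_r=pooled_r,
        final_params=select_params(X, y, spec),
        oof_pred=oof,
        fold_id=fold_id,
    )
    return model


def fit_regional_models(
    features: FeatureSet,
    ages,
    atlas: AtlasSpec | None = None,
    spec: ModelSpec | None = None,
    evaluate: bool = True,
) -> dict[str, BrainAgeModel]:
    """One independent SVR per region, on that region's voxel features only.

    With ``evaluate=False`` the outer CV loop is skipped and each model is
    the whole-set CV-selected refit (cheaper; no CVResult attached).
    """
    atlas = atlas or features.atlas
    models: dict[str, BrainAgeModel] = {}
    for rid in atlas.region_ids:
        cols = atlas.voxel_columns(rid)
        if not cols:
            raise ValueError(f"region {rid!r} has no voxel feature columns")
        block = features.voxels[cols]
        fit = nested_cv_fit if evaluate else fit_model
        models[rid] = fit(block.to_numpy(dtype=float), ages, spec,
                          feature_names=cols)
    return models


# ---------------------------------------------------------------- BAG

@dataclass
class BagResult:
    """Predicted ages and brain-age gaps, long format.

    ``table`` columns: subject_id, scope ('global' or a region_id),
    predicted_age, age, bag (= predicted_age - age).
    """

    table: pd.DataFrame

    def wide(self, value: str = "bag") -> pd.DataFrame:
        """Subjects x scopes matrix of ``bag`` or ``predicted_age``."""
        return self.table.pivot(index="subject_id", columns="scope",
                                values=value)

    def global_bag(self) -> pd.Series:
        sub = self.table[self.table["scope"] == "global"]
        return pd.Series(sub["bag"].to_numpy(), index=sub["subject_id"].to_numpy(),
                         name="bag_global")

    def region_bag(self, region_id: str) -> pd.Series:
        sub = self.table[self.table["scope"] == region_id]
        if sub.empty:
            raise KeyError(f"no BAG values for scope {region_id!r}")
        return pd.Series(sub["bag"].to_numpy(), index=sub["subject_id"].to_numpy(),
                         name=f"bag_{region_id}")

    @property
    def scopes(self) -> list[str]:
        return list(dict.fromkeys(self.table["scope"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BagResult":
        # round_trip parsing keeps cached-and-resumed runs bit-identical
        return cls(table=pd.read_csv(path, sep="\t",
                                     float_precision="round_trip"))


def predict_and_bag(
    global_model: BrainAgeModel | None,
    regional_models: dict[str, BrainAgeModel] | None,
    features: FeatureSet,
    ages,
) -> BagResult:
    """Apply fitted models to a cohort and compute BAG per scope.

    No refitting occurs.  Feature columns are joined by name; a schema
    mismatch raises an error listing the missing/extra columns.
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) != features.n_subjects:
        raise ValueError("ages misaligned with feature rows")
    rows = []
    ids = features.subject_ids
    if global_model is not None:
        pred = global_model.predict(features.region_mean())
        rows.append(pd.DataFrame({
            "subject_id": ids, "scope": "global",
            "predicted_age": pred, "age": ages, "bag": pred - ages,
        }))
    for rid, model in (regional_models or {}).items():
        pred = model.predict(features.region_block(rid))
        rows.append(pd.DataFrame({
            "subject_id": ids, "scope": rid,
            "predicted_age": pred, "age": ages, "bag": pred - ages,
        }))
    if not rows:
        raise ValueError("no models supplied")
    return BagResult(table=pd.concat(rows, ignore_index=True))
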