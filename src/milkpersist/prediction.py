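"""Linear prediction of 305-day decay (and M305 as a control) at an
insemination moment.

The model is plain OLS on standardised predictors:

    y = mu + LCC + daily_yield + age + calving_season + parity_group
           + HLCC + HM305 + e,        e ~ N(0, sigma^2)

with y the 305-day decay (persistency target) or, as a methodological
control, M305.  All continuous predictors are z-scored with the *training*
mean/sd so the coefficients are directly comparable effect sizes; calving
season is dummy-coded against Winter and parity group against primiparous.
Evaluation uses held-out test rows only, with R^2, RMSE, MAE and MAPE.
10-fold cross-validation on the training set is reporting-only — OLS has no
hyperparameters to tune.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold

__all__ = [
    "CONTINUOUS_PREDICTORS",
    "CATEGORICAL_REFERENCES",
    "ModelSpec",
    "EvaluationReport",
    "split_train_test",
    "standardize",
    "fit_linear_model",
    "cross_validate",
    "compute_metrics",
    "coefficient_ranking",
    "evaluate_model",
    "plot_coefficient_funnel",
]

logger = logging.getLogger(__name__)

CONTINUOUS_PREDICTORS = [
    "magnitude",
    "time_to_peak",
    "offset",
    "decay",
    "daily_yield_kg",
    "age_months",
    "herd_magnitude",
    "herd_time_to_peak",
    "herd_offset",
    "herd_decay",
    "herd_m305",
]

#: Categorical predictors with their reference (absorbed) level.
CATEGORICAL_REFERENCES = {
    "calving_season": "Winter",
    "parity_group": "primiparous",
}


@dataclass(frozen=True)
class ModelSpec:
    """What to predict, from what."""

    target: str = "decay_305"  # or "m305_target"
    moment: int | None = None
    continuous: tuple[str, ...] = tuple(CONTINUOUS_PREDICTORS)
    categorical: tuple[str, ...] = tuple(CATEGORICAL_REFERENCES)

    def __post_init__(self):
        if self.target not in ("decay_305", "m305_target"):
            raise ValueError(f"unknown target {self.target!r}")


@dataclass
class EvaluationReport:
    """Held-out metrics plus the ranked standardised coefficients."""

    target: str
    moment: int | None
    r2: float
    rmse: float
    mae: float
    mape: float
    n_test: int
    coefficients: pd.DataFrame = field(repr=False, default=None)
    cv_metrics: pd.DataFrame | None = field(repr=False, default=None)

    def metrics_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "mae": self.mae,
            "mape": self.mape,
            "n_test": self.n_test,
        }


def split_train_test(
    dataset: pd.DataFrame, fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random row-level (cow-parity-record) split, deterministic given seed."""
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    n_train = int(round(fraction * len(dataset)))
    train = dataset.iloc[perm[:n_train]]
    test = dataset.iloc[perm[n_train:]]
    return train, test


def standardize(
    train: pd.DataFrame,
    test: pd.DataFrame,
    columns=None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict, list]:
    """Z-score continuous columns with the training mean/sd.

    Constant training columns (sd = 0) cannot be scaled and are dropped
    from both tables with a warning — e.g. the offset of primiparous cows,
    which is pinned by its prior.  Returns
    ``(train_std, test_std, scaler, dropped)`` where ``scaler`` maps each
    kept column to its ``(mean, sd)``.
    """
    if columns is None:
        columns = [c for c in CONTINUOUS_PREDICTORS if c in train.columns]
    train = train.copy()
    test = test.copy()
    scaler: dict[str, tuple[float, float]] = {}
    dropped: list[str] = []
    for col in columns:
        mean = float(train[col].mean())
        sd = float(train[col].std(ddof=0))
        if sd == 0.0 or not np.isfinite(sd):
            dropped.append(col)
            train = train.drop(columns=col)
            test = test.drop(columns=col, errors="ignore")
            logger.warning("dropping constant predictor column %r", col)
            continue
        scaler[col] = (mean, sd)
        train[col] = (train[col] - mean) / sd
        test[col] = (test[col] - mean) / sd
    return train, test, scaler, dropped


def _design_matrix(df: pd.DataFrame, spec: ModelSpec, dropped=()) -> pd.DataFrame:
    cols = [c for c in spec.continuous if c in df.columns and c not in dropped]
    X = df[cols].astype(float).copy()
    for cat in spec.categorical:
        ref = CATEGORICAL_REFERENCES[cat]
        dummies = pd.get_dummies(df[cat], prefix=cat, dtype=float)
        ref_col = f"{cat}_{ref}"
        dummies = dummies.drop(columns=ref_col, errors="ignore")
        X = pd.concat([X, dummies], axis=1)
    X.insert(0, "const", 1.0)
    return X


class LinearPredictionModel:
    """Fitted OLS wrapper keeping the design-column order and scaler."""

    def __init__(self, result, columns, spec, scaler=None, dropped=()):
        self.result = result
        self.columns = list(columns)
        self.spec = spec
        self.scaler = scaler or {}
        self.dropped = tuple(dropped)

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def bse(self) -> pd.Series:
        return self.result.bse

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(df, self.spec, self.dropped)
        X = X.reindex(columns=self.columns, fill_value=0.0)
        return np.asarray(self.result.predict(X))


def fit_linear_model(
    train: pd.DataFrame, spec: ModelSpec, scaler=None, dropped=()
) -> LinearPredictionModel:
    """OLS fit on (already standardised) training rows.

    Raises a ``ValueError`` naming the offending column when the design
    matrix is rank-deficient (e.g. a duplicated predictor).
    """
    X = _design_matrix(train, spec, dropped)
    y = train[spec.target].astype(float)

    arr = X.to_numpy()
    for i in range(arr.shape[1]):
        for j in range(i + 1, arr.shape[1]):
            if np.allclose(arr[:, i], arr[:, j]):
                raise ValueError(
                    f"rank-deficient design: column {X.columns[j]!r} duplicates "
                    f"{X.columns[i]!r}"
                )
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        raise ValueError(
            f"rank-deficient design matrix (rank {rank} < {arr.shape[1]} columns "
            f"{list(X.columns)})"
        )
    result = sm.OLS(y, X).fit()
    return LinearPredictionModel(result, X.columns, spec, scaler, dropped)


def compute_metrics(predicted, observed) -> dict:
    """R^2, RMSE, MAE and MAPE of predictions against held-out observations.

    R^2 = 1 - SS_res/SS_tot; MAPE averages |error/observed| over rows with
    non-zero observations (excluded rows are counted and logged; decay
    targets are strictly positive after filtering, so normally none).
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.size == 0 or pred.shape != obs.shape:
        raise ValueError("predicted and observed must be equal-length and non-empty")
    err = pred - obs
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    nonzero = obs != 0
    n_excl = int((~nonzero).sum())
    if n_excl:
        logger.warning("MAPE: excluding %d rows with observed value 0", n_excl)
    mape = (
        float(np.mean(np.abs(err[nonzero] / obs[nonzero]))) if nonzero.any() else np.nan
    )
    return {
        "r2": r2,
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
        "mape": mape,
        "n": int(pred.size),
        "n_mape_excluded": n_excl,
    }


def cross_validate(
    train: pd.DataFrame,
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """k-fold CV on the training set (reporting only, no tuning).

    Standardisation is re-fitted inside every fold on that fold's training
    part.  Returns per-fold metrics and the out-of-fold predictions aligned
    to ``train``'s index.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(train) < k:
        raise ValueError("need at least k rows")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    oof = pd.Series(np.nan, index=train.index, dtype=float)
    for fold, (tr_idx, va_idx) in enumerate(kf.split(train)):
        tr, va = train.iloc[tr_idx], train.iloc[va_idx]
        tr_s, va_s, scaler, dropped = standardize(tr, va)
        model = fit_linear_model(tr_s, spec, scaler, dropped)
        pred = model.predict(va_s)
        metrics = compute_metrics(pred, va_s[spec.target])
        metrics["fold"] = fold
        rows.append(metrics)
        oof.iloc[va_idx] = pred
    return pd.DataFrame(rows).set_index("fold"), oof


def coefficient_ranking(model: LinearPredictionModel) -> pd.DataFrame:
    """Coefficients sorted by |standardised estimate| (ties alphabetical)."""
    params = model.params.drop(labels=["const"], errors="ignore")
    bse = model.bse.drop(labels=["const"], errors="ignore")
    tbl = pd.DataFrame(
        {"term": params.index, "estimate": params.values, "se": bse.values}
    )
    tbl["abs_estimate"] = tbl["estimate"].abs()
    tbl = tbl.sort_values(
        ["abs_estimate", "term"], ascending=[False, True], kind="stable"
    ).drop(columns="abs_estimate")
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    return tbl.reset_index(drop=True)


def evaluate_model(
    train: pd.DataFrame,
    test: pd.DataFrame,
    spec: ModelSpec,
    cv_folds: int | None = None,
    seed: int = 0,
) -> tuple[EvaluationReport, LinearPredictionModel]:
    """Standardise, fit on train, evaluate on held-out test."""
    train_s, test_s, scaler, dropped = standardize(train, test)
    model = fit_linear_model(train_s, spec, scaler, dropped)
    pred = model.predict(test_s)
    metrics = compute_metrics(pred, test_s[spec.target])
    cv = None
    if cv_folds:
        cv, _ = cross_validate(train, spec, k=cv_folds, seed=seed)
    report = EvaluationReport(
        target=spec.target,
        moment=spec.moment,
        r2=metrics["r2"],
        rmse=metrics["rmse"],
        mae=metrics["mae"],
        mape=metrics["mape"],
        n_test=metrics["n"],
        coefficients=coefficient_ranking(model),
        cv_metrics=cv,
    )
    return report, model


def plot_coefficient_funnel(ranking: pd.DataFrame, ax=None):
    """Funnel plot of ranked standardised coefficients with +/-1 SE bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(ranking) + 1))
    y = np.arange(len(ranking))[::-1]
    ax.errorbar(ranking["estimate"], y, xerr=ranking["se"], fmt="o", capsize=3)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(ranking["term"])
    ax.set_xlabel("standardised coefficient")
    return ax
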