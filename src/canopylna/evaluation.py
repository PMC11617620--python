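"""Fit/validation metrics, data splitting and model comparison.

Metrics follow common agronomic remote-sensing usage:

* ``r`` - Pearson correlation between observed and predicted.
* ``r2`` - coefficient of determination 1 - SSE/SST about the mean of the
  observed values; on a validation set this can be negative and is
  reported as-is.
* ``rrmse`` - root mean square error divided by the *mean of the observed
  values*, in percent. The denominator convention matters: some authors
  divide by the observed range instead, which gives smaller numbers. The
  mean-based form is used throughout this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvalReport",
    "rrmse",
    "pearson_r",
    "r2_validation",
    "evaluate_predictions",
    "split_train_val",
    "kfold_cv",
    "compare_models",
]


class EvaluationError(ValueError):
    pass


@dataclass
class EvalReport:
    """Fit/validation diagnostics for one model on one dataset."""

    model_label: str
    dataset_label: str
    n: int
    r: float
    r2: float
    rrmse_pct: float
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {"model_label": self.model_label,
                "dataset_label": self.dataset_label, "n": self.n,
                "r": self.r, "r2": self.r2, "rrmse_pct": self.rrmse_pct}


def rrmse(observed, predicted) -> float:
    """Relative RMSE in percent: 100 * RMSE / mean(observed)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0:
        raise EvaluationError("rrmse requires at least one observation")
    m = obs.mean()
    if m == 0:
        raise EvaluationError("rrmse undefined: mean of observed is zero")
    return float(100.0 * np.sqrt(np.mean((obs - pred) ** 2)) / m)


def pearson_r(x, y) -> float:
    """Pearson correlation; NaN when either variance is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise EvaluationError("pearson_r requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def r2_validation(observed, predicted) -> float:
    """1 - SSE/SST about mean(observed); may be negative on validation data."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    sst = np.sum((obs - obs.mean()) ** 2)
    if sst == 0:
        return float("nan")
    return float(1.0 - np.sum((obs - pred) ** 2) / sst)


def evaluate_predictions(observed, predicted, model_label: str = "model",
                         dataset_label: str = "data") -> EvalReport:
    """Bundle r, r2 and RRMSE for one observed/predicted pairing."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    return EvalReport(model_label=model_label, dataset_label=dataset_label,
                      n=obs.size, r=pearson_r(obs, pred),
                      r2=r2_validation(obs, pred),
                      rrmse_pct=rrmse(obs, pred), residuals=obs - pred)


def split_train_val(df: pd.DataFrame, frac: float = 0.7,
                    seed: int = 0,
                    strata: list[str] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reproducible stratified train/validation split of a record table.

    Rows are shuffled within each stratum (combination of the ``strata``
    columns) and the first round(frac * n_stratum) go to train, so stratum
    proportions are preserved to rounding. Single-member strata go to
    train with a warning. The two frames are disjoint and exhaustive.
    """
    if len(df) < 10:
        raise EvaluationError("split requires n >= 10")
    rng = np.random.default_rng(seed)
    if strata:
        groups = [g for _, g in df.groupby(strata, sort=True)]
    else:
        groups = [df]
    train_idx: list = []
    val_idx: list = []
    for g in groups:
        idx = g.index.to_numpy()
        if len(idx) == 1:
            warnings.warn("stratum with a single member assigned to train",
                          stacklevel=2)
            train_idx.extend(idx)
            continue
        perm = rng.permutation(len(idx))
        n_train = int(round(frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[perm[:n_train]])
        val_idx.extend(idx[perm[n_train:]])
    return df.loc[sorted(train_idx)], df.loc[sorted(val_idx)]


def kfold_cv(fit_predict, X, y, k: int = 10, seed: int = 0,
             model_label: str = "model") -> tuple[list[EvalReport], EvalReport]:
    """k-fold cross-validation of an arbitrary fit/predict procedure.

    ``fit_predict(X_train, y_train, X_test) -> predictions``. Folds are
    disjoint and exhaustive; the pooled report concatenates all held-out
    predictions. ``k`` is reduced (with a warning) when n < k.
    """
    from sklearn.model_selection import KFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise EvaluationError("cv requires n >= 2")
    if n < k:
        warnings.warn(f"reducing folds from {k} to {n}", stacklevel=2)
        k = n
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    pooled_obs = np.empty(n)
    pooled_pred = np.empty(n)
    fold_reports = []
    for fold, (tr, te) in enumerate(kf.split(X)):
        pred = np.asarray(fit_predict(X[tr], y[tr], X[te]), dtype=float)
        pooled_obs[te] = y[te]
        pooled_pred[te] = pred
        fold_reports.append(EvalReport(
            model_label=model_label, dataset_label=f"fold{fold}",
            n=len(te), r=float("nan") if len(te) < 3 else
            pearson_r(y[te], pred),
            r2=r2_validation(y[te], pred), rrmse_pct=rrmse(y[te], pred),
            residuals=y[te] - pred))
    pooled = evaluate_predictions(pooled_obs, pooled_pred,
                                  model_label=model_label,
                                  dataset_label=f"cv{k}-pooled")
    return fold_reports, pooled


def compare_models(reports: list[EvalReport]) -> pd.DataFrame:
    """Comparison table of evaluation reports, best (lowest RRMSE) first.

    Ties are broken by model label for a deterministic ordering.
    """
    df = pd.DataFrame([r.to_dict() for r in reports])
    return (df.sort_values(["rrmse_pct", "model_label"], kind="mergesort")
            .reset_index(drop=True))
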