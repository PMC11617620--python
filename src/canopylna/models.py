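"""Per-layer VI regressions and the vertically stratified canopy estimator.

The modelling chain:

1. For each leaf layer, regress layer LNA on one vegetation index observed
   at one view zenith angle (:class:`LayerLinearRegressor` or
   :class:`LayerRandomForestRegressor`), after screening all (VI, VZA)
   pairs for the strongest correlation (:func:`screen_vi_vza`).
2. Relate each layer's LNA to canopy LNA by an OLS link
   ``LNA_canopy = k * LNA_layer + c`` (:func:`estimate_link`). When all
   three layers are summed, the links are the identity (k=1, c=0).
3. Compose layer models and links into a canopy estimator
   (:class:`CompositeCanopyRegressor`):

       LNA_canopy = sum_i k_i * f_i(VI_i at VZA_i) + intercept

   For all-linear components the composition is itself affine with slope
   k_i * a_i on each VI; intercepts propagate as sum_i k_i * b_i plus,
   under the default ``sum_links`` rule, the link intercepts sum_i c_i.
   This propagation reproduces the printed single-layer canopy models of
   the source coefficient registry; a bare rule ``none`` that drops the
   link intercepts is available.

A non-stratified baseline (one regression of canopy LNA on a single
VI/VZA) is provided for comparison, as is a single multivariate random
forest over the selected per-layer (VI, VZA) features.

All estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
compose with sklearn model selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .evaluation import kfold_cv, pearson_r, rrmse

__all__ = [
    "DegenerateFitError",
    "RFConfig",
    "LayerCanopyLink",
    "LayerLinearRegressor",
    "LayerRandomForestRegressor",
    "CompositeCanopyRegressor",
    "fit_layer_linear",
    "fit_layer_rf",
    "fit_nonstratified",
    "fit_composite_rf",
    "screen_vi_vza",
    "estimate_link",
    "compose_canopy_model",
    "predict_canopy",
    "feature_name",
    "published_registry",
    "composite_to_dict",
    "composite_from_dict",
]

logger = logging.getLogger(__name__)


class DegenerateFitError(ValueError):
    """Raised when a regression target or predictor has zero variance."""


@dataclass(frozen=True)
class RFConfig:
    """Random-forest tuning: 500 trees, one candidate feature per split.

    ``mtry`` follows the square-root-of-p rule; the per-layer models are
    univariate so mtry is 1, and the three-feature composite forest keeps
    mtry = floor(sqrt(3)) = 1.
    """

    ntree: int = 500
    mtry: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1 or self.mtry < 1:
            raise ValueError("ntree and mtry must be >= 1")


@dataclass(frozen=True)
class LayerCanopyLink:
    """OLS link LNA_canopy = k * LNA_layer + c for one layer or aggregate."""

    layer_id: str
    k: float
    c: float
    r2: float = float("nan")


def feature_name(vi_name: str, vza: float) -> str:
    """Column key for one (VI, VZA) feature, e.g. ``NDRE@-30``."""
    return f"{vi_name}@{vza:g}"


def _as_column(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.ndim != 2 or X.shape[1] != 1:
        raise ValueError("layer regressors are univariate; X must be a "
                         "single column")
    return X


class LayerLinearRegressor(RegressorMixin, BaseEstimator):
    """OLS regression of one layer's LNA on one VI at one VZA.

    Parameters
    ----------
    layer_id, vi_name, vza : identification tags carried into composition
        and serialization; not used in fitting.

    Attributes (after fit)
    ----------------------
    slope_, intercept_ : the affine map LNA = slope * VI + intercept.
    r_ : training Pearson correlation (NaN when the target is constant).
    rrmse_pct_ : training relative RMSE in percent.
    """

    model_kind = "linear"

    def __init__(self, layer_id: str | None = None,
                 vi_name: str | None = None, vza: float | None = None):
        self.layer_id = layer_id
        self.vi_name = vi_name
        self.vza = vza

    def fit(self, X, y):
        X = _as_column(X)
        y = np.asarray(y, dtype=float)
        if len(y) < 3:
            raise ValueError("need at least 3 paired observations")
        x = X[:, 0]
        mask = np.isfinite(x) & np.isfinite(y)
        x, y = x[mask], y[mask]
        if len(y) < 3:
            raise ValueError("fewer than 3 finite paired observations")
        if np.ptp(x) == 0:
            raise DegenerateFitError("predictor VI has zero variance")
        slope, intercept = np.polyfit(x, y, 1)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.n_obs_ = int(len(y))
        self.n_features_in_ = 1
        pred = self.slope_ * x + self.intercept_
        self.r_ = pearson_r(x, y) if np.ptp(y) > 0 else float("nan")
        self.rrmse_pct_ = rrmse(y, pred) if y.mean() != 0 else float("nan")
        return self

    @classmethod
    def from_coefficients(cls, slope: float, intercept: float,
                          layer_id: str | None = None,
                          vi_name: str | None = None,
                          vza: float | None = None) -> "LayerLinearRegressor":
        """Build a ready-to-evaluate model from known coefficients."""
        m = cls(layer_id=layer_id, vi_name=vi_name, vza=vza)
        m.slope_ = float(slope)
        m.intercept_ = float(intercept)
        m.n_obs_ = 0
        m.n_features_in_ = 1
        m.r_ = float("nan")
        m.rrmse_pct_ = float("nan")
        return m

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return self.slope_ * _as_column(X)[:, 0] + self.intercept_


class LayerRandomForestRegressor(RegressorMixin, BaseEstimator):
    """Random-forest regression of one layer's LNA on one VI at one VZA.

    Defaults follow the study configuration (500 trees, mtry=1). A k-fold
    cross-validated RRMSE is recorded at fit time as a robustness
    diagnostic (``cv_rrmse_pct_``); set ``cv_folds=0`` to skip it. Forest
    predictions are averages of training targets and therefore stay
    within the training-target range.
    """

    model_kind = "rf"

    def __init__(self, layer_id: str | None = None,
                 vi_name: str | None = None, vza: float | None = None,
                 n_estimators: int = 500, max_features: int = 1,
                 cv_folds: int = 10, random_state: int = 0):
        self.layer_id = layer_id
        self.vi_name = vi_name
        self.vza = vza
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.cv_folds = cv_folds
        self.random_state = random_state

    def _make_forest(self) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            random_state=self.random_state)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        y = np.asarray(y, dtype=float)
        self.n_features_in_ = X.shape[1]
        if self.cv_folds >= 2:
            def fit_predict(Xtr, ytr, Xte):
                return self._make_forest().fit(Xtr, ytr).predict(Xte)
            _, pooled = kfold_cv(fit_predict, X, y, k=self.cv_folds,
                                 seed=self.random_state)
            self.cv_rrmse_pct_ = pooled.rrmse_pct
            self.cv_r_ = pooled.r
        else:
            self.cv_rrmse_pct_ = float("nan")
            self.cv_r_ = float("nan")
        self.forest_ = self._make_forest().fit(X, y)
        pred = self.forest_.predict(X)
        self.r_ = pearson_r(y, pred) if np.ptp(y) > 0 and len(y) >= 3 \
            else float("nan")
        self.rrmse_pct_ = rrmse(y, pred) if y.mean() != 0 else float("nan")
        self.n_obs_ = int(len(y))
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        return self.forest_.predict(X)


class CompositeCanopyRegressor(RegressorMixin, BaseEstimator):
    """Canopy LNA as a link-weighted sum of per-layer models.

    ``components`` is a list of (fitted layer model, LayerCanopyLink)
    pairs, each layer appearing at most once. Prediction on a feature
    frame (columns named by :func:`feature_name`) is

        sum_i k_i * f_i(X[vi_i@vza_i]) + intercept-rule terms

    ``intercept_rule='sum_links'`` (default) adds every link intercept
    c_i; ``'none'`` drops them (the bare weighted-sum reading).
    """

    model_kind = "composite"

    def __init__(self, components=None, intercept_rule: str = "sum_links",
                 provenance: str = "fitted"):
        self.components = components
        self.intercept_rule = intercept_rule
        self.provenance = provenance

    def _validate(self):
        if not self.components:
            raise ValueError("composite requires at least one component")
        if self.intercept_rule not in ("sum_links", "none"):
            raise ValueError(f"unknown intercept_rule {self.intercept_rule!r}")
        seen = set()
        for model, link in self.components:
            if model.layer_id != link.layer_id:
                raise ValueError(
                    f"component layer {model.layer_id!r} does not match "
                    f"link layer {link.layer_id!r}")
            if link.layer_id in seen:
                raise ValueError(f"duplicate layer {link.layer_id!r}")
            seen.add(link.layer_id)

    def fit(self, X=None, y=None):
        """No-op fit: components are fitted upstream; validates structure."""
        self._validate()
        self.n_features_in_ = len(self.components)
        return self

    @property
    def feature_names_(self) -> list[str]:
        return [feature_name(m.vi_name, m.vza) for m, _ in self.components]

    @property
    def is_linear(self) -> bool:
        return all(m.model_kind == "linear" for m, _ in self.components)

    def as_affine(self) -> tuple[dict[str, float], float]:
        """Closed-form (coefficients per feature, intercept); linear only."""
        self._validate()
        if not self.is_linear:
            raise ValueError("closed form only exists for all-linear "
                             "composites")
        coefs: dict[str, float] = {}
        intercept = 0.0
        for model, link in self.components:
            key = feature_name(model.vi_name, model.vza)
            coefs[key] = coefs.get(key, 0.0) + link.k * model.slope_
            intercept += link.k * model.intercept_
            if self.intercept_rule == "sum_links":
                intercept += link.c
        return coefs, intercept

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._validate()
        missing = [f for f in self.feature_names_ if f not in X.columns]
        if missing:
            raise KeyError(f"feature frame missing columns {missing}")
        total = np.zeros(len(X), dtype=float)
        for model, link in self.components:
            vi = X[feature_name(model.vi_name, model.vza)].to_numpy(float)
            total += link.k * model.predict(vi.reshape(-1, 1))
            if self.intercept_rule == "sum_links":
                total += link.c
        return total


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over the estimators)

def fit_layer_linear(vi_values, lna_values, layer_id: str, vi_name: str,
                     vza: float) -> LayerLinearRegressor:
    """OLS fit of one layer's LNA on one VI at one VZA."""
    return LayerLinearRegressor(layer_id=layer_id, vi_name=vi_name,
                                vza=vza).fit(vi_values, lna_values)


def fit_layer_rf(vi_values, lna_values, config: RFConfig | None = None,
                 layer_id: str | None = None, vi_name: str | None = None,
                 vza: float | None = None,
                 cv_folds: int = 10) -> LayerRandomForestRegressor:
    """Random-forest fit of one layer's LNA on one VI at one VZA."""
    config = config or RFConfig()
    return LayerRandomForestRegressor(
        layer_id=layer_id, vi_name=vi_name, vza=vza,
        n_estimators=config.ntree, max_features=config.mtry,
        cv_folds=cv_folds, random_state=config.seed,
    ).fit(vi_values, lna_values)


def fit_nonstratified(vi_values, lna_canopy, model_kind: str = "linear",
                      vi_name: str | None = None, vza: float | None = None,
                      config: RFConfig | None = None, cv_folds: int = 10):
    """Baseline: one canopy-LNA regression on a single VI/VZA, no layers."""
    if model_kind == "linear":
        return fit_layer_linear(vi_values, lna_canopy, "canopy",
                                vi_name, vza)
    if model_kind == "rf":
        return fit_layer_rf(vi_values, lna_canopy, config=config,
                            layer_id="canopy", vi_name=vi_name, vza=vza,
                            cv_folds=cv_folds)
    raise ValueError(f"unknown model_kind {model_kind!r}")


def fit_composite_rf(features: pd.DataFrame, lna_canopy,
                     config: RFConfig | None = None,
                     cv_folds: int = 10) -> LayerRandomForestRegressor:
    """Single multivariate forest on the selected per-layer (VI, VZA) features.

    This is the machine-learning counterpart of the stratified composite:
    the per-layer optimal indices at their optimal angles are fed jointly
    to one forest predicting canopy LNA. Distinct from composing three
    per-layer forests through links (which :func:`compose_canopy_model`
    also supports).
    """
    config = config or RFConfig()
    model = LayerRandomForestRegressor(
        layer_id="canopy", vi_name="+".join(features.columns), vza=None,
        n_estimators=config.ntree, max_features=config.mtry,
        cv_folds=cv_folds, random_state=config.seed)
    model.fit(features.to_numpy(float), np.asarray(lna_canopy, float))
    model.feature_names_in_ = np.asarray(features.columns, dtype=object)
    return model


def estimate_link(lna_layer, lna_canopy, layer_id: str) -> LayerCanopyLink:
    """OLS link of canopy LNA on one layer's LNA."""
    x = np.asarray(lna_layer, dtype=float)
    y = np.asarray(lna_canopy, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise DegenerateFitError("layer LNA has zero variance")
    k, c = np.polyfit(x, y, 1)
    r = pearson_r(x, y) if np.ptp(y) > 0 else float("nan")
    return LayerCanopyLink(layer_id=layer_id, k=float(k), c=float(c),
                           r2=float(r ** 2) if np.isfinite(r) else float("nan"))


def screen_vi_vza(vi_table: pd.DataFrame, lna_table: pd.DataFrame,
                  layer_id: str) -> tuple[pd.DataFrame, dict]:
    """Rank every (VI, VZA) pair by its linear relation to one layer's LNA.

    ``vi_table``: long format (plot_id, stage, vza, vi_name, value).
    ``lna_table``: per-plot layer LNA (plot_id, stage, layer_id, lna), the
    long profile frame from the agronomy module.

    Returns the ranked table (columns vi_name, vza, r, abs_r, rrmse_pct,
    n) and the selected optimum as a dict. Selection maximizes |R|,
    breaking ties by lower RRMSE, then by VI name and VZA for
    determinism.
    """
    lna = lna_table[lna_table["layer_id"] == layer_id]
    merged = vi_table.merge(lna[["plot_id", "stage", "lna"]],
                            on=["plot_id", "stage"], how="inner")
    if merged.empty:
        missing = sorted(set(zip(vi_table["plot_id"], vi_table["stage"]))
                         - set(zip(lna["plot_id"], lna["stage"])))
        raise KeyError(f"no overlap between VI table and layer LNA; VI keys "
                       f"without agronomy: {missing[:10]}")
    rows = []
    for (name, vza), grp in merged.groupby(["vi_name", "vza"], sort=True):
        x = grp["value"].to_numpy(float)
        y = grp["lna"].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.ptp(x) == 0:
            continue
        r = pearson_r(x, y)
        slope, intercept = np.polyfit(x, y, 1)
        rm = rrmse(y, slope * x + intercept)
        rows.append({"vi_name": name, "vza": vza, "r": r,
                     "abs_r": abs(r), "rrmse_pct": rm, "n": len(x)})
    table = (pd.DataFrame(rows)
             .sort_values(["abs_r", "rrmse_pct", "vi_name", "vza"],
                          ascending=[False, True, True, True],
                          kind="mergesort")
             .reset_index(drop=True))
    optimum = table.iloc[0].to_dict()
    return table, optimum


def compose_canopy_model(layer_models, links,
                         intercept_rule: str = "sum_links",
                         provenance: str = "fitted"
                         ) -> CompositeCanopyRegressor:
    """Assemble per-layer models and links into the canopy estimator."""
    links_by_layer = {ln.layer_id: ln for ln in links}
    if len(links_by_layer) != len(links):
        raise ValueError("duplicate layer in links")
    components = []
    for model in layer_models:
        if model.layer_id not in links_by_layer:
            raise ValueError(f"no link supplied for layer {model.layer_id!r}")
        components.append((model, links_by_layer[model.layer_id]))
    return CompositeCanopyRegressor(components=components,
                                    intercept_rule=intercept_rule,
                                    provenance=provenance).fit()


def predict_canopy(composite: CompositeCanopyRegressor,
                   vi_table: pd.DataFrame) -> pd.DataFrame:
    """Per-plot canopy LNA predictions from a long VI table.

    Plots missing any component (VI, VZA) are skipped and counted in the
    log. Negative predictions are retained but flagged in the
    ``negative`` column.
    """
    wide = vi_table.copy()
    wide["feature"] = [feature_name(n, z) for n, z
                       in zip(wide["vi_name"], wide["vza"])]
    wide = wide.pivot_table(index=["plot_id", "stage"], columns="feature",
                            values="value", aggfunc="first")
    needed = composite.feature_names_
    have = [f for f in needed if f in wide.columns]
    if len(have) < len(needed):
        raise KeyError(f"VI table lacks features "
                       f"{sorted(set(needed) - set(have))}")
    complete = wide.dropna(subset=needed)
    n_skipped = len(wide) - len(complete)
    if n_skipped:
        logger.info("predict_canopy: skipped %d plot-stage records missing "
                    "component VIs", n_skipped)
    pred = composite.predict(complete)
    out = complete.reset_index()[["plot_id", "stage"]]
    out["lna_canopy_pred"] = pred
    out["negative"] = pred < 0
    out.attrs["n_skipped"] = n_skipped
    return out


# ---------------------------------------------------------------------------
# published coefficient registry

@dataclass(frozen=True)
class PublishedRegistry:
    """Printed layer-canopy links, canopy composites and layer slopes."""

    links: dict[str, LayerCanopyLink]
    composites: dict[str, CompositeCanopyRegressor]
    layer_reri_slopes: dict[str, float]
    nonstratified_reri_slopes: dict[float, float]
    layer_optima: dict[str, dict]


def _published_composite(terms, intercept) -> CompositeCanopyRegressor:
    """Composite whose affine form equals printed canopy coefficients.

    ``terms``: list of (layer_id, vi_name, vza, canopy_slope). The printed
    intercept is attached to the first component's layer model so the
    identity links (k=1, c=0) reproduce the row exactly.
    """
    components = []
    for j, (layer, vi_name, vza, slope) in enumerate(terms):
        model = LayerLinearRegressor.from_coefficients(
            slope, intercept if j == 0 else 0.0,
            layer_id=layer, vi_name=vi_name, vza=vza)
        components.append((model, LayerCanopyLink(layer, k=1.0, c=0.0)))
    return CompositeCanopyRegressor(components=components,
                                    intercept_rule="sum_links",
                                    provenance="published").fit()


def published_registry() -> PublishedRegistry:
    """Ready-to-evaluate objects holding the printed model coefficients.

    Links: canopy LNA regressed on each layer/aggregate LNA. Composites:
    the printed canopy estimation rows keyed by the layer scheme they
    stratify over ("1st".."5th", "sum"). Also the per-layer RERI_730
    slopes (upper/middle/lower: 6.39, 5.68, 3.06), the non-stratified
    RERI_730 canopy slopes per VZA, and the screened per-layer optima
    (VI, VZA, R, RRMSE%).
    """
    links = {
        "1st": LayerCanopyLink("1st", k=1.36, c=1.12, r2=0.78),
        "2nd": LayerCanopyLink("2nd", k=2.34, c=0.48, r2=0.84),
        "3rd": LayerCanopyLink("3rd", k=3.61, c=0.91, r2=0.73),
        "4th": LayerCanopyLink("4th", k=1.15, c=0.10, r2=0.95),
        "5th": LayerCanopyLink("5th", k=1.37, c=0.95, r2=0.68),
    }
    composites = {
        "1st": _published_composite([("1st", "EVI", 0, 8.75)], -0.09),
        "2nd": _published_composite([("2nd", "RERI_730", -30, 13.29)], -1.88),
        "3rd": _published_composite([("3rd", "NDRE", -45, 18.30)], 0.62),
        "4th": _published_composite(
            [("1st", "EVI", 0, 8.75), ("2nd", "RERI_730", -30, 13.29)],
            -1.97),
        "5th": _published_composite(
            [("2nd", "RERI_730", -30, 13.29), ("3rd", "NDRE", -45, 18.30)],
            -1.26),
        "sum": _published_composite(
            [("1st", "NDRE", 0, 16.04), ("2nd", "NDRE", -30, 21.86),
             ("3rd", "NDRE", -45, 18.30)], 1.76),
    }
    return PublishedRegistry(
        links=links,
        composites=composites,
        layer_reri_slopes={"1st": 6.39, "2nd": 5.68, "3rd": 3.06},
        nonstratified_reri_slopes={0: 16.96, -30: 14.62, -45: 14.03},
        layer_optima={
            "1st": {"vi_name": "EVI", "vza": 0, "r": 0.88,
                    "rrmse_pct": 18.3},
            "2nd": {"vi_name": "RERI_730", "vza": -30, "r": 0.90,
                    "rrmse_pct": 18.1},
            "3rd": {"vi_name": "NDRE", "vza": -45, "r": 0.91,
                    "rrmse_pct": 18.4},
            "canopy": {"vi_name": "RERI_730", "vza": -30, "r": 0.89,
                       "rrmse_pct": 23.4},
        })


# ---------------------------------------------------------------------------
# serialization of linear composites

def composite_to_dict(composite: CompositeCanopyRegressor) -> dict:
    """JSON-ready dict of an all-linear composite (coefficients + tags)."""
    if not composite.is_linear:
        raise ValueError("only all-linear composites serialize to JSON; "
                         "persist forest components separately")
    return {
        "intercept_rule": composite.intercept_rule,
        "provenance": composite.provenance,
        "components": [
            {"layer_id": m.layer_id, "vi_name": m.vi_name, "vza": m.vza,
             "slope": m.slope_, "intercept": m.intercept_,
             "k": ln.k, "c": ln.c, "r2": ln.r2}
            for m, ln in composite.components],
    }


def composite_from_dict(payload: dict) -> CompositeCanopyRegressor:
    components = []
    for comp in payload["components"]:
        model = LayerLinearRegressor.from_coefficients(
            comp["slope"], comp["intercept"], layer_id=comp["layer_id"],
            vi_name=comp["vi_name"], vza=comp["vza"])
        components.append((model, LayerCanopyLink(
            comp["layer_id"], k=comp["k"], c=comp["c"],
            r2=comp.get("r2", float("nan")))))
    return CompositeCanopyRegressor(
        components=components,
        intercept_rule=payload.get("intercept_rule", "sum_links"),
        provenance=payload.get("provenance", "fitted")).fit()


def save_composites(composites: dict[str, CompositeCanopyRegressor],
                    path) -> None:
    with open(path, "w") as fh:
        json.dump({k: composite_to_dict(v) for k, v in composites.items()},
                  fh, indent=2)


def load_composites(path) -> dict[str, CompositeCanopyRegressor]:
    with open(path) as fh:
        return {k: composite_from_dict(v) for k, v in json.load(fh).items()}
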