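"""End-to-end orchestration: screen, fit, link, compose, validate.

These helpers run the full stratified workflow on the long tables the
agronomy and VI modules produce (and that the synthetic generator emits
in the same schema):

* :func:`fit_lna_sum` - the stratified canopy estimator: per-layer
  (VI, VZA) screening, per-layer regression, identity links for the
  three-layer sum, composition.
* :func:`fit_lna_non` - the non-stratified baseline: one canopy
  regression per VZA on that angle's best index.
* :func:`run_comparison` - 70/30 train/validation comparison of the
  stratified and non-stratified estimators (linear and random forest),
  mirroring a standard model-intercomparison report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import EvalReport, evaluate_predictions, split_train_val
from .models import (CompositeCanopyRegressor, LayerCanopyLink,
                     LayerRandomForestRegressor, RFConfig, feature_name,
                     fit_composite_rf, fit_layer_linear, fit_layer_rf,
                     fit_nonstratified, compose_canopy_model, screen_vi_vza)

__all__ = [
    "StratifiedFit",
    "fit_lna_sum",
    "fit_lna_non",
    "features_frame",
    "run_comparison",
]

SUM_LAYERS = ("1st", "2nd", "3rd")


@dataclass
class StratifiedFit:
    """Everything the stratified fit produced, for inspection and reuse."""

    composite: CompositeCanopyRegressor
    layer_models: list
    links: list[LayerCanopyLink]
    selections: dict[str, dict]
    screening: dict[str, pd.DataFrame] = field(default_factory=dict)
    rf_composite: LayerRandomForestRegressor | None = None


def _layer_pairs(profile_frame: pd.DataFrame, vi_table: pd.DataFrame,
                 layer_id: str, vi_name: str, vza: float) -> pd.DataFrame:
    lna = profile_frame[profile_frame["layer_id"] == layer_id]
    vi = vi_table[(vi_table["vi_name"] == vi_name)
                  & (vi_table["vza"] == vza)]
    return vi.merge(lna[["plot_id", "stage", "lna"]],
                    on=["plot_id", "stage"], how="inner")


def features_frame(vi_table: pd.DataFrame,
                   selections: list[tuple[str, float]]) -> pd.DataFrame:
    """Wide per-plot frame of the selected (VI, VZA) features.

    Indexed by (plot_id, stage); rows missing any feature are dropped.
    """
    sub = vi_table.copy()
    sub["feature"] = [feature_name(n, z)
                      for n, z in zip(sub["vi_name"], sub["vza"])]
    wanted = [feature_name(n, z) for n, z in selections]
    wide = (sub[sub["feature"].isin(wanted)]
            .pivot_table(index=["plot_id", "stage"], columns="feature",
                         values="value", aggfunc="first"))
    return wide.dropna(subset=[w for w in wanted if w in wide.columns])


def fit_lna_sum(profile_frame: pd.DataFrame, vi_table: pd.DataFrame,
                model_kind: str = "linear",
                composition: str = "per_layer_optimal",
                vi_name: str | None = None,
                vza_by_layer: dict[str, float] | None = None,
                rf_config: RFConfig | None = None,
                cv_folds: int = 0) -> StratifiedFit:
    """Fit the three-layer stratified canopy estimator.

    ``composition='per_layer_optimal'`` screens each layer over the full
    (VI, VZA) grid; ``'single_vi_all_layers'`` uses ``vi_name`` at the
    angle assigned to each layer (default: upper at nadir, middle at
    -30 deg, lower at -45 deg - the visibility ordering). The three-layer
    sum uses identity links (k=1, c=0). For ``model_kind='rf'`` the
    per-layer forests are composed through the same links, and a single
    multivariate forest over the three selected features is fitted as
    well (``rf_composite``).
    """
    if composition not in ("per_layer_optimal", "single_vi_all_layers"):
        raise ValueError(f"unknown composition {composition!r}")
    vza_by_layer = vza_by_layer or {"1st": 0, "2nd": -30, "3rd": -45}

    selections: dict[str, dict] = {}
    screening: dict[str, pd.DataFrame] = {}
    for lid in SUM_LAYERS:
        if composition == "per_layer_optimal":
            table, optimum = screen_vi_vza(vi_table, profile_frame, lid)
            screening[lid] = table
            selections[lid] = {"vi_name": optimum["vi_name"],
                               "vza": optimum["vza"]}
        else:
            if vi_name is None:
                raise ValueError("single_vi_all_layers needs vi_name")
            selections[lid] = {"vi_name": vi_name,
                               "vza": vza_by_layer[lid]}

    layer_models = []
    for lid in SUM_LAYERS:
        sel = selections[lid]
        pairs = _layer_pairs(profile_frame, vi_table, lid,
                             sel["vi_name"], sel["vza"])
        x = pairs["value"].to_numpy(float)
        y = pairs["lna"].to_numpy(float)
        if model_kind == "linear":
            layer_models.append(fit_layer_linear(x, y, lid,
                                                 sel["vi_name"],
                                                 sel["vza"]))
        elif model_kind == "rf":
            layer_models.append(fit_layer_rf(x, y, config=rf_config,
                                             layer_id=lid,
                                             vi_name=sel["vi_name"],
                                             vza=sel["vza"],
                                             cv_folds=cv_folds))
        else:
            raise ValueError(f"unknown model_kind {model_kind!r}")

    links = [LayerCanopyLink(lid, k=1.0, c=0.0) for lid in SUM_LAYERS]
    composite = compose_canopy_model(layer_models, links)

    rf_composite = None
    if model_kind == "rf":
        feats = features_frame(
            vi_table, [(selections[lid]["vi_name"], selections[lid]["vza"])
                       for lid in SUM_LAYERS])
        canopy = (profile_frame[profile_frame["layer_id"] == "canopy"]
                  .set_index(["plot_id", "stage"])["lna"]
                  .reindex(feats.index))
        rf_composite = fit_composite_rf(feats, canopy.to_numpy(float),
                                        config=rf_config,
                                        cv_folds=cv_folds)

    return StratifiedFit(composite=composite, layer_models=layer_models,
                         links=links, selections=selections,
                         screening=screening, rf_composite=rf_composite)


def fit_lna_non(profile_frame: pd.DataFrame, vi_table: pd.DataFrame,
                vza: float, model_kind: str = "linear",
                rf_config: RFConfig | None = None, cv_folds: int = 0):
    """Non-stratified baseline at one VZA: canopy LNA on that angle's
    best-screening index. Returns (model, selection dict)."""
    sub = vi_table[vi_table["vza"] == vza]
    table, optimum = screen_vi_vza(sub, profile_frame, "canopy")
    pairs = _layer_pairs(profile_frame, vi_table, "canopy",
                         optimum["vi_name"], vza)
    model = fit_nonstratified(
        pairs["value"].to_numpy(float), pairs["lna"].to_numpy(float),
        model_kind=model_kind, vi_name=optimum["vi_name"], vza=vza,
        config=rf_config, cv_folds=cv_folds)
    return model, {"vi_name": optimum["vi_name"], "vza": vza,
                   "screening": table}


def _subset_by_keys(df: pd.DataFrame, keys: pd.DataFrame) -> pd.DataFrame:
    idx = pd.MultiIndex.from_frame(keys[["plot_id", "stage"]])
    mask = pd.MultiIndex.from_arrays([df["plot_id"], df["stage"]]).isin(idx)
    return df[mask]


def run_comparison(profile_frame: pd.DataFrame, vi_table: pd.DataFrame,
                   split_seed: int = 0, frac: float = 0.7,
                   model_kinds: tuple[str, ...] = ("linear", "rf"),
                   rf_config: RFConfig | None = None,
                   cv_folds: int = 0) -> dict[str, EvalReport]:
    """Train/validate the stratified vs non-stratified estimators.

    Records (plot x stage) are split 70/30, stratified by stage and
    nitrogen treatment. Returns validation reports keyed by
    ``LR-LNA_Sum``, ``LR-LNA_non`` (best single VZA), ``RF-LNA_Sum`` (the
    multivariate forest) and ``RF-LNA_non``, as requested via
    ``model_kinds``; per-VZA baselines appear as ``LR-LNA_non@<vza>``.
    """
    records = (profile_frame[profile_frame["layer_id"] == "canopy"]
               [["plot_id", "stage", "n_treatment", "lna"]]
               .reset_index(drop=True))
    train_keys, val_keys = split_train_val(records, frac=frac,
                                           seed=split_seed,
                                           strata=["stage", "n_treatment"])
    prof_tr = _subset_by_keys(profile_frame, train_keys)
    prof_va = _subset_by_keys(profile_frame, val_keys)
    vi_tr = _subset_by_keys(vi_table, train_keys)
    vi_va = _subset_by_keys(vi_table, val_keys)

    canopy_val = (prof_va[prof_va["layer_id"] == "canopy"]
                  .set_index(["plot_id", "stage"])["lna"])
    vzas = sorted(vi_table["vza"].unique(), reverse=True)
    reports: dict[str, EvalReport] = {}

    for kind in model_kinds:
        prefix = "LR" if kind == "linear" else "RF"
        fit = fit_lna_sum(prof_tr, vi_tr, model_kind=kind,
                          rf_config=rf_config, cv_folds=cv_folds)
        sels = [(fit.selections[lid]["vi_name"], fit.selections[lid]["vza"])
                for lid in SUM_LAYERS]
        feats_va = features_frame(vi_va, sels)
        obs = canopy_val.reindex(feats_va.index).to_numpy(float)
        if kind == "rf" and fit.rf_composite is not None:
            cols = list(fit.rf_composite.feature_names_in_)
            pred = fit.rf_composite.predict(feats_va[cols].to_numpy(float))
        else:
            pred = fit.composite.predict(feats_va)
        reports[f"{prefix}-LNA_Sum"] = evaluate_predictions(
            obs, pred, model_label=f"{prefix}-LNA_Sum",
            dataset_label="validation")

        best = None
        for vza in vzas:
            model, sel = fit_lna_non(prof_tr, vi_tr, vza, model_kind=kind,
                                     rf_config=rf_config, cv_folds=cv_folds)
            feats = features_frame(vi_va, [(sel["vi_name"], vza)])
            obs_n = canopy_val.reindex(feats.index).to_numpy(float)
            pred_n = model.predict(
                feats[feature_name(sel["vi_name"], vza)]
                .to_numpy(float).reshape(-1, 1))
            rep = evaluate_predictions(
                obs_n, pred_n, model_label=f"{prefix}-LNA_non@{vza:g}",
                dataset_label="validation")
            reports[f"{prefix}-LNA_non@{vza:g}"] = rep
            if best is None or rep.rrmse_pct < best.rrmse_pct:
                best = rep
        assert best is not None
        reports[f"{prefix}-LNA_non"] = EvalReport(
            model_label=f"{prefix}-LNA_non", dataset_label="validation",
            n=best.n, r=best.r, r2=best.r2, rrmse_pct=best.rrmse_pct,
            residuals=best.residuals)
    return reports
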