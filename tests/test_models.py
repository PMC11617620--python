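import numpy as np
import pandas as pd
import pytest

from canopylna.models import (CompositeCanopyRegressor, DegenerateFitError,
                              LayerCanopyLink, LayerLinearRegressor,
                              RFConfig, compose_canopy_model,
                              composite_from_dict, composite_to_dict,
                              estimate_link, feature_name, fit_layer_linear,
                              fit_layer_rf, fit_nonstratified,
                              predict_canopy, published_registry,
                              screen_vi_vza)

from conftest import make_vi_table


class TestLayerLinear:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(0, 1, 10)
        m = fit_layer_linear(x, 2 * x + 1, "1st", "NDRE", 0)
        assert m.slope_ == pytest.approx(2.0)
        assert m.intercept_ == pytest.approx(1.0)
        assert m.rrmse_pct_ == pytest.approx(0.0, abs=1e-10)

    def test_constant_target_flags_undefined_correlation(self):
        m = fit_layer_linear(np.arange(5.0), np.ones(5), "1st", "NDRE", 0)
        assert np.isnan(m.r_)
        assert m.slope_ == pytest.approx(0.0)

    def test_zero_predictor_variance_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_layer_linear(np.ones(5), np.arange(5.0), "1st", "NDRE", 0)

    def test_slope_within_sampling_error_of_planted_value(self):
        """OLS sampling-theory oracle: with known noise the fitted slope
        lies within 3 standard errors of the generating slope."""
        rng = np.random.default_rng(11)
        n, slope, intercept, sigma = 200, 5.68, -1.0, 0.4
        x = rng.uniform(0.2, 1.2, n)
        y = slope * x + intercept + rng.normal(0, sigma, n)
        m = fit_layer_linear(x, y, "2nd", "RERI_730", -30)
        resid = y - m.predict(x)
        se = np.sqrt(np.sum(resid**2) / (n - 2)
                     / np.sum((x - x.mean()) ** 2))
        assert abs(m.slope_ - slope) < 3 * se

    def test_sklearn_param_protocol(self):
        m = LayerLinearRegressor(layer_id="1st", vi_name="EVI", vza=0)
        assert m.get_params()["vi_name"] == "EVI"
        m.set_params(vza=-30)
        assert m.vza == -30


class TestLayerRandomForest:
    def make_data(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, n)
        return x, 3 * x + rng.normal(0, 0.3, n)

    def test_deterministic_under_fixed_seed(self):
        x, y = self.make_data()
        m1 = fit_layer_rf(x, y, RFConfig(seed=3), "1st", "NDRE", 0)
        m2 = fit_layer_rf(x, y, RFConfig(seed=3), "1st", "NDRE", 0)
        assert m1.cv_rrmse_pct_ == m2.cv_rrmse_pct_
        assert np.array_equal(m1.predict(x), m2.predict(x))

    def test_constant_target_predicts_constant(self):
        x = np.linspace(0, 1, 15)
        m = fit_layer_rf(x, np.full(15, 2.5), cv_folds=0)
        assert np.allclose(m.predict(x), 2.5)

    def test_predictions_bounded_by_training_targets(self):
        x, y = self.make_data()
        m = fit_layer_rf(x, y, cv_folds=0)
        pred = m.predict(np.linspace(-5, 5, 50))
        assert pred.min() >= y.min() - 1e-12
        assert pred.max() <= y.max() + 1e-12

    def test_training_error_not_above_cv_error(self):
        x, y = self.make_data(n=60, seed=5)
        m = fit_layer_rf(x, y, cv_folds=10)
        assert m.rrmse_pct_ <= m.cv_rrmse_pct_

    def test_study_defaults(self):
        cfg = RFConfig()
        assert (cfg.ntree, cfg.mtry) == (500, 1)


class TestEstimateLink:
    def test_identity_link(self):
        x = np.linspace(1, 5, 10)
        link = estimate_link(x, x, "1st")
        assert link.k == pytest.approx(1.0)
        assert link.c == pytest.approx(0.0, abs=1e-12)
        assert link.r2 == pytest.approx(1.0)

    def test_planted_link_recovered_exactly_without_noise(self):
        x = np.linspace(0.5, 3.0, 20)
        link = estimate_link(x, 2.34 * x + 0.48, "2nd")
        assert link.k == pytest.approx(2.34)
        assert link.c == pytest.approx(0.48)

    def test_noisy_link_within_sampling_error(self):
        rng = np.random.default_rng(21)
        n, k, c = 200, 2.34, 0.48
        x = rng.uniform(0.5, 3.0, n)
        y = k * x + c + rng.normal(0, 0.3, n)
        link = estimate_link(x, y, "2nd")
        resid = y - (link.k * x + link.c)
        se = np.sqrt(np.sum(resid**2) / (n - 2)
                     / np.sum((x - x.mean()) ** 2))
        assert abs(link.k - k) < 3 * se

    def test_zero_layer_variance_raises(self):
        with pytest.raises(DegenerateFitError):
            estimate_link(np.ones(5), np.arange(5.0), "2nd")


class TestComposition:
    def test_middle_layer_scaling_reproduces_printed_canopy_slope(self):
        layer = LayerLinearRegressor.from_coefficients(
            5.68, 0.0, layer_id="2nd", vi_name="RERI_730", vza=-30)
        comp = compose_canopy_model(
            [layer], [LayerCanopyLink("2nd", k=2.34, c=0.48)])
        coefs, _ = comp.as_affine()
        assert round(coefs["RERI_730@-30"], 2) == 13.29

    def test_identity_link_reduces_to_layer_model(self):
        layer = LayerLinearRegressor.from_coefficients(
            2.0, 0.5, layer_id="1st", vi_name="NDRE", vza=0)
        comp = compose_canopy_model([layer],
                                    [LayerCanopyLink("1st", k=1.0, c=0.0)])
        X = pd.DataFrame({"NDRE@0": np.linspace(0, 1, 7)})
        assert np.allclose(comp.predict(X),
                           layer.predict(X["NDRE@0"].to_numpy()))

    def test_duplicate_layer_rejected(self):
        layer = LayerLinearRegressor.from_coefficients(
            1.0, 0.0, layer_id="1st", vi_name="NDRE", vza=0)
        with pytest.raises(ValueError, match="duplicate"):
            CompositeCanopyRegressor(components=[
                (layer, LayerCanopyLink("1st", 1.0, 0.0)),
                (layer, LayerCanopyLink("1st", 1.0, 0.0))]).fit()

    def test_numeric_prediction_equals_closed_form(self, rng):
        layers = [
            LayerLinearRegressor.from_coefficients(
                a, b, layer_id=lid, vi_name=vi, vza=vza)
            for a, b, lid, vi, vza in [
                (6.39, -0.2, "1st", "EVI", 0),
                (5.68, -1.0, "2nd", "RERI_730", -30),
                (3.06, 0.1, "3rd", "NDRE", -45)]]
        links = [LayerCanopyLink("1st", 1.36, 1.12),
                 LayerCanopyLink("2nd", 2.34, 0.48),
                 LayerCanopyLink("3rd", 3.61, 0.91)]
        comp = compose_canopy_model(layers, links)
        X = pd.DataFrame({feature_name(m.vi_name, m.vza):
                          rng.uniform(0, 1, 25) for m in layers})
        coefs, intercept = comp.as_affine()
        closed = sum(coefs[f] * X[f].to_numpy() for f in coefs) + intercept
        assert np.allclose(comp.predict(X), closed, atol=1e-10)

    def test_three_layer_sum_equals_sum_of_layer_predictions(self, rng):
        layers = [LayerLinearRegressor.from_coefficients(
            s, b, layer_id=lid, vi_name="NDRE", vza=vza)
            for s, b, lid, vza in [(16.04, 0.3, "1st", 0),
                                   (21.86, 0.1, "2nd", -30),
                                   (18.30, -0.2, "3rd", -45)]]
        links = [LayerCanopyLink(lid, 1.0, 0.0)
                 for lid in ("1st", "2nd", "3rd")]
        comp = compose_canopy_model(layers, links)
        X = pd.DataFrame({feature_name("NDRE", z): rng.uniform(0, 0.8, 10)
                          for z in (0, -30, -45)})
        parts = sum(m.predict(X[feature_name("NDRE", m.vza)].to_numpy())
                    for m in layers)
        assert np.allclose(comp.predict(X), parts)

    def test_intercept_rule_none_drops_link_intercepts(self):
        layer = LayerLinearRegressor.from_coefficients(
            5.68, -1.0, layer_id="2nd", vi_name="RERI_730", vza=-30)
        link = LayerCanopyLink("2nd", 2.34, 0.48)
        with_links = compose_canopy_model([layer], [link]).as_affine()[1]
        bare = compose_canopy_model([layer], [link],
                                    intercept_rule="none").as_affine()[1]
        assert with_links == pytest.approx(bare + 0.48)


class TestPublishedRegistry:
    def test_layer_links(self):
        reg = published_registry()
        link = reg.links["1st"]
        assert (link.k, link.c, link.r2) == (1.36, 1.12, 0.78)
        assert reg.links["2nd"].k == 2.34

    def test_sum_composite_coefficients(self):
        coefs, intercept = published_registry().composites["sum"].as_affine()
        assert coefs == {"NDRE@0": 16.04, "NDRE@-30": 21.86,
                         "NDRE@-45": 18.30}
        assert intercept == pytest.approx(1.76)

    def test_layer_reri_slopes(self):
        slopes = published_registry().layer_reri_slopes
        assert [slopes[k] for k in ("1st", "2nd", "3rd")] == \
            [6.39, 5.68, 3.06]

    def test_upper_middle_composite_is_sum_of_single_layer_rows(self):
        """Internal consistency of the printed table: the two-layer
        composites equal the sums of their single-layer rows."""
        reg = published_registry()
        c1, i1 = reg.composites["1st"].as_affine()
        c2, i2 = reg.composites["2nd"].as_affine()
        c4, i4 = reg.composites["4th"].as_affine()
        assert c4 == {**c1, **c2}
        assert i4 == pytest.approx(i1 + i2)  # -0.09 + -1.88 = -1.97
        _, i3 = reg.composites["3rd"].as_affine()
        _, i5 = reg.composites["5th"].as_affine()
        assert i5 == pytest.approx(i2 + i3)  # -1.88 + 0.62 = -1.26


class TestPredictCanopy:
    def make_composite(self):
        return published_registry().composites["sum"]

    def test_zero_vis_return_intercept(self):
        table = make_vi_table([("p1", "s", z, "NDRE", 0.0)
                               for z in (0, -30, -45)])
        out = predict_canopy(self.make_composite(), table)
        assert out["lna_canopy_pred"].iloc[0] == pytest.approx(1.76)

    def test_hand_computed_example(self):
        vals = {0: 0.2, -30: 0.25, -45: 0.3}
        table = make_vi_table([("p1", "s", z, "NDRE", v)
                               for z, v in vals.items()])
        expected = 16.04 * 0.2 + 21.86 * 0.25 + 18.30 * 0.3 + 1.76
        out = predict_canopy(self.make_composite(), table)
        assert out["lna_canopy_pred"].iloc[0] == pytest.approx(expected)

    def test_plot_missing_an_angle_is_skipped_and_counted(self):
        rows = [("p1", "s", z, "NDRE", 0.2) for z in (0, -30, -45)]
        rows += [("p2", "s", z, "NDRE", 0.2) for z in (0, -30)]  # no -45
        out = predict_canopy(self.make_composite(), make_vi_table(rows))
        assert list(out["plot_id"]) == ["p1"]
        assert out.attrs["n_skipped"] == 1

    def test_negative_predictions_flagged_not_clipped(self):
        comp = published_registry().composites["2nd"]  # intercept -1.88
        table = make_vi_table([("p1", "s", -30, "RERI_730", 0.0)])
        out = predict_canopy(comp, table)
        assert out["lna_canopy_pred"].iloc[0] == pytest.approx(-1.88)
        assert bool(out["negative"].iloc[0])


class TestScreening:
    def lna_table(self, plots, values):
        return pd.DataFrame({"plot_id": plots,
                             "stage": ["s"] * len(plots),
                             "layer_id": ["1st"] * len(plots),
                             "lna": values})

    def test_planted_noiseless_pair_selected(self, rng):
        plots = [f"p{i}" for i in range(12)]
        lna = rng.uniform(1, 3, 12)
        rows = []
        for p, l in zip(plots, lna):
            rows.append((p, "s", 0, "NDRE", 0.1 + 0.2 * l))  # exact line
            rows.append((p, "s", -30, "NDRE",
                         0.1 + 0.2 * l + rng.normal(0, 0.2)))
            rows.append((p, "s", 0, "EVI", rng.uniform(0, 1)))
        table, optimum = screen_vi_vza(make_vi_table(rows),
                                       self.lna_table(plots, lna), "1st")
        assert (optimum["vi_name"], optimum["vza"]) == ("NDRE", 0)
        assert optimum["abs_r"] == pytest.approx(1.0)

    def test_tie_broken_by_lower_rrmse(self):
        plots = [f"p{i}" for i in range(6)]
        lna = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5])
        rows = []
        for p, l in zip(plots, lna):
            rows.append((p, "s", 0, "A", l))        # |R|=1, RRMSE=0
            rows.append((p, "s", 0, "B", -2 * l))   # |R|=1, RRMSE=0 too
        # both perfect: falls through to lexicographic name order
        _, optimum = screen_vi_vza(make_vi_table(rows),
                                   self.lna_table(plots, lna), "1st")
        assert optimum["vi_name"] == "A"

    def test_ranking_matches_brute_force(self, small_dataset):
        profile_frame, vi_table, _ = small_dataset
        table, _ = screen_vi_vza(vi_table, profile_frame, "2nd")
        lna = (profile_frame[profile_frame.layer_id == "2nd"]
               .set_index(["plot_id", "stage"])["lna"])
        for _, row in table.iterrows():
            sub = vi_table[(vi_table.vi_name == row["vi_name"])
                           & (vi_table.vza == row["vza"])]
            y = lna.loc[list(zip(sub.plot_id, sub.stage))].to_numpy()
            x = sub["value"].to_numpy()
            assert row["r"] == pytest.approx(np.corrcoef(x, y)[0, 1])
        assert (table["abs_r"].to_numpy()[:-1]
                >= table["abs_r"].to_numpy()[1:] - 1e-12).all()

    def test_disjoint_tables_raise_join_error(self):
        rows = [("pX", "s", 0, "NDRE", 0.5)] * 3
        with pytest.raises(KeyError, match="no overlap"):
            screen_vi_vza(make_vi_table(rows),
                          self.lna_table(["pA", "pB", "pC"], [1, 2, 3]),
                          "1st")


class TestNonStratified:
    def test_noiseless_canopy_recovery(self):
        x = np.linspace(0.1, 0.9, 12)
        m = fit_nonstratified(x, 14.62 * x - 1.5, model_kind="linear",
                              vi_name="RERI_730", vza=-30)
        assert m.layer_id == "canopy"
        assert m.slope_ == pytest.approx(14.62)

    def test_rf_variant_deterministic(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 30)
        y = 10 * x + rng.normal(0, 0.5, 30)
        m1 = fit_nonstratified(x, y, "rf", config=RFConfig(seed=2),
                               cv_folds=0)
        m2 = fit_nonstratified(x, y, "rf", config=RFConfig(seed=2),
                               cv_folds=0)
        assert np.array_equal(m1.predict(x), m2.predict(x))


class TestSerialization:
    def test_linear_composite_round_trip(self, tmp_path, rng):
        comp = published_registry().composites["sum"]
        again = composite_from_dict(composite_to_dict(comp))
        X = pd.DataFrame({f: rng.uniform(0, 1, 8)
                          for f in comp.feature_names_})
        assert np.allclose(comp.predict(X), again.predict(X))
        assert again.provenance == "published"
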