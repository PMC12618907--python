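"""MaxEnt core: features, penalized Gibbs fit, prediction."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import riskpipe as rp
from riskpipe import synthetic as syn
from riskpipe.maxent import build_features, occurrence_predictor_table


@pytest.fixture(scope="module")
def binary_problem():
    rng = np.random.default_rng(0)
    fb = (rng.random((400, 1)) < 0.3).astype(float)
    fp = (rng.random((50, 1)) < 0.7).astype(float)
    return fp, fb


class TestFeatures:
    def test_lq_feature_count(self, rng):
        fs = build_features(rng.random((100, 3)), classes="LQ")
        assert len(fs) == 6

    def test_lqhp_feature_count_with_ten_knots(self, rng):
        fs = build_features(rng.random((100, 3)), classes="LQHP", n_hinge_knots=10)
        # 3 linear + 3 quadratic + C(3,2) products + 3 vars * 2 dirs * 10 knots
        assert len(fs) == 3 + 3 + 3 + 60

    def test_all_features_scaled_to_unit_interval(self, rng):
        x = rng.standard_normal((200, 3)) * 7 + 3
        fs = build_features(x, classes="LQHP", n_hinge_knots=5)
        f = fs.transform(x)
        assert f.min() >= 0.0 and f.max() <= 1.0

    def test_hinge_value_matches_formula(self, rng):
        x = rng.random((300, 1)) * 10
        fs = build_features(x, classes="H", n_hinge_knots=4)
        f = fs.transform(x)
        for j, d in enumerate(fs.definitions):
            if d.direction == "forward":
                expected = np.maximum(0, x[:, 0] - d.knot) / (x[:, 0].max() - d.knot)
            else:
                expected = np.maximum(0, d.knot - x[:, 0]) / (d.knot - x[:, 0].min())
            np.testing.assert_allclose(f[:, j], np.clip(expected, 0, 1), atol=1e-12)

    def test_hinge_knots_strictly_inside_range(self, rng):
        x = rng.random((300, 2))
        fs = build_features(x, classes="LQH", n_hinge_knots=20)
        for d in fs.definitions:
            if d.kind == "hinge":
                v = d.variables[0]
                assert fs.var_min[v] < d.knot < fs.var_max[v]

    def test_unknown_class_token_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            build_features(rng.random((10, 2)), classes="LX")

    def test_products_need_two_variables(self, rng):
        with pytest.raises(ValueError, match="2 variables"):
            build_features(rng.random((10, 1)), classes="P")


class TestFit:
    def test_binary_feature_matches_closed_form(self, binary_problem):
        fp, fb = binary_problem
        p_bar, b_bar = fp.mean(), fb.mean()
        lam_true = np.log(p_bar * (1 - b_bar) / ((1 - p_bar) * b_bar))
        model = rp.fit(fp, fb, reg_multiplier=0.0, tol=1e-12)
        assert model.lambdas[0] == pytest.approx(lam_true, abs=1e-6)

    def test_two_binary_features_match_moment_equations(self, rng):
        # independent binary features: Gibbs weights solve each moment
        # equation separately; verified against scipy root finding
        from scipy.optimize import brentq

        f1 = (rng.random(600) < 0.4).astype(float)
        f2 = (rng.random(600) < 0.6).astype(float)
        fb = np.column_stack([f1, f2])
        fp = np.column_stack(
            [(rng.random(80) < 0.7).astype(float),
             (rng.random(80) < 0.3).astype(float)]
        )
        model = rp.fit(fp, fb, reg_multiplier=0.0, tol=1e-13, max_iter=20000)

        def expected_mean(lams, col):
            w = np.exp(fb @ lams)
            return (w * fb[:, col]).sum() / w.sum()

        for col in range(2):
            resid = expected_mean(model.lambdas, col) - fp[:, col].mean()
            assert abs(resid) < 1e-6

    def test_huge_regularization_zeroes_all_weights(self, binary_problem):
        fp, fb = binary_problem
        model = rp.fit(fp, fb, reg_multiplier=1e6)
        assert np.all(model.lambdas == 0.0)
        np.testing.assert_allclose(
            rp.predict(model, fb, "raw"), 1.0 / fb.shape[0], atol=1e-15
        )

    def test_duplicated_presences_leave_fit_unchanged(self, binary_problem):
        fp, fb = binary_problem
        a = rp.fit(fp, fb, reg_multiplier=0.0, tol=1e-12)
        b = rp.fit(np.vstack([fp, fp]), fb, reg_multiplier=0.0, tol=1e-12)
        np.testing.assert_allclose(a.lambdas, b.lambdas, atol=1e-6)

    def test_objective_non_decreasing(self, occurrences, background, masked_stack):
        model = rp.fit_occurrence_model(
            occurrences, background, masked_stack, classes="LQH",
            reg_multiplier=1.0,
        )
        assert np.all(np.diff(model.objective_log) >= -1e-9)

    def test_non_finite_features_rejected(self, binary_problem):
        fp, fb = binary_problem
        bad = fb.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            rp.fit(fp, bad)

    def test_single_presence_rejected(self, binary_problem):
        _, fb = binary_problem
        with pytest.raises(ValueError, match="2 presence"):
            rp.fit(fb[:1], fb)


class TestPredict:
    @pytest.fixture(scope="class")
    def fitted(self, occurrences, background, masked_stack):
        model = rp.fit_occurrence_model(
            occurrences, background, masked_stack, classes="LQ",
            reg_multiplier=1.0,
        )
        pres, _, _ = occurrence_predictor_table(occurrences, masked_stack)
        bg = masked_stack.table(background.rows, background.cols)
        train_bg = model.feature_set.transform(np.vstack([bg, pres]))
        return model, train_bg

    def test_raw_sums_to_one_over_training_background(self, fitted):
        model, train_bg = fitted
        assert rp.predict(model, train_bg, "raw").sum() == pytest.approx(1.0, abs=1e-9)

    def test_cloglog_in_unit_interval_and_monotone_in_raw(self, fitted):
        model, train_bg = fitted
        raw = rp.predict(model, train_bg, "raw")
        clog = rp.predict(model, train_bg, "cloglog")
        assert clog.min() >= 0.0 and clog.max() <= 1.0
        order = np.argsort(raw)
        assert np.all(np.diff(clog[order]) >= -1e-15)

    def test_rankings_identical_under_raw_and_cloglog(self, fitted, masked_stack):
        model, _ = fitted
        raw = rp.predict_surface(model, masked_stack, "raw")
        clog = rp.predict_surface(model, masked_stack, "cloglog")
        m = masked_stack.mask
        rho = spearmanr(raw.data[m], clog.data[m]).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_feature_mismatch_rejected(self, fitted):
        model, train_bg = fitted
        with pytest.raises(ValueError, match="match"):
            rp.predict(model, train_bg[:, :-1])


class TestModelComplexity:
    def test_count_parameters(self, binary_problem):
        fp, fb = binary_problem
        model = rp.fit(fp, fb, reg_multiplier=1e6)
        assert rp.count_parameters(model) == 0
        model.lambdas = np.array([0.5])
        assert rp.count_parameters(model) == 1

    def test_sparsity_monotone_over_regularization_ladder(
        self, occurrences, background, masked_stack
    ):
        ks = []
        for m in (0.5 * i for i in range(1, 11)):
            model = rp.fit_occurrence_model(
                occurrences, background, masked_stack, classes="LQH",
                reg_multiplier=m,
            )
            ks.append(rp.count_parameters(model))
        assert all(a >= b for a, b in zip(ks, ks[1:]))
        assert ks[-1] <= len(model.feature_set)


class TestRecoveryAndImportance:
    def test_virtual_species_recovery(self):
        spec = syn.WorldSpec(n_rows=100, n_cols=100, n_predictors=4,
                             smoothness=8.0, seed=21)
        stack = syn.generate_climate_stack(spec)
        niche = syn.NicheSpec(optimum=(0.8, -0.5, 0.2, 0.0),
                              tolerance=(0.8, 1.0, 1.2, 1.5), max_prob=0.9)
        truth = syn.generate_virtual_species(stack, niche)
        occ = syn.sample_presences(truth, 200, seed=22)
        zones = syn.generate_zone_raster(stack, 3, seed=23)
        bg = rp.select_background(occ, zones, stack, n_points=5000, seed=24)
        model = rp.fit_occurrence_model(occ, bg, stack, classes="LQ",
                                        reg_multiplier=1.0)
        pred = rp.predict_surface(model, stack)
        m = stack.mask
        rho = spearmanr(pred.data[m], truth.data[m]).statistic
        assert rho >= 0.9

    def test_importance_concentrates_on_informative_variable(self):
        spec = syn.WorldSpec(n_rows=50, n_cols=50, n_predictors=3,
                             smoothness=5.0, seed=31)
        stack = syn.generate_climate_stack(spec)
        # niche driven by predictor 0 only
        niche = syn.NicheSpec(optimum=(0.5, 0.0, 0.0),
                              tolerance=(0.5, 50.0, 50.0), max_prob=0.9)
        truth = syn.generate_virtual_species(stack, niche)
        occ = syn.sample_presences(truth, 120, seed=32)
        zones = syn.generate_zone_raster(stack, 2, seed=33)
        bg = rp.select_background(occ, zones, stack, n_points=1500, seed=34)
        model = rp.fit_occurrence_model(occ, bg, stack, classes="LQ",
                                        reg_multiplier=1.0)
        pres, _, _ = occurrence_predictor_table(occ, stack)
        bg_table = stack.table(bg.rows, bg.cols)
        imp = rp.permutation_importance(model, pres, bg_table, seed=35)
        assert imp.sum() == pytest.approx(100.0, abs=1e-9)
        assert imp[0] == max(imp) and imp[0] > 50.0
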