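import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

import paleoniche as pn
from paleoniche.sdm import _mess_similarity


def _table(X, y, contrast_kind="pseudoabsence", weights=None):
    names = [f"v{i}" for i in range(X.shape[1])]
    return pn.TrainingTable(X, y, names, contrast_kind, weights)


class TestFitGLM:
    def test_recovers_logistic_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        y = rng.binomial(1, expit(2.0 * x))
        model = pn.fit_glm(_table(x[:, None], y), degree=1)
        # coefficients are on standardized scale; recover raw slope
        slope = model.parameters["coefficients"][1] / model.parameters["standardize_sd"][0]
        assert slope > 0
        assert abs(slope - 2.0) < 0.5
        # independent ML oracle on the same draw
        import statsmodels.api as sm
        oracle = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert slope == pytest.approx(oracle.params[1], abs=1e-4)

    def test_weight_two_equals_duplicated_rows(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 2))
        y = (X[:, 0] + rng.normal(scale=1.0, size=80) > 0).astype(int)
        dup = pn.fit_glm(_table(np.vstack([X, X]), np.concatenate([y, y])))
        weighted = pn.fit_glm(_table(X, y, weights=np.full(80, 2.0)))
        np.testing.assert_allclose(dup.parameters["coefficients"],
                                   weighted.parameters["coefficients"], atol=1e-8)

    def test_uninformative_predictors_give_near_zero_d2(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 2))
        y = rng.binomial(1, 0.5, size=400)
        model = pn.fit_glm(_table(X, y))
        assert model.fit_metric[0] == "deviance_explained"
        assert model.fit_metric[1] == pytest.approx(0.0, abs=0.05)

    def test_complete_separation_flagged_not_fatal(self):
        x = np.concatenate([np.linspace(-2, -1, 20), np.linspace(1, 2, 20)])
        y = (x > 0).astype(int)
        model = pn.fit_glm(_table(x[:, None], y), degree=1)
        scores = model.predict(x[:, None])
        assert pn.auc(scores[y == 1], scores[y == 0]) == 1.0


class TestFitRF:
    def test_pure_noise_has_low_variance_explained(self):
        rng = np.random.default_rng(3)
        scores = []
        for seed in range(5):
            X = rng.normal(size=(500, 3))
            y = rng.binomial(1, 0.5, size=500)
            m = pn.fit_rf(_table(X, y), n_trees=100, seed=seed)
            scores.append(m.fit_metric[1])
        assert np.mean(scores) <= 0.1

    def test_threshold_signal_recovered_with_top_importance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(500, 3))
        y = (X[:, 0] > np.median(X[:, 0])).astype(int)
        m = pn.fit_rf(_table(X, y), n_trees=200, seed=0)
        assert m.fit_metric[1] > 0.8
        assert max(m.importance, key=m.importance.get) == "v0"

    def test_constant_variable_has_zero_importance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 3))
        X[:, 2] = 7.0
        y = (X[:, 0] > 0).astype(int)
        m = pn.fit_rf(_table(X, y), n_trees=100, seed=0)
        assert m.importance["v2"] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pn.fit_rf(_table(np.ones((20, 1)), np.ones(20, int)))


class TestFitMaxentLike:
    def test_presences_from_background_give_near_zero_gain(self):
        rng = np.random.default_rng(6)
        bg = rng.normal(size=(400, 3))
        pres = bg[rng.choice(400, 200, replace=False)]
        t = _table(np.vstack([pres, bg]),
                   np.concatenate([np.ones(200, int), np.zeros(400, int)]),
                   contrast_kind="background")
        m = pn.fit_maxent_like(t)
        assert m.fit_metric[0] == "gain"
        assert abs(m.fit_metric[1]) < 0.05

    def test_huge_regularization_zeroes_coefficients(self, presence_table):
        t = pn.TrainingTable(presence_table.X, presence_table.y,
                             presence_table.variable_names, "background")
        m = pn.fit_maxent_like(t, reg_multiplier=1e6)
        np.testing.assert_allclose(m.parameters["lambda"], 0.0, atol=1e-10)
        assert m.fit_metric[1] == pytest.approx(0.0, abs=1e-10)

    def test_concentrated_presences_get_positive_linear_coefficient(self):
        rng = np.random.default_rng(7)
        bg = rng.normal(size=(500, 1))
        pres = rng.normal(loc=1.5, scale=0.5, size=(100, 1))
        assert pres.mean() > bg.mean()  # sign oracle
        t = _table(np.vstack([pres, bg]),
                   np.concatenate([np.ones(100, int), np.zeros(500, int)]),
                   contrast_kind="background")
        m = pn.fit_maxent_like(t, reg_multiplier=1.0)
        assert m.parameters["lambda"][0] > 0


class TestProjection:
    def test_clamp_irrelevant_on_training_stack(self, small_stack, presence_table):
        model = pn.fit_glm(pn.TrainingTable(
            small_stack.env_table(), (small_stack.env_table()[:, 0] > 0).astype(int),
            small_stack.variable_names))
        on = pn.project(model, small_stack, clamp=True)
        off = pn.project(model, small_stack, clamp=False)
        np.testing.assert_allclose(on.values, off.values)

    def test_far_out_of_range_equals_range_edge(self):
        x = np.linspace(-1, 1, 200)
        y = (x > 0).astype(int)
        model = pn.fit_glm(_table(x[:, None], y), degree=1)
        sd = x.std()
        far = model.predict(np.array([[1 + 10 * sd]]), clamp=True)
        edge = model.predict(np.array([[1.0]]), clamp=False)
        assert far[0] == pytest.approx(edge[0], abs=1e-12)

    def test_nodata_cells_stay_nodata(self, small_stack, niche):
        mask = small_stack.nodata_mask.copy()
        mask[:5, :5] = True
        stack = pn.ClimateStack(dict(small_stack.variables), small_stack.cell_size,
                                small_stack.origin, mask)
        suit = pn.true_suitability(stack, niche)
        occ = pn.sample_occurrences(suit, 80, seed=1)
        pa = pn.sample_pseudoabsences(stack, occ, seed=2)
        model = pn.fit_glm(pn.build_training_table(stack, occ, pa))
        out = pn.project(model, stack)
        assert out.nodata_mask[0, 0]

    def test_missing_variable_named(self, small_stack, presence_table):
        model = pn.fit_glm(presence_table)
        missing = small_stack.subset(small_stack.variable_names[1:])
        with pytest.raises(ValueError, match=presence_table.variable_names[0]):
            pn.project(model, missing)


class TestAUC:
    def test_worked_case(self):
        assert pn.auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_perfect_and_tied(self):
        assert pn.auc([3, 4], [1, 2]) == 1.0
        assert pn.auc([1, 2, 3], [1, 2, 3]) == 0.5
        assert pn.auc([1.0], [1.0]) == 0.5

    @given(st.integers(1, 60), st.integers(1, 60), st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_all_pairs(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        # discrete scores force plenty of ties
        pos = rng.integers(0, 8, n_pos).astype(float)
        neg = rng.integers(0, 8, n_neg).astype(float)
        brute = np.mean([(1.0 if p > n else 0.5 if p == n else 0.0)
                         for p in pos for n in neg])
        assert pn.auc(pos, neg) == pytest.approx(brute, abs=1e-12)


class TestSamplers:
    def test_background_fraction_count_and_determinism(self, small_stack):
        bg = pn.sample_background(small_stack, 0.2, seed=3)
        assert len(bg) == int(0.2 * small_stack.n_unmasked)
        bg2 = pn.sample_background(small_stack, 0.2, seed=3)
        assert bg.records.equals(bg2.records)

    def test_fraction_one_is_every_cell(self, small_stack):
        bg = pn.sample_background(small_stack, 1.0, seed=0)
        assert len(bg) == small_stack.n_unmasked
        assert not bg.records.duplicated(["x", "y"]).any()

    def test_pseudoabsences_avoid_presences(self, small_stack):
        occ = pn.sample_background(small_stack, 0.5, seed=1)  # many cells
        pres = pn.OccurrenceSet(occ.records.assign(role="presence"))
        pa = pn.sample_pseudoabsences(small_stack, pres, n=100, seed=2)
        merged = pa.records.merge(pres.records, on=["x", "y"], how="inner")
        assert merged.empty

    def test_default_pseudoabsence_count_equals_presences(self, small_stack):
        pres = pn.sample_background(small_stack, 0.1, seed=4)
        pres = pn.OccurrenceSet(pres.records.assign(role="presence"))
        pa = pn.sample_pseudoabsences(small_stack, pres, seed=5)
        assert len(pa) == len(pres)


class TestBootstrapValidate:
    def test_separable_data_gives_auc_one(self):
        x = np.concatenate([np.linspace(-3, -1, 50), np.linspace(1, 3, 50)])
        y = (x > 0).astype(int)
        rep = pn.bootstrap_validate(lambda t: pn.fit_glm(t, degree=1),
                                    _table(x[:, None], y), seed=0)
        assert rep.auc_internal_mean == 1.0

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 2))
        y = rng.permutation(np.repeat([0, 1], 200))
        rep = pn.bootstrap_validate(lambda t: pn.fit_glm(t, degree=1),
                                    _table(X, y), seed=1)
        assert rep.auc_internal_mean == pytest.approx(0.5, abs=0.1)

    def test_deterministic_report(self, presence_table):
        kwargs = dict(iterations=5, test_fraction=0.4, seed=9)
        a = pn.bootstrap_validate(pn.fit_glm, presence_table, **kwargs)
        b = pn.bootstrap_validate(pn.fit_glm, presence_table, **kwargs)
        assert a.as_dict() == b.as_dict()


class TestExternalValidate:
    def test_fossils_at_top_cells_score_one(self, small_stack, niche):
        suit = pn.true_suitability(small_stack, niche)
        flat = np.argsort(suit.values.ravel())[-20:]
        helper = pn.ClimateStack({"v": suit.values}, 1.0)
        x, y = helper.cell_centers(flat)
        from conftest import make_occurrences
        fossils = make_occurrences(x, y, role="fossil")
        contrast = pn.sample_background(small_stack, 0.3, seed=0)
        assert pn.external_validate(suit, fossils, contrast) > 0.95

    def test_constant_map_is_half(self, small_stack):
        suit = pn.SuitabilityMap(np.full(small_stack.shape, 0.5), 1.0)
        bg1 = pn.sample_background(small_stack, 0.1, seed=1)
        bg2 = pn.sample_background(small_stack, 0.1, seed=2)
        assert pn.external_validate(suit, bg1, bg2) == 0.5

    def test_random_fossils_near_half(self, small_stack, niche):
        suit = pn.true_suitability(small_stack, niche)
        fossils = pn.sample_background(small_stack, 0.05, seed=3)
        contrast = pn.sample_background(small_stack, 0.4, seed=4)
        assert pn.external_validate(suit, fossils, contrast) == pytest.approx(0.5, abs=0.12)


class TestMess:
    def test_reference_median_scores_100(self):
        # v at the median of an even-sized reference: f = 50 -> s = 100
        ref = _table(np.arange(1.0, 101.0)[:, None],
                     np.array([1] * 50 + [0] * 50))
        stack = pn.ClimateStack({"v0": np.full((10, 10), 50.5)}, 1.0)
        res = pn.mess(stack, ref)
        assert res.mess[0, 0] == pytest.approx(100.0)

    def test_worked_case_v30_of_1_to_100(self):
        ref = _table(np.arange(1.0, 101.0)[:, None],
                     np.array([1] * 50 + [0] * 50))
        stack = pn.ClimateStack({"v0": np.full((10, 10), 30.0)}, 1.0)
        res = pn.mess(stack, ref)
        # f = 29 values below 30 -> s = 2 * 29 = 58
        assert res.mess[0, 0] == pytest.approx(58.0)

    def test_below_minimum_is_negative_and_flagged(self):
        ref = _table(np.arange(1.0, 101.0)[:, None],
                     np.array([1] * 50 + [0] * 50))
        stack = pn.ClimateStack({"v0": np.full((10, 10), -5.0)}, 1.0)
        res = pn.mess(stack, ref)
        assert res.mess[0, 0] < 0

    @given(st.integers(0, 2 ** 31 - 1))
    def test_negative_iff_out_of_range(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(30, 2))
        X = rng.normal(scale=2.0, size=(36, 2))
        table = _table(np.vstack([ref, ref]), np.array([1] * 30 + [0] * 30))
        stack = pn.ClimateStack({"v0": X[:, 0].reshape(6, 6),
                                 "v1": X[:, 1].reshape(6, 6)}, 1.0)
        res = pn.mess(stack, table)
        lo, hi = table.X.min(axis=0), table.X.max(axis=0)
        out = ((X < lo) | (X > hi)).any(axis=1).reshape(6, 6)
        np.testing.assert_array_equal(res.mess < 0, out)

    def test_mod_is_most_dissimilar_variable(self):
        ref = _table(np.column_stack([np.arange(1.0, 101.0), np.arange(1.0, 101.0)]),
                     np.array([1] * 50 + [0] * 50))
        stack = pn.ClimateStack({"v0": np.full((5, 5), 50.0),
                                 "v1": np.full((5, 5), 150.0)}, 1.0)  # v1 novel
        res = pn.mess(stack, ref)
        assert res.mod_labels()[0, 0] == "v1"
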