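import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform

from bioregions.betadiv import DissimilarityMatrix
from bioregions.data import SiteRegistry
from bioregions.drivers import (DEFAULT_SETS, aicc, build_candidates,
                                explained_deviance, fit_multinomial,
                                null_deviance, partition_deviance,
                                permanova_2way, rank_candidates,
                                residual_diagnostics, waicc)


class TestFitMultinomial:
    def test_binary_case_matches_logistic_oracle(self):
        r = np.random.default_rng(0)
        x = r.normal(size=(150, 2))
        eta = 0.9 * x[:, 0] - 0.7 * x[:, 1]
        y = (r.random(150) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_multinomial(y, pd.DataFrame(x, columns=["a", "b"]),
                              ridge=1e-10)
        z = (x - x.mean(0)) / x.std(0)
        ref = sm.Logit((y != fit.reference).astype(int),
                       sm.add_constant(z)).fit(disp=0)
        np.testing.assert_allclose(fit.coef.ravel(), np.asarray(ref.params),
                                   atol=1e-6)
        assert fit.log_lik == pytest.approx(ref.llf, abs=1e-6)

    def test_intercept_only_null_deviance_closed_form(self):
        y = np.array([0] * 25 + [1] * 15 + [2] * 10)
        fit = fit_multinomial(y, pd.DataFrame(index=range(50)))
        assert fit.deviance == pytest.approx(null_deviance(y), abs=1e-8)

    def test_separable_data_deviance_vanishes(self):
        x = np.concatenate([np.linspace(-3, -1, 20), np.linspace(1, 3, 20)])
        y = np.repeat([0, 1], 20)
        fit = fit_multinomial(y, x[:, None], ridge=1e-8)
        assert fit.deviance < 1e-3

    def test_probabilities_sum_to_one(self):
        r = np.random.default_rng(1)
        y = r.integers(0, 4, 80)
        x = r.normal(size=(80, 3))
        fit = fit_multinomial(y, x)
        np.testing.assert_allclose(fit.probabilities.sum(axis=1), 1.0,
                                   atol=1e-10)

    def test_nested_model_loglik_monotone(self):
        r = np.random.default_rng(2)
        x = r.normal(size=(100, 3))
        y = r.integers(0, 3, 100)
        lls = []
        for p in (1, 2, 3):
            lls.append(fit_multinomial(y, x[:, :p]).log_lik)
        assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6

    def test_tiny_class_rejected(self):
        y = np.array([0] * 10 + [1])
        with pytest.raises(ValueError):
            fit_multinomial(y, np.zeros((11, 1)))


class TestInformationCriteria:
    def test_aicc_formula(self):
        assert aicc(-100.0, 5, 50) == pytest.approx(211.3636, abs=1e-4)

    def test_aicc_requires_enough_observations(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 10, 11)

    def test_equal_models_split_weight(self):
        w = waicc([100.0, 100.0])
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_weights_normalized_and_shift_invariant(self):
        r = np.random.default_rng(3)
        a = r.uniform(100, 150, 8)
        w = waicc(a)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w, waicc(a + 57.0), atol=1e-12)


class TestCandidates:
    def test_enumeration(self):
        cands = build_candidates()
        singles = {v for vs in DEFAULT_SETS.values() for v in vs}
        for v in singles:
            assert v in cands
        # single-variable named sets collapse onto their lone predictor
        assert "current_climate" not in cands and "AI" in cands
        assert "footprint" in cands
        assert set(cands["full"]) == singles
        assert set(cands["current_climate+historical_climate"]) == {
            "AI", "HAI", "hydric_change", "thermal_change"}

    def test_no_duplicate_designs(self):
        cands = build_candidates()
        keys = [frozenset(v) for v in cands.values()]
        assert len(keys) == len(set(keys))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            build_candidates({"soil": []})

    def test_mems_appended_to_every_candidate(self):
        r = np.random.default_rng(4)
        n = 90
        table = pd.DataFrame(r.normal(size=(n, 9)),
                             columns=[v for vs in DEFAULT_SETS.values()
                                      for v in vs])
        y = r.integers(0, 3, n)
        mems = r.normal(size=(n, 2))
        mt = rank_candidates(y, table, build_candidates(), mems)
        for name, fit in mt.fits.items():
            assert "MEM1" in fit.predictor_names
            assert "MEM2" in fit.predictor_names


class TestExplainedDeviance:
    def test_null_model_zero(self):
        y = np.array([0] * 20 + [1] * 20)
        fit = fit_multinomial(y, pd.DataFrame(index=range(40)))
        assert explained_deviance(fit) == pytest.approx(0.0, abs=1e-8)

    def test_perfect_model_one(self):
        x = np.concatenate([np.full(20, -2.0), np.full(20, 2.0)])
        y = np.repeat([0, 1], 20)
        fit = fit_multinomial(y, x[:, None], ridge=1e-8)
        assert explained_deviance(fit) == pytest.approx(1.0, abs=1e-3)

    def test_monotone_in_nested_predictors(self):
        r = np.random.default_rng(5)
        x = r.normal(size=(120, 4))
        y = (x[:, 0] + 0.5 * x[:, 1] + r.normal(0, 1, 120) > 0).astype(int)
        eds = [explained_deviance(fit_multinomial(y, x[:, :p]))
               for p in (1, 2, 3, 4)]
        assert all(b >= a - 1e-6 for a, b in zip(eds, eds[1:]))


class TestDeviancePartition:
    def test_additive_identity(self):
        r = np.random.default_rng(6)
        n = 100
        env = pd.DataFrame({"e": r.normal(size=n)})
        mem = pd.DataFrame({"MEM1": r.normal(size=n)})
        y = (env["e"] + mem["MEM1"] + r.normal(0, 1, n) > 0).astype(int)
        part = partition_deviance(y, env, mem)
        assert (part.unique_env + part.unique_spatial + part.shared
                == pytest.approx(part.total_explained, abs=1e-10))

    def test_spatial_only_signal(self):
        r = np.random.default_rng(7)
        n = 150
        mem = pd.DataFrame({"MEM1": r.normal(size=n)})
        env = pd.DataFrame({"e": r.normal(size=n)})
        y = (mem["MEM1"] > 0).astype(int)
        part = partition_deviance(y, env, mem)
        assert part.unique_env < 0.05

    def test_orthogonal_effects_share_nothing(self):
        # moderate effects: deviance partitions, unlike variance ones, can
        # go slightly negative in the shared slot under strong suppression
        r = np.random.default_rng(8)
        n = 400
        env = pd.DataFrame({"e": r.normal(size=n)})
        mem = pd.DataFrame({"MEM1": r.normal(size=n)})
        y = (0.5 * env["e"] + 0.5 * mem["MEM1"]
             + r.normal(0, 1.0, n) > 0).astype(int)
        part = partition_deviance(y, env, mem)
        assert abs(part.shared) < 0.05


class TestPermanova:
    def test_sequential_terms_match_anova_oracle(self):
        r = np.random.default_rng(9)
        n = 36
        y = r.normal(size=n)
        fa = r.integers(0, 3, n)
        fb = r.integers(0, 2, n)
        d = squareform(pdist(y[:, None]))
        dm = DissimilarityMatrix([str(i) for i in range(n)], d / d.max())
        tab = permanova_2way(dm, fa, fb, n_perm=49, seed=0).set_index("term")
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        df = pd.DataFrame({"y": y / d.max(), "A": pd.Categorical(fa),
                           "B": pd.Categorical(fb)})
        ref = anova_lm(smf.ols("y ~ A + B + A:B", df).fit(), typ=1)
        assert tab.loc["A", "pseudo_F"] == pytest.approx(ref.loc["A", "F"],
                                                         rel=1e-8)
        assert tab.loc["B", "pseudo_F"] == pytest.approx(ref.loc["B", "F"],
                                                         rel=1e-8)
        assert tab.loc["AxB", "pseudo_F"] == pytest.approx(
            ref.loc["A:B", "F"], rel=1e-8)

    def test_irrelevant_factor_near_zero_r2(self):
        r = np.random.default_rng(10)
        n = 40
        x = r.normal(size=(n, 5))
        d = squareform(pdist(x))
        dm = DissimilarityMatrix([str(i) for i in range(n)], d / d.max())
        fa = r.integers(0, 2, n)
        fb = r.integers(0, 3, n)       # unrelated to x
        tab = permanova_2way(dm, fa, fb, n_perm=199, seed=1).set_index("term")
        assert tab.loc["B", "R2"] < 0.15
        assert tab.loc["B", "p"] > 0.1

    def test_single_level_factor_rejected(self):
        d = np.array([[0.0, 0.5], [0.5, 0.0]])
        dm = DissimilarityMatrix(["a", "b"], d)
        with pytest.raises(ValueError):
            permanova_2way(dm, np.array([0, 0]), np.array([0, 1]))


class TestResidualDiagnostics:
    def test_constant_residuals_rejected(self):
        y = np.repeat([0, 1], 10)
        x = np.concatenate([np.full(10, -3.0), np.full(10, 3.0)])
        fit = fit_multinomial(y, x[:, None], ridge=1e-10)
        reg = SiteRegistry([f"s{i}" for i in range(20)],
                           np.linspace(-41, -40, 20), np.full(20, -9.0))
        # a perfectly separated fit leaves all residuals ~0 -> constant
        with pytest.raises(ValueError):
            residual_diagnostics(fit, reg)

    def test_returns_correlogram(self):
        r = np.random.default_rng(11)
        n = 40
        x = r.normal(size=(n, 1))
        y = (x[:, 0] + r.normal(0, 2, n) > 0).astype(int)
        fit = fit_multinomial(y, x)
        reg = SiteRegistry([f"s{i}" for i in range(n)],
                           r.uniform(-41, -40, n), r.uniform(-9, -8, n))
        cg = residual_diagnostics(fit, reg, n_classes=6, n_perm=49)
        assert cg.morans_i.size == 6
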