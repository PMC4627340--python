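import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from prognet.errors import InputError
from prognet.survstats import (
    cox_score_test,
    fit_cox,
    kaplan_meier,
    logrank_test,
    pvalue_score,
    survival_at,
)


def _sim(seed, n=300, beta=np.log(2), censor_scale=None, binary=True):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float) if binary else rng.standard_normal(n)
    t = rng.exponential(1.0 / (0.05 * np.exp(beta * x)))
    if censor_scale is None:
        return x, t, np.ones(n, dtype=int)
    c = rng.exponential(censor_scale, n)
    return x, np.minimum(t, c), (t <= c).astype(int)


class TestFitCox:
    def test_recovers_hr2(self):
        x, t, e = _sim(seed=11, n=2000)
        res = fit_cox(x, (t, e)).result
        assert res.converged
        assert abs(res.beta - np.log(2)) < 0.1
        assert res.hazard_ratio > 0

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.standard_normal(n)
        z = rng.binomial(1, 0.4, n).astype(float)
        t = np.round(rng.exponential(1 / (0.05 * np.exp(0.6 * x - 0.3 * z))), 0) + 1
        e = rng.binomial(1, 0.8, n)
        fit = fit_cox(np.c_[x, z], (t, e))
        df = pd.DataFrame({"t": t, "e": e, "x": x, "z": z})
        oracle = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.beta, oracle.params_.values, atol=1e-6)
        np.testing.assert_allclose(
            [r.se for r in fit.results], oracle.standard_errors_.values, atol=1e-6
        )

    def test_breslow_matches_lifelines(self):
        rng = np.random.default_rng(6)
        n = 200
        x = rng.standard_normal(n)
        t = np.round(rng.exponential(20, n), 0) + 1
        e = rng.binomial(1, 0.7, n)
        fit = fit_cox(x, (t, e), ties="breslow")
        # verify the Breslow score equation is solved: gradient at beta-hat is 0
        from prognet.survstats import _partial_loglik, _prepare

        X, tt, ee = _prepare(x, (t, e))
        _, grad, _ = _partial_loglik(fit.beta, X - X.mean(axis=0), tt, ee, "breslow")
        assert np.abs(grad).max() < 1e-6

    def test_null_type_one_error(self):
        hits = 0
        reps = 1000
        for seed in range(reps):
            x, t, e = _sim(seed=10_000 + seed, n=100, beta=0.0, binary=False)
            res = fit_cox(x, (t, e)).result
            hits += res.p_value < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_constant_covariate_rejected(self, exp_survival):
        with pytest.raises(InputError, match="constant"):
            fit_cox(np.zeros(len(exp_survival.sample_ids)), exp_survival)

    def test_zero_events_rejected(self):
        with pytest.raises(InputError, match="no events"):
            fit_cox(np.arange(5.0), (np.arange(1.0, 6.0), np.zeros(5, dtype=int)))

    def test_perfect_separation_flagged(self):
        # covariate that perfectly orders survival: monotone likelihood
        t = np.arange(1.0, 41.0)
        x = t.copy()
        res = fit_cox(x, (t, np.ones(40, dtype=int)), max_iter=100).result
        assert not res.converged

    def test_wald_ci_contains_truth_usually(self):
        cover = 0
        for seed in range(50):
            x, t, e = _sim(seed=seed, n=300, censor_scale=60.0)
            lo, hi = fit_cox(x, (t, e)).result.ci()
            cover += lo <= np.log(2) <= hi
        assert cover >= 43  # ~95% nominal


class TestScoreLogrankIdentity:
    @pytest.mark.parametrize("seed", range(20))
    def test_equivalence_without_ties(self, seed):
        x, t, e = _sim(seed=200 + seed, n=150, censor_scale=80.0)
        if len(np.unique(x)) < 2:
            pytest.skip("degenerate draw")
        chi2, p = cox_score_test(x, (t, e))
        lr = logrank_test((t, e), x)
        assert abs(chi2 - lr.chi_square) <= 1e-10 * max(lr.chi_square, 1e-12)
        assert abs(p - lr.p_value) < 1e-10

    def test_identical_groups_chi2_zero(self):
        # exactly duplicated survival in the two groups: U = 0 at every
        # event time by symmetry
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.ones(6, dtype=int)
        g = np.array([0, 0, 0, 1, 1, 1])
        chi2, _ = cox_score_test(g, (t, e))
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_symmetric(self):
        x, t, e = _sim(seed=3, n=100, censor_scale=60.0)
        chi2_a, _ = cox_score_test(x, (t, e))
        chi2_b, _ = cox_score_test(1 - x, (t, e))
        assert np.isclose(chi2_a, chi2_b, rtol=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            cox_score_test(np.zeros(5), (np.arange(1.0, 6.0), np.ones(5, dtype=int)))


class TestKaplanMeier:
    def test_no_censoring_empirical(self):
        km = kaplan_meier((np.array([1.0, 2, 3, 4]), np.ones(4, dtype=int)))
        assert survival_at(km, 2.5) == pytest.approx(0.5)

    def test_all_censored(self):
        km = kaplan_meier((np.array([1.0, 2, 3]), np.zeros(3, dtype=int)))
        assert survival_at(km, 100.0) == 1.0

    def test_hand_computed_with_censoring(self):
        # times {1, 2+, 3}: S(1) = 2/3, S(3) = 0
        km = kaplan_meier((np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1])))
        assert survival_at(km, 0.5) == 1.0
        assert survival_at(km, 1.0) == pytest.approx(2 / 3)
        assert survival_at(km, 3.0) == pytest.approx(0.0)

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        t = rng.exponential(10, 100)
        km = kaplan_meier((t, np.ones(100, dtype=int)))
        for q in np.quantile(t, [0.1, 0.5, 0.9]):
            assert survival_at(km, q) == pytest.approx(1 - np.mean(t <= q))

    def test_survival_non_increasing_from_one(self, rng):
        t = rng.exponential(10, 50)
        e = rng.binomial(1, 0.7, 50)
        if e.sum() == 0:
            e[0] = 1
        km = kaplan_meier((t, e))
        assert (np.diff(km.survival) <= 1e-15).all()
        assert km.survival[0] <= 1.0
        assert ((km.survival >= 0) & (km.survival <= 1)).all()

    def test_exponential_median(self):
        rng = np.random.default_rng(77)
        t = rng.exponential(1 / 0.01, 5000)
        km = kaplan_meier((t, np.ones(5000, dtype=int)))
        assert abs(km.median - np.log(2) / 0.01) / (np.log(2) / 0.01) < 0.1

    def test_negative_times_rejected(self):
        with pytest.raises(InputError):
            kaplan_meier((np.array([-1.0]), np.array([1])))


class TestSurvivalAt:
    def test_before_first_event(self):
        km = kaplan_meier((np.array([5.0, 6.0]), np.array([1, 1])))
        assert survival_at(km, 1.0) == 1.0

    def test_beyond_last_time(self):
        km = kaplan_meier((np.array([1.0, 2.0]), np.array([1, 0])))
        assert survival_at(km, 1e9) == pytest.approx(0.5)

    def test_right_continuity_at_event(self):
        km = kaplan_meier((np.array([1.0, 2.0]), np.array([1, 1])))
        assert survival_at(km, 1.0) == pytest.approx(0.5)


class TestLogrank:
    def test_duplicated_data_chi2_zero(self):
        t = np.array([1.0, 3.0, 7.0, 9.0] * 2)
        e = np.ones(8, dtype=int)
        g = np.repeat([0, 1], 4)
        lr = logrank_test((t, e), g)
        assert lr.chi_square == pytest.approx(0.0, abs=1e-12)

    def test_three_group_monotone_in_shift(self):
        rng = np.random.default_rng(42)
        base = rng.exponential(10, 60)
        pvals = []
        for shift in (1.0, 2.0, 4.0):
            t = np.concatenate([base[:20], base[20:40], base[40:] * shift])
            e = np.ones(60, dtype=int)
            g = np.repeat([0, 1, 2], 20)
            pvals.append(logrank_test((t, e), g).p_value)
        assert pvals[0] > pvals[1] > pvals[2]

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            logrank_test((np.arange(1.0, 5.0), np.ones(4, dtype=int)), np.zeros(4))


class TestPvalueScore:
    def test_examples(self):
        assert pvalue_score(0.05) == pytest.approx(1.3010, abs=1e-4)
        assert pvalue_score(1.0) == 0.0
        assert pvalue_score(1e-6) == pytest.approx(6.0)

    def test_natural_log_base(self):
        assert pvalue_score(np.exp(-1), base=np.e) == pytest.approx(1.0)

    def test_invalid_p(self):
        with pytest.raises(InputError):
            pvalue_score(0.0)
        with pytest.raises(InputError):
            pvalue_score(-0.5)
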