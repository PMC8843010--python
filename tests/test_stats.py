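"""Oracle-backed tests for the trial-statistics suite."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as hst
from scipy import stats as sps

from anklesim import (InvalidInputError, SummaryStat,
                      breslow_test, fisher_exact_2x2, km_estimate,
                      mixed_anova_2x2, partial_eta_sq, rm_anova_power,
                      rm_anova_sample_size, welch_t_from_summary)
from anklesim.stats import breslow_permutation_p, f_p_value


class TestWelchFromSummary:
    def test_equal_means_give_p_one(self):
        a = SummaryStat(5.0, 1.0, 10)
        t, _, p = welch_t_from_summary(a, a)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_published_age_row(self):
        """58.2±12.1 (n=9) vs 55.6±18.9 (n=9) -> p ≈ 0.73."""
        _, _, p = welch_t_from_summary(SummaryStat(58.2, 12.1, 9),
                                       SummaryStat(55.6, 18.9, 9))
        assert p == pytest.approx(0.726, abs=0.01)

    def test_zero_variance_equal_means_convention(self):
        t, _, p = welch_t_from_summary(SummaryStat(3.0, 0.0, 5),
                                       SummaryStat(3.0, 0.0, 5))
        assert (t, p) == (0.0, 1.0)

    @given(hst.floats(-5, 5), hst.floats(0.5, 3), hst.integers(3, 30),
           hst.floats(-5, 5), hst.floats(0.5, 3), hst.integers(3, 30))
    def test_matches_scipy_from_raw_moments(self, m1, s1, n1, m2, s2, n2):
        """Same t/df/p as scipy's Welch test on data with those exact moments."""
        x = _with_moments(m1, s1, n1, seed=1)
        y = _with_moments(m2, s2, n2, seed=2)
        t_ref, p_ref = sps.ttest_ind(x, y, equal_var=False)
        t, df, p = welch_t_from_summary(
            SummaryStat(float(x.mean()), float(x.std(ddof=1)), n1),
            SummaryStat(float(y.mean()), float(y.std(ddof=1)), n2))
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)


def _with_moments(mean, sd, n, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestFisherExact:
    def test_published_gender_table(self):
        assert fisher_exact_2x2([[7, 2], [4, 5]]) == pytest.approx(0.335,
                                                                   abs=5e-4)

    def test_published_affected_side_table(self):
        assert fisher_exact_2x2([[5, 4], [8, 1]]) == pytest.approx(0.294,
                                                                   abs=5e-4)

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact_2x2([[9, 0], [9, 0]]) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            fisher_exact_2x2([[1, -1], [2, 3]])

    @given(hst.integers(0, 12), hst.integers(0, 12),
           hst.integers(0, 12), hst.integers(0, 12))
    def test_matches_scipy_reference(self, a, b, c, d):
        tab = [[a, b], [c, d]]
        p_ref = sps.fisher_exact(tab)[1]
        assert fisher_exact_2x2(tab) == pytest.approx(p_ref, abs=1e-10)


class TestMixedAnova:
    def test_identical_groups_give_null_interaction(self):
        pre = [1.0, 2.0, 3.0, 4.0]
        post = [2.0, 3.0, 4.0, 5.0]
        res = mixed_anova_2x2(pre, post, pre, post)
        assert res["interaction"].F == pytest.approx(0.0, abs=1e-12)

    def test_interaction_equals_squared_change_score_t(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            na, nb = int(rng.integers(3, 15)), int(rng.integers(3, 15))
            pa, qa = rng.normal(0, 1, na), rng.normal(1, 2, na)
            pb, qb = rng.normal(0, 1, nb), rng.normal(0, 2, nb)
            res = mixed_anova_2x2(pa, qa, pb, qb)
            t_ref = sps.ttest_ind(qa - pa, qb - pb, equal_var=True)[0]
            assert res["interaction"].F == pytest.approx(t_ref**2, rel=1e-10)
            assert res["interaction"].df2 == na + nb - 2

    def test_partial_eta_identity(self):
        rng = np.random.default_rng(3)
        pa, qa = rng.normal(0, 1, 9), rng.normal(1, 1, 9)
        pb, qb = rng.normal(0, 1, 9), rng.normal(0, 1, 9)
        r = mixed_anova_2x2(pa, qa, pb, qb)["interaction"]
        assert r.partial_eta_sq == pytest.approx(
            r.F * r.df1 / (r.F * r.df1 + r.df2), abs=1e-12)

    def test_published_interaction_triples(self):
        """Printed F on df (1,16) implies the printed eta^2 and p."""
        for F, eta, p in [(9.653, 0.376, 0.007), (8.273, 0.341, 0.011),
                          (8.878, 0.357, 0.009)]:
            assert partial_eta_sq(F, 1, 16) == pytest.approx(eta, abs=5e-4)
            assert f_p_value(F, 1, 16) == pytest.approx(p, abs=5e-4)

    def test_matches_pingouin_reference(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(8)
        for _ in range(5):
            n = 9
            pa, qa = rng.normal(0, 1, n), rng.normal(1, 1, n)
            pb, qb = rng.normal(0, 1, n), rng.normal(0.3, 1, n)
            res = mixed_anova_2x2(pa, qa, pb, qb)
            df = pd.DataFrame({
                "y": np.concatenate([pa, qa, pb, qb]),
                "time": ["pre"] * n + ["post"] * n + ["pre"] * n + ["post"] * n,
                "grp": ["a"] * 2 * n + ["b"] * 2 * n,
                "subj": list(range(n)) * 2 + list(range(n, 2 * n)) * 2})
            aov = pg.mixed_anova(df, dv="y", within="time", between="grp",
                                 subject="subj")
            for src, key in (("Interaction", "interaction"),
                             ("time", "time"), ("grp", "group")):
                F_ref = float(aov.loc[aov.Source == src, "F"].iloc[0])
                assert res[key].F == pytest.approx(F_ref, rel=1e-8)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            mixed_anova_2x2([1, 2], [1, 2, 3], [1, 2], [3, 4])

    def test_missing_cells_rejected(self):
        with pytest.raises(InvalidInputError):
            mixed_anova_2x2([1, np.nan], [1, 2], [1, 2], [3, 4])


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        km = km_estimate([(1, True), (2, True), (3, True)])
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert km.median == 2

    def test_all_censored_median_not_reached(self):
        km = km_estimate([(4, False), (6, False)])
        assert km.median is None
        assert km.survival_at(100.0) == 1.0

    def test_single_subject_single_event(self):
        km = km_estimate([(5, True)])
        assert km.survival_at(4.999) == 1.0
        assert km.survival_at(5.0) == 0.0
        assert km.median == 5

    def test_properties_and_empirical_equality_without_censoring(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 30)
        km = km_estimate([(x, True) for x in t])
        assert km.survival_at(0.0) == 1.0
        assert km.survival_at(t.min()) == pytest.approx(1.0 - 1 / 30)
        s = km.survival
        assert all(b <= a for a, b in zip(s, s[1:]))
        for q in (0.25, 0.5, 0.75):
            tq = np.quantile(t, q, method="inverted_cdf")
            assert km.survival_at(tq) == pytest.approx((t > tq).mean())

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(5)
        t = rng.exponential(8, 25)
        e = rng.random(25) < 0.6
        km = km_estimate(list(zip(t, e)))
        kmf = KaplanMeierFitter().fit(t, e)
        for tt in km.times:
            assert km.survival_at(tt) == pytest.approx(float(kmf.predict(tt)),
                                                       abs=1e-10)
        ref_med = float(kmf.median_survival_time_)
        assert (km.median or math.inf) == pytest.approx(ref_med)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            km_estimate([])


class TestBreslow:
    def test_identical_groups_null(self):
        g = [(1, True), (3, True), (5, False)]
        chi, p = breslow_test(g, g)
        assert chi == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_relabeling(self):
        rng = np.random.default_rng(6)
        a = list(zip(rng.exponential(5, 6), rng.random(6) < 0.8))
        b = list(zip(rng.exponential(9, 7), rng.random(7) < 0.8))
        assert breslow_test(a, b) == pytest.approx(breslow_test(b, a))

    def test_complete_separation_is_significant(self):
        a = [(1, True), (2, True), (3, True), (4, True)]
        b = [(10, True), (11, True), (12, True), (13, True)]
        chi, p = breslow_test(a, b)
        assert p < 0.05

    def test_matches_lifelines_gehan_wilcoxon(self):
        from lifelines.statistics import logrank_test
        for seed in range(12):
            rng = np.random.default_rng(seed)
            na, nb = int(rng.integers(4, 10)), int(rng.integers(4, 10))
            ta, tb = rng.exponential(10, na), rng.exponential(5, nb)
            ea, eb = rng.random(na) < 0.75, rng.random(nb) < 0.75
            if not (ea.any() or eb.any()):
                continue
            chi, p = breslow_test(list(zip(ta, ea)), list(zip(tb, eb)))
            ref = logrank_test(ta, tb, ea, eb, weightings="wilcoxon")
            assert chi == pytest.approx(float(ref.test_statistic), abs=1e-8)
            assert p == pytest.approx(float(ref.p_value), abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(InvalidInputError):
            breslow_test([(1, False)], [(2, False)])

    def test_permutation_reference_close_to_asymptotic(self):
        """χ²(1) p within discreteness+approximation error of permutation p."""
        rng = np.random.default_rng(7)
        a = list(zip(rng.exponential(12, 4), [True] * 4))
        b = list(zip(rng.exponential(3, 4), [True] * 4))
        _, p_asym = breslow_test(a, b)
        p_perm = breslow_permutation_p(a, b, n_perm=20_000, seed=0)
        assert p_asym == pytest.approx(p_perm, abs=0.06)


class TestSampleSize:
    def test_minimum_feasible_at_vanishing_power(self):
        assert rm_anova_sample_size(0.25, power=1e-6) == 4

    def test_doubling_f_quarters_required_noncentral_n(self):
        """λ ∝ f²·N: the pre-rounding N satisfying λ=target scales as 1/f²."""
        lam_needed = 10.0
        for f in (0.1, 0.2, 0.4):
            n_f = lam_needed * (1 - 0.5) / (f**2 * 2)
            n_2f = lam_needed * (1 - 0.5) / ((2 * f) ** 2 * 2)
            assert n_2f == pytest.approx(n_f / 4)

    def test_agrees_with_simulation_oracle(self):
        """Power by noncentral F matches power by direct simulation."""
        f, rho, n = 0.25, 0.5, 32
        analytic = rm_anova_power(f, n, rm_correlation=rho)
        rng = np.random.default_rng(10)
        sd, reps = 1.0, 1500
        # within-between design: subject effect variance rho, residual 1-rho.
        # Cell means (0, delta, 0, 0): interaction deviations are ±delta/4,
        # so Cohen's f = delta/(4*sd).
        delta = 4.0 * f * sd
        hits = 0
        for _ in range(reps):
            subj = rng.normal(0, math.sqrt(rho), n)
            eps = rng.normal(0, math.sqrt(1 - rho), (n, 2))
            y = subj[:, None] + eps
            half = n // 2
            y[:half, 1] += delta    # group A gains, group B does not
            res = mixed_anova_2x2(y[:half, 0], y[:half, 1],
                                  y[half:, 0], y[half:, 1])
            hits += res["interaction"].p < 0.05
        sim = hits / reps
        se = math.sqrt(sim * (1 - sim) / reps)
        assert analytic == pytest.approx(sim, abs=max(4 * se, 0.05))

    def test_attrition_inflates_and_rounds_to_group_multiple(self):
        base = rm_anova_sample_size(0.25, rm_correlation=0.5, attrition=0.0)
        inflated = rm_anova_sample_size(0.25, rm_correlation=0.5,
                                        attrition=0.10)
        assert inflated >= base / 0.9 - 2
        assert inflated % 2 == 0
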