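"""Survival estimators against hand/brute-force oracles, the two-regime
mortality analysis, and the temporal-scaling collapse."""

import itertools

import numpy as np
import pytest

from critaging.core_model import GompertzLaw, gompertz_cumhaz
from critaging.events import event_table
from critaging.survival import (
    estimate_plateau,
    fit_gompertz,
    fit_gompertz_curve,
    kaplan_meier,
    lifespan_summary,
    logrank_test,
    nelson_aalen,
    relative_extension,
    rescale_and_collapse,
    plateau_vs_alpha_report,
)


# ---------------------------------------------------------------- oracles
def brute_km_na(times, events):
    """Independent O(n^2) product-limit and cumulative-hazard enumeration
    with the deaths-before-censorings tie rule."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    uniq = np.unique(times[events == 1])
    s, m, v = [], [], []
    s_cur, m_cur, v_cur = 1.0, 0.0, 0.0
    for t in uniq:
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        n = sum(1 for ti in times if ti >= t)
        s_cur *= 1 - d / n
        m_cur += d / n
        v_cur += d / n**2
        s.append(s_cur)
        m.append(m_cur)
        v.append(v_cur)
    return uniq, np.array(s), np.array(m), np.array(v)


def brute_logrank(ta, ea, tb, eb):
    """Mantel-Cox statistic by explicit 2x2 tables at each death time."""
    times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O = E = V = 0.0
    for t in times:
        da = np.sum((ta == t) & (ea == 1))
        db = np.sum((tb == t) & (eb == 1))
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        d, n = da + db, na + nb
        if n < 2:
            continue
        O += da
        E += d * na / n
        V += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def all_small_fixtures(max_n=4):
    """Every event pattern on small integer time grids (exhaustive toys)."""
    for n in range(1, max_n + 1):
        for times in itertools.combinations_with_replacement([1.0, 2.0, 3.0], n):
            for events in itertools.product([0, 1], repeat=n):
                if sum(events) == 0:
                    continue
                yield np.array(times), np.array(events)


# ---------------------------------------------------------------- KM / NA
class TestKaplanMeierNelsonAalen:
    def test_two_deaths_stepwise(self):
        tab = event_table([1.0, 2.0], [1, 1])
        curve = kaplan_meier(tab)
        np.testing.assert_allclose(curve.survival, [0.5, 0.0])

    def test_censoring_tie_rule_hand_value(self):
        # deaths {2,4}, censored {3}: S(2)=2/3, S(4)=0
        tab = event_table([2.0, 3.0, 4.0], [1, 0, 1])
        curve = kaplan_meier(tab)
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 200)
        curve = kaplan_meier(event_table(t, np.ones(200, int)))
        ecdf = np.array([(t <= ti).mean() for ti in curve.times])
        np.testing.assert_allclose(curve.survival, 1 - ecdf, atol=1e-12)

    def test_nelson_aalen_hand_increments(self):
        tab = event_table([1.0, 2.0, 3.0], [1, 1, 1])
        haz = nelson_aalen(tab)
        np.testing.assert_allclose(haz.values, [1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2 + 1])
        np.testing.assert_allclose(haz.variance, [1 / 9, 1 / 9 + 1 / 4, 1 / 9 + 1 / 4 + 1])

    def test_all_censored_hazard_is_empty(self):
        tab = event_table([5.0, 6.0], [0, 0])
        haz = nelson_aalen(tab)
        assert len(haz.times) == 0

    def test_exhaustive_small_fixtures_match_enumeration(self):
        for times, events in all_small_fixtures():
            tab = event_table(times, events)
            t_o, s_o, m_o, v_o = brute_km_na(times, events)
            curve, haz = kaplan_meier(tab), nelson_aalen(tab)
            np.testing.assert_allclose(curve.survival, s_o, atol=1e-10)
            np.testing.assert_allclose(haz.values, m_o, atol=1e-10)
            np.testing.assert_allclose(haz.variance, v_o, atol=1e-10)

    def test_exp_negative_cumhaz_dominates_km(self):
        # exp(-m_NA) >= S_KM at every event time
        for times, events in all_small_fixtures():
            tab = event_table(times, events)
            curve, haz = kaplan_meier(tab), nelson_aalen(tab)
            assert (np.exp(-haz.values) >= curve.survival - 1e-12).all()

    def test_agrees_with_lifelines(self):
        from lifelines import KaplanMeierFitter, NelsonAalenFitter

        rng = np.random.default_rng(1)
        t = rng.exponential(10, 300).round(1)
        e = (rng.uniform(size=300) > 0.2).astype(int)
        tab = event_table(t, e)
        curve, haz = kaplan_meier(tab), nelson_aalen(tab)
        km = KaplanMeierFitter().fit(t, e)
        na = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(t, e)
        np.testing.assert_allclose(
            curve.survival, km.survival_function_at_times(curve.times), atol=1e-10
        )
        np.testing.assert_allclose(
            haz.values, na.cumulative_hazard_at_times(haz.times), atol=1e-10
        )

    def test_constant_hazard_slope(self):
        rng = np.random.default_rng(2)
        mu = 0.2
        t = rng.exponential(1 / mu, 5000)
        haz = nelson_aalen(event_table(t, np.ones(5000, int)))
        # regression through the bulk of the curve
        keep = haz.values < 3.0
        slope = np.polyfit(haz.times[keep], haz.values[keep], 1)[0]
        assert slope == pytest.approx(mu, rel=0.1)

    def test_empty_table_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            kaplan_meier(pd.DataFrame(columns=["time_days", "event", "group"]))


# ---------------------------------------------------------------- log-rank
class TestLogrank:
    def test_identical_tables_are_null(self):
        tab = event_table([1.0, 2.0, 3.0], [1, 1, 1])
        stat, p = logrank_test(tab, tab)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_matches_hand_tables(self):
        a = event_table([1.0, 2.0], [1, 1], "A")
        b = event_table([3.0, 4.0], [1, 1], "B")
        stat, _ = logrank_test(a, b)
        expected = brute_logrank(
            a["time_days"].to_numpy(), a["event"].to_numpy(),
            b["time_days"].to_numpy(), b["event"].to_numpy(),
        )
        assert stat == pytest.approx(expected, abs=1e-10)

    def test_p_value_agrees_with_permutation(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 20).round(1)
        groups = np.repeat([0, 1], 10)
        a = event_table(t[groups == 0], np.ones(10, int), "A")
        b = event_table(t[groups == 1], np.ones(10, int), "B")
        _, p = logrank_test(a, b)
        n_perm, hits = 2000, 0
        stat_obs, _ = logrank_test(a, b)
        for _ in range(n_perm):
            perm = rng.permutation(groups)
            sa = event_table(t[perm == 0], np.ones(10, int), "A")
            sb = event_table(t[perm == 1], np.ones(10, int), "B")
            s, _ = logrank_test(sa, sb)
            hits += s >= stat_obs - 1e-12
        p_perm = hits / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        # chi-square approximation vs exact permutation: allow both MC noise
        # and the asymptotic gap at n=20
        assert abs(p - p_perm) < 3 * se + 0.04

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(500):
            t = rng.exponential(10, 40)
            a = event_table(t[:20], np.ones(20, int), "A")
            b = event_table(t[20:], np.ones(20, int), "B")
            pvals.append(logrank_test(a, b)[1])
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01


# ------------------------------------------------------------- summaries
class TestLifespanSummary:
    def test_mean_and_max(self):
        s = lifespan_summary(event_table([10.0, 20.0, 30.0], [1, 1, 1]))
        assert s.mean_lifespan == 20.0
        assert s.max_lifespan == 30.0
        assert s.km_restricted_mean == pytest.approx(20.0)

    def test_single_death(self):
        s = lifespan_summary(event_table([17.0], [1]))
        assert s.mean_lifespan == s.max_lifespan == 17.0

    def test_restricted_mean_equals_naive_without_censoring(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(15, 500)
        s = lifespan_summary(event_table(t, np.ones(500, int)))
        assert s.km_restricted_mean == pytest.approx(s.mean_lifespan, rel=1e-9)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            lifespan_summary(event_table([5.0], [0]))


class TestRelativeExtension:
    @pytest.mark.parametrize(
        "treated,control,rounding,expected",
        [
            (26.9, 23.7, "one-decimal", 13.5),
            (160.0, 17.0, "nearest-ten", 840.0),
            (23.3, 23.3, "one-decimal", 0.0),
            (39.0, 17.0, "nearest-ten", 130.0),
        ],
    )
    def test_rounding_conventions(self, treated, control, rounding, expected):
        assert relative_extension(treated, control, rounding) == expected

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            relative_extension(10.0, 0.0)


# ------------------------------------------------------------ Gompertz fit
class TestFitGompertz:
    def test_recovers_exact_closed_form(self):
        law = GompertzLaw(M0=0.003, alpha=0.3)
        t = np.linspace(2, 25, 60)
        fit = fit_gompertz_curve(t, gompertz_cumhaz(law, t))
        assert fit.alpha == pytest.approx(0.3, rel=1e-6)
        assert fit.M0 == pytest.approx(0.003, rel=1e-6)

    def test_simulation_recovery_rate(self):
        law = GompertzLaw(M0=0.003, alpha=0.3)
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            t = law.sample(2000, rng)
            fit = fit_gompertz(event_table(t, np.ones(2000, int)))
            hits += abs(fit.alpha / 0.3 - 1) <= 0.10
        assert hits >= 90

    def test_exponential_cohort_yields_negligible_exponent(self):
        # constant-hazard data: the fitted exponent collapses toward zero
        rng = np.random.default_rng(7)
        t = rng.exponential(5.0, 20000)
        fit = fit_gompertz(event_table(t, np.ones(20000, int)))
        assert fit.alpha <= 0.02 / 5.0

    def test_too_few_deaths_in_window_rejected(self):
        with pytest.raises(ValueError, match="deaths inside"):
            fit_gompertz(event_table([1.0, 2.0, 3.0], [1, 1, 1]))


# ---------------------------------------------------------------- plateau
class TestEstimatePlateau:
    def test_constant_hazard_recovered(self):
        rng = np.random.default_rng(8)
        mu = 0.2
        t = rng.exponential(1 / mu, 5000)
        est = estimate_plateau(event_table(t, np.ones(5000, int)))
        assert abs(est.M_plateau - mu) < 3 * est.se + 0.05 * mu

    def test_gompertz_data_flagged_as_non_plateauing(self):
        law = GompertzLaw(M0=0.003, alpha=0.3)
        rng = np.random.default_rng(9)
        t = law.sample(5000, rng)
        est = estimate_plateau(event_table(t, np.ones(5000, int)))
        assert est.diagnostics["exceeds_midlife"]
        assert est.M_plateau > est.diagnostics["midlife_hazard"]

    def test_tail_needs_three_event_times(self):
        with pytest.raises(ValueError):
            estimate_plateau(event_table([1.0, 1.0, 1.0, 2.0], [1, 1, 1, 1]), tail=0.2)


# ------------------------------------------------------ rescaled collapse
class TestRescaleAndCollapse:
    def test_identical_curves_collapse_exactly(self):
        rng = np.random.default_rng(10)
        t = GompertzLaw(M0=0.005, alpha=0.1).sample(500, rng)
        c = kaplan_meier(event_table(t, np.ones(500, int), "A"))
        c2 = kaplan_meier(event_table(t, np.ones(500, int), "B"))
        stat, table = rescale_and_collapse([c, c2], [t.mean(), t.mean()])
        assert stat == 0.0
        assert table.shape[1] == 2

    def test_exact_time_scalings_collapse(self):
        # alpha2 = alpha1/3 with M0 scaled: S2(t) = S1(t/3)
        rng = np.random.default_rng(11)
        law1 = GompertzLaw(M0=0.009, alpha=0.3)
        law2 = GompertzLaw(M0=0.003, alpha=0.1)
        t1 = law1.sample(2000, rng)
        t2 = law2.sample(2000, rng)
        c1 = kaplan_meier(event_table(t1, np.ones(2000, int), "fast"))
        c2 = kaplan_meier(event_table(t2, np.ones(2000, int), "slow"))
        stat_resc, _ = rescale_and_collapse([c1, c2], [t1.mean(), t2.mean()])
        stat_raw, _ = rescale_and_collapse(
            [c1, c2], [1.0, 1.0], grid=np.linspace(0, 2 * max(t1.max(), t2.max()), 801)
        )
        assert stat_resc < 0.06
        assert stat_raw > 3 * stat_resc

    def test_scaling_violation_detected(self):
        # equal alpha, M0 differing 10x: not a time-scaling family
        rng = np.random.default_rng(12)
        t1 = GompertzLaw(M0=0.03, alpha=0.3).sample(2000, rng)
        t2 = GompertzLaw(M0=0.003, alpha=0.3).sample(2000, rng)
        c1 = kaplan_meier(event_table(t1, np.ones(2000, int), "hiM0"))
        c2 = kaplan_meier(event_table(t2, np.ones(2000, int), "loM0"))
        stat, _ = rescale_and_collapse([c1, c2], [t1.mean(), t2.mean()])
        assert stat > 0.1

    def test_invalid_lifespans_rejected(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(5, 50)
        c = kaplan_meier(event_table(t, np.ones(50, int)))
        with pytest.raises(ValueError):
            rescale_and_collapse([c, c], [5.0, 0.0])


class TestPlateauVsAlphaReport:
    def test_single_cohort_row(self):
        rng = np.random.default_rng(14)
        t = GompertzLaw(M0=0.005, alpha=0.2).sample(3000, rng)
        df = plateau_vs_alpha_report([event_table(t, np.ones(3000, int), "only")])
        assert len(df) == 1
        assert df.loc[0, "error"] == ""
        assert df.loc[0, "alpha_hat"] == pytest.approx(0.2, rel=0.15)

    def test_failing_cohort_contained(self):
        rng = np.random.default_rng(15)
        good = event_table(GompertzLaw(M0=0.005, alpha=0.2).sample(3000, rng),
                           np.ones(3000, int), "good")
        bad = event_table([1.0, 2.0, 3.0], [1, 1, 1], "bad")
        df = plateau_vs_alpha_report([good, bad])
        assert df.loc[df["group"] == "bad", "error"].iloc[0] != ""
        assert df.loc[df["group"] == "good", "error"].iloc[0] == ""
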