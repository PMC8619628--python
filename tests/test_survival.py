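"""Survival screen vs. hand-computed and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import stromaquant as sq
from stromaquant.content import FeatureVector
from stromaquant.survival import PatientRecord


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def mannwhitney_permutation_oracle(x, y):
    """Exact permutation distribution of the Mann-Whitney U statistic."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mean_u = n1 * len(y) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(r - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_obs, count / total


def spearman_rank_oracle(x, y):
    """Pearson correlation of average ranks — the defining formula."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def cox_partial_loglik_no_ties(beta, time, event, x):
    """Partial log-likelihood for one covariate, distinct event times."""
    order = np.argsort(time)
    time, event, x = time[order], event[order], x[order]
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = x[i:]  # later or equal times are at risk
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * risk)))
    return ll


def logrank_hand_oracle(time, event, group):
    """Two-group log-rank chi-square from the observed-minus-expected sums."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    labels = np.unique(group)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == labels[0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

class TestGroupComparisons:
    def test_identical_groups_t_test(self):
        stat, p = sq.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "t")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_mannwhitney_matches_permutation_oracle(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])
        u_oracle, p_oracle = mannwhitney_permutation_oracle(x, y)
        stat, p = sq.compare_groups(x, y, "mannwhitney")
        assert u_oracle == pytest.approx(4.5)
        assert stat == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle, abs=1e-9)  # both exactly 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            sq.compare_groups([2.0, 2.0], [3.0, 3.0], "t")

    def test_spearman_monotone_transforms(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        rho, _ = sq.spearman(x, 2 * x + 1)
        assert rho == pytest.approx(1.0)
        rho, _ = sq.spearman(x, -x ** 3)
        assert rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_spearman_matches_rank_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 10, 12).astype(float)  # ties included
        y = rng.integers(0, 10, 12).astype(float)
        rho, _ = sq.spearman(x, y)
        assert rho == pytest.approx(spearman_rank_oracle(x, y), abs=1e-12)


class TestCox:
    def test_matches_grid_search_partial_likelihood(self):
        """On random no-ties binary-covariate toys, the fitted coefficient
        maximizes the partial likelihood (1-D numerical oracle, 1e-4)."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 20:
            n = 8
            time = rng.permutation(np.arange(1.0, n + 1))
            event = np.ones(n, int)
            x = rng.integers(0, 2, n).astype(float)
            if x.sum() in (0, n):
                continue
            try:
                res = sq.cox_fit(time, event, pd.DataFrame({"x": x}))[0]
            except RuntimeError:
                continue  # separated draw; covered by its own test
            opt = optimize.minimize_scalar(
                lambda b: -cox_partial_loglik_no_ties(b, time, event, x),
                bounds=(-20, 20), method="bounded",
                options={"xatol": 1e-10})
            assert res.coefficient == pytest.approx(opt.x, abs=1e-4)
            assert res.log_likelihood == pytest.approx(-opt.fun, abs=1e-6)
            checked += 1

    def test_null_covariate_estimates_near_zero(self):
        rng = np.random.default_rng(3)
        n = 1000
        time = rng.exponential(20, n)
        event = (time < 36).astype(int)
        time = np.minimum(time, 36)
        x = rng.normal(0, 1, n)
        res = sq.cox_fit(time, event, pd.DataFrame({"x": x}))[0]
        assert abs(res.coefficient) < 0.1
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_monotone_likelihood_raises(self):
        # all treated subjects fail first: the partial likelihood is
        # monotone in beta and no finite maximizer exists
        time = np.arange(1.0, 7.0)
        event = np.ones(6, int)
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        with pytest.raises(RuntimeError, match="separation|converge"):
            sq.cox_fit(time, event, pd.DataFrame({"x": x}))

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant covariate"):
            sq.cox_fit([1, 2, 3, 4], [1, 1, 0, 1],
                       pd.DataFrame({"x": [2.0, 2.0, 2.0, 2.0]}))

    def test_aic_invariant_to_column_order(self):
        rng = np.random.default_rng(5)
        n = 120
        x = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        time = rng.exponential(20, n)
        event = (time < 30).astype(int)
        time = np.minimum(time, 30)
        aic_abc = sq.cox_fit(time, event, x)[0].aic
        aic_cba = sq.cox_fit(time, event, x[["c", "b", "a"]])[0].aic
        assert aic_abc == pytest.approx(aic_cba, abs=1e-8)


class TestLikelihoodRatio:
    @staticmethod
    def _sim(n, rng, beta=0.0):
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        rate = 0.05 * np.exp(beta * x2)
        t = rng.exponential(1 / rate)
        event = (t < 36).astype(int)
        return np.minimum(t, 36), event, pd.DataFrame({"x1": x1, "x2": x2})

    def test_identical_models(self):
        rng = np.random.default_rng(0)
        time, event, x = self._sim(100, rng)
        m = sq.cox_fit(time, event, x[["x1"]])
        chi2, df, p = sq.lr_test(m, m)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 0 and p == 1.0

    def test_null_added_covariate_is_chi2_one_df(self):
        rng = np.random.default_rng(1)
        chi2s = []
        for _ in range(400):
            time, event, x = self._sim(80, rng)
            small = sq.cox_fit(time, event, x[["x1"]])
            large = sq.cox_fit(time, event, x)
            chi2s.append(sq.lr_test(small, large)[0])
        # mean of chi2(1) is 1; 400 replicates give SE ~ sqrt(2/400) ~ 0.07
        assert np.mean(chi2s) == pytest.approx(1.0, abs=0.21)

    def test_true_effect_detected(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(40):
            time, event, x = self._sim(150, rng, beta=0.5)
            small = sq.cox_fit(time, event, x[["x1"]])
            large = sq.cox_fit(time, event, x)
            hits += sq.lr_test(small, large)[2] < 0.05
        assert hits >= 32  # >= 80% power at this n

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(3)
        time, event, x = self._sim(100, rng)
        small = sq.cox_fit(time, event, x[["x1"]])
        large = sq.cox_fit(time, event, x)
        with pytest.raises(ValueError, match="not nested"):
            sq.lr_test(large, small)


class TestProportionalHazardsCheck:
    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(4)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 120
            x = rng.normal(0, 1, n)
            t = rng.exponential(1 / (0.05 * np.exp(0.3 * x)))
            event = (t < 36).astype(int)
            t = np.minimum(t, 36)
            table = sq.ph_check(t, event, pd.DataFrame({"x": x}))
            rejections += table.loc["x", "p"] < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.04)

    def test_time_varying_effect_detected(self):
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(30):
            n = 500
            x = rng.normal(0, 1, n)
            # effect reverses over time: early hazard up, late hazard down
            t_early = rng.exponential(1 / (0.10 * np.exp(1.0 * x)))
            t_late = 10 + rng.exponential(1 / (0.10 * np.exp(-1.0 * x)))
            t = np.where(t_early < 10, t_early, t_late)
            event = (t < 36).astype(int)
            t = np.minimum(t, 36)
            table = sq.ph_check(t, event, pd.DataFrame({"x": x}))
            rejections += table.loc["x", "p"] < 0.05
        assert rejections / 30 > 0.5

    def test_deterministic_on_fixed_input(self):
        rng = np.random.default_rng(6)
        n = 80
        x = rng.normal(0, 1, n)
        t = rng.exponential(10, n)
        event = (t < 15).astype(int)
        t = np.minimum(t, 15)
        a = sq.ph_check(t, event, pd.DataFrame({"x": x}))
        b = sq.ph_check(t, event, pd.DataFrame({"x": x}))
        pd.testing.assert_frame_equal(a, b)


class TestKaplanMeier:
    def test_three_subject_hand_product_limit(self):
        times, surv = sq.km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
        s = dict(zip(times, surv))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[2.0] == pytest.approx(1 / 3)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10, 50)
        times, surv = sq.km_estimate(t, np.ones(50, int))
        for tk, sk in zip(times[1:], surv[1:]):
            assert sk == pytest.approx((t > tk).mean(), abs=1e-12)

    def test_survival_curves_start_at_one_and_decrease(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(10, 40)
        e = (t < 12).astype(int)
        times, surv = sq.km_estimate(np.minimum(t, 12), e)
        assert surv[0] == 1.0
        assert all(b <= a for a, b in zip(surv, surv[1:]))

    def test_identical_groups_give_null_logrank(self):
        t = [2.0, 4.0, 6.0, 8.0]
        e = [1, 1, 0, 1]
        km = sq.km_logrank(t + t, e + e, ["A"] * 4 + ["B"] * 4)
        assert km.logrank_chi2 == pytest.approx(0.0, abs=1e-9)
        assert km.logrank_p == pytest.approx(1.0)

    def test_logrank_matches_hand_oracle(self):
        time = [1.0, 3.0, 5.0, 7.0, 2.0, 4.0, 6.0, 8.0]
        event = [1, 1, 0, 1, 1, 1, 1, 0]
        group = ["A"] * 4 + ["B"] * 4
        km = sq.km_logrank(time, event, group)
        assert km.logrank_chi2 == pytest.approx(
            logrank_hand_oracle(time, event, group), abs=1e-6)

    def test_logrank_null_p_values_are_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(1000):
            t = rng.exponential(10, 40)
            e = (t < 15).astype(int)
            t = np.minimum(t, 15)
            g = np.array(["A"] * 20 + ["B"] * 20)
            ps.append(sq.km_logrank(t, e, g).logrank_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            sq.km_logrank([1, 2], [1, 1], ["A", "A"])


class TestDichotomize:
    def test_tie_at_mean_goes_low(self):
        labels = sq.dichotomize_at_mean([1.0, 2.0, 3.0])
        assert list(labels) == ["Low", "Low", "High"]

    def test_idempotent_labeling(self):
        x = np.array([0.1, 0.9, 0.5, 0.7])
        a = sq.dichotomize_at_mean(x)
        b = sq.dichotomize_at_mean(x)
        assert list(a) == list(b)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sq.dichotomize_at_mean([2.0, 2.0, 2.0])


class TestAggregation:
    def test_single_core_identity(self):
        fv = FeatureVector(af=0.3, i_r=80.0)
        assert sq.aggregate_patient([fv]) == fv

    def test_mean_and_missing_rule(self):
        cores = [FeatureVector(af=0.2, fiber_angle_deg=15.0),
                 FeatureVector(af=0.4),
                 FeatureVector(af=0.6, fiber_angle_deg=45.0)]
        mean = sq.aggregate_patient(cores)
        assert mean.af == pytest.approx(0.4)
        assert mean.fiber_angle_deg == pytest.approx(30.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sq.aggregate_patient([])


class TestUnivariableScreen:
    def test_recovers_true_effect_features(self):
        cfg = sq.CohortConfig(n_patients=300, seed=17,
                              feature_effects={"i_r": 0.05,
                                               "fiber_width_um": 1.2})
        records = sq.simulate_cohort(cfg)
        screen = sq.univariable_screen(records)
        assert "i_r" in screen.flagged
        assert "fiber_width_um" in screen.flagged
        hr = dict(zip(screen.table["variable"], screen.table["hr"]))
        assert hr["i_r"] > 1 and hr["fiber_width_um"] > 1

    def test_table_order_is_fixed_and_deterministic(self):
        cfg = sq.CohortConfig(n_patients=80, seed=23)
        records = sq.simulate_cohort(cfg)
        a = sq.univariable_screen(records)
        b = sq.univariable_screen(records)
        assert list(a.table["variable"]) == list(sq.SCREEN_FEATURES)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_collinear_features_put_in_separate_models(self):
        rng = np.random.default_rng(11)
        records = []
        for i in range(150):
            z = rng.normal()
            af = 0.3 + 0.1 * z
            width = 3.0 + 0.8 * z + rng.normal(0, 0.05)  # rho ~ 1 with af
            fv = FeatureVector(af=af, i_r=80.0 + rng.normal(0, 20),
                               norm_intensity=0.45, coherence=0.3,
                               fiber_width_um=width, fiber_length_um=60.0,
                               fiber_straightness=0.85, fiber_angle_deg=45.0)
            rate = 0.02 * np.exp(1.5 * z)
            t = rng.exponential(1 / rate)
            records.append(PatientRecord(
                patient_id=f"P{i}", core_features=[fv], mean_features=fv,
                time_months=float(max(min(t, 36.0), 1e-6)),
                event=int(t <= 36.0)))
        screen = sq.univariable_screen(records)
        assert {"af", "fiber_width_um"} <= set(screen.flagged)
        for group in screen.model_groups:
            assert not {"af", "fiber_width_um"} <= set(group)

    def test_too_few_events_rejected(self):
        cfg = sq.CohortConfig(n_patients=10, seed=3, baseline_hazard=1e-6)
        records = sq.simulate_cohort(cfg)
        with pytest.raises(ValueError, match="events"):
            sq.univariable_screen(records)
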