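import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as lifelines_logrank
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc

from ptfr_survkit import (
    SurvivalCohort,
    bootstrap632,
    brier_prediction_error,
    cd_auc,
    generate_cohort,
    harrell_cindex,
    log_rank_test,
)

from conftest import exponential_spec


def _structured(cohort):
    return np.array(
        list(zip(cohort.event.astype(bool), cohort.time_observed)),
        dtype=[("event", bool), ("time", float)],
    )


class TestHarrellCindex:
    def test_three_subject_enumeration(self):
        # pairs: (2,4): 0.9 > 0.5 concordant; (2,6): 0.9 > 0.7 concordant;
        # (4,6): 0.5 < 0.7 discordant -> 2/3
        c, se = harrell_cindex([2, 4, 6], [1, 1, 1], [0.9, 0.5, 0.7])
        assert c == pytest.approx(2 / 3)
        assert se == pytest.approx(np.sqrt((2 / 3) * (1 / 3) / 3))

    def test_perfect_concordance(self):
        times = np.arange(1.0, 11.0)
        c, _ = harrell_cindex(times, np.ones(10), -times)
        assert c == 1.0

    def test_negated_scores_flip(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 50)
        e = rng.binomial(1, 0.7, 50)
        r = rng.normal(size=50)
        c_pos, _ = harrell_cindex(t, e, r)
        c_neg, _ = harrell_cindex(t, e, -r)
        assert c_pos + c_neg == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 400)
        e = rng.binomial(1, 0.7, 400)
        c, se = harrell_cindex(t, e, rng.normal(size=400))
        # pairs share subjects, so the pair-count SE understates the sampling
        # noise of C; use a direct band for the null check instead
        assert abs(c - 0.5) < 0.05
        assert 0 < se < 0.01

    def test_matches_scikit_survival(self, exponential_cohort):
        rng = np.random.default_rng(2)
        risk = rng.normal(size=exponential_cohort.n)
        c_mine, _ = harrell_cindex(
            exponential_cohort.time_observed, exponential_cohort.event, risk
        )
        c_ref = concordance_index_censored(
            exponential_cohort.event.astype(bool),
            exponential_cohort.time_observed,
            risk,
        )[0]
        assert c_mine == pytest.approx(c_ref, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            harrell_cindex([5, 5], [0, 0], [1, 2])


class TestCdAuc:
    def test_perfect_separation(self):
        t = np.array([1.0, 2, 3, 10, 11, 12])
        e = np.ones(6)
        risk = -t
        assert cd_auc(t, e, risk, 5.0) == 1.0

    def test_no_censoring_equals_binary_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        t = rng.exponential(10, 200)
        risk = -t + rng.normal(0, 5, 200)
        t_eval = float(np.median(t))
        auc = cd_auc(t, np.ones(200), risk, t_eval)
        assert auc == pytest.approx(roc_auc_score(t <= t_eval, risk))

    def test_censored_toy_matches_weighted_pair_sum(self):
        """Six-subject censored example against an exhaustive weighted
        Mann-Whitney sum with censoring weights from an independent KM fit."""
        t = np.array([2.0, 4.0, 5.0, 6.0, 8.0, 9.0])
        e = np.array([1, 0, 1, 0, 1, 0])
        risk = np.array([0.9, 0.1, 0.8, 0.4, 0.2, 0.3])
        t_eval = 5.5
        kmf = KaplanMeierFitter()
        kmf.fit(t, 1 - e)  # censoring distribution
        g = lambda x: float(kmf.survival_function_at_times(x).iloc[0])
        num = den = 0.0
        for i in range(6):
            if not (t[i] <= t_eval and e[i] == 1):
                continue
            wi = 1.0 / g(t[i] - 1e-9)
            for j in range(6):
                if t[j] <= t_eval:
                    continue
                w = wi / g(t_eval)
                num += w * ((risk[i] > risk[j]) + 0.5 * (risk[i] == risk[j]))
                den += w
        assert cd_auc(t, e, risk, t_eval) == pytest.approx(num / den)

    def test_matches_scikit_survival(self, exponential_cohort):
        rng = np.random.default_rng(4)
        risk = rng.normal(size=exponential_cohort.n)
        t_eval = float(np.median(exponential_cohort.time_observed))
        mine = cd_auc(
            exponential_cohort.time_observed, exponential_cohort.event,
            risk, t_eval,
        )
        y = _structured(exponential_cohort)
        ref = cumulative_dynamic_auc(y, y, risk, [t_eval])[0][0]
        assert mine == pytest.approx(ref, abs=1e-10)

    def test_degenerate_windows_rejected(self):
        t = np.array([5.0, 6.0, 7.0])
        with pytest.raises(ValueError):
            cd_auc(t, [1, 1, 1], [1, 2, 3], 1.0)  # no cases yet
        with pytest.raises(ValueError):
            cd_auc(t, [1, 1, 1], [1, 2, 3], 10.0)  # nobody at risk after


class TestLogRank:
    def test_self_comparison_is_null(self, exponential_cohort):
        chi2, p = log_rank_test(exponential_cohort, exponential_cohort)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_detected(self):
        a = generate_cohort(exponential_spec(n=200, lam=0.02, seed=1))
        b = generate_cohort(exponential_spec(n=200, lam=0.004, seed=2))
        _, p = log_rank_test(a, b)
        assert p < 0.001

    def test_hand_tabulated_small_table(self):
        # group a: events at 1, 3; group b: event at 2, censored at 4
        a = SurvivalCohort(np.arange(2), [1.0, 3.0], [1, 1],
                           np.empty((2, 0)), ())
        b = SurvivalCohort(np.arange(2), [2.0, 4.0], [1, 0],
                           np.empty((2, 0)), ())
        # t=1: n=4, na=2, d=1 -> O-E = 1 - 1/2, V = (1/2)(1/2)
        # t=2: n=3, na=1, d=1 -> O-E = 0 - 1/3, V = (1/3)(2/3)
        # t=3: n=2, na=1, d=1 -> O-E = 1 - 1/2, V = (1/2)(1/2)
        o_minus_e = 0.5 - 1 / 3 + 0.5
        var = 0.25 + 2 / 9 + 0.25
        chi2, _ = log_rank_test(a, b)
        assert chi2 == pytest.approx(o_minus_e**2 / var)

    def test_matches_lifelines(self, exponential_cohort):
        half = exponential_cohort.n // 2
        a = exponential_cohort.subset(np.arange(half))
        b = exponential_cohort.subset(np.arange(half, exponential_cohort.n))
        chi2, p = log_rank_test(a, b)
        ref = lifelines_logrank(
            a.time_observed, b.time_observed, a.event, b.event
        )
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_eventless_group_rejected(self):
        a = SurvivalCohort(np.arange(2), [1.0, 2.0], [1, 1],
                           np.empty((2, 0)), ())
        b = SurvivalCohort(np.arange(2), [1.0, 2.0], [0, 0],
                           np.empty((2, 0)), ())
        with pytest.raises(ValueError):
            log_rank_test(a, b)


class TestBrier:
    def test_oracle_predictor_scores_zero(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        cohort = SurvivalCohort(np.arange(4), t, np.ones(4, dtype=int),
                                np.empty((4, 0)), ())

        def oracle(coh, times):
            return (coh.time_observed[:, None] > np.asarray(times)[None, :]
                    ).astype(float)

        curve, app = brier_prediction_error(oracle, cohort,
                                            np.linspace(0, 8, 9))
        np.testing.assert_allclose(curve, 0.0)
        assert app == 0.0

    def test_constant_half_predictor_without_censoring(self):
        t = np.linspace(1, 50, 30)
        cohort = SurvivalCohort(np.arange(30), t, np.ones(30, dtype=int),
                                np.empty((30, 0)), ())
        half = lambda coh, times: np.full((coh.n, len(times)), 0.5)
        curve, app = brier_prediction_error(half, cohort,
                                            np.linspace(0, 50, 11))
        np.testing.assert_allclose(curve, 0.25)
        assert app == pytest.approx(0.25)

    def test_censored_set_matches_hand_weighting(self):
        """Small censored cohort against an explicit IPCW sum with weights
        from an independent KM fit of the censoring distribution."""
        t = np.array([2.0, 3.0, 5.0, 7.0, 9.0])
        e = np.array([1, 0, 1, 0, 1])
        cohort = SurvivalCohort(np.arange(5), t, e, np.empty((5, 0)), ())
        rng = np.random.default_rng(5)
        surv = np.sort(rng.uniform(0.2, 1.0, size=(5, 1)))[:, ::-1]
        pred = lambda coh, times: np.tile(surv, (1, len(times)))[: coh.n]
        t_star = 6.0
        kmf = KaplanMeierFitter()
        kmf.fit(t, 1 - e)
        g = lambda x: float(kmf.survival_function_at_times(x).iloc[0])
        total = 0.0
        for i in range(5):
            s_i = surv[i, 0]
            if t[i] <= t_star and e[i] == 1:
                total += s_i**2 / g(t[i] - 1e-9)
            elif t[i] > t_star:
                total += (1 - s_i) ** 2 / g(t_star)
        curve, _ = brier_prediction_error(pred, cohort, np.array([0.0, t_star]))
        assert curve[1] == pytest.approx(total / 5)

    def test_grid_beyond_data_rejected(self):
        cohort = SurvivalCohort(np.arange(3), [1.0, 2, 3], [1, 1, 1],
                                np.empty((3, 0)), ())
        half = lambda coh, times: np.full((coh.n, len(times)), 0.5)
        with pytest.raises(ValueError, match="beyond"):
            brier_prediction_error(half, cohort, np.array([0.0, 10.0]))

    def test_km_marginal_beats_constant_half(self, exponential_cohort):
        from ptfr_survkit import kaplan_meier

        km = kaplan_meier(exponential_cohort)
        km_pred = lambda coh, times: np.tile(
            np.atleast_1d(km.evaluate(times)), (coh.n, 1)
        )
        half = lambda coh, times: np.full((coh.n, len(times)), 0.5)
        grid = np.linspace(0, np.quantile(
            exponential_cohort.time_observed, 0.9), 21)
        _, app_km = brier_prediction_error(km_pred, exponential_cohort, grid)
        _, app_half = brier_prediction_error(half, exponential_cohort, grid)
        assert app_km <= app_half


class TestBootstrap632:
    @staticmethod
    def constant_procedure(train):
        return lambda coh, times: np.full((coh.n, len(times)), 0.5)

    def test_degenerate_predictor_collapses_to_app_err(self, exponential_cohort):
        grid = np.linspace(
            0, np.quantile(exponential_cohort.time_observed, 0.8), 11
        )
        out = bootstrap632(self.constant_procedure, exponential_cohort, grid,
                           B=10, seed=0)
        # predictor independent of training data: oob error fluctuates around
        # the apparent error and err632 stays between the two
        assert min(out["app_err"], out["oob_err"]) <= out["err632"] <= max(
            out["app_err"], out["oob_err"]
        )
        assert out["err632"] == pytest.approx(
            0.368 * out["app_err"] + 0.632 * out["oob_err"]
        )

    def test_deterministic_per_seed(self, exponential_cohort):
        grid = np.linspace(
            0, np.quantile(exponential_cohort.time_observed, 0.8), 11
        )
        a = bootstrap632(self.constant_procedure, exponential_cohort, grid,
                         B=5, seed=3)
        b = bootstrap632(self.constant_procedure, exponential_cohort, grid,
                         B=5, seed=3)
        assert a == b

    def test_overfitting_predictor_pays_out_of_bag(self):
        """A 1-nearest-neighbour style memoriser is optimistic on its own
        training data, so the .632 error must exceed the apparent error."""
        cohort = generate_cohort(exponential_spec(n=120, beta=0.3, seed=14))
        grid = np.linspace(0, np.quantile(cohort.time_observed, 0.8), 11)

        def memoriser(train):
            tx = train.covariates[:, 0]
            tt = train.time_observed

            def predict(coh, times):
                idx = np.abs(coh.covariates[:, 0][:, None] - tx[None, :]).argmin(1)
                return (tt[idx][:, None] > np.asarray(times)[None, :]).astype(float)

            return predict

        out = bootstrap632(memoriser, cohort, grid, B=20, seed=1)
        assert out["err632"] > out["app_err"]
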