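"""Discrimination and calibration metrics for right-censored predictions.

All metrics here are implemented from first principles:

* Harrell's concordance index over comparable pairs, with a Noether-type
  pair-count standard error;
* cumulative/dynamic time-dependent AUC with inverse-probability-of-censoring
  weights (IPCW) from the Kaplan-Meier estimate of the censoring distribution;
* the two-group log-rank test;
* IPCW Brier-score prediction-error curves with their time-averaged apparent
  error; and
* the .632 bootstrap prediction error
  err632 = 0.368 x AppErr + 0.632 x mean out-of-bag error.

A survival predictor is any callable ``predict(cohort, times) -> (n, m)``
matrix of S(t | x_i) values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import SurvivalCohort
from .ptfr import StepSurvivalFunction, kaplan_meier

__all__ = [
    "ModelEvaluation",
    "harrell_cindex",
    "cd_auc",
    "log_rank_test",
    "censoring_km",
    "brier_prediction_error",
    "bootstrap632",
]


@dataclass(frozen=True)
class ModelEvaluation:
    """Performance summary for one fitted model on one cohort."""

    c_index: float
    c_index_se: float
    auc: float
    eval_time: float
    brier_times: np.ndarray = field(default_factory=lambda: np.array([]))
    brier_curve: np.ndarray = field(default_factory=lambda: np.array([]))
    app_err: float = float("nan")
    err632: float = float("nan")
    n_bootstrap: int = 0

    def to_dict(self) -> dict:
        return {
            "c_index": self.c_index,
            "c_index_se": self.c_index_se,
            "auc": self.auc,
            "eval_time": self.eval_time,
            "app_err": self.app_err,
            "err632": self.err632,
            "n_bootstrap": self.n_bootstrap,
        }


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------


def harrell_cindex(times, events, risk) -> tuple[float, float]:
    """Harrell's C over comparable pairs; ties in risk count one half.

    A pair (i, j) is comparable when the shorter observed time belongs to a
    subject with an event.  Returns (c, se) with the Noether-type pair-count
    standard error sqrt(c (1 - c) / n_pairs).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    r = np.asarray(risk, dtype=float)
    concordant = discordant = tied = 0
    n = len(t)
    for i in range(n):
        if e[i] != 1:
            continue
        comparable = (t > t[i]) | ((t == t[i]) & (e == 0))
        comparable[i] = False
        ri = r[comparable]
        concordant += int(np.sum(r[i] > ri))
        discordant += int(np.sum(r[i] < ri))
        tied += int(np.sum(r[i] == ri))
    pairs = concordant + discordant + tied
    if pairs == 0:
        raise ValueError("no comparable pairs under censoring")
    c = (concordant + 0.5 * tied) / pairs
    se = float(np.sqrt(max(c * (1 - c), 0.0) / pairs))
    return float(c), se


def censoring_km(times, events, tail_rule: str = "carry_last") -> StepSurvivalFunction:
    """Kaplan-Meier estimate G of the censoring distribution (roles of event
    and censoring reversed; ties resolved with events still at risk)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    cohort = SurvivalCohort(
        subject_id=np.arange(len(t)),
        time_observed=t,
        event=1 - e,
        covariates=np.empty((len(t), 0)),
        covariate_names=(),
    )
    if cohort.n_events == 0:  # no censoring at all: G == 1
        return StepSurvivalFunction(np.array([]), np.array([]), np.array([]),
                                    np.array([]), tail_rule)
    return kaplan_meier(cohort, tail_rule=tail_rule)


def _left_limit(g: StepSurvivalFunction, t: np.ndarray) -> np.ndarray:
    """G(t-): the step-function value immediately before each t."""
    t = np.asarray(t, dtype=float)
    return np.atleast_1d(g.evaluate(np.nextafter(t, -np.inf)))


def cd_auc(times, events, risk, t_eval: float) -> float:
    """Cumulative/dynamic AUC at ``t_eval`` with IPCW weights.

    Cases are subjects with an observed event by t_eval (weight 1/G(T_i-)),
    controls are those still event-free beyond t_eval (weight 1/G(t_eval));
    the statistic is the weighted Mann-Whitney sum over case-control pairs.
    Without censoring every weight is 1 and this is the classical binary AUC
    for the indicator {T <= t_eval}.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    r = np.asarray(risk, dtype=float)
    cases = (t <= t_eval) & (e == 1)
    controls = t > t_eval
    if not cases.any():
        raise ValueError(f"no events observed by t_eval={t_eval}")
    if not controls.any():
        raise ValueError(f"no subjects at risk beyond t_eval={t_eval}")
    g = censoring_km(t, e)
    w_case = 1.0 / _left_limit(g, t[cases])
    g_te = float(g.evaluate(t_eval))
    if g_te <= 0 or np.any(~np.isfinite(w_case)):
        raise ValueError("censoring survival vanishes before t_eval; AUC undefined")
    w_ctrl = np.full(controls.sum(), 1.0 / g_te)

    r_case, r_ctrl = r[cases], r[controls]
    cmp = (r_case[:, None] > r_ctrl[None, :]).astype(float)
    cmp += 0.5 * (r_case[:, None] == r_ctrl[None, :])
    w = w_case[:, None] * w_ctrl[None, :]
    return float(np.sum(w * cmp) / np.sum(w))


def log_rank_test(cohort_a: SurvivalCohort, cohort_b: SurvivalCohort) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, 1-df p-value)."""
    for label, c in (("a", cohort_a), ("b", cohort_b)):
        if c.n == 0:
            raise ValueError(f"group {label} is empty")
        if c.n_events == 0:
            raise ValueError(f"group {label} has no events")
    t = np.concatenate([cohort_a.time_observed, cohort_b.time_observed])
    e = np.concatenate([cohort_a.event, cohort_b.event])
    grp = np.concatenate([np.zeros(cohort_a.n), np.ones(cohort_b.n)])
    o_minus_e = 0.0
    var = 0.0
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        n_t = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        d_t = ((t == tt) & (e == 1)).sum()
        d1 = ((t == tt) & (e == 1) & (grp == 0)).sum()
        o_minus_e += d1 - d_t * n1 / n_t
        if n_t > 1:
            var += d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# calibration / prediction error
# ---------------------------------------------------------------------------


def brier_prediction_error(
    predict, data: SurvivalCohort, eval_times
) -> tuple[np.ndarray, float]:
    """IPCW Brier-score curve and its time-averaged apparent error.

    ``predict(cohort, times)`` must return the (n, m) matrix of predicted
    survival probabilities S(t | x_i).  At each grid time t a subject with an
    observed event by t contributes S(t|x)^2 / G(T-), a subject still under
    observation past t contributes (1 - S(t|x))^2 / G(t), and a subject
    censored by t contributes nothing.  AppErr is the trapezoidal integral of
    the curve divided by the grid span.
    """
    eval_times = np.asarray(eval_times, dtype=float)
    t_max = float(data.time_observed.max())
    if eval_times.max() > t_max:
        raise ValueError(
            f"evaluation grid extends to {eval_times.max()} beyond the last "
            f"observable time {t_max}"
        )
    t = data.time_observed
    e = data.event
    shat = np.asarray(predict(data, eval_times), dtype=float)
    if shat.shape != (data.n, len(eval_times)):
        raise ValueError("predictor returned a wrongly shaped survival matrix")
    g = censoring_km(t, e)
    g_tminus = _left_limit(g, t)
    curve = np.empty(len(eval_times))
    for k, tt in enumerate(eval_times):
        g_t = float(g.evaluate(tt))
        had_event = (t <= tt) & (e == 1)
        at_risk = t > tt
        contrib = np.zeros(data.n)
        contrib[had_event] = shat[had_event, k] ** 2 / g_tminus[had_event]
        if at_risk.any():
            if g_t <= 0:
                raise ValueError("censoring survival vanished inside the grid")
            contrib[at_risk] = (1.0 - shat[at_risk, k]) ** 2 / g_t
        curve[k] = contrib.mean()
    span = eval_times[-1] - eval_times[0]
    app_err = float(np.trapezoid(curve, eval_times) / span) if span > 0 else float(curve[0])
    return curve, app_err


def bootstrap632(
    fit_procedure,
    cohort: SurvivalCohort,
    eval_times,
    B: int = 100,
    seed: int = 0,
    max_redraws: int = 100,
) -> dict:
    """.632 bootstrap prediction error of a model-fitting procedure.

    ``fit_procedure(train_cohort)`` must return a survival predictor
    ``predict(cohort, times) -> (n, m)``.  The apparent error is the
    integrated IPCW Brier error of the model fit to the full cohort and
    evaluated on it; the out-of-bag error averages, over ``B`` bootstrap
    resamples, the integrated Brier error of the resample-fit model on the
    held-out subjects.  Resamples without events are redrawn (capped).
    Deterministic for a fixed seed.  Returns a dict with ``app_err``,
    ``oob_err`` and ``err632``.
    """
    rng = np.random.default_rng(seed)
    eval_times = np.asarray(eval_times, dtype=float)
    full_model = fit_procedure(cohort)
    _, app_err = brier_prediction_error(full_model, cohort, eval_times)

    oob_errs = []
    for _ in range(B):
        for _attempt in range(max_redraws):
            idx = rng.integers(0, cohort.n, size=cohort.n)
            oob_mask = np.ones(cohort.n, dtype=bool)
            oob_mask[idx] = False
            boot = cohort.subset(idx)
            oob = cohort.subset(np.flatnonzero(oob_mask))
            if boot.n_events > 0 and oob_mask.sum() >= 2 and oob.n_events > 0:
                break
        else:
            raise RuntimeError("could not draw a usable bootstrap resample")
        model = fit_procedure(boot)
        grid = eval_times[eval_times <= oob.time_observed.max()]
        if len(grid) < 2:
            continue
        _, err = brier_prediction_error(model, oob, grid)
        oob_errs.append(err)
    if not oob_errs:
        raise RuntimeError("no bootstrap resample produced a usable error")
    oob_err = float(np.mean(oob_errs))
    return {
        "app_err": app_err,
        "oob_err": oob_err,
        "err632": 0.368 * app_err + 0.632 * oob_err,
        "n_bootstrap": len(oob_errs),
    }
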