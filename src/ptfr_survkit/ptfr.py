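"""Person-Time Follow-up Rate (PTFR) estimation.

The formal PTFR of a right-censored cohort at horizon ``tau`` is

    eta = sum_i min(T_i, C_i, tau) / sum_i min(T_i, tau),

the observed person-time divided by the person-time that would have accrued
had nobody dropped out before ``tau``.  The numerator is read directly off
the data.  In the denominator the event time ``T_i`` of a subject censored
at ``c < tau`` is not observed; its expected contribution is reconstructed
from a nonparametric survival estimate ``S`` as the restricted conditional
residual time

    c + integral_c^tau S(t) dt / S(c),

the standard restricted-mean construction.  ``S`` comes either from the
Kaplan-Meier product-limit estimator (the NPMLE for right-censored data) or
from the Turnbull self-consistency EM for general interval censoring, which
reduces to Kaplan-Meier on right-censored encodings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .cohort import SurvivalCohort

__all__ = [
    "StepSurvivalFunction",
    "PTFREstimate",
    "kaplan_meier",
    "turnbull_npmle",
    "cohort_to_intervals",
    "observed_person_time",
    "expected_person_time",
    "formal_ptfr",
]


@dataclass(frozen=True)
class StepSurvivalFunction:
    """Right-continuous piecewise-constant survival estimate.

    ``survival_values[j]`` is S(t) immediately after (and at) ``jump_times[j]``;
    S(t) = 1 before the first jump.  ``tail_rule`` governs evaluation beyond
    the last jump: ``carry_last`` (Kaplan-Meier convention when the largest
    observation is censored) or ``drop_to_zero``.
    """

    jump_times: np.ndarray
    survival_values: np.ndarray
    at_risk_counts: np.ndarray
    event_counts: np.ndarray
    tail_rule: str = "carry_last"

    def __post_init__(self):
        object.__setattr__(self, "jump_times", np.asarray(self.jump_times, dtype=float))
        object.__setattr__(
            self, "survival_values", np.asarray(self.survival_values, dtype=float)
        )
        object.__setattr__(self, "at_risk_counts", np.asarray(self.at_risk_counts))
        object.__setattr__(self, "event_counts", np.asarray(self.event_counts))
        if self.tail_rule not in ("carry_last", "drop_to_zero"):
            raise ValueError(f"unknown tail_rule {self.tail_rule!r}")
        t, s = self.jump_times, self.survival_values
        if np.any(np.diff(t) <= 0):
            raise ValueError("jump_times must be strictly ascending")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("survival values outside [0, 1]")
        if np.any(np.diff(s) > 1e-12) or (len(s) and s[0] > 1 + 1e-12):
            raise ValueError("survival values must be non-increasing from S(0)=1")

    def evaluate(self, t) -> np.ndarray:
        """S(t), right-continuous: the value at the largest jump time <= t."""
        t = np.asarray(t, dtype=float)
        if len(self.jump_times) == 0:  # no mass observed anywhere: S == 1
            vals = np.ones_like(t, dtype=float)
            return vals if vals.ndim else float(vals)
        idx = np.searchsorted(self.jump_times, t, side="right") - 1
        vals = np.where(idx >= 0, self.survival_values[np.clip(idx, 0, None)], 1.0)
        if self.tail_rule == "drop_to_zero" and len(self.jump_times):
            vals = np.where(t > self.jump_times[-1], 0.0, vals)
        return vals if vals.ndim else float(vals)

    __call__ = evaluate

    def integrate(self, a: float, b: float) -> float:
        """Exact integral of the step function S over [a, b]."""
        if b <= a:
            return 0.0
        knots = self.jump_times[(self.jump_times > a) & (self.jump_times < b)]
        grid = np.concatenate(([a], knots, [b]))
        widths = np.diff(grid)
        heights = self.evaluate(grid[:-1])  # right-continuous: value on [t, next)
        return float(np.sum(widths * np.atleast_1d(heights)))

    def with_tail_rule(self, tail_rule: str) -> "StepSurvivalFunction":
        return StepSurvivalFunction(
            self.jump_times,
            self.survival_values,
            self.at_risk_counts,
            self.event_counts,
            tail_rule,
        )


@dataclass(frozen=True)
class PTFREstimate:
    """Formal PTFR with its ingredients: both person-time sums, the horizon
    tau, and the survival estimate used for the denominator."""

    observed_person_time: float
    expected_person_time: float
    eta: float
    tau: float
    n_subjects: int
    estimator: str
    survival_estimate: StepSurvivalFunction

    def __post_init__(self):
        if not (0.0 < self.eta <= 1.0 + 1e-12):
            raise ValueError(f"eta={self.eta} outside (0, 1]")

    def to_json(self) -> str:
        return json.dumps(
            {
                "eta": self.eta,
                "observed_person_time": self.observed_person_time,
                "expected_person_time": self.expected_person_time,
                "tau": self.tau,
                "n_subjects": self.n_subjects,
                "estimator": self.estimator,
                "tail_rule": self.survival_estimate.tail_rule,
            }
        )


# ---------------------------------------------------------------------------
# survival estimators
# ---------------------------------------------------------------------------


def kaplan_meier(
    cohort: SurvivalCohort, tail_rule: str = "carry_last"
) -> StepSurvivalFunction:
    """Product-limit estimate with jumps at event times only.

    Censorings tied with an event at the same time are resolved after the
    event (the tied censored subject is still in the risk set).
    """
    if cohort.n_events == 0:
        raise ValueError("Kaplan-Meier needs at least one event")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.time_observed, cohort.event)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[event_rows.index, "KM_estimate"].to_numpy()
    return StepSurvivalFunction(
        jump_times=times,
        survival_values=surv,
        at_risk_counts=event_rows["at_risk"].to_numpy(),
        event_counts=event_rows["observed"].to_numpy(),
        tail_rule=tail_rule,
    )


def cohort_to_intervals(cohort: SurvivalCohort) -> tuple[np.ndarray, np.ndarray]:
    """Encode right-censored data as censoring intervals (L, R].

    An exact event at t becomes (t^-, t] with an infinitesimal left offset;
    a censoring at c becomes (c, inf).
    """
    t = cohort.time_observed
    eps = 1e-9 * np.maximum(t, 1.0)
    left = np.where(cohort.event == 1, t - eps, t)
    right = np.where(cohort.event == 1, t, np.inf)
    return left, right


def turnbull_npmle(
    left: np.ndarray,
    right: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    tail_rule: str = "carry_last",
) -> StepSurvivalFunction:
    """Nonparametric MLE for interval-censored data (Turnbull estimator).

    Each subject's event lies in (left_i, right_i]; ``right_i`` may be
    infinite (right censoring).  Probability mass can only sit on the
    innermost ("Turnbull") intervals (q, p] with q a left endpoint, p a right
    endpoint and no other endpoint strictly inside.  The self-consistency EM
    iterates mass re-distribution until the sup-norm change of the masses
    falls below ``tol``; mass is attributed to the right endpoint of its
    interval when the step function is built, which reproduces Kaplan-Meier
    exactly on right-censored encodings.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(left >= right):
        raise ValueError("need left < right for every censoring interval")
    n = len(left)

    lefts = np.unique(left)
    rights = np.unique(right)
    endpoints = np.unique(np.concatenate([lefts, rights]))
    # innermost intervals: (q, p], q in lefts, p in rights, nothing strictly between
    q_list, p_list = [], []
    for q in lefts:
        later = endpoints[endpoints > q]
        if len(later) == 0:
            continue
        p = later[0]  # nearest endpoint above q; innermost iff it closes an interval
        if np.isin(p, rights):
            q_list.append(q)
            p_list.append(p)
    q_arr = np.array(q_list)
    p_arr = np.array(p_list)
    m = len(q_arr)
    if m == 0:
        raise ValueError("no innermost intervals found")

    # membership: (q_j, p_j] subset of (L_i, R_i]
    alpha = (q_arr[None, :] >= left[:, None]) & (p_arr[None, :] <= right[:, None])
    if np.any(~alpha.any(axis=1)):
        raise ValueError("a subject's interval contains no innermost interval")
    alpha = alpha.astype(float)

    s = np.full(m, 1.0 / m)
    for _ in range(max_iter):
        weighted = alpha * s[None, :]
        denom = weighted.sum(axis=1, keepdims=True)
        s_new = (weighted / denom).sum(axis=0) / n
        delta = float(np.max(np.abs(s_new - s)))
        s = s_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"Turnbull EM did not converge in {max_iter} iterations "
            f"(last sup-norm change {delta:.3e})"
        )

    finite = np.isfinite(p_arr)
    jumps = p_arr[finite]
    cum = np.cumsum(s[finite])
    surv = np.clip(1.0 - cum, 0.0, 1.0)
    # expected event counts per jump; at-risk reconstructed from survival mass
    ev = n * s[finite]
    at_risk = n * np.concatenate(([1.0], surv[:-1]))
    return StepSurvivalFunction(
        jump_times=jumps,
        survival_values=surv,
        at_risk_counts=np.round(at_risk).astype(int),
        event_counts=np.round(ev).astype(int),
        tail_rule=tail_rule,
    )


# ---------------------------------------------------------------------------
# person-time and the formal PTFR
# ---------------------------------------------------------------------------


def observed_person_time(cohort: SurvivalCohort, tau: float) -> float:
    """sum_i min(time_observed_i, tau) — person-time actually accrued."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return float(np.minimum(cohort.time_observed, tau).sum())


def expected_person_time(
    cohort: SurvivalCohort, tau: float, shat: StepSurvivalFunction
) -> float:
    """Person-time expected under no dropout before tau.

    Events contribute min(t, tau).  A subject censored at c >= tau would have
    been followed to tau regardless, so contributes tau.  A subject censored
    at c < tau contributes its restricted conditional residual time
    c + int_c^tau S(t)dt / S(c); when S(c) = 0 no event time beyond c is
    supported and the contribution is just c.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    total = 0.0
    for t, e in zip(cohort.time_observed, cohort.event):
        if e == 1 or t >= tau:
            total += min(t, tau)
        else:
            s_c = float(shat.evaluate(t))
            if s_c <= 0.0:
                total += t
            else:
                total += t + shat.integrate(t, tau) / s_c
    return float(total)


def formal_ptfr(
    cohort: SurvivalCohort,
    tau: float,
    estimator: str = "km",
    tail_rule: str = "carry_last",
    shat: StepSurvivalFunction | None = None,
) -> PTFREstimate:
    """Formal PTFR eta = observed person-time / expected person-time at tau.

    ``estimator`` selects the nonparametric survival estimate used to
    reconstruct the unobserved residual time of dropouts: ``"km"``
    (Kaplan-Meier, default for right-censored tables) or ``"turnbull"``
    (self-consistency EM on the interval encoding).  A precomputed ``shat``
    overrides both.
    """
    if shat is None:
        if estimator == "km":
            shat = kaplan_meier(cohort, tail_rule=tail_rule)
        elif estimator == "turnbull":
            left, right = cohort_to_intervals(cohort)
            shat = turnbull_npmle(left, right, tail_rule=tail_rule)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
    obs = observed_person_time(cohort, tau)
    exp = expected_person_time(cohort, tau, shat)
    return PTFREstimate(
        observed_person_time=obs,
        expected_person_time=exp,
        eta=obs / exp,
        tau=float(tau),
        n_subjects=cohort.n,
        estimator=estimator,
        survival_estimate=shat,
    )
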