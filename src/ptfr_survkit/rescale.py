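"""Follow-up rescaling: raise a cohort's PTFR by stretching follow-up times.

Every follow-up time is multiplied by one constant k > 1 while event status
and covariates stay untouched; the horizon tau is held at its original value.
Holding tau fixed is essential: the formal PTFR is exactly invariant under
rescaling times and tau together (the survival-estimate jumps scale along),
so only a fixed horizon lets longer follow-up register as a higher rate.

Two ways to choose k are provided: a bisection solve on the achieved formal
PTFR (default), and the naive person-time ratio k = target_eta / current_eta,
whose achieved formal PTFR generally differs from the target once capping at
tau interacts — both are reported so the discrepancy is visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .cohort import SurvivalCohort
from .ptfr import formal_ptfr

__all__ = ["RescalingResult", "rescale_followup", "person_time_factor",
           "solve_factor_for_target_ptfr"]


@dataclass(frozen=True)
class RescalingResult:
    factor: float
    target_eta: float
    achieved_eta: float
    tau: float
    rescaled_cohort: SurvivalCohort

    def to_json(self) -> str:
        return json.dumps(
            {
                "factor": self.factor,
                "target_eta": self.target_eta,
                "achieved_eta": self.achieved_eta,
                "tau": self.tau,
                "n_subjects": self.rescaled_cohort.n,
            }
        )


def rescale_followup(cohort: SurvivalCohort, factor: float) -> SurvivalCohort:
    """Multiply every follow-up time by ``factor``; nothing else changes.

    Scaled times are deliberately not re-rounded to whole days: rounding
    would perturb the achieved PTFR.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return cohort.replace_times(cohort.time_observed * factor)


def person_time_factor(
    cohort: SurvivalCohort, tau: float, target_eta: float, estimator: str = "km"
) -> float:
    """Naive scaling factor from the person-time ratio.

    Computes the target total person-time as target_eta x expected
    person-time and divides by the current observed person-time (both capped
    at tau on unscaled times); equals target_eta / current_eta.
    """
    est = formal_ptfr(cohort, tau, estimator=estimator)
    if not est.eta < target_eta < 1:
        raise ValueError(
            f"target_eta must lie in (current eta={est.eta:.4f}, 1); "
            "shrinking follow-up is not supported"
        )
    target_person_time = target_eta * est.expected_person_time
    return target_person_time / est.observed_person_time


def solve_factor_for_target_ptfr(
    cohort: SurvivalCohort,
    tau: float,
    target_eta: float,
    tolerance: float = 1e-4,
    estimator: str = "km",
    k_max: float = 50.0,
    scan_points: int = 20,
    max_iter: int = 200,
) -> RescalingResult:
    """Bisection on k for formal_ptfr(rescale(cohort, k), tau) = target_eta.

    A coarse ``scan_points``-point scan over [1, k_max] first checks that the
    achieved eta is non-decreasing in k (it is for every cohort with
    censoring before tau; the guard catches pathological inputs) and locates
    a bracket.  Returns k with |achieved - target| <= tolerance.
    """

    def eta_at(k: float) -> float:
        return formal_ptfr(rescale_followup(cohort, k), tau, estimator=estimator).eta

    current = eta_at(1.0)
    if target_eta >= 1:
        raise ValueError("target_eta must be < 1")
    if target_eta < current:
        raise ValueError(
            f"target eta {target_eta:.4f} below current {current:.4f}; "
            "shrinking follow-up is out of scope"
        )
    if abs(target_eta - current) <= tolerance:
        return RescalingResult(1.0, target_eta, current, float(tau), cohort)

    ks = np.geomspace(1.0, k_max, scan_points)
    etas = np.array([current] + [eta_at(k) for k in ks[1:]])
    if np.any(np.diff(etas) < -1e-9):
        raise RuntimeError(
            "achieved PTFR not monotone in the scaling factor; scan trace: "
            + ", ".join(f"k={k:.3g}:eta={e:.5f}" for k, e in zip(ks, etas))
        )
    above = np.flatnonzero(etas >= target_eta)
    if len(above) == 0:
        raise RuntimeError(
            f"bracket exhausted: eta({k_max}) = {etas[-1]:.4f} < target "
            f"{target_eta:.4f}"
        )
    hi_idx = above[0]
    lo, hi = ks[hi_idx - 1], ks[hi_idx]

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        e_mid = eta_at(mid)
        if abs(e_mid - target_eta) <= tolerance:
            return RescalingResult(
                float(mid), target_eta, e_mid, float(tau),
                rescale_followup(cohort, mid),
            )
        if e_mid < target_eta:
            lo = mid
        else:
            hi = mid
    e_hi = eta_at(hi)
    if abs(e_hi - target_eta) <= tolerance:
        return RescalingResult(
            float(hi), target_eta, e_hi, float(tau), rescale_followup(cohort, hi)
        )
    raise RuntimeError(
        f"bisection did not reach tolerance {tolerance} in {max_iter} "
        f"iterations (last eta {e_hi:.6f})"
    )
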