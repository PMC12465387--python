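"""Survival models compared by the pipeline: Cox PH and random survival forest.

The Cox proportional-hazards fit delegates to lifelines (Efron tie handling,
Wald intervals); the forest delegates to scikit-survival (log-rank splitting).
Both are wrapped behind a common surface — ``risk_score(cohort)`` for
discrimination metrics and ``predict_survival(cohort, times)`` for
calibration — so the evaluation machinery does not care which model it sees.

The global Schoenfeld proportional-hazards test and permutation variable
importance are implemented here directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from sksurv.ensemble import RandomSurvivalForest

from .cohort import SurvivalCohort
from .metrics import harrell_cindex
from .ptfr import kaplan_meier

__all__ = [
    "CoxFit",
    "RSFModel",
    "RSFConfig",
    "fit_cox",
    "schoenfeld_global_test",
    "fit_rsf",
    "permutation_vimp",
]


def _modelling_frame(cohort: SurvivalCohort) -> pd.DataFrame:
    df = pd.DataFrame(cohort.covariates, columns=list(cohort.covariate_names))
    df["time"] = cohort.time_observed
    df["event"] = cohort.event
    return df


def _check_collinearity(x: np.ndarray, names) -> None:
    if x.shape[1] < 2:
        return
    for j in range(1, x.shape[1]):
        prev = x[:, :j]
        resid = x[:, j] - prev @ np.linalg.lstsq(prev, x[:, j], rcond=None)[0]
        scale = max(np.linalg.norm(x[:, j]), 1.0)
        if np.linalg.norm(resid) / scale < 1e-10:
            raise ValueError(
                f"covariate {names[j]!r} is collinear with earlier columns"
            )


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit: named coefficients, hazard ratios with
    95% Wald intervals and p-values, plus prediction hooks."""

    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    _fitter: CoxPHFitter = field(repr=False)

    def risk_score(self, cohort: SurvivalCohort) -> np.ndarray:
        """Linear predictor x' beta-hat (lifelines centres at training means;
        a shared shift does not affect rank-based metrics)."""
        df = _modelling_frame(cohort)
        return self._fitter.predict_partial_hazard(df).to_numpy()

    def predict_survival(self, cohort: SurvivalCohort, times) -> np.ndarray:
        df = _modelling_frame(cohort)
        surv = self._fitter.predict_survival_function(df, times=np.asarray(times))
        return surv.to_numpy().T

    def summary_frame(self) -> pd.DataFrame:
        names = list(self.coefficients)
        return pd.DataFrame(
            {
                "variable": names,
                "hr": [self.hazard_ratios[v] for v in names],
                "ci_low": [self.ci_lower[v] for v in names],
                "ci_high": [self.ci_upper[v] for v in names],
                "p": [self.p_values[v] for v in names],
            }
        )


def fit_cox(cohort: SurvivalCohort) -> CoxFit:
    """Maximize the Cox partial likelihood (Efron ties) over all covariates."""
    if cohort.n_events < 2:
        raise ValueError("Cox fit needs at least 2 events")
    _check_collinearity(cohort.covariates, cohort.covariate_names)
    df = _modelling_frame(cohort)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox partial-likelihood fit failed: {exc}") from exc
    summary = cph.summary
    names = list(summary.index)
    return CoxFit(
        coefficients=dict(zip(names, summary["coef"])),
        hazard_ratios=dict(zip(names, summary["exp(coef)"])),
        ci_lower=dict(zip(names, summary["exp(coef) lower 95%"])),
        ci_upper=dict(zip(names, summary["exp(coef) upper 95%"])),
        p_values=dict(zip(names, summary["p"])),
        _fitter=cph,
    )


def schoenfeld_global_test(fit: CoxFit, cohort: SurvivalCohort) -> float:
    """Global Schoenfeld test of proportional hazards; returns the p-value.

    Score test for a common time-varying coefficient beta(t) = beta + theta
    g(t) with the Kaplan-Meier time transform g(t) = 1 - S_KM(t).  With
    Schoenfeld residuals s_k at the d event times, centred transformed times
    z_k, and V the covariance of beta-hat, the statistic is

        chi2 = d * u' V u / sum(z_k^2),   u = sum_k z_k s_k,

    on p degrees of freedom (the averaged-information approximation of
    Grambsch & Therneau).
    """
    if cohort.n_events == 0:
        raise ValueError("no events: proportional-hazards test undefined")
    if cohort.n_events < 2:
        raise ValueError("need at least 2 events for the Schoenfeld test")
    df = _modelling_frame(cohort)
    resid = fit._fitter.compute_residuals(df, kind="schoenfeld")
    # lifelines indexes residual rows by subject; recover each event's time
    event_times = df.loc[resid.index, "time"].to_numpy()
    order = np.argsort(event_times, kind="stable")
    s = resid.to_numpy()[order]
    t_k = event_times[order]

    km = kaplan_meier(cohort)
    g = 1.0 - np.atleast_1d(km.evaluate(t_k))
    z = g - g.mean()
    denom = float(np.sum(z**2))
    if denom <= 0:
        raise ValueError("degenerate time transform (all events tied)")
    u = s.T @ z
    v = fit._fitter.variance_matrix_.to_numpy()
    d = len(t_k)
    chi2 = float(d * u @ v @ u / denom)
    p = float(stats.chi2.sf(chi2, df=s.shape[1]))
    return p


@dataclass(frozen=True)
class RSFConfig:
    n_trees: int = 1000
    mtry: int | None = None  # default ceil(sqrt(p))
    min_node_size: int = 15
    seed: int = 0


@dataclass(frozen=True)
class RSFModel:
    """Random survival forest (log-rank splitting) with deterministic
    predictions for a fixed seed and training data."""

    config: RSFConfig
    covariate_names: tuple[str, ...]
    _forest: RandomSurvivalForest = field(repr=False)

    def risk_score(self, cohort: SurvivalCohort) -> np.ndarray:
        """Ensemble mortality: the aggregated cumulative hazard, higher =
        riskier."""
        return self._forest.predict(cohort.covariates)

    def predict_survival(self, cohort: SurvivalCohort, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        fns = self._forest.predict_survival_function(cohort.covariates)
        out = np.empty((cohort.n, len(times)))
        for i, fn in enumerate(fns):
            # survival is flat outside the training event-time range
            clipped = np.clip(times, fn.x[0], fn.x[-1])
            vals = fn(clipped)
            vals = np.where(times < fn.x[0], 1.0, vals)
            out[i] = vals
        return out


def fit_rsf(train: SurvivalCohort, config: RSFConfig | None = None) -> RSFModel:
    """Fit a random survival forest on the training cohort."""
    config = config or RSFConfig()
    if train.n_events == 0:
        raise ValueError("training cohort has no events")
    p = train.covariates.shape[1]
    mtry = config.mtry or int(np.ceil(np.sqrt(p)))
    forest = RandomSurvivalForest(
        n_estimators=config.n_trees,
        max_features=mtry,
        min_samples_leaf=config.min_node_size,
        random_state=config.seed,
        n_jobs=1,
    )
    y = np.array(
        list(zip(train.event.astype(bool), train.time_observed)),
        dtype=[("event", bool), ("time", float)],
    )
    forest.fit(train.covariates, y)
    return RSFModel(config=config, covariate_names=train.covariate_names,
                    _forest=forest)


def permutation_vimp(
    model,
    data: SurvivalCohort,
    metric: str = "cindex",
    n_permutations: int = 10,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Permutation variable importance under the chosen metric.

    importance_j = metric(original) - mean over permutations of the metric
    with column j shuffled; returned sorted descending.  Works for any model
    exposing ``risk_score``.
    """
    if metric != "cindex":
        raise ValueError(f"unknown metric {metric!r}")
    if data.n_events == 0:
        raise ValueError("importance needs events in the evaluation data")
    rng = np.random.default_rng(seed)
    base_c, _ = harrell_cindex(
        data.time_observed, data.event, model.risk_score(data)
    )
    importances = []
    for j, name in enumerate(data.covariate_names):
        drops = []
        for _ in range(n_permutations):
            x = data.covariates.copy()
            x[:, j] = rng.permutation(x[:, j])
            permuted = SurvivalCohort(
                subject_id=data.subject_id,
                time_observed=data.time_observed,
                event=data.event,
                covariates=x,
                covariate_names=data.covariate_names,
            )
            c_perm, _ = harrell_cindex(
                permuted.time_observed, permuted.event, model.risk_score(permuted)
            )
            drops.append(base_c - c_perm)
        importances.append((name, float(np.mean(drops))))
    importances.sort(key=lambda kv: kv[1], reverse=True)
    return importances
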