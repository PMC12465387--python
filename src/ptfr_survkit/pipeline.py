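"""End-to-end study pipeline.

Load (or synthesize) a cohort, quantify follow-up adequacy with the formal
PTFR, stretch follow-up to a target PTFR, fit Cox PH and a random survival
forest on both the original and the rescaled cohort, and write report tables:
hazard-ratio table, model-comparison table (C-index / SE / AUC / PTFR),
Kaplan-Meier curves with a log-rank comparison, permutation importances and
prediction-error summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SurvivalCohort, read_cohort_csv, train_test_split, write_cohort_csv
from .metrics import (
    ModelEvaluation,
    bootstrap632,
    cd_auc,
    harrell_cindex,
    log_rank_test,
)
from .models import RSFConfig, fit_cox, fit_rsf, permutation_vimp, schoenfeld_global_test
from .ptfr import formal_ptfr, kaplan_meier
from .rescale import person_time_factor, solve_factor_for_target_ptfr
from .synthetic import CohortSpec, generate_cohort

__all__ = ["RunConfig", "run_study", "evaluate_model"]


@dataclass
class RunConfig:
    """Configuration of one full study run."""

    input_csv: str | None = None
    input_schema: object = "heart_failure"
    synth_spec: CohortSpec | None = None
    tau: float = 285.0
    target_ptfr: float = 0.672
    train_fraction: float = 0.7
    seed: int = 0
    estimator: str = "km"
    rescale_strategy: str = "bisect"
    rsf: RSFConfig = field(default_factory=RSFConfig)
    n_bootstrap: int = 100
    n_vimp_permutations: int = 10
    eval_time: float | None = None  # default: median observed follow-up
    output_dir: str | None = None
    verbose: bool = False

    def load_cohort(self) -> SurvivalCohort:
        if self.input_csv is not None:
            return read_cohort_csv(self.input_csv, self.input_schema)
        if self.synth_spec is not None:
            return generate_cohort(self.synth_spec)
        raise ValueError("RunConfig needs input_csv or synth_spec")


def evaluate_model(
    model,
    test: SurvivalCohort,
    eval_time: float | None = None,
    fit_procedure=None,
    boot_cohort: SurvivalCohort | None = None,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> ModelEvaluation:
    """Discrimination on the held-out cohort; optional .632 prediction error.

    C-index and the cumulative/dynamic AUC (at ``eval_time``, default the
    median observed follow-up) are computed on ``test``.  When a refit
    procedure is supplied, IPCW Brier curves and the .632 bootstrap error are
    computed on ``boot_cohort`` (default: ``test``) with ``n_bootstrap``
    resamples.
    """
    risk = model.risk_score(test)
    c, se = harrell_cindex(test.time_observed, test.event, risk)
    t_eval = float(eval_time if eval_time is not None
                   else np.median(test.time_observed))
    auc = cd_auc(test.time_observed, test.event, risk, t_eval)

    brier_times = np.array([])
    brier_curve = np.array([])
    app_err = err632 = float("nan")
    n_boot_done = 0
    if fit_procedure is not None and n_bootstrap > 0:
        target = boot_cohort if boot_cohort is not None else test
        t90 = float(np.quantile(target.time_observed, 0.9))
        brier_times = np.linspace(0.0, t90, 31)
        from .metrics import brier_prediction_error

        brier_curve, _ = brier_prediction_error(
            fit_procedure(target), target, brier_times
        )
        boot = bootstrap632(fit_procedure, target, brier_times,
                            B=n_bootstrap, seed=seed)
        app_err = boot["app_err"]
        err632 = boot["err632"]
        n_boot_done = boot["n_bootstrap"]
    return ModelEvaluation(
        c_index=c, c_index_se=se, auc=auc, eval_time=t_eval,
        brier_times=brier_times, brier_curve=brier_curve,
        app_err=app_err, err632=err632, n_bootstrap=n_boot_done,
    )


def _km_curve_frame(cohort: SurvivalCohort, label: str) -> pd.DataFrame:
    km = kaplan_meier(cohort)
    return pd.DataFrame(
        {
            "dataset": label,
            "time": km.jump_times,
            "survival": km.survival_values,
            "at_risk": km.at_risk_counts,
            "events": km.event_counts,
        }
    )


def run_study(config: RunConfig) -> dict:
    """Run the full original-vs-rescaled study; returns the report bundle.

    When ``config.output_dir`` is set, writes ptfr.json, table1.csv,
    table2.csv, km_curves.csv, logrank.json, vimp.csv, prediction_error.csv
    and run_log.json there.
    """
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    bundle: dict = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed ({exc}); config={config!r}") from exc

    original = stage("load", config.load_cohort)
    ptfr_orig = stage("ptfr", formal_ptfr, original, config.tau,
                      estimator=config.estimator)
    if not ptfr_orig.eta < config.target_ptfr < 1:
        raise RuntimeError(
            f"stage 'rescale' failed: target PTFR {config.target_ptfr} must "
            f"exceed the cohort's current PTFR {ptfr_orig.eta:.4f}"
        )
    naive_factor = stage("rescale", person_time_factor, original, config.tau,
                         config.target_ptfr, config.estimator)
    rescaling = stage(
        "rescale", solve_factor_for_target_ptfr, original, config.tau,
        config.target_ptfr, estimator=config.estimator,
    )
    rescaled = rescaling.rescaled_cohort
    ptfr_resc = stage("ptfr", formal_ptfr, rescaled, config.tau,
                      estimator=config.estimator)

    # one split, inherited by the rescaled cohort so performance changes are
    # attributable to follow-up rather than resampling
    train_o, test_o = stage("split", train_test_split, original,
                            config.train_fraction, int(rng_seeds[0]))
    train_ids = set(train_o.subject_id.tolist())
    in_train = np.array([sid in train_ids for sid in rescaled.subject_id])
    train_r = rescaled.subset(np.flatnonzero(in_train))
    test_r = rescaled.subset(np.flatnonzero(~in_train))

    def cox_procedure(train):
        model = fit_cox(train)
        return model.predict_survival

    rsf_cfg = config.rsf

    def rsf_procedure(train):
        model = fit_rsf(train, rsf_cfg)
        return model.predict_survival

    rows_t2 = []
    vimp_rows = []
    pe_rows = []
    table1 = {}
    ph_p = {}
    evals: dict[tuple[str, str], ModelEvaluation] = {}
    for label, (train, test, full, eta) in {
        "original": (train_o, test_o, original, ptfr_orig.eta),
        "simulated": (train_r, test_r, rescaled, ptfr_resc.eta),
    }.items():
        cox_full = stage("cox", fit_cox, full)
        table1[label] = cox_full.summary_frame()
        ph_p[label] = stage("schoenfeld", schoenfeld_global_test, cox_full, full)

        cox_train = stage("cox", fit_cox, train)
        rsf_model = stage("rsf", fit_rsf, train, rsf_cfg)
        for model_label, model, proc in (
            ("CPHR", cox_train, cox_procedure),
            ("RSF", rsf_model, rsf_procedure),
        ):
            ev = stage(
                "evaluate", evaluate_model, model, test,
                eval_time=config.eval_time, fit_procedure=proc,
                boot_cohort=train, n_bootstrap=config.n_bootstrap,
                seed=int(rng_seeds[1]),
            )
            evals[(model_label, label)] = ev
            vimp = stage(
                "vimp", permutation_vimp, model, test,
                n_permutations=config.n_vimp_permutations, seed=int(rng_seeds[2]),
            )
            top = [name for name, _ in vimp[:3]]
            rows_t2.append(
                {
                    "model": model_label,
                    "dataset": label,
                    "c_index": round(ev.c_index, 4),
                    "se": round(ev.c_index_se, 4),
                    "auc": round(ev.auc, 4),
                    "eval_time": ev.eval_time,
                    "ptfr": round(eta, 3),
                    "top_variables": "; ".join(top),
                }
            )
            vimp_rows += [
                {"model": model_label, "dataset": label, "variable": name,
                 "importance": imp}
                for name, imp in vimp
            ]
            pe_rows += [
                {"model": model_label, "dataset": label, "time": t, "brier": b}
                for t, b in zip(ev.brier_times, ev.brier_curve)
            ]
            pe_rows.append(
                {"model": model_label, "dataset": label, "time": "app_err",
                 "brier": ev.app_err}
            )
            pe_rows.append(
                {"model": model_label, "dataset": label, "time": "err632",
                 "brier": ev.err632}
            )

    chi2, logrank_p = stage("logrank", log_rank_test, original, rescaled)

    bundle.update(
        original=original,
        rescaled=rescaled,
        ptfr={
            "original": json.loads(ptfr_orig.to_json()),
            "simulated": json.loads(ptfr_resc.to_json()),
        },
        rescaling={
            "strategy": config.rescale_strategy,
            "bisect_factor": rescaling.factor,
            "naive_person_time_factor": naive_factor,
            "achieved_eta": rescaling.achieved_eta,
            "target_eta": config.target_ptfr,
        },
        table1=table1,
        ph_global_p=ph_p,
        table2=pd.DataFrame(rows_t2),
        evaluations=evals,
        vimp=pd.DataFrame(vimp_rows),
        prediction_error=pd.DataFrame(pe_rows),
        logrank={"chi2": chi2, "p": logrank_p},
        km_curves=pd.concat(
            [_km_curve_frame(original, "original"),
             _km_curve_frame(rescaled, "simulated")],
            ignore_index=True,
        ),
    )

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "ptfr.json").write_text(json.dumps(bundle["ptfr"], indent=2))
        t1 = pd.concat(
            [df.assign(dataset=label) for label, df in table1.items()],
            ignore_index=True,
        )
        t1.to_csv(out / "table1.csv", index=False)
        bundle["table2"].to_csv(out / "table2.csv", index=False)
        bundle["km_curves"].to_csv(out / "km_curves.csv", index=False)
        (out / "logrank.json").write_text(json.dumps(bundle["logrank"], indent=2))
        bundle["vimp"].to_csv(out / "vimp.csv", index=False)
        bundle["prediction_error"].to_csv(out / "prediction_error.csv", index=False)
        write_cohort_csv(rescaled, out / "rescaled_cohort.csv")
        (out / "run_log.json").write_text(
            json.dumps(
                {
                    "seed": config.seed,
                    "tau": config.tau,
                    "target_ptfr": config.target_ptfr,
                    "estimator": config.estimator,
                    "train_fraction": config.train_fraction,
                    "rescale_strategy": config.rescale_strategy,
                    "rescaling": bundle["rescaling"],
                    "ph_global_p": ph_p,
                    "rsf": {
                        "n_trees": rsf_cfg.n_trees,
                        "min_node_size": rsf_cfg.min_node_size,
                        "mtry": rsf_cfg.mtry,
                        "seed": rsf_cfg.seed,
                    },
                    "n_bootstrap": config.n_bootstrap,
                    "eval_time_policy": "median observed follow-up"
                    if config.eval_time is None else config.eval_time,
                    "ties": "efron",
                    "schoenfeld_transform": "km",
                },
                indent=2,
            )
        )
    return bundle
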