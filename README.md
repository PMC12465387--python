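# ptfr-survkit

Follow-up adequacy analysis for right-censored survival cohorts: a formal
**Person-Time Follow-up Rate (PTFR)** estimator, a follow-up rescaling
simulator that lifts a cohort's PTFR to a target, and a model-comparison
harness contrasting Cox proportional-hazards regression with a random
survival forest (RSF) under the original and the improved follow-up regime.

It is written for biostatisticians and epidemiologists who need to ask: *is
the follow-up in this cohort good enough to trust the survival model built
on it — and what would change if follow-up were more complete?*

## The quantities

For subject *i* with latent event time *T_i* and censoring time *C_i*, and a
study horizon τ, the formal PTFR is

    η = Σᵢ min(T_i, C_i, τ) / Σᵢ min(T_i, τ),

observed person-time over the person-time expected had nobody dropped out
before τ. The numerator is read off the data. In the denominator the event
time of a subject censored at *c* < τ is unobserved; its contribution is
reconstructed from a nonparametric survival estimate Ŝ as the restricted
conditional residual time *c* + ∫_c^τ Ŝ(t)dt / Ŝ(c). Ŝ is the
Kaplan–Meier product-limit estimate by default, or the Turnbull
self-consistency NPMLE on the interval encoding (the two coincide for
right-censored data). A PTFR of at least 60% is the conventional bar for
reliable survival modelling.

The rescaling simulator multiplies every follow-up time by one constant
*k* > 1 (events and covariates untouched, τ held fixed) and solves for the
*k* whose recomputed formal PTFR hits the target.

Model performance is measured with self-implemented metrics: Harrell's
C-index with a pair-count standard error, IPCW cumulative/dynamic AUC,
two-group log-rank, IPCW Brier-score prediction-error curves, and the
.632 bootstrap error 0.368·AppErr + 0.632·mean out-of-bag error.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
synthetic heart-failure-like cohort (n = 299, τ = 285 days, dropout heavy
enough that the true PTFR is ≈ 0.45):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_ptfr.py
python analysis/03_rescale.py
python analysis/04_models.py --seed 1 --n-bootstrap 20
```

With seed 1 this prints, in turn:

```
km        carry_last    eta = 0.4370 (28829 / 65973 person-days)
...
current PTFR 0.437 -> target 0.672
bisection factor 2.437 achieves 0.6720
naive person-time factor 1.538 achieves only 0.5537 (capping at tau makes the response sublinear)
```

and the model comparison on the shared held-out 30%:

```
model   dataset  c_index     se    auc  ptfr                            top_variables
 CPHR  original   0.7525 0.0137 0.7918 0.437 age; ejection_fraction; serum_creatinine
  RSF  original   0.7667 0.0135 0.8095 0.437 age; ejection_fraction; serum_creatinine
 CPHR simulated   0.7525 0.0137 0.7918 0.672 age; ejection_fraction; serum_creatinine
  RSF simulated   0.7667 0.0135 0.8095 0.672 age; ejection_fraction; serum_creatinine
```

Reading this: the cohort's follow-up covers only 43.7% of the person-time a
dropout-free study would have accrued by day 285; multiplying every
follow-up time by 2.437 raises that to the 67.2% target; and with follow-up
improved, discrimination metrics are unchanged here because a constant
rescaling preserves every time ordering — the models see identical ranks
(see `docs/methods.md` for why this is a feature of the design, not a bug).
The forest edges out the Cox model on held-out discrimination, and both
agree on the leading predictors.

`analysis/05_real_data.py` reruns everything on the public heart-failure
clinical-records CSV if you download it to
`data/heart_failure_clinical_records_dataset.csv` (it is not redistributed
here).

The same machinery is scriptable via the CLI:

```bash
ptfr-survkit synth --n 299 --seed 1 --out cohort.csv
ptfr-survkit ptfr cohort.csv --tau 285 --schema '{"time":"time","event":"event","covariates":[]}'
ptfr-survkit rescale cohort.csv --tau 285 --target-ptfr 0.672 --out rescaled.csv --schema '...'
ptfr-survkit run --config cfg.yaml
```

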