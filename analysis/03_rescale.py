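"""Raise follow-up adequacy by rescaling: solve for the multiplier that
lifts the cohort's formal PTFR to the target (default 67.2%).

Both factor-finding strategies are reported: the bisection solve on the
achieved PTFR (used for the output cohort) and the naive person-time ratio,
which undershoots once capping at tau interacts.
"""

import argparse
import json
from pathlib import Path

from ptfr_survkit import (
    HEART_FAILURE_COVARIATES,
    formal_ptfr,
    person_time_factor,
    read_cohort_csv,
    rescale_followup,
    solve_factor_for_target_ptfr,
    write_cohort_csv,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--tau", type=float, default=285.0)
    ap.add_argument("--target-ptfr", type=float, default=0.672)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort_csv(
        args.outdir / "cohort.csv",
        {"time": "time", "event": "event",
         "covariates": HEART_FAILURE_COVARIATES},
    )
    current = formal_ptfr(cohort, args.tau).eta
    res = solve_factor_for_target_ptfr(cohort, args.tau, args.target_ptfr)
    naive = person_time_factor(cohort, args.tau, args.target_ptfr)
    naive_eta = formal_ptfr(rescale_followup(cohort, naive), args.tau).eta

    write_cohort_csv(res.rescaled_cohort, args.outdir / "cohort_rescaled.csv")
    payload = {
        "current_eta": current,
        "target_eta": args.target_ptfr,
        "bisect_factor": res.factor,
        "bisect_achieved_eta": res.achieved_eta,
        "naive_person_time_factor": naive,
        "naive_achieved_eta": naive_eta,
        "tau": args.tau,
    }
    (args.outdir / "rescaling.json").write_text(json.dumps(payload, indent=2))
    print(f"current PTFR {current:.3f} -> target {args.target_ptfr:.3f}")
    print(f"bisection factor {res.factor:.3f} achieves {res.achieved_eta:.4f}")
    print(f"naive person-time factor {naive:.3f} achieves only {naive_eta:.4f}"
          " (capping at tau makes the response sublinear)")


if __name__ == "__main__":
    main()
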