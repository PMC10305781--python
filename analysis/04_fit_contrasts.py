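#!/usr/bin/env python
"""Fit the hierarchical models and compute directed contrasts.

For each response (PD, dSI, then the presence scales WPQ/MPQS/MPQP and
perceived difficulty): fit the cell-means varying-intercept model, compare
it against the covariate-augmented variant by Bayes factor with a LOO
check, diagnose the winner (R-hat, Bayesian R², posterior predictive
check) and report the contrast battery — condition contrast c12, trial
contrasts within condition (c1t12, ...), and condition contrasts per trial
(c12t1, ...), each with a 95% credible interval and the probability of
direction.  Writes one contrast table per response under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from bowmimic.stats import (
    SamplerSettings,
    WorkflowConfig,
    run_workflow,
    score_questionnaires,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--draws", type=int, default=1000, help="posterior draws per chain")
    ap.add_argument("--no-compare", action="store_true", help="skip model comparison")
    args = ap.parse_args()

    dataset_csv = args.out / "calibrated_dataset.csv"
    q_csv = args.out / "cohort" / "questionnaires.csv"
    for p in (dataset_csv, q_csv):
        if not p.exists():
            raise SystemExit(f"{p} not found — run the earlier analysis steps first")
    dataset = pd.read_csv(dataset_csv)
    qscores = score_questionnaires(pd.read_csv(q_csv))

    print("questionnaire reliability (Cronbach's alpha):",
          {k: round(v, 2) for k, v in qscores.alphas.items()})

    config = WorkflowConfig(
        sampler=SamplerSettings(chains=4, warmup=args.draws, draws=args.draws, seed=args.seed),
        compare=not args.no_compare,
        seed=args.seed,
    )
    report = run_workflow(dataset, qscores, config)

    for response, table in report.contrast_tables.items():
        table.to_csv(args.out / f"contrasts_{response}.csv", index=False)
        diag = report.diagnostics[response]
        cmp = report.comparisons.get(response)
        c12 = table.set_index("Label").loc["c12"]
        print(f"\n== {response} ==")
        if cmp is not None:
            print(f"  Bayes factor (simple / covariate): {cmp.bf:.2f}  "
                  f"elpd diff {cmp.elpd_diff:+.2f} +- {cmp.elpd_diff_se:.2f}")
        print(f"  converged: {diag['converged']} (max R-hat {diag['max_rhat']:.4f}); "
              f"R2 conditional {diag['r2_conditional']:.2f}, marginal {diag['r2_marginal']:.2f}")
        print(f"  c12 (2D - 3D): {c12['Estimate']:+.3f} "
              f"[{c12['CI.Lower']:+.3f}, {c12['CI.Upper']:+.3f}], "
              f"post prob {c12['Post.Prob']:.3f}")
    print(f"\nwrote contrast tables to {args.out}/")


if __name__ == "__main__":
    main()
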