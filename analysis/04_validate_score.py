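"""Internal validation of the developed score: ROC and precision-recall
discrimination with bootstrap intervals, and Harrell optimism correction of
the whole development pipeline.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from echorisk.cohort import read_cohort
from echorisk.metrics import evaluate_scores, optimism_correct, pr_auc, roc_auc
from echorisk.pipeline import score_development_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--b-boot", type=int, default=2000)
    parser.add_argument("--b-optimism", type=int, default=200)
    args = parser.parse_args()

    cohort = read_cohort(RESULTS / "cohort.csv")
    scores = pd.read_csv(RESULTS / "scores.csv", index_col=0)["total"].to_numpy()
    y = cohort.adverse()

    report = evaluate_scores(scores, y, B=args.b_boot, seed=args.seed)
    print(f"apparent AUC_roc {report.auc_roc:.3f} "
          f"(95% CI {report.ci_roc[0]:.3f}-{report.ci_roc[1]:.3f}; "
          f"baseline 0.50)")
    print(f"apparent AUC_pr  {report.auc_pr:.3f} "
          f"(95% CI {report.ci_pr[0]:.3f}-{report.ci_pr[1]:.3f}; "
          f"baseline {report.baseline_auc_pr:.2f} = prevalence)")

    out = report.to_dict()
    for metric, name in ((roc_auc, "auc_roc"), (pr_auc, "auc_pr")):
        res = optimism_correct(
            cohort,
            score_development_pipeline(B_pls=100, seed=args.seed),
            metric=metric,
            B=args.b_optimism,
            seed=args.seed,
        )
        out[f"optimism_{name}"] = res.optimism
        out[f"corrected_{name}"] = res.corrected
        print(f"optimism-corrected {name}: {res.corrected:.3f} "
              f"(apparent {res.apparent:.3f}, optimism {res.optimism:+.3f}, "
              f"B = {res.B} pipeline refits)")

    (RESULTS / "evaluation.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {RESULTS / 'evaluation.json'}")


if __name__ == "__main__":
    main()
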