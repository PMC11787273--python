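"""Post-hoc outcome models on the developed score: per-outcome risk curves,
mixed-effects confirmation of the score-outcome association, the
septostomy covariate check, and the adverse-vs-uneventful score comparison.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from echorisk.cohort import read_cohort
from echorisk.outcome_models import (
    confirm_association,
    covariate_check,
    fit_risk_curves,
    group_compare,
)
from echorisk.screening import FAST

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--plot", action="store_true")
    args = parser.parse_args()

    cohort = read_cohort(RESULTS / "cohort.csv")
    scores = pd.read_csv(RESULTS / "scores.csv", index_col=0)["total"].to_numpy()
    y = cohort.adverse()

    curves = fit_risk_curves(scores, cohort=cohort, seed=args.seed)
    rows = []
    for c in curves:
        print(f"risk curve [{c.outcome}]: slope {c.slope:+.4f} per point "
              f"(95% CrI {c.slope_ci[0]:+.4f} to {c.slope_ci[1]:+.4f}, "
              f"{c.n_events} events)")
        for g, m, lo, hi in zip(c.grid, c.risk_median, c.risk_low, c.risk_high):
            rows.append({"outcome": c.outcome, "score": g, "risk": m,
                         "risk_low": lo, "risk_high": hi})
    pd.DataFrame(rows).to_csv(RESULTS / "risk_curves.csv", index=False)

    assoc = confirm_association(cohort, scores, settings=FAST, seed=args.seed)
    print(f"mixed-effects confirmation: beta {assoc.beta_median:+.2f} per SD "
          f"of score [{assoc.ci_low:+.2f}, {assoc.ci_high:+.2f}], "
          f"p_B = {assoc.p_tail:.4f}")

    sept = covariate_check(cohort, "septostomy", settings=FAST,
                           seed=args.seed)
    print(f"septostomy: OR {sept.odds_ratio:.1f} "
          f"(95% CrI {sept.or_ci[0]:.1f} to {sept.or_ci[1]:.1f})")

    comp = group_compare(scores[y.astype(bool)], scores[~y.astype(bool)])
    print(f"scores, adverse vs uneventful: median {comp.median_a:.0f} "
          f"(IQR {comp.iqr_a[0]:.0f}-{comp.iqr_a[1]:.0f}) vs "
          f"{comp.median_b:.0f} (IQR {comp.iqr_b[0]:.0f}-{comp.iqr_b[1]:.0f}); "
          f"z = {comp.z:.1f}, p = {comp.p:.3f}")

    (RESULTS / "outcome_models.json").write_text(json.dumps({
        "score_association": dataclasses.asdict(assoc),
        "septostomy_or": sept.odds_ratio,
        "septostomy_or_ci": sept.or_ci,
        "group_compare": dataclasses.asdict(comp),
    }, indent=2))

    if args.plot:
        from echorisk.cli import _plot_curves

        _plot_curves(scores, cohort, curves, RESULTS / "risk_curves.png")
        print(f"wrote {RESULTS / 'risk_curves.png'}")


if __name__ == "__main__":
    main()
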