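#!/usr/bin/env python
"""Combination-rescue screen of anti-PD-1 non-reactive tumors.

Scores every anti-PD-1-based combination condition with the same IRS
machinery (medium reference) and asks which tumors that fail single-agent
PD-1 blockade reach the reactivity cutoff under at least one combination.
"""

from pathlib import Path

import insitro as ins
from insitro import io, scoring
from insitro.pipeline import condition_scores

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    bundle = io.read_cohort(COHORT)
    res = ins.run_scoring_pipeline(bundle["concentrations"])

    conditions = [c for c in bundle["config"]["conditions"] if c.startswith("aPD1")]
    long_scores = condition_scores(
        bundle["concentrations"], res.selected_analytes, conditions
    )
    rescue = scoring.combination_rescue(long_scores[["tumor_id", "condition", "irs_percent"]])

    rescue.matrix.to_csv(OUT / "rescue_matrix.csv")
    rescue.per_tumor.to_csv(OUT / "rescue.csv")

    low = rescue.per_tumor[~rescue.per_tumor["irs_high_alone"]]
    n_rescued = int(low["rescued"].sum())
    print(f"IRS_low on anti-PD-1 alone: {len(low)}/{len(rescue.per_tumor)}")
    print(f"rescued by >= 1 combination: {n_rescued}/{len(low)} "
          f"({100 * n_rescued / max(len(low), 1):.0f}%)")
    print("immune-reactive tumors per condition:")
    for cond, n in rescue.per_condition.items():
        print(f"  {cond}: {int(n)}")
    print(f"wrote {OUT}/rescue.csv and rescue_matrix.csv")


if __name__ == "__main__":
    main()
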