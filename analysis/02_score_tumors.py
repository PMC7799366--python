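#!/usr/bin/env python
"""Score the cohort: fold ratios, TCR-dependent selection, IRS and HRS.

Reads results/cohort/, runs the full scoring pipeline (anti-CD3/anti-CD28
fold ratios -> median > 1.5 selection -> anti-PD-1 IRS at cutoff 41.18 ->
HRS over all 27 analytes), and writes per-tumor scores plus the selected
panel to results/.
"""

import json
from pathlib import Path

import insitro as ins
from insitro import io

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    bundle = io.read_cohort(COHORT)
    res = ins.run_scoring_pipeline(bundle["concentrations"])

    scores = res.scores
    n_high = int((scores["irs_label"] == "IRS_high").sum())
    hrs_med = float(scores["hrs"].median())

    io.write_report(
        {
            "scores": scores,
            "summary": {
                "n_tumors": len(scores),
                "selected_analytes": res.selected_analytes,
                "n_irs_high": n_high,
                "irs_high_percent": round(100 * n_high / len(scores), 1),
                "hrs_cohort_median": hrs_med,
                **res.parameters,
            },
        },
        OUT,
    )

    print(f"TCR-dependent analytes selected ({len(res.selected_analytes)}): "
          f"{', '.join(sorted(res.selected_analytes))}")
    print(f"IRS_high (immune reactive): {n_high}/{len(scores)} "
          f"({100 * n_high / len(scores):.0f}%) at cutoff {res.parameters['cutoff']}")
    print(f"HRS cohort median: {hrs_med} "
          f"({int((scores['hrs_label'] == 'HRS_high').sum())} tumors HRS_high)")
    print(f"wrote {OUT}/scores.csv and {OUT}/report.json")


if __name__ == "__main__":
    main()
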