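#!/usr/bin/env python
"""Survival validation of the designated prognostic analyte.

On the simulated expression/PFS cohort: maximally selected rank-statistic
cutpoint with permutation significance, Kaplan-Meier curves for the median
and optimal splits, log-rank tests, and the univariate Cox hazard ratio.
"""

import json
from pathlib import Path

import pandas as pd

from insitro import io, survival

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    surv = io.read_cohort(COHORT)["survival"]

    scan = survival.maxstat_cutpoint(surv, n_permutations=2000, seed=1)
    scan.table.to_csv(OUT / "cutpoint_scan.csv", index=False)

    med_groups = survival.median_split(surv)
    opt_groups = pd.Series(
        ["low" if b <= scan.cutpoint else "high" for b in surv["biomarker"]],
        index=surv.index,
    )

    km = survival.km_estimate(surv, opt_groups)
    pd.concat({g: t for g, t in km.items()}, names=["group"]).to_csv(OUT / "km.csv")

    stat_med, p_med = survival.logrank(surv, med_groups)
    stat_opt, p_opt = survival.logrank(surv, opt_groups)
    cox = survival.cox_univariate(surv)

    with open(OUT / "cox.json", "w") as fh:
        json.dump(
            {
                "coef": cox.coef, "hazard_ratio": cox.hazard_ratio,
                "ci": [cox.ci_low, cox.ci_high], "p": cox.p_value,
                "n": cox.n, "events": cox.n_events,
                "maxstat_cutpoint": scan.cutpoint,
                "maxstat_p_permutation": scan.p_permutation,
            },
            fh, indent=2,
        )

    print(f"maxstat cutpoint: {scan.cutpoint:.3f} "
          f"(|Z| = {abs(scan.statistic):.2f}, permutation p = {scan.p_permutation:.4g})")
    print(f"log-rank, median split:  chi2 = {stat_med:.2f}, p = {p_med:.3g}")
    print(f"log-rank, optimal split: chi2 = {stat_opt:.2f}, p = {p_opt:.3g}")
    print(f"Cox HR per unit expression: {cox.hazard_ratio:.3f} "
          f"[{cox.ci_low:.3f}, {cox.ci_high:.3f}], p = {cox.p_value:.3g} "
          f"({cox.n_events}/{cox.n} events)")
    print(f"wrote {OUT}/cutpoint_scan.csv, km.csv, cox.json")


if __name__ == "__main__":
    main()
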