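#!/usr/bin/env python
"""Biomarker screen: which baseline factors track immune reactivity?

Compares unstimulated (medium) supernatant concentrations and usable flow
phenotype features between IRS_high and IRS_low tumors (Wilcoxon rank-sum,
BH correction; significant at FDR < 0.2, associated at P < 0.051), builds
the volcano table, and computes the Spearman matrix between soluble
factors and phenotype features.
"""

import warnings
from pathlib import Path

import insitro as ins
from insitro import io, stats

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    bundle = io.read_cohort(COHORT)
    res = ins.run_scoring_pipeline(bundle["concentrations"])
    labels = res.scores.set_index("tumor_id")["irs_label"]

    supernatant = io.wide_matrix(bundle["concentrations"], "medium").T  # analyte x tumor
    sf = stats.wilcoxon_bh(supernatant, labels)
    volcano = stats.volcano_table(sf)
    sf.to_csv(OUT / "biomarkers.csv")
    volcano.to_csv(OUT / "volcano.csv")

    pheno = io.flag_low_event_features(bundle["phenotype"])
    usable = pheno[pheno["usable"]].copy()
    usable["feature"] = usable["subset"] + "/" + usable["marker"]
    ph_wide = usable.pivot(index="feature", columns="tumor_id", values="value")
    ph = stats.wilcoxon_bh(ph_wide, labels.reindex(ph_wide.columns))
    ph.to_csv(OUT / "biomarkers_phenotype.csv")

    corr = stats.spearman_matrix(supernatant.T, ph_wide.T)
    corr.rho.to_csv(OUT / "spearman_rho.csv")

    top = sf.sort_values("p_value").head(5)
    print("top baseline soluble factors by rank-sum p (IRS_high vs IRS_low):")
    for f, r in top.iterrows():
        tag = "significant" if r["significant"] else ("associated" if r["associated"] else "")
        print(f"  {f}: p={r['p_value']:.3g} fdr={r['fdr']:.3g} {tag}")
    print("phenotype features:")
    for f, r in ph.sort_values("p_value").iterrows():
        print(f"  {f}: p={r['p_value']:.3g} fdr={r['fdr']:.3g}")
    print(f"wrote {OUT}/biomarkers.csv, biomarkers_phenotype.csv, volcano.csv, spearman_rho.csv")


if __name__ == "__main__":
    warnings.filterwarnings("ignore", category=UserWarning)
    main()
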