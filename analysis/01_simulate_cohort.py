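#!/usr/bin/env python
"""Simulate the study-sized cohort and apply sample eligibility QC.

42 tumors, exactly 7 designed anti-PD-1 responders, the 27-plex soluble
factor panel with 17 TCR-inducible analytes, plus metadata, flow-phenotype
summaries, ground-truth labels and a 90-patient survival table.  Writes
the cohort bundle under results/cohort/ for the downstream steps.
"""

from pathlib import Path

import insitro as ins
from insitro import io

OUT = Path("results/cohort")


def main() -> None:
    cfg = ins.default_config(n_tumors=42, responder_fraction=7 / 42, seed=1)
    conc, meta, truth, pheno, surv = ins.generate_cohort(cfg)

    qc = io.qc_cohort(meta)
    n_eligible = int(qc["eligible"].sum())

    io.write_cohort(OUT, conc, qc, truth=truth, phenotype=pheno,
                    survival=surv, config=cfg)

    print(f"simulated {cfg.n_tumors} tumors x {len(cfg.conditions)} conditions "
          f"x {len(cfg.analyte_names)} analytes -> {OUT}/")
    print(f"designed responders: {(truth['responder_class'] == 'responder').sum()}, "
          f"hypo-responders: {(truth['responder_class'] == 'hypo_responder').sum()}")
    print(f"eligible after QC (CD45 > 0.2%, > 1e6 cells): {n_eligible}/{len(qc)}")
    print(f"missing measurements: {(conc['censor_flag'] == 'missing').sum()}, "
          f"below LLOQ: {(conc['censor_flag'] == 'below_lloq').sum()}")


if __name__ == "__main__":
    main()
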