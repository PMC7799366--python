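import numpy as np
import pandas as pd
import pytest

import insitro as ins


def make_conc(rows):
    """Long concentration table from (tumor, condition, analyte, conc, flag)."""
    return pd.DataFrame(
        rows, columns=["tumor_id", "condition", "analyte", "concentration", "censor_flag"]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    cfg = ins.default_config(n_tumors=20, seed=7)
    conc, meta, truth, pheno, surv = ins.generate_cohort(cfg)
    return {
        "config": cfg,
        "concentrations": conc,
        "metadata": meta,
        "truth": truth,
        "phenotype": pheno,
        "survival": surv,
    }


@pytest.fixture(scope="session")
def study_cohort():
    """The study-sized cohort: 42 tumors, exactly 7 responders."""
    cfg = ins.default_config(n_tumors=42, responder_fraction=7 / 42, seed=1)
    conc, meta, truth, pheno, surv = ins.generate_cohort(cfg)
    return {
        "config": cfg,
        "concentrations": conc,
        "truth": truth,
        "survival": surv,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
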