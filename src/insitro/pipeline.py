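"""End-to-end scoring pipeline: concentrations in, per-tumor scores out."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import scoring
from .synthetic import ANTI_PD1, MEDIUM, TCR_CONDITION


@dataclass
class PipelineResult:
    selected_analytes: list
    tcr_fold_ratios: pd.DataFrame
    pd1_fold_ratios: pd.DataFrame
    scores: pd.DataFrame
    parameters: dict = field(default_factory=dict)


def run_scoring_pipeline(
    concentrations: pd.DataFrame,
    reference_condition: str = MEDIUM,
    tcr_condition: str = TCR_CONDITION,
    treatment_condition: str = ANTI_PD1,
    selection_threshold: float = scoring.POSITIVITY_THRESHOLD,
    positivity_threshold: float = scoring.POSITIVITY_THRESHOLD,
    cutoff: float = scoring.IRS_CUTOFF,
    selected_analytes: list | None = None,
) -> PipelineResult:
    """Fold ratios -> TCR-dependent selection -> IRS/HRS per tumor.

    The TCR-dependent panel is derived from the anti-CD3/anti-CD28 fold
    ratios over the reference condition unless ``selected_analytes`` is
    given.  Scores are computed on the treatment (anti-PD-1) fold ratios;
    HRS uses every analyte present.
    """
    tcr_fr = scoring.fold_ratio_table(concentrations, tcr_condition, reference_condition)
    if selected_analytes is None:
        selected_analytes = scoring.select_tcr_dependent(tcr_fr, selection_threshold)
    pd1_fr = scoring.fold_ratio_table(
        concentrations, treatment_condition, reference_condition
    )
    scores = scoring.score_cohort(
        pd1_fr,
        selected_analytes,
        cutoff=cutoff,
        positivity_threshold=positivity_threshold,
    )
    return PipelineResult(
        selected_analytes=list(selected_analytes),
        tcr_fold_ratios=tcr_fr,
        pd1_fold_ratios=pd1_fr,
        scores=scores,
        parameters={
            "reference_condition": reference_condition,
            "tcr_condition": tcr_condition,
            "treatment_condition": treatment_condition,
            "selection_threshold": selection_threshold,
            "positivity_threshold": positivity_threshold,
            "cutoff": cutoff,
        },
    )


def condition_scores(
    concentrations: pd.DataFrame,
    selected_analytes: list,
    conditions: list,
    reference_condition: str = MEDIUM,
    cutoff: float = scoring.IRS_CUTOFF,
) -> pd.DataFrame:
    """Long table of IRS per tumor for each listed stimulation condition."""
    parts = []
    for cond in conditions:
        fr = scoring.fold_ratio_table(concentrations, cond, reference_condition)
        sc = scoring.score_cohort(fr, selected_analytes, cutoff=cutoff)
        sc["condition"] = cond
        parts.append(sc)
    return pd.concat(parts, ignore_index=True)
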