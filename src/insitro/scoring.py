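"""Fold-ratio scoring of ex vivo stimulated tumor secretomes.

The readout of the assay is, per tumor, a panel of soluble-factor (SF)
concentrations measured after 60 h of culture under each stimulation
condition.  All downstream scores are built from *fold ratios* (FR): the
concentration under a stimulation condition divided by the concentration in
the unstimulated (medium) control, per tumor and analyte.

Two bespoke scores are computed here:

* the Immune Reactivity Score (IRS): the number of TCR-dependent analytes
  whose FR under PD-1 blockade reaches the positivity threshold (1.5),
  expressed as a percent of the 17-analyte panel; a tumor is "immune
  reactive" (IRS_high) when IRS >= 41.18, equivalently when at least 7 of
  the 17 analytes are positive;
* the Hypo-Responsive Score (HRS): the number of analytes, over the full
  panel, whose FR under PD-1 blockade falls below 0.1 (a ten-fold drop);
  tumors above the cohort median HRS are called HRS_high.

The module also hosts the TCR-dependent analyte selection (cohort median FR
under anti-CD3/anti-CD28 cross-linking > 1.5), the diagnostic-cutoff
optimizer used to align the IRS with the unsupervised cluster labels, and
the combination-rescue summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

#: FR at or above which a TCR-dependent analyte counts as positive.
POSITIVITY_THRESHOLD = 1.5
#: IRS percent cutoff separating IRS_high from IRS_low (== 7 of 17 positives).
IRS_CUTOFF = 41.18
#: FR below which an analyte counts toward the hypo-responsive score.
HYPO_THRESHOLD = 0.1
#: Published cohort-median HRS threshold (the cohort estimate is preferred).
HRS_PUBLISHED_THRESHOLD = 5.5
#: Size of the TCR-dependent panel the percent transform is defined on.
PANEL_SIZE = 17

FOLD_RATIO_COLUMNS = [
    "tumor_id",
    "condition",
    "analyte",
    "fold_ratio",
    "reference_condition",
    "policy_applied",
]


@dataclass
class ScoreResult:
    """Per-tumor, per-condition score bundle.

    ``irs_percent`` is ``round(100 * n_positive / denominator, 2)``; under
    the default fixed-denominator convention the denominator is the selected
    panel size and missing analytes count as non-positive, so adding missing
    data can never raise the score.
    """

    tumor_id: str
    condition: str
    n_positive: int
    n_evaluable: int
    irs_percent: float
    irs_label: str
    hrs: int | None = None
    hrs_evaluable: int | None = None
    hrs_label: str | None = None


@dataclass
class CutoffResult:
    """Outcome of the IRS-cutoff optimization against cluster labels."""

    cutoff: float
    sensitivity: float
    specificity: float
    positive_likelihood_ratio: float
    table: pd.DataFrame
    informative: bool = True


@dataclass
class RescueTable:
    """Combination-rescue summary.

    ``matrix`` is tumors x conditions of IRS percent (NaN = untested);
    ``per_tumor`` carries the rescued flag and the best combination;
    ``per_condition`` counts immune-reactive tumors per condition.
    """

    matrix: pd.DataFrame
    per_tumor: pd.DataFrame
    per_condition: pd.Series
    cutoff: float
    anti_pd1_condition: str
    excluded_tumors: list = field(default_factory=list)


def fold_ratio_table(
    conc: pd.DataFrame,
    stim_condition: str,
    reference_condition: str = "medium",
    policy: str = "half_lloq",
) -> pd.DataFrame:
    """Compute per-tumor, per-analyte fold ratios stim / reference.

    ``conc`` is a long concentration table with columns ``tumor_id``,
    ``condition``, ``analyte``, ``concentration``, ``censor_flag`` (values
    in {in_range, below_lloq, above_uloq, missing}).  Below-LLOQ entries are
    stored as the reported LLOQ, so the half-LLOQ substitution divides the
    stored value by two.

    Policy (default ``"half_lloq"``):

    * reference flagged below_lloq, stimulated usable -> reference replaced
      by LLOQ/2 before division (``policy_applied = half_lloq_substitution``);
    * both operands below_lloq, or either missing -> FR is missing
      (``policy_applied = undefined_missing``);
    * otherwise plain division (``policy_applied = none``).

    With ``policy="strict"`` any censored operand yields a missing FR.
    """
    if stim_condition == reference_condition:
        raise ValidationError("stimulation and reference conditions are identical")
    present = set(conc["condition"].unique())
    for cond in (stim_condition, reference_condition):
        if cond not in present:
            raise ValidationError(f"condition {cond!r} not present in table")
    if policy not in ("half_lloq", "strict"):
        raise ValidationError(f"unknown fold-ratio policy {policy!r}")

    cols = ["tumor_id", "analyte", "concentration", "censor_flag"]
    stim = conc.loc[conc["condition"] == stim_condition, cols]
    ref = conc.loc[conc["condition"] == reference_condition, cols]
    merged = stim.merge(
        ref, on=["tumor_id", "analyte"], how="outer", suffixes=("_stim", "_ref")
    )

    fr = np.full(len(merged), np.nan)
    applied = np.full(len(merged), "undefined_missing", dtype=object)

    s_val = merged["concentration_stim"].to_numpy(float)
    r_val = merged["concentration_ref"].to_numpy(float)
    s_flag = merged["censor_flag_stim"].fillna("missing").to_numpy(object)
    r_flag = merged["censor_flag_ref"].fillna("missing").to_numpy(object)

    s_missing = (s_flag == "missing") | ~np.isfinite(s_val)
    r_missing = (r_flag == "missing") | ~np.isfinite(r_val)
    both_lloq = (s_flag == "below_lloq") & (r_flag == "below_lloq")
    usable = ~(s_missing | r_missing | both_lloq)
    if policy == "strict":
        usable &= (s_flag == "in_range") & (r_flag == "in_range")

    sub = usable & (r_flag == "below_lloq")
    denom = np.where(sub, r_val / 2.0, r_val)
    ok = usable & (denom > 0)
    fr[ok] = s_val[ok] / denom[ok]
    applied[ok] = "none"
    applied[ok & sub] = "half_lloq_substitution"

    out = pd.DataFrame(
        {
            "tumor_id": merged["tumor_id"],
            "condition": stim_condition,
            "analyte": merged["analyte"],
            "fold_ratio": fr,
            "reference_condition": reference_condition,
            "policy_applied": applied,
        }
    )
    return out.sort_values(["tumor_id", "analyte"], ignore_index=True)


def select_tcr_dependent(
    fr: pd.DataFrame, threshold: float = POSITIVITY_THRESHOLD, min_tumors: int = 2
) -> list[str]:
    """Select TCR-dependent analytes from anti-CD3/anti-CD28 fold ratios.

    An analyte is TCR-dependent when its cohort median FR (missing values
    excluded) strictly exceeds ``threshold``.  Deterministic given the
    table; analytes with fewer than ``min_tumors`` non-missing values are
    skipped with a warning.
    """
    if fr.empty:
        raise ValidationError("empty fold-ratio table")
    n_tumors = fr["tumor_id"].nunique()
    if n_tumors < max(min_tumors, 2):
        warnings.warn(
            f"cohort of {n_tumors} tumor(s): per-analyte medians are unstable",
            stacklevel=2,
        )
    selected = []
    for analyte, grp in fr.groupby("analyte", sort=True):
        vals = grp["fold_ratio"].dropna()
        if len(vals) == 0:
            continue
        if len(vals) < min_tumors and n_tumors >= min_tumors:
            warnings.warn(
                f"analyte {analyte!r} has {len(vals)} non-missing value(s); skipped",
                stacklevel=2,
            )
            continue
        if float(vals.median()) > threshold:
            selected.append(analyte)
    return selected


def immune_reactivity_score(
    fr_row: pd.Series,
    selected: list[str],
    positivity_threshold: float = POSITIVITY_THRESHOLD,
    cutoff: float = IRS_CUTOFF,
    strict_positivity: bool = False,
    denominator: str = "fixed",
    tumor_id: str = "",
    condition: str = "",
) -> ScoreResult:
    """Score one tumor under one condition.

    ``fr_row`` maps analyte -> fold ratio (NaN = missing).  ``n_positive``
    counts selected analytes at FR >= threshold (strictly > when
    ``strict_positivity``); missing analytes count as non-positive under the
    default fixed denominator, or shrink the denominator when
    ``denominator="evaluable"``.
    """
    if len(selected) == 0:
        raise ValidationError("empty selected analyte set")
    if len(selected) != PANEL_SIZE:
        warnings.warn(
            f"selected panel has {len(selected)} analytes (expected {PANEL_SIZE}); "
            "the percent denominator follows the panel size",
            stacklevel=2,
        )
    vals = fr_row.reindex(selected).to_numpy(float)
    evaluable = np.isfinite(vals)
    if strict_positivity:
        positive = evaluable & (vals > positivity_threshold)
    else:
        positive = evaluable & (vals >= positivity_threshold)
    n_positive = int(positive.sum())
    n_evaluable = int(evaluable.sum())
    denom = n_evaluable if denominator == "evaluable" else len(selected)
    if denominator == "evaluable" and denom == 0:
        raise ValidationError("no evaluable analytes under evaluable-denominator mode")
    irs_percent = round(100.0 * n_positive / denom, 2)
    return ScoreResult(
        tumor_id=tumor_id,
        condition=condition,
        n_positive=n_positive,
        n_evaluable=n_evaluable,
        irs_percent=irs_percent,
        irs_label=classify_irs(irs_percent, cutoff),
    )


def classify_irs(irs_percent: float | ScoreResult, cutoff: float = IRS_CUTOFF) -> str:
    """IRS_high iff the percent score reaches the cutoff (default 41.18).

    With the fixed 17-analyte denominator this is equivalent to having at
    least 7 positive analytes.
    """
    if isinstance(irs_percent, ScoreResult):
        irs_percent = irs_percent.irs_percent
    return "IRS_high" if irs_percent >= cutoff else "IRS_low"


def hypo_responsive_score(
    fr_row: pd.Series, hypo_threshold: float = HYPO_THRESHOLD
) -> tuple[int, int]:
    """Count analytes with FR below the hypo-responsiveness threshold.

    Returns ``(hrs, n_evaluable)``; missing analytes contribute 0.
    """
    vals = fr_row.to_numpy(float)
    evaluable = np.isfinite(vals)
    return int((evaluable & (vals < hypo_threshold)).sum()), int(evaluable.sum())


def hrs_threshold(hrs_values) -> float:
    """Cohort median of HRS values, used as the HRS_high/HRS_low threshold."""
    vals = pd.Series(hrs_values).dropna()
    if len(vals) < 2:
        raise ValidationError("need at least 2 tumors to estimate the HRS median")
    return float(vals.median())


def classify_hrs(hrs: int, threshold: float, strict: bool = True) -> str:
    """HRS_high when above the threshold (strictly by default).

    The source convention is ambiguous between ``> 5.55`` and ``>= 5.5``;
    both are supported and a fixed user-supplied threshold near the
    published value triggers a reminder of the discrepancy.
    """
    if abs(threshold - HRS_PUBLISHED_THRESHOLD) < 0.1 and threshold != HRS_PUBLISHED_THRESHOLD:
        warnings.warn(
            "fixed HRS threshold close to the published 5.5/5.55 pair; "
            "check which convention you intend",
            stacklevel=2,
        )
    high = hrs > threshold if strict else hrs >= threshold
    return "HRS_high" if high else "HRS_low"


def irs_candidates(panel_size: int = PANEL_SIZE) -> np.ndarray:
    """All achievable IRS percent values k*100/panel_size, 2-decimal rounded."""
    return np.round(100.0 * np.arange(panel_size + 1) / panel_size, 2)


def optimize_cutoff(scores, labels, panel_size: int = PANEL_SIZE) -> CutoffResult:
    """Pick the IRS cutoff best concordant with cluster labels.

    ``labels`` are condition-positive for R_clus (accepts booleans or the
    strings ``R_clus``/``NR_clus``).  Candidates are the achievable percent
    values ``k * 100 / panel_size``.  For each candidate ``c``:
    sensitivity = P(score >= c | R_clus), specificity = P(score < c |
    NR_clus); LR+ = sens / (1 - spec), computed with a Haldane +0.5
    correction on all four confusion cells whenever specificity is exactly
    1.  The maximizer of LR+ is returned; ties go to the larger Youden J,
    then to the smaller cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    lab = np.asarray(
        [x if isinstance(x, (bool, np.bool_)) else x == "R_clus" for x in labels]
    )
    if len(scores) != len(lab):
        raise ValidationError("scores and labels differ in length")
    if lab.all() or not lab.any():
        raise ValidationError("both label classes must be present")

    pos, neg = scores[lab], scores[~lab]
    rows = []
    for c in irs_candidates(panel_size):
        tp = int((pos >= c).sum())
        fn = len(pos) - tp
        tn = int((neg < c).sum())
        fp = len(neg) - tn
        sens = tp / len(pos)
        spec = tn / len(neg)
        if spec == 1.0:
            sens_h = (tp + 0.5) / (len(pos) + 1.0)
            spec_h = (tn + 0.5) / (len(neg) + 1.0)
            lr = sens_h / (1.0 - spec_h)
        else:
            lr = sens / (1.0 - spec)
        rows.append(
            {
                "cutoff": c,
                "sensitivity": sens,
                "specificity": spec,
                "lr_plus": lr,
                "youden_j": sens + spec - 1.0,
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["lr_plus", "youden_j", "cutoff"], ascending=[False, False, True]
    )
    best = order.iloc[0]
    informative = len(np.unique(scores)) > 1
    return CutoffResult(
        cutoff=float(best["cutoff"]),
        sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
        positive_likelihood_ratio=float(best["lr_plus"]),
        table=table,
        informative=informative,
    )


def combination_rescue(
    scores: pd.DataFrame,
    cutoff: float = IRS_CUTOFF,
    anti_pd1_condition: str = "aPD1",
    condition_order: list[str] | None = None,
) -> RescueTable:
    """Summarize which IRS_low tumors a combination condition rescues.

    ``scores`` is long with columns ``tumor_id``, ``condition``,
    ``irs_percent``.  A tumor is *rescued* when its single-agent anti-PD-1
    IRS is below the cutoff but at least one tested combination reaches it.
    The best condition is the tested combination with the highest IRS
    (ties broken by ``condition_order``, default: sorted condition names).
    Untested combinations stay NaN in the matrix and never count as
    failures.  Tumors lacking the anti-PD-1 condition are excluded with a
    warning.
    """
    required = {"tumor_id", "condition", "irs_percent"}
    if not required.issubset(scores.columns):
        raise ValidationError(f"scores table must have columns {sorted(required)}")
    matrix = scores.pivot_table(
        index="tumor_id", columns="condition", values="irs_percent", aggfunc="first"
    )
    if anti_pd1_condition not in matrix.columns:
        raise ValidationError(f"anti-PD-1 condition {anti_pd1_condition!r} absent")

    excluded = matrix.index[matrix[anti_pd1_condition].isna()].tolist()
    if excluded:
        warnings.warn(
            f"{len(excluded)} tumor(s) lack the {anti_pd1_condition} condition; excluded",
            stacklevel=2,
        )
        matrix = matrix.drop(index=excluded)

    combos = [c for c in matrix.columns if c != anti_pd1_condition]
    if condition_order is None:
        condition_order = sorted(combos)
    combos = [c for c in condition_order if c in combos]

    records = []
    for tumor, row in matrix.iterrows():
        base = row[anti_pd1_condition]
        high_alone = base >= cutoff
        tested = row[combos].dropna()
        best_cond, best_irs = None, np.nan
        if len(tested):
            best_irs = tested.max()
            # first condition in the documented order achieving the max
            best_cond = next(c for c in combos if c in tested.index and tested[c] == best_irs)
        rescued = bool((not high_alone) and len(tested) and (tested >= cutoff).any())
        records.append(
            {
                "tumor_id": tumor,
                "anti_pd1_irs": base,
                "irs_high_alone": bool(high_alone),
                "n_combos_tested": int(len(tested)),
                "best_condition": best_cond,
                "best_irs": best_irs,
                "rescued": rescued,
            }
        )
    per_tumor = pd.DataFrame(records).set_index("tumor_id")
    per_condition = (matrix >= cutoff).sum()
    return RescueTable(
        matrix=matrix,
        per_tumor=per_tumor,
        per_condition=per_condition,
        cutoff=cutoff,
        anti_pd1_condition=anti_pd1_condition,
        excluded_tumors=excluded,
    )


def score_cohort(
    fr: pd.DataFrame,
    selected: list[str],
    all_analytes: list[str] | None = None,
    cutoff: float = IRS_CUTOFF,
    positivity_threshold: float = POSITIVITY_THRESHOLD,
    hypo_threshold: float = HYPO_THRESHOLD,
) -> pd.DataFrame:
    """Score every tumor in a fold-ratio table; returns one row per tumor.

    IRS uses the ``selected`` panel; HRS uses ``all_analytes`` (default:
    every analyte present).  HRS labels are assigned against the cohort
    median via :func:`hrs_threshold` when at least two tumors are scored.
    """
    if all_analytes is None:
        all_analytes = sorted(fr["analyte"].unique())
    wide = fr.pivot(index="tumor_id", columns="analyte", values="fold_ratio")
    condition = fr["condition"].iloc[0] if len(fr) else ""
    rows = []
    for tumor, row in wide.iterrows():
        res = immune_reactivity_score(
            row,
            selected,
            positivity_threshold=positivity_threshold,
            cutoff=cutoff,
            tumor_id=str(tumor),
            condition=str(condition),
        )
        res.hrs, res.hrs_evaluable = hypo_responsive_score(
            row.reindex(all_analytes), hypo_threshold
        )
        rows.append(res)
    out = pd.DataFrame([r.__dict__ for r in rows])
    if len(out) >= 2:
        thr = hrs_threshold(out["hrs"])
        out["hrs_label"] = [classify_hrs(h, thr) for h in out["hrs"]]
    return out
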