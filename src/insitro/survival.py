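"""Survival validation of a candidate predictive analyte.

A continuous biomarker (in the motivating application, tumor CXCL10
expression) is validated against progression-free survival: Kaplan-Meier
curves for the split, a log-rank comparison, a univariate Cox hazard
ratio, and a maximally-selected rank-statistic cutpoint — the biomarker
threshold maximizing the absolute standardized log-rank statistic over all
candidate splits within quantile bounds, with selection-adjusted
significance obtained by permuting the biomarker across patients.

Kaplan-Meier, log-rank and Cox fits delegate to lifelines; the
standardized log-rank statistic and the cutpoint scan are implemented here
(the scan needs the signed per-split statistic, and permutation inference
replaces the asymptotic improved-Bonferroni approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import ValidationError


@dataclass
class CutpointScan:
    table: pd.DataFrame          # cutpoint, n_low, statistic (signed Z), abs_statistic
    cutpoint: float
    statistic: float             # signed Z at the selected cutpoint
    p_permutation: float | None
    lower_quantile: float
    upper_quantile: float
    n_permutations: int


@dataclass
class CoxResult:
    coef: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    converged: bool = True


def km_estimate(records: pd.DataFrame, group_labels: pd.Series | None = None) -> dict:
    """Kaplan-Meier step functions, one per group.

    ``records`` needs ``time`` and ``event`` columns.  Returns group ->
    DataFrame(time, survival, at_risk); censoring at an event time is
    handled after the events (the standard product-limit convention).
    With no events the estimate is identically 1.
    """
    if group_labels is None:
        group_labels = pd.Series("all", index=records.index)
    if isinstance(group_labels.dtype, pd.CategoricalDtype):
        groups = list(group_labels.cat.categories)
    else:
        groups = list(pd.unique(group_labels))
    out = {}
    for g in groups:
        sub = records.loc[group_labels == g]
        if len(sub) == 0:
            raise ValidationError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        times = kmf.event_table.index.to_numpy(float)
        out[g] = pd.DataFrame(
            {
                "time": times,
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(float),
                "at_risk": kmf.event_table["at_risk"].to_numpy(int),
            }
        )
    return out


def logrank(records: pd.DataFrame, group_labels: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, two-sided p)."""
    groups = pd.unique(group_labels)
    if len(groups) != 2:
        raise ValidationError("log-rank test requires exactly two groups")
    if records["event"].sum() < 1:
        raise ValidationError("need at least one event")
    a = records.loc[group_labels == groups[0]]
    b = records.loc[group_labels == groups[1]]
    res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


def standardized_logrank(time, event, in_group) -> float:
    """Signed standardized log-rank statistic Z = (O - E) / sqrt(V).

    ``in_group`` marks membership of the "low" group; positive Z means the
    low group observed more events than expected (worse outcome).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    g = np.asarray(in_group, bool)
    order = np.argsort(time, kind="stable")
    time, event, g = time[order], event[order], g[order]

    num = 0.0
    var = 0.0
    i = 0
    n = len(time)
    while i < n:
        t = time[i]
        at_risk = n - i
        at_risk_g = int(g[i:].sum())
        j = i
        d = d_g = 0
        while j < n and time[j] == t:
            if event[j]:
                d += 1
                d_g += int(g[j])
            j += 1
        if d > 0 and at_risk > 1:
            e = d * at_risk_g / at_risk
            v = (
                d
                * (at_risk_g / at_risk)
                * (1 - at_risk_g / at_risk)
                * (at_risk - d)
                / (at_risk - 1)
            )
            num += d_g - e
            var += v
        i = j
    if var <= 0:
        return 0.0
    return num / np.sqrt(var)


def _scan(biomarker, time, event, candidates) -> pd.DataFrame:
    rows = []
    for c in candidates:
        low = biomarker <= c
        z = standardized_logrank(time, event, low)
        rows.append({"cutpoint": c, "n_low": int(low.sum()), "statistic": z,
                     "abs_statistic": abs(z)})
    return pd.DataFrame(rows)


def candidate_cutpoints(biomarker, lower_quantile=0.1, upper_quantile=0.9) -> np.ndarray:
    """Distinct biomarker values whose low/high split keeps the low-group
    proportion within the quantile bounds."""
    b = np.asarray(biomarker, float)
    n = len(b)
    values = np.unique(b)
    out = []
    for c in values:
        frac_low = (b <= c).sum() / n
        if lower_quantile <= frac_low <= upper_quantile:
            out.append(c)
    return np.asarray(out)


def maxstat_cutpoint(
    records: pd.DataFrame,
    biomarker: str = "biomarker",
    lower_quantile: float = 0.1,
    upper_quantile: float = 0.9,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> CutpointScan:
    """Maximally selected rank-statistic cutpoint with permutation p.

    Candidates are the distinct biomarker values keeping both groups within
    the quantile bounds; the selected cutpoint maximizes |Z| (ties -> the
    lower cutpoint).  Significance: the biomarker is permuted across
    patients ``n_permutations`` times, the scan maximum recomputed, and
    p = (1 + #{permuted max >= observed max}) / (B + 1).  Pass
    ``n_permutations=0`` to skip the permutation test.
    """
    if len(records) < 10:
        raise ValidationError("need at least 10 records for a cutpoint scan")
    if records["event"].sum() < 2:
        raise ValidationError("need at least 2 events")
    b = records[biomarker].to_numpy(float)
    time = records["time"].to_numpy(float)
    event = records["event"].to_numpy(int)
    cands = candidate_cutpoints(b, lower_quantile, upper_quantile)
    if len(cands) == 0:
        raise ValidationError("no candidate cutpoint within the quantile bounds")
    table = _scan(b, time, event, cands)
    best_abs = table["abs_statistic"].max()
    best = table.loc[table["abs_statistic"] == best_abs, "cutpoint"].min()
    best_z = float(table.loc[table["cutpoint"] == best, "statistic"].iloc[0])

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            bp = rng.permutation(b)
            cp = candidate_cutpoints(bp, lower_quantile, upper_quantile)
            mx = _scan(bp, time, event, cp)["abs_statistic"].max()
            if mx >= best_abs:
                hits += 1
        p_perm = (1 + hits) / (n_permutations + 1)

    return CutpointScan(
        table=table,
        cutpoint=float(best),
        statistic=best_z,
        p_permutation=p_perm,
        lower_quantile=lower_quantile,
        upper_quantile=upper_quantile,
        n_permutations=n_permutations,
    )


def median_split(records: pd.DataFrame, biomarker: str = "biomarker") -> pd.Series:
    """Low/high labels at the cohort median (the fixed-split special case)."""
    med = records[biomarker].median()
    return pd.Series(
        np.where(records[biomarker] <= med, "low", "high"), index=records.index
    )


def cox_univariate(records: pd.DataFrame, covariate: str = "biomarker") -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron tie handling).

    Returns the coefficient, hazard ratio with 95% Wald CI, and p.  A
    constant covariate or fewer than two events is an error; lifelines'
    convergence failures (including monotone likelihood under perfect
    separation) propagate as errors with the fitter's diagnostics.
    """
    if records["event"].sum() < 2:
        raise ValidationError("need at least 2 events for a Cox fit")
    if records[covariate].nunique() < 2:
        raise ValidationError(f"covariate {covariate!r} is constant")
    cph = CoxPHFitter()
    df = records[["time", "event", covariate]].copy()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence / separation
        raise ValidationError(f"Cox fit failed: {exc}") from exc
    s = cph.summary.loc[covariate]
    return CoxResult(
        coef=float(s["coef"]),
        hazard_ratio=float(s["exp(coef)"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p_value=float(s["p"]),
        n=len(df),
        n_events=int(df["event"].sum()),
    )
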