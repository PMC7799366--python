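"""Group-comparison and correlation statistics for biomarker screening.

Features (soluble-factor concentrations or flow-phenotype percentages) are
compared between IRS_high and IRS_low tumors with the two-sided Wilcoxon
rank-sum test — exact when the combined sample is small and tie-free,
normal approximation with tie and continuity correction otherwise — and
Benjamini-Hochberg FDR control across the tested family.  The volcano
table carries the log10 group-central ratio against -log10 p.  Spearman
matrices use midranks for ties and a t-approximation for the two-sided p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

FDR_SIGNIFICANT = 0.2     # volcano "significant" fill
P_ASSOCIATED = 0.051      # volcano "associated" highlight
EXACT_MAX_N = 25          # exact rank-sum up to this combined n (no ties)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small tie-free samples."""
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def wilcoxon_bh(features: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Rank-sum screen of every feature between two groups, BH-corrected.

    ``features``: rows = features, columns = tumors; ``groups``: tumor ->
    boolean (True = IRS_high) or the labels ``IRS_high``/``IRS_low``.
    Features with an empty group are skipped with a warning; constant
    features report p = 1 with ``constant`` flagged.  BH is applied across
    the features actually tested.
    """
    g = groups.map(lambda v: v if isinstance(v, (bool, np.bool_)) else v == "IRS_high")
    if g.all() or not g.any():
        raise ValidationError("both groups must be present")
    hi_ids = g.index[g].tolist()
    lo_ids = g.index[~g].tolist()

    rows = []
    for feat, vals in features.iterrows():
        hi = vals.reindex(hi_ids).dropna().to_numpy(float)
        lo = vals.reindex(lo_ids).dropna().to_numpy(float)
        if len(hi) == 0 or len(lo) == 0:
            warnings.warn(f"feature {feat!r} has an empty group; skipped", stacklevel=2)
            continue
        both = np.concatenate([hi, lo])
        constant = bool(np.all(both == both[0]))
        p = 1.0 if constant else _rank_sum_p(hi, lo)
        rows.append(
            {
                "feature": feat,
                "n_high": len(hi),
                "n_low": len(lo),
                "mean_high": float(np.mean(hi)),
                "mean_low": float(np.mean(lo)),
                "median_high": float(np.median(hi)),
                "median_low": float(np.median(lo)),
                "p_value": p,
                "constant": constant,
            }
        )
    if not rows:
        raise ValidationError("no testable features")
    out = pd.DataFrame(rows).set_index("feature")
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < FDR_SIGNIFICANT
    out["associated"] = out["p_value"] < P_ASSOCIATED
    return out


def volcano_table(results: pd.DataFrame, central: str = "mean") -> pd.DataFrame:
    """Figure-ready volcano: log10 central ratio vs -log10 p / fdr.

    ``central`` is ``"mean"`` (default) or ``"median"``.  A zero central in
    one group is replaced by half the smallest positive central in the
    family (logged in the ``zero_substituted`` column); features with both
    centrals zero are excluded with a warning.
    """
    if central not in ("mean", "median"):
        raise ValidationError("central must be 'mean' or 'median'")
    hi = results[f"{central}_high"].to_numpy(float)
    lo = results[f"{central}_low"].to_numpy(float)
    both_zero = (hi == 0) & (lo == 0)
    if both_zero.any():
        warnings.warn(
            f"excluded {int(both_zero.sum())} feature(s) with both group centrals zero",
            stacklevel=2,
        )
    keep = ~both_zero
    hi, lo = hi[keep], lo[keep]
    res = results.loc[keep]
    positives = np.concatenate([hi[hi > 0], lo[lo > 0]])
    floor = positives.min() / 2.0 if len(positives) else np.nan
    substituted = (hi == 0) | (lo == 0)
    hi = np.where(hi == 0, floor, hi)
    lo = np.where(lo == 0, floor, lo)
    return pd.DataFrame(
        {
            "log10_ratio": np.log10(hi / lo),
            "neg_log10_p": -np.log10(res["p_value"].to_numpy(float)),
            "neg_log10_fdr": -np.log10(res["fdr"].to_numpy(float)),
            "significant": res["significant"].to_numpy(bool),
            "associated": res["associated"].to_numpy(bool),
            "zero_substituted": substituted,
        },
        index=res.index,
    )


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    n_pairs: pd.DataFrame
    stars: pd.DataFrame   # True where p < 0.05
    min_pairs: int


def spearman_matrix(
    x: pd.DataFrame, y: pd.DataFrame | None = None, min_pairs: int = 5
) -> CorrelationMatrix:
    """Spearman correlations between the columns of ``x`` and ``y``.

    Inputs are tumors x features with a shared tumor index; ``y=None``
    computes the symmetric matrix of ``x`` with itself.  Pairs with fewer
    than ``min_pairs`` complete observations stay missing; a feature with
    insufficient overlap everywhere yields an all-missing row with a
    warning.
    """
    symmetric = y is None
    if y is None:
        y = x
    else:
        y = y.reindex(x.index)
    rho = pd.DataFrame(np.nan, index=x.columns, columns=y.columns)
    pmat = pd.DataFrame(np.nan, index=x.columns, columns=y.columns)
    npairs = pd.DataFrame(0, index=x.columns, columns=y.columns)
    for fx in x.columns:
        for fy in y.columns:
            a, b = x[fx], y[fy]
            ok = a.notna() & b.notna()
            n = int(ok.sum())
            npairs.loc[fx, fy] = n
            if n < min_pairs:
                continue
            if symmetric and fx == fy:
                rho.loc[fx, fy], pmat.loc[fx, fy] = 1.0, 0.0
                continue
            r, p = sps.spearmanr(a[ok], b[ok])
            rho.loc[fx, fy], pmat.loc[fx, fy] = r, p
    for fx in x.columns:
        if rho.loc[fx].isna().all():
            warnings.warn(
                f"feature {fx!r} has < {min_pairs} paired observations everywhere",
                stacklevel=2,
            )
    return CorrelationMatrix(
        rho=rho, p=pmat, n_pairs=npairs, stars=pmat < 0.05, min_pairs=min_pairs
    )
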