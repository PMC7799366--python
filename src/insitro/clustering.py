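"""Unsupervised responder classification by hierarchical bi-clustering.

Fold ratios are log2-transformed and z-scored per analyte across tumors,
then tumors and analytes are clustered agglomeratively; cutting the tumor
dendrogram at k = 2 yields the two microenvironment categories.  The group
with the higher grand-mean z (most analytes elevated above the cohort mean
after stimulation) is labeled R_clus, the other NR_clus.

Two distance/linkage pairs are first-class because the source protocol is
stated both ways: Euclidean with Ward linkage and correlation with average
linkage.  Missing cells are never imputed: pairwise distances use the
pairwise-complete entries, rescaled by the fraction observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError


@dataclass
class TransformedMatrix:
    """Tumors x analytes matrix of z-scored log2 fold ratios."""

    values: pd.DataFrame
    stim_condition: str = ""
    reference_condition: str = ""
    ddof: int = 0
    dropped_analytes: list = field(default_factory=list)

    @property
    def mask(self) -> pd.DataFrame:
        """True where the entry is missing."""
        return self.values.isna()


@dataclass
class ClusterAssignment:
    labels: pd.Series                 # tumor_id -> "R_clus"/"NR_clus" (or "G1"/"G2")
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None
    row_order: list
    col_order: list
    distance: str
    linkage: str
    informative: bool = True
    margin: float | None = None       # grand-mean z separation between groups


def transform(fr: pd.DataFrame, ddof: int = 0) -> TransformedMatrix:
    """z-score of log2 fold ratios, per analyte across tumors.

    Population (n) standard deviation by default; ``ddof=1`` for the sample
    convention.  Analytes with fewer than two observed values or zero
    variance are dropped with a warning; missingness propagates.
    """
    if (fr["fold_ratio"].dropna() <= 0).any():
        raise ValidationError("fold ratios must be positive where present")
    wide = fr.pivot(index="tumor_id", columns="analyte", values="fold_ratio")
    log2 = np.log2(wide)
    dropped = []
    keep = {}
    for a in log2.columns:
        col = log2[a]
        obs = col.dropna()
        if len(obs) < 2:
            dropped.append(a)
            continue
        sd = obs.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            dropped.append(a)
            continue
        keep[a] = (col - obs.mean()) / sd
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} analyte(s) with <2 values or zero variance: "
            f"{dropped}",
            stacklevel=2,
        )
    values = pd.DataFrame(keep, index=log2.index)
    return TransformedMatrix(
        values=values,
        stim_condition=str(fr["condition"].iloc[0]) if len(fr) else "",
        reference_condition=str(fr["reference_condition"].iloc[0])
        if "reference_condition" in fr and len(fr)
        else "",
        ddof=ddof,
        dropped_analytes=dropped,
    )


def pairwise_complete_distances(X: pd.DataFrame, metric: str = "euclidean") -> np.ndarray:
    """Condensed distance matrix over rows using pairwise-complete entries.

    Euclidean distances are rescaled by the fraction of coordinates
    observed (``d^2 * p / p_obs``), so on complete data they equal ordinary
    Euclidean distances exactly.  Correlation distance is 1 - Pearson r
    over the shared observed entries.  A row sharing no observed entries
    with some other row is an error naming the row.
    """
    A = X.to_numpy(float)
    n, p = A.shape
    obs = np.isfinite(A)
    out = np.zeros(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            shared = obs[i] & obs[j]
            m = int(shared.sum())
            if m == 0:
                raise ValidationError(
                    f"rows {X.index[i]!r} and {X.index[j]!r} share no observed entries"
                )
            xi, xj = A[i, shared], A[j, shared]
            if metric == "euclidean":
                d2 = float(np.sum((xi - xj) ** 2)) * (p / m)
                out[k] = np.sqrt(d2)
            elif metric == "correlation":
                if m < 2 or np.std(xi) == 0 or np.std(xj) == 0:
                    out[k] = 1.0
                else:
                    out[k] = 1.0 - float(np.corrcoef(xi, xj)[0, 1])
            else:
                raise ValidationError(f"unknown metric {metric!r}")
            k += 1
    return out


_LINKAGE_FOR = {"euclidean": "ward", "correlation": "average"}


def hierarchical_bicluster(
    m: TransformedMatrix,
    distance: str = "euclidean",
    linkage: str | None = None,
) -> ClusterAssignment:
    """Cluster tumors (rows) and analytes (columns); cut tumors at k = 2.

    Default pairing is Euclidean/Ward; correlation defaults to average
    linkage.  Ties in the merge sequence are resolved deterministically by
    scipy's lowest-index-first convention.
    """
    X = m.values
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 tumors to cluster")
    if linkage is None:
        linkage = _LINKAGE_FOR.get(distance, "average")

    d_rows = pairwise_complete_distances(X, metric=distance)
    Z_rows = hierarchy.linkage(d_rows, method=linkage)
    d_cols = pairwise_complete_distances(X.T, metric=distance)
    Z_cols = hierarchy.linkage(d_cols, method=linkage)

    cut = hierarchy.fcluster(Z_rows, t=2, criterion="maxclust")
    informative = len(np.unique(cut)) == 2
    if not informative:
        warnings.warn(
            "tumor dendrogram does not split into two groups (degenerate input); "
            "clustering is uninformative",
            stacklevel=2,
        )
    labels = pd.Series(
        [f"G{c}" for c in cut], index=X.index, name="cluster"
    )
    return ClusterAssignment(
        labels=labels,
        row_linkage=Z_rows,
        col_linkage=Z_cols,
        row_order=[X.index[i] for i in hierarchy.leaves_list(Z_rows)],
        col_order=[X.columns[i] for i in hierarchy.leaves_list(Z_cols)],
        distance=distance,
        linkage=linkage,
        informative=informative,
    )


def label_responder_cluster(
    assignment: ClusterAssignment, m: TransformedMatrix
) -> ClusterAssignment:
    """Name the group with the higher grand-mean z R_clus, the other NR_clus."""
    groups = assignment.labels.unique()
    if len(groups) != 2:
        raise ValidationError("exactly two groups are required to assign R_clus/NR_clus")
    means = {
        g: float(np.nanmean(m.values.loc[assignment.labels == g].to_numpy(float)))
        for g in groups
    }
    g0, g1 = groups
    if means[g0] == means[g1]:
        raise ValidationError(
            "grand-mean z exactly tied between groups; assign R_clus manually"
        )
    r = g0 if means[g0] > means[g1] else g1
    mapping = {g: ("R_clus" if g == r else "NR_clus") for g in groups}
    assignment.labels = assignment.labels.map(mapping)
    assignment.margin = abs(means[g0] - means[g1])
    return assignment


@dataclass
class Concordance:
    confusion: pd.DataFrame           # rows: R_clus/NR_clus, cols: IRS_high/IRS_low
    sensitivity: float
    specificity: float


def concordance(cluster_labels: pd.Series, irs_labels: pd.Series) -> Concordance:
    """2x2 agreement of the IRS against the cluster classifier.

    R_clus is condition-positive and IRS_high test-positive, so
    sensitivity = P(IRS_high | R_clus), specificity = P(IRS_low | NR_clus).
    """
    if set(cluster_labels.index) != set(irs_labels.index):
        raise ValidationError("cluster and IRS labels cover different tumor sets")
    irs = irs_labels.reindex(cluster_labels.index)
    tab = pd.DataFrame(
        0,
        index=["R_clus", "NR_clus"],
        columns=["IRS_high", "IRS_low"],
    )
    for c, s in zip(cluster_labels, irs):
        tab.loc[c, s] += 1
    sens_den = tab.loc["R_clus"].sum()
    spec_den = tab.loc["NR_clus"].sum()
    sens = tab.loc["R_clus", "IRS_high"] / sens_den if sens_den else np.nan
    spec = tab.loc["NR_clus", "IRS_low"] / spec_den if spec_den else np.nan
    return Concordance(confusion=tab, sensitivity=float(sens), specificity=float(spec))
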