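"""Hierarchical statistics for technical repeats nested in biological isolations.

Wells from the same cell isolation are correlated (high intraclass
correlation), so treating them as independent inflates false positives
(pseudo-replication).  The hierarchical ANOVA here first averages technical
repeats within each isolation, then tests the condition effect across
isolation means — each biological isolation counts exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "ClusteredSample",
    "HierarchicalAnovaResult",
    "variance_components_icc",
    "hierarchical_anova",
    "adjust_bonferroni",
]


@dataclass(frozen=True)
class ClusteredSample:
    """Replicate values with their isolation (cluster) and condition labels."""

    values: np.ndarray
    cluster_id: np.ndarray
    condition: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        clusters = np.asarray(self.cluster_id).ravel()
        if values.size != clusters.size:
            raise ValueError("values and cluster_id must have equal length")
        condition = self.condition
        if condition is not None:
            condition = np.asarray(condition).ravel()
            if condition.size != values.size:
                raise ValueError("condition must have the same length as values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cluster_id", clusters)
        object.__setattr__(self, "condition", condition)


@dataclass(frozen=True)
class HierarchicalAnovaResult:
    F: float
    p: float
    df: tuple[float, float]
    sigma2_between: float
    sigma2_within: float
    icc: float
    n_conditions: int
    n_clusters: int
    n_values: int
    method: str = "cluster_means"


def variance_components_icc(
    sample: ClusteredSample,
) -> tuple[float, float, float]:
    """One-way random-effects variance components via expected mean squares.

    Returns ``(sigma2_between, sigma2_within, icc)`` with
    ``icc = sigma2_between / (sigma2_between + sigma2_within)``.  A negative
    between-cluster estimate (MS_between <= MS_within) is truncated at zero,
    so the ICC lies in [0, 1] always.
    """
    values, clusters = sample.values, sample.cluster_id
    unique = pd.unique(clusters)
    if unique.size < 2:
        raise InsufficientDataError("need >= 2 clusters for variance components")
    groups = [values[clusters == c] for c in unique]
    sizes = np.array([g.size for g in groups], dtype=float)
    if not np.any(sizes >= 2):
        raise InsufficientDataError("need >= 2 values in at least one cluster")
    n_total = sizes.sum()
    k = unique.size
    grand = values.mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    ms_between = ss_between / (k - 1)
    df_within = n_total - k
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    # average cluster size for unbalanced designs (expected-mean-squares n0)
    n0 = (n_total - np.sum(sizes**2) / n_total) / (k - 1)
    sigma2_within = ms_within
    sigma2_between = max((ms_between - ms_within) / n0, 0.0)
    denom = sigma2_between + sigma2_within
    icc = sigma2_between / denom if denom > 0 else 0.0
    return sigma2_between, sigma2_within, float(icc)


def hierarchical_anova(
    sample: ClusteredSample, method: str = "cluster_means"
) -> HierarchicalAnovaResult:
    """One-way ANOVA on isolation means (pseudo-replication-immune).

    Technical repeats are averaged within each (condition, cluster) cell,
    then a one-way ANOVA tests the condition effect across cluster means.
    Duplicating wells within a cluster therefore changes nothing.

    ``method="design_effect"`` instead runs the well-level ANOVA with the
    F statistic deflated by the Kish design effect ``1 + (m̄ - 1) * ICC``
    (m̄ = mean cluster size) and cluster-based denominator df — a variant
    exposed for comparison, not the default.

    Variance components / ICC are estimated on condition-centred values so
    a real condition effect does not masquerade as between-cluster variance.
    """
    if sample.condition is None:
        raise ValueError("sample.condition is required for hierarchical ANOVA")
    values, clusters, condition = sample.values, sample.cluster_id, sample.condition
    conds = pd.unique(condition)
    if conds.size < 2:
        raise InsufficientDataError("need >= 2 conditions")
    df = pd.DataFrame({"y": values, "cluster": clusters, "cond": condition})
    cell_means = df.groupby(["cond", "cluster"], sort=False)["y"].mean().reset_index()
    counts = cell_means.groupby("cond")["cluster"].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise InsufficientDataError(f"conditions with < 2 clusters: {bad}")
    centred = df["y"] - df.groupby("cond")["y"].transform("mean")
    s2b, s2w, icc = variance_components_icc(
        ClusteredSample(centred.to_numpy(), clusters)
    )
    if method == "cluster_means":
        groups = [g["y"].to_numpy() for _, g in cell_means.groupby("cond", sort=False)]
        k = len(groups)
        n_means = sum(g.size for g in groups)
        res = stats.f_oneway(*groups)
        F = float(res.statistic)
        p = float(res.pvalue)
        if not np.isfinite(F):  # all cluster means identical
            F, p = 0.0, 1.0
        dof = (k - 1.0, float(n_means - k))
    elif method == "design_effect":
        groups = [g["y"].to_numpy() for _, g in df.groupby("cond", sort=False)]
        res = stats.f_oneway(*groups)
        m_bar = len(df) / len(cell_means)
        deff = 1.0 + (m_bar - 1.0) * icc
        F = float(res.statistic) / deff
        k = len(groups)
        dof = (k - 1.0, float(len(cell_means) - k))
        p = float(stats.f.sf(F, *dof)) if np.isfinite(F) else 1.0
        if not np.isfinite(F):
            F, p = 0.0, 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return HierarchicalAnovaResult(
        F=F,
        p=p,
        df=dof,
        sigma2_between=s2b,
        sigma2_within=s2w,
        icc=icc,
        n_conditions=int(conds.size),
        n_clusters=int(pd.unique(clusters).size),
        n_values=int(values.size),
        method=method,
    )


def adjust_bonferroni(p_values) -> list[float]:
    """Bonferroni adjustment: ``p_adj = min(1, m * p)`` with m = family size."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return list(np.minimum(1.0, p * p.size))
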