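"""Two-color expression filtering: lowess normalization, replicate t-test,
fold-change selection, and hierarchical clustering.

Each array carries a sample channel (Cy5) and a common-reference channel
(Cy3).  Per spot, M = log2(sample/reference) and A = (1/2) log2(sample *
reference); per chip, M is corrected by subtracting a locally weighted
(lowess) regression of M on A, removing intensity-dependent dye bias.  A
gene passes the filter when, in at least one condition, the one-sample
t-test of its replicate corrected log-ratios against 0 has p < alpha and
its condition-mean fold change meets the threshold (2.5-fold by default,
in either direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "FilterResult",
    "ClusterResult",
    "normalize",
    "replicate_test",
    "condition_folds",
    "select_genes",
    "select_from_folds",
    "hierarchical_cluster",
]


@dataclass
class ExpressionMatrix:
    """Gene x array two-channel intensities with array annotations.

    ``sample`` and ``reference`` are gene-by-array frames with identical
    index/columns; ``samples`` is the sample sheet indexed by array id
    with columns ``condition`` and ``replicate``.
    """

    sample: pd.DataFrame
    reference: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.sample.index.equals(self.reference.index) or not self.sample.columns.equals(
            self.reference.columns
        ):
            raise ValueError("sample and reference frames must share index and columns")
        missing = set(self.sample.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"arrays missing from the sample sheet: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.sample.index

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.samples["condition"]))


@dataclass
class NormalizedMatrix:
    """Per-array M/A values and lowess-corrected log-ratios."""

    M: pd.DataFrame
    A: pd.DataFrame
    M_corrected: pd.DataFrame
    samples: pd.DataFrame
    excluded: pd.DataFrame  # boolean: spot had non-positive intensity

    @property
    def fold(self) -> pd.DataFrame:
        """Normalized fold change vs reference, per spot (2**M_corrected)."""
        return 2.0**self.M_corrected

    def arrays_for(self, condition: str) -> list[str]:
        sheet = self.samples
        return list(sheet.index[sheet["condition"] == condition])


@dataclass
class FilterResult:
    table: pd.DataFrame  # per gene: fold/p/qualifies per condition + selected
    criteria: dict

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


@dataclass
class ClusterResult:
    linkage: np.ndarray
    order: list  # gene labels in dendrogram leaf order
    labels: pd.Index


def normalize(matrix: ExpressionMatrix, span: float = 0.4) -> NormalizedMatrix:
    """Per-spot log-ratios with per-chip intensity-dependent correction.

    Spots with a non-positive intensity in either channel are flagged,
    excluded from the lowess fit, and given a missing ratio.  Requires at
    least 50 usable genes per array for the local regression to have
    support.
    """
    s = matrix.sample.to_numpy(dtype=float)
    r = matrix.reference.to_numpy(dtype=float)
    bad = ~((s > 0) & (r > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2(s / r)
        a = 0.5 * np.log2(s * r)
    m[bad] = np.nan
    a[bad] = np.nan
    corrected = np.full_like(m, np.nan)
    for j in range(m.shape[1]):
        ok = ~np.isnan(m[:, j])
        if ok.sum() < 50:
            raise ValueError(
                f"array {matrix.sample.columns[j]!r} has {int(ok.sum())} usable genes; "
                "need >= 50 for lowess"
            )
        aj, mj = a[ok, j], m[ok, j]
        if np.ptp(mj) == 0:  # constant ratios: lowess trend is that constant
            corrected[ok, j] = 0.0
            continue
        delta = 0.01 * (aj.max() - aj.min())
        trend = sm_lowess(mj, aj, frac=span, delta=delta, return_sorted=False)
        corrected[ok, j] = mj - trend
    idx, cols = matrix.sample.index, matrix.sample.columns
    return NormalizedMatrix(
        M=pd.DataFrame(m, index=idx, columns=cols),
        A=pd.DataFrame(a, index=idx, columns=cols),
        M_corrected=pd.DataFrame(corrected, index=idx, columns=cols),
        samples=matrix.samples,
        excluded=pd.DataFrame(bad, index=idx, columns=cols),
    )


def replicate_test(norm: NormalizedMatrix, condition: str) -> pd.Series:
    """Two-sided one-sample t-test of replicate log-ratios against zero.

    Genes with fewer than two non-missing replicates get a missing
    p-value.  A zero replicate variance with a non-zero mean is floored at
    machine epsilon (scaled by the mean magnitude) so identical non-null
    replicates yield a vanishing p rather than a 0/0.
    """
    arrays = norm.arrays_for(condition)
    if not arrays:
        raise ValueError(f"no arrays annotated with condition {condition!r}")
    vals = norm.M_corrected[arrays].to_numpy(dtype=float)
    n = np.sum(~np.isnan(vals), axis=1)
    mean = np.nanmean(np.where(np.isnan(vals), np.nan, vals), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(vals, axis=1, ddof=1)
    floor = np.finfo(float).eps * np.maximum(np.abs(mean), 1.0)
    sd = np.maximum(sd, floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=np.maximum(n - 1, 1))
    p = np.where((n >= 2) & np.isfinite(tstat), p, np.nan)
    # mean exactly 0 with zero spread: no evidence against the null
    p = np.where((n >= 2) & (mean == 0.0) & (np.nanstd(vals, axis=1) == 0.0), 1.0, p)
    return pd.Series(p, index=norm.M_corrected.index, name=condition)


def condition_folds(norm: NormalizedMatrix) -> pd.DataFrame:
    """Per-condition fold change vs reference: 2**(mean corrected M)."""
    cols = {}
    for cond in pd.unique(norm.samples["condition"]):
        arrays = norm.arrays_for(cond)
        cols[cond] = 2.0 ** norm.M_corrected[arrays].mean(axis=1, skipna=True)
    return pd.DataFrame(cols, index=norm.M_corrected.index)


def select_from_folds(
    folds: pd.DataFrame,
    p_values: pd.DataFrame,
    fold_threshold: float = 2.5,
    alpha: float = 0.05,
    direction: str = "both",
) -> FilterResult:
    """Apply the fold-change / p-value filter to precomputed tables.

    A gene is selected iff some condition has ``p < alpha`` and its fold
    meets the criterion — ``direction="both"``: fold >= threshold or
    <= 1/threshold; ``direction="up"``: fold >= threshold only.  Missing
    folds or p-values never qualify.
    """
    if fold_threshold <= 0 or alpha <= 0:
        raise ValueError("thresholds must be > 0")
    if direction not in ("both", "up"):
        raise ValueError("direction must be 'both' or 'up'")
    conditions = list(folds.columns)
    table = pd.DataFrame(index=folds.index)
    qualifies = pd.DataFrame(False, index=folds.index, columns=conditions)
    for cond in conditions:
        f = folds[cond]
        p = p_values[cond]
        meets_fold = f >= fold_threshold
        if direction == "both":
            meets_fold = meets_fold | (f <= 1.0 / fold_threshold)
        q = meets_fold & (p < alpha)
        qualifies[cond] = q.fillna(False)
        table[f"fold_{cond}"] = f
        table[f"p_{cond}"] = p
        table[f"qualifies_{cond}"] = qualifies[cond]
    table["selected"] = qualifies.any(axis=1)
    return FilterResult(
        table=table,
        criteria={"fold_threshold": fold_threshold, "alpha": alpha, "direction": direction},
    )


def select_genes(
    norm: NormalizedMatrix,
    fold_threshold: float = 2.5,
    alpha: float = 0.05,
    direction: str = "both",
) -> FilterResult:
    """Run the full filter on a normalized matrix (all conditions)."""
    folds = condition_folds(norm)
    pvals = pd.DataFrame(
        {cond: replicate_test(norm, cond) for cond in folds.columns}, index=folds.index
    )
    return select_from_folds(folds, pvals, fold_threshold, alpha, direction)


def hierarchical_cluster(profiles: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering on 1 - Pearson correlation distance.

    ``profiles`` holds condition-mean log-ratios (genes x conditions).
    Constant-profile genes have undefined correlation; they are assigned
    the maximum distance (2.0) to every other gene, with a warning.  Leaf
    order is made deterministic by optimal leaf ordering.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 gene profiles to cluster")
    x = profiles.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant-expression profile(s): correlation undefined, "
            "assigned maximum distance",
            stacklevel=2,
        )
    centered = x - x.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered**2).sum(axis=1))
    denom[constant] = 1.0
    unit = centered / denom[:, None]
    corr = unit @ unit.T
    dist = 1.0 - np.clip(corr, -1.0, 1.0)
    dist[constant, :] = 2.0
    dist[:, constant] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    z = hierarchy.optimal_leaf_ordering(z, squareform(dist, checks=False))
    order_idx = hierarchy.leaves_list(z)
    return ClusterResult(linkage=z, order=[profiles.index[i] for i in order_idx], labels=profiles.index)
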