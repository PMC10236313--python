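"""Condition-vs-control enrichment testing and inducible calling.

The window-level differential test is a deliberately simple stand-in for
a dedicated differential peak caller: per window, a one-sided exact
binomial test of the stimulated count out of the pooled count against the
expected proportion given the two library depths, with Benjamini-Hochberg
adjustment across windows and an FDR gate (default 0.1). Externally
produced differential peak files can be supplied instead, bypassing it.

Inducible genes are called from a quantile-normalized expression matrix
(log2-scale intensities) by an unpaired equal-variance t-test combined
with a log2 fold-change threshold (> 1 and p < 0.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import Interval, IntervalIndex
from .enhancers import EnhancerCall
from .signal import LibraryStats, Tags, count_tag_midpoints_in_windows


@dataclass
class WindowTestResult:
    window: Interval
    count_stim: int
    count_ctrl: int
    depth_stim: int
    depth_ctrl: int
    p_value: float
    q_value: float
    enriched: bool


@dataclass
class InducibleGeneCall:
    gene: str
    log2_fold_change: float
    p_value: float
    inducible: bool


def binomial_enrichment_pvalues(
    counts_stim: np.ndarray,
    counts_ctrl: np.ndarray,
    depth_stim: int,
    depth_ctrl: int,
) -> np.ndarray:
    """Vectorized one-sided exact binomial p-values.

    P(X >= k_stim) for X ~ Binomial(k_stim + k_ctrl, d_s / (d_s + d_c));
    windows with zero pooled count are untestable and get p = 1.
    """
    if depth_stim < 1 or depth_ctrl < 1:
        raise ValueError("library depths must be >= 1")
    k = np.asarray(counts_stim, dtype=np.int64)
    n = k + np.asarray(counts_ctrl, dtype=np.int64)
    p0 = depth_stim / (depth_stim + depth_ctrl)
    with np.errstate(divide="ignore"):
        pvals = sps.binom.sf(k - 1, n, p0)
    pvals = np.where(n == 0, 1.0, pvals)
    return np.minimum(pvals, 1.0)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (monotone, in [p, 1])."""
    if len(pvals) == 0:
        return np.asarray([], dtype=float)
    return multipletests(pvals, method="fdr_bh")[1]


def window_differential_test(
    windows: Sequence[Interval],
    tags_stim: Tags,
    tags_ctrl: Tags,
    depth_stim: LibraryStats,
    depth_ctrl: LibraryStats,
    fdr: float = 0.1,
) -> list[WindowTestResult]:
    """Test each window for stimulated-over-control enrichment.

    Tags are assigned to windows by midpoint. BH adjustment is computed
    across all tested windows; ``enriched`` means q < fdr.
    """
    k_stim = count_tag_midpoints_in_windows(tags_stim, windows)
    k_ctrl = count_tag_midpoints_in_windows(tags_ctrl, windows)
    pvals = binomial_enrichment_pvalues(
        k_stim, k_ctrl, depth_stim.total_mapped, depth_ctrl.total_mapped
    )
    qvals = benjamini_hochberg(pvals)
    return [
        WindowTestResult(
            window=w,
            count_stim=int(k_stim[i]),
            count_ctrl=int(k_ctrl[i]),
            depth_stim=depth_stim.total_mapped,
            depth_ctrl=depth_ctrl.total_mapped,
            p_value=float(pvals[i]),
            q_value=float(qvals[i]),
            enriched=bool(qvals[i] < fdr),
        )
        for i, w in enumerate(windows)
    ]


def call_inducible_enhancers(
    enhancers: Iterable[EnhancerCall],
    h4ac_results: Sequence[WindowTestResult] = (),
    h3k9ac_results: Sequence[WindowTestResult] = (),
) -> list[EnhancerCall]:
    """Flag enhancers intersecting an enriched H4ac or H3K9ac window.

    Returns the flagged subset; overlap with either mark suffices and an
    enhancer is counted once regardless of how many windows it touches.
    """
    enriched = IntervalIndex(
        r.window
        for r in list(h4ac_results) + list(h3k9ac_results)
        if r.enriched
    )
    flagged = []
    for enh in enhancers:
        if enriched.overlaps(enh.peak.interval):
            enh.inducible = True
            flagged.append(enh)
        else:
            enh.inducible = False
    return flagged


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one distribution.

    Each column's sorted values are replaced by the row-wise mean of all
    columns' sorted values; ties within a column receive the mean of the
    reference values at their tied ranks.
    """
    ranks = expr.rank(method="first").astype(int) - 1
    reference = np.sort(expr.values, axis=0).mean(axis=1)
    normalized = pd.DataFrame(
        reference[ranks.values], index=expr.index, columns=expr.columns
    )
    # average reference values over within-column ties
    avg_rank = expr.rank(method="average")
    for col in expr.columns:
        if expr[col].duplicated().any():
            mapping = normalized[col].groupby(avg_rank[col]).transform("mean")
            normalized[col] = mapping
    return normalized


def call_inducible_genes(
    expr: pd.DataFrame,
    group_labels: Sequence[Literal["stim", "unstim"]],
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    equal_var: bool = True,
    normalize: bool = True,
) -> list[InducibleGeneCall]:
    """Call stimulus-induced genes from a genes x samples log2 matrix.

    After quantile normalization, each gene gets the log2 fold change of
    group means (stim - unstim) and a two-sided unpaired t-test p-value
    (Student's equal-variance by default; Welch via ``equal_var=False``).
    Inducible means log2FC > ``lfc_threshold`` and p < ``alpha``.
    """
    labels = np.asarray(group_labels)
    if len(labels) != expr.shape[1]:
        raise ValueError("one group label per sample column is required")
    stim = labels == "stim"
    unstim = labels == "unstim"
    if stim.sum() < 2 or unstim.sum() < 2:
        raise ValueError("each group needs >= 2 samples (variance undefined)")
    mat = quantile_normalize(expr) if normalize else expr
    a = mat.values[:, stim]
    b = mat.values[:, unstim]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    import warnings

    with warnings.catch_warnings():
        # quantile normalization can leave a null gene with (near-)identical
        # values in both groups; the NaN guard below reports p = 1 for those
        warnings.simplefilter("ignore", RuntimeWarning)
        tres = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
    pvals = np.where(np.isnan(tres.pvalue), 1.0, tres.pvalue)
    return [
        InducibleGeneCall(
            gene=str(g),
            log2_fold_change=float(lfc[i]),
            p_value=float(pvals[i]),
            inducible=bool(lfc[i] > lfc_threshold and pvals[i] < alpha),
        )
        for i, g in enumerate(mat.index)
    ]


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene, header row samples)."""
    return pd.read_csv(path, sep="\t", index_col=0)
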