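"""Expression-matrix preprocessing and gene-set phenotype scores.

Preprocessing follows the classic clustering recipe for a bulk log2
expression matrix: drop transcripts with more than 20% missing values, keep
the top 5,000 most variable transcripts, median-centre per transcript, build
the Pearson sample-correlation matrix and hierarchically cluster it with
uncentred-correlation distance (the Cluster 3.0 metric) and average linkage.
Gene-set scores are per-sample means over set members; strata are the
rank-based top quartile and the combined 3-group TIL/MCC split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


def load_expression_tsv(path) -> pd.DataFrame:
    """Read a transcripts x samples TSV of log2 values ("NA" = missing)."""
    mat = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if mat.index.duplicated().any():
        raise ValueError("duplicate transcript ids")
    if mat.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    return mat


def filter_and_select_variable(
    matrix: pd.DataFrame, max_missing_frac: float = 0.20, top_n: int = 5000
) -> pd.DataFrame:
    """Drop transcripts with > ``max_missing_frac`` missing values, then keep
    the ``top_n`` most variable of the rest (missing values ignored in the
    variance; ties broken by input order)."""
    if matrix.empty:
        raise ValueError("empty expression matrix")
    missing = matrix.isna().mean(axis=1)
    kept = matrix.loc[missing <= max_missing_frac]
    if kept.empty:
        raise ValueError("all transcripts removed by the missingness filter")
    variances = kept.var(axis=1, skipna=True).fillna(0.0)
    if len(kept) <= top_n:
        if len(kept) < top_n:
            logger.warning(
                "only %d transcripts pass the filter (< top_n=%d); keeping all",
                len(kept), top_n,
            )
        return kept
    order = np.argsort(-variances.values, kind="stable")[:top_n]
    return kept.iloc[np.sort(order)]


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Centre each transcript row at zero median (over non-missing entries)."""
    return matrix.sub(matrix.median(axis=1, skipna=True), axis=0)


def uncentered_correlation_distance(rows: np.ndarray) -> np.ndarray:
    """Pairwise 1 - sum(x*y)/(||x||*||y||) over rows (NaNs pairwise-complete)."""
    n = rows.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(np.isnan(rows[i]) | np.isnan(rows[j]))
            x, y = rows[i, mask], rows[j, mask]
            denom = np.sqrt(np.sum(x**2)) * np.sqrt(np.sum(y**2))
            if denom == 0:
                raise ValueError(f"zero-norm row at index {i} or {j}")
            dist[i, j] = dist[j, i] = 1.0 - float(np.sum(x * y)) / denom
    return np.clip(dist, 0.0, None)


@dataclass
class ClusterResult:
    """Hierarchical clustering of the sample-correlation matrix."""

    linkage: np.ndarray
    labels: pd.Series  # cluster id per sample
    leaf_order: list[str]
    correlation: pd.DataFrame

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with branch lengths."""
        names = list(self.correlation.index)
        n = len(names)

        def node(i: int) -> tuple[str, float]:
            if i < n:
                return names[i], 0.0
            a, b, height, _ = self.linkage[i - n]
            sa, ha = node(int(a))
            sb, hb = node(int(b))
            return f"({sa}:{height - ha:.6g},{sb}:{height - hb:.6g})", height

        tree, _ = node(2 * n - 2)
        return tree + ";"


def sample_correlation_cluster(
    matrix: pd.DataFrame, k: int | None = None, cut_height: float | None = None
) -> ClusterResult:
    """Pearson-correlate all samples, then cluster the correlation matrix.

    The samples x samples Pearson matrix (pairwise-complete) is treated as
    the feature matrix; distances between its rows are uncentred correlation
    and merging uses average linkage.  ``k`` (number of clusters) or
    ``cut_height`` controls the flat labels; with neither, every sample gets
    cluster 1.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 transcripts")
    stds = matrix.std(axis=0, skipna=True)
    flat = stds[stds == 0]
    if len(flat):
        raise ValueError(
            f"zero-variance sample(s), correlation undefined: {list(flat.index)}"
        )
    corr = matrix.corr(method="pearson", min_periods=2)
    if corr.isna().any().any():
        raise ValueError("undefined correlations (insufficient overlap)")
    dist = uncentered_correlation_distance(corr.values)
    link = linkage(squareform(dist, checks=False), method="average")
    if k is not None:
        lab = fcluster(link, t=k, criterion="maxclust")
    elif cut_height is not None:
        lab = fcluster(link, t=cut_height, criterion="distance")
    else:
        lab = np.ones(corr.shape[0], dtype=int)
    labels = pd.Series(lab, index=corr.index, name="cluster")
    leaf_order = [corr.index[i] for i in leaves_list(link)]
    return ClusterResult(link, labels, leaf_order, corr)


@dataclass
class GeneSetScore:
    """Per-sample mean expression over the members of one gene set."""

    name: str
    scores: pd.Series
    n_genes_used: int
    missing_genes: list[str]


def geneset_score(matrix: pd.DataFrame, gene_list: list[str], name: str) -> GeneSetScore:
    """Average expression of a gene set per sample (missing entries excluded)."""
    present = [g for g in gene_list if g in matrix.index]
    absent = [g for g in gene_list if g not in matrix.index]
    if not present:
        raise ValueError(f"no genes of set {name!r} present in the matrix")
    if absent:
        logger.info("gene set %s: %d listed genes absent", name, len(absent))
    scores = matrix.loc[present].mean(axis=0, skipna=True)
    scores.name = name
    return GeneSetScore(name, scores, len(present), absent)


def quartile_group(scores: pd.Series) -> pd.Series:
    """Label the ceil(n/4) highest-scoring samples TOP_QUARTILE, rest REST.

    Boundary ties are broken by stable sample order with a warning.
    """
    n = len(scores)
    if n < 4:
        raise ValueError("need at least 4 samples for quartile grouping")
    k = int(np.ceil(n / 4))
    order = np.argsort(-scores.values, kind="stable")
    top = order[:k]
    boundary = scores.values[order[k - 1]]
    if k < n and scores.values[order[k]] == boundary:
        logger.warning("tied scores at the quartile boundary; stable order used")
    labels = pd.Series("REST", index=scores.index, name="group")
    labels.iloc[top] = "TOP_QUARTILE"
    return labels


TIL_MCC_LEVELS = ["high_TIL_low_MCC", "intermediate", "low_TIL_high_MCC"]


def til_mcc_groups(til_scores: pd.Series, mcc_scores: pd.Series) -> pd.Series:
    """Three-group split from the TIL and MCC top quartiles.

    Group 1 = TIL top quartile only (favourable), group 3 = MCC top quartile
    only (unfavourable), group 2 = everyone else, including samples in both
    or neither top quartile.
    """
    if not til_scores.index.equals(mcc_scores.index):
        raise ValueError("TIL and MCC scores cover different samples")
    til_top = quartile_group(til_scores) == "TOP_QUARTILE"
    mcc_top = quartile_group(mcc_scores) == "TOP_QUARTILE"
    labels = pd.Series("intermediate", index=til_scores.index, name="group")
    labels[til_top & ~mcc_top] = "high_TIL_low_MCC"
    labels[mcc_top & ~til_top] = "low_TIL_high_MCC"
    return pd.Series(
        pd.Categorical(labels, categories=TIL_MCC_LEVELS, ordered=True),
        index=labels.index, name="group",
    )
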