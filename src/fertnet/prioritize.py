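"""Gene prioritization: 3-way TF ranking, family enrichment, clustering.

Transcription factors in the co-association network are ranked by (i) number
of network connections, (ii) multi-trait pleiotropy χ² and (iii) sperm
expression abundance; a TF is selected when it ranks in the top-k (default
10) of at least one criterion, so the selected set can exceed k.  Family
enrichment in the AWM uses the exact hypergeometric upper tail.  Profiles of
selected genes are hierarchically clustered (1 − Pearson distance, average
linkage) over both genes and traits.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .awm import Network

logger = logging.getLogger(__name__)

__all__ = ["rank_and_select", "family_enrichment", "cluster_profiles",
           "ProfileClustering"]


def rank_and_select(
    net: Network,
    chi2: pd.Series,
    sperm_expr: pd.Series,
    tf_set,
    top_k: int = 10,
) -> pd.DataFrame:
    """Rank network TFs by connectivity, pleiotropy and sperm expression.

    Ranks are competition ranks (ties share the minimum rank), 1-based and
    descending in the criterion.  ``selected`` marks TFs with any rank
    ≤ ``top_k``; ``criteria`` lists which criteria fired.  Genes without an
    expression record are treated as abundance 0 (logged).
    """
    tf_set = set(tf_set)
    if not tf_set:
        warnings.warn("empty TF set: nothing to rank")
        cols = ["gene_id", "degree", "degree_rank", "chi2", "chi2_rank",
                "sperm_expr", "expr_rank", "selected", "criteria"]
        return pd.DataFrame(columns=cols)
    genes = [g for g in net.nodes if g in tf_set]
    degree = net.degree.reindex(genes).fillna(0).astype(int)
    chi2_v = chi2.reindex(genes)
    if chi2_v.isna().any():
        raise KeyError(
            f"pleiotropy statistic missing for: "
            f"{sorted(chi2_v.index[chi2_v.isna()])[:5]}")
    expr = sperm_expr.reindex(genes)
    n_missing = int(expr.isna().sum())
    if n_missing:
        logger.info("%d TF genes lack expression; abundance set to 0",
                    n_missing)
        expr = expr.fillna(0.0)

    out = pd.DataFrame({
        "gene_id": genes,
        "degree": degree.to_numpy(),
        "chi2": chi2_v.to_numpy(),
        "sperm_expr": expr.to_numpy(),
    })
    for col, rank_col in (("degree", "degree_rank"), ("chi2", "chi2_rank"),
                          ("sperm_expr", "expr_rank")):
        out[rank_col] = out[col].rank(ascending=False,
                                      method="min").astype(int)
    crit = {
        "connectivity": out["degree_rank"] <= top_k,
        "pleiotropy": out["chi2_rank"] <= top_k,
        "expression": out["expr_rank"] <= top_k,
    }
    out["selected"] = crit["connectivity"] | crit["pleiotropy"] \
        | crit["expression"]
    out["criteria"] = [
        ",".join(name for name, mask in crit.items() if mask.iloc[i])
        for i in range(len(out))]
    return out


def family_enrichment(awm_genes, family_genes, genome_size: int) -> float:
    """Exact hypergeometric upper tail P(X ≥ k) of family capture by the AWM.

    Population N = ``genome_size`` genes of which K belong to the family;
    the AWM draws n genes and captures k of the family.  Computed by exact
    integer summation.
    """
    awm_genes = set(awm_genes)
    family_genes = set(family_genes)
    n_total = int(genome_size)
    k_family = len(family_genes)
    n_draw = len(awm_genes)
    k_obs = len(awm_genes & family_genes)
    if k_family > n_total or n_draw > n_total:
        raise ValueError("family and AWM must be subsets of the genome")
    if k_obs > min(k_family, n_draw):
        raise ValueError("observed overlap exceeds min(|family|, |awm|)")
    if k_obs == 0:
        return 1.0
    total = math.comb(n_total, n_draw)
    acc = 0
    for i in range(k_obs, min(k_family, n_draw) + 1):
        acc += math.comb(k_family, i) * math.comb(n_total - k_family,
                                                  n_draw - i)
    return float(Fraction(acc, total))


@dataclass
class ProfileClustering:
    """Dendrogram leaf orders and 2-cluster cuts for genes and traits."""

    row_order: list[str]
    col_order: list[str]
    row_clusters: pd.Series
    col_clusters: pd.Series
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def _cluster_axis(mat: np.ndarray, labels: list[str]):
    """Average-linkage clustering with 1 − Pearson distance on rows of mat.

    Constant rows have undefined correlation; each is placed in its own
    cluster (warned) and appended after the clustered items.
    """
    sd = mat.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant profiles placed in own cluster")
    active = np.flatnonzero(~const)
    if active.size < 2:
        order = list(labels)
        clusters = pd.Series(np.arange(1, len(labels) + 1), index=labels)
        return order, clusters, None
    sub = mat[active]
    dist = 1.0 - np.corrcoef(sub)
    dist = np.clip(0.5 * (dist + dist.T), 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method="average")
    leaf_idx = leaves_list(link)
    cut = fcluster(link, t=2, criterion="maxclust")
    order = [labels[active[i]] for i in leaf_idx]
    clusters = pd.Series(0, index=labels, dtype=int)
    for pos, i in enumerate(active):
        clusters.loc[labels[i]] = int(cut[pos])
    next_label = int(cut.max()) + 1 if cut.size else 1
    for i in np.flatnonzero(const):
        order.append(labels[i])
        clusters.loc[labels[i]] = next_label
        next_label += 1
    return order, clusters, link


def cluster_profiles(profiles: pd.DataFrame) -> ProfileClustering:
    """Hierarchically cluster co-association profiles on both axes.

    ``profiles`` is a gene × trait matrix (e.g. the AWM rows of the selected
    TFs).  Distance is 1 − Pearson correlation, linkage is average, and each
    axis gets a 2-cluster cut (the tallest merge), echoing the two major
    trait groups of the source analysis.  The partition is invariant to the
    input row order.
    """
    if profiles.shape[0] < 2 or profiles.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 traits")
    # canonical order so the result does not depend on input arrangement
    prof = profiles.sort_index(axis=0)
    mat = prof.to_numpy(dtype=float)
    row_order, row_clusters, row_link = _cluster_axis(
        mat, list(prof.index))
    col_order, col_clusters, col_link = _cluster_axis(
        mat.T, list(prof.columns))
    return ProfileClustering(
        row_order=row_order, col_order=col_order,
        row_clusters=row_clusters, col_clusters=col_clusters,
        row_linkage=row_link, col_linkage=col_link)
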