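"""Association Weight Matrix construction and PCIT network inference.

SNPs are anchored to every annotated gene whose body (±10 kb window) covers
their position.  Each gene is represented by one SNP — the one with the
smallest key-trait p-value, ties broken by larger association count then
smaller position — and enters the AWM if either (i) its representative is
associated with the key trait (p < α), or (ii) it is pleiotropic: associated
with strictly more traits than N_key, the average association count of the
key-trait genes.

The PCIT algorithm then prunes the gene × gene co-association (Pearson
correlation of AWM rows across the trait columns): for every trio (x, y, z)
the three first-order partial correlations are computed, the local tolerance
is the average ratio of partial to direct correlation, and the edge (x, y)
is discarded when, for some z, |r_xy| is below the tolerance times both
|r_xz| and |r_yz|.  Surviving nonzero correlations become signed edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "map_snp_to_genes",
    "AWM",
    "build_awm",
    "Network",
    "pcit",
    "export_network",
    "import_network",
]

GENE_WINDOW_BP = 10_000


class AWMError(RuntimeError):
    """AWM construction failed (e.g. no gene passes the key-trait rule)."""


def map_snp_to_genes(
    snp_map: pd.DataFrame,
    gene_map: pd.DataFrame,
    window: int = GENE_WINDOW_BP,
) -> pd.DataFrame:
    """Assign each SNP to every gene within ``window`` bp of its body.

    A SNP at position bp is assigned to gene [start, end] when
    bp ∈ [start − window, end + window]; SNPs in several genes keep all
    assignments.  Returns a (snp_id, gene_id) DataFrame.
    """
    rows = []
    for chrom, genes in gene_map.groupby("chrom", sort=False):
        snps = snp_map[snp_map["chrom"] == chrom]
        if snps.empty:
            continue
        bp = snps["bp"].to_numpy()
        ids = snps["snp_id"].to_numpy(dtype=object)
        order = np.argsort(bp)
        bp_sorted, ids_sorted = bp[order], ids[order]
        for gene_id, start, end in zip(genes["gene_id"], genes["start"],
                                       genes["end"]):
            lo = np.searchsorted(bp_sorted, start - window, side="left")
            hi = np.searchsorted(bp_sorted, end + window, side="right")
            for j in range(lo, hi):
                rows.append((ids_sorted[j], gene_id))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id"])


@dataclass
class AWM:
    """Gene × trait co-association matrix.

    ``table`` has one row per selected gene with its representative SNP,
    position, the z-score per trait, the key-trait p-value, the association
    count and the strongest-trait label.  ``n_key`` is the (real-valued)
    average association count among the key-trait genes.
    """

    table: pd.DataFrame
    traits: list[str]
    key_trait: str
    alpha: float
    n_key: float

    @property
    def values(self) -> pd.DataFrame:
        return self.table.set_index("gene_id")[self.traits]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table["gene_id"].to_numpy(dtype=object)


def build_awm(
    effects,
    assignments: pd.DataFrame,
    snp_map: pd.DataFrame,
    key_trait: str = "PNS",
    alpha: float = 0.01,
) -> AWM:
    """Select SNP-genes into the AWM by key-trait association or pleiotropy.

    ``effects`` is a :class:`~fertnet.snp_effects.SNPEffectMatrix`;
    ``assignments`` the SNP→gene table from :func:`map_snp_to_genes`.
    """
    traits = effects.traits
    if key_trait not in traits:
        raise ValueError(f"key trait {key_trait!r} not among {traits}")
    cand = assignments.merge(
        snp_map[["snp_id", "chrom", "bp"]], on="snp_id", how="left")
    cand = cand[cand["snp_id"].isin(effects.z.index)]
    if cand.empty:
        raise AWMError("no SNP is assigned to any gene")
    cand = cand.assign(
        p_key=effects.p[key_trait].reindex(cand["snp_id"]).to_numpy(),
        n_assoc=effects.n_assoc.reindex(cand["snp_id"]).to_numpy(),
    )
    # one representative SNP per gene: smallest key-trait p, then larger
    # association count, then smaller position
    cand = cand.sort_values(
        ["gene_id", "p_key", "n_assoc", "bp"],
        ascending=[True, True, False, True], kind="mergesort")
    reps = cand.drop_duplicates("gene_id", keep="first").reset_index(drop=True)

    key_genes = reps[reps["p_key"] < alpha]
    if key_genes.empty:
        raise AWMError("key trait yields empty AWM (no gene with "
                       f"p_{key_trait} < {alpha})")
    n_key = float(key_genes["n_assoc"].mean())
    pleio = reps[(reps["p_key"] >= alpha) & (reps["n_assoc"] > n_key)]
    selected = pd.concat([key_genes, pleio]).sort_index()

    z_rows = effects.z.reindex(selected["snp_id"])
    strongest = z_rows.abs().idxmax(axis=1).to_numpy()
    table = selected[["gene_id", "snp_id", "chrom", "bp", "p_key",
                      "n_assoc"]].reset_index(drop=True)
    for tr in traits:
        table[tr] = z_rows[tr].to_numpy()
    table["strongest_trait"] = strongest
    logger.info("AWM: %d key-trait genes, %d pleiotropic (N_%s = %.3f), "
                "%d total", len(key_genes), len(pleio), key_trait, n_key,
                len(table))
    return AWM(table=table, traits=list(traits), key_trait=key_trait,
               alpha=alpha, n_key=n_key)


@dataclass
class Network:
    """Undirected signed co-association network.

    ``edges`` has columns gene_a, gene_b, correlation, sign with each
    unordered pair at most once; ``degree`` covers every node (zero for
    isolated nodes).
    """

    nodes: list[str]
    edges: pd.DataFrame

    @property
    def degree(self) -> pd.Series:
        counts = pd.Series(0, index=pd.Index(self.nodes, name="gene_id"),
                           dtype=int)
        if len(self.edges):
            for col in ("gene_a", "gene_b"):
                vc = self.edges[col].value_counts()
                counts = counts.add(vc, fill_value=0)
        counts.index.name = "gene_id"
        return counts.astype(int)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


_DEGENERATE = 1.0 - 1e-12


def pcit(awm: AWM | pd.DataFrame) -> Network:
    """PCIT pruning of the gene co-association matrix.

    Correlations are computed across AWM rows over the trait columns.  With
    fewer than 3 genes no trio exists and every nonzero correlation is kept.
    Pairs with |r| = 1 are treated as significant and their trios skipped.
    """
    values = awm.values if isinstance(awm, AWM) else awm
    genes = list(values.index)
    x = values.to_numpy(dtype=float)
    if np.any(x.std(axis=1) == 0):
        bad = [g for g, s in zip(genes, x.std(axis=1)) if s == 0]
        raise ValueError(f"zero-variance AWM rows: {bad}")
    g = len(genes)
    r = np.corrcoef(x) if g > 1 else np.ones((1, 1))
    r = np.clip(r, -1.0, 1.0)
    keep = np.ones((g, g), dtype=bool)
    if g >= 3:
        degen = np.abs(r) >= _DEGENERATE
        np.fill_diagonal(degen, False)
        if degen.any():
            logger.warning("%d degenerate |r|=1 pairs kept; their trios "
                           "skipped", int(degen.sum() // 2))
        kill = np.zeros((g, g), dtype=bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            for zi in range(g):
                a = r[:, zi]
                rxy = r
                axa = a[:, None]
                aya = a[None, :]
                sa = np.sqrt(1.0 - axa**2)
                sb = np.sqrt(1.0 - aya**2)
                sxy = np.sqrt(1.0 - rxy**2)
                p_xy = (rxy - axa * aya) / (sa * sb)
                p_xz = (axa - rxy * aya) / (sxy * sb)
                p_yz = (aya - rxy * axa) / (sxy * sa)
                eps = (p_xy / rxy + p_xz / axa + p_yz / aya) / 3.0
                cand = (np.abs(rxy) < np.abs(eps * axa)) \
                    & (np.abs(rxy) < np.abs(eps * aya))
                cand &= np.isfinite(eps)
                # exclude self-pairs, the conditioning node, degenerate trios
                cand[zi, :] = False
                cand[:, zi] = False
                np.fill_diagonal(cand, False)
                trio_degen = (np.abs(rxy) >= _DEGENERATE) \
                    | (np.abs(axa) >= _DEGENERATE) \
                    | (np.abs(aya) >= _DEGENERATE)
                cand &= ~trio_degen
                kill |= cand
        keep = ~(kill | kill.T)
    rows = []
    for i in range(g):
        for j in range(i + 1, g):
            if keep[i, j] and r[i, j] != 0.0:
                rows.append((genes[i], genes[j], float(r[i, j]),
                             "pos" if r[i, j] > 0 else "neg"))
    edges = pd.DataFrame(rows,
                         columns=["gene_a", "gene_b", "correlation", "sign"])
    return Network(nodes=genes, edges=edges)


def export_network(net: Network, outdir, prefix: str = "network") -> dict:
    """Write the edge list (TSV), SIF lines and a node table with degree.

    Returns the mapping of artefact name to path.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / f"{prefix}_edges.tsv",
        "sif": out / f"{prefix}.sif",
        "nodes": out / f"{prefix}_nodes.tsv",
    }
    net.edges[["gene_a", "gene_b", "correlation"]].to_csv(
        paths["edges"], sep="\t", index=False, float_format="%.6g")
    with open(paths["sif"], "w") as fh:
        for row in net.edges.itertuples(index=False):
            fh.write(f"{row.gene_a}\t{row.sign}\t{row.gene_b}\n")
    nodes = net.degree.rename("degree").reset_index()
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    return paths


def import_network(edges_path, nodes_path=None) -> Network:
    """Re-read an exported edge list (and optional node table)."""
    edges = pd.read_csv(edges_path, sep="\t")
    edges["sign"] = np.where(edges["correlation"] > 0, "pos", "neg")
    if nodes_path is not None:
        nodes = pd.read_csv(nodes_path, sep="\t")["gene_id"].astype(str).tolist()
    else:
        nodes = sorted(set(edges["gene_a"]).union(edges["gene_b"]))
    return Network(nodes=list(nodes), edges=edges)
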