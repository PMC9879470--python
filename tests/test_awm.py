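"""SNP→gene anchoring, AWM selection rules, PCIT network inference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fertnet.awm import (AWMError, Network, build_awm, export_network,
                         import_network, map_snp_to_genes, pcit)
from fertnet.snp_effects import SNPEffectMatrix, standardize_and_test


# ---------------------------------------------------------------------------
# SNP -> gene anchoring

def _maps(snps, genes):
    snp_map = pd.DataFrame(snps, columns=["snp_id", "chrom", "bp"])
    gene_map = pd.DataFrame(genes, columns=["gene_id", "chrom", "start",
                                            "end"])
    return snp_map, gene_map


def test_window_arithmetic():
    snp_map, gene_map = _maps(
        [("s1", "1", 5000), ("s2", "1", 1), ("s3", "1", 11000)],
        [("gA", "1", 10001, 12000), ("gB", "1", 20002, 30000)])
    out = map_snp_to_genes(snp_map, gene_map, window=10000)
    pairs = set(map(tuple, out.to_numpy()))
    assert ("s1", "gA") in pairs      # distance 5001 <= 10000
    assert ("s2", "gA") in pairs      # distance exactly 10000: inclusive
    assert ("s2", "gB") not in pairs  # distance 20001 > 10000
    assert ("s3", "gA") in pairs      # inside the gene body
    assert ("s1", "gB") not in pairs  # distance 15002 > 10000


def test_snp_inside_gene_and_multi_gene_assignment():
    snp_map, gene_map = _maps(
        [("s1", "2", 1500)],
        [("g1", "2", 1000, 2000), ("g2", "2", 1400, 1600)])
    out = map_snp_to_genes(snp_map, gene_map, window=0)
    assert set(out["gene_id"]) == {"g1", "g2"}


def test_empty_intersection_is_valid():
    snp_map, gene_map = _maps([("s1", "1", 100)], [("g1", "2", 50, 80)])
    out = map_snp_to_genes(snp_map, gene_map)
    assert len(out) == 0


# ---------------------------------------------------------------------------
# AWM selection

def _effects_from_pz(p_key, z=None, n_traits=4, alpha=0.01):
    """Build a SNPEffectMatrix with prescribed key-trait p and n_assoc."""
    n = len(p_key)
    traits = [f"T{i}" for i in range(n_traits - 1)] + ["PNS"]
    rng = np.random.default_rng(0)
    zmat = pd.DataFrame(rng.normal(size=(n, n_traits)) * 0.01,
                        index=[f"s{i}" for i in range(n)], columns=traits)
    pmat = pd.DataFrame(0.5, index=zmat.index, columns=traits)
    pmat["PNS"] = p_key
    if z is not None:
        for snp, cols in z.items():
            for c, val in cols.items():
                pmat.loc[snp, c] = val
    n_assoc = (pmat < alpha).sum(axis=1)
    return SNPEffectMatrix(s_hat=zmat, z=zmat, p=pmat, n_assoc=n_assoc,
                           alpha=alpha)


def test_four_gene_toy_pins_selection_and_strict_inequality():
    # p_PNS = {.005, .5, .5, .002}; n_assoc = {2, 3, 1, 4}
    p_key = [0.005, 0.5, 0.5, 0.002]
    extra = {  # drive n_assoc to 2,3,1,4 (PNS counts toward n_assoc)
        "s0": {"T0": 0.001},
        "s1": {"T0": 0.001, "T1": 0.001, "T2": 0.001},
        "s2": {"T0": 0.001},
        "s3": {"T0": 0.001, "T1": 0.001, "T2": 0.001},
    }
    eff = _effects_from_pz(p_key, z=extra)
    assert list(eff.n_assoc) == [2, 3, 1, 4]
    snp_map = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(4)],
        "chrom": ["1"] * 4,
        "bp": [1000, 2000, 3000, 4000],
    })
    assignments = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(4)],
        "gene_id": [f"g{i + 1}" for i in range(4)],
    })
    awm = build_awm(eff, assignments, snp_map, key_trait="PNS", alpha=0.01)
    # step 2: genes 1 and 4 (p < .01); N_PNS = mean(2, 4) = 3
    assert awm.n_key == 3.0
    # step 4: gene 2 has n_assoc = 3, NOT > 3 -> excluded
    assert set(awm.gene_ids) == {"g1", "g4"}


def test_pleiotropic_gene_admitted_when_above_threshold():
    p_key = [0.005, 0.5, 0.5]
    extra = {"s1": {"T0": 0.001, "T1": 0.001, "T2": 0.001}}  # n_assoc 3 > 1
    eff = _effects_from_pz(p_key, z=extra)
    snp_map = pd.DataFrame({"snp_id": ["s0", "s1", "s2"], "chrom": ["1"] * 3,
                            "bp": [1, 2, 3]})
    assignments = pd.DataFrame({"snp_id": ["s0", "s1", "s2"],
                                "gene_id": ["g1", "g2", "g3"]})
    awm = build_awm(eff, assignments, snp_map)
    assert set(awm.gene_ids) == {"g1", "g2"}


def test_representative_snp_tie_breaking():
    # two SNPs in one gene: same p_key, distinct n_assoc -> larger wins
    p_key = [0.005, 0.005]
    extra = {"s1": {"T0": 0.001}}
    eff = _effects_from_pz(p_key, z=extra)
    snp_map = pd.DataFrame({"snp_id": ["s0", "s1"], "chrom": ["1", "1"],
                            "bp": [100, 200]})
    assignments = pd.DataFrame({"snp_id": ["s0", "s1"],
                                "gene_id": ["g1", "g1"]})
    awm = build_awm(eff, assignments, snp_map)
    assert awm.table.iloc[0]["snp_id"] == "s1"


def test_all_null_effects_raise_documented_error():
    rng = np.random.default_rng(1)
    raw = pd.DataFrame(rng.normal(scale=1.0, size=(50, 3)) * 1e-6 +
                       rng.normal(size=(50, 3)),
                       index=[f"s{i}" for i in range(50)],
                       columns=["T0", "T1", "PNS"])
    eff = standardize_and_test(raw, alpha=1e-12)  # nothing passes
    snp_map = pd.DataFrame({"snp_id": raw.index, "chrom": "1",
                            "bp": np.arange(50) + 1})
    assignments = pd.DataFrame({"snp_id": raw.index,
                                "gene_id": [f"g{i}" for i in range(50)]})
    with pytest.raises(AWMError, match="empty AWM"):
        build_awm(eff, assignments, snp_map, alpha=1e-12)


# ---------------------------------------------------------------------------
# PCIT

def pcit_brute_force(values: pd.DataFrame) -> set[tuple[str, str]]:
    """Independent exhaustive-trio implementation of the PCIT rule."""
    genes = list(values.index)
    x = values.to_numpy(float)
    g = len(genes)
    r = np.clip(np.corrcoef(x), -1.0, 1.0)

    def partial(rxy, rxz, ryz):
        return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))

    kill = np.zeros((g, g), dtype=bool)
    for a, b, c in itertools.combinations(range(g), 3):
        if max(abs(r[a, b]), abs(r[a, c]), abs(r[b, c])) >= 1 - 1e-12:
            continue
        p_ab = partial(r[a, b], r[a, c], r[b, c])
        p_ac = partial(r[a, c], r[a, b], r[b, c])
        p_bc = partial(r[b, c], r[a, b], r[a, c])
        eps = (p_ab / r[a, b] + p_ac / r[a, c] + p_bc / r[b, c]) / 3.0
        if not np.isfinite(eps):
            continue
        if abs(r[a, b]) < abs(eps * r[a, c]) and \
           abs(r[a, b]) < abs(eps * r[b, c]):
            kill[a, b] = kill[b, a] = True
        if abs(r[a, c]) < abs(eps * r[a, b]) and \
           abs(r[a, c]) < abs(eps * r[b, c]):
            kill[a, c] = kill[c, a] = True
        if abs(r[b, c]) < abs(eps * r[a, b]) and \
           abs(r[b, c]) < abs(eps * r[a, c]):
            kill[b, c] = kill[c, b] = True
    return {tuple(sorted((genes[i], genes[j])))
            for i in range(g) for j in range(i + 1, g)
            if not kill[i, j] and r[i, j] != 0.0}


def _edge_set(net: Network) -> set[tuple[str, str]]:
    return {tuple(sorted(p))
            for p in net.edges[["gene_a", "gene_b"]].to_numpy()}


def test_exchangeable_trio_keeps_all_edges():
    # three rows with pairwise correlation rho > 0: no edge dominated
    rng = np.random.default_rng(0)
    base = rng.normal(size=12)
    rows = np.vstack([base + rng.normal(scale=0.8, size=12)
                      for _ in range(3)])
    vals = pd.DataFrame(rows, index=["x", "y", "z"])
    net = pcit(vals)
    assert net.n_edges == 3


def test_chain_structure_removes_indirect_edge():
    # x and y related only through z (r_xy ~ r_xz r_zy).  For a 3-node chain
    # with r_xz = r_yz = rho the indirect edge is discarded whenever
    # rho * sqrt(1 + rho^2) < 2/3, i.e. rho below ~0.61; use rho = 0.5
    rng = np.random.default_rng(4)
    n = 4000
    z = rng.normal(size=n)
    x = 0.5 * z + rng.normal(scale=np.sqrt(0.75), size=n)
    y = 0.5 * z + rng.normal(scale=np.sqrt(0.75), size=n)
    vals = pd.DataFrame(np.vstack([x, y, z]), index=["x", "y", "z"])
    net = pcit(vals)
    edges = _edge_set(net)
    assert ("x", "z") in edges and ("y", "z") in edges
    assert ("x", "y") not in edges
    # the same case agrees with the exhaustive-trio oracle
    assert edges == pcit_brute_force(vals)


def test_oracle_equivalence_on_random_awms():
    rng = np.random.default_rng(12)
    for _ in range(50):
        vals = pd.DataFrame(rng.standard_normal((20, 10)),
                            index=[f"g{i:02d}" for i in range(20)])
        assert _edge_set(pcit(vals)) == pcit_brute_force(vals)


def test_permutation_invariance_of_edge_set():
    rng = np.random.default_rng(3)
    vals = pd.DataFrame(rng.standard_normal((15, 10)),
                        index=[f"g{i:02d}" for i in range(15)])
    net = pcit(vals)
    shuffled = vals.sample(frac=1.0, random_state=1)
    net2 = pcit(shuffled)
    assert _edge_set(net) == _edge_set(net2)


def test_degenerate_pair_kept_and_small_inputs():
    rng = np.random.default_rng(5)
    base = rng.normal(size=10)
    vals = pd.DataFrame(np.vstack([base, 2 * base, rng.normal(size=10),
                                   rng.normal(size=10)]),
                        index=["a", "b", "c", "d"])
    net = pcit(vals)  # a,b perfectly correlated
    assert ("a", "b") in _edge_set(net)
    # fewer than 3 rows: every nonzero correlation kept
    two = pcit(vals.iloc[:2])
    assert two.n_edges == 1
    with pytest.raises(ValueError, match="zero-variance"):
        pcit(pd.DataFrame(np.zeros((3, 5)), index=["a", "b", "c"]))


# ---------------------------------------------------------------------------
# export / import

def test_network_export_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    vals = pd.DataFrame(rng.standard_normal((8, 10)),
                        index=[f"g{i}" for i in range(8)])
    net = pcit(vals)
    paths = export_network(net, tmp_path)
    back = import_network(paths["edges"], paths["nodes"])
    assert back.degree.sort_index().equals(net.degree.sort_index())
    sif = paths["sif"].read_text().strip().splitlines()
    assert len(sif) == net.n_edges
    for line, row in zip(sif, net.edges.itertuples(index=False)):
        assert line.split("\t")[1] == ("pos" if row.correlation > 0
                                       else "neg")


def test_empty_network_export(tmp_path):
    net = Network(nodes=["a", "b"], edges=pd.DataFrame(
        columns=["gene_a", "gene_b", "correlation", "sign"]))
    paths = export_network(net, tmp_path)
    assert paths["sif"].read_text() == ""
    edges = pd.read_csv(paths["edges"], sep="\t")
    assert len(edges) == 0
    nodes = pd.read_csv(paths["nodes"], sep="\t")
    assert list(nodes["degree"]) == [0, 0]
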