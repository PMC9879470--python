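"""Backsolved SNP effects, the association weight matrix, and the PCIT
co-association network.

Per-SNP effects are recovered from the whole-data GEBVs (s = lam M' G^-1 u,
lam = 0.85), z-scored per trait and tested; the multi-trait pleiotropy chi2
flags SNPs affecting several traits.  SNPs are anchored to genes within
10 kb, one representative SNP per gene, and genes enter the AWM when
associated with the key trait (percent normal sperm) or pleiotropic beyond
the average association count of the key-trait genes.  PCIT then prunes the
gene x gene co-association matrix to the significant edges.
"""

import warnings

import pandas as pd

import fertnet as fn
from fertnet.awm import build_awm, export_network, map_snp_to_genes, pcit
from fertnet.simulate import read_dataset
from fertnet.snp_effects import (backsolve_snp_effects, pleiotropy_chi2,
                                 standardize_and_test)

warnings.simplefilter("ignore")

ds = read_dataset("results/data")
grm = fn.compute_grm(ds.genotypes)
gebv_w = pd.read_csv("results/gebv_whole.tsv", sep="\t",
                     index_col="animal_id")

raw = backsolve_snp_effects(ds.genotypes, grm, gebv_w, lam=0.85)
effects = pleiotropy_chi2(standardize_and_test(raw, alpha=0.01))
table = effects.z.copy()
table["n_assoc"] = effects.n_assoc
table["chi2"] = effects.chi2
table["chi2_p"] = effects.chi2_p
table.to_csv("results/snp_effects.tsv", sep="\t", float_format="%.6g")
print(f"backsolved {len(table)} SNP effects over {len(effects.traits)} traits")
print(f"  SNPs with pleiotropy p < 0.01: {(effects.chi2_p < 0.01).sum()}")

assignments = map_snp_to_genes(ds.genotypes.snp_map, ds.gene_map,
                               window=10000)
print(f"  SNP-gene assignments within 10 kb: {len(assignments)} "
      f"({assignments['gene_id'].nunique()} genes hit)")

awm = build_awm(effects, assignments, ds.genotypes.snp_map,
                key_trait="PNS", alpha=0.01)
awm.table.to_csv("results/awm.tsv", sep="\t", index=False,
                 float_format="%.6g")
n_key = (awm.table["p_key"] < awm.alpha).sum()
print(f"AWM: {len(awm.table)} SNP-genes "
      f"({n_key} key-trait, {len(awm.table) - n_key} pleiotropic; "
      f"N_PNS = {awm.n_key:.2f})")

net = pcit(awm)
export_network(net, "results", prefix="network")
deg = net.degree
print(f"PCIT network: {len(net.nodes)} genes, {net.n_edges} significant "
      f"edges")
if len(deg):
    top = deg.sort_values(ascending=False).head(3)
    print("  highest-degree genes: "
          + ", ".join(f"{g} ({d})" for g, d in top.items()))
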