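"""3-way prioritization of transcription factors and family enrichment.

Transcription factors in the co-association network are ranked by network
connectivity, pleiotropy chi2 and sperm-expression abundance; any TF in the
top 10 of at least one criterion is selected (the union can exceed 10).
The labelled gene family is tested for enrichment among AWM genes with the
exact hypergeometric upper tail, and the selected genes' co-association
profiles are hierarchically clustered on both axes.
"""

import json
import warnings

import pandas as pd

import fertnet as fn
from fertnet.awm import AWM, import_network
from fertnet.prioritize import (cluster_profiles, family_enrichment,
                                rank_and_select)
from fertnet.simulate import read_dataset

warnings.simplefilter("ignore")

ds = read_dataset("results/data")
awm_table = pd.read_csv("results/awm.tsv", sep="\t")
traits = list(ds.config.traits)
net = import_network("results/network_edges.tsv", "results/network_nodes.tsv")
effects = pd.read_csv("results/snp_effects.tsv", sep="\t",
                      index_col="snp_id")

tf_set = set(ds.gene_map.loc[ds.gene_map["tf_flag"].astype(bool), "gene_id"])
chi2_gene = pd.Series(
    effects["chi2"].reindex(awm_table["snp_id"]).to_numpy(),
    index=awm_table["gene_id"])
expr = ds.sperm_expr.set_index("gene_id")["abundance"]

ranks = rank_and_select(net, chi2_gene, expr, tf_set, top_k=10)
ranks.to_csv("results/tf_ranks.tsv", sep="\t", index=False,
             float_format="%.6g")
sel = ranks[ranks["selected"]]
print(f"{len(ranks)} TFs in the network; {len(sel)} selected "
      "(top 10 in at least one criterion):")
for _, row in sel.iterrows():
    print(f"  {row['gene_id']}: degree {row['degree']} "
          f"(rank {row['degree_rank']}), chi2 {row['chi2']:.1f} "
          f"(rank {row['chi2_rank']}), expr {row['sperm_expr']:.2f} "
          f"(rank {row['expr_rank']}) via {row['criteria']}")

family = set(ds.gene_map.loc[ds.gene_map["family"] != "", "gene_id"])
awm_genes = set(awm_table["gene_id"])
p = family_enrichment(awm_genes, family, len(ds.gene_map))
captured = len(awm_genes & family)
print(f"\nfamily enrichment: {captured}/{len(family)} family genes in the "
      f"{len(awm_genes)}-gene AWM of {len(ds.gene_map)} genes; "
      f"hypergeometric P = {p:.4f}")
with open("results/enrichment.json", "w") as fh:
    json.dump({"captured": captured, "family_size": len(family),
               "awm_size": len(awm_genes), "genome_size": len(ds.gene_map),
               "p_value": p}, fh, indent=2)

if len(sel) >= 2:
    prof = awm_table.set_index("gene_id").loc[sel["gene_id"], traits]
    clus = cluster_profiles(prof)
    with open("results/profile_clusters.json", "w") as fh:
        json.dump({"row_order": clus.row_order,
                   "col_order": clus.col_order,
                   "col_clusters": {k: int(v) for k, v in
                                    clus.col_clusters.items()}}, fh,
                  indent=2)
    groups = {}
    for t, c in clus.col_clusters.items():
        groups.setdefault(c, []).append(t)
    print("\ntrait clusters of the selected genes' co-association profiles:")
    for c, ts in sorted(groups.items()):
        print(f"  cluster {c}: {', '.join(ts)}")
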