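"""Reported summary tables of the motivating multi-breed bull study.

These are the published estimates this pipeline re-derives on synthetic
data: the across-breed genomic correlations of each trait for all 15 breed
pairs, and the X-chromosome composition of the SNP panel and of the
association weight matrix.  They serve as inputs for arithmetic summaries
(per-breed and per-trait averages, chromosome proportions), not as expected
values for any estimator in this package.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "breed_pair_genomic_correlations",
    "mean_genomic_correlation_by_breed",
    "mean_genomic_correlation_by_trait",
    "x_chromosome_counts",
    "x_chromosome_percentages",
]

_TABLE = """\
breed_1\tbreed_2\tWT\tCOND\tSC\tSHEATH\tDENS\tMASS\tMOT\tPNS\tPD\tMP
BRM\tTRC\t0.73\t0.05\t0.49\t0.67\t-0.01\t-0.06\t-0.04\t-0.01\t0.00\t0.03
BRM\tSGT\t0.01\t0.01\t0.62\t0.94\t0.03\t0.01\t0.01\t0.01\t0.00\t0.01
BRM\tDMT\t0.02\t0.00\t0.43\t0.14\t0.06\t0.01\t0.02\t0.03\t0.03\t0.02
BRM\tUBK\t0.00\t0.02\t0.37\t0.36\t0.02\t-0.06\t-0.08\t-0.01\t0.01\t0.00
BRM\tBTC\t0.04\t0.04\t0.03\t0.14\t0.00\t0.00\t0.00\t0.00\t0.00\t0.00
TRC\tSGT\t0.02\t-0.03\t0.33\t0.60\t0.10\t-0.01\t0.02\t0.01\t0.03\t0.06
TRC\tDMT\t0.01\t0.01\t0.54\t0.02\t0.00\t-0.08\t0.00\t-0.01\t0.01\t0.01
TRC\tUBK\t0.02\t0.14\t0.49\t0.80\t0.08\t0.07\t0.01\t0.03\t0.03\t0.02
TRC\tBTC\t0.68\t0.07\t0.11\t0.63\t-0.04\t-0.04\t0.04\t0.01\t0.00\t0.01
SGT\tDMT\t0.01\t-0.16\t0.75\t0.80\t0.00\t-0.01\t0.00\t0.00\t0.02\t0.01
SGT\tUBK\t0.01\t0.00\t0.63\t0.57\t0.00\t0.02\t0.00\t0.00\t0.02\t0.00
SGT\tBTC\t0.01\t0.07\t0.05\t0.94\t0.00\t0.00\t-0.01\t0.02\t0.01\t0.00
DMT\tUBK\t0.02\t0.00\t0.28\t0.04\t0.00\t-0.01\t-0.01\t0.01\t0.01\t0.01
DMT\tBTC\t0.02\t0.00\t0.06\t0.68\t0.00\t0.00\t0.00\t0.01\t0.01\t0.00
UBK\tBTC\t-0.01\t0.04\t0.27\t0.39\t0.00\t0.00\t0.01\t0.01\t0.00\t0.01
"""

#: X-chromosome composition: (on_x, total) pairs
X_COUNTS = {
    "awm_genes": (283, 3479),
    "panel_snps": (24058, 680758),
}


def breed_pair_genomic_correlations() -> pd.DataFrame:
    """Across-breed genomic correlation per trait for the 15 breed pairs."""
    return pd.read_csv(io.StringIO(_TABLE), sep="\t")


def mean_genomic_correlation_by_breed() -> pd.Series:
    """Average over the 50 estimates each breed is involved in
    (10 traits × 5 comparison breeds)."""
    tab = breed_pair_genomic_correlations()
    traits = [c for c in tab.columns if c not in ("breed_1", "breed_2")]
    breeds = sorted(set(tab["breed_1"]) | set(tab["breed_2"]))
    out = {}
    for b in breeds:
        rows = tab[(tab["breed_1"] == b) | (tab["breed_2"] == b)]
        out[b] = float(rows[traits].to_numpy().mean())
    return pd.Series(out, name="mean_rg")


def mean_genomic_correlation_by_trait() -> pd.Series:
    """Average over the 15 breed-pair estimates per trait."""
    tab = breed_pair_genomic_correlations()
    traits = [c for c in tab.columns if c not in ("breed_1", "breed_2")]
    return tab[traits].mean().rename("mean_rg")


def x_chromosome_counts() -> dict[str, tuple[int, int]]:
    """(on X, total) counts for the AWM genes and the SNP panel."""
    return dict(X_COUNTS)


def x_chromosome_percentages() -> dict[str, float]:
    """Percentage of items on the X chromosome."""
    return {k: 100.0 * on_x / total for k, (on_x, total) in X_COUNTS.items()}
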