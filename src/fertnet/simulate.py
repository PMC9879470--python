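"""Synthetic multi-breed dataset generator.

Emulates the statistical structure the downstream analyses assume: six
breeds diverged under the Balding-Nichols model, ten traits generated from an
additive multi-trait model with configurable heritabilities and genetic and
residual correlation matrices, non-genetic fixed effects, pleiotropic QTL
anchored near genes, transcription-factor annotations, a labelled gene family
for the enrichment test, and sperm expression correlated with a subset of
causal genes.

Loci are independent by default (no linkage disequilibrium); an optional
first-order autocorrelation of adjacent ancestral frequencies is available
via ``SimConfig.ld_rho``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import ConfigError, SimConfig
from .grm import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_annotations",
    "make_dataset",
    "write_dataset",
    "read_dataset",
]

ANCHOR_WINDOW_BP = 10_000  # QTL are anchored within this window of a gene


# ---------------------------------------------------------------------------
# genotypes

def _chrom_labels(cfg: SimConfig) -> list[str]:
    labels = [str(i + 1) for i in range(cfg.n_chrom)]
    if cfg.x_last and cfg.n_chrom > 1:
        labels[-1] = "X"
    return labels


def _snp_layout(cfg: SimConfig) -> pd.DataFrame:
    """Evenly spaced SNP positions over the configured chromosomes."""
    labels = _chrom_labels(cfg)
    base = cfg.m_snps // cfg.n_chrom
    extra = cfg.m_snps % cfg.n_chrom
    rows = []
    snp = 0
    for c, lab in enumerate(labels):
        n_c = base + (1 if c < extra else 0)
        for j in range(n_c):
            rows.append((f"snp{snp:06d}", lab, (j + 1) * cfg.snp_spacing_bp))
            snp += 1
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "bp"])


def _breed_freqs(p_anc: np.ndarray, fst: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols draw of one breed's frequencies given the ancestral."""
    if fst < 1e-8:  # zero-divergence limit
        return p_anc.copy()
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return rng.beta(a, b)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Generate the multi-breed dosage matrix.

    Ancestral frequencies are uniform on (0.05, 0.95); each breed's
    frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F) with F the divergence
    parameter, and dosages are Binomial(2, breed frequency).  SNPs that end
    up monomorphic pooled over all animals are resampled once and dropped if
    still monomorphic.  Deterministic given the seed.
    """
    cfg.validate()
    rng = cfg.rng("geno")
    layout = _snp_layout(cfg)
    m = len(layout)

    if cfg.ld_rho > 0:
        # AR(1) latent field mapped through the normal CDF to (0.05, 0.95)
        z = np.empty(m)
        z[0] = rng.standard_normal()
        innov = rng.standard_normal(m - 1) if m > 1 else np.empty(0)
        for j in range(1, m):
            z[j] = cfg.ld_rho * z[j - 1] + np.sqrt(1 - cfg.ld_rho**2) * innov[j - 1]
        p_anc = 0.05 + 0.90 * norm.cdf(z)
    else:
        p_anc = rng.uniform(0.05, 0.95, size=m)

    fam = int(cfg.half_sib_family_size)

    def draw_breed(p_b: np.ndarray, n_b: int) -> np.ndarray:
        if fam <= 1:
            return rng.binomial(2, p_b, size=(n_b, p_b.size))
        # paternal half-sib families: one gamete from a shared sire drawn
        # from the breed pool, one gamete from the pool itself
        n_fam = -(-n_b // fam)
        sires = rng.binomial(2, p_b, size=(n_fam, p_b.size))
        sire_of = np.repeat(np.arange(n_fam), fam)[:n_b]
        paternal = rng.binomial(1, sires[sire_of] / 2.0)
        maternal = rng.binomial(1, p_b, size=(n_b, p_b.size))
        return paternal + maternal

    def draw(cols: np.ndarray | slice) -> np.ndarray:
        p_sub = p_anc[cols]
        blocks = []
        for n_b in cfg.n_per_breed:
            p_b = _breed_freqs(p_sub, cfg.fst, rng)
            blocks.append(draw_breed(p_b, n_b))
        return np.vstack(blocks).astype(np.int8)

    dosages = draw(slice(None))
    pooled = dosages.mean(axis=0) / 2.0
    mono = (pooled == 0.0) | (pooled == 1.0)
    if mono.any():
        cols = np.flatnonzero(mono)
        dosages[:, cols] = draw(cols)
        pooled = dosages[:, cols].mean(axis=0) / 2.0
        still = cols[(pooled == 0.0) | (pooled == 1.0)]
        if still.size:
            logger.info("dropping %d SNPs monomorphic after resampling", still.size)
            keep = np.setdiff1d(np.arange(m), still)
            dosages = dosages[:, keep]
            layout = layout.iloc[keep].reset_index(drop=True)

    animal_ids = np.array(
        [f"{b}_{i:05d}" for b, n_b in zip(cfg.breeds, cfg.n_per_breed)
         for i in range(n_b)], dtype=object)
    breed_labels = np.array(
        [b for b, n_b in zip(cfg.breeds, cfg.n_per_breed) for _ in range(n_b)],
        dtype=object)
    return GenotypeMatrix(
        animal_ids=animal_ids,
        breed_labels=breed_labels,
        snp_ids=layout["snp_id"].to_numpy(dtype=object),
        snp_map=layout,
        dosages=dosages,
    )


# ---------------------------------------------------------------------------
# deterministic gene grid and QTL anchoring (shared by traits and annotations)

def gene_grid(geno: GenotypeMatrix, cfg: SimConfig) -> pd.DataFrame:
    """Non-overlapping genes tiled deterministically on each chromosome."""
    rows = []
    g = 0
    for chrom, sub in geno.snp_map.groupby("chrom", sort=False):
        length = int(sub["bp"].max()) + cfg.snp_spacing_bp
        n_genes = max(1, int(round(cfg.gene_density * length / 1e6)))
        slot = length / n_genes
        body = min(cfg.gene_length_bp, max(1, int(slot // 2)))
        for j in range(n_genes):
            centre = (j + 0.5) * slot
            start = max(1, int(centre - body / 2))
            end = start + body - 1
            rows.append((f"gene{g:05d}", chrom, start, end))
            g += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _near_gene_mask(snp_map: pd.DataFrame, genes: pd.DataFrame,
                    window: int = ANCHOR_WINDOW_BP) -> np.ndarray:
    mask = np.zeros(len(snp_map), dtype=bool)
    for chrom, gsub in genes.groupby("chrom", sort=False):
        sel = snp_map["chrom"] == chrom
        bp = snp_map.loc[sel, "bp"].to_numpy()
        hit = np.zeros(bp.size, dtype=bool)
        for start, end in zip(gsub["start"], gsub["end"]):
            hit |= (bp >= start - window) & (bp <= end + window)
        mask[np.flatnonzero(sel)] = hit
    return mask


def qtl_indices(geno: GenotypeMatrix, cfg: SimConfig) -> np.ndarray:
    """Causal SNP column indices, anchored near genes, seeded independently."""
    if cfg.n_qtl > geno.m_snps:
        raise ConfigError("n_qtl exceeds the number of available SNPs")
    rng = cfg.rng("qtl")
    genes = gene_grid(geno, cfg)
    near = np.flatnonzero(_near_gene_mask(geno.snp_map, genes))
    if near.size < cfg.n_qtl:
        logger.warning(
            "only %d SNPs near genes for %d QTL; sampling from all SNPs",
            near.size, cfg.n_qtl)
        near = np.arange(geno.m_snps)
    return np.sort(rng.choice(near, size=cfg.n_qtl, replace=False))


# ---------------------------------------------------------------------------
# traits

def _match_moments(x: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Centre ``x`` and recolour so its sample covariance (ddof=1) is ``cov``."""
    n, t = x.shape
    xc = x - x.mean(axis=0)
    if n <= t + 1:
        return xc @ np.linalg.cholesky(cov + 1e-10 * np.eye(t)).T
    s = np.cov(xc, rowvar=False, ddof=1).reshape(t, t)
    ls = np.linalg.cholesky(s + 1e-12 * np.eye(t))
    lt = np.linalg.cholesky(cov + 1e-10 * np.eye(t))
    white = np.linalg.solve(ls, xc.T).T
    return white @ lt.T


def simulate_traits(
    geno: GenotypeMatrix, cfg: SimConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Generate the phenotype table and the truth tables.

    QTL effects are multivariate normal with the genetic correlation matrix,
    scaled so each trait's realised breeding-value variance equals its target
    heritability (phenotypic variance 1); residuals are multivariate normal
    with the residual correlation matrix scaled to 1−h².  Fixed effects of
    population, year of birth, cohort (nested in population) and an age
    covariate are added on top.

    Returns the phenotype table and a truth dict with ``effects`` (causal SNP
    allelic effects per trait), ``tbv`` (true breeding values per animal) and
    ``qtl_snps``.
    """
    cfg.validate()
    rng = cfg.rng("traits")
    n, t = geno.n_animals, len(cfg.traits)
    h2 = np.asarray(cfg.h2, dtype=float)
    rg = cfg.bent_rg()
    re_ = cfg.bent_re()

    qtl = qtl_indices(geno, cfg)
    zc = geno.dosages[:, qtl] - geno.dosages[:, qtl].mean(axis=0)
    ra = float(cfg.rg_across_breeds)
    shared = _match_moments(rng.standard_normal((cfg.n_qtl, t)), rg)
    if ra >= 1.0:
        beta_by_breed = {b: shared for b in cfg.breeds}
    else:
        # each breed mixes the shared component with its own, so that
        # corr(beta_a, beta_b) = ra between breeds and cov = Rg within
        beta_by_breed = {}
        for b in cfg.breeds:
            own = _match_moments(rng.standard_normal((cfg.n_qtl, t)), rg)
            beta_by_breed[b] = np.sqrt(ra) * shared + np.sqrt(1.0 - ra) * own
    breeds = geno.breed_labels
    tbv = np.empty((n, t))
    for b in cfg.breeds:
        rows = np.flatnonzero(breeds == b)
        tbv[rows] = zc[rows] @ beta_by_breed[b]
    v = tbv.var(axis=0, ddof=1)
    scale = np.where((h2 > 0) & (v > 0), np.sqrt(np.divide(
        h2, v, out=np.ones_like(v), where=v > 0)), 0.0)
    tbv *= scale
    beta = shared * scale
    beta_by_breed = {b: m * scale for b, m in beta_by_breed.items()}

    resid = _match_moments(rng.standard_normal((n, t)), re_)
    resid *= np.sqrt(1.0 - h2)

    # non-genetic fixed effects
    breeds = geno.breed_labels
    year = rng.integers(0, cfg.n_years, size=n)
    cohort = rng.integers(0, cfg.n_cohorts, size=n)
    pop_eff = rng.normal(0.0, cfg.fixed_effect_sd, size=(len(cfg.breeds), t))
    year_eff = rng.normal(0.0, cfg.fixed_effect_sd, size=(cfg.n_years, t))
    coh_eff = rng.normal(0.0, cfg.fixed_effect_sd,
                         size=(len(cfg.breeds), cfg.n_cohorts, t))
    breed_idx = np.array([cfg.breeds.index(b) for b in breeds])
    lo = np.array([cfg.age_windows.get(b, (360.0, 700.0))[0] for b in breeds])
    hi = np.array([cfg.age_windows.get(b, (360.0, 700.0))[1] for b in breeds])
    age = rng.uniform(lo, hi)
    age_sd = age.std(ddof=1) if n > 1 else 1.0
    slope = rng.standard_normal(t) * cfg.age_effect_sd / max(age_sd, 1e-9)

    y = (tbv + resid
         + pop_eff[breed_idx]
         + year_eff[year]
         + coh_eff[breed_idx, cohort]
         + np.outer(age - age.mean(), slope))

    if cfg.missing_rate > 0:
        mask = rng.random(size=(n, t)) < cfg.missing_rate
        y = np.where(mask, np.nan, y)

    pheno = pd.DataFrame({
        "animal_id": geno.animal_ids,
        "breed": breeds,
        "population": breeds,
        "year_of_birth": 2016 + year,
        "cohort": cohort + 1,
        "age": np.round(age, 1),
    })
    for j, trait in enumerate(cfg.traits):
        pheno[trait] = y[:, j]

    truth = {
        "effects": pd.DataFrame(
            beta, index=pd.Index(geno.snp_ids[qtl], name="snp_id"),
            columns=list(cfg.traits)),
        "effects_by_breed": {
            b: pd.DataFrame(m, index=pd.Index(geno.snp_ids[qtl],
                                              name="snp_id"),
                            columns=list(cfg.traits))
            for b, m in beta_by_breed.items()},
        "tbv": pd.DataFrame(
            tbv, index=pd.Index(geno.animal_ids, name="animal_id"),
            columns=list(cfg.traits)),
        "qtl_snps": pd.DataFrame({"snp_id": geno.snp_ids[qtl]}),
    }
    return pheno, truth


# ---------------------------------------------------------------------------
# annotations

def simulate_annotations(
    geno: GenotypeMatrix, cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene map (with TF flags and a labelled family) and sperm expression.

    Expression is log-normal; a configurable fraction of causal-adjacent
    genes (those with a QTL within the anchoring window) gets a
    multiplicative abundance boost.  Deterministic given the seed.
    """
    cfg.validate()
    rng = cfg.rng("annot")
    genes = gene_grid(geno, cfg).copy()
    n_genes = len(genes)
    if cfg.n_tf > n_genes:
        raise ConfigError(f"n_tf={cfg.n_tf} exceeds the {n_genes} simulated genes")
    if cfg.family_size > n_genes:
        raise ConfigError(
            f"family_size={cfg.family_size} exceeds the {n_genes} simulated genes")

    tf_rows = rng.choice(n_genes, size=cfg.n_tf, replace=False)
    fam_rows = rng.choice(n_genes, size=cfg.family_size, replace=False)
    genes["tf_flag"] = False
    genes.loc[genes.index[tf_rows], "tf_flag"] = True
    genes["family"] = ""
    genes.loc[genes.index[fam_rows], "family"] = cfg.family_label

    log_expr = rng.normal(1.0, 1.0, size=n_genes)
    qtl = qtl_indices(geno, cfg)
    qtl_map = geno.snp_map.iloc[qtl]
    causal_adjacent = np.zeros(n_genes, dtype=bool)
    for i, (chrom, start, end) in enumerate(
            zip(genes["chrom"], genes["start"], genes["end"])):
        near = qtl_map[(qtl_map["chrom"] == chrom)
                       & (qtl_map["bp"] >= start - ANCHOR_WINDOW_BP)
                       & (qtl_map["bp"] <= end + ANCHOR_WINDOW_BP)]
        causal_adjacent[i] = len(near) > 0
    if cfg.expr_boost > 1.0 and causal_adjacent.any():
        cand = np.flatnonzero(causal_adjacent)
        n_boost = int(round(cfg.expr_boost_frac * cand.size))
        boosted = rng.choice(cand, size=n_boost, replace=False)
        log_expr[boosted] += np.log(cfg.expr_boost)
    genes["causal_adjacent"] = causal_adjacent

    expr = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "abundance": np.exp(log_expr),
    })
    return genes, expr


# ---------------------------------------------------------------------------
# the assembled dataset

@dataclass
class SyntheticDataset:
    """All tables of one simulated study: genotypes, phenotypes, gene map,
    sperm expression, and the generating truth."""

    config: SimConfig
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    gene_map: pd.DataFrame
    sperm_expr: pd.DataFrame
    truth: dict[str, pd.DataFrame]


def make_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Run all generator stages for one configuration."""
    cfg.validate()
    geno = simulate_genotypes(cfg)
    gene_map, sperm_expr = simulate_annotations(geno, cfg)
    pheno, truth = simulate_traits(geno, cfg)
    return SyntheticDataset(
        config=cfg, genotypes=geno, phenotypes=pheno,
        gene_map=gene_map, sperm_expr=sperm_expr, truth=truth)


# ---------------------------------------------------------------------------
# plain-text serialization

_FLOAT_FMT = "%.10g"


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write all tables as tab/comma-delimited text, plus the config echo."""
    from pathlib import Path

    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    geno = ds.genotypes
    raw = pd.DataFrame(geno.dosages, columns=list(geno.snp_ids))
    raw.insert(0, "breed", geno.breed_labels)
    raw.insert(0, "animal_id", geno.animal_ids)
    raw.to_csv(out / "genotypes.raw.tsv", sep="\t", index=False)

    snp_map = geno.snp_map.copy()
    snp_map["ref_freq"] = geno.allele_freqs()
    snp_map.to_csv(out / "snp_map.tsv", sep="\t", index=False,
                   float_format=_FLOAT_FMT)

    ds.phenotypes.to_csv(out / "phenotypes.csv", index=False,
                         float_format=_FLOAT_FMT)
    bed = ds.gene_map[["chrom", "start", "end", "gene_id", "tf_flag", "family"]]
    bed.to_csv(out / "gene_map.tsv", sep="\t", index=False)
    ds.sperm_expr.to_csv(out / "sperm_expr.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)
    ds.truth["effects"].to_csv(out / "truth_effects.tsv", sep="\t",
                               float_format=_FLOAT_FMT)
    by_breed = ds.truth.get("effects_by_breed")
    if by_breed is not None and ds.config.rg_across_breeds < 1.0:
        stacked = pd.concat(
            {b: df for b, df in by_breed.items()}, names=["breed", "snp_id"])
        stacked.to_csv(out / "truth_effects_by_breed.tsv", sep="\t",
                       float_format=_FLOAT_FMT)
    ds.truth["tbv"].to_csv(out / "truth_tbv.tsv", sep="\t",
                           float_format=_FLOAT_FMT)
    (out / "config.yaml").write_text(yaml.safe_dump(
        ds.config.to_dict(), sort_keys=True))


def read_genotypes(path) -> GenotypeMatrix:
    """Read a dosage TSV (animal_id, breed, SNP columns) plus its SNP map."""
    from pathlib import Path

    path = Path(path)
    raw = pd.read_csv(path / "genotypes.raw.tsv", sep="\t")
    snp_map = pd.read_csv(path / "snp_map.tsv", sep="\t",
                          dtype={"chrom": str})
    snp_ids = [c for c in raw.columns if c not in ("animal_id", "breed")]
    dose = raw[snp_ids].to_numpy(dtype=float)
    if np.isnan(dose).any():
        frac = float(np.isnan(dose).mean())
        logger.warning("mean-imputing %.4f missing dosages", frac)
        col_mean = np.nanmean(dose, axis=0)
        idx = np.where(np.isnan(dose))
        dose[idx] = np.take(col_mean, idx[1])
    dose = np.clip(np.rint(dose), 0, 2).astype(np.int8)
    return GenotypeMatrix(
        animal_ids=raw["animal_id"].to_numpy(dtype=object),
        breed_labels=raw["breed"].to_numpy(dtype=object),
        snp_ids=np.asarray(snp_ids, dtype=object),
        snp_map=snp_map[["snp_id", "chrom", "bp"]],
        dosages=dose,
    )


def read_dataset(path) -> SyntheticDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    from pathlib import Path

    import yaml

    path = Path(path)
    cfg = SimConfig.from_dict(yaml.safe_load((path / "config.yaml").read_text()))
    geno = read_genotypes(path)
    pheno = pd.read_csv(path / "phenotypes.csv")
    bed = pd.read_csv(path / "gene_map.tsv", sep="\t", dtype={"chrom": str},
                      keep_default_na=False)
    gene_map = bed[["gene_id", "chrom", "start", "end", "tf_flag", "family"]]
    expr = pd.read_csv(path / "sperm_expr.tsv", sep="\t")
    truth = {
        "effects": pd.read_csv(path / "truth_effects.tsv", sep="\t",
                               index_col="snp_id"),
        "tbv": pd.read_csv(path / "truth_tbv.tsv", sep="\t",
                           index_col="animal_id"),
    }
    by_breed_path = path / "truth_effects_by_breed.tsv"
    if by_breed_path.exists():
        stacked = pd.read_csv(by_breed_path, sep="\t",
                              index_col=["breed", "snp_id"])
        truth["effects_by_breed"] = {
            b: stacked.loc[b] for b in stacked.index.get_level_values(0).unique()}
    truth["qtl_snps"] = pd.DataFrame({"snp_id": truth["effects"].index})
    return SyntheticDataset(
        config=cfg, genotypes=geno, phenotypes=pheno,
        gene_map=gene_map, sperm_expr=expr, truth=truth)
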