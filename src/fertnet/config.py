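"""Simulation configuration and the default generating parameters.

The defaults describe a six-breed population of tropically adapted bulls
measured for ten fertility-related traits: four on the bull (body weight WT,
condition score COND, scrotal circumference SC, sheath score SHEATH) and six
on its semen (density DENS, mass activity MASS, progressive motility MOT,
percent normal sperm PNS, percent proximal droplets PD, percent midpiece
abnormalities MP).  The default heritabilities and the genetic/residual
correlation matrices are the multi-breed bivariate-GREML estimates reported
for these traits, used here as generating values so the downstream estimators
can be checked for recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TRAITS",
    "BREEDS",
    "DEFAULT_H2",
    "default_rg",
    "default_re",
    "nearest_psd_correlation",
    "SimConfig",
    "ConfigError",
]

TRAITS: tuple[str, ...] = (
    "WT", "COND", "SC", "SHEATH", "DENS", "MASS", "MOT", "PNS", "PD", "MP",
)

BREEDS: tuple[str, ...] = ("BRM", "TRC", "SGT", "DMT", "UBK", "BTC")

#: per-trait heritability defaults (generating values)
DEFAULT_H2: dict[str, float] = dict(zip(TRAITS, (
    0.37, 0.17, 0.47, 0.57, 0.20, 0.21, 0.19, 0.24, 0.22, 0.22,
)))

# genetic correlations, upper triangle in TRAITS order
_RG_UPPER = {
    ("WT", "COND"): 0.31, ("WT", "SC"): 0.43, ("WT", "SHEATH"): 0.07,
    ("WT", "DENS"): 0.08, ("WT", "MASS"): 0.08, ("WT", "MOT"): 0.03,
    ("WT", "PNS"): -0.08, ("WT", "PD"): 0.00, ("WT", "MP"): 0.02,
    ("COND", "SC"): 0.11, ("COND", "SHEATH"): -0.14, ("COND", "DENS"): 0.07,
    ("COND", "MASS"): 0.13, ("COND", "MOT"): 0.00, ("COND", "PNS"): 0.09,
    ("COND", "PD"): -0.16, ("COND", "MP"): 0.05,
    ("SC", "SHEATH"): 0.24, ("SC", "DENS"): 0.17, ("SC", "MASS"): 0.14,
    ("SC", "MOT"): 0.06, ("SC", "PNS"): 0.05, ("SC", "PD"): -0.04,
    ("SC", "MP"): 0.05,
    ("SHEATH", "DENS"): -0.06, ("SHEATH", "MASS"): -0.07,
    ("SHEATH", "MOT"): -0.15, ("SHEATH", "PNS"): -0.26,
    ("SHEATH", "PD"): 0.27, ("SHEATH", "MP"): 0.12,
    ("DENS", "MASS"): 0.73, ("DENS", "MOT"): 0.34, ("DENS", "PNS"): 0.29,
    ("DENS", "PD"): -0.18, ("DENS", "MP"): -0.18,
    ("MASS", "MOT"): 0.68, ("MASS", "PNS"): 0.52, ("MASS", "PD"): -0.32,
    ("MASS", "MP"): -0.30,
    ("MOT", "PNS"): 0.53, ("MOT", "PD"): -0.22, ("MOT", "MP"): -0.40,
    ("PNS", "PD"): -0.70, ("PNS", "MP"): -0.51,
    ("PD", "MP"): 0.06,
}

# residual correlations, stored as (row, col) with row later in TRAITS order
_RE_LOWER = {
    ("COND", "WT"): 0.34,
    ("SC", "WT"): 0.44, ("SC", "COND"): 0.15,
    ("SHEATH", "WT"): 0.03, ("SHEATH", "COND"): 0.00, ("SHEATH", "SC"): 0.04,
    ("DENS", "WT"): 0.06, ("DENS", "COND"): 0.00, ("DENS", "SC"): 0.17,
    ("DENS", "SHEATH"): 0.01,
    ("MASS", "WT"): 0.08, ("MASS", "COND"): 0.01, ("MASS", "SC"): 0.15,
    ("MASS", "SHEATH"): 0.02, ("MASS", "DENS"): 0.68,
    ("MOT", "WT"): 0.05, ("MOT", "COND"): -0.01, ("MOT", "SC"): 0.11,
    ("MOT", "SHEATH"): 0.06, ("MOT", "DENS"): 0.34, ("MOT", "MASS"): 0.63,
    ("PNS", "WT"): 0.11, ("PNS", "COND"): 0.07, ("PNS", "SC"): 0.20,
    ("PNS", "SHEATH"): 0.05, ("PNS", "DENS"): 0.26, ("PNS", "MASS"): 0.35,
    ("PNS", "MOT"): 0.35,
    ("PD", "WT"): -0.08, ("PD", "COND"): -0.06, ("PD", "SC"): -0.17,
    ("PD", "SHEATH"): -0.05, ("PD", "DENS"): -0.21, ("PD", "MASS"): -0.22,
    ("PD", "MOT"): -0.16, ("PD", "PNS"): -0.69,
    ("MP", "WT"): -0.04, ("MP", "COND"): 0.00, ("MP", "SC"): -0.08,
    ("MP", "SHEATH"): -0.02, ("MP", "DENS"): -0.08, ("MP", "MASS"): -0.16,
    ("MP", "MOT"): -0.22, ("MP", "PNS"): -0.44, ("MP", "PD"): 0.01,
}


def _corr_from_pairs(pairs: dict[tuple[str, str], float]) -> np.ndarray:
    t = len(TRAITS)
    mat = np.eye(t)
    idx = {name: i for i, name in enumerate(TRAITS)}
    for (a, b), r in pairs.items():
        mat[idx[a], idx[b]] = r
        mat[idx[b], idx[a]] = r
    return mat


def default_rg() -> np.ndarray:
    """Default 10x10 genetic correlation matrix (unit diagonal)."""
    return _corr_from_pairs(_RG_UPPER)


def default_re() -> np.ndarray:
    """Default 10x10 residual correlation matrix (unit diagonal)."""
    return _corr_from_pairs(_RE_LOWER)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def nearest_psd_correlation(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Bend a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues below ``eps`` are truncated to ``eps`` and the result is
    rescaled to unit diagonal.  Correlation matrices assembled pairwise (as a
    table of bivariate estimates is) need not be jointly PSD, so bending is
    applied before any Cholesky factorisation.
    """
    mat = np.asarray(mat, dtype=float)
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        out = sym
    else:
        vals = np.clip(vals, eps, None)
        out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


# per-breed observation-age windows in days (lower, upper); the research-herd
# breeds record semen traits around 360-700 d, the stud herds around 390-600 d
DEFAULT_AGE_WINDOWS: dict[str, tuple[float, float]] = {
    "BRM": (330.0, 390.0),
    "TRC": (670.0, 730.0),
    "SGT": (570.0, 630.0),
    "DMT": (570.0, 630.0),
    "UBK": (410.0, 470.0),
    "BTC": (360.0, 420.0),
}


@dataclass
class SimConfig:
    """Configuration of the synthetic multi-breed dataset generator.

    Parameters
    ----------
    n_per_breed
        Animal count per breed (aligned with ``breeds``).
    breeds
        Breed codes.
    m_snps
        Number of SNPs before monomorphic filtering.
    n_chrom
        Number of chromosomes; with ``x_last`` the last one is labelled "X".
    fst
        Balding-Nichols divergence parameter in (0, 1).
    n_qtl
        Number of causal SNPs (pleiotropic, anchored near genes).
    rg_across_breeds
        Correlation of the QTL effect vectors between any two breeds: 1
        (default) means every breed shares the same allelic effects, 0 means
        fully breed-specific genetic backgrounds, mirroring the weak
        across-breed genomic correlations seen for most fertility traits.
    half_sib_family_size
        1 (default) draws every animal independently from its breed's allele
        frequencies; k > 1 groups each breed into paternal half-sib families
        of size k (one gamete from a shared sire, one from the breed pool),
        mimicking the sire-family structure of stud herds.  Within-breed
        relatives are what make within-breed cross-validation outperform
        leave-one-breed-out validation.
    h2
        Target heritability per trait (phenotypic variance 1 scale).
    rg, re
        Genetic / residual correlation matrices (10x10, unit diagonal).
    n_years, n_cohorts
        Level counts of the year-of-birth and (within-population) cohort
        fixed effects.
    snp_spacing_bp
        Even base-pair spacing between adjacent SNPs, mirroring a high-density
        panel (~1 SNP per 4 kb).
    gene_density
        Genes per Mbp of simulated genome.
    gene_length_bp
        Fixed gene body length used by the annotation tiler.
    family_size
        Size of the labelled gene family used by the enrichment test.
    n_tf
        Number of genes flagged as transcription factors.
    expr_boost
        Multiplicative boost of sperm expression for boosted causal-adjacent
        genes (1 = no boost).
    expr_boost_frac
        Fraction of causal-adjacent genes receiving the boost.
    fixed_effect_sd
        SD of the population/year/cohort effect draws on the trait scale.
    age_effect_sd
        SD contributed by the age covariate to each trait.
    missing_rate
        Per-trait fraction of records set missing (default none).
    ld_rho
        Optional first-order autocorrelation of adjacent ancestral allele
        frequencies (0 = independent loci, the default).
    seed
        Master seed; each generator stage derives its own stream from it.
    """

    n_per_breed: list[int] = field(default_factory=lambda: [300] * 6)
    breeds: list[str] = field(default_factory=lambda: list(BREEDS))
    m_snps: int = 5000
    n_chrom: int = 30
    x_last: bool = True
    fst: float = 0.15
    n_qtl: int = 400
    rg_across_breeds: float = 1.0
    half_sib_family_size: int = 1
    h2: np.ndarray = field(
        default_factory=lambda: np.array([DEFAULT_H2[t] for t in TRAITS]))
    traits: tuple[str, ...] = TRAITS
    rg: np.ndarray = field(default_factory=default_rg)
    re: np.ndarray = field(default_factory=default_re)
    n_years: int = 3
    n_cohorts: int = 2
    snp_spacing_bp: int = 4000
    gene_density: float = 10.0
    gene_length_bp: int = 20000
    family_size: int = 25
    family_label: str = "SPG"
    n_tf: int = 30
    expr_boost: float = 3.0
    expr_boost_frac: float = 0.5
    fixed_effect_sd: float = 0.3
    age_effect_sd: float = 0.2
    age_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_WINDOWS))
    missing_rate: float = 0.0
    ld_rho: float = 0.0
    seed: int = 0

    # fixed per-stage RNG stream offsets so stages can be rerun independently
    _STREAMS = {"geno": 11, "qtl": 23, "traits": 37, "annot": 53, "folds": 71}

    def rng(self, stage: str) -> np.random.Generator:
        """RNG stream for a named generator stage, derived from the seed."""
        if stage not in self._STREAMS:
            raise KeyError(f"unknown RNG stage {stage!r}")
        return np.random.default_rng(
            np.random.SeedSequence((int(self.seed), self._STREAMS[stage])))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    @property
    def n_animals(self) -> int:
        return int(sum(self.n_per_breed))

    def validate(self) -> "SimConfig":
        """Raise :class:`ConfigError` on invalid values; return self."""
        if len(self.n_per_breed) != len(self.breeds):
            raise ConfigError("n_per_breed and breeds must have equal length")
        if len(set(self.breeds)) != len(self.breeds):
            raise ConfigError("duplicate breed codes")
        counts = {
            "n_per_breed entries": self.n_per_breed,
            "m_snps": [self.m_snps],
            "n_chrom": [self.n_chrom],
            "n_qtl": [self.n_qtl],
            "n_years": [self.n_years],
            "n_cohorts": [self.n_cohorts],
            "family_size": [self.family_size],
            "n_tf": [self.n_tf],
        }
        for name, vals in counts.items():
            for v in vals:
                if not np.isfinite(v) or int(v) != v or v <= 0:
                    raise ConfigError(f"{name} must be positive integers, got {v}")
        if not np.isfinite(self.fst) or not 0.0 < self.fst < 1.0:
            raise ConfigError(f"fst must lie in (0, 1), got {self.fst}")
        if not 0.0 <= self.rg_across_breeds <= 1.0:
            raise ConfigError("rg_across_breeds must lie in [0, 1]")
        if int(self.half_sib_family_size) != self.half_sib_family_size \
                or self.half_sib_family_size < 1:
            raise ConfigError("half_sib_family_size must be a positive integer")
        if self.n_qtl > self.m_snps:
            raise ConfigError("n_qtl cannot exceed m_snps")
        h2 = np.asarray(self.h2, dtype=float)
        if h2.shape != (len(self.traits),):
            raise ConfigError("h2 must have one entry per trait")
        if not np.all(np.isfinite(h2)) or np.any(h2 < 0) or np.any(h2 >= 1):
            raise ConfigError("heritabilities must lie in [0, 1)")
        if self.gene_density <= 0 or not np.isfinite(self.gene_density):
            raise ConfigError("gene_density must be positive")
        if self.expr_boost < 1.0:
            raise ConfigError("expr_boost must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        for name, mat in (("rg", self.rg), ("re", self.re)):
            m = np.asarray(mat, dtype=float)
            if m.shape != (len(self.traits),) * 2:
                raise ConfigError(f"{name} must be square over the traits")
            if not np.all(np.isfinite(m)):
                raise ConfigError(f"{name} contains non-finite values")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ConfigError(f"{name} must be symmetric")
            if not np.allclose(np.diag(m), 1.0, atol=1e-10):
                raise ConfigError(f"{name} must have unit diagonal")
            if np.any(np.abs(m) > 1 + 1e-10):
                raise ConfigError(f"{name} entries must lie in [-1, 1]")
        return self

    def to_dict(self) -> dict:
        """Plain-python representation (YAML/JSON safe)."""
        d = dataclasses.asdict(self)
        d["h2"] = [float(v) for v in np.asarray(self.h2)]
        d["rg"] = np.asarray(self.rg).round(12).tolist()
        d["re"] = np.asarray(self.re).round(12).tolist()
        d["traits"] = list(self.traits)
        d["age_windows"] = {k: [float(a), float(b)]
                            for k, (a, b) in self.age_windows.items()}
        d.pop("_STREAMS", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("h2", "rg", "re"):
            if key in d:
                d[key] = np.asarray(d[key], dtype=float)
        if "traits" in d:
            d["traits"] = tuple(d["traits"])
        if "age_windows" in d:
            d["age_windows"] = {k: (float(v[0]), float(v[1]))
                                for k, v in d["age_windows"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    def bent_rg(self) -> np.ndarray:
        return nearest_psd_correlation(self.rg)

    def bent_re(self) -> np.ndarray:
        return nearest_psd_correlation(self.re)
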