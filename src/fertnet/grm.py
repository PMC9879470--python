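"""Genotype container, VanRaden Method-1 genomic relationships, and PCA.

The genomic relationship matrix (GRM) is G = ZZᵀ / (2Σpⱼ(1−pⱼ)) with Z the
dosage matrix column-centred at twice the allele frequency.  Allele
frequencies default to the observed (pooled) frequencies of the analysis set;
within-breed GRMs are obtained by subsetting the genotypes first so that
within-breed frequencies are used.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "GRM", "compute_grm", "compute_pca", "subset_grm"]


def chrom_sort_key(label: str) -> tuple[int, float | str]:
    """Sort numeric chromosome labels numerically, then X/Y/MT, then others."""
    s = str(label)
    if re.fullmatch(r"\d+", s):
        return (0, float(s))
    order = {"X": 0, "Y": 1, "MT": 2, "M": 2}
    if s.upper() in order:
        return (1, order[s.upper()])
    return (2, s)


@dataclass
class GenotypeMatrix:
    """Animals × SNPs dosage matrix with breed labels and a SNP map.

    ``dosages`` holds allele counts in {0, 1, 2}; missing values are not
    allowed (the loader mean-imputes and rounds at read time).  ``snp_map``
    is a DataFrame with columns ``snp_id``, ``chrom``, ``bp`` sorted by
    (chromosome, position).
    """

    animal_ids: np.ndarray
    breed_labels: np.ndarray
    snp_ids: np.ndarray
    snp_map: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.breed_labels = np.asarray(self.breed_labels, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        n, m = self.dosages.shape
        if len(self.animal_ids) != n or len(self.breed_labels) != n:
            raise ValueError("animal ids/breeds do not match dosage rows")
        if len(self.snp_ids) != m or len(self.snp_map) != m:
            raise ValueError("snp ids/map do not match dosage columns")
        if len(set(self.animal_ids)) != n:
            raise ValueError("duplicated animal ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicated SNP ids")
        vals = np.unique(self.dosages)
        if not np.isin(vals, [0, 1, 2]).all():
            raise ValueError("dosages must be coded 0/1/2")
        keys = [chrom_sort_key(c) for c in self.snp_map["chrom"]]
        order = sorted(range(m), key=lambda i: (keys[i], int(self.snp_map["bp"].iloc[i])))
        if order != list(range(m)):
            raise ValueError("snp_map must be sorted by (chrom, bp)")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Observed pooled allele frequency per SNP."""
        return self.dosages.mean(axis=0) / 2.0

    def subset_animals(self, ids) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        rows = np.array([index[a] for a in ids], dtype=int)
        return GenotypeMatrix(
            animal_ids=self.animal_ids[rows],
            breed_labels=self.breed_labels[rows],
            snp_ids=self.snp_ids,
            snp_map=self.snp_map,
            dosages=self.dosages[rows],
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Column subset by boolean mask or integer index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            animal_ids=self.animal_ids,
            breed_labels=self.breed_labels,
            snp_ids=self.snp_ids[keep],
            snp_map=self.snp_map.iloc[keep].reset_index(drop=True),
            dosages=self.dosages[:, keep],
        )


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with the centering metadata.

    ``denom`` is 2Σpⱼ(1−pⱼ) over the SNPs actually used, ``freqs`` the
    per-SNP allele frequency used for centering and ``snp_ids`` the SNPs
    retained after monomorphic filtering.
    """

    animal_ids: np.ndarray
    values: np.ndarray
    denom: float
    freqs: np.ndarray
    snp_ids: np.ndarray
    _eig: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM dimension does not match animal ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if self.denom <= 0:
            raise ValueError("GRM denominator must be positive")

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (ascending eigenvalues, eigenvectors)."""
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.values)
            self._eig = (vals, vecs)
        return self._eig

    def index_of(self, ids) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([index[a] for a in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message clarity
            raise KeyError(f"animal id {exc.args[0]!r} not in GRM") from None


def compute_grm(
    geno: GenotypeMatrix,
    freqs: np.ndarray | None = None,
) -> GRM:
    """VanRaden Method-1 GRM.

    Parameters
    ----------
    geno
        Genotypes of the analysis set.
    freqs
        Optional supplied allele frequencies (one per SNP).  When omitted,
        observed pooled frequencies are used and SNPs monomorphic in the set
        are dropped (with a logged count).
    """
    if freqs is None:
        p = geno.allele_freqs()
        poly = (p > 0.0) & (p < 1.0)
        n_mono = int((~poly).sum())
        if n_mono:
            logger.info("dropping %d monomorphic SNPs from GRM", n_mono)
        if not poly.any():
            raise ValueError("all SNPs monomorphic; GRM undefined")
        dose = geno.dosages[:, poly]
        p = p[poly]
        snp_ids = geno.snp_ids[poly]
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (geno.m_snps,):
            raise ValueError("supplied freqs must have one entry per SNP")
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError("supplied freqs must lie strictly in (0, 1)")
        dose = geno.dosages
        snp_ids = geno.snp_ids
    z = dose - 2.0 * p
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    g = (z @ z.T) / denom
    g = 0.5 * (g + g.T)
    return GRM(animal_ids=geno.animal_ids, values=g, denom=denom,
               freqs=p, snp_ids=snp_ids)


def subset_grm(grm: GRM, ids) -> GRM:
    """Principal submatrix of the GRM in the requested animal order.

    The centering frequencies and denominator are carried through unchanged
    (the submatrix is still centred at the full-set frequencies, as the
    breed-pair fits require).
    """
    rows = grm.index_of(ids)
    return GRM(
        animal_ids=grm.animal_ids[rows],
        values=grm.values[np.ix_(rows, rows)],
        denom=grm.denom,
        freqs=grm.freqs,
        snp_ids=grm.snp_ids,
    )


def compute_pca(
    geno: GenotypeMatrix,
    k: int,
    grm: GRM | None = None,
) -> pd.DataFrame:
    """Top-k principal-component scores of the centred dosage matrix.

    Scores are eigenvectors of the GRM scaled by the root eigenvalues (times
    √denom, i.e. the classical genotype PCA).  Each component's sign is fixed
    so its largest-magnitude SNP loading is positive.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if k >= geno.n_animals:
        raise ValueError("k must be smaller than the number of animals")
    if grm is None:
        grm = compute_grm(geno)
    vals, vecs = grm.eigendecomposition()
    top = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[top], 0.0, None)
    scores = vecs[:, top] * np.sqrt(lam * grm.denom)
    # sign convention via SNP loadings of the centred dosage matrix
    keep = np.isin(geno.snp_ids, grm.snp_ids)
    z = geno.dosages[:, keep] - 2.0 * grm.freqs
    loadings = z.T @ vecs[:, top]
    for j in range(k):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=pd.Index(geno.animal_ids, name="animal_id"),
        columns=[f"PC{i + 1}" for i in range(k)])
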