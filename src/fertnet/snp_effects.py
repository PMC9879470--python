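"""Backsolved SNP effects, standardization, association tests, pleiotropy.

Per-SNP effects are recovered from animal-level GEBVs as ŝ = λ Mᵀ G⁻¹ û,
with M the frequency-centred dosage matrix used to build G and λ the ratio
of SNP variance to genetic variance (0.85 throughout, following the source
analysis).  Effects are z-score standardized per trait; two-sided p-values
come from the standard normal, and the pleiotropic potential of SNP i is
χ²ᵢ = zᵢᵀ V⁻¹ zᵢ on t degrees of freedom, with V the trait × trait
correlation matrix of the standardized effects computed over all SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .config import nearest_psd_correlation
from .grm import GRM, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SNPEffectMatrix",
    "backsolve_snp_effects",
    "standardize_and_test",
    "pleiotropy_chi2",
]

DEFAULT_LAMBDA = 0.85
RIDGE_EPS = 1e-6


@dataclass
class SNPEffectMatrix:
    """SNP × trait effects with their tests.

    ``s_hat`` raw backsolved effects, ``z`` per-trait z-scores, ``p``
    two-sided normal p-values, ``n_assoc`` per-SNP count of traits with
    p < alpha, ``chi2``/``chi2_p`` the multi-trait pleiotropy statistic.
    """

    s_hat: pd.DataFrame
    z: pd.DataFrame
    p: pd.DataFrame
    n_assoc: pd.Series
    alpha: float
    chi2: pd.Series | None = None
    chi2_p: pd.Series | None = None
    v_matrix: np.ndarray | None = None

    @property
    def snp_ids(self) -> np.ndarray:
        return self.z.index.to_numpy(dtype=object)

    @property
    def traits(self) -> list[str]:
        return list(self.z.columns)


def _solve_g(grm: GRM, rhs: np.ndarray) -> np.ndarray:
    """G⁻¹ rhs via Cholesky with a logged ridge fallback on singularity.

    A GRM centred at observed frequencies always satisfies G·1 = 0, so the
    plain factorisation either fails or carries a vanishing pivot; the ridge
    is harmless for GEBV right-hand sides because they are exactly
    orthogonal to the null direction (1ᵀû = 0).
    """
    try:
        cf = cho_factor(grm.values, lower=True, check_finite=False)
        piv = np.diag(cf[0])
        if piv.min() > 1e-6 * piv.max():
            return cho_solve(cf, rhs, check_finite=False)
    except np.linalg.LinAlgError:
        pass
    eps = RIDGE_EPS * float(np.trace(grm.values)) / grm.n
    logger.warning("GRM (near-)singular; adding ridge %.3g to the diagonal",
                   eps)
    cf = cho_factor(grm.values + eps * np.eye(grm.n), lower=True,
                    check_finite=False)
    return cho_solve(cf, rhs, check_finite=False)


def backsolve_snp_effects(
    geno: GenotypeMatrix,
    grm: GRM,
    u_w: pd.DataFrame,
    lam: float = DEFAULT_LAMBDA,
) -> pd.DataFrame:
    """Raw SNP effects ŝ = λ Mᵀ G⁻¹ û_w per trait.

    ``u_w`` holds whole-data GEBVs indexed by animal_id (one column per
    trait) and must cover exactly the GRM's animals; M is rebuilt from the
    genotypes with the same SNP set and centering frequencies stored in the
    GRM.
    """
    if "animal_id" in u_w.columns:
        u_w = u_w.set_index("animal_id")
    missing = set(grm.animal_ids) - set(u_w.index)
    if missing:
        raise KeyError(f"GEBVs missing for animals: {sorted(missing)[:5]}")
    u = u_w.reindex(grm.animal_ids).to_numpy(dtype=float)
    ginv_u = _solve_g(grm, u)
    keep = np.isin(geno.snp_ids, grm.snp_ids)
    m = geno.dosages[:, keep] - 2.0 * grm.freqs
    s_hat = lam * (m.T @ ginv_u)
    return pd.DataFrame(
        s_hat, index=pd.Index(geno.snp_ids[keep], name="snp_id"),
        columns=list(u_w.columns))


def standardize_and_test(
    raw: pd.DataFrame,
    alpha: float = 0.01,
) -> SNPEffectMatrix:
    """z-score the effects per trait and attach normal p-values.

    ``n_assoc`` counts, per SNP, the traits with p < ``alpha``.  A
    zero-variance effect column signals a degenerate backsolve and raises.
    """
    if len(raw) < 2:
        raise ValueError("need at least 2 SNPs to standardize")
    s = raw.to_numpy(dtype=float)
    mu = s.mean(axis=0)
    sd = s.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [c for c, v in zip(raw.columns, sd) if v == 0]
        raise ValueError(f"zero-variance effect column(s): {bad}")
    z = (s - mu) / sd
    p = 2.0 * norm.sf(np.abs(z))
    zdf = pd.DataFrame(z, index=raw.index, columns=raw.columns)
    pdf = pd.DataFrame(p, index=raw.index, columns=raw.columns)
    n_assoc = (pdf < alpha).sum(axis=1)
    return SNPEffectMatrix(s_hat=raw, z=zdf, p=pdf, n_assoc=n_assoc,
                           alpha=alpha)


def pleiotropy_chi2(
    effects: SNPEffectMatrix | pd.DataFrame,
    v: np.ndarray | None = None,
) -> SNPEffectMatrix | tuple[pd.Series, pd.Series]:
    """Multi-trait pleiotropy χ² per SNP on t degrees of freedom.

    V defaults to the correlation matrix of the z-scores over all SNPs; a
    non-invertible V is bent to the nearest PSD correlation first.  When
    called with a :class:`SNPEffectMatrix` the statistic is attached and the
    object returned; with a bare z DataFrame the (chi2, p) Series pair is
    returned.
    """
    zdf = effects.z if isinstance(effects, SNPEffectMatrix) else effects
    z = zdf.to_numpy(dtype=float)
    t = z.shape[1]
    if v is None:
        v = np.corrcoef(z, rowvar=False).reshape(t, t)
    cond = np.linalg.cond(v)
    if not np.isfinite(cond) or cond > 1e12:
        logger.warning("trait correlation matrix ill-conditioned; bending")
        v = nearest_psd_correlation(v)
        if np.linalg.cond(v) > 1e12:
            raise np.linalg.LinAlgError(
                "trait correlation matrix singular after bending")
    chi2 = np.einsum("ij,jk,ik->i", z, np.linalg.inv(v), z)
    chi2 = np.clip(chi2, 0.0, None)
    pvals = chi2_dist.sf(chi2, df=t)
    chi2_s = pd.Series(chi2, index=zdf.index, name="chi2")
    p_s = pd.Series(pvals, index=zdf.index, name="chi2_p")
    if isinstance(effects, SNPEffectMatrix):
        effects.chi2 = chi2_s
        effects.chi2_p = p_s
        effects.v_matrix = v
        return effects
    return chi2_s, p_s
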