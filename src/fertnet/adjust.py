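"""Pre-adjustment of phenotypes for non-genetic fixed effects.

Each trait is regressed (ordinary least squares, per trait on its non-missing
records) on population, year of birth and cohort as categorical effects plus
age and the first two genotype principal components as covariates; the
adjusted phenotype y* is the residual.  Cohort is modelled nested within
population.  All downstream genetic analyses consume y*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["AdjustedPhenotypes", "adjust_phenotypes", "reml_covariates"]

MIN_RECORDS = 30


@dataclass
class AdjustedPhenotypes:
    """Adjusted traits (residual scale) plus per-trait fit summaries.

    ``values`` is a DataFrame indexed by animal_id with one column per
    adjusted trait; records missing the trait remain missing.  ``summaries``
    maps trait -> dict(coefficients, r2, n).
    """

    values: pd.DataFrame
    summaries: dict[str, dict] = field(default_factory=dict)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


def reml_covariates(breed_labels: pd.Series,
                    pca: pd.DataFrame | None = None) -> pd.DataFrame:
    """Population dummies (reference level dropped) plus PC1/PC2, indexed by
    animal.  These are the contrasts the pre-adjustment removes from the
    phenotypes; passing them to the GREML fits as fixed effects keeps the
    restricted likelihood from expecting genetic variance along them.
    """
    breed_labels = pd.Series(breed_labels)
    out = pd.get_dummies(breed_labels.astype(str), prefix="population",
                         drop_first=True, dtype=float)
    if pca is not None:
        for col in ("PC1", "PC2"):
            if col in pca.columns:
                out[col.lower()] = pca[col].reindex(out.index)
    out.index.name = "animal_id"
    return out


def _design(block: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Intercept + dummy-coded categoricals (reference level dropped) +
    covariates."""
    parts = [pd.Series(1.0, index=block.index, name="intercept")]
    for name, col in (
        ("population", block["population"].astype(str)),
        ("year_of_birth", block["year_of_birth"].astype(str)),
    ):
        dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
        parts.append(dummies)
    # cohort nested within population: drop one cohort level per population
    pop = block["population"].astype(str)
    coh = block["cohort"].astype(str)
    for p in pop.unique():
        sel = pop == p
        levels = sorted(coh[sel].unique())
        for lev in levels[1:]:
            parts.append(pd.Series(
                (sel & (coh == lev)).astype(float),
                name=f"cohort_{p}/{lev}"))
    for cov in covariates:
        parts.append(block[cov].astype(float))
    return pd.concat(parts, axis=1)


def adjust_phenotypes(
    pheno: pd.DataFrame,
    pca: pd.DataFrame | None = None,
    traits: list[str] | None = None,
) -> AdjustedPhenotypes:
    """OLS-adjust each trait; return residuals y* and fit summaries.

    Parameters
    ----------
    pheno
        Phenotype table with columns ``animal_id``, ``population``,
        ``year_of_birth``, ``cohort``, ``age`` and the trait columns.
    pca
        Optional principal-component scores indexed by animal_id; the first
        two components enter as covariates.
    traits
        Trait columns to adjust; defaults to every column after ``age``.
    """
    pheno = pheno.set_index("animal_id") if "animal_id" in pheno.columns else pheno
    if traits is None:
        meta = {"breed", "population", "year_of_birth", "cohort", "age",
                "pc1", "pc2"}
        traits = [c for c in pheno.columns if c not in meta]
    covariates = ["age"]
    work = pheno.copy()
    if pca is not None:
        work = work.join(pca.rename(columns={"PC1": "pc1", "PC2": "pc2"}))
    for pc in ("pc1", "pc2"):
        if pc in work.columns:
            covariates.append(pc)

    out = pd.DataFrame(index=work.index, dtype=float)
    summaries: dict[str, dict] = {}
    for trait in traits:
        y = pd.to_numeric(work[trait], errors="coerce")
        obs = y.notna()
        n_obs = int(obs.sum())
        if n_obs == 0:
            warnings.warn(f"trait {trait}: all records missing; skipped")
            continue
        if n_obs < MIN_RECORDS:
            raise ValueError(
                f"trait {trait}: {n_obs} non-missing records "
                f"(minimum {MIN_RECORDS})")
        block = work.loc[obs]
        x = _design(block, covariates)
        xm = x.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(xm)
        if rank < xm.shape[1]:
            warnings.warn(
                f"trait {trait}: design rank {rank} < {xm.shape[1]} columns; "
                "aliased columns effectively dropped")
        beta, *_ = np.linalg.lstsq(xm, y.loc[obs].to_numpy(), rcond=None)
        fitted = xm @ beta
        resid = y.loc[obs].to_numpy() - fitted
        tss = float(np.sum((y.loc[obs] - y.loc[obs].mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0
        col = pd.Series(np.nan, index=work.index, name=trait)
        col.loc[obs] = resid
        out[trait] = col
        summaries[trait] = {
            "coefficients": dict(zip(x.columns, beta)),
            "r2": r2,
            "n": n_obs,
        }
    out.index.name = "animal_id"
    return AdjustedPhenotypes(values=out, summaries=summaries)
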