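"""Shared fixtures: one small six-breed dataset with its GRM/PCA/adjusted
phenotypes, reused (read-only) across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import fertnet as fn
from fertnet.adjust import reml_covariates


@pytest.fixture(scope="session")
def small_cfg() -> fn.SimConfig:
    return fn.SimConfig(n_per_breed=[80] * 6, m_snps=2000, n_qtl=150, seed=3)


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    return fn.make_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_grm(small_ds):
    return fn.compute_grm(small_ds.genotypes)


@pytest.fixture(scope="session")
def small_pca(small_ds, small_grm):
    return fn.compute_pca(small_ds.genotypes, 2, grm=small_grm)


@pytest.fixture(scope="session")
def small_adj(small_ds, small_pca, small_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn.adjust_phenotypes(small_ds.phenotypes, small_pca,
                                    traits=list(small_cfg.traits))


@pytest.fixture(scope="session")
def small_fixed(small_ds, small_pca):
    breeds = pd.Series(small_ds.genotypes.breed_labels,
                       index=small_ds.genotypes.animal_ids)
    return reml_covariates(breeds, small_pca)


@pytest.fixture(scope="session")
def small_breeds(small_ds) -> pd.Series:
    return pd.Series(small_ds.genotypes.breed_labels,
                     index=small_ds.genotypes.animal_ids)


def single_breed_grm(n: int, m: int, seed: int):
    """A plain single-population genotype set and its GRM, for REML tests."""
    rng = np.random.default_rng(seed)
    cfg = fn.SimConfig(n_per_breed=[n], breeds=["POP"], m_snps=m,
                       n_qtl=min(100, m), fst=0.05, seed=seed)
    geno = fn.simulate_genotypes(cfg)
    return geno, fn.compute_grm(geno)
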