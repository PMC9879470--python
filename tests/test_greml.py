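"""REML correctness (grid-search oracle), parameter recovery, GEBV algebra,
and the across-breed genomic-correlation fits."""

import warnings

import numpy as np
import pandas as pd
import pytest

import fertnet as fn
from fertnet.greml import (fit_greml, genomic_correlation_across_breeds,
                           run_all_bivariates)
from fertnet.grm import GRM, compute_grm, subset_grm

from conftest import single_breed_grm


def _toy_grm(n, seed=0, blocks=True):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, 4 * n))
    g = z @ z.T / (4 * n)
    if blocks:
        g += 0.2  # shared relatedness
    ids = np.array([f"t{i:03d}" for i in range(n)], dtype=object)
    return GRM(animal_ids=ids, values=0.5 * (g + g.T), denom=1.0,
               freqs=np.full(4 * n, 0.5), snp_ids=np.arange(4 * n).astype(object))


def _reml_ll_oracle(y, g_mat, sg, se):
    """Direct dense evaluation of the restricted log-likelihood."""
    n = len(y)
    v = sg * g_mat + se * np.eye(n)
    x = np.ones((n, 1))
    vi = np.linalg.inv(v)
    xtvx = x.T @ vi @ x
    beta = np.linalg.solve(xtvx, x.T @ vi @ y)
    r = y - x @ beta
    _, ld = np.linalg.slogdet(v)
    _, ld2 = np.linalg.slogdet(xtvx)
    return float(-0.5 * (ld + ld2 + r @ vi @ r + (n - 1) * np.log(2 * np.pi)))


def test_univariate_reml_matches_grid_search_oracle():
    grm = _toy_grm(6, seed=5)
    rng = np.random.default_rng(2)
    chol = np.linalg.cholesky(grm.values + 1e-9 * np.eye(6))
    y = chol @ rng.normal(size=6) + rng.normal(scale=0.8, size=6)
    ydf = pd.DataFrame({"T": y}, index=pd.Index(grm.animal_ids,
                                                name="animal_id"))
    fit = fit_greml(ydf, grm, min_records=6, tol=1e-10)
    sg_grid = np.linspace(1e-4, 4.0, 200)
    se_grid = np.linspace(1e-4, 4.0, 200)
    lls = [( _reml_ll_oracle(y, grm.values, sg, se), sg, se)
           for sg in sg_grid for se in se_grid]
    best_ll, best_sg, best_se = max(lls)
    step_sg = sg_grid[1] - sg_grid[0]
    step_se = se_grid[1] - se_grid[0]
    assert fit.loglik >= best_ll - 1e-6
    assert abs(fit.Vg[0, 0] - best_sg) <= step_sg
    assert abs(fit.Ve[0, 0] - best_se) <= step_se


def test_univariate_h2_recovery():
    # generating h2 = 0.5 at n=1000, m=5000: estimate within [0.38, 0.62]
    h2_hat = []
    for seed in (1, 2, 3):
        geno, grm = single_breed_grm(1000, 5000, seed)
        rng = np.random.default_rng(100 + seed)
        vals, vecs = grm.eigendecomposition()
        u = vecs @ (np.sqrt(np.clip(vals, 0, None))
                    * rng.normal(size=grm.n)) * np.sqrt(0.5)
        y = u + rng.normal(scale=np.sqrt(0.5), size=grm.n)
        ydf = pd.DataFrame({"T": y}, index=pd.Index(grm.animal_ids,
                                                    name="animal_id"))
        h2_hat.append(float(fit_greml(ydf, grm).h2[0]))
    assert 0.38 <= np.mean(h2_hat) <= 0.62, h2_hat


def test_pure_noise_trait_estimates_near_zero_h2():
    hits = 0
    reps = 10
    for seed in range(reps):
        geno, grm = single_breed_grm(600, 600, 200 + seed)
        rng = np.random.default_rng(seed)
        y = rng.normal(size=grm.n)
        ydf = pd.DataFrame({"T": y}, index=pd.Index(grm.animal_ids,
                                                    name="animal_id"))
        fit = fit_greml(ydf, grm)
        hits += fit.h2[0] <= 0.1
    assert hits >= 0.9 * reps


def test_loglik_nondecreasing_over_accepted_iterations(small_adj, small_grm,
                                                       small_fixed):
    fit = fit_greml(small_adj.values[["SHEATH"]], small_grm,
                    fixed=small_fixed)
    path = np.asarray(fit.loglik_path)
    assert np.all(np.diff(path) >= 0)
    assert fit.converged


def test_estimates_invariant_to_animal_order(small_adj, small_grm,
                                             small_fixed):
    base = fit_greml(small_adj.values[["SC", "PNS"]], small_grm,
                     fixed=small_fixed)
    rng = np.random.default_rng(0)
    perm = rng.permutation(small_grm.n)
    grm_shuffled = subset_grm(small_grm, small_grm.animal_ids[perm])
    y_shuffled = small_adj.values[["SC", "PNS"]].iloc[perm[::-1]]
    other = fit_greml(y_shuffled, grm_shuffled, fixed=small_fixed)
    assert np.abs(base.Vg - other.Vg).max() < 1e-10
    assert np.abs(base.Ve - other.Ve).max() < 1e-10
    assert abs(base.loglik - other.loglik) < 1e-10


def test_gebv_shrinkage_and_snp_blup_equivalence():
    geno, grm = single_breed_grm(200, 800, 7)
    rng = np.random.default_rng(7)
    vals, vecs = grm.eigendecomposition()
    u = vecs @ (np.sqrt(np.clip(vals, 0, None)) * rng.normal(size=grm.n))
    y = u * np.sqrt(0.5) + rng.normal(scale=np.sqrt(0.5), size=grm.n)
    ydf = pd.DataFrame({"T": y}, index=pd.Index(grm.animal_ids,
                                                name="animal_id"))
    fit = fit_greml(ydf, grm)
    gebv = fit.gebv["T"].to_numpy()
    assert gebv.var(ddof=1) <= fit.Vg[0, 0] * (1 + 1e-6)
    # independent SNP-space path: u = Z a with ridge coefficients a
    sg, se = fit.Vg[0, 0], fit.Ve[0, 0]
    keep = np.isin(geno.snp_ids, grm.snp_ids)
    z = geno.dosages[:, keep] - 2.0 * grm.freqs
    v = sg * grm.values + se * np.eye(grm.n)
    vi = np.linalg.inv(v)
    ones = np.ones((grm.n, 1))
    beta = np.linalg.solve(ones.T @ vi @ ones,
                           ones.T @ vi @ y).item()
    a = (sg / grm.denom) * (z.T @ (vi @ (y - beta)))
    u_snp = z @ a
    assert np.abs(u_snp - gebv).max() < 1e-6


def test_unphenotyped_animals_receive_gebvs(small_adj, small_grm,
                                            small_fixed):
    y = small_adj.values["WT"].copy()
    masked_ids = y.index[:50]
    y.loc[masked_ids] = np.nan
    fit = fit_greml(y.to_frame(), small_grm, fixed=small_fixed)
    assert fit.gebv.shape[0] == small_grm.n
    assert np.isfinite(fit.gebv["WT"].reindex(masked_ids)).all()
    assert fit.gebv["WT"].reindex(masked_ids).abs().sum() > 0


def test_id_mismatch_raises(small_adj, small_grm):
    y = small_adj.values[["WT"]].copy()
    y.index = ["zz" + str(i) for i in range(len(y))]
    with pytest.raises(KeyError):
        fit_greml(y, small_grm)


def test_bivariate_fit_recovers_residual_correlation(small_adj, small_grm,
                                                     small_fixed):
    # at this sample size the residual correlation is well identified while
    # the genomic correlation is noisy (its quantitative recovery is checked
    # at n=2000 in the acceptance suite); assert the robust quantities
    fit = fit_greml(small_adj.values[["DENS", "MASS"]], small_grm,
                    fixed=small_fixed)
    assert fit.converged
    assert abs(fit.re - 0.68) < 0.2  # generating value 0.68
    assert abs(fit.rg) <= 1.0
    assert np.all((fit.h2 >= 0) & (fit.h2 <= 1))
    fit2 = fit_greml(small_adj.values[["PNS", "PD"]], small_grm,
                     fixed=small_fixed)
    assert abs(fit2.re - (-0.69)) < 0.2  # generating value -0.69


def test_run_all_bivariates_summary_definitions(small_adj, small_grm,
                                                small_fixed):
    traits = ["WT", "SC", "SHEATH", "PNS"]
    fits, summary, gebv_w = run_all_bivariates(
        small_adj, small_grm, traits=traits, fixed=small_fixed)
    assert len(fits) == 6
    # diagonal = arithmetic mean of the per-pair h2 estimates
    for trait in traits:
        samples = []
        for (a, b), fit in fits.items():
            if a == trait:
                samples.append(fit.h2[0])
            elif b == trait:
                samples.append(fit.h2[1])
        assert len(samples) == 3
        assert np.isclose(summary.loc[trait, trait], np.mean(samples))
    # above diagonal rg, below re
    f = fits[("WT", "SC")]
    assert np.isclose(summary.loc["WT", "SC"], f.rg)
    assert np.isclose(summary.loc["SC", "WT"], f.re)
    # whole-data GEBV = mean over the fits containing the trait
    manual = np.mean([fits[k].gebv["PNS"].reindex(gebv_w.index).to_numpy()
                      for k in fits if "PNS" in k], axis=0)
    assert np.allclose(gebv_w["PNS"].to_numpy(), manual)


def test_independent_traits_yield_near_zero_rg():
    # h2 = 0.5 for every trait keeps each genomic correlation identified;
    # with the identity generating matrices all 45 estimates are null
    cfg = fn.SimConfig(n_per_breed=[400, 400], breeds=["A", "B"],
                       m_snps=1200, n_qtl=150, rg=np.eye(10),
                       re=np.eye(10), h2=np.full(10, 0.5), seed=17)
    ds = fn.make_dataset(cfg)
    grm = compute_grm(ds.genotypes)
    pca = fn.compute_pca(ds.genotypes, 2, grm=grm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adj = fn.adjust_phenotypes(ds.phenotypes, pca,
                                   traits=list(cfg.traits))
        breeds = pd.Series(ds.genotypes.breed_labels,
                           index=ds.genotypes.animal_ids)
        fixed = fn.adjust.reml_covariates(breeds, pca)
        _, summary, _ = run_all_bivariates(adj, grm, fixed=fixed)
    rgs = summary.to_numpy()[np.triu_indices(10, k=1)]
    assert np.nanmedian(np.abs(rgs)) < 0.1


@pytest.fixture(scope="module")
def across_breed_shared():
    """Two breeds with identical QTL effects (true across-breed rg = 1)."""
    cfg = fn.SimConfig(n_per_breed=[800, 800], breeds=["A", "B"],
                       m_snps=3000, n_qtl=200, rg_across_breeds=1.0, seed=31)
    ds = fn.make_dataset(cfg)
    grm = compute_grm(ds.genotypes)
    pca = fn.compute_pca(ds.genotypes, 2, grm=grm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adj = fn.adjust_phenotypes(ds.phenotypes, pca,
                                   traits=list(cfg.traits))
    breeds = pd.Series(ds.genotypes.breed_labels,
                       index=ds.genotypes.animal_ids)
    return adj, grm, breeds


def test_across_breed_rg_recovery_at_upper_boundary(across_breed_shared):
    adj, grm, breeds = across_breed_shared
    est = genomic_correlation_across_breeds("SHEATH", "A", "B", adj, grm,
                                            breeds)
    assert est.converged
    assert est.rg_across >= 0.7


def test_across_breed_null_rg_stays_small():
    hits = 0
    reps = 5
    for seed in range(reps):
        cfg = fn.SimConfig(n_per_breed=[400, 400], breeds=["A", "B"],
                           m_snps=2000, n_qtl=200, rg_across_breeds=0.0,
                           seed=600 + seed)
        ds = fn.make_dataset(cfg)
        grm = compute_grm(ds.genotypes)
        pca = fn.compute_pca(ds.genotypes, 2, grm=grm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adj = fn.adjust_phenotypes(ds.phenotypes, pca,
                                       traits=list(cfg.traits))
        breeds = pd.Series(ds.genotypes.breed_labels,
                           index=ds.genotypes.animal_ids)
        est = genomic_correlation_across_breeds("SHEATH", "A", "B", adj,
                                                grm, breeds)
        hits += abs(est.rg_across) <= 0.25
    assert hits >= 0.8 * reps


def test_across_breed_requires_enough_records(small_adj, small_grm,
                                              small_breeds):
    tiny = small_breeds.copy()
    tiny.iloc[10:] = "OTHER"  # leaves < 30 animals labelled BRM
    with pytest.raises(ValueError):
        genomic_correlation_across_breeds("WT", "BRM", "OTHER",
                                          small_adj, small_grm, tiny.iloc[:40])
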