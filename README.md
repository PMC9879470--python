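# fertnet

Multi-breed genomic prediction and gene co-association networks for bull
fertility traits.

In tropical beef systems most herds are naturally mated, so identifying
fertile bulls early matters for both productivity and genetic progress. No
single breed offers a reference population large enough for accurate
genomic prediction of fertility, which motivates pooling breeds — and
raises two questions this package addresses end-to-end: *how well do
genomic breeding values (GEBVs) transfer across breeds?* and *which genes
drive the co-association of fertility traits?*

`fertnet` is written for quantitative geneticists who want the full
analysis chain as tested, reusable code, exercised on a synthetic
multi-breed population whose generating values are the study-scale
parameter estimates for ten bull fertility traits (body weight WT,
condition COND, scrotal circumference SC, sheath score SHEATH, and the
semen traits DENS, MASS, MOT, PNS, PD, MP).

## The models in brief

* **Genomic relationships**: G = ZZᵀ/(2Σpⱼ(1−pⱼ)), Z the allele-dosage
  matrix centred at 2pⱼ (VanRaden Method 1); population structure from the
  top principal components of Z.
* **Genetic parameters**: bivariate GREML, y* = Xβ + u + e with
  cov(u) = Σg ⊗ G, fitted by average-information REML (O(n) iterations in
  the GRM eigenbasis). One fit per trait pair (45 in all); each trait's
  heritability is reported as the mean over its nine fits. The same
  machinery, with the trait split by breed and zero residual covariance,
  estimates across-breed genomic correlations.
* **Validation (LR method)**: whole- vs partial-data GEBVs give
  ACC_LR = √(cov(û_w, û_p)/((1+F̄−2f̄)σ²g)), Bias_LR = mean(û_p)−mean(û_w),
  Disp_LR = 1 − cov(û_w, û_p)/var(û_p), under leave-one-breed-out and
  within-breed 5-fold schemes, plus the classical ACC_R = cor(û_p, y*)/√h².
* **Functional step**: SNP effects backsolved as ŝ = λMᵀG⁻¹û_w (λ = 0.85),
  z-scored, tested, and summarised per SNP by the pleiotropy statistic
  χ² = zᵀV⁻¹z on 10 df; SNPs anchored to genes within 10 kb form the
  association weight matrix (AWM), whose row–row correlations are pruned by
  the PCIT algorithm into a signed gene co-association network.
* **Prioritization**: transcription factors ranked by network degree,
  pleiotropy χ² and sperm-expression abundance; any top-10 rank selects the
  gene. Family enrichment uses the exact hypergeometric upper tail.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The `analysis/` scripts run the whole narrative on a 720-bull, 3,000-SNP
demonstration dataset (six breeds × 120, half-sib families of 8):

```bash
python analysis/01_simulate_dataset.py
python analysis/02_population_structure.py
python analysis/03_genetic_parameters.py
python analysis/04_across_breed_correlations.py
python analysis/05_validation.py
python analysis/06_snp_effects_network.py
python analysis/07_prioritize_genes.py
```

Selected output from an actual run:

```
PC1-PC2 silhouette on breed labels: 0.728 (positive = breeds form distinct clusters)

per-trait |h2 - generating value|:
  WT      est 0.35  generating 0.37  |err| 0.02
  SHEATH  est 0.50  generating 0.57  |err| 0.07
  PNS     est 0.22  generating 0.24  |err| 0.02

scheme 1: mean ACC_R 0.181  mean ACC_LR 0.218  mean bias +0.0029  mean disp -0.012
scheme 2: mean ACC_R 0.340  mean ACC_LR 0.331  mean bias -0.0017  mean disp -0.119
per-trait ACC_LR gain from having the breed in the reference
(scheme2 - scheme1): +0.114 on average, 10/10 traits positive

AWM: 28 SNP-genes (26 key-trait, 2 pleiotropic; N_PNS = 2.35)
PCIT network: 28 genes, 354 significant edges

trait clusters of the selected genes' co-association profiles:
  cluster 1: PD, MP
  cluster 2: WT, COND, SC, SHEATH, DENS, MASS, MOT, PNS
```

Reading this: the six breeds separate cleanly on two PCs; the 45 bivariate
fits recover the generating heritabilities at demo scale; GEBV accuracy
drops on every trait when the validated breed is absent from the reference
while the LR bias stays at zero; and the co-association profiles of the
prioritised genes split the sperm-defect traits (PD, MP, where lower is
better) from the remaining traits.

The same pipeline is scriptable through a config file:

```bash
fertnet run --config config.yaml --seed 7 --outdir my_run
```

with subcommands (`simulate`, `grm`, `adjust`, `greml`, `validate`,
`snpfx`, `awm`, `pcit`, `prioritize`) that execute the pipeline up to that
stage, resuming from persisted artefacts; `manifest.json` records a SHA-256
hash of every output, identical across reruns at the same seed.

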