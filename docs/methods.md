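# Methods

`fertnet` re-implements, as a tested pipeline on synthetic data, a
multi-breed genomic analysis of bull fertility: genomic relationship
matrices and population structure, bivariate GREML genetic parameters and
genomic breeding values (GEBVs), LR-method cross-validation of predictions,
SNP-effect backsolving with a multi-trait pleiotropy test, an association
weight matrix (AWM) feeding PCIT network inference, and a three-way
prioritization of transcription factors. This note records the models, the
parameter choices, and the places where the design was genuinely open.

## The synthetic study

The real study population (six tropically adapted breeds, ten
fertility-related traits, imputed high-density genotypes) is not publicly
deposited, so every analysis here runs on a generator
(`fertnet.simulate`) that reproduces the statistical structure the
downstream methods rely on:

**Genotypes.** Ancestral allele frequencies are uniform on (0.05, 0.95).
Each breed's frequencies follow the Balding–Nichols model,
Beta(p(1−F)/F, (1−p)(1−F)/F) with divergence F (default Fst = 0.15, the
order of divergence among indicine-influenced beef breeds); dosages are
Binomial(2, breed frequency). Loci are independent — there is no linkage
disequilibrium, so a 10 kb gene window is an annotation device here, not an
LD model. An optional first-order autocorrelation of adjacent ancestral
frequencies (`ld_rho`) exists for sensitivity checks. SNPs monomorphic
pooled over all animals are resampled once, then dropped (the GRM
denominator must stay positive). Optionally each breed is organised into
paternal half-sib families (`half_sib_family_size`): one gamete from a
shared sire, one from the breed pool, giving within-family additive
relationships of ~0.25. The default is unrelated animals; the validation
experiments use families of 10 because within-breed relatives are exactly
what distinguishes within-breed from across-breed prediction.

**Traits.** `n_qtl` causal SNPs (default 400) are drawn among SNPs within
10 kb of a gene. Their effect vectors across the ten traits are multivariate
normal with the study's reported genetic-correlation matrix; the draw is
recoloured so the sample covariance equals the target exactly, and each
trait's realised breeding-value variance is rescaled to equal its target
heritability exactly (phenotypic variance 1). Residuals are likewise
recoloured to the reported residual-correlation matrix, scaled to 1−h².
The reported correlation tables are assembled from pairwise bivariate fits
and need not be jointly positive semidefinite, so both matrices are bent by
eigenvalue truncation at 1e-8 and rescaled to unit diagonal before use.
Fixed effects of population, year of birth, cohort (nested within
population, SD 0.3 each) and an age covariate (uniform within breed-specific
windows spanning roughly 360–700 d, contributing SD 0.2) are added on top.
All ten traits are Gaussian on a standardized scale; the real score traits
(1–5) are ordinal, which the GREML analysis ignores anyway. An optional
`rg_across_breeds` < 1 mixes a shared and a breed-specific effect component
so that the QTL effect vectors of two breeds correlate at the requested
value (1 = fully shared, the default; 0 = independent backgrounds). This
exercises the across-breed correlation estimator at known truth, but note
that values < 1 deliberately violate the single-G GREML model, which then
underestimates the multi-breed genetic variance — see the validation
discussion below.

**Annotations.** Genes are tiled deterministically and non-overlapping along
each chromosome at `gene_density` per Mbp. The default density (10/Mbp) is
chosen so the gene:SNP ratio matches the real panel (~27.6k genes per 680.8k
SNPs) on the miniature simulated genome (1 SNP per 4 kb, chromosome lengths
scaled to the SNP count), rather than matching real genes-per-Mbp, because
every downstream step cares about that ratio and not about physical length.
A configurable number of genes is flagged as transcription factors and one
family of 25 genes is labelled for the enrichment test. Sperm expression is
log-normal (log-mean 1, log-SD 1), with a configurable fraction of
causal-adjacent genes boosted by a multiplicative factor (default 3), so
expression carries signal about causal loci without being deterministic.

Each generator stage draws from its own RNG stream derived from the master
seed, so stages can be regenerated independently, and the whole dataset is
byte-identical across reruns after serialization.

What the generator does **not** emulate: linkage disequilibrium and its
across-breed differences, genotyping/imputation error, selection,
ascertainment of the SNP panel, non-Gaussian trait scales, repeated
records, and maternal pedigree. Passing tests therefore demonstrate the
estimators' behaviour under a clean additive model — not their robustness
to the real data's complications.

## Genomic relationships and structure

G = ZZᵀ / (2Σpⱼ(1−pⱼ)) with Z the dosage matrix centred at 2pⱼ (VanRaden
Method 1). Frequencies default to the observed pooled frequencies of the
analysis set; within-breed GRMs are built by subsetting the genotypes first.
Note that observed-frequency centering makes G exactly singular (G·1 = 0);
everywhere G itself must be solved (SNP backsolving) a ridge of
1e-6 × mean diagonal is added after a Cholesky pivot check — harmless
because GEBVs are exactly orthogonal to the null direction. Principal
components are eigenvectors of G scaled by root eigenvalues, with each
component's sign fixed so its largest-magnitude SNP loading is positive.
X-chromosome SNPs are treated like autosomes (dosage 0/1/2), a documented
simplification.

## Pre-adjustment and the REML fixed effects

Each trait is pre-adjusted by OLS on population, year of birth, cohort
(nested within population), age, and PC1/PC2, per trait on its non-missing
records; the adjusted phenotype y* is the residual.

The GREML model is y* = Xβ + u + e with cov(u) = Σg ⊗ G, cov(e) = Σe ⊗ I.
X is an intercept by default, but the pipeline passes the population dummies
and PC1/PC2 back in as fixed covariates. The reason is structural: the
pre-adjustment removes the between-breed contrasts from y*, while the
multi-breed G retains huge eigenvalues exactly along those contrasts. A
purely random model then sees directions where it predicts variance σ²g·d
(d ≈ 25 at six breeds, Fst 0.15) but observes none, and that penalty drives
σ̂²g to zero regardless of sample size. Projecting the same contrasts out of
the restricted likelihood (the classical lost-degrees-of-freedom correction
for pre-adjusted data) restores consistent within-breed estimates. This is
the package's own choice; fitting without covariates remains available.

## AI-REML

Average-information REML with step-halving and, when the AI step fails, a
line-searched gradient step. Convergence at |Δlog L| < 1e-8 or 200
iterations; proposed variances are floored at 1e-8 × phenotypic variance
and covariances capped at |r| = 0.999. Balanced fits (all traits observed
on the same animals) work in the GRM eigenbasis, cached on the GRM object,
making each iteration O(n) — this is what lets 45 bivariate fits at n=2000
run in seconds. Arbitrary missingness (and the across-breed fits, where the
two "traits" live on disjoint animals and the residual covariance is
structurally unidentifiable and fixed at 0) uses a dense-covariance path
with one Cholesky per iteration. Correctness is pinned by a brute-force
grid search of the restricted likelihood on toys, and estimates are made
exactly invariant to animal ordering by sorting animals internally.

GEBVs come from the mixed-model equations at the converged components and
are produced for unphenotyped animals through their genomic relationships.
Per-trait reported heritability is the average over the nine bivariate fits
containing the trait, and the whole-data GEBV per trait is likewise the
average over those nine fits' GEBVs (the same averaging logic, applied to
predictions).

## Validation and Method LR

Scheme 1 is leave-one-breed-out (one fold per breed); scheme 2 partitions
every breed into five random 20% folds. Whole-data and partial-data
univariate fits are compared on the validation animals of each breed:

* ACC_R = cor(û_p, y*)/√h² (can exceed 1; that is a property of the
  estimator, demonstrated in the tests);
* ACC_LR = √( cov(û_w, û_p) / ((1 + F̄ − 2f̄)·σ²g) ), with F̄ the mean
  diagonal of the validation G-block minus 1, 2f̄ the mean off-diagonal
  (self-pairs excluded — the averaging set is a documented choice), and σ²g
  the additive variance from the partial fit. The square root is applied
  because the covariance ratio estimates the *squared* accuracy; the
  source formula prints the ratio without the radical, which we read as a
  typesetting loss;
* Bias_LR = mean(û_p) − mean(û_w); Disp_LR = 1 − cov(û_w, û_p)/var(û_p).

A negative covariance leaves ACC_LR undefined (reported missing, not 0);
a numerically zero var(û_p) (partial fit at the variance floor) leaves the
dispersion undefined. Under random scheme-2 folds on unselected data the
fold-mean bias and dispersion are centred on zero; dispersion carries a
small negative finite-sample bias (the ratio's denominator is estimated
from a few dozen animals per cell), visible but within the Monte-Carlo
band at the sizes used here.

The scheme-1 < scheme-2 accuracy ordering requires within-breed information
that does not transfer across breeds. With unrelated animals and fully
shared QTL effects the two schemes are indistinguishable (SNP effects
transfer perfectly when there is no LD), so the validation experiments
simulate paternal half-sib families of 10: scheme 2's reference then
contains relatives of every validation animal, scheme 1's does not, and the
ordering emerges on every trait while the model stays correctly specified.
Weakening effect sharing instead (rg_across_breeds < 1) reproduces the
ordering in *true* accuracy but misspecifies the single-G model, making
σ²g,partial scheme-dependent and the LR accuracy unstable — an instructive
failure mode, not a usable study condition.

The metric-level ANOVA fits metric ~ h² (partial-fit estimate, a covariate
that varies by fold/breed) + breed + trait (+ fold where present) by OLS
and reports R² and per-factor F-tests.

## SNP effects, AWM, PCIT

Backsolving: ŝ = λ Mᵀ G⁻¹ û_w per trait with λ = 0.85 (the assumed ratio of
SNP variance to genetic variance, exposed as a knob) and M the centred
dosage matrix underlying G. Effects are z-scored per trait over all SNPs;
two-sided p-values come from the standard normal. The pleiotropy statistic
is χ²ᵢ = zᵢᵀV⁻¹zᵢ on t degrees of freedom with V the trait × trait
correlation of the standardized effects computed over **all** SNPs (not
only selected ones), bent to the nearest PSD correlation if
ill-conditioned.

AWM: SNPs are anchored to every gene whose body ±10 kb covers them. One
representative SNP per gene: smallest key-trait (percent normal sperm)
p-value, ties broken by larger association count, then smaller position. A
gene enters if its representative is key-trait associated (p < 0.01), and
the remaining genes enter if associated with strictly more traits than
N_PNS, the (real-valued) mean association count of the key-trait genes —
the strict inequality is pinned by a hand-evaluated toy in the tests.

PCIT: Pearson correlations across AWM rows (over the ten trait columns);
for every trio the three first-order partial correlations are computed, the
local tolerance is the mean ratio of partial to direct correlation, and an
edge is discarded when some third gene dominates it through both of its
sides. The implementation is vectorised over the conditioning gene and is
verified edge-for-edge against an exhaustive-trio brute force on random
inputs. Pairs with |r| = 1 are kept and their trios skipped; with fewer
than three genes every nonzero correlation is kept.

## Prioritization

TFs in the network are ranked (competition ranking, ties share the minimum
rank) by degree, pleiotropy χ² and sperm-expression abundance; a TF is
selected when it is top-10 in at least one criterion, so the selection can
exceed 10. Missing expression counts as abundance 0. Family enrichment is
the exact hypergeometric upper tail P(X ≥ k), computed by integer
summation (an exact, hence conservative, discrete test: its attainable size
is just below the nominal level, which the calibration test accounts for).
Profiles of selected genes are clustered with 1 − Pearson distance and
average linkage on both axes, with a 2-cluster cut per axis (the tallest
merge); constant profiles get their own cluster. Rows are sorted by id
before clustering so the partition is independent of input order.

## Problem sizes

The acceptance script re-runs everything from scratch at: 30 replicates of
n=2000 / m=5000 for parameter recovery; one six-breed experiment of
n=900 / m=3000 with half-sib families for the validation schemes; 50 random
20-gene AWMs for the PCIT oracle; 20,000 null SNPs for the χ² calibration.
The unit-test suite repeats the same experiments at reduced replicate
counts and sizes with identical tolerances. The demonstration dataset under
`analysis/` uses 720 bulls and 3,000 SNPs so the full narrative runs in
about a minute; at that size individual genomic correlations are noisy
(across-breed estimates can pin at ±1), which the scripts state where it
occurs.

## Known limitations

* No LD: gene anchoring and "functional variant" language are structural
  stand-ins; nothing here validates fine-mapping resolution.
* The across-breed correlation estimator is weakly identified below a few
  hundred animals per breed; estimates pile at the ±1 bound.
* Heritability recovery is quoted for the multi-breed design with the
  adjustment covariates passed to the REML; omitting them reintroduces the
  between-breed penalty described above.
* The LR accuracy assumes the fitted covariance model is correct; under
  breed-heterogeneous genetic backgrounds its σ²g denominator becomes
  scheme-dependent and comparisons across schemes lose meaning.
* Score traits are simulated Gaussian; ordinal-scale effects (floor/ceiling,
  probit-style thresholds) are untested.
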