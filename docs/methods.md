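# Methods

This note documents the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## Preprocessing

Raw untargeted intensities are assumed nonnegative with missing values
arising from detection limits (left censoring). `scale_impute` rescales each
metabolite so the median of its *detected* values is 1, then imputes missing
cells with the metabolite's post-scaling minimum detected value — the
standard vendor convention for left-censored peak intensities. Metabolites
are kept only if their identity is known and they are detected in at least
80% of the adenoma + control samples (the carcinoma group never influences
the filter, so the discovery set is fixed before the follow-up analyses);
prevalence comparisons use ≥ at the threshold. Retained profiles are log₁₀
transformed.

Genus relative abundances use a looser ≥ 20% prevalence cut (microbiome
data are much sparser) and the arcsine square root transform asin(√x), the
usual variance stabilizer for proportions.

Pathways are a two-level hierarchy (superpathway → subpathway). A pathway
enters the PERMANOVA set if it has ≥ 5 members among the retained
metabolites. For the correlation screens each subpathway is summarized by
the first principal component of its column-centered member matrix,
retained only when PC1 explains **more than** 20% of the member variance
(strict inequality, versus the inclusive prevalence cuts — both read off
the respective "at least"/"more than" rules). Because an eigenvector's sign
is arbitrary, PC1 is anchored: if its scores correlate negatively (Pearson)
with the per-sample mean member intensity the axis is flipped, so higher
PC1 always reads as higher average intensity; an exactly zero correlation
leaves the sign unchanged. PCA here is centered but not variance-scaled:
inputs are already median-scaled and log-transformed, so features share a
scale and scaling would only amplify noise in flat features.

## Distances and ordinations

Metabolome: Euclidean distances and centered PCA. Microbiome: unweighted
UniFrac (presence = count > 0; computed via scikit-bio) and principal
coordinate analysis by Gower centering (−½ J d² J) and eigendecomposition.
Negative PCoA eigenvalues are reported but excluded both from the returned
axes and from the variance-explained denominator; no Cailliez/Lingoes
correction is applied, as UniFrac distances here are close to
Euclidean-embeddable and a correction would change every axis for the sake
of a tiny negative tail. Both PCA and PCoA fix each axis's sign so that the
largest-magnitude sample coordinate is positive; leading-axis correlations
are therefore reproducible, but their *sign* is still a convention, so
coupling results report |ρ| alongside signed ρ.

## PERMANOVA

Implemented from the Gower matrix G: for a hat matrix H of a design, the
explained sum of squares is tr(HG). Three decompositions:

- **marginal** — each factor alone; R² = SS_f / SS_total;
- **adjusted** — each factor's drop-one SS in the full model,
  SS_f = tr(H_full G) − tr(H_−f G), order-invariant (equivalent to vegan's
  `adonis2(..., by="margin")`, against which the implementation is tested);
- **sequential** — factors added in order (`by="terms"`), provided for
  completeness and documented as order-dependent.

The adjusted mode is the default reading of "a model adjusted for all
factors": it is order-invariant and produces one number per factor.
P-values use free permutation of sample labels with the bias-corrected
estimator (1 + b)/(1 + B), so p ∈ (0, 1] always. Pathway-level tests reuse
one permutation stream and one pair of hat matrices across all pathway
distance matrices, which makes 999 permutations over dozens of pathways
cheap (einsum over the stacked Gower matrices).

The unrecorded-smoking level is kept as an explicit factor level by default
(preserving all samples); a complete-case option exists. For the
cohort-matching Fisher test the same convention applies — keeping the
missing row reproduces the published demographic p-value for smoking
(0.340), whereas complete-case analysis gives 0.269.

## Per-metabolite permutation F-test

The statistic is the partial F comparing group + covariates against
covariates only. Under the default **Freedman–Lane** scheme the reduced-
model residuals are permuted; because the reduced fitted values lie inside
both model spaces, both residual sums of squares of the permuted response
depend only on the permuted residual matrix, which makes the test fully
vectorizable over metabolites (two Q'E products per permutation for the
whole matrix). A raw-label scheme (permute y directly) is provided; under
exchangeable nulls the two agree, and both are exposed because the choice
is genuinely open in this design. Direction of a hit is the sign of the
adjusted group coefficient. The permutation count for per-feature tests
defaults to 9999 (their p-values feed an FDR procedure and benefit from
resolution); multivariate tests default to 999.

## Multiple testing

Storey q-values estimate π₀ from π̂₀(λ) = #{p > λ}/(m(1 − λ)) on the grid
λ = 0.05, 0.10, …, 0.95, smoothed by a least-squares natural cubic spline
with 3 degrees of freedom and read off at λ = 0.95, clipped to (0, 1];
q-values are the usual step-up cumulative minima of π₀·m·p/rank. With π₀
fixed at 1 the procedure reduces exactly to Benjamini–Hochberg (tested
against statsmodels), and with fewer than 10 p-values it falls back to
π₀ = 1 with a warning. Bonferroni adjustment accepts a family size larger
than the supplied vector (the screens adjust over the full genus × target
grid even when only a subset is reported).

BH families for the pathway tests are per level (superpathways separately
from subpathways): the minimal reading consistent with reporting q < 0.1 at
each level. The carcinoma re-test adjusts only across the adenoma-hit
subpathways, deliberately shrinking the burden for the small carcinoma
group.

## Exact r × c Fisher test

Two-sided p by the probability-ordering rule: enumerate every table with
the observed margins (rows in ascending margin order; the last row is
forced), accumulate the multivariate-hypergeometric probabilities of tables
no more probable than the observed one, with a relative tie tolerance of
1e-12. Above a configurable enumeration cap the test falls back to
margin-preserving Monte Carlo (Patefield sampling via scipy), flagged in
the result. The published demographic tables need between ~3 × 10³ (sex)
and ~1.4 × 10⁶ (age) tables and enumerate in well under 10 s each.

## Coupling statistics

RV = tr(XᵗY YᵗX)/√(tr((XᵗX)²)·tr((YᵗY)²)) on column-centered coordinate
blocks, with row-permutation significance (coinertia). Symmetric
Procrustes: both configurations centered and scaled to unit sum of squares,
optimal rotation from the SVD of YᵗX, m² = 1 − (Σσ)², correlation
= √(1 − m²) (so corr² + m² = 1 exactly), protest-style row permutation.
By default all positive-eigenvalue axes enter; the analysis drivers use the
10 leading axes of each block, a choice that keeps the permutation loops
fast while capturing the dominant structure, and the axis count is a
parameter everywhere.

## Synthetic cohort generator

The generator is the package's test bed; its defaults are the study
conditions the pipeline is designed for.

*Metadata.* 102/102/36 control/adenoma/carcinoma samples. Age, sex and race
are drawn i.i.d. from the cohort's marginal proportions independently of
group — the definition of frequency matching — and smoking independently
with its cohort rate; exactly one control has an unrecorded smoking
history.

*Metabolome.* log₁₀ intensity = baseline (N(6, 0.5), i.e. raw intensities
~10⁶) + a subpathway factor (per-sample N(0,1) scaled by ~0.4, giving
within-pathway correlation so subpathway PC1s are meaningful) + planted
effects + latent term + N(0, 0.25) noise. 24 planted differential
metabolites at log₁₀ effect 0.3, concentrated in 5 perturbed subpathways
(~4 each) with the rest scattered; one planted effect is negative, the
rest positive. Carcinoma samples receive 0.6 × the adenoma effect
(attenuation along the adenoma–carcinoma sequence); per-subpathway
overrides allow persistence scenarios. 30 sex-affected metabolites at
effect 0.4 (calibrated so sex explains ~1.4% of overall variance, slightly
more than group at ~0.9%, matching the cohort the generator emulates);
about a quarter of them overlap the differential set. Missingness is
MNAR: each feature has a detection threshold at a quantile of its own
intensity distribution (most features ~90–100% detected, a 22% tail at
10–75%), which is what makes minimum-value imputation the appropriate
inverse. 12% of features carry no identity/pathway annotation.

*Microbiome.* A random rooted bifurcating tree (successive random joins,
exponential branch lengths) over 300 OTUs in three strata: an abundant
always-present core (40%), a coupled block (55%) of rarer taxa whose
log-abundance — and therefore presence/absence, which is all unweighted
UniFrac sees — shifts along the latent factor, and a thin rare-noise tail.
Counts are Dirichlet-multinomial (depth 20 000, concentration 400) and are
summed over a random OTU→genus map into 100 genera.

*Coupling.* A shared latent factor t drives the microbiome block; the
metabolome follows its own latent t_m = ρ_m·t + √(1 − ρ_m²)·u. Each
block's leading ordination axis tracks its own latent tightly (the
coupled-OTU loading scale 0.85 keeps the UniFrac gradient firmly on PCo1,
|ρ| ≈ 0.89 with t; the metabolite latent loadings N(0, 0.25) put PC1 on
t_m at |ρ| ≈ 0.99), so the realized PCo1–PC1 correlation is ρ_m times an
axis-fidelity product calibrated by simulation at 0.855. The requested
target (default 0.68) is divided by this constant to set ρ_m; realized
values average 0.68 ± 0.06 across seeds. This two-latent construction was
chosen over a single shared factor after simulation showed the
single-factor variant either saturated the correlation or destabilized it
(PCo1 swapping with noise axes at intermediate coupling strengths).

*What it does not emulate.* Mass-spectral artifacts (adducts, isotopes,
run-day batches — the vendor normalization is emulated only through its
output, median-scaled intensities), compositional genus correlations beyond
the shared multinomial denominator, strain-level structure, and any real
phylogenetic signal in which taxa couple to the metabolome. Passing
recovery tests therefore demonstrate that the statistics find what the
generative model plants under realistic sizes/noise — not that they would
find every signal type in real data.

## Problem sizes and runtime conventions

The test suite runs reduced cohorts (40/40/14, 150–200 metabolites) for
unit-level checks and the full 102/102/36 configuration for the recovery
suite (20 seeds, 999 feature permutations, 199 multivariate permutations —
the recovery metrics depend on the feature-level tests, so the multivariate
permutation count is kept modest there). The acceptance script uses 6
seeded replicates at full scale with the same permutation settings, and 10
ordination axes for the RV/Procrustes statistics. All randomness flows from
`numpy.random.SeedSequence` spawns of a single seed; identical
(data, config, seed) triples give identical results to the byte.

## Known limitations

- PERMANOVA permutations are free (unrestricted); blocked/restricted
  designs are out of scope.
- The adjusted decomposition's term sums of squares need not add to the
  total for non-orthogonal designs (they are drop-one quantities); the
  sequential mode provides an exact decomposition when one is needed.
- Spearman p-values use the t approximation (adequate for n ≥ ~36 as
  here); an exact-permutation option exists for n ≤ 9.
- The Monte Carlo Fisher fallback yields a simulation estimate with its
  own error (~(p(1−p)/B)^½); the enumeration cap is set high enough that
  all tables in this workflow enumerate exactly.
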