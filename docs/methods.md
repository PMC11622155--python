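# Methods

`geascan` implements a complete genotype–environment association (GEA)
workflow for populations sampled along environmental gradients — the
setting is estuarine seagrass meadows genotyped with a
reduced-representation SNP assay — ending in a climate-adjusted
"donor registry" that matches each meadow to a source population whose
current conditions already resemble the meadow's projected future. This
note records the models, the defaults and why they are set where they
are, what the synthetic data does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Genotype model and synthetic data

Genotypes are biallelic SNP calls coded 0/1/2 against the locus's
reference allele, with a reserved sentinel for no-calls. The generator
(`geascan.simulate`) draws ancestral allele frequencies Uniform(0.05,
0.95) — so minor-allele-frequency filters have realistic work to do — and
per-deme frequencies from the Balding–Nichols beta model
p_i ~ Beta(p(1−F)/F, (1−p)(1−F)/F), giving a single F_ST knob; diploid
calls are independent Binomial(2, p_deme) draws. Adaptive structure is
planted by shifting deme frequencies at chosen loci along a standardized
deme-level covariate z: p → logit⁻¹(logit(p) + βz). Standardizing the
covariate makes β comparable across variables with different units; β = 2
on the logit scale is a strong but not deterministic cline (a deme one
standard deviation warmer shifts a 0.5-frequency locus to 0.88).

Degradation mirrors the artefacts of a real panel: independent
missingness at a target rate (default study condition 20%), technical
replicate pairs whose calls are flipped to a different valid call with a
small probability (0.2% by default, safely below the 0.9% bitwise-distance
error threshold used to vet replicates), and clonal duplicates (exact
copies). Per-locus call-rate metadata is recomputed after degradation;
reproducibility and mean read depth are *drawn* (concentrated near 1, and
log-normal around ~7×, respectively), not simulated from reads — the
generator makes no sequence-level claims. The deposited study panel
reports its mean read depth with a percent sign (7.07%); it is treated
here as 7.07× since depth is a count.

The default study-scale configuration is 13 demes of ~26 individuals and
a few thousand loci at F_ST ≈ 0.05, with the shipped 13-meadow × 9-variable
NSW environmental table (`load_nsw_env_table()`) providing site names and
covariates. What the generator does **not** emulate: linkage between
loci, clonal somatic variation, site-level heterogeneity in missingness
or depth, and within-meadow environmental variation (every individual
carries its site's value). Tests passing on this synthetic panel show the
machinery is calibrated and recovers planted structure; they do not show
that any particular real dataset satisfies the model's assumptions.

## Quality control

Filters run sequentially in a fixed order — locus call rate ≥ 0.67,
individual call rate ≥ 0.25, locus reproducibility ≥ 0.99, mean depth in
[2, 50], minor-allele frequency ≥ 0.01 — with locus call rates
recomputed after the individual filter and MAF computed over the
retained individuals, mirroring a sequential pipeline. The underlying
toolchains do not enforce an order, so the order here follows the one in
which the thresholds are conventionally described; the QC report records
per-step retention so order sensitivity is visible. Loci with unknown
(NaN) reproducibility or depth metadata pass those filters rather than
being discarded.

Bitwise distance between individuals counts genotype-state differences
over jointly non-missing loci; "proportion of allelic differences" is
ambiguous between state- and allele-level counting, so a `per_allele`
flag offers the halved het/hom weighting. Nearest-neighbour imputation
searches globally (not within meadows), breaks ties toward the lowest
individual index, and falls through to the next-nearest individual when
the nearest lacks a call at the target locus. Clonal ramets are
deliberately *not* removed before outlier scans — in largely clonal
organisms the ramets carry much of the standing adaptive variation — but
`dedup_clones` exists for analyses that need Hardy–Weinberg assumptions.

## Environmental predictors

Raw water-quality series are restricted to the warm-season sampling
window (October–April) and daylight hours (06:00–18:00 local clock; the
window is configurable since "daylight" is not defined more precisely in
the source datasets), collapsed to daily means, and summarised as
mean/min/max/range. Annual rates of change are the slopes of Gaussian
identity-link fits of monthly means on time in years. One caveat worth
recording: a seasonal cycle is not orthogonal to time over a finite
window, so rate estimates from short full-year series absorb a
phase-dependent bias; the warm-season window brackets the austral
seasonal peak roughly symmetrically, which largely decouples the cycle
from the trend (the `03_environment` driver demonstrates recovery of a
planted +0.2 °C yr⁻¹ trend to within ~0.02).

Collinearity pruning is greedy: among the worst-offending pair with
|Pearson r| above the threshold (default 0.7), the member with the larger
mean absolute correlation to all other predictors is dropped —
deterministic and standard practice. A variance-inflation check
(VIF = 1/(1−R²), default threshold 10, the conventional cutoff since none
is stated in the source material) iteratively removes the largest
offender. The shipped nine-variable table is the already-pruned predictor
set; the exact 20 → 9 drop sequence used originally is not reproduced,
only the mechanism.

## Ancestry structure

The sparse-NMF fit factorises the dosage matrix G/2 into admixture
proportions Q (rows projected onto the probability simplex after each
update) and ancestral frequencies F (clipped to [0, 1]) by alternating
weighted least squares, masking missing entries. This is a least-squares
surrogate for the original tool's solver; its role in the pipeline is
only to pick the number of latent populations K and hand it to the
latent-factor scan, for which the surrogate is sufficient. The ridge term
penalises the *mean* per-locus loading norm (effective per-locus penalty
α/n_loci, α = 10 by default): scaling the penalty this way keeps it mild
at any panel size, matching the regime of the original tool's default —
a raw ‖F‖² penalty makes the effective shrinkage grow with K and shrink
with deme size, which empirically biases model selection toward K = 1.

K selection holds out a random 5% of observed entries, scores them by the
mean negative log-likelihood under Binomial(2, (QF)ᵢⱼ) (the masked
cross-entropy), and picks the K with the lowest score across repeated
seeded fits; the full repetition distribution is recorded and a median
criterion is available. PCA on binomially scaled genotypes
((g − 2p)/√(2p(1−p)), monomorphic loci excluded) supplies the score
vectors for the structure-based outlier scan.

## The three outlier scans

**Redundancy analysis (RDA).** Centred genotypes are regressed on the
standardized site-level predictors (expanded to individuals); the SVD of
the fitted values gives the constrained axes and per-locus loadings.
Outliers load beyond mean ± 2.5 SD on any constrained axis (a two-tailed
normal tail of ≈ 0.0012 per axis); a flag pools all axes' loadings
instead, since the source description does not choose between the two.
Overall model significance is a pseudo-F permutation test that permutes
the *site-level* rows of the environment table (sites, not individuals,
are the exchangeable units when predictors are site-constant); per-axis
tests permute the same way against each axis's eigenvalue. Outlier loci
are attributed to the predictor they correlate with most strongly for
the per-variable count grid.

**PCA outlier scan.** Each scaled locus is regressed on the top-K PC
scores; the K-vector of regression z-scores gets a robust Mahalanobis
distance (minimum-covariance-determinant estimate), the distances are
recalibrated by the genomic inflation factor (median distance over the
χ²_K median), and χ²_K p-values follow. Two thresholding modes exist
because the source describes both: Bonferroni-adjusted p < 0.05, and
Benjamini–Hochberg q-values with q < 0.1; the q-value mode at 0.1 is the
default as it matches the reported candidate set.

**Latent-factor ridge scan (LFMM).** Per predictor: the predictor is
regressed out of the genotype matrix, the top-K left singular vectors of
the residual serve as latent factors, and each locus is regressed on
[1, predictor, factors] with a small ridge penalty on the factor
coefficients only (penalty scale 10⁻⁴ × the mean diagonal of the design
Gram matrix — the original penalty is unstated, so it is exposed as a
parameter and kept small enough that K = 0 reduces exactly to ordinary
least squares). z-scores are calibrated by the genomic inflation factor
and outliers must satisfy *both* BH-adjusted p < 0.05 *and* raw
p < 0.001 — the only reading that uses both stated rules; each part can
be switched off. The scan is run per variable (the per-variable count
grid implies this), and a locus flagged for several variables counts once
toward the method's outlier set.

**Consensus.** Loci flagged by ≥ 2 of the 3 methods form the candidate
set for the turnover and zygosity analyses. Consensus is monotone in the
method count and reduces the union's false positives at modest
sensitivity cost, which is the point of requiring agreement between
methods with different confounding controls.

## Turnover forests

For each candidate locus a random regression forest (default 500 trees,
⌈p/3⌉ predictors per split, minimum leaf 5, unlimited depth — all
configurable) is fit to the predictors, with individual genotypes as the
default response (a site-frequency mode exists; the source does not say
which was used). Each split's weighted impurity decrease is logged
against its (predictor, threshold); per predictor, split importances are
binned (200 equal-width bins over the observed range), standardized by
the density of split *opportunities* (midpoints of consecutive distinct
predictor values) with the bin totals rescaled to conserve the raw sum,
weighted by the locus's out-of-bag R² (loci with R² ≤ 0 are excluded as
uninformative), and accumulated along the threshold axis into a
right-continuous, non-decreasing cumulative-importance curve whose
endpoint equals the predictor's total aggregated importance exactly.

One leakage effect deserves note: with individual-level responses and
site-constant predictors, out-of-bag rows share sites with training
rows, so a predictor can retain apparent importance purely by
identifying sites (even after permuting its values across sites). The
site-frequency mode removes this channel, and the permutation-
destroys-importance property is guaranteed only there; predictor
*rankings* in individual mode are still driven by genuine gradient
structure in practice, as the planted-recovery tests show.

## Zygosity profiles

Per meadow × candidate locus, the proportions of reference homozygotes,
heterozygotes and alternate homozygotes over non-missing calls; meadows
with no calls at a locus yield flagged undefined records rather than
silent drops. Profiles are ordered along any predictor (ties broken by
meadow name) so stacked compositions align with the turnover curve.
"Reference" is purely the designated reference allele of the locus
record — a labelling convention, not an inference of ancestral state.

## Donor registry

Projection is deliberately simple: projected = current + rate × years,
with the rate (+0.2 °C yr⁻¹ for average and maximum summer temperature),
base year (2024) and horizons (2030/2040/2050) all parameters, never
constants. No climate-model scenarios, confounders or mitigation enter.
A donor for a recipient × variable × horizon cell is a meadow whose
*current* value meets the projected condition; the default rule
("min_above") picks the smallest sufficient donor, ties alphabetical,
with self-matching disallowed; a "nearest" rule is provided. Displayed
values are rounded half-up to 2 decimals; comparisons use unrounded
values with a 0.005 tolerance so display rounding cannot flip a match.

The comparison report against a published registry classifies every cell
as agreeing, as *printed-violates-rule* (the printed donor's current
value is below the projected condition, so no ≥-rule reproduces it — 8
of the 78 NSW cells are in this class), or as *rule-ambiguous* (the
printed donor satisfies ≥ but is not the smallest sufficient donor — one
NSW cell, where a meadow 0.02 °C cooler also qualifies). Surfacing these
cells explicitly, rather than tuning the rule to match them, is the
intended behaviour: the registry is sound (every emitted donor satisfies
the rule) and complete (no donor is emitted only when none qualifies),
and the report localises exactly where a published grid departs from its
own stated rule.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which the statistical claims are
comfortably testable: null calibration on 300 individuals × 5000 loci;
planted-recovery on 13 demes × 26 individuals × 1200 loci with 60 planted
loci at β = 2 over the real AvTemp gradient; K-selection on 3 demes × 28
individuals × 1000 loci at F_ST = 0.15 with 10 repetitions per K; turnover
forests at 60–100 trees in tests (500 remains the analysis default).
Convergence of the NMF is declared at a relative loss change below 10⁻⁶
or 200 iterations; predicted binomial probabilities are clipped to
[10⁻⁶, 1−10⁻⁶] before log-likelihoods; SVDs use LAPACK via NumPy with
loadings defined up to sign (tests compare up to sign). Degenerate
inputs fail loudly and specifically: empty post-filter matrices name the
step, all-missing loci refuse imputation, monomorphic panels refuse PCA,
and predictor sets larger than the site count refuse the constrained
ordination.

## Known limitations

The LFMM surrogate estimates factors once per predictor rather than
jointly with the effects; the per-axis RDA permutation test is marginal,
not sequential-conditional; the turnover standardization follows the
published construction in spirit but fixes its own binning; and none of
the published outlier *counts* are reproduction targets — they depend on
the deposited data, solver internals and seeds, so the pipeline is
validated by calibration and planted-truth recovery instead.
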