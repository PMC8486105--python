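# Methods

## The trial model

The unit of analysis is a balanced screening trial: G genotypes × two
phosphorus regimes (NLP = non-limiting, LP = limiting) × r replicates,
with one observation per trait per plant. All analyses assume the
fully-crossed, balanced layout; unbalanced panels are detected by
`trait_io.validate_panel` and rejected by the ANOVA path rather than
silently imputed.

For a single trait the generating model used for simulation, and the one
implicitly fitted by the variance decomposition, is

    y_ijk = μ + δ·1[j = LP] + g_i + (gp)_ij + e_ijk

with genotype effects g_i ~ N(0, σ²G), interaction effects
(gp)_ij ~ N(0, σ²GP) and residuals e_ijk ~ N(0, σ²e), all independent.
The regime shift δ is a fixed effect: additive on the trait scale by
default, or multiplicative on the mean (`shift_type: multiplicative`)
when a target response ratio is wanted directly. Normality is a modelling
choice of this package — the analysis formulas themselves are
moment-based and distribution-free.

## Variance components, heritability, CV

Sums of squares are the classical balanced-design decomposition computed
from cell and marginal means (`variance_blup.anova_two_way`); the suite
cross-checks them against an independent OLS + ANOVA-table route
(statsmodels) on the same layout. F statistics for genotype, regime and
interaction are all formed against the error mean square. That matches a
fixed-effects testing view and reports one p-value per factor; under a
random-interaction view the genotype F would use MS_GxP as denominator.
The choice is recorded in every ANOVA report header.

Components come from equating observed to expected mean squares:

    σ̂²e  = MS_error
    σ̂²GP = (MS_GxP − MS_error) / r
    σ̂²G  = (MS_G − MS_GxP) / (p·r)

Negative moment estimates are truncated to zero and flagged. Broad-sense
heritability is on a genotype-mean basis across the p regimes:

    H² = σ²G / (σ²G + σ²GP/p + σ²e/(p·r))

which is the standard plot-mean estimator for p environments × r
replicates. The residual CV is 100·√MS_error / |grand mean|. H² is
invariant to rescaling the trait; both properties are tested.

BLUP genotype summaries are computed per regime from a one-way
random-genotype fit within that regime: BLUP_i = μ̂ + k(ȳ_i − μ̂) with
k = σ̂²G/(σ̂²G + σ̂²e/r) clipped to [0, 1]. Per-regime fitting is chosen
because the response coefficients downstream compare a genotype's two
regime summaries; a pooled fit with regime as fixed would shrink both
regimes toward a common genotype effect and attenuate exactly the
interaction signal the response index is meant to capture. With no
apparent genotype variance the predictions collapse to the regime grand
mean rather than erroring.

The regime comparison is a two-sided independent t-test on genotype
summary values, Welch's unequal-variance form by default (the regimes
visibly differ in spread for several traits); the pooled form is a flag.

## P response: PRC, membership, CPRI

PRC_ij = X_ij(LP)/X_ij(NLP) is computed from genotype summary values —
raw replicate means by default, BLUPs by flag; the flag is carried into
every report header. Entries with a non-positive NLP summary are excluded
(NaN, with a reason) instead of producing infinities.

Membership is the within-trait min–max rescaling of PRC across genotypes.
A trait whose PRC range collapses (max = min) carries no ranking signal;
it is flagged degenerate and dropped from the CPRI, whose |PRC| weights
are renormalised over the remaining traits. The CPRI is then

    CPRI_i = Σ_j U_ij · |PRC_ij| / Σ_j |PRC_ij|

over the included traits. It is 1 exactly when the genotype attains every
trait-wise maximum and 0 at every minimum; the suite verifies bounds,
both extremal characterisations and exact (1e-12) agreement with a
brute-force loop evaluation on randomized matrices.

Responsiveness classes partition [0, 1] as 1: (0.70, 1], 2: (0.50, 0.70],
3: (0.30, 0.50], 4: (0.10, 0.30], 5: [0, 0.10]. The verbal class ranges
in the literature overlap at the cut points; half-open-below intervals
are adopted so each value gets exactly one class, with a boundary value
taking the less-responsive class.

Two per-trait mean-response conventions exist and disagree whenever
genotype level and response are correlated: the ratio of regime means and
the mean of per-genotype ratios. The ratio of means is the headline value
(it is robust to individual genotypes with near-zero NLP summaries, whose
ratios explode); the mean of ratios is reported alongside. Group percent
change in the top/bottom-k tables is defined as
100·(group-mean LP − group-mean NLP)/group-mean NLP and the definition is
printed in the output header, since other definitions circulate.

## Performance classes and diversity

Per trait × regime, genotypes are classed low (< x̄ − SD),
medium ([x̄ − SD, x̄ + SD]) and high (> x̄ + SD) on their summary values,
using the sample (n−1) SD; at N ≈ 180 the population-SD alternative moves
thresholds by <0.3% and the choice is stated in the report metadata.
Values exactly on a threshold are medium (the verbal definitions overlap
at equality). Diversity is the Shannon–Weaver index over the three class
proportions with natural log and no normalisation; this convention is the
one consistent with published three-class diversity values such as
(28, 128, 26)/182 → 0.81 and (42, 105, 35)/182 → 0.97, which a normalised
(÷ln 3) index cannot reproduce. H′ = 0 when one class holds everything
and increases to ln 3 under equal occupancy (a majorization property the
suite checks on random triples).

## Correlations, PCA, subclass distributions

Pearson correlations are computed within regime over genotype summaries,
with two-sided p-values from t = r√((N−2)/(1−r²)). No multiplicity
adjustment is applied by default — matching how such matrices are usually
reported — and a Benjamini–Hochberg flag is available.

PCA uses the correlation matrix (traits standardised to unit variance):
the panel mixes centimetres, square centimetres, millimetres, cubic
centimetres and counts spanning five orders of magnitude, so a covariance
PCA would be dominated by the count traits. Observation rows are pooled
genotype × regime combinations, so regime displacement appears in the
scores; component signs follow a fixed convention (largest-magnitude
loading positive) for deterministic output.

A diameter class's share of its parent trait is
100·mean(subclass)/Σ mean(subclasses). The subclass-sum denominator makes
the five shares sum to exactly 100 and reproduces published fine-root
length shares (82.36% NLP / 87.66% LP for the 0–0.5 mm class); the
separately measured parent total differs from the subclass sum by
measurement error and is available as an alternative denominator flag.

## The synthetic generator

`synthetic_trial.generate_trial` draws from the model above; the
defaults (`default_config`) emulate a large bread-wheat hydroponic
screen: 182 genotypes × 2 regimes × 3 replicates, NLP trait means and LP
shifts matching the qualitative response pattern (LP raises
TRL/TSA/TRV/TRT/TRF, lowers PRL/RAD, with mean response ratios ≈0.9–1.6),
residual CVs of ≈6–24% and implied heritabilities of ≈0.47–0.83. The
variance components behind those defaults are backed out of
calibration mean squares via the expected-mean-squares relations, with
σ²e implied by the residual CV and the across-regime grand mean
(`_spec_from_calibration`).

Subclass values are allocated compositionally: each parent observation is
split over the five diameter intervals by a Dirichlet draw centred on a
regime-specific probability vector with concentration 200 (chosen to give
a few-percent replicate-to-replicate wobble in the dominant class —
plausible for repeated scans of sibling seedlings; no empirical subclass
noise model was available to calibrate against). Zero-probability
intervals get exactly zero. Conservation (subclasses sum to the parent)
holds by construction to float round-off.

Physically non-negative values are floored at 1e-6 trait units and the
truncation count is recorded in the truth ledger. With normal effects at
the default (study-scale) variances, high-variance count traits (TRT,
TRF) produce a small fraction of floored observations; these create a few
extreme per-genotype response ratios, which is why the ratio-of-means is
the headline response summary. The ledger also stores the implied per
trait H² and mean response ratio, which the recovery tests compare
against downstream estimates.

What the generator does *not* emulate: skewed or heavy-tailed trait
distributions, correlation between traits within a plant (traits are
drawn independently, so multivariate structure in simulated PCA/
correlation output is regime-driven only), spatial or temporal batch
effects, and missing cells. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
real-data pathologies.

## Problem sizes in the validation suite

Recovery and calibration checks use sizes chosen to keep Monte-Carlo
error well inside the asserted bands: heritability recovery averages 20
seeds at 200 genotypes × 3 replicates (band ±0.05 around the closed-form
0.857); the interaction-test type-I rate uses 1000 null trials at 20
genotypes (band [0.03, 0.07] at α = 0.05); CPRI properties use 1000
random response matrices up to 10 × 10; subclass-mass recovery uses 120
genotypes (band ±1 percentage point around the configured 82.36/87.66).

## Known limitations

- No REML or general mixed-model engine: all components are balanced-
  design moment estimates, and unbalanced data are rejected rather than
  modelled.
- The five-class CPRI boundaries and the three-class x̄ ± SD thresholds
  are conventions, not estimated quantities; alternative conventions
  change class counts but not the underlying indices.
- Correlation/PCA p-values assume bivariate normality of genotype
  summaries; with N in the hundreds this is mild but unverified.
- The WinRhizo dialect covers the common tabular export headers listed in
  `trait_io.WINRHIZO_ALIASES`; exotic locale or version variants need an
  explicit alias.
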