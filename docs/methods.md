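# Methods

This note documents the statistical procedures, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results at the margins.

## Study design being modelled

A two-cohort case-control comparison of erythrocyte-membrane fatty
acids: 63 ASD cases and 49 neurotypical controls, 11 measured fatty
acids expressed as percent of total fatty acids, plus four derived
measures (DHA/AA, EPA/AA, n-3/n-6, total PUFA). The scientific question
is individual-level separability, so every analyte gets both a
two-sample test (population question) and a C-statistic (classification
question).

### Derived measures

Within the measured panel the n-3 PUFAs are DHA and EPA and the n-6
PUFAs are AA, DGLA and LA. The n-3/n-6 ratio is (DHA+EPA)/(AA+DGLA+LA).
The "total PUFA" measure is the long-chain sum AA+DGLA+DHA+EPA: the
dietary precursor LA (~14% of total fatty acids) enters the ratio
denominator but not the total, which otherwise would be dominated by a
single abundant precursor and sit near 40 rather than the mid-20s range
the panel reports. Derived values are always recomputed from the
measured panel (idempotent); zero denominators propagate as missing
with a warning, and missing values are excluded pairwise per analyte —
never imputed.

## Test-selection tree

Gates run at α = 0.05 (configurable):

1. Anderson–Darling normality per cohort, case 3 (mean and variance
   estimated), small-sample-corrected statistic
   A\*² = A²(1 + 0.75/n + 2.25/n²), p from the D'Agostino–Stephens
   piecewise-exponential approximation. This is the standard published
   approximation for the composite-normality case; it matches the
   statsmodels implementation to ~1e-12 and is tested against it.
2. Both cohorts normal → F-test (F = s₁²/s₂², two-sided
   p = 2·min(cdf, sf) under F(n₁−1, n₂−1)): equal variances → Student's
   t; unequal → Welch's t.
3. Any cohort non-normal → two-sample Kolmogorov–Smirnov (asymptotic p
   at effective n = n₁n₂/(n₁+n₂)): same shape → Mann–Whitney U
   (midranks, tie-corrected normal approximation with continuity
   correction at realistic n; exact enumeration for tie-free pooled
   n ≤ 12), reported with medians; different shape → Welch's t on
   means, flagged with a note.

All p-values are two-sided. Under a fully null normal spec the tree's
end-to-end rejection rate at the 63-vs-49 design is 0.05 ± 0.015 over
1000 simulated cohorts (the gates consume some α but the effect is
within Monte-Carlo noise). Multiplicity correction is Bonferroni by
default (Holm available), applied across the 15 analytes and reported
alongside raw p-values.

The individual tests are delegated to scipy.stats; the tree, the
Anderson–Darling p-value, and all reporting logic are this package's.

## Power calculation

Per-group n for a two-sample comparison uses the normal approximation
n = 2·((z₁₋α/₂ + z_power)/d)², rounded to the *nearest* integer —
at d = 0.5, α = 0.1 two-sided, power 0.8 this gives 49.47 → 49
(a ceiling convention would print 50). The exact-t power at n = 49 is
0.792; the simulation test allows that approximation gap.

## Densities, intervals, C-statistics

KDE uses a Gaussian kernel with the robust Silverman bandwidth
h = 0.9·min(s, IQR/1.34)·n^(−1/5). Two numerical guards: (i) when a
near-duplicate cluster collapses the IQR below s/1000 the rule falls
back to the s scale (a bandwidth orders of magnitude below the data
spread is degenerate, not robust); (ii) the evaluation grid is 512
points over the range padded by 4 bandwidths, refined locally around
data points for n ≤ 512 whenever the base spacing under-resolves the
kernel, keeping the trapezoid mass within 1e-3 of 1.

Interval estimates are central quantiles of the fitted PDF's CDF
(linear interpolation on the grid); coverage 0.95 by default.

The PDF-based C-statistic is computed as the double integral
P(X > Y) = ∫ f_X(u) F_Y(u) du rather than by threshold-sweeping an ROC
curve; for continuous densities the two are mathematically identical,
and the integral form is simpler and directly testable against the
empirical U/(n₁n₂) identity. The orientation-free value
C = max(A, 1−A) is reported because a summary table does not declare a
per-analyte direction. Empirical and PDF-based estimates agree within
0.02 for n ≥ 50 from smooth distributions (the method-equivalence
band); on the synthetic study cohort, swapping the robust Silverman
factor for the plain 1.06·s factor also stays inside that band, which
is why 2-decimal reported values are insensitive to the bandwidth
variant.

## Multivariate analysis

**FDA.** Variables default to the full 15-measure panel. Inputs are
standardized (zero mean, unit variance) before fitting because
percentages and dimensionless ratios live on different scales;
standardization leaves the score C-statistic unchanged in exact
arithmetic while stabilizing the scatter inversion. The direction is
w ∝ (S_W + λI)⁻¹(m_ASD − m_NEU) with λ = 1e-8 by default (λ = 0 raises
on a singular scatter). The score C-statistic uses the PDF-integral
method, matching how score distributions are presented. No
cross-validation is applied by default: the reported value is a fitting
result and is interpreted as an optimistic bound; when a fitted
classifier is already weak, a cross-validated one will be weaker.

**PLS.** Severity scores are treated as opaque numeric columns. Linear
PLS1 is fitted by NIPALS; kernel PLS1 operates on the doubly centered
Gram matrix (RBF γ defaults to 1/median squared pairwise distance) —
with a linear kernel both project y onto the same Krylov score space
and give identical fitted values, which the tests exploit. Defaults:
2 components; in-sample R² always, leave-one-out R² on request (it can
be negative).

**Seafood correlations.** Pearson by default — the analysis frames the
relation as a regression of composition on meals/month — with Spearman
as an option; pairwise-complete per analyte and group; fewer than 3
pairs yields a missing value.

## Synthetic cohort generator

A Gaussian copula supplies dependence: latents z ~ N(0, R) with R the
11-analyte correlation matrix augmented with one seafood latent.
Marginals are transformed per analyte to normal or lognormal with
target mean and CV (lognormal matched by moments); case means are
shifted by cohens_d pooled SDs on the raw scale, keeping the absolute
SD at the control value; normal draws are clipped at zero (negligible
mass at realistic CVs). Seafood counts are the Poisson(rate = 3/month)
quantile transform of the seafood latent; its target correlations with
DHA/EPA (0.374, 0.393) are specified on the latent scale and achieved
on the output scale up to the attenuation of the marginal transforms
and count discretization — verified empirically (~0.35–0.38 at study
size), not analytically.

`default_paper_spec()` sets control means to the reference control
central values and back-solves each CV from the reported central 95%
interval width, cv = (hi − lo)/(2·1.96·mean); effect sizes are implied
by the reference case central values (e.g. DGLA 8% lower in cases,
d ≈ −0.45, which maps to a binormal C of Φ(0.45/√2) ≈ 0.62). Marginal
families follow the observed routing: normal where a t-family test was
selected through the normality gate, lognormal for the right-skewed,
rank-tested analytes. Between-analyte correlations are modest
within-pathway values (DHA–EPA 0.5; AA–DGLA–LA 0.2–0.3;
palmitic–stearic 0.3; oleic–palmitoleic 0.3) chosen once as
physiologically plausible; they matter for the multivariate stages
only. 8 Asperger's and 7 PDD-NOS subtype flags are assigned at random
among the 63 cases.

What the generator does **not** emulate: compositional closure (the 11
relative concentrations are drawn independently, so per-subject sums
scatter around ~99.8 rather than being constrained ≤ 100); age/gender
matching and comorbidity structure; measurement error of the assay; and
any real dependence between severity instruments and the panel. For
skewed analytes whose published intervals are asymmetric (EPA,
palmitoleic) the CV back-solve is approximate — the spec accepts manual
CV overrides. Consequences for test interpretation: passing tests show
the *machinery* is correct under realistic marginals and effect sizes;
they do not certify distributional details of any real cohort, and the
synthetic FDA C-statistic (~0.77–0.85 across seeds) runs higher than a
real panel's because independent per-analyte shifts are the most
favorable geometry for a linear discriminant.

## Figure digitisation

Normalized (zero-mean) cross-correlation of a user-selected marker
patch over the grayscale figure; local maxima at correlation ≥ 0.8
(default) survive greedy non-maximum suppression within one template
half-width; peaks are refined to sub-pixel accuracy by a 1-D quadratic
fit per axis (offsets clamped to ±0.5 px). Pixel centers map to data
units through two user-supplied anchors per axis (affine; y inversion
handled). Validation is by round trip on synthetic renders: 40/40
non-overlapping markers recovered within 1 px, data values within half
a data-unit-per-pixel. Known limitation: markers closer than the
suppression radius collapse to a single detection, and heavily
overlapping markers depress the correlation peak below threshold; the
original extractions' handling of overlaps is unknown, so none is
claimed.

## Pipeline

`run_full_analysis` is deterministic given source, config and seed; the
univariate table always carries the 15 analytes in canonical order with
each routing decision recorded; sections that cannot run (no seafood
data, no subtype metadata) are flagged per-section rather than aborting
the report. The sensitivity rerun repeats the univariate table after
excluding the Asperger's and PDD-NOS subtypes (cases only; controls are
never removed).

## Problem sizes used in the checks

The shipped checks use: 1000 null cohorts for type-I calibration;
20 000 draws per group for the closed-form binormal C comparison
(±0.01); 300–500 generator seeds for seed-averaged recovery of the
DGLA means and C-statistic at the 63-vs-49 design; 10 000-draw samples
for mean/CV recovery (1%/5%); and 40-marker renders for digitisation.
These sizes put Monte-Carlo error comfortably inside each stated
tolerance while keeping the whole suite fast.
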