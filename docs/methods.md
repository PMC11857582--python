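# Methods

## The model

For a trait measured on both members of a twin pair, the classical twin
design decomposes the phenotypic variance into additive genetic (A), shared
environmental (C) and unique environmental (E) parts by contrasting
monozygotic (MZ) pairs, who share all segregating genes, with same-sex
dizygotic (DZ) pairs, who share half on average. Writing path coefficients
a, c, e (and d for dominance in the ADE variant), each pair contributes a
bivariate normal likelihood with

- member means `β₀ + β_age·age + β_sex·[sex = M]`,
- common variance `σ² = a² + c² + d² + e²`,
- within-pair covariance `a² + c² + d²` (MZ) and `a²/2 + c² + d²/4` (DZ).

C and D are not jointly identifiable from MZ/DZ data alone, so the models
offered are ACE, ADE, AE, CE and E. Reported components are the
standardized proportions (each squared path over σ²), which sum to 1 by
construction.

## Estimation

The log-likelihood is maximized over unconstrained path coefficients —
squaring enforces nonnegative variance components without constrained
optimization. Two exact reductions keep every evaluation cheap and the
whole fit independent of the pair count:

1. The mean model is profiled out in closed form: for fixed covariance
   parameters the maximizing (β₀, β_age, β_sex) is the GLS solution, which
   (like the residual quadratic forms) is computable from per-zygosity
   sufficient statistics accumulated once per dataset.
2. For the correlation-parameterized profile likelihood used by the
   confidence intervals, the total variance is also profiled in closed form
   (σ̂² = Q/N for residual quadratic form Q over N subjects).

Optimization uses L-BFGS-B from five starts — a Falconer-informed start
(moment estimates from identity-weighted residual correlations) plus four
multiplicatively jittered copies with a seeded generator — followed by a
gradient-free Nelder–Mead polish. A fit is flagged converged when either
the line-search optimizer or the polish reports convergence; the polish
exists because finite-difference gradient noise (≈1e−4 on log-likelihoods
of magnitude 1e4) makes a fixed absolute gradient tolerance unattainable,
so stationarity is certified by the derivative-free criterion instead.
Trait values are internally standardized by their overall SD (and age
centered at the sample mean) for conditioning; all reported quantities are
transformed back to trait units. The E-only model is solved in closed form
(OLS means, σ̂² = RSS/N).

Degenerate inputs fail loudly: constant traits, fewer than three complete
pairs per zygosity group, and unknown model labels raise typed errors
rather than returning garbage.

## Model comparison and intervals

Nested models are compared by the likelihood-ratio statistic
`2·(ℓ_full − ℓ_reduced)`, floored at zero, with degrees of freedom equal to
the difference in free variance parameters, against the naive χ² reference.
For a variance component on its boundary the naive reference is
conservative (it over-states p); the 50:50 χ²₀/χ²₁ mixture is available
behind a flag for single-parameter reductions. Selection follows the
parsimony rule: adopt AE when ACE→AE is non-significant (p > 0.05) and
ACE→CE is rejected, symmetrically for CE; when both reductions are
non-significant the reduced model with the higher log-likelihood wins (ties
go to AE, a documented arbitrary choice); when both are rejected ACE is
retained.

Confidence intervals for standardized components are profile-likelihood
intervals: the set of proportion values whose profile log-likelihood (all
other parameters re-maximized — a one-dimensional inner search over the
split of the remaining mass for three-component models, closed form
otherwise) lies within `χ²₁(0.95)/2 ≈ 1.92` of the maximum, intersected
with [0, 1]. Endpoints are found by bisection; boundary-touching intervals
are truncated at 0 or 1. Simulated coverage for a² in AE fits at large n
runs slightly above nominal (≈97–98% at 95%), the expected behavior of
profile intervals for a proportion near a boundary under the naive cutoff.

## Correlations and moment estimates

Intra-pair correlations are Pearson correlations on the double-entered
pairing (each pair contributes both member orderings), making the estimate
invariant to arbitrary member order; the Fisher-z interval uses the number
of pairs, not the doubled row count, as the effective sample size. A
one-way ANOVA intraclass correlation is available behind a flag. By
default correlations are computed on residuals from an OLS regression of
the trait on age and sex, mirroring the covariate adjustment inside the
likelihood; an unadjusted mode exists. Falconer moment estimates
h² = 2(rMZ − rDZ), c² = 2rDZ − rMZ, e² = 1 − rMZ sum to 1 identically; if a
component is negative the triple is clamped to [0, 1] and renormalized,
with the event flagged and logged.

## Descriptive-statistics routing

Continuous variables are Shapiro–Wilk tested per zygosity group at the
working alpha; the Student t-test (mean±SD summaries) is used only when
both groups pass, otherwise Mann–Whitney U (median±IQR, reported as
Q3 − Q1 and labeled as such, since IQR conventions vary). Categorical
variables go to the chi-squared test without continuity correction (a flag
enables it). Subjects, not pairs, are the unit of these comparisons.
Simulated type-I error of each route is ≈5% at α = 0.05.

## The synthetic cohort generator

The generator draws, per family and trait, standard-normal latent A, C, D
and E scores with between-member correlations 1/0.5 (A), 1/1 (C), 1/0.25
(D) and 0 (E) for MZ/DZ, scales them by the path coefficients and the
trait SD, and adds the covariate mean model — so the within-pair
covariance algebra holds exactly by construction, not asymptotically. Ages
are drawn uniformly on median ± IQR/2 (default 50 ± 13.5 years, matching
the study's two printed summaries); sex is Bernoulli with 71.2% female;
age and sex are shared within a family (same-sex design). The default
layout is 37 ordinary MZ pairs, 19 ordinary DZ pairs and 2 MZ triplet
sets: 56 ordinary pairs and 118 subjects that expand to 62 analyzable
pairs (43 MZ + 19 DZ). Triplet sets are expanded into all three member
pairs, each entering the likelihood as an independent pair exactly as the
cohort-assembly rule prescribes; the induced dependence between pairs
sharing a member is logged as a warning but not modeled.

Default trait battery: 16 measures (total + six regional gray-matter
volumes, six average thicknesses, brainstem and two cerebellar volumes)
with generating proportions set to the reported regional estimates where
point values exist (frontal/temporal/parietal volumes 0.912/0.907/0.879;
parietal/occipital thickness 0.879/0.881; frontal/temporal/pre-central
thickness C = 0.63/0.665/0.666) and to range endpoints or midpoints where
only ranges are reported. Means, SDs and age/sex effects are plausible
adult values chosen once (e.g. frontal gray matter 160 ± 18 cm³, thickness
≈ 2.0–2.8 ± 0.1 mm, volumes declining ≈0.2–0.3%/year, male offsets ≈8% on
volumes). Note the source abstract pairs heritabilities of ≈0.91 with
"E < 1%", which is arithmetically impossible in an AE model; the generator
uses e² = 1 − a², consistent with the point estimates.

What the generator does **not** emulate: cross-trait correlations between
regions (the analyses are univariate), measurement error distinct from E,
non-normal trait distributions, volumetric segmentation artifacts, and
missingness mechanisms beyond whole-value deletion. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions — not robustness to the ways real morphometric
data violate them.

## Problem sizes used in validation

Replication-style checks use 100 replicates of 2000 + 2000 pairs for
component recovery (Monte-Carlo SE of the mean ≈ 0.0003), 200 replicates
at 1000 pairs/zygosity for model-selection consistency, 200 replicates at
10⁴ pairs for CI coverage, 10⁴ replicates for test-routing type-I error,
and 20 datasets of ≤50 pairs for grid-search oracle equivalence (a 51³
proportion-simplex grid with whitened-least-squares means and scipy
bivariate-normal densities as the independent route).

## Known limitations

- The naive χ² LRT reference under-rejects for boundary hypotheses; the
  mixture reference mitigates but is opt-in.
- Profile CIs over-cover modestly near proportion boundaries.
- Pairs derived from the same triplet are treated as independent, slightly
  understating standard errors for cohorts with triplets.
- The descriptive router treats any non-mandatory column as numeric;
  categorical risk factors must be numerically coded (0/1) except for sex.
- No sex-limitation, GxE moderation, or multivariate (Cholesky) models.
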