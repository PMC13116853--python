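# Methods

This package implements the statistical pathway for assessing whether two
wireworm-monitoring instruments — soil cores (direct, instantaneous larval
counts from a fixed soil volume) and bait traps (indirect, mobility-dependent
counts accumulated over ~10 days, 3 m from the paired core) — measure the
same underlying *Agriotes* population, and for converting per-trap damage
thresholds into soil-sampling densities. The raw per-point field data are
not deposited; a calibrated synthetic generator stands in for them so that
every stage of the pipeline is testable end to end.

## Data model and missingness

One observation is a (soil count, trap count) pair for one species at one
sampling point inside a field. Counts are non-negative integers; either
member may be missing (destroyed trap, unprocessed core), and missingness is
encoded by a configurable token (default: empty cell), never by zero — a
zero is a valid observation of absence. All pairwise analyses (contingency
tables, correlations, regression fits) use complete cases per species;
per-method summaries use each method's own valid values, which is why their
N's differ. How pairs with exactly one missing member entered the original
count models is not recoverable; complete-case analysis is the assumption
made here.

## Synthetic data generator

The generative model has three layers:

1. **Field effects.** Each field carries a log-scale random intercept
   `u_f ~ N(0, σ_f²)` shared by both methods. This produces site-level
   aggregation: fields that are jointly rich or jointly empty in both
   instruments.
2. **Soil counts.** `soil ~ ZINB(mean = μ_s·exp(u_f), size θ_s, zero
   inflation π_s)`, using the NB convention `Var = μ + μ²/θ`.
3. **Trap counts.** `trap ~ ZINB(mean = exp(a + b·soil + u_f), θ_t, π_t)`.
   Conditioning on the *same point's* soil count creates fine-scale (3 m)
   concordance over and above the field effect. `σ_f` and `b` are therefore
   separate dials for the two kinds of agreement that the permutation test
   is designed to separate.

Independent completely-at-random missingness masks are applied per method
(no mechanism is documented for the field data). One seeded generator per
dataset draws field effects before point-level draws, in field order, so an
identical configuration always reproduces the identical dataset.

**Calibration.** The trap-side intercepts/slopes `(a, b)` are the fitted
log-link coefficients for the three species (b = 0.799, 1.757, 0.567 for
*A. brevis* / *A. sordidus* / *A. ustulatus*), and the trap zero-inflation
shares are the fitted ZINB estimates (0.103, ~0, 0.116). The field-effect
SD was fixed at σ_f = 0.4 (the between-field variance is not quantified in
the source material; 0.4 gives between-field count ratios of roughly 2–3×,
a realistic level of aggregation for patchily distributed soil larvae).
Given σ_f, the soil parameters (μ_s, θ_s, π_s) were solved by bounded least
squares so that the marginal mean, zero fraction and variance (integrated
over the field effect by Gauss–Hermite quadrature) match the observed
per-method summary statistics; trap dispersions θ_t were then solved by
root finding so the marginal trap zero fractions match as well. The frozen
defaults reproduce soil zero fractions of 86.96/93.94/89.41 % and trap zero
fractions of 67.07/70.13/44.61 % within Monte-Carlo error at large n. Two
calibration outcomes are worth noting: the soil-side zero inflation is
absorbed into the NB dispersion for *A. brevis* and *A. ustulatus* (π_s ≈ 0
with θ_s < 1), which is a well-known ZINB identifiability feature at very
low means, and the *A. sordidus* soil counts are essentially
Poisson-with-extra-zeros (θ_s at its calibration bound of 30, π_s ≈ 0.125).

**What the generator does not emulate:** explicit 2-D geometry (grid
coordinates, variograms, distance decay) — the 3 m pairing is represented
only by the conditional-generation link; temporal structure across the
multi-year campaigns; and species co-occurrence at shared points (species
are generated independently). Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it assumes, not that the
assumptions hold for any particular field dataset. Trap marginal means come
out ~15 % above the observed ones, an unavoidable consequence of fixing
(a, b) at their fitted values while adding the field effect.

## Descriptive statistics

Summary conventions, chosen to reproduce integral printed values on count
data: SD uses the n−1 denominator; MAD is the *median* absolute deviation
from the median, unscaled (no 1.4826 factor — the scaled version could not
produce the integral values reported for trap counts); skewness m₃/m₂^1.5
and non-excess kurtosis m₄/m₂² with n denominators (normal → 3); IQR by
linear interpolation (type-7 quantiles; the convention is configurable in
principle but not exposed); Gini = Σᵢⱼ|xᵢ−xⱼ|/(2n²x̄), computed via the
sorted-rank identity and defined as 0 for an all-zero vector. When the
variance is zero, skewness and kurtosis are reported as missing rather
than zero. Note there are two "MAD"s in this domain: the descriptive
median-based one above, and the model-validation *mean* absolute deviation
(`mad_mean` in `ValidationMetrics`); they are deliberately distinct names.

## Presence/absence association

The 2×2 table cross-classifies soil presence against trap presence. Both
chi-squared variants are first-class because both are needed: the
species-level independence tests reproduce the printed p-values only with
the *uncorrected* statistic, while the observed statistic of the
permutation test matches the *Yates-corrected* form. The Yates adjustment
subtracts 0.5 from |O−E| floored at zero. Fisher's exact test is two-sided
with probability-mass ordering (the convention of the R implementation the
original analysis used), with a ~1e−7 relative tolerance for ties; it is
checked against an exhaustive same-margin enumeration oracle. The Phi
coefficient is (ad−bc)/√(margin product), sign retained, and satisfies
φ²·n = uncorrected χ² identically.

## Within-field permutation test

Null hypothesis: given field membership, the 3 m pairing carries no
information — trap values are exchangeable across the points of a field.
Each of the 600,000 default replicates re-pairs trap against soil
observations uniformly at random within every field (preserving each
field's marginal detection frequencies) and recomputes the Yates-corrected
χ² of the global presence/absence table; the p-value is the add-one
proportion `(1 + #{null ≥ observed}) / (1 + n_perm)`, which can never be
exactly zero.

Two implementation decisions matter:

- **Exact distributional shortcut.** For a presence/absence statistic the
  permuted table depends on a replicate only through the per-field count of
  doubly-positive points, which under uniform re-pairing is exactly
  hypergeometric (which of the s_f soil-positive points receive one of the
  t_f trap-positive values). `permutation_test` samples these per-field
  overlaps directly — distributionally identical to materializing each
  re-paired dataset and orders of magnitude faster. The literal re-pairing
  operation is retained as `permute_within_fields` and the equivalence of
  the two null distributions is exercised in the test suite.
- **Tie handling.** The null is discrete, and the observed statistic
  frequently coincides with an atom of the null. The observed value used
  for the ≥ comparison is computed by the same vectorized arithmetic as the
  null statistics so ties are exact rather than at the mercy of
  floating-point rounding. Ties counting as "≥" make the test slightly
  conservative; calibration runs show type-I error of 0.03–0.04 at nominal
  0.05, within the expected band for a discrete permutation null.

Whether soil is permuted against trap or vice versa is immaterial for this
statistic; trap-side permutation is implemented. Degenerate permuted
tables cannot arise because global margins are preserved (asserted).

## Gaussian diagnostics

OLS of trap counts (raw, log(y+1), √y) on soil counts, then Shapiro–Wilk
on residuals (fixed-seed subsample above 5000), the studentized (Koenker)
Breusch–Pagan test with the model predictors as auxiliary regressors, and
the Durbin–Watson statistic in input row order (the original spatial
ordering is unrecoverable). No exact DW p-value exists without the
design-dependent null, so a row-shuffling permutation p-value is provided
instead; the verdict labels are what the downstream narrative uses. These
diagnostics exist to justify the count models, not to be remediated.

## Count models

Seven families of `trap ~ soil` (log link, single predictor): Poisson,
quasi-Poisson (Poisson point estimates, dispersion-scaled SEs, no
likelihood), NB2, ZIP, ZINB, hurdle-NB, and a plain linear model as the
degenerate Gaussian baseline. The zero-inflation component is always
intercept-only — one structural-zero probability per model, matching the
single value the model-comparison stage reports. The hurdle is a logit
detection part (intercept **and** slope, since detection-given-presence is
a model of the soil–trap relationship, not a nuisance) plus a
zero-truncated NB for the positives; its reported "zero-inflation" is the
mean structural-zero share implied by the detection part. An intercept-only
design (`intercept_only=True`, with `response=` selecting either method)
serves the per-method abundance fits of the threshold stage.

Parameter counts for AIC/BIC (single-predictor design): Poisson 2, NB 3,
ZIP 3, ZINB 4, hurdle 5, LM 3 (including the error variance); the counts
are held fixed across all comparisons. Dispersion is Pearson X²/(n−k)
using each family's own mean–variance relationship. Estimation is ML via
multi-start optimization (optimizer default plus method-of-moments starts
with the structural-zero share backed out of the observed zero fraction;
moment starts are guarded against degenerate pre-fits and the NB alpha
start is clipped to [0.1, 5]); the best converged run by log-likelihood
wins, with a non-converged best-likelihood fallback before raising a
convergence error that carries the optimizer trace. A diverging NB size
(equidispersion) is capped at 1e6 and flagged rather than failing.
Marginal/conditional R² for the ZINB are deliberately **not** computed:
the variance partition they would require depends on a random-effect
structure the single-level ZINB does not contain, so no value this package
could produce would be comparable; the model-comparison table carries
AIC/BIC/dispersion/π instead. GLS and mixed-model baselines are likewise
out of scope — they inform no downstream conclusion.

Validation metrics per fit: RMSE and mean absolute deviation of observed
counts against fitted marginal means ((1−π)·μᵢ for zero-inflated
families, detection-probability-weighted truncated mean for the hurdle),
Pearson correlation of fitted vs observed (reported missing when fits are
constant), observed vs model-predicted zero frequency (mean of each
observation's P(Y=0)), and IRR = exp(b).

## Threshold conversion

The chain follows the ZINB moment formulas exactly: E(Y) = (1−π)μ and
Var(Y) = (1−π)(μ + μ²/θ) + π(1−π)μ², with per-observation moments averaged
across the dataset (the soil-side fit is intercept-only, since soil
abundance is the response there; the trap side uses the soil-predictor
fit). The trap-to-core ratio R carries a first-order delta-method SD
assuming zero covariance between the two estimates — an acknowledged
simplification, since both come from the same sites, retained because the
two models are estimated separately. A per-trap damage threshold T (1, 2,
5 larvae for the three species) converts to T/R larvae per core with SD
T·sd(R)/R², and to larvae/m² by the factor 88 (a 12 cm core is 1/88 m²).
The delta approximation is only trustworthy at low coefficients of
variation; the test suite documents its domain (within 15 % of Monte Carlo
when CVs < 0.3) and the reported ratio SDs — far larger than the ratios
themselves — should be read as dispersion of individual counts, not as
standard errors of the mean ratio.

## Problem sizes and numerical tolerances

Defaults emulate the field campaigns: 16 fields of 12–48 points per
species-dataset (~480 points). The test suite uses 5,000-point
single-field datasets for parameter recovery (estimates within 3 reported
SEs of truth), 500 datasets × 2,000 replicates for permutation type-I
calibration, 10⁶-draw simulation oracles for the ZINB moments and the
delta-method SD, and exhaustive enumeration for Fisher p-values at small
margins. ML convergence is judged by the optimizers' default relative
tolerances; AIC/BIC identities are checked to machine precision.

## Known limitations

- Complete-case pairing may bias association estimates if missingness is
  not completely at random; no mechanism is documented either way.
- The generator's field effect is log-additive and shared identically by
  both methods; real aggregation may be method-specific.
- The permutation test's null distribution is discrete; at small numbers
  of positive points per field the test is conservative.
- Intercept-only zero inflation cannot express covariate-dependent
  structural absence.
- The separately printed pooled association summary (χ² = 65.2, φ = 0.36)
  is mutually inconsistent and cannot be derived from the printed pooled
  cells (which give χ² ≈ 44.6, φ ≈ 0.20); the pipeline computes pooled
  statistics from cells and treats the printed pair as unreproducible.
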