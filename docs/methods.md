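# Methods

## Unit of analysis and conventions

The unit of analysis is the multiset of integer gradation levels (0–255) of
the masked pixels of one channel of one leaf image. Masks come from the
alpha channel of a transparent-background cutout (`alpha > 0` = leaf) or,
for flat images, from a gray-level threshold (`gray < t` = leaf; the
background is assumed brighter than the blade, as on a white matte
countertop). No denoising is applied beyond masking, and no resizing by
default: resampling perturbs the histogram, so the optional strict-replica
resize (1000 × 1330) uses nearest-neighbour interpolation, which preserves
the gradation value set. Pixel samples are taken in row-major scan order so
that streamed output is deterministic; all implemented statistics are
order-invariant.

Gray is Y = round(0.2989·R + 0.5870·G + 0.1140·B), the BT.601 luma weights,
rounded half-away-from-zero and clamped to [0, 255] — the integer-level
behaviour of common image toolboxes. Because the weights sum to 0.9999,
achromatic pixels (R = G = B = v) map to v exactly for every v in 0–255.

## Distribution parameters

Per channel: mean, median (even-n midpoint rule; may be non-integer), mode
(most frequent integer level, smallest on ties, never computed on smoothed
densities), skewness and kurtosis from *population* (biased) central
moments m_k = Σ(v − mean)^k / n:

    g1 = m3 / m2^1.5        kurtosis = m4 / m2^2  (raw)  or  m4/m2^2 − 3  (excess)

Excess kurtosis is the default: the near-symmetric red/green channels of
real leaves report kurtosis ≈ 0.1–0.5, which is the excess convention's
scale (the raw convention would put them near 3). The `raw` option restores
strict fidelity to environments whose `kurtosis` function does not subtract
3. Zero-variance samples flag skewness/kurtosis as NaN (`degenerate`)
rather than raising.

The 13 color indices are the three channel means plus R+G+B, the three
ratios to that sum (which sum to 1 by construction), and the pairwise
differences and sums. Ratios are NaN when R+G+B = 0.

## Normality testing

**Lilliefors.** D = sup|F_n(x) − Φ((x − x̄)/s)| with s the (n−1)-normalised
SD. Because the null parameters are estimated, p-values come from a
simulated null: 20,000 standard-normal replicates per sample size on a grid
4…2000 (fixed seed; `scripts/make_lilliefors_table.py`), quantiles stored at
11 significance levels and shipped as package data. Critical values are
interpolated linearly in 1/√n inside the grid; above it, the largest
calibrated row is scaled by √(n_max/n), the statistic's asymptotic law.
p-values are clipped to the conventional tabulated range [0.001, 0.5], so a
strongly non-normal pixel-scale sample reports exactly p = 0.001. The table
reproduces the classical n = 50, α = 0.05 critical value 0.1247.

**Jarque–Bera.** JB = (n/6)(S² + (K − 3)²/4) with S, K the biased sample
skewness and raw kurtosis, referred to χ²(2). The asymptotic tail is
adequate at the pixel-scale n this package targets (the type-I error at
n = 1000 sits inside the 95% binomial band of 0.05 over 2000 replicates, as
the test suite verifies); no small-sample table is provided.

A practical caveat verified by the test suite: *discretization is real
non-normality*. Rounding a Gaussian channel with σ ≈ 20–30 levels to
integers produces a lattice deviation of order 0.005–0.01 in D, which the
Lilliefors test resolves once n exceeds a few thousand pixels. Normality of
the underlying continuous law should be tested either on small samples or on
the continuous values.

## Correlation and multiple comparisons

Pearson r against SPAD with two-tailed t-test p-values (n − 2 df); stars at
0.05 (*) and 0.01 (**), no multiple-testing correction across the 20
features (deliberately, for comparability with common practice in this
literature). Duncan's multiple range test takes the one-way ANOVA MSE,
computes least significant ranges from studentized-range quantiles at the
protection level 1 − (1 − α)^(p−1) for a span of p ordered means (harmonic
mean group size for unbalanced designs), and assigns compact letters to
maximal runs of ordered means whose range does not exceed their least
significant range; subranges of a non-significant range are declared
non-significant (step-down protection). With k = 2 the procedure reduces to
the pooled t-test.

## Model families

* **Stepwise OLS** (families F1/F2): forward entry by smallest partial-F
  p-value (< 0.05), backward elimination (> 0.10) after each entry — the
  defaults of mainstream statistics packages. Candidates whose addition
  pushes the column-equilibrated design condition number above 1e8, and
  constant columns, are skipped with a warning (the 13 indices are exact
  linear combinations of the 3 means, so collinear entries are expected).
  Selection stops once the fit is numerically perfect (SSE ≤ 1e−12·SST),
  which makes noiseless recovery runs deterministic. Note that selection
  *support* is only identifiable when candidates are not near-duplicates:
  on image-derived tables, R_Mean and R_Median correlate at ≈ 0.999 and no
  selection method can distinguish them.
* **Fourier (single harmonic)**, family F3: y = a0 + a1·cos(wx) + b1·sin(wx).
  For fixed w the problem is linear; the free frequency is found on a grid
  spanning [0.5·2π/range(x), 2π/Δx_min] (capped at the average-spacing
  Nyquist rate, spacing ≤ π/(4·range)), with the best local minima refined
  by bounded scalar minimisation of the profiled SSE and a final full
  Gauss–Newton polish. SSE ties resolve to the smallest frequency. The
  grid bounds comfortably bracket the published frequency w = 1.314 rad per
  gradation level for median-scale predictors.
* **Cubic surface**, family F4: least squares over monomials x1^i·x2^j.
  Default is the 9-term published set (a full bivariate cubic minus the x1³
  monomial, exactly as printed); `terms="full"` gives the complete 10-term
  poly33 basis. Columns are norm-equilibrated before solving; coefficients
  are reported on the original scale (the 9-term set is closed under
  scaling, so this is exact).

Published coefficient sets F1–F4 are embedded verbatim and evaluated
exactly (F3 in radians). Evaluation reports SSE, RMSE = √(SSE/n),
R² = 1 − SSE/SST, adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1), and
per-sample predictive accuracy (1 − |ŷ − y|/y)·100% (undefined when any
measured value is ≤ 0). The "eliminate abnormal" step is an optional
|standardized residual| > k filter (k configurable, default 3 when
enabled) with the removed count reported, since no canonical rule exists.
The accuracy standard deviation is reported on the fractional scale by
default — published tables mix a %-scale mean with fraction-scale SDs — and
`sd_scale="percent"` switches.

## Synthetic data generator

The generator reproduces what the analysis actually measures — the marginal
gradation law per channel — and nothing more. Each masked pixel of an
elliptical blade is drawn i.i.d. from the channel's law, rounded
half-away-from-zero and clipped:

* **R, G**: skew-normal SN(ξ, ω, α), solved from (mean, SD, skewness)
  targets via the closed-form moment map (|γ1| < 0.9953).
* **B**: scaled beta, because the blue channel's printed skewness (1.5–2.1)
  exceeds the skew-normal maximum. The mean pins b/a; skewness is solved by
  bisection. Where the target (mean, skewness) cannot be realized on the
  0–255 support, the support is widened and the law's tail above the
  gradation ceiling is kept below 1% (best-effort below 0.1%); the
  generator warns whenever more than 0.1% of mass is clipped. This mirrors
  real blue channels, whose histograms are themselves truncated at the
  sensor ceiling.

The default age profile uses the published per-age channel means and
skewness (40/50/60/65 days: R mean rising 98.6 → 154.6, R skewness falling
+0.46 → −0.59; analogous G and B trajectories). Within-age SDs are not
published; ω = 20 (R) and 18 (G) gradation levels are typical single-leaf
channel spreads, and between-leaf variability is a Gaussian jitter of the
per-leaf mean (SD 4 levels; halved for the low-mean blue channel, whose
jittered targets are also clamped to the envelope where a beta law keeps
clipping negligible) and of the per-leaf skewness (SD 0.05). SPAD is the
chosen published model evaluated on the *realized* features plus N(0, σ²)
noise with σ = 1.5 by default, commensurate with hand-held SPAD meter
repeatability; σ = 0 makes published-coefficient recovery exact, which the
pipeline tests exploit. All randomness descends from one master seed
through spawned per-leaf seed sequences, so datasets are bit-reproducible.

What the generator does *not* emulate: spatial texture and venation (pixels
are exchangeable; every implemented statistic is marginal, so this is
irrelevant to the methods under test), inter-channel correlation at the
pixel level, lighting gradients, specular highlights, and segmentation
errors. Passing tests therefore demonstrate correctness of the estimators
and fitters under the stated marginal laws, not robustness to imaging
artifacts.

Default canvas in library use is 500 × 665 (half the strict-replica frame);
tests and examples use 100–333 px canvases, which already give 5·10³–5·10⁴
masked pixels per leaf — ample for the per-leaf moments — while keeping the
full suite in seconds.

## Numerical choices and degenerate inputs

* Rounding is half-away-from-zero throughout (matching the reference
  integer-level behaviour); numpy's half-to-even is never used on levels.
* Mode ties break to the smallest level; Duncan mean ties keep input order.
* Empty masks, zero-variance samples, measured SPAD ≤ 0 (for accuracy), and
  rank-deficient designs raise typed errors (`DegenerateInputError`,
  `FitError`, …) rather than propagating NaNs — except skewness/kurtosis
  and ratio indices, which are defined as NaN-flagged so that feature
  tables of degenerate leaves remain writable.
* Lilliefors p interpolation is linear in log α between tabulated levels.

## Known limitations

* The published headline fit statistics (R² 0.583–0.719, accuracy
  78–82%) were obtained on 400 real tobacco-leaf images that were never
  deposited; they cannot be recomputed here. The package instead verifies
  the arithmetic derivable from the published tables (the 21% adjusted-R²
  and 5% accuracy gains of the surface model over the linear one), exact
  evaluation of the published models, and coefficient recovery of every
  family from data simulated under its own published coefficients.
* Lilliefors p-values between grid levels are interpolation-accurate to
  roughly the Monte-Carlo error of 20,000 replicates (≈ 0.003 near α=0.05).
* Stepwise selection inherits the classical weaknesses of p-value-driven
  selection (overfitting risk with many candidates); it is provided for
  comparability, not as a recommended model-building strategy.
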