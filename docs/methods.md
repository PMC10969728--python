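# Methods

## Scope and data model

`encapkin` models three linked measurements on hydrocolloid-stabilised
essential-oil emulsions: (i) turbidity-based storage stability, (ii)
spray-dried powder yield and encapsulation efficiency, and (iii) volatile
release from a compressed disc monolith.  All computation runs on tidy
containers: `DecaySeries` (one trajectory; days for stability, seconds for
release), `SampleRecord` (formulation identity), pandas frames for tables.
The bundled reference dataset (`encapkin.studydata`) covers six emulsions
sweeping guar:xanthan from 1.0:0.0 to 0.0:1.0 g/100 g at three storage
temperatures (5/20/35 °C), with a disc geometry of 40 mm × 5 mm.

## Stability kinetics

The stability index S(t) = A_t/A_0 × 100 % is deliberately uncapped: day-2
turbidity recoveries above 100 % occur in the data and carry information.
Fits run on the absolute absorbance trajectory with day 0 set to the
activity reading (index 100 %), reconstructed by inverting the index —
published fit intercepts track the activity values, which identifies this
as the fitted quantity.  Fits operate on the mean trajectory; replicate-
level series are supported but the reference dataset only reports means.

* Zero order: OLS line; standard errors from the residual variance, set to
  0 when there are no residual degrees of freedom (saturated 2-point fit,
  whose R² is exactly 1).
* First order: nonlinear least squares of P0·exp(s·t) on the original
  scale (so the loss matches the measurement scale), initialised from the
  log-linear regression, |s| bounded by 10 day⁻¹.  R² is computed on the
  original scale and may be negative for bad fits.
* Rates are stored as magnitude + direction ("decay"/"growth") because
  both signs occur in the integrated laws; printed regression slopes are
  negative and are recovered via `signed_rate`.
* R² = 1 − SS_res/SS_tot about the mean; for constant data it is defined
  as 1 for a perfect fit and 0 otherwise.

The rate-peak detector labels a temperature profile "peaked" only when the
maximum rate magnitude is strictly interior and strictly exceeds both
neighbours; "flat" requires all rates equal within 1e−9.  With the
three-temperature design this is an exact, assumption-free classification.

## Release processing

**Plateau trimming.**  The release experiment stops once three consecutive
balance readings agree; the trimmer finds the first index j whose triple
(j, j+1, j+2) lies pairwise within a tolerance (default 1e−4 g, a typical
analytical-balance resolution) and keeps points 0..j+1 — the plateau entry
plus one confirming reading — never fewer than three points.  A series
with no plateau is returned unchanged.

**Normalisation.**  remaining(t) = (w(t) − plateau) / (w(0) − plateau),
with the option of an independently known oil load as denominator.  The
plateau mass models the non-volatile carrier (the monolith is weighed
whole).

## Effective diffusivity — two routes, two conventions

The kinetic route converts a fitted first-order rate constant by the slab
relation D = k·L²/π² (k in s⁻¹).  The Fickian route fits the one-term slab
eigenfunction f(t) = A·exp(−D·π²·t/L²) directly.

Two deliberate conventions are exposed rather than hidden:

* **Characteristic length L has no default.**  The textbook convention for
  a disc releasing through its faces is the half-thickness (2.5 mm here),
  but the reference dataset's kinetic-route diffusivity column is
  numerically consistent with L = 0.020 m (the disc radius) for four of
  six samples, while its reported 150-min release ratio is consistent with
  L = 0.005 m (full thickness) in the one-term model.  The package
  documents both reproductions (`studydata.L_KINETIC_ROUTE`,
  `studydata.L_FICKIAN_ROUTE`) and refuses to guess; every estimate
  records the L it used.  Two samples (S4, S5) are not reproduced by any
  single L that fits the others and are treated as documented exceptions.
* **One-term amplitude A.**  The surface-concentration form uses A = 4/π
  (value 4/π ≈ 1.273 at t = 0 — a truncation artifact, deliberately not
  clamped); the leading mass-average eigenfunction carries A = 8/π².
  Fitting the 4/π form to mass-remaining data biases D upward by a factor
  ≈ (ln-amplitude mismatch absorbed into the decay), measured at ~1.8× on
  this geometry, so `estimate_diffusivities` defaults to "series" for
  gravimetric data while `fit_fickian_truncated` defaults to "surface",
  the convention under which the reference results are quoted.

Because the single eigenfunction is a long-time approximation, the fit is
windowed to τ = Dπ²t/L² ≥ ln(4/π) ≈ 0.2416 (where the surface form first
drops to 1), re-evaluating the window from the current D estimate until it
stabilises; set the threshold to 0 to mimic naive whole-curve fitting.
On noiseless full-series curves sampled every 30 min to 10 h at the study
geometry, the windowed series-amplitude fit recovers D to ≈ 0.4 %
(residual truncation bias), and the kinetic route recovers it to ≈ 13 %
(the exponential is a proxy for the series mixture) — the regression
guards assert ≤ 10 % and ≤ 25 % respectively.

## Synthetic data generator

The generator emulates the study conditions: 4 daily points for stability
(3 stability days plus the day-0 activity), 30-min sampling over ~10 h for
release, additive Gaussian noise on the measured signal (matching the
symmetric ± uncertainties such instruments report), never clipped.  The
default stability noise is 5 AU: the reference dataset's printed
dispersions have median 3.5 / mean 4.4 AU in absolute absorbance, and 5 AU
is an upper-typical value.  Release-balance noise has no reported
magnitude and is configurable with no inferred default.  Seeds are
mandatory; replicate ensembles spawn independent child streams from the
config seed, so results are bit-reproducible.

The full slab solution is evaluated exactly: the eigenfunction series
(default 50 terms) for τ ≥ 0.05, where it is converged beyond double
precision, and the image-solution short-time form
released(τ) = 2s·[π^{−1/2} + 2Σ(−1)ⁿ ierfc(n/s)], s = 2√τ/π, for
τ < 0.05, whose error is O(exp(−π²/4τ)).  Naive truncation leaves a
coefficient-tail deficit of ≈ 0.2/n_terms at t = 0 (0.4 % at 50 terms),
which would contaminate normalisation; the hybrid makes remaining(0) = 1
exact.  The one-term "truncated" generator keeps the literal leading term.

What passing synthetic tests do **not** show: real release curves include
moisture loss, temperature transients and surface effects that the pure
Fickian model omits; real stability series may have non-Gaussian,
level-dependent noise.  Parameter-recovery results are statements about
the estimators under the stated noise model, not about laboratory
accuracy.

## Correlation analysis

The parameter table holds one row per sample: activity, zero/first-order
stability rates, both diffusivities, encapsulation efficiency.
Temperature-resolved quantities are collapsed by an explicit mode (default
"mean" over 5/20/35 °C; "T5"/"T20"/"T35" select one temperature), stamped
into the table metadata — the reference analysis never states its
aggregation, and the activity-involving correlations it reports are not
reproduced by any of the four modes, so they are documented as
non-reproducible rather than matched.  Pearson r uses `scipy.stats`;
constant vectors and n < 3 are refused.  No p-values are attached (none
are reported for the reference matrix).

## Pipeline and IO

CSVs are comma-separated UTF-8 with "." decimals; stability files carry
(sample_id, temperature_C, day, absorbance), release files
(sample_id, time_min, weight_g) with minutes converted to seconds on read.
Malformed rows are dropped with their line numbers; missing columns are
schema errors.  `run_pipeline` requires both characteristic lengths up
front (fail-fast, before any computation) and accepts either raw release
weights (fully computed path) or pre-fitted release constants — the
reference dataset publishes only the latter, in which case the kinetic-
route diffusivity is still computed from k and L while the Fickian
diffusivity is taken as given.  Outputs (fits, diffusivities with a
geometry-provenance column, parameter table, correlation matrix in square
and long form, JSON run log with versions/seed/geometry) are byte-identical
across reruns of the same config.

## Known limitations

* 1-D through-thickness diffusion only; no radial/2-D disc correction,
  no temperature dependence of D, no moisture-loss deconvolution.
* Replicate-level stability fitting is supported but untested against
  reference values (only means are published); a few published fit rows
  (e.g. the guar-only sample at 5 °C) are not exactly reproduced by OLS on
  reconstructed means, consistent with replicate-level fitting upstream.
* Encapsulation-efficiency magnitudes cannot be recomputed (no raw masses
  or calibration points are published); they enter only as inputs.
* The Arrhenius analysis is limited to the qualitative peak detector; no
  activation energies are estimated.
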