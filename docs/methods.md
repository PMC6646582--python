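# Methods

## The fatigue model

Every analysis in this package rests on the mono-exponential fatigue
model of a normalized neuromuscular variable DV ∈ {IMVC, VA, Q_tw},
expressed in percent of its pre-fatigue baseline, against accumulated
contraction time *t* (seconds of actual maximal contraction, not wall
time):

    DV(t) = A + (100 − A) · exp(−t/τ)

The model structurally passes through 100 at t = 0. Its two parameters
are the asymptote *A* (percent of baseline; the stable state the
variable converges to, read as the individual's critical threshold) and
the curvature constant τ (seconds; 1 − e⁻³ ≈ 95.02 % of the total
decline 100 − A is completed by 3τ, independent of *A*). The model is
fitted independently per subject × condition × variable — the design is
explicitly individual-based and no hierarchical pooling is done.

### Fitting

`fit_exponential` minimizes the sum of squared errors with
`scipy.optimize.least_squares` (trust-region reflective), bounds
A ∈ [0, 100] and τ ∈ (0, 10⁴]. Initialization uses A₀ = min(values) and
τ₀ = the first time the series falls below A₀ + (100 − A₀)/e (else the
median time), plus four restarts jittered by ±50 % from a fixed
internal seed; the best SSE wins. The t = 0 point (exactly 100) is
included by default — it constrains nothing, since the model passes
through it, but stabilizes the total sum of squares; `include_t0=False`
fits only the post-baseline tests.

Goodness of fit is R² = 1 − SSE/SST about the series mean, and each
individual regression is tested against the constant-mean model with an
F-test on (1, n − 2) degrees of freedom — the convention adopted here
for "the regression is significant", since nothing finer-grained is
standard for this design. Boundary solutions (A pinned at 100, e.g. a
constant series) are flagged `degenerate` rather than rejected.
Internally A and τ are never rounded; only the wide table export rounds
to the integer precision conventional in publications.

## Twitch interpolation

One neuromuscular test is a ~4 s maximal isometric contraction with a
100 Hz doublet delivered at the visually-identified torque plateau,
followed ~2 s later by a doublet on the relaxed, potentiated muscle.
From the 2 kHz trace:

* **IMVC plateau** — mean torque over the 500 ms before the
  superimposed stimulus (end-exclusive of the stimulus sample).
* **T_max** — maximal torque of the *current* contraction before the
  stimulus (the contraction is the contiguous segment above 10 % of the
  torque at stimulation), not of the whole trace.
* **ST** — maximal torque strictly after the stimulation (0.3 s search
  window) minus T_stim, the torque at the stimulus instant. The raw
  value can be negative when relaxation has begun or noise dominates; it
  is clamped to 0 with a warning, and the unclamped value is kept for
  audit.
* **Q_tw** — post-stimulus maximum (0.5 s window) minus the mean torque
  over the 100 ms before the resting stimulus; a local baseline is used
  because dynamometer zero offsets drift. The test errors if torque at
  the stimulus exceeds 10 % of the trace maximum ("not at rest").
* **VA** = (1 − (ST · T_stim/T_max)/Q_tw) · 100, clamped to [0, 100]
  with a warning; the T_stim/T_max factor corrects for stimuli delivered
  slightly off the true peak. VA is invariant to uniform rescaling of
  the whole trace.

The post-stimulus windows (0.3 s superimposed, 0.5 s resting) are not
physiologically canonical constants; they comfortably cover a 100 Hz
doublet twitch and are configurable per call. When no stimulus markers
are recorded, stimuli are located as the two largest positive
torque-derivative peaks at least 1 s apart — a doublet onset produces a
derivative spike far sharper than any voluntary torque change.

Baseline tests are gated at 95 % of the control IMVC (inclusive), and
normalization maps the baseline value to exactly 100.

## Iso-decrement mapping

Eliminating *t* between two fitted models gives the closed forms

    t(IMVC)  = −τ_IMVC · ln[(IMVC − A_IMVC)/(100 − A_IMVC)]
    DV(IMVC) = A_DV + (100 − A_DV) · [(IMVC − A_IMVC)/(100 − A_IMVC)]^(τ_IMVC/τ_DV)

`dv_at_imvc` implements the second expression directly and is verified
(to 10⁻⁹ over random draws) against the composition
`predict ∘ invert_imvc`. "10/20/30 % IMVC decrease" means target levels
of 90/80/70 % of baseline on the normalized scale. A target at or below
a subject's A_IMVC is unreachable — the fitted torque never falls that
far — and is excluded from cohort means with a flag and a logged count;
in the packaged table this affects one subject in the low-force
condition at the 30 % level (A_IMVC = 76) and several high-force
subjects whose asymptotes are ≥ 70.

## Cohort statistics

Paired HF-vs-LF t-tests are classical two-sided tests on the paired
differences. Both a raw p and a Bonferroni p (min(1, p·m)) are always
reported; the family size m defaults to the number of tests executed in
one battery call (6 parameter tests, plus 6 decrement tests when
estimates are supplied), because no universal family definition exists
for this design and published values of this kind are typically raw.
Regressions are ordinary least squares with the signed Pearson r,
R² = r², and the slope t-test on n − 2 df. Shapiro–Wilk diagnostics of
the paired differences are available but purely informational.

`summarize_cohort` averages the table as given: summarizing a table of
printed integer parameters therefore reproduces the rounded-then-
averaged values, which can differ in the last digit from a summary
computed on unrounded parameters (e.g. the LF evoked-torque asymptote
column of the packaged table averages to 64.1 while its published
summary row prints 63). The published correlations are reproduced from
the integer table within ±0.02 on R²; the cross-condition evoked-torque
asymptote regression computes to R² ≈ 0.45, between the two values
(0.49 and 0.43) that its source reports in different places, so no
exact target is claimed for it.

## Synthetic data

The generator emulates the study conditions, not arbitrary data:

* **Cohort parameters.** The 12 latent parameters (A, τ) × (IMVC, VA,
  Q_tw) × (HF, LF) are drawn from a multivariate normal with the
  published cohort means and SDs as defaults (e.g. A_IMVC-HF 64 ± 9 %,
  τ_VA-LF 90 ± 45 s). The default correlation structure encodes the
  individual-level findings — corr(A_VA, A_Qtw) = −0.70 within each
  condition and corr(A_Qtw-HF, A_Qtw-LF) = +0.67 — with all other
  cross-correlations zero. That matrix is slightly indefinite (smallest
  eigenvalue −0.111); it is repaired by eigenvalue clipping and
  re-normalization to unit diagonal, which moves entries by at most
  0.064. A repair displacing any entry beyond `repair_tol` (default
  0.15) raises instead of silently changing the model. Rows violating
  A ∈ (0, 100] or τ > 0 are redrawn, which preserves the correlation
  only approximately — acceptable at the configured SDs, where
  truncation is rare.
* **Time series.** Observations follow the exponential model on the
  schedule 0, 20, …, 160 s (a test every twenty 1-s contractions) plus
  homoscedastic Gaussian noise on the percent scale; t = 0 is noise-free
  because the baseline defines the normalization. The default noise SD
  of 3.0 percent points was calibrated once by Monte Carlo so that
  individual fits on default cohorts average R² ≈ 0.9, matching the
  spread of published per-subject fit quality; no noise magnitude is
  reported for the original series.
* **Traces.** A test trace is a linear rise (1 s) to a maximal plateau,
  a superimposed doublet at 2.5 s, continued effort for 1 s, exponential
  voluntary relaxation (τ = 0.08 s), and a resting doublet at 4.5 s, at
  2 kHz. The doublet transient uses amp·(s/Tc)·e^(1−s/Tc) — single-
  peaked, zero at onset, analytic maximum amp at s = Tc (default
  60 ms) — chosen for those properties, not as a contractile model.
  Ground-truth metrics are recorded at construction, and noiseless
  extraction recovers them within 0.5 % (in practice < 0.01 %).

What the generator does **not** emulate: isokinetic (moving)
contractions, EMG/M-waves, heteroscedastic or autocorrelated
measurement error, within-session torque drift, and any physiological
coupling between VA, Q_tw and IMVC (the three series of one synthetic
subject are conditionally independent given the latent parameters).
Passing tests therefore demonstrate correctness of the estimation
machinery under the stated noise model, not robustness to every
pathology of real dynamometry.

## Numerical choices and degenerate inputs

* Exact float round-tripping through CSV (`%.17g` on write,
  `round_trip` parsing on read).
* The 95 % baseline gate is inclusive with a 10⁻¹² tolerance so that a
  ratio of exactly 0.95 passes regardless of binary representation.
* Zero-variance paired differences: t = 0, p = 1 when the mean
  difference is zero; p = 0 (t → ∞ convention), flagged, otherwise.
* Unreachable decrement levels raise in the scalar functions and are
  flagged (NaN value) in the batch estimator.
* All randomness flows from integer seeds; identical seeds give
  bit-identical cohorts, series and traces.

## Problem sizes

The test-suite and acceptance computations use 13-subject cohorts for
fixture statistics (the published cohort size), 500 simulated subjects
for noisy parameter-recovery summaries, 2 000 subjects for Monte-Carlo
checks of the generator's moments, 1 000 random draws for the
iso-decrement identity, and 50 noisy series for the lattice-search
cross-check of the fitter; these sizes give Monte-Carlo error well
below the tolerances asserted.

## Known limitations

* The mono-exponential form is assumed, never tested against
  alternatives (bi-exponential, hyperbolic); variables that have not
  approached their asymptote within 160 s (large τ, common for VA-LF)
  yield poorly identified A with this schedule — the fit reports wide
  residuals rather than warning specifically.
* Voluntary activation is a torque-based estimate; nothing
  electromyographic is modeled or processed.
* Torque units are N·m throughout; sources that mix N and N·m for
  isokinetic peaks must be converted upstream.
* Bonferroni is the only multiplicity correction offered, by design.
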