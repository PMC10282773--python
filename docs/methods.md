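# Methods

## Scope and model

`urwave` analyzes two kinds of data. First, single-sample oscillation
recordings (reporter luminescence, sampled uniformly, hours scale) that may
contain a damped circadian (~24 h) rhythm and a transient ultradian
(~3 h) rhythm on top of a decaying baseline. Second, gene × time
expression matrices from short dense time courses (default 16 points,
19–26.5 h, 30-min steps) in which some genes oscillate at ultradian
periods. The package's claims are about these structures; the synthetic
generators (below) produce exactly them, which is what the test suite
exercises.

## Wavelet conventions

- **Wavelet.** Analytic Morlet, ω₀ = 6. Scale↔period conversion uses the
  Fourier factor 4π/(ω₀ + √(2 + ω₀²)) ≈ 1.033, so scales and periods
  nearly coincide.
- **Grid.** Log₂-spaced periods, 1–48 h, dj = 0.05 octave (≈112 scales).
  Period estimates are therefore quantized at ~3.5% resolution: a 3 h
  rhythm rounds to 3.03 h, a 24 h rhythm to 24.25 or 23.43 h.
- **Transform.** Frequency-domain multiplication with
  ψ̂(sω) = π^(−1/4) √(2πs/dt) exp(−(sω − ω₀)²/2) for ω > 0, after padding
  to a power of two ≥ 4n. The default boundary handling is symmetric
  (reflect) extension before zero padding. Plain zero padding is available
  (`padding="zero"`), but it loses ~21% RMS of a 16–32 h band
  reconstruction of a 24 h cosine at the record edges of a 72 h trace;
  reflection reduces that to ~5% and brings mean white-noise power to 1.02.
  The ≥4n pad length keeps kernel-periodization error ~1e−9, so the
  transform matches a direct time-domain convolution oracle to better than
  1e−6.
- **Normalization.** Power = |W|²/σ², σ² the variance of the detrended,
  mean-centered trace. With this convention i.i.d. noise has expected
  power ≈ 1 at every scale, which is what gives the 1.0 detection
  threshold its meaning. When the circadian-subtracted residual is
  re-transformed, power is still normalized by the *parent* trace's σ², so
  ultradian power remains comparable across samples and against the
  threshold.
- **Cone of influence.** e-folding boundary: at distance d from the nearer
  record edge, periods above (Fourier factor)·d/√2 are flagged. All power
  averages exclude COI-flagged cells; without this, edge artifacts inflate
  ultradian power at the record ends. At ultradian scales this discards
  roughly the first and last 3 h of a trace.
- **Reconstruction.** Delta-function inverse CWT,
  x_n = dj √dt / (C_δ π^(−1/4)) Σ_j Re(W)/√s_j, with C_δ = 0.776 (ω₀ = 6).
  Full-band reconstruction of an in-band cosine is accurate to ~1.4%
  relative RMS; reconstruction restricted to 16–32 h of a 3 h signal leaks
  < 1% RMS.
- **Preprocessing.** Linear detrend + mean-centering by default
  (`detrend="none"` available). A trace whose detrended values are
  constant is flagged degenerate and yields an all-zero decomposition.
  Trend curvature that a linear fit cannot remove (e.g. an exponential
  baseline) legitimately remains in the residual; it sits at periods well
  above the ultradian band and does not contaminate the 2–6 h statistics.

## Ultradian statistics

- **Average UR power**: mean of normalized power over the 2–6 h band and
  over the full record (COI excluded), per sample; the group value is the
  mean over samples. A time window can restrict the average; the full
  record is the default because the oscillation's own duration is part of
  the signal being scored.
- **Detection**: strictly greater than the threshold (default 1.0); a
  value exactly at the threshold is a non-detection (boundary convention,
  arbitrary but documented).
- **Dominant period**: ridge of time-averaged band power; ties break to
  the shorter period.
- **Onset/offset**: first/last run of consecutive supra-threshold points
  in the instantaneous (band-mean) power series lasting ≥ min_run_h
  (default 2 h, measured end-minus-start). Wavelet temporal smearing at
  3 h scale is ±~2 h, so recovered onsets/offsets sit within about 2 h of
  the true envelope edges.
- **Group comparison**: one-way ANOVA + Tukey HSD (scipy), compact letter
  display from maximal cliques of the non-significance graph, α = 0.01 by
  default.

## Periodicity tests for expression time courses

All three methods scan the 2–5 h window (fine grid step 0.1 h for
Lomb–Scargle and cosinor; 0.5 h periods × 0.5 h lags for the rank test).
Expression values are log2(x+1)-transformed by default.

- **Lomb–Scargle**: Scargle's τ-shifted form, normalized by total sum of
  squares so each ordinate is the variance fraction explained; on uniform
  grids it equals the classical periodogram. Single-frequency false-alarm
  probability (1 − z)^((N−3)/2).
- **JTK-style rank test**: Kendall S between data ranks and cosine
  template ranks; the null distribution of S against a tied template is
  computed exactly by convolving Gaussian-binomial inversion counts (the
  Jonckheere–Terpstra construction), reducing to the classical exact
  Kendall null when the template has no ties. Data are assumed untied
  (continuous); heavy ties trigger a warning.
- **Cosinor regression**: OLS of intercept (+ optional linear trend) +
  cos + sin per candidate period, partial F-test (2, N−3); phase and
  amplitude from the winning fit.

**Multiplicity and calibration.** Scanning many periods makes the raw peak
statistic anticonservative. The single-series functions default to simple
analytic adjustments (Šidák over T·Δf independent frequencies;
Bonferroni over the template grid), which are adequate for screening but
measurably miscalibrated on a 16-point design (~9% at nominal 5% for the
scans). The gene caller therefore maps each method's peak statistic
through its design-specific null distribution, estimated once per sampling
design by Monte Carlo (20 000 standard-normal series, fixed internal seed,
cached; smoothed-ECDF body, union-bound linear tail). These statistics are
scale- and location-invariant, so the Gaussian calibration applies to any
i.i.d. noise on the log scale.

**Integration.** Fisher's combination is exact only for independent
p-values, and the three methods are far from independent here (the
Lomb–Scargle and cosinor scans correlate at ~0.999 on the default design);
plain Fisher yields ~12% null calls at α = 0.05. The caller uses Brown's
method — the Fisher statistic referred to a scaled χ² whose scale and df
come from the same design-null Monte Carlo — restoring ~5% null calls.
`integrate_calls` keeps plain Fisher as its default for transparency and
accepts the Brown parameters explicitly. Integrated period is the mean of
method periods; phase is a −log p-weighted circular mean (rank-test lag
and cosinor phase); amplitude comes from the cosinor fit. No across-gene
multiple-testing correction is applied: the rhythmic call is raw p < α,
so ~α of truly flat genes are expected among the calls by design.

## Synthetic generators

Trace model (defaults):
baseline 100·exp(−0.02 t); circadian 15·exp(−0.02 t)·cos(2πt/24 + φ_CR);
ultradian 12·env(t)·cos(2πt/3 + φ_UR) with a raised-cosine envelope active
19–60 h (2 h ramps); Gaussian noise sd 1.5; 72 h at 30-min sampling
(145 points). Phases are uniform per sample (asynchronous excision);
a `phase_jitter_h` option instead shares base phases and jitters them.
The envelope is a raised cosine because the oscillation appears and
dampens gradually; its exact shape is not critical to any statistic.

The amplitude/noise/decay defaults were fixed once so that the model
reproduces the intended threshold semantics with wide margins: wild-type
sets score a group average UR power ≈ 1.35, noise-only sets (both
oscillation amplitudes zero) ≈ 0.12, and the supra-threshold window of the
group instantaneous power recovers the 19–60 h envelope within ±2 h.
Noise-only traces score *below* 1 (not at 1) because their σ² includes
slow baseline curvature that contributes nothing to the 2–6 h band — as in
real recordings, where baseline drift dominates trace variance.

Expression model (defaults): 16 timepoints 19–26.5 h; rhythmic fraction
0.3; periods uniform in 2.9–4.3 h; phases uniform; log2 amplitude 1.0 with
lognormal noise sd 1/3 (amplitude-to-noise 3); baselines lognormal
(log2 mean 5, sd 1). A negative-binomial count option (gamma–Poisson,
dispersion 0.05) is provided for count-scale data.

What the generators do **not** emulate: spatial structure (the petiole
localization of the rhythm), non-stationary period drift, correlated noise
across samples or genes, read-depth/library-size effects, and missing
data. Passing tests therefore demonstrate correctness of the statistics
under the stated model, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

- Periods below 2·dt are outside the resolvable range (error); at periods
  very near 2·dt the Morlet spectrum is truncated at Nyquist and kernel
  tails decay slowly, so exact shift covariance holds only for periods
  comfortably above 2·dt.
- Constant series: p = 1 / degenerate decomposition, never an exception in
  the pipelines.
- Ties in expression ranks use midranks; the exact rank-test null assumes
  untied data and is approximate under heavy ties (warned).
- All randomness is seeded; pipelines are bit-reproducible given config +
  seed. The design-null calibration uses a fixed internal seed independent
  of user seeds.

## Problem sizes used in the checks

The packaged acceptance checks run the default 145-point traces (single
traces and sets of 24, with 20 replicate sets for the threshold
separation), 2000 flat genes for null calibration, and ten 1000-gene
truth matrices for recovery — sizes at which every quantity they assert is
stable across seeds.

## Known limitations

- The absolute meaning of the 1.0 threshold is tied to the
  variance-normalization convention; recordings whose variance is
  dominated by artifacts (spikes, steps) will depress normalized UR power
  and can mask a genuine rhythm.
- The circadian band is fixed at 16–32 h and the ultradian band at 2–6 h
  by default; rhythms near band edges are attenuated by the Morlet
  scale response (~0.4 octave half-width).
- Brown's correction calibrates the *combined* null globally, not
  per-gene; with very heavy-tailed noise the per-method calibrated p's
  remain rank-based (JTK) or approximately (LS/cosinor) valid, but the
  combination inherits their correlation structure from the Gaussian
  design null.
- The 16-point design gives period estimates with ~0.1–0.3 h typical
  error at SNR ≥ 2; phase estimates are meaningful only for called genes.
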