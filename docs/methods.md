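# Methods

This note records the models, conventions, and numerical choices behind
`locodyn`, in the order the pipeline runs.

## Activity extraction (local variance)

The raw sensor trace is partitioned into consecutive non-overlapping windows
of `window_s` seconds. Within each window an ordinary least-squares line is
fitted and subtracted, and the *population* variance (divide by n) of the
residuals becomes one activity sample. Population rather than sample
normalization is used because the quantity is an energy and only relative
levels survive the per-record normalization anyway. A trailing window that
is not completely filled is discarded rather than padded — padding would
bias the final variance downward. Windows of fewer than two raw samples are
rejected (the residual of a linearly detrended single point is identically
zero and carries no information).

Two window sizes matter in practice: 60 s for spectral work (minutes-to-days
rhythms) and 0.1 s for bout statistics (sub-second to minutes intermittency).
Normalization divides by the record mean, making records of animals with
different body mass comparable ("nVar" units); the threshold basis is the
mean of *strictly positive* values, with no epsilon floor.

The acquisition hardware's analog band-pass filter is not modeled: it shapes
the raw voltage before sampling and has no analysis counterpart. Synthetic
raw signals are generated band-limited by construction.

## Morlet wavelet spectrum

The continuous wavelet transform uses the analytic Morlet wavelet with
non-dimensional frequency `omega0 = 6` (the standard choice balancing time
and frequency localization; configurable). Scale and Fourier-equivalent
frequency are related by `f = (omega0 + sqrt(2 + omega0^2)) / (4 pi s)`, and
the scale grid is logarithmic with 16 voices per octave over
[1e-5, 1e-2] Hz. One grid step is 2^(1/16) ≈ 4.4%, enough to resolve a
24 h vs 23.1 h shift (≈5.5%, 1.3 grid steps).

Numerical choices, in decreasing order of consequence:

* **The record mean is subtracted before transforming.** The offset carries
  no rhythm information, but against the zero padding it acts as a
  record-length rectangular pulse whose low-frequency edge response tilts
  the circadian band and drags the apparent peak toward shorter periods by
  more than a grid step on a 3-day record. Demeaning removes the artifact;
  all reported recoveries assume it.
* **Zero padding to a power of two at least twice the record length.**
  Padding to at least 2n keeps circular wraparound of the largest-scale
  kernels negligible; padding is removed before the modulus is used.
* **L2 (energy) normalization** of the kernel,
  `sqrt(2 pi s / dt) * pi^(-1/4) * exp(-(s w - omega0)^2 / 2)` on positive
  frequencies. Under this convention the time-averaged modulus of a
  sinusoid peaks at the scale whose Fourier-equivalent frequency equals the
  sinusoid's — the sqrt(s) amplitude factor exactly offsets the
  Fourier-factor displacement of the Gaussian center.
* **The analyzed band is clipped to the Nyquist frequency** of the series at
  the pipeline level (a 60 s series has Nyquist 8.33e-3 Hz, below the
  nominal 1e-2 Hz upper edge). Requesting an over-Nyquist band explicitly is
  an error. The circadian and ultradian bands lie far below and are
  unaffected.
* The cone of influence is computed and carried as metadata but **not**
  excluded from the time integration: the spectrum is an average over the
  entire record, short as it is, and all comparisons share the same edges.

The normalized spectrum is the per-scale time integral of |W|, divided by
its own trapezoidal integral over the frequency grid (unit area, so records
average and compare cleanly). Band areas are trapezoidal integrals with the
band edges placed by log-frequency interpolation when they fall between grid
points.

**Peak detection.** A spectral peak is a local maximum with prominence at
least 5% of the global density maximum; maxima on the first or last grid
point count (a rhythm at the edge of the analyzed range still produces one).
The circadian period is the period (plain reciprocal, 1/f) of the
highest-density significant peak inside 1.0e-5 to 2.0e-5 Hz; if the band
holds none, the record is arrhythmic and the period is undefined. The
prominence criterion applies to the circadian search as well as the
ultradian one: without it, sampling wobble in an arrhythmic record's in-band
spectrum would masquerade as a circadian peak. A genuine rhythm sitting
exactly at the band edge is indistinguishable from a monotone rising
background — a limitation shared by any fixed-band method.

Period conversions for reporting use the plain reciprocal 1/f (hours or
seconds), which reproduces the standard band-edge labels (e.g., 3.24e-5 Hz
↔ 8.6 h).

## Bout statistics

Classification: value > theta is active, value <= theta resting, with
theta = m × (mean of non-zero values), default m = 1. The first and last
runs are truncated by the recording boundaries — their true lengths are
unknowable — and are discarded; keeping them would bias the duration tails
downward.

Durations rescaled by the individual mean are tabulated as survival
functions P(>=x) on a shared logarithmic grid (20 points per decade over
[1e-2, 1e2]). Because durations are integer multiples of dt, binning at the
rescaled sampling width is exactly the empirical survival function, which is
what is stored. Samples below 50 durations are flagged low-confidence.

Both laws are fitted by orthogonal distance regression (ODRPACK's
Levenberg-Marquardt trust-region core) with unit weights on both
coordinates and 5-start local-minimum selection on the chi-square (sum of
squared orthogonal residuals):

* power law on (log10 x, log10 P) over x in [0.2, 20] — linear in its
  parameters, so recovery of noiseless curves is exact;
* stretched exponential `-(x/x0)^beta` on (x, ln P) over x in [0.1, 10].

The lower fit bounds (0.2 and 0.1) reflect where the respective laws begin
to hold — the resting power law spans roughly two decades up to x = 20 —
and both ranges are configuration-exposed. Per-individual fits are the
primary quantities; group curves (pointwise mean ± SEM on the shared grid,
optional vertical alignment for display only) are figure material, never
fitted.

Group comparisons (mean ± SEM per group, one-way ANOVA, Dunnett versus
control) are delegated to scipy.stats and reported as tables.

### Known estimator behavior

On durations sampled directly from the generating laws, both estimators are
calibrated: bias below 0.015 and replicate SD below 0.04 at n = 5000 (the
acceptance script recomputes this). On full rhythm-modulated records two
systematic effects appear, both shared by any threshold-based analysis:

* multiplicative rate modulation turns the rest-duration law into a mixture
  of rescaled power laws, flattening the apparent tail (fitted gamma lands
  below the bout-level truth by up to ~0.1);
* bursts whose magnitude falls below the threshold merge adjacent rests,
  reshaping the distribution body. With realistic baseline noise the
  threshold sits far below burst magnitudes across the whole sweep range
  and merging is rare; on a noise-free record the sweep's upper thresholds
  cut into the burst-magnitude distribution itself.

Cohort contrasts are therefore the meaningful output: the attenuation acts
on both groups alike, and a generated exponent difference of 0.11 remains
separable at every threshold multiplier with realistic cohort sizes.

## Priority-queue model

A list of exactly L demands (default 10); priorities i.i.d. uniform on
(1e-6, 1) — the small floor prevents zero-probability starvation at large
selection exponents without affecting the tail over simulated horizons. Each
step executes index i with probability x_i^alpha / sum x_j^alpha, records
the waiting time (current step minus arrival step; initial demands arrive at
step 0), and replaces the demand with a fresh uniform priority. Selection
weights are maintained relative to the current maximum priority so that
large alpha cannot underflow the weight vector. Executions during the first
1e3 steps (configurable burn-in) are discarded for stationarity; demands
still queued at the end are censored and excluded — including them with
truncated waiting times would bias the tail downward.

Waiting-time tails are fitted with the same power-law fitter over
tau in [2, 200], avoiding the discrete tau = 1 mass and the finite-horizon
cutoff. Two regimes matter: at alpha = 1 the cumulative exponent is ~1 and
the [2, 200] window sits inside the scale-free range; at alpha = 2 the
immediate-execution probability is so high (the newly arrived demand is
executed ~99.8% of the time) that the asymptotic tau^(-1/2) tail emerges
only beyond tau ≈ 1e3, so a fit in [2, 200] reads the pre-asymptotic
crossover (≈0.3) rather than the asymptotic value 1/alpha. The monotone
ordering — fitted exponent strictly decreasing in alpha — holds regardless
and is the model's load-bearing qualitative prediction.

## Synthetic records

The generator is an alternating renewal (telegraph) process:

* resting durations: truncated Pareto, P(>=a) = (a/scale)^(-gamma) on
  [scale, cap], sampled by inverse CDF and quantized to the sampling grid.
  An untruncated law with gamma < 1 has no mean, so a cap is mandatory; the
  spec-level default is the record length, while the phenotype presets cap
  at 2000 × scale (~200 s at dt = 0.1 s) because the scale-free range of
  real bout statistics spans about two decades above the mean — multi-hour
  rests belong to circadian gating, not the bout law, and a record-length
  cap would flood the circadian band with bout-noise power (renewal-process
  low-frequency power grows like cap^(2-gamma)).
* active durations: Weibull, P(>=a) = exp(-(a/scale)^beta), quantized with a
  one-sample floor.
* burst magnitudes: log-normal (positive, right-skewed like variance data;
  pluggable), constant within an epoch.
* rhythms: a multiplicative envelope, product of (1 + depth cos(2 pi t/T))
  terms for the circadian period and each ultradian component (random
  phases). The envelope multiplies burst magnitude and/or divides drawn
  resting durations (onset-rate modulation); both switches are independent,
  and both on by default because joint modulation gives the clearest
  day/night contrast.
* baseline: folded-Gaussian noise (default sd 0.02, well below burst
  magnitudes), added everywhere.

Spectral-resolution records are produced by generating at 0.1 s and
averaging into 60 s windows (`generate_spectral_series`) — each window then
aggregates hundreds of bouts, which is exactly how windowed-variance
actigraphy turns a bout process into a smooth rhythm-carrying signal.

Default bout scales at dt = 0.1 s (rest scale 0.1 s, active scale 0.25 s)
put mean durations near 2 s resting / 0.4 s active, the range typical of
rodent piezo data. Consecutive durations are drawn independently — real
bout sequences may be correlated, and nothing here tests robustness to such
correlation. The generator also makes no attempt at light-dark entrainment
dynamics, sensor transfer functions, or inter-individual parameter spread
beyond the seed.

Every record carries a log of its epochs (state, start, length, magnitude).
With zero noise, zero modulation depth, and a threshold placed between
baseline and the smallest burst, extraction returns the drawn interior
durations exactly — the round-trip identity that anchors the bout pipeline.

### What passing tests do and do not show

The synthetic process matches the *statistical structure* the analyses
assume: prescribed bout laws, multiplicative rhythm envelopes, positive
bursts over near-zero baseline. Passing tests therefore demonstrate that the
pipeline recovers known structure of that kind from realistic record
lengths and sampling — they do not certify behavior on data whose structure
deviates (correlated bouts, nonstationary bout laws, sensor artifacts, gaps;
artifact rejection and gap interpolation are explicitly out of scope).

## Reported problem sizes

The shipped checks use 3-day records (2.59e6 samples at 0.1 s, 4320 at
60 s), 100 Monte-Carlo replicates of 5000 durations for estimator
calibration, 1e6-step queue simulations, and a 12-vs-9 individual cohort
contrast over the 13-point threshold sweep — sizes at which every stochastic
check above is stable across seeds while the whole suite stays comfortably
fast on one CPU.
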