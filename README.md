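# locodyn

Analysis of intermittent locomotor dynamics in actigraphy-like recordings:
Morlet-wavelet quantification of circadian and ultradian rhythms, statistics
of rest/activity bout durations, and a stochastic priority-queuing model of
the behavioral burst process — together with a synthetic locomotor-record
generator that provides ground truth for every stage.

## Who this is for

Chronobiologists and behavioral neuroscientists working with long,
high-resolution activity recordings (piezo sensors, force platforms,
accelerometers) who want, beyond mean activity levels, the *dynamical*
structure of behavior: how rhythmic it is across the circadian and ultradian
bands, and how intermittent it is at the scale of individual rest/activity
bouts. These measures behave as quantitative behavioral phenotypes — for
example, circadian-clock-compromised animals separate cleanly from controls
in specific parameters while remaining indistinguishable in others.

## The methods in brief

**Activity extraction.** A raw sensor trace sampled at rate 1/dt is cut into
non-overlapping windows; within each window a straight line is fitted and
subtracted, and the population variance of the residuals becomes one
activity sample (window sizes: 60 s for spectral work, 0.1 s for bout
statistics). Records are normalized by their mean variance ("nVar" units).

**Rhythms.** The continuous wavelet transform with the Morlet wavelet
psi(eta) = pi^(-1/4) exp(i w0 eta) exp(-eta^2/2), w0 = 6, using the
scale-frequency relation f = (w0 + sqrt(2 + w0^2)) / (4 pi s). The modulus
|W(s,t)| is integrated over time and normalized to unit area on
[1e-5, 1e-2] Hz. The summary per record:

* `T_cir` — period (h) of the dominant spectral peak in the circadian band
  1.0e-5 to 2.0e-5 Hz, or undefined for arrhythmic records;
* `A_cir`, `A_ult` — band areas (circadian; ultradian = 2.0e-5 to 1.1e-4 Hz,
  i.e. ~2.6-14 h);
* `R = A_ult / A_cir` — relative ultradian weight.

**Bout statistics.** Samples above a threshold theta = m x (mean of non-zero
activity) are active, the rest resting; maximal runs become bout durations.
After rescaling by individual means, resting-bout survival follows a power
law P(>=x) ~ x^(-gamma) (fit over x in [0.2, 20]) and active-bout survival a
stretched exponential P(>=x) = exp(-(x/x0)^beta) (fit over [0.1, 10]), both
fitted by multi-start orthogonal distance regression with
Levenberg-Marquardt refinement. Smaller gamma = fatter resting tail = more
intermittent behavior. A threshold sweep (m = 0.6 ... 1.8) probes
robustness.

**Priority-queue model.** A list of L = 10 demands with i.i.d. uniform
priorities; each step one demand is executed with probability proportional
to x^alpha and replaced. Waiting times between executions reproduce the
heavy-tailed resting-bout law: uniform selection (alpha = 0) is geometric,
proportional selection (alpha = 1) gives a cumulative tail exponent near 1,
and preferential selection (alpha > 1) gives the fatter tail seen in more
intermittent phenotypes.

**Synthetic records.** An alternating renewal process with truncated-Pareto
resting durations (exponent `gamma_true`), Weibull active durations
(`beta_true`), log-normal burst magnitudes, and multiplicative
circadian/ultradian modulation of burst rate and magnitude. Presets `wt`,
`per2`, `clock`, `bmal1` encode four phenotype scenarios (circadian periods
24.0 / 23.1 / 27.7 / none h; gamma 0.95 / 0.84 / 0.99 / 0.97; beta
0.59 / 0.55 / 0.62 / 0.65). Every generated record carries a ground-truth
log of its epochs.

## Worked example

```sh
# 3-day wild-type-like record at 0.1 s resolution, with ground-truth sidecar
locodyn --seed 7 --out-dir . synth --preset wt --days 3 --out wt.tsv
# -> wrote wt.tsv (2592000 samples) and ground-truth sidecar

# bout extraction + both distribution fits at the default threshold
locodyn --out-dir . durations wt.tsv
# -> gamma=0.867  beta=0.578  <a_r>=1.166 s  <a_a>=0.408 s
```

The fitted scaling exponent (0.867) and stretching exponent (0.578) sit near
the generator's truth (0.95 / 0.59); rhythm modulation of the bout process
flattens the apparent resting tail slightly (see `docs/methods.md`), which
is why cohort comparisons — not single absolute values — are the meaningful
output. Mean bout durations (~1.2 s resting, ~0.41 s active) are in the
range typical of rodent piezo recordings.

```python
import locodyn as ld

series, _ = ld.generate_spectral_series(ld.make_spec("wt", seed=7))
ld.write_series("wt60.tsv", series)  # same record aggregated to 60 s windows
```

```sh
locodyn --out-dir . spectrum wt60.tsv
# -> T_cir=23.36 h  A_cir=0.04947  A_ult=0.06953  R=1.4056...
```

The circadian peak lands at 23.36 h, one scale-grid step (4.4%) from the
generated 24 h rhythm — grid resolution, not bias. `R > 1` says this record
carries more ultradian than circadian spectral weight.

```sh
locodyn --seed 7 --out-dir . queue --alpha 1.0 --steps 200000
# -> alpha=1.0  executions=199000  mean tau=10.003
```

With proportional selection the mean waiting time equals the list length
(L = 10), and the waiting-time distribution written alongside has a
power-law tail with cumulative exponent near 1 — the wild-type-like resting
law.

A cohort-level report (`locodyn report --preset-groups wt:12,per2:9 ...`)
produces per-individual tables plus group mean ± SEM with one-way ANOVA and
Dunnett comparisons.

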