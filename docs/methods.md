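# Methods

## Signal model

The simulator emulates surface EMG under *severe myoelectric fatigue*:
a wide-sense-stationary Gaussian process whose power spectrum is
compressed into the low-frequency band. The target PSD is the band-pass
shape

    P(f) = k² f_h⁴ f² / [(f² + f_l²)(f² + f_h²)²]

with defaults k = 1, f_l = 20 Hz, f_h = 40 Hz, sampled at f_s = 1024 Hz.
The shape vanishes at DC (the f² numerator), peaks near 23 Hz, and decays
as f⁻⁴ well beyond f_h. These parameters are the study conditions, not
tuning knobs: they pin the spectral peak low enough to represent
contractions driven to failure.

**Shaping filter.** The amplitude response √P(|f|) is sampled on a dense
FFT grid (4096 points for the default 512-tap filter, i.e. ≥ 8× the
filter length). Because P(0) = 0, the magnitude is floored at 10⁻¹² of
its maximum before the logarithm. The minimum-phase impulse response is
obtained by real-cepstrum folding — numerically identical to assigning
the phase −H{ln|A|} via the Hilbert transform — and truncated to
`min(N, 512)` taps. The truncation is benign: > 99.6 % of the impulse
energy sits in the first 64 taps, and the realized magnitude response
correlates with √P at r > 0.999 over 5–200 Hz.

**Realizations.** For an N-sample signal (N = round(T·f_s/1000); 256
samples at T = 250 ms up to 2048 at T = 2000 ms), N + L unit-variance
Gaussian samples drive the filter and only the last N outputs are kept,
so the start-up transient of the convolution is discarded and every
realization is a steady-state segment. Measurement noise is an
independent Gaussian stream rescaled so that the ratio of *empirical*
clean power to *empirical* noise power matches the target SNR exactly for
each realization (not merely in expectation); the SNR grid is
{5, 10, 15, 20} dB.

**Seeding.** A master seed spawns one `SeedSequence` per
(duration-index, SNR-index, realization, stream) tuple, with separate
streams for the shaped-noise driver and the measurement noise. Any cell
of the design can therefore be regenerated in isolation, and the whole
study is bit-reproducible from one integer.

## PSD estimators

**Welch.** Segments of M = round(0.25·N) samples advance by
hop = round(0.25·M) (75 % overlap), which yields exactly 13 segments for
*every* study duration — the segment count, not the overlap wording, is
the binding constraint. Each segment is mean-removed (a flag can disable
this), tapered with a Tukey window (taper fraction 0.5, the conventional
default for the tapered-cosine family; exposed in `WelchConfig`),
zero-padded to the full signal length N, and converted to a one-sided
modified periodogram |DFT|²/(M·U·f_s) with U = mean(w²); the estimate is
the average over segments. Zero-padding to N puts Welch and Burg on the
same f_s/N grid.

**Burg.** The lattice recursion estimates one reflection coefficient per
stage by the closed-form minimizer of the summed forward + backward
squared prediction error; prediction coefficients follow by the
Levinson–Durbin update and the error power shrinks by (1 − k²) per stage.
This guarantees |k| < 1 (stable models) and a non-increasing error path,
both asserted in tests; the recursion is additionally cross-checked
against a brute-force per-stage scalar minimizer, since no independent
Burg implementation ships with the scientific Python stack. The AR
spectrum σ²/(f_s·|A(f)|²) is evaluated on the same N-point grid as Welch
(`nfft = N`); a sensitivity probe with an 8× denser grid moved the
short-signal MDF error by < 0.1 Hz, so grid parity costs nothing. Model
orders {3, 4, 7, 10, 15, 30} are fixed study factors, not selected by
information criteria.

Both estimators use the one-sided density convention (interior lines
doubled, power per Hz). MNF and MDF are scale-invariant, so the
convention only matters for the Parseval-consistency tests.

## Features

MNF is the power-weighted mean of the grid frequencies. MDF linearly
interpolates the cumulative-power curve between the two bracketing lines;
a bin-snapping mode is kept as an option, but interpolation is the
default because at T = 250 ms the grid is 4 Hz wide and snapping would
dominate the error budget. The analytic reference evaluates the
closed-form PSD on a 5 mHz grid over [0, f_s/2] and applies the same two
definitions; halving the step moves both values by < 0.005 Hz.

### Reference values

Dense-grid integration gives **MNF = 40.76 Hz** and **MDF = 31.89 Hz**
for the default parameters, cross-checked against adaptive quadrature
plus root finding. The values often quoted for this parameter pair,
39.84 Hz and 30.95 Hz, are *not* reproducible from the closed form by
direct integration at any grid step, truncation, or index convention we
tried (the closest reconstruction, a 2 Hz grid truncated at 256 Hz,
still misses the median by 0.1 Hz). The package therefore uses its own
integrated values as the error-study ground truth y_d — self-consistent,
and empirically the better match to the benchmark error levels. The
discrepancy (≈ 0.9 Hz in both features) should be kept in mind when
comparing absolute MAE numbers below ~2 Hz against external reports.

## Study design and statistics

The full factorial crosses 7 methods × 8 durations × 4 SNRs with C
realizations per cell (C = 1000 at full scale). Every method sees the
same realizations within a cell, so method contrasts are paired by
construction. Per-realization absolute errors |y_d − y_c| feed both the
per-cell MAE ± SD summaries (a signed-bias column is also emitted) and
the ANOVA; analyzing per-realization errors rather than cell aggregates
preserves the residual degrees of freedom of the balanced design.

The ANOVA cascade: a three-way fixed-effects ANOVA on
(method, duration, SNR); if the three-way interaction is significant
(α = 0.05), two-way ANOVAs per SNR level; where the method × duration
interaction is significant, one-way ANOVAs on method per duration; where
it is not, a one-way on method at that SNR; Tukey HSD on the method
factor wherever its effect is significant. Sums of squares come from
statsmodels OLS/anova_lm (type is irrelevant for the balanced design; an
explicit balance check rejects anything else), and SS additivity to the
total is asserted at 10⁻⁸ relative. A constant response is special-cased
to "no effects" rather than propagating 0/0 F ratios.

## Problem sizes used by tests and the acceptance run

The shipped benchmark runs C = 200 realizations per cell over durations
{250, 1000, 2000} ms — the corner cells that carry the headline numbers —
rather than the full 8-duration, C = 1000 grid; at this scale the full
pipeline completes in seconds and the MAE levels are stable to ≈ 0.3 Hz
(SE of the mean). The `analysis/` drivers default to C = 100 over all
eight durations and accept the full C = 1000 as an argument. At C ≤ 100
the MDF three-way interaction does not reach significance (it requires
the full-scale replication count), so the cascade degrades gracefully to
the pooled one-way analysis.

## What the generator does and does not emulate

It reproduces: the stationary fatigue-compressed spectral shape, the
duration/SNR grid, exact per-realization SNR, and independent signal and
noise streams. It does **not** model multi-channel recordings, motor-unit
recruitment or firing structure, force variation, nonstationary
(time-varying) spectra within a realization, movement artifacts, or
power-line interference. Passing benchmarks therefore demonstrate
estimator behavior under the idealized stationary model, not performance
on real recordings — where the true spectral parameters are unknowable
and only the relative robustness conclusions (MDF over MNF; low AR
orders for compressed spectra) can be expected to transfer.

## Known limitations

- MNF error levels at low SNR are dominated by the flat noise floor
  (mixture arithmetic alone predicts a ≈ 52 Hz bias at 5 dB), so the
  low-SNR MNF benchmark mostly measures the noise model, not estimator
  subtleties.
- The Burg-15 MDF error for the shortest signals at 20 dB sits at
  ≈ 3.5–4.3 Hz depending on the seed: the estimator is nearly unbiased
  there but its realization spread (SD ≈ 5 Hz at N = 256) is intrinsic
  to the model; reports of ≈ 3 Hz for that cell are at the optimistic
  edge of what this pipeline measures.
- The best-method MNF error at 20 dB measures ≈ 2 Hz here, slightly
  *below* commonly reported ≈ 3 Hz levels; the difference traces to the
  reference-value choice (see above) and to Burg-3's truncation of the
  noise floor.
- The Tukey taper fraction and the MDF interpolation convention are
  defensible defaults, not uniquely determined by the study description;
  both are exposed as options.
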