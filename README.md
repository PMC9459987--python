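# emgfatigue

Simulation and benchmarking toolkit for spectral fatigue indices of
surface electromyography (sEMG).

During a sustained fatiguing contraction the sEMG power spectrum
compresses toward low frequencies, and the standard way to track this is
through the **mean frequency (MNF)** and **median frequency (MDF)** of the
power spectral density (PSD). Real recordings are short and noisy, the
PSD can only be *estimated*, and different estimators (Welch averaged
periodograms vs. Burg autoregressive models of various orders) trade bias
against variance differently — especially when the spectrum is crammed
into the 10–60 Hz band, as it is under severe fatigue. This package
answers, by seeded Monte-Carlo simulation: *which estimator, at which
settings, recovers MNF and MDF most accurately as a function of signal
duration and signal-to-noise ratio (SNR)?*

It is written for biomedical-signal-processing researchers and
physiologists who need a defensible choice of spectral estimator for
fatigue tracking, and for anyone who wants a clean, tested reference
implementation of the Welch and Burg estimators and of the shaped-noise
sEMG simulator.

## The model

Synthetic fatigued sEMG is colored Gaussian noise with target PSD

    P(f) = k² f_h⁴ f² / [(f² + f_l²)(f² + f_h²)²]

with k = 1, f_l = 20 Hz, f_h = 40 Hz, f_s = 1024 Hz — a band-pass shape
peaking near 23 Hz. A minimum-phase FIR shaping filter with magnitude
√P(f) (phase from the Hilbert transform of the log magnitude) colors
unit-variance white noise; independent white Gaussian noise is added at an
exact per-realization SNR. Features are

    MNF = Σ P_l f_l / Σ P_l          (power-weighted mean)
    MDF : Σ_{f<MDF} P_l = ½ Σ P_l    (half-power split, interpolated)

and estimator accuracy is the mean absolute error (MAE) against the
analytic reference of the ideal spectrum, over C realizations per
(method × duration × SNR) cell, followed by a three-way ANOVA cascade
with Tukey HSD post-hoc comparisons.

## Worked example

```python
import emgfatigue as ef

spec = ef.IdealSpectrum()                      # k=1, f_l=20, f_h=40, f_s=1024
ref = ef.ideal_reference()
print(f"reference MNF {ref.mnf:.2f} Hz, MDF {ref.mdf:.2f} Hz")

h = ef.design_shaping_filter(spec, length=512)
clean = ef.generate_clean(1000, spec, seed=42, shaping=h)   # 1000 ms -> 1024 samples
noisy = ef.add_noise(clean, snr_db=10.0, seed=43)

welch = ef.welch_psd(noisy.samples, spec.f_s)               # 13 averaged segments
burg3 = ef.burg_psd(ef.burg_fit(noisy.samples, 3), spec.f_s, nfft=noisy.n_samples)
print(f"Welch  MNF {ef.mean_frequency(welch):.1f} Hz, MDF {ef.median_frequency(welch):.1f} Hz")
print(f"Burg-3 MNF {ef.mean_frequency(burg3):.1f} Hz, MDF {ef.median_frequency(burg3):.1f} Hz")
```

prints

```
reference MNF 40.76 Hz, MDF 31.89 Hz
Welch  MNF 61.4 Hz, MDF 32.7 Hz
Burg-3 MNF 57.5 Hz, MDF 26.3 Hz
```

At 10 dB both estimates of the mean frequency are pulled far above the
39–41 Hz reference by the flat noise floor (a ~20 Hz error), while the
median frequency moves only a few Hz — the single-realization picture of
the study's central finding that MDF is the noise-robust fatigue index.

## Analysis pipeline

Numbered drivers under `analysis/` reproduce the study end to end at desk
scale, writing tables under `results/`:

1. `01_ideal_reference.py` — analytic MNF/MDF reference values and grid
   convergence.
2. `02_simulate_signals.py` — example realizations for all eight durations
   (250–2000 ms) and an achieved-SNR audit.
3. `03_estimator_benchmark.py [C]` — the 7-method × 8-duration × 4-SNR MAE
   grid (C realizations/cell, default 100; the full study uses 1000).
4. `04_anova.py` — three-way ANOVA on per-realization absolute errors,
   descending to two-way/one-way analyses and Tukey HSD where interactions
   are significant.
5. `05_figures.py` — grouped MAE bar charts per SNR level.

The same pipeline is scriptable via the CLI, e.g.
`emgfatigue study --seed 1 --reduced 100 --outdir study_out`.

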