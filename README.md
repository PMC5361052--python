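# ecgbaseline

Benchmark of ECG baseline-wander removal filters with respect to preservation
of ischemic ST changes.

Baseline wander is a low-frequency (here 0–0.5 Hz) drift of the ECG isoline
caused by respiration, electrode polarization and patient movement.  Removing
it is a mandatory preprocessing step, but any filter that cancels low
frequencies can also distort the ST segment — the very feature a clinician
reads to diagnose ischemia or infarction (deviations as small as 50 µV
matter).  Judging which filter distorts the ST segment least requires a
ground-truth, artifact-free ischemic ECG, which real recordings cannot
provide.  This package builds that controlled environment in silico for
signal-processing engineers and physiologists who need to pick (or defend) a
baseline-removal filter for ST-segment analysis.

## What it does

1. **Synthesize** clean 12-lead ischemic-like ECGs: each beat is a QRS
   complex, an ST segment with a controllable per-lead elevation/depression
   (±0.05–0.5 mV), and a T wave; QT = 400 ms; no P wave.  RR intervals are
   Gaussian (mean 1 s, SD 50 ms).  Records are built at 500 Hz and
   resampled to f_s = 512 Hz; 100 s = 51200 samples.
2. **Corrupt** each lead with a stochastic sinusoidal artifact

   b(t) = C · Σ_{k=0}^{K} a_k · cos(2π · k · Δf · t + φ_k),

   with Δf = f_s/N = 0.01 Hz, K = f_c/Δf = 50 (band 0–0.5 Hz),
   a_k ~ U[0, 1], φ_k ~ U[0, 2π).  C sets the SNR
   (10·log₁₀(P_x/P_b), mean-squared powers) to one of
   [−10, −3, 0, +3, +10, +20] dB.
3. **Filter** with five standard methods: zero-phase Butterworth high-pass
   (order 2 per pass, 0.5 Hz), cascaded moving medians (400 ms, 2 s),
   cubic-spline interpolation of isoelectric anchors, wavelet baseline
   cancellation (level-9 Daubechies-8 DWT, approximation zeroed), and
   wavelet high-pass (level-8 Vaidyanathan DWT, order-1 IIR on the
   approximation subband).
4. **Score** each reconstruction x̂ against the clean x after trimming 1 s
   per end:
   * CC — Pearson correlation (morphology; scale/offset invariant),
   * l_operator = 1 − E{(x−x̂)²}/(E{x²}+E{x̂²}) (equals 1 only for identity),
   * ΔKP — amplitude change at the K point, the ST-window instant where the
     across-lead envelope max_i |x_i(t)| is minimal (a detection-free
     J-point surrogate),
   * wall-clock filtering time.
5. **Rank** methods: median ± IQR per criterion, then a paired one-sided
   Wilcoxon signed-rank test of the best-median filter against every other
   method; it is a "clear winner" only if the *maximum* pairwise p-value is
   below 0.05.

## Worked example

```python
import ecgbaseline as eb

config = eb.ExperimentConfig(n_setups=2, n_realizations=2, master_seed=7)
rows = eb.run_grid(config)
print(f"{config.grid_size} corrupted signals, {len(rows)} metric rows")
print(eb.summarize(rows))
```

prints

```
288 corrupted signals, 1728 metric rows
                      cc_med  cc_iqr  l_op_med  l_op_iqr  dkp_med  dkp_iqr  elapsed_med  elapsed_iqr
butterworth           0.9827  0.0436    0.8672    0.1247  -0.0185   0.1220       0.0006       0.0001
median                0.9146  0.1757    0.8926    0.2050  -0.0012   0.0377       0.0337       0.0020
none                  0.7438  0.3958    0.7429    0.4524   0.0007   0.0170       0.0000       0.0000
spline                0.9785  0.0552    0.9812    0.0503   0.0000   0.0010       0.0010       0.0001
wavelet_cancellation  0.9753  0.0659    0.8668    0.1297  -0.0184   0.1117       0.0015       0.0001
wavelet_highpass      0.9764  0.0549    0.8669    0.1302  -0.0178   0.1132       0.0023       0.0001
cc: best median = butterworth (max pairwise p = 3.3e-18; clear winner)
l_op: best median = spline (max pairwise p = 3.76e-38; clear winner)
dkp: best median = spline (max pairwise p = 2.85e-46; clear winner)
elapsed: best median = butterworth (max pairwise p = 1.82e-45; clear winner)
```

Reading the table: leaving the artifact unfiltered (`none`) drags the median
correlation down to ≈0.74, while every filter restores it above 0.91 — all
five are better than not filtering.  `dkp_med` is the median K-point
amplitude shift in mV (≈0 means ST levels survive), `elapsed_med` the median
per-signal filtering time in seconds (the Butterworth filter is fastest at
~0.6 ms per 100 s lead).  A 288-signal grid is small; medians move by a few
thousandths between seeds.

The same pipeline is scriptable from the shell:

```bash
ecgbaseline generate --n-setups 3 --seed 0 --out-dir records/
ecgbaseline evaluate --n-setups 3 --n-realizations 2 --seed 0 --out metrics.csv
ecgbaseline report --metrics metrics.csv --out-dir report/ --plots
```

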