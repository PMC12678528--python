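# ecgrecon — wave-masked linear reconstruction of 12-lead ECGs

Reduced-lead ECG devices record a handful of leads and synthesize the rest.
Because all leads view the same cardiac source, they are close to linearly
related: a per-sample linear transform

```
y = A x + C
```

maps the available body-surface potentials `x` (here leads I, II, V3) to the
missing precordial leads `y` (V1, V2, V4, V5, V6), with the coefficient matrix
`A` and intercept `C` fitted by least squares or stochastic gradient descent.
The four limb leads need no model at all — they follow algebraically from I
and II (Einthoven's law `III = II − I` and the Goldberger augmented leads).

A single global transform, however, forces one weighting on every part of the
beat.  **Wave masking** relaxes that: the P wave, QRS complex and T wave are
delineated on the available leads, each wave is isolated by zeroing all
samples outside its segments (P from lead II, QRS from V3, T from lead I),
and the three sparse masked channels are stacked with the raw leads into a
6-channel input.  A linear model over this augmented input can weight each
wave independently — a cheap preprocessing step that narrows the gap to deep
models while staying interpretable and fast.

The package provides, end to end:

- **io** — CSV / minimal WFDB / HDF5-container readers and writers (mV
  throughout), cohort metadata filtering (first use of each patient, normal
  rhythm, six condition flags false, no blank lead), trimming, polyphase
  resampling, and zero-phase Butterworth denoising;
- **delineate** — Pan–Tompkins-style R-peak detection and P/QRS/T on/offset
  location using only leads I, II, V3, with median fusion across leads and an
  import/export path for externally produced fiducial CSVs;
- **masking** — exact zero-masking and the fixed 6-channel augmented stack;
- **linear** — OLS (minimum-norm under rank deficiency) and seeded mini-batch
  SGD fits of `y = A x + C`, limb-lead derivation, and the five pipeline
  variants (`p1`: I,II,V2 inputs; `p2`: I,II,V3; `wmlr`: 6-channel masked;
  `lstm`, `ffn`: neural baselines);
- **baselines** — a reduced-scale two-layer LSTM (numpy) and a feed-forward
  committee (tanh–tanh–linear, 5 members averaged);
- **evaluate** — per-record per-lead Pearson r and RMSE, patient-wise k-fold
  cross-validation, aggregate median/mean/SD and box-plot tables, paired
  t-tests;
- **synth** — a sum-of-Gaussians 12-lead generator with exact fiducials and
  known (optionally wave-specific) linear lead mixing, so every claim above
  is testable against construction-level ground truth.

## Worked example

`examples/crossval_wave_masking.py` generates a 50-patient cohort whose waves
project to the leads with 20% wave-specific gain disparity at 20 dB SNR —
conditions under which no transform of the three raw leads can be exact —
and cross-validates the plain and wave-masked linear pipelines patient-wise:

```
plain linear (I,II,V3) — correlation per reconstructed lead:
         median    mean      sd
V1       0.9695  0.9698  0.0041
V2       0.9790  0.9792  0.0027
V4       0.9787  0.9788  0.0028
V5       0.9773  0.9779  0.0029
V6       0.9789  0.9790  0.0028
Average  0.9767  0.9769  0.0030

wave-masked linear — correlation per reconstructed lead:
         median    mean      sd
V1       0.9940  0.9940  0.0001
...
Average  0.9941  0.9941  0.0001

mean-correlation advantage of wave masking: +0.0172

paired t-tests on per-record RMSE (positive t favours wave masking):
  V1: t =   70.84, p = 5.00e-51 *
```

Each table row is the distribution of per-record correlations between a
reconstructed lead and its recorded original on held-out patients; the
masked pipeline converts the systematic misspecification of the 3-lead model
into noise-limited accuracy, and the paired t-tests mark the improvement
significant on every lead.  The other example scripts demonstrate cohort
simulation, delineation + masking, transform fitting (OLS/SGD against the
generator's exact mixing), and the neural baselines.

A thin CLI wires the same stages together with config files and run
manifests:

```sh
ecgrecon simulate --out cohort --seed 1
ecgrecon run --variant wmlr --fiducials truth --seed 1 --out report
ecgrecon compare report_a report_b --out comparison.json
```

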