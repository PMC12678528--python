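# Methods

## The reconstruction model

All processing treats an ECG record as a matrix of millivolt samples, one
column per lead, at a working rate of 500 Hz over 10 s windows.  The
reconstruction target is the set of precordial leads not present in the
reduced recording set; the limb leads III, aVR, aVL, aVF are never modelled
because they are exact algebraic combinations of leads I and II (Einthoven's
law and the Goldberger augmented-lead definitions), applied per sample.

The core model is a time-invariant per-sample linear transform `y = A x + C`.
Every time sample of every training record is one observation, and training
folds pool samples across patients: the fitted transform is a *generic*
(population-level) one, not a per-patient calibration.  Three input
configurations are supported: leads I, II, V2 (`p1`); leads I, II, V3 (`p2`);
and the wave-masked augmented stack (`wmlr`) consisting of
`[P-masked, QRS-masked, T-masked, I, II, V3]` in that fixed channel order.

Wave masking isolates one wave by zeroing every sample outside that wave's
delineated segments.  The default wave-to-lead assignment takes P from
lead II, QRS from V3 and T from lead I; it is configurable, as is the padding
value for masked regions (zero by default, and zero is the only padding the
verification suite exercises).  Masking intervals are half-open `[on, off)`
in 0-based sample indices, and the three wave segment sets of a beat are
disjoint by construction, so for any lead the P, QRS and T masks sum back to
the lead exactly on the segment union and to zero elsewhere.

Why masking can help: a transform of three raw leads can only apply one
weighting to the whole beat.  If the waves project to the body surface with
wave-specific gains (different spatial sources for atrial depolarization,
ventricular depolarization and repolarization), the per-wave information is
not linearly separable from three mixed channels, but the masked channels
hand it to the model directly.  The synthetic generator makes this mechanism
literal (below), which is what the end-to-end checks verify.

## Fitting

`fit_ols` solves the least-squares problem in closed form on centered data
(`numpy.linalg.lstsq`), returning the minimum-norm solution with a warning
when the inputs are rank-deficient — which is expected behaviour for the
augmented stack on cohorts whose leads span fewer dimensions than the six
channels.  Predictions, not coefficients, are the stable object in that
regime.

`fit_sgd` is a seeded mini-batch SGD fit performed on channels standardized
with training-fold statistics; the stored `A`, `C` are always mapped back to
raw millivolts, so predictions are invariant to the internal scaling (checked
to 1e-9).  Defaults: learning rate 0.05, momentum 0.9, 50 epochs, batch 1024,
early stop when the epoch loss improves by less than 1e-9.  The learning rate
and epoch budget were chosen from a conditioning argument: ECG leads are
strongly collinear (standardized-input correlation spectra of roughly
{3, 0.03, 0.004} on synthetic cohorts), and the smallest eigendirection sets
the number of gradient steps needed; with these defaults the SGD transform
matches OLS to ~2e-3 in standardized coefficients and ~1e-5 mV in prediction
RMSE on well-conditioned cohorts, comfortably inside the package's declared
equivalence contract (1e-2 / 1e-3).  A non-finite loss raises immediately,
naming the epoch.

## Delineation

Only leads I, II and V3 are used, emulating a reduced recording set.

R peaks: band-pass 5–15 Hz (zero-phase Butterworth), derivative, square,
150 ms moving-window integral, peak picking at 20% of the envelope's 99th
percentile with a 200 ms refractory period, then refinement to the absolute
extremum of the raw signal within ±60 ms.

Wave boundaries: the per-lead signal is first baseline-corrected by a
histogram-mode estimate (the isoelectric cluster is the tallest histogram
bin; a plain median is biased when waves occupy more than half the record).
QRS on/offsets are found by walking outward from R until a sustained (8 ms)
run below a low amplitude threshold (max of 5e-4 × R amplitude and 3 × a
noise-floor estimate from the quietest quarter of the record) — the brief
near-zero dips at the Q–R and R–S zero crossings do not trigger the stop, the
isoelectric PQ and ST gaps do.  P is the dominant extremum in a 200 ms window
before the QRS onset, T in a window from the QRS offset to 60% of the local
RR interval; each is accepted only above 5% of the R amplitude (relative, so
delineation is invariant to amplitude scaling) and its boundaries come from a
two-stage walk: a coarse sustained crossing at 5% of the wave peak, extended
toward a 5e-4-of-peak return-to-baseline threshold.  On clean signals the
boundaries land where the wave genuinely vanishes (within ~2 samples of a
truncated-Gaussian support edge); under noise the walk stops earlier, at the
coarse bound.

The three per-lead delineations are fused by matching beats on nearest R peak
(≤150 ms) and taking the per-fiducial median across the leads where the wave
was found.  Overlap repair gives QRS priority (P offsets clipped to the QRS
onset, T onsets to the QRS offset) and clamps every fiducial to the previous
beat's trailing edge; intervals emptied by clipping become absent.  Absent
waves simply contribute no masking segment.  Externally produced fiducials
can be imported from a one-file-per-record CSV dialect
(`beat,p_on,p_off,qrs_on,qrs_off,t_on,t_off,r_peak`, absent values empty) and
are validated against the same invariants.

## Preprocessing

Records are trimmed to the first `round(duration × fs)` samples, resampled by
polyphase rational resampling with anti-aliasing, and denoised with zero-phase
4th-order Butterworth filters: highpass 0.3 Hz (baseline wander), lowpass
100 Hz, optional 50/60 Hz mains notch (off by default).  Zero-phase filtering
preserves fiducial timing and is linear to numerical precision.  When the
metadata does not carry a blank-lead flag, a lead counts as blank iff its
absolute maximum stays below 1e-6 mV.  CSV record files carry only a header
of lead names, so readers take the sampling rate as an argument (default
500 Hz, the package's working rate); WFDB headers carry their own rate and
gain, and amplitudes are converted to mV on load (int16 storage at
1000 adu/mV quantizes to 0.001 mV, the one reader/writer pair that is exact
only to half that step rather than bit-exact).

## The synthetic generator

Each beat is a sum of truncated Gaussians — P, Q, R, S, T components with
per-component amplitude (mV), center relative to the R peak (s) and width
sigma (s), hard-truncated at ±4 sigma so every wave has a provably bounded
support whose half-open sample interval the generator reports as the exact
fiducial.  Defaults describe a typical adult sinus beat on the lead II scale:

| component | amplitude | center | sigma |
|-----------|-----------|--------|-------|
| P         | 0.15      | −150 ms | 18 ms |
| Q         | −0.12     | −22 ms  | 7 ms  |
| R         | 1.10      | 0       | 10 ms |
| S         | −0.25     | 28 ms   | 9 ms  |
| T         | 0.45      | 255 ms  | 30 ms |

Heart rate is drawn per patient from 50–90 bpm, RR intervals jitter by ±5%
per beat, and per-patient morphology jitter multiplies amplitudes by ±20% and
widths by ±10% (records of one patient share morphology and rate; seeding is
hierarchical cohort → patient → record, so cohorts are bit-reproducible).
The geometry guarantees disjoint P/QRS/T supports and no inter-beat overlap
across the whole parameter range; a morphology that violates this raises
rather than silently overlapping.

Leads are linear mixtures of the three wave sources plus a per-lead constant:
`lead_ℓ(t) = Σ_w M[ℓ,w] · s_w(t) + c_ℓ`.  The recording leads I, II, V3 have
zero offsets (they model baseline-corrected inputs, which also keeps the
masked channels pure scaled copies of the wave sources); the reconstruction
targets carry small nonzero constants so the intercept `C` is genuinely
exercised.  Limb leads are rendered from the I and II rows, so the Einthoven
and Goldberger identities hold by construction.  Optional white noise is
added per lead at a configured SNR (power ratio against the clean lead).

Two mixing modes define the two study regimes:

- **global** — one full-rank 12×3 gain matrix whose {I, II, V3} rows are
  linearly independent.  Every lead is then an *exact* linear function of the
  three input leads; the generator exposes the true `(A, C)` in closed form,
  giving the parameter-recovery and r≈1 sanity limits.
- **per_wave** — the I and II rows share a fixed QRS:T gain ratio and V3's
  row is an exact linear combination of them (the inputs span only two of the
  three wave dimensions), while each output lead's row is its in-span
  projection modulated per wave by `(1 ± d)` with disparity `d`.  The 3-lead
  model is then misspecified with residual growing monotonically in `d`,
  while the 6-channel masked model (given true fiducials) remains exact —
  a constructive, tunable test of the masking mechanism.  At `d = 0.2` and
  20 dB SNR the held-out mean-correlation advantage of masking is ≈ +0.017.

What the generator does *not* emulate: pathological morphologies (AF, bundle
branch block, ectopy), baseline wander and electrode artefacts, beat-to-beat
morphology variability within a record, T-P fusion at high heart rates, and
any nonlinear torso volume-conductor physics.  Passing the end-to-end checks
therefore demonstrates the pipeline's correctness and the masking mechanism
under the linear-mixing premise — not clinical-grade performance on real
recordings, for which the HDF5/metadata adapter exists.

## Neural baselines

Comparison scaffolding at desk scale, consuming the same per-sample datasets
as the linear pipelines and predicting in raw mV (inputs/outputs standardized
internally): a committee of feed-forward networks (two tanh hidden layers of
32 units and a linear head, 5 members trained on identical data with
different seeds, predictions averaged) built on scikit-learn's MLPRegressor,
and a two-layer LSTM (hidden 64 by default, tanh activations, per-timestep
linear head) implemented in numpy with Adam and backpropagation through time
on fixed windows (500 samples).  Training is CPU-only, seeded and
deterministic; these baselines make no accuracy claims beyond their sanity
properties.

## Evaluation conventions

Pearson r and RMSE are computed per record, per lead, over all samples of the
record, then aggregated across test records pooled over the folds.  Records
with a constant original or predicted signal have undefined correlation
(zero denominator); they are excluded from the r aggregates and counted in
the report.  Patient-wise k-fold cross-validation (k = 5) assigns whole
patients to folds of near-equal size (±1), deterministically per seed, so no
patient contributes to both sides of a fold.

Aggregate tables report median, mean and SD per lead plus an unweighted
"Average" row, and box-plot summaries (quartiles, min, max).  SD defaults to
the sample convention (ddof = 1, matching the package's worked reference
values) with a ddof switch; at cohort scale the distinction is immaterial,
but a fixed choice keeps outputs deterministic.  Pipeline comparisons use
classical paired t-tests on per-record per-lead RMSE from the same folds,
two-sided at p < 0.05, with no multiple-testing correction (noted in the
report output); degenerate cases are flagged (all-zero differences → t = 0,
p = 1; zero-variance nonzero differences → p = 0).

## Numerical choices and scale

Fixtures and verification cohorts are sized for a single CPU: 10–50 patients
per cohort, 10 s records at 500 Hz, which keeps the full test suite under
half a minute and the acceptance script under one.  Tolerances follow the
source of error: bit-exact where the operation is exact (masking, CSV
round-trips, raw channel pass-through), 1e-9 for linear-algebra identities,
1e-6 for parameter recovery from 1e5 observations, 1e-2/1e-3 for the
SGD–OLS equivalence, ±10 ms for fiducial recovery, and ±1 dB for SNR
calibration.  Ties and degenerate inputs are resolved explicitly: constant
channels get unit scale in standardization, rank-deficient fits return the
minimum-norm solution with a warning, and fold assignment uses a seeded
permutation with round-robin allocation.
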