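# Methods

## The analysis model

The package treats a 19-channel EEG recording as noisy observations of a
small number of latent processes. Three quantities summarise a condition:

1. **Band power.** Welch PSD per channel (Hann taper, 2 s windows, 50%
   overlap → 0.5 Hz resolution, enough to separate a ~1.2 Hz delta peak from
   the 0.5 Hz analysis edge), integrated (trapezoid) over delta 0.5–4,
   theta 4–8, alpha 8–13 and beta 13–30 Hz. These conventional band edges
   tile the 0.5–30 Hz preprocessing band.
2. **Participation ratio.** For the epoch covariance C with eigenvalues λᵢ,
   `Dim(C) = (Σλᵢ)²/Σλᵢ²`. It is scale-invariant, equals the channel count
   for isotropic covariance and 1 for rank-one covariance. Covariance uses
   the N−1 denominator on 10-s epochs; per-condition values average over
   epochs. Eigenvalues that come out slightly negative from round-off are
   clipped to zero.
3. **Latent attractor geometry.** A variational auto-encoder maps each time
   sample (a 19-vector) to a J-dimensional Gaussian posterior. The top-3
   (by variance) posterior-mean coordinates form a trajectory; its
   total-least-squares plane, the dihedral angle of that plane to the
   rest-condition reference plane, and the direct least-squares ellipse fit
   of the in-plane trajectory give per-trial (long, short) semi-axis
   features used for ANOVA and classification.

## Synthetic study generator

No EEG of this design is publicly deposited, so the generator is a
first-class module that emulates the study layout: 19 channels in the 10–20
montage at 256 Hz, four conditions (rest plus manipulation at 50/100/150
twirls/min), 3 min each (60 s in the scaled test/acceptance runs),
segmented into 10-s epochs.

Per condition the signal is

```
x(t) = W R(θ) l(t) + g_δ A (u_δ sin 2π·1.2t + v_δ cos 2π·1.2t)
     + g_α A (u_α sin 2π·10t + v_α cos 2π·10t) + ε(t)
```

* `l(t)` — latent ellipse `(a cos ωt, b sin ωt, 0)` plus in-plane jitter
  (sd 0.05) and off-plane noise (sd 0.05). ω is one revolution per twirl
  (manip_freq/60 Hz); the rest condition drifts at 0.8 Hz, kept inside the
  analysis band so preprocessing does not erase the rest-state ellipse.
* `R(θ)` — rotation about the first latent axis by the condition's plane
  angle; `W` — a per-subject random 19×3 matrix with orthonormal columns.
* Carriers — delta (1.2 Hz) and alpha (10 Hz) oscillations with spatial
  loadings u, v drawn from per-channel uniform phases and then
  **orthogonalised against the columns of W** (and each other). This makes
  band power and latent geometry separately controllable: the carriers
  cannot leak into the latent subspace, so projecting a recording through
  Wᵀ recovers the rotated latent exactly up to channel noise. The stored
  `study.json` sidecar (seeds + StateSpecs) supports such recovery tests.
* `ε` — white Gaussian channel noise (sd 0.08); base carrier amplitude
  A = 0.3 per channel at gain 1.

Default condition parameters:

| condition | manip (min⁻¹) | δ gain | α gain | plane angle | a | b |
|-----------|---------------|--------|--------|-------------|-----|-----|
| pre_acu | 0 | 1.0 | 1.0 | 0° | 1.0 | 0.8 |
| acu_50 | 50 | 4.0 | 1.1 | 15° | 1.4 | 0.8 |
| acu_100 | 100 | 2.5 | 1.6 | 30° | 1.7 | 0.8 |
| acu_150 | 150 | 1.2 | 2.0 | 45° | 2.0 | 0.8 |

Rationale: delta gain peaks at 50 twirls/min (resonance-like enhancement
near the intrinsic ~1.2 Hz rhythm), alpha gain grows with manipulation
rate, plane angle is linear in rate (slope 0.30°·min/twirl), and the
ellipse long axis grows with rate at fixed short axis. The eigenvalue
budget matters: the delta-carrier pair must dominate the covariance at
50 twirls/min for the participation ratio to be *minimal* there. If the
latent ellipse instead dominated every condition, its long-axis growth
would force the dimensionality minimum to 150 twirls/min — with these
gains the broadband participation ratio comes out ≈ 5.8 (rest), 2.7 (50),
4.5 (100), 4.5 (150), and delta/alpha run lower-dimensional than
theta/beta, reproducing the qualitative study pattern.

What the generator does **not** emulate: 1/f background spectra, eye-blink
and muscle artifacts, inter-subject montage variability, nonstationarity
within a condition, or volume-conduction structure. Passing tests therefore
show that the *analysis chain* behaves as specified on data satisfying its
assumptions, not that real acupuncture EEG has these properties.

## Preprocessing choices

* FIR band-pass: Hamming-windowed sinc, transition width
  `min(lo, (hi−lo)/2, 2 Hz)`, odd tap count `⌈3.3·fs/transition⌉`
  (≈ 53 dB stopband, < 0.1 dB passband ripple, doubled by
  forward–backward application). Applied zero-phase via `filtfilt` with
  even-extension padding, which keeps boundary transients small; signals
  that stop abruptly at a non-zero value still show edge leakage, so
  attenuation is specified against steady-state behaviour.
* Average re-reference subtracts the instantaneous cross-channel mean
  (idempotent, difference-preserving).
* Segmentation drops any trailing partial epoch.

## VAE design

The observation likelihood is Gaussian with unit variance on per-channel
z-scored data (the standardization affinity is stored in the model and
undone on reconstruction; the correlation metric is scale-invariant
anyway). Architecture: encoder 19 → 32 (tanh) → 2J heads (μ and log σ²),
decoder J → 32 (tanh) → 19, Glorot-initialised from a seed; `hidden=()`
gives the linear special case. Training minimises the negative ELBO with
L = 1 reparameterized draw per sample, minibatches of 20, and a choice of
plain SGD (library default, lr 1e-3), momentum, or Adam. The pipeline
default is Adam (lr 1e-3, 8 passes, every-4th-sample thinning of the
training set): plain SGD at a fixed small rate needs many more passes to
converge on standardized EEG batches, and Adam is itself a stochastic
gradient method. Training is bit-reproducible given the seed. One model is
trained per subject over all of that subject's conditions — inter-plane
angles are only meaningful when all conditions share one latent space (the
per-condition training unit remains available in the API).

**Gauge caveat.** A VAE latent space is identified only up to an affine
map (and the prior pushes pooled posteriors toward unit variance, i.e.
toward whitening). Within one subject this map is common to all
conditions, so per-condition differences — and hence classification —
survive it, but absolute plane angles and axis lengths measured in latent
coordinates are distorted. Quantitative geometry recovery (angles to 3°,
axes to 10%, regression slope to 10%) is therefore validated through the
generator's ground-truth unmixing (`recover_latent`, using the sidecar's
mixing seed); the VAE-route geometry is exported as data and used for
classification. Under the default study conditions the dominant latent
pair at 50 twirls/min is the delta-carrier oscillation, so the fitted
"attractor" there reflects the enhanced delta rhythm — consistent with
reading the attractor as the dominant oscillatory mode pair.

Per-trial features are normalised by each subject's mean long axis before
classification (`normalize_features="subject_mean"`), removing the
per-subject latent scale freedom; set `"none"` to disable.

## Numerical choices

* Plane fits: SVD of centred points; degenerate if the second singular
  value is ≤ 1e−9 of the first. Basis signs fixed by making the first
  non-negligible component positive, so angles are well defined. Dihedral
  angle via `atan2(‖n_a×n_b‖, |n_a·n_b|)` (stable near 0° and 90°),
  reported unsigned in [0°, 90°].
* Ellipse fits: Halir–Flusser direct least squares with the 4ac−b² = 1
  ellipse constraint, on centred/scaled coordinates for conditioning;
  semi-axes from the conic eigen-structure, a ≥ b enforced, orientation in
  [0, π), RMS algebraic residual reported. Non-elliptic solutions raise a
  degenerate-fit error. "Mean distance of the long and short axes" is
  implemented as the mean semi-axis length per condition.
* Latent trajectory ordering: descending posterior-mean variance, ties
  broken by original index (stable sort).
* Cross-validation: stratified folds (18 trials × 4 conditions would
  otherwise risk empty-class folds), standardization fitted inside each
  training fold only; classifier hyperparameters are scikit-learn defaults
  with a fixed seed.
* EDF output: 16-bit encoding with per-channel physical scaling, 1-second
  records; quantization error is bounded by the channel range / 65535.

## Problem sizes

Tests and the acceptance script run the study at 60 s per condition
(6 epochs) with 1 subject for the reconstruction sweep and 4 subjects for
dimensionality, geometry recovery and classification; the generator's
default remains the full 180 s / 18-epoch layout. These sizes were chosen
so the whole suite exercises every stage end to end at comfortable margins
(e.g. the reconstruction sweep and classification results are stable
across seeds at this size).

## Known limitations

* The Gaussian unit-variance likelihood makes the reconstruction term plain
  squared error; heteroscedastic or heavy-tailed channels are not modelled.
* The ANOVA on long-vs-short axes treats trials as independent; epochs cut
  from one continuous recording are weakly dependent.
* The angle–frequency regression through the VAE route inherits the gauge
  distortion discussed above; only the ground-truth route is quantitative.
* No artifact rejection, ICA, re-sampling, scalp interpolation or
  topographic rendering (per-channel tables stand in for topographies).
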