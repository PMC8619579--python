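# aculatent

Low-dimensional latent dynamics of multichannel EEG under manual acupuncture.

Manual needle manipulation at an acupoint (e.g. ST36, at 50/100/150 twirls per
minute) changes the large-scale oscillatory structure of the EEG: power rises
in the delta (~1.2 Hz) and alpha (~10 Hz) bands, the effective dimensionality
of the 19-channel signal drops, and the dominant latent trajectory traces an
elliptic attractor whose plane orientation and axis lengths depend on the
manipulation rate. `aculatent` implements that whole analysis chain as a
tested Python package, driven by a synthetic-study generator (no public EEG
of this kind exists), for researchers who want to reproduce, probe or extend
the method on data with known ground truth.

## What it computes

* **Preprocessing** — zero-phase FIR band-pass (0.5–30 Hz), average
  re-reference, segmentation into 10-s epochs (2560 samples at 256 Hz).
* **Spectral analysis** — Welch PSD (Hann, 2 s windows, 50% overlap), band
  powers over delta/theta/alpha/beta, between-condition power differences,
  Welch *t*-tests.
* **Dimensionality** — the participation ratio of the channel covariance
  `C` with eigenvalues `λᵢ`:

  `Dim(C) = (Σᵢ λᵢ)² / Σᵢ λᵢ²  ∈ [1, n_channels]`,

  equal to 19 for independent equal-variance channels and 1 for perfectly
  correlated activity; computed broadband and per sub-band.
* **VAE latent extraction** — a small dense variational auto-encoder
  (19 → 32 tanh → 2J encoder; J → 32 tanh → 19 decoder, numpy with
  hand-written backpropagation) trained by minibatch gradient descent
  (batch 20) on the ELBO

  `E_q[log p(x|z)] − KL(q(z|x) ‖ N(0, I))`,

  with the reparameterization trick and the closed-form Gaussian KL
  `−½ Σⱼ (1 + log σⱼ² − μⱼ² − σⱼ²)`.
* **Latent geometry** — total-least-squares plane fits of 3-D latent
  trajectories (the in-plane basis p1, p2 are the "acupuncture modes"),
  unsigned dihedral angles to the rest-state reference plane, the
  angle-vs-frequency regression, and direct least-squares
  (Fitzgibbon/Halir–Flusser) elliptic-attractor fits giving long/short
  semi-axes per trial.
* **Statistics & classification** — one-way ANOVA on axis lengths, and
  condition classification from (long, short) axis features with SVM, KNN,
  LDA and decision tree under stratified 5-fold cross-validation repeated
  10 times.

## Worked example

```python
from aculatent import SyntheticConfig
from aculatent.pipeline import PipelineConfig, run

cfg = PipelineConfig(synthetic=SyntheticConfig(n_subjects=2, duration_s=60.0))
results = run(cfg, "results")
print(results["dimensionality"].query("band == 'broadband'")
      .groupby("condition")["dim"].mean().round(2).to_string())
print(results["classification"].round(3).to_string())
print({k: round(v, 3) for k, v in results["reconstruction"].items()})
```

prints

```
condition
acu_100    4.51
acu_150    4.46
acu_50     2.68
pre_acu    5.83
       mean_accuracy  sd_accuracy
model
SVM            1.000        0.000
KNN            1.000        0.000
LDA            0.958        0.060
DT             0.992        0.042
{'s00': 0.889, 's01': 0.903}
```

Broadband dimensionality is highest at rest (5.83) and minimal at
50 twirls/min (2.68) — manipulation makes the activity more correlated,
most strongly when the stimulation rate sits near the intrinsic ~1.2 Hz
rhythm. All four classifiers separate the four conditions from the two
attractor-axis features almost perfectly, and a J=4 VAE reconstructs the
channels with mean correlation ≈ 0.89.

Because a VAE latent space is only defined up to an affine map, quantitative
subspace geometry is validated through the generator's stored ground truth
(the `study.json` sidecar):

```python
from aculatent import SyntheticConfig, generate_study, recover_latent
from aculatent import geometry

cfg = SyntheticConfig(n_subjects=2, duration_s=60.0)
study = generate_study(cfg)
recs = {r.condition: r for r in study if r.subject_id == "s00"}
ref = geometry.fit_plane(recover_latent(recs["pre_acu"], cfg, 0))
for cond, rec in recs.items():
    est = recover_latent(rec, cfg, 0)
    plane = geometry.fit_plane(est)
    fit = geometry.fit_ellipse(geometry.project_to_plane(est, plane))
    print(cond, round(geometry.plane_angle(plane, ref), 2),
          round(fit.long_axis, 2), round(fit.short_axis, 2))
```

```
pre_acu 0.0 1.0 0.82
acu_50 15.0 1.39 0.82
acu_100 29.9 1.68 0.82
acu_150 44.95 1.97 0.82
```

recovering the constructed plane angles (0/15/30/45°, i.e. linear in
manipulation frequency, slope 0.30°·min/twirl with R² = 1.00) and the
ellipse semi-axes to a few percent.

There is also a CLI:

```bash
acu-latent generate --out dataset --format edf   # write the synthetic study
acu-latent run --config config.yaml --out results
```

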