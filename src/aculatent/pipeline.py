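"""End-to-end analysis pipeline.

Chains the stages in study order: synthetic study generation (or loading) ->
preprocessing -> Welch spectral analysis -> participation-ratio
dimensionality -> per-subject VAE training -> latent-subspace geometry
(planes, angles, elliptic attractors) -> axis ANOVA and condition
classification.  ``run`` writes every stage's output as delimited tables
plus a JSON manifest of seeds and configuration.
"""
from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dimensionality as dim
from . import geometry, preprocess, spectral, stats, vae
from .core import DEFAULT_BANDS, Recording
from .synthetic import SyntheticConfig, generate_study


@dataclass
class VaeTrainingConfig:
    """Per-subject VAE settings; one model per subject, pooled over
    conditions so all conditions share a latent space."""

    J: int = 4
    hidden: tuple[int, ...] = (32,)
    n_epochs: int = 8
    batch_size: int = 20
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    stride: int = 4          # time subsampling of training samples
    seed: int = 7


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    vae: VaeTrainingConfig = field(default_factory=VaeTrainingConfig)
    epoch_len_s: float = 10.0
    bandpass_lo: float = 0.5
    bandpass_hi: float = 30.0
    welch_window_s: float = 2.0
    welch_overlap: float = 0.5
    reference_condition: str = "pre_acu"
    normalize_features: str = "subject_mean"  # or "none"
    cv_folds: int = 5
    cv_repeats: int = 10
    cv_seed: int = 0


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def preprocess_study(recordings: list[Recording], cfg: PipelineConfig) -> list[Recording]:
    return [preprocess.preprocess_recording(r, cfg.bandpass_lo, cfg.bandpass_hi)
            for r in recordings]


def spectral_tables(recordings: list[Recording], cfg: PipelineConfig):
    """Per-epoch band powers and acupuncture-vs-rest PSD differences."""
    summaries: dict[tuple[str, str], list[spectral.SpectralSummary]] = {}
    rows = []
    for rec in recordings:
        eps = preprocess.segment(rec, cfg.epoch_len_s)
        ss = [spectral.welch_psd(ep, rec.fs, cfg.welch_window_s, cfg.welch_overlap,
                                 channel_labels=rec.channel_labels)
              for ep in eps]
        summaries[(rec.subject_id, rec.condition)] = ss
        for i, s in enumerate(ss):
            for band_name, powers in s.band_powers.items():
                for ch, p in zip(rec.channel_labels, powers):
                    rows.append({"subject": rec.subject_id, "condition": rec.condition,
                                 "epoch": i, "channel": ch, "band": band_name,
                                 "power": p})
    band_powers = pd.DataFrame(rows)

    diffs = []
    conditions = list(dict.fromkeys(r.condition for r in recordings))
    subjects = list(dict.fromkeys(r.subject_id for r in recordings))
    ref = next((c for c in conditions if c == "pre_acu"), conditions[0])
    for subj in subjects:
        for cond in conditions:
            if cond == ref or (subj, cond) not in summaries:
                continue
            d = spectral.psd_difference(summaries[(subj, cond)], summaries[(subj, ref)])
            d = d.reset_index().assign(subject=subj, condition=cond)
            diffs.append(d)
    psd_diff = pd.concat(diffs, ignore_index=True) if diffs else pd.DataFrame()
    return band_powers, psd_diff, summaries


def dimensionality_table(recordings: list[Recording], cfg: PipelineConfig) -> pd.DataFrame:
    return pd.concat(
        [dim.band_dimensionality(r, DEFAULT_BANDS, cfg.epoch_len_s) for r in recordings],
        ignore_index=True,
    )


def train_subject_models(recordings: list[Recording], cfg: PipelineConfig):
    """One VAE per subject over all of that subject's conditions."""
    models: dict[str, vae.VaeModel] = {}
    histories: dict[str, list[float]] = {}
    subjects = list(dict.fromkeys(r.subject_id for r in recordings))
    for si, subj in enumerate(subjects):
        recs = [r for r in recordings if r.subject_id == subj]
        data = [r.data for r in recs]
        model = vae.init_vae(recs[0].n_channels, cfg.vae.J, cfg.vae.hidden,
                             seed=cfg.vae.seed + si)
        model, hist = vae.train(
            model, data, n_epochs=cfg.vae.n_epochs, batch_size=cfg.vae.batch_size,
            learning_rate=cfg.vae.learning_rate, seed=cfg.vae.seed + si,
            optimizer=cfg.vae.optimizer, stride=cfg.vae.stride,
        )
        models[subj] = model
        histories[subj] = hist
    return models, histories


def geometry_tables(recordings: list[Recording], models: dict[str, vae.VaeModel],
                    cfg: PipelineConfig):
    """Condition planes, angles to the rest-state reference plane, per-epoch
    elliptic attractor fits, and the long/short axis feature table."""
    plane_rows, feat_rows = [], []
    subjects = list(dict.fromkeys(r.subject_id for r in recordings))
    for subj in subjects:
        model = models[subj]
        recs = [r for r in recordings if r.subject_id == subj]
        planes: dict[str, geometry.PlaneModel] = {}
        trajs: dict[str, vae.LatentTrajectory] = {}
        for rec in recs:
            traj = vae.latent_trajectory(model, rec.data, rec.fs,
                                         subject_id=subj, condition=rec.condition)
            trajs[rec.condition] = traj
            planes[rec.condition] = geometry.fit_plane(traj)
        ref = planes.get(cfg.reference_condition)
        for rec in recs:
            plane = planes[rec.condition]
            angle = geometry.plane_angle(plane, ref) if ref is not None else np.nan
            plane_rows.append({
                "subject": subj, "condition": rec.condition,
                "angle_deg": angle, "residual_frac": plane.residual_frac,
            })
            eps = preprocess.segment(rec, cfg.epoch_len_s)
            for i, ep in enumerate(eps):
                etraj = vae.latent_trajectory(model, ep, rec.fs,
                                              subject_id=subj,
                                              condition=rec.condition, trial=i)
                pts = geometry.project_to_plane(etraj, plane)
                fit = geometry.fit_ellipse(pts)
                feat_rows.append({
                    "subject": subj, "condition": rec.condition, "trial": i,
                    "long_axis": fit.long_axis, "short_axis": fit.short_axis,
                    "fit_residual": fit.fit_residual,
                })
    planes_df = pd.DataFrame(plane_rows)
    features = pd.DataFrame(feat_rows)
    if cfg.normalize_features == "subject_mean" and not features.empty:
        scale = features.groupby("subject")["long_axis"].transform("mean")
        features["long_axis"] = features["long_axis"] / scale
        features["short_axis"] = features["short_axis"] / scale
    return planes_df, features


def angle_regression(planes_df: pd.DataFrame, freq_by_condition: dict[str, float],
                     reference: str = "pre_acu"):
    """OLS of the recovered plane angle on manipulation frequency (the
    reference condition enters at frequency 0)."""
    sub = planes_df.dropna(subset=["angle_deg"])
    freqs = sub["condition"].map(freq_by_condition)
    return geometry.angle_frequency_regression(sub["angle_deg"].to_numpy(),
                                               freqs.to_numpy())


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run(cfg: PipelineConfig, out_dir: str | Path,
        recordings: list[Recording] | None = None) -> dict:
    """Execute every stage and write the results directory.

    Returns the in-memory results as a dict of DataFrames/objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if recordings is None:
        recordings = generate_study(cfg.synthetic)
    pre = preprocess_study(recordings, cfg)

    band_powers, psd_diff, _ = spectral_tables(pre, cfg)
    band_powers.to_csv(out / "band_powers.tsv", sep="\t", index=False)
    if not psd_diff.empty:
        psd_diff.to_csv(out / "psd_difference.tsv", sep="\t", index=False)

    dims = dimensionality_table(pre, cfg)
    dims.to_csv(out / "dimensionality.tsv", sep="\t", index=False)

    models, histories = train_subject_models(pre, cfg)
    pd.DataFrame(histories).rename_axis("pass").to_csv(out / "vae_loss.tsv", sep="\t")
    recon = {
        subj: vae.reconstruction_performance(
            models[subj],
            [r.data for r in pre if r.subject_id == subj])
        for subj in models
    }
    pd.Series(recon, name="mean_correlation").rename_axis("subject") \
        .to_csv(out / "reconstruction.tsv", sep="\t")

    planes_df, features = geometry_tables(pre, models, cfg)
    planes_df.to_csv(out / "planes.tsv", sep="\t", index=False)
    features.to_csv(out / "attractor_features.tsv", sep="\t", index=False)

    freq_map = {s.label: s.manip_freq for s in cfg.synthetic.states}
    slope, intercept, r2 = angle_regression(planes_df, freq_map,
                                            cfg.reference_condition)

    tables = stats.axis_anova(features)
    tables["within"].to_csv(out / "anova_within.tsv", sep="\t")
    tables["between"].to_csv(out / "anova_between.tsv", sep="\t", index=False)

    accuracy = stats.compare_models(features, k=cfg.cv_folds,
                                    repeats=cfg.cv_repeats, seed=cfg.cv_seed)
    accuracy.to_csv(out / "classification.tsv", sep="\t")

    manifest = {
        "python": platform.python_version(),
        "config": _config_dict(cfg),
        "angle_regression": {"slope": slope, "intercept": intercept, "r2": r2},
        "reconstruction": recon,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "band_powers": band_powers, "psd_difference": psd_diff,
        "dimensionality": dims, "models": models, "loss": histories,
        "reconstruction": recon, "planes": planes_df, "features": features,
        "angle_regression": (slope, intercept, r2), "anova": tables,
        "classification": accuracy,
    }


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["vae"]["hidden"] = list(d["vae"]["hidden"])
    return d
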