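"""Synthetic 19-channel EEG study generator.

Emulates a manual-acupuncture EEG experiment: four conditions (rest with the
needle inserted, and needle manipulation at 50/100/150 twirls per minute),
each a 3-minute 19-channel recording at 256 Hz.  Each condition is built from

* a 3-dimensional latent trajectory tracing a noisy ellipse whose semi-axes
  and embedding-plane orientation depend on the condition,
* two narrowband "carrier" oscillations near 1.2 Hz (delta) and 10 Hz (alpha)
  with condition-dependent gains, emulating the oscillatory enhancement that
  needle manipulation produces, and
* white channel noise.

The latent trajectory is rotated about the first latent axis by a
condition-dependent plane angle and mixed into the channels through a random
orthonormal 19 x 3 matrix (one per subject).  The carrier spatial loadings are
orthogonalised against the mixing columns so that band power and latent
geometry are independently controllable; ground truth is stored in a JSON
sidecar so recovery tests can invert the construction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import CHANNELS_1020, Recording

#: Latent cycle rate for the rest condition (Hz). Kept inside the 0.5-30 Hz
#: analysis band so the rest-state ellipse survives preprocessing.
PRE_ACU_CYCLE_HZ = 0.8


@dataclass
class StateSpec:
    """One experimental condition and its generative parameters.

    Parameters
    ----------
    label
        Condition name (``pre_acu``, ``acu_50``, ``acu_100``, ``acu_150``).
    manip_freq
        Needle manipulation rate in twirls per minute (0 for rest).
    delta_gain, alpha_gain
        Dimensionless amplitude multipliers for the 1.2 Hz and 10 Hz carriers.
    plane_angle_deg
        Rotation of the latent embedding plane relative to the rest condition.
    ellipse_a, ellipse_b
        Semi-axes of the latent elliptic trajectory (arbitrary units).
    noise_sd
        Additive white channel noise standard deviation.
    """

    label: str
    manip_freq: float
    delta_gain: float = 1.0
    alpha_gain: float = 1.0
    plane_angle_deg: float = 0.0
    ellipse_a: float = 1.0
    ellipse_b: float = 0.8
    noise_sd: float = 0.08

    def __post_init__(self) -> None:
        if not (self.ellipse_a >= self.ellipse_b > 0):
            raise ValueError("need ellipse_a >= ellipse_b > 0")
        if not (0 <= self.plane_angle_deg <= 90):
            raise ValueError("plane_angle_deg must lie in [0, 90]")
        if self.delta_gain <= 0 or self.alpha_gain <= 0:
            raise ValueError("gains must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def cycle_hz(self) -> float:
        """Latent ellipse revolution rate: one cycle per twirl for
        manipulation conditions, a slow drift for rest."""
        return self.manip_freq / 60.0 if self.manip_freq > 0 else PRE_ACU_CYCLE_HZ


def default_states() -> list[StateSpec]:
    """The four default study conditions.

    Delta gain peaks at 50 twirls/min (near the ~1.2 Hz intrinsic rhythm, the
    resonance-like enhancement), alpha gain grows with manipulation rate, the
    embedding-plane angle is linear in manipulation rate, and the ellipse long
    axis grows with manipulation rate while the short axis is fixed.
    """
    return [
        StateSpec("pre_acu", 0, delta_gain=1.0, alpha_gain=1.0,
                  plane_angle_deg=0.0, ellipse_a=1.0, ellipse_b=0.8),
        StateSpec("acu_50", 50, delta_gain=4.0, alpha_gain=1.1,
                  plane_angle_deg=15.0, ellipse_a=1.4, ellipse_b=0.8),
        StateSpec("acu_100", 100, delta_gain=2.5, alpha_gain=1.6,
                  plane_angle_deg=30.0, ellipse_a=1.7, ellipse_b=0.8),
        StateSpec("acu_150", 150, delta_gain=1.2, alpha_gain=2.0,
                  plane_angle_deg=45.0, ellipse_a=2.0, ellipse_b=0.8),
    ]


@dataclass
class SyntheticConfig:
    """Full study layout: subjects x conditions, plus generator seeds."""

    n_subjects: int = 4
    n_channels: int = 19
    fs: float = 256.0
    duration_s: float = 180.0
    states: list[StateSpec] = field(default_factory=default_states)
    mixing_seed: int = 1234
    noise_seed: int = 5678
    carrier_amp: float = 0.3      # per-channel carrier amplitude at gain 1
    latent_jitter_sd: float = 0.05  # in-plane jitter around the ellipse
    latent_z_sd: float = 0.05       # off-plane latent noise

    def __post_init__(self) -> None:
        if self.n_channels < 4:
            raise ValueError("need at least 4 channels")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration_s must be an integer sample count")
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels == 19:
            return CHANNELS_1020
        return tuple(f"ch{i:02d}" for i in range(self.n_channels))


# ---------------------------------------------------------------------------
# latent trajectory
# ---------------------------------------------------------------------------

def generate_latent_trajectory(
    state: StateSpec,
    fs: float,
    duration_s: float,
    seed: int,
    jitter_sd: float = 0.05,
    z_sd: float = 0.05,
) -> np.ndarray:
    """Noisy elliptic latent trajectory, shape (samples, 3).

    The first two coordinates trace ``(a cos wt, b sin wt)`` plus Gaussian
    jitter; the third is low-amplitude noise, so the trajectory is confined to
    a plane.  ``w`` is one revolution per needle twirl for manipulation
    conditions and a slow drift for rest.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    w = 2 * np.pi * state.cycle_hz
    rng = np.random.default_rng([int(seed), 91])
    traj = np.empty((n, 3))
    traj[:, 0] = state.ellipse_a * np.cos(w * t)
    traj[:, 1] = state.ellipse_b * np.sin(w * t)
    traj[:, 2] = 0.0
    if jitter_sd > 0:
        traj[:, :2] += rng.normal(0.0, jitter_sd, size=(n, 2))
    if z_sd > 0:
        traj[:, 2] += rng.normal(0.0, z_sd, size=n)
    return traj


def rotation_about_first_axis(angle_deg: float) -> np.ndarray:
    """3x3 rotation by ``angle_deg`` about the first latent axis; tilts the
    trajectory plane by exactly that dihedral angle."""
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[1.0, 0.0, 0.0],
                     [0.0, c, -s],
                     [0.0, s, c]])


# ---------------------------------------------------------------------------
# channel embedding
# ---------------------------------------------------------------------------

def mixing_matrix(n_channels: int, seed: int) -> np.ndarray:
    """Random (n_channels, 3) matrix with orthonormal columns, deterministic
    in ``seed``; sign-fixed so the decomposition is unique."""
    rng = np.random.default_rng([int(seed), 17])
    a = rng.normal(size=(n_channels, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))  # make QR unique
    return q


def carrier_loadings(n_channels: int, seed: int, mixing: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Spatial loading vectors (sine, cosine parts) for the delta and alpha
    carriers.

    Drawn from per-channel phases uniform on [0, 2pi), then orthogonalised
    against the latent mixing columns (and one another) and rescaled to the
    uniform-phase norm, so the carriers live outside the latent subspace.
    """
    rng = np.random.default_rng([int(seed), 53])
    basis = [mixing[:, j].copy() for j in range(mixing.shape[1])]
    target = np.sqrt(n_channels / 2.0)  # norm of a uniform-phase loading
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in ("delta", "alpha"):
        phases = rng.uniform(0, 2 * np.pi, size=n_channels)
        pair = []
        for v in (np.cos(phases), np.sin(phases)):
            for b in basis:
                v = v - (v @ b) / (b @ b) * b
            v = v / np.linalg.norm(v) * target
            basis.append(v)
            pair.append(v)
        out[name] = (pair[0], pair[1])
    return out


def embed_recording(
    latent: np.ndarray,
    state: StateSpec,
    config: SyntheticConfig,
    seed: int,
    subject_index: int = 0,
) -> Recording:
    """Mix a latent trajectory into a 19-channel recording.

    channel = W @ R(plane_angle) @ latent + carriers + white noise, with W the
    subject's orthonormal mixing matrix and carriers at 1.2 Hz / 10 Hz scaled
    by the condition's gains.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 2 or latent.shape[1] != 3:
        raise ValueError("latent must be (samples, 3)")
    if latent.shape[0] != config.n_samples:
        raise ValueError(
            f"latent has {latent.shape[0]} rows, config implies {config.n_samples}"
        )
    n = latent.shape[0]
    t = np.arange(n) / config.fs
    w_mix = mixing_matrix(config.n_channels, config.mixing_seed + subject_index)
    rot = rotation_about_first_axis(state.plane_angle_deg)
    x = w_mix @ rot @ latent.T  # (channels, samples)

    loadings = carrier_loadings(config.n_channels, config.mixing_seed + subject_index, w_mix)
    for name, freq, gain in (("delta", 1.2, state.delta_gain),
                             ("alpha", 10.0, state.alpha_gain)):
        u, v = loadings[name]
        amp = config.carrier_amp * gain
        x += amp * (np.outer(u, np.sin(2 * np.pi * freq * t))
                    + np.outer(v, np.cos(2 * np.pi * freq * t)))

    if state.noise_sd > 0:
        rng = np.random.default_rng([int(seed), 7])
        x += rng.normal(0.0, state.noise_sd, size=x.shape)

    return Recording(
        data=x, fs=config.fs, channel_labels=config.channel_labels(),
        subject_id=f"s{subject_index:02d}", condition=state.label,
    )


def generate_study(config: SyntheticConfig) -> list[Recording]:
    """One Recording per (subject, condition); deterministic given seeds."""
    recs = []
    for s in range(config.n_subjects):
        for k, state in enumerate(config.states):
            seed = config.noise_seed + 1000 * s + k
            latent = generate_latent_trajectory(
                state, config.fs, config.duration_s, seed=seed + 500000,
                jitter_sd=config.latent_jitter_sd, z_sd=config.latent_z_sd,
            )
            recs.append(embed_recording(latent, state, config, seed=seed,
                                        subject_index=s))
    return recs


# ---------------------------------------------------------------------------
# ground-truth recovery helpers
# ---------------------------------------------------------------------------

def recover_latent(rec: Recording, config: SyntheticConfig, subject_index: int) -> np.ndarray:
    """Project a recording back into the subject's 3-dim latent subspace using
    the known mixing matrix (ground-truth route for recovery tests).

    Returns the rotated latent estimate, shape (samples, 3): carriers are
    orthogonal to the mixing columns by construction, so only the rotated
    latent plus projected noise survives.
    """
    w_mix = mixing_matrix(config.n_channels, config.mixing_seed + subject_index)
    return rec.data.T @ w_mix


# ---------------------------------------------------------------------------
# dataset output (delimited / EDF + JSON sidecar)
# ---------------------------------------------------------------------------

def save_study(
    recordings: list[Recording],
    config: SyntheticConfig,
    out_dir: str | Path,
    format: str = "delimited",
) -> list[Path]:
    """Write one file per recording plus a ``study.json`` sidecar holding the
    condition labels, seeds and ground-truth StateSpecs."""
    from . import preprocess  # late import: preprocess owns the file formats

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        stem = f"{rec.subject_id}_{rec.condition}"
        if format == "delimited":
            path = out_dir / f"{stem}.tsv"
            preprocess.write_delimited(rec, path)
        elif format == "edf":
            path = out_dir / f"{stem}.edf"
            preprocess.write_edf(rec, path)
        else:
            raise ValueError(f"unknown format {format!r}")
        paths.append(path)
    sidecar = {
        "n_subjects": config.n_subjects,
        "n_channels": config.n_channels,
        "fs": config.fs,
        "duration_s": config.duration_s,
        "mixing_seed": config.mixing_seed,
        "noise_seed": config.noise_seed,
        "carrier_amp": config.carrier_amp,
        "latent_jitter_sd": config.latent_jitter_sd,
        "latent_z_sd": config.latent_z_sd,
        "states": [asdict(s) for s in config.states],
        "files": [{"path": p.name, "subject": r.subject_id, "condition": r.condition}
                  for p, r in zip(paths, recordings)],
    }
    (out_dir / "study.json").write_text(json.dumps(sidecar, indent=2))
    return paths


def load_config(sidecar_path: str | Path) -> SyntheticConfig:
    """Rebuild a SyntheticConfig from a ``study.json`` sidecar."""
    d = json.loads(Path(sidecar_path).read_text())
    states = [StateSpec(**s) for s in d["states"]]
    return SyntheticConfig(
        n_subjects=d["n_subjects"], n_channels=d["n_channels"], fs=d["fs"],
        duration_s=d["duration_s"], states=states,
        mixing_seed=d["mixing_seed"], noise_seed=d["noise_seed"],
        carrier_amp=d["carrier_amp"], latent_jitter_sd=d["latent_jitter_sd"],
        latent_z_sd=d["latent_z_sd"],
    )
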