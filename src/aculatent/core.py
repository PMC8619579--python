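"""Shared containers for multichannel EEG analysis.

The whole package operates on :class:`Recording` objects — a labelled
channels x samples matrix with a sampling rate — segmented into
:class:`EpochSet` windows for epoch-wise statistics, and on named frequency
bands (:class:`BandDefinition`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: 19-electrode montage of the international 10-20 system.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)


class FormatError(ValueError):
    """A file does not parse as the expected recording format."""


class DegenerateGeometryError(ValueError):
    """Points are too degenerate (collinear, coincident) for a geometric fit."""


class DegenerateFitError(DegenerateGeometryError):
    """The algebraic conic fit did not produce an ellipse."""


class UndefinedDimensionalityError(ValueError):
    """Participation ratio requested for an all-zero covariance spectrum."""


class TrainingError(RuntimeError):
    """VAE optimisation produced a non-finite loss."""


@dataclass
class BandDefinition:
    """A named frequency band ``[lo, hi]`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi <= 30):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi <= 30, got [{self.lo}, {self.hi}]"
            )


#: Conventional EEG sub-bands tiling the 0.5-30 Hz analysis range.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

#: Broadband analysis range (matches the preprocessing band-pass).
BROADBAND = BandDefinition("broadband", 0.5, 30.0)


@dataclass
class Recording:
    """A channels x samples recording in microvolt-like arbitrary units."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = CHANNELS_1020
    subject_id: str = "s00"
    condition: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} channel labels"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with the signal matrix replaced."""
        return replace(self, data=data)


@dataclass
class EpochSet:
    """Consecutive fixed-length windows cut from one recording."""

    epochs: list[np.ndarray]
    epoch_len_s: float
    fs: float
    channel_labels: tuple[str, ...] = CHANNELS_1020
    subject_id: str = "s00"
    condition: str = "unknown"

    def __post_init__(self) -> None:
        n = int(round(self.epoch_len_s * self.fs))
        for i, ep in enumerate(self.epochs):
            if ep.shape != self.epochs[0].shape:
                raise ValueError(f"epoch {i} shape {ep.shape} != {self.epochs[0].shape}")
            if ep.shape[1] != n:
                raise ValueError(f"epoch {i} has {ep.shape[1]} samples, expected {n}")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def concatenate(self) -> np.ndarray:
        """Stitch the epochs back into one channels x samples matrix."""
        return np.concatenate(self.epochs, axis=1)
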