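"""Welch spectral analysis: PSD, band powers, between-condition differences.

Band power is the trapezoidal integral of the one-sided power spectral
density over a named band, per channel; condition contrasts are mean
band-power differences across epochs, emitted as labelled tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .core import BandDefinition, DEFAULT_BANDS


@dataclass
class SpectralSummary:
    """One epoch's Welch PSD: ``psd`` is channels x freqs, power per Hz."""

    freqs: np.ndarray
    psd: np.ndarray
    channel_labels: tuple[str, ...] = ()
    band_powers: dict[str, np.ndarray] = field(default_factory=dict)


def welch_psd(
    epoch: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    channel_labels: tuple[str, ...] = (),
) -> SpectralSummary:
    """Per-channel averaged periodogram with a Hann taper.

    The 2 s default window gives 0.5 Hz resolution — enough to separate the
    ~1.2 Hz delta peak from the band edge.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    nperseg = int(round(window_s * fs))
    if nperseg > epoch.shape[1]:
        raise ValueError(
            f"window ({window_s:g} s) longer than epoch ({epoch.shape[1] / fs:g} s)"
        )
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must lie in [0, 1)")
    freqs, psd = sps.welch(
        epoch, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap_frac * nperseg)), axis=1,
    )
    summary = SpectralSummary(freqs=freqs, psd=psd, channel_labels=tuple(channel_labels))
    for band in bands:
        if band.lo >= freqs[0] and band.hi <= freqs[-1]:
            summary.band_powers[band.name] = band_power(summary, band)
    return summary


def band_power(summary: SpectralSummary, band: BandDefinition) -> np.ndarray:
    """Trapezoidal integral of the PSD over ``[band.lo, band.hi]``, per channel."""
    freqs = summary.freqs
    if band.lo < freqs[0] or band.hi > freqs[-1]:
        raise ValueError(
            f"band {band.name!r} [{band.lo}, {band.hi}] outside grid "
            f"[{freqs[0]:g}, {freqs[-1]:g}]"
        )
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    return np.trapezoid(summary.psd[:, mask], freqs[mask], axis=1)


def psd_difference(
    state_summaries_a: list[SpectralSummary],
    state_summaries_b: list[SpectralSummary],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Mean over epochs of (band power in a) - (band power in b), per channel.

    Stands in for a difference topography: a (channel x band) labelled table.
    """
    ref = state_summaries_a[0]
    for s in state_summaries_a + state_summaries_b:
        if s.psd.shape[0] != ref.psd.shape[0] or not np.allclose(s.freqs, ref.freqs):
            raise ValueError("channel sets / frequency grids do not match")
    labels = ref.channel_labels or tuple(f"ch{i:02d}" for i in range(ref.psd.shape[0]))
    out = {}
    for band in bands:
        pa = np.mean([band_power(s, band) for s in state_summaries_a], axis=0)
        pb = np.mean([band_power(s, band) for s in state_summaries_b], axis=0)
        out[band.name] = pa - pb
    return pd.DataFrame(out, index=pd.Index(labels, name="channel"))


def band_compare_test(powers_a: np.ndarray, powers_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Welch t-test on per-epoch band powers -> (statistic, p)."""
    powers_a = np.asarray(powers_a, dtype=float)
    powers_b = np.asarray(powers_b, dtype=float)
    if powers_a.size < 2 or powers_b.size < 2:
        raise ValueError("need at least 2 epochs per group")
    res = stats.ttest_ind(powers_a, powers_b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
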