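"""Participation-ratio dimensionality of multichannel activity.

The effective dimensionality of a covariance matrix C with eigenvalues
``lambda_i`` is ``Dim(C) = (sum lambda_i)^2 / sum lambda_i^2``: it equals the
channel count for isotropic covariance, 1 for rank-one (perfectly correlated)
activity, and interpolates in between.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BandDefinition, BROADBAND, DEFAULT_BANDS, Recording,
    UndefinedDimensionalityError,
)
from . import preprocess


@dataclass
class CovarianceSpectrum:
    """Channel covariance matrix and its eigenvalues (sorted descending,
    negatives from round-off clipped to zero)."""

    C: np.ndarray
    eigenvalues: np.ndarray


def covariance(epoch: np.ndarray) -> CovarianceSpectrum:
    """Row-mean-removed sample covariance (denominator N-1) of a
    channels x samples epoch, with its eigenvalue spectrum."""
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate covariance")
    c = np.cov(epoch, ddof=1)
    c = np.atleast_2d(c)
    lam = np.linalg.eigvalsh(c)[::-1]
    lam = np.clip(lam, 0.0, None)
    return CovarianceSpectrum(C=c, eigenvalues=lam)


def participation_ratio(spec: CovarianceSpectrum) -> float:
    """``(sum lambda)^2 / sum lambda^2``; lies in [1, n_channels]."""
    lam = spec.eigenvalues
    s2 = float(np.sum(lam ** 2))
    if s2 <= 0.0:
        raise UndefinedDimensionalityError("all-zero covariance spectrum")
    return float(np.sum(lam)) ** 2 / s2


def band_dimensionality(
    rec: Recording,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    epoch_len_s: float = 10.0,
) -> pd.DataFrame:
    """Per-band, per-epoch participation ratio.

    For each band (plus a broadband row): band-pass filter, segment into
    epochs, estimate the epoch covariance, apply the participation ratio.
    """
    rows = []
    for band in (BROADBAND, *bands):
        filtered = preprocess.subband(rec, band)
        for i, ep in enumerate(preprocess.segment(filtered, epoch_len_s)):
            rows.append({
                "subject": rec.subject_id, "condition": rec.condition,
                "band": band.name, "epoch": i,
                "dim": participation_ratio(covariance(ep)),
            })
    return pd.DataFrame(rows)
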