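"""Recording I/O and the standard EEG preprocessing chain.

Preprocessing follows the usual resting-EEG recipe: zero-phase FIR band-pass
(0.5-30 Hz by default), average re-referencing, and segmentation into
fixed-length epochs (10 s at 256 Hz -> 2560 samples).  Recordings are read
and written either as European Data Format (EDF, 16-bit) or as tab-delimited
text with a header row of channel labels and one sample per row.
"""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import EpochSet, FormatError, Recording, BandDefinition

# ---------------------------------------------------------------------------
# delimited text I/O
# ---------------------------------------------------------------------------

def write_delimited(rec: Recording, path: str | Path, sep: str = "\t") -> Path:
    """Header row of channel labels, one sample per line; a leading comment
    line carries the sampling rate and provenance."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g} subject={rec.subject_id} condition={rec.condition}\n")
        fh.write(sep.join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.6f", delimiter=sep)
    return path


def _read_delimited(path: Path, fs: float | None, sep: str = "\t") -> Recording:
    meta = {"fs": fs, "subject": "s00", "condition": "unknown"}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    key, val = token.split("=", 1)
                    meta[key] = val
            header_line = fh.readline()
        else:
            header_line = first
        labels = header_line.rstrip("\n").split(sep)
        body = pd.read_csv(fh, sep=sep, header=None, dtype=str)
    if body.shape[1] != len(labels):
        raise FormatError(
            f"{path}: {len(labels)} channel labels but rows have {body.shape[1]} columns"
        )
    values = body.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = np.argwhere(values.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {body.iat[bad[0], bad[1]]!r} at "
            f"data row {bad[0] + 1}, column {labels[bad[1]]!r}"
        )
    if meta["fs"] is None:
        raise FormatError(f"{path}: no sampling rate in file and none supplied")
    return Recording(
        data=values.to_numpy().T, fs=float(meta["fs"]), channel_labels=labels,
        subject_id=str(meta["subject"]), condition=str(meta["condition"]),
    )


# ---------------------------------------------------------------------------
# EDF I/O (16-bit European Data Format; 1-second data records)
# ---------------------------------------------------------------------------

def write_edf(rec: Recording, path: str | Path) -> Path:
    """Minimal EDF writer: one 1-second data record per elapsed second,
    per-channel physical scaling to the full 16-bit digital range.

    The recording must span a whole number of seconds and ``fs`` must be an
    integer (EDF stores integer samples-per-record).
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))
    n_rec, rem = divmod(rec.n_samples, fs_i)
    if rem or n_rec == 0:
        raise ValueError("EDF writer requires a whole number of seconds of data")
    nch = rec.n_channels

    pmin = rec.data.min(axis=1)
    pmax = rec.data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((rec.data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    def fixed(text: str, width: int) -> bytes:
        b = text.encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        fixed("0", 8),
        fixed(f"subject {rec.subject_id}", 80),
        fixed(f"condition {rec.condition}", 80),
        fixed("01.01.00", 8),
        fixed("00.00.00", 8),
        fixed(str(256 * (1 + nch)), 8),
        fixed("", 44),
        fixed(str(n_rec), 8),
        fixed("1", 8),
        fixed(str(nch), 4),
    ])
    sig = b"".join([
        b"".join(fixed(lbl, 16) for lbl in rec.channel_labels),
        b"".join(fixed("synthetic EEG", 80) for _ in range(nch)),
        b"".join(fixed("uV", 8) for _ in range(nch)),
        b"".join(fixed(f"{v:.6g}"[:8], 8) for v in pmin),
        b"".join(fixed(f"{v:.6g}"[:8], 8) for v in pmax),
        b"".join(fixed(str(dmin), 8) for _ in range(nch)),
        b"".join(fixed(str(dmax), 8) for _ in range(nch)),
        b"".join(fixed("", 80) for _ in range(nch)),
        b"".join(fixed(str(fs_i), 8) for _ in range(nch)),
        b"".join(fixed("", 32) for _ in range(nch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            block = digital[:, r * fs_i:(r + 1) * fs_i]
            fh.write(block.tobytes())  # channel-major within each record
    return path


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for uV channels
    # provenance is encoded in the EDF patient/recording id fields
    meta = {"subject": "s00", "condition": "unknown"}
    try:
        with open(path, "rb") as fh:
            fh.seek(8)
            patient = fh.read(80).decode("ascii").strip()
            recording = fh.read(80).decode("ascii").strip()
        if patient.startswith("subject "):
            meta["subject"] = patient.split(" ", 1)[1]
        if recording.startswith("condition "):
            meta["condition"] = recording.split(" ", 1)[1]
    except Exception:
        pass
    return Recording(
        data=data, fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        subject_id=meta["subject"], condition=meta["condition"],
    )


def read_recording(path: str | Path, format: str | None = None,
                   fs: float | None = None) -> Recording:
    """Read a recording from EDF or delimited text.

    ``format`` is inferred from the extension when omitted; ``fs`` overrides
    or supplies the sampling rate for delimited files without a comment line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited":
        return _read_delimited(path, fs)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _design_fir(lo: float, hi: float, fs: float) -> np.ndarray:
    # Hamming-windowed sinc; transition width sized to the band so the
    # ~53 dB stopband and <0.1 dB passband ripple specs hold after filtfilt.
    transition = min(lo, (hi - lo) / 2.0, 2.0)
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # odd length -> type I linear phase
    return sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")


def bandpass(rec: Recording, lo: float = 0.5, hi: float = 30.0) -> Recording:
    """Zero-phase (forward-backward) FIR band-pass filter."""
    if not (0 < lo < hi < rec.fs / 2):
        raise ValueError(f"need 0 < lo < hi < fs/2, got [{lo}, {hi}] at fs {rec.fs}")
    taps = _design_fir(lo, hi, rec.fs)
    padlen = min(3 * (len(taps) - 1), rec.n_samples - 2)
    # even-extension padding keeps boundary kinks (hence edge transients)
    # small for signals that do not end near zero phase
    out = sps.filtfilt(taps, [1.0], rec.data, axis=1, padlen=padlen,
                       padtype="even")
    return rec.with_data(out)


def subband(rec: Recording, band: BandDefinition) -> Recording:
    """Band-pass restricted to one named sub-band (delta/theta/alpha/beta)."""
    return bandpass(rec, band.lo, band.hi)


# ---------------------------------------------------------------------------
# re-referencing and segmentation
# ---------------------------------------------------------------------------

def average_rereference(rec: Recording) -> Recording:
    """Subtract the instantaneous cross-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def segment(rec: Recording, epoch_len_s: float = 10.0) -> EpochSet:
    """Cut into consecutive non-overlapping epochs; the trailing partial
    epoch, if any, is dropped."""
    n_per = epoch_len_s * rec.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("epoch_len_s * fs must be an integer sample count")
    n_per = int(round(n_per))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        raise ValueError(
            f"recording ({rec.duration_s:g} s) shorter than one epoch ({epoch_len_s:g} s)"
        )
    epochs = [rec.data[:, i * n_per:(i + 1) * n_per].copy() for i in range(n_epochs)]
    return EpochSet(
        epochs=epochs, epoch_len_s=epoch_len_s, fs=rec.fs,
        channel_labels=rec.channel_labels, subject_id=rec.subject_id,
        condition=rec.condition,
    )


def preprocess_recording(rec: Recording, lo: float = 0.5, hi: float = 30.0) -> Recording:
    """The standard chain: band-pass then average re-reference."""
    return average_rereference(bandpass(rec, lo, hi))
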