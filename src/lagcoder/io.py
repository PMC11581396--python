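"""On-disk artifacts and EEG preprocessing to the analysis rate.

EEG and feature arrays are stored as compressed ``.npz`` containers with a
JSON metadata sidecar (``<stem>.json``) holding sampling rate, labels and
run id; word tables are TSV with a header row.  Preprocessing follows the
standard low-frequency speech-tracking recipe: 0.5-8 Hz zero-phase
Butterworth band-pass, polyphase down-sampling to 32 Hz, re-referencing to
the mastoid average.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .containers import FeatureSeries, Recording, WordTable

__all__ = [
    "bandpass_eeg",
    "resample_recording",
    "rereference",
    "read_word_table",
    "write_word_table",
    "save_recording",
    "load_recording",
    "save_features",
    "load_features",
    "read_wav",
]

ANALYSIS_FS = 32.0


def bandpass_eeg(rec: Recording, lo: float = 0.5, hi: float = 8.0,
                 order: int = 3) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    The filter is the stated 3rd-order design run forward-backward
    (``sosfiltfilt``), so the effective magnitude order doubles and the
    phase response is zero -- no spurious lag enters downstream lag-resolved
    weight estimates.
    """
    if rec.fs <= 2 * hi:
        raise ValueError(
            f"sampling rate {rec.fs} Hz violates the Nyquist bound for a "
            f"{hi} Hz upper band edge (need fs > {2 * hi} Hz)"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=0)
    return Recording(rec.run_id, out, rec.fs, list(rec.channel_labels),
                     list(rec.reference_channels))


def resample_ratio(fs_in: float, fs_out: float) -> Fraction:
    frac = Fraction(fs_out).limit_denominator(10**6) / \
        Fraction(fs_in).limit_denominator(10**6)
    return frac.limit_denominator(10**6)


def resample_array(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase anti-aliased resampling along axis 0.

    Output length is ``ceil(n * fs_out / fs_in)`` (the polyphase
    convention); for integer-second runs at commensurate rates this is
    exactly ``duration * fs_out``.
    """
    frac = resample_ratio(fs_in, fs_out)
    # padtype="line" keeps constant signals exactly constant at the edges
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=0,
                                padtype="line")


def resample_recording(rec: Recording, to_fs: float = ANALYSIS_FS) -> Recording:
    if to_fs >= rec.fs:
        raise ValueError(
            f"resample_recording only down-samples: requested {to_fs} Hz "
            f"from {rec.fs} Hz"
        )
    out = resample_array(rec.data, rec.fs, to_fs)
    return Recording(rec.run_id, out, to_fs, list(rec.channel_labels),
                     list(rec.reference_channels))


def rereference(rec: Recording) -> Recording:
    """Subtract the mastoid average from every scalp channel.

    The reference channels are dropped from the output.
    """
    if not rec.reference_channels:
        raise ValueError("Recording declares no reference channels")
    missing = [c for c in rec.reference_channels if c not in rec.channel_labels]
    if missing:
        raise ValueError(
            f"reference channel(s) {missing} not found; available labels: "
            f"{list(rec.channel_labels)}"
        )
    ref_idx = [rec.channel_labels.index(c) for c in rec.reference_channels]
    keep_idx = [i for i in range(rec.n_channels) if i not in ref_idx]
    ref = rec.data[:, ref_idx].mean(axis=1, keepdims=True)
    out = rec.data[:, keep_idx] - ref
    labels = [rec.channel_labels[i] for i in keep_idx]
    return Recording(rec.run_id, out, rec.fs, labels, [])


# ---------------------------------------------------------------------------
# word tables

def read_word_table(path) -> WordTable:
    df = pd.read_csv(path, sep="\t")
    return WordTable(df)


def write_word_table(wt, path) -> None:
    df = wt.df if isinstance(wt, WordTable) else WordTable(pd.DataFrame(wt)).df
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# array containers (npz + JSON sidecar)

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_recording(rec: Recording, path) -> Path:
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, data=rec.data)
    meta = {
        "kind": "recording",
        "run_id": rec.run_id,
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "reference_channels": list(rec.reference_channels),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_recording(path) -> Recording:
    path = Path(path).with_suffix(".npz")
    meta = json.loads(_sidecar(path).read_text())
    with np.load(path) as z:
        data = z["data"]
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains non-finite samples")
    return Recording(meta["run_id"], data, meta["fs"], meta["channel_labels"],
                     meta.get("reference_channels", []))


def save_features(fs: FeatureSeries, path) -> Path:
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, data=fs.data)
    meta = {"kind": "features", "name": fs.name, "fs": fs.fs,
            "run_id": fs.run_id, "meta": fs.meta}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_features(path) -> FeatureSeries:
    path = Path(path).with_suffix(".npz")
    meta = json.loads(_sidecar(path).read_text())
    with np.load(path) as z:
        data = z["data"]
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains non-finite samples")
    return FeatureSeries(meta["name"], data, meta["fs"], meta.get("run_id", ""),
                         meta.get("meta", {}))


def read_wav(path):
    """Read a mono PCM WAV file; returns (wave as float64 in [-1, 1], fs)."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains non-finite samples")
    return data, float(fs)
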