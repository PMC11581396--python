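"""Core in-memory containers for run-structured EEG/feature analyses.

A *session* is a set of runs recorded under identical conditions: every run
shares the sampling rate and channel set.  Time is in seconds, 0-based;
sample ``i`` covers the interval ``[i/fs, (i+1)/fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Recording", "FeatureSeries", "WordTable"]


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} contains NaN or Inf values")


@dataclass
class Recording:
    """One run of multichannel EEG: a time x channel matrix plus metadata.

    Parameters
    ----------
    run_id : str
        Identifier of the run within its session.
    data : ndarray, shape (n_times, n_channels)
        Signal in microvolt-scale arbitrary units.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per column of ``data``.
    reference_channels : list of str
        Labels of the reference (mastoid) channels, or empty if already
        referenced.
    """

    run_id: str
    data: np.ndarray
    fs: float
    channel_labels: list
    reference_channels: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (time x channel)")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError(
                f"got {len(self.channel_labels)} channel labels for "
                f"{self.data.shape[1]} data columns"
            )
        _check_finite(self.data, f"Recording {self.run_id!r}")

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs


@dataclass
class FeatureSeries:
    """A named time x dimension regressor matrix aligned to one run."""

    name: str
    data: np.ndarray
    fs: float
    run_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2:
            raise ValueError("FeatureSeries.data must be 1-D or 2-D")
        _check_finite(self.data, f"FeatureSeries {self.name!r}")

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


_REQUIRED_COLUMNS = ("word", "onset_s", "offset_s")
_OPTIONAL_COLUMNS = ("surprisal", "token_count")


class WordTable:
    """Per-word alignment records for one run.

    Wraps a :class:`pandas.DataFrame` with columns ``word``, ``onset_s``,
    ``offset_s`` and optionally ``surprisal`` (nonnegative, e.g. GPT-style
    negative log word probability) and ``token_count``.  Rows must be sorted
    by onset with strictly positive, non-overlapping intervals.
    """

    def __init__(self, df: pd.DataFrame):
        df = pd.DataFrame(df).reset_index(drop=True)
        for col in _REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"WordTable requires column {col!r}")
        for col in ("onset_s", "offset_s", "surprisal", "token_count"):
            if col in df.columns:
                vals = np.asarray(df[col], dtype=float)
                if np.any(~np.isfinite(vals)):
                    bad = int(np.flatnonzero(~np.isfinite(vals))[0])
                    raise ValueError(f"non-finite {col!r} at row {bad}")
        onset = np.asarray(df["onset_s"], dtype=float)
        offset = np.asarray(df["offset_s"], dtype=float)
        bad = np.flatnonzero(onset >= offset)
        if bad.size:
            raise ValueError(
                f"row {int(bad[0])}: onset_s must be < offset_s "
                f"({onset[bad[0]]} >= {offset[bad[0]]})"
            )
        if len(df) > 1:
            unordered = np.flatnonzero(np.diff(onset) < 0)
            if unordered.size:
                raise ValueError(
                    f"row {int(unordered[0]) + 1}: rows must be sorted by onset_s"
                )
            overlap = np.flatnonzero(onset[1:] < offset[:-1])
            if overlap.size:
                raise ValueError(
                    f"row {int(overlap[0]) + 1}: interval overlaps previous word"
                )
        if "surprisal" in df.columns and len(df) and float(df["surprisal"].min()) < 0:
            raise ValueError("surprisal values must be nonnegative")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WordTable):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def has_surprisal(self) -> bool:
        return "surprisal" in self.df.columns

    @property
    def onsets(self) -> np.ndarray:
        return np.asarray(self.df["onset_s"], dtype=float)

    @property
    def offsets(self) -> np.ndarray:
        return np.asarray(self.df["offset_s"], dtype=float)

    @property
    def surprisals(self) -> np.ndarray:
        if not self.has_surprisal:
            raise ValueError("WordTable has no surprisal column")
        return np.asarray(self.df["surprisal"], dtype=float)

    def sample_spans(self, fs: float) -> list:
        """(start, stop) sample index pairs per word at rate ``fs``.

        A word occupies samples ``round(onset*fs) .. round(offset*fs) - 1``,
        consistent with the convention that sample i covers [i/fs, (i+1)/fs).
        """
        starts = np.rint(self.onsets * fs).astype(int)
        stops = np.rint(self.offsets * fs).astype(int)
        return list(zip(starts.tolist(), stops.tolist()))
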