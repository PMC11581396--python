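"""Synthetic sessions with known ground truth.

Generates run-structured stimulus features (envelope-like, embedding-like,
surprisal spike trains), per-channel lag-resolved convolution kernels, and
EEG as kernel-convolved features plus Gaussian noise at a controlled
signal-to-noise variance ratio.  A perfect model of such data has the
analytic accuracy ceiling ``sqrt(snr / (1 + snr))``, which anchors
parameter-recovery tests.

All randomness flows from one session seed through named substreams
(words, latents, kernels, noise), so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import FeatureSeries, Recording, WordTable
from .encoder import LagSpec, build_lagged_design
from .features import surprisal_spikes

__all__ = [
    "SessionSpec",
    "GroundTruth",
    "substream",
    "gen_word_table",
    "gen_shared_latent",
    "gen_feature_bank",
    "gen_kernels",
    "synthesize_eeg",
    "accuracy_ceiling",
]

_STREAMS = {"words": 0, "latents": 1, "kernels": 2, "noise": 3}


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Named, independent random substream of a session seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[name], index)))


@dataclass
class SessionSpec:
    """Run structure of a synthetic session (defaults mirror a ~1 h
    audiobook session: 20 runs of 3 minutes at the 32 Hz analysis rate)."""

    n_runs: int = 20
    run_len_s: float = 180.0
    fs: float = 32.0
    n_channels: int = 16
    word_rate: float = 3.0   # mean words / s

    def __post_init__(self):
        if self.n_runs < 3:
            raise ValueError("need at least 3 runs for nested CV")
        n = self.run_len_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("run_len_s * fs must be integral")

    @property
    def n_samples(self) -> int:
        return int(round(self.run_len_s * self.fs))


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    kernels: list                 # per bank: (n_features, n_lags, n_channels)
    snr: float
    shared_fraction: float = 0.0
    seed: int = 0
    lags: LagSpec = field(default_factory=LagSpec)
    noise_sd: np.ndarray | None = None


def gen_word_table(spec: SessionSpec, seed: int, run: int = 0,
                   median_duration_s: float = 0.25,
                   surprisal_median: float = 3.0) -> WordTable:
    """Poisson word onsets with log-normal durations and surprisals.

    Durations are truncated so intervals never overlap (a 1-sample gap is
    kept at the analysis rate); surprisal is i.i.d. log-normal.
    """
    rng = substream(seed, "words", run)
    gap = 1.0 / spec.fs
    # onsets closer than 2 samples to the previous word are thinned below;
    # a dead-time correction keeps the realized rate at word_rate
    dead = 2 * gap
    if spec.word_rate * dead >= 0.9:
        raise ValueError("word_rate too high for the analysis rate")
    rate = spec.word_rate / (1.0 - spec.word_rate * dead)
    t, onsets = 0.0, []
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= spec.run_len_s - 0.5 - 2 * gap:
            break
        # thin onsets closer than 2 samples to the previous word so every
        # word keeps room for a positive duration plus a 1-sample gap
        if not onsets or t - onsets[-1] >= dead:
            onsets.append(t)
    onsets = np.asarray(onsets)
    durations = np.exp(np.log(median_duration_s)
                       + 0.5 * rng.standard_normal(onsets.size))
    max_dur = np.append(np.diff(onsets), spec.run_len_s - 0.5 - onsets[-1]) - gap
    durations = np.minimum(durations, max_dur)
    surprisal = np.exp(np.log(surprisal_median)
                       + 0.6 * rng.standard_normal(onsets.size))
    words = [f"w{run}_{i}" for i in range(onsets.size)]
    return WordTable(pd.DataFrame({
        "word": words, "onset_s": onsets, "offset_s": onsets + durations,
        "surprisal": surprisal, "token_count": np.ones(onsets.size, int)}))


def _smooth_noise(rng: np.random.Generator, n: int, dims: int,
                  fs: float, cutoff: float = 8.0) -> np.ndarray:
    """Unit-variance low-pass (< cutoff Hz) Gaussian noise columns."""
    x = rng.standard_normal((n, dims))
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=0)
    return x / x.std(axis=0)


def gen_shared_latent(spec: SessionSpec, seed: int, n_dims: int = 10) -> list:
    """Per-run smooth latent shared across feature banks."""
    return [_smooth_noise(substream(seed, "latents", 1000 + r),
                          spec.n_samples, n_dims, spec.fs)
            for r in range(spec.n_runs)]


def gen_feature_bank(kind: str, spec: SessionSpec, seed: int,
                     word_tables: list | None = None,
                     shared_latent: list | None = None,
                     shared_fraction: float = 0.0, n_dims: int | None = None,
                     bank: int = 0) -> list:
    """One feature bank: a list of per-run FeatureSeries.

    kinds: ``envelope_like`` (rectified low-pass Gaussian noise, nonneg),
    ``embedding_like`` (smooth Gaussian latents; each dimension is
    ``sqrt(f) * shared + sqrt(1 - f) * unique`` when a shared latent is
    supplied) and ``spikes`` (surprisal impulse trains from word tables).
    """
    out = []
    for r in range(spec.n_runs):
        rng = substream(seed, "latents", bank * spec.n_runs + r)
        if kind == "envelope_like":
            d = n_dims or 2
            x = np.maximum(_smooth_noise(rng, spec.n_samples, d, spec.fs), 0.0)
        elif kind == "embedding_like":
            d = n_dims or 10
            x = _smooth_noise(rng, spec.n_samples, d, spec.fs)
            if shared_latent is not None:
                f = float(shared_fraction)
                if not 0.0 <= f <= 1.0:
                    raise ValueError("shared_fraction must be in [0, 1]")
                s = shared_latent[r][:, :d]
                x = np.sqrt(f) * s + np.sqrt(1.0 - f) * x
        elif kind == "spikes":
            if word_tables is None:
                raise ValueError("spikes need word tables")
            fs_ = surprisal_spikes(word_tables[r], spec.fs, spec.n_samples)
            x = fs_.data
        else:
            raise ValueError(f"unknown feature kind {kind!r}")
        out.append(FeatureSeries(f"{kind}{bank}", x, spec.fs, run_id=f"run{r:02d}"))
    return out


def gen_kernels(spec: SessionSpec, lags: LagSpec, seed: int,
                n_features: int = 2, bank: int = 0) -> np.ndarray:
    """Per-channel damped-sinusoid kernels on the causal lag grid.

    ``g(tau) = exp(-(tau - tau0)/tau_d) * sin(2 pi f_k (tau - tau0))`` for
    ``tau in [tau0, max_lag]`` and zero before the channel-specific onset
    latency tau0 in [30, 400] ms; decay tau_d in [50, 150] ms.  Shape
    (n_features, n_lags, n_channels).
    """
    rng = substream(seed, "kernels", bank)
    taus = lags.lag_times_s
    K = np.zeros((n_features, lags.n_lags, spec.n_channels))
    for c in range(spec.n_channels):
        for f in range(n_features):
            tau0 = rng.uniform(0.030, 0.400)
            tau_d = rng.uniform(0.050, 0.150)
            f_k = rng.uniform(1.5, 6.0)
            t = taus - tau0
            g = np.exp(-t / tau_d) * np.sin(2 * np.pi * f_k * t)
            g[t < 0] = 0.0
            K[f, :, c] = g * rng.choice([-1.0, 1.0])
    return K


def accuracy_ceiling(snr: float) -> float:
    """Held-out correlation of a perfect model at this SNR."""
    return float(np.sqrt(snr / (1.0 + snr)))


def synthesize_eeg(feature_banks: list, kernels: list, snr: float,
                   spec: SessionSpec, seed: int,
                   shared_fraction: float = 0.0,
                   lags: LagSpec | None = None) -> tuple:
    """EEG = sum over banks of (features convolved with kernels) + noise.

    ``feature_banks`` is a list of banks, each a list of per-run
    FeatureSeries; ``kernels[b]`` has shape (n_features_b, n_lags,
    n_channels).  Noise is i.i.d. Gaussian, independent across runs, scaled
    per channel so that var(clean)/var(noise) equals ``snr`` against the
    realized clean variance pooled over runs.

    Returns ``(recordings, ground_truth)``.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    lags = lags or LagSpec(fs=spec.fs)
    n_runs = len(feature_banks[0])
    clean = []
    for r in range(n_runs):
        acc = np.zeros((spec.n_samples, spec.n_channels))
        for bank, K in zip(feature_banks, kernels):
            D = build_lagged_design(bank[r], lags)
            acc += D @ K.reshape(-1, spec.n_channels)
        clean.append(acc)
    var_clean = np.concatenate(clean, axis=0).var(axis=0)
    noise_sd = np.sqrt(var_clean / snr)
    labels = [f"ch{c:03d}" for c in range(spec.n_channels)]
    recs = []
    for r in range(n_runs):
        rng = substream(seed, "noise", r)
        noise = rng.standard_normal(clean[r].shape) * noise_sd
        recs.append(Recording(f"run{r:02d}", clean[r] + noise, spec.fs, labels))
    gt = GroundTruth(kernels=list(kernels), snr=float(snr),
                     shared_fraction=shared_fraction, seed=seed, lags=lags,
                     noise_sd=noise_sd)
    return recs, gt
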