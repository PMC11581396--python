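"""Acoustic regressors: broadband envelope, rectified derivative, log-Mel.

The envelope emulates cochlear filtering with a bank of 4th-order gammatone
filters on ERB-spaced center frequencies (80 Hz - 8 kHz), weighted by an
equal-loudness contour; per-band envelopes (magnitude of the analytic
signal) are averaged into one broadband series and down-sampled with
anti-aliasing to the analysis rate.  The rectified first difference of the
envelope tracks acoustic onsets.  The log-Mel spectrogram mirrors the
standard ASR front end: 25 ms windows / 10 ms hop, 80 Slaney-style mel
filters up to 8 kHz, log10-compressed with an 8-order-of-magnitude dynamic
range clamp and affine rescale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import FeatureSeries
from .io import resample_array

__all__ = [
    "EnvelopeParams",
    "erb_space",
    "equal_loudness_gain",
    "broadband_envelope",
    "rectified_derivative",
    "env_and_dv",
    "mel_frequencies",
    "mel_filterbank",
    "log_mel_spectrogram",
]


@dataclass
class EnvelopeParams:
    n_bands: int = 128
    f_lo: float = 80.0
    f_hi: float = 8000.0
    audio_lowpass_cutoff: float = 22050.0
    out_fs: float = 32.0

    def __post_init__(self):
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if not self.f_lo < self.f_hi:
            raise ValueError("need f_lo < f_hi")


def erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """Center frequencies equally spaced on the Glasberg-Moore ERB scale."""
    ear_q, min_bw = 9.26449, 24.7
    lo = np.log(f_lo / ear_q + min_bw)
    hi = np.log(f_hi / ear_q + min_bw)
    erbs = np.linspace(lo, hi, n)
    return ear_q * (np.exp(erbs) - min_bw)


# 60-phon equal-loudness contour (ISO 226-style), sound pressure level in dB
# required for equal loudness at each frequency; sparse table, log-f interp.
_EL_FREQ = np.array([
    20, 25, 31.5, 40, 50, 63, 80, 100, 125, 160, 200, 250, 315, 400, 500,
    630, 800, 1000, 1250, 1600, 2000, 2500, 3150, 4000, 5000, 6300, 8000,
    10000, 12500,
])
_EL_SPL = np.array([
    109.5, 104.2, 99.0, 94.4, 90.3, 86.1, 82.0, 78.5, 75.2, 71.9, 69.0,
    66.2, 63.5, 61.1, 59.8, 58.6, 58.2, 60.0, 62.4, 59.8, 57.1, 56.2, 56.9,
    60.3, 66.1, 71.7, 73.2, 68.6, 68.4,
])


def equal_loudness_gain(freqs) -> np.ndarray:
    """Linear per-band gains from the 60-phon contour, 0 dB at 1 kHz.

    Bands that need a higher SPL for equal loudness are attenuated, so the
    weighted bank approximates perceived loudness per band.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    spl = np.interp(np.log10(freqs), np.log10(_EL_FREQ), _EL_SPL)
    ref = np.interp(np.log10(1000.0), np.log10(_EL_FREQ), _EL_SPL)
    return 10.0 ** (-(spl - ref) / 20.0)


def broadband_envelope(wave: np.ndarray, fs_audio: float,
                       p: EnvelopeParams | None = None,
                       pre_lowpass: bool = True) -> FeatureSeries:
    """Average gammatone-band envelope of ``wave``, at ``p.out_fs`` Hz.

    ``pre_lowpass`` applies the nominal anti-hiss low-pass; it is a no-op
    whenever the cutoff is at or above Nyquist (i.e. for any fs_audio at or
    below 44.1 kHz), and exists only to document the preprocessing slot.
    """
    p = p or EnvelopeParams()
    wave = np.asarray(wave, dtype=float).ravel()
    if wave.size == 0:
        raise ValueError("empty waveform")
    if fs_audio < 2 * p.f_hi:
        raise ValueError(
            f"fs_audio={fs_audio} too low for f_hi={p.f_hi} (Nyquist)")
    if pre_lowpass and p.audio_lowpass_cutoff < fs_audio / 2:
        sos = signal.butter(4, p.audio_lowpass_cutoff, btype="low",
                            fs=fs_audio, output="sos")
        wave = signal.sosfiltfilt(sos, wave)
    centers = erb_space(p.f_lo, p.f_hi, p.n_bands)
    gains = equal_loudness_gain(centers)
    env = np.zeros_like(wave)
    for fc, g in zip(centers, gains):
        b, a = signal.gammatone(fc, "iir", fs=fs_audio)
        band = signal.lfilter(b, a, wave)
        env += g * np.abs(signal.hilbert(band))
    env /= p.n_bands
    out = resample_array(env, fs_audio, p.out_fs)
    np.maximum(out, 0.0, out=out)  # anti-aliasing ripple can dip below zero
    return FeatureSeries("envelope", out, p.out_fs,
                         meta={"n_bands": p.n_bands, "f_lo": p.f_lo,
                               "f_hi": p.f_hi})


def rectified_derivative(env: FeatureSeries) -> FeatureSeries:
    """Half-wave-rectified first difference of a 1-dim envelope.

    ``out[t] = max(env[t] - env[t-1], 0)`` with one leading zero so the
    output is length-aligned (and concatenable) with its input.
    """
    if env.n_features != 1:
        raise ValueError("rectified_derivative expects a 1-dim series")
    x = env.data[:, 0]
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    dv = np.maximum(np.diff(x), 0.0)
    out = np.concatenate([[0.0], dv])
    return FeatureSeries("envelope_derivative", out, env.fs, env.run_id)


def env_and_dv(wave: np.ndarray, fs_audio: float,
               p: EnvelopeParams | None = None) -> FeatureSeries:
    """Envelope (column 0) concatenated with its rectified derivative."""
    env = broadband_envelope(wave, fs_audio, p)
    dv = rectified_derivative(env)
    data = np.column_stack([env.data[:, 0], dv.data[:, 0]])
    return FeatureSeries("env_dv", data, env.fs, meta=env.meta)


# ---------------------------------------------------------------------------
# log-Mel spectrogram

def _hz_to_mel(f):
    """Slaney mel scale: linear below 1 kHz, logarithmic above."""
    f = np.asarray(f, dtype=float)
    f_sp, min_log_hz = 200.0 / 3, 1000.0
    min_log_mel = min_log_hz / f_sp
    logstep = np.log(6.4) / 27.0
    mel = f / f_sp
    above = f >= min_log_hz
    mel = np.where(above, min_log_mel + np.log(np.maximum(f, 1e-12) / min_log_hz) / logstep, mel)
    return mel


def _mel_to_hz(m):
    m = np.asarray(m, dtype=float)
    f_sp, min_log_hz = 200.0 / 3, 1000.0
    min_log_mel = min_log_hz / f_sp
    logstep = np.log(6.4) / 27.0
    f = m * f_sp
    above = m >= min_log_mel
    return np.where(above, min_log_hz * np.exp(logstep * (m - min_log_mel)), f)


def mel_frequencies(n_mels: int, fmin: float = 0.0,
                    fmax: float = 8000.0) -> np.ndarray:
    """``n_mels + 2`` edge frequencies of a mel filterbank (Hz)."""
    mels = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    return _mel_to_hz(mels)


def mel_filterbank(sr: float, n_fft: int, n_mels: int = 80,
                   fmin: float = 0.0, fmax: float = 8000.0) -> np.ndarray:
    """Triangular, area-normalized mel filter matrix (n_mels x n_bins)."""
    fft_freqs = np.fft.rfftfreq(n_fft, 1.0 / sr)
    edges = mel_frequencies(n_mels, fmin, fmax)
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, ctr, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        fb[i] *= 2.0 / (hi - lo)  # Slaney area normalization
    return fb


def log_mel_spectrogram(wave: np.ndarray, fs_audio: float = 16000.0,
                        n_mels: int = 80, out_fs: float = 32.0,
                        win_s: float = 0.025, hop_s: float = 0.010,
                        dynamic_range: float = 8.0) -> FeatureSeries:
    """80-band log-Mel spectrogram at ``out_fs`` Hz.

    Expects audio already resampled to 16 kHz upstream.  log10 of mel power
    is clamped at ``max - dynamic_range`` and affinely rescaled by
    ``(x + 4) / 4``, the convention of the ASR preprocessing this mirrors.
    """
    wave = np.asarray(wave, dtype=float)
    if wave.ndim != 1:
        raise ValueError("log_mel_spectrogram expects mono audio (1-D)")
    if fs_audio != 16000.0:
        raise ValueError(f"expected 16 kHz input, got {fs_audio} Hz")
    n_fft = int(round(win_s * fs_audio))
    hop = int(round(hop_s * fs_audio))
    win = np.hanning(n_fft)
    n_frames = 1 + max(0, (wave.size - n_fft)) // hop
    if n_frames < 1:
        raise ValueError("waveform shorter than one analysis window")
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = wave[idx] * win
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    fb = mel_filterbank(fs_audio, n_fft, n_mels, 0.0, 8000.0)
    mel = power @ fb.T
    logmel = np.log10(np.maximum(mel, 1e-10))
    logmel = np.maximum(logmel, logmel.max() - dynamic_range)
    logmel = (logmel + 4.0) / 4.0
    frame_fs = fs_audio / hop
    out = resample_array(logmel, frame_fs, out_fs)
    return FeatureSeries("log_mel", out, out_fs,
                         meta={"n_mels": n_mels, "frame_fs": frame_fs,
                               "dynamic_range": dynamic_range})
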