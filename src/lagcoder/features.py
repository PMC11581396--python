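"""Deep-model activations and word tables -> aligned regressors.

Contains the :class:`EmbeddingExtractor` contract plus stub extractors
(context-free frame statistics, a leaky/box past-integrator, random
projection of the recent waveform) used throughout the test suite, the
causal sliding-window extraction loop, external-corpus PCA projection,
surprisal impulse ("spike") trains, word-stretched vectors, token-to-word
summation and the ablation operators (within-word shuffle, lexicalization,
global shuffle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .containers import FeatureSeries, WordTable
from .io import resample_array

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingExtractor",
    "FrameStatExtractor",
    "PastIntegratorExtractor",
    "RandomProjectionExtractor",
    "sliding_window_extract",
    "resample_features",
    "PcaProjection",
    "fit_external_pca",
    "project_pca",
    "surprisal_spikes",
    "word_stretch",
    "sum_tokens_to_words",
    "AblationSpec",
    "ablate",
]


class EmbeddingExtractor:
    """Contract for audio-segment -> per-layer frame-matrix callables.

    Implementations expose ``native_fs`` (frame rate, Hz), ``n_layers`` and
    ``dim``, and when called with ``(wave, fs_audio)`` return a list of
    ``n_layers`` arrays of shape (n_frames, dim) where
    ``n_frames == round(len(wave)/fs_audio * native_fs)`` within +/- 1.
    Output must be deterministic given identical input.
    """

    native_fs: float = 50.0
    n_layers: int = 1
    dim: int = 1

    def __call__(self, wave: np.ndarray, fs_audio: float) -> list:
        raise NotImplementedError

    def n_frames(self, n_samples: int, fs_audio: float) -> int:
        return int(round(n_samples / fs_audio * self.native_fs))

    def _frame_slices(self, wave: np.ndarray, fs_audio: float):
        n = self.n_frames(wave.size, fs_audio)
        step = fs_audio / self.native_fs
        for j in range(n):
            a = int(round(j * step))
            b = int(round((j + 1) * step))
            yield wave[a:max(b, a + 1)]


class FrameStatExtractor(EmbeddingExtractor):
    """Context-free stub: each frame is a fixed projection of per-frame
    statistics (mean, rms, max, zero-cross rate) of its own audio slice.

    Being context-free, its output is invariant to the sliding-window size,
    which makes it the reference point for context-restriction tests.
    """

    def __init__(self, native_fs: float = 50.0, dim: int = 4,
                 n_layers: int = 1, seed: int = 0):
        self.native_fs = float(native_fs)
        self.dim = int(dim)
        self.n_layers = int(n_layers)
        rng = np.random.default_rng(seed)
        self._proj = rng.standard_normal((n_layers, 4, dim)) / np.sqrt(4)

    def __call__(self, wave, fs_audio):
        wave = np.asarray(wave, dtype=float)
        stats = []
        for sl in self._frame_slices(wave, fs_audio):
            zc = np.mean(np.abs(np.diff(np.sign(sl)))) / 2 if sl.size > 1 else 0.0
            stats.append([sl.mean(), np.sqrt(np.mean(sl ** 2)),
                          sl.max(initial=0.0), zc])
        stats = np.asarray(stats, dtype=float).reshape(-1, 4)
        return [stats @ self._proj[k] for k in range(self.n_layers)]


class PastIntegratorExtractor(EmbeddingExtractor):
    """Context-dependent stub: frame value integrates the visible past.

    Frame at time t carries box-averaged statistics of the audio in
    ``[t - integration_s, t]`` *as visible inside the window handed to the
    extractor*, so restricting the sliding-window context genuinely changes
    its output once ``max_context_s < integration_s``.
    """

    def __init__(self, integration_s: float = 10.0, native_fs: float = 50.0,
                 dim: int = 4, n_layers: int = 1, seed: int = 0):
        self.integration_s = float(integration_s)
        self.native_fs = float(native_fs)
        self.dim = int(dim)
        self.n_layers = int(n_layers)
        rng = np.random.default_rng(seed)
        self._proj = rng.standard_normal((n_layers, 2, dim)) / np.sqrt(2)

    def __call__(self, wave, fs_audio):
        wave = np.asarray(wave, dtype=float)
        n = self.n_frames(wave.size, fs_audio)
        step = fs_audio / self.native_fs
        back = int(round(self.integration_s * fs_audio))
        csum = np.concatenate([[0.0], np.cumsum(wave)])
        csum2 = np.concatenate([[0.0], np.cumsum(wave ** 2)])
        stats = np.empty((n, 2))
        for j in range(n):
            b = min(int(round((j + 1) * step)), wave.size)
            a = max(0, b - back)
            m = max(b - a, 1)
            stats[j, 0] = (csum[b] - csum[a]) / m
            stats[j, 1] = np.sqrt(max((csum2[b] - csum2[a]) / m, 0.0))
        return [stats @ self._proj[k] for k in range(self.n_layers)]


class RandomProjectionExtractor(EmbeddingExtractor):
    """Context-free stub: fixed random projection of each frame's samples."""

    def __init__(self, native_fs: float = 50.0, dim: int = 10,
                 n_layers: int = 1, seed: int = 0, fs_audio: float = 16000.0):
        self.native_fs = float(native_fs)
        self.dim = int(dim)
        self.n_layers = int(n_layers)
        self._frame_len = int(round(fs_audio / native_fs))
        rng = np.random.default_rng(seed)
        self._proj = rng.standard_normal(
            (n_layers, self._frame_len, dim)) / np.sqrt(self._frame_len)

    def __call__(self, wave, fs_audio):
        wave = np.asarray(wave, dtype=float)
        out = []
        for sl in self._frame_slices(wave, fs_audio):
            sl = np.pad(sl, (0, max(0, self._frame_len - sl.size)))[:self._frame_len]
            out.append(sl)
        frames = np.asarray(out, dtype=float).reshape(-1, self._frame_len)
        return [frames @ self._proj[k] for k in range(self.n_layers)]


def sliding_window_extract(extractor: EmbeddingExtractor, wave: np.ndarray,
                           fs_audio: float, run_id: str = "",
                           window_s: float = 30.0, step_s: float = 0.125,
                           max_context_s: float = 30.0) -> list:
    """Causal sliding-window extraction; one FeatureSeries per layer.

    The window is stepped forward in ``step_s`` increments; at each step
    ending at time t the extractor sees only audio in
    ``[max(0, t - max_context_s), t]`` and the frames falling inside the
    final step interval are kept, so every output frame is computed from
    at most ``max_context_s`` seconds of preceding audio.
    """
    if max_context_s > window_s:
        raise ValueError("max_context_s must be <= window_s")
    wave = np.asarray(wave, dtype=float).ravel()
    dur = wave.size / fs_audio
    nfs = extractor.native_fs
    total_frames = extractor.n_frames(wave.size, fs_audio)
    chunks = [[] for _ in range(extractor.n_layers)]
    n_steps = int(np.ceil(dur / step_s - 1e-9))
    kept = 0
    for s in range(n_steps):
        t = min((s + 1) * step_s, dur)
        t0 = max(0.0, t - max_context_s)
        # snap the window start up to the native frame grid so extractor
        # frames align with the global frame grid (never exceeds the
        # requested context)
        g_start = int(np.ceil(t0 * nfs - 1e-9))
        t0 = g_start / nfs
        a = int(round(t0 * fs_audio))
        b = int(round(t * fs_audio))
        seg = wave[a:b]
        layers = extractor(seg, fs_audio)
        n_frames = layers[0].shape[0]
        expected = extractor.n_frames(seg.size, fs_audio)
        if abs(n_frames - expected) > 1:
            raise ValueError(
                f"extractor returned {n_frames} frames for a segment where "
                f"{expected} were expected (tolerance +/- 1)"
            )
        g0 = int(round(t0 * nfs))          # global index of first frame
        # frames straddling the step end are deferred to the next step so
        # every kept frame was computed from audio fully covering it
        if s == n_steps - 1:
            hi = total_frames
        else:
            hi = min(int(np.floor(t * nfs + 1e-9)), total_frames)
        lo = kept                          # each global frame kept exactly once
        sl = slice(lo - g0, hi - g0)
        for k, mat in enumerate(layers):
            chunks[k].append(mat[sl])
        kept = hi
    out = []
    for k in range(extractor.n_layers):
        data = np.concatenate(chunks[k], axis=0)
        out.append(FeatureSeries(f"layer{k}", data, nfs, run_id,
                                 meta={"max_context_s": max_context_s,
                                       "step_s": step_s}))
    return out


def resample_features(fs: FeatureSeries, to_fs: float = 32.0,
                      n_target: int | None = None) -> FeatureSeries:
    """Anti-aliased resampling to the analysis rate, optionally padded or
    truncated by at most one sample to match a paired EEG run."""
    data = resample_array(fs.data, fs.fs, to_fs)
    meta = dict(fs.meta)
    if n_target is not None:
        delta = n_target - data.shape[0]
        if abs(delta) > 1:
            raise ValueError(
                f"resampled length {data.shape[0]} differs from target "
                f"{n_target} by more than 1 sample")
        if delta > 0:
            data = np.vstack([data, data[-1:]])
        elif delta < 0:
            data = data[:n_target]
        meta["length_adjust"] = int(delta)
    return FeatureSeries(fs.name, data, to_fs, fs.run_id, meta)


# ---------------------------------------------------------------------------
# PCA projection from an external corpus

@dataclass
class PcaProjection:
    layer: int
    axes: np.ndarray   # dim x k, orthonormal columns, decreasing variance
    mean: np.ndarray   # dim
    explained_variance_ratio: np.ndarray | None = None


def fit_external_pca(corpus_activations: list, k: int = 10,
                     layer: int = 0) -> PcaProjection:
    """Mean-centered PCA of concatenated corpus activation matrices.

    The axes are fit once on held-out corpus data and never refit on
    analysis data, keeping the projection independent of the EEG stimuli.
    """
    X = np.concatenate([np.asarray(m, dtype=float) for m in corpus_activations],
                       axis=0)
    dim = X.shape[1]
    if k > dim:
        raise ValueError(f"k={k} exceeds activation dimension {dim}")
    if X.shape[0] < dim:
        raise ValueError(
            f"corpus has {X.shape[0]} frames, need >= dim={dim}")
    pca = PCA(n_components=k, svd_solver="full").fit(X)
    return PcaProjection(layer, pca.components_.T.copy(), pca.mean_.copy(),
                         pca.explained_variance_ratio_.copy())


def project_pca(fs: FeatureSeries, p: PcaProjection) -> FeatureSeries:
    data = (fs.data - p.mean) @ p.axes
    meta = dict(fs.meta, pca_layer=p.layer, pca_k=p.axes.shape[1])
    return FeatureSeries(f"{fs.name}_pca", data, fs.fs, fs.run_id, meta)


# ---------------------------------------------------------------------------
# word-aligned regressors

def surprisal_spikes(wt: WordTable, fs: float, n_samples: int) -> FeatureSeries:
    """Impulse train: each word's surprisal at the sample nearest its onset,
    zero elsewhere; coincident words sum."""
    if not wt.has_surprisal:
        raise ValueError("WordTable has no surprisal column")
    out = np.zeros(n_samples)
    if len(wt):
        idx = np.rint(wt.onsets * fs).astype(int)
        if np.any(wt.onsets >= n_samples / fs):
            bad = int(np.flatnonzero(wt.onsets >= n_samples / fs)[0])
            raise ValueError(
                f"row {bad}: onset {wt.onsets[bad]} s beyond the run "
                f"({n_samples / fs} s)")
        idx = np.minimum(idx, n_samples - 1)
        np.add.at(out, idx, wt.surprisals)
    return FeatureSeries("surprisal", out, fs)


def word_stretch(word_vectors: np.ndarray, wt: WordTable, fs: float,
                 n_samples: int) -> FeatureSeries:
    """Each word's vector held constant over its [onset, offset) samples;
    silent periods are zero."""
    word_vectors = np.atleast_2d(np.asarray(word_vectors, dtype=float))
    if word_vectors.shape[0] != len(wt):
        raise ValueError(
            f"{word_vectors.shape[0]} vectors for {len(wt)} words")
    out = np.zeros((n_samples, word_vectors.shape[1]))
    for i, (a, b) in enumerate(wt.sample_spans(fs)):
        out[max(a, 0):min(b, n_samples)] = word_vectors[i]
    return FeatureSeries("word_vectors", out, fs)


def sum_tokens_to_words(token_values: np.ndarray,
                        token_word_map: np.ndarray) -> np.ndarray:
    """Pointwise-sum token rows (vectors or scalars) into word rows.

    ``token_word_map[i]`` is the word index of token i; multi-token words
    (e.g. "skiff" -> "sk" + "iff") get the sum of their token vectors, and
    likewise summed surprisal.
    """
    token_values = np.asarray(token_values, dtype=float)
    squeeze = token_values.ndim == 1
    token_values = np.atleast_2d(token_values.T).T
    token_word_map = np.asarray(token_word_map, dtype=int)
    n_words = int(token_word_map.max()) + 1 if token_word_map.size else 0
    out = np.zeros((n_words, token_values.shape[1]))
    np.add.at(out, token_word_map, token_values)
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# ablations

_ABLATION_KINDS = ("within_word_shuffle", "lexicalize", "global_shuffle", "none")


@dataclass
class AblationSpec:
    kind: str = "none"
    seed: int = 0
    n_repeats: int = 1  # conventional defaults: 20 within-word, 10 global

    def __post_init__(self):
        if self.kind not in _ABLATION_KINDS:
            raise ValueError(f"unknown ablation kind {self.kind!r}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def ablate(fs: FeatureSeries, wt: WordTable | None, spec: AblationSpec,
           repeat: int = 0) -> FeatureSeries:
    """Apply one ablation draw (``repeat`` indexes the seeded repetition).

    within_word_shuffle permutes frame rows uniformly within each word's
    boundaries (frames between words stay put); lexicalize replaces each
    word's frames by their feature-wise mean; global_shuffle permutes every
    frame row across the whole run.
    """
    if spec.kind == "none":
        return fs
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, repeat)))
    data = fs.data.copy()
    if spec.kind == "global_shuffle":
        data = data[rng.permutation(data.shape[0])]
    else:
        if wt is None:
            raise ValueError(f"{spec.kind} requires a WordTable")
        for i, (a, b) in enumerate(wt.sample_spans(fs.fs)):
            a, b = max(a, 0), min(b, data.shape[0])
            if b - a < 1:
                logger.warning("word %d spans no frames at %.0f Hz; skipped",
                               i, fs.fs)
                continue
            if spec.kind == "within_word_shuffle":
                data[a:b] = data[a:b][rng.permutation(b - a)]
            else:  # lexicalize
                data[a:b] = data[a:b].mean(axis=0)
    meta = dict(fs.meta, ablation=spec.kind, ablation_repeat=repeat)
    return FeatureSeries(fs.name, data, fs.fs, fs.run_id, meta)
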