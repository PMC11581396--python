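"""Sliding-window extraction, PCA projection, word-aligned regressors and
ablation operators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagcoder.containers import FeatureSeries, WordTable
from lagcoder.features import (AblationSpec, FrameStatExtractor,
                               PastIntegratorExtractor, ablate,
                               fit_external_pca, project_pca,
                               resample_features, sliding_window_extract,
                               sum_tokens_to_words, surprisal_spikes,
                               word_stretch)

FS_AUDIO = 1000.0


class TestSlidingWindow:
    def test_context_free_extractor_matches_full_pass(self, rng):
        wave = rng.standard_normal(int(FS_AUDIO))
        ext = FrameStatExtractor(native_fs=50, dim=3)
        out = sliding_window_extract(ext, wave, FS_AUDIO)[0]
        full = ext(wave, FS_AUDIO)[0]
        assert out.n_times == pytest.approx(50, abs=1)
        assert np.allclose(out.data, full[:out.n_times])

    def test_context_restriction_invariant_for_context_free_stub(self, rng):
        wave = rng.standard_normal(int(4 * FS_AUDIO))
        ext = FrameStatExtractor(native_fs=50, dim=2)
        outs = [sliding_window_extract(ext, wave, FS_AUDIO,
                                       max_context_s=c)[0].data
                for c in (0.5, 1.0, 5.0, 30.0)]
        for o in outs[1:]:
            assert np.allclose(o, outs[0])

    def test_causality_locality_probe(self, rng):
        """With 0.5 s context, a perturbation at t=5 s cannot change frames
        around t=10 s."""
        wave = rng.standard_normal(int(12 * FS_AUDIO))
        perturbed = wave.copy()
        perturbed[int(5 * FS_AUDIO):int(5.2 * FS_AUDIO)] += 10.0
        ext = PastIntegratorExtractor(integration_s=0.5, native_fs=50)
        a = sliding_window_extract(ext, wave, FS_AUDIO, max_context_s=0.5)[0]
        b = sliding_window_extract(ext, perturbed, FS_AUDIO,
                                   max_context_s=0.5)[0]
        late = slice(int(9.5 * 50), int(10.5 * 50))
        early = slice(int(5.0 * 50), int(5.5 * 50))
        assert np.allclose(a.data[late], b.data[late])
        assert not np.allclose(a.data[early], b.data[early])

    def test_runs_processed_independently(self, rng):
        ext = FrameStatExtractor(native_fs=50, dim=2)
        w1 = rng.standard_normal(int(FS_AUDIO))
        w2 = rng.standard_normal(int(FS_AUDIO))
        a = sliding_window_extract(ext, w1, FS_AUDIO)[0].data
        b = sliding_window_extract(ext, w2, FS_AUDIO)[0].data
        again = sliding_window_extract(ext, w1, FS_AUDIO)[0].data
        assert np.allclose(a, again)
        assert a.shape == b.shape


class TestResampleFeatures:
    def test_constant_preserved(self):
        fs = FeatureSeries("x", np.full((100, 2), 1.7), 50.0)
        out = resample_features(fs, 32.0)
        assert out.n_times == 64
        # constant value preserved to within the polyphase passband ripple
        assert np.allclose(out.data, 1.7, atol=1e-3)

    def test_sinusoid_preserved(self):
        t = np.arange(500) / 50.0
        fs = FeatureSeries("x", np.sin(2 * np.pi * 2 * t), 50.0)
        out = resample_features(fs, 32.0)
        ideal = np.sin(2 * np.pi * 2 * np.arange(out.n_times) / 32.0)
        r = np.corrcoef(out.data[8:-8, 0], ideal[8:-8])[0, 1]
        assert r > 0.99

    def test_length_alignment_recorded(self):
        fs = FeatureSeries("x", np.ones(100), 50.0)
        out = resample_features(fs, 32.0, n_target=65)
        assert out.n_times == 65 and out.meta["length_adjust"] == 1
        with pytest.raises(ValueError, match="more than 1"):
            resample_features(fs, 32.0, n_target=99)


class TestPca:
    def test_rank_one_corpus(self, rng):
        pattern = rng.standard_normal(8)
        corpus = np.outer(rng.standard_normal(200), pattern)
        p = fit_external_pca([corpus], k=3)
        assert p.explained_variance_ratio[0] > 0.999

    def test_isotropic_corpus_spreads_variance(self, rng):
        dim = 20
        corpus = rng.standard_normal((20000, dim))
        p = fit_external_pca([corpus], k=10)
        assert np.allclose(p.explained_variance_ratio, 1.0 / dim, atol=0.01)

    def test_reconstruction_error_equals_discarded_variance(self, rng):
        X = rng.standard_normal((300, 6)) @ np.diag([3, 2, 1.5, 1, 0.5, 0.2])
        p = fit_external_pca([X], k=4)
        proj = (X - p.mean) @ p.axes
        recon = proj @ p.axes.T + p.mean
        sse = np.sum((X - recon) ** 2)
        cov_eigs = np.sort(np.linalg.eigvalsh(np.cov(X.T, bias=True)))
        assert sse == pytest.approx(X.shape[0] * cov_eigs[:2].sum(), rel=1e-6)

    def test_projection_identities(self, rng):
        corpus = rng.standard_normal((500, 8))
        p = fit_external_pca([corpus], k=4)
        at_mean = FeatureSeries("x", np.tile(p.mean, (5, 1)), 32.0)
        assert np.allclose(project_pca(at_mean, p).data, 0.0, atol=1e-9)
        axis0 = FeatureSeries("x", (p.mean + p.axes[:, 0])[None, :], 32.0)
        out = project_pca(axis0, p).data[0]
        assert np.allclose(out, np.eye(4)[0], atol=1e-9)

    def test_k_larger_than_dim_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            fit_external_pca([rng.standard_normal((50, 4))], k=10)


class TestWordAligned:
    def test_spike_placement_and_values(self, word_table):
        wt = WordTable(pd.DataFrame({"word": ["a", "b"],
                                     "onset_s": [1.0, 2.0],
                                     "offset_s": [1.5, 2.5],
                                     "surprisal": [3.0, 5.0]}))
        out = surprisal_spikes(wt, 32.0, 96)
        nz = np.flatnonzero(out.data[:, 0])
        assert list(nz) == [32, 64]
        assert out.data[32, 0] == 3.0 and out.data[64, 0] == 5.0

    def test_spike_mass_conserved(self, word_table):
        out = surprisal_spikes(word_table, 32.0, 128)
        assert out.data.sum() == pytest.approx(word_table.surprisals.sum())

    def test_empty_table_gives_zeros(self):
        wt = WordTable(pd.DataFrame({"word": [], "onset_s": [],
                                     "offset_s": [], "surprisal": []}))
        assert np.all(surprisal_spikes(wt, 32.0, 64).data == 0)

    def test_missing_surprisal_rejected(self):
        wt = WordTable(pd.DataFrame({"word": ["a"], "onset_s": [0.1],
                                     "offset_s": [0.3]}))
        with pytest.raises(ValueError, match="surprisal"):
            surprisal_spikes(wt, 32.0, 64)

    def test_word_stretch_span_and_silence(self):
        wt = WordTable(pd.DataFrame({"word": ["a"], "onset_s": [0.0],
                                     "offset_s": [1.0]}))
        v = np.array([[2.0, -1.0]])
        out = word_stretch(v, wt, 32.0, 64)
        assert np.allclose(out.data[:32], v[0])
        assert np.all(out.data[32:] == 0)

    def test_adjacent_words_never_blend(self):
        wt = WordTable(pd.DataFrame({"word": ["a", "b"],
                                     "onset_s": [0.0, 1.0],
                                     "offset_s": [1.0, 2.0]}))
        v = np.array([[1.0], [5.0]])
        out = word_stretch(v, wt, 32.0, 64).data[:, 0]
        assert set(np.unique(out)) == {1.0, 5.0}

    def test_nonzero_duration_matches_word_duration(self, word_table):
        v = np.ones((3, 2))
        out = word_stretch(v, word_table, 32.0, 128)
        nonzero = np.sum(np.any(out.data != 0, axis=1))
        total = np.sum(np.rint(word_table.offsets * 32)
                       - np.rint(word_table.onsets * 32))
        assert abs(nonzero - total) <= len(word_table)

    def test_token_summation(self):
        # multi-token word ("sk" + "iff") sums vectors and surprisals
        tokens = np.array([[1.0, 2.0], [0.5, 0.5], [3.0, 0.0]])
        out = sum_tokens_to_words(tokens, [0, 0, 1])
        assert np.allclose(out, [[1.5, 2.5], [3.0, 0.0]])
        surp = sum_tokens_to_words(np.array([1.2, 0.8, 2.0]), [0, 0, 1])
        assert np.allclose(surp, [2.0, 2.0])
        assert out.sum(axis=0) == pytest.approx(tokens.sum(axis=0))


class TestAblate:
    def _series(self, rng, n=128, d=4):
        return FeatureSeries("x", rng.standard_normal((n, d)), 32.0)

    def _single_frame_table(self):
        on = np.arange(10) * 0.5
        return WordTable(pd.DataFrame({"word": [f"w{i}" for i in range(10)],
                                       "onset_s": on,
                                       "offset_s": on + 1 / 32.0}))

    def test_single_frame_words_shuffle_is_identity(self, rng):
        x = self._series(rng, n=160)
        spec = AblationSpec("within_word_shuffle", seed=3)
        out = ablate(x, self._single_frame_table(), spec)
        assert np.array_equal(out.data, x.data)

    def test_lexicalize_idempotent(self, rng, word_table):
        x = self._series(rng)
        spec = AblationSpec("lexicalize")
        once = ablate(x, word_table, spec)
        twice = ablate(once, word_table, spec)
        assert np.allclose(once.data, twice.data)

    def test_within_word_shuffle_preserves_word_means(self, rng, word_table):
        x = self._series(rng)
        out = ablate(x, word_table, AblationSpec("within_word_shuffle", seed=1))
        for a, b in word_table.sample_spans(32.0):
            assert np.allclose(out.data[a:b].mean(axis=0),
                               x.data[a:b].mean(axis=0))
        mask = np.ones(128, dtype=bool)
        for a, b in word_table.sample_spans(32.0):
            mask[a:b] = False
        assert np.array_equal(out.data[mask], x.data[mask])

    def test_global_shuffle_preserves_row_multiset(self, rng, word_table):
        x = self._series(rng)
        out = ablate(x, word_table, AblationSpec("global_shuffle", seed=1))
        assert not np.array_equal(out.data, x.data)
        srt = lambda m: m[np.lexsort(m.T)]
        assert np.allclose(srt(out.data), srt(x.data))

    @given(seed=st.integers(0, 50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_shuffles_commute_with_linear_projection(self, seed):
        """Permutations are row operations, so shuffling then projecting
        equals projecting then shuffling with the same seed."""
        rng = np.random.default_rng(99)
        x = FeatureSeries("x", rng.standard_normal((64, 6)), 32.0)
        wt = WordTable(pd.DataFrame({"word": ["a", "b"],
                                     "onset_s": [0.0, 1.0],
                                     "offset_s": [0.9, 1.9]}))
        proj = rng.standard_normal((6, 3))
        spec = AblationSpec("within_word_shuffle", seed=seed)
        a = ablate(x, wt, spec).data @ proj
        xp = FeatureSeries("xp", x.data @ proj, 32.0)
        b = ablate(xp, wt, spec).data
        assert np.allclose(a, b)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown ablation"):
            AblationSpec("scramble")
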