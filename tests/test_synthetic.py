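"""Synthetic generator: planted spectra, rank structure, determinism, corpora."""

import numpy as np
import pytest
from scipy import signal as sps

from avmtf import audio
from avmtf.rcca import accumulate_covariances, fit_rcca
from avmtf.synthetic import (SourceSpec, SyntheticGroundTruth,
                             flagship_ground_truth, generate_feature_corpus,
                             generate_feature_views, generate_sources,
                             generate_waveform_corpus, write_waveform_corpus)


def periodogram_peak(x, rate=25.0):
    f, p = sps.periodogram(x, fs=rate)
    return f[np.argmax(p)]


class TestGenerateSources:
    def test_spectral_peak_within_band(self):
        S = generate_sources([SourceSpec(4.0, 1.0)], 1500, 25.0, seed=1)
        assert abs(periodogram_peak(S[:, 0]) - 4.0) <= 0.5

    @pytest.mark.parametrize("fc,bw", [(1.5, 1.0), (3.0, 0.5), (8.0, 2.0)])
    def test_power_concentrated_in_band(self, fc, bw):
        S = generate_sources([SourceSpec(fc, bw)], 3000, 25.0, seed=2)
        f, p = sps.periodogram(S[:, 0], fs=25.0)
        inside = (f >= fc - bw / 2 - 0.1) & (f <= fc + bw / 2 + 0.1)
        assert p[inside].sum() / p.sum() > 0.99

    def test_columns_zero_mean_amplitude_scaled(self):
        S = generate_sources([SourceSpec(4.0, 1.0, 2.0), SourceSpec(2.0, 0.5)], 1000, 25.0, 3)
        assert np.allclose(S.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(S.std(axis=0), [2.0, 1.0], atol=1e-9)

    def test_seed_determinism(self):
        specs = [SourceSpec(4.0, 1.5), SourceSpec(2.0, 1.0)]
        S1 = generate_sources(specs, 800, 25.0, seed=7)
        S2 = generate_sources(specs, 800, 25.0, seed=7)
        assert np.array_equal(S1, S2)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            SourceSpec(12.4, 1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            generate_sources([SourceSpec(4.0, 1.0)], 30, 25.0, 0)


class TestFeatureViews:
    def test_noiseless_single_source_rank_one_cross_covariance(self):
        gt = flagship_ground_truth(audio_noise_sd=0.0, visual_noise_sd=0.0,
                                   speaker_jitter=0.0, freq_jitter_sd=0.0)
        gt.sources = gt.sources[:1]
        gt.audio_mixing = gt.audio_mixing[:1]
        gt.visual_mixing = gt.visual_mixing[:1]
        S = generate_sources(gt.sources, 2000, 25.0, 1)
        XA, XV = generate_feature_views(S, gt, 0, seed=1)
        sv = np.linalg.svd(XA.T @ XV, compute_uv=False)
        assert sv[1] / sv[0] < 1e-8

    def test_noiseless_recovery_unit_canonical_correlations(self):
        # rank-2 noiseless views: the two shared sources give rho ~ 1 and
        # every further component ~ 0 (a whisper of regularization keeps
        # the rank-deficient covariances invertible)
        gt = flagship_ground_truth(audio_noise_sd=0.0, visual_noise_sd=0.0,
                                   speaker_jitter=0.0, freq_jitter_sd=0.0)
        S = generate_sources(gt.sources, 3000, 25.0, 2)
        XA, XV = generate_feature_views(S, gt, 0, seed=2)
        model = fit_rcca(accumulate_covariances([(XA, XV)]), 1e-7, 1e-7, 6)
        assert np.all(model.rho[:2] > 0.999)
        assert np.all(model.rho[2:] < 0.3)

    def test_noiseless_unregularized_advises_lambda(self):
        gt = flagship_ground_truth(audio_noise_sd=0.0, visual_noise_sd=0.0,
                                   speaker_jitter=0.0, freq_jitter_sd=0.0)
        S = generate_sources(gt.sources, 3000, 25.0, 2)
        XA, XV = generate_feature_views(S, gt, 0, seed=2)
        with pytest.raises(np.linalg.LinAlgError, match="lambda > 0"):
            fit_rcca(accumulate_covariances([(XA, XV)]), 0.0, 0.0, 6)

    def test_dimension_mismatch_rejected(self):
        gt = flagship_ground_truth()
        S = generate_sources(gt.sources[:1], 500, 25.0, 1)
        with pytest.raises(ValueError, match="sources"):
            generate_feature_views(S, gt, 0, seed=0)

    def test_zero_jitter_same_mixing_across_speakers(self):
        gt = flagship_ground_truth(speaker_jitter=0.0, freq_jitter_sd=0.0)
        S = generate_sources(gt.sources, 1000, 25.0, 5)
        XA0, _ = generate_feature_views(S, gt, 0, seed=9)
        XA1, _ = generate_feature_views(S, gt, 1, seed=9)
        assert np.allclose(XA0, XA1)


class TestCorpora:
    def test_bookkeeping_counts(self):
        gt = flagship_ground_truth(seed=3)
        c = generate_feature_corpus(gt, 20, 5, 100, seed=3)
        assert len(c.video_ids) == 100
        assert len(c.speakers()) == 20
        assert all(XA.shape == (100, 25) and XV.shape == (100, 204)
                   for XA, XV, _ in c.pairs())

    def test_corpus_seed_determinism(self):
        gt = flagship_ground_truth(seed=4)
        c1 = generate_feature_corpus(gt, 3, 2, 200, seed=4)
        c2 = generate_feature_corpus(gt, 3, 2, 200, seed=4)
        for a, b in zip(c1.X_A, c2.X_A):
            assert np.array_equal(a, b)

    def test_independent_views_have_no_cross_correlation(self):
        gt = flagship_ground_truth(seed=5)
        c = generate_feature_corpus(gt, 2, 1, 8000, seed=5, independent=True)
        r = np.abs(c.X_A[0].T @ c.X_V[0] / 8000)
        assert r.max() < 0.06  # ~4 sigma of a null correlation at T=8000


class TestWaveformCorpus:
    @pytest.fixture(scope="class")
    def single_source_corpus(self):
        gt = SyntheticGroundTruth(
            sources=[SourceSpec(4.0, 0.8)], audio_mixing=np.ones((1, 25)),
            visual_mixing=np.ones((1, 204)), audio_noise_sd=0.0,
            visual_noise_sd=0.5, speaker_jitter=0.0, freq_jitter_sd=0.0, seed=0)
        return generate_waveform_corpus(gt, 1, 1, 10.0, seed=0)

    def test_front_end_recovers_planted_modulation(self, single_source_corpus, gamma_bank, mfb):
        c = single_source_corpus
        w = audio.AudioWaveform(c.waveforms[0], c.audio_rate)
        env = audio.gammatone_envelopes(w, gamma_bank)
        X = audio.modulation_decompose(env, mfb)
        var = X[50:].var(axis=0)
        assert abs(mfb.center_freqs[var.argmax()] - 4.0) <= 0.5

    def test_clip_fraction_reported(self, single_source_corpus):
        assert 0 <= single_source_corpus.clip_fractions[0] < 0.2

    def test_zero_amplitude_modulator_suppresses_planted_rate(self, single_source_corpus,
                                                              gamma_bank, mfb):
        gt = SyntheticGroundTruth(
            sources=[SourceSpec(4.0, 0.8, amplitude=0.0)],
            audio_mixing=np.ones((1, 25)), visual_mixing=np.ones((1, 204)),
            audio_noise_sd=0.0, visual_noise_sd=0.5,
            speaker_jitter=0.0, freq_jitter_sd=0.0, seed=0)
        c0 = generate_waveform_corpus(gt, 1, 1, 10.0, seed=0)

        def chan4_var(corpus):
            w = audio.AudioWaveform(corpus.waveforms[0], corpus.audio_rate)
            X = audio.modulation_decompose(audio.gammatone_envelopes(w, gamma_bank), mfb)
            j = np.argmin(np.abs(mfb.center_freqs - 4.0))
            return X[50:].var(axis=0)[j]

        # residual carrier-envelope fluctuation at 4 Hz is tiny compared to
        # the same corpus with the modulator switched on
        assert chan4_var(c0) < 0.01 * chan4_var(single_source_corpus)

    def test_corpus_partition(self):
        gt = flagship_ground_truth(seed=1)
        c = generate_waveform_corpus(gt, 4, 2, 3.0, seed=1)
        assert len(c.video_ids) == 8
        assert len(set(c.speaker_ids)) == 4
        assert all(len(ls.positions) == 75 for ls in c.landmark_series)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            generate_waveform_corpus(flagship_ground_truth(), 1, 1, 0.0)

    def test_round_trip_through_writer(self, tmp_path):
        gt = flagship_ground_truth(seed=2)
        c = generate_waveform_corpus(gt, 2, 1, 2.5, seed=2)
        out = write_waveform_corpus(c, tmp_path / "corpus")
        assert (out / "manifest.csv").exists()
        assert (out / "ground_truth.json").exists()
        w = audio.load_audio(out / f"{c.video_ids[0]}.wav")
        assert len(w.samples) == len(c.waveforms[0])
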