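"""Template construction and feature extraction per paradigm."""

import numpy as np
import pytest

from stbf.containers import DEFAULT_MONTAGE, TrialSet
from stbf.core import (
    PooledCovariance,
    SegmentStack,
    SpatiotemporalPattern,
    lcmv_weights,
)
from stbf.paradigms import (
    cvep_features,
    cvep_patterns_and_weights,
    cvep_segment_length,
    cvep_segments,
    cvep_spec,
    fit_paradigm,
    get_spec,
    p300_features,
    p300_pattern,
    p300_spec,
    ssvep_features,
    ssvep_patterns_and_weights,
    ssvep_segments,
    ssvep_spec,
    trialset_features,
)
from stbf.synth import SynthConfig, generate_session


def identity_weights(pattern: SpatiotemporalPattern):
    """Beamformer under identity covariance: w = a / (a'a)."""
    dim = pattern.flat.size
    return lcmv_weights(PooledCovariance(sigma=np.eye(dim), n_segments=10), pattern)


class TestP300:
    def test_pattern_is_class_mean_difference(self):
        t = np.ones((2, 3))
        nt = np.zeros((2, 3))
        stack = SegmentStack(data=np.stack([t, nt], axis=-1), fs=64.0)
        pat = p300_pattern(stack, np.array([True, False]))
        np.testing.assert_array_equal(pat.pattern, t - nt)

    def test_identical_classes_give_zero_pattern_then_weight_error(self):
        seg = np.random.default_rng(0).standard_normal((2, 3))
        stack = SegmentStack(data=np.stack([seg, seg], axis=-1), fs=64.0)
        pat = p300_pattern(stack, np.array([True, False]))
        with pytest.raises(ValueError, match="unconstrained"):
            lcmv_weights(PooledCovariance(sigma=np.eye(6), n_segments=5), pat)

    def test_empty_class_errors(self):
        stack = SegmentStack(data=np.zeros((2, 3, 2)), fs=64.0)
        with pytest.raises(ValueError, match="target and one non-target"):
            p300_pattern(stack, np.array([True, True]))

    def test_features_constraint_identity(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((3, 4))
        pat = SpatiotemporalPattern(pattern=a)
        w = identity_weights(pat)
        # target 2's averaged epoch equals A, all others zero
        epochs = np.zeros((3, 4, 5))
        epochs[:, :, 2] = a
        stack = SegmentStack(data=epochs, fs=64.0)
        y = p300_features(stack, np.arange(5), w, n_targets=5)
        np.testing.assert_allclose(y, [0, 0, 1, 0, 0], atol=1e-12)

    def test_features_linearity_average_then_filter(self):
        rng = np.random.default_rng(2)
        pat = SpatiotemporalPattern(pattern=rng.standard_normal((3, 4)))
        w = identity_weights(pat)
        epochs = rng.standard_normal((3, 4, 8))
        targets = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        stack = SegmentStack(data=epochs, fs=64.0)
        y = p300_features(stack, targets, w, n_targets=2)
        # filtering each epoch then averaging the outputs gives the same value
        from stbf.core import apply_beamformer

        for i in range(2):
            outs = [apply_beamformer(w, epochs[:, :, k])
                    for k in np.flatnonzero(targets == i)]
            assert y[i] == pytest.approx(np.mean(outs), abs=1e-10)

    def test_missing_target_in_trial_errors(self):
        pat = SpatiotemporalPattern(pattern=np.ones((2, 2)))
        w = identity_weights(pat)
        stack = SegmentStack(data=np.zeros((2, 2, 3)), fs=64.0)
        with pytest.raises(ValueError, match="no epochs"):
            p300_features(stack, np.array([0, 0, 1]), w, n_targets=3)

    def test_preset_pattern_shape_10x38(self):
        spec = p300_spec(cues_per_target=1)
        ts = generate_session(SynthConfig(spec=spec, snr=2.0, seed=3))
        from stbf.preprocess import condition_trials

        fitted = fit_paradigm(condition_trials(ts), spec)
        assert fitted.patterns[0].shape == (10, 38)
        assert fitted.covariance_dims == [380]


class TestSsvepSegments:
    def test_period_lengths_42_and_34(self):
        trial = np.zeros((10, 2560))
        assert ssvep_segments(trial, 12.0, 512.0).n == 42
        assert ssvep_segments(trial, 15.0, 512.0).n == 34

    def test_segment_count_period_aligned(self):
        # 5-s trial at 512 Hz, 12 Hz, 120 ms skip: starts at floor(61.44 +
        # s*42.667); 58 aligned complete segments fit
        trial = np.zeros((10, 2560))
        st = ssvep_segments(trial, 12.0, 512.0, skip=0.12)
        assert st.r == 58

    def test_segments_track_period_boundaries(self):
        # each segment of an exact-period sinusoid starts within one sample
        # of the same phase
        fs, f = 512.0, 12.0
        t = np.arange(2560) / fs
        trial = np.sin(2 * np.pi * f * t)[None, :]
        st = ssvep_segments(trial, f, fs)
        first_samples = st.data[0, 0, :]
        assert np.ptp(first_samples) < 2 * np.pi * f / fs  # < 1 sample of phase

    def test_too_short_trial_errors(self):
        with pytest.raises(ValueError, match="too short"):
            ssvep_segments(np.zeros((2, 30)), 12.0, 512.0)


class TestSsvepPatterns:
    def _noiseless_trialset(self, freqs=(16.0, 16.0), phases=(0.0, np.pi),
                            fs=512.0, seconds=2.0, cues_per_target=2):
        spec = get_spec("ssvep", n_targets=len(freqs), frequencies=freqs,
                        phases=phases, cues_per_target=cues_per_target,
                        trial_seconds=seconds)
        t = np.arange(int(seconds * fs)) / fs
        trials, cues = [], []
        for rep in range(cues_per_target):
            for i in range(len(freqs)):
                wave = np.sin(2 * np.pi * freqs[i] * t + phases[i])
                trials.append(np.vstack([wave, 0.5 * wave]))
                cues.append(i)
        ts = TrialSet(data=np.stack(trials, axis=-1), fs=fs,
                      cues=np.array(cues), channel_names=["Oz", "O1"],
                      paradigm="ssvep")
        return ts, spec

    def test_noiseless_pattern_recovers_injected_period(self):
        # 16 Hz divides 512 Hz exactly, so averaging is an identity
        ts, spec = self._noiseless_trialset()
        pairs = ssvep_patterns_and_weights(ts, spec)
        n = int(512 // 16)
        t = np.arange(n) / 512.0
        start = int(np.floor(spec.transient_skip * 512.0))
        expected = np.sin(2 * np.pi * 16.0 * (t + start / 512.0))
        np.testing.assert_allclose(pairs[0][0].pattern[0], expected, atol=1e-10)

    def test_antiphase_targets_have_sign_flipped_patterns(self):
        ts, spec = self._noiseless_trialset()
        pairs = ssvep_patterns_and_weights(ts, spec)
        a, b = pairs[0][0].pattern.ravel(), pairs[1][0].pattern.ravel()
        corr = (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert corr <= -0.99

    def test_preset_weight_dims_in_target_order(self):
        spec = ssvep_spec(cues_per_target=2)
        ts = generate_session(SynthConfig(spec=spec, snr=2.0, seed=4))
        pairs = ssvep_patterns_and_weights(ts, spec)
        dims = [w.m * w.n for _, w in pairs]
        assert dims == [420, 420, 340, 340]

    def test_uncued_target_errors(self):
        ts, spec = self._noiseless_trialset()
        ts.cues[:] = 0
        with pytest.raises(ValueError, match="never cued"):
            ssvep_patterns_and_weights(ts, spec)

    def test_features_constraint_identity_and_zero_trial(self):
        ts, spec = self._noiseless_trialset()
        pairs = ssvep_patterns_and_weights(ts, spec, ridge=1e-8)
        weights = [w for _, w in pairs]
        y = ssvep_features(ts.data[:, :, 0], ts.fs, spec, weights)
        assert y[0] == pytest.approx(1.0, abs=1e-6)
        y0 = ssvep_features(np.zeros_like(ts.data[:, :, 0]), ts.fs, spec, weights)
        np.testing.assert_allclose(y0, 0.0, atol=1e-12)

    def test_training_order_invariance(self):
        spec = ssvep_spec(cues_per_target=2)
        ts = generate_session(SynthConfig(spec=spec, snr=1.0, seed=5))
        perm = np.random.default_rng(0).permutation(ts.n_trials)
        pairs_a = ssvep_patterns_and_weights(ts, spec)
        pairs_b = ssvep_patterns_and_weights(ts.subset(perm), spec)
        for (pa, wa), (pb, wb) in zip(pairs_a, pairs_b):
            np.testing.assert_allclose(pa.pattern, pb.pattern, atol=1e-10)
            np.testing.assert_allclose(wa.w, wb.w, atol=1e-8)


class TestCvep:
    def test_segment_length_63_at_120hz(self):
        spec = cvep_spec()
        assert cvep_segment_length(spec, 120.0) == 63

    def test_ten_repetitions_give_ten_segments(self):
        spec = cvep_spec()
        trial = np.zeros((10, 630))
        assert cvep_segments(trial, 120.0, spec).r == 10

    def test_one_second_gives_one_complete_segment(self):
        spec = cvep_spec()
        assert cvep_segments(np.zeros((10, 120)), 120.0, spec).r == 1

    def test_too_short_trial_errors(self):
        spec = cvep_spec()
        with pytest.raises(ValueError, match="shorter than one code cycle"):
            cvep_segments(np.zeros((10, 62)), 120.0, spec)

    def test_noiseless_patterns_are_lagged_copies(self):
        spec = cvep_spec(cues_per_target=1)
        ts = generate_session(SynthConfig(spec=spec, snr=np.inf, seed=6, fs=120.0))
        pairs = cvep_patterns_and_weights(ts, spec)
        oz = ts.channel_names.index("Oz")
        a0 = pairs[0][0].pattern[oz]
        for i in (5, 17, 31):
            ai = pairs[i][0].pattern[oz]
            xc = [a0 @ np.roll(ai, -k) for k in range(63)]
            assert int(np.argmax(xc)) == spec.lags[i] - spec.lags[0]

    def test_preset_32_weight_vectors_of_length_630(self):
        spec = cvep_spec(cues_per_target=1)
        ts = generate_session(SynthConfig(spec=spec, snr=1.0, seed=7, fs=120.0))
        pairs = cvep_patterns_and_weights(ts, spec)
        assert len(pairs) == 32
        assert all(w.w.size == 630 for _, w in pairs)

    def test_zero_variance_training_uses_pinv_and_flags(self):
        # every trial identical per target: covariance rank-deficient
        spec = cvep_spec(cues_per_target=2)
        one = generate_session(SynthConfig(spec=spec, snr=np.inf, seed=8, fs=120.0))
        pairs = cvep_patterns_and_weights(one, spec)
        assert any(w.used_pinv for _, w in pairs)

    def test_feature_vector_length_and_identity(self):
        spec = cvep_spec(cues_per_target=1)
        ts = generate_session(SynthConfig(spec=spec, snr=2.0, seed=9, fs=120.0))
        fitted = fit_paradigm(ts, spec, ridge=1e-6)
        y = cvep_features(ts.data[:, :, 0], 120.0, spec, fitted.weights)
        assert y.shape == (32,)


class TestUnifiedInterface:
    def test_feature_matrix_shapes(self):
        spec = ssvep_spec(cues_per_target=2)
        ts = generate_session(SynthConfig(spec=spec, snr=1.0, seed=10))
        fitted = fit_paradigm(ts, spec)
        feats = trialset_features(ts, fitted)
        assert feats.shape == (8, 4)

    def test_high_snr_decoding_recovers_cue(self):
        spec = ssvep_spec(cues_per_target=2)
        ts = generate_session(SynthConfig(spec=spec, snr=50.0, seed=11))
        fitted = fit_paradigm(ts, spec)
        feats = trialset_features(ts, fitted)
        assert np.array_equal(feats.argmax(axis=1), ts.cues)
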