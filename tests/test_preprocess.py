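"""Baseline removal, centering and whitening contracts."""

import numpy as np
import pytest

from fetalica import (
    DegenerateInputError,
    ECGSegment,
    InvalidArgumentError,
    SynthConfig,
    center,
    estimate_baseline,
    generate_abdominal,
    preprocess,
    remove_baseline,
    whiten,
)

FS = 250.0


def sine(freq, n=2500, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestEstimateBaseline:
    def test_dc_gain_unity(self):
        seg = ECGSegment(np.full((1, 2000), 3.7), fs=FS)
        baseline = estimate_baseline(seg)
        np.testing.assert_allclose(baseline, 3.7, rtol=1e-6)

    def test_attenuates_50hz(self):
        # |H| of a 3rd-order Butterworth at 10x cutoff is ~1e-3; zero-phase
        # filtering applies it twice
        baseline = estimate_baseline(sine(50.0), fs=FS)
        assert np.max(np.abs(baseline[0, 200:-200])) < 0.01

    def test_passes_slow_drift(self):
        baseline = estimate_baseline(sine(0.3), fs=FS)
        assert np.max(np.abs(baseline[0, 200:-200])) > 0.95

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            estimate_baseline(sine(1.0), fs=FS, cutoff_hz=200.0)

    def test_causal_mode_available(self):
        zp = estimate_baseline(sine(0.3), fs=FS, zero_phase=True)
        causal = estimate_baseline(sine(0.3), fs=FS, zero_phase=False)
        assert zp.shape == causal.shape
        assert not np.allclose(zp, causal)  # causal mode has group delay


class TestRemoveBaseline:
    def test_zero_in_zero_out(self):
        x1 = remove_baseline(np.zeros((2, 1000)), fs=FS)
        np.testing.assert_array_equal(x1, 0.0)

    def test_recovers_clean_signal_under_drift(self):
        cfg = SynthConfig(seed=5, noise_sd=0.0, baseline_amp=0.0)
        segment, truth = generate_abdominal(cfg)
        clean = segment.data
        drift = 0.8 * np.sin(2 * np.pi * 0.5 * np.arange(segment.n_samples) / FS)
        x1 = remove_baseline(clean + drift, fs=FS)
        # the 5 Hz filter necessarily shaves sub-5 Hz P/T-wave energy from
        # the beats themselves, so the exact reference is the filtered
        # clean signal; against the raw clean signal the QRS content still
        # dominates the correlation
        clean_f = remove_baseline(clean, fs=FS)
        for ch in range(3):
            assert np.corrcoef(x1[ch], clean_f[ch])[0, 1] > 0.999
            assert np.corrcoef(x1[ch], clean[ch])[0, 1] > 0.8

    def test_idempotent_away_from_transition_band(self):
        # a low-pass filter is not a projection, so exact idempotence only
        # holds for spectra away from the cut-off transition band
        x = sine(0.3, amp=2.0) + sine(50.0)
        once = remove_baseline(x, fs=FS)
        twice = remove_baseline(once, fs=FS)
        rms = np.sqrt(np.mean(once**2))
        assert np.sqrt(np.mean((twice - once) ** 2)) < 0.01 * rms


class TestCenter:
    def test_simple_example(self):
        x2, means = center(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(x2, [[-1.0, 0.0, 1.0]])
        np.testing.assert_allclose(means, [2.0])

    def test_centered_input_unchanged(self):
        x = np.array([[-1.0, 0.0, 1.0], [2.0, 0.0, -2.0]])
        x2, means = center(x)
        np.testing.assert_allclose(x2, x)
        np.testing.assert_allclose(means, 0.0)

    def test_row_means_vanish(self, rng):
        x = rng.normal(5.0, 2.0, size=(4, 777))
        x2, _ = center(x)
        assert np.max(np.abs(x2.mean(axis=1))) < 1e-12 * np.max(np.abs(x))


class TestWhiten:
    def test_known_diagonal_covariance(self, rng):
        # cov diag(4, 1) -> whitening matrix diag(1/2, 1) up to sign/permutation
        n = 200_000
        x = np.vstack([2.0 * rng.standard_normal(n), rng.standard_normal(n)])
        x2, _ = center(x)
        _, v, _, _ = whiten(x2)
        # expected diag(1/2, 1) up to row sign and permutation
        rows = np.abs(v)[np.argsort(np.argmax(np.abs(v), axis=1))]
        np.testing.assert_allclose(rows, np.diag([0.5, 1.0]), atol=0.02)

    def test_whitened_covariance_is_identity(self, clean_mixture):
        segment, _ = clean_mixture
        x2, _ = center(segment.data)
        x_white, *_ = whiten(x2)
        cov = x_white @ x_white.T / (x_white.shape[1] - 1)
        assert np.max(np.abs(cov - np.eye(3))) < 1e-6

    def test_orthogonal_input_stays_white(self, rng):
        x = rng.standard_normal((3, 5000))
        x2, _ = center(x)
        x_white, *_ = whiten(x2)
        cov = x_white @ x_white.T / (x_white.shape[1] - 1)
        assert np.max(np.abs(cov - np.eye(3))) < 1e-6

    def test_inverse_reconstructs_input(self, clean_mixture):
        segment, _ = clean_mixture
        x2, _ = center(segment.data)
        x_white, v, e, d = whiten(x2)
        back = e @ np.diag(np.sqrt(d)) @ x_white
        np.testing.assert_allclose(back, x2, rtol=1e-6, atol=1e-9)

    def test_rank_deficient_names_channel_pair(self, rng):
        a = rng.standard_normal(1000)
        x = np.vstack([a, 2.0 * a, rng.standard_normal(1000)])
        x2, _ = center(x)
        with pytest.raises(DegenerateInputError, match="channels 0 and 1"):
            whiten(x2)

    def test_all_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            whiten(np.zeros((3, 100)))


def test_full_chain_contract(default_mixture):
    segment, _ = default_mixture
    res = preprocess(segment)
    assert np.max(np.abs(res.x2.mean(axis=1))) < 1e-9
    cov = res.x_white @ res.x_white.T / (res.x_white.shape[1] - 1)
    assert np.max(np.abs(cov - np.eye(3))) < 1e-6
    np.testing.assert_allclose(res.x_white, res.whitening_matrix @ res.x2, atol=1e-9)
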