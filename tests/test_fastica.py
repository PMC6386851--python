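"""Fixed-point iteration: contrast, convergence, separation quality,
sign/permutation indeterminacy, and the exhaustive-search oracle."""

import numpy as np
import pytest

from fetalica import (
    FastICAConfig,
    NotWhitenedError,
    amari_index,
    contrast_g,
    fastica_one_unit,
    fastica_separate,
)
from fetalica.preprocess import center, whiten
from fetalica.validation import composite_unmixing, grid_oracle_study, match_abs_corr


@pytest.mark.parametrize("y,gy,gpy", [(2.0, 8.0, 12.0), (0.0, 0.0, 0.0), (-1.0, -1.0, 3.0)])
def test_contrast_values(y, gy, gpy):
    g, gp = contrast_g(np.array([y]))
    assert g[0] == gy and gp[0] == gpy


def _two_channel_whitened(rng, n=4000):
    t = np.arange(n) / 250.0
    s1 = np.sign(np.sin(2 * np.pi * 3.1 * t + 0.7))  # sub-Gaussian
    s2 = rng.laplace(size=n)  # super-Gaussian
    s = np.vstack([s1 / s1.std(), s2 / s2.std()])
    a = np.array([[1.0, 0.4], [0.3, 0.9]])
    x2, _ = center(a @ s)
    x_white, v, *_ = whiten(x2)
    w_true = v @ a  # columns = whitened source directions
    return x_white, w_true / np.linalg.norm(w_true, axis=0)


class TestOneUnit:
    def test_recovers_source_direction(self, rng):
        x_white, w_true = _two_channel_whitened(rng)
        w0 = w_true[:, 0] + 0.1 * rng.standard_normal(2)
        w, _, ok = fastica_one_unit(x_white, w0 / np.linalg.norm(w0))
        assert ok
        assert abs(w @ w_true[:, 0]) > 0.999

    def test_fixed_point_converges_immediately(self, rng):
        x_white, _ = _two_channel_whitened(rng)
        w, n_iter, ok = fastica_one_unit(x_white, np.array([1.0, 0.0]))
        w2, n_iter2, ok2 = fastica_one_unit(x_white, w)
        assert ok2 and n_iter2 <= 2
        assert abs(w2 @ w) > 1 - 1e-5

    def test_unit_norm_output(self, rng):
        x_white, _ = _two_channel_whitened(rng)
        w, *_ = fastica_one_unit(x_white, rng.standard_normal(2))
        assert np.linalg.norm(w) == pytest.approx(1.0)

    def test_rejects_unwhitened_input(self, rng):
        x = rng.standard_normal((2, 1000))
        x[1] = x[0] + 0.1 * x[1]
        with pytest.raises(NotWhitenedError):
            fastica_one_unit(x, np.array([1.0, 0.0]))

    def test_deterministic(self, rng):
        x_white, _ = _two_channel_whitened(rng)
        w0 = np.array([0.6, 0.8])
        w_a, *_ = fastica_one_unit(x_white, w0)
        w_b, *_ = fastica_one_unit(x_white, w0)
        np.testing.assert_array_equal(w_a, w_b)


class TestSeparate:
    def test_recovers_all_sources(self, whitened_mixture):
        x_white, v, truth = whitened_mixture
        sep = fastica_separate(x_white, FastICAConfig(seed=1))
        assert min(match_abs_corr(sep.sources, truth.sources)) > 0.99

    def test_rows_orthonormal(self, whitened_mixture):
        x_white, *_ = whitened_mixture
        sep = fastica_separate(x_white, FastICAConfig(seed=1))
        gram = sep.w_matrix @ sep.w_matrix.T
        assert np.max(np.abs(gram - np.eye(sep.n_components))) < 1e-6

    def test_sources_unit_variance(self, whitened_mixture):
        x_white, *_ = whitened_mixture
        sep = fastica_separate(x_white, FastICAConfig(seed=1))
        np.testing.assert_allclose(sep.sources.var(axis=1, ddof=1), 1.0, atol=1e-3)

    def test_two_seeds_agree_up_to_sign_permutation(self, whitened_mixture):
        x_white, *_ = whitened_mixture
        a = fastica_separate(x_white, FastICAConfig(seed=1))
        b = fastica_separate(x_white, FastICAConfig(seed=99))
        c = np.abs(np.corrcoef(np.vstack([a.sources, b.sources]))[:3, 3:])
        # every source of run A matches exactly one of run B
        assert np.all(c.max(axis=1) > 0.999)
        assert sorted(np.argmax(c, axis=1).tolist()) == [0, 1, 2]

    def test_amari_index_small_on_clean_mixture(self, whitened_mixture):
        x_white, v, truth = whitened_mixture
        sep = fastica_separate(x_white, FastICAConfig(seed=1))
        assert amari_index(composite_unmixing(sep.w_matrix, v, truth)) < 0.05

    def test_warm_start_preserves_component_order(self, whitened_mixture):
        x_white, *_ = whitened_mixture
        a = fastica_separate(x_white, FastICAConfig(seed=1))
        b = fastica_separate(x_white, FastICAConfig(seed=2), w_init=a.w_matrix)
        assert np.all(np.abs(np.sum(a.w_matrix * b.w_matrix, axis=1)) > 0.99)

    def test_newton_form_agrees_with_simplified(self, whitened_mixture):
        x_white, *_ = whitened_mixture
        a = fastica_separate(x_white, FastICAConfig(seed=1))
        b = fastica_separate(x_white, FastICAConfig(seed=1, use_newton_form=True))
        c = np.abs(np.corrcoef(np.vstack([a.sources, b.sources]))[:3, 3:])
        assert np.all(c.max(axis=1) > 0.999)


def test_amari_index_of_permutation_is_zero():
    p = np.array([[0.0, 2.0, 0.0], [0.0, 0.0, -1.0], [0.5, 0.0, 0.0]])
    assert amari_index(p) == pytest.approx(0.0)
    assert amari_index(np.ones((3, 3))) > 0.5


def test_fixed_points_sit_on_grid_kurtosis_maxima():
    """One-unit solutions coincide with exhaustive-search optima within 1 deg."""
    out = grid_oracle_study(n_trials=6, seed=3)
    assert out["max_angle_deg"] < 1.0
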