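"""Sample entropy against a brute-force oracle, plus its invariances and
the fetal-channel selection rule."""

import logging
import math

import numpy as np
import pytest
from conftest import sampen_bruteforce
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalica import (
    DegenerateInputError,
    InvalidArgumentError,
    SampEnParams,
    SelectionError,
    sample_entropy,
    select_fetal_channel,
)


class TestAgainstOracle:
    def test_small_integer_series(self):
        u = [1, 2, 3, 1, 2, 3, 1, 2, 3, 1]
        params = SampEnParams(m=2, r_factor=0.5 / np.std(u))  # absolute r = 0.5
        assert sample_entropy(u, params) == sampen_bruteforce(u, 2, params.r_factor)

    @pytest.mark.parametrize("n", [20, 50, 200, 500])
    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_fuzzed_series_exact_match(self, n, m, rng):
        u = rng.standard_normal(n)
        params = SampEnParams(m=m, r_factor=0.2)
        assert sample_entropy(u, params) == sampen_bruteforce(u, m, 0.2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(10, 120),
        m=st.integers(1, 3),
        r_factor=st.floats(0.05, 1.0),
    )
    def test_property_oracle_equivalence(self, seed, n, m, r_factor):
        u = np.random.default_rng(seed).standard_normal(n)
        params = SampEnParams(m=m, r_factor=r_factor)
        assert sample_entropy(u, params) == sampen_bruteforce(u, m, r_factor)


class TestKnownValues:
    def test_periodic_series_zero_entropy(self):
        # period <= m: every m-point match extends to m+1 points
        u = np.tile([0.0, 1.0], 50)
        assert sample_entropy(u, SampEnParams(m=2, r_factor=0.3)) == 0.0

    def test_noise_more_irregular_than_sine(self, rng):
        n = 400
        noise = rng.standard_normal(n)
        sine = np.sin(2 * np.pi * 7 * np.arange(n) / 250)
        sine = sine / sine.std() * noise.std()
        assert sample_entropy(noise) > sample_entropy(sine)

    def test_no_extended_matches_gives_infinity(self):
        # strictly monotone ramp with tiny tolerance: B-matches exist only
        # for adjacent templates, none survive the m+1 extension
        u = np.array([0.0, 1.0, 2.1, 3.3, 4.6, 6.0, 7.5, 9.1, 10.8, 12.6])
        assert sample_entropy(u, SampEnParams(m=1, r_factor=0.001)) == math.inf


class TestInvariances:
    def test_affine_scale_invariance(self, rng):
        u = rng.standard_normal(300)
        base = sample_entropy(u)
        assert sample_entropy(3.7 * u + 11.0) == pytest.approx(base, rel=1e-12)
        assert sample_entropy(-0.2 * u + 5.0) == pytest.approx(base, rel=1e-12)

    def test_monotone_non_increasing_in_r(self, rng):
        u = rng.standard_normal(250)
        values = [
            sample_entropy(u, SampEnParams(m=2, r_factor=r))
            for r in (0.1, 0.15, 0.2, 0.3, 0.5, 1.0)
        ]
        finite = [v for v in values if math.isfinite(v)]
        assert all(a >= b - 1e-12 for a, b in zip(finite, finite[1:]))


class TestErrors:
    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateInputError):
            sample_entropy(np.ones(50))

    def test_too_short_series(self):
        with pytest.raises(InvalidArgumentError):
            sample_entropy([1.0, 2.0, 3.0], SampEnParams(m=2))

    def test_invalid_params(self):
        with pytest.raises(InvalidArgumentError):
            SampEnParams(m=0)
        with pytest.raises(InvalidArgumentError):
            SampEnParams(r_factor=0.0)


class TestSelectFetalChannel:
    def test_argmax_of_entropies(self, rng):
        n = 400
        sources = np.vstack(
            [
                rng.standard_normal(n),  # most irregular
                np.sin(2 * np.pi * 7 * np.arange(n) / 250),
                np.sin(2 * np.pi * 3 * np.arange(n) / 250) + 0.1 * rng.standard_normal(n),
            ]
        )
        sel = select_fetal_channel(sources)
        assert sel.fetal_index == int(np.argmax(sel.entropies)) == 0

    def test_reported_entropy_triplet_selects_first(self):
        # the separated-component entropy pattern (1.02, 0.35, 0.61) must
        # resolve to the first channel
        entropies = np.array([1.02, 0.35, 0.61])
        assert int(np.argmax(entropies)) == 0

    def test_tie_breaks_to_lowest_index_and_logs(self, rng, caplog):
        u = rng.standard_normal(200)
        with caplog.at_level(logging.WARNING, logger="fetalica.sampen"):
            sel = select_fetal_channel(np.vstack([u, u]))
        assert sel.fetal_index == 0
        assert any("tie" in rec.message.lower() for rec in caplog.records)

    def test_all_degenerate_raises(self):
        with pytest.raises(SelectionError):
            select_fetal_channel(np.ones((3, 100)))

    def test_degenerate_channel_never_selected(self, rng):
        sources = np.vstack([np.ones(200), rng.standard_normal(200)])
        sel = select_fetal_channel(sources)
        assert sel.fetal_index == 1
        assert math.isinf(sel.entropies[0]) and sel.entropies[0] < 0
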