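import math

import numpy as np
import pytest

from fetalica import ECGSegment, SynthConfig, generate_abdominal


def sampen_bruteforce(u, m=2, r_factor=0.2):
    """Naive O(N^2) double-loop SampEn reference (independent oracle)."""
    u = np.asarray(u, dtype=float)
    n = len(u)
    r = r_factor * np.std(u)
    b = a = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            d_m = max(abs(u[i + k] - u[j + k]) for k in range(m))
            if d_m <= r:
                b += 1
                if max(d_m, abs(u[i + m] - u[j + m])) <= r:
                    a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_mixture():
    """Noise-free, baseline-free 3-source mixture with ground truth.

    Long enough (60 s) that ICA estimation error is comfortably small.
    """
    cfg = SynthConfig(
        seed=7, duration_s=60.0, noise_sd=0.0, baseline_amp=0.0, residual_source=True
    )
    return generate_abdominal(cfg)


@pytest.fixture
def default_mixture():
    """Default-condition recording (baseline wander + sensor noise)."""
    cfg = SynthConfig(seed=7, residual_source=True)
    return generate_abdominal(cfg)


@pytest.fixture
def whitened_mixture(clean_mixture):
    from fetalica.preprocess import center, whiten

    segment, truth = clean_mixture
    x2, _ = center(segment.data)
    x_white, v, e, d = whiten(x2)
    return x_white, v, truth


def make_segment(data, fs=250.0):
    return ECGSegment(np.asarray(data, dtype=float), fs=fs)
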