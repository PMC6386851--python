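"""Fetal R-peak detection and heart-rate computation.

The extracted fetal source carries an arbitrary sign (an inherent
indeterminacy of ICA), so the trace is first oriented to make its dominant
deflection positive.  R-peaks are then detected as local maxima exceeding a
fraction of the window maximum, with a refractory period that keeps only
the larger of two competing peaks.  The heart rate is 60 over the mean RR
interval, classified against a configurable normal range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import InvalidArgumentError

#: Default normal fetal heart-rate band (beats/min), inclusive.
NORMAL_LOW_BPM = 110.0
NORMAL_HIGH_BPM = 160.0


@dataclass
class HeartRateResult:
    """R-peaks, RR intervals and the classified beats-per-minute estimate.

    ``bpm`` is ``None`` (and ``status`` is ``"indeterminate"``) when fewer
    than two peaks are available.
    """

    peaks: np.ndarray
    rr_intervals_s: np.ndarray
    bpm: float | None
    status: str  # "normal" | "abnormal" | "indeterminate"


def orient_polarity(source: np.ndarray) -> np.ndarray:
    """Flip the trace, if needed, so its largest-magnitude sample is positive.

    Idempotent; resolves the sign indeterminacy of ICA outputs before
    peak detection.
    """
    source = np.asarray(source, dtype=float)
    if source.size == 0:
        return source
    peak = source[np.argmax(np.abs(source))]
    return -source if peak < 0 else source


def detect_r_peaks(
    source: np.ndarray,
    fs: float,
    threshold_factor: float = 0.6,
    refractory_s: float = 0.2,
) -> np.ndarray:
    """Detect R-peaks by amplitude thresholding with a refractory period.

    Local maxima above ``threshold_factor * max(source)`` are kept, and of
    any two candidates closer than ``refractory_s`` the larger survives.
    A flat or non-positive window yields an empty peak list.
    """
    if not fs > 0:
        raise InvalidArgumentError(f"fs must be positive, got {fs}")
    source = np.asarray(source, dtype=float)
    peak = source.max(initial=-np.inf)
    if not np.isfinite(peak) or peak <= 0 or np.ptp(source) == 0:
        return np.array([], dtype=int)
    distance = max(1, int(round(refractory_s * fs)))
    peaks, _ = signal.find_peaks(source, height=threshold_factor * peak, distance=distance)
    return peaks.astype(int)


def compute_heart_rate(
    peaks: np.ndarray,
    fs: float,
    low_bpm: float = NORMAL_LOW_BPM,
    high_bpm: float = NORMAL_HIGH_BPM,
) -> HeartRateResult:
    """Heart rate from detected peaks: ``bpm = 60 / mean(RR seconds)``.

    With fewer than two peaks the rate is undefined and the result is
    flagged ``indeterminate``.
    """
    if not fs > 0:
        raise InvalidArgumentError(f"fs must be positive, got {fs}")
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size >= 2 and np.any(np.diff(peaks) <= 0):
        raise InvalidArgumentError("peak indices must be strictly increasing")
    if peaks.size < 2:
        return HeartRateResult(
            peaks=peaks, rr_intervals_s=np.array([]), bpm=None, status="indeterminate"
        )
    rr = np.diff(peaks) / fs
    bpm = 60.0 / float(rr.mean())
    return HeartRateResult(
        peaks=peaks,
        rr_intervals_s=rr,
        bpm=bpm,
        status=classify_heart_rate(bpm, low_bpm, high_bpm),
    )


def classify_heart_rate(
    bpm: float | None,
    low_bpm: float = NORMAL_LOW_BPM,
    high_bpm: float = NORMAL_HIGH_BPM,
) -> str:
    """Classify a rate against the normal band (bounds inclusive)."""
    if bpm is None:
        return "indeterminate"
    return "normal" if low_bpm <= bpm <= high_bpm else "abnormal"
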