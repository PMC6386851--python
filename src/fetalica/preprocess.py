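"""Abdominal-signal preprocessing: baseline drift cancellation, mean value
cancellation, and PCA whitening.

The baseline of each channel is estimated with a third-order low-pass
Butterworth filter (cut-off 5 Hz) and subtracted.  Centering removes the
per-channel mean; whitening diagonalises the sample covariance via its
eigendecomposition so that the whitened data has identity covariance — the
precondition that reduces the ICA fixed-point update to its simplified
form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DegenerateInputError, InvalidArgumentError
from .segment import ECGSegment

#: Relative eigenvalue floor: covariance eigenvalues below
#: ``EIG_FLOOR_REL * trace(cov)`` mark the input as rank deficient.
EIG_FLOOR_REL = 1e-12


@dataclass
class PreprocessResult:
    """All intermediate products of the preprocessing chain.

    ``x_white = whitening_matrix @ x2`` with ``whitening_matrix =
    D^{-1/2} E^T`` built from the eigenvectors ``E`` (columns of
    ``eigvecs``) and eigenvalues ``D`` (``eigvals``) of ``cov(x2)``.
    """

    x1: np.ndarray  # baseline-cancelled
    x2: np.ndarray  # centered
    x_white: np.ndarray  # whitened
    whitening_matrix: np.ndarray
    means: np.ndarray  # per-channel mean removed from x1
    eigvecs: np.ndarray  # covariance eigenvectors, as columns
    eigvals: np.ndarray  # covariance eigenvalues


def _as_matrix(x: ECGSegment | np.ndarray) -> np.ndarray:
    if isinstance(x, ECGSegment):
        return x.data
    x = np.asarray(x, dtype=float)
    return x[np.newaxis, :] if x.ndim == 1 else x


def estimate_baseline(
    segment: ECGSegment | np.ndarray,
    fs: float | None = None,
    cutoff_hz: float = 5.0,
    order: int = 3,
    zero_phase: bool = True,
) -> np.ndarray:
    """Estimate the slow baseline of each channel by low-pass filtering.

    Parameters
    ----------
    segment
        An :class:`ECGSegment`, or a raw ``(n_channels, n_samples)`` array
        (then ``fs`` is required).
    cutoff_hz, order
        Butterworth design; defaults are a third-order filter at 5 Hz.
    zero_phase
        Apply the filter forward and backward (no group delay; default), or
        causally as a streaming implementation would.
    """
    if isinstance(segment, ECGSegment):
        fs = segment.fs
    if fs is None:
        raise InvalidArgumentError("fs is required when passing a bare array")
    if not 0 < cutoff_hz < fs / 2:
        raise InvalidArgumentError(
            f"cutoff ({cutoff_hz} Hz) must lie below the Nyquist rate ({fs / 2} Hz)"
        )
    x = _as_matrix(segment)
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def remove_baseline(
    segment: ECGSegment | np.ndarray,
    fs: float | None = None,
    cutoff_hz: float = 5.0,
    order: int = 3,
    zero_phase: bool = True,
) -> np.ndarray:
    """Return the baseline-drift-cancelled signal (observed minus baseline)."""
    x = _as_matrix(segment)
    return x - estimate_baseline(segment, fs=fs, cutoff_hz=cutoff_hz, order=order, zero_phase=zero_phase)


def center(x1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove the per-channel mean.

    Returns the centered matrix and the vector of removed means.
    """
    x1 = _as_matrix(x1)
    means = x1.mean(axis=1)
    return x1 - means[:, np.newaxis], means


def whiten(x2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Whiten centered data via the covariance eigendecomposition.

    Returns ``(x_white, whitening_matrix, eigvecs, eigvals)`` where
    ``whitening_matrix = D^{-1/2} E^T``, so ``cov(x_white) = I`` and the
    original data is recovered as ``E @ D^{1/2} @ x_white``.

    Raises
    ------
    DegenerateInputError
        If any covariance eigenvalue falls below ``1e-12 * trace`` — i.e.
        the channels are (numerically) linearly dependent.  The message
        names the most correlated channel pair to aid diagnosis.
    """
    x2 = _as_matrix(x2)
    n = x2.shape[1]
    if n < 2:
        raise InvalidArgumentError("need at least 2 samples to estimate covariance")
    cov = x2 @ x2.T / (n - 1)
    tr = np.trace(cov)
    if tr <= 0:
        raise DegenerateInputError("all channels are constant (zero covariance)")
    eigvals, eigvecs = np.linalg.eigh(cov)
    floor = EIG_FLOOR_REL * tr
    if np.any(eigvals < floor):
        i, j = _most_correlated_pair(cov)
        raise DegenerateInputError(
            f"covariance is rank deficient (eigenvalue {eigvals.min():.3g} below "
            f"floor {floor:.3g}); channels {i} and {j} are most nearly dependent"
        )
    whitening_matrix = (eigvecs / np.sqrt(eigvals)).T  # D^{-1/2} E^T
    x_white = whitening_matrix @ x2
    return x_white, whitening_matrix, eigvecs, eigvals


def _most_correlated_pair(cov: np.ndarray) -> tuple[int, int]:
    d = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    corr = np.abs(cov / np.outer(d, d))
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.argmax(corr), corr.shape)
    return int(min(i, j)), int(max(i, j))


def preprocess(
    segment: ECGSegment,
    cutoff_hz: float = 5.0,
    order: int = 3,
    zero_phase: bool = True,
) -> PreprocessResult:
    """Run the full chain: baseline removal, centering, whitening."""
    x1 = remove_baseline(segment, cutoff_hz=cutoff_hz, order=order, zero_phase=zero_phase)
    x2, means = center(x1)
    x_white, v, e, d = whiten(x2)
    return PreprocessResult(
        x1=x1, x2=x2, x_white=x_white, whitening_matrix=v, means=means, eigvecs=e, eigvals=d
    )
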