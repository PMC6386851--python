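"""The universal multichannel signal container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError


@dataclass
class ECGSegment:
    """A contiguous block of multichannel ECG samples.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    t0
        Index of the first sample within the originating stream (0-based);
        used only for bookkeeping when segments are cut from a longer
        recording.
    """

    data: np.ndarray
    fs: float = 250.0
    t0: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[np.newaxis, :]
        if self.data.ndim != 2 or self.data.size == 0:
            raise InvalidArgumentError(
                f"expected a non-empty 2-D (n_channels, n_samples) matrix, "
                f"got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("signal contains non-finite values")
        if not self.fs > 0:
            raise InvalidArgumentError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        """Span of the segment in seconds."""
        return self.n_samples / self.fs

    def select_channels(self, channels: list[int]) -> "ECGSegment":
        """Return a new segment containing only the given channel rows."""
        return ECGSegment(self.data[list(channels), :], fs=self.fs, t0=self.t0)
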