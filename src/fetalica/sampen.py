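"""Sample entropy (SampEn) and entropy-based fetal-channel selection.

SampEn(m, r, N) of a series ``u`` is the negative log of the conditional
probability that two subsequences matching for ``m`` points (Chebyshev
distance below the tolerance ``r``, self-matches excluded) also match for
``m + 1`` points:

    SampEn = -ln( sum_i A_i^{m+1}(r) / sum_i B_i^m(r) )

with both counts taken over the ``N - m`` template vectors.  Larger values
mean greater irregularity.  After blind source separation, the fetal ECG
component is consistently the most irregular of the recovered sources, so
the channel with maximal SampEn is selected as the fetal channel.

The tolerance is specified relative to the series' standard deviation
(``r = r_factor * SD``), which makes SampEn invariant under affine
rescaling of the input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError, SelectionError
from .fastica import SeparationResult

logger = logging.getLogger(__name__)


@dataclass
class SampEnParams:
    """Embedding dimension ``m`` and relative tolerance ``r_factor``.

    The defaults (m = 2, r = 0.2 SD) are the standard convention for
    physiological series of a few hundred samples.
    """

    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise InvalidArgumentError(f"m must be >= 1, got {self.m}")
        if not self.r_factor > 0:
            raise InvalidArgumentError(f"r_factor must be positive, got {self.r_factor}")


@dataclass
class ChannelSelection:
    """Per-source SampEn values and the argmax fetal-channel index."""

    entropies: np.ndarray
    fetal_index: int
    params: SampEnParams


def sample_entropy(u: np.ndarray, params: SampEnParams | None = None) -> float:
    """Compute SampEn(m, r_factor * SD, N) of a 1-D series.

    Matches within tolerance are counted with ``d <= r`` (Chebyshev
    distance), self-matches excluded.  Returns ``inf`` when no template
    match survives the extension to ``m + 1`` points, and ``0`` when every
    one does.

    Raises
    ------
    InvalidArgumentError
        If the series is shorter than ``m + 2`` points.
    DegenerateInputError
        If the series is constant (zero standard deviation), so no
        meaningful tolerance exists.
    """
    params = params or SampEnParams()
    u = np.asarray(u, dtype=float).ravel()
    n = u.size
    m = params.m
    if n <= m + 1:
        raise InvalidArgumentError(
            f"series of length {n} is too short for m={m} (need > {m + 1})"
        )
    sd = float(np.std(u))
    if sd == 0.0:
        raise DegenerateInputError("constant series: SampEn tolerance is undefined")
    r = params.r_factor * sd

    # Both template sets use the N - m vectors starting at i = 0 .. N-m-1.
    windows = np.lib.stride_tricks.sliding_window_view(u, m + 1)[: n - m]
    # Chebyshev distances for the m-point prefixes and the full m+1 windows.
    diff = np.abs(windows[:, None, :] - windows[None, :, :])
    d_m = diff[:, :, :m].max(axis=2)
    d_m1 = diff.max(axis=2)
    off_diag = ~np.eye(n - m, dtype=bool)
    b = int(np.count_nonzero((d_m <= r) & off_diag))
    a = int(np.count_nonzero((d_m1 <= r) & off_diag))
    if b == 0 or a == 0:
        return math.inf
    return -math.log(a / b)


def select_fetal_channel(
    sources: SeparationResult | np.ndarray,
    params: SampEnParams | None = None,
) -> ChannelSelection:
    """Pick the fetal channel as the separated source with maximal SampEn.

    Degenerate (constant) sources are assigned ``-inf`` so they are never
    selected; if every source is degenerate a :class:`SelectionError` is
    raised.  Exact ties are broken toward the lowest index and logged.
    """
    params = params or SampEnParams()
    y = sources.sources if isinstance(sources, SeparationResult) else np.asarray(sources, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 source channels to select from")
    entropies = np.empty(y.shape[0])
    for i, row in enumerate(y):
        try:
            entropies[i] = sample_entropy(row, params)
        except DegenerateInputError:
            entropies[i] = -math.inf
    if np.all(np.isneginf(entropies)):
        raise SelectionError("all separated sources are degenerate")
    fetal_index = int(np.argmax(entropies))  # argmax returns the lowest index on ties
    if np.count_nonzero(entropies == entropies[fetal_index]) > 1:
        logger.warning(
            "SampEn tie at %.6g; selecting lowest channel index %d",
            entropies[fetal_index],
            fetal_index,
        )
    return ChannelSelection(entropies=entropies, fetal_index=fetal_index, params=params)
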