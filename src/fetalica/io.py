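"""Plain-text matrix reading/writing and YAML configuration.

The reader accepts whitespace- or comma-delimited numeric matrices, skips
an optional header row, and auto-detects orientation (more rows than
columns means samples are stored row-wise, the layout of public cutaneous
recording exports).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidArgumentError
from .segment import ECGSegment


def _is_numeric_row(line: str) -> bool:
    tokens = line.replace(",", " ").split()
    if not tokens:
        return False
    try:
        [float(tok) for tok in tokens]
    except ValueError:
        return False
    return True


def load_matrix(path: str | Path) -> np.ndarray:
    """Load a delimited numeric matrix exactly as stored (no reorientation)."""
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise InvalidArgumentError(f"{path}: empty matrix file")
    skip = 0 if _is_numeric_row(lines[0]) else 1
    if skip and (len(lines) == 1 or not _is_numeric_row(lines[1])):
        raise InvalidArgumentError(f"{path}: not a numeric matrix file")
    delimiter = "," if ("," in lines[skip]) else None
    data = np.loadtxt(lines[skip:], delimiter=delimiter, ndmin=2)
    return data


def read_segment(
    path: str | Path,
    fs: float = 250.0,
    channels: list[int] | None = None,
    orientation: str = "auto",
) -> ECGSegment:
    """Read a matrix file into an :class:`ECGSegment`.

    Parameters
    ----------
    orientation
        ``"auto"`` (more rows than columns implies samples x channels),
        ``"channels"`` (rows are channels) or ``"samples"`` (rows are
        samples).
    channels
        Optional subset of channel indices to keep, applied after
        orientation.
    """
    data = load_matrix(path)
    if orientation not in ("auto", "channels", "samples"):
        raise InvalidArgumentError(f"unknown orientation {orientation!r}")
    transpose = (
        orientation == "samples"
        or (orientation == "auto" and data.shape[0] > data.shape[1])
    )
    if transpose:
        data = data.T
    seg = ECGSegment(data, fs=fs)
    if channels is not None:
        seg = seg.select_channels(channels)
    return seg


def write_matrix(path: str | Path, segment: ECGSegment) -> Path:
    """Write a segment as a plain-text matrix, one sample per row."""
    path = Path(path)
    np.savetxt(path, segment.data.T, fmt="%.9g")
    return path


def load_config(path: str | Path) -> dict:
    """Load a (possibly nested) YAML configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InvalidArgumentError(f"{path}: configuration must be a mapping")
    return cfg
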