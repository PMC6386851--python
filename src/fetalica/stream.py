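"""Streaming transport: the 146-byte data package and 400-sample windowing.

The wearable collector ships three-channel, 24-bit ADC samples to the phone
in fixed 146-byte packages, each carrying 45 sample values (15 consecutive
time points per channel).  Acquisition is started with the two-byte command
``0x01 0x00``.  The receiver accumulates decoded samples and hands every
complete 400-sample window (1.6 s at 250 Hz) to the extraction pipeline.

Only the total size (146 bytes) and the payload counts (45 values, 15 per
channel) of the package are fixed by the original device; the internal
byte layout implemented here is this package's own codec dialect
(version 1):

    offset  size  field
    0       2     magic 0xA5 0x5A
    2       2     sequence counter, big-endian unsigned
    4       1     payload value count (45)
    5       135   15 time points x 3 channels, channel-interleaved
                  (c0, c1, c2 per time point), each value a 3-byte
                  big-endian two's-complement ADC count
    140     2     CRC-16/CCITT-FALSE over bytes 0..139, big-endian
    142     4     reserved, zero

It is self-consistent with every published count but makes no claim of
wire compatibility with any particular firmware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .errors import (
    InvalidArgumentError,
    PackageCRCError,
    PackageLengthError,
    PackageMagicError,
)
from .segment import ECGSegment

logger = logging.getLogger(__name__)

PACKAGE_BYTES = 146
SAMPLES_PER_PACKAGE = 45
POINTS_PER_CHANNEL = 15
N_CHANNELS = 3
MAGIC = b"\xa5\x5a"
ADC_MIN = -(2**23)
ADC_MAX = 2**23 - 1
_CRC_OFFSET = 140
_CODEC_VERSION = 1

START_COMMAND = b"\x01\x00"


def crc16_ccitt(data: bytes, poly: int = 0x1021, init: int = 0xFFFF) -> int:
    """CRC-16/CCITT-FALSE (poly 0x1021, init 0xFFFF, no reflection)."""
    crc = init
    for byte in data:
        crc ^= byte << 8
        for _ in range(8):
            crc = ((crc << 1) ^ poly) if crc & 0x8000 else (crc << 1)
            crc &= 0xFFFF
    return crc


@dataclass
class DataPackage:
    """One decoded 146-byte package: 15 three-channel sample triples."""

    seq: int
    samples: np.ndarray  # (POINTS_PER_CHANNEL, N_CHANNELS) signed ADC counts
    raw: bytes

    def channel(self, i: int) -> np.ndarray:
        """The 15 consecutive samples of channel ``i``."""
        return self.samples[:, i]


def start_command() -> bytes:
    """The two-byte acquisition start command sent to the collector."""
    return START_COMMAND


def encode_package(seq: int, samples: np.ndarray) -> bytes:
    """Encode 15 three-channel sample triples into one 146-byte package.

    ``samples`` is ``(15, 3)`` integer ADC counts, each within the signed
    24-bit range.
    """
    samples = np.asarray(samples)
    if samples.shape != (POINTS_PER_CHANNEL, N_CHANNELS):
        raise InvalidArgumentError(
            f"samples must have shape ({POINTS_PER_CHANNEL}, {N_CHANNELS}), "
            f"got {samples.shape}"
        )
    if not np.issubdtype(samples.dtype, np.integer):
        as_int = samples.astype(np.int64)
        if not np.array_equal(as_int, samples):
            raise InvalidArgumentError("sample counts must be integers")
        samples = as_int
    if samples.min() < ADC_MIN or samples.max() > ADC_MAX:
        raise InvalidArgumentError(
            f"ADC counts must lie in [{ADC_MIN}, {ADC_MAX}]"
        )
    if not 0 <= seq <= 0xFFFF:
        raise InvalidArgumentError(f"seq must fit in 16 bits, got {seq}")

    buf = bytearray()
    buf += MAGIC
    buf += seq.to_bytes(2, "big")
    buf.append(SAMPLES_PER_PACKAGE)
    for triple in samples:
        for value in triple:
            buf += int(value).to_bytes(3, "big", signed=True)
    crc = crc16_ccitt(bytes(buf))
    buf += crc.to_bytes(2, "big")
    buf += b"\x00\x00\x00\x00"
    assert len(buf) == PACKAGE_BYTES
    return bytes(buf)


def decode_package(raw: bytes) -> DataPackage:
    """Decode one raw package, validating length, magic and CRC."""
    if len(raw) != PACKAGE_BYTES:
        raise PackageLengthError(
            f"expected {PACKAGE_BYTES} bytes, got {len(raw)}"
        )
    if raw[:2] != MAGIC:
        raise PackageMagicError(f"bad magic {raw[:2].hex()} (expected {MAGIC.hex()})")
    stored_crc = int.from_bytes(raw[_CRC_OFFSET : _CRC_OFFSET + 2], "big")
    actual_crc = crc16_ccitt(raw[:_CRC_OFFSET])
    if stored_crc != actual_crc:
        raise PackageCRCError(
            f"CRC mismatch: stored {stored_crc:#06x}, computed {actual_crc:#06x}"
        )
    seq = int.from_bytes(raw[2:4], "big")
    values = [
        int.from_bytes(raw[5 + 3 * k : 8 + 3 * k], "big", signed=True)
        for k in range(SAMPLES_PER_PACKAGE)
    ]
    samples = np.asarray(values, dtype=np.int64).reshape(POINTS_PER_CHANNEL, N_CHANNELS)
    return DataPackage(seq=seq, samples=samples, raw=raw)


class WindowAccumulator:
    """Collects decoded packages and emits non-overlapping sample windows.

    A window (default 400 samples per channel, i.e. 1.6 s at 250 Hz) is
    emitted as soon as every channel holds enough new samples; leftover
    samples stay buffered for the next window, so over a gap-free stream no
    sample is lost or duplicated.  A sequence-counter discontinuity is
    logged and resets the buffer, discarding the partial window.
    """

    def __init__(self, window_size: int = 400, fs: float = 250.0, gain: float = 1.0):
        if window_size < 1:
            raise InvalidArgumentError(f"window_size must be >= 1, got {window_size}")
        self.window_size = window_size
        self.fs = fs
        #: linear ADC-count -> physical-unit conversion; counts pass
        #: through unchanged by default (no published calibration constant)
        self.gain = gain
        self.emitted_windows = 0
        self._buffer: list[np.ndarray] = []
        self._last_seq: int | None = None
        self._t0 = 0

    @property
    def buffered_samples(self) -> int:
        """Samples per channel currently waiting for the next window."""
        return sum(b.shape[0] for b in self._buffer)

    def push(self, package: DataPackage) -> list[ECGSegment]:
        """Add one package; return any windows completed by it (0 or 1)."""
        if self._last_seq is not None:
            expected = (self._last_seq + 1) & 0xFFFF
            if package.seq != expected:
                logger.warning(
                    "sequence discontinuity: expected %d, got %d; resetting buffer "
                    "(%d buffered samples dropped)",
                    expected,
                    package.seq,
                    self.buffered_samples,
                )
                self._t0 += self.buffered_samples
                self._buffer.clear()
        self._last_seq = package.seq
        self._buffer.append(package.samples.astype(float) * self.gain)

        out: list[ECGSegment] = []
        while self.buffered_samples >= self.window_size:
            stacked = np.concatenate(self._buffer, axis=0)  # (n, 3) samples x channels
            window, rest = stacked[: self.window_size], stacked[self.window_size :]
            self._buffer = [rest] if rest.size else []
            out.append(ECGSegment(window.T, fs=self.fs, t0=self._t0))
            self._t0 += self.window_size
            self.emitted_windows += 1
        return out


def accumulate(
    packages: Iterable[DataPackage],
    window_size: int = 400,
    fs: float = 250.0,
    gain: float = 1.0,
) -> Iterator[ECGSegment]:
    """Stream adapter: decoded packages in, complete windows out."""
    acc = WindowAccumulator(window_size=window_size, fs=fs, gain=gain)
    for pkg in packages:
        yield from acc.push(pkg)


def read_packages(path) -> Iterator[DataPackage]:
    """Replay a raw package stream file (concatenated 146-byte packages)."""
    with open(path, "rb") as fh:
        while True:
            raw = fh.read(PACKAGE_BYTES)
            if not raw:
                break
            yield decode_package(raw)


def samples_to_packages(data: np.ndarray, start_seq: int = 0) -> Iterator[bytes]:
    """Chop a ``(3, n)`` integer sample matrix into encoded packages.

    Trailing samples that do not fill a complete package are dropped.
    """
    data = np.asarray(data)
    if data.ndim != 2 or data.shape[0] != N_CHANNELS:
        raise InvalidArgumentError(f"expected a ({N_CHANNELS}, n) matrix, got {data.shape}")
    n_pkg = data.shape[1] // POINTS_PER_CHANNEL
    for k in range(n_pkg):
        block = data[:, k * POINTS_PER_CHANNEL : (k + 1) * POINTS_PER_CHANNEL]
        yield encode_package((start_seq + k) & 0xFFFF, block.T)
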