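"""End-to-end per-window extraction pipeline.

Each 400-sample window flows through baseline removal, centering and
whitening, FastICA separation, sample-entropy fetal-channel selection,
polarity orientation, and R-peak based heart-rate estimation.  The
orchestration mirrors the on-device processing loop: windows are
independent, except that (optionally) each window's separation is
warm-started from the previous window's separation matrix to reduce
permutation flicker between consecutive windows.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FetalicaError
from .fastica import FastICAConfig, SeparationResult, fastica_separate
from .heartrate import (
    NORMAL_HIGH_BPM,
    NORMAL_LOW_BPM,
    HeartRateResult,
    compute_heart_rate,
    detect_r_peaks,
    orient_polarity,
)
from .io import read_segment
from .preprocess import PreprocessResult, preprocess
from .sampen import ChannelSelection, SampEnParams, select_fetal_channel
from .segment import ECGSegment

logger = logging.getLogger(__name__)

#: Smoothing factor of the exponential moving average used for the
#: displayed heart rate; the raw per-window value is always retained.
EMA_ALPHA = 0.3


@dataclass
class HRConfig:
    threshold_factor: float = 0.6
    refractory_s: float = 0.2
    low_bpm: float = NORMAL_LOW_BPM
    high_bpm: float = NORMAL_HIGH_BPM


@dataclass
class PipelineConfig:
    """Aggregated configuration for the whole extraction chain.

    ``channels`` selects which columns of a multichannel file feed the
    three-channel pipeline (emulating the choice of three electrodes out
    of five).  Nested YAML keys map to the stage configs:
    ``baseline.cutoff_hz``, ``baseline.order``, ``baseline.zero_phase``,
    ``ica.tol``, ``ica.max_iter``, ``ica.seed``, ``ica.warm_start``,
    ``ica.use_newton_form``, ``sampen.m``, ``sampen.r_factor``,
    ``hr.threshold_factor``, ``hr.refractory_s``, ``hr.low_bpm``,
    ``hr.high_bpm``.
    """

    channels: list[int] = field(default_factory=lambda: [0, 1, 2])
    window_size: int = 400
    fs: float = 250.0
    baseline_cutoff_hz: float = 5.0
    baseline_order: int = 3
    baseline_zero_phase: bool = True
    ica: FastICAConfig = field(default_factory=FastICAConfig)
    warm_start: bool = True
    sampen: SampEnParams = field(default_factory=SampEnParams)
    hr: HRConfig = field(default_factory=HRConfig)

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        """Build from a nested mapping (e.g. parsed YAML)."""
        baseline = cfg.get("baseline", {})
        ica = dict(cfg.get("ica", {}))
        warm_start = ica.pop("warm_start", True)
        return cls(
            channels=list(cfg.get("channels", [0, 1, 2])),
            window_size=int(cfg.get("window_size", 400)),
            fs=float(cfg.get("fs", 250.0)),
            baseline_cutoff_hz=float(baseline.get("cutoff_hz", 5.0)),
            baseline_order=int(baseline.get("order", 3)),
            baseline_zero_phase=bool(baseline.get("zero_phase", True)),
            ica=FastICAConfig(**ica),
            warm_start=bool(warm_start),
            sampen=SampEnParams(**cfg.get("sampen", {})),
            hr=HRConfig(**cfg.get("hr", {})),
        )


@dataclass
class WindowResult:
    """Everything computed for one processing window."""

    window_index: int
    preprocess: PreprocessResult | None
    separation: SeparationResult | None
    selection: ChannelSelection | None
    fetal_trace: np.ndarray | None
    hr: HeartRateResult
    skipped: bool = False
    skip_reason: str | None = None
    timings: dict[str, float] = field(default_factory=dict)


def process_window(
    segment: ECGSegment,
    config: PipelineConfig | None = None,
    w_init: np.ndarray | None = None,
) -> WindowResult:
    """Run the full extraction chain on one window.

    A degenerate window (rank-deficient covariance, all-constant sources)
    is never fatal: the result is flagged ``skipped`` with the reason, and
    the heart rate comes back ``indeterminate``.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    indeterminate = HeartRateResult(
        peaks=np.array([], dtype=int), rr_intervals_s=np.array([]), bpm=None, status="indeterminate"
    )
    try:
        t0 = time.perf_counter()
        pre = preprocess(
            segment,
            cutoff_hz=config.baseline_cutoff_hz,
            order=config.baseline_order,
            zero_phase=config.baseline_zero_phase,
        )
        timings["preprocess"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        sep = fastica_separate(pre.x_white, config.ica, w_init=w_init)
        timings["fastica"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        sel = select_fetal_channel(sep, config.sampen)
        timings["sampen"] = time.perf_counter() - t0
    except (DegenerateInputError, FetalicaError) as exc:
        logger.warning("window %d skipped: %s", segment.t0 // max(config.window_size, 1), exc)
        return WindowResult(
            window_index=segment.t0 // max(config.window_size, 1),
            preprocess=None,
            separation=None,
            selection=None,
            fetal_trace=None,
            hr=indeterminate,
            skipped=True,
            skip_reason=str(exc),
            timings=timings,
        )

    t0 = time.perf_counter()
    fetal = orient_polarity(sep.sources[sel.fetal_index])
    peaks = detect_r_peaks(
        fetal, segment.fs, threshold_factor=config.hr.threshold_factor, refractory_s=config.hr.refractory_s
    )
    hr = compute_heart_rate(peaks, segment.fs, low_bpm=config.hr.low_bpm, high_bpm=config.hr.high_bpm)
    timings["heartrate"] = time.perf_counter() - t0

    return WindowResult(
        window_index=segment.t0 // max(config.window_size, 1),
        preprocess=pre,
        separation=sep,
        selection=sel,
        fetal_trace=fetal,
        hr=hr,
        timings=timings,
    )


def iter_windows(segment: ECGSegment, window_size: int) -> list[ECGSegment]:
    """Cut a long segment into consecutive non-overlapping windows."""
    n_windows = segment.n_samples // window_size
    return [
        ECGSegment(
            segment.data[:, k * window_size : (k + 1) * window_size],
            fs=segment.fs,
            t0=segment.t0 + k * window_size,
        )
        for k in range(n_windows)
    ]


def process_segment(
    segment: ECGSegment, config: PipelineConfig | None = None
) -> list[WindowResult]:
    """Window a segment and process every window, warm-starting the ICA
    from the previous window's separation when configured."""
    config = config or PipelineConfig()
    results: list[WindowResult] = []
    w_prev: np.ndarray | None = None
    for win in iter_windows(segment, config.window_size):
        res = process_window(win, config, w_init=w_prev if config.warm_start else None)
        if res.separation is not None:
            w_prev = res.separation.w_matrix
        results.append(res)
    return results


def summarize(results: list[WindowResult]) -> pd.DataFrame:
    """Per-window report: entropies, chosen channel, heart rate, status.

    Adds a carried heart rate (last known value for skipped windows) and an
    exponential moving average for display smoothing; the raw per-window
    estimate is kept untouched.
    """
    rows = []
    carried: float | None = None
    ema: float | None = None
    n_src = max((r.separation.n_components for r in results if r.separation), default=3)
    for r in results:
        ent = r.selection.entropies if r.selection is not None else [np.nan] * n_src
        if r.hr.bpm is not None:
            carried = r.hr.bpm
            ema = r.hr.bpm if ema is None else EMA_ALPHA * r.hr.bpm + (1 - EMA_ALPHA) * ema
        row = {
            "window_index": r.window_index,
            "fetal_index": r.selection.fetal_index if r.selection is not None else -1,
            "bpm": r.hr.bpm,
            "bpm_carried": carried,
            "bpm_ema": ema,
            "status": r.hr.status,
            "n_peaks": int(r.hr.peaks.size),
            "skipped": r.skipped,
        }
        for i in range(n_src):
            row[f"sampen_{i}"] = ent[i] if i < len(ent) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_file(
    path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[WindowResult], pd.DataFrame]:
    """Process a matrix file end to end; optionally write report files.

    Outputs (when ``out_dir`` is given): ``windows.csv`` with the
    per-window report and ``fetal_trace.csv`` with the concatenated
    oriented fetal source (unit variance per window; amplitude is not
    physically calibrated).
    """
    config = config or PipelineConfig()
    segment = read_segment(path, fs=config.fs, channels=config.channels)
    results = process_segment(segment, config)
    summary = summarize(results)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "windows.csv", index=False)
        traces = [
            r.fetal_trace if r.fetal_trace is not None else np.full(config.window_size, np.nan)
            for r in results
        ]
        trace = np.concatenate(traces) if traces else np.array([])
        pd.DataFrame(
            {
                "sample": np.arange(trace.size),
                "time_s": np.arange(trace.size) / config.fs,
                "fetal": trace,
            }
        ).to_csv(out_dir / "fetal_trace.csv", index=False)
    return results, summary
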