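"""Monte-Carlo validation studies over the synthetic corpus.

These runners generate seeded synthetic abdominal records, push them
through the extraction chain, and score the results against the stored
ground truth.  They are used both by the test suite and by the
reproducibility script, so the study conditions are defined in exactly one
place:

* **Separation accuracy** — noise-free, baseline-free three-source
  mixtures, long records (ICA estimation error shrinks as 1/sqrt(n));
  scored by source correlation after sign/permutation matching and by the
  Amari index of the composite unmixing.
* **Grid-search oracle** — on two-channel toy mixtures, every one-unit
  fixed point must sit on a local maximum of the exhaustively evaluated
  kurtosis profile over unmixing directions.
* **Entropy ordering** — default-condition recordings (sensor noise at
  the collector floor); checks that the fetal source has the maximal
  sample entropy among the separated components, and how often the full
  irregularity ranking fetal > maternal > residual holds.
* **Fetal heart rate** — clean recordings (see
  :data:`fetalica.synth.CLEAN_NOISE_SD`); record-level rate = median of
  the per-window estimates, compared against the configured fetal rate.
"""

from __future__ import annotations

import logging

import numpy as np

from .fastica import FastICAConfig, amari_index, fastica_one_unit, fastica_separate
from .pipeline import PipelineConfig, process_segment
from .preprocess import center, whiten
from .synth import CLEAN_NOISE_SD, SynthConfig, generate_abdominal

logger = logging.getLogger(__name__)

#: Fetal-rate band sampled in the heart-rate study (beats/min).
FHR_STUDY_BPM_RANGE = (120.0, 180.0)


def match_abs_corr(estimated: np.ndarray, true: np.ndarray) -> np.ndarray:
    """For each true source row, the best |correlation| over estimated rows."""
    k = estimated.shape[0]
    c = np.abs(np.corrcoef(np.vstack([estimated, true]))[:k, k:])
    return c.max(axis=0)


def composite_unmixing(w_matrix, whitening_matrix, truth) -> np.ndarray:
    """Composite map from unit-variance sources to separated components.

    The mixing matrix columns are rescaled by each source's standard
    deviation so the product refers to unit-variance sources — the
    normalisation under which a perfect separation is a scaled
    permutation and the Amari index is meaningful.
    """
    scale = truth.sources.std(axis=1)
    return w_matrix @ whitening_matrix @ (truth.mixing_matrix * scale[np.newaxis, :])


def ica_accuracy_study(
    n_records: int = 100, duration_s: float = 150.0, seed: int = 0
) -> dict:
    """Separation accuracy on noise-free three-source mixtures.

    Whole-record whitening + FastICA (no windowing, no baseline wander, no
    noise), one random mixing matrix per record.
    """
    min_corrs, amaris = [], []
    for i in range(n_records):
        cfg = SynthConfig(
            seed=seed + i,
            duration_s=duration_s,
            noise_sd=0.0,
            baseline_amp=0.0,
            residual_source=True,
        )
        segment, truth = generate_abdominal(cfg)
        x2, _ = center(segment.data)
        x_white, v, _, _ = whiten(x2)
        sep = fastica_separate(x_white, FastICAConfig(seed=seed + i))
        min_corrs.append(float(match_abs_corr(sep.sources, truth.sources).min()))
        amaris.append(amari_index(composite_unmixing(sep.w_matrix, v, truth)))
    return {
        "n_records": n_records,
        "duration_s": duration_s,
        "min_abs_corr": float(np.min(min_corrs)),
        "mean_abs_corr": float(np.mean(min_corrs)),
        "max_amari": float(np.max(amaris)),
        "mean_amari": float(np.mean(amaris)),
    }


def _grid_kurtosis_maxima(x_white: np.ndarray, step_deg: float = 0.05) -> np.ndarray:
    """Angles (radians, in [0, pi)) of local maxima of |excess kurtosis| of
    ``w(theta)^T X`` over an exhaustive direction grid."""
    thetas = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    w = np.vstack([np.cos(thetas), np.sin(thetas)])
    y = w.T @ x_white
    m2 = (y**2).mean(axis=1)
    kurt = np.abs((y**4).mean(axis=1) - 3.0 * m2**2)
    prev = np.roll(kurt, 1)
    nxt = np.roll(kurt, -1)
    return thetas[(kurt >= prev) & (kurt >= nxt)]


def grid_oracle_study(
    n_trials: int = 20, n_samples: int = 4000, seed: int = 0, n_starts: int = 8
) -> dict:
    """Fixed points of the one-unit iteration vs the exhaustive grid oracle.

    Two-channel mixtures of a sub-Gaussian square wave and a
    super-Gaussian Laplace series; every converged one-unit solution
    (started from several directions, no deflation) must lie within a
    degree of some local maximum of the grid-evaluated kurtosis profile.
    """
    worst = 0.0
    for trial in range(n_trials):
        rng = np.random.default_rng(seed + trial)
        t = np.arange(n_samples) / 250.0
        s1 = np.sign(np.sin(2 * np.pi * 3.1 * t + rng.uniform(0, 2 * np.pi)))
        s2 = rng.laplace(size=n_samples)
        s = np.vstack([s1 / s1.std(), s2 / s2.std()])
        x = rng.normal(size=(2, 2)) @ s
        x2, _ = center(x)
        x_white, *_ = whiten(x2)
        maxima = _grid_kurtosis_maxima(x_white)
        for j in range(n_starts):
            theta0 = np.pi * j / n_starts
            w0 = np.array([np.cos(theta0), np.sin(theta0)])
            w, _, ok = fastica_one_unit(x_white, w0, FastICAConfig(seed=seed))
            if not ok:
                continue
            theta = np.arctan2(w[1], w[0]) % np.pi
            d = np.abs(theta - maxima)
            d = np.minimum(d, np.pi - d)
            worst = max(worst, float(np.rad2deg(d.min())))
    return {"n_trials": n_trials, "n_samples": n_samples, "max_angle_deg": worst}


def _score_record(results, truth) -> dict:
    """Window-level scores of one processed record against its ground truth."""
    n_windows = 0
    fetal_max = 0
    full_order = 0
    bpms: list[float] = []
    entropy_triples: list[tuple[float, float, float]] = []
    window_size = 400
    for r in results:
        if r.skipped:
            continue
        n_windows += 1
        sl = slice(r.window_index * window_size, (r.window_index + 1) * window_size)
        true_rows = np.vstack(
            [
                truth.sources[truth.fetal_source_index, sl],
                truth.sources[truth.maternal_source_index, sl],
            ]
            + ([truth.sources[2, sl]] if truth.sources.shape[0] > 2 else [])
        )
        k = r.separation.sources.shape[0]
        c = np.abs(np.corrcoef(np.vstack([r.separation.sources, true_rows]))[:k, k:])
        fet_row = int(np.argmax(c[:, 0]))
        if r.selection.fetal_index == fet_row:
            fetal_max += 1
        if true_rows.shape[0] == 3:
            mat_row = int(np.argmax(c[:, 1]))
            res_row = int(np.argmax(c[:, 2]))
            e = r.selection.entropies
            if len({fet_row, mat_row, res_row}) == 3:
                entropy_triples.append((e[fet_row], e[mat_row], e[res_row]))
                if e[fet_row] > e[mat_row] > e[res_row]:
                    full_order += 1
        if r.hr.bpm is not None:
            bpms.append(r.hr.bpm)
    return {
        "n_windows": n_windows,
        "fetal_max": fetal_max,
        "full_order": full_order,
        "bpm": float(np.median(bpms)) if bpms else None,
        "entropy_triples": entropy_triples,
    }


def entropy_ordering_study(n_records: int = 100, seed: int = 0) -> dict:
    """How often the fetal source has the maximal SampEn among the
    separated components, under default (sensor-floor-noise) recordings.

    Also reports the rate of the full irregularity ranking
    fetal > maternal > residual — a soft property, logged rather than
    enforced per window.
    """
    rng = np.random.default_rng(seed)
    tot_w = tot_max = tot_order = 0
    triples: list[tuple[float, float, float]] = []
    for i in range(n_records):
        fetal_bpm = float(rng.uniform(*FHR_STUDY_BPM_RANGE))
        cfg = SynthConfig(seed=seed + i, fetal_bpm=fetal_bpm, residual_source=True)
        segment, truth = generate_abdominal(cfg)
        pc = PipelineConfig()
        pc.ica.seed = seed + i
        score = _score_record(process_segment(segment, pc), truth)
        tot_w += score["n_windows"]
        tot_max += score["fetal_max"]
        tot_order += score["full_order"]
        triples.extend(score["entropy_triples"])
    finite = np.asarray([t for t in triples if np.all(np.isfinite(t))])
    out = {
        "n_records": n_records,
        "n_windows": tot_w,
        "fetal_max_rate": tot_max / tot_w,
        "full_order_rate": tot_order / tot_w,
        "mean_entropy_fetal": float(finite[:, 0].mean()),
        "mean_entropy_maternal": float(finite[:, 1].mean()),
        "mean_entropy_residual": float(finite[:, 2].mean()),
    }
    logger.info(
        "entropy ordering: fetal-max %.1f%%, full ranking %.1f%% of %d windows",
        100 * out["fetal_max_rate"],
        100 * out["full_order_rate"],
        tot_w,
    )
    return out


def fhr_study(
    n_records: int = 100, seed: int = 0, noise_sd: float = CLEAN_NOISE_SD
) -> dict:
    """End-to-end fetal heart-rate recovery on clean recordings.

    Fetal rates are drawn uniformly from ``FHR_STUDY_BPM_RANGE``; a record
    counts as correctly identified when the majority of its windows select
    the true fetal component, and as accurate when the record-level rate
    (median of per-window estimates) is within 2 bpm of the configured
    rate.
    """
    rng = np.random.default_rng(seed)
    id_ok = bpm_ok = 0
    errors = []
    for i in range(n_records):
        fetal_bpm = float(rng.uniform(*FHR_STUDY_BPM_RANGE))
        cfg = SynthConfig(
            seed=seed + i, fetal_bpm=fetal_bpm, noise_sd=noise_sd, residual_source=True
        )
        segment, truth = generate_abdominal(cfg)
        pc = PipelineConfig()
        pc.ica.seed = seed + i
        score = _score_record(process_segment(segment, pc), truth)
        if score["n_windows"] and score["fetal_max"] > score["n_windows"] / 2:
            id_ok += 1
        if score["bpm"] is not None:
            err = abs(score["bpm"] - fetal_bpm)
            errors.append(err)
            if err <= 2.0:
                bpm_ok += 1
    return {
        "n_records": n_records,
        "noise_sd": noise_sd,
        "channel_id_rate": id_ok / n_records,
        "bpm_within_2_rate": bpm_ok / n_records,
        "mean_abs_bpm_error": float(np.mean(errors)) if errors else None,
        "max_abs_bpm_error": float(np.max(errors)) if errors else None,
    }
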