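"""End-to-end glue: raw record → filtered → fiducials → normalized beats.

These functions chain the individual stages with one ``PipelineConfig`` and
structured logging of every beat exclusion, and are what both the CLI and
the evaluation protocol drive.
"""

from __future__ import annotations

import logging

import numpy as np

from . import fiducials, normalize, preprocess, synth
from .config import PipelineConfig
from .synth import AcquisitionConfig, EcgRecord

__all__ = ["extract_beats", "synthesize_corpus", "corpus_beats"]

logger = logging.getLogger(__name__)


def extract_beats(
    record: EcgRecord, cfg: PipelineConfig | None = None
) -> tuple[list[normalize.NormalizedBeat], dict]:
    """Run filtering, detection, delineation and normalization on one record.

    Returns the amplitude-normalized beats plus an ``info`` dict counting
    beats dropped at each stage (nothing is dropped silently).
    """
    cfg = cfg or PipelineConfig()
    spec = preprocess.design_bandpass(
        record.fs, cfg.filter_low_hz, cfg.filter_high_hz, cfg.filter_numtaps
    )
    filtered = (
        record if record.provenance == "filtered"
        else preprocess.apply_filter(record, spec)
    )
    x = filtered.signal
    d = fiducials.detection_transform(x)
    th = fiducials.DetectionThresholds(
        negative_fraction=cfg.negative_fraction,
        positive_fraction=cfg.positive_fraction,
        window_s=cfg.threshold_window_s,
    )
    candidates, strengths = fiducials.detect_r_candidates(
        x, d, th, fs=record.fs
    )
    r_peaks = fiducials.validate_rr(
        candidates, record.fs, cfg.min_bpm, cfg.max_bpm, strengths
    )

    # Local RR (s) per validated R peak: interval to the previous peak, the
    # next one for the first peak.  Sets each beat's time-scale factor for
    # the rate-dependent delineation windows and normalization paddings.
    rr_local = np.full(len(r_peaks), 1.0)
    if len(r_peaks) > 1:
        diffs = np.diff(r_peaks) / record.fs
        rr_local[1:] = diffs
        rr_local[0] = diffs[0]
    rr_by_r = {int(r): float(rr) for r, rr in zip(r_peaks, rr_local)}

    sets = []
    n_window_skipped = 0
    for r in r_peaks:
        f = fiducials.delineate(
            x, d, int(r), record.fs,
            pqr_latency_s=cfg.pqr_latency_ms / 1000.0,
            rst_latency_s=cfg.rst_latency_ms / 1000.0,
            time_scale=rr_by_r[int(r)],
        )
        if f is None:
            n_window_skipped += 1
        else:
            sets.append(f)
    valid = fiducials.filter_valid_beats(sets, x, record.fs)

    beats = []
    n_degenerate = 0
    for i, f in enumerate(valid):
        b = normalize.time_normalize(
            x, f, cfg.n_pre, cfg.n_post, fs=record.fs,
            beat_index=i, subject=record.subject,
            p_onset_pad_s=cfg.p_onset_pad_ms / 1000.0,
            t_end_pad_s=cfg.t_end_pad_ms / 1000.0,
            time_scale=rr_by_r.get(f.R, 1.0),
        )
        if b is None:
            n_degenerate += 1
        else:
            beats.append(b)
    r_amplitudes = [x[f.R] for f in valid]
    if beats:
        beats = normalize.amplitude_normalize(beats, r_amplitudes)

    info = {
        "n_candidates": int(len(candidates)),
        "n_r_peaks": int(len(r_peaks)),
        "n_window_skipped": n_window_skipped,
        "n_invalid": len(sets) - len(valid),
        "n_degenerate": n_degenerate,
        "n_beats": len(beats),
        "r_peaks": np.asarray(r_peaks, dtype=int),
    }
    logger.info(
        "%s: %d candidates -> %d R peaks -> %d valid beats "
        "(%d window-skipped, %d invalid, %d degenerate)",
        record.subject, info["n_candidates"], info["n_r_peaks"],
        info["n_beats"], n_window_skipped, info["n_invalid"], n_degenerate,
    )
    return beats, info


def synthesize_corpus(
    cfg: PipelineConfig | None = None,
    acquisition: AcquisitionConfig | None = None,
):
    """Generate the multi-subject synthetic corpus the config describes.

    Returns a list of ``(record, ground_truth)`` pairs, one per subject,
    with per-subject noise seeds derived deterministically from the root
    seed.
    """
    cfg = cfg or PipelineConfig()
    base = acquisition or AcquisitionConfig(
        fs=cfg.fs, duration_s=cfg.duration_s,
        white_noise_sd_mv=cfg.white_noise_sd_mv,
    )
    morphs = synth.make_population(cfg.n_subjects, cfg.seed)
    noise_seeds = synth.derive_seeds(cfg.seed + 1, cfg.n_subjects)
    return [
        synth.synthesize_recording(m, base.replace(seed=int(s)))
        for m, s in zip(morphs, noise_seeds)
    ]


def corpus_beats(
    corpus, cfg: PipelineConfig | None = None
) -> dict[str, np.ndarray]:
    """Extract normalized-beat matrices for every subject of a corpus."""
    cfg = cfg or PipelineConfig()
    out = {}
    for record, _truth in corpus:
        beats, _info = extract_beats(record, cfg)
        if beats:
            out[record.subject] = np.stack([b.samples for b in beats])
        else:
            logger.warning("subject %s produced no valid beats", record.subject)
    return out
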