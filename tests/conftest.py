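import numpy as np
import pytest

import fingerbeat as fb
from fingerbeat.pipeline import corpus_beats, extract_beats, synthesize_corpus

#: Acquisition with every noise source disabled.
NOISE_FREE = dict(
    baseline_amplitude_mv=0.0,
    white_noise_sd_mv=0.0,
    powerline_amplitude_mv=0.0,
)


@pytest.fixture(scope="session")
def pipeline_config():
    return fb.PipelineConfig()


@pytest.fixture(scope="session")
def noisefree_corpus(pipeline_config):
    """16 subjects x 2 min at 1000 Hz, no noise, ramping 133 -> 70 BPM."""
    acq = fb.AcquisitionConfig(**NOISE_FREE)
    return synthesize_corpus(pipeline_config, acq)


@pytest.fixture(scope="session")
def noisefree_beats(noisefree_corpus, pipeline_config):
    return corpus_beats(noisefree_corpus, pipeline_config)


@pytest.fixture(scope="session")
def clean_short_recording():
    """Single subject, 10 s at constant 60 BPM, zero jitter, zero noise."""
    morph = fb.make_subject(7)
    cfg = fb.AcquisitionConfig(
        duration_s=10.0, hr_profile_bpm=(60.0,), rr_jitter_ms=0.0,
        seed=1, **NOISE_FREE,
    )
    return fb.synthesize_recording(morph, cfg)


def detector_scores(corpus, cfg, tol_s=0.010):
    """Sensitivity and positive predictivity of R detection on a corpus."""
    tp = fp = fn = 0
    for record, truth in corpus:
        _beats, info = extract_beats(record, cfg)
        det = info["r_peaks"]
        tol = int(round(tol_s * record.fs))
        matched = set()
        for g in truth.r_indices:
            j = int(np.argmin(np.abs(det - g))) if len(det) else None
            if j is not None and abs(det[j] - g) <= tol and j not in matched:
                tp += 1
                matched.add(j)
            else:
                fn += 1
        fp += len(det) - len(matched)
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    return sensitivity, ppv
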