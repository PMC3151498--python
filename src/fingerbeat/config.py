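"""Declarative pipeline configuration.

One document carries every tunable parameter of the pipeline, with defaults
anchored to the method's stated values: [0.5, 30] Hz filter band, RR
validity limits of 150/30 BPM, 300-sample beats, and the 30-run / 30-beat
enrollment / 30-beat test evaluation protocol.  Unknown keys are rejected
so that typos fail loudly before any computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .normalize import BEAT_LENGTH

__all__ = ["PipelineConfig", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    schema_version: int = SCHEMA_VERSION
    # preprocess
    filter_low_hz: float = 0.5
    filter_high_hz: float = 30.0
    filter_numtaps: int | None = None  # None → automatic from fs and low edge
    # fiducials
    min_bpm: float = 30.0
    max_bpm: float = 150.0
    negative_fraction: float = 0.4
    positive_fraction: float = 0.1
    threshold_window_s: float = 2.0
    pqr_latency_ms: float = 250.0
    rst_latency_ms: float = 400.0
    # normalize
    n_pre: int = 100
    n_post: int = 200
    p_onset_pad_ms: float = 80.0
    t_end_pad_ms: float = 120.0
    # evaluate
    n_runs: int = 30
    n_enroll_beats: int = 30
    n_test_beats: int = 30
    # synth / global
    n_subjects: int = 16
    duration_s: float = 120.0
    fs: float = 1000.0
    white_noise_sd_mv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema version {self.schema_version}"
            )
        if not 0 < self.filter_low_hz < self.filter_high_hz:
            raise ValueError("filter band must satisfy 0 < low < high")
        if not 0 < self.min_bpm < self.max_bpm:
            raise ValueError("BPM limits must satisfy 0 < min < max")
        if self.n_pre + self.n_post != BEAT_LENGTH:
            raise ValueError(
                f"n_pre + n_post must equal {BEAT_LENGTH}, got "
                f"{self.n_pre} + {self.n_post}"
            )
        if self.n_runs < 1 or self.n_enroll_beats < 1 or self.n_test_beats < 1:
            raise ValueError("protocol counts must be >= 1")

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_mapping(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    def digest(self) -> str:
        """Short stable hash embedded in output artifacts for provenance."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
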