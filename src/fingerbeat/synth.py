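"""Synthetic multi-subject finger-ECG generator with exact ground truth.

Each heartbeat is modelled as a sum of five Gaussian-shaped waves (P, Q, R,
S, T) placed on an RR grid derived from a heart-rate profile.  Faster heart
rates compress the whole beat: wave offsets and widths scale linearly with
the local RR interval, emulating the compression/expansion a changing heart
rate produces in real recordings.  Additive baseline wander (slow sinusoid),
white Gaussian noise and 50 Hz powerline interference emulate the main
finger-ECG noise sources.  Every generated R centre and per-wave centre is
returned as ground truth, so downstream detection and delineation can be
scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveParams",
    "SubjectMorphology",
    "AcquisitionConfig",
    "GroundTruth",
    "EcgRecord",
    "make_subject",
    "make_population",
    "synthesize_recording",
]

WAVE_NAMES = ("P", "Q", "R", "S", "T")

#: Reference RR interval (ms) at which morphology parameters are specified.
#: Beats at other rates are pure time-scalings of the reference shape.
REFERENCE_RR_MS = 1000.0

#: A beat is only placed if its QRS complex fits this far before the end of
#: the recording (s); a truncated QRS is not a scoreable beat.
QRS_MARGIN_S = 0.150

# Per-wave sampling ranges for make_subject: (centre_ms, amplitude_mV, width_ms)
# centre is relative to the R peak; ranges are wide enough that independent
# draws are distinguishable with high probability.
_MORPH_RANGES = {
    "P": ((-200.0, -140.0), (0.10, 0.30), (18.0, 32.0)),
    "Q": ((-48.0, -32.0), (-0.20, -0.06), (8.0, 14.0)),
    "R": ((0.0, 0.0), (0.80, 1.50), (9.0, 15.0)),
    "S": ((32.0, 48.0), (-0.35, -0.10), (8.0, 14.0)),
    "T": ((210.0, 300.0), (0.20, 0.50), (40.0, 70.0)),
}


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian wave: centre offset from R (ms), amplitude (mV), width (ms)."""

    center_ms: float
    amplitude_mv: float
    width_ms: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("wave width must be > 0")


@dataclass(frozen=True)
class SubjectMorphology:
    """Per-subject P-QRS-T shape parameters at the reference RR interval."""

    subject: str
    waves: dict[str, WaveParams]

    def __post_init__(self) -> None:
        missing = set(WAVE_NAMES) - set(self.waves)
        if missing:
            raise ValueError(f"morphology missing waves: {sorted(missing)}")
        c = {w: self.waves[w].center_ms for w in WAVE_NAMES}
        if not (c["P"] < c["Q"] < c["R"] < c["S"] < c["T"]):
            raise ValueError("wave centres must be ordered P < Q < R < S < T")
        if c["R"] != 0.0:
            raise ValueError("R centre must be 0 (the time anchor)")
        for w in ("P", "R", "T"):
            if self.waves[w].amplitude_mv <= 0:
                raise ValueError(f"{w} amplitude must be > 0")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Recording-level parameters for one synthetic acquisition.

    The heart-rate profile is a sequence of BPM values interpolated
    piecewise-linearly over the recording duration; the default ramps from a
    high to a low rate, exercising beat compression/expansion.  Noise
    defaults emulate finger ECG: 0.1 mV baseline wander at 0.3 Hz, 0.05 mV
    white noise and 0.02 mV of 50 Hz mains pickup.
    """

    fs: float = 1000.0
    duration_s: float = 120.0
    hr_profile_bpm: tuple[float, ...] = (133.0, 70.0)
    rr_jitter_ms: float = 20.0
    baseline_amplitude_mv: float = 0.1
    baseline_freq_hz: float = 0.3
    white_noise_sd_mv: float = 0.05
    powerline_amplitude_mv: float = 0.02
    powerline_freq_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if not self.hr_profile_bpm:
            raise ValueError("heart-rate profile must be non-empty")
        for bpm in self.hr_profile_bpm:
            if not 20.0 < bpm < 200.0:
                raise ValueError(f"heart rate {bpm} BPM outside (20, 200)")
        if self.baseline_freq_hz >= 0.5:
            raise ValueError("baseline wander frequency must be < 0.5 Hz")
        for name in (
            "rr_jitter_ms",
            "baseline_amplitude_mv",
            "white_noise_sd_mv",
            "powerline_amplitude_mv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "AcquisitionConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class EcgRecord:
    """Single-channel amplitude series (mV) with sampling rate and label."""

    signal: np.ndarray
    fs: float
    subject: str
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1 or self.signal.size == 0:
            raise ValueError("signal must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")


@dataclass
class GroundTruth:
    """True beat annotations: R centres and per-wave centres (sample indices)."""

    subject: str
    r_indices: np.ndarray
    wave_indices: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r_indices = np.asarray(self.r_indices, dtype=int)
        if self.r_indices.size and np.any(np.diff(self.r_indices) <= 0):
            raise ValueError("R indices must be strictly increasing")


def make_subject(seed: int, subject: str | None = None) -> SubjectMorphology:
    """Draw a random subject morphology; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    waves = {}
    for name in WAVE_NAMES:
        (c_lo, c_hi), (a_lo, a_hi), (w_lo, w_hi) = _MORPH_RANGES[name]
        waves[name] = WaveParams(
            center_ms=float(rng.uniform(c_lo, c_hi)),
            amplitude_mv=float(rng.uniform(a_lo, a_hi)),
            width_ms=float(rng.uniform(w_lo, w_hi)),
        )
    return SubjectMorphology(subject=subject or f"s{seed:03d}", waves=waves)


def make_population(n_subjects: int, seed: int = 0) -> list[SubjectMorphology]:
    """Generate ``n_subjects`` morphologies with distinct derived seeds."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    child_seeds = derive_seeds(seed, n_subjects)
    return [
        make_subject(int(s), subject=f"s{i:03d}")
        for i, s in enumerate(child_seeds)
    ]


def derive_seeds(root_seed: int, n: int) -> np.ndarray:
    """Deterministically partition a root seed into n child seeds (< 2^31)."""
    return np.random.SeedSequence(root_seed).generate_state(n) % (2**31)


def _r_times(config: AcquisitionConfig, rng: np.random.Generator) -> np.ndarray:
    """R-peak times (s) from the interpolated heart-rate profile plus jitter.

    The first beat sits half an RR interval into the recording; each
    subsequent RR interval follows the instantaneous rate at the previous
    beat.  Jitter is zero-mean Gaussian, truncated so RR stays in
    [400, 2000] ms (the physiological validity band downstream).
    """
    profile = np.asarray(config.hr_profile_bpm, dtype=float)
    knots = np.linspace(0.0, config.duration_s, num=len(profile)) if len(
        profile
    ) > 1 else np.array([0.0])

    def bpm_at(t: float) -> float:
        if len(profile) == 1:
            return float(profile[0])
        return float(np.interp(t, knots, profile))

    times = []
    t = 0.5 * 60.0 / bpm_at(0.0)
    while t < config.duration_s - QRS_MARGIN_S:
        times.append(t)
        rr = 60.0 / bpm_at(t)
        if config.rr_jitter_ms > 0:
            rr += rng.normal(0.0, config.rr_jitter_ms / 1000.0)
        rr = float(np.clip(rr, 0.400, 2.000))
        t = t + rr
    return np.asarray(times)


def synthesize_recording(
    morph: SubjectMorphology, config: AcquisitionConfig
) -> tuple[EcgRecord, GroundTruth]:
    """Render one acquisition and its exact beat annotations.

    Each beat is the five-Gaussian reference shape time-scaled by
    ``RR_local / REFERENCE_RR_MS``; the scaled wave centres are the ground
    truth.  Raises ``ValueError`` if the duration cannot hold a single beat.
    """
    fs = config.fs
    n = int(round(config.duration_s * fs))
    rng = np.random.default_rng(config.seed)
    r_times = _r_times(config, rng)
    if len(r_times) == 0:
        raise ValueError(
            f"duration {config.duration_s}s too short for a single beat"
        )

    signal = np.zeros(n)
    t_axis = np.arange(n) / fs
    r_indices = np.asarray(np.round(r_times * fs), dtype=int)
    wave_indices: dict[str, list[int]] = {w: [] for w in WAVE_NAMES}

    # Local RR (s) controlling each beat's time-scale: interval to the
    # previous beat (to the next one for the first beat).
    rr_local = np.empty(len(r_times))
    if len(r_times) == 1:
        rr_local[0] = REFERENCE_RR_MS / 1000.0
    else:
        rr_local[1:] = np.diff(r_times)
        rr_local[0] = rr_local[1]

    for r_t, r_idx, rr in zip(r_times, r_indices, rr_local):
        scale = (rr * 1000.0) / REFERENCE_RR_MS
        for name in WAVE_NAMES:
            w = morph.waves[name]
            center_s = r_t + w.center_ms * scale / 1000.0
            width_s = w.width_ms * scale / 1000.0
            lo = max(0, int(np.floor((center_s - 5 * width_s) * fs)))
            hi = min(n, int(np.ceil((center_s + 5 * width_s) * fs)) + 1)
            if hi > lo:
                tt = t_axis[lo:hi]
                signal[lo:hi] += w.amplitude_mv * np.exp(
                    -0.5 * ((tt - center_s) / width_s) ** 2
                )
            # Edge beats may place a wave centre outside the record; keep the
            # entry so per-beat arrays stay aligned with r_indices.
            wave_indices[name].append(int(round(center_s * fs)))

    keep = r_indices < n
    r_indices = r_indices[keep]
    clean_waves = {
        w: np.asarray(v, dtype=int)[keep] for w, v in wave_indices.items()
    }

    if config.baseline_amplitude_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += config.baseline_amplitude_mv * np.sin(
            2 * np.pi * config.baseline_freq_hz * t_axis + phase
        )
    if config.powerline_amplitude_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += config.powerline_amplitude_mv * np.sin(
            2 * np.pi * config.powerline_freq_hz * t_axis + phase
        )
    if config.white_noise_sd_mv > 0:
        signal += rng.normal(0.0, config.white_noise_sd_mv, size=n)

    record = EcgRecord(signal=signal, fs=fs, subject=morph.subject)
    truth = GroundTruth(
        subject=morph.subject, r_indices=r_indices, wave_indices=clean_waves
    )
    return record, truth
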