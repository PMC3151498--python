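"""Two-part time normalization and amplitude normalization of beats.

Heart-rate changes compress or expand the heartbeat waveform, so beats are
resampled onto a fixed 300-sample grid in two parts anchored on the beat's
own fiducials instead of a fixed window around R: the segment from the P
onset to the R peak becomes ``n_pre`` samples and the segment from just
after R to the T end becomes ``n_post`` samples.  The R peak therefore sits
at the same index (n_pre - 1) in every normalized beat.  Amplitudes are then
divided by the acquisition's mean R amplitude, removing intra-subject gain
differences.

Delineation yields peak positions only, so the P onset is taken as the P
peak minus 80 ms and the T end as the T peak plus 120 ms (both clipped to
the beat's search window); both paddings are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .fiducials import SCALE_BOUNDS, FiducialSet

__all__ = [
    "NormalizedBeat",
    "BEAT_LENGTH",
    "time_normalize",
    "amplitude_normalize",
]

logger = logging.getLogger(__name__)

BEAT_LENGTH = 300
DEFAULT_N_PRE = 100
DEFAULT_N_POST = 200

#: Padding (s) from the P peak back to the assumed P onset, at 60 BPM.
P_ONSET_PAD_S = 0.080
#: Padding (s) from the T peak forward to the assumed T end, at 60 BPM.
T_END_PAD_S = 0.120


@dataclass(frozen=True)
class NormalizedBeat:
    """A time- and amplitude-normalized heartbeat of exactly 300 samples."""

    samples: np.ndarray
    r_index: int
    beat_index: int
    subject: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if arr.shape != (BEAT_LENGTH,):
            raise ValueError(
                f"normalized beat must have exactly {BEAT_LENGTH} samples"
            )


def time_normalize(
    x,
    f: FiducialSet,
    n_pre: int = DEFAULT_N_PRE,
    n_post: int = DEFAULT_N_POST,
    fs: float = 1000.0,
    beat_index: int = 0,
    subject: str = "",
    p_onset_pad_s: float = P_ONSET_PAD_S,
    t_end_pad_s: float = T_END_PAD_S,
    time_scale: float = 1.0,
) -> NormalizedBeat | None:
    """Resample one beat onto the fixed two-part grid.

    The interval [P onset, R] maps to ``n_pre`` uniformly spaced points
    (endpoints included, so the last one is exactly x[R]) and (R, T end]
    maps to ``n_post`` points.  Linear interpolation keeps the resampling
    monotone and overshoot-free.  Returns ``None`` for a degenerate beat
    (P onset at or after R), with the reason logged.

    ``time_scale`` is the beat's local time-compression factor (local RR
    divided by the 1-s reference RR, clamped to [0.4, 2]); the onset/end
    paddings are multiplied by it so that the normalization maps a
    rate-compressed beat and its slow counterpart onto the same grid —
    wave durations, paddings included, shorten with heart rate.
    """
    if n_pre + n_post != BEAT_LENGTH:
        raise ValueError(f"n_pre + n_post must equal {BEAT_LENGTH}")
    if n_pre < 2 or n_post < 1:
        raise ValueError("n_pre must be >= 2 and n_post >= 1")
    x = np.asarray(x, dtype=float)

    scale = float(np.clip(time_scale, *SCALE_BOUNDS))
    p_onset = max(f.left_most, f.P - int(round(p_onset_pad_s * scale * fs)))
    t_end = min(f.right_most, f.T + int(round(t_end_pad_s * scale * fs)))
    if p_onset >= f.R or t_end <= f.R:
        logger.debug("beat R=%d rejected: degenerate interval", f.R)
        return None
    if p_onset < 0 or t_end >= len(x):
        logger.debug("beat R=%d rejected: segment outside record", f.R)
        return None

    idx = np.arange(len(x), dtype=float)
    pre_grid = np.linspace(p_onset, f.R, n_pre)
    post_grid = f.R + (t_end - f.R) * np.arange(1, n_post + 1) / n_post
    samples = np.concatenate(
        (np.interp(pre_grid, idx, x), np.interp(post_grid, idx, x))
    )
    samples[n_pre - 1] = x[f.R]  # exact by construction; enforce bitwise
    return NormalizedBeat(
        samples=samples, r_index=n_pre - 1, beat_index=beat_index,
        subject=subject,
    )


def amplitude_normalize(
    beats: list[NormalizedBeat], r_amplitudes
) -> list[NormalizedBeat]:
    """Divide every beat by the acquisition's mean R amplitude.

    All beats from one acquisition share the single normalization factor, so
    the mean of the normalized R values is 1.  A non-positive mean R
    amplitude indicates an upstream polarity or detection failure and raises.
    """
    if not beats:
        return []
    r_amplitudes = np.asarray(r_amplitudes, dtype=float)
    factor = float(np.mean(r_amplitudes))
    if factor <= 0:
        raise ValueError(
            f"mean R amplitude must be > 0, got {factor!r}"
        )
    return [replace(b, samples=b.samples / factor) for b in beats]
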