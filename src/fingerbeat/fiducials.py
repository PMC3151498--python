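"""QRS detection and P-QRS-T delineation.

R peaks are found with an adapted Engelse–Zeelenberg cascade: the filtered
signal is differentiated, comb-filtered and smoothed,

    y0[n] = x[n] - x[n-1]
    y1[n] = y0[n] - y0[n-4]
    y2[n] = sum_{i=0..4} c_i * y1[n-i],   c = [1, 4, 6, 4, 1]

(samples before index 0 are zero).  A positive R spike produces a pronounced
negative lobe in y2 flanked by two smaller positive lobes; candidates are
the negative lobes that are flanked on *both* sides by a positive excursion,
refined to the local maximum of x.  Candidate R peaks are then validated
against physiological RR-interval limits (150 BPM minimum spacing, 30 BPM
maximum), and each beat is delineated:

* [iStartQ, iEndQ] / [iStartS, iEndS]: the positive excursions of y2
  immediately before / after the R negative lobe; Q and S are the minima of
  x on those intervals.
* P is the maximum of x on [leftMostIndex, iStartQ] and T the maximum on
  [iEndS, rightMostIndex], where the bounds are the R time minus a typical
  PQR latency (250 ms) and plus a typical RST latency (400 ms).

A beat is kept only if (a) the P and T peak amplitudes are positive and
(b) the P peak leads the Q trough by at least 30 ms.

The original algorithm's fixed amplitude thresholds are replaced by an
adaptive rule (fractions of a windowed 98th percentile of |y2|), making
detection invariant to overall signal scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectionSignals",
    "DetectionThresholds",
    "FiducialSet",
    "detection_transform",
    "detect_r_candidates",
    "validate_rr",
    "delineate",
    "filter_valid_beats",
]

logger = logging.getLogger(__name__)

#: Smoothing kernel of the final cascade stage (binomial weights).
SMOOTHING_WEIGHTS = np.array([1.0, 4.0, 6.0, 4.0, 1.0])

#: Upper bounds on PQR and RST latencies (s) framing the P and T searches.
PQR_LATENCY_S = 0.250
RST_LATENCY_S = 0.400

#: Minimum lead of the P peak before the Q trough for a valid beat (s).
P_BEFORE_Q_S = 0.030

#: Half-width of the local-maximum refinement window around a lobe (s).
REFINE_WINDOW_S = 0.050

#: Window within which a negative lobe must be flanked by positive ones (s).
FLANK_WINDOW_S = 0.080

#: Constant delay (samples) of the y2 cascade relative to x: half a sample
#: from the differentiator plus two each from the comb and smoother.
CASCADE_DELAY = 4

#: Clamp on the local time-scale factor (local RR / 1-s reference RR)
#: applied to rate-dependent windows.
SCALE_BOUNDS = (0.4, 2.0)


@dataclass(frozen=True)
class DetectionSignals:
    """The three cascade outputs, each the same length as the input."""

    y0: np.ndarray
    y1: np.ndarray
    y2: np.ndarray


@dataclass(frozen=True)
class DetectionThresholds:
    """Adaptive lobe thresholds.

    ``negative_fraction`` and ``positive_fraction`` multiply the 98th
    percentile of |y2| computed over non-overlapping windows of
    ``window_s`` seconds; the negative threshold is the negated product.
    """

    negative_fraction: float = 0.4
    positive_fraction: float = 0.1
    window_s: float = 2.0
    percentile: float = 98.0

    def __post_init__(self) -> None:
        if self.negative_fraction <= 0 or self.positive_fraction <= 0:
            raise ValueError("threshold fractions must be > 0")
        if self.window_s <= 0:
            raise ValueError("adaptation window must be > 0")


@dataclass
class FiducialSet:
    """Per-beat fiducial sample indices (0-based, on the filtered record)."""

    P: int
    Q: int
    R: int
    S: int
    T: int
    i_start_q: int
    i_end_q: int
    i_start_s: int
    i_end_s: int
    left_most: int
    right_most: int
    valid: bool = True

    def ordering_ok(self) -> bool:
        return (
            self.left_most <= self.P < self.i_start_q <= self.Q
            <= self.i_end_q < self.R < self.i_start_s <= self.S
            <= self.i_end_s < self.T <= self.right_most
        )


def detection_transform(x) -> DetectionSignals:
    """Apply the three-stage cascade; samples before index 0 are zero."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise ValueError("input must be a 1-D series of length >= 10")
    y0 = np.empty_like(x)
    y0[0] = x[0]
    y0[1:] = x[1:] - x[:-1]
    y1 = y0.copy()
    y1[4:] -= y0[:-4]
    y2 = np.convolve(y1, SMOOTHING_WEIGHTS)[: len(x)]
    return DetectionSignals(y0=y0, y1=y1, y2=y2)


def _threshold_envelope(y2: np.ndarray, fs: float, th: DetectionThresholds):
    """Per-sample (negative, positive) thresholds from windowed percentiles."""
    n = len(y2)
    win = max(1, int(round(th.window_s * fs)))
    stat = np.empty(n)
    for start in range(0, n, win):
        stop = min(n, start + win)
        stat[start:stop] = np.percentile(np.abs(y2[start:stop]), th.percentile)
    return -th.negative_fraction * stat, th.positive_fraction * stat


def detect_r_candidates(
    x,
    d: DetectionSignals,
    th: DetectionThresholds | None = None,
    fs: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate R-peak candidates.

    Returns ``(indices, strengths)``: strictly increasing sample indices of
    the local maxima of ``x`` refined within ±50 ms of each qualifying
    negative lobe, and the |y2| depth of that lobe (used later to break
    RR-validation conflicts).  An empty result is allowed.
    """
    x = np.asarray(x, dtype=float)
    th = th or DetectionThresholds()
    y2 = d.y2
    neg_thr, pos_thr = _threshold_envelope(y2, fs, th)

    below = y2 < neg_thr
    if not below.any():
        return np.empty(0, dtype=int), np.empty(0)
    # Contiguous runs below the negative threshold = candidate negative lobes.
    run_starts = np.flatnonzero(below & ~np.roll(below, 1))
    run_ends = np.flatnonzero(below & ~np.roll(below, -1))
    if below[0]:
        run_starts = np.concatenate(([0], run_starts[run_starts != 0]))
    if below[-1]:
        run_ends = np.concatenate((run_ends[run_ends != len(y2) - 1],
                                   [len(y2) - 1]))

    flank = max(1, int(round(FLANK_WINDOW_S * fs)))
    refine = max(1, int(round(REFINE_WINDOW_S * fs)))
    indices: list[int] = []
    strengths: list[float] = []
    for s, e in zip(run_starts, run_ends):
        seg = y2[s : e + 1]
        m = s + int(np.argmin(seg))
        left = y2[max(0, s - flank) : s]
        right = y2[e + 1 : e + 1 + flank]
        if left.size == 0 or right.size == 0:
            continue
        if left.max() <= pos_thr[m] or right.max() <= pos_thr[m]:
            continue
        lo = max(0, m - refine)
        hi = min(len(x), m + refine + 1)
        r_idx = lo + int(np.argmax(x[lo:hi]))
        if indices and r_idx <= indices[-1]:
            # Two lobes refined onto the same maximum: keep the stronger.
            if -y2[m] > strengths[-1]:
                strengths[-1] = float(-y2[m])
            continue
        indices.append(r_idx)
        strengths.append(float(-y2[m]))
    return np.asarray(indices, dtype=int), np.asarray(strengths)


def validate_rr(
    candidates,
    fs: float,
    min_bpm: float = 30.0,
    max_bpm: float = 150.0,
    strengths=None,
) -> np.ndarray:
    """Keep candidates whose spacing respects physiological RR limits.

    Pairs closer than the minimum latency (60/max_bpm seconds, 400 ms at
    150 BPM) are resolved by dropping the weaker candidate (smaller lobe
    strength; the earlier one wins ties or when strengths are absent).
    Gaps longer than the maximum latency (60/min_bpm, 2000 ms at 30 BPM)
    are logged as segment boundaries but delete nothing.
    """
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        return candidates
    if np.any(np.diff(candidates) < 0):
        raise ValueError("candidates must be sorted ascending")
    if strengths is None:
        strengths = np.zeros(len(candidates))
    strengths = np.asarray(strengths, dtype=float)
    min_lat = int(round(fs * 60.0 / max_bpm))
    max_lat = int(round(fs * 60.0 / min_bpm))

    kept_idx: list[int] = []
    kept_str: list[float] = []
    for idx, s in zip(candidates, strengths):
        if kept_idx and idx - kept_idx[-1] < min_lat:
            if s > kept_str[-1]:
                kept_idx[-1] = int(idx)
                kept_str[-1] = float(s)
            continue
        kept_idx.append(int(idx))
        kept_str.append(float(s))

    gaps = np.diff(kept_idx)
    for i in np.flatnonzero(gaps > max_lat):
        logger.debug(
            "RR gap of %.0f ms between samples %d and %d exceeds the "
            "%d BPM limit; treated as a segment boundary",
            gaps[i] / fs * 1000.0, kept_idx[i], kept_idx[i + 1], min_bpm,
        )
    return np.asarray(kept_idx, dtype=int)


def _positive_run(y2: np.ndarray, start: int, step: int) -> tuple[int, int] | None:
    """First contiguous y2 > 0 run scanning from ``start`` in ``step`` direction."""
    n = len(y2)
    i = start
    while 0 <= i < n and y2[i] <= 0:
        i += step
    if not 0 <= i < n:
        return None
    j = i
    while 0 <= j + step < n and y2[j + step] > 0:
        j += step
    return (min(i, j), max(i, j))


def delineate(
    x,
    d: DetectionSignals,
    r: int,
    fs: float,
    pqr_latency_s: float = PQR_LATENCY_S,
    rst_latency_s: float = RST_LATENCY_S,
    time_scale: float = 1.0,
) -> FiducialSet | None:
    """Delineate the beat anchored at validated R index ``r``.

    ``time_scale`` is the beat's local time-compression factor (local RR
    over the 1-s reference RR, clamped to [0.4, 2]); the PQR/RST latency
    bounds shrink with it so that, at high heart rates, the P and T search
    windows stay inside the beat instead of reaching into its neighbours.

    Returns ``None`` (with a logged reason) when the record does not hold
    the full search window around ``r``.
    """
    x = np.asarray(x, dtype=float)
    y2 = d.y2
    scale = float(np.clip(time_scale, *SCALE_BOUNDS))
    left_most = r - int(round(pqr_latency_s * scale * fs))
    right_most = r + int(round(rst_latency_s * scale * fs))
    if left_most < 0 or right_most >= len(x):
        logger.debug("beat at sample %d skipped: window outside record", r)
        return None

    # Centre of the R negative lobe of y2 near r (the cascade delays it by a
    # few samples relative to the refined R).
    refine = max(1, int(round(REFINE_WINDOW_S * fs)))
    lo = max(0, r - refine)
    hi = min(len(y2), r + refine + 1)
    m = lo + int(np.argmin(y2[lo:hi]))

    q_run = _positive_run(y2, m, -1)
    s_run = _positive_run(y2, m, +1)
    if q_run is None or s_run is None:
        logger.debug("beat at sample %d skipped: no flanking y2 lobes", r)
        return None
    # Map lobe endpoints from y2 back to x by removing the cascade delay.
    i_start_q, i_end_q = (max(0, i - CASCADE_DELAY) for i in q_run)
    i_start_s, i_end_s = (max(0, i - CASCADE_DELAY) for i in s_run)
    if i_start_q < left_most or i_end_s > right_most:
        logger.debug("beat at sample %d skipped: lobes outside window", r)
        return None

    q = i_start_q + int(np.argmin(x[i_start_q : i_end_q + 1]))
    s = i_start_s + int(np.argmin(x[i_start_s : i_end_s + 1]))
    p = left_most + int(np.argmax(x[left_most : i_start_q + 1]))
    t = i_end_s + int(np.argmax(x[i_end_s : right_most + 1]))

    fs_set = FiducialSet(
        P=p, Q=q, R=r, S=s, T=t,
        i_start_q=i_start_q, i_end_q=i_end_q,
        i_start_s=i_start_s, i_end_s=i_end_s,
        left_most=left_most, right_most=right_most,
    )
    fs_set.valid = fs_set.ordering_ok()
    return fs_set


def filter_valid_beats(
    sets: list[FiducialSet], x, fs: float
) -> list[FiducialSet]:
    """Keep beats satisfying the amplitude and P-lead validity rules.

    (a) P and T peak amplitudes must be strictly positive;
    (b) the P peak must lead the Q trough by at least 30 ms.
    """
    x = np.asarray(x, dtype=float)
    lead = P_BEFORE_Q_S * fs
    out = []
    for f in sets:
        if not f.valid:
            logger.debug("beat R=%d rejected: fiducial ordering", f.R)
            continue
        if x[f.P] <= 0 or x[f.T] <= 0:
            logger.debug("beat R=%d rejected: rule (a) P/T amplitude", f.R)
            continue
        if f.P > f.Q - lead:
            logger.debug("beat R=%d rejected: rule (b) P lead < 30 ms", f.R)
            continue
        out.append(f)
    return out
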