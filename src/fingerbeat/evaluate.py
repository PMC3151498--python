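"""Cross-validated identification/authentication evaluation.

The protocol mirrors a random-resampling cross-validation: in each of 30
runs, every subject contributes 30 randomly chosen beats averaged into an
enrollment template and 30 *different* beats averaged into a test template.
All test-vs-enrollment distances are computed; identification decisions use
the 1-NN rule, and the same distances feed the authentication analysis as
genuine scores (test template vs own enrollment) and impostor scores (test
template vs every other enrollment).  Results are aggregated over runs into
a distance matrix, a confusion matrix, identification accuracy, FAR/FRR
curves, the global equal error rate, and per-subject (user-tuned) EERs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .biometric import EnrollmentDatabase, Template, build_template, identify
from .normalize import NormalizedBeat

__all__ = [
    "RunConfig",
    "EvaluationResult",
    "cross_validate",
    "far_frr_curves",
    "compute_eer",
    "user_tuned_eer",
    "scale_distance_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID_POINTS = 512


@dataclass(frozen=True)
class RunConfig:
    """Cross-validation protocol parameters."""

    n_runs: int = 30
    n_enroll_beats: int = 30
    n_test_beats: int = 30
    seed: int = 0
    grid_points: int = DEFAULT_GRID_POINTS

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.n_enroll_beats < 1 or self.n_test_beats < 1:
            raise ValueError("per-template beat counts must be >= 1")
        if self.grid_points < 2:
            raise ValueError("threshold grid needs >= 2 points")


@dataclass
class EvaluationResult:
    """Aggregated evaluation outputs."""

    subjects: list[str]
    distance_matrix: np.ndarray  # mean over runs, min-max scaled to [0, 1]
    confusion_matrix: np.ndarray  # integer counts, rows = true subject
    accuracy: float
    thresholds: np.ndarray
    far: np.ndarray
    frr: np.ndarray
    eer: float
    eer_threshold: float
    subject_eers: dict[str, float] = field(default_factory=dict)
    mean_subject_eer: float = float("nan")


def _as_matrix(beats) -> np.ndarray:
    if isinstance(beats, np.ndarray):
        return np.atleast_2d(np.asarray(beats, dtype=float))
    return np.stack([
        b.samples if isinstance(b, NormalizedBeat) else np.asarray(b)
        for b in beats
    ])


def cross_validate(beats_by_subject: dict, cfg: RunConfig) -> EvaluationResult:
    """Run the full random-resampling evaluation.

    ``beats_by_subject`` maps subject id to either a list of
    ``NormalizedBeat`` or a 2-D array (beats × samples).  Subjects without
    enough beats for disjoint enrollment and test draws are excluded with a
    warning.  Deterministic for a fixed ``cfg.seed``.
    """
    need = cfg.n_enroll_beats + cfg.n_test_beats
    pool: dict[str, np.ndarray] = {}
    for subject in sorted(beats_by_subject):
        mat = _as_matrix(beats_by_subject[subject])
        if mat.shape[0] < need:
            logger.warning(
                "subject %s excluded: %d beats < %d required",
                subject, mat.shape[0], need,
            )
            continue
        pool[subject] = mat
    subjects = sorted(pool)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects with enough beats")
    n_sub = len(subjects)

    dist_sum = np.zeros((n_sub, n_sub))
    confusion = np.zeros((n_sub, n_sub), dtype=int)
    genuine: list[float] = []
    impostor: list[float] = []
    # Impostor scores directed at each claimed subject (matrix column).
    genuine_by_subject: dict[str, list[float]] = {s: [] for s in subjects}
    impostor_by_subject: dict[str, list[float]] = {s: [] for s in subjects}

    root = np.random.SeedSequence(cfg.seed)
    run_seeds = root.generate_state(cfg.n_runs)
    for run in range(cfg.n_runs):
        rng = np.random.default_rng(run_seeds[run])
        db = EnrollmentDatabase(metadata={"seed": cfg.seed, "run": run})
        tests: dict[str, Template] = {}
        for subject in subjects:
            mat = pool[subject]
            order = rng.permutation(mat.shape[0])
            enroll_rows = mat[order[: cfg.n_enroll_beats]]
            test_rows = mat[
                order[cfg.n_enroll_beats : cfg.n_enroll_beats + cfg.n_test_beats]
            ]
            db.add(build_template(enroll_rows, subject))
            tests[subject] = build_template(test_rows, subject)

        dist = np.array([
            [
                float(np.linalg.norm(
                    tests[si].vector - db.templates[sj].vector
                ))
                for sj in subjects
            ]
            for si in subjects
        ])
        dist_sum += dist
        for i, subject in enumerate(subjects):
            decided, _ = identify(tests[subject], db)
            confusion[i, subjects.index(decided)] += 1
            genuine.append(dist[i, i])
            genuine_by_subject[subject].append(dist[i, i])
            for j, other in enumerate(subjects):
                if j != i:
                    impostor.append(dist[i, j])
                    impostor_by_subject[other].append(dist[i, j])

    genuine_arr = np.asarray(genuine)
    impostor_arr = np.asarray(impostor)
    grid = threshold_grid(
        np.concatenate((genuine_arr, impostor_arr)), cfg.grid_points
    )
    far, frr = far_frr_curves(genuine_arr, impostor_arr, grid)
    eer, eer_th = compute_eer(far, frr, grid)
    subject_eers, mean_subject_eer = user_tuned_eer(
        {
            s: (
                np.asarray(genuine_by_subject[s]),
                np.asarray(impostor_by_subject[s]),
            )
            for s in subjects
        },
        grid,
    )
    return EvaluationResult(
        subjects=subjects,
        distance_matrix=scale_distance_matrix(dist_sum / cfg.n_runs),
        confusion_matrix=confusion,
        accuracy=float(np.trace(confusion) / confusion.sum()),
        thresholds=grid,
        far=far,
        frr=frr,
        eer=eer,
        eer_threshold=eer_th,
        subject_eers=subject_eers,
        mean_subject_eer=mean_subject_eer,
    )


def threshold_grid(scores, n_points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Evenly spaced thresholds spanning [0, 1.05 × max score]."""
    scores = np.asarray(scores, dtype=float)
    hi = float(scores.max()) * 1.05 if scores.size else 1.0
    if hi <= 0:
        hi = 1.0
    return np.linspace(0.0, hi, n_points)


def far_frr_curves(genuine, impostor, grid) -> tuple[np.ndarray, np.ndarray]:
    """Error-rate curves on a threshold grid.

    FAR(t) is the fraction of impostor scores strictly below t (accepted);
    FRR(t) the fraction of genuine scores at or above t (rejected) —
    consistent with the strict-accept rule.  FAR is non-decreasing and FRR
    non-increasing in t.
    """
    genuine = np.asarray(genuine, dtype=float)
    impostor = np.asarray(impostor, dtype=float)
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("both score lists must be non-empty")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("threshold grid must be sorted ascending")
    far = np.searchsorted(np.sort(impostor), grid, side="left") / impostor.size
    frr = 1.0 - np.searchsorted(np.sort(genuine), grid, side="left") / genuine.size
    return far, frr


def compute_eer(far, frr, grid) -> tuple[float, float]:
    """Equal error rate at the FAR/FRR crossing, by linear interpolation.

    Raises if the curves never bracket a crossing on the grid (extend it).
    """
    far = np.asarray(far, dtype=float)
    frr = np.asarray(frr, dtype=float)
    grid = np.asarray(grid, dtype=float)
    diff = far - frr  # non-decreasing under the monotonicity contract
    if diff[0] > 0 or diff[-1] < 0:
        raise ValueError(
            "FAR/FRR curves do not bracket a crossing; extend the grid"
        )
    k = int(np.searchsorted(diff >= 0, True))  # first grid point with diff>=0
    if diff[k] == 0:
        return float(far[k]), float(grid[k])
    # Interpolate both piecewise-linear curves between grid[k-1] and grid[k].
    t0, t1 = grid[k - 1], grid[k]
    d0, d1 = diff[k - 1], diff[k]
    frac = -d0 / (d1 - d0)
    t_star = t0 + frac * (t1 - t0)
    eer = far[k - 1] + frac * (far[k] - far[k - 1])
    return float(eer), float(t_star)


def user_tuned_eer(
    scores_by_subject: dict, grid
) -> tuple[dict[str, float], float]:
    """Per-subject EERs from each subject's own genuine/impostor scores.

    ``scores_by_subject`` maps subject → (genuine scores, impostor scores
    directed at that subject).  Subjects lacking either pool are excluded
    with a warning.  Returns the per-subject EERs and their mean.
    """
    eers: dict[str, float] = {}
    for subject in sorted(scores_by_subject):
        genuine, impostor = scores_by_subject[subject]
        genuine = np.asarray(genuine, dtype=float)
        impostor = np.asarray(impostor, dtype=float)
        if genuine.size == 0 or impostor.size == 0:
            logger.warning(
                "subject %s excluded from user-tuned EER: empty score pool",
                subject,
            )
            continue
        far, frr = far_frr_curves(genuine, impostor, grid)
        eers[subject], _ = compute_eer(far, frr, grid)
    if not eers:
        raise ValueError("no subject had both genuine and impostor scores")
    return eers, float(np.mean(list(eers.values())))


def scale_distance_matrix(raw) -> np.ndarray:
    """Min-max scale a distance matrix to [0, 1] for display.

    A constant matrix maps to all zeros.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty matrix")
    if np.any(raw < 0):
        raise ValueError("distances must be non-negative")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)
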