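"""Mean-heartbeat templates, enrollment database, 1-NN matching.

A subject's template is the element-wise mean of their normalized beats;
the features are directly the amplitudes of this mean waveform.
Identification returns the enrolled subject at minimum Euclidean distance
(1-NN); authentication accepts a claimed identity when the distance is
strictly below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .normalize import BEAT_LENGTH, NormalizedBeat

__all__ = [
    "Template",
    "EnrollmentDatabase",
    "build_template",
    "template_distance",
    "identify",
    "authenticate",
]


@dataclass(frozen=True)
class Template:
    """Mean-wave feature vector for one subject."""

    vector: np.ndarray
    subject: str
    n_beats: int

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", v)
        if v.shape != (BEAT_LENGTH,):
            raise ValueError(
                f"template vector must have length {BEAT_LENGTH}"
            )
        if self.n_beats < 1:
            raise ValueError("template must average at least one beat")


@dataclass
class EnrollmentDatabase:
    """Subject → template mapping with creation metadata."""

    templates: dict[str, Template] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)

    def add(self, template: Template) -> None:
        if template.subject in self.templates:
            raise ValueError(f"subject {template.subject!r} already enrolled")
        lengths = {len(t.vector) for t in self.templates.values()}
        if lengths and len(template.vector) not in lengths:
            raise ValueError("all enrolled templates must share one length")
        self.templates[template.subject] = template

    def __len__(self) -> int:
        return len(self.templates)

    def __contains__(self, subject: str) -> bool:
        return subject in self.templates

    def subjects(self) -> list[str]:
        return sorted(self.templates)


def build_template(
    beats: list[NormalizedBeat] | np.ndarray, subject: str
) -> Template:
    """Average normalized beats into a single mean-heartbeat template.

    Accepts either ``NormalizedBeat`` objects (which must all carry the
    given subject label) or a 2-D array of beat rows.
    """
    if isinstance(beats, np.ndarray):
        mat = np.atleast_2d(np.asarray(beats, dtype=float))
    else:
        if not beats:
            raise ValueError("cannot build a template from zero beats")
        wrong = {b.subject for b in beats} - {subject}
        if wrong:
            raise ValueError(
                f"beats from other subjects present: {sorted(wrong)}"
            )
        mat = np.stack([b.samples for b in beats])
    if mat.shape[0] == 0:
        raise ValueError("cannot build a template from zero beats")
    return Template(
        vector=mat.mean(axis=0), subject=subject, n_beats=mat.shape[0]
    )


def template_distance(a: Template, b: Template) -> float:
    """Euclidean distance between two template vectors."""
    if len(a.vector) != len(b.vector):
        raise ValueError(
            f"template length mismatch: {len(a.vector)} vs {len(b.vector)}"
        )
    return float(np.linalg.norm(a.vector - b.vector))


def identify(test: Template, db: EnrollmentDatabase) -> tuple[str, float]:
    """1-NN identification: the enrolled subject at minimum distance.

    Ties are broken deterministically by the lexicographically smallest
    subject identifier.
    """
    if len(db) == 0:
        raise ValueError("enrollment database is empty")
    best_subject, best_dist = None, np.inf
    for subject in db.subjects():  # sorted → smallest id wins ties
        dist = template_distance(test, db.templates[subject])
        if dist < best_dist:
            best_subject, best_dist = subject, dist
    return best_subject, best_dist


def authenticate(
    test: Template, claimed: str, db: EnrollmentDatabase, threshold: float
) -> bool:
    """Accept the claimed identity iff distance < threshold (strict)."""
    if claimed not in db:
        raise KeyError(f"claimed subject {claimed!r} is not enrolled")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return template_distance(test, db.templates[claimed]) < threshold
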