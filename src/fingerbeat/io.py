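"""Plain-text readers and writers for every pipeline artifact.

All formats are delimited text with a ``#``-prefixed header carrying the
metadata (sampling rate, subject id, provenance, ...).  Floats are written
with 17 significant digits, so every round-trip is lossless to full double
precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .biometric import EnrollmentDatabase, Template
from .evaluate import EvaluationResult
from .fiducials import FiducialSet
from .synth import EcgRecord, GroundTruth

FLOAT_FMT = "%.17g"


def _header_fields(line: str) -> dict[str, str]:
    if not line.startswith("#"):
        raise ValueError(f"missing header line, got: {line[:60]!r}")
    return dict(
        item.split("=", 1) for item in line[1:].split() if "=" in item
    )


# -- ECG records -------------------------------------------------------------

def write_record(record: EcgRecord, path: str | Path) -> None:
    """Two-column text: sample index, amplitude (mV)."""
    path = Path(path)
    header = (
        f"fs={record.fs!r} subject={record.subject} "
        f"provenance={record.provenance}"
    )
    data = np.column_stack(
        (np.arange(len(record.signal)), record.signal)
    )
    np.savetxt(path, data, fmt=("%d", FLOAT_FMT), header=header)


def read_record(path: str | Path) -> EcgRecord:
    path = Path(path)
    with path.open() as fh:
        meta = _header_fields(fh.readline())
    data = np.loadtxt(path, ndmin=2)
    return EcgRecord(
        signal=data[:, 1],
        fs=float(meta["fs"]),
        subject=meta.get("subject", ""),
        provenance=meta.get("provenance", "raw"),
    )


# -- ground truth ------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Rows of (beat_index, wave_label, sample_index)."""
    lines = [f"# subject={truth.subject}"]
    for i, r in enumerate(truth.r_indices):
        for wave, indices in truth.wave_indices.items():
            lines.append(f"{i}\t{wave}\t{indices[i]}")
        if not truth.wave_indices:
            lines.append(f"{i}\tR\t{r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    lines = Path(path).read_text().splitlines()
    meta = _header_fields(lines[0])
    waves: dict[str, dict[int, int]] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        beat, wave, idx = line.split("\t")
        waves.setdefault(wave, {})[int(beat)] = int(idx)
    n_beats = 1 + max(max(d) for d in waves.values())
    wave_indices = {
        w: np.array([d[i] for i in range(n_beats)]) for w, d in waves.items()
    }
    return GroundTruth(
        subject=meta.get("subject", ""),
        r_indices=wave_indices["R"],
        wave_indices=wave_indices,
    )


# -- fiducial annotations ----------------------------------------------------

_FID_COLUMNS = ("P", "Q", "R", "S", "T")


def write_fiducials(sets: list[FiducialSet], path: str | Path) -> None:
    """Rows of (beat_index, P, Q, R, S, T, valid)."""
    lines = ["# beat_index\t" + "\t".join(_FID_COLUMNS) + "\tvalid"]
    for i, f in enumerate(sets):
        vals = "\t".join(str(getattr(f, c)) for c in _FID_COLUMNS)
        lines.append(f"{i}\t{vals}\t{int(f.valid)}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- normalized beats --------------------------------------------------------

def write_beats(beats, path: str | Path) -> None:
    """One row per normalized beat, 300 columns."""
    if not beats:
        raise ValueError("no beats to write")
    subject = beats[0].subject
    r_index = beats[0].r_index
    mat = np.stack([b.samples for b in beats])
    np.savetxt(
        path, mat, fmt=FLOAT_FMT,
        header=f"subject={subject} r_index={r_index}",
    )


def read_beats(path: str | Path) -> tuple[np.ndarray, str, int]:
    """Returns (matrix, subject, r_index)."""
    path = Path(path)
    with path.open() as fh:
        meta = _header_fields(fh.readline())
    mat = np.loadtxt(path, ndmin=2)
    return mat, meta.get("subject", ""), int(meta.get("r_index", 0))


# -- enrollment database -----------------------------------------------------

def write_database(db: EnrollmentDatabase, path: str | Path) -> None:
    """One record per subject: id, beat count, then the template values."""
    lines = [
        "# fingerbeat enrollment database "
        + " ".join(f"{k}={v}" for k, v in sorted(db.metadata.items(),
                                                 key=lambda kv: kv[0]))
    ]
    for subject in db.subjects():
        t = db.templates[subject]
        values = " ".join(FLOAT_FMT % v for v in t.vector)
        lines.append(f"{subject} {t.n_beats} {values}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_database(path: str | Path) -> EnrollmentDatabase:
    lines = Path(path).read_text().splitlines()
    db = EnrollmentDatabase(metadata=_header_fields(lines[0]))
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split()
        db.add(Template(
            vector=np.array([float(v) for v in parts[2:]]),
            subject=parts[0],
            n_beats=int(parts[1]),
        ))
    return db


# -- evaluation results ------------------------------------------------------

def write_result(result: EvaluationResult, outdir: str | Path) -> None:
    """Serialize an evaluation: summary, matrices and curves as text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = result.subjects

    summary = [
        f"accuracy {result.accuracy!r}",
        f"eer {result.eer!r}",
        f"eer_threshold {result.eer_threshold!r}",
        f"mean_subject_eer {result.mean_subject_eer!r}",
    ] + [
        f"subject_eer:{s} {result.subject_eers[s]!r}"
        for s in sorted(result.subject_eers)
    ]
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")

    def grid_lines(mat, fmt):
        lines = ["subject\t" + "\t".join(ids)]
        for s, row in zip(ids, mat):
            lines.append(s + "\t" + "\t".join(fmt % v for v in row))
        return "\n".join(lines) + "\n"

    (outdir / "distance_matrix.tsv").write_text(
        grid_lines(result.distance_matrix, FLOAT_FMT)
    )
    (outdir / "confusion_matrix.tsv").write_text(
        grid_lines(result.confusion_matrix, "%d")
    )
    curve = ["threshold\tfar\tfrr"] + [
        "\t".join(FLOAT_FMT % v for v in row)
        for row in zip(result.thresholds, result.far, result.frr)
    ]
    (outdir / "curves.tsv").write_text("\n".join(curve) + "\n")
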