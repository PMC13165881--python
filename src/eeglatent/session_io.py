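"""Ingest zipped text-file EEG recordings into a session-level cohort matrix.

A corpus is a ZIP archive of plain-text recordings, one file per therapy
session, named ``Patient<k>_<Before|During|After>_<YYYY[-MM-DD]>.txt``.
Each file holds delimited numeric rows over the 10 canonical streams
(see :mod:`eeglatent.streams`), optionally preceded by a header row.
Each session is summarized by its per-stream mean, sessions are stacked
into an N x 10 characteristic matrix, and the matrix is standardized by
per-column z-score before any modelling.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .streams import (
    Moment,
    N_STREAMS,
    STREAM_NAMES,
    STREAMS,
    resolve_stream,
)

__all__ = [
    "RecordingFile",
    "SessionSummary",
    "CohortMatrix",
    "EmptyCohortError",
    "EmptyRecordingError",
    "DialectError",
    "DegenerateFeatureError",
    "scan_archive",
    "parse_recording",
    "summarize_session",
    "build_cohort_matrix",
    "zscore_matrix",
    "inverse_zscore",
    "read_cohort",
    "cohort_to_csv",
    "cohort_from_csv",
]


class EmptyCohortError(ValueError):
    """Archive contains no recognizable recording files."""


class EmptyRecordingError(ValueError):
    """A recording file contains no valid numeric rows."""


class DialectError(ValueError):
    """A recording file does not match the accepted text dialect."""


class DegenerateFeatureError(ValueError):
    """A feature column has zero dispersion and cannot be standardized."""


#: ``Patient<k>_<moment>_<date>.txt`` — moment case-insensitive, date either a
#: bare year or an ISO calendar date.
FILENAME_RE = re.compile(
    r"^patient(?P<patient>\d+)_(?P<moment>before|during|after)_"
    r"(?P<date>\d{4}(?:-\d{2}-\d{2})?)\.txt$",
    re.IGNORECASE,
)

_LABEL_COLUMNS = ["patient_id", "moment", "date"]


def _parse_date(text: str) -> _dt.date:
    if len(text) == 4:
        return _dt.date(int(text), 1, 1)
    return _dt.date.fromisoformat(text)


def parse_member_name(name: str) -> dict | None:
    """Parse an archive member name under the recording grammar.

    Returns ``{"patient_id", "moment", "date"}`` or None for non-matching
    names. Directory components are ignored.
    """
    m = FILENAME_RE.match(Path(name).name)
    if m is None:
        return None
    return {
        "patient_id": int(m.group("patient")),
        "moment": Moment.parse(m.group("moment")),
        "date": _parse_date(m.group("date")),
    }


@dataclass
class RecordingFile:
    """One parsed session recording.

    ``samples`` is a float matrix with one column per canonical stream;
    entries that failed numeric conversion are stored as NaN and counted
    in ``n_invalid_dropped`` (they are excluded from all statistics).
    """

    patient_id: int
    moment: Moment
    date: _dt.date
    samples: np.ndarray
    n_invalid_dropped: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_STREAMS:
            raise ValueError(
                f"samples must have {N_STREAMS} columns, got shape {self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise EmptyRecordingError("recording has no rows")


@dataclass
class SessionSummary:
    """Per-session mean of each stream, with identifying labels."""

    patient_id: int
    moment: Moment
    date: _dt.date
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (N_STREAMS,):
            raise ValueError(f"features must be length {N_STREAMS}")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")


@dataclass
class CohortMatrix:
    """Session-by-stream characteristic matrix with aligned labels.

    ``values`` is N x 10; ``labels`` is a DataFrame with columns
    patient_id / moment / date aligned row-for-row.  When
    ``standardized`` is true, ``norm_stats`` carries the per-column mean
    and (population) standard deviation used, so standardization is
    exactly invertible.
    """

    values: np.ndarray
    labels: pd.DataFrame
    standardized: bool = False
    norm_stats: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_STREAMS:
            raise ValueError(f"values must be N x {N_STREAMS}")
        if self.values.shape[0] < 1:
            raise ValueError("cohort must contain at least one session")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels must align 1:1 with value rows")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_sessions(self) -> int:
        return self.values.shape[0]

    def moments(self) -> pd.Series:
        return self.labels["moment"].map(lambda m: m.value if isinstance(m, Moment) else str(m))


# ---------------------------------------------------------------------------
# Archive scanning and parsing
# ---------------------------------------------------------------------------

def scan_archive(archive_path: str | Path) -> tuple[list[dict], dict]:
    """List the recordings an archive contains, without parsing contents.

    Returns ``(entries, manifest)`` where each entry carries the member
    name plus the labels parsed from it, and the manifest summarizes
    counts by moment and by patient together with skipped members.
    """
    archive_path = Path(archive_path)
    if not archive_path.exists():
        raise FileNotFoundError(f"archive not found: {archive_path}")
    entries: list[dict] = []
    skipped: list[dict] = []
    with zipfile.ZipFile(archive_path) as zf:
        for info in zf.infolist():
            if info.is_dir():
                continue
            meta = parse_member_name(info.filename)
            if meta is None:
                skipped.append({"name": info.filename, "reason": "name does not match recording grammar"})
                continue
            entries.append({"name": info.filename, **meta})
    if not entries:
        raise EmptyCohortError(f"no recording files found in {archive_path}")
    by_moment = {m.value: 0 for m in Moment}
    by_patient: dict[str, int] = {}
    for e in entries:
        by_moment[e["moment"].value] += 1
        key = str(e["patient_id"])
        by_patient[key] = by_patient.get(key, 0) + 1
    manifest = {
        "total": len(entries),
        "by_moment": by_moment,
        "by_patient": dict(sorted(by_patient.items(), key=lambda kv: int(kv[0]))),
        "skipped": skipped,
    }
    return entries, manifest


_FLOAT_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _tokenize(line: str) -> list[str]:
    line = line.strip()
    if not line:
        return []
    if "," in line:
        return [t.strip() for t in line.split(",")]
    return line.split()


def parse_recording(text: str, declared_name: str) -> RecordingFile:
    """Parse the text content of one recording file.

    The dialect is delimited text (comma or whitespace runs), with an
    optional first header row naming the streams under common aliases.
    Headerless files must carry exactly 10 columns in canonical order.
    Unparseable tokens are dropped per-token (stored as NaN) and counted.
    """
    meta = parse_member_name(declared_name)
    if meta is None:
        raise DialectError(f"file name does not match recording grammar: {declared_name!r}")

    lines = [_tokenize(ln) for ln in text.splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise EmptyRecordingError(f"empty recording: {declared_name}")

    # Header detection: a first row whose tokens all resolve to stream names.
    column_order: list[int]
    first = lines[0]
    resolved = [resolve_stream(tok) for tok in first]
    if all(r is not None for r in resolved):
        seen = set()
        for r in resolved:
            if r in seen:
                raise DialectError(f"duplicate stream {r.value!r} in header of {declared_name}")
            seen.add(r)
        if len(resolved) != N_STREAMS:
            missing = [s.value for s in STREAMS if s not in seen]
            raise DialectError(f"header of {declared_name} missing streams: {missing}")
        # column_order[j] = position in file of canonical stream j
        pos = {r: i for i, r in enumerate(resolved)}
        column_order = [pos[s] for s in STREAMS]
        data_lines = lines[1:]
    else:
        if any(r is not None for r in resolved):
            raise DialectError(f"partial header in {declared_name}: {first}")
        column_order = list(range(N_STREAMS))
        data_lines = lines

    if not data_lines:
        raise EmptyRecordingError(f"empty recording (header only): {declared_name}")

    n_invalid = 0
    rows = []
    for tokens in data_lines:
        if len(tokens) != N_STREAMS:
            raise DialectError(
                f"{declared_name}: expected {N_STREAMS} columns, got {len(tokens)}"
            )
        row = np.empty(N_STREAMS)
        for j, src in enumerate(column_order):
            tok = tokens[src]
            if _FLOAT_RE.match(tok):
                row[j] = float(tok)
            else:
                row[j] = np.nan
                n_invalid += 1
        rows.append(row)
    samples = np.array(rows)
    if not np.any(np.isfinite(samples)):
        raise EmptyRecordingError(f"no valid numeric entries in {declared_name}")
    return RecordingFile(samples=samples, n_invalid_dropped=n_invalid, **meta)


def summarize_session(rec: RecordingFile) -> SessionSummary:
    """Summarize a recording by the mean of each stream's retained values."""
    finite = np.isfinite(rec.samples)
    empty = ~finite.any(axis=0)
    if empty.any():
        names = [STREAM_NAMES[j] for j in np.flatnonzero(empty)]
        raise EmptyRecordingError(
            f"stream(s) with no retained values: {', '.join(names)}"
        )
    with np.errstate(invalid="ignore"):
        features = np.nanmean(rec.samples, axis=0)
    return SessionSummary(rec.patient_id, rec.moment, rec.date, features)


def build_cohort_matrix(sessions: list[SessionSummary]) -> CohortMatrix:
    """Stack session summaries into a raw N x 10 cohort matrix."""
    if not sessions:
        raise EmptyCohortError("no sessions to build a cohort from")
    values = np.stack([s.features for s in sessions])
    labels = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in sessions],
            "moment": [s.moment for s in sessions],
            "date": [s.date for s in sessions],
        }
    )
    return CohortMatrix(values=values, labels=labels, standardized=False)


def zscore_matrix(m: CohortMatrix) -> CohortMatrix:
    """Standardize each column to zero mean, unit (population) variance.

    The per-column mean and standard deviation are stored in
    ``norm_stats`` for exact inversion. A zero-dispersion column raises
    :class:`DegenerateFeatureError` naming the stream.
    """
    if m.standardized:
        raise ValueError("matrix is already standardized")
    mu = m.values.mean(axis=0)
    sigma = m.values.std(axis=0)  # population divisor N
    bad = sigma <= 0
    if bad.any():
        names = [STREAM_NAMES[j] for j in np.flatnonzero(bad)]
        raise DegenerateFeatureError(
            f"degenerate feature(s) with zero dispersion: {', '.join(names)}"
        )
    values = (m.values - mu) / sigma
    return CohortMatrix(
        values=values,
        labels=m.labels.copy(),
        standardized=True,
        norm_stats={"mu": mu, "sigma": sigma},
    )


def inverse_zscore(m: CohortMatrix) -> CohortMatrix:
    """Undo standardization using the stored normalization statistics."""
    if not m.standardized or m.norm_stats is None:
        raise ValueError("matrix is not standardized")
    values = m.values * m.norm_stats["sigma"] + m.norm_stats["mu"]
    return CohortMatrix(values=values, labels=m.labels.copy(), standardized=False)


def read_cohort(archive_path: str | Path) -> tuple[CohortMatrix, dict]:
    """Parse every recording in an archive into a raw cohort matrix.

    Returns the raw CohortMatrix (rows in archive order) and the scan
    manifest augmented with the total number of invalid tokens dropped.
    """
    entries, manifest = scan_archive(archive_path)
    sessions: list[SessionSummary] = []
    n_invalid = 0
    with zipfile.ZipFile(archive_path) as zf:
        for e in entries:
            text = zf.read(e["name"]).decode("utf-8")
            rec = parse_recording(text, e["name"])
            n_invalid += rec.n_invalid_dropped
            sessions.append(summarize_session(rec))
    manifest = dict(manifest, n_invalid_dropped=n_invalid)
    return build_cohort_matrix(sessions), manifest


# ---------------------------------------------------------------------------
# CSV / JSON round trips
# ---------------------------------------------------------------------------

def cohort_to_csv(m: CohortMatrix, path: str | Path) -> None:
    df = m.labels.copy()
    df["moment"] = m.moments()
    for j, name in enumerate(STREAM_NAMES):
        df[name] = m.values[:, j]
    df.to_csv(path, index=False)


def cohort_from_csv(path: str | Path, standardized: bool = False) -> CohortMatrix:
    df = pd.read_csv(path, parse_dates=["date"])
    labels = pd.DataFrame(
        {
            "patient_id": df["patient_id"].astype(int),
            "moment": df["moment"].map(Moment.parse),
            "date": df["date"].dt.date,
        }
    )
    values = df[list(STREAM_NAMES)].to_numpy(dtype=float)
    return CohortMatrix(values=values, labels=labels, standardized=standardized)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
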