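"""Robust-design capture-history data model and I/O.

A study consists of T primary periods (seasons), the t-th containing J_t
secondary occasions (single-day surveys).  Detections are binary per
(individual, primary, secondary) cell.  Occasions are referred to 1-based in
reports and file formats; storage is contiguous primary-major (all of primary
1's secondaries, then primary 2's, ...).

Supported on-disk dialects:

* MARK-style ``.inp`` files: one capture-history string over ``{0,1}`` per
  line, an optional frequency, a terminating ``;`` and ``/* ... */`` comments.
* A long-format CSV with columns ``individual_id, primary, secondary,
  detected`` (1-based indices).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

QUALITY_GRADES = frozenset({"excellent", "good", "poor"})
DISTINCTIVENESS_GRADES = frozenset({"D1", "D2", "D3", "D4"})


class InpParseError(ValueError):
    """Raised when a ``.inp`` capture-history file is malformed."""


@dataclass(frozen=True)
class StudyDesign:
    """Labels and occasion counts of the nested primary/secondary design."""

    primary_labels: tuple[str, ...]
    secondaries_per_primary: tuple[int, ...]
    calendar: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.primary_labels) == 0:
            raise ValueError("design needs at least one primary period")
        if len(set(self.primary_labels)) != len(self.primary_labels):
            raise ValueError("primary labels must be unique")
        if len(self.secondaries_per_primary) != len(self.primary_labels):
            raise ValueError("one secondary count per primary required")
        if any(j < 1 for j in self.secondaries_per_primary):
            raise ValueError("every primary needs >= 1 secondary occasion")

    @classmethod
    def balanced(cls, n_primary: int, n_secondary: int,
                 labels: Sequence[str] | None = None) -> "StudyDesign":
        if labels is None:
            labels = tuple(f"primary_{t + 1}" for t in range(n_primary))
        return cls(tuple(labels), tuple([n_secondary] * n_primary))

    @property
    def n_primary(self) -> int:
        return len(self.primary_labels)

    @property
    def total_occasions(self) -> int:
        return int(sum(self.secondaries_per_primary))

    def primary_slice(self, t: int) -> slice:
        """Column slice of primary ``t`` (0-based) in the flat occasion axis."""
        offsets = np.concatenate([[0], np.cumsum(self.secondaries_per_primary)])
        return slice(int(offsets[t]), int(offsets[t + 1]))


@dataclass
class CaptureMatrix:
    """Binary detections, individuals x flat secondary occasions."""

    individual_ids: list
    detections: np.ndarray  # shape (n, total_occasions), values 0/1
    design: StudyDesign

    def __post_init__(self) -> None:
        self.detections = np.asarray(self.detections, dtype=np.int8)
        if self.detections.ndim != 2:
            raise ValueError("detections must be 2-D")
        if self.detections.shape != (len(self.individual_ids),
                                     self.design.total_occasions):
            raise ValueError("detections shape does not match ids/design")
        if not np.isin(self.detections, (0, 1)).all():
            raise ValueError("detections must be 0/1")
        if self.n_individuals and (self.detections.sum(axis=1) == 0).any():
            raise ValueError("every individual must have >= 1 detection")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids must be unique")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def primary_block(self, t: int) -> np.ndarray:
        """(n, J_t) detection sub-matrix of primary ``t`` (0-based)."""
        return self.detections[:, self.design.primary_slice(t)]

    def history_strings(self) -> list[str]:
        return ["".join(map(str, row)) for row in self.detections]


@dataclass
class PooledMatrix:
    """Season-pooled detections: 1 iff any secondary detection in the primary."""

    individual_ids: list
    detections: np.ndarray  # shape (n, T)
    design: StudyDesign

    def __post_init__(self) -> None:
        self.detections = np.asarray(self.detections, dtype=np.int8)
        if self.detections.shape != (len(self.individual_ids),
                                     self.design.n_primary):
            raise ValueError("pooled shape does not match ids/design")
        if not np.isin(self.detections, (0, 1)).all():
            raise ValueError("pooled detections must be 0/1")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_occasions(self) -> int:
        return self.design.n_primary


@dataclass(frozen=True)
class PhotoRecord:
    """One graded photographic identification record.

    ``individual_id`` may be ``None`` for fins that could not be matched.
    ``primary``/``secondary`` are 1-based indices into the study design.
    """

    sighting_id: str
    quality: str
    distinctiveness: str
    primary: int
    secondary: int
    individual_id: str | None = None

    def __post_init__(self) -> None:
        if self.quality not in QUALITY_GRADES:
            raise ValueError(f"unknown quality grade {self.quality!r}")
        if self.distinctiveness not in DISTINCTIVENESS_GRADES:
            raise ValueError(
                f"unknown distinctiveness grade {self.distinctiveness!r}")


@dataclass
class MArray:
    """Reduced m-array of first recaptures.

    ``m[i, j]`` counts animals released at occasion i (0-based) whose next
    detection is at occasion j > i; ``releases[i]`` counts animals detected at
    occasion i; ``never[i]`` those released at i and never detected again.
    """

    releases: np.ndarray
    m: np.ndarray
    never: np.ndarray

    @property
    def n_occasions(self) -> int:
        return len(self.releases)


# ---------------------------------------------------------------------------
# photo-record filtering and matrix construction
# ---------------------------------------------------------------------------

def filter_photo_records(
    records: Iterable[PhotoRecord],
    keep_quality: frozenset | set = frozenset({"excellent", "good"}),
    keep_distinctiveness: frozenset | set = frozenset({"D1", "D2"}),
) -> tuple[list[PhotoRecord], dict[str, int]]:
    """Apply the quality / distinctiveness inclusion rules.

    Poor-quality images are excluded outright; of the remainder only highly
    distinctive fins (D1/D2 by default) enter capture histories.  Returns the
    surviving records and removal counts keyed by reason.
    """
    kept: list[PhotoRecord] = []
    removed = {"quality": 0, "distinctiveness": 0}
    for rec in records:
        if rec.quality not in keep_quality:
            removed["quality"] += 1
        elif rec.distinctiveness not in keep_distinctiveness:
            removed["distinctiveness"] += 1
        else:
            kept.append(rec)
    return kept, removed


def build_capture_matrix(records: Iterable[PhotoRecord],
                         design: StudyDesign) -> CaptureMatrix:
    """Collapse identified records into a binary capture matrix.

    A cell is 1 iff the individual has >= 1 record in that (primary,
    secondary).  Individuals are ordered by first detection, ties broken by
    id.  Unidentified records (``individual_id is None``) are dropped with a
    logged count.
    """
    cells: dict[str, set[int]] = {}
    n_unidentified = 0
    for rec in records:
        if rec.individual_id is None:
            n_unidentified += 1
            continue
        t, j = rec.primary - 1, rec.secondary - 1
        if not (0 <= t < design.n_primary):
            raise ValueError(f"record primary {rec.primary} outside design")
        if not (0 <= j < design.secondaries_per_primary[t]):
            raise ValueError(
                f"record secondary {rec.secondary} outside primary "
                f"{rec.primary} (J={design.secondaries_per_primary[t]})")
        flat = design.primary_slice(t).start + j
        cells.setdefault(rec.individual_id, set()).add(flat)
    if n_unidentified:
        logger.warning("dropped %d records without an individual id",
                       n_unidentified)
    ids = sorted(cells, key=lambda i: (min(cells[i]), str(i)))
    det = np.zeros((len(ids), design.total_occasions), dtype=np.int8)
    for row, ind in enumerate(ids):
        det[row, sorted(cells[ind])] = 1
    return CaptureMatrix(ids, det, design)


def pool_primaries(matrix: CaptureMatrix) -> PooledMatrix:
    """Pool secondaries within each primary (max over the primary's columns)."""
    pooled = np.column_stack([
        matrix.primary_block(t).max(axis=1)
        for t in range(matrix.design.n_primary)
    ]).astype(np.int8)
    return PooledMatrix(list(matrix.individual_ids), pooled, matrix.design)


def m_array(pooled: PooledMatrix) -> MArray:
    """Reduced m-array of first recaptures from a pooled matrix."""
    T = pooled.n_occasions
    if T < 2:
        raise ValueError("m-array needs >= 2 occasions")
    det = pooled.detections
    releases = det.sum(axis=0).astype(int)
    m = np.zeros((T, T), dtype=int)
    never = np.zeros(T, dtype=int)
    for row in det:
        occ = np.flatnonzero(row)
        for i, j in zip(occ[:-1], occ[1:]):
            m[i, j] += 1
        never[occ[-1]] += 1
    assert (m.sum(axis=1) + never == releases).all()
    return MArray(releases=releases, m=m, never=never)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COMMENT_RE = re.compile(r"/\*.*?\*/", re.DOTALL)


def read_inp(path: str | Path, design: StudyDesign) -> CaptureMatrix:
    """Read a MARK-dialect ``.inp`` capture-history file.

    Each logical record is ``<history> <freq>;`` where ``<history>`` is a
    string over {0,1} of length ``design.total_occasions`` and ``<freq>`` a
    positive integer (default 1 when omitted).  ``/* ... */`` comments are
    stripped.  Frequencies are expanded to one row per individual; negative
    frequencies (losses on capture) are rejected.
    """
    text = Path(path).read_text()
    text = _COMMENT_RE.sub(" ", text)
    n_expected = design.total_occasions
    histories: list[str] = []
    # map raw text back to 1-based line numbers for error messages
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        for stmt in filter(None, (s.strip() for s in line.split(";")[:-1])):
            parts = stmt.split()
            hist = parts[0]
            freq = 1
            if len(parts) > 1:
                try:
                    freq = int(parts[1])
                except ValueError as exc:
                    raise InpParseError(
                        f"line {lineno}: bad frequency {parts[1]!r}") from exc
            if freq < 0:
                raise InpParseError(
                    f"line {lineno}: negative frequency (loss on capture) "
                    "not supported")
            if set(hist) - {"0", "1"}:
                raise InpParseError(
                    f"line {lineno}: characters outside {{0,1}} in history")
            if len(hist) != n_expected:
                raise InpParseError(
                    f"line {lineno}: history length {len(hist)} != design "
                    f"total occasions {n_expected}")
            histories.extend([hist] * freq)
        if line and not line.endswith(";") and line.split(";")[-1].strip():
            raise InpParseError(f"line {lineno}: missing ';' terminator")
    det = np.array([[int(c) for c in h] for h in histories],
                   dtype=np.int8).reshape(len(histories), n_expected)
    ids = [f"ind_{k + 1}" for k in range(len(histories))]
    return CaptureMatrix(ids, det, design)


def write_inp(matrix: CaptureMatrix, path: str | Path) -> None:
    """Write a matrix in the ``.inp`` dialect readable by :func:`read_inp`.

    One line per individual with frequency 1; histories are never wrapped.
    """
    design = matrix.design
    lines = [f"/* {matrix.n_individuals} individuals, "
             f"{design.n_primary} primaries x "
             f"{tuple(design.secondaries_per_primary)} secondaries */"]
    lines += [f"{h} 1;" for h in matrix.history_strings()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_long_csv(path: str | Path, design: StudyDesign) -> CaptureMatrix:
    """Read the native long-format dialect.

    Columns (fixed names): ``individual_id, primary, secondary, detected``;
    ``primary``/``secondary`` 1-based; only rows with ``detected == 1``
    contribute.
    """
    df = pd.read_csv(path)
    required = {"individual_id", "primary", "secondary", "detected"}
    if missing := required - set(df.columns):
        raise ValueError(f"long-format CSV missing columns {sorted(missing)}")
    recs = [
        PhotoRecord(sighting_id=f"row_{i}", quality="good",
                    distinctiveness="D1", primary=int(r.primary),
                    secondary=int(r.secondary),
                    individual_id=str(r.individual_id))
        for i, r in enumerate(df.itertuples())
        if int(r.detected) == 1
    ]
    return build_capture_matrix(recs, design)


def write_long_csv(matrix: CaptureMatrix, path: str | Path) -> None:
    rows = []
    for ind, row in zip(matrix.individual_ids, matrix.detections):
        for t in range(matrix.design.n_primary):
            sl = matrix.design.primary_slice(t)
            for j in range(matrix.design.secondaries_per_primary[t]):
                rows.append((ind, t + 1, j + 1, int(row[sl.start + j])))
    pd.DataFrame(rows, columns=["individual_id", "primary", "secondary",
                                "detected"]).to_csv(path, index=False)
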