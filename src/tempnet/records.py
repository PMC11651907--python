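"""Reading and writing timestamped contact records.

Proximity-sensor deployments (RFID badges, phone apps) distribute their
data as plain-text temporal edge lists: one line per recorded interval in
which a pair of individuals was in contact, ``t i j``, where ``t`` is a
timestamp and ``i``/``j`` are badge identifiers.  The recording resolution
is fixed per study (15 s, 20 s or 5 min in the published deployments this
package targets).  This module parses that dialect into
:class:`ContactRecordSet`, the canonical in-memory form used by every
downstream computation, and writes it back out losslessly.

Node identifiers are opaque strings throughout: the public datasets mix
integer badge ids and anonymised string codes, and nothing downstream
needs arithmetic on them.  Timestamps are normalised to seconds since the
first observation at read time; the original epoch of the first record is
retained as metadata.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ContactRecord",
    "ContactRecordSet",
    "ParseReport",
    "TijFormatError",
    "ContactValidationError",
    "read_tij",
    "write_tij",
    "read_node_attributes",
    "to_undirected",
]


class TijFormatError(ValueError):
    """A line of a tij file could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class ContactValidationError(ValueError):
    """A parsed record violates a structural invariant (self-contact,
    timestamp off the recording grid, attribute table problems...)."""


@dataclass(frozen=True, order=True)
class ContactRecord:
    """One recorded contact interval.

    ``time`` is in seconds since study start and must lie on the recording
    grid (a non-negative multiple of the resolution); ``source`` and
    ``target`` are node identifiers and must differ.  For undirected data
    the pair is stored canonically with ``source < target``.
    """

    time: int
    source: str
    target: str

    def pair(self, directed: bool) -> tuple[str, str]:
        if directed or self.source < self.target:
            return (self.source, self.target)
        return (self.target, self.source)


@dataclass
class ParseReport:
    """Bookkeeping from one :func:`read_tij` call.

    Duplicate lines are collapsed silently into the record set, but the
    counts are kept here so the data loss stays observable.
    """

    lines_read: int = 0
    records_kept: int = 0
    duplicates_collapsed: int = 0
    comments_skipped: int = 0

    def rows(self) -> list[tuple[str, int]]:
        return [
            ("lines_read", self.lines_read),
            ("records_kept", self.records_kept),
            ("duplicates_collapsed", self.duplicates_collapsed),
            ("comments_skipped", self.comments_skipped),
        ]


@dataclass
class ContactRecordSet:
    """An ordered, validated collection of contact records.

    Invariants: records are sorted by (time, source, target); all records
    share one recording ``resolution``; every time is a non-negative
    multiple of the resolution; no self-contacts.  When the set is
    undirected, every record has ``source < target`` and simultaneous
    mirror-image records have been collapsed.
    """

    records: list[ContactRecord]
    directed: bool
    resolution: int
    node_attributes: dict[str, dict[str, str]] | None = None
    epoch_offset: int = 0
    parse_report: ParseReport | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ContactValidationError("resolution must be a positive number of seconds")
        self.records = sorted(self.records)
        for rec in self.records:
            _validate_record(rec, self.resolution, self.directed)
        if self.node_attributes is not None:
            missing = self.nodes() - set(self.node_attributes)
            if missing:
                raise ContactValidationError(
                    f"{len(missing)} nodes present in records but absent from "
                    f"node_attributes (e.g. {sorted(missing)[:3]})"
                )

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for rec in self.records:
            out.add(rec.source)
            out.add(rec.target)
        return out

    def __len__(self) -> int:
        return len(self.records)

    def span(self) -> tuple[int, int]:
        """[first record start, last record end) in seconds."""
        if not self.records:
            return (0, 0)
        return (self.records[0].time, self.records[-1].time + self.resolution)


def _validate_record(rec: ContactRecord, resolution: int, directed: bool) -> None:
    if rec.source == rec.target:
        raise ContactValidationError(f"self-contact {rec.source!r} at t={rec.time}")
    if rec.time < 0 or rec.time % resolution != 0:
        raise ContactValidationError(
            f"time {rec.time} is not a non-negative multiple of resolution {resolution}"
        )
    if not directed and rec.source > rec.target:
        raise ContactValidationError(
            f"undirected record ({rec.source}, {rec.target}) is not canonically ordered"
        )


def _split_line(line: str) -> list[str]:
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def read_tij(
    path: str | Path,
    directed: bool = True,
    resolution: int = 20,
    columns: tuple[int, int, int] = (0, 1, 2),
) -> ContactRecordSet:
    """Parse a ``t i j`` temporal edge list.

    Lines are whitespace- or comma-separated; the three indices in
    ``columns`` locate time, source and target (extra columns are
    ignored).  Blank lines and ``#`` comments are skipped.  Duplicate
    ``(t, i, j)`` lines collapse to one record; for undirected data,
    ``(t, i, j)`` and ``(t, j, i)`` collapse to one canonical record.
    Timestamps are shifted so the earliest becomes 0; the shift is kept in
    ``epoch_offset``.

    Raises :class:`TijFormatError` for malformed lines (with the line
    number) and :class:`ContactValidationError` for self-contacts or
    timestamps off the recording grid.
    """
    report = ParseReport()
    raw: list[tuple[int, str, str]] = []
    ti, si, gi = columns
    need = max(columns) + 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                if line:
                    report.comments_skipped += 1
                continue
            report.lines_read += 1
            fields = _split_line(line)
            if len(fields) < need:
                raise TijFormatError(
                    f"expected at least {need} columns, got {len(fields)}", lineno
                )
            try:
                t = int(fields[ti])
            except ValueError as exc:
                raise TijFormatError(f"non-integer timestamp {fields[ti]!r}", lineno) from exc
            i, j = fields[si], fields[gi]
            if i == j:
                raise ContactValidationError(f"self-contact {i!r} at t={t} (line {lineno})")
            raw.append((t, i, j))

    epoch = min((t for t, _, _ in raw), default=0)
    seen: set[tuple[int, str, str]] = set()
    records: list[ContactRecord] = []
    for t, i, j in raw:
        t0 = t - epoch
        if t0 % resolution != 0:
            raise ContactValidationError(
                f"timestamp {t} is not on the {resolution} s recording grid "
                f"relative to study start {epoch}"
            )
        if not directed and i > j:
            i, j = j, i
        key = (t0, i, j)
        if key in seen:
            report.duplicates_collapsed += 1
            continue
        seen.add(key)
        records.append(ContactRecord(t0, i, j))
    report.records_kept = len(records)
    return ContactRecordSet(
        records=records,
        directed=directed,
        resolution=resolution,
        epoch_offset=epoch,
        parse_report=report,
    )


def write_tij(record_set: ContactRecordSet, path: str | Path) -> None:
    """Write the canonical tab-separated ``t i j`` form, sorted by time.

    Round-trips bit-exactly with :func:`read_tij` (times are written as
    normalised seconds-from-start; the stored epoch offset is not
    re-applied).  An empty set produces an empty file.
    """
    with open(path, "w") as fh:
        for rec in record_set.records:
            fh.write(f"{rec.time}\t{rec.source}\t{rec.target}\n")


def write_parse_report(report: ParseReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["quantity", "count"])
        writer.writerows(report.rows())


def read_node_attributes(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a node-attribute table (CSV with header; first column = node id).

    Every node maps to a dict of attribute label per column.  Empty cells
    become the explicit label ``"unknown"``.  Duplicate node rows raise
    :class:`ContactValidationError`.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ContactValidationError(f"attribute file {path} is empty") from None
        attrs: dict[str, dict[str, str]] = {}
        for row in reader:
            if not row or not any(cell.strip() for cell in row):
                continue
            node = row[0].strip()
            if node in attrs:
                raise ContactValidationError(f"duplicate attribute row for node {node!r}")
            attrs[node] = {
                col: (row[k].strip() if k < len(row) and row[k].strip() else "unknown")
                for k, col in enumerate(header[1:], start=1)
            }
    return attrs


def to_undirected(record_set: ContactRecordSet) -> ContactRecordSet:
    """Collapse a directed record set to undirected canonical form.

    Simultaneous ``i -> j`` and ``j -> i`` records merge into a single
    unordered contact.  Idempotent: undirected input is returned
    unchanged (same object).
    """
    if not record_set.directed:
        return record_set
    seen: set[tuple[int, str, str]] = set()
    records: list[ContactRecord] = []
    for rec in record_set.records:
        i, j = sorted((rec.source, rec.target))
        key = (rec.time, i, j)
        if key in seen:
            continue
        seen.add(key)
        records.append(ContactRecord(rec.time, i, j))
    return replace(record_set, records=records, directed=False, parse_report=None)
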