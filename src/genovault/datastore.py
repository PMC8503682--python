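"""Single-file relational study store.

The database is a plain SQLite file holding one metadata table and seven
result tables connected by primary/foreign keys: mutations (DNA panel and
RNA-expressed, distinguished by an ``origin`` column), CNV segments with
their one-to-many gene and cytoband annotations, isoform and gene counts,
and gene fusions.  Being a single ordinary file, the store travels with a
study and can be opened by any SQLite client; table and column names are
fixed (see :data:`genovault.records.RECORD_TYPES`).

Referential integrity is enforced twice: at insert time by this module (so
violations are reported with record context) and by the engine's foreign
keys.  ``check_integrity`` re-audits a whole database from scratch.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field as dc_field, fields as dc_fields
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

from .records import (
    RECORD_TYPES,
    TABLE_KINDS,
    CnvSegment,
    record_fields,
)

SCHEMA_VERSION = "1.0"

_SQL_TYPES = {int: "INTEGER", float: "REAL", str: "TEXT", bool: "INTEGER"}

# python type per column, used both for DDL and for reading rows back
_COLUMN_PYTYPES: dict[str, dict[str, type]] = {
    kind: {f.name: f.type if isinstance(f.type, type) else eval(f.type)  # noqa: S307 — dataclass annotations are our own literals
           for f in dc_fields(cls)}
    for kind, cls in RECORD_TYPES.items()
}

_FOREIGN_KEYS = {
    "mutations": ("sample_id", "study_metadata", "sample_id"),
    "cnv_segments": ("sample_id", "study_metadata", "sample_id"),
    "isoform_counts": ("sample_id", "study_metadata", "sample_id"),
    "gene_counts": ("sample_id", "study_metadata", "sample_id"),
    "fusions": ("sample_id", "study_metadata", "sample_id"),
    "cnv_gene_annotations": ("segment_id", "cnv_segments", "segment_id"),
    "cnv_band_annotations": ("segment_id", "cnv_segments", "segment_id"),
}


class DatastoreError(Exception):
    """Raised for schema, key or invariant problems in the study store."""


@dataclass
class IntegrityReport:
    """Outcome of a full referential/invariant audit.

    ``passed`` is true exactly when all three violation lists are empty.
    """

    orphan_rows: list[tuple[str, str, str]] = dc_field(default_factory=list)
    duplicate_keys: list[tuple[str, str]] = dc_field(default_factory=list)
    invariant_violations: list[tuple[str, str, str]] = dc_field(
        default_factory=list
    )

    @property
    def passed(self) -> bool:
        return not (
            self.orphan_rows or self.duplicate_keys or self.invariant_violations
        )


def _ddl(table_kind: str) -> str:
    cols = []
    pytypes = _COLUMN_PYTYPES[table_kind]
    for name in record_fields(table_kind):
        cols.append(f"{name} {_SQL_TYPES[pytypes[name]]} NOT NULL")
    key = RECORD_TYPES[table_kind].key
    constraints = [f"PRIMARY KEY ({', '.join(key)})"]
    if table_kind == "study_metadata":
        constraints.append("UNIQUE (sample_id, assay_type)")
    fk = _FOREIGN_KEYS.get(table_kind)
    # engine-level FK only where the target is a declared unique key;
    # sample_id is not unique alone in study_metadata (one row per assay),
    # so sample references are enforced by the library and check_integrity
    if fk and fk[1] == "cnv_segments":
        col, reftab, refcol = fk
        constraints.append(f"FOREIGN KEY ({col}) REFERENCES {reftab}({refcol})")
    body = ",\n  ".join(cols + constraints)
    return f"CREATE TABLE {table_kind} (\n  {body}\n)"


class StudyDatabase:
    """Handle to an open study database.

    Usable as a context manager; ``close`` is idempotent.
    """

    def __init__(self, path: str | Path, conn: sqlite3.Connection):
        self.path = Path(path)
        self._conn = conn

    # -- lifecycle -----------------------------------------------------

    def close(self) -> None:
        if self._conn is not None:
            self._conn.close()
            self._conn = None

    def __enter__(self) -> "StudyDatabase":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def conn(self) -> sqlite3.Connection:
        if self._conn is None:
            raise DatastoreError("database handle is closed")
        return self._conn

    # -- introspection -------------------------------------------------

    def list_tables(self) -> list[str]:
        """The eight schema tables (internal tables excluded), sorted."""
        rows = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table'"
        ).fetchall()
        return sorted(
            r[0] for r in rows
            if not r[0].startswith(("_", "sqlite_"))
        )

    @property
    def schema_version(self) -> str:
        row = self.conn.execute(
            "SELECT schema_version FROM _provenance"
        ).fetchone()
        return row[0]

    def count(self, table_kind: str) -> int:
        _check_kind(table_kind)
        return self.conn.execute(
            f"SELECT COUNT(*) FROM {table_kind}"
        ).fetchone()[0]

    def sample_ids(self) -> set[str]:
        rows = self.conn.execute(
            "SELECT DISTINCT sample_id FROM study_metadata"
        ).fetchall()
        return {r[0] for r in rows}


def _check_kind(table_kind: str) -> None:
    if table_kind not in RECORD_TYPES:
        raise DatastoreError(
            f"unknown table_kind {table_kind!r}; expected one of {TABLE_KINDS}"
        )


def create_database(
    path: str | Path,
    schema_version: str = SCHEMA_VERSION,
    overwrite: bool = False,
) -> StudyDatabase:
    """Create an empty study database at ``path``.

    Refuses to clobber an existing file unless ``overwrite`` is set.
    """
    path = Path(path)
    if path.exists():
        if not overwrite:
            raise DatastoreError(
                f"{path} already exists; pass overwrite=True to replace it"
            )
        path.unlink()
    conn = sqlite3.connect(path)
    conn.execute("PRAGMA foreign_keys = ON")
    with conn:
        for kind in TABLE_KINDS:
            conn.execute(_ddl(kind))
        conn.execute(
            "CREATE TABLE _provenance (schema_version TEXT NOT NULL)"
        )
        conn.execute(
            "INSERT INTO _provenance (schema_version) VALUES (?)",
            (schema_version,),
        )
    return StudyDatabase(path, conn)


def open_database(
    path: str | Path, expect_version: str | None = SCHEMA_VERSION
) -> StudyDatabase:
    """Open an existing database, checking its schema version.

    A version mismatch is an explicit error — there is no silent migration.
    Pass ``expect_version=None`` to skip the check.
    """
    path = Path(path)
    if not path.exists():
        raise DatastoreError(f"no database at {path}")
    conn = sqlite3.connect(path)
    conn.execute("PRAGMA foreign_keys = ON")
    db = StudyDatabase(path, conn)
    try:
        version = db.schema_version
    except sqlite3.Error as exc:
        conn.close()
        raise DatastoreError(f"{path} is not a study database: {exc}") from exc
    if expect_version is not None and version != expect_version:
        conn.close()
        raise DatastoreError(
            f"schema version mismatch: file has {version!r}, "
            f"expected {expect_version!r}"
        )
    return db


def bulk_insert(
    db: StudyDatabase, table_kind: str, records: Sequence[Any]
) -> int:
    """Insert a homogeneous batch of records, all-or-nothing.

    Every record is validated against its type invariants and its foreign
    keys before anything is written; the first offending record aborts the
    whole batch with a message naming it.
    Returns the number of rows inserted.
    """
    _check_kind(table_kind)
    cls = RECORD_TYPES[table_kind]
    fk = _FOREIGN_KEYS.get(table_kind)
    known_samples = (
        db.sample_ids() if fk and fk[1] == "study_metadata" else None
    )
    known_segments: set[str] | None = None
    if table_kind in ("cnv_gene_annotations", "cnv_band_annotations"):
        known_segments = {
            r[0]
            for r in db.conn.execute("SELECT segment_id FROM cnv_segments")
        }
    for i, rec in enumerate(records):
        if not isinstance(rec, cls):
            raise DatastoreError(
                f"record {i} is {type(rec).__name__}, expected {cls.__name__} "
                f"for table {table_kind}"
            )
        try:
            rec.validate()
        except ValueError as exc:
            raise DatastoreError(
                f"batch rejected: record {i} of {table_kind} invalid: {exc}"
            ) from exc
        if known_samples is not None and rec.sample_id not in known_samples:
            raise DatastoreError(
                f"batch rejected: record {i} of {table_kind} references "
                f"unknown sample_id {rec.sample_id!r}"
            )
        if known_segments is not None and rec.segment_id not in known_segments:
            raise DatastoreError(
                f"batch rejected: record {i} of {table_kind} references "
                f"unknown segment_id {rec.segment_id!r}"
            )
    if table_kind == "cnv_segments":
        _check_segment_overlaps(db, records)
    cols = record_fields(table_kind)
    placeholders = ", ".join("?" for _ in cols)
    sql = f"INSERT INTO {table_kind} ({', '.join(cols)}) VALUES ({placeholders})"
    rows = [
        tuple(
            int(v) if isinstance(v, bool) else v
            for v in (getattr(rec, c) for c in cols)
        )
        for rec in records
    ]
    try:
        with db.conn:
            db.conn.executemany(sql, rows)
    except sqlite3.IntegrityError as exc:
        raise DatastoreError(
            f"batch rejected by engine constraint on {table_kind}: {exc}"
        ) from exc
    return len(rows)


def _check_segment_overlaps(
    db: StudyDatabase, records: Sequence[CnvSegment]
) -> None:
    """Segments of one sample must not overlap on a chromosome."""
    existing: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for sid, chrom, start, end, seg in db.conn.execute(
        "SELECT sample_id, chrom, start, end, segment_id FROM cnv_segments"
    ):
        existing.setdefault((sid, chrom), []).append((start, end, seg))
    for i, rec in enumerate(records):
        key = (rec.sample_id, rec.chrom)
        for start, end, seg in existing.get(key, []):
            if rec.start <= end and start <= rec.end:
                raise DatastoreError(
                    f"batch rejected: segment record {i} "
                    f"({rec.segment_id}) overlaps {seg} on "
                    f"{rec.sample_id}/{rec.chrom}"
                )
        existing.setdefault(key, []).append((rec.start, rec.end, rec.segment_id))


def query_table(
    db: StudyDatabase,
    table_kind: str,
    filter: Mapping[str, Any] | None = None,
    order_by: Iterable[str] | None = None,
) -> list[Any]:
    """Fetch typed records matching equality predicates.

    Ordering is total and deterministic: the caller's ``order_by`` fields
    first, then the table's primary key.  Unknown fields raise.
    """
    _check_kind(table_kind)
    cls = RECORD_TYPES[table_kind]
    cols = record_fields(table_kind)
    filter = dict(filter or {})
    for f in list(filter) + list(order_by or []):
        if f not in cols:
            raise DatastoreError(
                f"unknown field {f!r} for table {table_kind}; "
                f"known fields: {cols}"
            )
    where = ""
    params: list[Any] = []
    if filter:
        clauses = []
        for k, v in filter.items():
            clauses.append(f"{k} = ?")
            params.append(int(v) if isinstance(v, bool) else v)
        where = " WHERE " + " AND ".join(clauses)
    ordering = list(order_by or []) + [k for k in cls.key]
    sql = (
        f"SELECT {', '.join(cols)} FROM {table_kind}{where} "
        f"ORDER BY {', '.join(dict.fromkeys(ordering))}"
    )
    pytypes = _COLUMN_PYTYPES[table_kind]
    out = []
    for row in db.conn.execute(sql, params):
        kwargs = {
            c: (bool(v) if pytypes[c] is bool else v)
            for c, v in zip(cols, row)
        }
        out.append(cls(**kwargs))
    return out


def check_integrity(db: StudyDatabase) -> IntegrityReport:
    """Audit the whole store: orphans, duplicate keys, invariant violations.

    Violations are data, not errors — they are enumerated in the report
    rather than raised.
    """
    report = IntegrityReport()
    # orphan foreign keys
    for table, (col, reftab, refcol) in _FOREIGN_KEYS.items():
        sql = (
            f"SELECT t.{col} FROM {table} t "
            f"LEFT JOIN {reftab} r ON t.{col} = r.{refcol} "
            f"WHERE r.{refcol} IS NULL"
        )
        for (missing,) in db.conn.execute(sql):
            report.orphan_rows.append((table, str(missing), f"{reftab}.{refcol}"))
    # duplicate primary/unique keys (PRIMARY KEY DDL normally prevents these;
    # re-checked so a hand-edited file is still audited)
    uniques: dict[str, tuple[str, ...]] = {
        kind: RECORD_TYPES[kind].key for kind in TABLE_KINDS
    }
    for table, key in uniques.items():
        keycols = ", ".join(key)
        sql = (
            f"SELECT {keycols}, COUNT(*) c FROM {table} "
            f"GROUP BY {keycols} HAVING c > 1"
        )
        for row in db.conn.execute(sql):
            report.duplicate_keys.append((table, "/".join(map(str, row[:-1]))))
    dup_meta = (
        "SELECT sample_id, assay_type, COUNT(*) c FROM study_metadata "
        "GROUP BY sample_id, assay_type HAVING c > 1"
    )
    for sid, assay, _ in db.conn.execute(dup_meta):
        report.duplicate_keys.append(("study_metadata", f"{sid}/{assay}"))
    # per-row type invariants
    for kind in TABLE_KINDS:
        for rec in query_table(db, kind):
            try:
                rec.validate()
            except ValueError as exc:
                report.invariant_violations.append(
                    (kind, "/".join(str(getattr(rec, k)) for k in rec.key),
                     str(exc))
                )
    # segment overlap invariant
    segs = query_table(db, "cnv_segments", order_by=["sample_id", "chrom", "start"])
    prev: dict[tuple[str, str], CnvSegment] = {}
    for seg in segs:
        key = (seg.sample_id, seg.chrom)
        p = prev.get(key)
        if p is not None and seg.start <= p.end:
            report.invariant_violations.append(
                ("cnv_segments", seg.segment_id,
                 f"overlaps {p.segment_id} on {seg.sample_id}/{seg.chrom}")
            )
        prev[key] = seg
    return report
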