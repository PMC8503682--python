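"""Extract/transform/load: upstream pipeline dialects -> structured CSV -> database.

Four upstream dialects are consumed: VCF 4.x (panel or RNA-expressed
mutations), ichorCNA-style ``.seg`` tab-separated segment tables, long/wide
tab-separated count matrices, and STAR-Fusion-style fusion TSVs.  Each
parser produces typed records; ``write_structured_csv`` renders any record
batch into a canonical, byte-deterministic CSV (RFC 4180, UTF-8, LF, fixed
column order, primary-key row order), and ``import_structured_csv`` is the
single ingestion path into the database — keeping a human-auditable
intermediate between pipeline output and store.
"""

from __future__ import annotations

import csv
import io
import tempfile
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Any, IO, Sequence

import pysam

from . import datastore
from .records import (
    RECORD_TYPES,
    CnvSegment,
    FusionRecord,
    GeneCountRecord,
    IsoformCountRecord,
    MutationRecord,
    StudyMetadataRecord,
    cn_type_for_copy_number,
    record_fields,
)


class EtlError(Exception):
    """Raised for malformed upstream files or structured-CSV mismatches."""


def normalize_chrom(chrom: str, add_prefix: bool = False) -> str:
    """Strip or add the ``chr`` prefix. Off by default everywhere."""
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"chr{bare}" if add_prefix else bare


# ---------------------------------------------------------------------------
# VCF

def _as_path(source: str | Path | IO[str], suffix: str) -> tuple[Path, bool]:
    """Materialize a text stream to a temp file; pass paths through."""
    if isinstance(source, (str, Path)):
        return Path(source), False
    tmp = tempfile.NamedTemporaryFile(
        "w", suffix=suffix, delete=False, encoding="utf-8"
    )
    tmp.write(source.read())
    tmp.close()
    return Path(tmp.name), True


def _prescan_vcf(path: Path) -> None:
    """Cheap structural check so errors carry line numbers.

    pysam reports malformed records without positions; a data line with
    fewer than 8 tab-separated fields is rejected here by line number.
    """
    with open(path, encoding="utf-8") as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if line.startswith("#"):
                continue
            if line.count("\t") < 7:
                raise EtlError(
                    f"{path.name} line {lineno}: VCF data line has fewer "
                    "than 8 fields"
                )
        if not saw_header:
            raise EtlError(f"{path.name}: missing #CHROM header line")


def parse_vcf(
    source: str | Path | IO[str],
    sample_id: str,
    origin: str,
    strip_chr_prefix: bool = False,
) -> list[MutationRecord]:
    """Parse a VCF into mutation records, one per ALT allele per line.

    Depth comes from per-sample FORMAT ``DP`` (falling back to INFO ``DP``),
    alt support from the ALT component of FORMAT ``AD``.  When neither is
    present, depth and alt_count are 0, vaf is 0 and the filter string is
    annotated ``nodepth``.  Multi-allelic lines are split into one record
    per ALT.  FILTER is preserved verbatim (``.`` when unfiltered).
    """
    if origin not in ("dna_panel", "rna_expressed"):
        raise EtlError(f"origin must be dna_panel or rna_expressed, got {origin!r}")
    path, is_tmp = _as_path(source, ".vcf")
    try:
        _prescan_vcf(path)
        try:
            vcf = pysam.VariantFile(str(path))
        except (ValueError, OSError) as exc:
            raise EtlError(f"{path.name}: malformed VCF header: {exc}") from exc
        records: list[MutationRecord] = []
        with vcf:
            vcf_samples = list(vcf.header.samples)
            for rec in vcf:
                if rec.alts is None:
                    continue
                filt = ";".join(rec.filter.keys()) or "."
                call = rec.samples[vcf_samples[0]] if vcf_samples else None
                ad = None
                depth = None
                if call is not None:
                    ad = call.get("AD")
                    if ad is not None and all(a is None for a in ad):
                        ad = None
                    depth = call.get("DP")
                if depth is None:
                    depth = rec.info.get("DP")
                gene = rec.info.get("GENE", "")
                if isinstance(gene, tuple):
                    gene = gene[0] or ""
                chrom = (
                    normalize_chrom(rec.chrom) if strip_chr_prefix else rec.chrom
                )
                for i, alt in enumerate(rec.alts):
                    alt_count = 0
                    if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                        alt_count = int(ad[i + 1])
                    d = int(depth) if depth is not None else 0
                    row_filt = filt
                    if depth is None and ad is None:
                        d = 0
                        alt_count = 0
                        row_filt = f"{filt};nodepth" if filt != "." else "nodepth"
                    if d > 0 and alt_count > d:
                        d = alt_count  # clamped: AD can exceed a thinned DP
                    vaf = alt_count / d if d > 0 else 0.0
                    records.append(
                        MutationRecord(
                            sample_id=sample_id,
                            origin=origin,
                            chrom=chrom,
                            pos=rec.pos,
                            ref_allele=rec.ref,
                            alt_allele=str(alt),
                            gene_symbol=str(gene),
                            depth=d,
                            alt_count=alt_count,
                            vaf=vaf,
                            filter_status=row_filt,
                        )
                    )
        return records
    finally:
        if is_tmp:
            path.unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# CNV segment tables (ichorCNA-style .seg dialect)

_SEG_ALIASES = {
    "chrom": {"chrom", "chr", "chromosome"},
    "start": {"start", "loc.start"},
    "end": {"end", "loc.end"},
    "median_logR": {"median_logr", "median.logr", "median", "seg.median.logr",
                    "logr", "seg.mean"},
    "copy_number": {"copy.number", "copy_number", "cn"},
    "subclone": {"subclone", "subclone.status"},
}


def _open_text(source: str | Path | IO[str]) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, encoding="utf-8")
    return source


def parse_cnv_segments(
    source: str | Path | IO[str],
    sample_id: str,
    strip_chr_prefix: bool = False,
) -> list[CnvSegment]:
    """Parse a tab-separated segment table into CNV segment records.

    Header names are matched case-insensitively against the common
    segment-table aliases (``chrom``/``chr``, ``start``/``loc.start``,
    ``median``/``logR``/``seg.median.logR``, ``copy.number``...).  The call
    label is derived from the copy number (diploid convention), not read
    from any ``call`` column; a subclone column is honored when present.
    """
    fh = _open_text(source)
    with fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise EtlError("empty segment file") from None
        lower = [h.strip().lower() for h in header]
        idx: dict[str, int] = {}
        for field, aliases in _SEG_ALIASES.items():
            for i, h in enumerate(lower):
                if h in aliases:
                    idx[field] = i
                    break
        required = ("chrom", "start", "end", "median_logR", "copy_number")
        missing = [f for f in required if f not in idx]
        if missing:
            raise EtlError(
                f"segment header {header} lacks required columns; expected "
                f"names for {missing} (aliases: "
                f"{ {m: sorted(_SEG_ALIASES[m]) for m in missing} })"
            )
        out: list[CnvSegment] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            start = int(float(row[idx["start"]]))
            end = int(float(row[idx["end"]]))
            if start > end:
                raise EtlError(f"line {lineno}: start {start} > end {end}")
            cn = int(float(row[idx["copy_number"]]))
            subclone = False
            if "subclone" in idx:
                subclone = row[idx["subclone"]].strip().lower() in (
                    "1", "true", "yes", "y",
                )
            chrom = row[idx["chrom"]].strip()
            if strip_chr_prefix:
                chrom = normalize_chrom(chrom)
            out.append(
                CnvSegment(
                    segment_id=f"{sample_id}_seg{lineno - 1:04d}",
                    sample_id=sample_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    median_logR=float(row[idx["median_logR"]]),
                    copy_number=cn,
                    cn_type=cn_type_for_copy_number(cn),
                    subclone=subclone,
                )
            )
        return out


# ---------------------------------------------------------------------------
# count matrices

_META_COLS = ("gene_symbol", "locus")


def _parse_counts(
    source: str | Path | IO[str], id_col: str, isoform: bool
) -> list[Any]:
    fh = _open_text(source)
    with fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise EtlError("empty count matrix") from None
        header = [h.strip() for h in header]
        if not header or header[0] != id_col:
            raise EtlError(
                f"count matrix must start with a {id_col!r} column, "
                f"got {header[:1]}"
            )
        meta_idx: dict[str, int] = {}
        col = 1
        if isoform:
            if len(header) < 2 or header[1] != "gene_id":
                raise EtlError(
                    "isoform matrix must carry gene_id as its second column"
                )
            meta_idx["gene_id"] = 1
            col = 2
        while col < len(header) and header[col] in _META_COLS:
            meta_idx[header[col]] = col
            col += 1
        sample_ids = header[col:]
        if not sample_ids:
            raise EtlError("count matrix has no sample columns")
        first_sample = col
        seen: set[str] = set()
        out: list[Any] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            feat = row[0].strip()
            if feat in seen:
                raise EtlError(f"line {lineno}: duplicated id {feat!r}")
            seen.add(feat)
            gene_symbol = row[meta_idx["gene_symbol"]] if "gene_symbol" in meta_idx else ""
            locus = row[meta_idx["locus"]] if "locus" in meta_idx else ""
            for sid, cell in zip(sample_ids, row[first_sample:]):
                value = float(cell)
                if value < 0:
                    raise EtlError(
                        f"line {lineno}: negative count {value} for "
                        f"{feat!r}/{sid!r}"
                    )
                if isoform:
                    out.append(
                        IsoformCountRecord(
                            sample_id=sid,
                            isoform_id=feat,
                            gene_id=row[meta_idx["gene_id"]].strip(),
                            gene_symbol=gene_symbol,
                            locus=locus,
                            count=value,
                        )
                    )
                else:
                    out.append(
                        GeneCountRecord(
                            sample_id=sid,
                            gene_id=feat,
                            gene_symbol=gene_symbol,
                            locus=locus,
                            count=value,
                        )
                    )
        return out


def parse_gene_counts(source: str | Path | IO[str]) -> list[GeneCountRecord]:
    """Long-form gene count records from a wide tab-separated matrix.

    Layout: ``gene_id`` first, optional ``gene_symbol``/``locus`` metadata
    columns, then one column per sample.  Zero counts are retained.
    """
    return _parse_counts(source, "gene_id", isoform=False)


def parse_isoform_counts(source: str | Path | IO[str]) -> list[IsoformCountRecord]:
    """Long-form isoform count records; layout adds a ``gene_id`` column."""
    return _parse_counts(source, "isoform_id", isoform=True)


# ---------------------------------------------------------------------------
# fusions (STAR-Fusion-style TSV)

_FUSION_ALIASES = {
    "name": {"#fusionname", "fusionname", "fusion_name", "#fusion_name"},
    "junction": {"junctionreadcount", "junction_reads", "junctionreads"},
    "spanning": {"spanningfragcount", "spanning_pairs", "spanningfrags"},
    "left": {"leftbreakpoint", "left_breakpoint"},
    "right": {"rightbreakpoint", "right_breakpoint"},
}


def parse_fusions(
    source: str | Path | IO[str], sample_id: str
) -> list[FusionRecord]:
    """Parse a fusion TSV: ``GENEA--GENEB`` names, support counts, breakpoints."""
    fh = _open_text(source)
    with fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise EtlError("empty fusion file") from None
        lower = [h.strip().lower().replace(".", "") for h in header]
        idx = {}
        for field, aliases in _FUSION_ALIASES.items():
            for i, h in enumerate(lower):
                if h in aliases:
                    idx[field] = i
                    break
            if field not in idx:
                raise EtlError(
                    f"fusion header {header} lacks a column for {field!r} "
                    f"(accepted: {sorted(aliases)})"
                )
        out: list[FusionRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            name = row[idx["name"]].strip()
            if "--" not in name:
                raise EtlError(
                    f"line {lineno}: fusion name {name!r} lacks '--' separator"
                )
            left_gene, right_gene = name.split("--", 1)
            rec = FusionRecord(
                sample_id=sample_id,
                left_gene=left_gene,
                right_gene=right_gene,
                left_breakpoint=row[idx["left"]].strip(),
                right_breakpoint=row[idx["right"]].strip(),
                junction_reads=int(row[idx["junction"]]),
                spanning_pairs=int(row[idx["spanning"]]),
            )
            try:
                rec.validate()
            except ValueError as exc:
                raise EtlError(f"line {lineno}: {exc}") from exc
            out.append(rec)
        return out


# ---------------------------------------------------------------------------
# study metadata CSV

def parse_metadata(source: str | Path | IO[str]) -> list[StudyMetadataRecord]:
    """Read study metadata from a structured CSV (same header as the table)."""
    fh = _open_text(source)
    with fh:
        reader = csv.DictReader(fh)
        expected = set(record_fields("study_metadata"))
        got = set(reader.fieldnames or [])
        if got != expected:
            raise EtlError(
                f"metadata header mismatch: missing {sorted(expected - got)}, "
                f"extra {sorted(got - expected)}"
            )
        out = []
        for row in reader:
            row["replicate"] = int(row["replicate"])
            out.append(StudyMetadataRecord(**row))
        return out


# ---------------------------------------------------------------------------
# structured CSV (the canonical intermediate)

def format_value(v: Any) -> str:
    """Canonical cell text: bools as 0/1, floats via shortest round-trip repr."""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _sort_key(rec: Any) -> tuple:
    return tuple(getattr(rec, k) for k in type(rec).key)


def write_structured_csv(records: Sequence[Any], path: str | Path) -> Path:
    """Render a homogeneous record batch as canonical structured CSV.

    RFC 4180, UTF-8, LF line endings, fixed column order, rows sorted by
    primary key — identical record sets always yield identical bytes.
    """
    if not records:
        raise EtlError(
            "cannot infer table kind from an empty batch; use "
            "write_structured_csv_kind"
        )
    kind = type(records[0]).table
    return write_structured_csv_kind(kind, records, path)


def write_structured_csv_kind(
    table_kind: str, records: Sequence[Any], path: str | Path
) -> Path:
    if table_kind not in RECORD_TYPES:
        raise EtlError(f"unknown table kind {table_kind!r}")
    cls = RECORD_TYPES[table_kind]
    for i, rec in enumerate(records):
        if not isinstance(rec, cls):
            raise EtlError(
                f"record {i} is {type(rec).__name__}; batch must be "
                f"homogeneous {cls.__name__}"
            )
    cols = record_fields(table_kind)
    path = Path(path)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(cols)
    for rec in sorted(records, key=_sort_key):
        writer.writerow([format_value(getattr(rec, c)) for c in cols])
    path.write_bytes(buf.getvalue().encode("utf-8"))
    return path


def read_structured_csv(table_kind: str, path: str | Path) -> list[Any]:
    """Parse a structured CSV back into typed records (import's front half)."""
    if table_kind not in RECORD_TYPES:
        raise EtlError(f"unknown table kind {table_kind!r}")
    cls = RECORD_TYPES[table_kind]
    pytypes = {
        f.name: f.type if isinstance(f.type, type) else eval(f.type)  # noqa: S307
        for f in dc_fields(cls)
    }
    expected = list(record_fields(table_kind))
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise EtlError(f"{path}: empty structured CSV") from None
        if header != expected:
            missing = [c for c in expected if c not in header]
            extra = [c for c in header if c not in expected]
            raise EtlError(
                f"{path}: header mismatch for {table_kind}: "
                f"missing {missing}, extra {extra}"
            )
        out = []
        for row in reader:
            kwargs = {}
            for col, cell in zip(expected, row):
                t = pytypes[col]
                if t is bool:
                    kwargs[col] = cell == "1"
                elif t is int:
                    kwargs[col] = int(cell)
                elif t is float:
                    kwargs[col] = float(cell)
                else:
                    kwargs[col] = cell
            out.append(cls(**kwargs))
        return out


def import_structured_csv(
    db: datastore.StudyDatabase, table_kind: str, path: str | Path
) -> int:
    """Import a structured CSV into the store; returns rows inserted."""
    records = read_structured_csv(table_kind, path)
    if not records:
        return 0
    return datastore.bulk_insert(db, table_kind, records)


# ---------------------------------------------------------------------------
# end-to-end study ETL

def etl_study(
    study_dir: str | Path,
    db_path: str | Path,
    overwrite: bool = False,
) -> datastore.StudyDatabase:
    """Full extract→structure→import of a study directory into a fresh store.

    Expects the layout emitted by the synthetic generator (and documented in
    the README): ``metadata.csv``, ``annotation/{genes.gtf,cytobands.tsv,
    chrom.sizes}``, ``rna/counts_{gene,isoform}.tsv``, per-sample
    ``dna/*.vcf``, ``rna/vcf/*.vcf``, ``cnv/*.seg`` and
    ``rna/fusions/*.fusions.tsv``.  Segment↔gene and segment↔cytoband
    annotations are computed here from the fixtures.  Every table passes
    through a structured CSV in ``<study_dir>/structured/`` — the single,
    auditable ingestion path.
    """
    from . import annotation as ann

    study_dir = Path(study_dir)
    structured = study_dir / "structured"
    structured.mkdir(exist_ok=True)
    db = datastore.create_database(db_path, overwrite=overwrite)

    def stage(kind: str, records) -> int:
        path = structured / f"{kind}.csv"
        write_structured_csv_kind(kind, records, path)
        return import_structured_csv(db, kind, path)

    stage("study_metadata", parse_metadata(study_dir / "metadata.csv"))

    mutations = []
    for vcf in sorted((study_dir / "dna").glob("*.vcf")):
        mutations += parse_vcf(vcf, vcf.stem, "dna_panel")
    for vcf in sorted((study_dir / "rna" / "vcf").glob("*.vcf")):
        mutations += parse_vcf(vcf, vcf.stem, "rna_expressed")
    stage("mutations", mutations)

    segments = []
    for seg in sorted((study_dir / "cnv").glob("*.seg")):
        segments += parse_cnv_segments(seg, seg.stem)
    stage("cnv_segments", segments)

    gene_models = ann.read_gene_models(study_dir / "annotation" / "genes.gtf")
    cytobands = ann.read_cytobands(study_dir / "annotation" / "cytobands.tsv")
    gene_rows = ann.annotate_segment_genes(segments, gene_models)
    band_rows = ann.annotate_segment_cytobands(segments, cytobands)
    if gene_rows:
        stage("cnv_gene_annotations", gene_rows)
    if band_rows:
        stage("cnv_band_annotations", band_rows)

    stage("isoform_counts",
          parse_isoform_counts(study_dir / "rna" / "counts_isoform.tsv"))
    stage("gene_counts",
          parse_gene_counts(study_dir / "rna" / "counts_gene.tsv"))

    fusions = []
    for tsv in sorted((study_dir / "rna" / "fusions").glob("*.fusions.tsv")):
        fusions += parse_fusions(tsv, tsv.name.split(".")[0])
    stage("fusions", fusions)
    return db
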