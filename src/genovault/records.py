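"""Typed records for the study database tables.

Each record class mirrors one table of the fixed schema and knows how to
validate its own invariants (``validate`` raises :class:`ValueError` with a
message naming the offending field).  Coordinates are 1-based inclusive
throughout; conversions to 0-based half-open happen only at export
boundaries (BED/BEDPE).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields
from typing import ClassVar

ASSAY_TYPES = ("dna_panel", "cnv_lowpass", "rna_seq")
MUTATION_ORIGINS = ("dna_panel", "rna_expressed")
CN_TYPES = ("amplification", "normal", "deletion")

_BREAKPOINT_RE = re.compile(r"^[^:]+:\d+:[+-]$")


def cn_type_for_copy_number(copy_number: int) -> str:
    """Copy-number call label under the diploid-autosome convention.

    >2 amplification, ==2 normal, <2 deletion.
    """
    if copy_number > 2:
        return "amplification"
    if copy_number == 2:
        return "normal"
    return "deletion"


@dataclass
class StudyMetadataRecord:
    record_id: str
    study_id: str
    patient_id: str
    sample_id: str
    tissue_type: str
    assay_type: str
    replicate: int
    pipeline_name: str
    pipeline_version: str
    reference_build: str

    table: ClassVar[str] = "study_metadata"
    key: ClassVar[tuple[str, ...]] = ("record_id",)

    def validate(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(
                f"assay_type {self.assay_type!r} not in {ASSAY_TYPES}"
            )
        if int(self.replicate) < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


@dataclass
class MutationRecord:
    sample_id: str
    origin: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene_symbol: str
    depth: int
    alt_count: int
    vaf: float
    filter_status: str

    table: ClassVar[str] = "mutations"
    key: ClassVar[tuple[str, ...]] = (
        "sample_id", "origin", "chrom", "pos", "ref_allele", "alt_allele",
    )

    def validate(self) -> None:
        if self.origin not in MUTATION_ORIGINS:
            raise ValueError(f"origin {self.origin!r} not in {MUTATION_ORIGINS}")
        if int(self.pos) < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("ref_allele and alt_allele must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref_allele == alt_allele ({self.ref_allele!r})")
        if self.depth < 0 or self.alt_count < 0:
            raise ValueError("depth and alt_count must be non-negative")
        if self.alt_count > self.depth:
            raise ValueError(
                f"alt_count {self.alt_count} exceeds depth {self.depth}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.depth > 0 and abs(self.vaf - self.alt_count / self.depth) > 1e-9:
            raise ValueError(
                f"vaf {self.vaf} != alt_count/depth "
                f"({self.alt_count}/{self.depth})"
            )


@dataclass
class CnvSegment:
    segment_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    median_logR: float
    copy_number: int
    cn_type: str
    subclone: bool

    table: ClassVar[str] = "cnv_segments"
    key: ClassVar[tuple[str, ...]] = ("segment_id",)

    def validate(self) -> None:
        if not self.segment_id:
            raise ValueError("segment_id must be non-empty")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.copy_number < 0:
            raise ValueError("copy_number must be non-negative")
        if self.cn_type not in CN_TYPES:
            raise ValueError(f"cn_type {self.cn_type!r} not in {CN_TYPES}")
        expected = cn_type_for_copy_number(self.copy_number)
        if self.cn_type != expected:
            raise ValueError(
                f"cn_type {self.cn_type!r} inconsistent with copy_number "
                f"{self.copy_number} (expected {expected!r})"
            )


@dataclass
class CnvGeneAnnotation:
    segment_id: str
    gene_id: str
    gene_symbol: str

    table: ClassVar[str] = "cnv_gene_annotations"
    key: ClassVar[tuple[str, ...]] = ("segment_id", "gene_id")

    def validate(self) -> None:
        if not self.segment_id or not self.gene_id:
            raise ValueError("segment_id and gene_id must be non-empty")


@dataclass
class CnvBandAnnotation:
    segment_id: str
    cytoband: str

    table: ClassVar[str] = "cnv_band_annotations"
    key: ClassVar[tuple[str, ...]] = ("segment_id", "cytoband")

    def validate(self) -> None:
        if not self.segment_id or not self.cytoband:
            raise ValueError("segment_id and cytoband must be non-empty")


@dataclass
class IsoformCountRecord:
    sample_id: str
    isoform_id: str
    gene_id: str
    gene_symbol: str
    locus: str
    count: float

    table: ClassVar[str] = "isoform_counts"
    key: ClassVar[tuple[str, ...]] = ("sample_id", "isoform_id")

    def validate(self) -> None:
        if not self.isoform_id:
            raise ValueError("isoform_id must be non-empty")
        if not self.gene_id:
            raise ValueError(f"isoform {self.isoform_id}: gene_id empty")
        if self.count < 0:
            raise ValueError(
                f"count must be >= 0, got {self.count} "
                f"({self.sample_id}/{self.isoform_id})"
            )


@dataclass
class GeneCountRecord:
    sample_id: str
    gene_id: str
    gene_symbol: str
    locus: str
    count: float

    table: ClassVar[str] = "gene_counts"
    key: ClassVar[tuple[str, ...]] = ("sample_id", "gene_id")

    def validate(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.count < 0:
            raise ValueError(
                f"count must be >= 0, got {self.count} "
                f"({self.sample_id}/{self.gene_id})"
            )


@dataclass
class FusionRecord:
    sample_id: str
    left_gene: str
    right_gene: str
    left_breakpoint: str   # "chrom:pos:strand", pos 1-based
    right_breakpoint: str
    junction_reads: int
    spanning_pairs: int

    table: ClassVar[str] = "fusions"
    key: ClassVar[tuple[str, ...]] = (
        "sample_id", "left_gene", "right_gene",
        "left_breakpoint", "right_breakpoint",
    )

    def validate(self) -> None:
        for bp in (self.left_breakpoint, self.right_breakpoint):
            if not _BREAKPOINT_RE.match(bp):
                raise ValueError(
                    f"breakpoint {bp!r} not of the form chrom:pos:strand"
                )
        if (self.left_gene == self.right_gene
                and self.left_breakpoint == self.right_breakpoint):
            raise ValueError(
                f"degenerate fusion {self.left_gene}--{self.right_gene}: "
                "identical genes and breakpoints"
            )
        if self.junction_reads < 0 or self.spanning_pairs < 0:
            raise ValueError("read support counts must be non-negative")
        if self.junction_reads + self.spanning_pairs < 1:
            raise ValueError(
                f"fusion {self.left_gene}--{self.right_gene} has no "
                "supporting reads"
            )


def parse_breakpoint(text: str) -> tuple[str, int, str]:
    """Split ``chrom:pos:strand`` into a typed triple."""
    if not _BREAKPOINT_RE.match(text):
        raise ValueError(f"breakpoint {text!r} not of the form chrom:pos:strand")
    chrom, pos, strand = text.rsplit(":", 2)
    return chrom, int(pos), strand


# table kind name -> record class, in fixed schema order
RECORD_TYPES = {
    cls.table: cls
    for cls in (
        StudyMetadataRecord,
        MutationRecord,
        CnvSegment,
        CnvGeneAnnotation,
        CnvBandAnnotation,
        IsoformCountRecord,
        GeneCountRecord,
        FusionRecord,
    )
}

TABLE_KINDS = tuple(RECORD_TYPES)


def record_fields(table_kind: str) -> tuple[str, ...]:
    """Ordered column names for a table kind."""
    cls = RECORD_TYPES[table_kind]
    return tuple(f.name for f in fields(cls))
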