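"""Genomic-interval computations over 1-based inclusive coordinates.

Covers segment↔gene and segment↔cytoband overlap annotation (the
one-to-many relations of the CNV tables), nearest-annotated-gene lookup for
novel loci, and the isoform→gene count roll-up.  Strand is carried for
provenance but ignored by overlap and distance logic: CNV segments are
unstranded.

Implementation is a per-chromosome sort + binary-search scan; the test
suite holds these to an all-pairs brute-force oracle.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

from .records import (
    CnvBandAnnotation,
    CnvGeneAnnotation,
    CnvSegment,
    GeneCountRecord,
    IsoformCountRecord,
)


class AnnotationError(Exception):
    pass


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class CytobandRow:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    band_name: str

    def __post_init__(self):
        if self.start > self.end:
            raise AnnotationError(
                f"band {self.band_name}: start {self.start} > end {self.end}"
            )


Interval = tuple[str, int, int]


def intervals_overlap(a: Interval, b: Interval) -> bool:
    """True iff the two 1-based inclusive intervals share any base.

    Touching endpoints overlap: (1, 1000, 2000) meets (1, 2000, 3000).
    """
    for iv in (a, b):
        if iv[1] > iv[2]:
            raise AnnotationError(f"interval {iv} has start > end")
    return a[0] == b[0] and a[1] <= b[2] and b[1] <= a[2]


class _ChromIndex:
    """Sorted-start index with a running max-end for overlap scans."""

    def __init__(self, items: Sequence[tuple[int, int, object]]):
        items = sorted(items, key=lambda t: (t[0], t[1]))
        self.starts = [t[0] for t in items]
        self.items = items
        self.max_end_prefix = []
        m = 0
        for _, end, _ in items:
            m = max(m, end)
            self.max_end_prefix.append(m)

    def overlapping(self, start: int, end: int) -> list[object]:
        # candidates have item.start <= end; walk back while an earlier
        # interval could still reach `start`
        hi = bisect.bisect_right(self.starts, end)
        out = []
        for i in range(hi - 1, -1, -1):
            if self.max_end_prefix[i] < start:
                break
            s, e, payload = self.items[i]
            if e >= start:
                out.append(payload)
        out.reverse()
        return out


def _index_by_chrom(
    items: Iterable[tuple[str, int, int, object]]
) -> dict[str, _ChromIndex]:
    per: dict[str, list[tuple[int, int, object]]] = {}
    for chrom, start, end, payload in items:
        per.setdefault(chrom, []).append((start, end, payload))
    return {chrom: _ChromIndex(v) for chrom, v in per.items()}


def annotate_segment_genes(
    segments: Sequence[CnvSegment], gene_models: Sequence[GeneModel]
) -> list[CnvGeneAnnotation]:
    """One annotation row per (segment, overlapping gene) pair.

    Output sorted by (segment_id, gene_id); segments touching no gene
    contribute nothing.
    """
    index = _index_by_chrom(
        (g.chrom, g.start, g.end, g) for g in gene_models
    )
    out = []
    for seg in segments:
        idx = index.get(seg.chrom)
        if idx is None:
            continue
        for g in idx.overlapping(seg.start, seg.end):
            out.append(
                CnvGeneAnnotation(
                    segment_id=seg.segment_id,
                    gene_id=g.gene_id,
                    gene_symbol=g.gene_symbol,
                )
            )
    out.sort(key=lambda a: (a.segment_id, a.gene_id))
    return out


def annotate_segment_cytobands(
    segments: Sequence[CnvSegment], cytobands: Sequence[CytobandRow]
) -> list[CnvBandAnnotation]:
    """One row per (segment, overlapping cytoband), sorted."""
    index = _index_by_chrom(
        (b.chrom, b.start, b.end, b) for b in cytobands
    )
    out = []
    for seg in segments:
        idx = index.get(seg.chrom)
        if idx is None:
            continue
        for b in idx.overlapping(seg.start, seg.end):
            out.append(
                CnvBandAnnotation(
                    segment_id=seg.segment_id, cytoband=b.band_name
                )
            )
    out.sort(key=lambda a: (a.segment_id, a.cytoband))
    return out


def nearest_annotated_gene(
    locus: Interval, gene_models: Sequence[GeneModel]
) -> tuple[GeneModel | None, int | None]:
    """Closest gene on the locus' chromosome, with signed endpoint-gap distance.

    Distance is 0 when the intervals overlap; otherwise the gap between the
    closest endpoints, signed negative when the gene lies before (5' of)
    the locus and positive when after.  Ties break to the lexicographically
    smaller gene_id.  Returns (None, None) when the chromosome carries no
    gene at all.
    """
    if not gene_models:
        raise AnnotationError("empty gene model set")
    chrom, start, end = locus
    if start > end:
        raise AnnotationError(f"locus {locus} has start > end")
    best: tuple[int, str, GeneModel] | None = None
    for g in gene_models:
        if g.chrom != chrom:
            continue
        if g.start <= end and start <= g.end:
            dist = 0
        elif g.end < start:
            dist = -(start - g.end)
        else:
            dist = g.start - end
        key = (abs(dist), g.gene_id)
        if best is None or key < (abs(best[0]), best[1]):
            best = (dist, g.gene_id, g)
    if best is None:
        return None, None
    return best[2], best[0]


def rollup_isoform_to_gene(
    isoform_counts: Sequence[IsoformCountRecord],
) -> list[GeneCountRecord]:
    """Sum isoform counts into per-(sample, gene) totals.

    Conserves per-sample total mass exactly (pure summation).  The gene
    symbol and locus are taken from the first isoform seen for the gene.
    """
    totals: dict[tuple[str, str], float] = {}
    meta: dict[str, tuple[str, str]] = {}
    for iso in isoform_counts:
        if not iso.gene_id:
            raise AnnotationError(
                f"isoform {iso.isoform_id} has no gene_id; cannot roll up"
            )
        key = (iso.sample_id, iso.gene_id)
        totals[key] = totals.get(key, 0.0) + iso.count
        meta.setdefault(iso.gene_id, (iso.gene_symbol, iso.locus))
    out = [
        GeneCountRecord(
            sample_id=sid,
            gene_id=gid,
            gene_symbol=meta[gid][0],
            locus=meta[gid][1],
            count=count,
        )
        for (sid, gid), count in totals.items()
    ]
    out.sort(key=lambda r: (r.sample_id, r.gene_id))
    return out


# ---------------------------------------------------------------------------
# fixture readers

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gene_models(source: str | Path | IO[str]) -> list[GeneModel]:
    """Gene models from a minimal gene-line GTF or a 1-based TSV.

    GTF: only ``gene`` feature lines are used; ``gene_id`` and
    ``gene_name`` are read from the attribute column.  TSV: header
    ``gene_id  gene_symbol  chrom  start  end  strand`` with 1-based
    inclusive coordinates.  Format is sniffed from the header line.
    """
    fh = open(source, encoding="utf-8") if isinstance(source, (str, Path)) else source
    with fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    first = lines[0].split("\t")
    out: list[GeneModel] = []
    if first[0] == "gene_id":  # TSV dialect
        for ln in lines[1:]:
            f = ln.split("\t")
            out.append(
                GeneModel(f[0], f[1], f[2], int(f[3]), int(f[4]), f[5])
            )
        return out
    for i, ln in enumerate(lines, start=1):
        f = ln.split("\t")
        if len(f) < 9:
            raise AnnotationError(f"GTF line {i}: fewer than 9 columns")
        if f[2] != "gene":
            continue
        attrs = dict(_GTF_ATTR.findall(f[8]))
        if "gene_id" not in attrs:
            raise AnnotationError(f"GTF line {i}: no gene_id attribute")
        out.append(
            GeneModel(
                gene_id=attrs["gene_id"],
                gene_symbol=attrs.get("gene_name", ""),
                chrom=f[0],
                start=int(f[3]),
                end=int(f[4]),
                strand=f[6] if f[6] in "+-" else "+",
            )
        )
    return out


def read_cytobands(source: str | Path | IO[str]) -> list[CytobandRow]:
    """Cytobands from a UCSC-style cytoBand TSV.

    The file is 0-based half-open (chrom, chromStart, chromEnd, name,
    gieStain); converted on read to 1-based inclusive.
    """
    fh = open(source, encoding="utf-8") if isinstance(source, (str, Path)) else source
    out = []
    with fh:
        for ln in fh:
            if not ln.strip() or ln.startswith(("#", "track")):
                continue
            f = ln.rstrip("\n").split("\t")
            if len(f) < 4:
                raise AnnotationError(f"cytoband line {ln!r}: fewer than 4 columns")
            out.append(
                CytobandRow(
                    chrom=f[0],
                    start=int(f[1]) + 1,
                    end=int(f[2]),
                    band_name=f[3],
                )
            )
    return out


def read_chrom_sizes(source: str | Path | IO[str]) -> dict[str, int]:
    """``chrom.sizes`` two-column TSV -> {chrom: length}."""
    fh = open(source, encoding="utf-8") if isinstance(source, (str, Path)) else source
    sizes = {}
    with fh:
        for ln in fh:
            if not ln.strip():
                continue
            chrom, size = ln.split()[:2]
            sizes[chrom] = int(size)
    return sizes
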