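"""Concentric-track construction for circos-style multi-omic plots.

Assembles, from database queries only, the six tracks of an integrated
per-sample figure: (i) chromosome ideogram, (ii) DNA panel mutations,
(iii) RNA-expressed mutations, (iv) CNV segments labelled
amplification/normal/deletion, (v) per-gene expression (TPM), and
(vi) gene-fusion links.  The contract is the track *data*; any circos-style
renderer can consume the exported BED/BEDPE files.

Internally coordinates stay 1-based inclusive; ``export_tracks`` converts
to 0-based half-open exactly once at the file boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

from . import datastore, expression
from .annotation import GeneModel
from .datastore import StudyDatabase
from .etl import format_value
from .records import parse_breakpoint


class CircosError(Exception):
    pass


@dataclass
class PointFeature:
    chrom: str
    pos: int          # 1-based
    name: str
    value: float      # vaf for mutation tracks


@dataclass
class SegmentFeature:
    chrom: str
    start: int        # 1-based inclusive
    end: int
    name: str
    value: float      # median logR
    label: str        # amplification | normal | deletion


@dataclass
class GeneValueFeature:
    chrom: str
    start: int
    end: int
    gene_id: str
    value: float      # TPM


@dataclass
class LinkFeature:
    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    name: str
    value: float      # junction + spanning support


@dataclass
class TrackSet:
    """The six concentric tracks, outermost first."""

    ideogram: dict[str, int]                      # chrom -> length
    dna_mutations: list[PointFeature] = dc_field(default_factory=list)
    rna_mutations: list[PointFeature] = dc_field(default_factory=list)
    cnv: list[SegmentFeature] = dc_field(default_factory=list)
    expression: list[GeneValueFeature] = dc_field(default_factory=list)
    fusions: list[LinkFeature] = dc_field(default_factory=list)
    notices: list[str] = dc_field(default_factory=list)

    TRACK_ORDER = (
        "ideogram", "dna_mutations", "rna_mutations",
        "cnv", "expression", "fusions",
    )


def _check_locus(chrom: str, end: int, sizes: Mapping[str, int], what: str):
    if chrom not in sizes:
        raise CircosError(f"{what}: chromosome {chrom!r} not in ideogram")
    if end > sizes[chrom]:
        raise CircosError(
            f"{what}: position {end} beyond {chrom} length {sizes[chrom]}"
        )


def build_track_set(
    db: StudyDatabase,
    sample_id: str,
    gene_models: Sequence[GeneModel],
    gene_lengths_kb: Mapping[str, float],
    chrom_sizes: Mapping[str, int],
    somatic_only: bool = True,
) -> TrackSet:
    """Assemble all six tracks for one sample from stored results.

    Nothing is re-called: tracks reflect the database exactly.  The DNA
    panel track is somatic-filtered by default (FILTER == PASS and vaf > 0,
    the tumor-vs-germline reading); the RNA track keeps every expressed
    variant.  Missing data kinds yield empty tracks plus a notice.
    """
    tracks = TrackSet(ideogram=dict(sorted(chrom_sizes.items())))
    by_gene = {g.gene_id: g for g in gene_models}

    for origin, dest in (("dna_panel", tracks.dna_mutations),
                         ("rna_expressed", tracks.rna_mutations)):
        muts = datastore.query_table(
            db, "mutations", filter={"sample_id": sample_id, "origin": origin}
        )
        for m in muts:
            if origin == "dna_panel" and somatic_only and not (
                m.filter_status == "PASS" and m.vaf > 0
            ):
                continue
            _check_locus(m.chrom, m.pos, chrom_sizes,
                         f"mutation {m.chrom}:{m.pos}")
            dest.append(
                PointFeature(
                    chrom=m.chrom,
                    pos=m.pos,
                    name=f"{m.ref_allele}>{m.alt_allele}",
                    value=m.vaf,
                )
            )
        if not muts:
            tracks.notices.append(f"no {origin} mutations for {sample_id}")

    segs = datastore.query_table(
        db, "cnv_segments", filter={"sample_id": sample_id}
    )
    for s in segs:
        _check_locus(s.chrom, s.end, chrom_sizes, f"segment {s.segment_id}")
        tracks.cnv.append(
            SegmentFeature(
                chrom=s.chrom, start=s.start, end=s.end, name=s.segment_id,
                value=s.median_logR, label=s.cn_type,
            )
        )
    if not segs:
        tracks.notices.append(f"no CNV segments for {sample_id}")

    counts = datastore.query_table(
        db, "gene_counts", filter={"sample_id": sample_id}
    )
    if counts:
        import pandas as pd

        df = pd.DataFrame(
            {sample_id: {r.gene_id: r.count for r in counts}}
        ).sort_index()
        cm = expression.CountMatrix(df, {sample_id: "sample"})
        lengths = {g: gene_lengths_kb[g] for g in cm.gene_ids
                   if g in gene_lengths_kb}
        known = [g for g in cm.gene_ids if g in lengths and g in by_gene]
        cm = expression.CountMatrix(df.loc[known], {sample_id: "sample"})
        tpm_values = expression.tpm(cm, lengths)[sample_id]
        for gid in known:
            g = by_gene[gid]
            _check_locus(g.chrom, g.end, chrom_sizes, f"gene {gid}")
            tracks.expression.append(
                GeneValueFeature(
                    chrom=g.chrom, start=g.start, end=g.end,
                    gene_id=gid, value=float(tpm_values.loc[gid]),
                )
            )
    else:
        tracks.notices.append(f"no gene counts for {sample_id}")

    fusions = datastore.query_table(
        db, "fusions", filter={"sample_id": sample_id}
    )
    for f in fusions:
        ca, pa, sa = parse_breakpoint(f.left_breakpoint)
        cb, pb, sb = parse_breakpoint(f.right_breakpoint)
        _check_locus(ca, pa, chrom_sizes, f"fusion {f.left_gene}--{f.right_gene}")
        _check_locus(cb, pb, chrom_sizes, f"fusion {f.left_gene}--{f.right_gene}")
        tracks.fusions.append(
            LinkFeature(
                chrom_a=ca, pos_a=pa, strand_a=sa,
                chrom_b=cb, pos_b=pb, strand_b=sb,
                name=f"{f.left_gene}--{f.right_gene}",
                value=float(f.junction_reads + f.spanning_pairs),
            )
        )
    if not fusions:
        tracks.notices.append(f"no fusions for {sample_id}")

    _sort_tracks(tracks)
    return tracks


def _sort_tracks(tracks: TrackSet) -> None:
    tracks.dna_mutations.sort(key=lambda p: (p.chrom, p.pos, p.name))
    tracks.rna_mutations.sort(key=lambda p: (p.chrom, p.pos, p.name))
    tracks.cnv.sort(key=lambda s: (s.chrom, s.start, s.name))
    tracks.expression.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    tracks.fusions.sort(
        key=lambda f: (f.chrom_a, f.pos_a, f.chrom_b, f.pos_b, f.name)
    )


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open (an exact bijection)."""
    return start - 1, end


def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def _write(path: Path, lines: list[str]) -> None:
    buf = io.StringIO()
    for ln in lines:
        buf.write(ln)
        buf.write("\n")
    path.write_bytes(buf.getvalue().encode("utf-8"))


def export_tracks(tracks: TrackSet, directory: str | Path) -> dict[str, Path]:
    """Write the track set as BED-dialect files (links as BEDPE).

    Files: ``ideogram.chrom.sizes``, ``dna_mutations.bed``,
    ``rna_mutations.bed``, ``cnv.bed`` (name=segment, score column carries
    logR, extra column the call label), ``expression.bed`` (score = TPM),
    ``fusions.bedpe``.  Byte-deterministic: fixed ordering and canonical
    float formatting.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    p = directory / "ideogram.chrom.sizes"
    _write(p, [f"{c}\t{n}" for c, n in sorted(tracks.ideogram.items())])
    out["ideogram"] = p

    for name, feats in (("dna_mutations", tracks.dna_mutations),
                        ("rna_mutations", tracks.rna_mutations)):
        p = directory / f"{name}.bed"
        lines = []
        for f in feats:
            s, e = to_bed_interval(f.pos, f.pos)
            lines.append(f"{f.chrom}\t{s}\t{e}\t{f.name}\t{format_value(f.value)}")
        _write(p, lines)
        out[name] = p

    p = directory / "cnv.bed"
    lines = []
    for f in tracks.cnv:
        s, e = to_bed_interval(f.start, f.end)
        lines.append(
            f"{f.chrom}\t{s}\t{e}\t{f.name}\t{format_value(f.value)}\t{f.label}"
        )
    _write(p, lines)
    out["cnv"] = p

    p = directory / "expression.bed"
    lines = []
    for f in tracks.expression:
        s, e = to_bed_interval(f.start, f.end)
        lines.append(
            f"{f.chrom}\t{s}\t{e}\t{f.gene_id}\t{format_value(f.value)}"
        )
    _write(p, lines)
    out["expression"] = p

    p = directory / "fusions.bedpe"
    lines = []
    for f in tracks.fusions:
        sa, ea = to_bed_interval(f.pos_a, f.pos_a)
        sb, eb = to_bed_interval(f.pos_b, f.pos_b)
        lines.append(
            f"{f.chrom_a}\t{sa}\t{ea}\t{f.chrom_b}\t{sb}\t{eb}\t"
            f"{f.name}\t{format_value(f.value)}\t{f.strand_a}\t{f.strand_b}"
        )
    _write(p, lines)
    out["fusions"] = p
    return out


def import_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED file back into 1-based inclusive loci (round-trip check)."""
    out = []
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        if not ln.strip():
            continue
        f = ln.split("\t")
        start, end = from_bed_interval(int(f[1]), int(f[2]))
        out.append((f[0], start, end))
    return out
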