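"""Synthetic multi-omic study generator with planted truth.

Emits a complete downstream-analysis study in the exact upstream dialects
the ETL layer consumes — per-sample VCFs (panel and RNA-expressed
mutations), ichorCNA-style ``.seg`` tables, isoform/gene count matrices,
fusion TSVs, study metadata, and annotation fixtures (gene-line GTF,
UCSC-style cytobands, chrom.sizes) — together with a truth table recording
every planted signal.

The default configuration is the study design the analyses are described
against: three tissue types × three replicates, where T1 is biologically
distinct from T2 and T3 (which share expression means), for 21 assay runs
in total (9 RNA-seq, 9 low-pass CNV, 3 DNA panel).  RNA counts follow an
explicit negative-binomial model,

    count_ij ~ NB(mean = s_j · mu_i · 2^(beta_i · x_j), dispersion)

with x_j = 1 for T1 samples, beta_i the planted log2 fold change (0 for
non-differential genes), and s_j a drawn library-size factor.  Gene counts
are drawn at the gene level and partitioned multinomially over isoforms, so
the isoform→gene roll-up is exact by construction.

Randomness: one global seed; every stage draws from its own
``SeedSequence([seed, stage])`` stream, so adding a stage never perturbs
the output of earlier stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np

from .etl import format_value, write_structured_csv_kind
from .records import StudyMetadataRecord

# stage ids for the per-stage random streams
_STAGE_GENOME = 1
_STAGE_COUNTS = 2
_STAGE_CNV = 3
_STAGE_MUT = 4
_STAGE_FUS = 5

DEFAULT_CHROM_SIZES = {
    "1": 20_000_000,
    "2": 16_000_000,
    "3": 12_000_000,
    "4": 10_000_000,
    "5": 8_000_000,
}


@dataclass
class StudyConfig:
    """Generator knobs; the defaults are the reference study conditions."""

    n_tissue_types: int = 3
    n_replicates: int = 3
    n_genes: int = 500
    max_isoforms_per_gene: int = 3
    fraction_de: float = 0.2          # of genes, differential T1 vs {T2, T3}
    fraction_novel: float = 0.1       # of genes, absent from the GTF fixture
    lfc_low: float = 2.0              # |planted log2FC| ~ Uniform[low, high]
    lfc_high: float = 4.0
    nb_dispersion: float = 0.1
    mean_log_mu: float = 4.5          # log-normal base expression (log scale)
    mean_log_sigma: float = 1.0
    library_size_sigma: float = 0.15  # log-normal spread of size factors
    n_mutations: int = 30             # per panel sample
    expressed_fraction: float = 0.5   # of panel mutations re-seen in RNA
    n_cnv_segments: int = 12          # per CNV sample, whole genome
    cnv_noise_sd: float = 0.05        # Gaussian noise on planted logR
    subclone_fraction: float = 0.2
    n_fusions: int = 5                # per RNA sample
    seed: int = 42
    chrom_sizes: dict[str, int] = dc_field(
        default_factory=lambda: dict(DEFAULT_CHROM_SIZES)
    )

    def validate(self) -> None:
        for frac in (self.fraction_de, self.fraction_novel,
                     self.expressed_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_tissue_types < 2 or self.n_replicates < 1:
            raise ValueError("need >=2 tissue types and >=1 replicate")

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), stage])
        )

    @property
    def tissues(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_tissue_types)]

    @property
    def rna_samples(self) -> list[str]:
        return [
            f"{t}R{r + 1}"
            for t in self.tissues
            for r in range(self.n_replicates)
        ]

    @property
    def panel_samples(self) -> list[str]:
        return [f"{t}R1" for t in self.tissues]

    def tissue_of(self, sample_id: str) -> str:
        return sample_id.split("R")[0]


@dataclass
class TruthTable:
    """Everything planted, for field-for-field verification after ETL."""

    de_genes: dict[str, float] = dc_field(default_factory=dict)
    novel_genes: list[str] = dc_field(default_factory=list)
    size_factors: dict[str, float] = dc_field(default_factory=dict)
    gene_loci: dict[str, dict] = dc_field(default_factory=dict)
    gene_lengths_kb: dict[str, float] = dc_field(default_factory=dict)
    isoforms: dict[str, list[str]] = dc_field(default_factory=dict)
    cnv: dict[str, list[dict]] = dc_field(default_factory=dict)
    mutations: dict[str, list[dict]] = dc_field(default_factory=dict)
    expressed_mutations: dict[str, list[dict]] = dc_field(default_factory=dict)
    fusions: dict[str, list[dict]] = dc_field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON serializable: {type(o)}")

        return json.dumps(asdict(self), sort_keys=True, indent=1,
                          default=default)


# ---------------------------------------------------------------------------
# genome layout

@dataclass
class SyntheticGenome:
    chrom_sizes: dict[str, int]
    genes: list  # of annotation.GeneModel
    novel_ids: set[str]
    isoform_ids: dict[str, list[str]]
    isoform_props: dict[str, np.ndarray]


def build_genome(config: StudyConfig) -> SyntheticGenome:
    """Lay out gene models, novel loci and isoform structure."""
    from .annotation import GeneModel

    rng = config._rng(_STAGE_GENOME)
    sizes = config.chrom_sizes
    chroms = list(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    per_chrom = np.floor(weights / weights.sum() * config.n_genes).astype(int)
    per_chrom[0] += config.n_genes - per_chrom.sum()

    genes: list[GeneModel] = []
    idx = 0
    for chrom, count in zip(chroms, per_chrom):
        if count == 0:
            continue
        spacing = sizes[chrom] // (count + 1)
        for slot in range(count):
            idx += 1
            start = spacing * (slot + 1)
            width = int(rng.integers(5_000, min(50_000, spacing - 1_000)))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"SYNG{idx:05d}",
                    gene_symbol=f"SG{idx}",
                    chrom=chrom,
                    start=start,
                    end=start + width - 1,
                    strand=strand,
                )
            )
    n_novel = int(round(config.fraction_novel * config.n_genes))
    novel_positions = rng.choice(len(genes), size=n_novel, replace=False)
    novel_ids = set()
    relabelled = []
    for i, g in enumerate(genes):
        if i in set(int(p) for p in novel_positions):
            nid = f"MSTRG.{i + 1}"
            novel_ids.add(nid)
            relabelled.append(
                GeneModel(nid, "", g.chrom, g.start, g.end, g.strand)
            )
        else:
            relabelled.append(g)
    genes = relabelled

    isoform_ids: dict[str, list[str]] = {}
    isoform_props: dict[str, np.ndarray] = {}
    for g in genes:
        k = int(rng.integers(1, config.max_isoforms_per_gene + 1))
        isoform_ids[g.gene_id] = [f"{g.gene_id}.t{j + 1}" for j in range(k)]
        props = rng.dirichlet(np.ones(k))
        isoform_props[g.gene_id] = props
    return SyntheticGenome(
        chrom_sizes=dict(sizes),
        genes=genes,
        novel_ids=novel_ids,
        isoform_ids=isoform_ids,
        isoform_props=isoform_props,
    )


def annotated_genes(genome: SyntheticGenome) -> list:
    """Gene models that go into the GTF fixture (novel loci withheld)."""
    return [g for g in genome.genes if g.gene_id not in genome.novel_ids]


# ---------------------------------------------------------------------------
# RNA counts

def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB with Var = m + dispersion·m²  (size n = 1/dispersion)."""
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def generate_counts(
    config: StudyConfig, genome: SyntheticGenome | None = None
) -> tuple[np.ndarray, np.ndarray, TruthTable]:
    """Draw gene- and isoform-level count matrices plus their truth part.

    Returns (gene_counts [genes × samples], isoform_counts
    [isoforms × samples], truth).  Row orders follow ``genome.genes`` and
    the per-gene isoform lists.
    """
    config.validate()
    if genome is None:
        genome = build_genome(config)
    rng = config._rng(_STAGE_COUNTS)
    samples = config.rna_samples
    n_genes = len(genome.genes)

    mu = np.exp(rng.normal(config.mean_log_mu, config.mean_log_sigma, n_genes))
    mu = np.maximum(mu, 1.0)
    n_de = int(round(config.fraction_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    beta = np.zeros(n_genes)
    magnitudes = rng.uniform(config.lfc_low, config.lfc_high, n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    beta[de_idx] = magnitudes * signs
    s = np.exp(rng.normal(0.0, config.library_size_sigma, len(samples)))
    x = np.array([1.0 if config.tissue_of(sid) == "T1" else 0.0
                  for sid in samples])

    means = s[None, :] * mu[:, None] * np.power(2.0, beta[:, None] * x[None, :])
    gene_counts = _nb_draw(rng, means, config.nb_dispersion)

    iso_rows = sum(len(genome.isoform_ids[g.gene_id]) for g in genome.genes)
    isoform_counts = np.zeros((iso_rows, len(samples)), dtype=np.int64)
    row = 0
    for gi, g in enumerate(genome.genes):
        props = genome.isoform_props[g.gene_id]
        k = len(props)
        for sj in range(len(samples)):
            total = int(gene_counts[gi, sj])
            if k == 1:
                isoform_counts[row, sj] = total
            else:
                isoform_counts[row:row + k, sj] = rng.multinomial(total, props)
        row += k

    truth = TruthTable()
    truth.de_genes = {
        genome.genes[int(i)].gene_id: float(beta[int(i)]) for i in de_idx
    }
    truth.novel_genes = sorted(genome.novel_ids)
    truth.size_factors = {sid: float(v) for sid, v in zip(samples, s)}
    for g in genome.genes:
        truth.gene_loci[g.gene_id] = {
            "chrom": g.chrom, "start": g.start, "end": g.end,
            "strand": g.strand,
        }
        truth.gene_lengths_kb[g.gene_id] = (g.end - g.start + 1) / 1000.0
        truth.isoforms[g.gene_id] = list(genome.isoform_ids[g.gene_id])
    return gene_counts, isoform_counts, truth


# ---------------------------------------------------------------------------
# CNV profiles

def generate_cnv(config: StudyConfig) -> dict[str, list[dict]]:
    """Per-sample planted segment lists tiling the genome.

    Each CNV sample receives ``n_cnv_segments`` contiguous, non-overlapping
    segments spread over the chromosomes; non-neutral segments carry
    copy_number in {1, 3, 4, 5} and median logR = log2(cn/2) + noise.
    """
    config.validate()
    rng = config._rng(_STAGE_CNV)
    chroms = list(config.chrom_sizes)
    out: dict[str, list[dict]] = {}
    for sid in config.rna_samples:  # CNV assay run for every sample
        per_chrom = np.zeros(len(chroms), dtype=int)
        for i in range(config.n_cnv_segments):
            per_chrom[i % len(chroms)] += 1
        segments = []
        for chrom, k in zip(chroms, per_chrom):
            if k == 0:
                continue
            L = config.chrom_sizes[chrom]
            cuts = np.sort(rng.choice(
                np.arange(2, L - 1, 1000), size=k - 1, replace=False
            )) if k > 1 else np.array([], dtype=int)
            bounds = [1, *[int(c) for c in cuts], L]
            for a, b in zip(bounds[:-1], bounds[1:]):
                start = a if a == 1 else a + 1
                if rng.random() < 0.5:
                    cn = 2
                else:
                    cn = int(rng.choice([1, 3, 4, 5]))
                logr = float(
                    np.log2(cn / 2.0) + rng.normal(0.0, config.cnv_noise_sd)
                )
                subclone = bool(
                    cn != 2 and rng.random() < config.subclone_fraction
                )
                segments.append({
                    "chrom": chrom, "start": start, "end": int(b),
                    "copy_number": cn, "median_logR": round(logr, 4),
                    "subclone": subclone,
                })
        out[sid] = segments
    return out


# ---------------------------------------------------------------------------
# mutations and fusions

_BASES = np.array(list("ACGT"))


def generate_mutations_and_fusions(
    config: StudyConfig, genome: SyntheticGenome
) -> tuple[dict[str, list[dict]], dict[str, list[dict]], dict[str, list[dict]]]:
    """(panel mutations, expressed subsets, fusions), keyed by sample.

    Panel mutations land inside annotated genes with Beta-distributed
    allele fractions; a configured fraction of each panel sample's
    mutations is re-emitted as RNA-expressed calls for the same sample.
    Fusion partners are drawn from annotated gene pairs with positive
    junction support.
    """
    rng = config._rng(_STAGE_MUT)
    ann_genes = annotated_genes(genome)
    mutations: dict[str, list[dict]] = {}
    expressed: dict[str, list[dict]] = {}
    for sid in config.panel_samples:
        rows = []
        positions_seen = set()
        while len(rows) < config.n_mutations:
            g = ann_genes[int(rng.integers(len(ann_genes)))]
            pos = int(rng.integers(g.start, g.end + 1))
            if (g.chrom, pos) in positions_seen:
                continue
            positions_seen.add((g.chrom, pos))
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            depth = int(rng.poisson(400)) + 50
            vaf_true = float(rng.beta(2.0, 6.0))
            alt_count = int(rng.binomial(depth, vaf_true))
            if alt_count == 0:
                alt_count = 1
            rows.append({
                "chrom": g.chrom, "pos": pos, "ref": str(ref),
                "alt": str(alt), "gene_symbol": g.gene_symbol,
                "depth": depth, "alt_count": alt_count,
                "vaf": alt_count / depth,
            })
        rows.sort(key=lambda r: (r["chrom"], r["pos"]))
        mutations[sid] = rows
        n_exp = int(round(config.expressed_fraction * len(rows)))
        chosen = sorted(
            int(i) for i in rng.choice(len(rows), size=n_exp, replace=False)
        )
        expressed[sid] = [rows[i] for i in chosen]

    frng = config._rng(_STAGE_FUS)
    fusions: dict[str, list[dict]] = {}
    for sid in config.rna_samples:
        rows = []
        for _ in range(config.n_fusions):
            i, j = frng.choice(len(ann_genes), size=2, replace=False)
            left, right = ann_genes[int(i)], ann_genes[int(j)]
            lpos = int(frng.integers(left.start, left.end + 1))
            rpos = int(frng.integers(right.start, right.end + 1))
            rows.append({
                "left_gene": left.gene_id, "right_gene": right.gene_id,
                "left_breakpoint": f"{left.chrom}:{lpos}:{left.strand}",
                "right_breakpoint": f"{right.chrom}:{rpos}:{right.strand}",
                "junction_reads": int(frng.integers(5, 51)),
                "spanning_pairs": int(frng.integers(0, 21)),
            })
        rows.sort(key=lambda r: (r["left_breakpoint"], r["right_breakpoint"]))
        fusions[sid] = rows
    return mutations, expressed, fusions


# ---------------------------------------------------------------------------
# file emission

def _vcf_text(
    config: StudyConfig, rows: list[dict], sample_label: str
) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        '##source=genovault-synthetic',
    ]
    for chrom, size in config.chrom_sizes.items():
        lines.append(f"##contig=<ID={chrom},length={size}>")
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + sample_label,
    ]
    for r in rows:
        ref_count = r["depth"] - r["alt_count"]
        lines.append(
            f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t100\tPASS\t"
            f"DP={r['depth']};GENE={r['gene_symbol']}\tGT:AD:DP\t"
            f"0/1:{ref_count},{r['alt_count']}:{r['depth']}"
        )
    return "\n".join(lines) + "\n"


def _seg_text(rows: list[dict], sample_id: str) -> str:
    header = ("ID\tchrom\tstart\tend\tnum.mark\tmedian.logR\t"
              "copy.number\tcall\tsubclone.status")
    call = {True: "AMP", False: "DEL"}
    lines = [header]
    for r in sorted(rows, key=lambda r: (r["chrom"], r["start"])):
        label = ("NEUT" if r["copy_number"] == 2
                 else call[r["copy_number"] > 2])
        n_mark = max(1, (r["end"] - r["start"]) // 1_000_000)
        lines.append(
            f"{sample_id}\t{r['chrom']}\t{r['start']}\t{r['end']}\t{n_mark}\t"
            f"{format_value(float(r['median_logR']))}\t{r['copy_number']}\t"
            f"{label}\t{'TRUE' if r['subclone'] else 'FALSE'}"
        )
    return "\n".join(lines) + "\n"


def _fusion_text(rows: list[dict]) -> str:
    header = ("#FusionName\tJunctionReadCount\tSpanningFragCount\t"
              "LeftBreakpoint\tRightBreakpoint")
    lines = [header]
    for r in rows:
        lines.append(
            f"{r['left_gene']}--{r['right_gene']}\t{r['junction_reads']}\t"
            f"{r['spanning_pairs']}\t{r['left_breakpoint']}\t"
            f"{r['right_breakpoint']}"
        )
    return "\n".join(lines) + "\n"


def _counts_text(
    genome: SyntheticGenome,
    gene_counts: np.ndarray,
    isoform_counts: np.ndarray,
    samples: list[str],
    level: str,
) -> str:
    if level == "gene":
        header = ["gene_id", "gene_symbol", "locus", *samples]
        lines = ["\t".join(header)]
        for gi, g in enumerate(genome.genes):
            locus = f"{g.chrom}:{g.start}-{g.end}"
            row = [g.gene_id, g.gene_symbol, locus,
                   *[str(int(v)) for v in gene_counts[gi]]]
            lines.append("\t".join(row))
    else:
        header = ["isoform_id", "gene_id", "gene_symbol", "locus", *samples]
        lines = ["\t".join(header)]
        row_i = 0
        for g in genome.genes:
            locus = f"{g.chrom}:{g.start}-{g.end}"
            for iso in genome.isoform_ids[g.gene_id]:
                row = [iso, g.gene_id, g.gene_symbol, locus,
                       *[str(int(v)) for v in isoform_counts[row_i]]]
                lines.append("\t".join(row))
                row_i += 1
    return "\n".join(lines) + "\n"


def _gtf_text(genome: SyntheticGenome) -> str:
    lines = []
    for g in annotated_genes(genome):
        attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_symbol}";'
        lines.append(
            f"{g.chrom}\tsynthetic\tgene\t{g.start}\t{g.end}\t.\t"
            f"{g.strand}\t.\t{attrs}"
        )
    return "\n".join(lines) + "\n"


def _cytoband_text(config: StudyConfig) -> str:
    """Four quarter bands per chromosome, UCSC 0-based half-open."""
    lines = []
    for chrom, size in config.chrom_sizes.items():
        q = size // 4
        bands = [
            (0, q, "p2"), (q, 2 * q, "p1"),
            (2 * q, 3 * q, "q1"), (3 * q, size, "q2"),
        ]
        for start, end, name in bands:
            lines.append(f"{chrom}\t{start}\t{end}\t{name}\tgpos50")
    return "\n".join(lines) + "\n"


def write_study(
    config: StudyConfig, directory: str | Path
) -> tuple[dict[str, Path], TruthTable]:
    """Emit the full study file tree; returns (manifest, truth).

    Byte-deterministic for a fixed config: regenerating with the same seed
    reproduces every file exactly.
    """
    config.validate()
    directory = Path(directory)
    for sub in ("annotation", "rna", "rna/vcf", "rna/fusions", "dna", "cnv"):
        (directory / sub).mkdir(parents=True, exist_ok=True)

    genome = build_genome(config)
    gene_counts, isoform_counts, truth = generate_counts(config, genome)
    cnv = generate_cnv(config)
    mutations, expressed, fusions = generate_mutations_and_fusions(
        config, genome
    )
    truth.cnv = cnv
    truth.mutations = mutations
    truth.expressed_mutations = expressed
    truth.fusions = fusions

    manifest: dict[str, Path] = {}

    def emit(name: str, path: Path, text: str) -> None:
        path.write_bytes(text.encode("utf-8"))
        manifest[name] = path

    meta_records = []
    i = 0
    for sid in config.rna_samples:
        tissue = config.tissue_of(sid)
        rep = int(sid.split("R")[1])
        assays = ["rna_seq", "cnv_lowpass"]
        if sid in config.panel_samples:
            assays.append("dna_panel")
        for assay in assays:
            i += 1
            meta_records.append(
                StudyMetadataRecord(
                    record_id=f"M{i:03d}",
                    study_id="SYNTH01",
                    patient_id=f"P{tissue}",
                    sample_id=sid,
                    tissue_type=tissue,
                    assay_type=assay,
                    replicate=rep,
                    pipeline_name="genovault-synthetic",
                    pipeline_version="1",
                    reference_build="SYNTH1",
                )
            )
    meta_path = directory / "metadata.csv"
    write_structured_csv_kind("study_metadata", meta_records, meta_path)
    manifest["metadata"] = meta_path

    emit("gene_models", directory / "annotation" / "genes.gtf",
         _gtf_text(genome))
    emit("cytobands", directory / "annotation" / "cytobands.tsv",
         _cytoband_text(config))
    emit(
        "chrom_sizes", directory / "annotation" / "chrom.sizes",
        "".join(f"{c}\t{n}\n" for c, n in config.chrom_sizes.items()),
    )
    emit("gene_counts", directory / "rna" / "counts_gene.tsv",
         _counts_text(genome, gene_counts, isoform_counts,
                      config.rna_samples, "gene"))
    emit("isoform_counts", directory / "rna" / "counts_isoform.tsv",
         _counts_text(genome, gene_counts, isoform_counts,
                      config.rna_samples, "isoform"))
    for sid in config.panel_samples:
        emit(f"dna_vcf/{sid}", directory / "dna" / f"{sid}.vcf",
             _vcf_text(config, mutations[sid], "TUMOR"))
        emit(f"rna_vcf/{sid}", directory / "rna" / "vcf" / f"{sid}.vcf",
             _vcf_text(config, expressed[sid], "TUMOR"))
    for sid in config.rna_samples:
        emit(f"seg/{sid}", directory / "cnv" / f"{sid}.seg",
             _seg_text(cnv[sid], sid))
        emit(f"fusions/{sid}",
             directory / "rna" / "fusions" / f"{sid}.fusions.tsv",
             _fusion_text(fusions[sid]))
    emit("truth", directory / "truth.json", truth.to_json() + "\n")
    return manifest, truth
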