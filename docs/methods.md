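# Methods

This note documents the models, conventions and numerical choices behind
genovault, what the synthetic-study generator does and does not emulate,
and the design decisions taken where more than one defensible option
existed.

## Data model and coordinate conventions

The store is one SQLite file with a fixed schema: a study-metadata table
(one row per assay run; `(sample_id, assay_type)` unique) and seven result
tables — mutations (DNA panel and RNA-expressed in one table, separated by
an `origin` column), CNV segments with one-to-many gene and cytoband
annotation tables, isoform counts, gene counts, and fusions. A one-row
internal `_provenance` table carries the schema version; opening a file
with a different version is an explicit error, never a silent migration.

All genomic coordinates are stored **1-based inclusive** (the VCF and
segment-table convention). Conversion to 0-based half-open happens exactly
once, at the BED/BEDPE export boundary, and is an exact bijection
(`start−1, end`). Chromosome names are stored as given; an optional ETL
flag strips/adds the `chr` prefix (off by default). Text keys compare
case-sensitively.

Referential integrity is enforced at insert time by the library, so a bad
batch is rejected whole with the offending record named. SQLite's own
foreign-key machinery backs the `segment_id` references; `sample_id`
references cannot be engine-enforced (the column is not unique by itself in
the metadata table — one row per assay) and are therefore checked by the
library and re-audited by `check_integrity`, which also re-validates every
row invariant (e.g. `alt_count ≤ depth`, `vaf = alt_count/depth`,
`cn_type` consistent with copy number, per-sample segment
non-overlap).

## ETL

Four upstream dialects are parsed: VCF 4.x (via pysam; depth prefers
per-sample `FORMAT/DP` with `INFO/DP` fallback, alt support from the ALT
component of `FORMAT/AD`, multi-allelic records split per ALT; records with
neither field get depth 0 and a `nodepth` annotation on the filter string),
ichorCNA-style `.seg` tables (header matched case-insensitively against
common alias sets; the amplification/normal/deletion call is derived from
copy number under the diploid convention, not read from the file), wide
tab-separated count matrices, and STAR-Fusion-style TSVs
(`GENEA--GENEB` names, junction/spanning support, `chrom:pos:strand`
breakpoints).

Everything enters the database through one path: parse → canonical
structured CSV (RFC 4180, UTF-8, LF, fixed column order, primary-key row
order, shortest round-trip float repr) → import. The intermediate CSV is
deliberately kept as a human-auditable artifact; identical record sets
always produce byte-identical files.

## Interval annotation

Overlap between 1-based inclusive intervals is `a.start ≤ b.end ∧ b.start ≤
a.end` (touching endpoints overlap). Segment↔gene and segment↔cytoband
annotation use a per-chromosome sorted index with a running-max-end scan —
an O((n+m) log) approach chosen over interval trees for simplicity at
study scale; the test suite holds it to an all-pairs oracle. Strand is
stored for provenance but ignored in overlap and distance logic, since CNV
segments are unstranded.

"Nearest annotated gene" for a novel locus is defined as the minimal gap
between closest interval endpoints among same-chromosome genes (distance 0
iff overlap), signed negative when the gene lies 5' of the locus and
positive when 3'; ties break to the lexicographically smaller gene id so
reports are deterministic. Alternatives (midpoint distance, TSS distance)
would be defensible; the endpoint-gap definition is stated in the report
semantics and used consistently.

The isoform→gene roll-up is a pure per-(sample, gene) sum, so per-sample
total mass is conserved exactly.

## Normalization and differential expression

Size factors are median-of-ratios: with geometric mean `g_i` of gene i
across samples, `s_j = median over {i : g_i > 0} of k_ij / g_i`. Two exact
invariants follow (and are tested): scaling one sample's counts by c scales
its factor *relative to every other sample* by exactly c (the absolute
factor moves by c^((n−1)/n) because the reference geometric mean absorbs
c^(1/n)); and re-estimating factors on normalized counts returns one
common value (the geometric mean of the original factors) for every
sample, i.e. a second normalization changes nothing up to a global
constant. When no gene is positive in all samples the estimator is
undefined and the error message points to a pseudo-reference (+1)
fallback, which the caller must opt into explicitly.

TPM divides counts by gene length in kilobases and rescales each sample to
1e6; an all-zero sample is flagged and left at zero rather than divided.

The differential-expression test is a per-gene two-sample t on
`log2(normalized + 1)`, Benjamini–Hochberg adjusted (via statsmodels).
This is intentionally a transparent, assumption-light test rather than a
negative-binomial shrinkage model; the report JSON sidecar names the
method. **Pooled variance is the default**: with three replicates per
group the pooled form has exact degrees of freedom, and on null NB
simulations (2000 genes, 3 vs 3, dispersion 0.1) its p-values stay close
to uniform (KS D ≈ 0.02), whereas Welch's Satterthwaite approximation is
measurably anti-conservative on these small, skewed samples (KS D ≈
0.03–0.05). Welch remains available via `equal_var=False` for designs with
genuinely unequal group variances. Genes with zero variance in both groups
receive p = 1 (equal means) or p = 0 (unequal) as the degenerate limit.
Observed behaviour at the default study conditions: mean planted-log2FC
error well inside ±0.3, empirical FDR at BH 0.05 around 0.02–0.05, and
per-seed recovery of planted |log2FC| ≥ 2 genes of roughly 0.70–0.85 — the
price of the simple test on lowly-expressed genes, stated here so report
consumers calibrate expectations.

Fold changes use a pseudocount (default 1): `log2((μ_case + 1)/(μ_ctrl +
1))`, antisymmetric under group swap. Group dispersions are sample
standard deviations (n−1); a singleton group reports sd 0.

Novel vs annotated is decided structurally — a gene id absent from the
supplied gene models is novel — so the reports work regardless of which
assembler produced the ids.

The CNV report emits one row per (gene, containing segment); the cytoband
column joins the sorted names of all bands the segment overlaps with ";",
since a single segment frequently spans several bands.

## EDA

Quartiles use linear interpolation (type 7). Violin densities are Gaussian
KDEs of `log2(count + 1)` on a fixed 512-point grid padded by three
bandwidths (so the numerical integral is ≈1); a constant sample degenerates
to a narrow Gaussian spike rather than failing.

PCA input is `log2(normalized + 1)` with genes centered and **not**
unit-scaled (the common RNA-seq convention), decomposed by SVD. Variance
fractions are `σ_k²/Σσ²` of the full spectrum, so they sum to 1 over all
components. Signs are fixed by making the largest-magnitude gene loading
of each component positive — scores are then fully determined, which the
byte-level reproducibility gate requires.

Top-variable genes are ranked by variance of the log-transformed
normalized counts, ties broken by gene id. Hierarchical clustering is
agglomerative with Euclidean distance and average linkage (configurable);
the heatmap shows the top 20 genes as group means, z-scaled per row
(population sd; constant rows left at zero), with row/column orders taken
from clustering each axis.

## Cluster diagnostics

The k-means implementation is self-contained: k-means++ seeding, Lloyd
iterations with ties broken to the lowest cluster index, empty clusters
re-seated on the worst-fit point, convergence at 1e-8 relative inertia
change (300-iteration cap), best of `n_init = 10` restarts by inertia,
first winner on ties. All randomness flows from one seed, making fits
bit-reproducible — a hard contract here, because the clustering artifacts
participate in the checksum comparison gate. (scikit-learn's k-means is
used in the test suite as an independent cross-check, not in the
implementation.)

The clustergram's vertical axis is the projection of each cluster centroid
onto the first principal component of the full data ("PCA-weighted mean"
is interpreted as exactly this), node size is cluster cardinality
("amount of information" interpreted as membership count), and edge
weights count observations moving between clusters of consecutive k fits.
Both interpretations are fixed and documented because the source phrases
admit alternatives.

Silhouette uses mean intra-cluster distance excluding self for `a_i`, the
minimum mean distance to any other cluster for `b_i`, and assigns 0 to
singleton-cluster members by convention. `suggest_k` maximizes the overall
mean silhouette over the candidate range, preferring the smaller k on
ties.

## Circos tracks

The six tracks are assembled purely from database queries — nothing is
re-called. The DNA panel track is somatic-filtered by default (`FILTER ==
PASS` and vaf > 0), reflecting the tumor-vs-germline reading of a panel
run; the RNA track keeps every expressed variant. Expression is per-gene
TPM (not binned). Any feature beyond its chromosome length is an error
naming the feature. Exports are BED (points and segments) and BEDPE
(fusion links) plus a `chrom.sizes` ideogram, all byte-deterministic.

## Synthetic study generator

Defaults describe the reference study: 3 tissue types × 3 replicates → 21
assay runs (9 RNA-seq, 9 low-pass CNV, 3 DNA panel, one per tissue), 500
genes with 1–3 isoforms each on a 5-chromosome miniature genome (66 Mb),
20% of genes differential between T1 and {T2, T3} with |log2FC| drawn
uniform [2, 4] and random sign, NB dispersion 0.1, log-normal library-size
factors (sd 0.15), 30 panel mutations per panel sample with Beta(2, 6)
allele fractions (half re-emitted as RNA-expressed calls), 12 CNV segments
per sample tiling the genome with copy numbers {1, 3, 4, 5} on non-neutral
segments and `logR = log2(cn/2) + N(0, 0.05)`, and 5 fusions per RNA
sample drawn from annotated gene pairs. Ten percent of genes are withheld
from the GTF fixture and renamed `MSTRG.*`-style to exercise the
novel-gene path. Gene counts are drawn at the gene level and split
multinomially across isoforms, so the roll-up identity is exact by
construction.

Randomness: every stage (genome layout, counts, CNV, mutations, fusions)
draws from its own `SeedSequence([seed, stage])` stream, so adding a stage
never perturbs earlier output, and a fixed seed reproduces the file tree
byte-for-byte.

What it does *not* emulate: read-level artifacts (no FastQ/BAM), GC or
length biases, between-isoform switching, sample contamination, germline
CNV, and the long-tailed mutation spectra of real panels. Passing tests
therefore demonstrate that the machinery is correct and reproducible under
a faithful NB study model — not that the simple t-test matches shrinkage
estimators on real, messier data.

## Reproducibility harness

`render_all_reports` refuses to run on a database that fails the integrity
audit, then renders the eleven-analysis suite with canonical
serialization: sorted rows, fixed column order, LF/UTF-8, and floats
written with Python's shortest round-trip `repr`. Equal computations thus
yield equal bytes, and runs are compared by SHA-256 per artifact —
stricter and more automatable than visual comparison of rendered plots.
Images are deliberately absent from the contract (font and rasterizer
variance would break byte equality without informational gain); the data
artifacts behind any plot are the comparison unit. The manifest records
tool version, seed, config hash, input checksums and environment, so an
Identical matrix certifies that two runs computed the same thing from the
same inputs. ETL-derived artifacts are seed-independent; only the
clustering family consumes the seed.

## Problem sizes

The default study (500 genes × 9 samples, 21 assays) keeps every
end-to-end path — generation, ETL, reporting, 100-seed k-recovery,
50-simulation DGE recovery — in seconds on one CPU, while remaining large
enough that normalization, multiple testing and cluster selection behave
like they do at scale. All sizes are configuration, not constants.

## Known limitations

Single-writer SQLite semantics (no concurrency guarantees); no schema
migration; autosome-only diploid CNV convention; unstranded annotation;
the t-test's reduced power on lowly-expressed genes relative to NB
shrinkage models; VCF INFO fields other than DP/GENE are dropped on
import.
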