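# genovault

**Portable study store and reproducible downstream analysis suite for
multi-omic NGS pipeline outputs.**

Downstream (post-pipeline) genomic analysis is where collaboration breaks:
the upstream pipelines emit a zoo of per-assay files — VCFs from a targeted
DNA panel, expressed-mutation VCFs from RNA-seq, ichorCNA-style copy-number
segment tables, StringTie/Ballgown count matrices, STAR-Fusion tables — and
every collaborator re-assembles them ad hoc, so results rarely reproduce
bit-for-bit across machines. genovault addresses this for study-scale
multi-omic data (bulk transcriptomics + panel DNA + low-pass CNV):

1. **ETL** parses the upstream dialects into typed records, writes them as
   auditable structured CSV, and imports them into a **single-file SQLite
   database** with a fixed relational schema (study metadata + seven result
   tables linked by primary/foreign keys). The file travels with the study
   and any SQLite client can query it.
2. A **typed query API** (`query_table`, equality predicates, total
   deterministic ordering) is the only interface between analyses and data,
   with `check_integrity` auditing orphans, duplicate keys and per-row
   invariants.
3. A **deterministic report suite** renders eleven analyses — circos
   tracks, novel/annotated differential-expression tables, CNV gene
   report, violin/box count summaries, PCA, hierarchical clustering with
   heatmap, clustergram, silhouette table, and k-means runs — as
   canonical-form CSV/JSON artifacts, and a **reproducibility harness**
   compares two runs checksum-by-checksum into an
   Identical/Different/Missing matrix.

## The statistics at the core

- **Normalization** — median-of-ratios size factors:
  `s_j = median_i ( k_ij / (∏_v k_iv)^(1/m) )` over genes with a positive
  geometric mean; normalized counts are `k_ij / s_j`.
- **Differential expression** — per-gene two-sample t on
  `log2(normalized + 1)` (pooled variance by default, Welch optional) with
  Benjamini–Hochberg adjustment; reports carry `log2FC = log2((μ_case +
  1)/(μ_ctrl + 1))` plus per-group mean/sd over replicates. Novel genes
  (absent from the gene models) are reported with their nearest annotated
  gene by signed endpoint-gap distance.
- **Copy number** — segments carry `logR = log2(tumor/germline)` and a
  diploid-convention call (cn > 2 amplification, = 2 normal, < 2
  deletion), annotated one-to-many with overlapping genes and cytobands.
- **Cluster diagnostics** — self-contained k-means (k-means++ seeding,
  Lloyd to 1e-8 inertia tolerance, best of `n_init` restarts, fully
  seed-deterministic), silhouette `s(i) = (b_i − a_i)/max(a_i, b_i)`, a
  clustergram tracking PC1-projected centroids and observation flow across
  k, and `suggest_k` = argmax mean silhouette (ties to smaller k).
- **Synthetic studies** — a first-class generator plants truth in the exact
  upstream dialects: negative-binomial counts
  `k_ij ~ NB(s_j · μ_i · 2^(β_i x_j), α)` with tissue T1 biologically
  distinct from T2/T3, planted CNV segments, mutations (a fraction
  re-expressed in RNA), and fusions, with a JSON truth table.

## Worked example

```sh
python examples/03_cluster_model_selection.py
```

builds a 21-experiment synthetic study (seed 42), loads it into a database
and runs model selection:

```
mean silhouette per k: {2: 0.519, 3: 0.187, 4: 0.185, 5: 0.011, 6: 0.009, 7: 0.009}
suggested k: 2
clustergram transitions (k, from, to) -> samples: {(1, 0, 1): 3, (1, 0, 0): 6, (2, 1, 0): 3, (2, 0, 1): 3, (2, 0, 2): 3}
k=2 membership: {'T1R1': 1, 'T1R2': 1, 'T1R3': 1, 'T2R1': 0, ...}
```

The silhouette peaks at k = 2 and the k = 2 fit isolates the three T1
replicates: although three tissue labels exist, T2 and T3 share expression
means, so two clusters is the right model — exactly the planted structure.
`examples/04_reproducibility_check.py` renders the full suite twice and
prints the per-analysis comparison (all eleven rows `Identical`); the other
examples cover database construction, differential expression and circos
track export.

A thin CLI wraps the same library calls:

```sh
genovault simulate --out study --seed 42
genovault etl --kind study --in study --db study.db
genovault report --db study.db --annotation-dir study/annotation --out run1
genovault compare run1/manifest.json run2/manifest.json
genovault circos --db study.db --sample T1R1 --annotation-dir study/annotation --out tracks
```

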