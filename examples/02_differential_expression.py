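"""Median-of-ratios normalization and the novel/annotated DGE reports.

Size factors make replicate libraries comparable; the per-gene t-test on
log2(normalized + 1) with Benjamini–Hochberg adjustment then contrasts
tissue T1 against T2+T3.  Genes absent from the gene models are reported
separately as "novel", each with its nearest annotated gene.
"""

import tempfile
from pathlib import Path

from genovault import annotation as ann
from genovault import etl, expression
from genovault.synthetic import StudyConfig, write_study

workdir = Path(tempfile.mkdtemp(prefix="genovault_example_"))
write_study(StudyConfig(seed=42), workdir / "study")
db = etl.etl_study(workdir / "study", workdir / "study.db")

raw = expression.matrix_from_db(db, "gene_counts")
factors = expression.size_factors(raw)
print("size factors:",
      {s: round(f, 3) for s, f in factors.items()})

gene_models = ann.read_gene_models(workdir / "study/annotation/genes.gtf")
novel, annotated = expression.build_dge_report(
    db, case="T1", control=["T2", "T3"], gene_models=gene_models
)
print(f"{len(annotated)} annotated genes, {len(novel)} novel genes tested")
hits = [r for r in annotated + novel if r.adj_p < 0.05]
print(f"significant at BH 0.05: {len(hits)}")
top = min(hits, key=lambda r: (r.adj_p, r.gene_id))
print(f"top hit: {top.gene_id} ({top.gene_symbol}) log2FC={top.log2_fc:.2f} "
      f"adj_p={top.adj_p:.2e}")
# A positive log2FC means higher expression in T1 than in the pooled
# T2/T3 control group, on the normalized scale.
db.close()
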