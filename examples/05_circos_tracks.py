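"""Export the six concentric circos tracks for one sample.

Tracks (outermost inward): chromosome ideogram, DNA panel mutations,
RNA-expressed mutations, CNV segments, per-gene expression (TPM), and
gene-fusion links.  Files are BED/BEDPE (0-based half-open), ready for any
circos-style renderer.
"""

import tempfile
from pathlib import Path

from genovault import annotation as ann
from genovault import circos, etl
from genovault.synthetic import StudyConfig, write_study

workdir = Path(tempfile.mkdtemp(prefix="genovault_example_"))
write_study(StudyConfig(seed=42), workdir / "study")
db = etl.etl_study(workdir / "study", workdir / "study.db")

ann_dir = workdir / "study/annotation"
gene_models = ann.read_gene_models(ann_dir / "genes.gtf")
chrom_sizes = ann.read_chrom_sizes(ann_dir / "chrom.sizes")
lengths = {g.gene_id: (g.end - g.start + 1) / 1000.0 for g in gene_models}

tracks = circos.build_track_set(db, "T1R1", gene_models, lengths, chrom_sizes)
print(f"dna mutations: {len(tracks.dna_mutations)}  "
      f"rna mutations: {len(tracks.rna_mutations)}  "
      f"cnv segments: {len(tracks.cnv)}  "
      f"expression genes: {len(tracks.expression)}  "
      f"fusion links: {len(tracks.fusions)}")

files = circos.export_tracks(tracks, workdir / "tracks")
for name, path in files.items():
    first = path.read_text().splitlines()[:1]
    print(f"{name}: {path.name}  e.g. {first[0] if first else '(empty)'}")
# CNV rows carry the median log2 tumor/germline ratio and the
# amplification/normal/deletion call; fusion BEDPE rows pair the two
# breakpoints with their read support.
db.close()
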