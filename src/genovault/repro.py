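"""Deterministic report rendering, run manifests, and cross-run comparison.

``render_all_reports`` produces the full eleven-analysis suite — circos
tracks, novel/annotated differential-expression tables, CNV report, violin
and box summaries, PCA, hierarchical clustering with heatmap, clustergram,
silhouette table, and the k=2/k=3 k-means runs — as canonical-form CSV/JSON
artifacts, and records everything about the run (inputs, seed, config hash,
artifact checksums, environment) in a manifest.

Canonical form means: UTF-8, LF, fixed column order, deterministic row
order, and floating-point values serialized with Python's shortest
round-trip ``repr`` — so equal computations yield equal bytes, and two runs
can be compared by checksum alone.  This is deliberately stricter than
comparing rendered plots by eye: byte equality of the data artifacts is
automatable and transitive across platforms.  Images, were any rendered,
would sit outside the checksum gate (font and rasterizer variance); the
data artifacts are the contract.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
import platform
from dataclasses import asdict, dataclass, field as dc_field, fields as dc_fields
from pathlib import Path

import numpy as np

from . import __version__
from . import annotation as ann
from . import circos, cluster, datastore, eda, expression
from .datastore import StudyDatabase
from .etl import format_value


class ReproError(Exception):
    pass


ANALYSIS_NAMES = (
    "rcircos_tracks",
    "dge_novel",
    "dge_annotated",
    "cnv_report",
    "violin",
    "box",
    "pca",
    "hca_heatmap",
    "clustergram",
    "silhouette",
    "kmeans",
)


@dataclass
class ReportConfig:
    """Declarative description of one report run."""

    annotation_dir: str               # fixtures: genes.gtf, cytobands.tsv, chrom.sizes
    case_group: str = "T1"
    control_groups: tuple[str, ...] = ("T2", "T3")
    n_top_genes: int = 20
    suggest_k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    clustergram_k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    kmeans_ks: tuple[int, ...] = (2, 3)
    n_init: int = 10
    pseudocount: float = 1.0
    report_sample: str = "T1R1"       # sample for the CNV report and circos

    def canonical_json(self) -> str:
        d = asdict(self)
        d["annotation_dir"] = str(Path(self.annotation_dir).name)
        return json.dumps(d, sort_keys=True, separators=(",", ":"))

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


@dataclass
class RunManifest:
    tool: str
    version: str
    seed: int
    config_hash: str
    inputs: dict[str, str]            # name -> sha256
    artifacts: dict[str, str]         # analysis name -> sha256
    environment: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        d = json.loads(text)
        return cls(**{f.name: d[f.name] for f in dc_fields(cls)})

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_bytes((self.to_json() + "\n").encode("utf-8"))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


@dataclass
class ComparisonMatrix:
    """Per-analysis verdicts comparing two runs (Identical/Different/Missing)."""

    rows: list[dict] = dc_field(default_factory=list)

    @property
    def passed(self) -> bool:
        return bool(self.rows) and all(
            r["verdict"] == "Identical" for r in self.rows
        )


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_canonical_json(obj, path: Path) -> Path:
    text = json.dumps(_jsonable(obj), sort_keys=True, separators=(",", ":"))
    path.write_bytes((text + "\n").encode("utf-8"))
    return path


def write_rows_csv(rows, columns, path: Path) -> Path:
    """Canonical CSV from dataclass instances or dicts, given column order."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(columns)
    for row in rows:
        get = row.get if isinstance(row, dict) else lambda c: getattr(row, c)
        writer.writerow([
            "" if (v := get(c)) is None else format_value(v) for c in columns
        ])
    path.write_bytes(buf.getvalue().encode("utf-8"))
    return path


def render_all_reports(
    db: StudyDatabase,
    config: ReportConfig,
    seed: int,
    out_dir: str | Path,
) -> RunManifest:
    """Render the eleven-analysis suite into ``out_dir`` and manifest it.

    Aborts before rendering anything if the database fails its integrity
    audit.  The result is a pure function of (database contents, config,
    seed).
    """
    report = datastore.check_integrity(db)
    if not report.passed:
        raise ReproError(
            "database failed integrity check; refusing to render "
            f"(orphans={len(report.orphan_rows)}, "
            f"duplicates={len(report.duplicate_keys)}, "
            f"violations={len(report.invariant_violations)})"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann_dir = Path(config.annotation_dir)
    gene_models = ann.read_gene_models(ann_dir / "genes.gtf")
    chrom_sizes = ann.read_chrom_sizes(ann_dir / "chrom.sizes")
    gene_lengths = {
        g.gene_id: (g.end - g.start + 1) / 1000.0 for g in gene_models
    }

    raw = expression.matrix_from_db(db, "gene_counts")
    factors = expression.size_factors(raw)
    norm = expression.normalize_counts(raw, factors)
    logm = eda.log_transform(norm)
    X = logm.to_numpy(dtype=float).T  # samples × genes
    n_samples = X.shape[0]
    groups = sorted(set(norm.groups.values()))

    artifacts: dict[str, Path] = {}

    # i. circos track set
    tracks = circos.build_track_set(
        db, config.report_sample, gene_models, gene_lengths, chrom_sizes
    )
    track_payload = {
        "sample": config.report_sample,
        "ideogram": tracks.ideogram,
        "dna_mutations": [asdict(f) for f in tracks.dna_mutations],
        "rna_mutations": [asdict(f) for f in tracks.rna_mutations],
        "cnv": [asdict(f) for f in tracks.cnv],
        "expression": [asdict(f) for f in tracks.expression],
        "fusions": [asdict(f) for f in tracks.fusions],
        "notices": tracks.notices,
    }
    artifacts["rcircos_tracks"] = write_canonical_json(
        track_payload, out_dir / "rcircos_tracks.json"
    )

    # ii/iii. differential expression, novel and annotated
    novel, annotated = expression.build_dge_report(
        db, config.case_group, list(config.control_groups), gene_models,
        pseudocount=config.pseudocount,
    )
    dge_cols = [f.name for f in dc_fields(expression.DgeRow)]
    artifacts["dge_novel"] = write_rows_csv(
        novel, dge_cols, out_dir / "dge_novel.csv"
    )
    artifacts["dge_annotated"] = write_rows_csv(
        annotated, dge_cols, out_dir / "dge_annotated.csv"
    )

    # iv. CNV gene report
    cnv_rows = expression.build_cnv_report(db, config.report_sample)
    cnv_cols = [f.name for f in dc_fields(expression.CnvReportRow)]
    artifacts["cnv_report"] = write_rows_csv(
        cnv_rows, cnv_cols, out_dir / "cnv_report.csv"
    )

    # v/vi. count distribution: violin (densities) and box (quartiles)
    summary = eda.count_distribution_summary(raw)
    artifacts["violin"] = write_canonical_json(
        summary, out_dir / "violin.json"
    )
    box_rows = [
        {"sample_id": s, **{k: summary[s][k]
                            for k in ("min", "q1", "median", "q3", "max")}}
        for s in sorted(summary)
    ]
    artifacts["box"] = write_rows_csv(
        box_rows, ["sample_id", "min", "q1", "median", "q3", "max"],
        out_dir / "box.csv",
    )

    # vii. PCA
    pca_res = eda.pca(norm)
    artifacts["pca"] = write_canonical_json(
        {
            "samples": pca_res.scores.index.tolist(),
            "components": pca_res.scores.columns.tolist(),
            "scores": pca_res.scores.to_numpy(),
            "variance_explained": pca_res.variance_explained,
            "groups": {s: norm.groups.get(s, "") for s in norm.sample_ids},
        },
        out_dir / "pca.json",
    )

    # viii. HCA heatmap of group-mean normalized counts
    n_top = min(config.n_top_genes, norm.data.shape[0])
    heat = eda.heatmap_matrix(norm, groups, n_top=n_top)
    sample_tree = eda.hierarchical_cluster(logm, axis="samples")
    artifacts["hca_heatmap"] = write_canonical_json(
        {
            "rows": heat["row_order"],
            "cols": heat["col_order"],
            "values": heat["matrix"].to_numpy(),
            "sample_leaf_order": sample_tree.leaves(),
            "sample_merge_heights": sorted(sample_tree.merge_heights()),
        },
        out_dir / "hca_heatmap.json",
    )

    # ix. clustergram across k
    cg_range = [k for k in config.clustergram_k_range if k <= n_samples]
    cg = cluster.clustergram(X, cg_range, seed=seed, n_init=config.n_init)
    artifacts["clustergram"] = write_canonical_json(
        {
            "k_range": cg.k_range,
            "nodes": {
                f"{k}:{c}": v for (k, c), v in sorted(cg.nodes.items())
            },
            "edges": {
                f"{k}:{a}->{b}": n
                for (k, a, b), n in sorted(cg.edges.items())
            },
        },
        out_dir / "clustergram.json",
    )

    # x. silhouette model-selection table
    sk_range = [k for k in config.suggest_k_range if 2 <= k <= n_samples - 1]
    sk = cluster.suggest_k(X, sk_range, seed=seed, n_init=config.n_init)
    sil_rows = [
        {"k": k, "mean_silhouette": sk["scores"][k],
         "is_best": k == sk["k_best"]}
        for k in sorted(sk["scores"])
    ]
    artifacts["silhouette"] = write_rows_csv(
        sil_rows, ["k", "mean_silhouette", "is_best"],
        out_dir / "silhouette.csv",
    )

    # xi. the two k-means runs
    kmeans_payload = {}
    axis, mean = cluster._pc1_axis(X)
    for k in config.kmeans_ks:
        if k > n_samples:
            continue
        fit = cluster.kmeans(X, k, seed=seed, n_init=config.n_init)
        kmeans_payload[str(k)] = {
            "labels": {
                s: int(l) for s, l in zip(norm.sample_ids, fit.labels)
            },
            "inertia": fit.inertia,
            "sizes": np.bincount(fit.labels, minlength=k),
            "center_pc1": (fit.centers - mean) @ axis,
        }
    artifacts["kmeans"] = write_canonical_json(
        kmeans_payload, out_dir / "kmeans.json"
    )

    inputs = {"database": sha256_file(db.path)}
    for fixture in ("genes.gtf", "cytobands.tsv", "chrom.sizes"):
        p = ann_dir / fixture
        if p.exists():
            inputs[fixture] = sha256_file(p)
    manifest = RunManifest(
        tool="genovault",
        version=__version__,
        seed=int(seed),
        config_hash=config.hash(),
        inputs=inputs,
        artifacts={name: sha256_file(artifacts[name])
                   for name in ANALYSIS_NAMES},
        environment={
            "os": platform.system(),
            "python": platform.python_version(),
        },
    )
    manifest.save(out_dir / "manifest.json")
    return manifest


def compare_runs(
    manifest_a: RunManifest, manifest_b: RunManifest
) -> ComparisonMatrix:
    """Table-style comparison of two runs by artifact checksum.

    Verdict per analysis: Identical (equal checksums), Different, or
    Missing (absent from either run).  ``passed`` is true only when every
    row is Identical.
    """
    names = sorted(set(manifest_a.artifacts) | set(manifest_b.artifacts))
    matrix = ComparisonMatrix()
    for name in names:
        a = manifest_a.artifacts.get(name)
        b = manifest_b.artifacts.get(name)
        if a is None or b is None:
            verdict = "Missing"
        elif a == b:
            verdict = "Identical"
        else:
            verdict = "Different"
        matrix.rows.append({
            "name": name,
            "run_a": "Passed" if a is not None else "Missing",
            "run_b": "Passed" if b is not None else "Missing",
            "verdict": verdict,
        })
    return matrix
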