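"""Exploratory data analysis: count distributions, PCA, variable genes, HCA.

Every artifact here is a deterministic function of its inputs.  The PCA
convention: input is log2(normalized + 1) with genes centered, decomposed
by SVD; variance fractions are singular values squared over the total, and
each component's sign is fixed so its largest-magnitude gene loading is
positive.  Hierarchical clustering is agglomerative with Euclidean distance
and average linkage by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .expression import CountMatrix, ExpressionError


class EdaError(Exception):
    pass


DENSITY_GRID_POINTS = 512


def count_distribution_summary(matrix: CountMatrix) -> dict[str, dict]:
    """Per-sample five-number summary plus a kernel density of log2(count+1).

    Quartiles use linear interpolation (type 7).  The density is a Gaussian
    KDE evaluated on a fixed 512-point grid spanning the sample's
    log-transformed range padded by three bandwidths, so it integrates to
    ~1; a constant sample degenerates to a narrow Gaussian spike.
    """
    if matrix.data.shape[0] < 1:
        raise EdaError("empty count matrix")
    out: dict[str, dict] = {}
    for sample in matrix.sample_ids:
        values = matrix.data[sample].to_numpy(dtype=float)
        q = np.percentile(values, [0, 25, 50, 75, 100])
        logv = np.log2(values + 1.0)
        if np.ptp(logv) == 0:
            bw = 1e-3
            center = float(logv[0])
            grid = np.linspace(center - 6 * bw, center + 6 * bw,
                               DENSITY_GRID_POINTS)
            density = stats.norm.pdf(grid, loc=center, scale=bw)
        else:
            kde = stats.gaussian_kde(logv)
            bw = kde.factor * logv.std(ddof=1)
            grid = np.linspace(logv.min() - 3 * bw, logv.max() + 3 * bw,
                               DENSITY_GRID_POINTS)
            density = kde(grid)
        out[sample] = {
            "min": float(q[0]),
            "q1": float(q[1]),
            "median": float(q[2]),
            "q3": float(q[3]),
            "max": float(q[4]),
            "density_grid": grid.tolist(),
            "density": density.tolist(),
        }
    return out


@dataclass
class PcaResult:
    """Sample scores, gene loadings and per-component variance fractions."""

    scores: pd.DataFrame      # samples × components
    loadings: pd.DataFrame    # genes × components
    variance_explained: np.ndarray  # fraction of total variance, per component


def log_transform(matrix: CountMatrix) -> pd.DataFrame:
    """log2(x + 1) of a (normalized) count matrix, genes × samples."""
    return np.log2(matrix.data + 1.0)


def pca(matrix: CountMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples on log2(normalized + 1), gene-centered, via SVD.

    ``variance_explained`` entries are fractions of the *total* variance,
    so over all components they sum to 1.
    """
    if matrix.data.shape[1] < 2:
        raise EdaError("PCA needs at least 2 samples")
    X = log_transform(matrix).to_numpy(dtype=float).T  # samples × genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((S ** 2).sum())
    frac = (S ** 2) / total if total > 0 else np.zeros_like(S)
    k = len(S) if n_components is None else min(n_components, len(S))
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    # sign convention: the largest-|loading| gene of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comps = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comps),
        loadings=pd.DataFrame(loadings, index=matrix.gene_ids, columns=comps),
        variance_explained=frac[:k],
    )


def top_variable_genes(matrix: CountMatrix, n: int = 20) -> list[str]:
    """Gene ids ranked by variance of log2(normalized+1), descending.

    Ties break by ascending gene_id so the ranking is total.
    """
    if n <= 0:
        raise EdaError(f"n must be positive, got {n}")
    if n > matrix.data.shape[0]:
        raise EdaError(
            f"n={n} exceeds gene count {matrix.data.shape[0]}"
        )
    var = log_transform(matrix).var(axis=1, ddof=1)
    order = sorted(matrix.gene_ids, key=lambda g: (-var.loc[g], g))
    return order[:n]


@dataclass
class DendrogramNode:
    """Binary merge tree; leaves carry an item label, internal nodes a height."""

    merge_height: float
    children: tuple["DendrogramNode", "DendrogramNode"] | None
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.children[0].leaves() + self.children[1].leaves()

    def merge_heights(self) -> list[float]:
        if self.is_leaf:
            return []
        return (
            self.children[0].merge_heights()
            + self.children[1].merge_heights()
            + [self.merge_height]
        )


def hierarchical_cluster(
    data: pd.DataFrame,
    axis: str = "samples",
    method: str = "average",
) -> DendrogramNode:
    """Agglomerative clustering of rows (genes) or columns (samples).

    Euclidean distance, average linkage by default; merge heights are
    non-decreasing for the supported (reducible) linkages.  Input is the
    already-transformed matrix (callers pass log2(normalized+1)).
    """
    X = data.T if axis == "samples" else data
    labels = list(X.index)
    if len(labels) < 2:
        raise EdaError(f"need at least 2 items on axis {axis!r}")
    Z = hierarchy.linkage(X.to_numpy(dtype=float), method=method,
                          metric="euclidean")
    tree = hierarchy.to_tree(Z)

    def convert(node) -> DendrogramNode:
        if node.is_leaf():
            return DendrogramNode(0.0, None, labels[node.id])
        return DendrogramNode(
            float(node.dist),
            (convert(node.get_left()), convert(node.get_right())),
        )

    return convert(tree)


def heatmap_matrix(
    matrix: CountMatrix,
    group_labels: Sequence[str],
    n_top: int = 20,
) -> dict:
    """Row-scaled group-mean matrix of the top variable genes, with HCA orders.

    Rows are ``top_variable_genes(n_top)`` of the normalized matrix; cells
    are group means of log2(normalized+1), z-scaled per row (population sd);
    row and column orders come from hierarchical clustering of each axis.
    """
    if n_top > matrix.data.shape[0]:
        raise EdaError(f"n_top={n_top} exceeds gene count")
    genes = top_variable_genes(matrix, n_top)
    logm = log_transform(matrix)
    cols = {}
    for label in group_labels:
        samples = matrix.samples_in_group(label)
        if not samples:
            raise ExpressionError(f"unknown or empty group {label!r}")
        cols[label] = logm[samples].mean(axis=1)
    mean_matrix = pd.DataFrame(cols).loc[genes]
    centered = mean_matrix.sub(mean_matrix.mean(axis=1), axis=0)
    sd = mean_matrix.std(axis=1, ddof=0).replace(0, 1.0)
    scaled = centered.div(sd, axis=0)
    row_tree = hierarchical_cluster(scaled, axis="genes")
    col_tree = hierarchical_cluster(scaled, axis="samples")
    row_order = row_tree.leaves()
    col_order = col_tree.leaves()
    return {
        "matrix": scaled.loc[row_order, col_order],
        "row_order": row_order,
        "col_order": col_order,
        "row_tree": row_tree,
        "col_tree": col_tree,
    }
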