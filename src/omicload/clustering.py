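"""Hierarchical bicluster ordering of genes and samples for heatmap views.

Rows and columns are clustered independently (agglomerative, scipy linkage)
and each tree is flattened to a leaf order by a deterministic traversal:
at every merge the smaller child cluster is visited first, ties broken by
the lexicographically smallest label inside each child.  The order is
therefore a pure function of the data and labels — permuting the input rows
reproduces the same leaf sequence of gene ids.  Distance-minimizing
("optimal") leaf ordering is available behind a flag for presentation use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import AnnotationError, ValidationError
from .matrix_io import BaseMatrix, PathwayAnnotation
from .preprocessing import StandardizedMatrix

METRICS = ("euclidean", "correlation")
METHODS = ("average", "complete", "ward")


@dataclass
class ClusterHeatmapResult:
    """Row/column orders and merge trees from :func:`bicluster`.

    ``row_order``/``col_order`` are permutations of the input indices;
    ``row_linkage``/``col_linkage`` are scipy linkage matrices (child ids,
    merge height, cluster size per row).
    """

    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    metric: str
    method: str
    row_labels: list[str]
    col_labels: list[str]

    @property
    def ordered_gene_ids(self) -> list[str]:
        return [self.row_labels[i] for i in self.row_order]

    @property
    def ordered_sample_ids(self) -> list[str]:
        return [self.col_labels[i] for i in self.col_order]


def _deterministic_leaf_order(linkage: np.ndarray, labels: list[str]) -> list[int]:
    """Flatten a linkage tree: smaller cluster first, then smallest label."""
    n = linkage.shape[0] + 1
    size: dict[int, int] = {i: 1 for i in range(n)}
    min_label: dict[int, str] = {i: labels[i] for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for row, (a, b, _h, _s) in enumerate(linkage):
        node = n + row
        a, b = int(a), int(b)
        children[node] = (a, b)
        size[node] = size[a] + size[b]
        min_label[node] = min(min_label[a], min_label[b])

    order: list[int] = []
    stack = [n + linkage.shape[0] - 1 if linkage.shape[0] else 0]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
            continue
        a, b = children[node]
        first, second = sorted((a, b), key=lambda c: (size[c], min_label[c]))
        # LIFO stack: push the later child first
        stack.append(second)
        stack.append(first)
    return order


def _cluster_axis(
    values: np.ndarray, labels: list[str], metric: str, method: str,
    optimal_leaf_order: bool,
) -> tuple[np.ndarray, list[int]]:
    dists = pdist(values, metric=metric)
    if metric == "correlation" and not np.all(np.isfinite(dists)):
        raise ValidationError(
            "correlation distance undefined for a constant row/column"
        )
    linkage = hierarchy.linkage(dists, method=method)
    if optimal_leaf_order:
        linkage = hierarchy.optimal_leaf_ordering(linkage, dists)
        order = hierarchy.leaves_list(linkage).tolist()
    else:
        order = _deterministic_leaf_order(linkage, labels)
    return linkage, order


def bicluster(
    matrix: BaseMatrix,
    metric: str = "euclidean",
    method: str = "average",
    optimal_leaf_order: bool = False,
) -> ClusterHeatmapResult:
    """Cluster genes and samples independently and return both orderings.

    Defaults (euclidean distance, average linkage) are robust general-purpose
    choices; ward linkage requires euclidean distances.
    """
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}, got {metric!r}")
    if method not in METHODS:
        raise ValidationError(f"method must be one of {METHODS}, got {method!r}")
    if method == "ward" and metric != "euclidean":
        raise ValidationError("ward linkage requires the euclidean metric")
    if matrix.n_genes < 2 or matrix.n_samples < 2:
        raise ValidationError("bicluster needs at least 2 rows and 2 columns")
    if not np.all(np.isfinite(matrix.values)):
        raise ValidationError("matrix contains non-finite values")

    row_linkage, row_order = _cluster_axis(
        matrix.values, matrix.gene_ids, metric, method, optimal_leaf_order
    )
    col_linkage, col_order = _cluster_axis(
        matrix.values.T, matrix.sample_ids, metric, method, optimal_leaf_order
    )
    return ClusterHeatmapResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_linkage,
        col_linkage=col_linkage,
        metric=metric,
        method=method,
        row_labels=list(matrix.gene_ids),
        col_labels=list(matrix.sample_ids),
    )


def subset_heatmap(
    matrix: StandardizedMatrix, annotation: PathwayAnnotation, pathway_id: str
) -> StandardizedMatrix:
    """Restrict a standardized matrix to one pathway's genes.

    The subset keeps the z-values of the full matrix (its columns are no
    longer mean-0/sd-1 — deliberately, so heatmap colours stay comparable to
    the full data) and is ready for :func:`bicluster`.
    """
    members = set(annotation.genes_for(pathway_id))
    keep = [i for i, g in enumerate(matrix.gene_ids) if g in members]
    if not keep:
        raise AnnotationError(
            f"no member of pathway {pathway_id!r} is present in the matrix"
        )
    return StandardizedMatrix(
        gene_ids=[matrix.gene_ids[i] for i in keep],
        samples=matrix.samples,
        values=matrix.values[keep, :],
        column_stats=getattr(matrix, "column_stats", None),
        transform=getattr(matrix, "transform", "none"),
        validate_columns=False,
    )


def plot_heatmap(
    matrix: BaseMatrix, result: ClusterHeatmapResult, path, cmap: str = "RdBu_r"
) -> None:
    """Render the reordered matrix to a static image file (PNG/PDF/SVG)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    data = matrix.values[np.ix_(result.row_order, result.col_order)]
    height = max(2.0, min(12.0, 0.12 * data.shape[0] + 1.5))
    fig, ax = plt.subplots(figsize=(max(4.0, 0.5 * data.shape[1]), height))
    vmax = float(np.max(np.abs(data))) or 1.0
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(result.ordered_sample_ids, rotation=90, fontsize=7)
    if data.shape[0] <= 60:
        ax.set_yticks(range(data.shape[0]))
        ax.set_yticklabels(result.ordered_gene_ids, fontsize=6)
    else:
        ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.6, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
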