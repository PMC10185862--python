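"""Gene ranking by component loading, pathway scoring, and KEGG map overlays.

The enrichment statistic is deliberately simple: a pathway's score on a
component is the signed arithmetic mean of its member genes' loadings (gene
projections) on that component.  Pathways whose members moved coherently
along a component float to the top; incoherent pathways average toward
zero.  No null distribution is attached — the score is a ranking device,
not a hypothesis test.

Condition contrasts (e.g. LB20 - LB60 on the transcript layer) are binned
onto a fixed blue -> turquoise -> yellow -> orange -> red ramp for colouring
KEGG pathway maps, blue marking the most under-expressed genes and red the
most over-expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap, to_hex

from .decomposition import PCAResult
from .errors import AnnotationError, ValidationError
from .matrix_io import BaseMatrix, PathwayAnnotation

SCORE_MODES = ("signed_mean", "abs_mean")
CONTRAST_MODES = ("difference", "log2_ratio")


@dataclass
class GeneRanking:
    """Genes ordered by loading on one component (descending).

    Ties are broken lexicographically by gene id, so the order is total and
    reproducible.  ``entries`` columns: ``gene_id``, ``loading``.
    """

    component: int
    entries: pd.DataFrame
    tie_rule: str = "lexicographic"

    @property
    def gene_ids(self) -> list[str]:
        return self.entries["gene_id"].tolist()


@dataclass
class PathwayScoreTable:
    """Per-pathway mean loadings with ranks.

    ``table`` columns: ``pathway_id``, ``pathway_name``, ``n_genes``
    (members present in the matrix), ``score`` (signed mean loading),
    ``rank``.  ``mode`` records whether ranking used the signed score or its
    magnitude; the score itself is always the signed mean.
    """

    component: int
    mode: str
    min_size: int
    table: pd.DataFrame

    def rank_of(self, pathway_id: str) -> int:
        rows = self.table.loc[self.table["pathway_id"] == pathway_id, "rank"]
        if rows.empty:
            raise AnnotationError(f"pathway {pathway_id!r} not in score table")
        return int(rows.iloc[0])

    def score_of(self, pathway_id: str) -> float:
        rows = self.table.loc[self.table["pathway_id"] == pathway_id, "score"]
        if rows.empty:
            raise AnnotationError(f"pathway {pathway_id!r} not in score table")
        return float(rows.iloc[0])


@dataclass
class OverlayTable:
    """Per-gene contrast values binned to hex colours for map colouring.

    ``table`` columns: ``gene_id``, ``contrast_value``, ``bin``, ``colour``.
    Bin 0 is the blue (most under-expressed) end, the centre bin is neutral,
    the top bin red (most over-expressed).
    """

    table: pd.DataFrame
    n_bins: int
    clip: float
    palette: list[str]


def _gene_scores(pca, component: int) -> pd.Series:
    """1-based component -> per-gene loading Series (index = gene id)."""
    if isinstance(pca, PCAResult):
        col = pca.component_column(component)
        return pca.gene_scores[col]
    if isinstance(pca, pd.DataFrame):
        col = f"PC{int(component)}"
        if col not in pca.columns:
            raise ValidationError(f"gene-score table has no column {col!r}")
        return pca[col]
    raise ValidationError(f"expected PCAResult or DataFrame, got {type(pca).__name__}")


def rank_genes(pca, component: int) -> GeneRanking:
    """Order genes by descending loading on a component (1-based).

    Accepts a :class:`~omicload.decomposition.PCAResult` or a gene-scores
    DataFrame with ``PCk`` columns indexed by gene id.
    """
    scores = _gene_scores(pca, component)
    df = pd.DataFrame(
        {"gene_id": scores.index.astype(str), "loading": scores.to_numpy(float)}
    )
    df = df.sort_values(
        ["loading", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return GeneRanking(component=int(component), entries=df)


def top_k_annotation_fraction(
    ranking: GeneRanking,
    annotation: PathwayAnnotation,
    pathway_ids: Iterable[str],
    k: int,
) -> tuple[float, pd.DataFrame]:
    """Fraction of the top-k ranked genes annotated to any target pathway.

    Returns the fraction together with the k hit records (``gene_id``,
    ``loading``, ``annotated``, ``pathways`` — the matching target pathways,
    ';'-joined).
    """
    k = int(k)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(ranking.entries):
        raise ValidationError(
            f"k={k} exceeds the number of ranked genes ({len(ranking.entries)})"
        )
    targets = set(pathway_ids)
    members: dict[str, set[str]] = {}
    sub = annotation.records[annotation.records["pathway_id"].isin(targets)]
    for gid, grp in sub.groupby("gene_id"):
        members[str(gid)] = set(grp["pathway_id"])

    top = ranking.entries.head(k).copy()
    top["pathways"] = [
        ";".join(sorted(members.get(g, ()))) for g in top["gene_id"]
    ]
    top["annotated"] = top["pathways"] != ""
    fraction = float(top["annotated"].sum()) / k
    return fraction, top[["gene_id", "loading", "annotated", "pathways"]]


def score_pathways(
    pca,
    component: int,
    annotation: PathwayAnnotation,
    min_size: int = 3,
    mode: str = "signed_mean",
) -> PathwayScoreTable:
    """Score each pathway as the mean loading of its members on a component.

    Only members present in the analysed matrix count toward the mean and
    the size filter; pathways with fewer than ``min_size`` present members
    are excluded.  ``mode="signed_mean"`` ranks by descending score,
    ``mode="abs_mean"`` by descending ``|score|`` (the score column stays
    signed either way).  Genes in several pathways contribute fully to each.
    """
    if mode not in SCORE_MODES:
        raise ValidationError(f"mode must be one of {SCORE_MODES}, got {mode!r}")
    if int(min_size) < 1:
        raise ValidationError("min_size must be >= 1")
    scores = _gene_scores(pca, component)
    present = scores.to_dict()

    rows = []
    for pid, genes in annotation.gene_sets().items():
        loadings = [present[g] for g in genes if g in present]
        if len(loadings) < min_size:
            continue
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": annotation.pathway_name(pid),
                "n_genes": len(loadings),
                "score": float(np.mean(loadings)),
            }
        )
    if not rows:
        raise AnnotationError(
            f"no pathway has at least {min_size} member(s) present in the matrix"
        )
    table = pd.DataFrame(rows)
    key = table["score"] if mode == "signed_mean" else table["score"].abs()
    table = (
        table.assign(_key=-key)
        .sort_values(["_key", "pathway_id"], kind="mergesort")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return PathwayScoreTable(
        component=int(component), mode=mode, min_size=int(min_size), table=table
    )


def condition_contrast(
    matrix: BaseMatrix,
    cond_a: str,
    cond_b: str,
    layer: str = "transcript",
    mode: str = "difference",
) -> pd.Series:
    """Per-gene contrast between two conditions on one omic layer.

    ``difference`` subtracts the two columns as stored (intended for
    standardized values); ``log2_ratio`` computes ``log2((a+1)/(b+1))`` for
    raw abundances.  Result is antisymmetric in (a, b).
    """
    if mode not in CONTRAST_MODES:
        raise ValidationError(f"mode must be one of {CONTRAST_MODES}, got {mode!r}")
    ja = matrix.column_index(cond_a, layer)
    jb = matrix.column_index(cond_b, layer)
    a, b = matrix.values[:, ja], matrix.values[:, jb]
    if mode == "difference":
        vals = a - b
    else:
        if np.any(a < 0) or np.any(b < 0):
            raise ValidationError("log2_ratio mode requires non-negative abundances")
        vals = np.log2(a + 1.0) - np.log2(b + 1.0)
    return pd.Series(vals, index=pd.Index(matrix.gene_ids, name="gene"),
                     name=f"{cond_a}-{cond_b}")


#: anchors of the diverging overlay ramp, blue (under) to red (over)
OVERLAY_ANCHORS = ("#0000ff", "#40e0d0", "#ffff00", "#ffa500", "#ff0000")


def overlay_palette(n_bins: int) -> list[str]:
    """``n_bins`` hex colours sampled evenly from the fixed diverging ramp."""
    # high lookup resolution so the anchor colours are hit exactly
    cmap = LinearSegmentedColormap.from_list(
        "kegg_overlay", OVERLAY_ANCHORS, N=4097
    )
    return [to_hex(cmap(t)) for t in np.linspace(0.0, 1.0, n_bins)]


def bin_to_colours(
    contrasts: pd.Series, n_bins: int = 11, clip: float = 2.0
) -> OverlayTable:
    """Clip contrasts to ``[-clip, clip]`` and bin them onto the colour ramp.

    ``n_bins`` must be odd so a centre (neutral) bin exists; a contrast of
    exactly zero lands there, values at or beyond the clip land in the
    outermost bins, and negating every contrast mirrors the bins about the
    centre.
    """
    n_bins = int(n_bins)
    if n_bins < 3 or n_bins % 2 == 0:
        raise ValidationError(f"n_bins must be an odd integer >= 3, got {n_bins}")
    clip = float(clip)
    if not clip > 0:
        raise ValidationError(f"clip must be positive, got {clip}")
    vals = np.asarray(contrasts, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("contrast values must be finite")
    clipped = np.clip(vals, -clip, clip)
    # symmetric construction (offset from the centre bin computed on |v|) so
    # that negating the contrasts mirrors the bins exactly, ties included
    half = (n_bins - 1) // 2
    width = 2.0 * clip / n_bins
    offset = np.minimum(
        half, np.floor((np.abs(clipped) + width / 2.0) / width).astype(int)
    )
    bins = half + np.sign(clipped).astype(int) * offset
    palette = overlay_palette(n_bins)
    index = (
        contrasts.index.astype(str)
        if isinstance(contrasts, pd.Series)
        else pd.RangeIndex(len(vals)).astype(str)
    )
    table = pd.DataFrame(
        {
            "gene_id": index,
            "contrast_value": vals,
            "bin": bins,
            "colour": [palette[b] for b in bins],
        }
    )
    return OverlayTable(table=table, n_bins=n_bins, clip=clip, palette=palette)


def export_kegg_overlay(overlay: OverlayTable, path) -> None:
    """Write ``gene_id<TAB>#RRGGBB`` rows in the KEGG colour-mapper convention.

    The single header line starts with '#' so colour-mapping tools skip it.
    An empty overlay produces a header-only file and a warning.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#gene_id\tcolour\n")
        for row in overlay.table.itertuples(index=False):
            fh.write(f"{row.gene_id}\t{row.colour}\n")
    if len(overlay.table) == 0:
        warnings.warn(f"wrote empty overlay (header only) to {path}", stacklevel=2)
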