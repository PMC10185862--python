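"""PCA of the standardized genes x samples matrix and the A1/A2 layer rotation.

Orientation convention
----------------------
Genes are the observations, sample columns the features.  A full SVD of the
standardized grid ``Z = U S V^T`` yields

* ``sample_coordinates`` — the rows of ``V`` (unit-norm axis weights per
  sample), the points drawn when the 14 samples are plotted in PC space;
  a singular-value-scaled variant is exposed alongside;
* ``gene_scores`` — ``U S``, each gene's projection onto the axes; these are
  the per-gene "loadings" ranked and averaged downstream;
* ``variance_fraction`` — ``s_k^2 / sum_j s_j^2`` over the full spectrum.

Both readings of the ambiguous word "loading" therefore coexist: samples get
axis weights, genes get projections.

Sign convention: each component is flipped so the sample weight of largest
magnitude is positive, making repeated runs bit-identical.

A1/A2 rotation
--------------
Per condition ``i`` the standardized transcript/protein column pair is
replaced by the sum and difference columns ``A1_i = Zt_i + Zp_i`` and
``A2_i = Zt_i - Zp_i``.  A1 carries structure common to both layers; A2
isolates between-layer disagreement.  The map is a bijection:
``Zt = (A1 + A2)/2``, ``Zp = (A1 - A2)/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LayerPairingError, ValidationError
from .matrix_io import BaseMatrix, SampleDescriptor, sample_column_name
from .preprocessing import ColumnStats, StandardizedMatrix

ROTATED_LAYERS = ("A1", "A2")


class RotatedMatrix(BaseMatrix):
    """Standardized matrix re-expressed as per-condition A1/A2 columns.

    Carries the pre-rotation sample descriptors and column stats so
    :func:`invert_rotation` can restore the original labelling.
    """

    ALLOWED_LAYERS = ROTATED_LAYERS

    def __init__(
        self,
        gene_ids,
        samples,
        values,
        original_samples: list[SampleDescriptor] | None = None,
        original_stats: list[ColumnStats] | None = None,
        transform: str = "none",
    ):
        self.original_samples = list(original_samples) if original_samples else None
        self.original_stats = list(original_stats) if original_stats else None
        self.transform = transform
        super().__init__(gene_ids=gene_ids, samples=samples, values=values)
        per_cond: dict[str, set[str]] = {}
        for s in self.samples:
            per_cond.setdefault(s.condition, set()).add(s.layer)
        bad = sorted(c for c, layers in per_cond.items() if layers != set(ROTATED_LAYERS))
        if bad:
            raise LayerPairingError(
                f"conditions without exactly one A1 and one A2 column: {', '.join(bad)}"
            )


@dataclass
class PCAResult:
    """Outcome of :func:`run_pca`.

    ``sample_coordinates``/``scaled_sample_coordinates`` are samples x PCs
    DataFrames (unit axis weights, and weights scaled by singular values);
    ``gene_scores`` is genes x PCs.  Component columns are named ``PC1``… and
    component arguments throughout the package are 1-based.
    """

    singular_values: np.ndarray
    variance_fraction: np.ndarray
    sample_coordinates: pd.DataFrame
    gene_scores: pd.DataFrame
    n_components: int
    samples: list[SampleDescriptor] = field(default_factory=list)

    @property
    def scaled_sample_coordinates(self) -> pd.DataFrame:
        return self.sample_coordinates * self.singular_values

    def component_column(self, component: int) -> str:
        """Validate a 1-based component index and return its column name."""
        if not 1 <= int(component) <= self.n_components:
            raise ValidationError(
                f"component must be in 1..{self.n_components}, got {component}"
            )
        return f"PC{int(component)}"

    def coordinates_by_layer(self, component: int = 1) -> dict[str, np.ndarray]:
        """Sample weights on one component grouped by omic layer."""
        col = self.component_column(component)
        out: dict[str, list[float]] = {}
        for desc in self.samples:
            out.setdefault(desc.layer, []).append(
                float(self.sample_coordinates.loc[desc.sample_id, col])
            )
        return {k: np.asarray(v) for k, v in out.items()}


def run_pca(matrix: BaseMatrix, n_components: int | None = None) -> PCAResult:
    """Full-SVD principal component analysis of a genes x samples grid.

    ``variance_fraction`` is computed over the complete spectrum, so it sums
    to one when all ``min(n_genes, n_samples)`` components are retained.
    """
    z = matrix.values
    if not np.all(np.isfinite(z)):
        raise ValidationError("matrix contains non-finite values")
    rank_bound = min(z.shape)
    if n_components is None:
        n_components = rank_bound
    n_components = int(n_components)
    if not 1 <= n_components <= rank_bound:
        raise ValidationError(
            f"n_components must be in 1..{rank_bound}, got {n_components}"
        )

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # deterministic orientation: largest-|weight| sample positive per component
    for k in range(len(s)):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]

    total = float(np.sum(s**2))
    if total == 0.0:
        raise ValidationError("matrix is identically zero; PCA undefined")
    fractions = (s**2) / total

    cols = [f"PC{k + 1}" for k in range(n_components)]
    coords = pd.DataFrame(
        vt[:n_components].T, index=matrix.sample_ids, columns=cols
    )
    coords.index.name = "sample_id"
    scores = pd.DataFrame(
        u[:, :n_components] * s[:n_components], index=matrix.gene_ids, columns=cols
    )
    scores.index.name = "gene"
    return PCAResult(
        singular_values=s[:n_components].copy(),
        variance_fraction=fractions[:n_components].copy(),
        sample_coordinates=coords,
        gene_scores=scores,
        n_components=n_components,
        samples=list(matrix.samples),
    )


def rotate_layers(matrix: StandardizedMatrix) -> RotatedMatrix:
    """Replace each condition's transcript/protein pair by sum/difference columns.

    ``A1_i = Zt_i + Zp_i`` and ``A2_i = Zt_i - Zp_i`` for every condition
    ``i``; output columns are condition-major (A1 before A2).  Requires every
    condition to carry exactly one column of each layer.
    """
    per_cond: dict[str, dict[str, int]] = {}
    for j, s in enumerate(matrix.samples):
        per_cond.setdefault(s.condition, {})[s.layer] = j
    bad = sorted(
        c
        for c, layers in per_cond.items()
        if set(layers) != {"transcript", "protein"}
    )
    if bad:
        raise LayerPairingError(
            f"conditions without a transcript+protein pair: {', '.join(bad)}"
        )

    samples: list[SampleDescriptor] = []
    cols: list[np.ndarray] = []
    for cond in matrix.conditions:
        jt = per_cond[cond]["transcript"]
        jp = per_cond[cond]["protein"]
        zt, zp = matrix.values[:, jt], matrix.values[:, jp]
        samples.append(SampleDescriptor(f"{cond}_A1", cond, "A1"))
        cols.append(zt + zp)
        samples.append(SampleDescriptor(f"{cond}_A2", cond, "A2"))
        cols.append(zt - zp)
    return RotatedMatrix(
        gene_ids=matrix.gene_ids,
        samples=samples,
        values=np.column_stack(cols),
        original_samples=list(matrix.samples),
        original_stats=list(getattr(matrix, "column_stats", []) or []),
        transform=getattr(matrix, "transform", "none"),
    )


def invert_rotation(matrix: RotatedMatrix) -> StandardizedMatrix:
    """Algebraic inverse of :func:`rotate_layers`.

    ``Zt = (A1 + A2)/2`` and ``Zp = (A1 - A2)/2``; the pre-rotation sample
    labels (and column stats, when carried) are restored.
    """
    per_cond: dict[str, dict[str, int]] = {}
    for j, s in enumerate(matrix.samples):
        per_cond.setdefault(s.condition, {})[s.layer] = j

    orig_ids: dict[tuple[str, str], str] = {}
    if matrix.original_samples:
        orig_ids = {
            (s.condition, s.layer): s.sample_id for s in matrix.original_samples
        }

    samples: list[SampleDescriptor] = []
    cols: list[np.ndarray] = []
    for cond in matrix.conditions:
        a1 = matrix.values[:, per_cond[cond]["A1"]]
        a2 = matrix.values[:, per_cond[cond]["A2"]]
        for layer, col in (("transcript", (a1 + a2) / 2.0), ("protein", (a1 - a2) / 2.0)):
            sid = orig_ids.get((cond, layer), sample_column_name(cond, layer))
            samples.append(SampleDescriptor(sid, cond, layer))
            cols.append(col)

    stats = None
    if matrix.original_stats:
        by_id = {st.sample_id: st for st in matrix.original_stats}
        stats = [by_id[s.sample_id] for s in samples if s.sample_id in by_id] or None
    return StandardizedMatrix(
        gene_ids=matrix.gene_ids,
        samples=samples,
        values=np.column_stack(cols),
        column_stats=stats,
        transform=matrix.transform,
        validate_columns=False,
    )


def pca_on_rotated(
    matrix: RotatedMatrix,
    restandardize: bool = False,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of the A1/A2 matrix; sample coordinates carry A1/A2 labels.

    The rotated columns are *not* re-z-scored by default — the rotation acts
    on an already-standardized matrix and rescaling would equalise the A1/A2
    magnitudes the analysis is interested in.  ``restandardize=True`` exposes
    the alternative (it fails on identically-zero A2 columns).
    """
    target: BaseMatrix = matrix
    if restandardize:
        from .preprocessing import standardize

        std = standardize(matrix, pre_transform="none")
        target = RotatedMatrix(
            gene_ids=std.gene_ids,
            samples=matrix.samples,
            values=std.values,
            original_samples=matrix.original_samples,
            original_stats=matrix.original_stats,
            transform=matrix.transform,
        )
    return run_pca(target, n_components=n_components)
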