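"""Per-column z-standardization, distribution diagnostics and layer alignment.

Every sample column is standardized independently as ``Z = (x - mu) / sigma``
with ``mu`` the column mean and ``sigma`` the population standard deviation
(divisor N).  Raw abundance tables are heavy-tailed, so an optional
``log2(x + 1)`` pre-transform (on by default where the CLI reads raw
abundances) symmetrizes the per-column distributions before scaling; the
transform applied is recorded on the result.

Diagnostics mirror the manual QC a practitioner performs on the z-scored
columns — histogram shape, skewness and whether every column spans a
comparable range — and warn rather than abort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LayerPairingError, ValidationError, ZeroVarianceError
from .matrix_io import (
    BaseMatrix,
    OmicsMatrix,
    SampleDescriptor,
    sample_column_name,
)

#: Supported pre-transforms for :func:`standardize`.
PRE_TRANSFORMS = ("none", "log2p1")


@dataclass(frozen=True)
class ColumnStats:
    """Per-column location/scale recorded at standardization time.

    ``mu``/``sigma`` are taken on the (possibly log-transformed) values and
    allow mapping z-scores back to that scale.
    """

    sample_id: str
    mu: float
    sigma: float
    min: float
    max: float
    skewness: float


class StandardizedMatrix(BaseMatrix):
    """Matrix of column z-scores with the stats and transform that made them.

    Columns are mean-0, population-sd-1 to 1e-9 unless ``validate_columns``
    is disabled (used for row subsets, whose z-values deliberately stay on
    the full-matrix scale).
    """

    def __init__(
        self,
        gene_ids,
        samples,
        values,
        column_stats: list[ColumnStats] | None = None,
        transform: str = "none",
        validate_columns: bool = True,
    ):
        self.column_stats = list(column_stats) if column_stats is not None else []
        self.transform = transform
        self.validate_columns = validate_columns
        super().__init__(gene_ids=gene_ids, samples=samples, values=values)
        self._validate()

    def _validate(self) -> None:
        if self.transform not in PRE_TRANSFORMS:
            raise ValidationError(f"unknown transform tag {self.transform!r}")
        if self.validate_columns and self.n_genes > 0:
            mean = self.values.mean(axis=0)
            sd = self.values.std(axis=0)
            if np.abs(mean).max(initial=0.0) > 1e-9 or np.abs(sd - 1).max(initial=0.0) > 1e-9:
                j = int(np.argmax(np.abs(mean) + np.abs(sd - 1)))
                raise ValidationError(
                    f"column {self.samples[j].sample_id!r} is not standardized "
                    f"(mean={mean[j]:.3g}, sd={sd[j]:.3g})"
                )


def standardize(matrix: BaseMatrix, pre_transform: str = "none") -> StandardizedMatrix:
    """Z-score every column: ``(x - mu) / sigma`` with population ``sigma``.

    Parameters
    ----------
    matrix
        Abundance (or already-standardized) matrix; columns are treated
        independently.
    pre_transform
        ``"log2p1"`` first maps ``x -> log2(x + 1)`` (requires ``x >= 0``);
        ``"none"`` scales the values as they are.

    Raises
    ------
    ZeroVarianceError
        If any column is constant, naming the offending sample.
    """
    if pre_transform not in PRE_TRANSFORMS:
        raise ValidationError(
            f"pre_transform must be one of {PRE_TRANSFORMS}, got {pre_transform!r}"
        )
    x = matrix.values
    if pre_transform == "log2p1":
        if np.any(x < 0):
            raise ValidationError("log2p1 pre-transform requires non-negative values")
        x = np.log2(x + 1.0)

    mu = x.mean(axis=0)
    sigma = x.std(axis=0)  # population (divisor N)
    for j, s in enumerate(sigma):
        if s == 0.0:
            raise ZeroVarianceError(
                f"column {matrix.samples[j].sample_id!r} has zero variance"
            )
    z = (x - mu) / sigma
    skew = stats.skew(x, axis=0, bias=True)
    col_stats = [
        ColumnStats(
            sample_id=d.sample_id,
            mu=float(mu[j]),
            sigma=float(sigma[j]),
            min=float(x[:, j].min()),
            max=float(x[:, j].max()),
            skewness=float(np.atleast_1d(skew)[j]),
        )
        for j, d in enumerate(matrix.samples)
    ]
    return StandardizedMatrix(
        gene_ids=matrix.gene_ids,
        samples=matrix.samples,
        values=z,
        column_stats=col_stats,
        transform=pre_transform,
    )


#: histogram support and resolution used by :func:`distribution_diagnostics`
DIAG_BIN_EDGES = np.linspace(-5.0, 5.0, 21)


@dataclass
class DiagnosticsReport:
    """Per-column distribution summary of a standardized matrix.

    ``table`` columns: ``sample_id``, ``min``, ``max``, ``skewness``,
    ``comparability_flag`` and the 20 histogram-count columns ``bin_00`` …
    ``bin_19`` over z in [-5, 5].  The flag marks columns whose extreme
    magnitude differs from the across-column median of that extreme by more
    than ``factor``.
    """

    table: pd.DataFrame
    bin_edges: np.ndarray = field(default_factory=lambda: DIAG_BIN_EDGES.copy())
    factor: float = 2.0

    @property
    def flagged(self) -> list[str]:
        return self.table.loc[self.table["comparability_flag"], "sample_id"].tolist()


def distribution_diagnostics(
    matrix: StandardizedMatrix, factor: float = 2.0
) -> DiagnosticsReport:
    """Histogram/skewness/extreme-range report for each z-scored column.

    A column is flagged when ``|min|`` or ``|max|`` is more than ``factor``
    times (or less than 1/``factor`` of) the across-column median of that
    extreme — the automated version of checking that every column "spans a
    comparable range".  Flags warn; they never abort the pipeline.
    """
    if factor <= 1.0:
        raise ValidationError("comparability factor must exceed 1")
    z = matrix.values
    mins = z.min(axis=0)
    maxs = z.max(axis=0)
    skews = np.atleast_1d(stats.skew(z, axis=0, bias=True))
    med_min = np.median(np.abs(mins))
    med_max = np.median(np.abs(maxs))

    def _off(value: float, med: float) -> bool:
        if med == 0.0:
            return abs(value) > 0.0
        ratio = abs(value) / med
        return ratio > factor or ratio < 1.0 / factor

    rows = []
    for j, desc in enumerate(matrix.samples):
        counts, _ = np.histogram(z[:, j], bins=DIAG_BIN_EDGES)
        flag = _off(mins[j], med_min) or _off(maxs[j], med_max)
        row = {
            "sample_id": desc.sample_id,
            "min": float(mins[j]),
            "max": float(maxs[j]),
            "skewness": float(skews[j]),
            "comparability_flag": bool(flag),
        }
        row.update({f"bin_{b:02d}": int(c) for b, c in enumerate(counts)})
        rows.append(row)
    table = pd.DataFrame(rows)
    flagged = table.loc[table["comparability_flag"], "sample_id"].tolist()
    if flagged:
        warnings.warn(
            "columns with non-comparable extremes: " + ", ".join(flagged),
            stacklevel=2,
        )
    return DiagnosticsReport(table=table, factor=factor)


def align_layers(transcript: BaseMatrix, protein: BaseMatrix) -> OmicsMatrix:
    """Join single-layer matrices into one condition-major two-layer matrix.

    Both inputs must cover identical condition sets; genes are intersected
    (order taken from ``transcript``) and any dropped ids are reported in a
    warning.  Output columns are ordered condition-major, transcript before
    protein, matching the joint matrix the decomposition expects.
    """
    for m, layer in ((transcript, "transcript"), (protein, "protein")):
        off = [s.sample_id for s in m.samples if s.layer != layer]
        if off:
            raise LayerPairingError(
                f"{layer} matrix contains columns of another layer: {', '.join(off)}"
            )
    t_conditions = transcript.conditions
    if set(t_conditions) != set(protein.conditions):
        only_t = sorted(set(t_conditions) - set(protein.conditions))
        only_p = sorted(set(protein.conditions) - set(t_conditions))
        raise LayerPairingError(
            f"condition sets differ (transcript only: {only_t}, protein only: {only_p})"
        )

    protein_genes = set(protein.gene_ids)
    shared = [g for g in transcript.gene_ids if g in protein_genes]
    if not shared:
        raise LayerPairingError("transcript and protein matrices share no genes")
    dropped = sorted(
        (set(transcript.gene_ids) | set(protein.gene_ids)) - set(shared)
    )
    if dropped:
        warnings.warn(
            f"align_layers dropped {len(dropped)} gene(s) absent from one layer: "
            + ", ".join(dropped),
            stacklevel=2,
        )

    t_rows = {g: i for i, g in enumerate(transcript.gene_ids)}
    p_rows = {g: i for i, g in enumerate(protein.gene_ids)}
    t_idx = [t_rows[g] for g in shared]
    p_idx = [p_rows[g] for g in shared]

    samples: list[SampleDescriptor] = []
    cols: list[np.ndarray] = []
    for cond in t_conditions:
        jt = transcript.column_index(cond, "transcript")
        jp = protein.column_index(cond, "protein")
        samples.append(
            SampleDescriptor(sample_column_name(cond, "transcript"), cond, "transcript")
        )
        cols.append(transcript.values[t_idx, jt])
        samples.append(
            SampleDescriptor(sample_column_name(cond, "protein"), cond, "protein")
        )
        cols.append(protein.values[p_idx, jp])
    return OmicsMatrix(
        gene_ids=shared, samples=samples, values=np.column_stack(cols)
    )
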