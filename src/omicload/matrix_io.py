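"""Reading, validating and writing expression matrices and pathway annotations.

The on-disk formats are plain delimited text (tab or comma, auto-detected):

* expression tables — header row, first column holds gene identifiers,
  remaining columns named ``<condition>_<RNA|PROT>`` (override with an
  explicit ``layer_map``);
* annotation tables — two or three columns ``gene_id``, ``pathway_id``
  and optionally ``pathway_name``.

Gene identifiers are opaque strings; no KEGG-ID normalisation is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import ClassVar, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AnnotationError,
    DuplicateGeneError,
    MissingValueError,
    TableFormatError,
    ValidationError,
)

#: Omic layers an abundance matrix may carry.
LAYERS = ("transcript", "protein")

#: Column-name suffixes of the default naming dialect.
LAYER_SUFFIXES = {"RNA": "transcript", "PROT": "protein"}
_SUFFIX_FOR_LAYER = {v: k for k, v in LAYER_SUFFIXES.items()}


@dataclass(frozen=True)
class SampleDescriptor:
    """Identity of one matrix column: which condition, which omic layer."""

    sample_id: str
    condition: str
    layer: str


def parse_sample_column(name: str) -> tuple[str, str]:
    """Parse ``<condition>_<RNA|PROT>`` into ``(condition, layer)``.

    Raises :class:`TableFormatError` if the suffix is not recognised.
    """
    if "_" in name:
        condition, _, suffix = name.rpartition("_")
        layer = LAYER_SUFFIXES.get(suffix.upper())
        if condition and layer is not None:
            return condition, layer
    raise TableFormatError(
        f"cannot parse sample column {name!r}: expected '<condition>_<RNA|PROT>' "
        "or an explicit layer_map entry"
    )


def sample_column_name(condition: str, layer: str) -> str:
    """Inverse of :func:`parse_sample_column` for the default dialect."""
    suffix = _SUFFIX_FOR_LAYER.get(layer, layer)
    return f"{condition}_{suffix}"


def _validate_samples(samples: Sequence[SampleDescriptor], allowed_layers) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample ids: {', '.join(dups)}")
    pairs = [(s.condition, s.layer) for s in samples]
    if len(set(pairs)) != len(pairs):
        dups = sorted({p for p in pairs if pairs.count(p) > 1})
        raise ValidationError(f"duplicate (condition, layer) pairs: {dups}")
    for s in samples:
        if s.layer not in allowed_layers:
            raise ValidationError(
                f"sample {s.sample_id!r} has layer {s.layer!r}; "
                f"expected one of {allowed_layers}"
            )


@dataclass
class BaseMatrix:
    """A dense genes x samples grid plus row/column identities.

    ``values[i, j]`` is gene ``gene_ids[i]`` in sample ``samples[j]``.
    """

    gene_ids: list[str]
    samples: list[SampleDescriptor]
    values: np.ndarray

    ALLOWED_LAYERS: ClassVar[tuple] = LAYERS

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dups: set[str] = set()
            for g in self.gene_ids:
                if g in seen:
                    dups.add(g)
                seen.add(g)
            raise DuplicateGeneError(f"duplicate gene ids: {', '.join(sorted(dups))}")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValidationError(
                f"value grid has shape {self.values.shape}, expected "
                f"({len(self.gene_ids)}, {len(self.samples)})"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite values")
        _validate_samples(self.samples, self.ALLOWED_LAYERS)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def conditions(self) -> list[str]:
        """Condition names in first-appearance order."""
        out: list[str] = []
        for s in self.samples:
            if s.condition not in out:
                out.append(s.condition)
        return out

    def column_index(self, condition: str, layer: str) -> int:
        for j, s in enumerate(self.samples):
            if s.condition == condition and s.layer == layer:
                return j
        raise ValidationError(f"no column for condition {condition!r}, layer {layer!r}")

    def layer_columns(self, layer: str) -> list[int]:
        return [j for j, s in enumerate(self.samples) if s.layer == layer]

    def to_frame(self) -> pd.DataFrame:
        """Genes x samples DataFrame; columns are sample ids, index name 'gene'."""
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene"
        return df


class OmicsMatrix(BaseMatrix):
    """Raw abundance matrix over transcript/protein columns."""


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise TableFormatError(
        f"{path}: could not detect a tab or comma delimiter in the header row"
    )


def read_expression_table(
    path,
    layer_map: Mapping[str, tuple[str, str]] | None = None,
    *,
    impute: bool = False,
    delimiter: str | None = None,
    matrix_class=OmicsMatrix,
) -> OmicsMatrix:
    """Read a delimited expression table into an :class:`OmicsMatrix`.

    Parameters
    ----------
    path
        Delimited text file with a header row; the first column holds gene ids.
    layer_map
        Optional mapping ``column name -> (condition, layer)``.  When given it
        must cover every sample column; when omitted columns are parsed with the
        ``<condition>_<RNA|PROT>`` dialect.
    impute
        Replace missing/non-numeric cells with the gene's within-layer median
        instead of raising :class:`MissingValueError`.
    delimiter
        Force a delimiter instead of auto-detecting tab vs comma.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise TableFormatError(f"{path}: empty table (no genes or no sample columns)")

    gene_ids = df.iloc[:, 0].astype(str).tolist()
    dup = df.iloc[:, 0][df.iloc[:, 0].duplicated()].unique().tolist()
    if dup:
        raise DuplicateGeneError(
            f"{path}: duplicate gene ids: {', '.join(map(str, sorted(dup)))}"
        )

    columns = list(df.columns[1:])
    samples = []
    for col in columns:
        if layer_map is not None:
            if col not in layer_map:
                raise ValidationError(f"{path}: column {col!r} missing from layer_map")
            condition, layer = layer_map[col]
        else:
            condition, layer = parse_sample_column(col)
        samples.append(SampleDescriptor(sample_id=col, condition=condition, layer=layer))

    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        if not impute:
            i, j = map(int, np.argwhere(bad)[0])
            raise MissingValueError(
                f"{path}: non-numeric or missing cell at gene {gene_ids[i]!r}, "
                f"column {columns[j]!r} (pass impute=True to fill with the "
                "gene's within-layer median)"
            )
        for layer in {s.layer for s in samples}:
            cols = [j for j, s in enumerate(samples) if s.layer == layer]
            block = values[:, cols]
            med = np.nanmedian(block, axis=1)
            if np.isnan(med).any():
                g = gene_ids[int(np.argwhere(np.isnan(med))[0][0])]
                raise MissingValueError(
                    f"{path}: gene {g!r} has no observed value in layer {layer!r}; "
                    "cannot impute"
                )
            rr, cc = np.where(~np.isfinite(block))
            block[rr, cc] = med[rr]
            values[:, cols] = block
    return matrix_class(gene_ids=gene_ids, samples=samples, values=values)


@dataclass
class PathwayAnnotation:
    """Many-to-many gene <-> pathway membership.

    ``records`` has columns ``gene_id``, ``pathway_id``, ``pathway_name``,
    one row per (gene, pathway) pair, ordered by ``(pathway_id, gene_id)``.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "pathway_id", "pathway_name"]
        if list(self.records.columns) != required:
            raise AnnotationError(
                f"annotation columns must be {required}, got {list(self.records.columns)}"
            )
        if len(self.records) == 0:
            raise AnnotationError("no annotations")
        if self.records.duplicated(subset=["gene_id", "pathway_id"]).any():
            raise AnnotationError("duplicate (gene_id, pathway_id) records")
        self.records = (
            self.records.sort_values(["pathway_id", "gene_id"], kind="mergesort")
            .reset_index(drop=True)
        )

    @classmethod
    def from_records(
        cls, rows: Iterable[tuple], dedup: bool = True
    ) -> "PathwayAnnotation":
        """Build from ``(gene_id, pathway_id[, pathway_name])`` tuples."""
        norm = []
        for row in rows:
            row = tuple(row)
            if len(row) == 2:
                row = (row[0], row[1], row[1])
            norm.append(row[:3])
        df = pd.DataFrame(norm, columns=["gene_id", "pathway_id", "pathway_name"])
        if dedup:
            df = df.drop_duplicates(subset=["gene_id", "pathway_id"])
        return cls(records=df)

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.records["pathway_id"].unique())

    def pathway_name(self, pathway_id: str) -> str:
        rows = self.records[self.records["pathway_id"] == pathway_id]
        if rows.empty:
            raise AnnotationError(f"unknown pathway {pathway_id!r}")
        return str(rows["pathway_name"].iloc[0])

    def genes_for(self, pathway_id: str) -> list[str]:
        rows = self.records[self.records["pathway_id"] == pathway_id]
        if rows.empty:
            raise AnnotationError(f"unknown pathway {pathway_id!r}")
        return rows["gene_id"].tolist()

    def pathways_for(self, gene_id: str) -> list[str]:
        return self.records.loc[
            self.records["gene_id"] == gene_id, "pathway_id"
        ].tolist()

    def gene_sets(self) -> dict[str, list[str]]:
        """Mapping pathway_id -> member gene ids."""
        return {
            pid: grp["gene_id"].tolist()
            for pid, grp in self.records.groupby("pathway_id", sort=True)
        }


def read_pathway_annotation(path, *, delimiter: str | None = None) -> PathwayAnnotation:
    """Read a 2- or 3-column gene -> pathway table.

    Duplicated (gene, pathway) rows are collapsed; a malformed row raises
    :class:`AnnotationError` naming its line number.
    """
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    sep = delimiter
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_skipped = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if sep is None:
            sep = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) not in (2, 3) or any(p == "" for p in parts[:2]):
            raise AnnotationError(
                f"{path}: malformed annotation row at line {lineno}: {line!r}"
            )
        if not header_skipped:
            header_skipped = True
            if parts[0].lower() in ("gene", "gene_id") or parts[1].lower() in (
                "pathway",
                "pathway_id",
            ):
                continue
        name = parts[2] if len(parts) == 3 else parts[1]
        rows.append((parts[0], parts[1], name))
    if not rows:
        raise AnnotationError(f"{path}: no annotations")
    df = pd.DataFrame(rows, columns=["gene_id", "pathway_id", "pathway_name"])
    df = df.drop_duplicates(subset=["gene_id", "pathway_id"])
    return PathwayAnnotation(records=df)


#: float format preserving full double precision so write->read round-trips.
_FLOAT_FMT = "%.17g"


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def write_table(obj, path) -> None:
    """Write any of the pipeline's tabular results to delimited text.

    Accepts matrices (:class:`BaseMatrix` subclasses), annotations, result
    tables exposing a ``.table`` or ``.entries`` DataFrame, or a plain
    DataFrame.  Numeric cells round-trip to within 1e-12.
    """
    path = Path(path)
    sep = _delimiter_for(path)
    if isinstance(obj, BaseMatrix):
        df = pd.DataFrame(obj.values, columns=obj.sample_ids)
        df.insert(0, "gene", obj.gene_ids)
        df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
        return
    if isinstance(obj, PathwayAnnotation):
        obj.records.to_csv(path, sep=sep, index=False)
        return
    for attr in ("table", "entries", "records"):
        inner = getattr(obj, attr, None)
        if isinstance(inner, pd.DataFrame):
            inner.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
            return
    if isinstance(obj, pd.DataFrame):
        out = obj
        if out.index.name is not None:
            out = out.reset_index()
        out.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
        return
    raise ValidationError(f"don't know how to write object of type {type(obj).__name__}")
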