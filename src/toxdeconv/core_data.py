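"""Data model and IO for expression matrices and sample metadata.

The central container is :class:`ExpressionMatrix`: a nonnegative genes x
samples matrix of normalized intensity ratios (the ``V`` of the NMF
deconvolution), carried together with unique gene and sample identifiers.
Expression tables are tab-separated text with genes as rows (first column =
gene identifier, header row = sample identifiers); sample metadata is a
CSV/TSV table with one row per sample.

Compound-wise slicing produces :class:`CompoundDataset` objects (treated +
matched control columns over an identical gene order), the unit every
downstream step (deconvolution, fold changes, simulation) operates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "System",
    "DoseLevel",
    "ExpressionMatrix",
    "SampleMeta",
    "CompoundDataset",
    "read_expression_table",
    "write_expression_table",
    "read_metadata_table",
    "write_metadata_table",
    "split_by_compound",
    "intersect_genes",
    "control_mean_profile",
]


class System(str, Enum):
    """Assay system a sample belongs to."""

    IN_VITRO = "in_vitro"
    IN_VIVO_SINGLE = "in_vivo_single"
    IN_VIVO_REPEAT = "in_vivo_repeat"


class DoseLevel(str, Enum):
    CONTROL = "control"
    LOW = "low"
    MIDDLE = "middle"
    HIGH = "high"


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x samples expression-ratio matrix.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene identifiers, one per row.
    sample_ids : sequence of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Nonnegative normalized intensity ratios.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if m != len(self.gene_ids) or n != len(self.sample_ids):
            raise DataError(
                f"shape mismatch: values are {m}x{n} but there are "
                f"{len(self.gene_ids)} gene ids and {len(self.sample_ids)} sample ids"
            )
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise DataError(f"duplicate gene id(s): {sorted(dup_g)[:5]}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise DataError(f"duplicate sample id(s): {sorted(dup_s)[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values contain non-finite entries")
        if np.any(self.values < 0):
            gi, si = np.argwhere(self.values < 0)[0]
            raise DataError(
                f"negative expression value {self.values[gi, si]:g} at "
                f"gene {self.gene_ids[gi]!r}, sample {self.sample_ids[si]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(map(str, frame.index)),
            sample_ids=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise DataError(f"unknown sample id(s): {missing[:5]}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids), self.values[:, cols])

    def select_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise DataError(f"unknown gene id(s): {missing[:5]}")
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.sample_ids, self.values[rows, :])


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


@dataclass
class SampleMeta:
    """Metadata for one sample (one expression column)."""

    sample_id: str
    compound: str
    system: System
    dose_level: DoseLevel
    time_label: str
    replicate: int
    is_control: bool

    def __post_init__(self) -> None:
        self.system = System(self.system)
        self.dose_level = DoseLevel(self.dose_level)
        self.replicate = int(self.replicate)
        self.is_control = bool(self.is_control)
        if self.replicate < 1:
            raise DataError(f"sample {self.sample_id!r}: replicate must be >= 1")
        if self.is_control != (self.dose_level is DoseLevel.CONTROL):
            raise DataError(
                f"sample {self.sample_id!r}: is_control must be true iff dose_level is control"
            )


@dataclass
class CompoundDataset:
    """Treated and matched-control expression columns of one compound.

    ``treated`` and ``controls`` share an identical gene order; the treated
    matrix is the per-compound ``V`` fed to the deconvolution, the control
    columns define the environmental reference used for component labeling
    and fold changes.
    """

    compound: str
    treated: ExpressionMatrix
    controls: ExpressionMatrix
    system: System

    def __post_init__(self) -> None:
        self.system = System(self.system)
        if self.treated.gene_ids != self.controls.gene_ids:
            raise DataError(
                f"compound {self.compound!r}: treated and control matrices "
                "must share identical gene ids in identical order"
            )
        if self.treated.n_samples < 1 or self.controls.n_samples < 1:
            raise DataError(
                f"compound {self.compound!r}: need >= 1 treated and >= 1 control sample"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.treated.gene_ids


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "sample_id",
    "compound",
    "system",
    "dose_level",
    "time_label",
    "replicate",
    "is_control",
]


def read_expression_table(
    path: str | Path, metadata_path: str | Path | None = None
) -> tuple[ExpressionMatrix, list[SampleMeta]]:
    """Read a TSV expression table and (optionally) its sample metadata.

    The first column holds gene identifiers, the header row sample
    identifiers. Every sample column must have a metadata row when
    ``metadata_path`` is given.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    dup = frame.index[frame.index.duplicated()].unique().tolist()
    if dup:
        raise DataError(f"{path}: duplicate gene id(s): {dup[:5]}")
    expr = ExpressionMatrix.from_frame(frame)
    meta: list[SampleMeta] = []
    if metadata_path is not None:
        meta = read_metadata_table(metadata_path)
        by_id = {m.sample_id: m for m in meta}
        missing = [s for s in expr.sample_ids if s not in by_id]
        if missing:
            raise DataError(
                f"{metadata_path}: missing metadata row(s) for sample(s) {missing[:5]}"
            )
        meta = [by_id[s] for s in expr.sample_ids]
    return expr, meta


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV (full float precision)."""
    frame = expr.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_metadata_table(path: str | Path) -> list[SampleMeta]:
    """Read a CSV/TSV sample-metadata table (delimiter sniffed)."""
    table = pd.read_csv(path, sep=None, engine="python")
    missing_cols = [c for c in _META_COLUMNS if c not in table.columns]
    if missing_cols:
        raise DataError(f"{path}: metadata table lacks column(s) {missing_cols}")
    rows = []
    for rec in table.to_dict("records"):
        rows.append(
            SampleMeta(
                sample_id=str(rec["sample_id"]),
                compound=str(rec["compound"]),
                system=System(rec["system"]),
                dose_level=DoseLevel(rec["dose_level"]),
                time_label=str(rec["time_label"]),
                replicate=int(rec["replicate"]),
                is_control=_parse_bool(rec["is_control"]),
            )
        )
    dup = _duplicates(m.sample_id for m in rows)
    if dup:
        raise DataError(f"{path}: duplicate sample_id(s) in metadata: {sorted(dup)[:5]}")
    keys = _duplicates(
        f"{m.compound}|{m.system.value}|{m.dose_level.value}|{m.time_label}|{m.replicate}"
        for m in rows
    )
    if keys:
        raise DataError(
            f"{path}: duplicate (compound, system, dose, time, replicate) key(s): {sorted(keys)[:3]}"
        )
    return rows


def _parse_bool(x: object) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise DataError(f"cannot parse boolean value {x!r}")


def write_metadata_table(meta: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "compound": m.compound,
                "system": m.system.value,
                "dose_level": m.dose_level.value,
                "time_label": m.time_label,
                "replicate": m.replicate,
                "is_control": m.is_control,
            }
            for m in meta
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Slicing
# ---------------------------------------------------------------------------


def split_by_compound(
    expr: ExpressionMatrix, meta: Sequence[SampleMeta], system: System | str
) -> list[CompoundDataset]:
    """One :class:`CompoundDataset` per compound with treated and control samples.

    Compounds with treated samples but no control samples in the given
    system are dropped with a warning (the pipeline only uses compounds
    with matched controls). Output order follows first appearance of each
    compound in the metadata.
    """
    system = System(system)
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in expr.sample_ids if s not in by_id]
    if missing:
        raise DataError(f"missing metadata for sample(s) {missing[:5]}")

    compounds: list[str] = []
    treated_cols: dict[str, list[str]] = {}
    control_cols: dict[str, list[str]] = {}
    for s in expr.sample_ids:
        m = by_id[s]
        if m.system is not system:
            continue
        if m.compound not in treated_cols:
            compounds.append(m.compound)
            treated_cols[m.compound] = []
            control_cols[m.compound] = []
        (control_cols if m.is_control else treated_cols)[m.compound].append(s)

    datasets: list[CompoundDataset] = []
    for comp in compounds:
        if not treated_cols[comp]:
            continue
        if not control_cols[comp]:
            warnings.warn(
                f"compound {comp!r} has treated samples but no controls in "
                f"{system.value}; dropped",
                stacklevel=2,
            )
            continue
        datasets.append(
            CompoundDataset(
                compound=comp,
                treated=expr.select_samples(treated_cols[comp]),
                controls=expr.select_samples(control_cols[comp]),
                system=system,
            )
        )
    return datasets


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the sorted intersection of their gene ids."""
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise DataError("gene intersection is empty")
    return a.select_genes(common), b.select_genes(common)


def control_mean_profile(ds: CompoundDataset) -> np.ndarray:
    """Per-gene arithmetic mean across the control columns."""
    return ds.controls.values.mean(axis=1)
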