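"""Fold-change ranking and directional gene-signature selection.

For each compound the per-gene fold change FC = mean(treated) / mean(control)
is computed on the linear ratio scale, genes are ranked from highest to
lowest FC, and the top g genes form the up-signature, the bottom g the
down-signature (g = 200 by default, i.e. 400 signature genes per compound).
Ties are broken lexicographically by gene identifier so the selection is
deterministic. A stability scan over cut-offs (50..550 step 50) reports the
mean pairwise directional Dice similarity across compounds per cut-off.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "GeneSignature",
    "fold_changes",
    "select_signature",
    "stability_scan",
]

DEFAULT_CUTOFF = 200


@dataclass
class GeneSignature:
    """Ranked fold changes plus directional top/bottom gene sets."""

    compound: str
    fold_changes: pd.Series = field(repr=False)
    up_genes: list[str]
    down_genes: list[str]
    g: int

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "g": self.g,
            "up_genes": list(self.up_genes),
            "down_genes": list(self.down_genes),
        }


def fold_changes(
    treated: np.ndarray,
    control: np.ndarray,
    gene_ids: Sequence[str] | None = None,
    pseudocount: float = 0.0,
) -> pd.Series:
    """Per-gene FC = mean(treated) / mean(control), linear ratio scale.

    ``treated`` and ``control`` are genes x replicates matrices (1-D vectors
    are treated as single columns). A zero control mean raises unless a
    positive ``pseudocount`` is supplied (added to both group means).
    """
    t = np.atleast_2d(np.asarray(treated, dtype=float).T).T
    c = np.atleast_2d(np.asarray(control, dtype=float).T).T
    if t.shape[0] != c.shape[0]:
        raise DataError("treated and control matrices must share the gene order")
    tm = t.mean(axis=1) + pseudocount
    cm = c.mean(axis=1) + pseudocount
    zero = np.nonzero(cm <= 0)[0]
    if zero.size:
        name = gene_ids[zero[0]] if gene_ids is not None else f"row {zero[0]}"
        raise DataError(f"zero control mean for gene {name}; cannot form fold change")
    fc = tm / cm
    index = list(gene_ids) if gene_ids is not None else [str(i) for i in range(len(fc))]
    if len(index) != len(fc):
        raise DataError("gene_ids length does not match the matrices")
    return pd.Series(fc, index=index, name="fold_change")


def select_signature(
    fc: pd.Series | np.ndarray,
    g: int = DEFAULT_CUTOFF,
    gene_ids: Sequence[str] | None = None,
    compound: str = "",
) -> GeneSignature:
    """Top-g / bottom-g directional signature of a ranked FC vector.

    Genes are ranked from highest to lowest fold change; up = first g,
    down = last g (ordered most-extreme-first). Requires at least 2g genes.
    """
    if isinstance(fc, pd.Series):
        values = fc.to_numpy(dtype=float)
        genes = np.asarray(fc.index.astype(str))
    else:
        values = np.asarray(fc, dtype=float)
        if gene_ids is None:
            raise ConfigError("gene_ids required when fc is a bare array")
        genes = np.asarray([str(x) for x in gene_ids])
    if genes.shape[0] != values.shape[0]:
        raise DataError("gene_ids length does not match fc")
    if not np.all(np.isfinite(values)):
        raise DataError("fold changes must be finite")
    if g < 1:
        raise ConfigError("cut-off g must be >= 1")
    m = values.shape[0]
    if m < 2 * g:
        raise DataError(f"need at least {2 * g} genes for cut-off g={g}, got {m}")
    # primary key: FC descending; tie-break: gene id ascending (lexsort is stable)
    order = np.lexsort((genes, -values))
    ranked = genes[order]
    up = ranked[:g].tolist()
    down = ranked[-g:][::-1].tolist()  # most downregulated first
    series = pd.Series(values, index=genes, name="fold_change")
    return GeneSignature(
        compound=compound, fold_changes=series, up_genes=up, down_genes=down, g=g
    )


def stability_scan(
    fc_by_compound: Mapping[str, pd.Series],
    cutoffs: Sequence[int] = tuple(range(50, 551, 50)),
) -> pd.DataFrame:
    """Mean pairwise directional Dice similarity across compounds per cut-off.

    Quantifies how stable the signature overlap structure is as the cut-off
    grows; a plateau indicates a safe signature size. Cut-offs larger than
    half the gene count are skipped with a warning.
    """
    from .prank import dice_coefficient  # local import to avoid a cycle

    compounds = list(fc_by_compound)
    if len(compounds) < 2:
        raise DataError("stability scan needs at least two compounds")
    m = min(len(fc_by_compound[c]) for c in compounds)
    rows = []
    for g in cutoffs:
        if 2 * g > m:
            warnings.warn(
                f"cut-off {g} exceeds half the gene count ({m}); skipped", stacklevel=2
            )
            continue
        sigs = [select_signature(fc_by_compound[c], g=g, compound=c) for c in compounds]
        dices = [
            dice_coefficient(a, b) for a, b in itertools.combinations(sigs, 2)
        ]
        rows.append({"cutoff": g, "mean_dice": float(np.mean(dices)), "n_pairs": len(dices)})
    return pd.DataFrame(rows, columns=["cutoff", "mean_dice", "n_pairs"])
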