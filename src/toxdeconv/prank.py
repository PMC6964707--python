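"""Pairwise signature similarity (directional Dice) and PRank concordance.

Within one assay system, every unordered compound pair (i, j) gets a
directional Dice coefficient

    Dice(i, j) = (|up_i & up_j| + |down_i & down_j|) / (2 g)

(g = 200 gives the printed denominator 400). Concordance between two
systems is the PRank score: the reference system's pair similarities are
binarized at a cut-off (default 0.4, close to the 95% quantile of the
Dice distribution), the query system's similarities serve as continuous
scores, and the ROC-AUC of that ranking is reported. Because the label /
score orientation between two systems is symmetric, both one-way AUCs and
their mean are available. Two companion diagnostics: the number of pairs
falling on opposite sides of the cut-off in the two systems, and the mean
absolute difference (MAD) of the paired Dice coefficients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import ConfigError, DataError
from .signatures import GeneSignature

__all__ = [
    "DiceMatrix",
    "PRankResult",
    "dice_coefficient",
    "pairwise_dice",
    "prank_score",
    "count_inconsistent_pairs",
    "mean_absolute_difference",
]

DEFAULT_PRANK_CUTOFF = 0.4


@dataclass
class DiceMatrix:
    """Symmetric matrix of directional Dice coefficients over compounds."""

    compounds: list[str]
    values: np.ndarray = field(repr=False)
    g: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.compounds)
        if v.shape != (n, n):
            raise DataError("Dice matrix shape does not match the compound list")
        if not np.allclose(v, v.T):
            raise DataError("Dice matrix must be symmetric")
        if np.any((v < 0) | (v > 1)):
            raise DataError("Dice coefficients must lie in [0, 1]")
        self.values = v

    @property
    def n_pairs(self) -> int:
        n = len(self.compounds)
        return n * (n - 1) // 2

    def pair_values(self) -> np.ndarray:
        """Condensed vector of the n(n-1)/2 unordered off-diagonal pairs."""
        iu = np.triu_indices(len(self.compounds), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compounds, columns=self.compounds)


@dataclass
class PRankResult:
    """Cross-system concordance summary."""

    score: float
    score_ref_a: float
    score_ref_b: float
    cutoff: float
    direction: str
    n_pairs: int
    inconsistent_pairs: int
    mad: float

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "score_ref_a": self.score_ref_a,
            "score_ref_b": self.score_ref_b,
            "cutoff": self.cutoff,
            "direction": self.direction,
            "n_pairs": self.n_pairs,
            "inconsistent_pairs": self.inconsistent_pairs,
            "mad": self.mad,
        }


def dice_coefficient(sig_i: GeneSignature, sig_j: GeneSignature) -> float:
    """Directional Dice similarity of two signatures sharing the cut-off g."""
    if sig_i.g != sig_j.g:
        raise ConfigError(
            f"signatures use different cut-offs (g={sig_i.g} vs g={sig_j.g})"
        )
    n_up = len(set(sig_i.up_genes) & set(sig_j.up_genes))
    n_down = len(set(sig_i.down_genes) & set(sig_j.down_genes))
    return (n_up + n_down) / (2 * sig_i.g)


def pairwise_dice(signatures: Sequence[GeneSignature]) -> DiceMatrix:
    """Dice coefficients for all unordered compound pairs (diagonal = 1)."""
    if len(signatures) < 2:
        raise DataError("need at least two signatures")
    compounds = [s.compound for s in signatures]
    if len(set(compounds)) != len(compounds):
        raise DataError("duplicate compound id among signatures")
    g = signatures[0].g
    n = len(signatures)
    values = np.eye(n)
    for (i, a), (j, b) in itertools.combinations(enumerate(signatures), 2):
        values[i, j] = values[j, i] = dice_coefficient(a, b)
    return DiceMatrix(compounds=compounds, values=values, g=g)


def _check_same_pairs(a: DiceMatrix, b: DiceMatrix) -> None:
    if a.compounds != b.compounds:
        raise DataError("Dice matrices cover different compound sets or orders")


def prank_score(
    ref: DiceMatrix,
    query: DiceMatrix,
    cutoff: float = DEFAULT_PRANK_CUTOFF,
    direction: str = "mean",
) -> PRankResult:
    """ROC-AUC concordance of two systems' pairwise similarities.

    ``direction`` selects which system provides the binarized labels:
    ``"ref_a"`` (labels from ``ref``), ``"ref_b"`` (labels from ``query``)
    or ``"mean"`` (average of both one-way AUCs, the default since the
    orientation is not intrinsically fixed). Binarization uses a closed
    boundary (Dice >= cutoff -> 1).
    """
    if direction not in {"ref_a", "ref_b", "mean"}:
        raise ConfigError(f"unknown direction {direction!r}")
    _check_same_pairs(ref, query)
    a = ref.pair_values()
    b = query.pair_values()

    def one_way(labels_from: np.ndarray, scores: np.ndarray, which: str) -> float:
        labels = (labels_from >= cutoff).astype(int)
        if labels.min() == labels.max():
            raise DataError(
                f"degenerate labels: all pairs on one side of cutoff {cutoff} "
                f"in the {which} system"
            )
        return float(roc_auc_score(labels, scores))

    auc_a = auc_b = np.nan
    if direction in {"ref_a", "mean"}:
        auc_a = one_way(a, b, "reference")
    if direction in {"ref_b", "mean"}:
        auc_b = one_way(b, a, "query")
    if direction == "ref_a":
        score = auc_a
    elif direction == "ref_b":
        score = auc_b
    else:
        score = 0.5 * (auc_a + auc_b)
    return PRankResult(
        score=float(score),
        score_ref_a=float(auc_a),
        score_ref_b=float(auc_b),
        cutoff=cutoff,
        direction=direction,
        n_pairs=int(a.size),
        inconsistent_pairs=count_inconsistent_pairs(ref, query, cutoff),
        mad=mean_absolute_difference(ref, query),
    )


def count_inconsistent_pairs(
    a: DiceMatrix, b: DiceMatrix, cutoff: float = DEFAULT_PRANK_CUTOFF
) -> int:
    """Pairs on opposite sides of the cut-off in the two systems."""
    _check_same_pairs(a, b)
    xa = a.pair_values() >= cutoff
    xb = b.pair_values() >= cutoff
    return int(np.sum(xa != xb))


def mean_absolute_difference(a: DiceMatrix, b: DiceMatrix) -> float:
    """Mean over pairs of |Dice_a - Dice_b|."""
    _check_same_pairs(a, b)
    return float(np.mean(np.abs(a.pair_values() - b.pair_values())))
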