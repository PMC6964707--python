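"""Counting the main latent factors of an expression matrix.

The factor count k that the deconvolution needs is read off the spectrum of
the *uncentered* covariance Z = V'V of the genes x samples matrix V (no
mean-centering, deliberately -- the data are positive intensity ratios and
the dominant factor is the shared baseline state). Three derived
quantities are exposed:

* reduced eigenvalues  REV_j = lambda_j / ((r - j + 1)(c - j + 1)),
  which deflate each eigenvalue by the degrees of freedom left at step j;
* successive REV ratios, whose argmax flags the most significant factor;
* cumulative contributions lambda_j / sum(lambda), from which k is the
  smallest j whose cumulative contribution reaches the 99% threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .core_data import ExpressionMatrix
from .errors import ConfigError, DataError

__all__ = [
    "FactorAnalysisResult",
    "covariance_uncentered",
    "eigen_spectrum",
    "reduced_eigenvalues",
    "rev_ratios",
    "count_main_factors",
    "analyze_factors",
    "ReducedEigenvalueFactorCount",
]

#: relative clamp tolerance for tiny-negative eigenvalues
_EIG_CLAMP_RTOL = 1e-10


@dataclass
class FactorAnalysisResult:
    """Spectrum-derived diagnostics and the selected factor count."""

    eigenvalues: np.ndarray
    rev: np.ndarray
    ratios: np.ndarray
    contributions: np.ndarray
    cumulative: np.ndarray
    n_main_factors: int

    @property
    def most_significant_factor(self) -> int:
        """1-based index t of the largest REV ratio."""
        return int(np.argmax(self.ratios)) + 1

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "rev": self.rev.tolist(),
            "ratios": self.ratios.tolist(),
            "contributions": self.contributions.tolist(),
            "cumulative": self.cumulative.tolist(),
            "n_main_factors": self.n_main_factors,
        }


def covariance_uncentered(V: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Uncentered covariance Z = V'V (c x c for an r x c matrix V)."""
    A = V.values if isinstance(V, ExpressionMatrix) else np.asarray(V, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise DataError("input matrix must be a nonempty 2-D array")
    Z = A.T @ A
    return 0.5 * (Z + Z.T)  # exact symmetry against rounding


def eigen_spectrum(Z: np.ndarray, atol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigenvalues and matching orthonormal eigenvectors of symmetric Z.

    Tiny-negative eigenvalues from floating point are clamped to 0 at a
    relative tolerance of 1e-10 of the largest eigenvalue.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != Z.shape[1]:
        raise DataError("Z must be square")
    scale = max(np.abs(Z).max(), 1.0)
    if np.abs(Z - Z.T).max() > atol * scale:
        raise DataError("Z is not symmetric within tolerance")
    evals, evecs = np.linalg.eigh(0.5 * (Z + Z.T))
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    clamp = _EIG_CLAMP_RTOL * max(evals[0], 0.0) if evals.size else 0.0
    evals = np.where(evals < 0, np.where(evals > -max(clamp, atol * scale), 0.0, evals), evals)
    if np.any(evals < 0):
        raise DataError("Z has significantly negative eigenvalues; not positive semidefinite")
    return evals, evecs


def reduced_eigenvalues(eigenvalues: np.ndarray, r: int, c: int) -> np.ndarray:
    """REV_j = lambda_j / ((r - j + 1)(c - j + 1)), j = 1..len(eigenvalues)."""
    lam = np.asarray(eigenvalues, dtype=float)
    j = np.arange(1, lam.size + 1)
    denom = (r - j + 1) * (c - j + 1)
    if np.any(denom <= 0):
        bad = int(j[denom <= 0][0])
        raise ConfigError(
            f"REV denominator non-positive at j={bad} for matrix size {r}x{c}"
        )
    return lam / denom


def rev_ratios(rev: np.ndarray) -> np.ndarray:
    """Successive ratios REV_t / REV_{t+1}; zero denominators yield +inf."""
    rev = np.asarray(rev, dtype=float)
    if rev.size < 2:
        raise ConfigError("need at least two reduced eigenvalues to form ratios")
    num, den = rev[:-1], rev[1:]
    if np.any(den == 0):
        warnings.warn("zero REV denominator; ratio reported as +inf", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
    # 0/0 counts as +inf sentinel too (factor beyond the rank)
    return ratios


def count_main_factors(eigenvalues: np.ndarray, threshold: float = 0.99) -> int:
    """Smallest j whose cumulative eigenvalue contribution reaches ``threshold``."""
    lam = np.asarray(eigenvalues, dtype=float)
    total = lam.sum()
    if not total > 0:
        raise DataError("eigenvalue sum must be positive")
    if not 0 < threshold <= 1:
        raise ConfigError("threshold must lie in (0, 1]")
    cumulative = np.cumsum(lam) / total
    hits = np.nonzero(cumulative >= threshold - 1e-12)[0]
    return int(hits[0]) + 1 if hits.size else lam.size


def analyze_factors(
    V: ExpressionMatrix | np.ndarray, threshold: float = 0.99
) -> FactorAnalysisResult:
    """Full factor-count analysis of a genes x samples matrix."""
    A = V.values if isinstance(V, ExpressionMatrix) else np.asarray(V, dtype=float)
    r, c = A.shape
    evals, _ = eigen_spectrum(covariance_uncentered(A))
    rev = reduced_eigenvalues(evals, r, c)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratios = rev_ratios(rev) if rev.size >= 2 else np.empty(0)
    total = evals.sum()
    if not total > 0:
        raise DataError("matrix is all zero; factor analysis undefined")
    contributions = evals / total
    cumulative = np.cumsum(contributions)
    return FactorAnalysisResult(
        eigenvalues=evals,
        rev=rev,
        ratios=ratios,
        contributions=contributions,
        cumulative=cumulative,
        n_main_factors=count_main_factors(evals, threshold),
    )


class ReducedEigenvalueFactorCount(BaseEstimator):
    """Estimator wrapper selecting the number of main factors.

    Follows the scikit-learn convention: ``X`` has shape
    (n_samples, n_features=genes), i.e. it is the transpose of the
    genes x samples matrix the domain functions use.

    Attributes
    ----------
    eigenvalues_ : ndarray
        Descending eigenvalues of the uncentered covariance.
    rev_ : ndarray
        Reduced eigenvalues.
    ratios_ : ndarray
        Successive REV ratios.
    contributions_, cumulative_ : ndarray
        Per-factor and cumulative eigenvalue shares.
    n_main_factors_ : int
        Selected factor count k.
    """

    def __init__(self, threshold: float = 0.99):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        res = analyze_factors(X.T, threshold=self.threshold)
        self.eigenvalues_ = res.eigenvalues
        self.rev_ = res.rev
        self.ratios_ = res.ratios
        self.contributions_ = res.contributions
        self.cumulative_ = res.cumulative
        self.n_main_factors_ = res.n_main_factors
        return self

    def fit_predict(self, X, y=None) -> int:
        return self.fit(X).n_main_factors_

    def _more_tags(self):  # pragma: no cover - sklearn compat shim
        return {"requires_y": False}

    def score(self, X, y=None) -> float:
        """Cumulative contribution of the selected factors (diagnostic)."""
        check_is_fitted(self, "cumulative_")
        return float(self.cumulative_[self.n_main_factors_ - 1])
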