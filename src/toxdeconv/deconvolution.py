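"""Post-modified NMF deconvolution.

The per-compound genes x samples matrix V is factorized as V ~ W.H with
W (genes x k) and H (k x samples) nonnegative, by alternating least
squares: each half-step solves an unconstrained least-squares problem and
clamps negative entries to zero. The "post-modification" then

1. rescales H so every column sums to one (H*), turning the weights into
   relative component contents per sample,
2. re-estimates the signature matrix by ordinary least squares against the
   original data, W* = V H*' (H* H*')^-1, clamping the (rare) negative
   entries of W* to zero.

Because ALS from random starts lands in local minima, the fit is repeated:
``restarts`` random initializations per outer round, keeping the
minimum-RMSE fit; ``repeats`` outer rounds whose winners are aligned by
maximum correlation of their W* columns and averaged; one final refit of
W* against V from the averaged H*.

For k = 2 the component whose W* column correlates best with the mean
control profile is labeled *environmental* (the body's internal state),
the other *drug_responding*.

:class:`PostModifiedNMF` exposes the whole procedure as a scikit-learn
transformer (``X`` of shape (n_samples, n_genes); ``components_`` of shape
(k, n_genes); ``transform`` returns per-sample component weights).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .core_data import CompoundDataset, ExpressionMatrix, control_mean_profile
from .errors import ConfigError, DataError

__all__ = [
    "NMFConfig",
    "DeconvolutionResult",
    "als_nmf",
    "normalize_weights",
    "refit_signatures",
    "label_components",
    "multi_restart_deconvolute",
    "PostModifiedNMF",
    "ENVIRONMENTAL",
    "DRUG_RESPONDING",
]

ENVIRONMENTAL = "environmental"
DRUG_RESPONDING = "drug_responding"


@dataclass
class NMFConfig:
    """Configuration of the multi-restart deconvolution.

    Defaults are scaled down for desk use (50 restarts x 10 repeats); the
    full-scale setting is 1000 x 100 (100,000 fits per compound).
    """

    k: int = 2
    restarts: int = 50
    repeats: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    seed: int | None = None
    include_controls: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.restarts < 1 or self.repeats < 1:
            raise ConfigError("restarts and repeats must be >= 1")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.tol < 0:
            raise ConfigError("tol must be >= 0")


@dataclass
class DeconvolutionResult:
    """Outcome of the post-modified NMF on one compound."""

    compound: str
    gene_ids: list[str]
    sample_ids: list[str]
    W_star: np.ndarray = field(repr=False)
    H_star: np.ndarray = field(repr=False)
    labels: list[str]
    rmse: float
    negative_fraction: float
    control_correlations: np.ndarray
    restart_rmse: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return self.W_star.shape[1]

    def component_index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def w_env(self) -> np.ndarray:
        return self.W_star[:, self.component_index(ENVIRONMENTAL)]

    @property
    def w_drug(self) -> np.ndarray:
        return self.W_star[:, self.component_index(DRUG_RESPONDING)]


def _as_matrix(V: ExpressionMatrix | np.ndarray) -> np.ndarray:
    A = V.values if isinstance(V, ExpressionMatrix) else np.asarray(V, dtype=float)
    if A.ndim != 2:
        raise DataError("V must be a 2-D matrix")
    if np.any(A < 0):
        raise DataError("V must be nonnegative")
    return A


def _solve_clamped(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """argmin_X ||B - A X||_F solved by normal equations, negatives clamped."""
    G = A.T @ A
    try:
        X = np.linalg.solve(G, A.T @ B)
    except np.linalg.LinAlgError:
        X = np.linalg.pinv(G) @ (A.T @ B)
    np.maximum(X, 0.0, out=X)
    return X


def _als_iterate(A, W, max_iter, tol):
    """Inner ALS loop, numpy reference semantics.

    Returns (W, H, loss, flag, iters_done); flag 1 signals an all-zero H
    row (dead component) so the caller can re-initialize and resume.
    """
    n = A.shape[1]
    k = W.shape[1]
    nA2 = (A * A).sum()
    prev = np.inf
    loss = np.inf
    H = np.zeros((k, n))
    it = 0
    for it in range(1, max_iter + 1):
        H = _solve_clamped(W, A)
        if (H.sum(axis=1) == 0.0).any():
            return W, H, loss, 1, it
        Gh = H @ H.T
        HAt = H @ A.T
        try:
            W = np.linalg.solve(Gh, HAt).T
        except np.linalg.LinAlgError:
            W = (np.linalg.pinv(Gh) @ HAt).T
        np.maximum(W, 0.0, out=W)
        # ||A - WH||^2 via the trace identity; avoids the m x n residual
        loss2 = nA2 - 2.0 * (W * HAt.T).sum() + ((W.T @ W) * Gh).sum()
        loss = np.sqrt(loss2) if loss2 > 0.0 else 0.0
        if prev < np.inf and abs(prev - loss) <= tol * prev:
            break
        prev = loss
    return W, H, loss, 0, it


def _als_kernel(A, W, max_iter, tol):  # pragma: no cover - jitted hot path
    """Loop-explicit ALS kernel for numba (no BLAS/LAPACK call overhead).

    Same contract as :func:`_als_iterate`; flag 2 signals a singular
    normal matrix (caller falls back to the numpy path).
    """
    m, n = A.shape
    k = W.shape[1]
    At = np.ascontiguousarray(A.T)  # (n, m): unit-stride gene axis
    Wt = np.ascontiguousarray(W.T)  # (k, m)
    nA2 = 0.0
    for j in range(n):
        for i in range(m):
            nA2 += At[j, i] * At[j, i]
    G = np.empty((k, k))
    RHS = np.empty((k, n))
    H = np.zeros((k, n))
    HAt = np.empty((k, m))
    Gh0 = np.empty((k, k))
    prev = np.inf
    loss = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # H-step: solve (W'W) H = W'A, clamp negatives
        for a in range(k):
            for b in range(k):
                s = 0.0
                for i in range(m):
                    s += Wt[a, i] * Wt[b, i]
                G[a, b] = s
            for j in range(n):
                s = 0.0
                for i in range(m):
                    s += Wt[a, i] * At[j, i]
                RHS[a, j] = s
        if _gauss_solve(G, RHS) != 0:
            return Wt.T.copy(), H, loss, 2, it
        for a in range(k):
            rowsum = 0.0
            for j in range(n):
                v = RHS[a, j]
                if v < 0.0:
                    v = 0.0
                H[a, j] = v
                rowsum += v
            if rowsum == 0.0:
                return Wt.T.copy(), H, loss, 1, it
        # W-step: solve (HH') W' = H A', clamp negatives
        Gh = np.empty((k, k))
        for a in range(k):
            for b in range(k):
                s = 0.0
                for j in range(n):
                    s += H[a, j] * H[b, j]
                Gh[a, b] = s
                Gh0[a, b] = s
        for a in range(k):
            for i in range(m):
                HAt[a, i] = 0.0
            for j in range(n):
                c = H[a, j]
                for i in range(m):
                    HAt[a, i] += c * At[j, i]
        SOL = HAt.copy()
        if _gauss_solve(Gh, SOL) != 0:
            return Wt.T.copy(), H, loss, 2, it
        for a in range(k):
            for i in range(m):
                v = SOL[a, i]
                if v < 0.0:
                    v = 0.0
                Wt[a, i] = v
        # loss^2 = ||A||^2 - 2 tr(W' A H') + tr(W'W HH')
        cross = 0.0
        for a in range(k):
            for i in range(m):
                cross += Wt[a, i] * HAt[a, i]
        gww = 0.0
        for a in range(k):
            for b in range(k):
                s = 0.0
                for i in range(m):
                    s += Wt[a, i] * Wt[b, i]
                gww += s * Gh0[a, b]
        loss2 = nA2 - 2.0 * cross + gww
        loss = np.sqrt(loss2) if loss2 > 0.0 else 0.0
        if prev < np.inf and abs(prev - loss) <= tol * prev:
            break
        prev = loss
    return Wt.T.copy(), H, loss, 0, it


def _gauss_solve_py(G, B):  # pragma: no cover - jitted hot path
    """In-place Gaussian elimination with partial pivoting; 0 on success."""
    k = G.shape[0]
    n = B.shape[1]
    for col in range(k):
        piv = col
        best = abs(G[col, col])
        for r in range(col + 1, k):
            if abs(G[r, col]) > best:
                best = abs(G[r, col])
                piv = r
        if best < 1e-300:
            return 1
        if piv != col:
            for c in range(k):
                G[col, c], G[piv, c] = G[piv, c], G[col, c]
            for c in range(n):
                B[col, c], B[piv, c] = B[piv, c], B[col, c]
        inv = 1.0 / G[col, col]
        for r in range(col + 1, k):
            f = G[r, col] * inv
            if f != 0.0:
                for c in range(col, k):
                    G[r, c] -= f * G[col, c]
                for c in range(n):
                    B[r, c] -= f * B[col, c]
    for col in range(k - 1, -1, -1):
        inv = 1.0 / G[col, col]
        for c in range(n):
            s = B[col, c]
            for r in range(col + 1, k):
                s -= G[col, r] * B[r, c]
            B[col, c] = s * inv
    return 0


try:  # optional speedup; the numpy path is the reference semantics
    from numba import njit as _njit

    _gauss_solve = _njit(cache=True)(_gauss_solve_py)
    _als_iterate_fast = _njit(cache=True)(_als_kernel)
except ImportError:  # pragma: no cover
    _gauss_solve = _gauss_solve_py
    _als_iterate_fast = _als_iterate


def als_nmf(
    V: ExpressionMatrix | np.ndarray,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One ALS-NMF fit from a random dense start.

    Returns (W, H, rmse) with rmse = ||V - WH||_F / sqrt(m*n). W is
    initialized uniform(0, 1] scaled by the overall mean of V; both
    half-steps clamp negatives to zero. Iteration stops at ``max_iter`` or
    when the relative change of the loss falls below ``tol``.
    """
    A = _as_matrix(V)
    m, n = A.shape
    if k >= n:
        raise ConfigError(f"k={k} must be smaller than the number of samples n={n}")
    if k > m:
        raise ConfigError(f"k={k} exceeds the number of genes m={m}")
    if not A.any():
        raise DataError("V is all zero; NMF undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    scale = A.mean()
    A = np.ascontiguousarray(A)
    W = (1.0 - rng.random((m, k))) * scale  # uniform (0, 1] * mean(V)
    remaining = max_iter
    while True:
        W, H, loss, flag, used = _als_iterate_fast(A, W, remaining, tol)
        if flag == 2:  # singular normal matrix: retreat to the pinv-robust path
            W, H, loss, flag, used2 = _als_iterate(A, W, remaining - used, tol)
            used += used2
        remaining -= used
        if flag != 1 or remaining <= 0:
            break
        # revive dead components with fresh random columns and resume
        dead_rows = ~H.any(axis=1)
        W[:, dead_rows] = (1.0 - rng.random((m, int(dead_rows.sum())))) * scale
    if not np.isfinite(loss):
        loss = float(np.linalg.norm(A - W @ H))
    return W, H, float(loss / np.sqrt(m * n))


def normalize_weights(H: np.ndarray, sample_ids: Sequence[str] | None = None) -> np.ndarray:
    """Rescale H so that every column sums to one (H*)."""
    H = np.asarray(H, dtype=float)
    sums = H.sum(axis=0)
    bad = np.nonzero(sums <= 0)[0]
    if bad.size:
        name = sample_ids[bad[0]] if sample_ids is not None else f"column {bad[0]}"
        raise DataError(f"zero-sum weight column for sample {name}")
    return H / sums


def refit_signatures(
    V: ExpressionMatrix | np.ndarray,
    H_star: np.ndarray,
    clamp_negatives: bool = True,
) -> tuple[np.ndarray, float]:
    """Least-squares re-estimate W* = V H*'(H* H*')^-1.

    Returns (W_star, negative_fraction). With ``clamp_negatives`` (the
    default) negative entries are set to zero; ``negative_fraction`` is the
    fraction of entries that were (or would be) clamped.
    """
    A = _as_matrix(V)
    H = np.asarray(H_star, dtype=float)
    G = H @ H.T
    k = H.shape[0]
    if np.linalg.matrix_rank(G) < k:
        raise DataError(
            "H* H*' is singular (degenerate weights, e.g. identical columns); "
            "cannot refit signatures"
        )
    W = A @ H.T @ np.linalg.inv(G)
    neg = float(np.mean(W < 0))
    if clamp_negatives:
        W = np.maximum(W, 0.0)
    return W, neg


def label_components(
    W_star: np.ndarray, control_profile: np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Label the two W* columns by Pearson correlation with the control profile.

    The column with the higher correlation is the environmental component,
    the other the drug-responding component.
    """
    W = np.asarray(W_star, dtype=float)
    if W.ndim != 2 or W.shape[1] != 2:
        raise ConfigError("component labeling is defined for exactly k = 2 components")
    c = np.asarray(control_profile, dtype=float)
    if c.shape[0] != W.shape[0]:
        raise DataError("control profile length does not match the number of genes")
    corrs = np.empty(2)
    for j in range(2):
        col = W[:, j]
        if np.std(col) == 0 or np.std(c) == 0:
            warnings.warn(
                f"zero-variance column {j}; correlation undefined, labeled drug_responding",
                stacklevel=2,
            )
            corrs[j] = -np.inf
        else:
            corrs[j] = np.corrcoef(col, c)[0, 1]
    env = int(np.argmax(corrs))
    labels = [DRUG_RESPONDING, DRUG_RESPONDING]
    labels[env] = ENVIRONMENTAL
    out = np.where(np.isfinite(corrs), corrs, np.nan)
    return labels, out


def _align_components(W_ref: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Permutation mapping columns of W onto W_ref by greedy max correlation."""
    k = W_ref.shape[1]
    C = np.corrcoef(W_ref.T, W.T)[:k, k:]
    C = np.nan_to_num(C, nan=-1.0)
    best = np.argmax(C, axis=1)
    if len(set(best.tolist())) < k:
        warnings.warn(
            "component alignment ambiguous; resolved by greedy assignment",
            stacklevel=2,
        )
    perm = np.full(k, -1)
    flat = np.dstack(np.unravel_index(np.argsort(C, axis=None)[::-1], C.shape))[0]
    used_ref, used_col = set(), set()
    for i, j in flat:
        if i in used_ref or j in used_col:
            continue
        perm[i] = j
        used_ref.add(int(i))
        used_col.add(int(j))
        if len(used_ref) == k:
            break
    return perm


def multi_restart_deconvolute(
    ds: CompoundDataset, config: NMFConfig
) -> DeconvolutionResult:
    """Full post-modified NMF with restarts, repeat-averaging and labeling.

    For each of ``config.repeats`` outer rounds, ``config.restarts`` ALS
    fits are run from fresh random starts and the minimum-RMSE fit is
    post-modified (H normalized, W* refit). The rounds' winners are aligned
    to the first winner and averaged; the averaged H* is re-normalized and
    W* refit once more against V before labeling (k = 2 only).
    """
    V = ds.treated.values
    sample_ids = list(ds.treated.sample_ids)
    if config.include_controls:
        V = np.hstack([V, ds.controls.values])
        sample_ids = sample_ids + list(ds.controls.sample_ids)
    rng = np.random.default_rng(config.seed)

    winners: list[tuple[np.ndarray, np.ndarray]] = []
    restart_rmse = np.empty((config.repeats, config.restarts))
    for rep in range(config.repeats):
        best = None
        for rs in range(config.restarts):
            W, H, rmse = als_nmf(
                V, config.k, max_iter=config.max_iter, tol=config.tol, seed=rng
            )
            restart_rmse[rep, rs] = rmse
            if best is None or rmse < best[2]:
                best = (W, H, rmse)
        W, H, _ = best
        H_star = normalize_weights(H, sample_ids)
        W_star, _ = refit_signatures(V, H_star)
        winners.append((W_star, H_star))

    W_ref = winners[0][0]
    W_acc = np.zeros_like(W_ref)
    H_acc = np.zeros_like(winners[0][1])
    for W_star, H_star in winners:
        perm = _align_components(W_ref, W_star)
        W_acc += W_star[:, perm]
        H_acc += H_star[perm, :]
    W_avg = W_acc / len(winners)
    H_avg = H_acc / len(winners)

    H_final = normalize_weights(H_avg, sample_ids)
    W_final, neg_frac = refit_signatures(V, H_final)
    rmse = float(np.linalg.norm(V - W_final @ H_final) / np.sqrt(V.size))

    if config.k == 2:
        labels, corrs = label_components(W_final, control_mean_profile(ds))
    else:
        labels = [f"component_{j}" for j in range(config.k)]
        corrs = np.full(config.k, np.nan)

    return DeconvolutionResult(
        compound=ds.compound,
        gene_ids=list(ds.gene_ids),
        sample_ids=sample_ids,
        W_star=W_final,
        H_star=H_final,
        labels=labels,
        rmse=rmse,
        negative_fraction=neg_frac,
        control_correlations=corrs,
        restart_rmse=restart_rmse,
    )


class PostModifiedNMF(TransformerMixin, BaseEstimator):
    """Post-modified NMF as a scikit-learn transformer.

    Parameters mirror :class:`NMFConfig`. ``X`` follows the scikit-learn
    orientation (n_samples, n_features=genes), the transpose of the
    genes x samples matrix the domain functions use.

    Attributes
    ----------
    components_ : ndarray of shape (n_components, n_genes)
        Rows are the refit component signatures (W* transposed).
    weights_ : ndarray of shape (n_components, n_samples)
        Column-stochastic relative weights H* of the training samples.
    reconstruction_rmse_ : float
        ||V - W* H*||_F / sqrt(m n) of the final fit.
    negative_fraction_ : float
        Fraction of W* entries clamped to zero in the final refit.
    """

    def __init__(
        self,
        n_components: int = 2,
        restarts: int = 50,
        repeats: int = 10,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.restarts = restarts
        self.repeats = repeats
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _config(self) -> NMFConfig:
        return NMFConfig(
            k=self.n_components,
            restarts=self.restarts,
            repeats=self.repeats,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DataError("X must be 2-D (n_samples, n_genes)")
        V = X.T
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(V.shape[0])],
            [f"s{j}" for j in range(V.shape[1])],
            V,
        )
        ds = CompoundDataset(
            compound="_fit",
            treated=expr,
            controls=expr.select_samples([expr.sample_ids[0]]),
            system="in_vitro",
        )
        res = multi_restart_deconvolute(ds, self._config())
        self.components_ = res.W_star.T.copy()
        self.weights_ = res.H_star.copy()
        self.reconstruction_rmse_ = res.rmse
        self.negative_fraction_ = res.negative_fraction
        self.n_features_in_ = X.shape[1]
        return self.weights_.T.copy()

    def transform(self, X):
        """Project new samples on the fitted signatures; returns H*' per sample."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"X has {X.shape[1]} features; estimator was fitted with {self.n_features_in_}"
            )
        H = _solve_clamped(self.components_.T, X.T)
        return normalize_weights(H).T

    def inverse_transform(self, W):
        check_is_fitted(self, "components_")
        return np.asarray(W) @ self.components_
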