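"""Simulated in vivo profiles from in vitro data plus the environmental component.

After deconvoluting an in vivo compound into W* = [w_env, w_drug] and the
column-stochastic weights H*, a simulated in vivo matrix is obtained by
swapping the drug-responding column for the compound's averaged in vitro
profile (optionally rescaled by a linear regression fitted across genes,
y = A x + B with y = drug-responding component, x = in vitro profile, which
maps the in vitro measurement scale onto the in vivo drug-component scale)
and recombining:

    V_simulated = [w_env, A * w_invitro + B] . H*

Gene-wise concordance between a component and an in vitro profile is
summarized by the R^2 of the ordinary least-squares fit and the raw RMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_data import CompoundDataset
from .deconvolution import DeconvolutionResult
from .errors import DataError

__all__ = [
    "RegressionParams",
    "SimulationBundle",
    "average_invitro",
    "fit_scale_regression",
    "build_modified_W",
    "simulate_invivo",
    "concordance_metrics",
    "simulate_compound",
]

logger = logging.getLogger(__name__)


@dataclass
class RegressionParams:
    """Across-genes linear link between the drug component and in vitro data."""

    slope: float
    intercept: float
    r_squared: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class SimulationBundle:
    """All pieces of one compound's simulated in vivo matrix."""

    compound: str
    w_env: np.ndarray = field(repr=False)
    w_invitro: np.ndarray = field(repr=False)
    W_modified: np.ndarray = field(repr=False)
    H_invivo_star: np.ndarray = field(repr=False)
    V_simulated: np.ndarray = field(repr=False)
    regression: RegressionParams | None = None


def average_invitro(invitro: CompoundDataset, gene_ids: list[str] | None = None) -> np.ndarray:
    """Per-gene mean over the in vitro treated replicate columns."""
    if gene_ids is not None and invitro.gene_ids != list(gene_ids):
        raise DataError(
            "in vitro gene order does not match the in vivo matrices; "
            "run intersect_genes first"
        )
    return invitro.treated.values.mean(axis=1)


def fit_scale_regression(w_drug: np.ndarray, w_invitro: np.ndarray) -> RegressionParams:
    """OLS of the drug component (y) on the in vitro profile (x) across genes."""
    y = np.asarray(w_drug, dtype=float)
    x = np.asarray(w_invitro, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("w_drug and w_invitro must be equal-length vectors")
    if x.size < 2:
        raise DataError("need at least two genes to fit a regression")
    if np.var(x) == 0:
        raise DataError("in vitro profile has zero variance; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionParams(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def build_modified_W(
    w_env: np.ndarray,
    w_invitro: np.ndarray,
    regression: RegressionParams | None = None,
    env_index: int = 0,
) -> np.ndarray:
    """Assemble W_modified = [w_env, corrected w_invitro] (m x 2).

    ``env_index`` keeps the environmental column at the position it held in
    the original W* so that H* rows stay matched. With a regression the
    inserted column is A*x + B; negatives after the affine correction are
    clamped to zero (fraction logged).
    """
    e = np.asarray(w_env, dtype=float)
    x = np.asarray(w_invitro, dtype=float)
    if e.shape != x.shape or e.ndim != 1:
        raise DataError("w_env and w_invitro must be equal-length vectors")
    if np.any(e < 0):
        raise DataError("environmental component must be nonnegative")
    if env_index not in (0, 1):
        raise DataError("env_index must be 0 or 1 for k = 2")
    col = regression.apply(x) if regression is not None else x.copy()
    neg = float(np.mean(col < 0))
    if neg > 0:
        logger.info("clamped %.4f%% negative entries after affine correction", 100 * neg)
        col = np.maximum(col, 0.0)
    W = np.empty((e.size, 2))
    W[:, env_index] = e
    W[:, 1 - env_index] = col
    return W


def simulate_invivo(W_modified: np.ndarray, H_invivo_star: np.ndarray) -> np.ndarray:
    """V_simulated = W_modified . H* (shapes must conform)."""
    W = np.asarray(W_modified, dtype=float)
    H = np.asarray(H_invivo_star, dtype=float)
    if W.ndim != 2 or H.ndim != 2 or W.shape[1] != H.shape[0]:
        raise DataError(
            f"non-conformable shapes {W.shape} x {H.shape} for the simulation product"
        )
    return W @ H


def concordance_metrics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(R^2 of the OLS fit of y on x, raw RMSE sqrt(mean((x - y)^2)))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise DataError("x and y must be equal-length vectors of length >= 2")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DataError("zero variance input; R^2 undefined")
    r = stats.pearsonr(x, y).statistic
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    return float(r**2), rmse


def simulate_compound(
    deconv: DeconvolutionResult,
    invitro: CompoundDataset,
    regress: bool = True,
) -> SimulationBundle:
    """End-to-end simulation of one compound from its deconvolution result."""
    if invitro.gene_ids != deconv.gene_ids:
        raise DataError(
            "in vitro gene order does not match the deconvolution; "
            "run intersect_genes first"
        )
    w_invitro = average_invitro(invitro)
    regression = fit_scale_regression(deconv.w_drug, w_invitro) if regress else None
    env_index = deconv.component_index("environmental")
    W_mod = build_modified_W(deconv.w_env, w_invitro, regression, env_index=env_index)
    V_sim = simulate_invivo(W_mod, deconv.H_star)
    return SimulationBundle(
        compound=deconv.compound,
        w_env=deconv.w_env.copy(),
        w_invitro=w_invitro,
        W_modified=W_mod,
        H_invivo_star=deconv.H_star.copy(),
        V_simulated=V_sim,
        regression=regression,
    )
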