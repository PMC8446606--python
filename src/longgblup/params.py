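"""Time-scale genetic parameters from a fitted random regression model.

The coefficient covariance ``G0`` induces a genetic covariance between any
two days via the basis: ``Sigma = T G0 T'``.  Per-day heritability divides
the genetic variance by genetic-plus-residual variance, with the residual
variance taken from the DAP class of each day under heterogeneous fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .residuals import ResidualClassMap
from .rrm import RRMFit

__all__ = [
    "GeneticParams",
    "genetic_covariance",
    "heritability",
    "genetic_correlation",
    "gebv_trajectories",
]


@dataclass
class GeneticParams:
    dap_grid: np.ndarray
    Sigma: np.ndarray                    # (d, d) genetic covariance over the grid
    h2: np.ndarray | None = None         # (d,) per-day heritability
    gen_corr: np.ndarray | None = None   # (d, d) genetic correlation


def genetic_covariance(fit: RRMFit, basis=None, dap_grid=None) -> GeneticParams:
    """Genetic covariance over the DAP grid, ``Sigma = T G0 T'``.

    Defaults: the fit's own basis and every integer DAP in its range.
    """
    basis = basis if basis is not None else fit.basis
    if dap_grid is None:
        dap_grid = np.arange(int(basis.dap_min), int(basis.dap_max) + 1)
    dap_grid = np.asarray(dap_grid)
    T = basis.design_matrix(dap_grid)  # raises on out-of-range grid
    Sigma = T @ fit.G0_hat @ T.T
    return GeneticParams(dap_grid=dap_grid, Sigma=0.5 * (Sigma + Sigma.T))


def heritability(params: GeneticParams, fit: RRMFit,
                 residual_map: ResidualClassMap | None = None) -> np.ndarray:
    """Per-day narrow-sense heritability h2(j) = sigma2_a(j) / (sigma2_a(j) + sigma2_e(class(j)))."""
    rmap = residual_map if residual_map is not None else fit.residual_map
    cls = rmap.class_of(params.dap_grid)
    sig_e = np.asarray(fit.residual_variances)[cls]
    sig_a = np.diag(params.Sigma).copy()
    total = sig_a + sig_e
    if np.any(total <= 0):
        bad = params.dap_grid[total <= 0]
        raise ValueError(f"zero total variance; heritability undefined at DAP {bad}")
    h2 = sig_a / total
    params.h2 = h2
    return h2


def genetic_correlation(params: GeneticParams) -> np.ndarray:
    """DAP x DAP genetic correlation r(j,j') = Sigma(j,j') / sqrt(Sigma(j,j) Sigma(j',j')).

    Days with zero genetic variance get NaN rows/columns rather than raising.
    """
    d = np.diag(params.Sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(d, d))
        corr = np.where(denom > 0, params.Sigma / denom, np.nan)
    np.fill_diagonal(corr, np.where(d > 0, 1.0, np.nan))
    params.gen_corr = corr
    return corr


def gebv_trajectories(fit: RRMFit, basis=None, dap_grid=None) -> np.ndarray:
    """Line x DAP matrix of genomic breeding values, row i = T g_hat_i."""
    basis = basis if basis is not None else fit.basis
    if dap_grid is None:
        dap_grid = np.arange(int(basis.dap_min), int(basis.dap_max) + 1)
    T = basis.design_matrix(np.asarray(dap_grid))
    return fit.g_hat @ T.T
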