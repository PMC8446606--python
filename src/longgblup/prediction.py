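"""Cross-validated genomic prediction of breeding-value trajectories.

Lines are partitioned into k folds.  For each fold the model is refitted on
the training lines' phenotypes only — validation lines keep their genotypes
(they stay in G), which is what makes prediction of unphenotyped lines
possible.  Per DAP, accuracy is the Pearson correlation between full-data
and reduced-data GEBVs over the validation lines, and bias is the slope of
regressing the full-data GEBV on the reduced-data GEBV; both are averaged
over folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PhenotypeTable
from .grm import GRMResult
from .residuals import ResidualClassMap
from .rrm import RandomRegressionGBLUP

logger = logging.getLogger(__name__)

__all__ = ["CVResult", "make_folds", "cv_predict", "accuracy_and_bias"]


@dataclass
class CVResult:
    dap_grid: np.ndarray
    accuracy: np.ndarray        # (d,) mean Pearson r over folds
    bias: np.ndarray            # (d,) mean slope b1 over folds
    per_fold: pd.DataFrame      # long table: fold, dap, r, b1, n_val
    folds: np.ndarray           # fold index per line (grm order)
    line_ids: list
    seed: int | None = None


def make_folds(line_ids, k: int = 5, seed: int | None = None,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform random partition of lines into k folds of near-equal size."""
    n = len(line_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of lines n={n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    # first (n mod k) folds get the extra line
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    assignment = np.repeat(np.arange(k), sizes)
    return assignment[rng.permutation(n)]


def accuracy_and_bias(full: np.ndarray, reduced: np.ndarray):
    """Per-DAP Pearson r and regression slope of full on reduced GEBV.

    Both inputs are (n_val, d) matrices over the same validation lines.
    """
    fc = full - full.mean(axis=0)
    rc = reduced - reduced.mean(axis=0)
    var_r = (rc ** 2).mean(axis=0)
    var_f = (fc ** 2).mean(axis=0)
    cov = (fc * rc).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((var_r > 0) & (var_f > 0), cov / np.sqrt(var_r * var_f), np.nan)
        b1 = np.where(var_r > 0, cov / var_r, np.nan)
    return r, b1


def cv_predict(
    phenotypes: PhenotypeTable,
    grm: GRMResult,
    basis,
    residual_map: ResidualClassMap | None = None,
    residual_mode: str = "heterogeneous",
    folds: np.ndarray | None = None,
    k: int = 5,
    seed: int | None = None,
    dap_grid=None,
    reestimate_varcomps: bool = True,
    pool_validation: bool = False,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> CVResult:
    """k-fold cross-validated prediction of GEBV trajectories.

    ``reestimate_varcomps=False`` reuses the full-data variance components in
    each fold (mixed-model solve only), trading exactness for speed.
    ``pool_validation=True`` pools validation lines across folds before
    computing r and b1 instead of averaging per-fold values.
    """
    if dap_grid is None:
        dap_grid = np.arange(int(basis.dap_min), int(basis.dap_max) + 1)
    dap_grid = np.asarray(dap_grid)
    if folds is None:
        folds = make_folds(grm.line_ids, k=k, seed=seed)
    folds = np.asarray(folds)
    k_eff = int(folds.max()) + 1

    def _fit(tbl, varcomps=None):
        est = RandomRegressionGBLUP(
            basis=basis, residual_mode=residual_mode, residual_map=residual_map,
            max_iter=max_iter, tol=tol, varcomps=varcomps,
        )
        return est.fit(tbl, grm).fit_

    full_fit = _fit(phenotypes)
    full_gebv = full_fit.gebv(dap_grid)           # (n, d) in grm line order
    fixed_vc = None if reestimate_varcomps else (
        full_fit.G0_hat, full_fit.residual_variances
    )

    rows = []
    pooled_full, pooled_red = [], []
    line_arr = np.asarray(grm.line_ids, dtype=object)
    for f in range(k_eff):
        val_mask = folds == f
        n_val = int(val_mask.sum())
        if n_val < 3:
            logger.warning("fold %d has %d validation line(s); skipped", f, n_val)
            continue
        train_lines = line_arr[~val_mask]
        red_fit = _fit(phenotypes.subset_lines(train_lines), varcomps=fixed_vc)
        red_gebv = red_fit.gebv(dap_grid)
        r, b1 = accuracy_and_bias(full_gebv[val_mask], red_gebv[val_mask])
        pooled_full.append(full_gebv[val_mask])
        pooled_red.append(red_gebv[val_mask])
        for j, dap in enumerate(dap_grid):
            rows.append({"fold": f, "dap": int(dap), "r": r[j], "b1": b1[j], "n_val": n_val})

    per_fold = pd.DataFrame(rows)
    if per_fold.empty:
        raise ValueError("no usable folds")
    if pool_validation:
        r, b1 = accuracy_and_bias(np.vstack(pooled_full), np.vstack(pooled_red))
        acc, bias = r, b1
    else:
        g = per_fold.groupby("dap", sort=True)
        acc = g["r"].mean().reindex(dap_grid).to_numpy()
        bias = g["b1"].mean().reindex(dap_grid).to_numpy()
    return CVResult(
        dap_grid=dap_grid, accuracy=acc, bias=bias, per_fold=per_fold,
        folds=folds, line_ids=list(grm.line_ids), seed=seed,
    )
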