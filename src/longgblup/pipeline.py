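"""End-to-end pipeline driver: fit, genetic parameters, CV, GWAS, artifacts.

Every stage writes deterministic CSV/JSON files (fixed float formatting, no
timestamps inside the data files), so identical (inputs, config, seed) runs
produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas as gwas_mod
from .config import RunConfig
from .data import GenotypePanel, PhenotypeTable
from .grm import qc_filter, vanraden_grm
from .params import (
    genetic_correlation,
    genetic_covariance,
    gebv_trajectories,
    heritability,
)
from .prediction import cv_predict, make_folds
from .rrm import RandomRegressionGBLUP, aic_compare

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

__all__ = ["run_pipeline", "candidate_model_grid"]


def candidate_model_grid(dap_min: int, dap_max: int):
    """The seven candidate covariance-function models compared by AIC:
    Legendre orders 3-5 and linear/quadratic B-splines with one knot
    (mid-range) or two knots (44 and 66 DAP on the default range, else the
    terciles of the range)."""
    from .basis import BSplineBasis, LegendreBasis

    mid = (dap_min + dap_max) // 2
    k2 = (44, 66) if (dap_min, dap_max) == (27, 83) else (
        dap_min + (dap_max - dap_min) // 3, dap_min + 2 * (dap_max - dap_min) // 3
    )
    models = [
        (f"legendre_{o}", LegendreBasis(order=o, dap_min=dap_min, dap_max=dap_max))
        for o in (3, 4, 5)
    ]
    models += [
        ("bspline_lin_1knot", BSplineBasis(1, (mid,), dap_min, dap_max)),
        ("bspline_lin_2knot", BSplineBasis(1, k2, dap_min, dap_max)),
        ("bspline_quad_1knot", BSplineBasis(2, (mid,), dap_min, dap_max)),
        ("bspline_quad_2knot", BSplineBasis(2, k2, dap_min, dap_max)),
    ]
    return models


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def run_pipeline(
    config: RunConfig,
    genotypes: GenotypePanel,
    phenotypes: PhenotypeTable,
    annotation=None,
    out_dir="pipeline_out",
    select_model: bool = False,
) -> dict:
    """Run QC -> (optional AIC model selection) -> REML fit -> genetic
    parameters -> cross-validation -> GWAS, writing artifacts under
    ``out_dir``.  Returns the in-memory results keyed by stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "config"
    try:
        config.to_json(out / "config.json")

        stage = "qc"
        panel = qc_filter(genotypes)
        grm = vanraden_grm(panel)
        phen, n_dropped = phenotypes.restrict_dap(config.dap_min, config.dap_max)
        if n_dropped:
            logger.info("dropped %d record(s) outside DAP range", n_dropped)
        phen = phen.subset_lines(grm.line_ids)

        stage = "model_selection"
        basis = config.basis()
        rmap = config.residual_map()
        if select_model:
            fits = []
            for label, cand in candidate_model_grid(config.dap_min, config.dap_max):
                est = RandomRegressionGBLUP(
                    basis=cand, residual_mode=config.residual_mode,
                    residual_map=rmap, max_iter=config.max_iter, tol=config.tol,
                    label=label,
                )
                fits.append(est.fit(phen, grm).fit_)
            table = aic_compare(fits)
            _write_csv(table, out / "model_selection.csv")
            results["model_selection"] = table
            best = table.loc[table["converged"], "model"].iloc[0]
            basis = dict(candidate_model_grid(config.dap_min, config.dap_max))[best]

        stage = "fit"
        est = RandomRegressionGBLUP(
            basis=basis, residual_mode=config.residual_mode, residual_map=rmap,
            max_iter=config.max_iter, tol=config.tol,
        )
        fit = est.fit(phen, grm).fit_
        results["fit"] = fit
        summary = {
            "basis": basis.to_config(),
            "G0": fit.G0_hat.tolist(),
            "residual_variances": fit.residual_variances.tolist(),
            "residual_intervals": fit.residual_map.to_config(),
            "logL_reml": fit.logL_reml,
            "n_varcomp_params": fit.n_varcomp_params,
            "AIC": fit.AIC,
            "converged": fit.converged,
            "n_iterations": fit.n_iterations,
            "seed": config.seed,
        }
        (out / "fit_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        coefs = pd.DataFrame(
            fit.g_hat, columns=[f"g{j}" for j in range(fit.g_hat.shape[1])]
        )
        coefs.insert(0, "line", fit.line_ids)
        _write_csv(coefs, out / "coefficient_blups.csv")

        stage = "genetic_params"
        dap_grid = np.arange(config.dap_min, config.dap_max + 1)
        gp = genetic_covariance(fit, basis, dap_grid)
        h2 = heritability(gp, fit)
        corr = genetic_correlation(gp)
        _write_csv(
            pd.DataFrame({"dap": dap_grid, "genetic_variance": np.diag(gp.Sigma), "h2": h2}),
            out / "h2_by_dap.csv",
        )
        corr_df = pd.DataFrame(corr, columns=[str(d) for d in dap_grid])
        corr_df.insert(0, "dap", dap_grid)
        _write_csv(corr_df, out / "genetic_correlation.csv")
        gebv = gebv_trajectories(fit, basis, dap_grid)
        gebv_df = pd.DataFrame(gebv, columns=[str(d) for d in dap_grid])
        gebv_df.insert(0, "line", fit.line_ids)
        _write_csv(gebv_df, out / "gebv_trajectories.csv")
        results["genetic_params"] = gp

        stage = "cv"
        folds = make_folds(
            grm.line_ids, k=config.cv_folds,
            rng=np.random.default_rng([config.seed, 1]),
        )
        cv = cv_predict(
            phen, grm, basis, residual_map=rmap, residual_mode=config.residual_mode,
            folds=folds, dap_grid=dap_grid,
            reestimate_varcomps=config.reestimate_varcomps,
            max_iter=config.max_iter, tol=config.tol,
        )
        _write_csv(
            pd.DataFrame({"dap": dap_grid, "accuracy": cv.accuracy, "bias_b1": cv.bias}),
            out / "cv_accuracy_by_dap.csv",
        )
        _write_csv(cv.per_fold, out / "cv_per_fold.csv")
        results["cv"] = cv

        stage = "gwas"
        traj = gwas_mod.backsolve_snp_effects(fit, grm)
        traj = gwas_mod.effects_over_time(traj, basis, dap_grid)
        eff = pd.DataFrame(traj.effects_by_dap, columns=[str(d) for d in dap_grid])
        eff.insert(0, "snp_id", traj.snp_ids)
        _write_csv(eff, out / "snp_effects_by_dap.csv")
        selected = gwas_mod.select_top_snps(traj, k=config.top_k)
        _write_csv(selected, out / "selected_snps_by_dap.csv")
        report = gwas_mod.duration_report(selected)
        _write_csv(report, out / "selected_snps_duration.csv")
        results["gwas"] = {"selected": selected, "duration": report}
        if annotation is not None:
            hits = gwas_mod.candidate_windows(
                selected, annotation, half_width=config.window_half_width
            )
            _write_csv(hits, out / "candidate_windows.csv")
            results["gwas"]["candidates"] = hits
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return results
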