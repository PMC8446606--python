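"""Longitudinal GWAS from back-solved SNP effects.

Per-coefficient SNP effects are recovered from the coefficient BLUPs by the
GBLUP back-solving identity ``u_m = D Z' (Z D Z')^{-1} g_m`` with D the
identity (equal prior SNP weights); the time trajectory of each SNP's effect
is then ``T u_s``.  Relevance is rank-based: the top-k SNPs by absolute
effect on each day, with the day sets classified by duration of presence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import GRMResult
from .rrm import RRMFit

logger = logging.getLogger(__name__)

__all__ = [
    "SnpEffectTrajectories",
    "backsolve_snp_effects",
    "effects_over_time",
    "select_top_snps",
    "classify_duration",
    "candidate_windows",
]


@dataclass
class SnpEffectTrajectories:
    u_hat: np.ndarray            # (s, m) per-coefficient SNP effects
    effects_by_dap: np.ndarray | None  # (s, d)
    dap_grid: np.ndarray | None
    snp_ids: list
    chrom: np.ndarray
    pos_bp: np.ndarray


def backsolve_snp_effects(fit: RRMFit, grm: GRMResult, weights: np.ndarray | None = None
                          ) -> SnpEffectTrajectories:
    """Back-solve per-coefficient SNP effects from the coefficient BLUPs.

    Uses the identity ``Z D Z' = k_scale * G`` (D = I by default), inverting
    through the relationship matrix; the Moore-Penrose pseudo-inverse is used
    when G is singular.  ``weights`` optionally supplies per-SNP prior
    weights (the diagonal of D).
    """
    if list(fit.line_ids) != list(grm.line_ids):
        raise ValueError("fit and GRM refer to different line sets/orders")
    Z = grm.Z_centered
    if weights is None:
        ZDZt = grm.k_scale * grm.G
        DZt = Z.T
    else:
        w = np.asarray(weights, float)
        DZt = w[:, None] * Z.T
        ZDZt = Z @ DZt
    # ZZ' is singular whenever allele frequencies come from the panel itself
    # (centered Z has zero column sums); the Hermitian pseudo-inverse equals
    # the ordinary inverse on full-rank instances and is the Moore-Penrose
    # solution otherwise.
    inv = np.linalg.pinv(ZDZt, rcond=1e-10, hermitian=True)
    # columns of g_hat are the per-coefficient GEBV vectors
    u_hat = DZt @ (inv @ fit.g_hat)   # (s, m)
    return SnpEffectTrajectories(
        u_hat=u_hat, effects_by_dap=None, dap_grid=None,
        snp_ids=list(grm.kept_snp_ids), chrom=grm.chrom.copy(), pos_bp=grm.pos_bp.copy(),
    )


def effects_over_time(traj: SnpEffectTrajectories, basis, dap_grid=None
                      ) -> SnpEffectTrajectories:
    """Project per-coefficient effects through the basis: row s = T u_s."""
    if dap_grid is None:
        dap_grid = np.arange(int(basis.dap_min), int(basis.dap_max) + 1)
    dap_grid = np.asarray(dap_grid)
    T = basis.design_matrix(dap_grid)
    if T.shape[1] != traj.u_hat.shape[1]:
        raise ValueError("basis coefficient count does not match u_hat columns")
    traj.effects_by_dap = traj.u_hat @ T.T
    traj.dap_grid = dap_grid
    return traj


def _chrom_sort_key(chrom: np.ndarray) -> np.ndarray:
    """Sortable numeric key per chromosome label (numeric labels first)."""
    uniq = pd.unique(chrom)

    def key(c):
        try:
            return (0, float(c), str(c))
        except (TypeError, ValueError):
            return (1, 0.0, str(c))

    order = {c: i for i, c in enumerate(sorted(uniq, key=key))}
    return np.array([order[c] for c in chrom], dtype=np.int64)


def select_top_snps(traj: SnpEffectTrajectories, k: int = 10) -> pd.DataFrame:
    """Top-k SNPs by |effect| per DAP; ties go to smaller (chrom, pos).

    Returns a long table with one row per (dap, selected SNP), columns
    ``dap, snp_id, chrom, pos_bp, effect, rank``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    E = traj.effects_by_dap
    if E is None:
        raise ValueError("call effects_over_time first")
    ckey = _chrom_sort_key(traj.chrom)
    s = E.shape[0]
    rows = []
    for j, dap in enumerate(traj.dap_grid):
        mag = np.abs(E[:, j])
        order = np.lexsort((traj.pos_bp, ckey, -mag))  # primary: magnitude desc
        top = order[: min(k, s)]
        for rank, idx in enumerate(top, start=1):
            rows.append(
                {
                    "dap": int(dap),
                    "snp_id": traj.snp_ids[idx],
                    "chrom": traj.chrom[idx],
                    "pos_bp": int(traj.pos_bp[idx]),
                    "effect": float(E[idx, j]),
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows)


def presence_days(selected: pd.DataFrame) -> dict:
    """Map snp_id -> sorted array of days on which the SNP was in the top set."""
    return {
        snp: np.sort(grp["dap"].unique())
        for snp, grp in selected.groupby("snp_id", sort=False)
    }


def classify_duration(days) -> str:
    """Duration category of a SNP's presence-day set.

    Maximal consecutive runs of days are computed; multiple runs mean
    ``intermittent``; a single run of d days is ``long`` (d > 30), ``mid``
    (10 <= d <= 30; runs of exactly 10 or exactly 30 days are boundary
    cases — both are assigned to mid), or ``short`` (d < 10).
    """
    days = np.sort(np.unique(np.asarray(days, dtype=int)))
    if days.size == 0:
        raise ValueError("empty presence-day set")
    n_runs = 1 + int(np.sum(np.diff(days) > 1))
    if n_runs > 1:
        return "intermittent"
    d = int(days[-1] - days[0] + 1)
    if d > 30:
        return "long"
    if d >= 10:
        return "mid"
    return "short"


def duration_report(selected: pd.DataFrame) -> pd.DataFrame:
    """Per selected SNP: presence days, duration category, first/last DAP."""
    rows = []
    for snp, days in presence_days(selected).items():
        sub = selected[selected["snp_id"] == snp].iloc[0]
        rows.append(
            {
                "snp_id": snp,
                "chrom": sub["chrom"],
                "pos_bp": int(sub["pos_bp"]),
                "n_days": int(days.size),
                "first_dap": int(days.min()),
                "last_dap": int(days.max()),
                "category": classify_duration(days),
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "pos_bp"]).reset_index(drop=True)


def candidate_windows(selected: pd.DataFrame, annotation, half_width: int = 25_000
                      ) -> pd.DataFrame:
    """Annotation features overlapping +-half_width around each selected SNP.

    Windows are closed 1-based intervals [pos - w, pos + w] (clipped at 1).
    ``annotation`` is a PyRanges object (from :func:`longgblup.io.read_annotation`).
    SNPs that fall inside a feature are flagged ``within_gene``.  Chromosomes
    absent from the annotation yield a warning and no hits.
    """
    import pyranges as pr

    snps = selected.drop_duplicates("snp_id")[["snp_id", "chrom", "pos_bp"]]
    ann_chroms = set(annotation.Chromosome.astype(str))
    missing = sorted(set(snps["chrom"].astype(str)) - ann_chroms)
    for c in missing:
        logger.warning("chromosome %s absent from annotation; no candidates", c)
    # convert closed 1-based windows to the 0-based half-open convention
    q = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": snps["chrom"].astype(str),
                "Start": np.maximum(snps["pos_bp"] - half_width - 1, 0),
                "End": snps["pos_bp"] + half_width,
                "snp_id": snps["snp_id"],
                "pos_bp": snps["pos_bp"],
            }
        )
    )
    joined = q.join(annotation)
    if len(joined) == 0:
        return pd.DataFrame(
            columns=["snp_id", "chrom", "pos_bp", "feature_start", "feature_end",
                     "feature_name", "within_gene"]
        )
    df = joined.df
    name_col = next(
        (c for c in ("Name", "ID", "gene_id", "Feature") if c in df.columns), None
    )
    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"],
            "chrom": df["Chromosome"].astype(str),
            "pos_bp": df["pos_bp"].astype(int),
            "feature_start": df["Start_b"].astype(int) + 1,  # back to 1-based
            "feature_end": df["End_b"].astype(int),
            "feature_name": df[name_col] if name_col else "",
            "within_gene": (df["Start_b"] < df["pos_bp"])
            & (df["pos_bp"] <= df["End_b"]),
        }
    )
    return out.sort_values(["snp_id", "chrom", "feature_start"]).reset_index(drop=True)
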