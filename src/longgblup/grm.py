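"""SNP quality control and the VanRaden genomic relationship matrix.

QC removes SNPs below a minor-allele-frequency or call-rate threshold and
mean-imputes remaining missing dosages.  The relationship matrix is VanRaden
method 1: ``G = Z Z' / (2 * sum p_j (1 - p_j))`` with ``Z`` the
column-centered dosage matrix ``M - 2p``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = ["GRMResult", "qc_filter", "vanraden_grm"]

#: diagonal lift applied before inverting G (logged when used)
G_DIAGONAL_LIFT = 1e-8


@dataclass
class GRMResult:
    G: np.ndarray            # (n, n) relationship matrix
    Z_centered: np.ndarray   # (n, s) centered dosages
    p_freq: np.ndarray       # (s,) ALT allele frequency per SNP
    k_scale: float           # 2 * sum p (1 - p)
    kept_snp_ids: list
    line_ids: list
    chrom: np.ndarray
    pos_bp: np.ndarray

    @property
    def n_lines(self) -> int:
        return self.G.shape[0]

    def G_inv(self) -> np.ndarray:
        """Inverse of G after a small diagonal lift for numerical safety."""
        G = self.G + G_DIAGONAL_LIFT * np.eye(self.n_lines)
        logger.debug("inverting G with diagonal lift %.1e", G_DIAGONAL_LIFT)
        return np.linalg.inv(G)


def allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Observed ALT allele frequency per SNP, ignoring missing calls."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(dosages, axis=0) / 2.0


def qc_filter(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
) -> GenotypePanel:
    """Drop SNPs failing MAF or call-rate thresholds; impute the rest.

    A SNP is removed when its minor allele frequency is below ``maf_min`` or
    the fraction of non-missing lines is below ``call_rate_min``.  Surviving
    missing dosages are imputed to the SNP mean ``2 * p_hat``.
    """
    if not 0 < maf_min <= 0.5:
        raise ValueError(f"maf_min must be in (0, 0.5], got {maf_min}")
    if not 0 < call_rate_min <= 1:
        raise ValueError(f"call_rate_min must be in (0, 1], got {call_rate_min}")
    dos = panel.dosages
    call_rate = 1.0 - np.isnan(dos).mean(axis=0)
    p = allele_frequencies(dos)
    maf = np.minimum(p, 1.0 - p)
    with np.errstate(invalid="ignore"):
        keep = (call_rate >= call_rate_min) & (maf >= maf_min) & ~np.isnan(maf)
    n_maf = int(np.sum(~keep & (call_rate >= call_rate_min)))
    n_cr = int(np.sum(call_rate < call_rate_min))
    logger.info(
        "QC removed %d SNP(s): %d low call rate, %d low MAF; %d kept",
        int((~keep).sum()), n_cr, n_maf, int(keep.sum()),
    )
    if not keep.any():
        raise ValueError("no SNPs survive QC filtering")
    dos = dos[:, keep].copy()
    pk = p[keep]
    miss = np.isnan(dos)
    if miss.any():
        dos[miss] = np.broadcast_to(2.0 * pk, dos.shape)[miss]
    panel_out = GenotypePanel.__new__(GenotypePanel)
    panel_out.line_ids = list(panel.line_ids)
    panel_out.dosages = dos  # imputed values are fractional; skip 0/1/2 check
    panel_out.snp_ids = [s for s, k in zip(panel.snp_ids, keep) if k]
    panel_out.chrom = panel.chrom[keep]
    panel_out.pos_bp = panel.pos_bp[keep]
    return panel_out


def vanraden_grm(panel: GenotypePanel) -> GRMResult:
    """VanRaden method-1 genomic relationship matrix from a QC'd panel.

    Allele frequencies are estimated from the analyzed panel itself; the
    panel must contain no missing dosages (run :func:`qc_filter` first).
    """
    dos = np.asarray(panel.dosages, dtype=float)
    if np.isnan(dos).any():
        raise ValueError("panel contains missing dosages; run qc_filter first")
    p = dos.mean(axis=0) / 2.0
    k_scale = float(2.0 * np.sum(p * (1.0 - p)))
    if k_scale <= 0:
        raise ValueError("all SNPs are fixed: zero scaling constant 2*sum(p(1-p))")
    Z = dos - 2.0 * p
    G = (Z @ Z.T) / k_scale
    return GRMResult(
        G=G,
        Z_centered=Z,
        p_freq=p,
        k_scale=k_scale,
        kept_snp_ids=list(panel.snp_ids),
        line_ids=list(panel.line_ids),
        chrom=panel.chrom.copy(),
        pos_bp=panel.pos_bp.copy(),
    )
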