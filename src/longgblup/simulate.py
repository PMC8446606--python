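"""Synthetic RIL panels and longitudinal phenotypes with known ground truth.

The genotype simulator emulates a nested-association-mapping style panel:
biparental families of recombinant inbred lines (RILs), each line a fully
inbred mosaic of its two founders produced by a Markov chain along each
chromosome with a per-interval recombination probability, plus a small
residual-heterozygosity rate.  The phenotype simulator inverts the random
regression model exactly: per-line coefficient vectors are drawn with
covariance ``G (x) G0`` (G the VanRaden matrix of the simulated panel), and
records are ``y = env_k + T b + T a_i + e`` with the residual variance of
each record's DAP class.  All truth is retained for parameter-recovery
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypePanel, PhenotypeTable
from .grm import vanraden_grm
from .residuals import ResidualClassMap

__all__ = [
    "SyntheticTruth",
    "simulate_ril_genotypes",
    "simulate_phenotypes",
    "g0_from_h2_profile",
    "v_shaped_h2",
    "default_mean_curve",
]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_ril_genotypes(
    n_families: int = 32,
    lines_per_family: int = 12,
    n_snps: int = 10_000,
    n_chrom: int = 20,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    recomb_prob: float | None = None,
    residual_het_rate: float = 0.01,
    chrom_length_bp: int = 50_000_000,
) -> GenotypePanel:
    """Simulate a RIL panel of biparental families from inbred founders.

    Each family has two founder haplotypes with Bernoulli(1/2) alleles; each
    RIL chromosome is one recombinant founder mosaic doubled (dosage 0/2),
    switching founder with probability ``recomb_prob`` per marker interval
    (default: an expected two crossovers per chromosome).  A residual
    heterozygosity rate sets a random subset of calls to dosage 1,
    mimicking incompletely fixed lines.
    """
    if min(n_families, lines_per_family, n_snps, n_chrom) < 1:
        raise ValueError("all counts must be >= 1")
    if n_snps < n_chrom:
        raise ValueError(f"n_snps ({n_snps}) must be >= n_chrom ({n_chrom})")
    if rng is None:
        rng = np.random.default_rng(seed)

    # spread SNPs across chromosomes as evenly as possible
    per_chrom = np.full(n_chrom, n_snps // n_chrom)
    per_chrom[: n_snps % n_chrom] += 1
    chroms, poss = [], []
    for c, sc in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(chrom_length_bp, size=sc, replace=False)) + 1
        chroms.extend([str(c)] * sc)
        poss.extend(pos.tolist())
    chrom = np.array(chroms, dtype=object)
    pos_bp = np.array(poss, dtype=np.int64)

    n_lines = n_families * lines_per_family
    dosages = np.empty((n_lines, n_snps), dtype=float)
    line_ids, families = [], []
    row = 0
    for fam in range(n_families):
        founders = rng.integers(0, 2, size=(2, n_snps))  # two haplotypes, alleles 0/1
        for rep in range(lines_per_family):
            hap = np.empty(n_snps, dtype=np.int64)
            start = 0
            for sc in per_chrom:
                r = recomb_prob if recomb_prob is not None else (
                    2.0 / max(sc - 1, 1)
                )
                state = int(rng.integers(0, 2))
                sl = np.empty(sc, dtype=np.int64)
                switches = rng.random(sc - 1) < r if sc > 1 else np.empty(0, bool)
                sl[0] = state
                for i, sw in enumerate(switches, start=1):
                    if sw:
                        state = 1 - state
                    sl[i] = state
                hap[start:start + sc] = sl
                start += sc
            geno = 2.0 * founders[hap, np.arange(n_snps)]
            if residual_het_rate > 0:
                het = rng.random(n_snps) < residual_het_rate
                geno[het] = 1.0
            dosages[row] = geno
            line_ids.append(f"F{fam + 1:02d}_L{rep + 1:03d}")
            families.append(fam + 1)
            row += 1

    snp_ids = [f"snp_{c}_{p}" for c, p in zip(chrom, pos_bp)]
    panel = GenotypePanel(line_ids, dosages, snp_ids, chrom, pos_bp)
    panel.family = np.array(families)  # carried along for truth bookkeeping
    return panel


# ---------------------------------------------------------------------------
# phenotype truth construction
# ---------------------------------------------------------------------------

def v_shaped_h2(dap_grid, high: float = 0.3, low: float = 0.05) -> np.ndarray:
    """A V-shaped heritability profile: high at the range ends, low mid-season.

    Mirrors the observed pattern of time-varying heritability for biomass,
    which dips sharply mid-season.
    """
    t = np.asarray(dap_grid, dtype=float)
    mid = 0.5 * (t.min() + t.max())
    half = 0.5 * (t.max() - t.min())
    frac = np.abs(t - mid) / half if half > 0 else np.zeros_like(t)
    return low + (high - low) * frac


def default_mean_curve(dap_grid) -> np.ndarray:
    """Logistic growth curve for the population mean (arbitrary trait units)."""
    t = np.asarray(dap_grid, dtype=float)
    return 10.0 / (1.0 + np.exp(-(t - 55.0) / 8.0))


def g0_from_h2_profile(
    basis,
    dap_grid,
    h2_profile,
    residual_var_by_dap,
    corr_length: float = 30.0,
) -> np.ndarray:
    """Coefficient covariance G0 approximating a target heritability profile.

    Builds the target time covariance ``Sigma*(t,t') = s(t) s(t')
    exp(-|t-t'|/corr_length)`` with genetic variance
    ``s(t)^2 = sigma2_e(t) h2(t) / (1 - h2(t))``, projects it onto the basis
    (least-squares covariance-function fit ``G0 = T+ Sigma* T+'``), and
    clips negative eigenvalues so G0 is positive semi-definite.  The realized
    profile ``diag(T G0 T')`` approximates but does not exactly equal the
    request; truth should always be computed from the returned G0.
    """
    t = np.asarray(dap_grid, dtype=float)
    h2 = np.asarray(h2_profile, dtype=float)
    if np.any((h2 < 0) | (h2 >= 1)):
        raise ValueError("h2 profile must lie in [0, 1)")
    se = np.broadcast_to(np.asarray(residual_var_by_dap, float), t.shape)
    g = se * h2 / (1.0 - h2)
    s = np.sqrt(g)
    rho = np.exp(-np.abs(t[:, None] - t[None, :]) / corr_length)
    Sigma_target = np.outer(s, s) * rho
    T = basis.design_matrix(t)
    Tp = np.linalg.pinv(T)
    G0 = Tp @ Sigma_target @ Tp.T
    w, V = np.linalg.eigh(0.5 * (G0 + G0.T))
    return (V * np.maximum(w, 0.0)) @ V.T


@dataclass
class SyntheticTruth:
    """Everything the generator knew: for parameter-recovery oracles."""

    G0: np.ndarray
    residual_variances: np.ndarray       # per class
    residual_map: ResidualClassMap
    b: np.ndarray                        # fixed curve coefficients
    env_effects: dict                    # env_rep label -> effect
    coefs: np.ndarray                    # (n, m) true per-line coefficients
    basis_config: dict
    family: np.ndarray | None
    dap_grid: np.ndarray
    Sigma: np.ndarray = field(repr=False, default=None)  # T G0 T' on dap_grid
    h2: np.ndarray = None                # truth plugged into the h2 formula
    mean_diag_G: float = float("nan")


def _psd_sqrt(Mat: np.ndarray, lift: float = 1e-8) -> np.ndarray:
    """Cholesky square root, falling back to an eigen square root if needed."""
    M = 0.5 * (Mat + Mat.T)
    try:
        return np.linalg.cholesky(M + lift * np.trace(M) / max(M.shape[0], 1) * np.eye(M.shape[0]))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        return V * np.sqrt(np.maximum(w, 0.0))


def simulate_phenotypes(
    panel: GenotypePanel,
    basis,
    g0: np.ndarray | None = None,
    h2_profile=None,
    residual_variances=1.0,
    residual_map: ResidualClassMap | None = None,
    dap_grid=None,
    env_reps=None,
    env_effects: dict | None = None,
    b: np.ndarray | None = None,
    missing_rate=0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, SyntheticTruth]:
    """Generate longitudinal phenotypes from the random regression model.

    Either ``g0`` (coefficient covariance, PSD) or ``h2_profile`` (target
    per-day heritability, converted via :func:`g0_from_h2_profile`) must be
    given; by default a V-shaped profile is used.  ``missing_rate`` drops
    each (line, env_rep, DAP) record independently — a scalar, or a dict per
    env_rep label to emulate unequal replication between environments.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if dap_grid is None:
        dap_grid = np.arange(int(basis.dap_min), int(basis.dap_max) + 1)
    dap_grid = np.asarray(dap_grid, dtype=int)
    if env_reps is None:
        env_reps = [f"E{e}_R{r}" for e in (1, 2, 3) for r in (1, 2)]
    K = len(env_reps)
    if residual_map is None:
        residual_map = ResidualClassMap.homogeneous(int(dap_grid.min()), int(dap_grid.max()))
    sigma2 = np.broadcast_to(
        np.atleast_1d(np.asarray(residual_variances, float)), (residual_map.n_classes,)
    ).astype(float)
    if np.any(sigma2 < 0):
        raise ValueError("residual variances must be >= 0")
    cls_grid = residual_map.class_of(dap_grid)
    se_by_dap = sigma2[cls_grid]

    m = basis.n_coef
    T_grid = basis.design_matrix(dap_grid)
    if g0 is None:
        if h2_profile is None:
            h2_profile = v_shaped_h2(dap_grid)
        g0 = g0_from_h2_profile(basis, dap_grid, h2_profile, se_by_dap)
    g0 = np.asarray(g0, dtype=float)
    eigs = np.linalg.eigvalsh(0.5 * (g0 + g0.T))
    if eigs.min() < -1e-8 * max(eigs.max(), 1.0):
        raise ValueError(f"G0 is not PSD: offending eigenvalue {eigs.min():.3e}")

    if b is None:
        b, *_ = np.linalg.lstsq(T_grid, default_mean_curve(dap_grid), rcond=None)
    b = np.asarray(b, dtype=float)
    if env_effects is None:
        scale = float(np.sqrt(np.mean(sigma2))) if np.mean(sigma2) > 0 else 1.0
        offs = np.linspace(-0.5, 0.5, K) * scale
        env_effects = dict(zip(env_reps, offs))

    # per-line coefficients with covariance G (x) G0 (line-major ordering)
    grm = vanraden_grm(panel)
    Lg = _psd_sqrt(grm.G)
    Lg0 = _psd_sqrt(g0, lift=0.0)
    n = panel.n_lines
    A = Lg @ rng.standard_normal((n, m)) @ Lg0.T   # (n, m) true coefficients

    genetic = A @ T_grid.T                          # (n, d)
    fixed_curve = T_grid @ b                        # (d,)

    records = []
    for k_lab in env_reps:
        env_val = env_effects[k_lab]
        rate = missing_rate.get(k_lab, 0.0) if isinstance(missing_rate, dict) else float(missing_rate)
        noise = rng.standard_normal((n, dap_grid.size)) * np.sqrt(se_by_dap)
        y = env_val + fixed_curve + genetic + noise
        keep = rng.random((n, dap_grid.size)) >= rate
        for i, line in enumerate(panel.line_ids):
            for j, dap in enumerate(dap_grid):
                if keep[i, j]:
                    records.append((line, k_lab, int(dap), y[i, j]))
    table = PhenotypeTable(
        pd.DataFrame(records, columns=["line", "env_rep", "dap", "value"])
    )

    Sigma = T_grid @ g0 @ T_grid.T
    sig_a = np.diag(Sigma)
    truth = SyntheticTruth(
        G0=g0,
        residual_variances=sigma2,
        residual_map=residual_map,
        b=b,
        env_effects=dict(env_effects),
        coefs=A,
        basis_config=basis.to_config(),
        family=getattr(panel, "family", None),
        dap_grid=dap_grid,
        Sigma=Sigma,
        h2=sig_a / (sig_a + se_by_dap),
        mean_diag_G=float(np.mean(np.diag(grm.G))),
    )
    return table, truth
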