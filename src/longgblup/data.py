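"""Core data containers for the longitudinal genomic pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel", "PhenotypeTable"]


@dataclass
class GenotypePanel:
    """A panel of lines genotyped at biallelic SNPs.

    dosages are ALT-allele counts in {0, 1, 2} stored as float with NaN for
    missing calls; rows are lines, columns SNPs.  Positions are 1-based.
    """

    line_ids: list
    dosages: np.ndarray          # (n_lines, n_snps) float, NaN = missing
    snp_ids: list
    chrom: np.ndarray            # (n_snps,) str labels
    pos_bp: np.ndarray           # (n_snps,) int, 1-based

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        n, s = self.dosages.shape
        if len(self.line_ids) != n:
            raise ValueError("line_ids length does not match dosage rows")
        if not (len(self.snp_ids) == self.chrom.size == self.pos_bp.size == s):
            raise ValueError("SNP metadata arrays must share one length")
        if len(set(self.line_ids)) != n:
            raise ValueError("line_ids must be unique")
        if np.any(self.pos_bp < 1):
            raise ValueError("pos_bp must be >= 1 (1-based positions)")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            bad = np.setdiff1d(np.unique(obs), (0.0, 1.0, 2.0))
            raise ValueError(f"dosages must be 0/1/2/missing; found {bad}")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class PhenotypeTable:
    """Long-format longitudinal phenotypes: one row per (line, env_rep, DAP).

    ``env_rep`` is a single opaque factor label for the environment x
    replication combination.
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("line", "env_rep", "dap", "value")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype table missing column(s): {missing}")
        df = self.df.loc[:, list(self.REQUIRED)].copy()
        df["dap"] = df["dap"].astype(int)
        df["value"] = df["value"].astype(float)
        dup = df.duplicated(subset=["line", "env_rep", "dap"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["line", "env_rep", "dap"]].tolist()
            raise ValueError(f"duplicate (line, env_rep, dap) key: {tuple(key)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lines(self) -> list:
        return sorted(self.df["line"].unique().tolist())

    @property
    def env_reps(self) -> list:
        return sorted(self.df["env_rep"].unique().tolist())

    def restrict_dap(self, dap_min: int, dap_max: int) -> tuple["PhenotypeTable", int]:
        """Drop records outside [dap_min, dap_max]; return (table, n_dropped)."""
        keep = (self.df["dap"] >= dap_min) & (self.df["dap"] <= dap_max)
        return PhenotypeTable(self.df.loc[keep]), int((~keep).sum())

    def subset_lines(self, line_ids) -> "PhenotypeTable":
        keep = self.df["line"].isin(set(line_ids))
        return PhenotypeTable(self.df.loc[keep])
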