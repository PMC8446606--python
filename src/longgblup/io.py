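"""Readers and writers for the pipeline's standard formats.

Genotypes come in as VCF (via cyvcf2) or as a SNP-major TSV matrix;
phenotypes as long-format CSV; annotation as BED or GFF3 (via pyranges).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypePanel, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_annotation",
    "write_grm_tsv",
    "read_grm_tsv",
]

_GENO_META_COLS = ["snp_id", "chrom", "pos_bp"]


def read_genotypes(path, format: str | None = None) -> GenotypePanel:
    """Read a genotype panel from VCF or TSV matrix.

    ``format`` is ``"vcf"`` or ``"tsv"``; when omitted it is inferred from the
    file suffix.  VCF records that are not biallelic SNPs are skipped with a
    logged count; half-missing genotypes are treated as missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffixes = "".join(path.suffixes).lower()
        format = "vcf" if ".vcf" in suffixes else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format in ("tsv", "tsv-matrix"):
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    snp_ids, chroms, poss, rows = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        geno = np.array([g[:2] for g in var.genotypes], dtype=float)  # (n, 2)
        geno[geno < 0] = np.nan
        dos = geno.sum(axis=1)  # NaN if either allele missing
        rows.append(dos)
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
    if n_skipped:
        logger.info("skipped %d non-biallelic VCF record(s)", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNPs read from {path}")
    dosages = np.vstack(rows).T  # lines x SNPs
    return GenotypePanel(line_ids, dosages, snp_ids, np.array(chroms), np.array(poss))


def _read_tsv(path: Path) -> GenotypePanel:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed genotype TSV {path}: {exc}") from exc
    missing = [c for c in _GENO_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed header in {path} (line 1): missing column(s) {missing}"
        )
    if len(df) == 0:
        raise ValueError(f"zero SNPs in {path}")
    line_ids = [c for c in df.columns if c not in _GENO_META_COLS]
    dosages = df[line_ids].to_numpy(dtype=float).T  # lines x SNPs
    return GenotypePanel(
        line_ids,
        dosages,
        df["snp_id"].astype(str).tolist(),
        df["chrom"].to_numpy(dtype=object),
        df["pos_bp"].to_numpy(dtype=np.int64),
    )


def write_genotypes(panel: GenotypePanel, path) -> None:
    """Write the SNP-major TSV matrix format (missing encoded as NA)."""
    df = pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "chrom": panel.chrom,
            "pos_bp": panel.pos_bp,
        }
    )
    dos = pd.DataFrame(panel.dosages.T, columns=panel.line_ids)
    # dosages are integral where observed; write them without a trailing .0
    out = pd.concat([df, dos], axis=1)
    for c in panel.line_ids:
        out[c] = out[c].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, dap_min: int | None = None, dap_max: int | None = None) -> PhenotypeTable:
    """Read the long-format phenotype CSV (columns line, env_rep, dap, value).

    Rows with DAP outside the configured range are dropped with a logged
    count.  A non-numeric value raises with the offending CSV line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"line": str, "env_rep": str})
    missing = [c for c in PhenotypeTable.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} missing column(s): {missing}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = vals.isna() & df["value"].notna()
    if bad.any():
        i = int(bad.idxmax())
        raise ValueError(
            f"non-numeric phenotype value {df['value'][i]!r} at {path} line {i + 2}"
        )
    df["value"] = vals
    df = df.dropna(subset=["value"])
    table = PhenotypeTable(df)
    if dap_min is not None and dap_max is not None:
        table, n_dropped = table.restrict_dap(dap_min, dap_max)
        if n_dropped:
            logger.info("dropped %d phenotype record(s) outside DAP range", n_dropped)
    return table


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.df.to_csv(path, index=False, float_format="%.10g")


def read_annotation(path):
    """Read annotation intervals from BED or GFF3 into a PyRanges object."""
    import pyranges as pr

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    if ".bed" in suffixes:
        return pr.read_bed(str(path))
    if ".gff" in suffixes or ".gff3" in suffixes or ".gtf" in suffixes:
        return pr.read_gff3(str(path))
    raise ValueError(f"annotation format not recognized for {path} (need BED or GFF3)")


def write_grm_tsv(G: np.ndarray, line_ids, path) -> None:
    pd.DataFrame(G, index=line_ids, columns=line_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_grm_tsv(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), df.index.astype(str).tolist()
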