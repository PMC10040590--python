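"""Readers, writers and run configuration.

Genotypes travel as CSV (first column the line id, one column per marker,
cells 0/1/2 or NA) or VCF (biallelic sites converted to alternate-allele
dosage; other records are skipped and counted).  Field books are CSV in
either long (line, env, block, trait, value) or wide (line, env, block +
one column per trait) layout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .fieldbook import FieldBook
from .genotypes import GenotypeMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_fieldbook",
    "write_fieldbook",
    "RunConfig",
    "load_config",
]


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Load a genotype matrix from CSV or VCF (format inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in (".vcf", ".bcf") or str(path).endswith(".vcf.gz") else "csv"
    if format == "csv":
        return _read_genotype_csv(path)
    if format == "vcf":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotype_csv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, dtype=str)
    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        cell = df[col].str.strip()
        ok = cell.isin(("0", "1", "2"))
        na = cell.isna() | cell.isin(("", "NA", "NaN", "nan", "."))
        bad = ~(ok | na)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"invalid genotype {cell.iloc[i]!r} at line {df.index[i]!r}, "
                f"marker {col!r} in {path}"
            )
        values[ok.to_numpy(), j] = cell[ok].astype(float)
    return GenotypeMatrix(values, list(df.index.astype(str)), list(df.columns))


def _read_genotype_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 dosage, 3 = missing
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    marker_ids: list[str] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = var.gt_types.astype(float)
        gt[gt == 3] = np.nan
        columns.append(gt)
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not columns:
        raise ValueError(f"no biallelic records in {path}")
    geno = GenotypeMatrix(np.column_stack(columns), samples, marker_ids)
    geno.n_skipped_records = n_skipped
    return geno


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    frame = geno.to_frame()
    out = frame.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "line"
    out.to_csv(path)


def read_fieldbook(path) -> FieldBook:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"field book {path} is empty")
    lower = {c.lower(): c for c in df.columns}
    rename = {lower[c]: c for c in ("line", "env", "block") if c in lower}
    df = df.rename(columns=rename)
    if {"trait", "value"}.issubset(df.columns):
        return FieldBook(df)
    return FieldBook.from_wide(df)


def write_fieldbook(fb: FieldBook, path, wide: bool = True) -> None:
    (fb.to_wide() if wide else fb.data).to_csv(path, index=False)


class QCThresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")
    maf_min: float = 0.05
    het_max: float = 0.2
    r2_max: float = 0.99


class MCMCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_iter: int = 2_000
    burn_in: int = 500
    thin: int = 2


class CVConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scenario: str = "single"
    n_reps: int = 50
    train_frac: float = 2.0 / 3.0


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    genotypes: str | None = None
    fieldbook: str | None = None
    output_dir: str = "gspred_out"
    qc: QCThresholds = Field(default_factory=QCThresholds)
    model: str = "gblup"
    mcmc: MCMCConfig = Field(default_factory=MCMCConfig)
    cv: CVConfig = Field(default_factory=CVConfig)
    seed: int = 0
    log_level: str = "INFO"


def load_config(path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig(**payload)
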