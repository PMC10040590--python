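"""Genotype containers, marker quality control and standardization.

Genotypes are biallelic SNP gene contents coded 0/1/2 (copies of the
alternate allele), held as a lines x markers matrix with string
identifiers on both axes.  Missing calls are represented as NaN in a
float matrix.  Quality control applies, in order, a minor-allele
frequency filter, a heterozygosity filter and LD pruning of tightly
linked (nearly duplicate) markers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "StandardizedMarkers",
    "apply_marker_qc",
    "standardize_markers",
    "EmptyPanelError",
]


class EmptyPanelError(ValueError):
    """Raised when quality control removes every marker."""


@dataclass
class GenotypeMatrix:
    """Lines x markers gene-content matrix (0/1/2, NaN = missing)."""

    values: np.ndarray  # float, n_lines x m_markers
    line_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = [str(s) for s in self.line_ids]
        self.marker_ids = [str(s) for s in self.marker_ids]
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (lines x markers)")
        n, m = self.values.shape
        if n != len(self.line_ids) or m != len(self.marker_ids):
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line_ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker_ids")
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(self.values) | np.isin(self.values, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid gene content {self.values[i, j]!r} at line "
                f"{self.line_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def m_markers(self) -> int:
        return self.values.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        """Per-marker alternate-allele frequency, missing calls excluded."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / 2.0

    @property
    def minor_allele_freqs(self) -> np.ndarray:
        p = self.allele_freqs
        return np.minimum(p, 1.0 - p)

    @property
    def het_rates(self) -> np.ndarray:
        """Fraction of (non-missing) calls equal to 1, per marker."""
        obs = ~np.isnan(self.values)
        het = np.nansum(self.values == 1.0, axis=0)
        n_obs = obs.sum(axis=0)
        out = np.full(self.m_markers, np.nan)
        ok = n_obs > 0
        out[ok] = het[ok] / n_obs[ok]
        return out

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.values[:, keep],
            self.line_ids,
            [self.marker_ids[j] for j in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.marker_ids[j] for j in keep],
        )

    def subset_lines(self, lines: list[str]) -> "GenotypeMatrix":
        idx = [self.line_ids.index(l) for l in lines]
        return GenotypeMatrix(self.values[idx, :], lines, self.marker_ids)

    def imputed(self) -> "GenotypeMatrix":
        """Mean-impute missing calls per marker (keeps 0/1/2 elsewhere)."""
        vals = self.values.copy()
        col_mean = np.nanmean(np.where(np.isnan(vals), np.nan, vals), axis=0)
        idx = np.where(np.isnan(vals))
        vals[idx] = col_mean[idx[1]]
        out = GenotypeMatrix.__new__(GenotypeMatrix)
        out.values = vals
        out.line_ids = list(self.line_ids)
        out.marker_ids = list(self.marker_ids)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.marker_ids)


@dataclass
class QCReport:
    """Markers removed by each filter, in application order."""

    removed_all_missing: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)
    removed_het: list[str] = field(default_factory=list)
    removed_ld: list[str] = field(default_factory=list)
    n_retained: int = 0

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "removed_all_missing": self.removed_all_missing,
                "removed_maf": self.removed_maf,
                "removed_het": self.removed_het,
                "removed_ld": self.removed_ld,
                "n_retained": self.n_retained,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _ld_prune(values: np.ndarray, r2_max: float, window: int = 1000) -> np.ndarray:
    """Greedy left-to-right LD pruning; earlier marker wins.

    Returns a boolean keep mask.  r^2 is the squared Pearson correlation of
    gene contents (mean-imputed) within a sliding window of `window` kept
    markers.
    """
    n, m = values.shape
    col_mean = np.nanmean(values, axis=0)
    filled = np.where(np.isnan(values), col_mean[None, :], values)
    centered = filled - filled.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    keep = np.ones(m, dtype=bool)
    kept: list[int] = []
    for j in range(m):
        start = 0 if len(kept) <= window else len(kept) - window
        drop = False
        for k in kept[start:]:
            denom = norms[j] * norms[k]
            if denom == 0:
                continue
            r = centered[:, j] @ centered[:, k] / denom
            if r * r >= r2_max:
                drop = True
                break
        if drop:
            keep[j] = False
        else:
            kept.append(j)
    return keep


def apply_marker_qc(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    het_max: float = 0.2,
    r2_max: float = 0.99,
    ld_window: int = 1000,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers by MAF, heterozygosity and LD, in that order.

    Markers with MAF < `maf_min`, heterozygosity rate > `het_max`, or squared
    correlation >= `r2_max` with an earlier retained marker are removed.
    Fully missing columns are removed first and reported separately.
    """
    for name, t in (("maf_min", maf_min), ("het_max", het_max), ("r2_max", r2_max)):
        if not (0 < t <= 1):
            raise ValueError(f"{name} must be in (0, 1], got {t}")
    if geno.m_markers == 0:
        raise EmptyPanelError("genotype matrix has no markers")

    report = QCReport()
    ids = np.asarray(geno.marker_ids)

    all_missing = np.isnan(geno.values).all(axis=0)
    report.removed_all_missing = list(ids[all_missing])
    current = geno.subset_markers(~all_missing)

    maf_fail = current.minor_allele_freqs < maf_min
    report.removed_maf = list(np.asarray(current.marker_ids)[maf_fail])
    current = current.subset_markers(~maf_fail)

    het_fail = current.het_rates > het_max
    report.removed_het = list(np.asarray(current.marker_ids)[het_fail])
    current = current.subset_markers(~het_fail)

    if current.m_markers == 0:
        raise EmptyPanelError("all markers removed by quality control")

    keep = _ld_prune(current.values, r2_max, window=ld_window)
    report.removed_ld = list(np.asarray(current.marker_ids)[~keep])
    current = current.subset_markers(keep)

    if current.m_markers == 0:
        raise EmptyPanelError("all markers removed by quality control")
    report.n_retained = current.m_markers
    return current, report


@dataclass
class StandardizedMarkers:
    """Column-centered, unit-sample-sd marker matrix W (ddof=1)."""

    values: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]
    column_means: np.ndarray
    column_sds: np.ndarray

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def m_markers(self) -> int:
        return self.values.shape[1]


def standardize_markers(
    geno: GenotypeMatrix, use_allele_freqs: bool = False
) -> StandardizedMarkers:
    """Center and scale gene contents to column mean 0 and sd 1.

    By default uses the sample mean and sample sd (ddof=1) of the observed
    codes.  With ``use_allele_freqs=True`` the Hardy-Weinberg variant is used
    instead: center by 2p and scale by sqrt(2p(1-p)).  Missing values must be
    imputed beforehand.
    """
    vals = geno.values
    if np.isnan(vals).any():
        raise ValueError("missing genotypes present; impute before standardizing")
    if use_allele_freqs:
        p = vals.mean(axis=0) / 2.0
        means = 2.0 * p
        sds = np.sqrt(2.0 * p * (1.0 - p))
    else:
        means = vals.mean(axis=0)
        sds = vals.std(axis=0, ddof=1)
    zero = sds == 0
    if zero.any():
        j = int(np.flatnonzero(zero)[0])
        raise ValueError(f"monomorphic marker {geno.marker_ids[j]!r} (zero variance)")
    W = (vals - means) / sds
    return StandardizedMarkers(
        W, list(geno.line_ids), list(geno.marker_ids), means, sds
    )


def center_markers(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Column-center raw 0/1/2 codes (no variance scaling).

    This is the marker coding used by the variable-selection models, which
    keep gene contents on their natural scale.  Returns (W, column_means).
    """
    vals = geno.imputed().values
    means = vals.mean(axis=0)
    return vals - means, means
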