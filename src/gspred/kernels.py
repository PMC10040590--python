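"""Line x line kernel construction: genomic relationship and Gaussian kernels.

The genomic relationship matrix G = WW'/m (W the standardized gene-content
matrix) captures additive similarity; the Gaussian kernel
GK(i, i') = exp(-theta * d^2_{ii'}) of squared Euclidean marker distances
captures interactions of all orders, with the bandwidth theta setting how
local the similarity is.  Kernel averaging fits several bandwidths at once
as separate random effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .genotypes import StandardizedMarkers

__all__ = [
    "KernelMatrix",
    "genomic_relationship",
    "gaussian_kernel",
    "kernel_averaging_list",
    "DEFAULT_BANDWIDTHS",
]

DEFAULT_BANDWIDTHS = (0.2, 1.2)

_SYM_TOL = 1e-10
_EIG_REL_TOL = 1e-8


@dataclass
class KernelMatrix:
    """Symmetric PSD line x line similarity matrix."""

    values: np.ndarray
    line_ids: list[str]
    kind: str = "custom"  # {"G", "GK", "custom"}
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        K = self.values
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kernel must be square")
        if K.shape[0] != len(self.line_ids):
            raise ValueError("line_ids length does not match kernel dimension")
        if np.abs(K - K.T).max() > _SYM_TOL:
            raise ValueError("kernel is not symmetric")
        self.values = (K + K.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eigendecompose(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues/vectors with tiny negative eigenvalues clipped to 0.

        Eigenvalues below -1e-8 * lambda_max indicate a genuinely indefinite
        matrix and raise; values inside the tolerance band are numerical noise
        and are clipped.
        """
        vals, vecs = np.linalg.eigh(self.values)
        lam_max = max(vals[-1], 0.0)
        if lam_max > 0 and vals[0] < -_EIG_REL_TOL * lam_max:
            raise ValueError(
                f"kernel is not positive semi-definite (min eigenvalue {vals[0]:g})"
            )
        return np.clip(vals, 0.0, None), vecs

    def subset(self, lines: list[str]) -> "KernelMatrix":
        idx = [self.line_ids.index(l) for l in lines]
        return KernelMatrix(
            self.values[np.ix_(idx, idx)], list(lines), self.kind, self.bandwidth
        )


def genomic_relationship(W: StandardizedMarkers) -> KernelMatrix:
    """G = WW'/m from standardized markers."""
    if W.m_markers < 1:
        raise ValueError("need at least one marker")
    G = W.values @ W.values.T / W.m_markers
    return KernelMatrix(G, list(W.line_ids), kind="G")


def gaussian_kernel(
    W: StandardizedMarkers, theta: float, scale_by_mean_distance: bool = False
) -> KernelMatrix:
    """GK(i, i') = exp(-theta * d^2_{ii'}) on standardized marker rows.

    ``scale_by_mean_distance`` divides d^2 by its off-diagonal mean before
    exponentiating, an interoperability convention used by some software;
    the plain formula applies no such scaling.
    """
    if theta < 0:
        raise ValueError(f"bandwidth theta must be >= 0, got {theta}")
    d2 = squareform(pdist(W.values, metric="sqeuclidean"))
    if scale_by_mean_distance and W.n_lines > 1:
        off = d2[np.triu_indices_from(d2, k=1)]
        if off.mean() > 0:
            d2 = d2 / off.mean()
    K = np.exp(-theta * d2)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, list(W.line_ids), kind="GK", bandwidth=float(theta))


def kernel_averaging_list(
    W: StandardizedMarkers,
    thetas: tuple[float, ...] = DEFAULT_BANDWIDTHS,
    scale_by_mean_distance: bool = False,
) -> list[KernelMatrix]:
    """One Gaussian kernel per bandwidth, for multi-kernel (averaging) fits."""
    if len(thetas) == 0:
        raise ValueError("thetas must be non-empty")
    return [
        gaussian_kernel(W, t, scale_by_mean_distance=scale_by_mean_distance)
        for t in thetas
    ]
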