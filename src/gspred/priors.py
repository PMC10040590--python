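"""MCMC settings and scaled-inverse-chi-square prior elicitation.

Variance components carry scaled inverse-chi-square priors with small
degrees of freedom (default nu = 5).  Scale parameters are elicited from
the sample phenotypic variance under the working assumption that the model
explains a fraction r2 (default 0.5) of it, using the mode-matching rule
S = V_target * (nu + 2), so the prior mode of each variance component sits
at its target share of the phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MCMCSettings",
    "PriorSpec",
    "default_hyperparameters",
    "sample_scaled_inv_chi2",
    "LONG_MCMC",
    "REDUCED_MCMC",
]


@dataclass(frozen=True)
class MCMCSettings:
    """Gibbs chain bookkeeping: total draws, burn-in, thinning, seed."""

    n_iter: int = 50_000
    burn_in: int = 20_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= 0:
            raise ValueError("n_iter must be positive")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin

    def with_seed(self, seed: int) -> "MCMCSettings":
        return replace(self, seed=int(seed))


#: Long chain used for final analyses.
LONG_MCMC = MCMCSettings(n_iter=50_000, burn_in=20_000, thin=5)
#: Short chain for tests, smoke runs and cross-validation sweeps.
REDUCED_MCMC = MCMCSettings(n_iter=2_000, burn_in=500, thin=2)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters for the variance-component priors.

    df:  degrees of freedom nu of every scaled inverse-chi-square prior.
    r2:  prior share of phenotypic variance attributed to genetics.
    pi:  prior exclusion probability of a marker (variable-selection models).
    Scale parameters (filled in by :func:`default_hyperparameters`):
      scale_u   — genetic variance scale, per kernel (kernel models);
      scale_alpha — marker-effect variance scale (marker models);
      scale_e   — residual variance scale.
    """

    df: float = 5.0
    r2: float = 0.5
    pi: float = 0.99
    scale_u: float | None = None
    scale_alpha: float | None = None
    scale_e: float | None = None

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("df must be > 0")
        if not (0 < self.r2 < 1):
            raise ValueError("r2 must be in (0, 1)")
        if not (0 < self.pi < 1):
            raise ValueError("pi must be in (0, 1)")
        for name in ("scale_u", "scale_alpha", "scale_e"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")


def default_hyperparameters(
    y: np.ndarray,
    model: str,
    kernels=None,
    W: np.ndarray | None = None,
    prior: PriorSpec | None = None,
) -> PriorSpec:
    """Complete a PriorSpec with data-driven scale parameters.

    Kernel models:   S_u = Vy * r2 * (nu + 2) / mean(diag(K)) per kernel
                     (the mean over kernels of mean diagonals is used when
                     several kernels share the budget).
    Marker models:   S_alpha = Vy * r2 * (nu + 2) / MSx with
                     MSx = sum_j var(w_.j) (sample variance, ddof=1);
                     spike-and-slab models with marker-specific variances
                     divide further by (1 - pi).
    Both:            S_e = Vy * (1 - r2) * (nu + 2).

    Scales already present on `prior` are kept.
    """
    prior = prior or PriorSpec()
    y = np.asarray(y, dtype=float)
    y = y[~np.isnan(y)]
    vy = float(np.var(y, ddof=1)) if y.size > 1 else 0.0
    if vy == 0.0:
        raise ValueError("phenotypic variance is zero; cannot set prior scales")
    nu2 = prior.df + 2.0

    scale_e = prior.scale_e
    if scale_e is None:
        scale_e = vy * (1.0 - prior.r2) * nu2

    scale_u = prior.scale_u
    scale_alpha = prior.scale_alpha
    if model == "kernel":
        if kernels is None:
            raise ValueError("kernel model requires kernels")
        if scale_u is None:
            mean_diag = float(np.mean([np.mean(np.diag(k.values)) for k in kernels]))
            scale_u = vy * prior.r2 * nu2 / mean_diag
    elif model == "marker":
        if W is None:
            raise ValueError("marker model requires the marker matrix W")
        if scale_alpha is None:
            msx = float(np.sum(np.var(W, axis=0, ddof=1)))
            if msx == 0:
                raise ValueError("marker matrix has zero total variance")
            scale_alpha = vy * prior.r2 * nu2 / msx
    else:
        raise ValueError(f"unknown model kind {model!r}")

    return replace(prior, scale_u=scale_u, scale_alpha=scale_alpha, scale_e=scale_e)


def sample_scaled_inv_chi2(
    rng: np.random.Generator, df: float, scale_sum: float
) -> float:
    """Draw from the scaled inverse-chi-square full conditional.

    Parameterized so the draw is scale_sum / chi2(df): for a prior
    Scale-inv-chi2(nu, S) updated with a sum of squares SS over k effects the
    full conditional is (S + SS) / chi2(nu + k), i.e. df = nu + k and
    scale_sum = S + SS.
    """
    return float(scale_sum / rng.chisquare(df))
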