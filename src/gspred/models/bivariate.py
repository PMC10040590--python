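"""Bivariate GBLUP for the genomic correlation between two environments.

The same trait measured in two environments is treated as a pair of
correlated genetic values per line:

    (u, eps) ~ N(0, Sigma_u x G,  Sigma_eps x I)

with 2x2 genetic and residual covariance matrices under inverse-Wishart
priors (identity scale matrices, small degrees of freedom).  The genomic
correlation r_g is Sigma_u[1,2] / sqrt(Sigma_u[1,1] Sigma_u[2,2]),
computed per posterior draw and averaged.

Sampling runs in the eigenbasis of G, where both the genetic prior and
the residual covariance stay row-wise independent 2x2 problems.  Missing
cells (a line unphenotyped in one environment) are data-augmented from
their conditional normal each sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from ..kernels import KernelMatrix
from ..priors import MCMCSettings

__all__ = ["BivariateGBLUP", "BivariateResults", "fit_bivariate_gblup", "genomic_correlation"]

_JITTER = 1e-8


class BivariateGBLUP:
    """Two-environment GBLUP with full genetic and residual covariances.

    Parameters
    ----------
    y1, y2 : pandas.Series indexed by line
        Phenotypes (BLUEs) of one trait in each environment.  Lines present
        in either series must appear in `G`; a line may be missing from one
        environment.
    G : KernelMatrix
        Genomic relationship matrix over all lines involved.
    df : float
        Inverse-Wishart degrees of freedom for both covariance priors
        (> dimension + 1; identity scale matrices).
    residual_covariance : {"full", "diagonal"}
        "full" (default) estimates the complete 2x2 residual covariance;
        "diagonal" forces residual independence between environments, which
        pushes any line-level covariance shared across environments into the
        genetic term.  Use "diagonal" when the two environments' errors are
        known to be independent (e.g. separate trials) and no
        permanent-environment effect should dilute r_g.
    """

    def __init__(
        self,
        y1: pd.Series,
        y2: pd.Series,
        G: KernelMatrix,
        df: float = 4.0,
        residual_covariance: str = "full",
    ) -> None:
        if df <= 3.0:
            raise ValueError("df must exceed dimension + 1 = 3")
        if residual_covariance not in ("full", "diagonal"):
            raise ValueError("residual_covariance must be 'full' or 'diagonal'")
        self.residual_covariance = residual_covariance
        self.G = G
        self.df = float(df)
        lines = list(G.line_ids)
        line_set = set(lines)
        for name, y in (("y1", y1), ("y2", y2)):
            unknown = [l for l in y.dropna().index if l not in line_set]
            if unknown:
                raise ValueError(f"{name} has lines missing from G: {unknown[:5]}")
        self.y = np.column_stack(
            [
                pd.Series(y1).reindex(lines).to_numpy(dtype=float),
                pd.Series(y2).reindex(lines).to_numpy(dtype=float),
            ]
        )
        if np.isnan(self.y).all(axis=1).any():
            keep = ~np.isnan(self.y).all(axis=1)
            self.y = self.y[keep]
            lines = [l for l, k in zip(lines, keep) if k]
            self.G = G.subset(lines)
        self.line_ids = lines
        obs_per_env = (~np.isnan(self.y)).sum(axis=0)
        if (obs_per_env < 3).any():
            raise ValueError("each environment needs at least 3 phenotyped lines")

    def fit(self, settings: MCMCSettings | None = None) -> "BivariateResults":
        settings = settings or MCMCSettings()
        rng = np.random.default_rng(settings.seed)
        y = self.y.copy()
        n = y.shape[0]
        missing = np.isnan(y)

        d, U = self.G.eigendecompose()
        d = np.maximum(d, _JITTER * max(d[-1], 1.0))

        S_u = np.eye(2)
        S_e = np.eye(2)
        nu_u = nu_e = self.df

        mu = np.nanmean(y, axis=0)
        y[missing] = np.take(mu, np.nonzero(missing)[1])
        Sigma_u = np.cov((y - mu).T) / 2.0 + 1e-6 * np.eye(2)
        Sigma_e = Sigma_u.copy()
        V = np.zeros((n, 2))  # genetic values in the eigenbasis

        n_saved = settings.n_saved
        Sigma_u_chain = np.empty((n_saved, 2, 2))
        Sigma_e_chain = np.empty((n_saved, 2, 2))
        mu_chain = np.empty((n_saved, 2))
        u_sum = np.zeros((n, 2))
        n_jitter = 0

        s = 0
        for it in range(settings.n_iter):
            u = U @ V
            # data augmentation for missing cells
            if missing.any():
                mean_full = mu + u
                for col in (0, 1):
                    rows = np.flatnonzero(missing[:, col])
                    if rows.size == 0:
                        continue
                    other = 1 - col
                    cond_var = Sigma_e[col, col] - Sigma_e[col, other] ** 2 / Sigma_e[other, other]
                    cond_mean = mean_full[rows, col] + (
                        Sigma_e[col, other] / Sigma_e[other, other]
                    ) * (y[rows, other] - mean_full[rows, other])
                    y[rows, col] = rng.normal(cond_mean, np.sqrt(max(cond_var, 1e-12)))

            # intercepts: joint normal with covariance Sigma_e / n
            resid = y - u
            try:
                chol_e = np.linalg.cholesky(Sigma_e)
            except np.linalg.LinAlgError:
                Sigma_e = Sigma_e + _JITTER * np.eye(2)
                chol_e = np.linalg.cholesky(Sigma_e)
                n_jitter += 1
            mu = resid.mean(axis=0) + (chol_e @ rng.standard_normal(2)) / np.sqrt(n)

            # genetic values in the eigenbasis: independent 2x2 rows,
            # solved analytically in batch over lines
            y_t = U.T @ (y - mu)
            Pe = np.linalg.inv(Sigma_e)
            Pu_base = np.linalg.inv(Sigma_u)
            P00 = Pu_base[0, 0] / d + Pe[0, 0]
            P01 = Pu_base[0, 1] / d + Pe[0, 1]
            P11 = Pu_base[1, 1] / d + Pe[1, 1]
            det = P00 * P11 - P01 * P01
            C00, C01, C11 = P11 / det, -P01 / det, P00 / det
            b = y_t @ Pe.T
            mean0 = C00 * b[:, 0] + C01 * b[:, 1]
            mean1 = C01 * b[:, 0] + C11 * b[:, 1]
            L00 = np.sqrt(C00)
            L10 = C01 / L00
            L11 = np.sqrt(np.maximum(C11 - L10 * L10, 1e-300))
            z = rng.standard_normal((n, 2))
            V[:, 0] = mean0 + L00 * z[:, 0]
            V[:, 1] = mean1 + L10 * z[:, 0] + L11 * z[:, 1]

            # covariance matrices (inverse-Wishart full conditionals)
            scatter_u = (V.T * (1.0 / d)) @ V
            Sigma_u = _draw_iw(rng, S_u + scatter_u, nu_u + n)
            u = U @ V
            E = y - mu - u
            if self.residual_covariance == "diagonal":
                Sigma_e = np.diag(
                    [
                        (1.0 + float(E[:, k] @ E[:, k])) / rng.chisquare(nu_e + n)
                        for k in (0, 1)
                    ]
                )
            else:
                Sigma_e = _draw_iw(rng, S_e + E.T @ E, nu_e + n)

            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                Sigma_u_chain[s] = Sigma_u
                Sigma_e_chain[s] = Sigma_e
                mu_chain[s] = mu
                u_sum += u
                s += 1

        return BivariateResults(
            model=self,
            settings=settings,
            Sigma_u_chain=Sigma_u_chain,
            Sigma_e_chain=Sigma_e_chain,
            mu_chain=mu_chain,
            genetic_values=pd.DataFrame(
                u_sum / n_saved,
                index=pd.Index(self.line_ids, name="line"),
                columns=["env1", "env2"],
            ),
            n_jitter=n_jitter,
        )


def _draw_iw(rng: np.random.Generator, scale: np.ndarray, df: float) -> np.ndarray:
    """Inverse-Wishart draw; non-PD scales are jittered until valid."""
    scale = (scale + scale.T) / 2.0
    for _ in range(5):
        try:
            return invwishart.rvs(df=df, scale=scale, random_state=rng)
        except (np.linalg.LinAlgError, ValueError):
            scale = scale + _JITTER * np.eye(scale.shape[0])
    raise np.linalg.LinAlgError("inverse-Wishart scale matrix not positive definite")


@dataclass
class BivariateResults:
    """Posterior summaries from a bivariate GBLUP fit."""

    model: BivariateGBLUP
    settings: MCMCSettings
    Sigma_u_chain: np.ndarray  # n_saved x 2 x 2
    Sigma_e_chain: np.ndarray
    mu_chain: np.ndarray
    genetic_values: pd.DataFrame
    n_jitter: int = 0

    @property
    def Sigma_u(self) -> np.ndarray:
        return self.Sigma_u_chain.mean(axis=0)

    @property
    def Sigma_e(self) -> np.ndarray:
        return self.Sigma_e_chain.mean(axis=0)

    def genomic_correlation(self) -> float:
        """Posterior mean of Sigma_u[0,1] / sqrt(Sigma_u[0,0] Sigma_u[1,1]).

        Computed per draw; draws with a zero genetic variance are skipped
        (and counted in `n_skipped_rg`).
        """
        v1 = self.Sigma_u_chain[:, 0, 0]
        v2 = self.Sigma_u_chain[:, 1, 1]
        cov = self.Sigma_u_chain[:, 0, 1]
        ok = (v1 > 0) & (v2 > 0)
        self.n_skipped_rg = int((~ok).sum())
        return float((cov[ok] / np.sqrt(v1[ok] * v2[ok])).mean())

    def heritability(self) -> pd.Series:
        """Per-environment h2 = Sigma_u[l,l] / (Sigma_u[l,l] + Sigma_e[l,l])."""
        out = {}
        for k, env in enumerate(("env1", "env2")):
            gu = self.Sigma_u_chain[:, k, k]
            ge = self.Sigma_e_chain[:, k, k]
            out[env] = float((gu / (gu + ge)).mean())
        return pd.Series(out, name="h2")

    def summary(self) -> str:
        rg = self.genomic_correlation()
        Su, Se = self.Sigma_u, self.Sigma_e
        return "\n".join(
            [
                "Bivariate GBLUP (Gibbs, inverse-Wishart priors)",
                f"  lines: {len(self.model.line_ids)}",
                f"  chain: {self.settings.n_iter} iter, {self.settings.burn_in}"
                f" burn-in, thin {self.settings.thin} ({self.mu_chain.shape[0]} draws)",
                f"  Sigma_u: [[{Su[0,0]:.4f}, {Su[0,1]:.4f}], [{Su[1,0]:.4f}, {Su[1,1]:.4f}]]",
                f"  Sigma_e: [[{Se[0,0]:.4f}, {Se[0,1]:.4f}], [{Se[1,0]:.4f}, {Se[1,1]:.4f}]]",
                f"  genomic correlation r_g: {rg:.3f}",
                f"  h2 per environment: "
                + ", ".join(f"{v:.3f}" for v in self.heritability()),
            ]
        )


def fit_bivariate_gblup(
    y1, y2, G, settings=None, df: float = 4.0, residual_covariance: str = "full"
) -> BivariateResults:
    return BivariateGBLUP(
        y1, y2, G, df=df, residual_covariance=residual_covariance
    ).fit(settings)


def genomic_correlation(fit: BivariateResults) -> float:
    return fit.genomic_correlation()
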