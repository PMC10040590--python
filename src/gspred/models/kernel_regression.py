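"""Bayesian kernel regression: GBLUP, RKHS and multi-kernel averaging.

Model:  y = 1 mu + sum_k u_k + eps,  u_k ~ N(0, K_k s2_uk),
        eps ~ N(0, I s2_e),
with flat prior on mu and scaled inverse-chi-square priors on every
variance component.  Each kernel is eigendecomposed once and the genetic
values are sampled in the eigenbasis, where their full conditional is
diagonal; lines without phenotypes are predicted from their kernel rows
against the fitted lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..kernels import KernelMatrix
from ..priors import MCMCSettings, PriorSpec, default_hyperparameters

__all__ = ["KernelRegression", "KernelRegressionResults"]

_EIG_DROP = 1e-10  # relative cutoff below which eigencomponents are inert


def _align_phenotype(
    y, kernels: list[KernelMatrix]
) -> tuple[np.ndarray, list[str]]:
    """Return y over kernel lines (NaN where unphenotyped) and the line order."""
    lines = list(kernels[0].line_ids)
    for k in kernels[1:]:
        if list(k.line_ids) != lines:
            raise ValueError("kernels disagree on line_ids or their order")
    if isinstance(y, pd.Series):
        unknown = [l for l in y.index if l not in set(lines)]
        if unknown:
            raise ValueError(f"phenotyped lines missing from kernel: {unknown[:5]}")
        y_full = y.reindex(lines).to_numpy(dtype=float)
    else:
        y_full = np.asarray(y, dtype=float)
        if y_full.shape[0] != len(lines):
            raise ValueError(
                f"phenotype length {y_full.shape[0]} does not match kernel "
                f"dimension {len(lines)}"
            )
    return y_full, lines


class KernelRegression:
    """Kernel-based whole-genome regression fitted by Gibbs sampling.

    Parameters
    ----------
    y : pandas.Series (indexed by line) or array over kernel lines
        Phenotypes (typically per-environment BLUEs).  NaN entries and lines
        absent from a Series index are treated as unphenotyped: they do not
        enter the likelihood and receive predictions.
    kernels : KernelMatrix or list of KernelMatrix
        One kernel (GBLUP with G; RKHS with a Gaussian kernel) or several
        (kernel averaging), all over the same lines in the same order.
    """

    def __init__(self, y, kernels) -> None:
        if isinstance(kernels, KernelMatrix):
            kernels = [kernels]
        if len(kernels) == 0:
            raise ValueError("need at least one kernel")
        self.kernels = list(kernels)
        self.y_full, self.line_ids = _align_phenotype(y, self.kernels)
        self.observed = ~np.isnan(self.y_full)
        if self.observed.sum() < 3:
            raise ValueError("need at least 3 phenotyped lines")

    def fit(
        self,
        settings: MCMCSettings | None = None,
        prior: PriorSpec | None = None,
        fix_variances: dict | None = None,
    ) -> "KernelRegressionResults":
        """Run the Gibbs sampler and summarize the thinned chain.

        ``fix_variances`` may pin ``sigma2_u`` (scalar or one value per
        kernel) and/or ``sigma2_e``, disabling their sampling — used for
        conjugate checks and model-identity comparisons.
        """
        settings = settings or MCMCSettings()
        obs = self.observed
        y_o = self.y_full[obs]
        n = y_o.size
        sub_kernels = [k.values[np.ix_(obs, obs)] for k in self.kernels]
        prior = default_hyperparameters(
            y_o,
            "kernel",
            kernels=[KernelMatrix(K, [self.line_ids[i] for i in np.flatnonzero(obs)])
                     for K in sub_kernels],
            prior=prior,
        )

        fix_variances = fix_variances or {}
        fixed_u = fix_variances.get("sigma2_u")
        if fixed_u is not None and np.isscalar(fixed_u):
            fixed_u = [float(fixed_u)] * len(sub_kernels)
        fixed_e = fix_variances.get("sigma2_e")

        # Eigenbasis per kernel; components with negligible eigenvalues carry
        # no genetic signal and are dropped from the sampler.
        Us, ds = [], []
        for K in sub_kernels:
            km = KernelMatrix(
                K, [self.line_ids[i] for i in np.flatnonzero(obs)]
            )
            d, U = km.eigendecompose()
            keep = d > _EIG_DROP * max(d[-1], 1.0)
            Us.append(U[:, keep])
            ds.append(d[keep])

        rng = np.random.default_rng(settings.seed)
        n_k = len(sub_kernels)
        mu = float(np.mean(y_o))
        vs = [np.zeros(d.size) for d in ds]
        us = [np.zeros(n) for _ in range(n_k)]
        s2_u = ([prior.scale_u / (prior.df + 2.0)] * n_k if fixed_u is None
                else list(fixed_u))
        s2_e = prior.scale_e / (prior.df + 2.0) if fixed_e is None else float(fixed_e)

        n_saved = settings.n_saved
        mu_chain = np.empty(n_saved)
        s2u_chain = np.empty((n_saved, n_k))
        s2e_chain = np.empty(n_saved)
        v_sum = [np.zeros(d.size) for d in ds]
        u_chain = np.empty((n_saved, n))

        s = 0
        for it in range(settings.n_iter):
            resid_nomu = y_o - np.sum(us, axis=0)
            mu = rng.normal(np.mean(resid_nomu), np.sqrt(s2_e / n))
            for k in range(n_k):
                r_k = y_o - mu - sum(us[j] for j in range(n_k) if j != k)
                z = Us[k].T @ r_k
                lam = ds[k] * s2_u[k]
                shrink = lam / (lam + s2_e)
                vs[k] = rng.normal(shrink * z, np.sqrt(shrink * s2_e))
                us[k] = Us[k] @ vs[k]
                if fixed_u is None:
                    ss = float(np.sum(vs[k] ** 2 / ds[k]))
                    s2_u[k] = (prior.scale_u + ss) / rng.chisquare(
                        prior.df + ds[k].size
                    )
            if fixed_e is None:
                r = y_o - mu - np.sum(us, axis=0)
                s2_e = (prior.scale_e + float(r @ r)) / rng.chisquare(prior.df + n)
            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                mu_chain[s] = mu
                s2u_chain[s] = s2_u
                s2e_chain[s] = s2_e
                u_chain[s] = np.sum(us, axis=0)
                for k in range(n_k):
                    v_sum[k] += vs[k]
                s += 1

        v_mean = [v / n_saved for v in v_sum]
        return KernelRegressionResults(
            model=self,
            prior=prior,
            settings=settings,
            mu_chain=mu_chain,
            s2u_chain=s2u_chain,
            s2e_chain=s2e_chain,
            u_chain=u_chain,
            _Us=Us,
            _ds=ds,
            _v_mean=v_mean,
        )


@dataclass
class KernelRegressionResults:
    """Posterior summaries and thinned chains from a kernel-regression fit."""

    model: KernelRegression
    prior: PriorSpec
    settings: MCMCSettings
    mu_chain: np.ndarray
    s2u_chain: np.ndarray  # n_saved x n_kernels
    s2e_chain: np.ndarray
    u_chain: np.ndarray  # n_saved x n_observed
    _Us: list[np.ndarray]
    _ds: list[np.ndarray]
    _v_mean: list[np.ndarray]

    @property
    def mu(self) -> float:
        return float(self.mu_chain.mean())

    @property
    def sigma2_u(self) -> np.ndarray:
        """Posterior mean genetic variance per kernel."""
        return self.s2u_chain.mean(axis=0)

    @property
    def sigma2_e(self) -> float:
        return float(self.s2e_chain.mean())

    @property
    def variance_shares(self) -> np.ndarray:
        """Posterior mean share of the genetic variance captured per kernel."""
        tot = self.s2u_chain.sum(axis=1, keepdims=True)
        return (self.s2u_chain / tot).mean(axis=0)

    def heritability(self) -> float:
        """Posterior mean of s2_u_total / (s2_u_total + s2_e)."""
        tot = self.s2u_chain.sum(axis=1)
        return float((tot / (tot + self.s2e_chain)).mean())

    @property
    def genetic_values(self) -> pd.Series:
        """Posterior-mean genetic values for every kernel line.

        Fitted lines take the posterior mean of their sampled values;
        unphenotyped lines take the kernel-conditional mean given those.
        """
        obs = self.model.observed
        lines = self.model.line_ids
        g = np.zeros(len(lines))
        g[obs] = self.u_chain.mean(axis=0)
        if (~obs).any():
            g[~obs] = self._predict_rows(np.flatnonzero(~obs))
        return pd.Series(g, index=pd.Index(lines, name="line"), name="g")

    def _predict_rows(self, rows: np.ndarray) -> np.ndarray:
        obs_idx = np.flatnonzero(self.model.observed)
        pred = np.zeros(rows.size)
        for k, kernel in enumerate(self.model.kernels):
            K_no = kernel.values[np.ix_(rows, obs_idx)]
            # u_new = K_no K_oo^+ u_o, via the eigenbasis of K_oo
            pred += K_no @ (self._Us[k] @ (self._v_mean[k] / self._ds[k]))
        return pred

    def predict(self, lines=None, phenotype_scale: bool = False) -> pd.Series:
        """Genetic values (optionally plus the intercept) for given lines."""
        g = self.genetic_values
        if lines is not None:
            unknown = [l for l in lines if l not in g.index]
            if unknown:
                raise KeyError(f"unknown lines: {unknown[:5]}")
            g = g.loc[list(lines)]
        return g + self.mu if phenotype_scale else g

    def diagnostics(self) -> pd.DataFrame:
        """Effective sample size and Geweke z per variance component."""
        from .diagnostics import chain_diagnostics

        chains = {"mu": self.mu_chain, "sigma2_e": self.s2e_chain}
        for k in range(self.s2u_chain.shape[1]):
            chains[f"sigma2_u[{k}]"] = self.s2u_chain[:, k]
        return chain_diagnostics(chains)

    def summary(self) -> str:
        lines = [
            "Kernel regression (Gibbs)",
            f"  kernels: {[k.kind for k in self.model.kernels]}",
            f"  lines fitted: {int(self.model.observed.sum())} "
            f"of {len(self.model.line_ids)}",
            f"  chain: {self.settings.n_iter} iter, {self.settings.burn_in} "
            f"burn-in, thin {self.settings.thin} ({self.mu_chain.size} draws)",
            f"  mu: {self.mu:.4f}",
        ]
        for k, s2 in enumerate(self.sigma2_u):
            kind = self.model.kernels[k].kind
            bw = self.model.kernels[k].bandwidth
            tag = f"{kind}" + (f"(theta={bw})" if bw is not None else "")
            lines.append(f"  sigma2_u[{tag}]: {s2:.4f}")
        lines.append(f"  sigma2_e: {self.sigma2_e:.4f}")
        lines.append(f"  h2: {self.heritability():.3f}")
        return "\n".join(lines)
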