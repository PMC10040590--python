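"""Marker-by-environment (M x E) interaction ridge regression.

Model, for line i in environment l:

    y_il = mu_l + sum_k w_ilk (alpha0_k + alpha_lk) + eps_il

The total effect of each marker is split into a main component alpha0_k
shared across environments (borrowing information among them) and an
environment-specific deviation alpha_lk; residual variances are
heterogeneous across environments.  Marker matrices are centered and
standardized per environment from the lines observed there.  The relative
size of the main-effect variance against the specific variances measures
how stable the genetic signal is across environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genotypes import GenotypeMatrix
from ..priors import MCMCSettings, PriorSpec
from . import _gibbs

__all__ = ["MarkerByEnvironment", "MxEResults", "fit_mxe"]


def _as_env_series(blues, trait: str | None) -> dict[str, pd.Series]:
    """Normalize input to {env: Series of phenotypes indexed by line}."""
    from ..fieldbook import BlueTable

    if isinstance(blues, BlueTable):
        if trait is None:
            raise ValueError("trait must be given when passing a BlueTable")
        return {env: blues.frames[env][trait] for env in blues.environments}
    if isinstance(blues, dict):
        return {str(k): pd.Series(v) for k, v in blues.items()}
    raise TypeError("blues must be a BlueTable or a {env: Series} mapping")


class MarkerByEnvironment:
    """M x E whole-genome ridge regression fitted by Gibbs sampling.

    Parameters
    ----------
    blues : BlueTable or {env: pandas.Series}
        One phenotype record per line per environment (NaN = unobserved in
        that environment; such cells are predicted).
    geno : GenotypeMatrix
        Genotypes for every line appearing in any environment.
    trait : str, optional
        Required when `blues` is a BlueTable.
    """

    def __init__(self, blues, geno: GenotypeMatrix, trait: str | None = None) -> None:
        env_y = _as_env_series(blues, trait)
        if len(env_y) < 2:
            raise ValueError(
                "M x E requires >= 2 environments; use a single-environment "
                "whole-genome regression for one environment"
            )
        self.envs = sorted(env_y)
        self.geno = geno.imputed()
        self.line_ids = list(self.geno.line_ids)
        line_set = set(self.line_ids)
        y_cols = {}
        for env in self.envs:
            s = env_y[env].dropna()
            unknown = [l for l in s.index if l not in line_set]
            if unknown:
                raise ValueError(
                    f"environment {env!r} has phenotyped lines without "
                    f"genotypes: {unknown[:5]}"
                )
            y_cols[env] = s
        shared = set.intersection(*(set(y_cols[e].index) for e in self.envs))
        if len(shared) < 2:
            raise ValueError("environments share fewer than 2 phenotyped lines")
        # line x env phenotype matrix over all genotyped lines (NaN = missing)
        self.y = pd.DataFrame(
            {env: y_cols[env].reindex(self.line_ids) for env in self.envs},
            index=pd.Index(self.line_ids, name="line"),
        )

    def fit(
        self,
        settings: MCMCSettings | None = None,
        prior: PriorSpec | None = None,
        fix_variances: dict | None = None,
    ) -> "MxEResults":
        """Run the Gibbs sampler.

        Prior scales follow the half-of-phenotypic-variance rule with the
        genetic budget split equally between the main and the specific
        component: each receives r2/2 of the per-environment phenotypic
        variance (mode matching, S = V_target * (nu + 2), divided by MSx to
        move to the marker-effect scale).

        ``fix_variances`` may pin ``sigma2_specific`` (scalar or per
        environment, on the marker-effect scale) and/or ``sigma2_e`` —
        used for the reduction-identity checks.
        """
        settings = settings or MCMCSettings()
        prior = prior or PriorSpec()
        L = len(self.envs)
        m = self.geno.m_markers

        # per-environment standardized marker blocks (training-line statistics)
        W_full: dict[str, np.ndarray] = {}
        obs_idx: dict[str, np.ndarray] = {}
        msx = np.empty(L)
        vy = np.empty(L)
        for k, env in enumerate(self.envs):
            y_env = self.y[env].to_numpy(dtype=float)
            obs = ~np.isnan(y_env)
            if obs.sum() < 3:
                raise ValueError(f"environment {env!r} has fewer than 3 phenotyped lines")
            raw = self.geno.values
            mean = raw[obs].mean(axis=0)
            sd = raw[obs].std(axis=0, ddof=1)
            sd[sd == 0] = 1.0  # monomorphic-in-training markers carry no signal
            W_full[env] = (raw - mean) / sd
            obs_idx[env] = np.flatnonzero(obs)
            msx[k] = float(np.sum(np.var(W_full[env][obs], axis=0, ddof=1)))
            vy[k] = float(np.var(y_env[obs], ddof=1))
            if vy[k] == 0:
                raise ValueError(f"environment {env!r} has zero phenotypic variance")

        nu2 = prior.df + 2.0
        half = prior.r2 / 2.0
        S_alpha0 = float(np.mean(vy) * half * nu2 / np.mean(msx))
        S_alpha_l = vy * half * nu2 / msx
        S_e_l = vy * (1.0 - prior.r2) * nu2

        y_stack = np.concatenate(
            [self.y[env].to_numpy(dtype=float)[obs_idx[env]] for env in self.envs]
        )
        W_stack = np.vstack([W_full[env][obs_idx[env]] for env in self.envs])
        env_start = np.zeros(L + 1, dtype=np.int64)
        for k, env in enumerate(self.envs):
            env_start[k + 1] = env_start[k] + obs_idx[env].size

        fix_variances = fix_variances or {}
        fix_specific = "sigma2_specific" in fix_variances
        spec_fixed = fix_variances.get("sigma2_specific", 0.0)
        spec_fixed = np.full(L, float(spec_fixed)) if np.isscalar(spec_fixed) else np.asarray(spec_fixed, float)
        fix_resid = "sigma2_e" in fix_variances
        res_fixed = fix_variances.get("sigma2_e", 0.0)
        res_fixed = np.full(L, float(res_fixed)) if np.isscalar(res_fixed) else np.asarray(res_fixed, float)

        (mu_chain, s2a0_chain, s2al_chain, s2el_chain, alpha0_mean,
         alphal_mean) = _gibbs.mxe_chain(
            np.ascontiguousarray(y_stack),
            np.ascontiguousarray(W_stack),
            env_start,
            float(prior.df),
            S_alpha0,
            np.ascontiguousarray(S_alpha_l),
            np.ascontiguousarray(S_e_l),
            int(settings.n_iter),
            int(settings.burn_in),
            int(settings.thin),
            int(settings.seed) % (2**31),
            fix_specific,
            np.ascontiguousarray(spec_fixed),
            fix_resid,
            np.ascontiguousarray(res_fixed),
        )
        return MxEResults(
            model=self,
            prior=prior,
            settings=settings,
            mu_chain=mu_chain,
            s2a0_chain=s2a0_chain,
            s2al_chain=s2al_chain,
            s2el_chain=s2el_chain,
            alpha0_mean=alpha0_mean,
            alphal_mean=alphal_mean,
            msx=msx,
            _W_full=W_full,
        )


@dataclass
class MxEResults:
    """Posterior summaries from an M x E fit.

    Marker-scale variances (sigma2_alpha0, sigma2_alpha_l) are converted to
    the genetic-value scale by multiplying with MSx, the summed column
    variance of the environment's marker block, making heritabilities and
    variance proportions comparable with kernel-model estimates.
    """

    model: MarkerByEnvironment
    prior: PriorSpec
    settings: MCMCSettings
    mu_chain: np.ndarray  # n_saved x L
    s2a0_chain: np.ndarray
    s2al_chain: np.ndarray  # n_saved x L
    s2el_chain: np.ndarray  # n_saved x L
    alpha0_mean: np.ndarray
    alphal_mean: np.ndarray  # L x m
    msx: np.ndarray
    _W_full: dict[str, np.ndarray]

    @property
    def envs(self) -> list[str]:
        return self.model.envs

    @property
    def mu(self) -> pd.Series:
        return pd.Series(self.mu_chain.mean(axis=0), index=self.envs, name="mu")

    def _main_var_chain(self, k: int) -> np.ndarray:
        return self.s2a0_chain * self.msx[k]

    def _specific_var_chain(self, k: int) -> np.ndarray:
        return self.s2al_chain[:, k] * self.msx[k]

    def variance_components(self) -> pd.DataFrame:
        """Posterior-mean (main, specific, residual) variances per environment."""
        rows = {}
        for k, env in enumerate(self.envs):
            rows[env] = {
                "main": float(self._main_var_chain(k).mean()),
                "specific": float(self._specific_var_chain(k).mean()),
                "residual": float(self.s2el_chain[:, k].mean()),
            }
        return pd.DataFrame(rows).T.rename_axis("env")

    def variance_proportions(self) -> pd.DataFrame:
        """Shares of main, specific and residual variance per environment."""
        vc = self.variance_components()
        return vc.div(vc.sum(axis=1), axis=0)

    def heritability(self, env: str | None = None):
        """Posterior mean of (main + specific) / total, per environment.

        Without `env`, returns the mean across environments (the convention
        used when a single value per trait is reported).
        """
        per_env = {}
        for k, e in enumerate(self.envs):
            g = self._main_var_chain(k) + self._specific_var_chain(k)
            per_env[e] = float((g / (g + self.s2el_chain[:, k])).mean())
        if env is not None:
            return per_env[env]
        return float(np.mean(list(per_env.values())))

    def heritability_by_env(self) -> pd.Series:
        return pd.Series(
            {e: self.heritability(e) for e in self.envs}, name="h2"
        ).rename_axis("env")

    def variance_derived_phenotypic_correlation(self) -> float:
        """r_y' = s2_main / sqrt(prod_l (s2_main + s2_specific_l + s2_e_l)).

        The main genetic variance is the component common to both
        environments; plug-in of posterior-mean variance components on the
        genetic-value scale.  Defined for exactly two environments.
        """
        if len(self.envs) != 2:
            raise ValueError("defined for exactly two environments")
        vc = self.variance_components()
        main = float(vc["main"].mean())
        denom = 1.0
        for env in self.envs:
            denom *= main + vc.loc[env, "specific"] + vc.loc[env, "residual"]
        return main / np.sqrt(denom)

    @property
    def genetic_values(self) -> pd.DataFrame:
        """Per-environment genetic values W_l (alpha0 + alpha_l), all lines."""
        cols = {}
        for k, env in enumerate(self.envs):
            cols[env] = self._W_full[env] @ (self.alpha0_mean + self.alphal_mean[k])
        return pd.DataFrame(
            cols, index=pd.Index(self.model.line_ids, name="line")
        )

    def predict(self, env: str, lines=None, phenotype_scale: bool = False) -> pd.Series:
        if env not in self.envs:
            raise KeyError(f"unknown environment {env!r}")
        g = self.genetic_values[env]
        if lines is not None:
            unknown = [l for l in lines if l not in g.index]
            if unknown:
                raise KeyError(f"unknown lines: {unknown[:5]}")
            g = g.loc[list(lines)]
        if phenotype_scale:
            return g + self.mu[env]
        return g

    def diagnostics(self) -> pd.DataFrame:
        from .diagnostics import chain_diagnostics

        chains = {"sigma2_alpha0": self.s2a0_chain}
        for k, env in enumerate(self.envs):
            chains[f"mu[{env}]"] = self.mu_chain[:, k]
            chains[f"sigma2_alpha[{env}]"] = self.s2al_chain[:, k]
            chains[f"sigma2_e[{env}]"] = self.s2el_chain[:, k]
        return chain_diagnostics(chains)

    def summary(self) -> str:
        vc = self.variance_components()
        vp = self.variance_proportions()
        out = [
            "Marker-by-environment interaction model (Gibbs)",
            f"  environments: {self.envs}",
            f"  markers: {self.alpha0_mean.size}; lines: {len(self.model.line_ids)}",
            f"  chain: {self.settings.n_iter} iter, {self.settings.burn_in} "
            f"burn-in, thin {self.settings.thin} ({self.mu_chain.shape[0]} draws)",
        ]
        for env in self.envs:
            out.append(
                f"  [{env}] main {vc.loc[env, 'main']:.4f} "
                f"({vp.loc[env, 'main']:.0%})  specific "
                f"{vc.loc[env, 'specific']:.4f} ({vp.loc[env, 'specific']:.0%})  "
                f"residual {vc.loc[env, 'residual']:.4f} "
                f"({vp.loc[env, 'residual']:.0%})  h2 "
                f"{self.heritability(env):.3f}"
            )
        if len(self.envs) == 2:
            out.append(
                f"  variance-derived phenotypic correlation: "
                f"{self.variance_derived_phenotypic_correlation():.3f}"
            )
        return "\n".join(out)


def fit_mxe(blues, geno, settings=None, prior=None, trait=None) -> MxEResults:
    return MarkerByEnvironment(blues, geno, trait=trait).fit(settings, prior)
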