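"""Variable-selection whole-genome regression: BayesB, BayesC, RR-BLUP.

Model:  y_i = mu + sum_j w_ij alpha_j + eps_i,
with w_ij the gene content coded 0/1/2, column-centered (not variance
scaled).  BayesB and BayesC place a spike-and-slab prior on each marker
effect — zero with probability pi (default 0.99), Gaussian otherwise —
with marker-specific (BayesB) or shared (BayesC) slab variances; the
ridge variant keeps every marker in with a common Gaussian prior, which
is the marker-space equivalent of GBLUP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genotypes import GenotypeMatrix
from ..priors import MCMCSettings, PriorSpec, default_hyperparameters
from . import _gibbs

__all__ = [
    "MarkerRegression",
    "MarkerRegressionResults",
    "fit_bayesb",
    "fit_bayesc",
]

_VARIANTS = {
    "rrblup": _gibbs.VARIANT_RR,
    "bayesb": _gibbs.VARIANT_BAYESB,
    "bayesc": _gibbs.VARIANT_BAYESC,
}


class MarkerRegression:
    """Marker-effect whole-genome regression fitted by single-site Gibbs.

    Parameters
    ----------
    y : pandas.Series indexed by line, or array over genotype lines
        Phenotypes; NaN / absent lines are excluded from fitting and can be
        predicted afterwards from their marker genotypes.
    geno : GenotypeMatrix
        QC'd genotypes.  Columns are centered with the means of the fitted
        lines; those means are reused when predicting new lines.
    variant : {"bayesb", "bayesc", "rrblup"}
    standardize : bool
        Scale centered columns to unit sample sd as well.  Off by default —
        the variable-selection models work on the natural 0/1/2 scale — but
        needed when matching a kernel model built from standardized markers
        (the GBLUP / RR-BLUP equivalence).
    """

    def __init__(
        self, y, geno: GenotypeMatrix, variant: str = "bayesc",
        standardize: bool = False,
    ) -> None:
        self.standardize = standardize
        if variant not in _VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {sorted(_VARIANTS)}")
        if geno.m_markers == 0:
            raise ValueError("genotype matrix has no markers")
        self.variant = variant
        self.geno = geno.imputed()
        lines = list(self.geno.line_ids)
        if isinstance(y, pd.Series):
            unknown = [l for l in y.index if l not in set(lines)]
            if unknown:
                raise ValueError(f"phenotyped lines missing from genotypes: {unknown[:5]}")
            y_full = y.reindex(lines).to_numpy(dtype=float)
        else:
            y_full = np.asarray(y, dtype=float)
            if y_full.shape[0] != len(lines):
                raise ValueError("phenotype length does not match genotype lines")
        self.y_full = y_full
        self.line_ids = lines
        self.observed = ~np.isnan(y_full)
        if self.observed.sum() < 3:
            raise ValueError("need at least 3 phenotyped lines")

    def fit(
        self,
        settings: MCMCSettings | None = None,
        prior: PriorSpec | None = None,
        fix_variances: dict | None = None,
    ) -> "MarkerRegressionResults":
        settings = settings or MCMCSettings()
        obs = self.observed
        raw = self.geno.values[obs]
        col_means = raw.mean(axis=0)
        W = raw - col_means
        col_sds = np.ones(W.shape[1])
        if self.standardize:
            col_sds = raw.std(axis=0, ddof=1)
            col_sds[col_sds == 0] = 1.0
            W = W / col_sds
        y_o = self.y_full[obs]

        prior = default_hyperparameters(y_o, "marker", W=W, prior=prior)
        scale_alpha = prior.scale_alpha
        if self.variant == "bayesb":
            scale_alpha = scale_alpha / (1.0 - prior.pi)

        fix_variances = fix_variances or {}
        fix_s2a = "sigma2_alpha" in fix_variances
        fix_s2e = "sigma2_e" in fix_variances

        (mu_chain, s2e_chain, s2a_chain, genvar_chain, alpha_mean, incl_prob,
         alpha_chain) = _gibbs.marker_chain(
            np.ascontiguousarray(y_o),
            np.ascontiguousarray(W),
            _VARIANTS[self.variant],
            float(prior.pi),
            float(prior.df),
            float(scale_alpha),
            float(prior.scale_e),
            int(settings.n_iter),
            int(settings.burn_in),
            int(settings.thin),
            int(settings.seed) % (2**31),
            fix_s2e,
            float(fix_variances.get("sigma2_e", 0.0)),
            fix_s2a,
            float(fix_variances.get("sigma2_alpha", 0.0)),
        )
        return MarkerRegressionResults(
            model=self,
            prior=prior,
            settings=settings,
            mu_chain=mu_chain,
            s2e_chain=s2e_chain,
            s2a_chain=s2a_chain,
            genvar_chain=genvar_chain,
            alpha_mean=alpha_mean,
            inclusion_prob=incl_prob,
            alpha_chain=alpha_chain,
            _col_means=col_means,
            _col_sds=col_sds,
        )


@dataclass
class MarkerRegressionResults:
    """Posterior summaries from a marker-effect regression."""

    model: MarkerRegression
    prior: PriorSpec
    settings: MCMCSettings
    mu_chain: np.ndarray
    s2e_chain: np.ndarray
    s2a_chain: np.ndarray
    genvar_chain: np.ndarray  # var(W alpha) per saved draw
    alpha_mean: np.ndarray
    inclusion_prob: np.ndarray
    alpha_chain: np.ndarray
    _col_means: np.ndarray
    _col_sds: np.ndarray

    @property
    def mu(self) -> float:
        return float(self.mu_chain.mean())

    @property
    def sigma2_e(self) -> float:
        return float(self.s2e_chain.mean())

    @property
    def sigma2_alpha(self) -> float:
        """Posterior mean slab variance (BayesB: mean over markers)."""
        return float(self.s2a_chain.mean())

    @property
    def genetic_variance(self) -> float:
        """Posterior mean variance of the genetic values W alpha."""
        return float(self.genvar_chain.mean())

    def heritability(self) -> float:
        return float(
            (self.genvar_chain / (self.genvar_chain + self.s2e_chain)).mean()
        )

    @property
    def marker_effects(self) -> pd.Series:
        return pd.Series(
            self.alpha_mean,
            index=pd.Index(self.model.geno.marker_ids, name="marker"),
            name="alpha",
        )

    @property
    def genetic_values(self) -> pd.Series:
        """W alpha-hat for every genotyped line (fitted or not)."""
        W_all = (self.model.geno.values - self._col_means) / self._col_sds
        g = W_all @ self.alpha_mean
        return pd.Series(
            g, index=pd.Index(self.model.line_ids, name="line"), name="g"
        )

    def predict(self, lines=None, phenotype_scale: bool = False) -> pd.Series:
        g = self.genetic_values
        if lines is not None:
            unknown = [l for l in lines if l not in g.index]
            if unknown:
                raise KeyError(f"unknown lines: {unknown[:5]}")
            g = g.loc[list(lines)]
        return g + self.mu if phenotype_scale else g

    def diagnostics(self) -> pd.DataFrame:
        from .diagnostics import chain_diagnostics

        return chain_diagnostics(
            {
                "mu": self.mu_chain,
                "sigma2_e": self.s2e_chain,
                "sigma2_alpha": self.s2a_chain,
                "genetic_variance": self.genvar_chain,
            }
        )

    def summary(self) -> str:
        n_markers = self.alpha_mean.size
        mean_incl = float(self.inclusion_prob.mean())
        lines = [
            f"Marker regression ({self.model.variant})",
            f"  lines fitted: {int(self.model.observed.sum())} "
            f"of {len(self.model.line_ids)}; markers: {n_markers}",
            f"  chain: {self.settings.n_iter} iter, {self.settings.burn_in} "
            f"burn-in, thin {self.settings.thin} ({self.mu_chain.size} draws)",
            f"  mu: {self.mu:.4f}",
            f"  sigma2_e: {self.sigma2_e:.4f}",
            f"  genetic variance: {self.genetic_variance:.4f}",
            f"  h2: {self.heritability():.3f}",
        ]
        if self.model.variant in ("bayesb", "bayesc"):
            lines.append(f"  pi: {self.prior.pi}  mean inclusion: {mean_incl:.4f}")
        return "\n".join(lines)


def fit_bayesb(y, geno, settings=None, prior=None) -> MarkerRegressionResults:
    return MarkerRegression(y, geno, "bayesb").fit(settings, prior)


def fit_bayesc(y, geno, settings=None, prior=None) -> MarkerRegressionResults:
    return MarkerRegression(y, geno, "bayesc").fit(settings, prior)
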