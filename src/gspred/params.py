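"""Genetic-parameter estimation across traits: the summary-table layer.

For each trait with data in two environments this assembles, from full
(unmasked) data:

* per-environment and mean genomic heritability from the M x E model;
* the genomic correlation r_g between environments (bivariate GBLUP);
* the sample phenotypic correlation r_y of the BLUEs;
* the variance-component-derived phenotypic correlation r_y'
  (main genetic variance over the geometric mean of total variances);
* the main / specific / residual variance proportions per environment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fieldbook import BlueTable
from .genotypes import GenotypeMatrix, standardize_markers
from .kernels import genomic_relationship
from .models.bivariate import BivariateGBLUP
from .models.mxe import MarkerByEnvironment
from .priors import MCMCSettings, PriorSpec, REDUCED_MCMC

__all__ = ["genetic_parameter_table", "variance_proportion_table"]


def _trait_blues(blues: BlueTable, trait: str) -> dict[str, pd.Series]:
    return {
        env: blues.frames[env][trait]
        for env in blues.environments
        if trait in blues.frames[env]
    }


def genetic_parameter_table(
    blues: BlueTable,
    geno: GenotypeMatrix,
    settings: MCMCSettings | None = None,
    prior: PriorSpec | None = None,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """One row per trait: h2 (mean and per environment), r_g, r_y, r_y'."""
    settings = settings or REDUCED_MCMC
    envs = blues.environments
    if len(envs) != 2:
        raise ValueError("genetic parameters are defined for two environments")
    e1, e2 = envs

    G = genomic_relationship(standardize_markers(geno.imputed()))
    rows = []
    all_traits = traits or sorted(
        set.intersection(*(set(blues.frames[e].columns) for e in envs))
    )
    for k, trait in enumerate(all_traits):
        ty = _trait_blues(blues, trait)
        mxe = MarkerByEnvironment(ty, geno).fit(
            settings.with_seed(settings.seed + 2 * k), prior
        )
        biv = BivariateGBLUP(ty[e1], ty[e2], G).fit(
            settings.with_seed(settings.seed + 2 * k + 1)
        )
        shared = ty[e1].dropna().index.intersection(ty[e2].dropna().index)
        r_y = float(np.corrcoef(ty[e1].loc[shared], ty[e2].loc[shared])[0, 1])
        row = {
            "trait": trait,
            "h2": mxe.heritability(),
            f"h2_{e1}": mxe.heritability(e1),
            f"h2_{e2}": mxe.heritability(e2),
            "r_g": biv.genomic_correlation(),
            "r_y": r_y,
            "r_y_prime": mxe.variance_derived_phenotypic_correlation(),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def variance_proportion_table(
    blues: BlueTable,
    geno: GenotypeMatrix,
    settings: MCMCSettings | None = None,
    prior: PriorSpec | None = None,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Main / specific / residual variance shares per trait and environment."""
    settings = settings or REDUCED_MCMC
    rows = []
    all_traits = traits or sorted(
        set.intersection(
            *(set(blues.frames[e].columns) for e in blues.environments)
        )
    )
    for k, trait in enumerate(all_traits):
        mxe = MarkerByEnvironment(_trait_blues(blues, trait), geno).fit(
            settings.with_seed(settings.seed + 101 + k), prior
        )
        vp = mxe.variance_proportions()
        for env in vp.index:
            rows.append(
                {
                    "trait": trait,
                    "env": env,
                    "main": vp.loc[env, "main"],
                    "specific": vp.loc[env, "specific"],
                    "residual": vp.loc[env, "residual"],
                }
            )
    return pd.DataFrame(rows)
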