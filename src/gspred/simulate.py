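"""Synthetic diversity-panel generator with known genetic truth.

Emulates the statistical structure of a multi-environment sesame breeding
trial: biallelic SNP genotypes with bounded minor-allele frequencies,
marker effects decomposed into an across-environment main component and
environment-specific deviations (which fixes the between-environment
genetic correlation), per-environment heritability targets hit exactly on
the realized genetic variance, and a randomized complete block field
layout around the line-by-environment means.

Defaults mirror a sesame landrace diversity panel grown over two seasons:
182 lines, two environments with 7 and 5 blocks, MAF in [0.05, 0.5].
The marker count defaults to 2,000 — genotypes here are linkage-free, so
beyond a few hundred markers the polygenic architecture is already dense
and larger panels only cost time (the field panel's 20k markers add
nothing statistically when markers are independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_multi_env_phenotypes",
    "simulate_field_trial",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the generator.

    h2 is the per-environment heritability of the line-by-environment means
    (the scale on which whole-genome regressions are fitted); r_g is the
    between-environment genetic correlation, realized through the ratio of
    main to total marker variance; pi_true is the fraction of markers with
    exactly zero effect (sparse architectures for variable-selection tests).
    """

    n_lines: int = 182
    m_markers: int = 2_000
    n_env: int = 2
    maf_range: tuple[float, float] = (0.05, 0.5)
    inbreeding: float = 0.95
    h2: tuple[float, ...] | float = 0.5
    r_g: float = 0.8
    pi_true: float = 0.0
    blocks: tuple[int, ...] = (7, 5)
    block_variance: float = 1.0
    plot_noise_variance: float = 1.0
    env_means: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        h2s = self.h2_per_env
        if any(not (0 < h < 1) for h in h2s):
            raise ValueError("h2 must be in (0, 1)")
        if not (0 <= self.r_g <= 1):
            raise ValueError("r_g must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if not (0 <= self.pi_true < 1):
            raise ValueError("pi_true must be in [0, 1)")
        if not (0 <= self.inbreeding <= 1):
            raise ValueError("inbreeding must be in [0, 1]")
        if len(self.blocks) < self.n_env:
            raise ValueError("need a block count per environment")

    @property
    def h2_per_env(self) -> tuple[float, ...]:
        if np.isscalar(self.h2):
            return tuple([float(self.h2)] * self.n_env)
        return tuple(float(h) for h in self.h2)

    @property
    def env_ids(self) -> list[str]:
        return [f"env{l + 1}" for l in range(self.n_env)]


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated dataset."""

    alpha_main: np.ndarray
    alpha_specific: np.ndarray  # n_env x m
    genetic_values: pd.DataFrame  # line x env
    realized_h2: dict[str, float]
    realized_r_g: float
    residual_variance: dict[str, float] = field(default_factory=dict)
    env_means: dict[str, float] = field(default_factory=dict)


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Independent biallelic genotypes with partial inbreeding.

    Allele frequencies are drawn uniformly within the configured MAF range;
    markers are linkage-free.  With inbreeding coefficient F a call is
    homozygous (2 with probability p, else 0) with probability F and
    Hardy-Weinberg Binomial(2, p) otherwise — a diversity panel of a
    predominantly selfing crop has F close to 1, which keeps marker
    heterozygosity rates well below typical QC cutoffs.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    p = rng.uniform(*cfg.maf_range, size=cfg.m_markers)
    shape = (cfg.n_lines, cfg.m_markers)
    hwe = rng.binomial(2, p, size=shape).astype(float)
    homozygous = 2.0 * rng.binomial(1, p, size=shape)
    is_inbred = rng.random(shape) < cfg.inbreeding
    values = np.where(is_inbred, homozygous, hwe)
    return GenotypeMatrix(
        values,
        [f"L{i + 1:04d}" for i in range(cfg.n_lines)],
        [f"M{j + 1:06d}" for j in range(cfg.m_markers)],
    )


def _orthogonal_noise(
    rng: np.random.Generator, g: np.ndarray, variance: float
) -> np.ndarray:
    """Noise with exact sample variance, empirically uncorrelated with g.

    Residualizing the draw on g and rescaling makes var(g) / var(g + e)
    hit its target identically, so heritability targets hold per dataset
    rather than only in expectation.
    """
    n = g.size
    e = rng.standard_normal(n)
    gc = g - g.mean()
    denom = float(gc @ gc)
    if denom > 0:
        e = e - gc * (float(gc @ e) / denom)
    e = e - e.mean()
    sd = e.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate residual draw")
    return e * (np.sqrt(variance) / sd)


def simulate_multi_env_phenotypes(
    geno: GenotypeMatrix,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, pd.Series], SyntheticTruth]:
    """Line-by-environment means under the M x E generative model.

    Marker effects on standardized gene contents: the main component gets a
    share r_g of unit total genetic variance and each environment-specific
    component the remaining 1 - r_g, so r_g is the expected genetic
    correlation between environments.  A pi_true fraction of markers is
    forced to zero effect.  Residuals at the line-mean level are scaled to
    the realized genetic variance so var(g)/var(y) equals the target h2
    exactly.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    vals = geno.imputed().values
    col_means = vals.mean(axis=0)
    col_sds = vals.std(axis=0, ddof=1)
    poly = col_sds > 0
    col_sds[~poly] = 1.0  # monomorphic-in-sample markers stay effect-free
    W = (vals - col_means) / col_sds
    W[:, ~poly] = 0.0
    n, m = W.shape
    active = rng.random(m) >= cfg.pi_true
    m_active = max(int(active.sum()), 1)

    alpha0 = np.where(active, rng.normal(0.0, np.sqrt(cfg.r_g / m_active), m), 0.0)
    g0 = W @ alpha0
    h2s = cfg.h2_per_env
    env_means = (
        dict(zip(cfg.env_ids, cfg.env_means))
        if cfg.env_means is not None
        else {e: 10.0 * (k + 1) for k, e in enumerate(cfg.env_ids)}
    )

    alpha_l = np.zeros((cfg.n_env, m))
    g = np.empty((n, cfg.n_env))
    means: dict[str, pd.Series] = {}
    realized_h2: dict[str, float] = {}
    resid_var: dict[str, float] = {}
    spec_sd = np.sqrt((1.0 - cfg.r_g) / m_active)
    for l, env in enumerate(cfg.env_ids):
        if cfg.r_g < 1.0:
            alpha_l[l] = np.where(active, rng.normal(0.0, spec_sd, m), 0.0)
        g[:, l] = g0 + W @ alpha_l[l]
        var_g = float(np.var(g[:, l], ddof=1))
        if var_g == 0:
            raise ValueError("degenerate genetic values (zero variance)")
        s2_e = var_g * (1.0 - h2s[l]) / h2s[l]
        e = _orthogonal_noise(rng, g[:, l], s2_e)
        y = env_means[env] + g[:, l] + e
        means[env] = pd.Series(
            y, index=pd.Index(geno.line_ids, name="line"), name=env
        )
        realized_h2[env] = var_g / float(np.var(y, ddof=1))
        resid_var[env] = s2_e

    if cfg.n_env >= 2:
        r = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
    else:
        r = 1.0
    gv = pd.DataFrame(
        g, index=pd.Index(geno.line_ids, name="line"), columns=cfg.env_ids
    )
    truth = SyntheticTruth(
        alpha_main=alpha0,
        alpha_specific=alpha_l,
        genetic_values=gv,
        realized_h2=realized_h2,
        realized_r_g=float(r),
        residual_variance=resid_var,
        env_means=env_means,
    )
    return means, truth


def simulate_field_trial(
    means: dict[str, pd.Series],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    trait: str = "trait",
):
    """Complete RCBD plot data around given line-by-environment means.

    Each plot value is its line-environment mean plus a shared random block
    effect N(0, block_variance) and independent plot noise
    N(0, plot_noise_variance).
    """
    from .fieldbook import FieldBook

    rng = rng or np.random.default_rng(cfg.seed + 2)
    records = []
    for l, (env, mu) in enumerate(sorted(means.items())):
        n_blocks = cfg.blocks[l]
        if n_blocks < 1:
            raise ValueError("need at least one block")
        b_eff = rng.normal(0.0, np.sqrt(cfg.block_variance), n_blocks)
        for o in range(n_blocks):
            noise = rng.normal(0.0, np.sqrt(cfg.plot_noise_variance), mu.size)
            for line, base, eps in zip(mu.index, mu.to_numpy(), noise):
                records.append(
                    {
                        "line": line,
                        "env": env,
                        "block": f"B{o + 1}",
                        "trait": trait,
                        "value": base + b_eff[o] + eps,
                    }
                )
    return FieldBook(pd.DataFrame.from_records(records))


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, dict[str, pd.Series], SyntheticTruth]:
    """Genotypes plus line-by-environment means under a single seed."""
    rng = np.random.default_rng(cfg.seed)
    geno = simulate_genotypes(cfg, rng)
    means, truth = simulate_multi_env_phenotypes(geno, cfg, rng)
    return geno, means, truth
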