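"""MCMC convergence diagnostics: effective sample size and Geweke z.

These are reported for inspection only and never gate any computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["geweke_z", "chain_diagnostics"]


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    z = (mean_first - mean_last) / sqrt(se_first^2 + se_last^2), with
    spectral-density-at-zero variance estimates approximated by the sample
    variances over each segment (adequate for thinned, weakly autocorrelated
    chains).
    """
    chain = np.asarray(chain, dtype=float)
    n = chain.size
    a = chain[: max(int(first * n), 2)]
    b = chain[n - max(int(last * n), 2):]
    var = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    if var == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(var))


def chain_diagnostics(chains: dict[str, np.ndarray]) -> pd.DataFrame:
    """Posterior mean, sd, effective sample size and Geweke z per chain."""
    import arviz as az

    rows = {}
    for name, chain in chains.items():
        chain = np.asarray(chain, dtype=float)
        rows[name] = {
            "mean": chain.mean(),
            "sd": chain.std(ddof=1),
            "ess": float(az.ess(az.convert_to_dataset(chain[None, :]))["x"]),
            "geweke_z": geweke_z(chain),
        }
    return pd.DataFrame(rows).T.rename_axis("parameter")
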