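"""Plot-level field-book data and per-environment BLUEs of line means.

Field trials follow a randomized complete block design (RCBD): every line
appears once per block within an environment.  Adjusted line means (best
linear unbiased estimates, BLUEs) come from the mixed model

    y_io = mu + g_i + b_o + eps_io

with genotype fixed and block random, fitted per trait and environment by
REML.  The returned BLUEs are coding-invariant line means (generalized
least squares of the line-mean parameterization), which downstream
whole-genome regressions consume as single records per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FieldBook", "BlueTable", "fit_rcbd_blues", "blues_for_all"]

_REQUIRED = ("line", "env", "block")


@dataclass
class FieldBook:
    """Long-format plot observations: line, env, block, trait, value."""

    data: pd.DataFrame  # columns: line, env, block, trait, value

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in (*_REQUIRED, "trait", "value") if c not in df.columns]
        if missing:
            raise ValueError(f"field book missing columns: {missing}")
        dup = df.duplicated(subset=["line", "env", "block", "trait"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                "duplicate plot record for "
                f"(line={row['line']}, env={row['env']}, block={row['block']}, "
                f"trait={row['trait']})"
            )
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "FieldBook":
        """Build from a wide table: line, env, block + one column per trait."""
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"field book missing columns: {missing}")
        traits = [c for c in df.columns if c not in _REQUIRED]
        if not traits:
            raise ValueError("no trait columns found")
        long = df.melt(
            id_vars=list(_REQUIRED), value_vars=traits,
            var_name="trait", value_name="value",
        ).dropna(subset=["value"])
        return cls(long)

    def to_wide(self) -> pd.DataFrame:
        wide = self.data.pivot_table(
            index=list(_REQUIRED), columns="trait", values="value", aggfunc="first"
        ).reset_index()
        wide.columns.name = None
        return wide

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["env"].astype(str).unique())

    @property
    def lines(self) -> list[str]:
        return sorted(self.data["line"].astype(str).unique())


@dataclass
class BlueTable:
    """Per-environment line x trait BLUEs plus fitted variance components."""

    frames: dict[str, pd.DataFrame]  # env -> (line index, trait columns)
    block_variance: dict[tuple[str, str], float] = field(default_factory=dict)
    residual_variance: dict[tuple[str, str], float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def environments(self) -> list[str]:
        return sorted(self.frames)

    def series(self, env: str, trait: str) -> pd.Series:
        return self.frames[env][trait]

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for env, frame in self.frames.items():
            part = frame.copy()
            part.insert(0, "env", env)
            parts.append(part.reset_index(names="line"))
        return pd.concat(parts, ignore_index=True)


def _em_reml_rcbd(
    y: np.ndarray, line_idx: np.ndarray, block_idx: np.ndarray,
    n_lines: int, n_blocks: int, tol: float = 1e-8, max_iter: int = 500,
) -> tuple[np.ndarray, float, float]:
    """EM-REML for the two-variance RCBD model; returns (BLUEs, s2_b, s2_e).

    Mixed-model equations with genotype fixed (line-mean coding X, so the
    solution is directly the vector of adjusted line means) and block random.
    EM updates: s2_b from the block solutions plus their prediction-error
    trace, s2_e from the residual quadratic form, until both stabilize.
    """
    n = y.size
    X = np.zeros((n, n_lines))
    X[np.arange(n), line_idx] = 1.0
    Z = np.zeros((n, n_blocks))
    Z[np.arange(n), block_idx] = 1.0

    XtX = X.T @ X
    XtZ = X.T @ Z
    ZtZ = Z.T @ Z
    Xty = X.T @ y
    Zty = Z.T @ y
    yty = y @ y

    s2_e = max(np.var(y, ddof=1), 1e-12)
    s2_b = s2_e / 2.0
    p = n_lines
    beta = np.zeros(p)
    for _ in range(max_iter):
        lam = s2_e / s2_b
        C = np.block([[XtX, XtZ], [XtZ.T, ZtZ + lam * np.eye(n_blocks)]])
        rhs = np.concatenate([Xty, Zty])
        Cinv = np.linalg.pinv(C)
        sol = Cinv @ rhs
        beta, b = sol[:p], sol[p:]
        # EM updates (Searle et al. form): trace term uses the b-block of C^{-1}
        Cbb = Cinv[p:, p:]
        s2_b_new = (b @ b + s2_e * np.trace(Cbb)) / n_blocks
        s2_e_new = (yty - beta @ Xty - b @ Zty) / (n - np.linalg.matrix_rank(XtX))
        s2_e_new = max(s2_e_new, 1e-12)
        s2_b_new = max(s2_b_new, 1e-12)
        if abs(s2_b_new - s2_b) < tol and abs(s2_e_new - s2_e) < tol:
            s2_b, s2_e = s2_b_new, s2_e_new
            break
        s2_b, s2_e = s2_b_new, s2_e_new
    return beta, float(s2_b), float(s2_e)


def fit_rcbd_blues(
    fb: FieldBook, environment: str, trait: str
) -> tuple[pd.Series, float, float, list[str]]:
    """BLUEs of line means for one trait in one environment.

    Returns (blues indexed by line, block variance, residual variance,
    warnings).  With fewer than 2 blocks the model is unidentifiable and raw
    line means are returned with a warning flag and zero block variance.
    """
    sub = fb.data[
        (fb.data["env"].astype(str) == str(environment))
        & (fb.data["trait"] == trait)
    ].dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no data for trait {trait!r} in environment {environment!r}")
    lines = sorted(sub["line"].astype(str).unique())
    blocks = sorted(sub["block"].astype(str).unique())
    warnings: list[str] = []
    if len(lines) < 2:
        raise ValueError("need at least 2 lines to fit the RCBD model")
    if len(blocks) < 2:
        warnings.append(
            f"env {environment!r} trait {trait!r}: fewer than 2 blocks; "
            "returning raw line means"
        )
        means = sub.groupby(sub["line"].astype(str))["value"].mean()
        return means.reindex(lines), 0.0, float("nan"), warnings

    line_pos = {l: i for i, l in enumerate(lines)}
    block_pos = {b: o for o, b in enumerate(blocks)}
    y = sub["value"].to_numpy(dtype=float)
    li = sub["line"].astype(str).map(line_pos).to_numpy()
    bi = sub["block"].astype(str).map(block_pos).to_numpy()
    beta, s2_b, s2_e = _em_reml_rcbd(y, li, bi, len(lines), len(blocks))
    blues = pd.Series(beta, index=pd.Index(lines, name="line"), name=trait)
    return blues, s2_b, s2_e, warnings


def blues_for_all(fb: FieldBook) -> BlueTable:
    """Fit RCBD BLUEs for every environment x trait combination."""
    frames: dict[str, pd.DataFrame] = {}
    table = BlueTable(frames)
    for env in fb.environments:
        cols = {}
        for trait in fb.traits:
            try:
                blues, s2_b, s2_e, warn = fit_rcbd_blues(fb, env, trait)
            except ValueError:
                continue
            cols[trait] = blues
            table.block_variance[(env, trait)] = s2_b
            table.residual_variance[(env, trait)] = s2_e
            table.warnings.extend(warn)
        if cols:
            frames[env] = pd.DataFrame(cols)
    if not frames:
        raise ValueError("no environment/trait combination could be fitted")
    return table
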