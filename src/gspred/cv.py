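"""Cross-validation designs for single- and multi-environment prediction.

Four designs are provided, mirroring the prediction problems a breeding
program faces:

* single  — repeated random subsampling within one environment (default
  2/3 training, 1/3 testing, 50 replicates);
* CV0     — whole-environment leave-out: all lines of one environment
  predict the same lines in the other;
* CV1     — brand-new lines: the test lines are unphenotyped in every
  environment;
* CV2     — sparse trials: each test cell (line, environment) has that
  line phenotyped in the other environment, so the interaction model can
  borrow information within line across environments.

Accuracy is the Pearson correlation between observed and predicted values
in the test set, averaged over replicates.  Paired model comparisons on
the same partitions use the corrected resampled t-test, which inflates
the variance of the mean difference to account for overlapping training
sets across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, standardize_markers
from .kernels import genomic_relationship, kernel_averaging_list
from .models.kernel_regression import KernelRegression
from .models.marker_regression import MarkerRegression
from .models.mxe import MarkerByEnvironment
from .priors import MCMCSettings, REDUCED_MCMC

__all__ = [
    "CVPartition",
    "CVResult",
    "make_partitions",
    "run_single_env_cv",
    "run_cv0",
    "run_cv1",
    "run_cv2",
    "corrected_resampled_ttest",
    "ridge_blup_predict",
]

SINGLE_MODELS = ("gblup", "rkhs", "bayesb", "bayesc")


@dataclass(frozen=True)
class CVPartition:
    """One replicate's line roles per environment."""

    replicate: int
    scenario: str
    test_lines: dict[str, tuple[str, ...]]  # env -> lines masked (TST) there
    seed: int

    def train_lines(self, env: str, all_lines) -> list[str]:
        tst = set(self.test_lines[env])
        return [l for l in all_lines if l not in tst]


def _replicate_seed(seed: int, replicate: int, salt: int = 0) -> int:
    return int(
        np.random.SeedSequence([seed, replicate, salt]).generate_state(1)[0]
        % (2**31)
    )


def make_partitions(
    lines,
    n_env: int,
    scenario: str,
    n_reps: int = 50,
    train_frac: float = 2.0 / 3.0,
    seed: int = 0,
) -> list[CVPartition]:
    """Deterministic replicate partitions for a CV scenario.

    single / cv1: one random 1/3 of lines is the test set, identically in
    every environment (training size is floor(n * train_frac)).
    cv2 (two environments): lines are split into thirds — one third masked
    in environment 1, a disjoint third masked in environment 2, the rest
    observed in both — so every masked cell's line is observed elsewhere.
    cv0: whole environments are left out; no subsampling is involved.
    """
    lines = [str(l) for l in lines]
    if len(set(lines)) != len(lines):
        raise ValueError("duplicate line ids")
    if len(lines) < 3:
        raise ValueError("need at least 3 lines")
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    if scenario not in ("single", "cv0", "cv1", "cv2"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario in ("cv0", "cv2") and n_env < 2:
        raise ValueError(f"{scenario} requires at least 2 environments")
    envs = [f"env{l + 1}" for l in range(n_env)]

    if scenario == "cv0":
        return [
            CVPartition(0, "cv0", {env: tuple(lines) for env in envs}, seed)
        ]

    n = len(lines)
    n_train = int(np.floor(n * train_frac))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("train_frac leaves an empty training or test set")

    parts: list[CVPartition] = []
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        perm = list(rng.permutation(lines))
        if scenario in ("single", "cv1"):
            tst = tuple(sorted(perm[n_train:]))
            roles = {env: tst for env in envs}
        else:  # cv2 thirds
            third = n // 3
            a = tuple(sorted(perm[:third]))
            b = tuple(sorted(perm[third: 2 * third]))
            roles = {envs[0]: a, envs[1]: b}
            for env in envs[2:]:
                roles[env] = ()
        parts.append(CVPartition(r, scenario, roles, seed))
    return parts


@dataclass
class CVResult:
    """Per-replicate predictive correlations plus aggregation helpers."""

    records: pd.DataFrame  # scenario, model, trait, env, replicate, accuracy
    n_undefined: int = 0
    warnings: list[str] = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        return (
            self.records.groupby(["scenario", "model", "trait", "env"])["accuracy"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )

    def accuracies(self, model: str, env: str | None = None) -> np.ndarray:
        df = self.records[self.records["model"] == model]
        if env is not None:
            df = df[df["env"] == env]
        return df.sort_values("replicate")["accuracy"].to_numpy()

    def compare(
        self, model_a: str, model_b: str, env: str, train_frac: float = 2.0 / 3.0
    ) -> tuple[float, float]:
        """Corrected resampled t-test of model_a vs model_b in one environment."""
        a = self.accuracies(model_a, env)
        b = self.accuracies(model_b, env)
        return corrected_resampled_ttest(a, b, train_frac)

    @classmethod
    def concat(cls, results: list["CVResult"]) -> "CVResult":
        return cls(
            pd.concat([r.records for r in results], ignore_index=True),
            n_undefined=sum(r.n_undefined for r in results),
            warnings=[w for r in results for w in r.warnings],
        )

    def plot(self, ax=None):
        """Bar chart of mean accuracy per model and environment."""
        import matplotlib.pyplot as plt

        agg = self.aggregate()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        pivot = agg.pivot_table(index="env", columns="model", values="mean")
        pivot.plot.bar(ax=ax, rot=0)
        ax.set_ylabel("predictive correlation")
        return ax


def _safe_corr(obs: np.ndarray, pred: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector is constant."""
    if obs.size < 2 or np.std(obs) == 0 or np.std(pred) == 0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


def run_single_env_cv(
    y: pd.Series,
    geno: GenotypeMatrix,
    models=SINGLE_MODELS,
    partitions: list[CVPartition] | None = None,
    settings: MCMCSettings | None = None,
    trait: str = "trait",
    env: str = "env1",
) -> CVResult:
    """Repeated-subsampling CV of the single-environment models.

    `y` holds one environment's BLUEs indexed by line; each model is fitted
    on the training lines of every partition and scored on the held-out
    lines.  Kernels are built once from genotypes (phenotype-free, so no
    leakage) and phenotypes are masked per replicate.
    """
    settings = settings or REDUCED_MCMC
    y = y.dropna()
    lines = list(y.index)
    if partitions is None:
        partitions = make_partitions(lines, 1, "single", seed=settings.seed)

    geno_sub = geno.subset_lines(lines).imputed()
    W = standardize_markers(geno_sub)
    kernels = {"gblup": [genomic_relationship(W)], "rkhs": kernel_averaging_list(W)}

    rows = []
    n_undef = 0
    warns: list[str] = []
    for part in partitions:
        tst = [l for l in lines if l in set(part.test_lines.get(env, part.test_lines[next(iter(part.test_lines))]))]
        tst_set = set(tst)
        if not tst:
            raise ValueError("partition has an empty test set for these lines")
        y_masked = y.copy()
        y_masked[y_masked.index.isin(tst_set)] = np.nan
        obs_tst = y.loc[tst].to_numpy()
        for mi, model in enumerate(models):
            fit_seed = _replicate_seed(settings.seed, part.replicate, mi)
            st = settings.with_seed(fit_seed)
            if model in kernels:
                res = KernelRegression(y_masked, kernels[model]).fit(st)
            elif model in ("bayesb", "bayesc"):
                res = MarkerRegression(y_masked, geno_sub, model).fit(st)
            else:
                raise ValueError(f"unknown model {model!r}")
            pred = res.predict(tst).to_numpy()
            acc = _safe_corr(obs_tst, pred)
            if np.isnan(acc):
                n_undef += 1
                warns.append(
                    f"undefined correlation: model={model} replicate={part.replicate}"
                )
            rows.append(
                {
                    "scenario": "single",
                    "model": model,
                    "trait": trait,
                    "env": env,
                    "replicate": part.replicate,
                    "accuracy": acc,
                }
            )
    return CVResult(pd.DataFrame(rows), n_undef, warns)


def _env_pair(blues: dict[str, pd.Series]) -> tuple[str, str]:
    envs = sorted(blues)
    if len(envs) != 2:
        raise ValueError("this scenario is defined for exactly two environments")
    return envs[0], envs[1]


def run_cv0(
    blues: dict[str, pd.Series],
    geno: GenotypeMatrix,
    settings: MCMCSettings | None = None,
    trait: str = "trait",
    directions: str = "both",
) -> CVResult:
    """Whole-environment leave-out with GBLUP.

    All lines of the source environment are fitted; accuracy is the
    correlation of their posterior-mean genetic values with the target
    environment's BLUEs on the shared lines.  Genetic values need no
    target-environment intercept because Pearson correlation is
    location-free.
    """
    settings = settings or REDUCED_MCMC
    e1, e2 = _env_pair(blues)
    pairs = {"both": [(e1, e2), (e2, e1)], "forward": [(e1, e2)], "reverse": [(e2, e1)]}[
        directions
    ]
    rows = []
    for k, (src, tgt) in enumerate(pairs):
        y_src = blues[src].dropna()
        y_tgt = blues[tgt].dropna()
        shared = [l for l in y_tgt.index if l in set(y_src.index)]
        if not shared:
            raise ValueError(f"no lines shared between {src} and {tgt}")
        geno_sub = geno.subset_lines(list(y_src.index)).imputed()
        G = genomic_relationship(standardize_markers(geno_sub))
        res = KernelRegression(y_src, G).fit(settings.with_seed(
            _replicate_seed(settings.seed, k, 10)
        ))
        acc = _safe_corr(
            y_tgt.loc[shared].to_numpy(), res.predict(shared).to_numpy()
        )
        rows.append(
            {
                "scenario": "cv0",
                "model": "gblup",
                "trait": trait,
                "env": tgt,
                "replicate": k,
                "accuracy": acc,
            }
        )
    return CVResult(pd.DataFrame(rows))


def _run_multi_env(
    blues: dict[str, pd.Series],
    geno: GenotypeMatrix,
    partitions: list[CVPartition],
    settings: MCMCSettings,
    trait: str,
    scenario: str,
) -> CVResult:
    """Shared engine for CV1/CV2: M x E arm plus per-environment GBLUP arm."""
    e1, e2 = _env_pair(blues)
    envs = [e1, e2]
    rows = []
    n_undef = 0
    warns: list[str] = []
    for part in partitions:
        # partition env labels are positional (env1, env2) -> actual names
        mask = {
            env: set(part.test_lines[f"env{k + 1}"]) for k, env in enumerate(envs)
        }
        masked_blues = {}
        for env in envs:
            y = blues[env].copy()
            y[y.index.isin(mask[env])] = np.nan
            masked_blues[env] = y

        st = settings.with_seed(_replicate_seed(settings.seed, part.replicate, 20))
        mxe = MarkerByEnvironment(masked_blues, geno).fit(st)
        for env in envs:
            tst = [l for l in blues[env].dropna().index if l in mask[env]]
            if not tst:
                continue
            obs = blues[env].loc[tst].to_numpy()
            acc = _safe_corr(obs, mxe.predict(env, tst).to_numpy())
            if np.isnan(acc):
                n_undef += 1
            rows.append(
                {
                    "scenario": scenario,
                    "model": "mxe",
                    "trait": trait,
                    "env": env,
                    "replicate": part.replicate,
                    "accuracy": acc,
                }
            )

        # single-environment GBLUP benchmark on the same training lines
        for ei, env in enumerate(envs):
            tst = [l for l in blues[env].dropna().index if l in mask[env]]
            if not tst:
                continue
            y_env = masked_blues[env].dropna()
            geno_env = geno.subset_lines(list(y_env.index) + tst).imputed()
            G = genomic_relationship(standardize_markers(geno_env))
            st_g = settings.with_seed(
                _replicate_seed(settings.seed, part.replicate, 30 + ei)
            )
            res = KernelRegression(
                y_env.reindex(geno_env.line_ids), G
            ).fit(st_g)
            obs = blues[env].loc[tst].to_numpy()
            acc = _safe_corr(obs, res.predict(tst).to_numpy())
            if np.isnan(acc):
                n_undef += 1
            rows.append(
                {
                    "scenario": scenario,
                    "model": "gblup",
                    "trait": trait,
                    "env": env,
                    "replicate": part.replicate,
                    "accuracy": acc,
                }
            )
    return CVResult(pd.DataFrame(rows), n_undef, warns)


def run_cv1(
    blues: dict[str, pd.Series],
    geno: GenotypeMatrix,
    partitions: list[CVPartition] | None = None,
    settings: MCMCSettings | None = None,
    trait: str = "trait",
) -> CVResult:
    """New-line prediction: test lines are masked in every environment."""
    settings = settings or REDUCED_MCMC
    if partitions is None:
        shared = sorted(
            set(blues[e].dropna().index for e in blues).pop()
            if len(blues) == 1
            else set.union(*(set(blues[e].dropna().index) for e in blues))
        )
        partitions = make_partitions(shared, 2, "cv1", seed=settings.seed)
    if any(p.scenario != "cv1" for p in partitions):
        raise ValueError("partitions were not built for cv1")
    return _run_multi_env(blues, geno, partitions, settings, trait, "cv1")


def run_cv2(
    blues: dict[str, pd.Series],
    geno: GenotypeMatrix,
    partitions: list[CVPartition] | None = None,
    settings: MCMCSettings | None = None,
    trait: str = "trait",
) -> CVResult:
    """Sparse-trial prediction: masked cells have the line observed elsewhere."""
    settings = settings or REDUCED_MCMC
    if partitions is None:
        shared = sorted(
            set.union(*(set(blues[e].dropna().index) for e in blues))
        )
        partitions = make_partitions(shared, 2, "cv2", seed=settings.seed)
    if any(p.scenario != "cv2" for p in partitions):
        raise ValueError("partitions were not built for cv2")
    return _run_multi_env(blues, geno, partitions, settings, trait, "cv2")


def corrected_resampled_ttest(
    acc_a, acc_b, train_frac: float = 2.0 / 3.0
) -> tuple[float, float]:
    """Paired t-test for repeated-subsampling CV with variance correction.

    t = dbar / sqrt((1/K + n_test/n_train) * s2_d) on K - 1 degrees of
    freedom, where the extra n_test/n_train term compensates for the
    dependence induced by overlapping training sets across replicates.
    Degenerate cases: zero variance of the differences gives t = 0, p = 1
    when the mean difference is zero, and +/-inf with p = 0 otherwise.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("accuracy vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    d = a[ok] - b[ok]
    K = d.size
    if K < 2:
        raise ValueError("need at least 2 paired replicates")
    rho = (1.0 - train_frac) / train_frac
    s2 = float(np.var(d, ddof=1))
    dbar = float(d.mean())
    if s2 == 0.0:
        if dbar == 0.0:
            return 0.0, 1.0
        return float(np.sign(dbar) * np.inf), 0.0
    t = dbar / np.sqrt((1.0 / K + rho) * s2)
    p = 2.0 * float(stats.t.sf(abs(t), K - 1))
    return float(t), p


def ridge_blup_predict(
    y_trn: np.ndarray, W_trn: np.ndarray, W_tst: np.ndarray, h2: float = 0.5
) -> np.ndarray:
    """Closed-form RR-BLUP predictions (no MCMC).

    Marker effects alpha-hat = W'(WW' + lambda I)^-1 (y - ybar) with
    lambda = m (1 - h2) / h2, the ridge penalty implied by an assumed
    heritability on standardized markers.  Used for fast nulls and
    calibration studies where posterior uncertainty is not needed.
    """
    y_trn = np.asarray(y_trn, dtype=float)
    n, m = W_trn.shape
    lam = m * (1.0 - h2) / h2
    yc = y_trn - y_trn.mean()
    K = W_trn @ W_trn.T + lam * np.eye(n)
    alpha = W_trn.T @ np.linalg.solve(K, yc)
    return W_tst @ alpha + y_trn.mean()
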