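"""Cross-validation designs, leakage guarantees and the corrected t-test."""

import numpy as np
import pandas as pd
import pytest

import gspred.cv as cv_mod
from gspred import (
    MCMCSettings,
    SimulationConfig,
    corrected_resampled_ttest,
    make_partitions,
    ridge_blup_predict,
    run_cv0,
    run_single_env_cv,
    simulate_dataset,
)


class TestPartitions:
    def test_two_thirds_split_of_182_lines(self):
        lines = [f"L{i}" for i in range(182)]
        parts = make_partitions(lines, 1, "single", n_reps=3, seed=1)
        for p in parts:
            tst = p.test_lines["env1"]
            assert len(tst) == 61  # floor(182 * 2/3) = 121 TRN
            assert len(p.train_lines("env1", lines)) == 121

    def test_same_seed_identical_partitions(self):
        lines = [f"L{i}" for i in range(30)]
        a = make_partitions(lines, 2, "cv1", n_reps=5, seed=9)
        b = make_partitions(lines, 2, "cv1", n_reps=5, seed=9)
        assert a == b

    def test_cv1_masks_same_lines_everywhere(self):
        lines = [f"L{i}" for i in range(40)]
        for p in make_partitions(lines, 2, "cv1", n_reps=4, seed=3):
            assert p.test_lines["env1"] == p.test_lines["env2"]

    def test_cv2_masked_cells_observed_in_other_environment(self):
        lines = [f"L{i}" for i in range(45)]
        for p in make_partitions(lines, 2, "cv2", n_reps=4, seed=3):
            a, b = set(p.test_lines["env1"]), set(p.test_lines["env2"])
            assert not a & b  # disjoint thirds: masked here -> observed there
            assert len(a) == len(b) == 15

    def test_cv0_requires_two_environments(self):
        with pytest.raises(ValueError, match="at least 2 environments"):
            make_partitions([f"L{i}" for i in range(10)], 1, "cv0")

    def test_degenerate_train_frac_rejected(self):
        lines = [f"L{i}" for i in range(10)]
        with pytest.raises(ValueError, match="empty training or test"):
            make_partitions(lines, 1, "single", train_frac=0.999)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_partitions([f"L{i}" for i in range(10)], 1, "cv9")


class TestCorrectedTtest:
    def test_identical_vectors(self):
        a = np.linspace(0.1, 0.5, 20)
        t, p = corrected_resampled_ttest(a, a.copy())
        assert (t, p) == (0.0, 1.0)

    def test_hand_computed_statistic(self):
        # K=50, dbar=0.1, s_d=0.1, train_frac=2/3
        # t = 0.1 / sqrt((1/50 + 0.5) * 0.01) ~= 1.387
        rng = np.random.default_rng(0)
        d = rng.standard_normal(50)
        d = (d - d.mean()) / d.std(ddof=1) * 0.1 + 0.1
        t, p = corrected_resampled_ttest(d, np.zeros(50), train_frac=2 / 3)
        assert t == pytest.approx(0.1 / np.sqrt((1 / 50 + 0.5) * 0.01), abs=1e-9)
        assert 0 < p < 1

    def test_constant_nonzero_difference(self):
        a = np.full(10, 0.6)
        b = np.full(10, 0.4)
        t, p = corrected_resampled_ttest(a, b)
        assert np.isinf(t) and p == 0.0

    def test_nan_pairs_dropped(self):
        a = np.array([0.5, np.nan, 0.6, 0.8])
        b = np.array([0.4, 0.5, np.nan, 0.6])
        t, p = corrected_resampled_ttest(a, b)
        assert np.isfinite(t)

    def test_antisymmetric_in_arguments(self, rng):
        a = rng.uniform(0.2, 0.8, 30)
        b = rng.uniform(0.2, 0.8, 30)
        t_ab, p_ab = corrected_resampled_ttest(a, b)
        t_ba, p_ba = corrected_resampled_ttest(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            corrected_resampled_ttest(np.zeros(5), np.zeros(6))


@pytest.fixture(scope="module")
def quick_cv(small_panel):
    _, geno, means, _ = small_panel
    parts = make_partitions(list(means["env1"].index), 1, "single",
                            n_reps=3, seed=5)
    st = MCMCSettings(800, 300, 2, seed=5)
    return run_single_env_cv(means["env1"], geno, ("gblup", "bayesc"), parts, st)


class TestSingleEnvCV:
    def test_record_layout(self, quick_cv):
        rec = quick_cv.records
        assert set(rec["model"]) == {"gblup", "bayesc"}
        assert rec.groupby("model")["replicate"].count().eq(3).all()
        assert rec["accuracy"].between(-1, 1).all()

    def test_aggregate_means(self, quick_cv):
        agg = quick_cv.aggregate()
        assert {"mean", "std", "count"}.issubset(agg.columns)
        assert (agg["count"] == 3).all()

    def test_no_test_phenotype_reaches_the_sampler(self, small_panel, monkeypatch):
        _, geno, means, _ = small_panel
        parts = make_partitions(list(means["env1"].index), 1, "single",
                                n_reps=2, seed=6)
        seen = []
        orig = cv_mod.KernelRegression.__init__

        def spy(self, y, kernels):
            if isinstance(y, pd.Series):
                seen.append(y.copy())
            orig(self, y, kernels)

        monkeypatch.setattr(cv_mod.KernelRegression, "__init__", spy)
        run_single_env_cv(means["env1"], geno, ("gblup",), parts,
                          MCMCSettings(200, 50, 2, seed=1))
        for part, y_seen in zip(parts, seen):
            tst = part.test_lines["env1"]
            assert y_seen[list(tst)].isna().all()


class TestCV0:
    def test_duplicate_environment_high_accuracy(self, short_chain):
        cfg = SimulationConfig(n_lines=100, m_markers=200, h2=0.6, seed=41)
        geno, means, _ = simulate_dataset(cfg)
        dup = {"env1": means["env1"], "env2": means["env1"].copy()}
        res = run_cv0(dup, geno, short_chain)
        assert (res.records["accuracy"] > 0.5).all()

    def test_one_direction_gives_one_row(self, small_panel, short_chain):
        _, geno, means, _ = small_panel
        res = run_cv0(means, geno, short_chain, directions="forward")
        assert len(res.records) == 1
        assert res.records.iloc[0]["env"] == "env2"

    def test_both_directions(self, small_panel, short_chain):
        _, geno, means, _ = small_panel
        res = run_cv0(means, geno, short_chain)
        assert sorted(res.records["env"]) == ["env1", "env2"]
        assert res.records["accuracy"].between(-1, 1).all()


class TestRidgeBlup:
    def test_matches_primal_ridge_solution(self, rng):
        n, m = 30, 50
        W = rng.standard_normal((n, m))
        y = rng.standard_normal(n)
        h2 = 0.5
        lam = m * (1 - h2) / h2
        alpha_primal = np.linalg.solve(W.T @ W + lam * np.eye(m),
                                       W.T @ (y - y.mean()))
        pred = ridge_blup_predict(y, W, W, h2)
        assert np.allclose(pred, W @ alpha_primal + y.mean(), atol=1e-8)
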