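"""Marker-by-environment model: variance partition and derived parameters."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from gspred import (
    MarkerByEnvironment,
    MCMCSettings,
    SimulationConfig,
    simulate_dataset,
)
from gspred.models.mxe import MxEResults
from gspred.priors import PriorSpec


def _fake_results(s2a0, s2al, s2el, msx=(1.0, 1.0), envs=("env1", "env2")):
    """MxEResults with constant chains, for exact formula checks."""
    n_draws = 4
    L = len(envs)
    return MxEResults(
        model=SimpleNamespace(envs=list(envs), line_ids=[]),
        prior=PriorSpec(),
        settings=MCMCSettings(10, 2, 1),
        mu_chain=np.zeros((n_draws, L)),
        s2a0_chain=np.full(n_draws, s2a0),
        s2al_chain=np.tile(np.asarray(s2al, float), (n_draws, 1)),
        s2el_chain=np.tile(np.asarray(s2el, float), (n_draws, 1)),
        alpha0_mean=np.zeros(3),
        alphal_mean=np.zeros((L, 3)),
        msx=np.asarray(msx, float),
        _W_full={},
    )


class TestDerivedFormulas:
    def test_variance_proportions_plug_in(self):
        res = _fake_results(1.0, [1.0, 1.0], [2.0, 2.0])
        vp = res.variance_proportions()
        assert np.allclose(vp.loc["env1"], [0.25, 0.25, 0.5])

    def test_proportions_sum_to_one_with_zero_residual(self):
        res = _fake_results(1.0, [3.0, 3.0], [0.0, 0.0])
        vp = res.variance_proportions()
        assert np.allclose(vp.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(vp["residual"], 0.0)

    def test_heritability_plug_in(self):
        res = _fake_results(0.5, [0.5, 0.5], [1.0, 1.0])
        assert res.heritability("env1") == pytest.approx(0.5)
        assert res.heritability() == pytest.approx(0.5)

    def test_zero_genetic_variance_gives_zero_h2(self):
        res = _fake_results(0.0, [0.0, 0.0], [1.0, 2.0])
        assert res.heritability() == pytest.approx(0.0)

    def test_phenotypic_correlation_plug_in(self):
        res = _fake_results(1.0, [0.0, 0.0], [1.0, 1.0])
        assert res.variance_derived_phenotypic_correlation() == pytest.approx(0.5)

    def test_phenotypic_correlation_asymmetric_case(self):
        # main 2, specific (1, 0), residual (1, 2) -> 2 / sqrt(4*4) = 0.5
        res = _fake_results(2.0, [1.0, 0.0], [1.0, 2.0])
        assert res.variance_derived_phenotypic_correlation() == pytest.approx(0.5)

    def test_zero_main_variance_gives_zero_correlation(self):
        res = _fake_results(0.0, [1.0, 1.0], [1.0, 1.0])
        assert res.variance_derived_phenotypic_correlation() == pytest.approx(0.0)


class TestFittedBehaviour:
    def test_duplicate_environments_put_mass_on_main_effect(self, short_chain):
        cfg = SimulationConfig(n_lines=120, m_markers=200, h2=0.6, r_g=1.0, seed=21)
        geno, means, _ = simulate_dataset(cfg)
        # env2 is an exact copy of env1
        means = {"env1": means["env1"], "env2": means["env1"].copy()}
        res = MarkerByEnvironment(means, geno).fit(short_chain)
        vc = res.variance_components()
        for env in res.envs:
            main, spec = vc.loc[env, "main"], vc.loc[env, "specific"]
            assert main / (main + spec) > 0.8
        vp = res.variance_proportions()
        assert np.all(vp["main"] > vp["specific"])

    def test_independent_environments_put_mass_on_specific_effect(self, short_chain):
        cfg = SimulationConfig(n_lines=120, m_markers=200, h2=0.5, r_g=0.0, seed=22)
        geno, means, _ = simulate_dataset(cfg)
        res = MarkerByEnvironment(means, geno).fit(short_chain)
        vc = res.variance_components()
        for env in res.envs:
            assert vc.loc[env, "main"] < vc.loc[env, "specific"]

    def test_environment_labels_exchangeable(self, short_chain):
        cfg = SimulationConfig(n_lines=100, m_markers=150, h2=0.5, r_g=0.7, seed=23)
        geno, means, _ = simulate_dataset(cfg)
        res = MarkerByEnvironment(means, geno).fit(short_chain)
        swapped = {"env1": means["env2"].rename("env1"),
                   "env2": means["env1"].rename("env2")}
        res_sw = MarkerByEnvironment(swapped, geno).fit(short_chain)
        vc, vc_sw = res.variance_components(), res_sw.variance_components()
        assert vc.loc["env1", "specific"] == pytest.approx(
            vc_sw.loc["env2", "specific"], rel=0.5, abs=0.15
        )
        assert vc.loc["env1", "main"] == pytest.approx(
            vc_sw.loc["env1", "main"], rel=0.3
        )

    def test_missing_cells_are_predicted(self, small_panel, short_chain):
        _, geno, means, truth = small_panel
        masked = {e: s.copy() for e, s in means.items()}
        held = list(means["env1"].index[:25])
        masked["env1"][held] = np.nan
        res = MarkerByEnvironment(masked, geno).fit(short_chain)
        pred = res.predict("env1", held)
        obs = means["env1"][held]
        assert np.corrcoef(pred, obs)[0, 1] > 0.2

    def test_single_environment_rejected(self, small_panel):
        _, geno, means, _ = small_panel
        with pytest.raises(ValueError, match="single-environment"):
            MarkerByEnvironment({"env1": means["env1"]}, geno)

    def test_no_shared_lines_rejected(self, small_panel):
        _, geno, means, _ = small_panel
        half1 = means["env1"].iloc[:60]
        half2 = means["env2"].iloc[60:61]
        with pytest.raises(ValueError, match="share"):
            MarkerByEnvironment({"env1": half1, "env2": half2}, geno)

    def test_seed_reproducibility(self, small_panel, short_chain):
        _, geno, means, _ = small_panel
        a = MarkerByEnvironment(means, geno).fit(short_chain)
        b = MarkerByEnvironment(means, geno).fit(short_chain)
        assert np.array_equal(a.s2a0_chain, b.s2a0_chain)
        assert np.array_equal(a.alphal_mean, b.alphal_mean)
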