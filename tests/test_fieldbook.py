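"""RCBD BLUEs: adjusted line means with block as a random effect."""

import numpy as np
import pandas as pd
import pytest

from gspred import FieldBook, blues_for_all, fit_rcbd_blues


def _book(n_lines, blocks, gen_value, env="E1", trait="t", rng=None, sigma_b=0.0, sigma_e=0.0):
    rng = rng or np.random.default_rng(0)
    rows = []
    b_eff = rng.normal(0, sigma_b, len(blocks))
    for o, block in enumerate(blocks):
        for i in range(n_lines):
            rows.append(
                {
                    "line": f"L{i}",
                    "env": env,
                    "block": block,
                    "trait": trait,
                    "value": gen_value(i) + b_eff[o] + rng.normal(0, sigma_e),
                }
            )
    return FieldBook(pd.DataFrame(rows))


class TestFieldBook:
    def test_duplicate_plot_rejected(self):
        df = pd.DataFrame(
            {
                "line": ["L1", "L1"],
                "env": ["E1", "E1"],
                "block": ["B1", "B1"],
                "trait": ["t", "t"],
                "value": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="duplicate plot record"):
            FieldBook(df)

    def test_wide_long_round_trip(self, rng):
        fb = _book(5, ["B1", "B2"], lambda i: float(i), rng=rng, sigma_e=1.0)
        wide = fb.to_wide()
        back = FieldBook.from_wide(wide)
        a = fb.data.sort_values(["line", "block"]).reset_index(drop=True)
        b = back.data.sort_values(["line", "block"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a[b.columns], b)


class TestRcbdBlues:
    def test_balanced_no_block_variance_equals_line_means(self, rng):
        fb = _book(10, ["B1", "B2", "B3"], lambda i: 2.0 * i, rng=rng,
                   sigma_b=0.0, sigma_e=0.5)
        blues, s2_b, s2_e, warn = fit_rcbd_blues(fb, "E1", "t")
        raw = fb.data.groupby("line")["value"].mean()
        assert np.allclose(blues.sort_index(), raw.sort_index(), atol=1e-8)
        assert not warn

    def test_balanced_equals_line_means_despite_block_effects(self, rng):
        # fixed-genotype RCBD property: with complete data the GLS line means
        # coincide with arithmetic means whatever the block variance
        fb = _book(8, ["B1", "B2", "B3", "B4"], lambda i: i / 2.0, rng=rng,
                   sigma_b=3.0, sigma_e=0.5)
        blues, *_ = fit_rcbd_blues(fb, "E1", "t")
        raw = fb.data.groupby("line")["value"].mean()
        assert np.allclose(blues.sort_index(), raw.sort_index(), atol=1e-6)

    def test_single_block_falls_back_to_raw_means(self, rng):
        fb = _book(5, ["B1"], lambda i: float(i), rng=rng)
        blues, s2_b, _, warn = fit_rcbd_blues(fb, "E1", "t")
        assert warn and "fewer than 2 blocks" in warn[0]
        assert s2_b == 0.0
        assert np.allclose(blues.sort_index().to_numpy(), np.arange(5.0))

    def test_recovers_known_genotype_means(self, rng):
        true = {i: float(rng.normal(0, 2)) for i in range(100)}
        fb = _book(100, [f"B{o}" for o in range(5)], lambda i: true[i],
                   rng=rng, sigma_b=1.0, sigma_e=1.0)
        blues, s2_b, s2_e, _ = fit_rcbd_blues(fb, "E1", "t")
        truth = np.array([true[int(l[1:])] for l in blues.index])
        assert np.corrcoef(blues.to_numpy(), truth)[0, 1] > 0.95
        assert s2_b >= 0 and s2_e > 0

    def test_constant_shift_moves_blues_by_constant(self, rng):
        fb = _book(6, ["B1", "B2", "B3"], lambda i: float(i), rng=rng,
                   sigma_b=1.0, sigma_e=0.5)
        blues, *_ = fit_rcbd_blues(fb, "E1", "t")
        shifted = FieldBook(fb.data.assign(value=fb.data["value"] + 7.5))
        blues2, *_ = fit_rcbd_blues(shifted, "E1", "t")
        assert np.allclose(blues2.to_numpy(), blues.to_numpy() + 7.5, atol=1e-6)

    def test_block_labels_are_exchangeable(self, rng):
        fb = _book(6, ["B1", "B2", "B3"], lambda i: float(i), rng=rng,
                   sigma_b=1.0, sigma_e=0.5)
        relabel = {"B1": "Z9", "B2": "A0", "B3": "Q5"}
        fb2 = FieldBook(fb.data.assign(block=fb.data["block"].map(relabel)))
        blues, *_ = fit_rcbd_blues(fb, "E1", "t")
        blues2, *_ = fit_rcbd_blues(fb2, "E1", "t")
        assert np.allclose(blues.to_numpy(), blues2.to_numpy(), atol=1e-8)

    def test_unbalanced_missing_plots_still_fit(self, rng):
        fb = _book(10, ["B1", "B2", "B3"], lambda i: float(i), rng=rng,
                   sigma_b=1.0, sigma_e=0.5)
        thinned = FieldBook(fb.data.sample(frac=0.8, random_state=1))
        blues, *_ = fit_rcbd_blues(thinned, "E1", "t")
        assert blues.notna().sum() >= 9

    def test_matches_independent_reml_on_unbalanced_data(self, rng):
        # statsmodels MixedLM (profiled-likelihood REML) as independent oracle
        import statsmodels.formula.api as smf

        fb = _book(12, ["B1", "B2", "B3", "B4"], lambda i: 0.5 * i, rng=rng,
                   sigma_b=1.0, sigma_e=0.7)
        fb = FieldBook(fb.data.sample(frac=0.85, random_state=2))
        blues, s2_b, s2_e, _ = fit_rcbd_blues(fb, "E1", "t")
        md = smf.mixedlm(
            "value ~ 0 + C(line)", fb.data, groups=fb.data["block"]
        ).fit(reml=True)
        sm_blues = pd.Series(
            {k.split("[")[1][:-1].replace("T.", ""): v
             for k, v in md.fe_params.items()}
        )
        assert np.abs(blues.sort_index() - sm_blues.sort_index()).max() < 1e-4
        assert s2_b == pytest.approx(float(md.cov_re.iloc[0, 0]), rel=1e-2)
        assert s2_e == pytest.approx(float(md.scale), rel=1e-2)

    def test_blues_for_all_covers_envs_and_traits(self, rng):
        fb1 = _book(5, ["B1", "B2"], lambda i: float(i), env="E1", rng=rng, sigma_e=0.5)
        fb2 = _book(5, ["B1", "B2"], lambda i: 2.0 * i, env="E2", rng=rng, sigma_e=0.5)
        fb = FieldBook(pd.concat([fb1.data, fb2.data], ignore_index=True))
        table = blues_for_all(fb)
        assert table.environments == ["E1", "E2"]
        assert list(table.frames["E1"].columns) == ["t"]
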