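"""Fixed/random-effects pooling, heterogeneity, model selection, screening."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megade import (
    ScreenCriteria,
    fixed_effect,
    forest_table,
    heterogeneity,
    pool_effects,
    pool_gene,
    random_effect,
    screen_genes,
)
from megade.pooling import tau2_reml

Y3, V3 = [0.5, 1.0, 1.5], [0.1, 0.1, 0.1]


class TestFixedEffect:
    def test_identical_inputs(self):
        est, se = fixed_effect([1, 1, 1], [1, 1, 1])
        assert est == pytest.approx(1.0, abs=1e-12)
        assert se == pytest.approx(math.sqrt(1 / 3), abs=1e-12)

    def test_equal_variance_hand_example(self):
        est, se = fixed_effect(Y3, V3)
        assert est == pytest.approx(1.0, abs=1e-12)
        assert se == pytest.approx(math.sqrt(1 / 30), abs=1e-12)

    def test_unequal_variance_hand_example(self):
        est, _ = fixed_effect([0, 2], [1, 3])
        assert est == pytest.approx(0.5, abs=1e-12)

    def test_estimate_within_input_range(self, rng):
        for _ in range(20):
            y = rng.normal(size=5)
            v = rng.uniform(0.01, 2.0, size=5)
            est, _ = fixed_effect(y, v)
            assert y.min() - 1e-12 <= est <= y.max() + 1e-12

    @pytest.mark.parametrize("y,v", [([1.0], [1.0]), ([1, 2], [1.0, 0.0])])
    def test_invalid_inputs_rejected(self, y, v):
        with pytest.raises(ValueError):
            fixed_effect(y, v)


class TestHeterogeneity:
    def test_no_dispersion(self):
        Q, df, p_Q, I2, tau2 = heterogeneity([1, 1, 1], [1, 1, 1], 1.0)
        assert Q == 0.0 and I2 == 0.0 and tau2 == 0.0
        assert p_Q == pytest.approx(1.0)

    def test_dl_hand_example(self):
        fe, _ = fixed_effect(Y3, V3)
        Q, df, p_Q, I2, tau2 = heterogeneity(Y3, V3, fe)
        assert Q == pytest.approx(5.0, abs=1e-12)
        assert df == 2
        assert I2 == pytest.approx(60.0, abs=1e-12)
        assert tau2 == pytest.approx(0.15, abs=1e-12)
        assert p_Q == pytest.approx(math.exp(-2.5), rel=1e-9)

    def test_truncation_below_df(self):
        y, v = [1.0, 1.1], [1.0, 1.0]
        fe, _ = fixed_effect(y, v)
        Q, df, p_Q, I2, tau2 = heterogeneity(y, v, fe)
        assert Q == pytest.approx(0.005, abs=1e-12)
        assert I2 == 0.0 and tau2 == 0.0


class TestRandomEffect:
    def test_reduces_to_fixed_when_tau2_zero(self):
        assert random_effect(Y3, V3, 0.0) == fixed_effect(Y3, V3)

    def test_hand_example_with_tau2(self):
        est, se = random_effect(Y3, V3, 0.15)
        assert est == pytest.approx(1.0, abs=1e-12)
        assert se == pytest.approx(math.sqrt(1 / 12), abs=1e-12)

    def test_large_tau2_limit_is_unweighted_mean(self, rng):
        y = rng.normal(size=6)
        v = rng.uniform(0.01, 1.0, size=6)
        est, _ = random_effect(y, v, 1e9)
        assert est == pytest.approx(y.mean(), rel=1e-6)


class TestPoolGene:
    def test_matches_brute_force_weighted_means(self, rng):
        """FE/RE estimates equal direct evaluation of the weighted-mean
        formulas on random <=5-study instances, to 1e-12."""
        for _ in range(50):
            k = rng.integers(2, 6)
            y = rng.normal(size=k)
            v = rng.uniform(0.01, 2.0, size=k)
            res = pool_gene("g", y, v)
            w = 1 / v
            assert res.fe_est == pytest.approx(np.sum(w * y) / np.sum(w), abs=1e-12)
            ws = 1 / (v + res.tau2)
            assert res.re_est == pytest.approx(np.sum(ws * y) / np.sum(ws), abs=1e-12)
            assert res.re_se >= res.fe_se
            assert (res.re_se > res.fe_se) == (res.tau2 > 0)
            assert res.ci_low <= res.est <= res.ci_high

    def test_matches_independent_reference_implementation(self):
        """Frozen output of an established meta-analysis package (metafor
        4.8, method="DL") on a 5-study fixture."""
        y = [0.31, -0.12, 0.84, 0.55, -0.40]
        v = [0.04, 0.11, 0.02, 0.07, 0.19]
        res = pool_gene("g", y, v)
        assert res.fe_est == pytest.approx(0.525000824402, abs=1e-9)
        assert res.fe_se == pytest.approx(0.098228328992, abs=1e-9)
        assert res.tau2 == pytest.approx(0.147773355956, abs=1e-9)
        assert res.Q == pytest.approx(14.411138499588, abs=1e-9)
        assert res.I2 == pytest.approx(72.243691918481, abs=1e-9)
        assert res.re_est == pytest.approx(0.331610905059, abs=1e-9)
        assert res.re_se == pytest.approx(0.209805206208, abs=1e-9)

    def test_model_selection_rule(self):
        # worked example: Q=5, df=2 -> p_Q ~ 0.082, fixed at q_alpha=0.05
        res = pool_gene("g", Y3, V3)
        assert res.model_used == "fixed"
        assert res.est == res.fe_est
        # extreme heterogeneity -> random
        res = pool_gene("g", [0.0, 5.0, -5.0, 8.0], [0.001] * 4)
        assert res.p_Q < 1e-10 and res.model_used == "random"
        assert res.est == res.re_est
        # homogeneous -> fixed
        res = pool_gene("g", [1.0, 1.0], [1.0, 1.0])
        assert res.model_used == "fixed"

    def test_reml_close_to_dl_on_balanced_data(self):
        y = [0.31, -0.12, 0.84, 0.55, -0.40]
        v = [0.1] * 5
        dl = pool_gene("g", y, v, tau2_method="DL").tau2
        reml = tau2_reml(y, v)
        assert reml == pytest.approx(dl, rel=0.35)

    @settings(derandomize=True, max_examples=40)
    @given(c=st.floats(0.1, 10.0))
    def test_scale_equivariance(self, c):
        res1 = pool_gene("g", Y3, V3)
        res2 = pool_gene("g", [y * c for y in Y3], [v * c * c for v in V3])
        assert res2.fe_est == pytest.approx(c * res1.fe_est, rel=1e-9)
        assert res2.re_est == pytest.approx(c * res1.re_est, rel=1e-9)
        assert res2.Q == pytest.approx(res1.Q, rel=1e-9)
        assert res2.I2 == pytest.approx(res1.I2, rel=1e-9)
        assert res2.p == pytest.approx(res1.p, rel=1e-6)


class TestPoolEffects:
    def test_groups_by_gene_and_skips_singletons(self):
        eff = pd.DataFrame(
            {
                "study_id": ["S1", "S2", "S3", "S1"],
                "gene": ["G1", "G1", "G1", "GONLY"],
                "lfc": [0.5, 1.0, 1.5, 2.0],
                "variance": [0.1, 0.1, 0.1, 0.1],
            }
        )
        meta = pool_effects(eff)
        assert list(meta["gene"]) == ["G1"]
        assert meta.loc[0, "k"] == 3
        assert meta.loc[0, "fe_est"] == pytest.approx(1.0, abs=1e-12)


class TestScreen:
    @staticmethod
    def row(gene, k, p, est):
        return {"gene": gene, "k": k, "p": p, "est": est}

    def test_three_criteria_and_asymmetric_bounds(self):
        results = pd.DataFrame(
            [
                # measured in only 6 of 14: fails coverage no matter what
                self.row("GCOV", 6, 1e-10, 3.0),
                # passes everything at the upper boundary side
                self.row("GPASS", 8, 0.01, 0.60),
                # down-regulation between -1.00 and -0.59 does NOT pass
                self.row("GASYM", 8, 0.001, -0.80),
                # strong down-regulation passes
                self.row("GDOWN", 8, 0.001, -1.20),
                # big effect, weak evidence
                self.row("GP", 14, 0.20, 2.0),
                # exact thresholds are strict inequalities
                self.row("GEDGE", 7, 0.049, 0.59),
            ]
        )
        out = screen_genes(results, 14).set_index("gene")
        assert not out.loc["GCOV", "pass_coverage"]
        assert out.loc["GCOV", "pass_p"] and out.loc["GCOV", "pass_lfc"]
        assert out.loc["GPASS", "passed"]
        assert out.loc["GASYM", "pass_p"] and not out.loc["GASYM", "pass_lfc"]
        assert out.loc["GDOWN", "passed"]
        assert not out.loc["GP", "pass_p"]
        assert not out.loc["GEDGE", "pass_lfc"]  # 0.59 is not > 0.59
        assert list(out["passed"]) == [False, True, False, True, False, False]

    def test_odd_total_rounds_up(self):
        results = pd.DataFrame([self.row("G", 7, 0.01, 1.0)])
        out = screen_genes(results, 13)
        assert out.loc[0, "pass_coverage"]  # ceil(6.5) = 7
        out = screen_genes(results, 15)
        assert not out.loc[0, "pass_coverage"]  # ceil(7.5) = 8

    def test_bh_column_is_reference_only(self):
        results = pd.DataFrame(
            [self.row("G1", 8, 0.04, 1.0), self.row("G2", 8, 0.5, 1.0)]
        )
        out = screen_genes(results, 14)
        assert (out["p_bh"] >= out["p"] - 1e-15).all()
        assert out.loc[0, "passed"]  # raw p drives the screen, not p_bh

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            ScreenCriteria(lfc_upper=-0.5, lfc_lower=-1.0)
        with pytest.raises(ValueError):
            ScreenCriteria(alpha=1.5)


class TestForest:
    def test_equal_variances_split_weights_evenly(self):
        eff = pd.DataFrame(
            {
                "study_id": ["S1", "S2", "S3"],
                "gene": ["G1"] * 3,
                "lfc": Y3,
                "variance": V3,
            }
        )
        table = forest_table("G1", eff, model="fixed")
        np.testing.assert_allclose(table["weight_pct"], [100 / 3] * 3)
        assert table["weight_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        half = 1.959963984540054 * math.sqrt(0.1)
        np.testing.assert_allclose(table["ci_high"] - table["lfc"], half)

    def test_random_model_weights_use_tau2(self):
        eff = pd.DataFrame(
            {
                "study_id": ["S1", "S2"],
                "gene": ["G1"] * 2,
                "lfc": [0.0, 1.0],
                "variance": [0.1, 0.4],
            }
        )
        fixed = forest_table("G1", eff, model="fixed")
        rand = forest_table("G1", eff, model="random", tau2=10.0)
        assert fixed.loc[0, "weight_pct"] == pytest.approx(80.0)
        # huge tau2 flattens the weights
        assert rand.loc[0, "weight_pct"] == pytest.approx(50.0, abs=1.0)

    def test_unknown_gene_rejected(self):
        eff = pd.DataFrame(
            {"study_id": ["S1"], "gene": ["G1"], "lfc": [0.0], "variance": [1.0]}
        )
        with pytest.raises(ValueError, match="no per-study effects"):
            forest_table("NOPE", eff)
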