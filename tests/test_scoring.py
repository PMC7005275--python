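"""Natural-spline fitting, guide residuals, gene Z-scores and ranks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from anchorscreen import (
    combine_conditions,
    fit_spline,
    gene_z,
    guide_residuals,
    natural_spline_basis,
    rank_scores,
    score_condition,
    spline_knots,
)
from anchorscreen.lfc import lfc_pipeline
from anchorscreen.synthetic_data import (
    SimulationConfig,
    replicate_grouping,
    simulate_screen,
)
from conftest import normal_equations_fit


class TestSplineFit:
    def test_linear_and_affine_data_fit_exactly(self):
        """Affine maps lie in the natural-spline span: residuals vanish."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        for y in (x, 2 * x + 1):
            model = fit_spline(x, y)
            assert np.allclose(model.predict(x), y, atol=1e-10)

    def test_naturalness_linear_extrapolation(self):
        """Beyond the boundary knots the prediction is linear in x."""
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, 200)
        y = np.sin(2 * x) + rng.normal(0, 0.05, 200)
        model = fit_spline(x, y)
        # second differences of predictions on an outside grid are ~0
        grid = np.linspace(2, 5, 50)
        pred = model.predict(grid)
        assert np.allclose(np.diff(pred, 2), 0.0, atol=1e-9)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_normal_equations_oracle(self, trial):
        """Predictions equal an explicit normal-equations solve to 1e-8."""
        rng = np.random.default_rng(100 + trial)
        x = rng.normal(size=200)
        y = np.tanh(x) + rng.normal(0, 0.3, size=200)
        model = fit_spline(x, y)
        design = np.column_stack(
            [np.ones(len(x)), natural_spline_basis(x, spline_knots(x, 3))]
        )
        coef = normal_equations_fit(design, y)
        assert np.allclose(model.predict(x), design @ coef, atol=1e-8)

    def test_three_df_means_three_basis_columns(self):
        x = np.linspace(0, 1, 50)
        basis = natural_spline_basis(x, spline_knots(x, 3))
        assert basis.shape == (50, 3)

    def test_degenerate_and_mismatched_inputs(self):
        with pytest.raises(ValueError, match="identical"):
            fit_spline(np.ones(20), np.arange(20.0))
        with pytest.raises(ValueError, match="mismatch"):
            fit_spline(np.arange(20.0), np.arange(19.0))
        with pytest.raises(ValueError, match="at least 10"):
            fit_spline(np.arange(5.0), np.arange(5.0))


class TestGuideResiduals:
    def test_identical_arms_zero_residuals_and_mean_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=80)
        model = fit_spline(x, x)
        resid = guide_residuals(model, x, x, [f"g{i}" for i in range(80)])
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_residual_mean_zero_with_intercept(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        y = 0.8 * x + rng.normal(0, 0.5, 300)
        model = fit_spline(x, y)
        resid = guide_residuals(model, x, y, [f"g{i}" for i in range(300)])
        assert abs(resid.mean()) < 1e-8

    def test_shift_in_y_shifts_residual_under_fixed_model(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = x.copy()
        model = fit_spline(x, y)
        y2 = y.copy()
        y2[7] += 1.25
        resid = guide_residuals(model, x, y2, [f"g{i}" for i in range(50)])
        assert resid.iloc[7] == pytest.approx(1.25, abs=1e-10)


class TestGeneZ:
    def test_worked_example(self):
        """Residuals {A: 1,1; B: -1,-1; C: 0,0} -> z(A) = 1.5811."""
        resid = pd.Series(
            [1.0, 1.0, -1.0, -1.0, 0.0, 0.0],
            index=pd.Index([f"g{i}" for i in range(6)], name="guide_id"),
        )
        guide_map = {"g0": "A", "g1": "A", "g2": "B", "g3": "B", "g4": "C", "g5": "C"}
        scores = gene_z(resid, guide_map)
        sd = np.std([1, 1, -1, -1, 0, 0], ddof=1)
        assert sd == pytest.approx(0.8944, abs=5e-5)
        assert scores.loc["A", "z"] == pytest.approx(1.0 / (sd / np.sqrt(2)), abs=1e-10)
        assert scores.loc["A", "z"] == pytest.approx(1.5811, abs=5e-5)
        assert scores.loc["B", "z"] == pytest.approx(-1.5811, abs=5e-5)
        assert scores.loc["C", "z"] == 0.0

    def test_gene_at_global_mean_is_zero(self):
        resid = pd.Series(
            [2.0, 2.0, -2.0, -2.0, 0.0, 0.0],
            index=pd.Index([f"g{i}" for i in range(6)], name="guide_id"),
        )
        gm = {"g0": "A", "g1": "A", "g2": "B", "g3": "B", "g4": "C", "g5": "C"}
        scores = gene_z(resid, gm)
        assert scores.loc["C", "z"] == 0.0
        # sign(z) == sign(mean_residual - global mean)
        assert np.all(np.sign(scores["z"]) == np.sign(scores["mean_residual"]))

    def test_degenerate_screen_errors(self):
        resid = pd.Series([1.0, 1.0], index=pd.Index(["g0", "g1"], name="guide_id"))
        with pytest.raises(ValueError, match="identical"):
            gene_z(resid, {"g0": "A", "g1": "B"})

    def test_unmapped_guide_errors(self):
        resid = pd.Series([1.0, 0.0], index=pd.Index(["g0", "g1"], name="guide_id"))
        with pytest.raises(ValueError, match="g1"):
            gene_z(resid, {"g0": "A"})


class TestRanks:
    def test_small_example(self):
        scores = pd.DataFrame(
            {"z": [-2.0, 0.0, 3.0], "mean_residual": [-1, 0, 1], "n_guides": [2, 2, 2]},
            index=pd.Index(["A", "B", "C"], name="gene_symbol"),
        )
        ranked = rank_scores(scores)
        assert ranked.loc["A", "rank_ascending"] == 1
        assert ranked.loc["C", "rank_ascending"] == 3
        assert ranked.loc["C", "rank_descending"] == 1
        assert ranked.loc["A", "rank_descending"] == 3

    def test_permutation_identity_distinct_z(self):
        rng = np.random.default_rng(5)
        z = rng.permutation(np.linspace(-4, 4, 25))
        scores = pd.DataFrame(
            {"z": z},
            index=pd.Index([f"G{i:02d}" for i in range(25)], name="gene_symbol"),
        )
        ranked = rank_scores(scores)
        assert sorted(ranked["rank_ascending"]) == list(range(1, 26))
        assert np.all(ranked["rank_ascending"] + ranked["rank_descending"] == 26)

    def test_ties_broken_lexicographically(self):
        scores = pd.DataFrame(
            {"z": [1.0, 1.0, -1.0]},
            index=pd.Index(["ZZZ", "AAA", "MMM"], name="gene_symbol"),
        )
        ranked = rank_scores(scores)
        assert ranked.loc["MMM", "rank_ascending"] == 1
        assert ranked.loc["AAA", "rank_ascending"] == 2
        assert ranked.loc["ZZZ", "rank_ascending"] == 3


class TestCombineConditions:
    def test_single_condition_identity(self):
        scores = pd.DataFrame(
            {"z": [1.0, -2.0]}, index=pd.Index(["A", "B"], name="gene_symbol")
        )
        combined = combine_conditions({"cond": scores})
        assert np.allclose(combined["avg_z"].sort_index(), scores["z"].sort_index())

    def test_opposite_conditions_cancel(self):
        a = pd.DataFrame({"z": [2.0]}, index=pd.Index(["A"], name="gene_symbol"))
        b = pd.DataFrame({"z": [-2.0]}, index=pd.Index(["A"], name="gene_symbol"))
        combined = combine_conditions({"c1": a, "c2": b})
        assert combined.loc["A", "avg_z"] == 0.0

    def test_missing_genes_excluded_not_imputed(self):
        a = pd.DataFrame({"z": [2.0, 1.0]}, index=pd.Index(["A", "B"], name="gene_symbol"))
        b = pd.DataFrame({"z": [4.0]}, index=pd.Index(["A"], name="gene_symbol"))
        combined = combine_conditions({"c1": a, "c2": b})
        assert combined.loc["A", "avg_z"] == 3.0
        assert combined.loc["B", "avg_z"] == 1.0
        assert combined.loc["B", "n_conditions"] == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            combine_conditions({})

    def test_averaging_shrinks_null_variance(self):
        """Averaging across three simulated anchor conditions shrinks the
        null-gene z variance toward one third of a single condition's."""
        zs = {}
        for cond_seed in (11, 12, 13):
            counts, truth = simulate_screen(
                SimulationConfig(n_genes=300, interaction_fraction=0.0, seed=cond_seed)
            )
            lfc = lfc_pipeline(counts, "pDNA", grouping=replicate_grouping(counts))
            zs[f"c{cond_seed}"] = score_condition(lfc, "control", "anchor", truth.guide_map)
        combined = combine_conditions(zs)
        single_var = np.var(zs["c11"]["z"])
        combined_var = np.var(combined["avg_z"])
        assert combined_var < 0.6 * single_var  # ~1/3 expected


def test_planted_shift_recovered_in_residuals(small_screen):
    """Synthetic-lethal genes planted at delta=-1 show guide mean residuals near -1."""
    config, counts, truth = small_screen
    lfc = lfc_pipeline(counts, "pDNA", grouping=replicate_grouping(counts))
    scores = score_condition(lfc, "control", "anchor", truth.guide_map)
    sl = truth.genes_with_label("synthetic_lethal")
    assert sl, "fixture should plant synthetic-lethal genes"
    mean_sl = scores.loc[sl, "mean_residual"].mean()
    # efficacy-weighted attenuation: expected shift is delta * mean efficacy
    expected = -config.interaction_magnitude * truth.guides["efficacy"].mean()
    assert mean_sl == pytest.approx(expected, abs=0.35)
    assert (scores.loc[sl, "z"] < 0).all()
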