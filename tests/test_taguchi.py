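"""S/N ratios, response tables, main-effects model/ANOVA, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pullulanopt import taguchi
from pullulanopt.design import PULLULAN_FACTORS, build_l27
from pullulanopt.taguchi import (
    best_levels,
    fit_main_effects,
    main_effects_anova,
    predict_at,
    residual_diagnostics,
    response_table,
    sn_ratio,
)

TABLE4_COMBINATION = {
    "sucrose": 60,
    "K2HPO4": 4,
    "NaCl": 1.5,
    "MgSO4": 0.3,
    "yeast_extract": 1,
    "pH": 5.5,
    "incubation_time": 48,
}

# Published response analysis: per-factor level means of the S/N ratio and
# of the mean yield, with delta and rank.
PRINTED_RESPONSE = {
    "S/N": {
        "sucrose": ((13.23, 14.49, 14.92), 1.69, 3),
        "K2HPO4": ((13.35, 14.35, 14.94), 1.59, 4),
        "NaCl": ((13.09, 14.42, 15.13), 2.04, 2),
        "MgSO4": ((12.56, 14.42, 15.66), 3.11, 1),
        "yeast_extract": ((14.27, 14.24, 14.13), 0.14, 7),
        "pH": ((14.76, 14.29, 13.59), 1.17, 6),
        "incubation_time": ((14.83, 14.26, 13.55), 1.29, 5),
    },
    "mean": {
        "sucrose": ((4.854, 5.324, 5.589), 0.736, 4),
        "K2HPO4": ((4.883, 5.249, 5.634), 0.750, 3),
        "NaCl": ((4.720, 5.289, 5.757), 1.037, 2),
        "MgSO4": ((4.391, 5.282, 6.093), 1.702, 1),
        "yeast_extract": ((5.243, 5.245, 5.278), 0.035, 7),
        "pH": ((5.543, 5.292, 4.931), 0.612, 6),
        "incubation_time": ((5.597, 5.263, 4.906), 0.691, 5),
    },
}

# Published ANOVA of the 27 run means (df=2 per factor; residual df=12).
PRINTED_ANOVA_SS = {
    "sucrose": 2.50,
    "K2HPO4": 2.53,
    "NaCl": 4.86,
    "MgSO4": 13.04,
    "yeast_extract": 0.01,
    "pH": 1.70,
    "incubation_time": 2.15,
}
PRINTED_ANOVA_F = {
    "sucrose": 87.62,
    "K2HPO4": 88.94,
    "NaCl": 170.44,
    "MgSO4": 457.60,
    "pH": 59.83,
    "incubation_time": 75.47,
}


class TestSNRatio:
    def test_larger_is_better_on_reconstructed_runs(self, report):
        assert sn_ratio((7.33, 7.17, 7.19)) == pytest.approx(17.18, abs=0.02)
        assert sn_ratio((3.99, 3.90, 3.55)) == pytest.approx(11.59, abs=0.02)
        assert report.sn["L7"] == pytest.approx(17.18, abs=0.02)
        assert report.sn.idxmax() == "L7"

    def test_closed_forms(self):
        assert sn_ratio((10, 10, 10), "larger") == pytest.approx(20.0)
        assert sn_ratio((1,), "larger") == pytest.approx(0.0)
        assert sn_ratio((10, 10, 10), "smaller") == pytest.approx(-20.0)
        # nominal-is-best: 10 log10(mean^2 / sample variance)
        y = np.array([9.0, 10.0, 11.0])
        assert sn_ratio(y, "nominal") == pytest.approx(10 * np.log10(100.0 / 1.0))

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="positive"):
            sn_ratio((1.0, -2.0), "larger")
        with pytest.raises(ValueError, match="variance"):
            sn_ratio((5.0, 5.0), "nominal")
        with pytest.raises(ValueError, match="empty"):
            sn_ratio((), "larger")
        with pytest.raises(ValueError, match="criterion"):
            sn_ratio((1.0,), "sideways")


class TestResponseTable:
    @pytest.mark.parametrize("metric", ["S/N", "mean"])
    def test_reproduces_published_level_means_delta_rank(self, report, metric):
        table = report.sn_table if metric == "S/N" else report.mean_table
        for factor, (levels, delta, rank) in PRINTED_RESPONSE[metric].items():
            got = table.level_means[factor].to_numpy()
            assert got == pytest.approx(levels, abs=0.01), factor
            assert table.delta[factor] == pytest.approx(delta, abs=0.01), factor
            assert table.rank[factor] == rank, factor

    def test_constant_metric_all_deltas_zero(self):
        design = build_l27(PULLULAN_FACTORS)
        table = response_table(design, np.full(27, 4.2))
        assert (table.delta == 0).all()
        # delta ties break by design column order
        assert table.rank.tolist() == list(range(1, 8))

    def test_shape_error(self):
        design = build_l27(PULLULAN_FACTORS)
        with pytest.raises(ValueError, match="per run"):
            response_table(design, np.ones(26))


class TestMainEffects:
    def test_fitted_values_match_published(self, report):
        assert report.mean_model.fitted["L1"] == pytest.approx(3.70, abs=0.01)
        assert report.mean_model.fitted["L7"] == pytest.approx(7.19, abs=0.01)

    def test_effects_sum_to_zero_and_constant_response(self):
        design = build_l27(PULLULAN_FACTORS)
        model = fit_main_effects(design, np.full(27, 3.3))
        assert np.allclose(model.effects.sum(), 0, atol=1e-9)
        assert np.allclose(model.fitted, 3.3)
        assert np.allclose(model.residuals, 0)

    def test_refuses_unbalanced_design(self):
        from pullulanopt.design import DesignMatrix, L27_ARRAY

        levels = L27_ARRAY.copy()
        levels[0, 0] = 2
        design = DesignMatrix(PULLULAN_FACTORS, levels)
        with pytest.raises(ValueError, match="balanced"):
            fit_main_effects(design, np.arange(27.0))

    def test_fitted_equals_predict_at_own_combination(self, report):
        # additive-model identity: fitting and pointwise prediction agree
        decoded = report.fixture.design.decoded()
        for run in decoded.index:
            combo = decoded.loc[run].to_dict()
            assert predict_at(report.mean_model, combo) == pytest.approx(
                report.mean_model.fitted[run], abs=1e-9
            )

    def test_predictions_at_published_combination(self, report):
        assert predict_at(report.mean_model, TABLE4_COMBINATION) == pytest.approx(7.17, abs=0.02)
        assert predict_at(report.sn_model, TABLE4_COMBINATION) == pytest.approx(17.64, abs=0.03)

    def test_predict_at_errors(self, report):
        with pytest.raises(KeyError, match="missing factor"):
            predict_at(report.mean_model, {"sucrose": 60})
        bad = dict(TABLE4_COMBINATION, sucrose=55)
        with pytest.raises(KeyError, match="not one of its levels"):
            predict_at(report.mean_model, bad)

    def test_zero_effect_model_predicts_grand_mean(self):
        design = build_l27(PULLULAN_FACTORS)
        model = fit_main_effects(design, np.full(27, 5.0))
        assert predict_at(model, TABLE4_COMBINATION) == pytest.approx(5.0)


class TestBestLevels:
    def test_sn_optimum_matches_published_assignment(self, report):
        assert report.optimum_sn_levels == {
            "sucrose": 60,
            "K2HPO4": 6,
            "NaCl": 1.5,
            "MgSO4": 0.3,
            "yeast_extract": 1,
            "pH": 5.5,
            "incubation_time": 48,
        }

    def test_tie_breaks_to_lower_level(self):
        design = build_l27(PULLULAN_FACTORS)
        table = response_table(design, np.full(27, 1.0))
        combo = best_levels(table, design)
        assert all(combo[f.name] == f.levels[0] for f in design.factors)

    def test_single_factor_argmax(self):
        design = build_l27(PULLULAN_FACTORS)
        values = design.column("NaCl").astype(float)  # metric increases with NaCl level
        table = response_table(design, values)
        assert best_levels(table, design)["NaCl"] == 1.5


class TestAnova:
    def test_reproduces_published_table(self, report):
        t = report.anova.table
        for factor, ss in PRINTED_ANOVA_SS.items():
            assert t.loc[factor, "SS"] == pytest.approx(ss, abs=0.03), factor
            assert t.loc[factor, "df"] == 2
        assert t.loc["Residual Error", "df"] == 12
        assert t.loc["Total", "df"] == 26
        assert t.loc["Total", "SS"] == pytest.approx(26.96, abs=0.03)
        for factor, f in PRINTED_ANOVA_F.items():
            assert t.loc[factor, "F"] == pytest.approx(f, rel=0.02), factor
        # yeast extract is the sole non-significant factor; its tiny printed
        # F (0.24) is dominated by 2-dp rounding, so check its p instead
        assert t.loc["yeast_extract", "p"] == pytest.approx(0.793, abs=0.01)
        assert (t.loc[list(PRINTED_ANOVA_F), "p"] < 0.001).all()
        assert report.anova.r_squared == pytest.approx(0.9937, abs=0.0005)
        assert report.anova.adj_r_squared == pytest.approx(0.9863, abs=0.001)

    def test_single_active_factor_closed_form(self):
        # effects (-d, 0, +d) on one factor, no noise: SS = 9 * 2d^2
        design = build_l27(PULLULAN_FACTORS)
        d = 0.7
        values = np.array([(-d, 0.0, d)[lv - 1] for lv in design.column("MgSO4")]) + 5.0
        t = main_effects_anova(design, values).table
        assert t.loc["MgSO4", "SS"] == pytest.approx(18 * d**2)
        others = [n for n in design.names if n != "MgSO4"]
        assert t.loc[others, "SS"].abs().max() < 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_decomposition_identity_random_response(self, seed):
        design = build_l27(PULLULAN_FACTORS)
        values = np.random.default_rng(seed).normal(5, 1, 27)
        result = main_effects_anova(design, values)
        t = result.table
        ss_sum = t.loc[design.names, "SS"].sum() + t.loc["Residual Error", "SS"]
        assert ss_sum == pytest.approx(t.loc["Total", "SS"], abs=1e-8)

    def test_agrees_with_statsmodels_oracle(self, report):
        # independent route: OLS with categorical factors
        smf = pytest.importorskip("statsmodels.formula.api")
        import statsmodels.api as sm

        design = report.fixture.design
        df = design.decoded().copy()
        df["y"] = report.run_means.to_numpy()
        formula = "y ~ " + " + ".join(f"C({n})" for n in design.names)
        fit = smf.ols(formula, data=df).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        for name in design.names:
            assert report.anova.table.loc[name, "SS"] == pytest.approx(
                anova.loc[f"C({name})", "sum_sq"], abs=1e-8
            )
        assert report.anova.r_squared == pytest.approx(fit.rsquared, abs=1e-9)

    def test_constant_response_is_error(self):
        design = build_l27(PULLULAN_FACTORS)
        with pytest.raises(ValueError, match="zero total variation"):
            main_effects_anova(design, np.full(27, 2.0))


class TestResidualDiagnostics:
    def test_mean_zero_on_fixture(self, report):
        assert report.diagnostics["mean"] == pytest.approx(0.0, abs=1e-9)
        counts = report.diagnostics["histogram"]["counts"]
        assert counts.sum() == 27

    def test_symmetric_residuals(self):
        diag = residual_diagnostics([-0.5, 0.0, 0.5], bins=3)
        counts = diag["histogram"]["counts"]
        assert counts.tolist() == counts[::-1].tolist()
        qq = diag["qq"]
        assert np.all(np.diff(qq["ordered_residuals"]) >= 0)

    def test_gaussian_residuals_straight_qq(self):
        resid = np.random.default_rng(7).normal(0, 0.1, 100)
        diag = residual_diagnostics(resid - resid.mean())
        assert diag["qq_correlation"] > 0.95
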