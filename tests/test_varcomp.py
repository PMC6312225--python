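import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carlit.synthetic import PanelScenario, simulate_eqr_panel
from carlit.varcomp import (
    ModelStructure,
    VarianceComponents,
    ZeroTotalVarianceError,
    compare_models,
    fit_reml,
    residuals_vs_fitted,
    round_half_away,
    validate_panel,
    variance_fractions,
)

WB_ONLY = ModelStructure(wb=True, year=False, surveyor=False, wb_slopes_in_year=False)


def one_way_panel(n_groups=7, n_reps=4, tau2=0.03, sigma2=0.005, seed=42):
    """Balanced one-way layout: groups as WB, replicate index as Year."""
    rng = np.random.default_rng(seed)
    effects = rng.normal(0.0, math.sqrt(tau2), n_groups)
    rows = []
    for g in range(n_groups):
        for r in range(n_reps):
            rows.append(
                (f"G{g}", str(r), "S1", 0.7 + effects[g] + rng.normal(0, math.sqrt(sigma2)))
            )
    return pd.DataFrame(rows, columns=["WB", "Year", "Surveyor", "EQR"])


def anova_moment_estimates(panel, n_reps):
    """Independent oracle: balanced one-way ANOVA moment estimators."""
    y = panel["EQR"].to_numpy()
    groups = panel["WB"].to_numpy()
    labels = sorted(set(groups))
    k = len(labels)
    n = y.size
    means = np.array([y[groups == g].mean() for g in labels])
    msb = n_reps * ((means - y.mean()) ** 2).sum() / (k - 1)
    msw = sum(((y[groups == g] - m) ** 2).sum() for g, m in zip(labels, means)) / (n - k)
    return (msb - msw) / n_reps, msw


def table3_components():
    return VarianceComponents(
        grand_mean=0.7,
        var_wb=0.031683,
        var_year=0.0,
        var_surveyor=0.0,
        var_wb_in_year={
            "Capo Mortola": 0.001691,
            "Laigueglia-Albenga": 0.003284,
            "Genova-Camogli": 0.013276,
            "Portofino": 0.001302,
            "Punta Mesco": 0.003444,
            "Cinque Terre": 0.004810,
            "Portovenere": 0.003429,
        },
        var_residual=0.004404,
    )


class TestVarianceFractions:
    def test_published_partition(self):
        fr = variance_fractions(table3_components(), rounded=True)
        assert fr["WB"] == 47
        assert fr["Year:Genova-Camogli"] == 20
        assert fr["Residual"] == 7
        assert fr["Year"] == 0
        assert fr["Surveyor"] == 0

    def test_exact_fractions_sum_to_100(self):
        fr = variance_fractions(table3_components())
        assert sum(fr.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_nonzero_component(self):
        vc = VarianceComponents(grand_mean=0.5, var_wb=0.02)
        assert variance_fractions(vc)["WB"] == pytest.approx(100.0)

    def test_zero_total_raises(self):
        with pytest.raises(ZeroTotalVarianceError):
            variance_fractions(VarianceComponents(grand_mean=0.5))

    def test_round_half_away(self):
        assert round_half_away(2.5) == 3
        assert round_half_away(19.72) == 20
        assert round_half_away(47.06) == 47
        assert round_half_away(-2.5) == -3

    @given(
        vs=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6).filter(
            lambda v: sum(v) > 1e-6
        )
    )
    @settings(max_examples=100)
    def test_fractions_sum_property(self, vs):
        vc = VarianceComponents(
            grand_mean=0.0,
            var_wb=vs[0],
            var_year=vs[1],
            var_wb_in_year={f"w{i}": v for i, v in enumerate(vs[2:])},
        )
        assert sum(variance_fractions(vc).values()) == pytest.approx(100.0, abs=1e-9)


class TestValidatePanel:
    def test_missing_column(self):
        with pytest.raises(ValueError, match="missing"):
            validate_panel(pd.DataFrame({"WB": ["a"], "EQR": [0.5]}))

    def test_duplicate_cells_rejected(self):
        df = pd.DataFrame(
            {"WB": ["a", "a"], "Year": ["1", "1"], "Surveyor": ["s", "s"], "EQR": [0.5, 0.6]}
        )
        with pytest.raises(ValueError, match="duplicated"):
            validate_panel(df)
        assert len(validate_panel(df, allow_replicates=True)) == 2

    def test_nonfinite_rejected(self):
        df = pd.DataFrame(
            {"WB": ["a", "b"], "Year": ["1", "1"], "Surveyor": ["s", "s"], "EQR": [0.5, np.nan]}
        )
        with pytest.raises(ValueError, match="non-finite"):
            validate_panel(df)


class TestFitReml:
    def test_constant_response(self):
        panel = one_way_panel()
        panel["EQR"] = 0.7
        fit = fit_reml(panel, WB_ONLY)
        assert fit.total == 0.0
        assert fit.var_residual == 0.0
        assert fit.grand_mean == pytest.approx(0.7)

    def test_matches_anova_oracle_on_balanced_one_way(self):
        panel = one_way_panel(n_groups=7, n_reps=4, seed=42)
        tau2_hat, sigma2_hat = anova_moment_estimates(panel, n_reps=4)
        assert tau2_hat > 0  # oracle applies only when non-negative
        fit = fit_reml(panel, WB_ONLY)
        assert fit.var_wb == pytest.approx(tau2_hat, rel=1e-6)
        assert fit.var_residual == pytest.approx(sigma2_hat, rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_oracle_equivalence_other_seeds(self, seed):
        panel = one_way_panel(n_groups=5, n_reps=6, tau2=0.02, sigma2=0.01, seed=seed)
        tau2_hat, sigma2_hat = anova_moment_estimates(panel, n_reps=6)
        if tau2_hat <= 0:
            pytest.skip("moment estimator negative; equivalence not defined")
        fit = fit_reml(panel, WB_ONLY)
        assert fit.var_wb == pytest.approx(tau2_hat, rel=1e-6)

    def test_boundary_zero_when_no_group_effect(self):
        panel = one_way_panel(n_groups=6, n_reps=8, tau2=0.0, sigma2=0.01, seed=3)
        tau2_hat, _ = anova_moment_estimates(panel, n_reps=8)
        fit = fit_reml(panel, WB_ONLY)
        if tau2_hat <= 0:
            assert fit.var_wb == 0.0
        else:
            assert fit.var_wb == pytest.approx(tau2_hat, rel=1e-5)

    def test_recovery_mean_close_to_truth(self):
        # small Monte-Carlo twin of the acceptance experiment
        ests = []
        for rep in range(20):
            panel = simulate_eqr_panel(
                PanelScenario(n_wb=30, n_year=8, n_surveyor=2,
                              var_wb=0.03, var_residual=0.004, seed=500 + rep)
            )
            fit = fit_reml(panel, WB_ONLY)
            ests.append((fit.var_wb, fit.var_residual))
        mean_wb, mean_res = np.mean(ests, axis=0)
        assert mean_wb == pytest.approx(0.03, rel=0.25)
        assert mean_res == pytest.approx(0.004, rel=0.25)

    def test_scaling_response_scales_variances(self):
        panel = one_way_panel(seed=11)
        f1 = fit_reml(panel, WB_ONLY)
        panel2 = panel.copy()
        panel2["EQR"] = panel2["EQR"] * 3.0
        f2 = fit_reml(panel2, WB_ONLY)
        assert f2.var_wb == pytest.approx(9 * f1.var_wb, rel=1e-5)
        assert f2.var_residual == pytest.approx(9 * f1.var_residual, rel=1e-5)
        fr1 = variance_fractions(f1)
        fr2 = variance_fractions(f2)
        for k in fr1:
            assert fr2[k] == pytest.approx(fr1[k], abs=1e-3)

    def test_identifiability_warning_at_small_size(self):
        panel = simulate_eqr_panel(
            PanelScenario(n_wb=7, n_year=4, n_surveyor=2, var_wb=0.03,
                          var_wb_in_year=0.004, var_residual=0.004, seed=1)
        )
        with pytest.warns(UserWarning, match="identifiability"):
            fit = fit_reml(panel)  # full structure: 11 variance parameters, 28 rows
        assert fit.total > 0
        assert set(fit.var_wb_in_year) == {f"WB{i + 1:02d}" for i in range(7)}

    def test_single_level_factor_rejected(self):
        panel = one_way_panel()
        with pytest.raises(ValueError, match="Surveyor"):
            fit_reml(panel, ModelStructure(wb=True, year=False, surveyor=True,
                                           wb_slopes_in_year=False))

    def test_confounded_factors_flagged(self):
        panel = one_way_panel(n_groups=4, n_reps=3)
        panel["Surveyor"] = "S" + panel["WB"].str[1:]  # surveyor == group
        with pytest.warns(UserWarning, match="confounded"):
            fit = fit_reml(
                panel,
                ModelStructure(wb=True, year=False, surveyor=True, wb_slopes_in_year=False),
            )
        assert any("confounded" in m for m in fit.messages)


class TestResiduals:
    def test_constant_panel_zero_residuals(self):
        panel = one_way_panel()
        panel["EQR"] = 0.7
        fit = fit_reml(panel, WB_ONLY)
        pairs = residuals_vs_fitted(panel, fit)
        assert all(r == 0.0 for _, r in pairs)

    def test_blup_shrinkage_oracle(self):
        # hand-computed: fitted group value = mu + shrink * (group mean - mu),
        # shrink = n tau2 / (n tau2 + sigma2) on a balanced one-way design
        panel = one_way_panel(n_groups=7, n_reps=4, seed=42)
        fit = fit_reml(panel, WB_ONLY)
        pairs = residuals_vs_fitted(panel, fit)
        y = panel["EQR"].to_numpy()
        tau2, sigma2 = fit.var_wb, fit.var_residual
        shrink = 4 * tau2 / (4 * tau2 + sigma2)
        mu = fit.grand_mean
        for g in sorted(set(panel["WB"])):
            mask = (panel["WB"] == g).to_numpy()
            expected_fit = mu + shrink * (y[mask].mean() - mu)
            for (f, r), obs in zip(
                [p for p, m in zip(pairs, mask) if m], y[mask]
            ):
                assert f == pytest.approx(expected_fit, abs=1e-8)
                assert r == pytest.approx(obs - expected_fit, abs=1e-8)

    def test_residuals_sum_to_zero(self):
        panel = simulate_eqr_panel(
            PanelScenario(n_wb=10, n_year=5, n_surveyor=2, var_wb=0.02,
                          var_year=0.001, var_residual=0.005, seed=9)
        )
        fit = fit_reml(
            panel, ModelStructure(wb=True, year=True, surveyor=False, wb_slopes_in_year=False)
        )
        pairs = residuals_vs_fitted(panel, fit)
        assert abs(sum(r for _, r in pairs)) < 1e-8


class TestCompareModels:
    def test_identical_structures_tie(self):
        panel = one_way_panel(seed=5)
        ranked = compare_models(panel, [WB_ONLY, WB_ONLY])
        assert ranked[0].aic == pytest.approx(ranked[1].aic)
        assert all(m.tied for m in ranked)

    def test_simpler_wins_on_constant_data(self):
        panel = one_way_panel()
        panel["EQR"] = 0.5
        panel["Surveyor"] = np.where(panel["Year"].astype(int) < 2, "S1", "S2")
        richer = ModelStructure(wb=True, year=False, surveyor=True, wb_slopes_in_year=False)
        ranked = compare_models(panel, [richer, WB_ONLY])
        assert ranked[0].structure == WB_ONLY

    def test_superfluous_term_usually_penalized(self):
        # truth has no surveyor variance; the leaner model should win most seeds
        wins = 0
        n_trials = 40
        richer = ModelStructure(wb=True, year=False, surveyor=True, wb_slopes_in_year=False)
        for rep in range(n_trials):
            panel = simulate_eqr_panel(
                PanelScenario(n_wb=10, n_year=4, n_surveyor=2, var_wb=0.02,
                              var_surveyor=0.0, var_residual=0.005, seed=2000 + rep)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ranked = compare_models(panel, [WB_ONLY, richer])
            if ranked[0].structure == WB_ONLY:
                wins += 1
        assert wins >= 0.8 * n_trials

    def test_needs_two_candidates(self):
        with pytest.raises(ValueError):
            compare_models(one_way_panel(), [WB_ONLY])


class TestModelStructure:
    def test_from_spec(self):
        s = ModelStructure.from_spec("wb,year")
        assert s.wb and s.year and not s.surveyor and not s.wb_slopes_in_year

    def test_from_spec_slopes_alias(self):
        assert ModelStructure.from_spec("wb_slopes").wb_slopes_in_year
        assert ModelStructure.from_spec("wb|year").wb_slopes_in_year

    def test_unknown_term(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelStructure.from_spec("wb,bogus")

    def test_name(self):
        assert ModelStructure().name == "WB+Year+Surveyor+WB|Year"
        assert WB_ONLY.name == "WB"
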