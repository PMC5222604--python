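import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clrnorm.detection import (
    bonferroni_threshold,
    detect_age_effects,
    fold_change_estimate,
    repeated_measures_anova,
    two_way_anova,
)
from clrnorm.normalisation import apply_normalisation, marker_normalisation_factors
from clrnorm.simulate import (
    DEFAULT_CANDIDATES,
    EXTENDED_SET,
    make_panel_design,
    reference_panel_params,
    simulate_panel,
)

ZT_GRID = np.arange(0, 24, 2, dtype=float)


def series_on_grid(values, replicates=2):
    index = np.repeat(ZT_GRID, replicates)
    return pd.Series(np.asarray(values, dtype=float), index=index)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, expected",
        [(0.05, 36, 0.05 / 36), (0.05, 1, 0.05), (0.01, 10, 0.001)],
    )
    def test_threshold_values(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=1e-12)

    def test_panel_family_threshold_matches_printed_value(self):
        assert bonferroni_threshold(0.05, 36) == pytest.approx(0.0013888, abs=1e-7)

    @pytest.mark.parametrize("alpha, m", [(0.05, 0), (0.0, 5), (1.5, 5)])
    def test_invalid_inputs_rejected(self, alpha, m):
        with pytest.raises(ValueError):
            bonferroni_threshold(alpha, m)


class TestRepeatedMeasuresAnova:
    def test_identical_groups_give_p_one(self, rng):
        y = series_on_grid(rng.lognormal(3, 0.3, size=24))
        assert repeated_measures_anova(y, y.copy()) == pytest.approx(1.0)

    def test_doubling_with_negligible_noise_is_overwhelming(self, rng):
        base = 100 + 10 * np.cos(2 * np.pi * np.repeat(ZT_GRID, 2) / 24)
        young = series_on_grid(base + rng.normal(0, 1e-3, 24))
        old = series_on_grid(2 * base + rng.normal(0, 1e-3, 24))
        assert repeated_measures_anova(np.log(young), np.log(old)) < 1e-30

    def test_matches_statsmodels_blocked_ols(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        young = series_on_grid(rng.lognormal(3, 0.3, size=24))
        old = series_on_grid(rng.lognormal(3.1, 0.3, size=24))
        ours = repeated_measures_anova(young, old)
        df = pd.DataFrame(
            {
                "y": np.concatenate([young.values, old.values]),
                "age": np.repeat([0, 1], 24),
                "zt": np.concatenate([young.index, old.index]),
            }
        )
        fit = smf.ols("y ~ C(age) + C(zt)", data=df).fit()
        theirs = sm.stats.anova_lm(fit, typ=2).loc["C(age)", "PR(>F)"]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_reduces_to_paired_t_test_with_single_replicate(self, rng):
        for _ in range(5):
            young = pd.Series(rng.normal(10, 1, size=12), index=ZT_GRID)
            old = pd.Series(rng.normal(10.5, 1, size=12), index=ZT_GRID)
            ours = repeated_measures_anova(young, old)
            paired = sps.ttest_rel(young.values, old.values).pvalue
            assert ours == pytest.approx(paired, abs=1e-6)

    def test_mismatched_grids_rejected(self, rng):
        young = pd.Series(rng.normal(size=12), index=ZT_GRID)
        old = pd.Series(rng.normal(size=12), index=ZT_GRID + 1)
        with pytest.raises(ValueError, match="grid"):
            repeated_measures_anova(young, old)

    def test_single_time_point_rejected(self, rng):
        young = pd.Series(rng.normal(size=4), index=[0.0] * 4)
        old = pd.Series(rng.normal(size=4), index=[0.0] * 4)
        with pytest.raises(ValueError):
            repeated_measures_anova(young, old)


class TestTwoWayAnova:
    @staticmethod
    def toy(rng, interaction=0.0, age_effect=0.0, time_effect=0.0, noise=1.0):
        ages = np.repeat([0, 1], 6)
        times = np.tile(np.repeat([0, 8, 16], 2), 2)
        y = (
            age_effect * ages
            + time_effect * np.sin(2 * np.pi * times / 24)
            + interaction * ages * (times == 16)
            + rng.normal(0, noise, size=12)
        )
        return y, ages, times

    def test_all_constant_data_non_significant(self):
        y = np.ones(12)
        ages = np.repeat([0, 1], 6)
        times = np.tile(np.repeat([0, 8, 16], 2), 2)
        res = two_way_anova(y, ages, times)
        assert res.p_interaction == 1.0 and res.p_age == 1.0 and res.p_time == 1.0
        assert not res.posthoc[["sig_05", "sig_01", "sig_001"]].any().any()

    def test_interaction_detected_and_matches_permutation_oracle(self, rng):
        y, ages, times = self.toy(rng, interaction=6.0, noise=1.0)
        res = two_way_anova(y, ages, times)
        assert res.p_interaction < 0.05

        # Freedman-Lane style oracle: permute residuals of the additive model
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = pd.DataFrame({"y": y, "age": ages, "time": times})
        additive = smf.ols("y ~ C(age) + C(time)", data=df).fit()
        fitted, resid = additive.fittedvalues.values, additive.resid.values

        def inter_f(yy):
            d = df.assign(y=yy)
            f = smf.ols("y ~ C(age) * C(time)", data=d).fit()
            return sm.stats.anova_lm(f, typ=2).loc["C(age):C(time)", "F"]

        observed = inter_f(y)
        perm_rng = np.random.default_rng(0)
        hits = sum(
            inter_f(fitted + perm_rng.permutation(resid)) >= observed for _ in range(400)
        )
        p_perm = (hits + 1) / 401
        assert abs(p_perm - res.p_interaction) < 0.05

    def test_time_effect_without_age_effect(self, rng):
        y, ages, times = self.toy(rng, time_effect=5.0, noise=0.5)
        res = two_way_anova(y, ages, times)
        assert res.p_time < 0.001
        assert res.p_age > 0.05

    def test_unreplicated_cells_rejected(self, rng):
        y = rng.normal(size=6)
        ages = np.repeat([0, 1], 3)
        times = np.tile([0, 8, 16], 2)
        with pytest.raises(ValueError, match="nreplicated"):
            two_way_anova(y, ages, times)


class TestFoldChangeEstimate:
    def test_identity_and_scaling(self, rng):
        y = series_on_grid(rng.lognormal(3, 0.2, 24))
        assert fold_change_estimate(y, y.copy()) == pytest.approx(1.0)
        assert fold_change_estimate(y, 1.5 * y) == pytest.approx(1.5, rel=1e-12)

    def test_exactly_multiplicative(self, rng):
        y = series_on_grid(rng.lognormal(3, 0.2, 24))
        o = series_on_grid(rng.lognormal(3, 0.2, 24))
        fc = fold_change_estimate(y, o)
        assert fold_change_estimate(y, 2.0 * o) == pytest.approx(2 * fc, rel=1e-12)

    def test_recovers_simulated_effect_within_ten_percent(self):
        # 1.52-fold age effect under realistic panel noise, 20 seeds
        from clrnorm.simulate import GeneSimParams

        design = make_panel_design(ages=(3, 24))
        params = {
            "target": GeneSimParams(
                gene_id="target",
                baseline=2000,
                circadian_amplitude=0.2,
                acrophase_h=8.0,
                age_log_fold_change=np.log(1.52),
            )
        }
        zt = design.table["zeitgeber_time_h"].to_numpy(dtype=float)
        young_mask = design.table["age_months"].to_numpy() == 3
        estimates = []
        for seed in range(20):
            matrix, _ = simulate_panel(design, params, seed=seed, tech_sigma=0.0)
            vals = matrix.values[0]
            young = pd.Series(vals[young_mask], index=zt[young_mask])
            old = pd.Series(vals[~young_mask], index=zt[~young_mask])
            estimates.append(fold_change_estimate(young, old))
        assert np.all(np.abs(np.array(estimates) / 1.52 - 1) < 0.10)

    def test_average_mode_flag(self, rng):
        y = series_on_grid(rng.lognormal(3, 0.2, 24))
        o = series_on_grid(rng.lognormal(3.2, 0.2, 24))
        geo = fold_change_estimate(y, o, average="geometric")
        ari = fold_change_estimate(y, o, average="arithmetic")
        assert ari >= geo  # AM-GM
        with pytest.raises(ValueError):
            fold_change_estimate(y, o, average="median")


class TestDetectAgeEffects:
    def test_perturbed_panel_recovery_single_seed(self):
        params, _, perturbed = reference_panel_params(0)
        design = make_panel_design(ages=(3, 24))
        matrix, _ = simulate_panel(design, params, seed=42)
        factors = marker_normalisation_factors(matrix, EXTENDED_SET)
        normalised = apply_normalisation(matrix, factors)
        test_genes = [g for g in matrix.gene_ids if g not in DEFAULT_CANDIDATES]
        table = detect_age_effects(normalised, design, 3, 24, genes=test_genes)
        assert len(table) == 36
        flagged = set(table.loc[table["significant"], "gene_id"])
        assert set(perturbed) <= flagged
        assert len(flagged - set(perturbed)) <= 1

    def test_direction_of_fold_changes(self):
        params, _, _ = reference_panel_params(0)
        design = make_panel_design(ages=(3, 24))
        matrix, _ = simulate_panel(design, params, seed=7)
        factors = marker_normalisation_factors(matrix, EXTENDED_SET)
        table = detect_age_effects(
            apply_normalisation(matrix, factors), design, 3, 24,
            genes=["Csnk1e", "Glut2"], family_size=36,
        )
        fc = table.set_index("gene_id")["fold_change"]
        assert fc["Csnk1e"] > 1.3  # up-regulated in old animals
        assert fc["Glut2"] < 0.9  # down-regulated

    def test_comparing_age_class_with_itself_finds_nothing(self):
        params, _, _ = reference_panel_params(0)
        design = make_panel_design(ages=(3, 24))
        matrix, _ = simulate_panel(design, params, seed=5)
        table = detect_age_effects(matrix, design, 3, 3, family_size=36)
        assert not table["significant"].any()
        assert np.allclose(table["fold_change"], 1.0)

    def test_missing_age_class_rejected(self):
        params, _, _ = reference_panel_params(0)
        design = make_panel_design(ages=(3, 24))
        matrix, _ = simulate_panel(design, params, seed=5)
        with pytest.raises(ValueError):
            detect_age_effects(matrix, design, 3, 12)
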