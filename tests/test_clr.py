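import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clrnorm.clr import (
    clr_gene_stats,
    clr_transform,
    geometric_mean,
    pairwise_correlations,
    pairwise_fold_changes,
)
from clrnorm.io import ExpressionMatrix

from .conftest import random_positive_matrix


class TestGeometricMean:
    @pytest.mark.parametrize(
        "values, expected",
        [([4, 4, 4], 4.0), ([2, 8], 4.0), ([1, 10, 100], 10.0)],
    )
    def test_known_values(self, values, expected):
        assert geometric_mean(values) == pytest.approx(expected)

    @pytest.mark.parametrize("values", [[0, 1], [-1, 2], []])
    def test_rejects_non_positive_or_empty(self, values):
        with pytest.raises(ValueError):
            geometric_mean(values)

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=1, max_size=20),
        st.floats(min_value=0.01, max_value=100),
    )
    @settings(deadline=None)
    def test_scale_equivariance(self, values, k):
        assert geometric_mean([k * v for v in values]) == pytest.approx(
            k * geometric_mean(values), rel=1e-9
        )


class TestClrTransform:
    def test_uniform_composition_maps_to_zero(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [1.0, 1.0, 1.0]}, index=list("abc")))
        assert np.allclose(clr_transform(m).data["s"], 0.0)

    def test_log_ratio_values(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [1.0, 10.0, 100.0]}, index=list("abc")))
        expected = [-2.302585, 0.0, 2.302585]
        assert np.allclose(clr_transform(m).data["s"], expected, atol=1e-6)

    def test_invariant_to_global_rescaling(self, rng):
        m = random_positive_matrix(rng, 15, 6)
        scaled = ExpressionMatrix(m.data * 5.0)
        assert np.allclose(
            clr_transform(m).data.values, clr_transform(scaled).data.values
        )

    def test_invariant_to_per_sample_library_size(self, rng):
        m = random_positive_matrix(rng, 25, 8)
        factors = rng.lognormal(0, 0.5, size=8)
        scaled = ExpressionMatrix(m.data * factors[None, :])
        diff = clr_transform(m).data.values - clr_transform(scaled).data.values
        assert np.abs(diff).max() < 1e-9

    def test_columns_sum_to_zero(self, rng):
        m = random_positive_matrix(rng, 40, 10)
        sums = clr_transform(m).data.sum(axis=0)
        assert np.abs(sums.to_numpy()).max() < 1e-9 * 40

    def test_zero_without_pseudocount_rejected(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [0.0, 1.0]}, index=["a", "b"]))
        with pytest.raises(ValueError):
            clr_transform(m, pseudocount=0.0)
        clr_transform(m, pseudocount=0.5)  # fine with a pseudocount

    def test_agrees_with_scikit_bio(self, rng):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        m = random_positive_matrix(rng, 12, 5)
        ours = clr_transform(m).data.values
        theirs = np.column_stack(
            [skbio_comp.clr(m.values[:, j]) for j in range(5)]
        )
        assert np.allclose(ours, theirs, atol=1e-10)


def brute_force_clr_stats(matrix: ExpressionMatrix, grouping=None):
    """Two-pass loop oracle: explicit clr, per-condition means, then stats."""
    genes = matrix.gene_ids
    samples = matrix.sample_ids
    clr_vals = {}
    for s in samples:
        col = [matrix.data.at[g, s] for g in genes]
        logs = [np.log(v) for v in col]
        mean_log = sum(logs) / len(logs)
        for g, lv in zip(genes, logs):
            clr_vals[(g, s)] = lv - mean_log
    if grouping is None:
        grouping = {s: s for s in samples}
    conditions = sorted(set(grouping[s] for s in samples))
    rows = {}
    for g in genes:
        cond_means = []
        for c in conditions:
            members = [s for s in samples if grouping[s] == c]
            cond_means.append(sum(clr_vals[(g, s)] for s in members) / len(members))
        mean = sum(cond_means) / len(cond_means)
        var = sum((v - mean) ** 2 for v in cond_means) / (len(cond_means) - 1)
        rows[g] = (mean, var)
    return rows


class TestClrGeneStats:
    def test_hand_computed_two_by_two(self):
        m = ExpressionMatrix(
            pd.DataFrame({"c1": [1.0, 3.0], "c2": [3.0, 1.0]}, index=["g1", "g2"])
        )
        stats = clr_gene_stats(clr_transform(m))
        expected_var = 2 * (np.log(np.sqrt(3))) ** 2  # approx 0.6035
        assert stats.at["g1", "var_clr"] == pytest.approx(expected_var, rel=1e-12)
        assert stats.at["g1", "mean_clr"] == pytest.approx(0.0, abs=1e-12)
        assert expected_var == pytest.approx(0.6035, abs=5e-4)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            m = random_positive_matrix(rng, 20, 8)
            grouping = {s: f"c{j % 4}" for j, s in enumerate(m.sample_ids)}
            stats = clr_gene_stats(clr_transform(m), grouping=grouping)
            oracle = brute_force_clr_stats(m, grouping)
            for g in m.gene_ids:
                mean, var = oracle[g]
                assert stats.at[g, "mean_clr"] == pytest.approx(mean, abs=1e-10)
                assert stats.at[g, "var_clr"] == pytest.approx(var, abs=1e-10)
            assert (stats["n_conditions"] == 4).all()

    def test_constant_proportion_gene_has_zero_variance(self, rng):
        base = rng.uniform(1, 100, size=(10, 6))
        base[0, :] = base[1:, :].sum(axis=0) * 0.25  # fixed share of the total
        factors = rng.lognormal(0, 1.0, size=6)
        m = ExpressionMatrix(
            pd.DataFrame(
                base * factors[None, :],
                index=[f"g{i}" for i in range(10)],
                columns=[f"s{j}" for j in range(6)],
            )
        )
        # a constant share means clr differs only through the varying others;
        # make all genes constant shares to pin variance at exactly zero
        shares = rng.uniform(1, 10, size=10)
        m2 = ExpressionMatrix(
            pd.DataFrame(
                shares[:, None] * factors[None, :],
                index=[f"g{i}" for i in range(10)],
                columns=[f"s{j}" for j in range(6)],
            )
        )
        stats = clr_gene_stats(clr_transform(m2))
        assert stats["var_clr"].max() < 1e-18

    def test_single_condition_rejected(self, rng):
        m = random_positive_matrix(rng, 5, 3)
        grouping = {s: "only" for s in m.sample_ids}
        with pytest.raises(ValueError):
            clr_gene_stats(clr_transform(m), grouping=grouping)

    def test_full_panel_has_192_conditions(self):
        from clrnorm.simulate import make_panel_design, reference_panel_params, simulate_panel

        params, _, _ = reference_panel_params(0)
        m, _ = simulate_panel(make_panel_design(), params, seed=3)
        stats = clr_gene_stats(clr_transform(m, pseudocount=0.5))
        assert (stats["n_conditions"] == 192).all()


class TestPairwiseFoldChanges:
    def test_four_conditions_give_six_pairs(self, rng):
        m = random_positive_matrix(rng, 10, 8)
        grouping = {s: f"c{j % 4}" for j, s in enumerate(m.sample_ids)}
        fc = pairwise_fold_changes(m, grouping)
        assert fc.shape == (10, 6)

    def test_identical_conditions_give_unit_fold_changes(self):
        col = [1.0, 5.0, 20.0]
        m = ExpressionMatrix(
            pd.DataFrame({"a": col, "b": col}, index=["g1", "g2", "g3"])
        )
        fc = pairwise_fold_changes(m)
        assert np.allclose(fc.values, 1.0)

    def test_doubled_gene_with_constant_background(self, rng):
        n = 100
        base = rng.uniform(10, 100, size=n)
        doubled = base.copy()
        doubled[0] *= 2
        m = ExpressionMatrix(
            pd.DataFrame(
                {"c1_young": base, "c2_old": doubled},
                index=[f"g{i}" for i in range(n)],
            )
        )
        fc = pairwise_fold_changes(m)  # single pair, oriented c1 -> c2
        # exact compositional value: 2 / 2**(1/n); tends to 2 for large n
        assert fc.iloc[0, 0] == pytest.approx(2 / 2 ** (1 / n), rel=1e-9)
        assert fc.iloc[0, 0] == pytest.approx(2.0, rel=0.02)


class TestPairwiseCorrelations:
    def test_perfect_and_inverse_correlation(self):
        m = ExpressionMatrix(
            pd.DataFrame(
                {"s1": [1, 2, 3], "s2": [2, 4, 2], "s3": [3, 6, 1]},
                index=["up", "double", "down"],
                dtype=float,
            )
        )
        corr = pairwise_correlations(m)
        assert corr.at["up", "up"] == pytest.approx(1.0)
        assert corr.at["up", "double"] == pytest.approx(1.0)
        assert corr.at["up", "down"] == pytest.approx(-1.0)
        assert np.allclose(corr.values, corr.values.T)

    def test_zero_variance_gene_reported_missing(self):
        m = ExpressionMatrix(
            pd.DataFrame(
                {"s1": [1.0, 5.0], "s2": [2.0, 5.0], "s3": [3.0, 5.0]},
                index=["g", "flat"],
            )
        )
        corr = pairwise_correlations(m)
        assert np.isnan(corr.at["g", "flat"])

    def test_too_few_samples_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            pairwise_correlations(small_matrix)
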