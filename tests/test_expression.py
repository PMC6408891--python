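"""Tau tissue-specificity, expression proportions, and rank tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from expanscan.expression import (
    classify_specific,
    compare_groups,
    compute_tau,
    dunn_posthoc,
    expression_proportions,
    holm_adjust,
    kruskal_wallis,
    summarize_by_group,
    tau_table,
)

vectors = st.lists(
    st.floats(min_value=0, max_value=1e4, allow_nan=False), min_size=2, max_size=12
).filter(lambda x: max(x) > 0)


class TestTau:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ((1, 0, 0, 0), 1.0),          # single-tissue expression
            ((5, 5, 5, 5), 0.0),          # perfectly broad
            ((2, 1, 1, 1), 0.5),          # hand evaluation of the index
            ((0, 4), 1.0),
        ],
    )
    def test_reference_values(self, x, expected):
        assert compute_tau(x) == pytest.approx(expected)

    def test_all_zero_is_undefined(self):
        assert np.isnan(compute_tau([0.0, 0.0, 0.0]))

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            compute_tau([1.0, -0.5])

    @given(x=vectors, c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_scale_invariance(self, x, c):
        tau = compute_tau(x)
        assert 0.0 <= tau <= 1.0
        assert compute_tau([c * v for v in x]) == pytest.approx(tau, abs=1e-9)

    @given(x=vectors, seed=st.integers(0, 2**16))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance(self, x, seed):
        perm = np.random.default_rng(seed).permutation(len(x))
        xp = np.asarray(x)[perm]
        assert compute_tau(xp) == pytest.approx(compute_tau(x), abs=1e-9)
        p, pp = expression_proportions(np.asarray(x)), expression_proportions(xp)
        assert np.allclose(pp, p[perm])

    @given(x=vectors)
    @settings(max_examples=100, deadline=None)
    def test_extremes_characterized(self, x):
        x = np.asarray(x)
        if np.count_nonzero(x) == 1:
            assert compute_tau(x) == pytest.approx(1.0)
        if np.all(x == x[0]):
            assert compute_tau(x) == pytest.approx(0.0)


class TestClassification:
    def test_threshold_is_strict(self):
        assert classify_specific(0.81) is True
        assert classify_specific(0.80) is False

    def test_undefined_tau_unclassified(self):
        assert classify_specific(float("nan")) is None


class TestProportions:
    def test_fractions_sum_to_one(self):
        assert expression_proportions([2, 3, 5]) == pytest.approx([0.2, 0.3, 0.5])

    def test_single_tissue_rejected(self):
        with pytest.raises(ValueError):
            expression_proportions([7])

    def test_zero_tissue_allowed(self):
        assert expression_proportions([0, 4]) == pytest.approx([0.0, 1.0])

    def test_all_zero_gives_nan_row(self):
        assert np.all(np.isnan(expression_proportions([0.0, 0.0])))


class TestKruskalWallis:
    def test_hand_derived_statistic(self):
        # ranks 1..6, R1=6, R2=15: H = 12/(6*7) * (36/3 + 225/3) - 3*7
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.H == pytest.approx(3.857142857, abs=1e-6)
        assert res.df == 1

    def test_identical_groups_give_zero(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.H == 0.0
        assert res.p_value == 1.0

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=8).tolist() for _ in range(3)]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([[np.exp(v) for v in g] for g in groups])
        assert a.H == pytest.approx(b.H, abs=1e-9)

    def test_null_calibration(self, rng):
        # size-alpha behaviour of the chi-squared approximation
        hits = 0
        n_reps = 400
        for _ in range(n_reps):
            groups = [rng.normal(size=25) for _ in range(3)]
            if kruskal_wallis(groups).p_value < 0.05:
                hits += 1
        assert 0.02 <= hits / n_reps <= 0.08


class TestDunnHolm:
    def test_holm_stepdown_example(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_pair_unchanged(self):
        table = dunn_posthoc([[1, 2, 3], [7, 8, 9]])
        assert table["adjusted_p"].iloc[0] == pytest.approx(table["raw_p"].iloc[0])

    def test_identical_groups_z_zero(self):
        table = dunn_posthoc([[3.0, 3.0, 3.0], [3.0, 3.0, 3.0]])
        assert table["z"].iloc[0] == 0.0
        assert table["raw_p"].iloc[0] == 1.0

    def test_adjustment_monotone_and_bounded(self, rng):
        groups = [rng.normal(loc=m, size=10) for m in (0, 0.5, 2.0, 3.0)]
        table = dunn_posthoc(groups).sort_values("raw_p")
        assert (table["adjusted_p"] >= table["raw_p"] - 1e-12).all()
        assert (table["adjusted_p"].diff().dropna() >= -1e-12).all()
        assert (table["adjusted_p"] <= 1.0).all()

    def test_tiny_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="size < 2"):
            table = dunn_posthoc([[1.0], [2, 3, 4], [5, 6, 7]])
        assert len(table) == 1  # only the pair of full-sized groups


class TestGroupSummaries:
    def _matrix(self, data, tissues=None):
        tissues = tissues or [f"t{i}" for i in range(len(next(iter(data.values()))))]
        return pd.DataFrame.from_dict(data, orient="index", columns=tissues)

    def test_identical_taus_collapse_ci(self):
        mat = self._matrix({f"g{i}": [8, 1, 1, 1] for i in range(5)})
        s = summarize_by_group(mat, {})
        row = s.loc["non_expanded"]
        assert row["tau_ci_low"] == pytest.approx(row["tau_ci_high"])

    def test_mean_proportions_average_genes(self):
        mat = self._matrix({"a": [10, 0], "b": [0, 10]})
        s = summarize_by_group(mat, {"a": "g1", "b": "g1"})
        assert s.loc["g1", "prop_t0"] == pytest.approx(0.5)
        assert s.loc["g1", "prop_t1"] == pytest.approx(0.5)

    def test_all_zero_genes_counted_not_summarized(self):
        mat = self._matrix({"a": [5, 1], "b": [0, 0]})
        s = summarize_by_group(mat, {})
        assert s.loc["non_expanded", "n_genes"] == 2
        assert s.loc["non_expanded", "n_defined"] == 1

    def test_planted_dominant_tissue_recovered(self):
        from expanscan.synthetic_data import ExpressionSpec, simulate_expression

        genes = [f"OCTBM_x{i:03d}" for i in range(20)]
        assign = {g: "group1" for g in genes}
        spec = ExpressionSpec(group_specific_fraction=1.0)
        mat, truth = simulate_expression(spec, genes, assign, seed=7)
        s = summarize_by_group(mat, assign)
        planted = truth["dominant_tissue"].dropna().unique()
        assert list(planted) == [s.loc["group1", "top_tissue"]]

    def test_compare_groups_detects_planted_contrast(self):
        from expanscan.synthetic_data import ExpressionSpec, simulate_expression

        genes = [f"g{i}" for i in range(120)]
        assign = {g: "group1" for g in genes[:30]}
        spec = ExpressionSpec(specific_fraction=0.1, group_specific_fraction=1.0)
        mat, _ = simulate_expression(spec, genes, assign, seed=3)
        kw, pairwise = compare_groups(mat, assign)
        assert kw.p_value < 0.01
        assert set(pairwise.columns) == {"group_a", "group_b", "z", "raw_p", "adjusted_p"}

    def test_tau_table_flags_specific_genes(self):
        mat = self._matrix({"spec": [100, 1, 1, 1], "broad": [5, 5, 5, 4]})
        tt = tau_table(mat)
        assert tt.loc["spec", "is_specific"]
        assert not tt.loc["broad", "is_specific"]
        assert tt.loc["spec", "argmax_tissue"] == "t0"
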