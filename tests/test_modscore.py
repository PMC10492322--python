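"""Unit and property tests for quantile normalization, U statistics, gene
and module scores, and the permutation FDR estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modmet import (
    ExpressionDataset,
    GroupComparison,
    gene_score,
    module_scores,
    permutation_fdr,
    quantile_normalize,
    score_all_genes,
    u_statistics,
)


def brute_force_u1(case, control) -> float:
    """Pair-counting oracle: #(case > control) + half credit per tie."""
    return float(
        sum((c > d) + 0.5 * (c == d) for c in case for d in control)
    )


def make_dataset(values, n_case, n_ctrl, log2=True):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = [f"s{i}" for i in range(n_case + n_ctrl)]
    labels = {
        s: ("case" if i < n_case else "ctrl") for i, s in enumerate(samples)
    }
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionDataset(genes, samples, values, labels, log2=log2)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        col = np.array([4.0, 1.0, 3.0])
        ds = make_dataset(np.column_stack([col] * 4), 2, 2)
        out = quantile_normalize(ds)
        np.testing.assert_allclose(out.values, ds.values)

    def test_two_by_two_rank_means(self):
        # columns [1, 5] and [3, 7] -> per-rank means (2, 6) in both columns
        ds = make_dataset(np.array([[1.0, 3.0], [5.0, 7.0]]), 1, 1)
        out = quantile_normalize(ds)
        np.testing.assert_allclose(out.values, [[2.0, 2.0], [6.0, 6.0]])

    def test_columns_share_sorted_values_afterwards(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(size=(30, 8)), 4, 4)
        out = quantile_normalize(ds).values
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_rank_order_within_column_preserved(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.normal(size=(20, 5)), 3, 2)
        out = quantile_normalize(ds).values
        for j in range(5):
            assert (
                np.argsort(out[:, j], kind="stable")
                == np.argsort(ds.values[:, j], kind="stable")
            ).all()

    def test_constant_column_gets_reference_mean(self):
        values = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        ds = make_dataset(values, 1, 1)
        out = quantile_normalize(ds)
        ref = np.sort(values, axis=0).mean(axis=1)
        np.testing.assert_allclose(out.values[:, 1], np.full(3, ref.mean()))


# ---------------------------------------------------------------------------
# U statistics and gene score
# ---------------------------------------------------------------------------

class TestUStatistics:
    @pytest.mark.parametrize(
        "case, control, expected_u1",
        [
            ([5, 6, 7], [1, 2, 3], 9.0),     # complete separation
            ([3, 1], [2, 4], 1.0),            # brute-force derived
            ([1, 2, 3], [1, 2, 3], 4.5),      # identical multisets
        ],
    )
    def test_worked_examples(self, case, control, expected_u1):
        u1, u2, _p = u_statistics(case, control)
        assert u1 == expected_u1
        assert u1 + u2 == len(case) * len(control)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            u_statistics([], [1, 2])

    @settings(max_examples=300, derandomize=True)
    @given(
        case=st.lists(st.integers(0, 4), min_size=1, max_size=8),
        control=st.lists(st.integers(0, 4), min_size=1, max_size=8),
    )
    def test_rank_formula_matches_pair_counting(self, case, control):
        u1, u2, _ = u_statistics(case, control)
        assert u1 == pytest.approx(brute_force_u1(case, control))
        assert u2 == pytest.approx(brute_force_u1(control, case))


class TestGeneScore:
    @pytest.mark.parametrize(
        "u1, n1, n2, expected",
        [
            (4.5, 3, 3, 0.0),     # null center
            (9.0, 3, 3, 1.5),     # maximum n1*n2/(n1+n2)
            (1.0, 2, 2, -0.5),    # plugged into the formula
        ],
    )
    def test_formula(self, u1, n1, n2, expected):
        assert gene_score(u1, n1, n2) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gene_score(10.0, 3, 3)

    @settings(max_examples=200, derandomize=True)
    @given(
        case=st.lists(st.integers(0, 6), min_size=2, max_size=8),
        control=st.lists(st.integers(0, 6), min_size=2, max_size=8),
    )
    def test_antisymmetry_and_bound(self, case, control):
        n1, n2 = len(case), len(control)
        u1, _, _ = u_statistics(case, control)
        u1_swapped, _, _ = u_statistics(control, case)
        s = gene_score(u1, n1, n2)
        assert gene_score(u1_swapped, n2, n1) == pytest.approx(-s)
        assert abs(s) <= n1 * n2 / (n1 + n2) + 1e-12


# ---------------------------------------------------------------------------
# per-gene scoring of a dataset
# ---------------------------------------------------------------------------

class TestScoreAllGenes:
    def test_records_satisfy_invariants(self, toy_dataset):
        rec = score_all_genes(toy_dataset, GroupComparison("case", "ctrl"))
        n1 = n2 = 3
        np.testing.assert_allclose(rec["u1"] + rec["u2"], n1 * n2)
        np.testing.assert_allclose(
            rec["score"], (rec["u1"] - rec["u2"]) / (n1 + n2)
        )
        assert rec.loc["gA", "u1"] == 9 and rec.loc["gA", "score"] == 1.5
        assert rec.loc["gB", "score"] == -1.5

    def test_constant_gene_scores_zero_p_one(self, toy_dataset):
        rec = score_all_genes(toy_dataset, GroupComparison("case", "ctrl"))
        assert rec.loc["gC", "score"] == 0.0
        assert rec.loc["gC", "p_value"] == 1.0

    def test_label_swap_negates_scores(self, toy_dataset):
        fwd = score_all_genes(toy_dataset, GroupComparison("case", "ctrl"))
        rev = score_all_genes(toy_dataset, GroupComparison("ctrl", "case"))
        np.testing.assert_allclose(fwd["score"], -rev["score"])
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"])

    def test_duplicated_gene_rows_get_identical_records(self):
        rng = np.random.default_rng(3)
        row = rng.normal(size=8)
        ds = make_dataset(np.vstack([row, row]), 4, 4)
        rec = score_all_genes(ds, GroupComparison("case", "ctrl"))
        assert rec.iloc[0].equals(rec.iloc[1])

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(10, 12))
        ds = make_dataset(values, 6, 6)
        perm = rng.permutation(12)
        ds_perm = ExpressionDataset(
            ds.gene_ids,
            [ds.sample_ids[j] for j in perm],
            values[:, perm],
            ds.labels,
        )
        a = score_all_genes(ds, GroupComparison("case", "ctrl"))
        b = score_all_genes(ds_perm, GroupComparison("case", "ctrl"))
        pd.testing.assert_frame_equal(a, b)

    def test_fold_change_uses_linear_scale(self):
        # log2 values: case mean 3, ctrl mean 1 -> linear ratio 8/2 = 4
        ds = make_dataset([[3.0, 3.0, 1.0, 1.0]], 2, 2, log2=True)
        rec = score_all_genes(ds, GroupComparison("case", "ctrl"))
        assert rec["fold_change"].iloc[0] == pytest.approx(4.0)

    def test_small_group_rejected(self):
        ds = make_dataset([[1.0, 2.0, 3.0]], 1, 2)
        with pytest.raises(ValueError):
            score_all_genes(ds, GroupComparison("case", "ctrl"))


# ---------------------------------------------------------------------------
# module scores
# ---------------------------------------------------------------------------

class TestModuleScores:
    @staticmethod
    def records(scores: dict[str, float]) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": list(scores.values())},
            index=pd.Index(scores, name="gene_id"),
        )

    def test_odd_median(self):
        rec = self.records({"a": 1.2, "b": -0.3, "c": 0.5})
        out = module_scores(rec, {"m": ["a", "b", "c"]})
        assert out.loc["m", "module_score"] == 0.5

    def test_even_median_is_mean_of_middle(self):
        rec = self.records({"a": 1.0, "b": 2.0, "c": 5.0, "d": -1.0})
        out = module_scores(rec, {"m": ["a", "b"]}, min_genes=2)
        assert out.loc["m", "module_score"] == 1.5

    def test_singleton_module(self):
        rec = self.records({"a": 0.7})
        out = module_scores(rec, {"m": ["a"]}, min_genes=1)
        assert out.loc["m", "module_score"] == 0.7

    def test_small_module_dropped_with_warning(self):
        rec = self.records({"a": 1.0, "b": 2.0})
        with pytest.warns(UserWarning, match="dropped"):
            out = module_scores(rec, {"m": ["a", "b"], "ok": ["a", "b"]},
                                min_genes=3)
        assert out.empty

    def test_gene_order_invariance(self):
        rec = self.records({"a": 1.0, "b": -2.0, "c": 0.3, "d": 4.0})
        fwd = module_scores(rec, {"m": ["a", "b", "c", "d"]})
        rev = module_scores(rec, {"m": ["d", "c", "b", "a"]})
        assert fwd.loc["m", "module_score"] == rev.loc["m", "module_score"]


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

class TestPermutationFdr:
    def test_deterministic_under_seed(self, null_dataset):
        ds, modules = null_dataset
        comp = GroupComparison("early", "normal")
        a = permutation_fdr(ds, comp, modules, n_perm=20, seed=7)
        b = permutation_fdr(ds, comp, modules, n_perm=20, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_fdr_monotone_in_abs_score(self, null_dataset):
        ds, modules = null_dataset
        res = permutation_fdr(
            ds, GroupComparison("early", "normal"), modules, n_perm=30, seed=1
        )
        ordered = res.reindex(
            res["module_score"].abs().sort_values(ascending=False).index
        )
        assert (np.diff(ordered["fdr"]) >= -1e-12).all()

    def test_dominant_module_gets_fdr_zero(self, null_dataset):
        ds, modules = null_dataset
        # plant a shift so one module's |score| exceeds every permuted score
        ds = ExpressionDataset(
            ds.gene_ids, ds.sample_ids, ds.values.copy(), ds.labels
        )
        cols = ds.group_columns("early")
        ds.values[:20, cols] += 5.0
        res = permutation_fdr(
            ds, GroupComparison("early", "normal"), modules, n_perm=30, seed=2
        )
        assert res.loc["M0", "fdr"] == 0.0
        assert bool(res.loc["M0", "significant"])

    def test_fdr_within_unit_interval(self, null_dataset):
        ds, modules = null_dataset
        res = permutation_fdr(
            ds, GroupComparison("early", "normal"), modules, n_perm=10, seed=3
        )
        assert res["fdr"].between(0, 1).all()
        assert (res["significant"] == (res["fdr"] < 0.05)).all()

    def test_zero_permutations_rejected(self, null_dataset):
        ds, modules = null_dataset
        with pytest.raises(ValueError):
            permutation_fdr(
                ds, GroupComparison("early", "normal"), modules, n_perm=0
            )
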