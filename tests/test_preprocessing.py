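"""QC chain: missing filter, kNN imputation, scaling, differential expression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from proteograph import (
    ExpressionMatrix,
    RawExpressionMatrix,
    SubtypeLabels,
    differential_expression,
    filter_missing,
    knn_impute,
    scale_expression,
    union_biomarkers,
)


def _raw(values, pids=None, sids=None):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    return RawExpressionMatrix(
        values,
        pids or [f"P{i}" for i in range(p)],
        sids or [f"S{j}" for j in range(n)],
    )


class TestFilterMissing:
    def test_exact_ten_percent_is_kept(self, rng):
        V = rng.random((3, 10))
        V[0, 0] = np.nan  # missing rate exactly 0.10: "over 10%" is strict
        out = filter_missing(_raw(V))
        assert out.protein_ids == ["P0", "P1", "P2"]

    def test_over_ten_percent_dropped(self, rng):
        V = rng.random((3, 10))
        V[0, :2] = np.nan
        out = filter_missing(_raw(V))
        assert out.protein_ids == ["P1", "P2"]

    def test_complete_matrix_identity(self, rng):
        V = rng.random((4, 6))
        out = filter_missing(_raw(V))
        assert np.array_equal(out.values, V)

    def test_all_dropped_raises(self):
        V = np.full((2, 4), np.nan)
        V[:, 0] = 1.0
        with pytest.raises(ValueError, match="all proteins"):
            filter_missing(_raw(V))


class TestKnnImpute:
    def test_twin_row_fills_missing_cell(self):
        V = np.array([
            [1.0, 2.0, 3.0, 4.0],
            [1.0, 2.0, np.nan, 4.0],
            [9.0, 9.0, 9.0, 9.0],
        ])
        out = knn_impute(_raw(V), k=1)
        assert out.values[1, 2] == pytest.approx(3.0)

    def test_complete_matrix_identity(self, rng):
        V = rng.random((5, 6))
        out = knn_impute(_raw(V), k=2)
        assert np.array_equal(out.values, V)

    def test_hand_computed_neighbor_mean(self):
        # distances from P0 over co-observed cells: P1 closest, then P2, P3
        V = np.array([
            [1.0, 1.0, np.nan],
            [1.1, 1.0, 10.0],
            [2.0, 2.0, 20.0],
            [5.0, 5.0, 30.0],
        ])
        out = knn_impute(_raw(V), k=2)
        assert out.values[0, 2] == pytest.approx((10.0 + 20.0) / 2)

    def test_all_missing_row_raises(self):
        V = np.array([[np.nan, np.nan], [1.0, 2.0], [1.0, 2.5]])
        with pytest.raises(ValueError, match="P0"):
            knn_impute(_raw(V), k=1)

    def test_too_few_neighbors_raises(self):
        V = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="neighbors"):
            knn_impute(_raw(V), k=5)


class TestScaleExpression:
    def test_row_mean_maps_to_half(self, rng):
        V = rng.random((3, 7))
        V[0, 0] = V[0, 1:].mean()  # ensure a value exactly at the row mean? no:
        x = ExpressionMatrix(V, [f"P{i}" for i in range(3)], [f"S{j}" for j in range(7)])
        out = scale_expression(x)
        # the value equal to the row mean maps to logistic(0) = 0.5
        row = V[1]
        z = (row - row.mean()) / row.std(ddof=1)
        assert np.allclose(out.values[1], expit(z))
        assert np.all((out.values > 0) & (out.values < 1))

    def test_two_point_row_hand_values(self):
        x = ExpressionMatrix(np.array([[0.0, 2.0], [5.0, 6.0]]), ["A", "B"], ["s1", "s2"])
        out = scale_expression(x)
        expected = expit(np.array([-1, 1]) / np.sqrt(2))
        assert np.allclose(out.values[0], expected)
        assert out.values[0, 0] == pytest.approx(0.3302, abs=2e-4)
        assert out.values[0, 1] == pytest.approx(0.6698, abs=2e-4)

    def test_mirrored_rows_sum_to_one(self, rng):
        row = rng.random(8)
        x = ExpressionMatrix(np.vstack([row, -row]), ["A", "B"], [f"s{j}" for j in range(8)])
        out = scale_expression(x)
        assert np.allclose(out.values[0] + out.values[1], 1.0)

    def test_zero_variance_row_names_protein(self):
        x = ExpressionMatrix(np.array([[1.0, 1.0], [0.0, 2.0]]), ["FLAT", "B"], ["s1", "s2"])
        with pytest.raises(ValueError, match="FLAT"):
            scale_expression(x)

    def test_double_scaling_guarded(self, rng):
        x = ExpressionMatrix(rng.random((3, 5)), [f"P{i}" for i in range(3)],
                             [f"S{j}" for j in range(5)])
        scaled = scale_expression(x)
        with pytest.raises(ValueError, match="already scaled"):
            scale_expression(scaled)


def _labels(Y):
    Y = np.asarray(Y)
    return SubtypeLabels(Y, [f"S{j}" for j in range(Y.shape[1])])


class TestDifferentialExpression:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(values, [f"P{i}" for i in range(values.shape[0])],
                                [f"S{j}" for j in range(values.shape[1])])

    def test_identical_groups_give_t_zero_p_one(self):
        # positives are a permutation of the negatives
        base = np.array([1.0, 2.0, 3.0, 4.0])
        V = np.vstack([np.r_[base, base[::-1]], np.r_[base * 2, 2 * base[::-1]]])
        Y = np.zeros((3, 8), dtype=int)
        Y[:, :4] = 1
        table = differential_expression(self._matrix(V), _labels(Y))
        assert np.allclose(table["t"], 0.0, atol=1e-12)
        assert np.allclose(table["p"], 1.0)

    def test_separated_groups_give_tiny_p(self, rng):
        pos = 10 + rng.normal(scale=1e-3, size=5)
        neg = rng.normal(scale=1e-3, size=5)
        V = np.r_[pos, neg][None, :].repeat(2, axis=0)
        Y = np.zeros((3, 10), dtype=int)
        Y[:, :5] = 1
        table = differential_expression(self._matrix(V), _labels(Y))
        assert (table["p"] < 1e-3).all()
        assert (table["direction"] == "up").all()

    def test_hand_welch_values(self):
        from scipy.stats import t as t_dist

        pos, neg = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        V = np.r_[pos, neg][None, :].repeat(2, axis=0)
        Y = np.zeros((3, 6), dtype=int)
        Y[:, :3] = 1
        table = differential_expression(self._matrix(V), _labels(Y))
        # hand Welch: se = sqrt(1/3 + 1/3), t = -3/se, df = 4
        se = np.sqrt(1 / 3 + 1 / 3)
        t_hand = -3 / se
        p_hand = 2 * t_dist.sf(abs(t_hand), df=4)
        row = table.iloc[0]
        assert row["t"] == pytest.approx(t_hand, rel=1e-9)
        assert row["p"] == pytest.approx(p_hand, rel=1e-6)
        assert row["log2fc"] == pytest.approx(-3.0)
        assert row["direction"] == "down"

    def test_degenerate_groups_raise(self, rng):
        V = rng.random((2, 6))
        Y = np.zeros((3, 6), dtype=int)
        Y[:, 0] = 1  # single positive
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_expression(self._matrix(V), _labels(Y))

    def test_adjusted_p_dominates_raw(self, rng):
        V = rng.random((10, 30))
        Y = rng.integers(0, 2, size=(3, 30))
        Y[:, :3] = 1
        Y[:, 3:6] = 0
        table = differential_expression(self._matrix(V), _labels(Y))
        assert (table["p_adj"] >= table["p"] - 1e-12).all()


class TestBenjaminiHochberg:
    def test_matches_step_up_enumeration(self):
        # exhaustive oracle over all orderings of short p-value lists
        from statsmodels.stats.multitest import multipletests

        def bh_oracle(pvals):
            m = len(pvals)
            order = np.argsort(pvals)
            adj = np.empty(m)
            running = 1.0
            for rank_idx in range(m - 1, -1, -1):
                i = order[rank_idx]
                running = min(running, pvals[i] * m / (rank_idx + 1))
                adj[i] = running
            return adj

        base = [0.01, 0.04, 0.3, 0.7, 0.049, 0.5]
        for m in range(1, 7):
            for pv in itertools.permutations(base[:m]):
                pv = np.array(pv)
                _, adj, _, _ = multipletests(pv, method="fdr_bh")
                assert np.allclose(adj, bh_oracle(pv), atol=1e-12)


class TestUnionBiomarkers:
    def _table(self, hits):
        rows = []
        for subtype, names in hits.items():
            for n in names:
                rows.append({"protein": n, "subtype": subtype, "p_adj": 0.01})
            rows.append({"protein": "NULL", "subtype": subtype, "p_adj": 0.9})
        return pd.DataFrame(rows)

    def test_union_over_subtypes(self):
        table = self._table({"Abeta": ["A", "B"], "MTA": ["B", "C"], "WMH": []})
        assert union_biomarkers(table) == ["A", "B", "C"]

    def test_alpha_zero_raises(self):
        table = self._table({"Abeta": ["A"], "MTA": [], "WMH": []})
        with pytest.raises(ValueError, match="relaxing"):
            union_biomarkers(table, alpha=0.0)

    def test_planted_effect_recall(self, rng):
        # 10 proteins shifted by 2 SD in positives out of 30; recall >= 0.9
        p, n = 30, 200
        Y = np.zeros((3, n), dtype=int)
        Y[:, :80] = 1
        V = rng.normal(size=(p, n))
        V[:10, :80] += 2.0
        x = ExpressionMatrix(V, [f"P{i}" for i in range(p)], [f"S{j}" for j in range(n)])
        table = differential_expression(x, _labels(Y))
        hits = union_biomarkers(table, alpha=0.05)
        planted = {f"P{i}" for i in range(10)}
        assert len(planted & set(hits)) >= 9
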