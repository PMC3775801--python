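"""Regularized-t arithmetic, permutation q-values, folds, probe collapsing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import retarray as ra
from retarray.diffexp import (SamDifferentialExpression, collapse_probes,
                              permutation_qvalues, rank_genes)


def _matrix(values, probes=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                        columns=[f"s{j}" for j in range(values.shape[1])])


class TestRegularizedT:
    def test_equal_group_means_give_zero(self):
        m = _matrix([[1.0, 2.0, 1.0, 2.0], [5.0, 5.0, 5.0, 5.0]])
        d, s, s0 = ra.regularized_t(m, [True, True, False, False], s0=0.5)
        assert d.loc["p0"] == 0.0 and d.loc["p1"] == 0.0

    def test_zero_variance_case_exact_arithmetic(self):
        # (1,1,1) vs (0,0,0) with s0 forced to 0.5: s = 0, d = 1/0.5 = 2
        m = _matrix([[1.0, 1.0, 1.0, 0.0, 0.0, 0.0]])
        d, s, s0 = ra.regularized_t(m, [True] * 3 + [False] * 3, s0=0.5)
        assert s.loc["p0"] == 0.0
        assert d.loc["p0"] == 2.0

    def test_pooled_standard_error_formula(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(5, 7)))
        mask = np.array([True, True, True, False, False, False, False])
        d, s, s0 = ra.regularized_t(m, mask, s0=0.0)
        g1, g2 = m.iloc[:, :3], m.iloc[:, 3:]
        ss1 = ((g1.sub(g1.mean(axis=1), axis=0)) ** 2).sum(axis=1)
        ss2 = ((g2.sub(g2.mean(axis=1), axis=0)) ** 2).sum(axis=1)
        expected = np.sqrt((1 / 3 + 1 / 4) * (ss1 + ss2) / 5)
        assert np.allclose(s, expected)

    def test_s0_percentile_linear_interpolation(self):
        # s_i grid 0.01..1.00: the 75th percentile under linear interpolation
        grid = np.round(np.arange(1, 101) / 100.0, 2)
        rng = np.random.default_rng(1)
        rows = []
        for s_target in grid:
            # two groups of 2 with within-group half-range h give
            # s = sqrt((1/2+1/2)*(2h^2+2h^2)/2) ... engineer via direct spread
            h = s_target / np.sqrt((1 / 2 + 1 / 2) * 4 / 2)
            mu = rng.normal()
            rows.append([mu - h, mu + h, mu - h, mu + h])
        m = _matrix(rows)
        d, s, s0 = ra.regularized_t(m, [True, True, False, False])
        assert np.allclose(np.sort(s), grid)
        assert s0 == pytest.approx(np.percentile(grid, 75))

    def test_groups_need_two_samples_each(self):
        m = _matrix([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="at least 2"):
            ra.regularized_t(m, [True, False, False])

    def test_constant_matrix_warns_s0_zero(self):
        m = _matrix(np.full((3, 4), 2.0))
        with pytest.warns(UserWarning, match="s0 is 0"):
            d, s, s0 = ra.regularized_t(m, [True, True, False, False])
        assert s0 == 0.0 and np.all(d == 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_label_swap_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        m = _matrix(rng.normal(size=(20, 8)))
        mask = np.array([True] * 4 + [False] * 4)
        d1, _, s0 = ra.regularized_t(m, mask)
        d2, _, _ = ra.regularized_t(m, ~mask, s0=s0)
        assert np.allclose(d1, -d2)


class TestFoldChange:
    def test_sign_conventions(self):
        m = _matrix([
            [3.0, 3.0, 3.0, 3.0],    # equal means -> f = 1
            [4.0, 4.0, 2.0, 2.0],    # 4x on linear scale -> f = 4
            [2.0, 2.0, 3.0, 3.0],    # half -> f = -2
        ])
        f = ra.fold_change(m, [True, True, False, False])
        assert f.loc["p0"] == pytest.approx(1.0)
        assert f.loc["p1"] == pytest.approx(4.0)
        assert f.loc["p2"] == pytest.approx(-2.0)

    def test_magnitude_at_least_one(self, small_study):
        _, matrix, meta, _ = small_study
        mask = (meta["group"] == "pos").to_numpy()
        f = ra.fold_change(matrix[meta.index], mask)
        assert np.all(np.abs(f) >= 1.0)

    def test_swap_negates_fold(self):
        m = _matrix([[4.0, 4.0, 2.0, 2.0]])
        mask = np.array([True, True, False, False])
        f1 = ra.fold_change(m, mask)
        f2 = ra.fold_change(m, ~mask)
        assert f1.loc["p0"] == pytest.approx(-f2.loc["p0"])


class TestPermutationQvalues:
    def test_null_data_gives_large_q(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.normal(size=(300, 10)))
        q = permutation_qvalues(m, [True] * 5 + [False] * 5, n_perm=100, seed=1)
        assert q.median() > 0.5

    def test_planted_noiseless_fold_has_tiny_q(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(8, 1, size=(200, 10))
        vals[0, :5] = 10.5   # fold 4 on log2: maximal separation, zero spread
        vals[0, 5:] = 8.5
        m = _matrix(vals)
        q = permutation_qvalues(m, [True] * 5 + [False] * 5, n_perm=200, seed=2)
        assert q.iloc[0] < 0.05

    def test_identity_permutation_gives_q_one(self):
        rng = np.random.default_rng(7)
        m = _matrix(rng.normal(size=(50, 6)))
        mask = np.array([True] * 3 + [False] * 3)
        res = SamDifferentialExpression(m, mask).fit(
            permutations=[mask], pi0=1.0)
        assert np.all(res.fdr_curve_raw >= 1.0)
        assert np.all(res.table["q"] == 1.0)

    def test_q_invariant_to_probe_order(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.normal(size=(80, 8)))
        mask = np.array([True] * 4 + [False] * 4)
        q1 = permutation_qvalues(m, mask, n_perm=60, seed=3)
        perm = rng.permutation(len(m))
        q2 = permutation_qvalues(m.iloc[perm], mask, n_perm=60, seed=3)
        assert np.allclose(q1.loc[m.index], q2.loc[m.index])

    def test_exhaustive_enumeration_for_small_samples(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.normal(size=(30, 6)))
        res = SamDifferentialExpression(m, [True] * 3 + [False] * 3).fit(n_perm=100)
        assert res.exhaustive and res.n_perm == 20  # C(6,3)

    def test_q_within_unit_interval(self, small_study):
        _, matrix, meta, _ = small_study
        mask = (meta["group"] == "pos").to_numpy()
        q = permutation_qvalues(matrix, mask, n_perm=50, seed=4)
        assert np.all((q >= 0) & (q <= 1))


class TestCollapseProbes:
    def _table(self):
        return pd.DataFrame(
            {"d": [3.0, 2.0, -1.0, 0.5], "s": [1.0] * 4,
             "q": [0.01, 0.2, 0.05, 0.05], "f": [2.0, 1.5, -1.2, 1.1]},
            index=pd.Index(["a1", "a2", "b1", "b2"], name="probe_id"))

    def test_one_probe_per_gene_identity(self):
        table = self._table()
        mapping = pd.Series({"a1": "GA", "a2": "GB", "b1": "GC", "b2": "GD"})
        out = collapse_probes(table, mapping)
        assert len(out) == 4

    def test_smallest_q_probe_represents_gene(self):
        table = self._table()
        mapping = pd.Series({"a1": "GA", "a2": "GA", "b1": "GB", "b2": "GB"})
        out = collapse_probes(table, mapping)
        assert out.loc["GA", "probe_id"] == "a1"    # q 0.01 beats 0.2

    def test_q_tie_broken_by_larger_abs_d(self):
        table = self._table()
        mapping = pd.Series({"a1": "GA", "a2": "GA", "b1": "GB", "b2": "GB"})
        out = collapse_probes(table, mapping)
        assert out.loc["GB", "probe_id"] == "b1"    # |d| 1.0 beats 0.5

    def test_unmapped_probes_dropped_with_warning(self):
        table = self._table()
        mapping = pd.Series({"a1": "GA", "a2": "GA"})
        with pytest.warns(UserWarning, match="unmapped"):
            out = collapse_probes(table, mapping)
        assert list(out.index) == ["GA"]

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            collapse_probes(self._table(), pd.Series(dtype=object))


class TestRankGenes:
    def test_order_by_q_then_abs_d_then_gene(self):
        table = pd.DataFrame(
            {"probe_id": ["p1", "p2", "p3", "p4"],
             "d": [1.0, -3.0, 2.0, 2.0],
             "s": [1.0] * 4,
             "q": [0.5, 0.01, 0.01, 0.2],
             "f": [1.1, -2.0, 1.5, 1.4]},
            index=pd.Index(["GD", "GA", "GB", "GC"], name="gene_id"))
        assert rank_genes(table) == ["GA", "GB", "GC", "GD"]

    def test_exact_ties_fall_back_to_gene_id(self):
        table = pd.DataFrame(
            {"probe_id": ["p1", "p2"], "d": [1.0, 1.0], "s": [1.0, 1.0],
             "q": [0.1, 0.1], "f": [1.2, 1.2]},
            index=pd.Index(["GZ", "GA"], name="gene_id"))
        assert rank_genes(table) == ["GA", "GZ"]


class TestRecoveryOnPlantedStudy:
    def test_planted_probes_dominate_top_of_ranking(self, small_study):
        _, matrix, meta, truth = small_study
        thr = ra.estimate_detection_threshold(matrix, method="valley")
        detected = ra.filter_detected(matrix, thr)
        mask = (meta["group"] == "pos").to_numpy()
        res = SamDifferentialExpression(detected, mask).fit(n_perm=100, seed=5)
        top = res.table.sort_values("q").head(30)
        planted_probe = top.index.str.rsplit("_p").str[0].isin(truth.de_genes)
        assert planted_probe.mean() > 0.8
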