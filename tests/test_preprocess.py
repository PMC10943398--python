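"""Batch correction, t statistics, BH adjustment, panel intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cuprosep import (
    bh_adjust,
    differential_expression,
    intersect_panel,
    merge_and_correct,
    moderated_ttest,
)
from cuprosep.errors import ArgumentError, DataError

from conftest import make_matrix


def bh_reference(p):
    """Independent step-up oracle: literal sort / scale / monotone / cap."""
    p = list(map(float, p))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBH:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value_identity(self):
        assert bh_adjust([0.3])[0] == 0.3

    def test_all_ones_capped(self):
        assert np.allclose(bh_adjust([1.0] * 5), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ArgumentError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_matches_stepup_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_reference(p), atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30), st.randoms())
    def test_permutation_invariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adj = bh_adjust(p)
        adj_perm = bh_adjust([p[i] for i in perm])
        assert np.allclose([adj[i] for i in perm], adj_perm, atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 50))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected, atol=1e-12)


class TestMergeAndCorrect:
    def test_single_batch_identity(self):
        m = make_matrix([[1, 2], [2, 3]], [[3, 4], [4, 5]])
        out = merge_and_correct([m])
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy(), atol=1e-12)

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(7, 1, size=(6, 10))
        delta = rng.normal(0, 2, size=10)
        a = make_matrix(base[:3], base[3:], batch=["A"] * 6)
        b = make_matrix(base[:3] + delta, base[3:] + delta, batch=["B"] * 6)
        b.values.index = [f"t{i}" for i in range(6)]
        b.group.index = b.values.index
        b.batch.index = b.values.index
        out = merge_and_correct([a, b])
        X = out.values
        for label in ("A", "B"):
            sub = X[(out.batch == label).to_numpy()]
            assert np.allclose(sub.mean(axis=0), X.mean(axis=0), atol=1e-8)
        # grand mean preserved and within-batch deviations untouched
        assert np.allclose(X.mean(axis=0), np.vstack([base, base + delta]).mean(axis=0), atol=1e-8)
        resid_a = X[(out.batch == "A").to_numpy()] - X[(out.batch == "A").to_numpy()].mean(axis=0)
        assert np.allclose(resid_a, base - base.mean(axis=0), atol=1e-8)

    def test_disjoint_genes_rejected(self):
        a = make_matrix([[1, 2], [2, 3]], [[3, 4], [4, 5]], genes=["g1", "g2"])
        b = make_matrix([[1, 2], [2, 3]], [[3, 4], [4, 5]], genes=["g3", "g4"])
        b.values.index = [f"t{i}" for i in range(4)]
        b.group.index = b.values.index
        b.batch.index = b.values.index
        with pytest.raises(DataError):
            merge_and_correct([a, b])

    def test_tiny_batch_rejected(self):
        m = make_matrix([[1, 2], [2, 3]], [[3, 4], [4, 5]], batch=["A", "A", "A", "B"])
        with pytest.raises(DataError):
            merge_and_correct([m])


class TestDifferentialExpression:
    def test_welch_worked_example(self):
        m = make_matrix([[1], [2], [3]], [[3], [4], [5]])
        r = differential_expression(m, moderation=False)[0]
        assert r.t_stat == pytest.approx(-2.449, abs=1e-3)
        assert r.p_raw == pytest.approx(0.0705, abs=1e-3)
        assert r.log2fc == pytest.approx(-2.0)
        assert r.direction == "down"

    def test_identical_groups_null(self):
        m = make_matrix([[1], [2], [3]], [[1], [2], [3]])
        r = differential_expression(m, moderation=False)[0]
        assert r.t_stat == 0.0 and r.p_raw == 1.0 and not r.is_de

    def test_zero_variance_equal_means(self):
        m = make_matrix([[5], [5], [5]], [[5], [5], [5]])
        r = differential_expression(m, moderation=False)[0]
        assert r.t_stat == 0.0 and r.p_raw == 1.0

    def test_fold_change_gate(self):
        """|FC| > 1.2 with small adjusted p flags the gene."""
        rng = np.random.default_rng(0)
        case = rng.normal(0, 0.01, size=(20, 1)) + np.log2(1.3)
        ctrl = rng.normal(0, 0.01, size=(20, 1))
        m = make_matrix(case, ctrl)
        r = differential_expression(m)[0]
        assert 2 ** abs(r.log2fc) > 1.2 and r.p_adj < 0.05 and r.is_de

    def test_below_fold_change_not_flagged(self):
        rng = np.random.default_rng(0)
        case = rng.normal(0, 0.01, size=(20, 1)) + np.log2(1.1)
        ctrl = rng.normal(0, 0.01, size=(20, 1))
        r = differential_expression(make_matrix(case, ctrl))[0]
        assert r.p_adj < 0.05 and not r.is_de

    def test_one_sample_group_rejected(self):
        m = make_matrix([[1.0]], [[2.0], [3.0]])
        with pytest.raises(DataError):
            differential_expression(m)

    def test_moderated_prior_zero_equals_pooled_t(self):
        rng = np.random.default_rng(42)
        Xa = rng.normal(size=(6, 200))
        Xb = rng.normal(size=(9, 200))
        t0, p0, _ = moderated_ttest(Xa, Xb, prior_df=0)
        ref = stats.ttest_ind(Xa, Xb, equal_var=True)
        assert np.allclose(t0, ref.statistic, atol=1e-12)
        assert np.allclose(p0, ref.pvalue, atol=1e-12)

    def test_moderation_shrinks_extreme_variances(self):
        """Genes with tiny sample variance get less extreme statistics."""
        rng = np.random.default_rng(3)
        Xa = rng.normal(0, 1, size=(4, 500))
        Xb = rng.normal(0, 1, size=(4, 500))
        Xa[:, 0] = [0.0, 0.001, -0.001, 0.0005]  # tiny variance, small shift
        Xb[:, 0] = [0.05, 0.051, 0.049, 0.0505]
        t_mod, _, _ = moderated_ttest(Xa, Xb)
        t_raw, _, _ = moderated_ttest(Xa, Xb, prior_df=0)
        assert abs(t_mod[0]) < abs(t_raw[0])

    def test_type_one_error_calibrated(self):
        """Raw p on null genes is uniform enough; FDR gate stays silent."""
        from cuprosep import simulate_cohort

        m, _ = simulate_cohort(10, 10, 4000, 0.0, 0.0, 1, 0.0, 0.5, seed=123)
        res = differential_expression(m)
        raw_rate = np.mean([r.p_raw < 0.05 for r in res])
        assert 0.035 <= raw_rate <= 0.065
        assert np.mean([r.is_de for r in res]) <= 0.005


class TestIntersectPanel:
    def _fake(self, genes, flags):
        return [
            type("R", (), {"gene": g, "is_de": f})() for g, f in zip(genes, flags)
        ]

    def test_worked_example(self):
        res = self._fake(["A", "B", "C"], [True, True, True])
        assert intersect_panel(res, {"B", "C", "D"}) == {"B", "C"}

    def test_disjoint_empty(self):
        res = self._fake(["A", "B"], [True, True])
        assert intersect_panel(res, {"X"}) == set()

    def test_panel_subset_of_de(self):
        res = self._fake(["A", "B", "C"], [True, True, True])
        assert intersect_panel(res, {"A", "C"}) == {"A", "C"}

    def test_non_de_genes_excluded(self):
        res = self._fake(["A", "B"], [True, False])
        assert intersect_panel(res, {"A", "B"}) == {"A"}
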