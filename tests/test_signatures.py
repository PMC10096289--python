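"""Correlation-weighted signature aggregation against literal oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import rankdata

from moadti import (
    GenePanel,
    Signature,
    aggregate_target,
    correlation_matrix,
    spearman_correlation,
    weighted_average,
    weighted_average_matrix,
)
from moadti.exceptions import EmptyInputError, InvalidInputError


# ------------------------------------------------------------------ oracles

def oracle_spearman(a, b):
    """Rank (average ties) then Pearson — the definitional route."""
    ra, rb = rankdata(a), rankdata(b)
    return np.corrcoef(ra, rb)[0, 1]


def oracle_weighted_average(X, floor=0.01):
    """Literal transcription of the weight formula: R from pairwise Spearman,
    floor off-diagonals, exclude self-correlation, normalize row sums."""
    n = X.shape[0]
    R = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                r = oracle_spearman(X[i], X[j])
                if np.isnan(r):
                    r = 0.0
                R[i, j] = max(r, floor)
    M = R - np.eye(n)
    row = M @ np.ones(n)
    w = row / (np.ones(n) @ row)
    return w @ X, w


def make_sig(values, panel, gene="TP53", kind="knockdown", cell="A", cond="c0",
             sid=None):
    return Signature(np.asarray(values, dtype=float), gene, kind, cell, cond,
                     sid or f"s{id(values) % 9973}", panel)


@pytest.fixture()
def panel5():
    return GenePanel(tuple(f"g{i}" for i in range(5)))


# ------------------------------------------------------------- spearman

class TestSpearman:
    def test_identity_is_one(self):
        v = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert spearman_correlation(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_rank_reversal_is_minus_one(self):
        assert spearman_correlation([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        a, b = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        assert spearman_correlation(a, b) == pytest.approx(oracle_spearman(a, b),
                                                           abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=20).astype(float)  # forces ties
        b = rng.integers(0, 5, size=20).astype(float)
        expected = oracle_spearman(a, b)
        if np.isnan(expected):
            expected = 0.0
        assert spearman_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        base = spearman_correlation(a, b)
        assert spearman_correlation(np.exp(a), b) == pytest.approx(base, abs=1e-12)
        assert spearman_correlation(a, 3 * b + 7) == pytest.approx(base, abs=1e-12)

    def test_constant_vector_correlates_zero(self):
        assert spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4]) == 0.0

    def test_invalid_inputs_raise(self):
        with pytest.raises(InvalidInputError):
            spearman_correlation([1, 2], [1, 2, 3])
        with pytest.raises(InvalidInputError):
            spearman_correlation([1], [2])


# ------------------------------------------------------ correlation matrix

class TestCorrelationMatrix:
    def test_single_signature(self, panel5):
        R = correlation_matrix([make_sig([1, 2, 3, 4, 5], panel5)])
        assert R.shape == (1, 1) and R[0, 0] == 1.0

    def test_identical_pair_all_ones(self, panel5):
        s = [1.0, 3.0, 2.0, 5.0, 4.0]
        R = correlation_matrix([make_sig(s, panel5), make_sig(s, panel5)])
        np.testing.assert_allclose(R, np.ones((2, 2)), atol=1e-12)

    def test_matches_pairwise_oracle(self, panel5, rng):
        sigs = [make_sig(rng.normal(size=5), panel5, sid=f"r{i}") for i in range(3)]
        R = correlation_matrix(sigs)
        assert np.allclose(R, R.T) and np.all(np.abs(R) <= 1 + 1e-12)
        for i in range(3):
            for j in range(3):
                expected = 1.0 if i == j else oracle_spearman(sigs[i].values,
                                                              sigs[j].values)
                assert R[i, j] == pytest.approx(expected, abs=1e-10)

    def test_mixed_panels_rejected(self, panel5):
        other = GenePanel(tuple(f"h{i}" for i in range(5)))
        with pytest.raises(InvalidInputError):
            correlation_matrix([make_sig([1, 2, 3, 4, 5], panel5),
                                make_sig([1, 2, 3, 4, 5], other)])


# ------------------------------------------------------- weighted average

class TestWeightedAverage:
    def test_single_input_identity(self, panel5):
        s = make_sig([2, 4, 6, 8, 10], panel5)
        agg = weighted_average([s])
        np.testing.assert_array_equal(agg.vector, s.values)
        np.testing.assert_array_equal(agg.weights, [1.0])

    def test_pair_is_simple_mean(self, panel5, rng):
        s1 = make_sig(rng.normal(size=5), panel5, sid="a")
        s2 = make_sig(rng.normal(size=5), panel5, sid="b")
        agg = weighted_average([s1, s2])
        np.testing.assert_allclose(agg.weights, [0.5, 0.5])
        np.testing.assert_allclose(agg.vector, (s1.values + s2.values) / 2)

    def test_three_signature_full_formula_oracle(self, panel5):
        X = np.array([[1, 2, 3, 4, 5], [1, 2, 3, 5, 4], [5, 4, 3, 2, 1]], float)
        agg = weighted_average_matrix(X)
        vec, w = oracle_weighted_average(X)
        np.testing.assert_allclose(agg.vector, vec, atol=1e-10)
        np.testing.assert_allclose(agg.weights, w, atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_instances_match_literal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 7)
        G = rng.integers(5, 31)
        X = rng.normal(size=(n, G))
        agg = weighted_average_matrix(X)
        vec, w = oracle_weighted_average(X)
        np.testing.assert_allclose(agg.vector, vec, atol=1e-10)
        np.testing.assert_allclose(agg.weights, w, atol=1e-10)
        assert abs(agg.weights.sum() - 1.0) < 1e-9

    def test_replicate_idempotence_exact(self, rng):
        x = rng.normal(size=12)
        for m in (2, 3, 5):
            agg = weighted_average_matrix(np.tile(x, (m, 1)))
            np.testing.assert_array_equal(agg.vector, x)

    def test_convexity_elementwise(self, rng):
        X = rng.normal(size=(5, 8))
        agg = weighted_average_matrix(X, floor=0.01)
        assert np.all(agg.weights > 0)
        assert np.all(agg.vector >= X.min(axis=0) - 1e-12)
        assert np.all(agg.vector <= X.max(axis=0) + 1e-12)

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(4, 10))
        perm = [2, 0, 3, 1]
        a = weighted_average_matrix(X)
        b = weighted_average_matrix(X[perm])
        np.testing.assert_allclose(a.vector, b.vector, atol=1e-10)
        np.testing.assert_allclose(a.weights[perm], b.weights, atol=1e-10)

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            weighted_average([])


# ------------------------------------------------------- two-stage target

class TestAggregateTarget:
    def test_single_signature_identity(self, panel5):
        s = make_sig([1, 2, 3, 4, 5], panel5)
        np.testing.assert_array_equal(aggregate_target([s]).vector, s.values)

    def test_identical_replicates_any_grouping(self, panel5):
        x = np.array([2.0, -1.0, 0.5, 3.0, 1.0])
        sigs = [make_sig(x, panel5, cell=c, cond=j, sid=f"{c}{j}")
                for c in "ABC" for j in ("c0", "c1")]
        agg = aggregate_target(sigs)
        np.testing.assert_array_equal(agg.vector, x)
        np.testing.assert_allclose(agg.weights, np.full(3, 1 / 3))

    def test_staged_oracle_and_difference_from_pooling(self, panel5, rng):
        vecs = {("A", "c0"): rng.normal(size=5), ("A", "c1"): rng.normal(size=5),
                ("B", "c0"): rng.normal(size=5), ("B", "c1"): rng.normal(size=5)}
        sigs = [make_sig(v, panel5, cell=c, cond=j, sid=f"{c}{j}")
                for (c, j), v in vecs.items()]
        agg = aggregate_target(sigs)
        inner_a, _ = oracle_weighted_average(
            np.vstack([vecs[("A", "c0")], vecs[("A", "c1")]]))
        inner_b, _ = oracle_weighted_average(
            np.vstack([vecs[("B", "c0")], vecs[("B", "c1")]]))
        outer, _ = oracle_weighted_average(np.vstack([inner_a, inner_b]))
        np.testing.assert_allclose(agg.vector, outer, atol=1e-10)
        pooled = aggregate_target(sigs, single_stage=True)
        assert not np.allclose(agg.vector, pooled.vector)

    def test_skew_resistance_two_stage_beats_pooling(self):
        # cell A: 10 noisy replicates of u; cell B: one replicate of v
        panel = GenePanel(tuple(f"g{i}" for i in range(30)))
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            u, v = rng.normal(size=30), rng.normal(size=30)
            target = (u + v) / 2
            sigs = [make_sig(u + 0.3 * rng.normal(size=30), panel, cell="A",
                             cond=f"c{j}", sid=f"A{j}") for j in range(10)]
            sigs.append(make_sig(v, panel, cell="B", cond="c0", sid="B0"))
            two = aggregate_target(sigs).vector
            pooled = aggregate_target(sigs, single_stage=True).vector
            if np.linalg.norm(two - target) < np.linalg.norm(pooled - target):
                wins += 1
        assert wins >= 8

    def test_mixed_gene_rejected(self, panel5):
        s1 = make_sig([1, 2, 3, 4, 5], panel5, gene="TP53")
        s2 = make_sig([1, 2, 3, 4, 5], panel5, gene="EGFR")
        with pytest.raises(InvalidInputError):
            aggregate_target([s1, s2])


finite_matrix = arrays(
    np.float64,
    st.tuples(st.integers(2, 6), st.integers(4, 12)),
    elements=st.floats(-50, 50, allow_nan=False, width=64),
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(X=finite_matrix)
def test_property_weights_convex_and_order_free(X):
    """Aggregation weights form a convex combination regardless of input:
    they sum to one, stay positive under a positive floor, and permuting
    the inputs permutes only the weights."""
    agg = weighted_average_matrix(X)
    assert abs(agg.weights.sum() - 1.0) <= 1e-9
    assert np.all(agg.weights > 0)
    assert np.all(agg.vector >= X.min(axis=0) - 1e-9)
    assert np.all(agg.vector <= X.max(axis=0) + 1e-9)
    perm = np.arange(X.shape[0])[::-1]
    flipped = weighted_average_matrix(X[perm])
    np.testing.assert_allclose(flipped.vector, agg.vector, atol=1e-9)
    np.testing.assert_allclose(flipped.weights, agg.weights[perm], atol=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    a=arrays(np.float64, 10, elements=st.floats(-50, 50, allow_nan=False)),
    b=arrays(np.float64, 10, elements=st.floats(-50, 50, allow_nan=False)),
)
def test_property_spearman_symmetric_and_bounded(a, b):
    r = spearman_correlation(a, b)
    assert -1.0 <= r <= 1.0
    assert spearman_correlation(b, a) == pytest.approx(r, abs=1e-12)


def test_signature_validation(panel5):
    with pytest.raises(InvalidInputError):
        make_sig([1, 2, 3], panel5)  # wrong length
    with pytest.raises(InvalidInputError):
        make_sig([1, 2, 3, 4, np.nan], panel5)
    with pytest.raises(InvalidInputError):
        Signature(np.ones(5), "TP53", "crispr", "A", "c0", "x", panel5)


def test_gene_panel_contracts():
    with pytest.raises(InvalidInputError):
        GenePanel(("a", "a", "b"))
    panel = GenePanel(("b", "a", "c"))
    idx = panel.index_of(["a", "b", "c"])
    np.testing.assert_array_equal(idx, [1, 0, 2])
    with pytest.raises(InvalidInputError):
        panel.index_of(["a", "b"])
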