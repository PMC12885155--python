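import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from guttmap import (
    DataError,
    ResponseMatrix,
    endorsement,
    error_matrix,
    loevinger,
    order_items,
    pair_counts,
    mat_report,
)
from conftest import (
    h_pair_covariance_oracle,
    h_pair_polytomous_oracle,
    random_dichotomous_matrix,
)


def full_run(R, w=None, **order_kw):
    ordering = order_items(endorsement(R, w), **order_kw)
    counts = pair_counts(R, ordering, w)
    return counts, error_matrix(counts), loevinger(counts)


class TestEndorsement:
    def test_unweighted_proportion(self):
        vals = np.column_stack([np.r_[np.ones(7), np.zeros(3)],
                                np.zeros(10)]).astype(int)
        R = ResponseMatrix(vals, ["a", "b"])
        np.testing.assert_allclose(endorsement(R), [0.7, 0.0])

    def test_weighted_mean(self):
        R = ResponseMatrix(np.array([[1, 0], [0, 1]]), ["a", "b"])
        np.testing.assert_allclose(
            endorsement(R, np.array([3.0, 1.0])), [0.75, 0.25]
        )

    def test_length_mismatch_raises(self):
        R = ResponseMatrix(np.array([[1, 0], [0, 1]]), ["a", "b"])
        with pytest.raises(DataError, match="length"):
            endorsement(R, np.ones(3))


class TestOrdering:
    def test_decreasing_sort(self):
        o = order_items(np.array([0.2, 0.9, 0.5]))
        assert o.order.tolist() == [1, 2, 0]

    def test_stable_tie_break(self):
        o = order_items(np.array([0.5, 0.5, 0.9]))
        assert o.order.tolist() == [2, 0, 1]

    def test_custom_passthrough(self):
        o = order_items(np.array([0.2, 0.9, 0.5]), "custom", [2, 0, 1])
        assert o.order.tolist() == [2, 0, 1]

    def test_invalid_permutation(self):
        with pytest.raises(DataError, match="permutation"):
            order_items(np.array([0.2, 0.9]), "custom", [0, 0])


class TestPairCounts:
    def test_enumerated_example(self, pair_example):
        counts, em, hs = full_run(pair_example)
        assert counts.F[0, 1] == pytest.approx(1.0)
        assert counts.E[0, 1] == pytest.approx(1.2)
        assert em.e_percent[0, 1] == pytest.approx(100 / 1.2)
        assert hs.h_pair[0, 1] == pytest.approx(1 / 6)
        assert hs.h_total == pytest.approx(1 / 6)

    def test_perfect_scale(self, perfect_guttman):
        counts, em, hs = full_run(perfect_guttman)
        assert counts.F[0, 1] == 0.0
        assert em.e_percent[0, 1] == 0.0
        assert hs.h_total == 1.0

    def test_exact_independence(self, independent_items):
        counts, em, hs = full_run(independent_items)
        assert counts.F[0, 1] == pytest.approx(counts.E[0, 1])
        assert em.e_percent[0, 1] == pytest.approx(100.0)
        assert hs.h_total == pytest.approx(0.0)

    def test_degenerate_item_flagged_undefined(self):
        vals = np.column_stack([np.ones(6), np.r_[np.ones(2), np.zeros(4)],
                                np.r_[np.ones(3), np.zeros(3)]]).astype(int)
        R = ResponseMatrix(vals, ["all1", "b", "c"])
        ordering = order_items(endorsement(R))
        counts = pair_counts(R, ordering)
        # pairs with the constant item are undefined, the (b, c) pair is not
        assert counts.undefined.sum() == 4
        assert not counts.undefined[counts.labels.index("b"),
                                    counts.labels.index("c")]
        with pytest.warns(UserWarning, match="excluded"):
            hs = loevinger(counts)
        assert np.isfinite(hs.h_total)

    def test_symmetry_and_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            R = random_dichotomous_matrix(rng, n=120, k=4)
            counts, em, hs = full_run(R)
            np.testing.assert_allclose(em.e_percent, em.e_percent.T,
                                       equal_nan=True)
            for a in range(4):
                for b in range(a + 1, 4):
                    ja, jb = counts.ordering[a], counts.ordering[b]
                    expected = h_pair_covariance_oracle(
                        R.values[:, ja], R.values[:, jb]
                    )
                    assert hs.h_pair[a, b] == pytest.approx(expected,
                                                            abs=1e-12)

    def test_weight_invariance_under_rescaling(self):
        rng = np.random.default_rng(5)
        R = random_dichotomous_matrix(rng, n=80, k=4)
        w = rng.uniform(0.5, 3.0, size=80)
        _, em1, hs1 = full_run(R, w)
        _, em2, hs2 = full_run(R, 17.3 * w)
        np.testing.assert_allclose(em1.e_percent, em2.e_percent,
                                   equal_nan=True, atol=1e-12)
        assert hs1.h_total == pytest.approx(hs2.h_total, abs=1e-12)
        np.testing.assert_allclose(hs1.h_item, hs2.h_item, atol=1e-12)


class TestPolytomous:
    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(23)
        vals = rng.integers(0, 3, size=(150, 3))
        R = ResponseMatrix(vals, ["a", "b", "c"], n_categories=[3, 3, 3])
        counts, _, hs = full_run(R)
        for a in range(3):
            for b in range(a + 1, 3):
                ja, jb = counts.ordering[a], counts.ordering[b]
                expected = h_pair_polytomous_oracle(
                    R.values[:, ja], R.values[:, jb], 2, 2
                )
                assert hs.h_pair[a, b] == pytest.approx(expected, abs=1e-12)

    def test_two_category_path_reduces_to_dichotomous(self):
        rng = np.random.default_rng(31)
        R = random_dichotomous_matrix(rng, n=100, k=4)
        R_poly = ResponseMatrix(R.values.copy(), R.item_labels,
                                n_categories=[2, 2, 2, 2])
        c1, em1, hs1 = full_run(R)
        c2, em2, hs2 = full_run(R_poly)
        np.testing.assert_array_equal(em1.e_percent, em2.e_percent)
        np.testing.assert_array_equal(hs1.h_item, hs2.h_item)
        assert hs1.h_total == hs2.h_total


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_error_ratio_complementarity_property(seed):
    """1 - e/100 always equals the pairwise Loevinger coefficient."""
    rng = np.random.default_rng(seed)
    R = random_dichotomous_matrix(rng, n=60, k=3)
    _, em, hs = full_run(R)
    off = ~np.eye(3, dtype=bool)
    np.testing.assert_allclose(1 - em.e_percent[off] / 100,
                               hs.h_pair[off], atol=1e-12)


class TestMatReport:
    def test_report_sections_and_rounding(self, pair_example):
        counts, em, hs = full_run(pair_example)
        text = mat_report(em, hs, counts.n_eff)
        assert "83.3" in text            # 100/1.2 at 1 decimal
        assert "0.167" in text           # 1/6 at 3 decimals
        assert "Total H: 0.167" in text
        assert "Effective n: 10" in text
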