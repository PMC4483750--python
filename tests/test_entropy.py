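"""Entropy weighting and forecast combination: oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import entrocast as ec


class TestNormalizeMatrix:
    def test_benefit_endpoints(self):
        r, flags = ec.normalize_matrix([[1.0, 3.0, 5.0]], "benefit")
        assert np.allclose(r, [[0.0, 0.5, 1.0]]) and flags == ()

    def test_cost_endpoints(self):
        r, flags = ec.normalize_matrix([[1.0, 3.0, 5.0]], "cost")
        assert np.allclose(r, [[1.0, 0.5, 0.0]]) and flags == ()

    def test_constant_row_all_ones_flagged(self):
        r, flags = ec.normalize_matrix([[4.0, 4.0, 4.0], [1.0, 2.0, 3.0]])
        assert np.allclose(r[0], 1.0) and flags == (0,)

    def test_too_few_columns(self):
        with pytest.raises(ValueError, match="at least 2"):
            ec.normalize_matrix([[1.0]])


class TestEntropy:
    def test_uniform_row_maximal(self):
        assert ec.entropy([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_point_mass_zero(self):
        assert ec.entropy([1.0, 0.0]) == 0.0  # 0·ln0 = 0 convention

    def test_direct_evaluation(self):
        # −(1/ln3)(0.25 ln0.25 + 0.25 ln0.25 + 0.5 ln0.5)
        expected = -(
            2 * 0.25 * np.log(0.25) + 0.5 * np.log(0.5)
        ) / np.log(3)
        assert ec.entropy([1.0, 1.0, 2.0]) == pytest.approx(expected)
        assert round(ec.entropy([1.0, 1.0, 2.0]), 4) == 0.9464

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            ec.entropy([0.0, 0.0])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=2, max_size=20).filter(
            lambda r: sum(r) > 0
        ),
        st.floats(min_value=0.1, max_value=100.0),
    )
    def test_scale_invariance(self, row, c):
        row = np.array(row)
        assert ec.entropy(row * c) == pytest.approx(ec.entropy(row), abs=1e-9)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=2, max_size=20).filter(
            lambda r: sum(r) > 0
        )
    )
    def test_bounds(self, row):
        assert 0.0 <= ec.entropy(row) <= 1.0 + 1e-12


class TestEntropyWeights:
    def test_symmetry(self):
        assert np.allclose(ec.entropy_weights([0.5, 0.5]), [0.5, 0.5])

    def test_hand_computed(self):
        # (1−0.9, 1−0.8) / (2 − 1.7) = (0.1, 0.2)/0.3
        assert np.allclose(ec.entropy_weights([0.9, 0.8]), [1 / 3, 2 / 3])

    def test_degenerate_fallback_equal_weights(self):
        with pytest.warns(RuntimeWarning, match="equal weights"):
            w = ec.entropy_weights([1.0, 1.0, 1.0])
        assert np.allclose(w, 1 / 3)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=8))
    def test_always_convex(self, p):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = ec.entropy_weights(p)
        assert np.all(w >= 0) and w.sum() == pytest.approx(1.0)


class TestCombine:
    def test_constant_forecasts_preserved(self):
        F = np.full((3, 4), 9.5)
        assert np.allclose(ec.combine(F, [0.2, 0.3, 0.5]), 9.5)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        F, G = rng.normal(size=(2, 3, 6))
        w = np.array([0.6, 0.1, 0.3])
        assert np.allclose(
            ec.combine(F + 2 * G, w), ec.combine(F, w) + 2 * ec.combine(G, w)
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        F = rng.uniform(1, 9, size=(3, 5))
        w = np.array([0.5, 0.2, 0.3])
        perm = [2, 0, 1]
        assert np.allclose(ec.combine(F, w), ec.combine(F[perm], w[perm]))

    @pytest.mark.parametrize(
        "weights,err",
        [([0.6, 0.6], "sum"), ([1.5, -0.5], "negative"), ([1.0], "rows")],
    )
    def test_invalid_weights(self, weights, err):
        with pytest.raises(ValueError, match=err):
            ec.combine(np.ones((2, 3)), weights)

    @given(st.integers(min_value=0, max_value=1000))
    def test_convex_hull(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.uniform(1, 100, size=(3, 8))
        w = rng.dirichlet(np.ones(3))
        c = ec.combine(F, w)
        assert np.all(c >= F.min(axis=0) - 1e-9) and np.all(c <= F.max(axis=0) + 1e-9)


class TestWeightsFromHistory:
    def test_identical_methods_equal_weights(self):
        y = np.array([10.0, 12.0, 9.0, 11.0])
        yhat = np.vstack([[9.0, 13.0, 8.0, 12.0]] * 2)
        w = ec.weights_from_history(y, yhat)
        assert np.allclose(w.weights, 0.5)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(20, 80, 6)
        yhat = y + rng.normal(0, 5, size=(3, 6))
        perm = [1, 2, 0]
        w = ec.weights_from_history(y, yhat).weights
        wp = ec.weights_from_history(y, yhat[perm]).weights
        assert np.allclose(w[perm], wp)

    @pytest.mark.parametrize("basis", ["accuracy_benefit", "abs_error_cost"])
    def test_toy_matrix_against_independent_chain(self, basis):
        """End-to-end oracle: naive loop implementation of normalize → f →
        entropy → weights on a fixed 3-method × 4-point history."""
        y = np.array([50.0, 60.0, 40.0, 55.0])
        yhat = np.array(
            [
                [48.0, 66.0, 42.0, 50.0],
                [55.0, 58.0, 30.0, 57.0],
                [50.5, 61.0, 44.0, 49.0],
            ]
        )
        rel = np.abs(y - yhat) / y
        X = np.clip(1 - rel, 0, None) if basis == "accuracy_benefit" else rel
        # naive per-row min-max (benefit / cost), proportions, entropy, weights
        r = np.empty_like(X)
        for i in range(3):
            lo, hi = X[i].min(), X[i].max()
            r[i] = (X[i] - lo) / (hi - lo) if basis == "accuracy_benefit" else (hi - X[i]) / (hi - lo)
        p = np.empty(3)
        for i in range(3):
            f = r[i] / r[i].sum()
            p[i] = -sum(fv * np.log(fv) for fv in f if fv > 0) / np.log(4)
        lam = (1 - p) / (3 - p.sum())
        result = ec.weights_from_history(y, yhat, basis=basis)
        assert np.allclose(result.weights, lam)
        assert np.allclose(result.entropies, p)
        assert result.basis == basis

    def test_bases_recorded_and_validated(self):
        y = np.array([10.0, 12.0])
        with pytest.raises(ValueError, match="basis"):
            ec.weights_from_history(y, np.ones((2, 2)), basis="nope")

    def test_positive_actuals_required(self):
        with pytest.raises(ValueError, match="positive"):
            ec.weights_from_history([1.0, -1.0], np.ones((2, 2)))
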