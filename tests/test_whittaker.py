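"""Whittaker smoother: difference matrix, banded solve, V-curve, detrending."""

import numpy as np
import pytest
import scipy.sparse
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sofismooth.whittaker import (
    DegenerateInputError,
    DifferenceSpec,
    InvalidSpecificationError,
    PixelTraceMatrix,
    SmoothingSpec,
    build_difference_matrix,
    default_lambda_grid,
    detrend_stack,
    select_lambda_vcurve,
    smooth_matrix,
    smooth_trace,
)


def dense_whittaker(y, lam, d):
    """Independent dense oracle: explicit solve of (I + lam D'D) mu = y."""
    n = y.size
    D = np.diff(np.eye(n), n=d, axis=0)
    return np.linalg.solve(np.eye(n) + lam * D.T @ D, y)


class TestDifferenceMatrix:
    def test_second_order_length_seven(self):
        D = build_difference_matrix(DifferenceSpec(n=7, d=2)).toarray()
        expected = np.array(
            [
                [1, -2, 1, 0, 0, 0, 0],
                [0, 1, -2, 1, 0, 0, 0],
                [0, 0, 1, -2, 1, 0, 0],
                [0, 0, 0, 1, -2, 1, 0],
                [0, 0, 0, 0, 1, -2, 1],
            ],
            dtype=float,
        )
        np.testing.assert_array_equal(D, expected)

    def test_first_order(self):
        D = build_difference_matrix(DifferenceSpec(n=3, d=1)).toarray()
        np.testing.assert_array_equal(D, [[1, -1, 0], [0, 1, -1]])

    @pytest.mark.parametrize("n,d", [(2, 2), (3, 3), (1, 1)])
    def test_too_short_signal_rejected(self, n, d):
        with pytest.raises(InvalidSpecificationError):
            DifferenceSpec(n=n, d=d)

    def test_sparse_representation(self):
        D = build_difference_matrix(DifferenceSpec(n=5000, d=2))
        assert scipy.sparse.issparse(D)
        assert D.shape == (4998, 5000)
        assert D.nnz == 4998 * 3


class TestSmoothTrace:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("lam", [0.1, 10.0, 1e4])
    def test_matches_dense_oracle(self, seed, lam):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(20)
        mu = smooth_trace(y, SmoothingSpec(lam, DifferenceSpec(20, 2)))
        np.testing.assert_allclose(mu, dense_whittaker(y, lam, 2), atol=1e-8)

    def test_vanishing_penalty_returns_input(self, rng):
        y = rng.standard_normal(40)
        mu = smooth_trace(y, SmoothingSpec(1e-10, DifferenceSpec(40, 2)))
        np.testing.assert_allclose(mu, y, atol=1e-8)

    def test_linear_signal_is_fixed_point(self):
        t = np.arange(30.0)
        y = 2 * t + 1
        # rounding in the banded solve grows with lam; 1e-6 covers lam = 1e8
        for lam in (1.0, 1e3, 1e8):
            mu = smooth_trace(y, SmoothingSpec(lam, DifferenceSpec(30, 2)))
            np.testing.assert_allclose(mu, y, rtol=1e-6)

    def test_large_lambda_converges_to_least_squares_line(self):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(50) + 3
        mu = smooth_trace(y, SmoothingSpec(1e12, DifferenceSpec(50, 2)))
        t = np.arange(50.0)
        line = np.polyval(np.polyfit(t, y, 1), t)
        assert np.linalg.norm(mu - line) / np.linalg.norm(line) < 1e-4

    def test_smoother_is_linear_operator(self, rng):
        spec = SmoothingSpec(50.0, DifferenceSpec(25, 2))
        y1, y2 = rng.standard_normal(25), rng.standard_normal(25)
        lhs = smooth_trace(3.0 * y1 - 2.0 * y2, spec)
        rhs = 3.0 * smooth_trace(y1, spec) - 2.0 * smooth_trace(y2, spec)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_rejects_non_finite(self):
        y = np.array([1.0, np.nan, 3.0, 4.0])
        with pytest.raises(ValueError, match="non-finite"):
            smooth_trace(y, SmoothingSpec(1.0, DifferenceSpec(4, 2)))

    def test_rejects_nonpositive_lambda(self):
        with pytest.raises(InvalidSpecificationError):
            SmoothingSpec(0.0, DifferenceSpec(10, 2))


class TestSmootherProperties:
    """Structural invariants of the penalized-least-squares smoother."""

    signals = arrays(
        np.float64,
        st.integers(5, 40),
        elements=st.floats(-1e4, 1e4, allow_nan=False, width=64),
    )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(y=signals, log_lam=st.floats(-4, 8))
    def test_residuals_sum_to_zero_and_fit_never_rougher(self, y, log_lam):
        lam = 10.0**log_lam
        spec = SmoothingSpec(lam, DifferenceSpec(y.size, 2))
        mu = smooth_trace(y, spec)
        scale = max(1.0, np.abs(y).sum())
        assert abs((y - mu).sum()) <= 1e-6 * scale
        D = build_difference_matrix(DifferenceSpec(y.size, 2)).toarray()
        assert np.sum((D @ mu) ** 2) <= np.sum((D @ y) ** 2) + 1e-9 * scale**2

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(y=signals)
    def test_objective_at_fit_not_above_objective_at_data(self, y):
        """mu-hat minimizes the penalized loss, so it beats mu = y."""
        lam = 100.0
        spec = SmoothingSpec(lam, DifferenceSpec(y.size, 2))
        mu = smooth_trace(y, spec)
        D = build_difference_matrix(DifferenceSpec(y.size, 2)).toarray()

        def loss(m):
            return np.sum((y - m) ** 2) + lam * np.sum((D @ m) ** 2)

        assert loss(mu) <= loss(y) * (1 + 1e-12) + 1e-9


class TestSmoothMatrix:
    def test_columnwise_equals_per_trace(self, rng):
        V = rng.standard_normal((60, 16))
        Y = PixelTraceMatrix(V, (4, 4))
        spec = SmoothingSpec(100.0, DifferenceSpec(60, 2))
        trend = smooth_matrix(Y, spec)
        for j in range(16):
            np.testing.assert_allclose(
                trend.fits[:, j], smooth_trace(V[:, j], spec), atol=1e-10
            )

    def test_constant_columns_unchanged(self):
        V = np.outer(np.ones(50), np.arange(1.0, 10.0))
        trend = smooth_matrix(
            PixelTraceMatrix(V, (3, 3)), SmoothingSpec(1e4, DifferenceSpec(50, 2))
        )
        np.testing.assert_allclose(trend.fits, V, rtol=1e-10)

    def test_unfold_refold_roundtrip(self, rng):
        stack = rng.normal(size=(10, 5, 7))
        Y = PixelTraceMatrix.from_stack(stack)
        np.testing.assert_array_equal(Y.to_stack(), stack)

    @pytest.mark.parametrize("lam", [1.0, 1e3, 1e6])
    def test_zero_sum_residuals(self, rng, lam):
        """The residual of every pixel sums to zero: D annihilates constants."""
        V = rng.normal(1000.0, 50.0, size=(200, 36))
        trend = smooth_matrix(
            PixelTraceMatrix(V, (6, 6)), SmoothingSpec(lam, DifferenceSpec(200, 2))
        )
        resid_sums = np.abs((V - trend.fits).sum(axis=0))
        assert np.all(resid_sums <= 1e-6 * np.abs(V.sum(axis=0)))


class TestVCurve:
    @staticmethod
    def brute_force_vcurve(V, grid, d):
        """Re-derive (f, p, v) with the dense oracle, independently."""
        n = V.shape[0]
        D = np.diff(np.eye(n), n=d, axis=0)
        f, p = [], []
        for lam in grid:
            M = np.linalg.solve(np.eye(n) + lam * D.T @ D, V)
            f.append(np.log10(np.sum((V - M) ** 2)))
            p.append(np.log10(np.sum((D @ M) ** 2)))
        f, p = np.array(f), np.array(p)
        return f, p, np.hypot(np.diff(f), np.diff(p))

    def test_matches_brute_force_on_three_point_grid(self, rng):
        t = np.arange(80.0)
        V = (np.exp(-t / 30)[:, None] * np.array([[100.0, 80.0]])
             + rng.normal(0, 2, (80, 2)))
        grid = np.array([1.0, 100.0, 10000.0])
        # a 3-point grid cannot have an interior minimum, so a warning is due
        with pytest.warns(UserWarning, match="grid edge"):
            res = select_lambda_vcurve(PixelTraceMatrix(V, (1, 2)), grid, d=2)
        f, p, v = self.brute_force_vcurve(V, grid, 2)
        np.testing.assert_allclose(res.log10_fit, f, atol=1e-8)
        np.testing.assert_allclose(res.log10_penalty, p, atol=1e-8)
        np.testing.assert_allclose(res.v, v, atol=1e-8)
        i = int(np.argmin(v))
        assert res.selected_lambda == pytest.approx(np.sqrt(grid[i] * grid[i + 1]))

    def test_white_noise_selects_interior_lambda(self, rng):
        V = rng.standard_normal((200, 16))
        res = select_lambda_vcurve(PixelTraceMatrix(V, (4, 4)))
        grid = default_lambda_grid()
        assert grid[0] < res.selected_lambda < grid[-1]
        assert res.interior

    def test_monotone_fit_and_penalty_norms(self, rng):
        V = rng.normal(100.0, 10.0, size=(150, 9))
        res = select_lambda_vcurve(PixelTraceMatrix(V, (3, 3)))
        assert np.all(np.diff(res.log10_fit) >= -1e-9)
        assert np.all(np.diff(res.log10_penalty) <= 1e-9)

    def test_linear_columns_are_degenerate(self):
        t = np.arange(50.0)
        V = np.column_stack([2 * t + 1, -0.5 * t + 4, np.full(50, 3.0)])
        with pytest.raises(DegenerateInputError, match="unnecessary"):
            select_lambda_vcurve(PixelTraceMatrix(V, (1, 3)))

    def test_short_grid_rejected(self, rng):
        Y = PixelTraceMatrix(rng.standard_normal((30, 4)), (2, 2))
        with pytest.raises(InvalidSpecificationError):
            select_lambda_vcurve(Y, np.array([1.0, 10.0]))

    def test_subsampling_bounds_columns(self, rng):
        V = rng.standard_normal((50, 100))
        res = select_lambda_vcurve(
            PixelTraceMatrix(V, (10, 10)), np.logspace(0, 4, 5), max_columns=20
        )
        assert res.n_columns_used == 20


class TestDetrendStack:
    def test_constant_stack_corrects_to_zero(self):
        stack = np.ones((40, 4, 4)) * 7.0
        corrected, trend, lam = detrend_stack(stack, "auto")
        np.testing.assert_allclose(corrected, 0.0, atol=1e-9)
        np.testing.assert_allclose(trend.fits, 7.0)

    def test_per_pixel_time_sum_vanishes(self, rng):
        stack = rng.normal(500.0, 20.0, size=(120, 5, 5))
        for lam in (1.0, 1e4):
            spec = SmoothingSpec(lam, DifferenceSpec(120, 2))
            corrected, _, _ = detrend_stack(stack, spec)
            sums = np.abs(corrected.sum(axis=0))
            bound = 1e-6 * np.abs(stack.mean(axis=0)) * stack.shape[0]
            assert np.all(sums <= bound)

    def test_removes_exponential_decay_envelope(self, rng):
        n = 300
        t = np.arange(n)
        img = rng.uniform(50, 100, (8, 8))
        stack = np.exp(-t / 100)[:, None, None] * img[None] + rng.normal(0, 1, (n, 8, 8))
        corrected, _, lam = detrend_stack(stack, "auto")
        var_ratio = corrected.var(axis=0) / stack.var(axis=0)
        assert np.all(var_ratio <= 0.05)

    def test_negative_values_preserved(self, rng):
        stack = rng.normal(10.0, 5.0, size=(50, 3, 3))
        corrected, _, _ = detrend_stack(
            stack, SmoothingSpec(1e3, DifferenceSpec(50, 2))
        )
        assert (corrected < 0).any()
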