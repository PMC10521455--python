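"""VAR(1) fitting, lagged/dynamic partial correlations and edge ranking."""

import numpy as np
import pytest

from cgrf import (
    ExpressionMatrix,
    dynamic_correlation_matrix,
    dynamic_inner_product,
    dynamic_partial_correlation,
    fit_var1,
    lagged_partial_correlation,
    lagged_partial_correlation_matrix,
    top_edges,
)


def _matrix(values, times=None):
    values = np.atleast_2d(np.asarray(values, float))
    p, T = values.shape
    if times is None:
        times = np.arange(T, dtype=float)
    return ExpressionMatrix(tuple(f"g{i}" for i in range(p)), times, values)


def simulate_var(A, T, noise_sd, seed, burn=100):
    rng = np.random.default_rng(seed)
    p = len(A)
    y = rng.normal(size=p)
    out = np.empty((p, T))
    for t in range(burn + T):
        y = A @ y + rng.normal(0.0, noise_sd, size=p)
        if t >= burn:
            out[:, t - burn] = y
    return out


class TestFitVar1:
    def test_two_point_scalar_series_solved_exactly(self):
        # pairs 1->2 and 2->4 pin down a=2, b=0
        model = fit_var1(_matrix([1.0, 2.0, 4.0]))
        assert model.A[0, 0] == pytest.approx(2.0, abs=1e-12)
        assert model.B[0] == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_coefficients_recovered(self):
        A = np.array([[0.5, 0.0], [0.3, 0.2]])
        rng = np.random.default_rng(0)
        y = rng.normal(size=2)
        vals = np.empty((2, 50))
        for t in range(50):
            vals[:, t] = y
            y = A @ y
        model = fit_var1(_matrix(vals))
        np.testing.assert_allclose(model.A, A, atol=1e-6)
        np.testing.assert_allclose(model.B, 0.0, atol=1e-6)

    def test_pure_intercept_process(self):
        rng = np.random.default_rng(1)
        vals = 3.0 + rng.normal(0.0, 0.05, size=(1, 200))
        model = fit_var1(_matrix(vals))
        se = np.sqrt(model.residual_cov[0, 0] / 199)
        assert abs(model.A[0, 0]) < 0.2
        assert model.B[0] == pytest.approx(3.0, abs=1.0)
        assert model.residual_cov[0, 0] > 0

    def test_residual_covariance_is_psd(self):
        A = 0.4 * np.eye(3)
        vals = simulate_var(A, 80, 0.5, seed=2)
        model = fit_var1(_matrix(vals))
        eigs = np.linalg.eigvalsh(model.residual_cov)
        assert eigs.min() >= -1e-8
        assert not model.rank_deficient

    def test_rank_deficient_panel_flagged(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(10, 6))  # p >= T-1
        with pytest.warns(UserWarning, match="rank deficient"):
            model = fit_var1(_matrix(vals))
        assert model.rank_deficient

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="3 time points"):
            fit_var1(_matrix([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="constant"):
            fit_var1(_matrix([[1.0, 1.0, 1.0], [1.0, 2.0, 4.0]]))


class TestLaggedPartialCorrelation:
    def test_independent_noise_stays_near_zero(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(5, 400))
        X = _matrix(vals)
        P = lagged_partial_correlation_matrix(X)
        off = P[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 0.15  # null sd ~ 1/sqrt(T)

    def test_planted_lagged_driver_detected(self):
        rng = np.random.default_rng(5)
        vals = np.empty((3, 300))
        y2 = rng.normal(size=300)
        vals[1] = y2
        vals[2] = rng.normal(size=300)
        vals[0, 0] = rng.normal()
        vals[0, 1:] = y2[:-1] + rng.normal(0.0, 0.05, size=299)
        p01 = lagged_partial_correlation(_matrix(vals), 0, 1)
        assert p01 > 0.9

    def test_matrix_form_matches_pairwise_regressions(self):
        """The precision-matrix implementation agrees with the literal
        two-regression definition on random 4-gene instances."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = _matrix(rng.normal(size=(4, 40)))
            P = lagged_partial_correlation_matrix(X)
            for i in range(4):
                for k in range(4):
                    pairwise = lagged_partial_correlation(X, i, k)
                    assert P[i, k] == pytest.approx(pairwise, abs=1e-10)

    def test_values_bounded_by_one(self):
        rng = np.random.default_rng(6)
        X = _matrix(rng.normal(size=(6, 100)))
        P = lagged_partial_correlation_matrix(X)
        assert np.all(np.abs(P) <= 1.0 + 1e-12)

    def test_edge_recovery_on_sparse_var(self):
        """On sparse stable VAR(1) panels (p=20, T=480, 10 planted
        coefficients of magnitude >= 0.4, noise sd 0.5), the 10 top-ranked
        lagged edges achieve precision >= 0.8 on average over 20 seeds."""
        precisions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            while True:
                A = np.zeros((20, 20))
                idx = rng.choice(20 * 20, size=10, replace=False)
                rows, cols = np.unravel_index(idx, (20, 20))
                keep = rows != cols
                if keep.sum() < 10:
                    continue
                A[rows, cols] = rng.choice([-1, 1], size=20)[:10] * rng.uniform(
                    0.4, 0.5, size=10
                )
                if np.max(np.abs(np.linalg.eigvals(A))) < 0.95:
                    break
            vals = simulate_var(A, 480, 0.5, seed=seed)
            P = lagged_partial_correlation_matrix(_matrix(vals))
            absP = np.abs(P)
            np.fill_diagonal(absP, 0.0)
            top = np.dstack(
                np.unravel_index(np.argsort(absP, axis=None)[::-1][:10], (20, 20))
            )[0]
            planted = {(i, j) for i, j in zip(*np.nonzero(A))}
            hit = sum((i, j) in planted for i, j in top)
            precisions.append(hit / 10.0)
        assert np.mean(precisions) >= 0.8


class TestDynamicInnerProduct:
    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(7)
        g, h = rng.normal(size=(2, 30))
        t = np.sort(rng.uniform(0, 10, size=30))
        assert dynamic_inner_product(g, h, t) == pytest.approx(
            dynamic_inner_product(h, g, t), abs=1e-12
        )

    def test_uniform_grid_weights(self):
        # on a unit-spaced grid: interior weights 1/T, end weights 1/(2T)
        T = 10
        t = np.arange(T, dtype=float)
        for j in range(T):
            e = np.zeros(T)
            e[j] = 1.0
            w = dynamic_inner_product(e, e, t)
            expected = 1.0 / (2 * T) if j in (0, T - 1) else 1.0 / T
            assert w == pytest.approx(expected, abs=1e-15)

    def test_bilinear_and_annihilates_zero(self):
        rng = np.random.default_rng(8)
        g, h, k = rng.normal(size=(3, 20))
        t = np.arange(20.0)
        assert dynamic_inner_product(g, np.zeros(20), t) == 0.0
        assert dynamic_inner_product(g, 2.0 * h + k, t) == pytest.approx(
            2.0 * dynamic_inner_product(g, h, t)
            + dynamic_inner_product(g, k, t),
            abs=1e-12,
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dynamic_inner_product([1, 2], [1, 2, 3], [0, 1, 2])


class TestDynamicCorrelation:
    def test_unit_diagonal(self):
        rng = np.random.default_rng(9)
        X = _matrix(rng.normal(size=(4, 50)))
        corr = dynamic_correlation_matrix(X)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-10)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)

    def test_negated_series_fully_anticorrelated(self):
        rng = np.random.default_rng(10)
        f = rng.normal(size=40)
        corr = dynamic_correlation_matrix(_matrix(np.vstack([f, -f])))
        assert corr[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_sine_and_cosine_orthogonal_over_full_period(self):
        t = np.linspace(0.0, 2.0 * np.pi, 2001)
        X = _matrix(np.vstack([np.sin(t), np.cos(t)]), times=t)
        corr = dynamic_correlation_matrix(X)
        assert abs(corr[0, 1]) < 0.05

    def test_converges_to_pearson_on_dense_uniform_grid(self):
        """On uniformly spaced times the trapezoid-weighted correlation
        approaches the ordinary Pearson correlation matrix."""
        rng = np.random.default_rng(11)
        T = 2000
        t = np.arange(T, dtype=float)
        base = np.cumsum(rng.normal(size=(4, T)), axis=1)  # smooth-ish walks
        vals = base + rng.normal(0, 0.5, size=(4, T))
        corr = dynamic_correlation_matrix(_matrix(vals))
        pearson = np.corrcoef(vals)
        assert np.max(np.abs(corr - pearson)) < 0.02

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            dynamic_correlation_matrix(
                _matrix([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
            )


class TestDynamicPartialCorrelation:
    def test_identity_input_identity_output(self):
        np.testing.assert_allclose(
            dynamic_partial_correlation(np.eye(4)), np.eye(4), atol=1e-12
        )

    def test_two_variables_partial_equals_marginal(self):
        for r in (-0.7, 0.0, 0.3, 0.95):
            corr = np.array([[1.0, r], [r, 1.0]])
            pcor = dynamic_partial_correlation(corr)
            assert pcor[0, 1] == pytest.approx(r, abs=1e-12)

    def test_matches_regression_residual_oracle(self):
        """Inverse-correlation partial correlations equal the correlation of
        the two variables' residuals after regressing out the third."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            raw = rng.normal(size=(3, 500))
            raw[1] += 0.5 * raw[0]
            raw[2] += -0.3 * raw[0] + 0.4 * raw[1]
            corr = np.corrcoef(raw)
            pcor = dynamic_partial_correlation(corr)
            for i, j, k in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
                zi = raw[i] - np.polyval(
                    np.polyfit(raw[k], raw[i], 1), raw[k]
                )
                zj = raw[j] - np.polyval(
                    np.polyfit(raw[k], raw[j], 1), raw[k]
                )
                oracle = np.corrcoef(zi, zj)[0, 1]
                assert pcor[i, j] == pytest.approx(oracle, abs=1e-10)

    def test_singular_input_suggests_shrinkage(self):
        corr = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            dynamic_partial_correlation(corr)
        # a positive intensity makes the computation well posed
        out = dynamic_partial_correlation(corr, shrinkage=0.1)
        assert np.all(np.isfinite(out))


class TestTopEdges:
    def test_two_edges_ranked_by_magnitude_with_signs(self):
        W = np.zeros((3, 3))
        W[1, 0] = 0.9   # edge g0 -> g1
        W[2, 1] = -0.8  # edge g1 -> g2
        el = top_edges(W, ["g0", "g1", "g2"], n_top=2, directed=True)
        assert [(e.source, e.target, e.sign, e.rank) for e in el.edges] == [
            ("g0", "g1", "+", 1),
            ("g1", "g2", "-", 2),
        ]

    def test_n_top_exceeding_edge_count_returns_all(self):
        W = np.zeros((3, 3))
        W[0, 1] = 0.5
        el = top_edges(W, ["a", "b", "c"], n_top=100, directed=True)
        assert len(el.edges) == 1

    def test_magnitude_ties_break_lexicographically(self):
        W = np.zeros((3, 3))
        W[1, 0] = 0.5  # a -> b
        W[0, 1] = -0.5  # b -> a
        W[2, 0] = 0.5  # a -> c
        el = top_edges(W, ["a", "b", "c"], n_top=3, directed=True)
        assert [(e.source, e.target) for e in el.edges] == [
            ("a", "b"),
            ("a", "c"),
            ("b", "a"),
        ]

    def test_undirected_uses_upper_triangle_only(self):
        W = np.array([[1.0, 0.4, 0.0], [0.4, 1.0, -0.6], [0.0, -0.6, 1.0]])
        el = top_edges(W, ["a", "b", "c"], n_top=10, directed=False)
        assert len(el.edges) == 2
        assert el.edges[0].weight == pytest.approx(-0.6)

    def test_self_loops_excluded_by_default(self):
        W = np.diag([0.9, 0.9])
        assert top_edges(W, ["a", "b"], n_top=5).edges == ()
        assert (
            len(top_edges(W, ["a", "b"], n_top=5, include_self_loops=True).edges)
            == 2
        )
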