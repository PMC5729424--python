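import numpy as np
import pandas as pd
import pytest
import scipy.stats

import envscreen as es
from envscreen.spatial import (
    SpatialWeights,
    gaussian_loglik,
    lr_test_lambda,
    morans_i,
    nagelkerke_r2,
    sar_error_fit,
    select_model,
)


def _simulate_sar(weights, lam, beta, sigma, seed, x=None):
    rng = np.random.default_rng(seed)
    n = weights.n
    if x is None:
        x = rng.standard_normal((n, len(beta)))
    w = weights.dense()
    eps = sigma * rng.standard_normal(n)
    u = np.linalg.solve(np.eye(n) - lam * w, eps)
    return x, x @ np.asarray(beta) + u


class TestWeights:
    def test_grid_neighbor_counts(self):
        rook = SpatialWeights.grid(3, 3, scheme="rook")
        assert rook.cardinality("g0_0") == 2
        assert rook.cardinality("g1_1") == 4
        queen = SpatialWeights.grid(3, 3, scheme="queen")
        assert queen.cardinality("g1_1") == 8
        assert queen.cardinality("g0_0") == 3

    def test_row_standardized_rows_sum_to_one(self):
        w = SpatialWeights.grid(4, 5, scheme="queen")
        assert np.allclose(w.dense().sum(axis=1), 1.0)

    def test_symmetry_enforced_by_union(self):
        w = SpatialWeights(["a", "b"], {"a": ["b"], "b": []})
        assert w.neighbors["b"] == ["a"]

    def test_islands_flagged(self):
        w = SpatialWeights(["a", "b", "c"], {"a": ["b"], "b": ["a"], "c": []})
        assert w.islands == ["c"]

    def test_gal_roundtrip(self, tmp_path):
        w = SpatialWeights.grid(3, 4, scheme="rook")
        p = tmp_path / "grid.gal"
        w.write_gal(p)
        back = SpatialWeights.read_gal(p)
        assert back.ids == w.ids
        assert back.neighbors == w.neighbors

    def test_polygon_contiguity_queen_vs_rook(self):
        def square(x, y):
            return {"type": "Polygon",
                    "coordinates": [[[x, y], [x + 1, y], [x + 1, y + 1],
                                     [x, y + 1], [x, y]]]}

        polys = {"a": square(0, 0), "b": square(1, 0),
                 "c": square(0, 1), "d": square(1, 1)}
        queen = SpatialWeights.from_polygons(polys, scheme="queen")
        rook = SpatialWeights.from_polygons(polys, scheme="rook")
        assert queen.cardinality("a") == 3  # corner contact counts
        assert rook.cardinality("a") == 2

    def test_knn_symmetrized(self):
        coords = {"a": (0, 0), "b": (1, 0), "c": (10, 0), "d": (11, 0)}
        w = SpatialWeights.knn(coords, k=1)
        assert "b" in w.neighbors["a"] and "a" in w.neighbors["b"]

    def test_eigenvalues_match_dense_spectrum(self):
        w = SpatialWeights.grid(4, 4, scheme="queen")
        direct = np.sort(np.linalg.eigvals(w.dense()).real)
        assert np.allclose(np.sort(w.eigenvalues()), direct, atol=1e-8)


class TestMoran:
    def test_checkerboard_is_exactly_minus_one(self):
        w = SpatialWeights.grid(6, 6, scheme="rook")
        vals = np.array([(-1.0) ** (r + c) for r in range(6) for c in range(6)])
        res = morans_i(vals, w, n_perm=99, seed=0)
        # algebraic oracle: every neighbor has opposite sign, so Wz = -z
        # and z'Wz = -z'z, giving I = -1 under row standardization
        assert res.I == pytest.approx(-1.0, abs=1e-10)
        assert res.p_value < 0.05

    def test_block_structure_strongly_positive(self):
        w = SpatialWeights.grid(8, 8, scheme="rook")
        vals = np.array([1.0 if c < 4 else -1.0
                         for r in range(8) for c in range(8)])
        vals += 0.01 * np.random.default_rng(0).standard_normal(64)
        res = morans_i(vals, w, n_perm=999, seed=1)
        assert res.I > 0.5 and res.p_value < 0.01

    def test_null_permutation_p_uniform(self):
        w = SpatialWeights.grid(7, 7, scheme="queen")
        rng = np.random.default_rng(99)
        ps = [morans_i(rng.standard_normal(49), w, n_perm=199, seed=s).p_value
              for s in range(200)]
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_errors_on_constant_or_island(self):
        w = SpatialWeights.grid(3, 3)
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(9), w)
        wi = SpatialWeights(["a", "b", "c"], {"a": ["b"], "b": ["a"], "c": []})
        with pytest.raises(ValueError, match="island"):
            morans_i(np.array([1.0, 2.0, 3.0]), wi)


class TestSARFit:
    def test_lambda_zero_data_reduces_to_ols(self):
        w = SpatialWeights.grid(10, 10)
        x, y = _simulate_sar(w, 0.0, [1.0, -0.5], 0.5, seed=1)
        fit = sar_error_fit(y, x, w)
        beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
        assert abs(fit.lambda_) < 0.2
        assert np.allclose(fit.coef_, beta_ols, atol=1e-2)
        # exact OLS match when lambda is pinned to zero numerically
        ll0 = fit._profile(0.0, w.dense(), w.eigenvalues(), y, x)
        assert np.allclose(ll0[1], beta_ols, atol=1e-10)

    def test_empty_adjacency_equals_gaussian_likelihood(self):
        ids = [f"u{i}" for i in range(30)]
        w = SpatialWeights(ids, {i: [] for i in ids})
        rng = np.random.default_rng(3)
        x = rng.standard_normal((30, 2))
        y = x @ np.array([1.0, 2.0]) + rng.standard_normal(30)
        fit = sar_error_fit(y, x, w)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        assert fit.loglik_ == pytest.approx(gaussian_loglik(y - x @ beta), abs=1e-6)

    def test_recovers_moderate_dependence(self):
        w = SpatialWeights.grid(15, 15)
        x, y = _simulate_sar(w, 0.6, [0.5, 0.6], 0.3, seed=7)
        fit = sar_error_fit(y, pd.DataFrame(x, columns=["a", "b"]), w)
        assert fit.lambda_ == pytest.approx(0.6, abs=0.2)
        assert fit.names_ == ["a", "b"]
        assert abs(fit.coef_[0] - 0.5) < 3 * fit.stderr_[0]
        assert fit.lr_lambda_p_ < 0.01

    def test_bic_identity_and_parameter_count(self):
        w = SpatialWeights.grid(8, 8)
        x, y = _simulate_sar(w, 0.3, [1.0], 0.5, seed=2)
        fit = sar_error_fit(y, x, w)
        assert fit.k_ == 3  # beta + lambda + sigma2
        assert fit.bic_ == pytest.approx(-2 * fit.loglik_ + 3 * np.log(64), abs=1e-8)

    def test_standardized_coefficient_invariant_to_predictor_scaling(self):
        from envscreen.transforms import standardize

        w = SpatialWeights.grid(9, 9)
        x, y = _simulate_sar(w, 0.4, [0.8], 0.4, seed=5)
        f1 = sar_error_fit(y, standardize(x[:, 0]), w)
        f2 = sar_error_fit(y, standardize(x[:, 0] * 37.0), w)
        assert f1.coef_[0] == pytest.approx(f2.coef_[0], abs=1e-8)

    def test_singular_design_rejected(self):
        w = SpatialWeights.grid(5, 5)
        x = np.ones((25, 2))
        with pytest.raises(ValueError, match="singular"):
            sar_error_fit(np.random.default_rng(0).standard_normal(25), x, w)

    def test_filtered_residuals_pass_moran_diagnostic(self):
        w = SpatialWeights.grid(10, 10)
        hits = 0
        for seed in range(20):
            x, y = _simulate_sar(w, 0.6, [0.5], 0.3, seed=seed)
            fit = sar_error_fit(y, x, w)
            res = fit.residual_moran(n_perm=199, seed=seed)
            hits += res.p_value > 0.05
        assert hits >= 18  # >= 90% of seeds show no residual autocorrelation


class TestLikelihoodRatioAndR2:
    def test_lr_known_values(self):
        assert lr_test_lambda(10.0, 10.0) == pytest.approx(1.0)
        assert lr_test_lambda(11.92, 10.0) == pytest.approx(
            scipy.stats.chi2.sf(3.84, 1), abs=1e-12)
        with pytest.raises(ValueError):
            lr_test_lambda(9.0, 10.0)

    def test_lambda_power_against_strong_dependence(self):
        w = SpatialWeights.grid(12, 12)
        sig = 0
        for s in range(20):
            x, y = _simulate_sar(w, 0.7, [0.5], 0.3, seed=s)
            sig += sar_error_fit(y, x, w).lr_lambda_p_ < 0.01
        assert sig >= 19  # lambda detected in >= 95% of seeds

    def test_nagelkerke_bounds_and_null(self):
        assert nagelkerke_r2(-50.0, -50.0, 100) == 0.0
        # near-perfect fit approaches 1
        n = 200
        ll_perfect = -0.5 * n * (np.log(2 * np.pi * 1e-12) + 1)
        ll_null = -0.5 * n * (np.log(2 * np.pi * 1.0) + 1)
        assert nagelkerke_r2(ll_perfect, ll_null, n) > 0.99
        with pytest.raises(ValueError):
            nagelkerke_r2(-60.0, -50.0, 100)

    def test_gaussian_regression_known_r2(self):
        rng = np.random.default_rng(8)
        n = 4000
        x = rng.standard_normal(n)
        y = x + rng.standard_normal(n)  # population R^2 = 0.5
        beta, *_ = np.linalg.lstsq(x[:, None], y, rcond=None)
        resid = y - beta[0] * x
        ll1 = gaussian_loglik(resid)
        ll0 = gaussian_loglik(y - y.mean())
        r2_ols = 1.0 - resid.var() / y.var()  # closed-form OLS R^2 oracle
        assert nagelkerke_r2(ll1, ll0, n) == pytest.approx(r2_ols, abs=0.05)


class TestSelection:
    def test_pure_noise_candidates_all_dropped(self):
        w = SpatialWeights.grid(10, 10)
        rng = np.random.default_rng(21)
        y = rng.standard_normal(100)
        cand = pd.DataFrame(rng.standard_normal((100, 3)),
                            columns=["a", "b", "c"])
        sel = select_model(y, cand, w)
        assert sel.terms == []

    def test_selected_bic_not_worse_than_full(self):
        w = SpatialWeights.grid(10, 10)
        x, y = _simulate_sar(w, 0.4, [0.8, 0.0, 0.6], 0.4, seed=13)
        cand = pd.DataFrame(x, columns=["a", "noise", "b"])
        sel = select_model(y, cand, w)
        full = sar_error_fit(y, cand.assign(intercept=1.0), w)
        assert sel.model.bic_ <= full.bic_ + 1e-9
        assert "noise" not in sel.terms
        assert {"a", "b"} <= set(sel.terms)

    def test_trace_and_ablation_recorded(self):
        w = SpatialWeights.grid(8, 8)
        x, y = _simulate_sar(w, 0.3, [1.0, 0.9], 0.3, seed=17)
        cand = pd.DataFrame(x, columns=["a", "b"])
        sel = select_model(y, cand, w)
        frame = sel.trace_frame()
        assert {"action", "term", "bic", "delta_bic", "p"} <= set(frame.columns)
        for term in sel.terms:
            assert sel.r2_ablation[term] <= sel.model.nagelkerke_r2_ + 1e-9
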