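import numpy as np
import pandas as pd
import pytest

from zoomacro import gam
from zoomacro.gam import GAMFit, backward_select, basis_dimension_rule, \
    build_basis, extract_curves, fit_additive_model, fit_latitude_gam, \
    predict, term_significance


def _deboor(t, c, p, x):
    """Independent B-spline evaluation via the de Boor recursion."""
    n = len(t) - p - 1
    out = np.zeros_like(x, dtype=float)
    for i, xv in enumerate(x):
        k = np.searchsorted(t, xv, side="right") - 1
        k = min(max(k, p), n - 1)
        d = [c[j + k - p] for j in range(p + 1)]
        for r in range(1, p + 1):
            for j in range(p, r - 1, -1):
                denom = t[j + 1 + k - r] - t[j + k - p]
                alpha = 0.0 if denom == 0 else (xv - t[j + k - p]) / denom
                d[j] = (1.0 - alpha) * d[j - 1] + alpha * d[j]
        out[i] = d[p]
    return out


class TestBasisDimensionRule:
    @pytest.mark.parametrize("n,p,k", [(100, 10, 10), (35, 10, 3),
                                       (400, 10, 40), (45, 10, 4)])
    def test_floor_of_ratio_clipped_at_minimum(self, n, p, k):
        assert basis_dimension_rule(n, p) == k

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            basis_dimension_rule(5, 10)


class TestBuildBasis:
    def test_partition_of_unity(self, rng):
        x = rng.uniform(-3, 7, 60)
        b = build_basis(x, 8)
        B = b.raw_matrix(x)
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_penalty_annihilates_straight_lines(self, rng):
        x = rng.uniform(0, 1, 50)
        b = build_basis(x, 8)
        # raw coefficients following a line have zero second differences
        D2 = np.diff(np.eye(8), n=2, axis=0)
        line_coef = 2.0 + 3.0 * np.arange(8)
        assert np.allclose(D2 @ line_coef, 0.0)
        # and the centred penalty has a one-dimensional null space
        assert b.null_dim == 1

    def test_matches_de_boor_recursion(self):
        x = np.linspace(0, 1, 10)
        b = build_basis(x, 5)
        # evaluate strictly inside the support so both routes see the same
        # points (the right boundary is half-open for B-splines)
        xe = np.clip(x, None, 1 - 1e-9)
        B = b.raw_matrix(xe)
        for j in range(b.k):
            c = np.zeros(b.k)
            c[j] = 1.0
            ref = _deboor(b.knots, c, b.degree, xe)
            assert np.allclose(B[:, j], ref, atol=1e-9)

    def test_needs_enough_distinct_values(self):
        with pytest.raises(ValueError):
            build_basis(np.array([1.0, 1, 1, 2, 2]), 5)


class TestFitAdditiveModel:
    def test_exact_linear_signal_unpenalized(self, rng):
        x = rng.uniform(0, 1, 80)
        y = 2.0 + 3.0 * x
        fit = fit_additive_model(y, pd.DataFrame({"x": x}), k=10)
        assert fit.pct_dev >= 0.999
        cur = extract_curves(fit).curves["x"]
        line = 3.0 * (cur.x - cur.x.mean())
        assert np.sqrt(np.mean((cur.value - line) ** 2)) <= 1e-3

    def test_sine_recovery(self):
        r = np.random.default_rng(0)
        x = r.uniform(0, 1, 200)
        y = np.sin(2 * np.pi * x) + r.normal(0, 0.1, 200)
        fit = fit_additive_model(y, pd.DataFrame({"x": x}))
        cur = extract_curves(fit).curves["x"]
        target = np.sin(2 * np.pi * cur.x)
        target = target - target.mean()
        assert np.sqrt(np.mean((cur.value - target) ** 2)) <= 0.1

    def test_pct_dev_agrees_with_rss_over_tss(self, rng):
        x = rng.uniform(0, 1, (120, 2))
        y = np.sin(3 * x[:, 0]) + rng.normal(0, 0.3, 120)
        cov = pd.DataFrame(x, columns=["a", "b"])
        fit = fit_additive_model(y, cov)
        mu, _ = predict(fit, cov)
        rss = float(np.sum((y - mu) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        assert fit.pct_dev == pytest.approx(1 - rss / tss, abs=1e-10)
        sigma2 = rss / (len(y) - fit.edf_total)
        assert fit.adj_r2 == pytest.approx(1 - sigma2 / (tss / (len(y) - 1)),
                                           abs=1e-10)

    def test_affine_covariate_rescaling_invariance(self, rng):
        x = rng.uniform(0, 1, 100)
        y = np.sin(4 * x) + rng.normal(0, 0.2, 100)
        f1 = fit_additive_model(y, pd.DataFrame({"x": x}), k=12)
        f2 = fit_additive_model(y, pd.DataFrame({"x": 100 * x - 40}), k=12)
        assert f1.pct_dev == pytest.approx(f2.pct_dev, abs=1e-8)
        c1 = extract_curves(f1).curves["x"].value
        c2 = extract_curves(f2).curves["x"].value
        assert np.allclose(c1, c2, atol=1e-8)

    def test_complete_case_filtering(self, rng):
        x = rng.uniform(0, 1, 60)
        y = x + rng.normal(0, 0.1, 60)
        x[:5] = np.nan
        fit = fit_additive_model(y, pd.DataFrame({"x": x}), k=8)
        assert fit.n_obs == 55

    def test_too_few_observations_raise(self, rng):
        with pytest.raises(ValueError):
            fit_additive_model(rng.normal(0, 1, 8),
                               pd.DataFrame({"x": rng.uniform(0, 1, 8)}), k=4)


class TestTermSignificance:
    def test_signal_outranks_noise(self):
        wins = 0
        for s in range(20):
            r = np.random.default_rng(s)
            X = pd.DataFrame(r.uniform(0, 1, (150, 3)),
                             columns=["sig", "n1", "n2"])
            y = np.sin(2 * np.pi * X.sig) + r.normal(0, 0.3, 150)
            fit = fit_additive_model(y, X)
            wins += term_significance(fit).covariate.iloc[0] == "sig"
        assert wins >= 19

    def test_ranking_invariant_under_covariate_reordering(self):
        r = np.random.default_rng(3)
        X = pd.DataFrame(r.uniform(0, 1, (120, 3)), columns=["a", "b", "c"])
        y = np.sin(2 * np.pi * X.a) + X.b ** 2 + r.normal(0, 0.2, 120)
        f1 = fit_additive_model(y, X)
        f2 = fit_additive_model(y, X[["c", "b", "a"]])
        r1 = term_significance(f1).set_index("covariate")["rank"]
        r2 = term_significance(f2).set_index("covariate")["rank"]
        assert (r1.sort_index() == r2.sort_index()).all()

    def test_dropped_terms_rank_last_with_p_one(self):
        r = np.random.default_rng(1)
        X = pd.DataFrame(r.uniform(0, 1, (100, 2)), columns=["sig", "noise"])
        y = 2 * X.sig + r.normal(0, 0.2, 100)
        fit = backward_select(fit_additive_model(y, X))
        tab = term_significance(fit)
        dropped = tab[tab.dropped]
        if len(dropped):
            assert (dropped.p == 1.0).all()
            assert dropped["rank"].min() > tab[~tab.dropped]["rank"].max()


class TestBackwardSelect:
    def test_all_significant_model_unchanged(self):
        r = np.random.default_rng(2)
        X = pd.DataFrame(r.uniform(0, 1, (150, 2)), columns=["a", "b"])
        y = np.sin(2 * np.pi * X.a) + 2 * X.b + r.normal(0, 0.2, 150)
        fit = fit_additive_model(y, X)
        out = backward_select(fit)
        assert not any(t.dropped for t in out.terms)

    def test_noise_covariate_removed(self):
        removed = 0
        for s in range(20):
            r = np.random.default_rng(s)
            X = pd.DataFrame(r.uniform(0, 1, (150, 3)),
                             columns=["s1", "s2", "noise"])
            y = np.sin(2 * np.pi * X.s1) + X.s2 + r.normal(0, 0.3, 150)
            out = backward_select(fit_additive_model(y, X))
            removed += out.term("noise").dropped
        # a ~5% per-term false-positive rate is inherent to alpha = 0.05
        assert removed >= 16

    def test_pure_noise_tends_to_intercept_only(self):
        hits = 0
        for s in range(15):
            r = np.random.default_rng(s)
            X = pd.DataFrame(r.uniform(0, 1, (100, 5)), columns=list("abcde"))
            y = r.normal(0, 1, 100)
            out = backward_select(fit_additive_model(y, X))
            hits += all(t.dropped for t in out.terms)
        assert hits >= 8
        # intercept-only limit: no deviance explained
        assert GAMFit is not None

    def test_intercept_only_has_zero_pct_dev(self):
        r = np.random.default_rng(7)
        x = r.uniform(0, 1, 60)
        y = r.normal(0, 1, 60)
        fit = fit_additive_model(y, pd.DataFrame({"x": x}), k=6)
        forced = gam._intercept_only(fit, ["x"])
        assert forced.pct_dev == 0.0
        assert forced.intercept == pytest.approx(y.mean())


class TestCurves:
    def test_every_curve_has_100_points_spanning_range(self):
        r = np.random.default_rng(5)
        X = pd.DataFrame(r.uniform(-2, 3, (80, 2)), columns=["a", "b"])
        y = X.a + r.normal(0, 0.2, 80)
        cs = extract_curves(fit_additive_model(y, X, k=8))
        for name, df in cs.curves.items():
            assert len(df) == 100
            assert df.x.iloc[0] == pytest.approx(X[name].min())
            assert df.x.iloc[-1] == pytest.approx(X[name].max())
            assert df.value.mean() == pytest.approx(0.0, abs=1e-8)

    def test_dropped_term_yields_zero_curve(self):
        r = np.random.default_rng(6)
        X = pd.DataFrame(r.uniform(0, 1, (150, 2)), columns=["sig", "noise"])
        y = np.sin(2 * np.pi * X.sig) + r.normal(0, 0.2, 150)
        out = backward_select(fit_additive_model(y, X))
        if out.term("noise").dropped:
            cur = extract_curves(out).curves["noise"]
            assert np.all(cur.value == 0.0)
            assert np.all(cur.se == 0.0)

    def test_linear_term_curve_is_affine_ramp(self, rng):
        x = rng.uniform(0, 2, 100)
        y = 1.0 + 4.0 * x
        cur = extract_curves(
            fit_additive_model(y, pd.DataFrame({"x": x}), k=10)).curves["x"]
        expected_span = 4.0 * (x.max() - x.min())
        assert cur.value.max() - cur.value.min() == pytest.approx(
            expected_span, rel=1e-4)


class TestLatitudeGAM:
    def test_constant_response_flat_prediction(self, rng):
        lat = rng.uniform(-60, 60, 40)
        y = np.full(40, 3.0) + rng.normal(0, 1e-9, 40)
        fit, curve = fit_latitude_gam(y, lat)
        assert np.ptp(curve.fit.to_numpy()) <= 1e-6
        assert fit.adj_r2 <= 1e-6

    def test_bimodal_abundance_recovered(self, rng):
        lat = rng.uniform(-80, 80, 150)
        y = (np.exp(-((np.abs(lat) - 70) / 15) ** 2)
             + np.exp(-(lat / 12) ** 2) + rng.normal(0, 0.05, 150))
        fit, curve = fit_latitude_gam(y, lat)
        v = curve.fit.to_numpy()
        interior = v[1:-1]
        is_max = (interior > v[:-2]) & (interior > v[2:])
        assert is_max.sum() >= 2

    def test_prediction_interpolates_fitted_values(self, rng):
        lat = rng.uniform(-60, 60, 50)
        y = np.cos(np.radians(lat)) + rng.normal(0, 0.05, 50)
        fit, _ = fit_latitude_gam(y, lat)
        mu, se = predict(fit, pd.DataFrame({"latitude": lat}))
        resid = y - mu
        assert fit.pct_dev == pytest.approx(
            1 - np.sum(resid ** 2) / np.sum((y - y.mean()) ** 2), abs=1e-8)
        assert (se > 0).all()

    def test_under_threshold_returns_none(self, rng):
        out = fit_latitude_gam(rng.normal(0, 1, 20), rng.uniform(-60, 60, 20))
        assert out is None
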