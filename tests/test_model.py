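import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import plateausdm as ps
from plateausdm.model import (MCMCConfig, PlateauParams, convergence_diagnostics,
                              log_likelihood, plateau_response,
                              presence_probability)


def params(beta0=0.0, c1=(0.3,), c2=(0.6,), b1=(10.0,), b2=(20.0,)):
    return PlateauParams(beta0, np.array(c1), np.array(c2),
                         np.array(b1), np.array(b2))


class TestPlateauResponse:
    @pytest.mark.parametrize("x, expected", [
        (0.45, 0.0),          # plateau interior
        (0.3, 0.0),           # left edge
        (0.2, -1.0),          # b1 * (0.3 - 0.2) = 1
        (0.7, -2.0),          # b2 * (0.7 - 0.6) = 2
    ])
    def test_arithmetic(self, x, expected):
        assert plateau_response(x, 0.3, 0.6, 10.0, 20.0) == pytest.approx(expected)

    @given(x=st.floats(-2, 3), c1=st.floats(0, 1), width=st.floats(0, 1),
           b1=st.floats(0, 50), b2=st.floats(0, 50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_shape_properties(self, x, c1, width, b1, b2):
        c2 = c1 + width
        f = plateau_response(x, c1, c2, b1, b2)
        assert f <= 0.0
        if c1 <= x <= c2:
            assert f == 0.0
        elif b1 > 1e-6 and b2 > 1e-6 and (x < c1 - 1e-9 or x > c2 + 1e-9):
            assert f < 0.0
        # continuity at the edges
        eps = 1e-9
        assert abs(plateau_response(c1 - eps, c1, c2, b1, b2)) < 1e-6 * (1 + b1)
        assert abs(plateau_response(c2 + eps, c1, c2, b1, b2)) < 1e-6 * (1 + b2)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="c1 <= c2"):
            params(c1=(0.8,), c2=(0.2,))
        with pytest.raises(ValueError, match="non-negative"):
            params(b1=(-1.0,))


class TestPresenceProbability:
    def test_on_plateau_equals_half_at_zero_intercept(self):
        p = presence_probability(np.array([[0.45]]), params(beta0=0.0))
        assert p[0] == pytest.approx(0.5)

    def test_far_beyond_edge_goes_to_zero(self):
        p = presence_probability(np.array([[5.0]]), params(beta0=0.0))
        assert p[0] < 1e-12 or p[0] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_beyond_descending_edge(self):
        p = presence_probability(np.array([[0.7], [0.8]]), params())
        assert p[1] < p[0]

    def test_missing_predictor_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            presence_probability(np.array([[np.nan]]), params())


class TestLogLikelihood:
    def test_null_model_is_n_log_half(self):
        n = 12
        y = np.array([1.0] * 6 + [0.0] * 6)
        X = np.full((n, 1), 0.45)
        assert log_likelihood(y, X, params(beta0=0.0)) == pytest.approx(
            n * np.log(0.5))

    def test_perfect_separation_bounded(self):
        y = np.array([1.0, 0.0])
        X = np.array([[0.45], [0.95]])
        ll = log_likelihood(y, X, params(beta0=30.0, b2=(300.0,)))
        assert -1e-6 < ll <= 0.0

    def test_matches_pointwise_sum_oracle(self, rng):
        p = params(beta0=0.7, c1=(0.2, 0.4), c2=(0.5, 0.8),
                   b1=(3.0, 8.0), b2=(5.0, 2.0))
        X = rng.uniform(0, 1, (10, 2))
        y = rng.integers(0, 2, 10).astype(float)
        expected = 0.0
        for i in range(10):
            lp = p.beta0
            for j in range(2):
                lp += -p.b1[j] * max(0.0, p.c1[j] - X[i, j]) \
                      - p.b2[j] * max(0.0, X[i, j] - p.c2[j])
            pr = 1.0 / (1.0 + np.exp(-lp))
            expected += y[i] * np.log(pr) + (1 - y[i]) * np.log(1 - pr)
        assert log_likelihood(y, X, p) == pytest.approx(expected, rel=1e-9)

    def test_invariant_under_data_permutation(self, rng):
        p = params()
        X = rng.uniform(0, 1, (30, 1))
        y = rng.integers(0, 2, 30).astype(float)
        perm = rng.permutation(30)
        assert log_likelihood(y, X, p) == pytest.approx(
            log_likelihood(y[perm], X[perm], p), rel=1e-12)


class TestPriors:
    def test_naive_edges_span_unit_interval(self):
        prior = ps.build_prior("naive", predictors=["a", "b"])
        for e in prior.predictors:
            assert e.mode == "free"
            assert e.c1_bounds == (0.0, 1.0)
            assert e.c2_bounds == (0.0, 1.0)

    def test_informed_restricts_constrained_predictors_only(self, prepped):
        prior = ps.build_prior("informed", ps.default_constraints(),
                               prepped.transform)
        tr = prepped.transform
        temp = prior.entry("temp_mean")
        lo = tr.normalize_value("temp_mean", 15.0)
        hi = tr.normalize_value("temp_mean", 18.0)
        assert temp.c1_bounds == pytest.approx((lo, hi))
        assert temp.b2_link_limit == pytest.approx(
            tr.normalize_value("temp_mean", 26.0))
        depth = prior.entry("depth")
        assert depth.c2_fixed == pytest.approx(
            tr.normalize_value("depth", 40.0))
        # salinity / current / distance remain unconstrained
        for name in ("salinity", "velocity", "dist_shore", "temp_range"):
            assert prior.entry(name).mode == "free"

    def test_unknown_constraint_predictor_is_error(self, prepped):
        con = [ps.PhysioConstraint("oxygen", (1.0, 2.0), 5.0)]
        with pytest.raises(ValueError, match="oxygen"):
            ps.build_prior("informed", con, prepped.transform)

    def test_constraint_outside_observed_range_is_error(self, prepped):
        con = [ps.PhysioConstraint("temp_mean", (40.0, 45.0), 50.0)]
        with pytest.raises(ValueError, match="outside"):
            ps.build_prior("informed", con, prepped.transform)

    def test_constraint_table_invariants(self):
        with pytest.raises(ValueError, match="hard limit"):
            ps.PhysioConstraint("temp_mean", (15.0, 18.0), 16.0, "upper")


class TestFit:
    @pytest.fixture(scope="class")
    def tiny_data(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (120, 2))
        truth = params(beta0=2.0, c1=(0.3, 0.2), c2=(0.6, 0.5),
                       b1=(10.0, 8.0), b2=(12.0, 9.0))
        y = (rng.uniform(size=120) < presence_probability(X, truth)).astype(float)
        return y, X

    def test_retained_draw_count(self, tiny_data):
        y, X = tiny_data
        prior = ps.build_prior("naive", predictors=["u", "v"])
        res = ps.PlateauModel(y, X, ["u", "v"], prior).fit(
            MCMCConfig(n_iter=150, n_warmup=100, seed=1))
        assert res.n_draws == 50
        assert res.n_chains == 2

    def test_seed_determinism(self, tiny_data):
        y, X = tiny_data
        prior = ps.build_prior("naive", predictors=["u", "v"])
        model = ps.PlateauModel(y, X, ["u", "v"], prior)
        r1 = model.fit(MCMCConfig(n_iter=120, n_warmup=80, seed=42))
        r2 = model.fit(MCMCConfig(n_iter=120, n_warmup=80, seed=42))
        for name in r1.draws:
            assert np.array_equal(r1.draws[name], r2.draws[name])

    def test_draws_respect_parameter_supports(self, quick_fit):
        res = quick_fit
        for name in res.names:
            assert (res.flat(f"b1[{name}]") >= 0).all()
            assert (res.flat(f"b2[{name}]") >= 0).all()
            assert (res.flat(f"c1[{name}]") <= res.flat(f"c2[{name}]")
                    + 1e-12).all()
            assert (res.flat(f"c1[{name}]") >= 0).all()
            assert (res.flat(f"c2[{name}]") <= 1).all()

    def test_informed_draws_respect_constraint_box(self, prepped):
        prior = ps.build_prior("informed", ps.default_constraints(),
                               prepped.transform)
        model = ps.PlateauModel(prepped.y, prepped.X, prepped.names, prior)
        res = model.fit(MCMCConfig(n_iter=150, n_warmup=100, seed=3))
        tr = prepped.transform
        lo = tr.normalize_value("temp_mean", 15.0) - 1e-9
        hi = tr.normalize_value("temp_mean", 18.0) + 1e-9
        assert (res.flat("c1[temp_mean]") >= lo).all()
        assert (res.flat("c2[temp_mean]") <= hi).all()
        assert np.allclose(res.flat("c2[depth]"),
                           tr.normalize_value("depth", 40.0))
        # linked slope satisfied draw-by-draw
        L = prior.floor_logit
        lim = prior.entry("temp_mean").b2_link_limit
        expect = (res.flat("beta0") - L) / (lim - res.flat("c2[temp_mean]"))
        assert np.allclose(res.flat("b2[temp_mean]"), expect)

    def test_single_label_data_is_error(self):
        prior = ps.build_prior("naive", predictors=["u"])
        with pytest.raises(ValueError, match="both"):
            ps.PlateauModel(np.ones(10), np.random.rand(10, 1), ["u"], prior)

    def test_save_load_roundtrip(self, quick_fit, tmp_path):
        quick_fit.save(tmp_path / "post.csv")
        back = ps.PlateauResults.load(tmp_path / "post.csv")
        assert back.names == quick_fit.names
        for name in quick_fit.draws:
            assert np.allclose(back.draws[name], quick_fit.draws[name])
        X = np.full((3, len(quick_fit.names)), 0.5)
        assert np.allclose(back.predict_mean(X), quick_fit.predict_mean(X))


class TestPosteriorPredict:
    def test_degenerate_posterior_zero_width(self, tiny_draws):
        res = tiny_draws
        for name in res.draws:
            res.draws[name][:] = res.draws[name].reshape(-1)[0]
        X = np.full((4, len(res.names)), 0.4)
        mean, lo, hi = res.predict(X)
        assert np.allclose(lo, hi)
        assert np.allclose(mean, lo)

    def test_interval_brackets_mean(self, quick_fit, rng):
        X = rng.uniform(0, 1, (6, len(quick_fit.names)))
        mean, lo, hi = quick_fit.predict(X)
        assert (lo <= mean + 1e-12).all()
        assert (mean <= hi + 1e-12).all()
        assert (mean >= 0).all() and (mean <= 1).all()

    def test_matches_direct_draw_average(self, quick_fit, rng):
        """Brute-force draw-by-draw averaging over 5 cells x 50 draws."""
        X = rng.uniform(0, 1, (5, len(quick_fit.names)))
        mean = quick_fit.predict_mean(X, thin_to=50)
        pts = list(quick_fit.param_points(thin_to=50))
        assert len(pts) == 50
        direct = np.zeros(5)
        for p in pts:
            lp = np.full(5, p.beta0)
            for j in range(X.shape[1]):
                lp += -p.b1[j] * np.maximum(0, p.c1[j] - X[:, j]) \
                      - p.b2[j] * np.maximum(0, X[:, j] - p.c2[j])
            direct += expit(lp)
        assert np.allclose(mean, direct / 50, atol=1e-12)


@pytest.fixture()
def tiny_draws(quick_fit):
    """A deep-copied small results object safe to mutate."""
    draws = {k: v[:, :20].copy() for k, v in quick_fit.draws.items()}
    return ps.PlateauResults(quick_fit.model, quick_fit.config, draws,
                             quick_fit.accept_rates)


class TestDiagnostics:
    def test_iid_normal_chains_have_unit_rhat(self, rng):
        draws = {"theta": rng.standard_normal((2, 800))}
        out = convergence_diagnostics(draws)
        assert out.loc["theta", "r_hat"] == pytest.approx(1.0, abs=0.05)

    def test_offset_chain_warns(self, rng):
        arr = rng.standard_normal((2, 400))
        arr[1] += 10.0
        with pytest.warns(UserWarning, match="R-hat"):
            out = convergence_diagnostics({"theta": arr})
        assert out.loc["theta", "r_hat"] > 1.5

    def test_ess_bounded_by_total_draws(self, quick_fit):
        out = quick_fit.diagnostics()
        total = quick_fit.n_chains * quick_fit.n_draws
        assert (out["ess"] <= total * 1.05).all()

    def test_single_chain_is_error(self, rng):
        with pytest.raises(ValueError, match="2 chains"):
            convergence_diagnostics({"x": rng.standard_normal((1, 100))})

    def test_summary_table_contents(self, quick_fit):
        s = quick_fit.summary()
        assert "beta0" in s.index
        assert {"mean", "sd", "r_hat", "ess"} <= set(s.columns)


class TestMCMCConfig:
    def test_invariants(self):
        with pytest.raises(ValueError, match="n_chains"):
            MCMCConfig(n_chains=1)
        with pytest.raises(ValueError, match="n_warmup"):
            MCMCConfig(n_iter=100, n_warmup=100)

    def test_defaults_follow_study_design(self):
        cfg = MCMCConfig()
        assert (cfg.n_chains, cfg.n_iter, cfg.n_warmup) == (2, 5000, 4000)
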