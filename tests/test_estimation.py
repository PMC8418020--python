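"""Estimation: Wald inference, influence and contrast quantities, ML fits
against independent oracles, and Monte-Carlo predictions."""

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize
from scipy.stats import multivariate_normal, norm

from dynlpm.estimation import (
    DegenerateContrastError,
    DynamicLatentProcessModel,
    FitResult,
    covariate_contrast,
    influence_at_time,
    influence_curve,
    predict_marker,
    predict_trajectory,
    wald,
)
from dynlpm.links import inverse_transform
from dynlpm.model import log_likelihood
from dynlpm.parameters import ParameterMap, zero_alpha
from dynlpm.reference import reference_parameters
from dynlpm.spec import default_model_spec

from conftest import make_d1_params, make_d1_spec

REF = {"age_cat": "q1", "sex": "male", "educ": "higher", "apoe4": 0}


# ---------------------------------------------------------------------------
# Wald machinery on a hand-built fit object
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def toy_fit():
    spec = make_d1_spec()
    pmap = ParameterMap(spec, "full")
    raw = pmap.pack(make_d1_params(spec))
    vcov = np.diag(np.linspace(0.01, 0.1, pmap.n_parameters))
    return FitResult(spec, pmap, raw, pmap.unpack(raw), vcov, -100.0, {"converged": True})


class TestWald:
    def test_selector_contrast_se_is_sqrt_diagonal(self, toy_fit):
        c = np.zeros(toy_fit.raw.size)
        c[2] = 1.0
        w = wald(toy_fit, c)
        assert w.se == pytest.approx(np.sqrt(toy_fit.vcov[2, 2]))
        assert w.estimate == pytest.approx(toy_fit.raw[2])

    def test_independent_coefficients_variances_add(self, toy_fit):
        c = np.zeros(toy_fit.raw.size)
        c[[1, 3]] = 1.0
        w = wald(toy_fit, c)
        assert w.se**2 == pytest.approx(toy_fit.vcov[1, 1] + toy_fit.vcov[3, 3])

    def test_p_value_matches_normal_cdf_at_1p96(self, toy_fit):
        # build a contrast whose z is exactly 1.96
        c = np.zeros(toy_fit.raw.size)
        i = 2
        c[i] = 1.0
        target = 1.96 * np.sqrt(toy_fit.vcov[i, i])
        fit2 = FitResult(
            toy_fit.spec, toy_fit.pmap, toy_fit.raw.copy(), toy_fit.params,
            toy_fit.vcov, toy_fit.loglik, toy_fit.convergence,
        )
        fit2.raw[i] = target
        w = wald(fit2, c)
        assert w.p_value == pytest.approx(2 * norm.sf(1.96), abs=1e-4)
        assert w.p_value == pytest.approx(0.05, abs=1e-3)

    def test_p_value_invariant_to_contrast_rescaling(self, toy_fit):
        c = np.zeros(toy_fit.raw.size)
        c[[0, 4]] = [1.0, -2.0]
        assert wald(toy_fit, c).p_value == pytest.approx(
            wald(toy_fit, 7.3 * c).p_value, rel=1e-12
        )

    def test_zero_variance_contrast_rejected(self, toy_fit):
        fit2 = FitResult(
            toy_fit.spec, toy_fit.pmap, toy_fit.raw, toy_fit.params,
            np.zeros_like(toy_fit.vcov), toy_fit.loglik, toy_fit.convergence,
        )
        c = np.zeros(toy_fit.raw.size)
        c[0] = 1.0
        with pytest.raises(DegenerateContrastError):
            wald(fit2, c)


# ---------------------------------------------------------------------------
# influence and covariate contrasts at the published estimates
# ---------------------------------------------------------------------------


class TestInfluenceAtTime:
    def test_t0_equals_intercept_for_every_direction_and_stage(self):
        spec = default_model_spec()
        p = reference_parameters(spec)
        for d, tgt in enumerate(spec.dimensions):
            for k, src in enumerate(spec.dimensions):
                for s in spec.stages:
                    e = influence_at_time(p, src, tgt, s, 0.0, spec=spec)
                    assert e.signed == pytest.approx(p.alpha[(d, k, s)][0])

    def test_negative_time_rejected(self):
        spec = default_model_spec()
        with pytest.raises(ValueError, match="non-negative"):
            influence_at_time(reference_parameters(spec), "cognition", "function", "CN", -1.0, spec=spec)

    def test_null_effect_with_symmetric_ci(self, toy_fit):
        spec = toy_fit.spec
        fit2 = FitResult(
            spec, toy_fit.pmap, toy_fit.raw.copy(), None, toy_fit.vcov,
            toy_fit.loglik, toy_fit.convergence,
        )
        i = toy_fit.pmap.alpha_raw_index(0, 0, "CN", 0)
        fit2.raw[i] = 0.0
        fit2.params = toy_fit.pmap.unpack(fit2.raw)
        e = influence_at_time(fit2, "cognition", "cognition", "CN", 1.0)
        assert e.signed == 0.0
        assert e.ci_high == pytest.approx(1.96 * e.se, rel=1e-3)
        assert e.ci_low == pytest.approx(-e.ci_high)

    def test_self_effect_curve_is_flat_and_ci_brackets_point(self, reduced_fit):
        c = influence_curve(reduced_fit.result_, "function", "function", "MCI", [0, 1, 2, 3])
        assert np.ptp(c.signed) == 0.0
        assert np.all(c.ci_low <= c.signed) and np.all(c.signed <= c.ci_high)


class TestCovariateContrast:
    def test_education_within_stage_from_published_cells(self):
        spec = default_model_spec()
        p = reference_parameters(spec)
        lo = dict(REF, stage="MCI", educ="lower")
        hi = dict(REF, stage="MCI", educ="higher")
        w = covariate_contrast(p, "cognition", lo, hi, spec=spec)
        assert w.estimate == pytest.approx(-0.649, abs=1e-12)
        w2 = covariate_contrast(p, "function", dict(lo, stage="AD"), dict(hi, stage="AD"), spec=spec)
        assert w2.estimate == pytest.approx(0.837, abs=1e-12)

    def test_identity_contrast_is_zero(self):
        spec = default_model_spec()
        p = reference_parameters(spec)
        prof = dict(REF, stage="AD", educ="lower")
        w = covariate_contrast(p, "function", prof, dict(prof), spec=spec)
        assert w.estimate == 0.0


# ---------------------------------------------------------------------------
# ML fits against independent oracles
# ---------------------------------------------------------------------------


def _free_mask(pmap):
    """Free = everything except influences and link coefficients."""
    fixed = list(range(pmap._link_start, pmap.n_parameters))
    for s in pmap.spec.stages:
        fixed.append(pmap.alpha_raw_index(0, 0, s, 0))
    return np.asarray(sorted(fixed))


class TestFitOracles:
    def test_d1_null_influence_fit_matches_independent_lmm_fit(self, d1_setup):
        """Same constrained Gaussian family optimized by an independent
        implementation must give the same ML estimates (to 1e-3)."""
        spec, truth, ds = d1_setup["spec"], d1_setup["truth"], d1_setup["dataset"]
        pmap = ParameterMap(spec, "full")
        fixed = _free_mask(pmap)
        est = DynamicLatentProcessModel(
            spec=spec, re_structure="full", init=truth, fixed=fixed,
            ftol=1e-12, compute_hessian=False,
        ).fit(ds)
        p_hat = est.params_

        # independent oracle: Var(u)=1 LMM, own parameterization and code path
        stage_x = {"CN": [0.0, 0.0], "MCI": [1.0, 0.0], "AD": [0.0, 1.0]}
        patterns = {}
        for s in ds.subjects:
            key = (s.stage, tuple(s.node))
            patterns.setdefault(key, []).append(s.value)

        def neg_ll(theta):
            b = theta[:2]
            g = theta[2:5]
            tau = np.exp(theta[5])
            rho = np.tanh(theta[6])
            sig = np.exp(theta[7])
            B = np.array([[1.0, rho * tau], [rho * tau, tau**2]])
            total = 0.0
            for (stage, nodes), vals in patterns.items():
                t = np.asarray(nodes) * spec.delta
                x = np.asarray(stage_x[stage])
                mean = b @ x + t * (g @ np.r_[1.0, x])
                Z = np.column_stack([np.ones_like(t), t])
                cov = Z @ B @ Z.T + sig**2 * np.eye(len(t))
                total += multivariate_normal.logpdf(np.asarray(vals), mean, cov).sum()
            return -total

        theta0 = np.array([*truth.beta[0], *truth.gamma[0], np.log(0.3),
                           np.arctanh(0.2), np.log(0.5)])
        res = optimize.minimize(neg_ll, theta0, method="BFGS",
                                options={"gtol": 1e-7, "maxiter": 500})
        b_hat, g_hat = res.x[:2], res.x[2:5]
        tau_hat, rho_hat, sig_hat = np.exp(res.x[5]), np.tanh(res.x[6]), np.exp(res.x[7])

        np.testing.assert_allclose(p_hat.beta[0], b_hat, atol=1e-3)
        np.testing.assert_allclose(p_hat.gamma[0], g_hat, atol=1e-3)
        B_hat = p_hat.re.cov()
        assert np.sqrt(B_hat[1, 1]) == pytest.approx(tau_hat, abs=1e-3)
        assert B_hat[0, 1] / np.sqrt(B_hat[1, 1]) == pytest.approx(rho_hat, abs=2e-3)
        assert p_hat.sigma[0] == pytest.approx(sig_hat, abs=1e-3)
        assert est.loglik_ == pytest.approx(-res.fun, abs=1e-4)

    def test_multistart_optima_agree(self, d1_setup):
        spec, truth, ds = d1_setup["spec"], d1_setup["truth"], d1_setup["dataset"]
        pmap = ParameterMap(spec, "full")
        fixed = _free_mask(pmap)
        est = DynamicLatentProcessModel(
            spec=spec, re_structure="full", init=truth, fixed=fixed,
            n_starts=5, start_jitter=0.08, ftol=1e-11,
            compute_hessian=False, random_state=1,
        ).fit(ds)
        ordered = sorted(est.starts_, key=lambda r: r["fun"])
        free = np.ones(pmap.n_parameters, dtype=bool)
        free[fixed] = False
        np.testing.assert_allclose(
            ordered[0]["raw"][free], ordered[1]["raw"][free], atol=1e-3
        )

    def test_sample_loglik_at_estimates_beats_truth(self, reduced_setup, reduced_fit):
        cfg = reduced_setup["config"]
        ll_truth = log_likelihood(reduced_setup["dataset"], cfg.spec, cfg.truth)
        assert reduced_fit.loglik_ >= ll_truth - 1e-6

    def test_fit_reports_convergence_and_score(self, reduced_setup, reduced_fit):
        assert reduced_fit.convergence_["converged"]
        assert np.isfinite(reduced_fit.score(reduced_setup["dataset"]))
        tab = reduced_fit.result_.change_table()
        assert "term" in tab.columns and len(tab) > 10


# ---------------------------------------------------------------------------
# Monte-Carlo predictions
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def drift_fit():
    """D=1 pure-drift fit object with uncertainty only on the change intercept."""
    spec = make_d1_spec()
    pmap = ParameterMap(spec, "full")
    params = make_d1_params(spec)
    raw = pmap.pack(params)
    vcov = np.zeros((pmap.n_parameters, pmap.n_parameters))
    i = pmap.gamma_index(0, 0)
    vcov[i, i] = 0.04**2
    return FitResult(spec, pmap, raw, params, vcov, -1.0, {"converged": True})


PROFILE = {"stage": "CN", "age_cat": "q1", "sex": "male", "educ": "higher", "apoe4": 0}


class TestPredictTrajectory:
    def test_zero_vcov_bands_collapse_on_point_curve(self, drift_fit):
        fit0 = FitResult(
            drift_fit.spec, drift_fit.pmap, drift_fit.raw, drift_fit.params,
            np.zeros_like(drift_fit.vcov), -1.0, {"converged": True},
        )
        tp = predict_trajectory(fit0, PROFILE, [0, 1, 2], n_draws=200, seed=1)
        np.testing.assert_allclose(tp.ci_low, tp.mean, atol=1e-12)
        np.testing.assert_allclose(tp.ci_high, tp.mean, atol=1e-12)

    def test_band_halfwidth_matches_delta_method_on_linear_drift(self, drift_fit):
        times = np.array([1.0, 2.0, 4.0])
        tp = predict_trajectory(drift_fit, PROFILE, times, n_draws=4000, seed=2)
        half = 0.5 * (tp.ci_high[:, 0] - tp.ci_low[:, 0])
        expected = 1.96 * 0.04 * times  # Var(E_t) = t^2 Var(gamma0), exact
        np.testing.assert_allclose(half, expected, rtol=0.05)

    def test_fixed_seed_reproducible(self, drift_fit):
        a = predict_trajectory(drift_fit, PROFILE, [0, 1, 3], n_draws=300, seed=9)
        b = predict_trajectory(drift_fit, PROFILE, [0, 1, 3], n_draws=300, seed=9)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        np.testing.assert_array_equal(a.ci_high, b.ci_high)


class TestPredictMarker:
    def test_noiseless_identity_reduces_to_inverse_link_of_mean(self):
        spec = make_d1_spec()
        params = make_d1_params(spec, beta=(5.0, 8.0), sigma=1e-9)
        from dynlpm.model import propagate

        times = [0.0, 1.0, 2.0]
        prof = dict(PROFILE, stage="MCI")
        y = predict_marker(params, prof, "Y", times, n_draws=50, seed=3,
                           marginal=False, spec=spec)
        nodes = [spec.grid_node(t * 12) for t in times]
        lam = propagate(spec, params, prof, "MCI", max(nodes)).E[nodes, 0]
        expected = inverse_transform(lam, spec.markers[0].link, params.links[0])
        np.testing.assert_allclose(y, expected, atol=1e-6)

    def test_bounded_within_marker_range_for_random_profiles(self, reduced_fit):
        rng = np.random.default_rng(0)
        spec = reduced_fit.spec_
        for _ in range(20):
            prof = {
                "stage": rng.choice(["CN", "MCI", "AD"]),
                "age_cat": f"q{rng.integers(1, 6)}",
                "sex": rng.choice(["male", "female"]),
                "educ": rng.choice(["higher", "lower"]),
                "apoe4": int(rng.integers(0, 2)),
            }
            y = predict_marker(reduced_fit.result_, prof, "FUN", [0, 2, 4.5],
                               n_draws=100, seed=5)
            assert np.all(y >= 0) and np.all(y <= 18)

    def test_monte_carlo_matches_hermite_quadrature_over_error(self):
        """MC expectation of the back-transformed value vs 61-node quadrature."""
        spec = default_model_spec()
        params = reference_parameters(spec)
        mi = spec.marker_index("MMSE")
        link, lp = spec.markers[mi].link, params.links[mi]
        prof = dict(PROFILE, stage="MCI")
        times = [0.0, 2.0]
        n_draws = 100_000
        y_mc = predict_marker(params, prof, "MMSE", times, n_draws=n_draws,
                              seed=8, marginal=False, spec=spec)
        from dynlpm.model import propagate

        nodes = [spec.grid_node(t * 12) for t in times]
        lam = propagate(spec, params, prof, "MCI", max(nodes)).E[nodes, 0]
        zq, wq = hermegauss(61)
        wq = wq / wq.sum()
        for j, l0 in enumerate(lam):
            vals = inverse_transform(l0 + params.sigma[mi] * zq, link, lp)
            quad = float(wq @ vals)
            # MC standard error of the mean marker value
            draws = inverse_transform(
                l0 + params.sigma[mi] * np.random.default_rng(8).standard_normal(n_draws),
                link, lp,
            )
            se = draws.std() / np.sqrt(n_draws)
            assert abs(y_mc[j] - quad) < 3 * se + 1e-9
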