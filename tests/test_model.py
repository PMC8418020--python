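"""Dynamics and likelihood: oracle checks and structural invariances."""

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import multivariate_normal

from dynlpm.data import Dataset, Subject
from dynlpm.model import (
    influence_matrix,
    log_likelihood,
    observation_moments,
    propagate,
    transform_subject_values,
)
from dynlpm.parameters import diagonal_re, zero_alpha
from dynlpm.reference import reference_parameters
from dynlpm.simulate import reduced_model_spec, reduced_truth
from dynlpm.spec import ConfigurationError, default_model_spec

from conftest import make_d1_params, make_d1_spec


class TestInfluenceMatrix:
    def test_null_influence_gives_zero_matrix(self):
        spec = default_model_spec()
        p = reference_parameters(spec)
        p.alpha = zero_alpha(spec)
        assert not np.any(influence_matrix(p, spec, "MCI", 1.5))

    def test_published_coefficients_at_zero_and_two_years(self):
        spec = default_model_spec()
        p = reference_parameters(spec)
        A0 = influence_matrix(p, spec, "CN", 0.0)
        assert A0[1, 0] == pytest.approx(-0.403)
        A2 = influence_matrix(p, spec, "CN", 2.0)
        assert A2[1, 0] == pytest.approx(-0.403 + 2 * (-0.281))
        # self-effects constant in time under the default structure
        assert A2[0, 0] == A0[0, 0] == pytest.approx(0.154)
        assert A2[1, 1] == A0[1, 1] == pytest.approx(-1.105)

    def test_unknown_stage_rejected(self):
        spec = default_model_spec()
        with pytest.raises(ConfigurationError, match="stage"):
            influence_matrix(reference_parameters(spec), spec, "prodromal", 0.0)


REF_COV = {"stage": "CN", "age_cat": "q1", "sex": "male", "educ": "higher", "apoe4": 0}


class TestPropagate:
    def test_initialization_contract(self):
        spec = reduced_model_spec()
        dec = propagate(spec, reduced_truth(spec), REF_COV, "AD", 10)
        np.testing.assert_array_equal(dec.P[0], np.eye(2))
        np.testing.assert_array_equal(dec.Q[0], 0.0)

    def test_null_influence_reduces_to_linear_drift(self):
        spec = reduced_model_spec()
        p = reduced_truth(spec)
        p.alpha = zero_alpha(spec)
        dec = propagate(spec, p, REF_COV, "CN", 12)
        j = np.arange(13)[:, None]
        np.testing.assert_allclose(dec.E, j * spec.delta * p.gamma[:, 0], atol=1e-12)
        np.testing.assert_allclose(dec.P, np.broadcast_to(np.eye(2), (13, 2, 2)), atol=1e-12)
        np.testing.assert_allclose(
            dec.Q, j[..., None] * spec.delta * np.eye(2), atol=1e-12
        )

    def test_moments_match_monte_carlo_of_raw_recursion(self):
        """Independent simulation oracle for the linear-Gaussian decomposition."""
        spec = reduced_model_spec()
        p = reduced_truth(spec)
        stage, n_steps, n_draws = "MCI", 8, 100_000
        cov = dict(REF_COV, stage=stage)
        rng = np.random.default_rng(99)
        B = p.re.cov()
        uv = rng.standard_normal((n_draws, 4)) @ np.linalg.cholesky(B).T
        # raw recursion, written independently of propagate()
        x_init = np.array([1.0, 0.0])  # stage MCI dummy row for ("stage",) design
        e0 = p.beta @ x_init
        g = p.gamma @ np.array([1.0, 1.0, 0.0])
        lam = e0 + uv[:, :2]
        kept = [lam.copy()]
        for j in range(n_steps):
            t = j * spec.delta
            A = np.array(
                [
                    [p.alpha[(0, 0, stage)][0], p.alpha[(0, 1, stage)] @ [1, t]],
                    [p.alpha[(1, 0, stage)] @ [1, t], p.alpha[(1, 1, stage)][0]],
                ]
            )
            lam = lam + spec.delta * (lam @ A.T + g + uv[:, 2:])
            kept.append(lam.copy())
        dec = propagate(spec, p, cov, stage, n_steps)
        for j in (0, 4, n_steps):
            draws = kept[j]
            mc_se = draws.std(axis=0) / np.sqrt(n_draws)
            np.testing.assert_array_less(
                np.abs(draws.mean(axis=0) - dec.E[j]), 3 * mc_se + 1e-12
            )
            L = np.column_stack([dec.P[j], dec.Q[j]])
            C = L @ B @ L.T
            emp = np.cov(draws.T)
            C_se = np.sqrt(
                (np.outer(np.diag(C), np.diag(C)) + C**2) / n_draws
            )
            np.testing.assert_array_less(np.abs(emp - C), 3 * C_se + 1e-12)


def _d1_subject(spec, values, months, stage="CN"):
    cov = dict(REF_COV, stage=stage)
    months = np.asarray(months, dtype=float)
    return Subject(
        "s1",
        stage,
        cov,
        months,
        np.zeros(len(months), dtype=int),
        np.array([spec.grid_node(m) for m in months]),
        np.asarray(values, dtype=float),
    )


class TestObservationMoments:
    def test_baseline_variance_is_one_plus_error_variance(self):
        spec = make_d1_spec()
        p = make_d1_params(spec, sigma=0.7)
        s = _d1_subject(spec, [12.0], [0.0])
        mu, cov, lj = observation_moments(s, spec, p)
        assert cov[0, 0] == pytest.approx(1.0 + 0.49)
        assert lj == pytest.approx(0.0)  # identity link

    def test_covariance_symmetric_psd(self):
        spec = default_model_spec()
        p = reference_parameters(spec)
        df, _ = __import__("dynlpm").simulate_cohort(
            __import__("dynlpm").CohortConfig(
                seed=2, n_per_stage={"CN": 3, "MCI": 3, "AD": 3}
            )
        )
        ds = Dataset.from_dataframe(df, spec)
        for s in ds.subjects:
            mu, cov, lj = observation_moments(s, spec, p)
            np.testing.assert_allclose(cov, cov.T, atol=1e-12)
            assert np.linalg.eigvalsh(cov).min() >= -1e-10

    def test_two_node_closed_form_random_intercept_slope(self):
        """Hand-computed mixed-model algebra for two grid-aligned visits."""
        spec = make_d1_spec()
        tau, rho, sig = 0.4, 0.3, 0.6
        p = make_d1_params(spec, v_sd=tau, uv_corr=rho, sigma=sig)
        s = _d1_subject(spec, [10.0, 11.0], [0.0, 3.0])  # nodes 0 and 1
        mu, cov, _ = observation_moments(s, spec, p)
        d = spec.delta
        var0 = 1.0 + sig**2
        cov01 = 1.0 + d * rho * tau  # cov(u, u + d v)
        var1 = 1.0 + d**2 * tau**2 + 2 * d * rho * tau + sig**2
        np.testing.assert_allclose(
            cov, [[var0, cov01], [cov01, var1]], atol=1e-12
        )
        # mean: beta'x + j*delta*gamma'x with A == 0
        g = p.gamma[0, 0]
        np.testing.assert_allclose(mu, [0.0, d * g], atol=1e-12)


class TestLogLikelihood:
    def test_d1_null_influence_matches_closed_form_lmm_oracle(self, d1_setup):
        """With no influences the model IS a random-intercept/slope LMM."""
        spec, p, ds = d1_setup["spec"], d1_setup["truth"], d1_setup["dataset"]
        stage_x = {"CN": [0.0, 0.0], "MCI": [1.0, 0.0], "AD": [0.0, 1.0]}
        B = p.re.cov()
        total = 0.0
        for s in ds.subjects:
            t = s.node * spec.delta
            x = np.asarray(stage_x[s.stage])
            mean = p.beta[0] @ x + t * (p.gamma[0] @ np.r_[1.0, x])
            Z = np.column_stack([np.ones_like(t), t])
            cov = Z @ B @ Z.T + p.sigma[0] ** 2 * np.eye(len(t))
            total += multivariate_normal.logpdf(s.value, mean, cov)
        assert log_likelihood(ds, spec, p) == pytest.approx(total, abs=1e-6)

    def test_gauss_hermite_quadrature_oracle_with_self_influence(self):
        """Dense 2-D Gauss-Hermite quadrature over (u, v) for a toy subject."""
        spec = make_d1_spec()
        a = (0.3, 0.0, 0.0)  # CN self-influence
        tau, rho, sig = 0.4, 0.25, 0.5
        p = make_d1_params(spec, alpha_self=a, v_sd=tau, uv_corr=rho, sigma=sig)
        s = _d1_subject(spec, [0.8, 1.6], [0.0, 6.0])
        ds = Dataset(spec, [s])
        nodes, weights = hermegauss(101)
        L = np.linalg.cholesky(p.re.cov())
        g = p.gamma[0, 0]
        logpost = []
        wsum = 0.0
        acc = 0.0
        for i, zu in enumerate(nodes):
            for j, zv in enumerate(nodes):
                u, v = L @ np.array([zu, zv])
                lam = u  # E0 = 0 at reference covariates
                lams = [lam]
                for step in range(2):
                    lam = lam + spec.delta * (a[0] * lam + g + v)
                    lams.append(lam)
                dens = np.prod(
                    [
                        np.exp(-0.5 * ((y - lams[n]) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
                        for y, n in zip(s.value, s.node)
                    ]
                )
                acc += weights[i] * weights[j] * dens
                wsum += weights[i] * weights[j]
        oracle = np.log(acc / wsum)  # probabilists' weights integrate N(0,1)
        assert log_likelihood(ds, spec, p) == pytest.approx(oracle, abs=1e-5)

    def test_additive_over_subjects_and_empty_subject_ignored(self, d1_setup):
        spec, p, ds = d1_setup["spec"], d1_setup["truth"], d1_setup["dataset"]
        base = log_likelihood(ds, spec, p)
        empty = Subject(
            "empty",
            "CN",
            dict(REF_COV),
            np.array([]),
            np.array([], dtype=int),
            np.array([], dtype=int),
            np.array([]),
        )
        ds2 = Dataset(spec, ds.subjects + [empty])
        assert log_likelihood(ds2, spec, p) == pytest.approx(base, abs=1e-10)

    def test_invariant_to_row_order(self, reduced_setup):
        cfg, df = reduced_setup["config"], reduced_setup["df"]
        base = log_likelihood(reduced_setup["dataset"], cfg.spec, cfg.truth)
        shuffled = df.sample(frac=1.0, random_state=4)
        ds2 = Dataset.from_dataframe(shuffled, cfg.spec)
        assert log_likelihood(ds2, cfg.spec, cfg.truth) == pytest.approx(base, abs=1e-8)

    def test_mar_deletion_marginalizes_the_moments(self, reduced_setup):
        """Dropping observations leaves exactly the Gaussian marginal."""
        cfg = reduced_setup["config"]
        ds = reduced_setup["dataset"]
        s = next(x for x in ds.subjects if x.n_obs >= 6)
        keep = np.arange(s.n_obs) % 2 == 0
        reduced = Subject(
            s.id, s.stage, s.covariates, s.time_months[keep],
            s.marker_idx[keep], s.node[keep], s.value[keep],
        )
        mu_f, cov_f, _ = observation_moments(s, cfg.spec, cfg.truth)
        mu_r, cov_r, lj_r = observation_moments(reduced, cfg.spec, cfg.truth)
        np.testing.assert_allclose(mu_r, mu_f[keep], atol=1e-12)
        np.testing.assert_allclose(cov_r, cov_f[np.ix_(keep, keep)], atol=1e-12)
        # likelihood of the reduced subject = marginal density from full moments
        z = transform_subject_values(reduced, cfg.spec, cfg.truth)
        expect = multivariate_normal.logpdf(
            z, mu_f[keep], cov_f[np.ix_(keep, keep)]
        ) + lj_r
        got = log_likelihood(Dataset(cfg.spec, [reduced]), cfg.spec, cfg.truth)
        assert got == pytest.approx(expect, abs=1e-8)
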