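"""Maximum-likelihood fitting and the derived inferential quantities.

The estimator maximizes the marginal MAR log-likelihood over the
unconstrained parameter vector by quasi-Newton search with finite-difference
gradients, optionally from several jittered starts.  Asymptotic covariance
comes from the inverse observed Hessian (central differences) at the
optimum.  On top of a fit the module provides two-sided Wald tests of linear
contrasts, time-varying influence estimates with delta-method intervals
(linear in the coefficients, so the delta method is exact), covariate
contrasts on the latent scale, and Monte-Carlo confidence bands for
predicted latent trajectories and marker-scale predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from ._numdiff import central_gradient, central_hessian, forward_gradient
from .data import Dataset
from .links import LinkParameters, ispline_basis, latent_range, inverse_transform
from .model import log_likelihood, propagate
from .parameters import (
    NumericalError,
    ParameterMap,
    Parameters,
    RandomEffectParameters,
    diagonal_re,
    full_re_from_cov,
    zero_alpha,
)
from .spec import ConfigurationError, ModelSpec, default_model_spec, design_row, spec_with_knots_from_data

_Z95 = 1.959963984540054  # normal 97.5% quantile


class InitializationError(RuntimeError):
    pass


class DegenerateContrastError(ValueError):
    pass


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """A fitted model: estimates, asymptotic covariance and diagnostics."""

    spec: ModelSpec
    pmap: ParameterMap
    raw: np.ndarray
    params: Parameters
    vcov: np.ndarray | None
    loglik: float
    convergence: dict

    @property
    def names(self) -> list:
        return self.pmap.names

    @property
    def converged(self) -> bool:
        return bool(self.convergence.get("converged", False))

    def se_raw(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        from .config import spec_to_dict

        return {
            "spec": spec_to_dict(self.spec),
            "re_structure": self.pmap.re_structure,
            "names": self.names,
            "raw": self.raw.tolist(),
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "loglik": float(self.loglik),
            "convergence": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.convergence.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        from .config import spec_from_dict

        spec = spec_from_dict(d["spec"])
        pmap = ParameterMap(spec, d["re_structure"])
        raw = np.asarray(d["raw"])
        vcov = None if d["vcov"] is None else np.asarray(d["vcov"])
        return cls(spec, pmap, raw, pmap.unpack(raw), vcov, d["loglik"], d["convergence"])

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # -- published-style coefficient tables ------------------------------
    def _coef_row(self, idx: int, suppress: bool):
        est = float(self.raw[idx])
        if self.vcov is None or suppress:
            return est, np.nan, np.nan
        se = float(np.sqrt(max(self.vcov[idx, idx], 0.0)))
        return est, est - _Z95 * se, est + _Z95 * se

    def baseline_table(self) -> pd.DataFrame:
        """Initial-level associations per dimension with 95% CIs."""
        suppress = bool(self.convergence.get("ci_suppressed", False))
        rows = []
        for j, col in enumerate(self.spec.init_columns):
            row = {"term": col}
            for d, dim in enumerate(self.spec.dimensions):
                est, lo, hi = self._coef_row(self.pmap.beta_index(d, j), suppress)
                row[f"{dim}"] = est
                row[f"{dim}_lo"] = lo
                row[f"{dim}_hi"] = hi
            rows.append(row)
        return pd.DataFrame(rows)

    def change_table(self) -> pd.DataFrame:
        """Change-rate associations: covariates plus temporal influences."""
        suppress = bool(self.convergence.get("ci_suppressed", False))
        spec = self.spec
        rows = []
        for j, col in enumerate(["intercept", *spec.change_columns]):
            row = {"term": col}
            for d, dim in enumerate(spec.dimensions):
                est, lo, hi = self._coef_row(self.pmap.gamma_index(d, j), suppress)
                row[f"{dim}"] = est
                row[f"{dim}_lo"] = lo
                row[f"{dim}_hi"] = hi
            rows.append(row)
        for k, src in enumerate(spec.dimensions):
            for b_name, b in (("", 0), (" x time", 1)):
                for s in spec.stages:
                    row = {"term": f"current {src} level, {s}{b_name}"}
                    any_entry = False
                    for d, dim in enumerate(spec.dimensions):
                        if b >= spec.influence_basis_size(d, k):
                            row[dim] = row[f"{dim}_lo"] = row[f"{dim}_hi"] = np.nan
                            continue
                        idx = self.pmap.alpha_raw_index(d, k, s, b)
                        est, lo, hi = self._coef_row(idx, suppress)
                        row[dim], row[f"{dim}_lo"], row[f"{dim}_hi"] = est, lo, hi
                        any_entry = True
                    if any_entry:
                        rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class WaldResult:
    estimate: float
    se: float
    z: float
    p_value: float
    ci_low: float
    ci_high: float


@dataclass
class InfluenceEstimate:
    """Effect of the current level of ``source`` on the subsequent annual
    change of ``target`` at time ``t`` (years in the cohort)."""

    source: str
    target: str
    stage: str
    t: float
    signed: float
    magnitude: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class InfluenceCurve:
    source: str
    target: str
    stage: str
    times: np.ndarray
    signed: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": self.source,
                "target": self.target,
                "stage": self.stage,
                "time_years": self.times,
                "influence": self.signed,
                "reduction_magnitude": np.abs(self.signed),
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass
class TrajectoryPrediction:
    dimensions: tuple
    times: np.ndarray
    mean: np.ndarray  # (n_times, D)
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d, dim in enumerate(self.dimensions):
            rows.append(
                pd.DataFrame(
                    {
                        "dimension": dim,
                        "time_years": self.times,
                        "mean": self.mean[:, d],
                        "ci_low": self.ci_low[:, d],
                        "ci_high": self.ci_high[:, d],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# deterministic initialization
# ---------------------------------------------------------------------------


def _init_link(values: np.ndarray, link_spec, spread: float = 2.0) -> LinkParameters:
    """Match the link to empirical quantiles mapped onto a Gaussian scale."""
    probs = np.linspace(0.02, 0.98, 25)
    yq = np.quantile(values, probs)
    z = spread * stats.norm.ppf(probs)
    I = ispline_basis(np.clip(yq, link_spec.y_min, link_spec.y_max), link_spec)
    A = I - I.mean(axis=0)
    b = z - z.mean()
    w, _ = optimize.nnls(A, b)
    if w.sum() <= 1e-8:  # degenerate data; fall back to a uniform ramp
        w = np.full(link_spec.n_basis, 4.0 / link_spec.n_basis)
    w = np.maximum(w, 1e-4)
    eta0 = float(z.mean() - I.mean(axis=0) @ w)
    return LinkParameters(eta0, np.sqrt(w))


def initial_parameters(
    dataset: Dataset, spec: ModelSpec, re_structure: str = "full"
) -> Parameters:
    """Deterministic warm start.

    Links from marginal quantile matching, fixed effects from crude
    per-dimension regressions of transformed values (levels at baseline,
    within-subject slopes for the change), influences at zero, independent
    random effects.
    """
    D = spec.n_dimensions
    links = []
    for mi, m in enumerate(spec.markers):
        vals = np.concatenate(
            [s.value[s.marker_idx == mi] for s in dataset.subjects]
        ) if dataset.subjects else np.array([])
        if vals.size < 3:
            links.append(LinkParameters(-2.0, np.sqrt(np.full(m.link.n_basis, 4.0 / m.link.n_basis))))
        else:
            links.append(_init_link(vals, m.link))

    def transformed(s, mi):
        w = links[mi].weights
        v = s.value[s.marker_idx == mi]
        return links[mi].eta0 + ispline_basis(v, spec.markers[mi].link) @ w

    # baseline levels -> beta;  within-subject slopes -> gamma
    p_init, p_change = len(spec.init_columns), len(spec.change_columns)
    X0, Y0 = [], [[] for _ in range(D)]
    Xs, Ys = [], [[] for _ in range(D)]
    for s in dataset.subjects:
        if s.n_obs == 0:
            continue
        z = np.concatenate([transformed(s, mi) for mi in np.unique(s.marker_idx)])
        order = np.argsort(
            np.concatenate([s.time_months[s.marker_idx == mi] for mi in np.unique(s.marker_idx)])
        )
        dims = np.concatenate(
            [
                np.full(np.sum(s.marker_idx == mi), spec.marker_dimension_index(mi))
                for mi in np.unique(s.marker_idx)
            ]
        )
        tt = np.concatenate(
            [s.time_months[s.marker_idx == mi] for mi in np.unique(s.marker_idx)]
        ) / 12.0
        row0, rows = [np.nan] * D, [np.nan] * D
        for d in range(D):
            zd, td = z[dims == d], tt[dims == d]
            at0 = td < spec.delta
            if np.any(at0):
                row0[d] = float(np.mean(zd[at0]))
            if len(np.unique(td)) >= 2:
                rows[d] = float(np.polyfit(td, zd, 1)[0])
        X0.append(design_row(spec.init_terms, s.covariates))
        Xs.append(design_row(spec.change_terms, s.covariates))
        for d in range(D):
            Y0[d].append(row0[d])
            Ys[d].append(rows[d])

    beta = np.zeros((D, p_init))
    gamma = np.zeros((D, 1 + p_change))
    X0 = np.asarray(X0) if X0 else np.zeros((0, p_init))
    Xs1 = (
        np.column_stack([np.ones(len(Xs)), np.asarray(Xs)])
        if Xs
        else np.zeros((0, 1 + p_change))
    )
    for d in range(D):
        y0 = np.asarray(Y0[d])
        ok = np.isfinite(y0)
        if ok.sum() > p_init:
            beta[d] = np.linalg.lstsq(X0[ok], y0[ok], rcond=None)[0]
        ys = np.asarray(Ys[d])
        ok = np.isfinite(ys)
        if ok.sum() > 1 + p_change:
            gamma[d] = np.linalg.lstsq(Xs1[ok], ys[ok], rcond=None)[0]

    if re_structure == "diagonal":
        re = diagonal_re(np.full(D, 0.3))
    else:
        B = np.eye(2 * D)
        B[D:, D:] *= 0.09
        re = full_re_from_cov(B)
    return Parameters(
        beta=beta,
        gamma=gamma,
        alpha=zero_alpha(spec),
        re=re,
        sigma=np.full(spec.n_markers, 0.5),
        links=links,
    )


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


class DynamicLatentProcessModel(BaseEstimator):
    """Dynamic latent process model estimated by maximum likelihood.

    Parameters
    ----------
    spec : ModelSpec or None
        Structural specification; the default two-dimension five-marker
        battery if None.
    re_structure : {"full", "diagonal"}
        Random-effect covariance structure (full Cholesky with the
        random-intercept block constrained to a correlation matrix, or
        independent effects for small-sample stability).
    init : "auto" | Parameters | array
        Starting point; "auto" builds a deterministic warm start from the
        data.
    n_starts : int
        Number of optimizer starts (first from ``init``, the rest jittered).
    fixed : sequence of int or bool mask, optional
        Raw-vector positions held at their initial values (e.g. link
        coefficients pinned to the identity, influences pinned to zero for
        reduction tests); their rows/columns of the covariance are zero.
    knots_from_data : bool
        Re-place each marker's interior knots at observed quantiles before
        fitting.

    Attributes (after fit)
    ----------------------
    result_ : FitResult
    params_ : Parameters
    vcov_ : ndarray or None
    loglik_ : float
    convergence_ : dict
    """

    def __init__(
        self,
        spec: ModelSpec | None = None,
        re_structure: str = "full",
        init="auto",
        maxiter: int = 1000,
        ftol: float = 1e-8,
        gtol: float = 1e-3,
        grad_rel_step: float = 1e-7,
        hessian_rel_step: float = 1e-4,
        n_starts: int = 1,
        start_jitter: float = 0.1,
        fixed=None,
        compute_hessian: bool = True,
        knots_from_data: bool = False,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.spec = spec
        self.re_structure = re_structure
        self.init = init
        self.maxiter = maxiter
        self.ftol = ftol
        self.gtol = gtol
        self.grad_rel_step = grad_rel_step
        self.hessian_rel_step = hessian_rel_step
        self.n_starts = n_starts
        self.start_jitter = start_jitter
        self.fixed = fixed
        self.compute_hessian = compute_hessian
        self.knots_from_data = knots_from_data
        self.random_state = random_state
        self.verbose = verbose

    # -- sklearn plumbing -------------------------------------------------
    def _resolve(self, X) -> Dataset:
        if isinstance(X, Dataset):
            return X
        spec = self.spec or default_model_spec()
        if self.knots_from_data:
            spec = spec_with_knots_from_data(spec, X)
        return Dataset.from_dataframe(X, spec)

    def fit(self, X, y=None):
        """Fit by maximum likelihood; ``X`` is a long-format frame or Dataset."""
        dataset = self._resolve(X)
        spec = dataset.spec
        if dataset.n_subjects == 0:
            raise ValueError("empty dataset")
        pmap = ParameterMap(spec, self.re_structure)

        def objective(x):
            try:
                ll = log_likelihood(dataset, spec, pmap.unpack(x))
            except (NumericalError, np.linalg.LinAlgError, FloatingPointError):
                return 1e10
            if not np.isfinite(ll):
                return 1e10
            return -ll

        if isinstance(self.init, Parameters):
            x0 = pmap.pack(self.init)
        elif isinstance(self.init, (np.ndarray, list, tuple)):
            x0 = np.asarray(self.init, dtype=float)
        else:
            x0 = pmap.pack(initial_parameters(dataset, spec, self.re_structure))
        f0 = objective(x0)
        if not np.isfinite(f0) or f0 >= 1e10:
            raise InitializationError(
                "log-likelihood is not finite at the initial parameters; "
                "check link weights (flat links) and error SDs"
            )

        free = np.ones(pmap.n_parameters, dtype=bool)
        if self.fixed is not None:
            fixed = np.asarray(self.fixed)
            if fixed.dtype == bool:
                free = ~fixed
            else:
                free[fixed.astype(int)] = False
        x_full = x0.copy()

        def objective_free(xf):
            x = x_full.copy()
            x[free] = xf
            return objective(x)

        rng = np.random.default_rng(self.random_state)
        starts = [x0[free]]
        for _ in range(self.n_starts - 1):
            starts.append(
                x0[free]
                + self.start_jitter
                * (1 + np.abs(x0[free]))
                * rng.standard_normal(int(free.sum()))
            )

        best = None
        self.starts_ = []
        for s_i, xs in enumerate(starts):
            res = optimize.minimize(
                objective_free,
                xs,
                jac=lambda x: forward_gradient(
                    objective_free, x, rel_step=self.grad_rel_step
                ),
                method="L-BFGS-B",
                options={
                    "maxiter": self.maxiter,
                    "ftol": self.ftol,
                    "gtol": self.gtol,
                    "maxcor": 20,
                },
            )
            if self.verbose:
                print(f"start {s_i}: f={res.fun:.6f} nit={res.nit} {res.message}")
            xr = x_full.copy()
            xr[free] = res.x
            self.starts_.append({"fun": float(res.fun), "raw": xr})
            if best is None or res.fun < best.fun:
                best = res
        xopt = x_full.copy()
        xopt[free] = best.x
        grad = central_gradient(objective_free, best.x, rel_step=1e-6)
        grad_norm = float(np.max(np.abs(grad)))
        converged = bool(best.success) and grad_norm <= self.gtol * max(
            1.0, abs(best.fun)
        )
        convergence = {
            "converged": converged,
            "iterations": int(best.nit),
            "n_starts": self.n_starts,
            "grad_norm": grad_norm,
            "message": str(best.message),
            "singular_hessian": False,
            "ci_suppressed": False,
        }

        vcov = None
        if self.compute_hessian:
            H = central_hessian(objective_free, best.x, rel_step=self.hessian_rel_step)
            H = 0.5 * (H + H.T)
            eigmin = float(np.linalg.eigvalsh(H).min())
            if eigmin <= 0:
                convergence["singular_hessian"] = True
                convergence["ci_suppressed"] = True
                vf = np.linalg.pinv(H)
            else:
                vf = np.linalg.inv(H)
            vcov = np.zeros((pmap.n_parameters, pmap.n_parameters))
            vcov[np.ix_(free, free)] = 0.5 * (vf + vf.T)

        self.result_ = FitResult(
            spec, pmap, xopt, pmap.unpack(xopt), vcov, -float(best.fun), convergence
        )
        self.params_ = self.result_.params
        self.vcov_ = vcov
        self.loglik_ = self.result_.loglik
        self.convergence_ = convergence
        self.spec_ = spec
        self.pmap_ = pmap
        self.n_parameters_ = pmap.n_parameters
        self.n_subjects_ = dataset.n_subjects
        return self

    def score(self, X, y=None) -> float:
        """Mean per-subject log-likelihood under the fitted parameters."""
        dataset = X if isinstance(X, Dataset) else Dataset.from_dataframe(X, self.spec_)
        return log_likelihood(dataset, self.spec_, self.params_) / dataset.n_subjects


def fit(dataset, spec: ModelSpec | None = None, init="auto", **options) -> FitResult:
    """Functional wrapper around :class:`DynamicLatentProcessModel`."""
    if not isinstance(dataset, Dataset):
        dataset = Dataset.from_dataframe(dataset, spec or default_model_spec())
    est = DynamicLatentProcessModel(spec=dataset.spec, init=init, **options)
    est.fit(dataset)
    return est.result_


# ---------------------------------------------------------------------------
# Wald inference and derived quantities
# ---------------------------------------------------------------------------


def wald(fit_result: FitResult, contrast) -> WaldResult:
    """Two-sided Wald test of a linear contrast of raw-scale coefficients."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != fit_result.raw.shape:
        raise ValueError(
            f"contrast length {c.size} does not match {fit_result.raw.size} parameters"
        )
    if fit_result.vcov is None:
        raise ValueError("fit has no covariance matrix (Hessian not computed)")
    est = float(c @ fit_result.raw)
    var = float(c @ fit_result.vcov @ c)
    if var <= 0:
        raise DegenerateContrastError("contrast has zero estimated variance")
    se = np.sqrt(var)
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    return WaldResult(est, se, z, p, est - _Z95 * se, est + _Z95 * se)


def _resolve_fit(obj, spec):
    """Accept a FitResult, fitted estimator, or bare Parameters (+spec)."""
    if isinstance(obj, DynamicLatentProcessModel):
        obj = obj.result_
    if isinstance(obj, FitResult):
        return obj.params, obj.spec, obj
    if isinstance(obj, Parameters):
        if spec is None:
            raise ValueError("spec is required with bare Parameters")
        return obj, spec, None
    raise TypeError(f"cannot interpret {type(obj).__name__} as fit or parameters")


def influence_at_time(
    obj,
    source: str,
    target: str,
    stage: str,
    t: float,
    spec: ModelSpec | None = None,
) -> InfluenceEstimate:
    """Temporal influence of ``source`` on the annual change of ``target``.

    Returns the signed effect and its magnitude (the "reduction" convention
    for negative effects); with a fitted model, delta-method SE and 95% CI
    on the signed scale.  The point estimate is linear in the influence
    coefficients, so the delta method is exact.
    """
    params, spec, fit_res = _resolve_fit(obj, spec)
    d = spec.dimension_index(target)
    k = spec.dimension_index(source)
    if stage not in spec.stages:
        raise ConfigurationError(f"unknown stage {stage!r}")
    if t < 0:
        raise ValueError("influence time must be non-negative")
    basis = spec.influence_time_basis(d, k, t)
    signed = float(np.dot(params.alpha[(d, k, stage)], basis))
    out = InfluenceEstimate(source, target, stage, float(t), signed, abs(signed))
    if fit_res is not None and fit_res.vcov is not None:
        c = np.zeros(fit_res.raw.size)
        for b, bb in enumerate(basis):
            c[fit_res.pmap.alpha_raw_index(d, k, stage, b)] = bb
        w = wald(fit_res, c)
        out.se, out.ci_low, out.ci_high = w.se, w.ci_low, w.ci_high
    return out


def influence_curve(
    fit_result, source: str, target: str, stage: str, times
) -> InfluenceCurve:
    times = np.asarray(times, dtype=float)
    ests = [
        influence_at_time(fit_result, source, target, stage, t) for t in times
    ]
    nan = float("nan")
    return InfluenceCurve(
        source,
        target,
        stage,
        times,
        np.array([e.signed for e in ests]),
        np.array([nan if e.se is None else e.se for e in ests]),
        np.array([nan if e.ci_low is None else e.ci_low for e in ests]),
        np.array([nan if e.ci_high is None else e.ci_high for e in ests]),
    )


def covariate_contrast(
    obj,
    dimension: str,
    profile_a: dict,
    profile_b: dict,
    spec: ModelSpec | None = None,
    part: str = "init",
):
    """Latent mean difference (profile_a minus profile_b) with Wald CI.

    ``part="init"`` contrasts initial levels, ``part="change"`` annual
    change rates.
    """
    params, spec, fit_res = _resolve_fit(obj, spec)
    d = spec.dimension_index(dimension)
    terms = spec.init_terms if part == "init" else spec.change_terms
    xa = design_row(terms, profile_a)
    xb = design_row(terms, profile_b)
    diff = xa - xb
    coef = params.beta[d] if part == "init" else params.gamma[d, 1:]
    est = float(coef @ diff)
    if fit_res is None or fit_res.vcov is None:
        return WaldResult(est, np.nan, np.nan, np.nan, np.nan, np.nan)
    c = np.zeros(fit_res.raw.size)
    for j, v in enumerate(diff):
        if v != 0.0:
            idx = (
                fit_res.pmap.beta_index(d, j)
                if part == "init"
                else fit_res.pmap.gamma_index(d, j + 1)
            )
            c[idx] = v
    if not np.any(c):
        return WaldResult(0.0, 0.0, np.nan, np.nan, 0.0, 0.0)  # identical profiles
    return wald(fit_res, c)


# ---------------------------------------------------------------------------
# Monte-Carlo predictions
# ---------------------------------------------------------------------------


def _vcov_factor(vcov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (vcov + vcov.T))
    if vals.min() < -1e-8 * max(vals.max(), 1.0):
        raise NumericalError(
            "parameter covariance is not positive semidefinite; inspect the "
            "Hessian (singular or away from an optimum)"
        )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def predict_trajectory(
    fit_result,
    profile: dict,
    times,
    n_draws: int = 2000,
    seed: int = 0,
) -> TrajectoryPrediction:
    """Predicted latent mean trajectories with Monte-Carlo 95% bands.

    Draws parameter vectors from the asymptotic normal of the estimates,
    propagates each through the dynamics, and takes pointwise 2.5/97.5
    percentiles; the point curve uses the estimates themselves.  Bands
    reflect estimation uncertainty only (confidence, not prediction, bands).
    """
    if isinstance(fit_result, DynamicLatentProcessModel):
        fit_result = fit_result.result_
    spec = fit_result.spec
    times = np.asarray(times, dtype=float)
    nodes = np.array([spec.grid_node(t * 12.0) for t in times])
    n_steps = int(nodes.max()) if nodes.size else 0
    stage = profile["stage"]
    point = propagate(spec, fit_result.params, profile, stage, n_steps).E[nodes]
    if fit_result.vcov is None:
        raise ValueError("fit has no covariance matrix; cannot draw bands")
    F = _vcov_factor(fit_result.vcov)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_draws, len(times), spec.n_dimensions))
    for i in range(n_draws):
        raw = fit_result.raw + F @ rng.standard_normal(fit_result.raw.size)
        try:
            p = fit_result.pmap.unpack(raw)
            draws[i] = propagate(spec, p, profile, stage, n_steps).E[nodes]
        except (NumericalError, FloatingPointError):
            draws[i] = np.nan
    lo, hi = np.nanpercentile(draws, [2.5, 97.5], axis=0)
    return TrajectoryPrediction(spec.dimensions, times, point, lo, hi)


def predict_marker(
    obj,
    profile: dict,
    marker: str,
    times,
    n_draws: int = 2000,
    seed: int = 0,
    marginal: bool = True,
    spec: ModelSpec | None = None,
) -> np.ndarray:
    """Expected marker-scale trajectory ``E[H^-1(Lambda + eps)]``.

    Monte-Carlo over the measurement error (and, when ``marginal``, the
    random effects); the inverse link keeps values inside the marker's
    range.  With zero error SD and no random effects this reduces to the
    latent mean mapped through the inverse link.
    """
    params, spec, _ = _resolve_fit(obj, spec)
    mi = spec.marker_index(marker)
    link_spec = spec.markers[mi].link
    d = spec.marker_dimension_index(mi)
    times = np.asarray(times, dtype=float)
    nodes = np.array([spec.grid_node(t * 12.0) for t in times])
    n_steps = int(nodes.max()) if nodes.size else 0
    decomp = propagate(spec, params, profile, profile["stage"], n_steps)
    mean = decomp.E[nodes, d]
    R = np.concatenate(
        [decomp.P[nodes, d, :], decomp.Q[nodes, d, :]], axis=1
    )  # (n_t, 2D)
    rng = np.random.default_rng(seed)
    if marginal:
        L = np.linalg.cholesky(params.re.cov())
        re = rng.standard_normal((n_draws, 2 * spec.n_dimensions)) @ L.T
        lam = mean + re @ R.T
    else:
        lam = np.tile(mean, (n_draws, 1))
    lam = lam + params.sigma[mi] * rng.standard_normal(lam.shape)
    y = inverse_transform(lam.ravel(), link_spec, params.links[mi])
    return y.reshape(lam.shape).mean(axis=0)
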