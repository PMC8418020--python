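"""Structural dynamics and the marginal (MAR) log-likelihood.

The two latent dimensions evolve on the discretized grid ``t_j = j * delta``
by the difference equation

    Lambda(t_{j+1}) = (I + delta * A_j) Lambda(t_j)
                      + delta * (gamma' x + v),
    Lambda(0)       = beta' x_init + u,

where ``A_j = A(t_j)`` is the stage-specific temporal-influence matrix
(entry ``[d, k]``: effect of the current level of dimension ``k`` on the
subsequent annual change of dimension ``d``) and ``(u, v)`` are Gaussian
random effects.  Because the recursion is affine in ``(u, v)``, the latent
vector at every node is exactly linear-Gaussian:

    Lambda(t_j) = E_j + P_j u + Q_j v,

with deterministic ``E_j`` (covariate-conditional mean) and loading matrices
``P_j`` (on ``u``) and ``Q_j`` (on ``v``) that follow the same recursion.
Transformed observations ``H_m(y)`` are then jointly Gaussian, and subjects
with intermittently missing markers contribute the marginal density of what
was actually observed (the missing-at-random mechanism of mixed-model
theory), plus the change-of-variable log-Jacobian of the links.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .data import Dataset, Subject
from .links import transform, transform_jacobian
from .parameters import NumericalError, Parameters
from .spec import ConfigurationError, ModelSpec, design_row

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class LatentDecomposition:
    """Per grid node: mean ``E_j`` and random-effect loadings ``P_j, Q_j``.

    ``E`` has shape (n_steps + 1, D); ``P`` and ``Q`` have shape
    (n_steps + 1, D, D).  ``P_0 = I`` and ``Q_0 = 0``; with all influences
    zero, ``P_j = I`` and ``Q_j = j * delta * I`` for every node.
    """

    delta: float
    E: np.ndarray
    P: np.ndarray
    Q: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.delta * np.arange(self.E.shape[0])


def influence_matrix(params: Parameters, spec: ModelSpec, stage: str, t: float) -> np.ndarray:
    """Temporal-influence matrix ``A(t)`` for one stage.

    ``A[d, k](t) = sum_b alpha[d<-k, stage, b] * basis_b(t)``; self-effects
    use the constant basis, cross-effects the linear-in-time basis.
    """
    if stage not in spec.stages:
        raise ConfigurationError(f"unknown stage {stage!r}")
    if t < 0:
        raise ValueError("influence time must be non-negative")
    D = spec.n_dimensions
    A = np.zeros((D, D))
    for d in range(D):
        for k in range(D):
            basis = spec.influence_time_basis(d, k, t)
            A[d, k] = float(np.dot(params.alpha[(d, k, stage)], basis))
    return A


def _stage_transition_matrices(params, spec, stage, n_steps) -> np.ndarray:
    """``I + delta * A(t_j)`` for j = 0..n_steps-1, shape (n_steps, D, D)."""
    D = spec.n_dimensions
    ts = spec.delta * np.arange(n_steps)
    A = np.zeros((n_steps, D, D))
    for d in range(D):
        for k in range(D):
            c = params.alpha[(d, k, stage)]
            A[:, d, k] = c[0] + c[1] * ts if len(c) == 2 else c[0]
    return np.eye(D) + spec.delta * A


def _run_recursion(T_all, n_steps, D, delta, E0, g):
    """Stacked recursion over ``S_j = [E_j | P_j | Q_j]`` (D x (1 + 2D))."""
    S = np.zeros((n_steps + 1, D, 1 + 2 * D))
    S[0, :, 0] = E0
    S[0, :, 1 : D + 1] = np.eye(D)
    const = np.zeros((D, 1 + 2 * D))
    const[:, 0] = delta * g
    const[:, D + 1 :] = delta * np.eye(D)
    for j in range(n_steps):
        S[j + 1] = T_all[j] @ S[j] + const
    return S


def propagate(
    spec: ModelSpec,
    params: Parameters,
    covariates,
    stage: str,
    n_steps: int,
) -> LatentDecomposition:
    """Run the latent recursion and return its linear-Gaussian decomposition.

    ``covariates`` is either a covariate dict or a precomputed pair
    ``(x_init, x_change)`` of design rows.
    """
    if n_steps * spec.delta > spec.horizon + 1e-9:
        raise ConfigurationError("n_steps * delta exceeds the model horizon")
    if isinstance(covariates, dict):
        x_init = design_row(spec.init_terms, covariates)
        x_change = design_row(spec.change_terms, covariates)
    else:
        x_init, x_change = covariates
    params.validate(spec)
    D = spec.n_dimensions
    delta = spec.delta
    E0 = params.beta @ x_init
    g = params.gamma @ np.concatenate([[1.0], x_change])
    if not np.all(np.isfinite(E0)) or not np.all(np.isfinite(g)):
        raise NumericalError("non-finite linear predictor (beta or gamma)")
    T_all = _stage_transition_matrices(params, spec, stage, n_steps)
    S = _run_recursion(T_all, n_steps, D, delta, E0, g)
    return LatentDecomposition(
        delta, S[:, :, 0], S[:, :, 1 : D + 1], S[:, :, D + 1 :]
    )


def _loading_rows(decomp: LatentDecomposition, node, dim_idx) -> np.ndarray:
    """Stack ``[P_j[d, :], Q_j[d, :]]`` rows for each observation."""
    return np.concatenate(
        [decomp.P[node, dim_idx, :], decomp.Q[node, dim_idx, :]], axis=1
    )


def observation_moments(subject: Subject, spec: ModelSpec, params: Parameters):
    """Gaussian moments of one subject's transformed observed markers.

    Returns ``(mean, covariance, log_jacobian_sum)``.  Only observed markers
    enter (MAR); the covariance is ``Z B Z' + diag(sigma_m^2)`` with ``Z``
    rows built from the latent loadings at each observation's grid node.
    """
    if subject.n_obs < 1:
        raise ValueError(f"subject {subject.id!r} has no observations")
    node = subject.node
    if np.any(node > spec.n_grid):
        raise ValueError(f"subject {subject.id!r}: observation outside the grid")
    decomp = propagate(spec, params, subject.covariates, subject.stage, int(node.max()))
    dim_idx = np.array([spec.marker_dimension_index(m) for m in subject.marker_idx])
    mean = decomp.E[node, dim_idx]
    Z = _loading_rows(decomp, node, dim_idx)
    B = params.re.cov()
    sig2 = params.sigma[subject.marker_idx] ** 2
    cov = Z @ B @ Z.T + np.diag(sig2)
    logjac = 0.0
    for i, m in enumerate(subject.marker_idx):
        jac = float(
            transform_jacobian(subject.value[i], spec.markers[m].link, params.links[m])
        )
        if jac <= 0:
            return mean, cov, -np.inf
        logjac += np.log(jac)
    return mean, cov, logjac


def transform_subject_values(subject: Subject, spec: ModelSpec, params: Parameters):
    return np.array(
        [
            float(transform(subject.value[i], spec.markers[m].link, params.links[m]))
            for i, m in enumerate(subject.marker_idx)
        ]
    )


def log_likelihood(dataset: Dataset, spec: ModelSpec | None, params: Parameters) -> float:
    """Marginal log-likelihood of the cohort, additive over subjects.

    Subjects sharing stage, covariates and observation pattern share their
    implied moments, which are computed once per such group.
    """
    spec = spec or dataset.spec
    params.validate(spec)
    B = params.re.cov()
    sigma2 = params.sigma**2
    eta0 = np.array([lp.eta0 for lp in params.links], dtype=object)
    weights = [lp.weights for lp in params.links]

    # stage-level decompositions reused across covariate groups
    groups = dataset.groups()
    max_steps: dict = {}
    for g in groups:
        max_steps[g.stage] = max(max_steps.get(g.stage, 0), g.n_steps)
    trans_cache = {
        stage: _stage_transition_matrices(params, spec, stage, n)
        for stage, n in max_steps.items()
    }

    D = spec.n_dimensions
    delta = spec.delta
    total = 0.0
    for g in groups:
        n_subj, n_obs = g.values.shape
        # latent decomposition for this group's covariates
        E0 = params.beta @ g.x_init
        gg = params.gamma @ np.concatenate([[1.0], g.x_change])
        S = _run_recursion(trans_cache[g.stage], g.n_steps, D, delta, E0, gg)
        rows = S[g.node, g.dim_idx, :]  # (n_obs, 1 + 2D)
        mean = rows[:, 0]
        Z = rows[:, 1:]
        cov = Z @ B @ Z.T + np.diag(sigma2[g.marker_idx])

        # transformed values and Jacobians, vectorized per marker
        z = np.empty((n_subj, n_obs))
        logjac = 0.0
        for m, (pos, I, M) in g.marker_blocks.items():
            z[:, pos] = float(eta0[m]) + I @ weights[m]
            jac = M @ weights[m]
            if np.any(jac <= 0):
                return -np.inf
            logjac += float(np.sum(np.log(jac)))

        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            sid = dataset.subjects[g.subject_indices[0]].id
            raise NumericalError(
                f"singular observation covariance (subject {sid!r} pattern)"
            ) from exc
        sol = solve_triangular(L, (z - mean).T, lower=True, check_finite=False)
        quad = float(np.sum(sol * sol))
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        total += (
            -0.5 * quad
            - 0.5 * n_subj * (logdet + n_obs * _LOG_2PI)
            + logjac
        )
    return total
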