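"""Parameter containers and the bijective map to an unconstrained vector.

Identifiability: the latent processes are standardized at baseline in the
reference category — the reference intercept of each initial level is
structurally zero (absent from the design) and the variance of each random
intercept ``u_d`` is fixed to one, so every fixed effect is in units of the
baseline SD of its dimension.

The unconstrained ("raw") vector concatenates, in order: initial-level fixed
effects ``beta``, change fixed effects ``gamma`` (intercept first), temporal
influence coefficients ``alpha``, random-effect covariance parameters, log
measurement-error SDs, and per-marker link coefficients (location ``eta0``
plus raw weights whose squares are the I-spline weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .links import LinkParameters
from .spec import ConfigurationError, ModelSpec


class NumericalError(RuntimeError):
    """A numerical failure during model evaluation."""


# ---------------------------------------------------------------------------
# random-effect covariance
# ---------------------------------------------------------------------------


@dataclass
class RandomEffectParameters:
    """Covariance of the stacked random effects ``(u_1..u_D, v_1..v_D)``.

    ``u`` are the random intercepts of the initial levels (unit variance by
    the standardization constraint), ``v`` the random effects on the annual
    rate of change.

    structure ``"full"``
        Lower Cholesky factor of the 2D x 2D covariance with the ``u`` rows
        constrained to unit norm (hyperspherical angles), making the
        ``u``-block exactly a correlation matrix; the ``v`` rows are free
        with log-parameterized diagonal.
    structure ``"diagonal"``
        Independent effects: Var(u_d) = 1, Var(v_d) = exp(2 raw_d).
    """

    structure: str
    raw: np.ndarray
    n_dimensions: int

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if self.structure not in ("full", "diagonal"):
            raise ConfigurationError(f"unknown RE structure {self.structure!r}")
        if self.raw.shape != (n_re_raw(self.structure, self.n_dimensions),):
            raise ConfigurationError(
                f"RE raw vector has length {self.raw.size}, expected "
                f"{n_re_raw(self.structure, self.n_dimensions)}"
            )

    def cholesky(self) -> np.ndarray:
        D = self.n_dimensions
        L = np.zeros((2 * D, 2 * D))
        if self.structure == "diagonal":
            L[np.arange(D), np.arange(D)] = 1.0
            L[np.arange(D, 2 * D), np.arange(D, 2 * D)] = np.exp(self.raw)
            return L
        pos = 0
        L[0, 0] = 1.0
        for i in range(1, D):  # unit-norm rows via spherical angles in (0, pi)
            angles = np.pi / (1.0 + np.exp(-self.raw[pos : pos + i]))
            pos += i
            sin_prod = 1.0
            for j, th in enumerate(angles):
                L[i, j] = sin_prod * np.cos(th)
                sin_prod *= np.sin(th)
            L[i, i] = sin_prod
        for i in range(D, 2 * D):
            L[i, :i] = self.raw[pos : pos + i]
            pos += i
            L[i, i] = np.exp(self.raw[pos])
            pos += 1
        return L

    def cov(self) -> np.ndarray:
        L = self.cholesky()
        return L @ L.T


def n_re_raw(structure: str, D: int) -> int:
    if structure == "diagonal":
        return D
    return D * (D - 1) // 2 + sum(i + 1 for i in range(D, 2 * D))


def diagonal_re(v_sd, D: int | None = None) -> RandomEffectParameters:
    v_sd = np.atleast_1d(np.asarray(v_sd, dtype=float))
    D = D or v_sd.size
    return RandomEffectParameters("diagonal", np.log(v_sd), D)


def full_re_from_cov(B: np.ndarray) -> RandomEffectParameters:
    """Raw parameters whose implied covariance is ``B`` (Var(u_d) must be 1)."""
    B = np.asarray(B, dtype=float)
    D = B.shape[0] // 2
    if not np.allclose(np.diag(B)[:D], 1.0):
        raise ConfigurationError("u-block of B must have unit variances")
    L = np.linalg.cholesky(B)
    raw = []
    for i in range(1, D):  # invert the spherical construction
        sin_prod = 1.0
        for j in range(i):
            c = np.clip(L[i, j] / sin_prod, -1 + 1e-12, 1 - 1e-12)
            th = np.arccos(c)
            raw.append(np.log(th / (np.pi - th)))
            sin_prod *= np.sin(th)
    for i in range(D, 2 * D):
        raw.extend(L[i, :i])
        raw.append(np.log(L[i, i]))
    return RandomEffectParameters("full", np.asarray(raw), D)


# ---------------------------------------------------------------------------
# full parameter set
# ---------------------------------------------------------------------------


@dataclass
class Parameters:
    """All estimable quantities of the model, on their natural scales.

    Attributes
    ----------
    beta : (D, p_init) array
        Initial-level fixed effects (reference intercept structurally 0).
    gamma : (D, 1 + p_change) array
        Change fixed effects, intercept in column 0; annual-rate units.
    alpha : dict
        ``(target_dim_index, source_dim_index, stage) -> coefficient vector``
        over the influence time basis ([1] self, [1, t] cross).
    re : RandomEffectParameters
    sigma : (M,) array
        Measurement-error SD per marker, latent scale.
    links : list of LinkParameters, one per marker.
    """

    beta: np.ndarray
    gamma: np.ndarray
    alpha: dict
    re: RandomEffectParameters
    sigma: np.ndarray
    links: list

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)

    def validate(self, spec: ModelSpec):
        D = spec.n_dimensions
        if self.beta.shape != (D, len(spec.init_columns)):
            raise ConfigurationError(f"beta shape {self.beta.shape} invalid")
        if self.gamma.shape != (D, 1 + len(spec.change_columns)):
            raise ConfigurationError(f"gamma shape {self.gamma.shape} invalid")
        if self.sigma.shape != (spec.n_markers,) or np.any(self.sigma <= 0):
            raise ConfigurationError("sigma must be positive, one per marker")
        for d in range(D):
            for k in range(D):
                for s in spec.stages:
                    a = np.asarray(self.alpha[(d, k, s)])
                    if a.shape != (spec.influence_basis_size(d, k),):
                        raise ConfigurationError(
                            f"alpha[{d},{k},{s}] has wrong basis size"
                        )
        if len(self.links) != spec.n_markers:
            raise ConfigurationError("one LinkParameters per marker required")
        for name, arr in (("beta", self.beta), ("gamma", self.gamma),
                          ("sigma", self.sigma), ("re", self.re.raw)):
            if not np.all(np.isfinite(arr)):
                raise NumericalError(f"non-finite values in parameter block {name!r}")


def zero_alpha(spec: ModelSpec) -> dict:
    return {
        (d, k, s): np.zeros(spec.influence_basis_size(d, k))
        for d in range(spec.n_dimensions)
        for k in range(spec.n_dimensions)
        for s in spec.stages
    }


# ---------------------------------------------------------------------------
# raw-vector mapping
# ---------------------------------------------------------------------------


class ParameterMap:
    """Bijective map between :class:`Parameters` and an unconstrained vector."""

    def __init__(self, spec: ModelSpec, re_structure: str = "full"):
        self.spec = spec
        self.re_structure = re_structure
        D = spec.n_dimensions
        p_init = len(spec.init_columns)
        p_change = len(spec.change_columns)
        names: list = []
        for dim in spec.dimensions:
            names += [f"beta[{dim}].{c}" for c in spec.init_columns]
        for dim in spec.dimensions:
            names += [f"gamma[{dim}].intercept"]
            names += [f"gamma[{dim}].{c}" for c in spec.change_columns]
        self._alpha_index: dict = {}
        for d in range(D):
            for k in range(D):
                for s in spec.stages:
                    nb = spec.influence_basis_size(d, k)
                    for b in range(nb):
                        self._alpha_index[(d, k, s, b)] = len(names)
                        basis = "t" if b == 1 else "1"
                        names.append(
                            f"alpha[{spec.dimensions[d]}<-{spec.dimensions[k]},{s},{basis}]"
                        )
        self._re_start = len(names)
        names += [f"re.raw[{i}]" for i in range(n_re_raw(re_structure, D))]
        self._sigma_start = len(names)
        names += [f"log_sigma[{m.name}]" for m in spec.markers]
        self._link_start = len(names)
        for m in spec.markers:
            names += [f"link[{m.name}].eta0"]
            names += [f"link[{m.name}].eta_raw[{l}]" for l in range(m.link.n_basis)]
        self.names = names
        self.n_parameters = len(names)
        self._D, self._p_init, self._p_change = D, p_init, p_change

    def alpha_raw_index(self, d: int, k: int, stage: str, b: int) -> int:
        """Raw-vector position of one influence coefficient (identity-mapped)."""
        return self._alpha_index[(d, k, stage, b)]

    def beta_index(self, d: int, j: int) -> int:
        return d * self._p_init + j

    def gamma_index(self, d: int, j: int) -> int:
        """Raw position of gamma[d, j]; j = 0 is the intercept."""
        return self._D * self._p_init + d * (1 + self._p_change) + j

    def pack(self, params: Parameters) -> np.ndarray:
        spec = self.spec
        params.validate(spec)
        if params.re.structure != self.re_structure:
            raise ConfigurationError(
                f"parameters use RE structure {params.re.structure!r}, "
                f"map expects {self.re_structure!r}"
            )
        parts = [params.beta.ravel(), params.gamma.ravel()]
        alpha_flat = []
        for d in range(self._D):
            for k in range(self._D):
                for s in spec.stages:
                    alpha_flat.append(np.asarray(params.alpha[(d, k, s)], dtype=float))
        parts.append(np.concatenate(alpha_flat))
        parts.append(params.re.raw)
        parts.append(np.log(params.sigma))
        for m, lp in zip(spec.markers, params.links):
            parts.append(np.concatenate([[lp.eta0], lp.eta_raw]))
        return np.concatenate(parts)

    def unpack(self, raw: np.ndarray) -> Parameters:
        raw = np.asarray(raw, dtype=float)
        if raw.shape != (self.n_parameters,):
            raise ConfigurationError(
                f"raw vector length {raw.size}, expected {self.n_parameters}"
            )
        spec, D = self.spec, self._D
        pos = 0
        beta = raw[pos : pos + D * self._p_init].reshape(D, self._p_init)
        pos += D * self._p_init
        gamma = raw[pos : pos + D * (1 + self._p_change)].reshape(D, 1 + self._p_change)
        pos += D * (1 + self._p_change)
        alpha = {}
        for d in range(D):
            for k in range(D):
                for s in spec.stages:
                    nb = spec.influence_basis_size(d, k)
                    alpha[(d, k, s)] = raw[pos : pos + nb].copy()
                    pos += nb
        n_re = n_re_raw(self.re_structure, D)
        re = RandomEffectParameters(self.re_structure, raw[pos : pos + n_re], D)
        pos += n_re
        sigma = np.exp(raw[pos : pos + spec.n_markers])
        pos += spec.n_markers
        links = []
        for m in spec.markers:
            nb = m.link.n_basis
            links.append(LinkParameters(raw[pos], raw[pos + 1 : pos + 1 + nb]))
            pos += 1 + nb
        return Parameters(beta, gamma, alpha, re, sigma, links)
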