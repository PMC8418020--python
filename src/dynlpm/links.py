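"""Monotone spline link functions between bounded markers and latent scales.

Psychometric scores (MMSE, IST, BVRT, TMT-B, ADL limitation sums) are bounded
and curvilinear: intervals of the raw score do not represent equal amounts of
the underlying trait, and ceiling/floor effects pile observations at the
bounds.  Each marker is therefore mapped to its latent dimension through a
marker-specific monotone transformation

    H(y) = eta0 + sum_l w_l * I_l(y),      w_l = eta_raw_l**2 >= 0,

where ``I_l`` are I-splines (integrated M-splines) on the marker's theoretical
range.  Non-negative weights make H nondecreasing by construction; squaring
raw coefficients keeps the parameter space unconstrained for the optimizer
while leaving the flat link representable.

M-splines are density-normalized B-splines (each integrates to one over its
support); I-splines are their running integrals, rising from 0 at the lower
bound to 1 at the upper bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline


class LinkDomainError(ValueError):
    """A marker value lies outside the marker's theoretical range."""


class InvalidLinkParametersError(ValueError):
    """Link parameters do not define a usable monotone transformation."""


@dataclass(frozen=True)
class LinkSpec:
    """Knot configuration of one marker's monotone spline link.

    Parameters
    ----------
    marker : str
        Marker name (e.g. ``"MMSE"``).
    y_min, y_max : float
        Theoretical bounds of the marker scale.  Boundary knots sit at these
        bounds rather than at observed extremes so the link is stable across
        datasets.
    degree : int
        Spline degree of the M-spline basis (quadratic by default).
    interior_knots : tuple of float
        Strictly increasing knots inside ``(y_min, y_max)``; typically the
        empirical quartiles (two knots) or the median (one knot).
    """

    marker: str
    y_min: float
    y_max: float
    degree: int = 2
    interior_knots: tuple = ()

    def __post_init__(self):
        if not np.isfinite(self.y_min) or not np.isfinite(self.y_max):
            raise ValueError(f"{self.marker}: non-finite bounds")
        if self.y_min >= self.y_max:
            raise ValueError(f"{self.marker}: y_min must be < y_max")
        if self.degree < 1:
            raise ValueError(f"{self.marker}: degree must be >= 1")
        knots = tuple(float(k) for k in self.interior_knots)
        inside = tuple(k for k in knots if self.y_min < k < self.y_max)
        uniq = tuple(dict.fromkeys(inside))  # preserves order, drops dups
        if uniq != knots:
            # very discrete markers can put several quantiles on one value
            warnings.warn(
                f"{self.marker}: interior knots {knots} collapsed to {uniq} "
                "(duplicates and knots at the bounds removed)",
                UserWarning,
                stacklevel=3,
            )
        if any(b <= a for a, b in zip(uniq, uniq[1:])):
            raise ValueError(f"{self.marker}: interior knots must be increasing")
        object.__setattr__(self, "interior_knots", uniq)
        if self.n_basis < 2:
            raise ValueError(f"{self.marker}: n_basis must be >= 2")

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + self.degree + 1

    @property
    def knot_vector(self) -> np.ndarray:
        d = self.degree
        return np.concatenate(
            [[self.y_min] * (d + 1), self.interior_knots, [self.y_max] * (d + 1)]
        )


def interior_knots_from_quantiles(values, n_knots: int) -> tuple:
    """Interior knots at equally spaced quantiles of observed marker values.

    ``n_knots=2`` gives the quartiles, ``n_knots=1`` the median.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to place knots")
    probs = (2 * np.arange(1, n_knots + 1) - 1) / (2 * n_knots)
    return tuple(float(q) for q in np.quantile(values, probs))


@dataclass
class LinkParameters:
    """Coefficients of one marker link: location ``eta0`` and raw weights."""

    eta0: float
    eta_raw: np.ndarray

    def __post_init__(self):
        self.eta_raw = np.asarray(self.eta_raw, dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return self.eta_raw**2

    @property
    def is_flat(self) -> bool:
        return not np.any(self.weights > 0)


@lru_cache(maxsize=None)
def _antiderivatives(spec: LinkSpec):
    """Per-basis antiderivative splines of the M-spline basis."""
    t = spec.knot_vector
    k = spec.degree
    out = []
    for l in range(spec.n_basis):
        c = np.zeros(spec.n_basis)
        c[l] = (k + 1) / (t[l + k + 1] - t[l])  # M-spline normalization
        out.append(BSpline(t, c, k, extrapolate=False).antiderivative())
    return tuple(out)


def _check_domain(y: np.ndarray, spec: LinkSpec):
    bad = (y < spec.y_min - 1e-12) | (y > spec.y_max + 1e-12) | ~np.isfinite(y)
    if np.any(bad):
        raise LinkDomainError(
            f"{spec.marker}: value(s) {np.atleast_1d(y)[np.atleast_1d(bad)][:5]} "
            f"outside theoretical range [{spec.y_min}, {spec.y_max}]"
        )


def mspline_basis(y, spec: LinkSpec) -> np.ndarray:
    """Evaluate the density-normalized M-spline basis at marker values ``y``.

    Returns an array of shape ``y.shape + (n_basis,)``; every entry is
    non-negative and each basis function integrates to one over its support.
    """
    y = np.asarray(y, dtype=float)
    _check_domain(y, spec)
    t = spec.knot_vector
    k = spec.degree
    yy = np.clip(y.ravel(), spec.y_min, spec.y_max)
    B = BSpline.design_matrix(yy, t, k, extrapolate=False).toarray()
    scale = (k + 1) / (t[k + 1 : k + 1 + spec.n_basis] - t[: spec.n_basis])
    return (B * scale).reshape(y.shape + (spec.n_basis,))


def ispline_basis(y, spec: LinkSpec) -> np.ndarray:
    """Evaluate the I-spline basis (running integrals of the M-splines).

    Each component is nondecreasing in ``y``, 0 at ``y_min`` and 1 at
    ``y_max``.
    """
    y = np.asarray(y, dtype=float)
    _check_domain(y, spec)
    yy = np.clip(y.ravel(), spec.y_min, spec.y_max)
    anti = _antiderivatives(spec)
    cols = [np.clip(a(yy) - a(spec.y_min), 0.0, 1.0) for a in anti]
    out = np.stack(cols, axis=-1)
    return out.reshape(y.shape + (spec.n_basis,))


def _check_params(spec: LinkSpec, params: LinkParameters):
    if params.eta_raw.shape != (spec.n_basis,):
        raise InvalidLinkParametersError(
            f"{spec.marker}: expected {spec.n_basis} raw weights, "
            f"got {params.eta_raw.shape}"
        )


def transform(y, spec: LinkSpec, params: LinkParameters):
    """Map marker values to the latent scale: ``eta0 + sum_l w_l I_l(y)``."""
    _check_params(spec, params)
    return params.eta0 + ispline_basis(y, spec) @ params.weights


def transform_jacobian(y, spec: LinkSpec, params: LinkParameters):
    """Derivative dH/dy = ``sum_l w_l M_l(y)``; non-negative everywhere."""
    _check_params(spec, params)
    return mspline_basis(y, spec) @ params.weights


def latent_range(spec: LinkSpec, params: LinkParameters) -> tuple:
    """Attainable latent interval ``[H(y_min), H(y_max)]``."""
    return params.eta0, params.eta0 + float(np.sum(params.weights))


def inverse_transform(lam, spec: LinkSpec, params: LinkParameters, n_iter: int = 80):
    """Invert the link: the marker value whose transform equals ``lam``.

    Values of ``lam`` outside the attainable latent interval are clamped to
    the corresponding bound.  Inversion is by vectorized bisection, accurate
    to ``(y_max - y_min) * 2**-n_iter``.
    """
    _check_params(spec, params)
    if params.is_flat:
        raise InvalidLinkParametersError(
            f"{spec.marker}: flat link (all weights zero) is not invertible"
        )
    lam = np.asarray(lam, dtype=float)
    scalar = lam.ndim == 0
    lam = np.atleast_1d(lam)
    lo = np.full(lam.shape, spec.y_min)
    hi = np.full(lam.shape, spec.y_max)
    w = params.weights
    anti = _antiderivatives(spec)

    def H(yy):
        cols = np.stack([a(yy) - a(spec.y_min) for a in anti], axis=-1)
        return params.eta0 + cols @ w

    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        below = H(mid) < lam
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    y = 0.5 * (lo + hi)
    h_min, h_max = latent_range(spec, params)
    y = np.where(lam <= h_min, spec.y_min, y)
    y = np.where(lam >= h_max, spec.y_max, y)
    return float(y[0]) if scalar else y


def identity_link_parameters(spec: LinkSpec) -> LinkParameters:
    """Parameters making H the identity map, for degree-1 no-knot specs.

    With two linear I-splines of equal weight the transform is exactly
    ``H(y) = y``; useful for reducing the model to an ordinary linear mixed
    model in tests and pipelines on already-Gaussian markers.
    """
    if spec.degree != 1 or spec.interior_knots:
        raise ValueError("identity link requires degree 1 and no interior knots")
    half_range = (spec.y_max - spec.y_min) / 2.0
    return LinkParameters(eta0=spec.y_min, eta_raw=np.sqrt([half_range, half_range]))
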