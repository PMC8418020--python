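"""Model specification: dimensions, markers, covariate designs, dynamics layout.

The structural model follows two latent dimensions (cognition and functional
dependency) on a finely discretized time grid of step ``delta`` years
(3 months by default), deliberately unrelated to the visit schedule.  Each
dimension's initial level and rate of change are regressed on baseline
covariates; the rate of change additionally depends on the *current* level of
every dimension through stage-specific temporal-influence coefficients
(constant in time for self-effects, linear in time for cross-effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .links import LinkSpec


class ConfigurationError(ValueError):
    """The model specification or a request against it is inconsistent."""


#: covariate factors and their non-reference levels (reference listed first)
FACTOR_LEVELS = {
    "stage": ("CN", "MCI", "AD"),
    "age_cat": ("q1", "q2", "q3", "q4", "q5"),
    "sex": ("male", "female"),
    "educ": ("higher", "lower"),
    "apoe4": (0, 1),
}

DEFAULT_INIT_TERMS = ("stage", "age_cat", "apoe4", "sex", "educ", "educ:stage")
DEFAULT_CHANGE_TERMS = ("stage", "age_cat", "apoe4", "sex", "educ")


def _term_columns(term: str) -> list:
    """Design column names contributed by one model term."""
    if term == "stage":
        return ["stage:MCI", "stage:AD"]
    if term == "age_cat":
        return [f"age_cat:{q}" for q in ("q2", "q3", "q4", "q5")]
    if term == "apoe4":
        return ["apoe4"]
    if term == "sex":
        return ["sex:female"]
    if term == "educ":
        return ["educ:lower"]
    if term == "educ:stage":
        return ["educ:lower*stage:MCI", "educ:lower*stage:AD"]
    raise ConfigurationError(f"unknown design term {term!r}")


def design_columns(terms) -> list:
    cols = []
    for term in terms:
        cols.extend(_term_columns(term))
    return cols


def design_row(terms, covariates: dict) -> np.ndarray:
    """Expand a subject's covariates into the design row for ``terms``.

    ``covariates`` maps factor names to levels, e.g.
    ``{"stage": "MCI", "age_cat": "q3", "sex": "female", "educ": "lower",
    "apoe4": 1}``.
    """
    stage = covariates["stage"]
    vals = []
    for term in terms:
        if term == "stage":
            vals += [float(stage == "MCI"), float(stage == "AD")]
        elif term == "age_cat":
            vals += [float(covariates["age_cat"] == q) for q in ("q2", "q3", "q4", "q5")]
        elif term == "apoe4":
            vals += [float(covariates["apoe4"])]
        elif term == "sex":
            vals += [float(covariates["sex"] == "female")]
        elif term == "educ":
            vals += [float(covariates["educ"] == "lower")]
        elif term == "educ:stage":
            low = float(covariates["educ"] == "lower")
            vals += [low * float(stage == "MCI"), low * float(stage == "AD")]
        else:
            raise ConfigurationError(f"unknown design term {term!r}")
    return np.asarray(vals)


@dataclass(frozen=True)
class MarkerSpec:
    """One observed marker: its name, latent dimension, and link knots."""

    name: str
    dimension: str
    link: LinkSpec


@dataclass(frozen=True)
class ModelSpec:
    """Full structural specification of the dynamic latent process model."""

    dimensions: tuple = ("cognition", "function")
    stages: tuple = ("CN", "MCI", "AD")
    markers: tuple = ()
    delta: float = 0.25  # discretization step, years (3 months)
    init_terms: tuple = DEFAULT_INIT_TERMS
    change_terms: tuple = DEFAULT_CHANGE_TERMS
    cross_time_linear: bool = True
    horizon: float = 4.75  # maximum grid time, years (57 months)

    def __post_init__(self):
        if self.delta <= 0:
            raise ConfigurationError("delta must be positive")
        if self.horizon <= 0:
            raise ConfigurationError("horizon must be positive")
        if not self.markers:
            raise ConfigurationError("at least one marker is required")
        for m in self.markers:
            if m.dimension not in self.dimensions:
                raise ConfigurationError(
                    f"marker {m.name!r} maps to unknown dimension {m.dimension!r}"
                )
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate marker names")

    # -- sizes ------------------------------------------------------------
    @property
    def n_dimensions(self) -> int:
        return len(self.dimensions)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_grid(self) -> int:
        """Number of grid steps covering [0, horizon]."""
        return int(round(self.horizon / self.delta))

    @property
    def init_columns(self) -> list:
        return design_columns(self.init_terms)

    @property
    def change_columns(self) -> list:
        return design_columns(self.change_terms)

    # -- lookups ----------------------------------------------------------
    def dimension_index(self, name: str) -> int:
        try:
            return self.dimensions.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown dimension {name!r}") from None

    def stage_index(self, stage: str) -> int:
        try:
            return self.stages.index(stage)
        except ValueError:
            raise ConfigurationError(f"unknown stage {stage!r}") from None

    def marker_index(self, name: str) -> int:
        for i, m in enumerate(self.markers):
            if m.name == name:
                return i
        raise ConfigurationError(f"unknown marker {name!r}")

    def marker_dimension_index(self, marker_index: int) -> int:
        return self.dimension_index(self.markers[marker_index].dimension)

    def influence_basis_size(self, d: int, k: int) -> int:
        """Number of time-basis coefficients of the d<-k influence."""
        return 1 if d == k or not self.cross_time_linear else 2

    def influence_time_basis(self, d: int, k: int, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("influence time must be non-negative")
        if self.influence_basis_size(d, k) == 1:
            return np.array([1.0])
        return np.array([1.0, float(t)])

    def grid_node(self, time_months: float) -> int:
        """Nearest grid node to a visit time; exact half-way ties round down."""
        t_years = float(time_months) / 12.0
        return int(np.floor(t_years / self.delta + 0.5 - 1e-9))

    def with_markers(self, markers) -> "ModelSpec":
        return replace(self, markers=tuple(markers))


#: theoretical marker ranges and default interior knots of the five-marker
#: battery (cognition: MMSE, IST, BVRT, TMT-B; function: ADL limitation sum).
#: TMT-B (correct moves per minute) is positive continuous; 90 is a safe
#: operational ceiling.  Interior knots default to typical cohort quartiles
#: (median for the ADL sum) and are normally re-placed from the data at
#: model-build time.
def default_markers() -> tuple:
    return (
        MarkerSpec("MMSE", "cognition", LinkSpec("MMSE", 0, 30, 2, (24.0, 28.0))),
        MarkerSpec("IST", "cognition", LinkSpec("IST", 0, 82, 2, (30.0, 45.0))),
        MarkerSpec("BVRT", "cognition", LinkSpec("BVRT", 0, 15, 2, (9.0, 12.0))),
        MarkerSpec("TMTB", "cognition", LinkSpec("TMTB", 0, 90, 2, (10.0, 25.0))),
        MarkerSpec("ADL", "function", LinkSpec("ADL", 0, 18, 2, (3.0,))),
    )


def default_model_spec(**overrides) -> ModelSpec:
    """The default two-dimension, five-marker specification."""
    kwargs = dict(markers=default_markers())
    kwargs.update(overrides)
    return ModelSpec(**kwargs)


def spec_with_knots_from_data(spec: ModelSpec, df) -> ModelSpec:
    """Re-place each marker's interior knots at its observed quantiles.

    Markers keep their configured *number* of knots; quartiles for two knots,
    the median for one.
    """
    from .links import interior_knots_from_quantiles

    new_markers = []
    for m in spec.markers:
        vals = df.loc[df["marker"] == m.name, "value"]
        n_knots = len(m.link.interior_knots)
        if n_knots and len(vals):
            knots = interior_knots_from_quantiles(vals, n_knots)
            link = LinkSpec(m.name, m.link.y_min, m.link.y_max, m.link.degree, knots)
            new_markers.append(MarkerSpec(m.name, m.dimension, link))
        else:
            new_markers.append(m)
    return spec.with_markers(new_markers)
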