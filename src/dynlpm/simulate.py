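"""Synthetic three-stage cohort generator.

Generates COGICARE-like longitudinal data with the statistical structure the
analysis assumes: 102 CN / 123 MCI / 72 AD participants, five bounded
markers observed through monotone links, 6-monthly visits over the first two
years followed by sparser follow-ups up to 57 months, marker-specific
administration patterns (TMT-B at two planned visits only, BVRT sparse for
CN), and monotone stage-dependent dropout that depends on observed
covariates only (missing at random).

The generator is the exact generative mirror of the analysis model: latent
trajectories follow the discretized difference equations, observations are
``inverse_link(latent + Gaussian error)``.  ``discrete`` mode additionally
rounds scores to their integer grid, reproducing realistic ceiling/floor
pile-ups at the cost of a small rounding bias (excluded from parameter
recovery checks for that reason).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import REQUIRED_COLUMNS
from .links import LinkSpec, inverse_transform, latent_range
from .parameters import Parameters
from .model import propagate
from .reference import reference_parameters
from .spec import MarkerSpec, ModelSpec, default_model_spec


class InvalidCohortConfigError(ValueError):
    pass


_FULL = (0.0, 6.0, 12.0, 18.0, 24.0, 36.0, 57.0)
_3C_ONLY = (0.0, 36.0, 57.0)


def _default_marker_schedule() -> dict:
    """Months at which each marker is administered, by stage."""
    return {
        "MMSE": {"CN": _FULL, "MCI": _FULL, "AD": _FULL},
        "IST": {"CN": _FULL, "MCI": _FULL, "AD": _FULL},
        "ADL": {"CN": _FULL, "MCI": _FULL, "AD": _FULL},
        # BVRT needs a face-to-face visit: sparse for CN
        "BVRT": {"CN": _3C_ONLY, "MCI": _FULL, "AD": _FULL},
        # TMT-B only at the two planned parent-cohort visits
        "TMTB": {"CN": (0.0, 36.0), "MCI": (0.0, 36.0), "AD": (0.0, 36.0)},
    }


@dataclass
class CohortConfig:
    """Study conditions of a simulated cohort.

    Defaults reproduce the observed cohort: per-stage sample sizes and
    covariate mixes, the visit schedule, administration patterns and
    stage-dependent monotone dropout (highest for AD).  ``truth`` defaults to
    the published estimates plus documented defaults for unprinted
    quantities.
    """

    spec: ModelSpec = field(default_factory=default_model_spec)
    truth: Parameters | None = None
    n_per_stage: dict = field(
        default_factory=lambda: {"CN": 102, "MCI": 123, "AD": 72}
    )
    p_female: dict = field(
        default_factory=lambda: {"CN": 0.6765, "MCI": 0.5854, "AD": 0.6528}
    )
    p_educ_lower: dict = field(
        default_factory=lambda: {"CN": 0.2255, "MCI": 0.3415, "AD": 0.3750}
    )
    p_apoe4: dict = field(
        default_factory=lambda: {"CN": 0.1471, "MCI": 0.1382, "AD": 0.3611}
    )
    age_probs: dict = field(
        default_factory=lambda: {s: (0.2,) * 5 for s in ("CN", "MCI", "AD")}
    )
    schedule_months: tuple = _FULL
    marker_schedule: dict = field(default_factory=_default_marker_schedule)
    dropout_hazard: dict = field(
        default_factory=lambda: {"CN": 0.13, "MCI": 0.13, "AD": 0.20}
    )
    mode: str = "continuous"
    #: decimals for rounding in discrete mode (integer grid by default)
    discrete_decimals: dict = field(default_factory=lambda: {"TMTB": 1})
    seed: int = 0

    def __post_init__(self):
        if self.truth is None:
            self.truth = reference_parameters(self.spec)
        if self.mode not in ("continuous", "discrete"):
            raise InvalidCohortConfigError(f"unknown mode {self.mode!r}")
        for s in self.spec.stages:
            if self.n_per_stage.get(s, 0) < 1:
                raise InvalidCohortConfigError(f"need n >= 1 for stage {s}")
            for p in (
                self.p_female[s],
                self.p_educ_lower[s],
                self.p_apoe4[s],
                *self.age_probs[s],
            ):
                if not 0.0 <= p <= 1.0:
                    raise InvalidCohortConfigError("proportions must be in [0, 1]")
            if not 0.0 <= self.dropout_hazard[s] < 1.0:
                raise InvalidCohortConfigError("dropout hazard must be in [0, 1)")
        months = set(self.schedule_months)
        for m in self.spec.markers:
            sched = self.marker_schedule.get(m.name)
            if sched is None:
                raise InvalidCohortConfigError(f"no schedule for marker {m.name}")
            for s in self.spec.stages:
                if not set(sched[s]) <= months:
                    raise InvalidCohortConfigError(
                        f"{m.name} schedule not a subset of the visit schedule"
                    )
        if max(self.schedule_months) > self.spec.horizon * 12 + 1e-9:
            raise InvalidCohortConfigError("schedule exceeds the model horizon")
        for lp, m in zip(self.truth.links, self.spec.markers):
            if lp.is_flat:
                raise InvalidCohortConfigError(f"flat link for {m.name} in truth")


def simulate_cohort(config: CohortConfig, seed: int | None = None):
    """Draw one cohort; returns ``(long dataframe, truth dict)``.

    The truth dict holds the generating parameters, each subject's random
    effects, and each subject's latent trajectory on the full grid.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    spec, truth = config.spec, config.truth
    D = spec.n_dimensions
    Lre = np.linalg.cholesky(truth.re.cov())
    n_grid = spec.n_grid

    rows = []
    re_draws = {}
    latents = {}
    lam_obs: dict = {i: [] for i in range(spec.n_markers)}  # latent values to invert
    row_refs: dict = {i: [] for i in range(spec.n_markers)}

    sid = 0
    for stage in spec.stages:
        hazard = config.dropout_hazard[stage]
        for _ in range(config.n_per_stage[stage]):
            sid += 1
            subject_id = f"S{sid:04d}"
            cov = {
                "stage": stage,
                "age_cat": f"q{1 + rng.choice(5, p=np.asarray(config.age_probs[stage]))}",
                "sex": "female" if rng.random() < config.p_female[stage] else "male",
                "educ": "lower" if rng.random() < config.p_educ_lower[stage] else "higher",
                "apoe4": int(rng.random() < config.p_apoe4[stage]),
            }
            uv = Lre @ rng.standard_normal(2 * D)
            decomp = propagate(spec, truth, cov, stage, n_grid)
            lam = decomp.E + decomp.P @ uv[:D] + decomp.Q @ uv[D:]
            re_draws[subject_id] = uv
            latents[subject_id] = lam
            # monotone dropout: first missed visit ends follow-up
            n_visits = 1
            while n_visits < len(config.schedule_months) and rng.random() >= hazard:
                n_visits += 1
            attended = config.schedule_months[:n_visits]
            for month in attended:
                node = spec.grid_node(month)
                for mi, m in enumerate(spec.markers):
                    if month not in config.marker_schedule[m.name][stage]:
                        continue
                    d = spec.marker_dimension_index(mi)
                    eps = truth.sigma[mi] * rng.standard_normal()
                    lam_obs[mi].append(lam[node, d] + eps)
                    row_refs[mi].append(len(rows))
                    rows.append(
                        {
                            "subject_id": subject_id,
                            **cov,
                            "time_months": month,
                            "marker": m.name,
                            "value": np.nan,
                        }
                    )

    # invert links marker by marker (vectorized bisection)
    for mi, m in enumerate(spec.markers):
        if not lam_obs[mi]:
            continue
        y = inverse_transform(np.asarray(lam_obs[mi]), m.link, truth.links[mi])
        if config.mode == "discrete":
            dec = config.discrete_decimals.get(m.name, 0)
            y = np.clip(np.round(y, dec), m.link.y_min, m.link.y_max)
        for ref, yy in zip(row_refs[mi], y):
            rows[ref]["value"] = float(yy)

    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    truth_info = {
        "parameters": truth,
        "random_effects": re_draws,
        "latent_trajectories": latents,
        "grid_times_years": spec.delta * np.arange(n_grid + 1),
    }
    return df, truth_info


def expected_median_visits(config: CohortConfig, stage: str) -> int:
    """Median number of attended visits implied by schedule and dropout."""
    h = config.dropout_hazard[stage]
    n_sched = len(config.schedule_months)
    # P(visits >= k) = (1-h)^(k-1); median = largest k with P >= 0.5
    med = 1
    for k in range(1, n_sched + 1):
        if (1 - h) ** (k - 1) >= 0.5:
            med = k
    return med


def summarize_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: counts, covariate mixes, measures per subject.

    One row per (statistic, marker) combination with one column per stage,
    mirroring the usual baseline-characteristics layout.
    """
    if df.empty:
        raise ValueError("empty dataset")
    stages = [s for s in ("CN", "MCI", "AD") if s in set(df["stage"])] or sorted(
        set(df["stage"])
    )
    base = df.drop_duplicates("subject_id")
    out = {}
    for s in stages:
        sub = base[base["stage"] == s]
        dsub = df[df["stage"] == s]
        col = {
            "N": len(sub),
            "female (%)": 100 * (sub["sex"] == "female").mean(),
            "educ lower (%)": 100 * (sub["educ"] == "lower").mean(),
            "apoe4 (%)": 100 * sub["apoe4"].astype(float).mean(),
        }
        n_visits = dsub.groupby("subject_id")["time_months"].nunique()
        col["visits: median (min-max)"] = (
            f"{n_visits.median():g} ({n_visits.min()}-{n_visits.max()})"
        )
        for marker, mdf in dsub.groupby("marker"):
            v = mdf["value"]
            col[f"{marker} value: median (min-max)"] = (
                f"{v.median():g} ({v.min():g}-{v.max():g})"
            )
            n = mdf.groupby("subject_id")["time_months"].nunique()
            col[f"{marker} measures/subject: median (min-max)"] = (
                f"{n.median():g} ({n.min()}-{n.max()})"
            )
        out[s] = col
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# reduced designs for fast simulation studies
# ---------------------------------------------------------------------------


def reduced_model_spec(delta: float = 0.25, horizon: float = 4.75) -> ModelSpec:
    """A light two-marker specification for simulation studies.

    One near-Gaussian score per dimension through a degree-1 spline link and
    a stage-only covariate design; the full influence structure (stage ×
    direction, linear-in-time cross-effects) is retained.
    """
    markers = (
        MarkerSpec("COG", "cognition", LinkSpec("COG", 0, 30, 1, ())),
        MarkerSpec("FUN", "function", LinkSpec("FUN", 0, 18, 1, ())),
    )
    return ModelSpec(
        markers=markers,
        delta=delta,
        init_terms=("stage",),
        change_terms=("stage",),
        horizon=horizon,
    )


def reduced_truth(spec: ModelSpec) -> Parameters:
    """Truth for the reduced spec: published stage effects and influences."""
    from .links import LinkParameters
    from .parameters import diagonal_re
    from .reference import BASELINE_CELLS, CHANGE_FIXED, influence_alpha

    beta = np.array(
        [
            [BASELINE_CELLS["cognition"][("MCI", "higher")],
             BASELINE_CELLS["cognition"][("AD", "higher")]],
            [BASELINE_CELLS["function"][("MCI", "higher")],
             BASELINE_CELLS["function"][("AD", "higher")]],
        ]
    )
    gamma = np.array(
        [
            [CHANGE_FIXED["cognition"]["intercept"], *CHANGE_FIXED["cognition"]["stage"]],
            [CHANGE_FIXED["function"]["intercept"], *CHANGE_FIXED["function"]["stage"]],
        ]
    )
    # spans chosen so the latent processes essentially never reach the score
    # bounds in continuous mode (the reduced study asserts exact Gaussian
    # recovery, so bound clamping must stay negligible)
    links = [
        LinkParameters(-12.0, np.sqrt([8.0, 8.0])),  # COG: latent span [-12, 4]
        LinkParameters(-7.0, np.sqrt([9.5, 9.5])),  # FUN: latent span [-7, 12]
    ]
    params = Parameters(
        beta=beta,
        gamma=gamma,
        alpha=influence_alpha(spec),
        re=diagonal_re([0.15, 0.40]),
        sigma=np.array([0.40, 0.30]),
        links=links,
    )
    params.validate(spec)
    return params


def reduced_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    spec = reduced_model_spec()
    sched = {
        "COG": {s: _FULL for s in spec.stages},
        "FUN": {s: _FULL for s in spec.stages},
    }
    kwargs = dict(
        spec=spec,
        truth=reduced_truth(spec),
        marker_schedule=sched,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)
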