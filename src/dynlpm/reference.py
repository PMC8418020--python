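"""Published COGICARE estimates (n = 297) as ready-made model inputs.

The COGICARE analysis of the bidirectional cognition-function dynamics
reported baseline-association and change-association coefficient tables in
baseline-SD units.  They are shipped here so that derived quantities
(influence-at-time curves, covariate contrasts) can be evaluated directly,
and so the synthetic cohort generator can simulate near the estimated regime.
Quantities the tables do not print (random-effect correlations, error SDs,
link coefficients) carry documented defaults chosen to give realistic marker
distributions; they are this package's choices, not reported values.
"""

from __future__ import annotations

import numpy as np

from .links import LinkParameters
from .parameters import Parameters, RandomEffectParameters, diagonal_re, full_re_from_cov
from .spec import ModelSpec, default_model_spec

# ---------------------------------------------------------------------------
# baseline associations (latent initial levels, reference cell = 0)
# design columns: stage:MCI, stage:AD, age q2..q5, apoe4, sex:female,
# educ:lower, educ:lower*MCI, educ:lower*AD
# ---------------------------------------------------------------------------

#: baseline cells (stage x education) as published
BASELINE_CELLS = {
    "cognition": {
        ("CN", "higher"): 0.0,
        ("MCI", "higher"): -0.882,
        ("AD", "higher"): -2.878,
        ("CN", "lower"): -0.868,
        ("MCI", "lower"): -1.531,
        ("AD", "lower"): -3.572,
    },
    "function": {
        ("CN", "higher"): 0.0,
        ("MCI", "higher"): 0.171,
        ("AD", "higher"): 1.974,
        ("CN", "lower"): 0.188,
        ("MCI", "lower"): 0.089,
        ("AD", "lower"): 2.811,
    },
}

_BASELINE_OTHER = {
    "cognition": {
        "age": (-0.284, -0.461, -0.288, -0.754),
        "apoe4": -0.010,
        "female": -0.016,
    },
    "function": {
        "age": (0.069, 0.304, 0.284, 1.028),
        "apoe4": -0.355,
        "female": 0.316,
    },
}

# ---------------------------------------------------------------------------
# change associations (annual rates)
# ---------------------------------------------------------------------------

CHANGE_FIXED = {
    "cognition": {
        "intercept": -0.247,
        "stage": (0.176, 0.377),
        "age": (-0.021, -0.040, 0.003, 0.043),
        "apoe4": -0.017,
        "female": 0.061,
        "educ_lower": 0.239,
    },
    "function": {
        "intercept": 0.201,
        "stage": (0.194, 2.166),
        "age": (-0.144, -0.091, 0.175, 0.732),
        "apoe4": -0.211,
        "female": 0.117,
        "educ_lower": -0.471,
    },
}

#: temporal-influence coefficients, keyed (target, source, stage); constant
#: basis for self-effects, (intercept, per-year slope) for cross-effects
INFLUENCE_COEFFICIENTS = {
    ("cognition", "cognition", "CN"): (0.154,),
    ("cognition", "cognition", "MCI"): (0.185,),
    ("cognition", "cognition", "AD"): (0.235,),
    ("cognition", "function", "CN"): (-0.086, 0.032),
    ("cognition", "function", "MCI"): (-0.010, -0.008),
    ("cognition", "function", "AD"): (-0.032, 0.033),
    ("function", "cognition", "CN"): (-0.403, -0.281),
    ("function", "cognition", "MCI"): (-0.307, -0.215),
    ("function", "cognition", "AD"): (-0.342, -0.043),
    ("function", "function", "CN"): (-1.105,),
    ("function", "function", "MCI"): (-0.643,),
    ("function", "function", "AD"): (-0.877,),
}

# ---------------------------------------------------------------------------
# documented defaults for unprinted quantities
# ---------------------------------------------------------------------------

#: measurement-error SD per marker, latent scale
DEFAULT_SIGMA = {"MMSE": 0.40, "IST": 0.45, "BVRT": 0.50, "TMTB": 0.55, "ADL": 0.30}

#: random-effect correlations/SDs: cognition and dependency intercepts
#: negatively correlated, modest slope heterogeneity, intercepts and slopes
#: independent
DEFAULT_U_CORR = -0.4
DEFAULT_V_SD = (0.15, 0.40)
DEFAULT_V_CORR = -0.3

#: link coefficients: (eta0, basis-weight fractions, total weight).  Weight
#: fractions rising toward the upper bound compress the latent scale into few
#: score points near the ceiling (MMSE); falling fractions give a floor
#: effect (TMT-B).
DEFAULT_LINKS = {
    "MMSE": (-12.0, (0.10, 0.15, 0.20, 0.25, 0.30), 16.0),
    "IST": (-12.0, (0.15, 0.20, 0.20, 0.20, 0.25), 16.0),
    "BVRT": (-12.0, (0.20, 0.20, 0.20, 0.20, 0.20), 16.0),
    "TMTB": (-12.0, (0.30, 0.25, 0.20, 0.15, 0.10), 16.0),
    "ADL": (-2.5, (0.30, 0.30, 0.20, 0.20), 14.5),
}


def baseline_beta(spec: ModelSpec) -> np.ndarray:
    """Published baseline coefficients on the additive design scale."""
    if spec.init_terms != ("stage", "age_cat", "apoe4", "sex", "educ", "educ:stage"):
        raise ValueError("published baseline estimates require the default init design")
    rows = []
    for dim in spec.dimensions:
        cells = BASELINE_CELLS[dim]
        other = _BASELINE_OTHER[dim]
        stage_mci = cells[("MCI", "higher")]
        stage_ad = cells[("AD", "higher")]
        educ = cells[("CN", "lower")]
        int_mci = cells[("MCI", "lower")] - stage_mci - educ
        int_ad = cells[("AD", "lower")] - stage_ad - educ
        rows.append(
            [stage_mci, stage_ad, *other["age"], other["apoe4"], other["female"],
             educ, int_mci, int_ad]
        )
    return np.asarray(rows)


def change_gamma(spec: ModelSpec) -> np.ndarray:
    if spec.change_terms != ("stage", "age_cat", "apoe4", "sex", "educ"):
        raise ValueError("published change estimates require the default change design")
    rows = []
    for dim in spec.dimensions:
        c = CHANGE_FIXED[dim]
        rows.append(
            [c["intercept"], *c["stage"], *c["age"], c["apoe4"], c["female"],
             c["educ_lower"]]
        )
    return np.asarray(rows)


def influence_alpha(spec: ModelSpec) -> dict:
    alpha = {}
    for d, dim in enumerate(spec.dimensions):
        for k, src in enumerate(spec.dimensions):
            for s in spec.stages:
                coefs = INFLUENCE_COEFFICIENTS[(dim, src, s)]
                nb = spec.influence_basis_size(d, k)
                alpha[(d, k, s)] = np.asarray(coefs[:nb], dtype=float)
    return alpha


def default_re(structure: str = "full", D: int = 2) -> RandomEffectParameters:
    if structure == "diagonal":
        return diagonal_re(np.asarray(DEFAULT_V_SD[:D]), D)
    sd_v = np.asarray(DEFAULT_V_SD[:D])
    B = np.eye(2 * D)
    if D == 2:
        B[0, 1] = B[1, 0] = DEFAULT_U_CORR
        B[2:, 2:] = np.array(
            [
                [sd_v[0] ** 2, DEFAULT_V_CORR * sd_v[0] * sd_v[1]],
                [DEFAULT_V_CORR * sd_v[0] * sd_v[1], sd_v[1] ** 2],
            ]
        )
    else:
        B[D:, D:] = np.diag(sd_v**2)
    return full_re_from_cov(B)


def default_link_parameters(spec: ModelSpec) -> list:
    links = []
    for m in spec.markers:
        if m.name in DEFAULT_LINKS:
            eta0, fracs, total = DEFAULT_LINKS[m.name]
            w = total * np.asarray(fracs[: m.link.n_basis])
            w = w * total / w.sum() if w.sum() else w  # renormalize if truncated
        else:  # generic gently increasing link spanning ~[-8, 4]
            eta0 = -8.0
            w = np.full(m.link.n_basis, 12.0 / m.link.n_basis)
        links.append(LinkParameters(eta0, np.sqrt(w)))
    return links


def reference_parameters(
    spec: ModelSpec | None = None, re_structure: str = "full"
) -> Parameters:
    """Full parameter set at the published estimates plus documented defaults."""
    spec = spec or default_model_spec()
    sigma = np.array([DEFAULT_SIGMA.get(m.name, 0.4) for m in spec.markers])
    params = Parameters(
        beta=baseline_beta(spec),
        gamma=change_gamma(spec),
        alpha=influence_alpha(spec),
        re=default_re(re_structure, spec.n_dimensions),
        sigma=sigma,
        links=default_link_parameters(spec),
    )
    params.validate(spec)
    return params
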