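"""Shared fixtures: small specifications, simulated cohorts, and one shared
moderate-size fit reused across test modules to keep the suite fast."""

import numpy as np
import pytest
from hypothesis import settings

from dynlpm.data import Dataset
from dynlpm.estimation import DynamicLatentProcessModel
from dynlpm.links import LinkSpec, LinkParameters, identity_link_parameters
from dynlpm.parameters import ParameterMap, Parameters, full_re_from_cov
from dynlpm.simulate import CohortConfig, reduced_cohort_config, simulate_cohort
from dynlpm.spec import MarkerSpec, ModelSpec

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# one-dimension reductions (ordinary linear-mixed-model territory)
# ---------------------------------------------------------------------------


def make_d1_spec(delta=0.25, horizon=4.75):
    """One latent dimension, one marker with an identity-capable link."""
    markers = (MarkerSpec("Y", "cognition", LinkSpec("Y", 0, 30, 1, ())),)
    return ModelSpec(
        dimensions=("cognition",),
        markers=markers,
        delta=delta,
        init_terms=("stage",),
        change_terms=("stage",),
        horizon=horizon,
    )


def make_d1_params(
    spec,
    beta=(-0.9, -2.0),
    gamma=(-0.2, 0.15, 0.4),
    alpha_self=(0.0, 0.0, 0.0),
    v_sd=0.3,
    uv_corr=0.2,
    sigma=0.5,
    links=None,
):
    B = np.array(
        [[1.0, uv_corr * v_sd], [uv_corr * v_sd, v_sd**2]]
    )
    alpha = {(0, 0, s): np.array([a]) for s, a in zip(spec.stages, alpha_self)}
    return Parameters(
        beta=np.array([list(beta)]),
        gamma=np.array([list(gamma)]),
        alpha=alpha,
        re=full_re_from_cov(B),
        sigma=np.array([sigma]),
        links=links or [identity_link_parameters(spec.markers[0].link)],
    )


def d1_cohort_config(spec, truth, n=(50, 40, 30), seed=0, **overrides):
    schedule = (0.0, 6.0, 12.0, 18.0, 24.0, 36.0, 57.0)
    kwargs = dict(
        spec=spec,
        truth=truth,
        n_per_stage=dict(zip(("CN", "MCI", "AD"), n)),
        marker_schedule={"Y": {s: schedule for s in spec.stages}},
        dropout_hazard={"CN": 0.0, "MCI": 0.0, "AD": 0.0},
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def d1_setup():
    spec = make_d1_spec()
    truth = make_d1_params(spec)
    cfg = d1_cohort_config(spec, truth, seed=41)
    df, info = simulate_cohort(cfg)
    return {"spec": spec, "truth": truth, "df": df, "dataset": Dataset.from_dataframe(df, spec)}


# ---------------------------------------------------------------------------
# reduced two-dimension cohort and one shared fit
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def reduced_setup():
    cfg = reduced_cohort_config(seed=7)
    df, info = simulate_cohort(cfg)
    return {
        "config": cfg,
        "df": df,
        "truth_info": info,
        "dataset": Dataset.from_dataframe(df, cfg.spec),
    }


@pytest.fixture(scope="session")
def tiny_report_runs(tmp_path_factory):
    """The same small inline-simulated analysis, run twice into two dirs."""
    from dynlpm.pipeline import AnalysisConfig, run_analysis

    outs = []
    for tag in ("a", "b"):
        out = tmp_path_factory.mktemp(f"report_{tag}")
        cfg = AnalysisConfig(
            cohort=reduced_cohort_config(
                seed=0, n_per_stage={"CN": 16, "MCI": 16, "AD": 12}
            ),
            re_structure="diagonal",
            fit_options={"maxiter": 400},
            n_draws=150,
            seed=5,
            outdir=str(out),
        )
        summary = run_analysis(cfg)
        outs.append((out, summary))
    return outs


@pytest.fixture(scope="session")
def reduced_fit(reduced_setup):
    """One ML fit of the reduced cohort at moderate size, shared by tests."""
    cfg = reduced_setup["config"]
    pmap = ParameterMap(cfg.spec, "diagonal")
    x_true = pmap.pack(cfg.truth)
    rng = np.random.default_rng(77)
    x0 = x_true + 0.05 * (1 + np.abs(x_true)) * rng.standard_normal(x_true.size)
    est = DynamicLatentProcessModel(
        spec=cfg.spec,
        re_structure="diagonal",
        init=x0,
        maxiter=400,
    ).fit(reduced_setup["dataset"])
    return est
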