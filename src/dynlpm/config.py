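"""YAML/JSON serialization of model and cohort configurations."""

from __future__ import annotations

import yaml

from .links import LinkSpec
from .spec import MarkerSpec, ModelSpec


def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "dimensions": list(spec.dimensions),
        "stages": list(spec.stages),
        "delta": spec.delta,
        "horizon": spec.horizon,
        "init_terms": list(spec.init_terms),
        "change_terms": list(spec.change_terms),
        "cross_time_linear": spec.cross_time_linear,
        "markers": [
            {
                "name": m.name,
                "dimension": m.dimension,
                "y_min": m.link.y_min,
                "y_max": m.link.y_max,
                "degree": m.link.degree,
                "interior_knots": list(m.link.interior_knots),
            }
            for m in spec.markers
        ],
    }


def spec_from_dict(d: dict) -> ModelSpec:
    markers = tuple(
        MarkerSpec(
            m["name"],
            m["dimension"],
            LinkSpec(
                m["name"],
                m["y_min"],
                m["y_max"],
                m.get("degree", 2),
                tuple(m.get("interior_knots", ())),
            ),
        )
        for m in d["markers"]
    )
    return ModelSpec(
        dimensions=tuple(d.get("dimensions", ("cognition", "function"))),
        stages=tuple(d.get("stages", ("CN", "MCI", "AD"))),
        markers=markers,
        delta=d.get("delta", 0.25),
        init_terms=tuple(d.get("init_terms", ())) or ModelSpec.init_terms,
        change_terms=tuple(d.get("change_terms", ())) or ModelSpec.change_terms,
        cross_time_linear=d.get("cross_time_linear", True),
        horizon=d.get("horizon", 4.75),
    )


def save_spec_yaml(spec: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec_yaml(path) -> ModelSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
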