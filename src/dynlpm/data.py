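"""Long-format longitudinal data, validated and prepared for the likelihood.

Input is one row per subject-visit-marker with columns ``subject_id, stage,
age_cat, sex, educ, apoe4, time_months, marker, value``.  Preparation maps
visit times to grid nodes, precomputes each observation's I-/M-spline basis
rows (they depend on the data only, not on parameters), and groups subjects
sharing stage, covariates and observation pattern so that the implied
Gaussian moments are computed once per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .links import ispline_basis, mspline_basis
from .spec import FACTOR_LEVELS, ModelSpec, design_row

REQUIRED_COLUMNS = (
    "subject_id",
    "stage",
    "age_cat",
    "sex",
    "educ",
    "apoe4",
    "time_months",
    "marker",
    "value",
)


class DataValidationError(ValueError):
    """Schema or range violations in an input dataset; itemized in ``items``."""

    def __init__(self, items):
        self.items = list(items)
        preview = "; ".join(self.items[:10])
        more = f" (+{len(self.items) - 10} more)" if len(self.items) > 10 else ""
        super().__init__(f"{len(self.items)} validation problem(s): {preview}{more}")


@dataclass
class Subject:
    """One participant: baseline covariates and observed marker history."""

    id: object
    stage: str
    covariates: dict
    time_months: np.ndarray
    marker_idx: np.ndarray
    node: np.ndarray
    value: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.value)


@dataclass
class _Group:
    """Subjects sharing stage, covariates and observation pattern."""

    stage: str
    x_init: np.ndarray
    x_change: np.ndarray
    marker_idx: np.ndarray
    node: np.ndarray
    dim_idx: np.ndarray
    n_steps: int
    subject_indices: list
    values: np.ndarray  # (n_subj, n_obs)
    # per marker present: (obs positions, I basis (n_subj, n_pos, n_basis),
    # M basis with the same shape)
    marker_blocks: dict


def validate_dataframe(df: pd.DataFrame, spec: ModelSpec) -> list:
    """Return a list of human-readable validation problems (empty if clean)."""
    problems = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing column(s) {missing}"]
    marker_names = {m.name for m in spec.markers}
    known = {
        "stage": set(spec.stages),
        "age_cat": set(FACTOR_LEVELS["age_cat"]),
        "sex": set(FACTOR_LEVELS["sex"]),
        "educ": set(FACTOR_LEVELS["educ"]),
    }
    for col, levels in known.items():
        bad = ~df[col].isin(levels)
        for idx in df.index[bad][:20]:
            problems.append(f"row {idx}: unknown {col} {df.at[idx, col]!r}")
    bad = ~df["apoe4"].isin([0, 1, True, False])
    for idx in df.index[bad][:20]:
        problems.append(f"row {idx}: apoe4 must be 0/1, got {df.at[idx, 'apoe4']!r}")
    bad = ~df["marker"].isin(marker_names)
    for idx in df.index[bad][:20]:
        problems.append(f"row {idx}: unknown marker {df.at[idx, 'marker']!r}")
    tm = pd.to_numeric(df["time_months"], errors="coerce")
    bad = tm.isna() | (tm < 0) | (tm > spec.horizon * 12 + spec.delta * 6)
    for idx in df.index[bad][:20]:
        problems.append(
            f"row {idx}: time_months {df.at[idx, 'time_months']!r} outside "
            f"[0, {spec.horizon * 12:g}]"
        )
    val = pd.to_numeric(df["value"], errors="coerce")
    for m in spec.markers:
        rows = df["marker"] == m.name
        v = val[rows]
        bad = v.isna() | (v < m.link.y_min) | (v > m.link.y_max)
        for idx in v.index[bad][:20]:
            problems.append(
                f"row {idx}: {m.name} value {df.at[idx, 'value']!r} outside "
                f"[{m.link.y_min:g}, {m.link.y_max:g}]"
            )
    # covariates must be constant within subject
    cov_cols = ["stage", "age_cat", "sex", "educ", "apoe4"]
    varying = df.groupby("subject_id")[cov_cols].nunique()
    for sid, row in varying.iterrows():
        for c in cov_cols:
            if row[c] > 1:
                problems.append(f"subject {sid!r}: covariate {c} varies over rows")
    return problems


class Dataset:
    """A validated cohort bound to a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, subjects: list):
        self.spec = spec
        self.subjects = list(subjects)
        self._groups = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec) -> "Dataset":
        problems = validate_dataframe(df, spec)
        if problems:
            raise DataValidationError(problems)
        subjects = []
        for sid, sub in df.groupby("subject_id", sort=True):
            first = sub.iloc[0]
            cov = {
                "stage": first["stage"],
                "age_cat": first["age_cat"],
                "sex": first["sex"],
                "educ": first["educ"],
                "apoe4": int(first["apoe4"]),
            }
            tm = sub["time_months"].to_numpy(dtype=float)
            order = np.argsort(tm, kind="stable")
            tm = tm[order]
            marker_idx = np.array(
                [spec.marker_index(m) for m in sub["marker"].to_numpy()[order]]
            )
            node = np.array([spec.grid_node(t) for t in tm])
            if np.any(node > spec.n_grid):
                raise DataValidationError(
                    [f"subject {sid!r}: observation beyond the model horizon"]
                )
            value = sub["value"].to_numpy(dtype=float)[order]
            subjects.append(
                Subject(sid, first["stage"], cov, tm, marker_idx, node, value)
            )
        return cls(spec, subjects)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return int(sum(s.n_obs for s in self.subjects))

    def observation_counts(self) -> pd.Series:
        counts = np.zeros(self.spec.n_markers, dtype=int)
        for s in self.subjects:
            np.add.at(counts, s.marker_idx, 1)
        return pd.Series(counts, index=[m.name for m in self.spec.markers])

    # -- likelihood preparation ------------------------------------------
    def groups(self) -> list:
        if self._groups is None:
            self._groups = self._build_groups()
        return self._groups

    def _build_groups(self) -> list:
        spec = self.spec
        keyed: dict = {}
        designs = {}
        for i, s in enumerate(self.subjects):
            if s.n_obs == 0:
                continue  # no contribution to the likelihood
            x_init = design_row(spec.init_terms, s.covariates)
            x_change = design_row(spec.change_terms, s.covariates)
            key = (
                s.stage,
                x_init.tobytes(),
                x_change.tobytes(),
                tuple(s.marker_idx),
                tuple(s.node),
            )
            designs[key] = (x_init, x_change)
            keyed.setdefault(key, []).append(i)
        groups = []
        for key, subj_idx in keyed.items():
            stage, _, _, marker_idx, node = key
            x_init, x_change = designs[key]
            marker_idx = np.asarray(marker_idx)
            node = np.asarray(node)
            values = np.stack([self.subjects[i].value for i in subj_idx])
            marker_blocks = {}
            for m in np.unique(marker_idx):
                pos = np.nonzero(marker_idx == m)[0]
                link = spec.markers[m].link
                v = values[:, pos]
                I = ispline_basis(v, link)
                M = mspline_basis(v, link)
                marker_blocks[int(m)] = (pos, I, M)
            groups.append(
                _Group(
                    stage=stage,
                    x_init=x_init,
                    x_change=x_change,
                    marker_idx=marker_idx,
                    node=node,
                    dim_idx=np.array(
                        [spec.marker_dimension_index(m) for m in marker_idx]
                    ),
                    n_steps=int(node.max()),
                    subject_indices=subj_idx,
                    values=values,
                    marker_blocks=marker_blocks,
                )
            )
        return groups


def read_dataset_csv(path, spec: ModelSpec) -> Dataset:
    df = pd.read_csv(path)
    return Dataset.from_dataframe(df, spec)
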