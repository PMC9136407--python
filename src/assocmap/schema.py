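"""Variable typing: categorical vs continuous, fixed vs random, level order.

Metadata variables play one of two roles in the linear model. *Fixed*
variables are tested for association with every feature; *random*
variables define random-intercept groups (typically subject ID in a
longitudinal cohort) that are accounted for but never tested.

Categorical levels are ordered alphabetically — users who need a custom
order prefix the level names (``a_never``, ``b_sometimes``, ``c_always``)
— and the first level is the default reference for treatment coding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"

#: Numeric columns with at most this many distinct non-missing values are
#: auto-classified categorical.
MAX_CATEGORICAL_UNIQUE = 4


class SchemaError(ValueError):
    """The variable schema is inconsistent with itself or with the data."""


def render_level(value: object) -> str:
    """Canonical string form of a categorical level.

    Numeric-categorical levels display without a trailing ``.0`` so that a
    column stored as float shows the levels a user typed (1, 2, 3).
    """
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def infer_variable_kind(values: pd.Series) -> str:
    """Classify one metadata column as categorical or continuous.

    String columns are always categorical. Numeric columns are categorical
    when they carry at most :data:`MAX_CATEGORICAL_UNIQUE` distinct
    non-missing values, continuous otherwise. Missing entries are ignored
    for counting.
    """
    present = values.dropna()
    if present.empty:
        raise SchemaError(f"column {values.name!r} is all-missing; cannot type it")
    if not pd.api.types.is_numeric_dtype(present):
        return CATEGORICAL
    return CATEGORICAL if present.nunique() <= MAX_CATEGORICAL_UNIQUE else CONTINUOUS


def order_levels(values: pd.Series | Iterable) -> list[str]:
    """Distinct non-missing levels in lexicographic order of their rendering."""
    series = values if isinstance(values, pd.Series) else pd.Series(list(values))
    levels = sorted({render_level(v) for v in series.dropna()})
    if len(levels) < 2:
        raise SchemaError(
            f"constant variable {series.name!r}: a single-level column cannot be tested"
        )
    return levels


def default_reference(levels: list[str]) -> str:
    """The alphabetically first level, used as reference unless overridden."""
    if not levels:
        raise SchemaError("no levels to pick a reference from")
    return levels[0]


@dataclass(frozen=True)
class VariableSchema:
    """Roles and kinds of every metadata column of a merged table."""

    sample_id_col: str
    random_vars: tuple[str, ...] = ()
    fixed_vars: Mapping[str, str] = field(default_factory=dict)
    level_order: Mapping[str, list[str]] = field(default_factory=dict)
    reference: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.random_vars) & set(self.fixed_vars)
        if overlap:
            raise SchemaError(f"variables both random and fixed: {sorted(overlap)}")
        if self.sample_id_col in self.random_vars or self.sample_id_col in self.fixed_vars:
            raise SchemaError(f"sample-ID column {self.sample_id_col!r} used as a variable")
        for var, kind in self.fixed_vars.items():
            if kind not in (CATEGORICAL, CONTINUOUS):
                raise SchemaError(f"unknown kind {kind!r} for variable {var!r}")
            if kind == CONTINUOUS and var in self.level_order:
                raise SchemaError(f"continuous variable {var!r} has a level order")
        for var, ref in self.reference.items():
            levels = self.level_order.get(var)
            if levels is not None and ref not in levels:
                raise SchemaError(
                    f"reference {ref!r} for {var!r} is not one of its levels {levels}"
                )

    @property
    def categorical_vars(self) -> list[str]:
        return [v for v, k in self.fixed_vars.items() if k == CATEGORICAL]

    def reference_for(self, var: str) -> str:
        if var in self.reference:
            return self.reference[var]
        return default_reference(list(self.level_order[var]))


def build_schema(
    raw,
    random: Iterable[str] = (),
    fixed: Mapping[str, str | None] | Iterable[str] = (),
    reference: Mapping[str, str] | None = None,
    sample_id_col: str | None = None,
) -> VariableSchema:
    """Construct a :class:`VariableSchema` against a parsed raw table.

    ``fixed`` maps variable names to an explicit kind or ``None`` for
    auto-inference (the ≤4-distinct-values rule); a plain iterable means
    infer everything. Level orders and default references are derived from
    the data; ``reference`` entries override per variable.
    """
    frame = raw.frame
    fixed_map = dict(fixed) if isinstance(fixed, Mapping) else {v: None for v in fixed}
    missing = [v for v in [*random, *fixed_map] if v not in frame.columns]
    if missing:
        raise SchemaError(f"schema references missing columns: {missing}")

    kinds: dict[str, str] = {}
    level_order: dict[str, list[str]] = {}
    for var, kind in fixed_map.items():
        kinds[var] = kind or infer_variable_kind(frame[var])
        if kinds[var] == CATEGORICAL:
            level_order[var] = order_levels(frame[var])

    refs = dict(reference or {})
    for var in kinds:
        if kinds[var] == CATEGORICAL and var not in refs:
            refs[var] = default_reference(level_order[var])

    return VariableSchema(
        sample_id_col=sample_id_col or raw.sample_id_col,
        random_vars=tuple(random),
        fixed_vars=kinds,
        level_order=level_order,
        reference=refs,
    )


def load_schema_config(path: str | Path) -> dict:
    """Load a schema config (YAML or JSON) into the ``build_schema`` kwargs.

    Layout::

        sample_id: sid
        random: [subject_id]
        fixed: {disease: categorical, visit_age_mo: continuous, parity: auto}
        reference: {disease: control}
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    fixed = cfg.get("fixed", {})
    if isinstance(fixed, Mapping):
        fixed = {k: (None if v in (None, "auto") else v) for k, v in fixed.items()}
    return {
        "sample_id_col": cfg.get("sample_id"),
        "random": list(cfg.get("random", [])),
        "fixed": fixed,
        "reference": dict(cfg.get("reference", {})),
    }
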