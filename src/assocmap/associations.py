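"""Per-feature multivariate linear models and BH-FDR association tests.

For every retained feature and every candidate model, the engine fits a
linear model of the (optionally AST-transformed) abundance on the model's
fixed variables — treatment-coded against their reference levels — with a
random intercept per random-variable group when random variables are
declared. All nominal p-values of one run (every feature × every tested
term) form a single Benjamini–Hochberg family, and the resulting q-values
are the significance currency of the downstream comparison heatmap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import VCSpec
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .preprocess import LOW_ABUNDANCE_THRESHOLD, complete_case_mask, prepare_features
from .schema import CONTINUOUS, SchemaError, VariableSchema, render_level

log = logging.getLogger(__name__)

#: Default FDR q-value threshold used for significance calls downstream.
DEFAULT_Q_THRESHOLD = 0.2

OK, FIT_FAILED, SKIPPED_CONSTANT = "ok", "fit_failed", "skipped_constant"


class DesignError(ValueError):
    pass


class AliasedDesignError(DesignError):
    """Two or more fixed-effect columns are perfectly collinear."""

    def __init__(self, column: str, aliased_with: str):
        self.column = column
        self.aliased_with = aliased_with
        super().__init__(
            f"rank-deficient design: column {column!r} is aliased with {aliased_with!r}"
        )


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: which variables it includes and how.

    ``reference`` overrides the schema's per-variable reference level for
    this model only. ``ast_enabled`` mirrors the AST checkbox: when off,
    features enter the fit untransformed.
    """

    name: str
    fixed: tuple[str, ...]
    random: tuple[str, ...] = ()
    reference: Mapping[str, str] = field(default_factory=dict)
    ast_enabled: bool = True
    q_threshold: float = DEFAULT_Q_THRESHOLD

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))
        if not self.fixed:
            raise ValueError(f"model {self.name!r}: at least one fixed variable required")
        if not 0 < self.q_threshold < 1:
            raise ValueError(f"model {self.name!r}: q_threshold must be in (0, 1)")

    def with_defaults_from(self, other: "ModelSpec") -> "ModelSpec":
        """Inherit variable selections from a previously defined model."""
        merged_ref = {**dict(other.reference), **dict(self.reference)}
        return replace(self, random=self.random or other.random, reference=merged_ref)


@dataclass
class AssociationResult:
    """One (feature, variable, level, model) test."""

    feature: str
    variable: str
    level: str  # "" for continuous variables
    reference: str  # "" for continuous variables
    model: str
    coefficient: float
    stderr: float
    p: float
    q: float
    n_used: int
    status: str = OK


@dataclass
class Design:
    """Fixed-effect matrix plus random-intercept grouping factors."""

    exog: pd.DataFrame  # includes the intercept column
    terms: list[tuple[str, str, str]]  # (variable, level, reference) per non-intercept col
    groups: pd.DataFrame  # one column per random variable (may be empty)

    @property
    def index(self) -> pd.Index:
        return self.exog.index


def _check_full_rank(exog: pd.DataFrame) -> None:
    X = exog.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # localize the offending column: first one that fails to add rank
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
            sub = X[:, :j]
            coefs, *_ = np.linalg.lstsq(sub, X[:, j], rcond=None)
            partner = int(np.argmax(np.abs(coefs[1:]))) + 1 if j > 1 else 0
            raise AliasedDesignError(exog.columns[j], exog.columns[partner])
    raise DesignError("rank-deficient design")  # pragma: no cover


def build_design(
    metadata: pd.DataFrame,
    schema: VariableSchema,
    spec: ModelSpec,
    mask: pd.Series | None = None,
) -> Design:
    """Build the treatment-coded fixed-effect matrix and random groupings.

    Categorical fixed variables contribute one indicator column per
    non-reference level (levels in schema order); continuous variables one
    column each. Levels absent from the masked data are dropped with a
    log note. A perfectly collinear design raises
    :class:`AliasedDesignError` naming the aliased pair.
    """
    if mask is None:
        mask = complete_case_mask(metadata, [*spec.fixed, *spec.random])
    meta = metadata.loc[mask]
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(meta))}
    terms: list[tuple[str, str, str]] = []
    for var in spec.fixed:
        kind = schema.fixed_vars.get(var)
        if kind is None:
            raise SchemaError(f"model {spec.name!r} uses undeclared variable {var!r}")
        if kind == CONTINUOUS:
            cols[var] = meta[var].to_numpy(dtype=float)
            terms.append((var, "", ""))
            continue
        rendered = meta[var].map(render_level)
        reference = dict(spec.reference).get(var, schema.reference_for(var))
        present = set(rendered)
        levels = [lv for lv in schema.level_order[var] if lv in present]
        if reference not in present:
            raise DesignError(
                f"reference level {reference!r} of {var!r} has no samples in the fit"
            )
        for lv in levels:
            if lv == reference:
                continue
            cols[f"{var}[{lv}]"] = (rendered == lv).to_numpy(dtype=float)
            terms.append((var, lv, reference))
        dropped = [lv for lv in schema.level_order[var] if lv not in present]
        if dropped:
            log.info("model %s: levels of %s absent after masking: %s", spec.name, var, dropped)
    exog = pd.DataFrame(cols, index=meta.index)
    _check_full_rank(exog)
    groups = pd.DataFrame(
        {v: meta[v].map(render_level) for v in spec.random}, index=meta.index
    )
    return Design(exog=exog, terms=terms, groups=groups)


def _fit_mixed(y: np.ndarray, design: Design):
    """REML linear mixed model with random intercepts.

    One random variable is the canonical path (groups = that variable).
    With several, intercepts are crossed: a single all-encompassing group
    with one variance component per variable.
    """
    if design.groups.shape[1] == 1:
        model = sm.MixedLM(y, design.exog.to_numpy(), groups=design.groups.iloc[:, 0].to_numpy())
    else:
        log.info("crossed random intercepts for %s", list(design.groups.columns))
        names, colnames, mats = [], [], []
        for var in design.groups.columns:
            dummies = pd.get_dummies(design.groups[var], dtype=float)
            names.append(var)
            colnames.append([dummies.columns.tolist()])
            mats.append([dummies.to_numpy()])
        vc = VCSpec(names, colnames, mats)
        model = sm.MixedLM(
            y,
            design.exog.to_numpy(),
            groups=np.zeros(len(y)),
            exog_vc=vc,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        result = model.fit(reml=True)
    return result


def fit_feature(y: np.ndarray | pd.Series, design: Design):
    """Fit one feature; return ``(status, [(coef, stderr, p) per term])``.

    Without random variables this is OLS with two-sided Wald t-tests on
    the residual degrees of freedom; with random variables a REML mixed
    model with normal-approximation Wald tests. Failures are reported as
    statuses, never raised, so one bad feature cannot abort a batch.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(design.exog):
        raise ValueError("y length does not match the design")
    if np.ptp(y) == 0:
        return SKIPPED_CONSTANT, []
    k = design.exog.shape[1]
    if len(y) < k + 1:
        return FIT_FAILED, []
    try:
        if design.groups.shape[1] == 0:
            res = sm.OLS(y, design.exog.to_numpy()).fit()
        else:
            res = _fit_mixed(y, design)
        params = np.asarray(res.params)[:k]
        bse = np.asarray(res.bse)[:k]
        pvals = np.asarray(res.pvalues)[:k]
    except (np.linalg.LinAlgError, ValueError) as exc:
        log.debug("fit failed: %s", exc)
        return FIT_FAILED, []
    stats = list(zip(params[1:], bse[1:], pvals[1:]))  # skip intercept
    if not all(np.isfinite(s) and np.isfinite(c) for c, s, _ in stats):
        return FIT_FAILED, []
    return OK, stats


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, preserving input order.

    Missing entries (failed fits) pass through as NaN and do not count
    toward the family size.
    """
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def run_model(
    table,
    schema: VariableSchema,
    spec: ModelSpec,
    threshold: float = LOW_ABUNDANCE_THRESHOLD,
) -> list[AssociationResult]:
    """Preprocess, fit every feature under one model, and BH-adjust.

    All nominal p-values of the run — every feature crossed with every
    tested term — are pooled into one BH family. Results come back sorted
    by q (missing last).
    """
    fm = prepare_features(table.features, ast_enabled=spec.ast_enabled, threshold=threshold)
    meta = table.metadata.loc[fm.data.index]
    mask = complete_case_mask(meta, [*spec.fixed, *spec.random])
    design = build_design(meta, schema, spec, mask)
    n_used = len(design.exog)

    results: list[AssociationResult] = []
    n_failed = 0
    for feat in fm.data.columns:
        y = fm.data.loc[design.index, feat]
        status, stats = fit_feature(y, design)
        if status != OK:
            n_failed += 1
            stats = [(np.nan, np.nan, np.nan)] * len(design.terms)
        for (var, level, ref), (coef, se, p) in zip(design.terms, stats):
            results.append(
                AssociationResult(
                    feature=feat, variable=var, level=level, reference=ref,
                    model=spec.name, coefficient=coef, stderr=se, p=p, q=np.nan,
                    n_used=n_used, status=status,
                )
            )
    if n_failed == fm.n_features:
        raise RuntimeError(f"model {spec.name!r}: every feature failed to fit")
    if n_failed:
        log.warning("model %s: %d feature(s) not fitted", spec.name, n_failed)

    qvals = bh_adjust([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = float(q)
    results.sort(key=lambda r: (not np.isfinite(r.q), r.q if np.isfinite(r.q) else 1.0,
                                r.feature, r.variable, r.level))
    return results


RESULT_COLUMNS = [
    "feature", "variable", "level", "reference", "coefficient",
    "stderr", "p", "q", "n_used", "status",
]


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten association results into the per-model results table."""
    return pd.DataFrame(
        [{c: getattr(r, c) for c in RESULT_COLUMNS} for r in results],
        columns=RESULT_COLUMNS,
    )
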