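"""Detail views of a single association: records, facet t-tests, plots.

Zooming in on one (feature, variable) pair of one model produces the
per-sample records behind the box/scatter plot: transformed abundance on
the y-axis, the variable on the x-axis, with the model's q-values attached
as reference-vs-level brackets. Samples with a missing x-value are kept
under an explicit "NA" category — visible, never tested. When the plot is
faceted by another variable the model q-values are replaced by plain
two-sided Welch t-tests computed within each facet panel on all plotted
samples (no model-based masking).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .associations import AssociationResult, ModelSpec, run_model
from .preprocess import prepare_features
from .schema import CATEGORICAL, CONTINUOUS, VariableSchema, render_level

NA_LABEL = "NA"


class DetailError(ValueError):
    pass


@dataclass
class DetailRecordSet:
    """Per-sample records for one association, plus bracket q-values.

    ``records`` columns: sample_id, y, x (level string or float), and
    optional facet / color / label columns. ``brackets`` maps each tested
    non-reference level to the model's q-value (empty for continuous x).
    """

    records: pd.DataFrame
    feature: str
    variable: str
    model: str
    x_kind: str  # categorical | continuous
    reference: str = ""
    x_order: list[str] = field(default_factory=list)  # levels incl. trailing NA
    brackets: Mapping[str, float] = field(default_factory=dict)

    def group(self, level: str) -> np.ndarray:
        sub = self.records[self.records["x"] == level]
        return sub["y"].to_numpy(dtype=float)


def association_detail(
    table,
    schema: VariableSchema,
    spec: ModelSpec,
    feature: str,
    variable: str,
    results: Sequence[AssociationResult] | None = None,
    facet: str | None = None,
    color: str | None = None,
    label: str | None = None,
) -> DetailRecordSet:
    """Build the record set behind a detail plot.

    ``results`` should be the output of :func:`run_model` for ``spec``;
    when omitted the model is re-run to obtain the bracket q-values. The
    y-values reproduce the preprocessing stage used in the fit (AST
    applied iff the model used it), and every preprocessed sample appears,
    including those excluded from the fit by missing metadata.
    """
    if variable not in spec.fixed:
        raise DetailError(f"variable {variable!r} is not tested under model {spec.name!r}")
    fm = prepare_features(table.features, ast_enabled=spec.ast_enabled)
    if feature not in fm.data.columns:
        raise DetailError(f"unknown or filtered-out feature {feature!r}")
    if results is None:
        results = run_model(table, schema, spec)

    meta = table.metadata.loc[fm.data.index]
    kind = schema.fixed_vars[variable]
    rec = pd.DataFrame(index=fm.data.index)
    rec["sample_id"] = fm.data.index
    rec["y"] = fm.data[feature].to_numpy(dtype=float)

    x_order: list[str] = []
    reference = ""
    if kind == CATEGORICAL:
        rendered = meta[variable].map(render_level, na_action="ignore")
        rec["x"] = rendered.fillna(NA_LABEL)
        reference = dict(spec.reference).get(variable, schema.reference_for(variable))
        x_order = list(schema.level_order[variable])
        if (rec["x"] == NA_LABEL).any():
            x_order.append(NA_LABEL)
    else:
        rec["x"] = meta[variable].to_numpy(dtype=float)

    for name, var in (("facet", facet), ("color", color), ("label", label)):
        if var is not None:
            if var not in meta.columns:
                raise DetailError(f"unknown {name} variable {var!r}")
            rec[name] = meta[var].map(render_level, na_action="ignore").fillna(NA_LABEL)

    brackets = {
        r.level: r.q
        for r in results
        if r.feature == feature and r.variable == variable and r.level
    }
    return DetailRecordSet(
        records=rec.reset_index(drop=True),
        feature=feature, variable=variable, model=spec.name,
        x_kind=kind, reference=reference, x_order=x_order, brackets=brackets,
    )


FACET_TEST_COLUMNS = ["facet", "level", "reference", "n_ref", "n_level", "t", "p", "testable"]


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def facet_ttest(records: DetailRecordSet, facet_var: str | None = None) -> pd.DataFrame:
    """Two-sided Welch t-tests of reference vs each level, per facet panel.

    Uses every plotted sample (the "NA" x-group excluded from testing but
    shown as its own category; a facet panel of missing facet values is a
    regular panel). Groups with fewer than 2 samples make a comparison
    untestable, reported with ``testable = False`` rather than aborting.
    """
    if records.x_kind != CATEGORICAL:
        raise DetailError("facet t-tests apply to categorical x only")
    rec = records.records
    if facet_var is not None and "facet" not in rec.columns:
        raise DetailError(
            f"records carry no facet column; rebuild the detail with facet={facet_var!r}"
        )
    facets = (
        [(lbl, sub) for lbl, sub in rec.groupby("facet", sort=True)]
        if "facet" in rec.columns
        else [("", rec)]
    )
    # keep the "NA" facet panel last, matching the display order
    facets.sort(key=lambda kv: (kv[0] == NA_LABEL, kv[0]))

    levels = [lv for lv in records.x_order if lv not in (records.reference, NA_LABEL)]
    rows = []
    for facet_label, sub in facets:
        ref_y = sub.loc[sub["x"] == records.reference, "y"].to_numpy(dtype=float)
        for lv in levels:
            lv_y = sub.loc[sub["x"] == lv, "y"].to_numpy(dtype=float)
            testable = len(ref_y) >= 2 and len(lv_y) >= 2
            t = p = np.nan
            if testable:
                t, p = _welch(ref_y, lv_y)
            rows.append(
                {"facet": facet_label, "level": lv, "reference": records.reference,
                 "n_ref": len(ref_y), "n_level": len(lv_y), "t": t, "p": p,
                 "testable": testable}
            )
    return pd.DataFrame(rows, columns=FACET_TEST_COLUMNS)


def _draw_panel(ax, sub: pd.DataFrame, records: DetailRecordSet, color: bool):
    import seaborn as sns

    order = [lv for lv in records.x_order if lv in set(sub["x"])]
    sns.boxplot(
        data=sub, x="x", y="y", order=order, ax=ax, color="white",
        showfliers=False, whis=1.5,
    )
    sns.stripplot(
        data=sub, x="x", y="y", order=order, ax=ax, size=3, alpha=0.7,
        hue="color" if color else None, jitter=0.2,
        palette="colorblind" if color else None,
    )
    if "label" in sub.columns:
        for _, row in sub.iterrows():
            ax.annotate(row["label"], (order.index(row["x"]), row["y"]),
                        fontsize=4, alpha=0.6)
    return order


def _annotate_brackets(ax, order, reference, stats: Mapping[str, float], prefix: str):
    if reference not in order:
        return
    y_top = ax.get_ylim()[1]
    step = 0.07 * (ax.get_ylim()[1] - ax.get_ylim()[0])
    i_ref = order.index(reference)
    height = y_top
    for lv, value in stats.items():
        if lv not in order:
            continue
        i_lv = order.index(lv)
        height += step
        ax.plot([i_ref, i_ref, i_lv, i_lv],
                [height - step / 3, height, height, height - step / 3],
                color="black", linewidth=0.8)
        txt = f"{prefix}={value:.3g}" if np.isfinite(value) else f"{prefix}=NA"
        ax.text((i_ref + i_lv) / 2, height, txt, ha="center", va="bottom", fontsize=7)
    ax.set_ylim(top=height + 1.5 * step)


def detail_figure(records: DetailRecordSet, faceted: bool = False):
    """Build the detail figure: box plot (categorical x) or scatter.

    Box geometry follows the usual convention — median line, first/third
    quartile box (linear-interpolation quartiles) — with one dot per
    sample. Unfaceted categorical plots carry the model's q-value
    brackets; faceted ones carry per-panel Welch t-test p-values instead.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rec = records.records
    if rec.empty:
        raise DetailError("no records to plot")
    use_color = "color" in rec.columns

    if records.x_kind == CONTINUOUS:
        fig, ax = plt.subplots(figsize=(6, 4))
        pts = rec.dropna(subset=["x"])
        if use_color:
            import seaborn as sns
            sns.scatterplot(data=pts, x="x", y="y", hue="color", ax=ax, s=15)
        else:
            ax.scatter(pts["x"], pts["y"], s=15, alpha=0.7)
        ax.set_xlabel(records.variable)
    elif faceted and "facet" in rec.columns:
        tests = facet_ttest(records)
        panels = list(dict.fromkeys(tests["facet"]))
        fig, axes = plt.subplots(
            1, len(panels), figsize=(3.2 * len(panels), 4), sharey=True, squeeze=False
        )
        for ax, panel in zip(axes[0], panels):
            sub = rec[rec["facet"] == panel]
            order = _draw_panel(ax, sub, records, use_color)
            ptab = tests[tests["facet"] == panel]
            _annotate_brackets(
                ax, order, records.reference,
                {row["level"]: row["p"] for _, row in ptab.iterrows()}, "p",
            )
            ax.set_title(str(panel), fontsize=9)
            ax.set_xlabel(records.variable)
        ax = axes[0][0]
    else:
        fig, ax = plt.subplots(figsize=(6, 4))
        order = _draw_panel(ax, rec, records, use_color)
        _annotate_brackets(ax, order, records.reference, records.brackets, "q")
        ax.set_xlabel(records.variable)
    ax.set_ylabel(f"{records.feature} (transformed abundance)")
    fig.suptitle(f"{records.feature} ~ {records.variable} [{records.model}]", fontsize=10)
    fig.tight_layout()
    return fig


def render_detail(
    records: DetailRecordSet,
    path: str | Path,
    faceted: bool = False,
) -> Path:
    """Render the detail figure to a file (PNG/PDF by extension)."""
    import matplotlib.pyplot as plt

    fig = detail_figure(records, faceted=faceted)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
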