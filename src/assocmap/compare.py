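"""Side-by-side comparison of association results across candidate models.

The comparison matrix is the data behind the birds-eye heatmap: rows are
the features found significant (q strictly below the threshold) in at
least one model; columns are (model, variable, level) triples grouped in
model-definition order. Entries keep the q-value even when it is not
significant, so a robust association can be traced across models and a
vanishing one spotted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .associations import DEFAULT_Q_THRESHOLD, AssociationResult
from .tables import write_tsv


class ComparisonError(ValueError):
    pass


LONG_COLUMNS = ["model", "feature", "variable", "level", "q", "significant"]


@dataclass
class ComparisonMatrix:
    """Aligned q-values of several model runs over the same data.

    ``long`` holds one row per (model, feature, term) of every retained
    feature; the wide heatmap layout is derived from it on demand. Cells
    a model never tested (e.g. a feature filtered out under different
    preprocessing flags) are absent from ``long`` and appear as NaN in the
    wide form — "not tested", distinct from "not significant".
    """

    long: pd.DataFrame
    q_threshold: float
    model_order: list[str]
    term_order: Mapping[str, list[tuple[str, str]]]  # model -> [(variable, level)]

    @property
    def features(self) -> list[str]:
        return sorted(self.long["feature"].unique())

    def wide(self) -> pd.DataFrame:
        """Features × (model, variable, level) q-value matrix in block order."""
        wide = self.long.pivot_table(
            index="feature", columns=["model", "variable", "level"], values="q",
            aggfunc="first", dropna=False,
        )
        ordered = [
            (m, v, lv) for m in self.model_order for (v, lv) in self.term_order[m]
            if (m, v, lv) in wide.columns
        ]
        return wide.loc[sorted(wide.index), ordered]


def compare_models(
    result_lists: Sequence[Sequence[AssociationResult]],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> ComparisonMatrix:
    """Align per-model results into the significance comparison matrix.

    A feature becomes a row iff any of its q-values in any model is
    strictly below ``q_threshold``; all of its entries (significant or
    not) are then retained for display.
    """
    if not result_lists:
        raise ComparisonError("no model results to compare")
    rows = []
    model_order: list[str] = []
    term_order: dict[str, list[tuple[str, str]]] = {}
    for results in result_lists:
        for r in results:
            if r.model not in model_order:
                model_order.append(r.model)
                term_order[r.model] = []
            if (r.variable, r.level) not in term_order[r.model]:
                term_order[r.model].append((r.variable, r.level))
            rows.append(
                {"model": r.model, "feature": r.feature, "variable": r.variable,
                 "level": r.level, "q": r.q,
                 "significant": int(np.isfinite(r.q) and r.q < q_threshold)}
            )
    long = pd.DataFrame(rows, columns=LONG_COLUMNS)
    keep = set(long.loc[long["significant"] == 1, "feature"])
    long = long[long["feature"].isin(keep)].reset_index(drop=True)
    long = long.sort_values(["feature", "model", "variable", "level"], kind="stable")
    long = long.reset_index(drop=True)
    return ComparisonMatrix(
        long=long, q_threshold=q_threshold,
        model_order=model_order, term_order=term_order,
    )


def filter_matrix(
    matrix: ComparisonMatrix,
    features: Sequence[str] | None = None,
    models: Sequence[str] | None = None,
    q_threshold: float | None = None,
) -> ComparisonMatrix:
    """Subset the matrix and re-apply the row rule under a new threshold."""
    long = matrix.long
    if features is not None:
        unknown = set(features) - set(long["feature"])
        if unknown:
            raise ComparisonError(f"unknown features: {sorted(unknown)}")
        long = long[long["feature"].isin(set(features))]
    if models is not None:
        unknown = set(models) - set(matrix.model_order)
        if unknown:
            raise ComparisonError(f"unknown models: {sorted(unknown)}")
        long = long[long["model"].isin(set(models))]
    thr = matrix.q_threshold if q_threshold is None else q_threshold
    long = long.copy()
    long["significant"] = (long["q"].notna() & (long["q"] < thr)).astype(int)
    keep = set(long.loc[long["significant"] == 1, "feature"])
    long = long[long["feature"].isin(keep)].reset_index(drop=True)
    if long.empty:
        raise ComparisonError("empty selection: no feature is significant in the subset")
    model_order = [m for m in matrix.model_order if models is None or m in set(models)]
    return ComparisonMatrix(
        long=long, q_threshold=thr, model_order=model_order,
        term_order={m: matrix.term_order[m] for m in model_order},
    )


def write_long_tsv(matrix: ComparisonMatrix, path: str | Path) -> Path:
    """Canonical long-format export: model, feature, variable, level, q, significant."""
    return write_tsv(matrix.long[LONG_COLUMNS], path, index=False)


def heatmap_figure(matrix: ComparisonMatrix, annotate: bool = False):
    """Build the birds-eye heatmap figure: color encodes -log10(q), only
    cells passing the significance threshold are colored; columns are
    blocked by model with separators."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    wide = matrix.wide()
    if wide.empty:
        raise ComparisonError("nothing significant to plot")
    score = -np.log10(wide.clip(lower=1e-300))
    score = score.where(wide < matrix.q_threshold)  # only significant cells colored
    labels = [f"{v}" + (f"={lv}" if lv else "") for (_, v, lv) in wide.columns]

    fig_w = max(6.0, 0.55 * len(labels) + 3)
    fig_h = max(3.5, 0.35 * len(wide) + 2)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    sns.heatmap(
        score, ax=ax, cmap="viridis", linewidths=0.5, linecolor="0.85",
        xticklabels=labels, yticklabels=wide.index.tolist(),
        cbar_kws={"label": "-log10(q)"},
        annot=wide.round(3).to_numpy() if annotate else None, fmt="",
    )
    # separators between model blocks
    edge = 0
    for m in matrix.model_order[:-1]:
        edge += sum(1 for c in wide.columns if c[0] == m)
        ax.axvline(edge, color="black", linewidth=1.5)
    # model block titles
    start = 0
    for m in matrix.model_order:
        width = sum(1 for c in wide.columns if c[0] == m)
        if width:
            ax.text(start + width / 2, -0.4, m, ha="center", va="bottom", fontsize=10)
            start += width
    ax.set_xlabel("model terms")
    ax.set_ylabel("feature")
    fig.tight_layout()
    return fig


def plot_heatmap(matrix: ComparisonMatrix, path: str | Path, annotate: bool = False) -> Path:
    """Render the birds-eye heatmap to a file (PNG/PDF by extension)."""
    import matplotlib.pyplot as plt

    fig = heatmap_figure(matrix, annotate=annotate)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
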