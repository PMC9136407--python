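"""Feature-table preprocessing: TSS, low-abundance filter, AST, NA mask.

The pipeline mirrors the standard relative-abundance workflow: total sum
scaling per sample, removal of features whose normalized total across all
samples falls below a small threshold, then the variance-stabilizing
arcsine square-root transform x ↦ arcsin(√x), which maps [0, 1] onto
[0, π/2] while keeping zeros at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Features whose post-TSS total over all samples is strictly below this
#: proportion are removed.
LOW_ABUNDANCE_THRESHOLD = 0.0001

RAW, TSS, FILTERED, AST = "raw", "tss", "filtered", "ast"


class PreprocessError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """A samples × features abundance matrix tagged with its pipeline stage."""

    data: pd.DataFrame
    stage: str = RAW

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def tss_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Total-sum-scale each sample so its features form a composition.

    Rows whose total is zero cannot be scaled and are dropped with a
    warning listing the affected sample IDs.
    """
    vals = matrix.data.to_numpy(dtype=float)
    if (vals < 0).any():
        raise PreprocessError("negative abundance entries; TSS requires values >= 0")
    totals = vals.sum(axis=1)
    zero = totals == 0
    if zero.any():
        dropped = matrix.data.index[zero].tolist()
        log.warning("dropping %d zero-total samples: %s", len(dropped), dropped)
    kept = matrix.data.loc[~zero]
    out = kept.div(kept.sum(axis=1), axis=0)
    return FeatureMatrix(data=out, stage=TSS)


def filter_low_abundance(
    matrix: FeatureMatrix, threshold: float = LOW_ABUNDANCE_THRESHOLD
) -> FeatureMatrix:
    """Drop features whose normalized total is strictly below ``threshold``.

    The comparison is strict: a feature summing to exactly the threshold
    is retained.
    """
    if matrix.stage != TSS:
        raise PreprocessError("filter_low_abundance expects a TSS-normalized matrix")
    totals = matrix.data.sum(axis=0)
    removed = totals.index[totals < threshold].tolist()
    if removed:
        log.info("removing %d low-abundance features: %s", len(removed), removed)
    kept = matrix.data.drop(columns=removed)
    if kept.shape[1] == 0:
        raise PreprocessError("empty feature set: every feature fell below the threshold")
    return FeatureMatrix(data=kept, stage=FILTERED)


def ast_transform(matrix: FeatureMatrix, enabled: bool = True) -> FeatureMatrix:
    """Apply the arcsine square-root transform, or pass through if disabled.

    Values must lie in [0, 1]; larger values indicate the matrix was not
    TSS-normalized first.
    """
    if not enabled:
        return FeatureMatrix(data=matrix.data.copy(), stage=matrix.stage)
    vals = matrix.data.to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise PreprocessError(
            "AST requires values in [0, 1]; apply TSS normalization first "
            "or disable the transform"
        )
    out = pd.DataFrame(
        np.arcsin(np.sqrt(vals)), index=matrix.data.index, columns=matrix.data.columns
    )
    return FeatureMatrix(data=out, stage=AST)


def prepare_features(
    features: pd.DataFrame,
    ast_enabled: bool = True,
    threshold: float = LOW_ABUNDANCE_THRESHOLD,
) -> FeatureMatrix:
    """Run the full TSS → filter → AST pipeline on a raw feature frame."""
    fm = tss_normalize(FeatureMatrix(data=features, stage=RAW))
    fm = filter_low_abundance(fm, threshold=threshold)
    return ast_transform(fm, enabled=ast_enabled)


def complete_case_mask(metadata: pd.DataFrame, variables: Iterable[str]) -> pd.Series:
    """Samples with no missing value in any of the model's variables.

    The mask governs fitting only: samples excluded here still appear in
    detail views, grouped under an explicit "NA" category.
    """
    variables = list(variables)
    missing = [v for v in variables if v not in metadata.columns]
    if missing:
        raise PreprocessError(f"model variables not in metadata: {missing}")
    if not variables:
        return pd.Series(True, index=metadata.index)
    return metadata[variables].notna().all(axis=1)
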