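"""Run configuration, pipeline orchestration, logging and report export.

One run reads the merged table, types the variables from a schema file,
preprocesses the features, fits every candidate model, and writes: one
results TSV per model, the long-format comparison TSV, the birds-eye
heatmap, and a run log recording versions, parameters and anything
dropped along the way. Outputs of identical runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import (
    DEFAULT_Q_THRESHOLD,
    FIT_FAILED,
    SKIPPED_CONSTANT,
    ModelSpec,
    results_to_frame,
    run_model,
)
from .compare import ComparisonMatrix, compare_models, heatmap_figure, plot_heatmap, write_long_tsv
from .preprocess import LOW_ABUNDANCE_THRESHOLD
from .schema import build_schema, load_schema_config
from .stratify import DetailRecordSet, detail_figure
from .tables import partition_columns, read_merged_table, write_tsv

log = logging.getLogger(__name__)

MAX_MODELS = 10


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    input_path: Path
    schema_path: Path
    models: Sequence[ModelSpec]
    out_dir: Path
    q_threshold: float = DEFAULT_Q_THRESHOLD
    ast_enabled: bool | None = None  # None: honor each model's own flag
    abundance_threshold: float = LOW_ABUNDANCE_THRESHOLD
    delimiter: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.input_path = Path(self.input_path)
        self.schema_path = Path(self.schema_path)
        self.out_dir = Path(self.out_dir)
        if not 1 <= len(self.models) <= MAX_MODELS:
            raise ConfigError(
                f"expected between 1 and {MAX_MODELS} models, got {len(self.models)}"
            )
        names = [m.name for m in self.models]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate model names: {names}")


def load_model_specs(path: str | Path) -> list[ModelSpec]:
    """Load model definitions from a YAML/JSON file.

    Layout: a list of mappings with keys ``name``, ``fixed``, ``random``,
    ``reference``, ``ast``, ``q_threshold``. A model that omits ``fixed``
    inherits the previous model's variables; ``add_fixed`` appends to
    them, so nested model families are one line each. Unnamed models are
    named model_1..k in order.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, list) or not raw:
        raise ConfigError(f"{path.name}: expected a non-empty list of model definitions")
    specs: list[ModelSpec] = []
    for i, entry in enumerate(raw, start=1):
        fixed = entry.get("fixed")
        if fixed is None:
            if not specs:
                raise ConfigError(f"model #{i}: the first model must list 'fixed'")
            fixed = list(specs[-1].fixed)
        fixed = list(fixed) + [v for v in entry.get("add_fixed", []) if v not in fixed]
        spec = ModelSpec(
            name=entry.get("name") or f"model_{i}",
            fixed=tuple(fixed),
            random=tuple(entry.get("random", [])),
            reference=dict(entry.get("reference", {})),
            ast_enabled=bool(entry.get("ast", True)),
            q_threshold=float(entry.get("q_threshold", DEFAULT_Q_THRESHOLD)),
        )
        if specs and "random" not in entry:
            spec = spec.with_defaults_from(specs[-1])
        specs.append(spec)
    return specs


def _setup_run_log(out_dir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("assocmap")
    root.addHandler(handler)
    root.setLevel(level.upper())
    return handler


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns a bundle of output paths.

    On any failure, partially written outputs are removed before the
    error propagates with its module context.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(out, config.log_level)
    written: list[Path] = [out / "run.log"]
    try:
        log.info("assocmap %s | numpy %s | pandas %s", __version__,
                 np.__version__, pd.__version__)
        log.info("input=%s schema=%s models=%s q_threshold=%s",
                 config.input_path, config.schema_path,
                 [m.name for m in config.models], config.q_threshold)

        raw = read_merged_table(config.input_path, delimiter=config.delimiter)
        schema = build_schema(raw, **load_schema_config(config.schema_path))
        table = partition_columns(raw, schema)

        totals = table.features.sum(axis=1)
        n_zero = int((totals == 0).sum())
        rel = table.features.loc[totals > 0].div(totals[totals > 0], axis=0)
        n_removed = int((rel.sum(axis=0) < config.abundance_threshold).sum())
        log.info("dropped samples (zero total): %d; removed features (< %g): %d",
                 n_zero, config.abundance_threshold, n_removed)

        results_paths: dict[str, Path] = {}
        all_results = []
        n_failed = 0
        for spec in config.models:
            if config.ast_enabled is not None:
                spec = replace(spec, ast_enabled=config.ast_enabled)
            res = run_model(table, schema, spec, threshold=config.abundance_threshold)
            n_failed += sum(1 for r in res if r.status in (FIT_FAILED, SKIPPED_CONSTANT))
            all_results.append(res)
            p = write_tsv(results_to_frame(res), out / f"results_{spec.name}.tsv", index=False)
            results_paths[spec.name] = p
            written.append(p)
        log.info("failed/skipped fits across models: %d", n_failed)

        matrix = compare_models(all_results, q_threshold=config.q_threshold)
        comparison_path = write_long_tsv(matrix, out / "comparison.tsv")
        written.append(comparison_path)
        heatmap_path = None
        if not matrix.long.empty:
            heatmap_path = plot_heatmap(matrix, out / "heatmap.png")
            written.append(heatmap_path)
        else:
            log.warning("no significant associations at q < %g; heatmap skipped",
                        config.q_threshold)

        return {
            "results": results_paths,
            "comparison": comparison_path,
            "heatmap": heatmap_path,
            "log": out / "run.log",
            "matrix": matrix,
            "table": table,
            "schema": schema,
            "model_results": dict(zip([m.name for m in config.models], all_results)),
        }
    except Exception as exc:
        log.error("pipeline failed in %s: %s", type(exc).__module__, exc)
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise
    finally:
        logging.getLogger("assocmap").removeHandler(handler)
        handler.close()


def export_report(
    matrix: ComparisonMatrix,
    details: Sequence[tuple[DetailRecordSet, bool]] = (),
    path: str | Path = "report.pdf",
) -> Path:
    """Export one PDF: the heatmap first, then each requested detail plot.

    ``details`` pairs a record set with its ``faceted`` flag.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    if matrix.long.empty:
        raise ConfigError("nothing significant to report")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with PdfPages(path) as pdf:
        fig = heatmap_figure(matrix)
        pdf.savefig(fig)
        plt.close(fig)
        for records, faceted in details:
            fig = detail_figure(records, faceted=faceted)
            pdf.savefig(fig)
            plt.close(fig)
    return path
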