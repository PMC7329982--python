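"""Pipeline orchestration, the two-feature scatter plot, and the command line.

The full pipeline mirrors how the descriptors are meant to be used:
FASTA in, per-class CTDC feature extraction, merge into one labeled CSV,
ensemble feature selection, and a scatter of the two top-ranked features
colored by class. Every intermediate artifact is persisted so each stage
can be inspected or re-run on its own.

CLI subcommands: ``simulate``, ``extract``, ``select``, ``plot``, ``run``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import click
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import yaml

from . import __version__
from .ctd_features import ctdc_extractor, load_grouping_table
from .mrmd_ensemble import (
    METRIC_NAMES,
    RANKER_METHODS,
    EnsembleResult,
    ensemble_select,
)
from .seq_dataset import (
    FeatureMatrix,
    FeatureTableError,
    build_feature_table,
    read_csv,
    read_fasta,
    write_csv,
)
from .synth_fixtures import make_separable_dataset

log = logging.getLogger("ctdselect")

#: Class colors used throughout: positive purple, negative green.
DEFAULT_CLASS_COLORS = {1: "purple", 0: "green"}


@dataclass(frozen=True)
class PlotSpec:
    """Which two features to plot, where, and in which class colors."""

    feature_x: str
    feature_y: str
    output_path: Path
    colors: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_COLORS))

    def __post_init__(self) -> None:
        if self.feature_x == self.feature_y:
            raise ValueError("feature_x and feature_y must differ")


def scatter_features(matrix: FeatureMatrix, spec: PlotSpec):
    """Scatter every sample at its two feature values, colored by class.

    Writes the figure to ``spec.output_path`` (format from the extension)
    and returns the matplotlib figure for introspection.
    """
    for f in (spec.feature_x, spec.feature_y):
        if f not in matrix.data.columns:
            raise FeatureTableError(
                f"unknown feature {f!r}; available: {matrix.feature_names}"
            )
    fig, ax = plt.subplots(figsize=(6, 5))
    for label, name in ((1, "positive"), (0, "negative")):
        mask = matrix.labels == label
        ax.scatter(
            matrix.data.loc[mask, spec.feature_x],
            matrix.data.loc[mask, spec.feature_y],
            s=12,
            alpha=0.6,
            c=spec.colors[label],
            label=f"{name} (n={int(mask.sum())})",
        )
    ax.set_xlabel(spec.feature_x)
    ax.set_ylabel(spec.feature_y)
    ax.legend()
    fig.tight_layout()
    out = Path(spec.output_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out)
    return fig


def _selection_report(result: EnsembleResult) -> dict:
    sel = result.selection
    return {
        "rankings": {
            r.method: {"order": r.ordered_features, "notes": r.notes}
            for r in result.rankings
        },
        "pagerank_scores": result.pagerank_scores,
        "aggregated_order": sel.aggregated_order,
        "objective_metric": sel.objective_metric,
        "chosen_prefix": sel.chosen_prefix,
        "objective_value": sel.objective_value,
        "prefix_metrics": {
            str(k): m.as_dict() for k, m in sorted(sel.prefix_metrics.items())
        },
    }


def run_pipeline(
    pos_fasta: str | Path,
    neg_fasta: str | Path,
    out_dir: str | Path,
    table_choice: str = "extended13",
    methods: Sequence[str] = RANKER_METHODS,
    objective: str = "f1",
    folds: int = 5,
    seed: int = 0,
    label_style: str = "standard",
    residue_policy: str = "drop",
    stride: int = 1,
    plot_format: str = "svg",
) -> dict:
    """FASTA -> CTDC features -> merged CSV -> ensemble selection -> scatter.

    Writes ``features.csv``, ``reduced.csv``, ``selection_report.json`` and
    ``scatter_top2.<fmt>`` under ``out_dir`` and returns the report dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "parameters": {
            "pos_fasta": str(pos_fasta),
            "neg_fasta": str(neg_fasta),
            "table": table_choice,
            "methods": list(methods),
            "objective": objective,
            "folds": folds,
            "seed": seed,
            "label_style": label_style,
            "residue_policy": residue_policy,
            "stride": stride,
        },
        "stages": {},
    }

    def _stage(name):
        t0 = time.perf_counter()

        def _done(**info):
            dt = time.perf_counter() - t0
            report["stages"][name] = {"seconds": round(dt, 3), **info}
            log.info("stage %s finished in %.2fs %s", name, dt, info)

        return _done

    try:
        done = _stage("extract")
        table = load_grouping_table(table_choice)
        pos = read_fasta(pos_fasta, residue_policy=residue_policy)
        neg = read_fasta(neg_fasta, residue_policy=residue_policy)
        matrix = build_feature_table(pos, neg, ctdc_extractor(table))
        features_csv = write_csv(matrix, out_dir / "features.csv", label_style=label_style)
        done(n_pos=len(pos), n_neg=len(neg), n_features=matrix.n_features,
             features_csv=str(features_csv))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'extract' failed: {exc}") from exc

    try:
        done = _stage("select")
        result = ensemble_select(
            matrix,
            methods=methods,
            folds=folds,
            objective=objective,
            seed=seed,
            stride=stride,
        )
        reduced = matrix.select(result.selection.chosen_prefix)
        reduced_csv = write_csv(reduced, out_dir / "reduced.csv", label_style=label_style)
        done(chosen=result.selection.chosen_prefix,
             objective_value=result.selection.objective_value,
             reduced_csv=str(reduced_csv))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'select' failed: {exc}") from exc

    try:
        done = _stage("plot")
        order = result.selection.aggregated_order
        spec = PlotSpec(
            feature_x=order[0],
            feature_y=order[1],
            output_path=out_dir / f"scatter_top2.{plot_format}",
        )
        fig = scatter_features(matrix, spec)
        plt.close(fig)
        done(feature_x=spec.feature_x, feature_y=spec.feature_y,
             plot=str(spec.output_path))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'plot' failed: {exc}") from exc

    report["selection"] = _selection_report(result)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def _load_config(ctx, param, value):
    if value is None:
        return {}
    cfg = yaml.safe_load(Path(value).read_text()) or {}
    if not isinstance(cfg, dict):
        raise click.BadParameter("config file must contain a mapping of option names")
    ctx.default_map = {**cfg, **(ctx.default_map or {})}
    return cfg


_config_option = click.option(
    "--config",
    type=click.Path(exists=True, dir_okay=False),
    callback=_load_config,
    is_eager=True,
    expose_value=False,
    help="YAML file providing defaults for any option of this command.",
)


@click.group()
@click.version_option(__version__)
@click.option("--log-level", default="INFO", show_default=True,
              type=click.Choice(["DEBUG", "INFO", "WARNING", "ERROR"]))
def main(log_level: str) -> None:
    """CTD descriptors + ensemble feature selection for two-class protein data."""
    logging.basicConfig(
        level=getattr(logging, log_level),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@main.command()
@_config_option
@click.option("--bias", type=float, default=0.3, show_default=True,
              help="Probability mass shifted toward the class-enriched residue sets.")
@click.option("--n-per-class", type=int, default=500, show_default=True)
@click.option("--min-length", type=int, default=100, show_default=True)
@click.option("--max-length", type=int, default=400, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(file_okay=False), required=True)
def simulate(bias, n_per_class, min_length, max_length, seed, out_dir):
    """Generate a two-class synthetic FASTA dataset plus a manifest."""
    pos, neg = make_separable_dataset(
        bias, n_per_class, seed, out_dir, length_range=(min_length, max_length)
    )
    click.echo(f"wrote {pos}")
    click.echo(f"wrote {neg}")


@main.command()
@_config_option
@click.option("--pos-fasta", type=click.Path(exists=True, dir_okay=False), required=True)
@click.option("--neg-fasta", type=click.Path(exists=True, dir_okay=False), required=True)
@click.option("--table", default="extended13", show_default=True,
              help="'core7', 'extended13' or a custom grouping-table file.")
@click.option("--descriptors", default="C", show_default=True,
              type=click.Choice(["C", "CT", "CTD"]))
@click.option("--residue-policy", default="drop", show_default=True,
              type=click.Choice(["strict", "drop", "map_to_x_then_drop"]))
@click.option("--label-style", default="standard", show_default=True,
              type=click.Choice(["standard", "zero_minusone"]))
@click.option("--out-csv", type=click.Path(dir_okay=False), required=True)
def extract(pos_fasta, neg_fasta, table, descriptors, residue_policy, label_style, out_csv):
    """Extract CTD descriptors from two FASTA files into one labeled CSV."""
    grouping_table = load_grouping_table(table)
    pos = read_fasta(pos_fasta, residue_policy=residue_policy)
    neg = read_fasta(neg_fasta, residue_policy=residue_policy)
    matrix = build_feature_table(pos, neg, ctdc_extractor(grouping_table, descriptors))
    write_csv(matrix, out_csv, label_style=label_style)
    click.echo(f"wrote {out_csv} ({matrix.n_samples} samples x {matrix.n_features} features)")


@main.command()
@_config_option
@click.option("--features-csv", type=click.Path(exists=True, dir_okay=False), required=True)
@click.option("--methods", default=",".join(RANKER_METHODS), show_default=True,
              help="Comma-separated subset of the ranking methods.")
@click.option("--damping", type=float, default=0.85, show_default=True)
@click.option("--folds", type=int, default=5, show_default=True)
@click.option("--objective", default="f1", show_default=True,
              type=click.Choice(list(METRIC_NAMES)))
@click.option("--stride", type=int, default=1, show_default=True,
              help="Evaluate every stride-th prefix length (the full length is always evaluated).")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(file_okay=False), required=True)
def select(features_csv, methods, damping, folds, objective, stride, seed, out_dir):
    """Ensemble feature selection on a labeled feature CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_csv(features_csv)
    method_list = [m.strip() for m in methods.split(",") if m.strip()]
    result = ensemble_select(
        matrix, methods=method_list, damping=damping, folds=folds,
        objective=objective, seed=seed, stride=stride,
    )
    reduced = matrix.select(result.selection.chosen_prefix)
    write_csv(reduced, out / "reduced.csv")
    (out / "selection_report.json").write_text(
        json.dumps(_selection_report(result), indent=2) + "\n"
    )
    click.echo(
        f"chose {len(result.selection.chosen_prefix)} feature(s): "
        f"{', '.join(result.selection.chosen_prefix)} "
        f"({objective}={result.selection.objective_value:.4f})"
    )


@main.command()
@_config_option
@click.option("--features-csv", type=click.Path(exists=True, dir_okay=False), required=True)
@click.option("--feature-x", required=True)
@click.option("--feature-y", required=True)
@click.option("--pos-color", default=DEFAULT_CLASS_COLORS[1], show_default=True)
@click.option("--neg-color", default=DEFAULT_CLASS_COLORS[0], show_default=True)
@click.option("--out-file", type=click.Path(dir_okay=False), required=True)
def plot(features_csv, feature_x, feature_y, pos_color, neg_color, out_file):
    """Two-feature class-separation scatter plot from a labeled feature CSV."""
    matrix = read_csv(features_csv)
    spec = PlotSpec(
        feature_x=feature_x,
        feature_y=feature_y,
        output_path=Path(out_file),
        colors={1: pos_color, 0: neg_color},
    )
    fig = scatter_features(matrix, spec)
    plt.close(fig)
    click.echo(f"wrote {out_file}")


@main.command()
@_config_option
@click.option("--pos-fasta", type=click.Path(exists=True, dir_okay=False), required=True)
@click.option("--neg-fasta", type=click.Path(exists=True, dir_okay=False), required=True)
@click.option("--table", default="extended13", show_default=True)
@click.option("--methods", default=",".join(RANKER_METHODS), show_default=True)
@click.option("--objective", default="f1", show_default=True,
              type=click.Choice(list(METRIC_NAMES)))
@click.option("--folds", type=int, default=5, show_default=True)
@click.option("--stride", type=int, default=1, show_default=True)
@click.option("--label-style", default="standard", show_default=True,
              type=click.Choice(["standard", "zero_minusone"]))
@click.option("--plot-format", default="svg", show_default=True,
              type=click.Choice(["svg", "pdf", "png"]))
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(file_okay=False), required=True)
def run(pos_fasta, neg_fasta, table, methods, objective, folds, stride,
        label_style, plot_format, seed, out_dir):
    """Full pipeline: extract, merge, select, and plot the top two features."""
    method_list = [m.strip() for m in methods.split(",") if m.strip()]
    report = run_pipeline(
        pos_fasta, neg_fasta, out_dir,
        table_choice=table, methods=method_list, objective=objective,
        folds=folds, seed=seed, label_style=label_style, stride=stride,
        plot_format=plot_format,
    )
    sel = report["selection"]
    click.echo(f"aggregated top-5: {', '.join(sel['aggregated_order'][:5])}")
    click.echo(
        f"chosen prefix ({len(sel['chosen_prefix'])} features, "
        f"{sel['objective_metric']}={sel['objective_value']:.4f}): "
        f"{', '.join(sel['chosen_prefix'])}"
    )
    click.echo(f"artifacts in {out_dir}")
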