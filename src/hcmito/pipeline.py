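"""End-to-end pipeline orchestration: simulate (optional) -> measure ->
normalize -> classify -> report, with a run manifest whose per-stage
counts reconcile. Identical (config, seed) pairs produce byte-identical
outputs."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .classify import classification_report, report_from_counts
from .config import PipelineConfig, config_to_dict
from .errors import PipelineError, StageError, ConfigError
from .io import (RunManifest, read_cell_table, read_channel_stack,
                 read_label_map, write_cell_table, write_json,
                 write_label_map, write_ome_stack, write_trace_table)
from .ratiometric import measure_stack, normalize_to_neuromast_median
from .synth import generate_cell_cohort, generate_neuromast_stack, generate_traces
from .traces import analyze_trace, summarize_kinetics, traces_from_table

log = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write the result bundle.

    Returns a dict of the in-memory results (cells table, classification
    report, manifest). Any stage failure aborts with a stage-tagged
    StageError and removes files written so far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list = []
    manifest = RunManifest(seed=config.seed,
                           config_snapshot=config_to_dict_pipeline(config),
                           software_version=__version__)
    manifest.record_inputs([config.stack_path, config.label_map_path,
                            config.trace_table_path, config.cell_table_path,
                            config.counts_path])
    results: dict = {}
    try:
        cells = _stage_collect_cells(config, out, written, manifest)
        if cells is not None:
            results["cells"] = cells
        _stage_traces(config, out, written, manifest, results)
        _stage_classify(config, out, written, manifest, results, cells)
        manifest_path = out / "manifest.json"
        write_json(manifest.as_dict(), manifest_path)
        written.append(manifest_path)
        results["manifest"] = manifest
        return results
    except PipelineError:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise


def config_to_dict_pipeline(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, Path):
            d[k] = str(v)
    return d


def _wrap(stage: str):
    def deco(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError as exc:
                if isinstance(exc, StageError):
                    raise
                raise StageError(stage, exc) from exc
        return inner
    return deco


@_wrap("measure")
def _stage_collect_cells(config, out, written, manifest) -> Optional[pd.DataFrame]:
    """Produce the per-cell table: simulated cohort, measured stack, or a
    user-supplied CSV; then per-neuromast median normalization."""
    cells = None
    if config.simulate:
        cohort, truth = generate_cell_cohort(config.simulation)
        stack, regions, _ = generate_neuromast_stack(config.simulation, cohort)
        written.append(write_ome_stack(stack, out / "stack.ome.tif"))
        written.append(write_label_map(regions, out / "labels.tif"))
        cells = cohort.rename(columns={"true_ratio": "ratio"})
        manifest.record_stage("simulate", len(cells), len(cells))
    elif config.cell_table_path is not None:
        cells = read_cell_table(config.cell_table_path)
    elif config.stack_path is not None and config.label_map_path is not None:
        stack = read_channel_stack(config.stack_path, config.channel_order,
                                   pixel_size_xy=config.pixel_size_xy)
        side_px = int(round(30.0 / stack.pixel_size_xy))
        origin = (stack.shape[1] - side_px - 2, stack.shape[2] - side_px - 2)
        regions = read_label_map(config.label_map_path, origin,
                                 stack.pixel_size_xy)
        cells = measure_stack(stack, regions,
                              clip_negative=config.clip_negative_means)
        cells["neuromast_id"] = "nm1"
        cells["fish_id"] = "fish01"
    if cells is None:
        return None
    n_in = len(cells)
    defined = cells["ratio"].notna()
    cells = cells.copy()
    if "normalized_ratio" not in cells.columns or cells["normalized_ratio"].isna().all():
        cells.loc[defined, "normalized_ratio"] = normalize_to_neuromast_median(
            cells.loc[defined])
    manifest.record_stage("normalize", n_in, int(defined.sum()),
                          {"undefined_ratio": int((~defined).sum())})
    if "outcome" not in cells.columns:
        cells["outcome"] = "na"
    path = write_cell_table(cells, out / "cells.csv")
    written.append(path)
    return cells


@_wrap("traces")
def _stage_traces(config, out, written, manifest, results) -> None:
    traces = None
    if config.simulate:
        traces, truth = generate_traces(config.simulation)
        written.append(write_trace_table(traces, out / "traces.csv"))
        truth_path = out / "trace_truth.csv"
        truth.to_csv(truth_path, index=False)
        written.append(truth_path)
    elif config.trace_table_path is not None:
        df = pd.read_csv(config.trace_table_path)
        sim = config.simulation
        traces = traces_from_table(df, sim.baseline_window, sim.stimulus_window)
    if traces is None:
        return
    kin = [analyze_trace(t) for t in traces]
    kin_df = pd.DataFrame([dataclasses.asdict(k) for k in kin])
    kin_path = out / "kinetics.csv"
    kin_df.to_csv(kin_path, index=False)
    written.append(kin_path)
    summary = summarize_kinetics(kin)
    sum_path = out / "kinetics_summary.csv"
    summary.to_csv(sum_path, index=False)
    written.append(sum_path)
    n_missing = int(kin_df["rise_time_75"].isna().sum())
    manifest.record_stage("kinetics", len(kin), len(kin) - n_missing,
                          {"undefined_rise_time": n_missing})
    results["kinetics"] = kin_df
    results["kinetics_summary"] = summary


@_wrap("classify")
def _stage_classify(config, out, written, manifest, results, cells) -> None:
    report = None
    if config.counts_path is not None:
        counts = pd.read_csv(config.counts_path)
        need = {"tp", "fn", "fp", "tn"}
        if not need.issubset(counts.columns):
            raise ConfigError(
                f"counts file must have columns {sorted(need)}")
        row = counts.iloc[0]
        report = report_from_counts(int(row.tp), int(row.fn), int(row.fp),
                                    int(row.tn),
                                    zero_cell_policy=config.zero_cell_policy)
        manifest.record_stage("classify", report.table.n, report.table.n)
    elif cells is not None and "outcome" in cells.columns \
            and (cells["outcome"] != "na").any():
        ok = cells["normalized_ratio"].notna()
        report = classification_report(
            cells.loc[ok, "normalized_ratio"].to_numpy(),
            cells.loc[ok, "outcome"].to_numpy(),
            zero_cell_policy=config.zero_cell_policy)
        manifest.record_stage(
            "classify", int(ok.sum()),
            int(ok.sum()) - report.n_outcome_na,
            {"outcome_na": report.n_outcome_na})
    if report is None:
        return
    path = write_json(report.as_dict(), out / "classification.json")
    written.append(path)
    txt = out / "classification.txt"
    txt.write_text(format_report_text(report))
    written.append(txt)
    results["classification"] = report


def format_report_text(report) -> str:
    """Human-readable classification report (display precision: 2 d.p.
    for proportions and the DOR; full precision stays in the JSON)."""
    t = report.table
    dor = f"{report.dor:.2f}" if report.dor_is_finite else "non-finite (zero cell)"
    lines = [
        "Median-split red/green classification vs live/die outcome",
        f"  counts: tp={t.tp} fn={t.fn} fp={t.fp} tn={t.tn} (n={t.n})",
        f"  sensitivity: {report.sensitivity:.2f}",
        f"  specificity: {report.specificity:.2f}",
        f"  diagnostic odds ratio: {dor}",
        f"  Fisher exact (two-sided) p: {report.fisher_p:.3g}",
    ]
    if report.pos is not None:
        lines.append(f"  P(surviving ratio < dying ratio): {report.pos:.2f}")
    if report.n_ties:
        lines.append(f"  cells exactly at the median (called green): {report.n_ties}")
    return "\n".join(lines) + "\n"
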