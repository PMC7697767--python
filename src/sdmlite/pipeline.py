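"""End-to-end orchestration of the distribution-modelling workflow.

One config drives the whole chain: clean occurrences -> extract climate ->
sample background -> k-fold split -> stepwise AIC variable selection on
training presences + background -> fit the envelope and/or maxent model on
the training presences -> evaluate on the held-out fold + background ->
maxSSS threshold -> project continuous and binary maps (globally and per
region) -> permutation importance (maxent) -> machine-readable JSON report.

Determinism: the single config seed deterministically derives one sub-seed
per named stage (CRC32 of "seed:stage"), so each stage is independently
reproducible and two runs with the same config are byte-identical apart from
file timestamps.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bioclim as _bioclim
from . import maxent as _maxent
from .evaluation import (apply_threshold, evaluate_scores,
                         permutation_importance, summarize_occurrence_climate)
from .grids import ClimateStack, crop_stack, extract_values, read_raster_stack, write_raster
from .occurrences import clean_occurrences, read_occurrences, write_occurrences
from .sampling import kfold_partition, sample_background
from .selection import stepwise_aic

__all__ = ["PipelineConfig", "run_pipeline", "project_region", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Everything one run needs; seed mandatory, paths resolved at run time."""

    occurrences: str
    raster_paths: list[str]
    raster_codes: list[str]
    out_dir: str
    seed: int
    lon_col: str = "lon"
    lat_col: str = "lat"
    n_background: int = 2000
    k_folds: int = 5
    test_fold: int = 1
    models: list[str] = field(default_factory=lambda: ["bioclim", "maxent"])
    bioclim_tails: str = "continuous"
    maxent_rm: float = 1.0
    maxent_classes: list[str] = field(default_factory=lambda: ["linear", "quadratic", "product"])
    maxent_output: str = "raw"
    importance_reps: int = 10
    regions: dict[str, list[float]] = field(default_factory=dict)  # name -> [W,S,E,N]
    raster_format: str = "asc"
    select_variables: bool = True

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = open(path, "r", encoding="utf-8").read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            obj = yaml.safe_load(text)
        else:
            obj = json.loads(text)
        return cls(**obj)


def _fit_model(name: str, config: PipelineConfig, train_presence: pd.DataFrame,
               background: pd.DataFrame, variables: list[str]):
    if name == "bioclim":
        model = _bioclim.BioclimEnvelope(tails=config.bioclim_tails)
        model.fit(train_presence[variables])
        return model
    if name == "maxent":
        model = _maxent.MaxEntSDM(classes=tuple(config.maxent_classes),
                                  rm=config.maxent_rm)
        X = pd.concat([train_presence[variables], background[variables]],
                      ignore_index=True)
        y = np.r_[np.ones(len(train_presence), dtype=int),
                  np.zeros(len(background), dtype=int)]
        model.fit(X, y)
        return model
    raise ValueError(f"unknown model {name!r}")


def _predict(model, X: pd.DataFrame, config: PipelineConfig) -> np.ndarray:
    if isinstance(model, _maxent.MaxEntSDM):
        return model.predict(X, output=config.maxent_output)
    return model.predict(X)


def _project(model, stack: ClimateStack, config: PipelineConfig) -> np.ndarray:
    if isinstance(model, _maxent.MaxEntSDM):
        return _maxent.project_maxent(model, stack, output=config.maxent_output)
    return _bioclim.project_envelope(model, stack)


def project_region(model, stack: ClimateStack, bbox, threshold: float,
                   config: PipelineConfig | None = None):
    """Crop to a lon/lat box, project, and threshold; returns (cont, binary, cropped_stack)."""
    config = config or PipelineConfig("", [], [], "", 0)
    sub = crop_stack(stack, bbox)
    cont = _project(model, sub, config)
    return cont, apply_threshold(cont, threshold), sub


def run_pipeline(config: PipelineConfig, stack: ClimateStack | None = None,
                 raw_occurrences: pd.DataFrame | None = None) -> dict:
    """Run the full workflow; returns the report (also written as JSON).

    ``stack`` and ``raw_occurrences`` may be passed directly (e.g. from the
    synthetic generator); otherwise they are read from the configured paths.
    Any stage failure aborts with the stage name; the partial report of the
    stages completed so far is still written.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": [], "manifest": []}
    stage = "setup"

    def done(name):
        report["stages"].append(name)

    def emit(grid, stack_for, name):
        path = os.path.join(config.out_dir, f"{name}.{config.raster_format}")
        write_raster(grid, stack_for, path)
        report["manifest"].append(path)
        return path

    try:
        stage = "read"
        if stack is None:
            stack = read_raster_stack(config.raster_paths, config.raster_codes)
        if raw_occurrences is None:
            raw_occurrences = read_occurrences(config.occurrences,
                                               config.lon_col, config.lat_col)
        done("read")

        stage = "clean"
        occ = clean_occurrences(raw_occurrences, stack)
        report["cleaning"] = {"n_input": len(raw_occurrences),
                              "n_retained": len(occ),
                              "dropped": occ.provenance}
        occ_path = os.path.join(config.out_dir, "occurrences_clean.csv")
        write_occurrences(occ.points, occ_path)
        report["manifest"].append(occ_path)
        done("clean")

        stage = "extract"
        presence = extract_values(stack, occ.points, label=1)
        done("extract")

        stage = "background"
        bg_points = sample_background(stack, config.n_background,
                                      stage_seed(config.seed, "background"))
        background = extract_values(stack, bg_points, label=0)
        bg_path = os.path.join(config.out_dir, "background.csv")
        with open(bg_path, "w", encoding="utf-8") as fh:
            fh.write(f"# n={config.n_background} seed={stage_seed(config.seed, 'background')}\n")
            bg_points.to_csv(fh, index=False)
        report["manifest"].append(bg_path)
        done("background")

        stage = "kfold"
        folds = kfold_partition(len(presence), config.k_folds,
                                stage_seed(config.seed, "kfold"))
        is_test = folds == config.test_fold
        train_presence = presence[~is_test].reset_index(drop=True)
        test_presence = presence[is_test].reset_index(drop=True)
        report["folds"] = {"k": config.k_folds, "test_fold": config.test_fold,
                           "n_train": int(len(train_presence)),
                           "n_test": int(len(test_presence))}
        done("kfold")

        stage = "select"
        train_table = pd.concat([train_presence, background], ignore_index=True)
        if config.select_variables:
            trace = stepwise_aic(train_table, list(stack.codes))
            variables = [c for c in stack.codes if c in trace.selected]
            report["selection"] = {"selected": variables,
                                   "trace": trace.steps,
                                   "skipped": trace.skipped}
        else:
            variables = list(stack.codes)
            report["selection"] = {"selected": variables, "trace": [],
                                   "skipped": []}
        if not variables:  # degenerate all-noise case: keep the full set
            variables = list(stack.codes)
            report["selection"]["note"] = "empty selection; full set retained"
        done("select")

        report["models"] = {}
        for name in config.models:
            stage = f"fit:{name}"
            model = _fit_model(name, config, train_presence, background, variables)
            model_path = os.path.join(config.out_dir, f"model_{name}.json")
            with open(model_path, "w", encoding="utf-8") as fh:
                fh.write(model.to_json())
            report["manifest"].append(model_path)

            stage = f"evaluate:{name}"
            sp = _predict(model, test_presence[variables], config)
            sb = _predict(model, background[variables], config)
            ev = evaluate_scores(sp, sb)
            entry = ev.to_dict()

            stage = f"project:{name}"
            cont = _project(model, stack, config)
            entry["suitability_raster"] = emit(cont, stack, f"suitability_{name}")
            binary = apply_threshold(cont, ev.threshold_maxsss)
            entry["binary_raster"] = emit(binary, stack, f"presence_{name}")
            entry["regions"] = {}
            for rname, bbox in config.regions.items():
                rcont, rbin, rstack = project_region(model, stack, bbox,
                                                     ev.threshold_maxsss, config)
                entry["regions"][rname] = {
                    "suitability_raster": emit(rcont, rstack, f"suitability_{name}_{rname}"),
                    "binary_raster": emit(rbin, rstack, f"presence_{name}_{rname}"),
                }

            if name == "maxent":
                stage = "importance"
                table = pd.concat([presence, background], ignore_index=True)
                data = table[["lon", "lat", "label"] + variables]
                imp = permutation_importance(
                    model, data, n_reps=config.importance_reps,
                    seed=stage_seed(config.seed, "importance"))
                entry["importance"] = {
                    r.variable: r.importance_pct for r in imp.itertuples()
                }
            report["models"][name] = entry
            done(name)

        stage = "summary"
        report["occurrence_climate"] = summarize_occurrence_climate(
            presence[["lon", "lat", "label"] + variables])
        done("summary")
    except Exception as exc:
        report["error"] = {"stage": stage, "message": str(exc)}
        _write_report(report, config.out_dir)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _write_report(report, config.out_dir)
    return report


def _write_report(report: dict, out_dir) -> None:
    path = os.path.join(out_dir, "report.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
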