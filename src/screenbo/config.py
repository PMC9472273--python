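"""Experiment grids: YAML configuration, seed derivation, batch execution.

A grid is the cross product of noise levels x acquisition metrics x retest
kinds x batch sizes, each cell run ``n_runs`` times with per-run seeds
derived from a base seed.  Arms within a run share the run seed, so the
initial batch and noise stream are paired across metrics and retest kinds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .campaign import CampaignConfig, CampaignTrace, RetestPolicy, run_campaign
from .evaluation import summarize_arm
from .surrogate import DEFAULT_UNCERTAINTY
from .library import (
    DEFAULT_NOISE_FORM,
    ScreeningLibrary,
    generate_friedman3_library,
    generate_linear_library,
    load_library_csv,
)

__all__ = [
    "DEFAULT_ALPHAS",
    "ExperimentGrid",
    "load_grid",
    "grid_from_dict",
    "run_seed_for",
    "build_library",
    "run_grid",
    "evaluate_traces",
]

CONFIG_VERSION = 1

#: Canonical injected-noise sweep.
DEFAULT_ALPHAS = (0.0, 0.05, 0.1, 0.15, 0.2, 0.25)

_GRID_KEYS = {
    "version",
    "library",
    "alphas",
    "metrics",
    "retest_kinds",
    "batch_sizes",
    "n_runs",
    "base_seed",
    "hit_quantile",
    "stop_fraction",
    "max_batches",
    "n_trees",
    "beta",
    "epsilon",
    "noise_form",
    "uncertainty",
    "max_retests_per_molecule",
    "uncertainty_weight",
    "retest_basis",
}

_LIBRARY_KEYS = {
    "generator",
    "n_samples",
    "n_features",
    "n_informative",
    "seed",
    "path",
    "feature_columns",
    "activity_column",
    "active_label_column",
}


@dataclass(frozen=True)
class ExperimentGrid:
    """One experiment campaign grid (see module docstring)."""

    library: dict
    alphas: tuple = DEFAULT_ALPHAS
    metrics: tuple = ("greedy", "random")
    retest_kinds: tuple = ("none",)
    batch_sizes: tuple = (100,)
    n_runs: int = 10
    base_seed: int = 0
    hit_quantile: float = 0.10
    stop_fraction: float = 0.5
    max_batches: int | None = None
    n_trees: int = 100
    beta: float = 2.0
    epsilon: float = 0.01
    noise_form: str = DEFAULT_NOISE_FORM
    uncertainty: str = DEFAULT_UNCERTAINTY
    max_retests_per_molecule: int = 1
    uncertainty_weight: float = 0.1
    retest_basis: str = "predicted"

    def __post_init__(self):
        for name in ("alphas", "metrics", "retest_kinds", "batch_sizes"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be a non-empty list")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.alphas) * len(self.metrics) * len(self.retest_kinds) * len(self.batch_sizes)

    def cells(self):
        for alpha in self.alphas:
            for metric in self.metrics:
                for kind in self.retest_kinds:
                    for batch_size in self.batch_sizes:
                        yield alpha, metric, kind, batch_size

    def campaign_config(self, alpha, metric, retest_kind, batch_size) -> CampaignConfig:
        policy = RetestPolicy(
            kind=retest_kind,
            max_retests_per_molecule=self.max_retests_per_molecule,
            uncertainty_weight=self.uncertainty_weight,
            basis=self.retest_basis,
        )
        return CampaignConfig(
            batch_size=batch_size,
            hit_quantile=self.hit_quantile,
            alpha=alpha,
            metric=metric,
            retest_policy=policy,
            n_runs=self.n_runs,
            stop_fraction=self.stop_fraction,
            n_trees=self.n_trees,
            beta=self.beta,
            epsilon=self.epsilon,
            max_batches=self.max_batches,
            noise_form=self.noise_form,
            uncertainty=self.uncertainty,
        )


def grid_from_dict(raw: dict) -> ExperimentGrid:
    unknown = set(raw) - _GRID_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    version = raw.get("version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise ValueError(f"unsupported config version {version}; expected {CONFIG_VERSION}")
    if "library" not in raw:
        raise ValueError("config must declare a 'library' section")
    lib = dict(raw["library"])
    unknown = set(lib) - _LIBRARY_KEYS
    if unknown:
        raise ValueError(f"unknown library key(s): {sorted(unknown)}")
    kwargs = {k: v for k, v in raw.items() if k not in ("version", "library")}
    for name in ("alphas", "metrics", "retest_kinds", "batch_sizes", "feature_columns"):
        if name in kwargs and kwargs[name] is not None:
            kwargs[name] = tuple(kwargs[name])
    return ExperimentGrid(library=lib, **kwargs)


def load_grid(path) -> ExperimentGrid:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    return grid_from_dict(raw)


def run_seed_for(base_seed: int, run_index: int) -> int:
    """Deterministic per-run seed below 2**31, derived from (base, index)."""
    return int(np.random.SeedSequence([int(base_seed), int(run_index)]).generate_state(1)[0] % (2**31))


def build_library(grid: ExperimentGrid) -> ScreeningLibrary:
    lib = grid.library
    generator = lib.get("generator", "csv")
    if generator == "linear":
        return generate_linear_library(
            lib.get("n_samples", 5000),
            lib.get("n_features", 10),
            lib.get("n_informative", 5),
            seed=lib.get("seed", 0),
            hit_quantile=grid.hit_quantile,
        )
    if generator == "friedman3":
        return generate_friedman3_library(
            lib.get("n_samples", 5000), seed=lib.get("seed", 0), hit_quantile=grid.hit_quantile
        )
    if generator == "csv":
        return load_library_csv(
            lib["path"],
            feature_columns=lib.get("feature_columns"),
            activity_column=lib.get("activity_column", "activity"),
            active_label_column=lib.get("active_label_column"),
            hit_quantile=grid.hit_quantile,
        )
    raise ValueError(f"unknown library generator {generator!r}")


def trace_filename(metric, alpha, retest_kind, batch_size, run_index) -> str:
    return f"{metric}_alpha{alpha:g}_retest-{retest_kind}_bs{batch_size}_run{run_index}.jsonl"


def run_grid(grid: ExperimentGrid, outdir, library: ScreeningLibrary | None = None) -> Path:
    """Run every cell x run of the grid; write traces and a summary CSV.

    Returns the path of ``summary.csv``.  Output bytes are a deterministic
    function of the grid (config + base seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if library is None:
        library = build_library(grid)

    traces: dict[tuple, list[CampaignTrace]] = {}
    for alpha, metric, kind, batch_size in grid.cells():
        config = grid.campaign_config(alpha, metric, kind, batch_size)
        cell = []
        for r in range(grid.n_runs):
            trace = run_campaign(library, config, run_seed_for(grid.base_seed, r))
            trace.config["run_index"] = r
            trace.to_jsonl(outdir / trace_filename(metric, alpha, kind, batch_size, r))
            cell.append(trace)
        traces[(alpha, metric, kind, batch_size)] = cell

    summary = _summarize(traces)
    summary_path = outdir / "summary.csv"
    summary.to_csv(summary_path, index=False, float_format="%.6g")
    return summary_path


def _summarize(traces: dict[tuple, list[CampaignTrace]], checkpoints=None) -> pd.DataFrame:
    rows = []
    for (alpha, metric, kind, batch_size), cell in sorted(traces.items(), key=lambda kv: str(kv[0])):
        cell_checkpoints = checkpoints or [len(cell[0].batches) - 1]
        random_cell = traces.get((alpha, "random", kind, batch_size))
        for cp in cell_checkpoints:
            if random_cell is not None and len(random_cell) == len(cell):
                res = summarize_arm(metric, cell, random_cell, cp)
                ef, ef_true = res.enrichment_factor, res.enrichment_factor_true_hits
            else:
                res = summarize_arm(metric, cell, cell, cp)  # self-paired: stats only
                ef = ef_true = float("nan")
            rows.append(
                {
                    "metric": metric,
                    "alpha": alpha,
                    "retest_kind": kind,
                    "batch_size": batch_size,
                    "checkpoint": cp,
                    "hits_mean": res.hits_mean,
                    "hits_std": res.hits_std,
                    "true_hits_mean": res.true_hits_mean,
                    "true_hits_std": res.true_hits_std,
                    "enrichment_factor": ef,
                    "enrichment_factor_true_hits": ef_true,
                }
            )
    return pd.DataFrame(rows)


def evaluate_traces(trace_dir, checkpoints=None, outdir=None) -> Path:
    """Re-summarize a directory of trace files into evaluation CSVs."""
    trace_dir = Path(trace_dir)
    paths = sorted(trace_dir.glob("*.jsonl"))
    if not paths:
        raise FileNotFoundError(f"no trace files (*.jsonl) found in {trace_dir}")
    cells: dict[tuple, list] = {}
    for path in paths:
        trace = CampaignTrace.from_jsonl(path)
        cfg = trace.config
        key = (cfg["alpha"], cfg["metric"], cfg["retest_policy"]["kind"], cfg["batch_size"])
        cells.setdefault(key, []).append(trace)
    for cell in cells.values():
        cell.sort(key=lambda t: t.config.get("run_index", t.run_seed))
    summary = _summarize(cells, checkpoints=checkpoints)
    outdir = Path(outdir) if outdir is not None else trace_dir
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "evaluation.csv"
    summary.to_csv(out, index=False, float_format="%.6g")
    return out
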