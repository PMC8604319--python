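"""Factorial sweep orchestration: contexts x strategies x parameter grids.

The context-relative standardization forces a two-pass design per
environmental context: first simulate every decision variable and collect
raw metrics, then resolve the standardization bounds from the pooled
ensemble, and only then score and aggregate.  Seeds are cell-local
(derived from context and strategy identity, not execution order), so the
result tables are identical for any worker count and any single cell can
be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .config import (
    EnvironmentalContext,
    ExperimentConfig,
    HarvestStrategySpec,
    build_decision_grid,
    build_environmental_grid,
)
from .dynamics import simulate_scenario
from .evaluation import (
    METRIC_NAMES,
    StandardizationBounds,
    composite_replicate_scores,
    compute_raw_metrics,
    resolve_bounds,
    standardize_frame,
)

__all__ = [
    "ExperimentResult",
    "CacheMismatchError",
    "run_experiment",
    "summarize_run",
    "KEY_COLUMNS",
]

logger = logging.getLogger("harvestmse")

#: identifying columns of one (context, strategy-spec) cell
KEY_COLUMNS = [
    "species",
    "sid",
    "variability",
    "start_scenario",
    "kind",
    "label",
    "constant_c",
    "proportion_p",
    "threshold_T",
    "grid_order",
]


class CacheMismatchError(RuntimeError):
    """A cache directory holds results from a different configuration."""


@dataclass
class ExperimentResult:
    """Master results of one factorial run.

    ``scores`` has one row per (context, strategy spec, composite set) with
    the mean composite score over replicates plus distribution summaries.
    ``replicate_scores`` (optional) has one row per (cell, replicate, set).
    """

    scores: pd.DataFrame
    replicate_scores: pd.DataFrame | None
    bounds: dict[tuple[str, int], StandardizationBounds]
    manifest: dict = field(default_factory=dict)


def _cell_key_values(context: EnvironmentalContext, spec: HarvestStrategySpec, order: int) -> dict:
    return {
        "species": context.species.name,
        "sid": context.sid,
        "variability": context.variability.value,
        "start_scenario": context.start_scenario.value,
        "kind": spec.kind.value,
        "label": spec.label,
        "constant_c": spec.constant_c,
        "proportion_p": spec.proportion_p,
        "threshold_T": spec.threshold_T,
        "grid_order": order,
    }


def simulate_cell(
    context: EnvironmentalContext,
    spec: HarvestStrategySpec,
    config: ExperimentConfig,
    grid_order: int,
) -> pd.DataFrame:
    """Simulate one cell and return its raw-metric rows (one per replicate)."""
    trajectories = simulate_scenario(context, spec, config)
    keys = _cell_key_values(context, spec, grid_order)
    rows = [
        {**keys, "replicate": i, **compute_raw_metrics(tr, context.species, config).as_dict()}
        for i, tr in enumerate(trajectories)
    ]
    df = pd.DataFrame(rows)
    for col in ("constant_c", "proportion_p", "threshold_T"):
        df[col] = df[col].astype(float)
    return df


def _cell_cache_path(cache_dir: Path, context, spec, cfg_hash: str) -> Path:
    import zlib

    tag = zlib.crc32(spec.label.encode()) & 0xFFFFFFFF
    return cache_dir / f"{context.species.name}_sid{context.sid}_{tag:08x}.csv"


def _simulate_cell_cached(context, spec, config, grid_order, cache_dir, cfg_hash):
    if cache_dir is None:
        return simulate_cell(context, spec, config, grid_order)
    path = _cell_cache_path(cache_dir, context, spec, cfg_hash)
    if path.exists():
        return pd.read_csv(path)
    df = simulate_cell(context, spec, config, grid_order)
    df.to_csv(path, index=False)
    return df


def run_experiment(
    config: ExperimentConfig,
    workers: int = 1,
    store_replicate_scores: bool = True,
    cache_dir: str | Path | None = None,
) -> ExperimentResult:
    """Run the full factorial sweep and assemble the master score table.

    Deterministic under a fixed ``config.master_seed`` regardless of
    ``workers``.  With ``cache_dir`` set, per-cell raw-metric tables are
    checkpointed on disk and reused on resume; a cache directory written
    under a different configuration raises :class:`CacheMismatchError`.
    """
    cfg_hash = config.config_hash()
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        meta = cache_dir / "cache_meta.json"
        if meta.exists():
            stored = json.loads(meta.read_text()).get("config_hash")
            if stored != cfg_hash:
                raise CacheMismatchError(
                    f"cache at {cache_dir} was written for config hash {stored}, "
                    f"current config hash is {cfg_hash}"
                )
        else:
            meta.write_text(json.dumps({"config_hash": cfg_hash}))

    contexts = build_environmental_grid(config)
    grids = {s.name: build_decision_grid(config, s) for s in config.species}

    score_rows: list[pd.DataFrame] = []
    replicate_rows: list[pd.DataFrame] = []
    bounds_by_context: dict[tuple[str, int], StandardizationBounds] = {}

    parallel = Parallel(n_jobs=workers) if workers != 1 else None
    t_run = time.perf_counter()
    for context in contexts:
        t0 = time.perf_counter()
        grid = grids[context.species.name]
        tasks = [(context, spec, config, order) for order, spec in enumerate(grid)]
        if parallel is None:
            cell_frames = [
                _simulate_cell_cached(*task[:4], cache_dir=cache_dir, cfg_hash=cfg_hash)
                for task in tasks
            ]
        else:
            cell_frames = parallel(
                delayed(_simulate_cell_cached)(*task[:4], cache_dir=cache_dir, cfg_hash=cfg_hash)
                for task in tasks
            )
        raw = pd.concat(cell_frames, ignore_index=True)
        bounds = resolve_bounds(raw[list(METRIC_NAMES)], config.timeframe_T)
        bounds_by_context[(context.species.name, context.sid)] = bounds
        std = raw.copy()
        std[list(METRIC_NAMES)] = standardize_frame(raw[list(METRIC_NAMES)], bounds)

        for set_name in config.evaluation_sets:
            scores = composite_replicate_scores(std, set_name)
            cell = std[KEY_COLUMNS + ["replicate"]].copy()
            cell["set"] = set_name
            cell["score"] = scores.to_numpy()
            if store_replicate_scores:
                replicate_rows.append(cell)
            agg = (
                cell.groupby(KEY_COLUMNS + ["set"], dropna=False, sort=False)["score"]
                .agg(
                    score_mean="mean",
                    score_sd="std",
                    score_q25=lambda s: s.quantile(0.25),
                    score_median="median",
                    score_q75=lambda s: s.quantile(0.75),
                    n_replicates="count",
                )
                .reset_index()
            )
            score_rows.append(agg)
        logger.info(
            "context %s: %d strategy specs x %d replicates in %.1fs",
            context.label,
            len(grid),
            config.n_replicates,
            time.perf_counter() - t0,
        )

    scores = pd.concat(score_rows, ignore_index=True)
    replicate_scores = (
        pd.concat(replicate_rows, ignore_index=True) if store_replicate_scores else None
    )
    manifest = {
        "config_hash": cfg_hash,
        "master_seed": config.master_seed,
        "n_replicates": config.n_replicates,
        "timeframe": config.timeframe_T,
        "package_version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "runtime_seconds": round(time.perf_counter() - t_run, 3),
        "tables": {
            "scores": int(len(scores)),
            "replicate_scores": int(len(replicate_scores)) if replicate_scores is not None else 0,
        },
    }
    logger.info("run complete: %d score records", len(scores))
    return ExperimentResult(
        scores=scores,
        replicate_scores=replicate_scores,
        bounds=bounds_by_context,
        manifest=manifest,
    )


def summarize_run(scores: pd.DataFrame | ExperimentResult, threshold: float = 85.0) -> dict:
    """Headline summaries of a completed score table.

    Cases are (context, strategy kind, set) combinations at their best
    parameters; the summary reports how many exceed ``threshold`` and how
    many are maximal (score 100).
    """
    if isinstance(scores, ExperimentResult):
        scores = scores.scores
    if scores is None or len(scores) == 0:
        raise ValueError("cannot summarize an empty results table")
    case_cols = ["species", "sid", "kind", "set"]
    best = scores.groupby(case_cols, sort=False)["score_mean"].max()
    per_context = (
        scores.groupby(["species", "sid"], sort=False)["score_mean"]
        .agg(["min", "max"])
        .reset_index()
    )
    n_cases = int(len(best))
    return {
        "n_records": int(len(scores)),
        "n_cases": n_cases,
        "threshold": float(threshold),
        "n_cases_above_threshold": int((best > threshold).sum()),
        "pct_cases_above_threshold": float(100.0 * (best > threshold).mean()),
        "n_cases_maximal": int((best >= 100.0 - 1e-9).sum()),
        "per_context_score_range": per_context,
    }
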