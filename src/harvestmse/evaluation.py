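"""Sustainability metrics: 10 per-replicate raw metrics, 0-100
standardization within each environmental context, and 6 composite sets.

Raw metrics are oriented so that higher is always more desirable (harvest
variability therefore enters as ``0 - sd``).  Standardization maps each
metric linearly to [0, 100] where 0 is the worst score and 100 the most
desirable outcome possible over all replications and decision variables of
the same environmental context: persistence and the year-count metrics use
absolute bounds (0..1, 0..T), while harvest volume metrics use the largest
value observed in the context ensemble and harvest consistency uses the
largest observed harvest variability as its worst pole.

Composite scores are unweighted means of a set's member metrics, computed
per replicate first and then averaged over replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import ExperimentConfig, SpeciesProfile
from .dynamics import Trajectory

__all__ = [
    "METRIC_NAMES",
    "COMPOSITE_SETS",
    "RawMetrics",
    "StandardizationBounds",
    "compute_raw_metrics",
    "resolve_bounds",
    "standardize",
    "standardize_frame",
    "composite_replicate_scores",
]

METRIC_NAMES = (
    "persistence",
    "above_quasi_extinct",
    "above_low",
    "stable_population",
    "below_high",
    "below_overabundant",
    "harvest_mean",
    "harvest_minimum",
    "harvest_non_zeros",
    "harvest_consistency",
)

#: The six evaluation perspectives.  Persistence belongs to every set;
#: "complete" is all ten metrics.
COMPOSITE_SETS: dict[str, frozenset[str]] = {
    "classic_harv": frozenset({"persistence", "harvest_mean"}),
    "classic_pop_harv": frozenset({"persistence", "stable_population", "harvest_mean"}),
    "population_focus": frozenset(
        {
            "persistence",
            "above_quasi_extinct",
            "above_low",
            "stable_population",
            "below_high",
            "below_overabundant",
        }
    ),
    "harvest_focus": frozenset(
        {
            "persistence",
            "harvest_mean",
            "harvest_minimum",
            "harvest_non_zeros",
            "harvest_consistency",
        }
    ),
    "complete_small_game": frozenset(
        {
            "persistence",
            "above_quasi_extinct",
            "above_low",
            "harvest_mean",
            "harvest_minimum",
            "harvest_non_zeros",
            "harvest_consistency",
        }
    ),
    "complete": frozenset(METRIC_NAMES),
}


@dataclass(frozen=True)
class RawMetrics:
    """Raw (unstandardized) metric values for one replicate."""

    persistence: int
    above_quasi_extinct: int
    above_low: int
    stable_population: int
    below_high: int
    below_overabundant: int
    harvest_mean: float
    harvest_minimum: float
    harvest_non_zeros: int
    harvest_consistency: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def compute_raw_metrics(
    trajectory: Trajectory,
    profile: SpeciesProfile,
    config: ExperimentConfig | None = None,
) -> RawMetrics:
    """The 10 raw metrics for one replicate trajectory.

    Year counts compare the population series (post-harvest by default,
    pre-harvest with ``config.metrics_on == "pre"``) to the species'
    critical thresholds with strict inequalities; ties count as not
    satisfying the criterion.  Harvest statistics are computed on the
    realized-harvest series; harvest consistency is minus its (population)
    standard deviation.
    """
    on = config.metrics_on if config is not None else "post"
    N = trajectory.N if on == "post" else trajectory.N_pre
    H = trajectory.H
    p = profile
    return RawMetrics(
        persistence=0 if trajectory.extinct else 1,
        above_quasi_extinct=int(np.sum(N > p.threshold_quasi_extinct)),
        above_low=int(np.sum(N > p.threshold_low)),
        stable_population=int(np.sum((N > p.threshold_low) & (N < p.threshold_high))),
        below_high=int(np.sum(N < p.threshold_high)),
        below_overabundant=int(np.sum(N < p.threshold_overabundant)),
        harvest_mean=float(np.mean(H)),
        harvest_minimum=float(np.min(H)),
        harvest_non_zeros=int(np.sum(H > 0)),
        harvest_consistency=-float(np.std(H)),
    )


@dataclass(frozen=True)
class StandardizationBounds:
    """Per-metric (worst, best) poles for one environmental context."""

    worst: Mapping[str, float]
    best: Mapping[str, float]


_COUNT_METRICS = (
    "above_quasi_extinct",
    "above_low",
    "stable_population",
    "below_high",
    "below_overabundant",
    "harvest_non_zeros",
)


def _as_frame(raw) -> pd.DataFrame:
    if isinstance(raw, pd.DataFrame):
        return raw
    return pd.DataFrame([m.as_dict() for m in raw])


def resolve_bounds(raw, timeframe_T: int) -> StandardizationBounds:
    """Standardization poles from one context's full decision-variable sweep.

    ``raw`` is the pooled raw-metric table (DataFrame with metric columns,
    or an iterable of :class:`RawMetrics`) over every strategy, parameter
    choice, and replicate of the context.  Persistence and year counts get
    absolute bounds; harvest mean/minimum are bounded above by the largest
    observed value; harvest consistency is bounded below by minus the
    largest observed harvest variability.
    """
    df = _as_frame(raw)
    if df.empty:
        raise ValueError("cannot resolve standardization bounds from an empty ensemble")
    worst = {"persistence": 0.0}
    best = {"persistence": 1.0}
    for name in _COUNT_METRICS:
        worst[name] = 0.0
        best[name] = float(timeframe_T)
    for name in ("harvest_mean", "harvest_minimum"):
        worst[name] = 0.0
        best[name] = float(df[name].max())
    worst["harvest_consistency"] = float(df["harvest_consistency"].min())
    best["harvest_consistency"] = 0.0
    return StandardizationBounds(worst=worst, best=best)


def _standardize_values(values, worst: float, best: float, name: str):
    if best == worst:
        # Degenerate ensemble (e.g. no strategy ever harvests): equal to the
        # ideal pole scores 100, anything else 0.
        warnings.warn(
            f"metric {name!r} has degenerate standardization bounds "
            f"(worst == best == {best}); scoring equality with the ideal as 100",
            stacklevel=3,
        )
        return np.where(np.asarray(values, dtype=float) == best, 100.0, 0.0)
    scaled = 100.0 * (np.asarray(values, dtype=float) - worst) / (best - worst)
    return np.clip(scaled, 0.0, 100.0)


def standardize(raw: RawMetrics, bounds: StandardizationBounds) -> dict[str, float]:
    """Standardized 0-100 values of one replicate's metrics."""
    return {
        name: float(
            _standardize_values([getattr(raw, name)], bounds.worst[name], bounds.best[name], name)[0]
        )
        for name in METRIC_NAMES
    }


def standardize_frame(df: pd.DataFrame, bounds: StandardizationBounds) -> pd.DataFrame:
    """Vectorized standardization of a raw-metric table (metric columns only)."""
    out = df.copy()
    for name in METRIC_NAMES:
        out[name] = _standardize_values(
            df[name].to_numpy(), bounds.worst[name], bounds.best[name], name
        )
    return out


def composite_replicate_scores(
    standardized: pd.DataFrame, set_name: str
) -> pd.Series:
    """Per-replicate composite score: unweighted mean of the set's members.

    ``standardized`` holds one row per replicate with standardized metric
    columns; non-metric key columns are ignored.
    """
    try:
        members = sorted(COMPOSITE_SETS[set_name])
    except KeyError:
        raise KeyError(
            f"unknown composite set {set_name!r}; known sets: {sorted(COMPOSITE_SETS)}"
        ) from None
    return standardized[members].mean(axis=1)
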