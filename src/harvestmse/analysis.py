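"""Comparative decision analysis on a completed score table.

Builds on the master scores (mean composite score per context, strategy
spec, and evaluation set) to answer the comparative questions: which
parameters are optimal per strategy, which strategy is optimal per
(context, set) case, how much value is forgone by a suboptimal choice,
how paired factor levels differ with everything else held equal, and how
much decision-making improves when the choice of strategy can condition
on environmental or evaluation context (the value of information).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ExperimentConfig, StrategyKind

__all__ = [
    "CASE_COLUMNS",
    "INFORMATION_LEVELS",
    "OptimalParameters",
    "ContrastResult",
    "DecisionRuleEvaluation",
    "optimality_table",
    "select_optimal_parameters",
    "rank_strategies",
    "compute_value_forgone",
    "pairwise_contrasts",
    "score_contrasts",
    "parameter_contrasts",
    "evaluate_decision_heuristics",
]

#: columns identifying one (environmental context, evaluation set) case
CASE_COLUMNS = ["species", "sid", "variability", "start_scenario", "set"]

#: partition columns per information level: what a decision-maker is allowed
#: to condition the strategy choice on
INFORMATION_LEVELS: dict[str, list[str]] = {
    "none": [],
    "species": ["species"],
    "variability": ["variability"],
    "start_population": ["start_scenario"],
    "full_environment": ["species", "variability", "start_scenario"],
    "evaluation_set": ["set"],
}

_KIND_ORDER = {k.value: i for i, k in enumerate(StrategyKind)}


# --------------------------------------------------------------------------
# Optimal parameters and strategies

@dataclass(frozen=True)
class OptimalParameters:
    """Best parameter choice of one strategy kind in one case."""

    kind: str
    label: str
    params: dict
    score: float
    tied_labels: tuple[str, ...]  #: all grid points within the tie tolerance


def optimality_table(
    scores: pd.DataFrame,
    tie_decimals: int = 6,
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Per (case, strategy kind): best parameters, rank, and value forgone.

    The best parameter vector is the argmax of the mean composite score
    over the kind's grid; ties (after rounding scores to ``tie_decimals``)
    are broken toward the smallest parameter vector in grid order, with the
    tied labels also reported.  Within each case, kinds are ranked by best
    score (ties share the better rank); kinds tied with the top score are
    flagged jointly optimal and carry value forgone exactly 0.  With a
    ``config``, constants and thresholds are also reported as fractions of
    the species' moderate size.
    """
    df = scores.copy()
    df["_round"] = df["score_mean"].round(tie_decimals)
    group_cols = CASE_COLUMNS + ["kind"]

    df = df.sort_values(["_round", "grid_order"], ascending=[False, True], kind="mergesort")
    best = df.groupby(group_cols, sort=False, dropna=False).head(1).copy()
    group_max = df.groupby(group_cols, sort=False, dropna=False)["_round"].transform("max")
    tied = df[df["_round"] == group_max]
    tie_info = (
        tied.sort_values("grid_order", kind="mergesort")
        .groupby(group_cols, sort=False, dropna=False)["label"]
        .agg(n_tied="size", tied_labels=lambda s: ";".join(s))
        .reset_index()
    )
    best = best.merge(tie_info, on=group_cols, how="left")
    best = best.rename(columns={"label": "best_label", "score_mean": "best_score"})

    case_round_max = best.groupby(CASE_COLUMNS, sort=False)["_round"].transform("max")
    best["is_optimal"] = best["_round"] == case_round_max
    # rank: 1 + number of kinds with a strictly better rounded score
    def _rank(group: pd.Series) -> pd.Series:
        return group.rank(method="min", ascending=False)

    best["rank"] = (
        best.groupby(CASE_COLUMNS, sort=False)["_round"].transform(_rank).astype(int)
    )
    case_raw_opt = best.groupby(CASE_COLUMNS, sort=False)["best_score"].transform("max")
    vf = (case_raw_opt - best["best_score"]).clip(lower=0.0)
    best["value_forgone"] = np.where(best["is_optimal"], 0.0, vf)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(case_raw_opt > 0, 100.0 * best["value_forgone"] / case_raw_opt, 0.0)
    best["value_forgone_pct"] = rel

    if config is not None:
        moderate = {s.name: s.moderate_size for s in config.species}
        mod = best["species"].map(moderate)
        best["constant_frac"] = best["constant_c"] / mod
        best["threshold_frac"] = best["threshold_T"] / mod

    keep = CASE_COLUMNS + [
        "kind",
        "best_label",
        "best_score",
        "constant_c",
        "proportion_p",
        "threshold_T",
        "n_tied",
        "tied_labels",
        "rank",
        "is_optimal",
        "value_forgone",
        "value_forgone_pct",
    ]
    if config is not None:
        keep += ["constant_frac", "threshold_frac"]
    out = best[keep].sort_values(CASE_COLUMNS + ["kind"], kind="mergesort").reset_index(drop=True)
    return out


def select_optimal_parameters(
    scores: pd.DataFrame,
    species: str,
    sid: int,
    set_name: str,
    kind: str | StrategyKind,
    tie_decimals: int = 6,
) -> OptimalParameters:
    """Best parameters (and score) of one strategy kind in one case."""
    kind = StrategyKind(kind).value
    sel = scores[
        (scores["species"] == species)
        & (scores["sid"] == sid)
        & (scores["set"] == set_name)
        & (scores["kind"] == kind)
    ]
    if sel.empty:
        raise KeyError(
            f"no score records for species={species!r} sid={sid} set={set_name!r} kind={kind!r}"
        )
    rounded = sel["score_mean"].round(tie_decimals)
    top = rounded.max()
    tied = sel[rounded == top].sort_values("grid_order", kind="mergesort")
    row = tied.iloc[0]
    params = {
        name: row[name]
        for name in ("constant_c", "proportion_p", "threshold_T")
        if pd.notna(row[name])
    }
    return OptimalParameters(
        kind=kind,
        label=row["label"],
        params=params,
        score=float(row["score_mean"]),
        tied_labels=tuple(tied["label"]),
    )


def rank_strategies(
    best_scores: Mapping[str, float], tie_tolerance: float = 0.0
) -> dict[str, int]:
    """Descending ranks of strategy kinds; kinds within tolerance share rank."""
    out = {}
    for kind, score in best_scores.items():
        out[kind] = 1 + sum(
            1 for other in best_scores.values() if other > score + tie_tolerance
        )
    return out


def compute_value_forgone(
    optimality: pd.DataFrame,
    species: str,
    sid: int,
    set_name: str,
    chosen_kind: str | StrategyKind,
) -> tuple[float, float]:
    """Value forgone (score points, and % of the optimal score) of a choice.

    The chosen kind is evaluated at its own optimal parameters against the
    case's optimal strategy; a jointly optimal choice forgoes exactly 0.
    """
    kind = StrategyKind(chosen_kind).value
    case = optimality[
        (optimality["species"] == species)
        & (optimality["sid"] == sid)
        & (optimality["set"] == set_name)
    ]
    if case.empty:
        raise KeyError(f"case species={species!r} sid={sid} set={set_name!r} not found")
    row = case[case["kind"] == kind]
    if row.empty:
        raise KeyError(f"strategy kind {kind!r} absent from case")
    return float(row["value_forgone"].iloc[0]), float(row["value_forgone_pct"].iloc[0])


# --------------------------------------------------------------------------
# Pairwise contrasts

@dataclass
class ContrastResult:
    """Paired differences (left - right) for one factor contrast."""

    factor: str
    left: str
    right: str
    differences: np.ndarray
    n_pairs: int
    n_unmatched: int
    median: float
    q1: float
    q3: float
    prop_below: float  #: proportion of pairs with difference < 0
    prop_zero: float
    prop_above: float


def pairwise_contrasts(
    df: pd.DataFrame,
    factor: str,
    levels: tuple[str, str],
    value_col: str,
    match_cols: Sequence[str],
) -> ContrastResult:
    """Differences between two factor levels with all other factors matched.

    Rows at the two levels are paired on ``match_cols``; unmatched
    complements are counted and excluded.  The proportions of pairs below,
    at, and above zero difference sum to 1.
    """
    match_cols = list(match_cols)
    left_name, right_name = levels
    left = df[df[factor] == left_name]
    right = df[df[factor] == right_name]
    if left.empty or right.empty:
        raise ValueError(f"factor {factor!r}: both levels {levels} must be present")
    merged = left.merge(right, on=match_cols, how="outer", suffixes=("_L", "_R"), indicator=True)
    paired = merged[merged["_merge"] == "both"]
    n_unmatched = int((merged["_merge"] != "both").sum())
    diffs = (paired[f"{value_col}_L"] - paired[f"{value_col}_R"]).to_numpy(dtype=float)
    if len(diffs) == 0:
        raise ValueError(f"factor {factor!r}: no matched pairs between levels {levels}")
    return ContrastResult(
        factor=factor,
        left=left_name,
        right=right_name,
        differences=diffs,
        n_pairs=len(diffs),
        n_unmatched=n_unmatched,
        median=float(np.median(diffs)),
        q1=float(np.quantile(diffs, 0.25)),
        q3=float(np.quantile(diffs, 0.75)),
        prop_below=float(np.mean(diffs < 0)),
        prop_zero=float(np.mean(diffs == 0)),
        prop_above=float(np.mean(diffs > 0)),
    )


_CONTRAST_FACTORS = ["species", "variability", "start_scenario", "set", "kind"]


def score_contrasts(
    optimality: pd.DataFrame, factor: str, levels: tuple[str, str]
) -> ContrastResult:
    """Contrast of best composite scores between two levels of one factor."""
    match = [c for c in _CONTRAST_FACTORS if c != factor]
    return pairwise_contrasts(optimality, factor, levels, "best_score", match)


def parameter_contrasts(
    optimality: pd.DataFrame,
    kind: str | StrategyKind,
    param: str,
    factor: str,
    levels: tuple[str, str],
) -> ContrastResult:
    """Contrast of optimal parameter values within one strategy kind.

    ``param`` is one of ``proportion_p``, ``constant_frac``,
    ``threshold_frac`` (the fractional columns keep constants/thresholds
    comparable across species).
    """
    kind = StrategyKind(kind).value
    sub = optimality[optimality["kind"] == kind]
    match = [c for c in _CONTRAST_FACTORS if c not in (factor, "kind")]
    return pairwise_contrasts(sub, factor, levels, param, match)


# --------------------------------------------------------------------------
# Information value of context knowledge

@dataclass
class DecisionRuleEvaluation:
    """How well a single strategy choice per information cell performs.

    ``cells`` holds, per partition cell and selection rule, the chosen
    strategy kind and its performance over the member cases; ``pooled``
    aggregates over all cases per rule.
    """

    information_level: str
    cells: pd.DataFrame
    pooled: dict[str, dict[str, float]]


def evaluate_decision_heuristics(
    optimality: pd.DataFrame, information_level: str
) -> DecisionRuleEvaluation:
    """Evaluate context-conditioned strategy choice at one information level.

    The (context, set) cases are partitioned by what the decision-maker
    knows (nothing, the species, the variability level, the starting
    population, the full environmental context, or the evaluation set).
    Within each cell a single strategy kind is chosen under two selection
    rules — most frequently optimal, and minimum mean value forgone — and
    judged by the fraction of member cases where the choice is (jointly)
    optimal and by the mean value forgone.
    """
    try:
        part_cols = INFORMATION_LEVELS[information_level]
    except KeyError:
        raise KeyError(
            f"unknown information level {information_level!r}; "
            f"known levels: {sorted(INFORMATION_LEVELS)}"
        ) from None

    df = optimality.copy()
    if not part_cols:
        df["_cell"] = "all"
        part_cols = ["_cell"]

    perf = (
        df.groupby(part_cols + ["kind"], sort=False)
        .agg(
            n_cases=("is_optimal", "size"),
            n_optimal=("is_optimal", "sum"),
            mean_value_forgone=("value_forgone", "mean"),
        )
        .reset_index()
    )
    perf["_kind_order"] = perf["kind"].map(_KIND_ORDER)

    cell_rows = []
    for cell_key, group in perf.groupby(part_cols, sort=False):
        if not isinstance(cell_key, tuple):
            cell_key = (cell_key,)
        chosen = {
            "most_frequent_optimal": group.sort_values(
                ["n_optimal", "mean_value_forgone", "_kind_order"],
                ascending=[False, True, True],
                kind="mergesort",
            ).iloc[0],
            "min_mean_forgone": group.sort_values(
                ["mean_value_forgone", "n_optimal", "_kind_order"],
                ascending=[True, False, True],
                kind="mergesort",
            ).iloc[0],
        }
        for rule, row in chosen.items():
            cell_rows.append(
                {
                    **dict(zip(part_cols, cell_key)),
                    "rule": rule,
                    "chosen_kind": row["kind"],
                    "n_cases": int(row["n_cases"]),
                    "n_optimal": int(row["n_optimal"]),
                    "pct_optimal": 100.0 * row["n_optimal"] / row["n_cases"],
                    "mean_value_forgone": float(row["mean_value_forgone"]),
                }
            )
    cells = pd.DataFrame(cell_rows)

    pooled = {}
    for rule, group in cells.groupby("rule", sort=False):
        n = group["n_cases"].sum()
        pooled[rule] = {
            "pct_optimal": float(100.0 * group["n_optimal"].sum() / n),
            "mean_value_forgone": float(
                (group["mean_value_forgone"] * group["n_cases"]).sum() / n
            ),
            "n_cases": int(n),
        }
    return DecisionRuleEvaluation(
        information_level=information_level, cells=cells, pooled=pooled
    )
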