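"""Comparative analysis: optimality, ranking, value forgone, contrasts,
and the information value of context knowledge."""

import itertools

import numpy as np
import pandas as pd
import pytest

from harvestmse.analysis import (
    INFORMATION_LEVELS,
    compute_value_forgone,
    evaluate_decision_heuristics,
    optimality_table,
    pairwise_contrasts,
    rank_strategies,
    score_contrasts,
    select_optimal_parameters,
)

SID_META = {1: ("low", "moderate"), 3: ("low", "quasi_extinction"), 2: ("high", "moderate")}


def make_scores(cells, species="sp", sid=1, set_name="complete"):
    """Build a score table from (kind, label, score) triples (grid order =
    list order within kind)."""
    variability, start = SID_META[sid]
    rows = []
    for order, (kind, label, score) in enumerate(cells):
        rows.append(
            {
                "species": species,
                "sid": sid,
                "variability": variability,
                "start_scenario": start,
                "kind": kind,
                "label": label,
                "constant_c": np.nan,
                "proportion_p": np.nan,
                "threshold_T": np.nan,
                "grid_order": order,
                "set": set_name,
                "score_mean": score,
            }
        )
    return pd.DataFrame(rows)


def random_case(rng, species="sp", sid=1, set_name="complete"):
    """A random (context, set) case with <=3 grid points per strategy."""
    cells = [("no_harvest", "nh", rng.uniform(0, 100))]
    for kind, prefix, n in [
        ("constant", "c", 3),
        ("proportional", "p", 3),
        ("threshold_proportional", "tp", 3),
    ]:
        for j in range(n):
            cells.append((kind, f"{prefix}{j}", rng.uniform(0, 100)))
    return make_scores(cells, species=species, sid=sid, set_name=set_name)


class TestOptimalParameters:
    def test_matches_exhaustive_enumeration(self):
        """Argmax over each kind's grid agrees with brute force on random
        score tables."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            scores = random_case(rng)
            for kind in scores["kind"].unique():
                sub = scores[scores["kind"] == kind]
                brute = sub.loc[sub["score_mean"].idxmax()]
                got = select_optimal_parameters(scores, "sp", 1, "complete", kind)
                assert got.score == pytest.approx(brute["score_mean"])
                assert got.label == brute["label"]

    def test_unimodal_peak(self):
        scores = make_scores(
            [("proportional", f"p{i}", s) for i, s in enumerate([10, 60, 90, 70])]
        )
        got = select_optimal_parameters(scores, "sp", 1, "complete", "proportional")
        assert got.label == "p2" and got.score == 90

    def test_constant_scores_tie_to_first_grid_point(self):
        scores = make_scores([("proportional", f"p{i}", 55.0) for i in range(3)])
        got = select_optimal_parameters(scores, "sp", 1, "complete", "proportional")
        assert got.label == "p0"
        assert got.tied_labels == ("p0", "p1", "p2")

    def test_no_harvest_single_score(self):
        scores = make_scores([("no_harvest", "nh", 33.0)])
        got = select_optimal_parameters(scores, "sp", 1, "complete", "no_harvest")
        assert got.score == 33.0 and got.params == {}

    def test_missing_grid_raises(self):
        scores = make_scores([("no_harvest", "nh", 33.0)])
        with pytest.raises(KeyError):
            select_optimal_parameters(scores, "sp", 1, "complete", "constant")


class TestRanking:
    def test_rank_semantics_with_ties(self):
        ranks = rank_strategies(
            {"no_harvest": 10, "constant": 88, "proportional": 88, "threshold_proportional": 90}
        )
        assert ranks == {
            "threshold_proportional": 1,
            "constant": 2,
            "proportional": 2,
            "no_harvest": 4,
        }

    def test_tie_tolerance_merges_near_ties(self):
        ranks = rank_strategies({"a": 90.0, "b": 89.5, "c": 10.0}, tie_tolerance=1.0)
        assert ranks["a"] == 1 and ranks["b"] == 1 and ranks["c"] == 3

    def test_optimality_table_ranks_match_rank_strategies(self):
        rng = np.random.default_rng(7)
        scores = random_case(rng)
        opt = optimality_table(scores)
        best = dict(zip(opt["kind"], opt["best_score"].round(6)))
        expected = rank_strategies(best)
        got = dict(zip(opt["kind"], opt["rank"]))
        assert got == expected


class TestValueForgone:
    def test_optimal_choice_forgoes_exactly_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            opt = optimality_table(random_case(rng))
            optimal_kinds = opt.loc[opt["is_optimal"], "kind"]
            for kind in optimal_kinds:
                points, rel = compute_value_forgone(opt, "sp", 1, "complete", kind)
                assert points == 0.0 and rel == 0.0

    def test_hand_computed_difference(self):
        scores = make_scores(
            [("proportional", "p0", 90.0), ("constant", "c0", 85.0)]
        )
        opt = optimality_table(scores)
        points, rel = compute_value_forgone(opt, "sp", 1, "complete", "constant")
        assert points == pytest.approx(5.0)
        assert rel == pytest.approx(100 * 5 / 90)  # 5.56% of the optimum

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        scores = random_case(rng)
        opt = optimality_table(scores)
        best_by_kind = scores.groupby("kind")["score_mean"].max()
        overall = best_by_kind.max()
        for kind, best in best_by_kind.items():
            points, _ = compute_value_forgone(opt, "sp", 1, "complete", kind)
            assert points == pytest.approx(overall - best)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        scores = random_case(rng)
        shuffled = scores.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(optimality_table(scores), optimality_table(shuffled))


class TestContrasts:
    def _two_level_table(self, offset):
        frames = []
        for sid, score_base in [(1, 50.0), (3, 50.0 - offset)]:
            for set_name in ("complete", "classic_harv"):
                frames.append(
                    make_scores(
                        [("proportional", "p0", score_base), ("no_harvest", "nh", score_base - 5)],
                        sid=sid,
                        set_name=set_name,
                    )
                )
        return optimality_table(pd.concat(frames, ignore_index=True))

    def test_identical_levels_give_zero_differences(self):
        opt = self._two_level_table(offset=0.0)
        c = score_contrasts(opt, "start_scenario", ("moderate", "quasi_extinction"))
        assert np.all(c.differences == 0)
        assert (c.prop_below, c.prop_zero, c.prop_above) == (0.0, 1.0, 0.0)

    def test_constant_offset_detected(self):
        opt = self._two_level_table(offset=2.0)
        c = score_contrasts(opt, "start_scenario", ("moderate", "quasi_extinction"))
        assert c.median == pytest.approx(2.0)
        assert c.prop_above == 1.0
        assert c.n_pairs == 4  # 2 sets x 2 kinds
        assert c.prop_below + c.prop_zero + c.prop_above == 1.0

    def test_unmatched_complements_excluded(self):
        opt = self._two_level_table(offset=2.0)
        opt = opt.drop(opt[(opt["sid"] == 3) & (opt["kind"] == "no_harvest")].index[:1])
        c = score_contrasts(opt, "start_scenario", ("moderate", "quasi_extinction"))
        assert c.n_pairs == 3
        assert c.n_unmatched == 1

    def test_missing_level_rejected(self):
        opt = self._two_level_table(offset=1.0)
        with pytest.raises(ValueError):
            score_contrasts(opt, "species", ("sp", "other"))


def heterogeneous_optimality(seed=0):
    """Cases over 2 species x 2 sids x 2 sets with random scores."""
    rng = np.random.default_rng(seed)
    frames = []
    for species in ("alpha", "beta"):
        for sid in (1, 2):
            for set_name in ("complete", "classic_harv"):
                frames.append(random_case(rng, species=species, sid=sid, set_name=set_name))
    return optimality_table(pd.concat(frames, ignore_index=True))


class TestDecisionHeuristics:
    def test_full_information_is_perfect(self):
        """A partition fine enough to isolate every case always chooses an
        optimal kind and forgoes nothing."""
        rng = np.random.default_rng(2)
        frames = [
            random_case(rng, species=sp, sid=1, set_name="complete")
            for sp in ("a", "b", "c")
        ]
        opt = optimality_table(pd.concat(frames, ignore_index=True))
        ev = evaluate_decision_heuristics(opt, "species")
        for rule in ("most_frequent_optimal", "min_mean_forgone"):
            assert ev.pooled[rule]["pct_optimal"] == 100.0
            assert ev.pooled[rule]["mean_value_forgone"] == 0.0

    def test_refinement_never_hurts_min_forgone_rule(self):
        opt = heterogeneous_optimality()
        vf = {
            level: evaluate_decision_heuristics(opt, level).pooled["min_mean_forgone"][
                "mean_value_forgone"
            ]
            for level in ("none", "species", "full_environment")
        }
        assert vf["species"] <= vf["none"] + 1e-12
        assert vf["full_environment"] <= vf["species"] + 1e-12

    def test_case_counts_partition_exactly(self):
        opt = heterogeneous_optimality()
        n_cases = len(opt[["species", "sid", "set"]].drop_duplicates())
        for level in INFORMATION_LEVELS:
            ev = evaluate_decision_heuristics(opt, level)
            for rule in ("most_frequent_optimal", "min_mean_forgone"):
                sub = ev.cells[ev.cells["rule"] == rule]
                assert sub["n_cases"].sum() == n_cases

    def test_none_level_matches_hand_aggregation(self):
        opt = heterogeneous_optimality()
        ev = evaluate_decision_heuristics(opt, "none")
        cells = ev.cells[ev.cells["rule"] == "most_frequent_optimal"]
        chosen = cells["chosen_kind"].iloc[0]
        by_kind = opt.groupby("kind")["is_optimal"].sum()
        assert by_kind[chosen] == by_kind.max()
        expected_pct = 100 * opt.loc[opt["kind"] == chosen, "is_optimal"].mean()
        assert ev.pooled["most_frequent_optimal"]["pct_optimal"] == pytest.approx(expected_pct)

    def test_unknown_level_rejected(self):
        with pytest.raises(KeyError):
            evaluate_decision_heuristics(heterogeneous_optimality(), "telepathy")
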