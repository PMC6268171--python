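"""Consensus docking-score aggregation."""

import numpy as np
import pandas as pd
import pytest

from zbscreen.consensus import SCORE_NAMES, consensus, load_scores, select_candidates
from zbscreen.synth import synth_score_table


def long_table(values: dict[str, dict[str, float]]) -> pd.DataFrame:
    rows = [{"candidate_id": cand, "pose_id": "p1", "score_name": name, "value": v}
            for cand, scores in values.items() for name, v in scores.items()]
    return pd.DataFrame(rows)


FIXTURE = {
    "A": {"GoldScore": 50, "ChemScore": 30, "ASP": 40, "CHEMPLP": 55,
          "CDOCKER": -30, "LibDock": 100},
    "B": {"GoldScore": 40, "ChemScore": 20, "ASP": 40, "CHEMPLP": 45,
          "CDOCKER": -20, "LibDock": 90},
    "C": {"GoldScore": 60, "ChemScore": 10, "ASP": 40, "CHEMPLP": 35,
          "CDOCKER": -10, "LibDock": 80},
}


def test_load_scores_complete_candidates():
    table = load_scores(long_table(FIXTURE))
    assert table.incomplete == []
    assert len(table.complete) == 3


def test_missing_score_flags_incomplete():
    broken = {k: dict(v) for k, v in FIXTURE.items()}
    del broken["B"]["LibDock"]
    table = load_scores(long_table(broken))
    assert table.incomplete == ["B"]
    assert list(table.complete.index) == ["A", "C"]


def test_unknown_score_name_is_an_error():
    df = long_table({"A": {"MagicScore": 1.0}})
    with pytest.raises(ValueError, match="unknown score"):
        load_scores(df)


def test_best_pose_respects_direction():
    df = pd.DataFrame([
        {"candidate_id": "A", "pose_id": "p1", "score_name": "GoldScore", "value": 40},
        {"candidate_id": "A", "pose_id": "p2", "score_name": "GoldScore", "value": 55},
        {"candidate_id": "A", "pose_id": "p1", "score_name": "CDOCKER", "value": -10},
        {"candidate_id": "A", "pose_id": "p2", "score_name": "CDOCKER", "value": -25},
    ])
    table = load_scores(df)
    assert table.best.loc["A", "GoldScore"] == 55      # higher-better: max
    assert table.best.loc["A", "CDOCKER"] == -25       # lower-better: min


def test_raw_sum_matches_hand_computed_fixture():
    # CDOCKER is negated to higher-better before summation
    table = load_scores(long_table(FIXTURE))
    ranking = consensus(table, "raw_sum").set_index("candidate_id")
    assert ranking.loc["A", "consensus"] == pytest.approx(305.0)
    assert ranking.loc["B", "consensus"] == pytest.approx(255.0)
    assert ranking.loc["C", "consensus"] == pytest.approx(235.0)
    assert list(ranking["rank"]) == [1, 2, 3]


def test_single_candidate_ranks_first():
    table = load_scores(long_table({"A": FIXTURE["A"]}))
    out = consensus(table)
    assert len(out) == 1 and out.iloc[0]["rank"] == 1


def test_dominant_candidate_wins_under_both_methods():
    df, plant = synth_score_table([f"c{i}" for i in range(8)], seed=13)
    table = load_scores(df)
    for method in ("raw_sum", "rank_sum"):
        ranking = consensus(table, method)
        assert ranking.iloc[0]["candidate_id"] == plant


def test_raw_sum_invariant_to_constant_shift_of_one_score():
    shifted = {c: dict(v) for c, v in FIXTURE.items()}
    for c in shifted:
        shifted[c]["ASP"] += 1000.0
    base = consensus(load_scores(long_table(FIXTURE)), "raw_sum")
    moved = consensus(load_scores(long_table(shifted)), "raw_sum")
    assert list(base["candidate_id"]) == list(moved["candidate_id"])


def test_rank_sum_invariant_to_monotone_transform_of_one_score():
    warped = {c: dict(v) for c, v in FIXTURE.items()}
    for c in warped:
        warped[c]["LibDock"] = float(np.exp(warped[c]["LibDock"] / 20.0))
    base = consensus(load_scores(long_table(FIXTURE)), "rank_sum")
    moved = consensus(load_scores(long_table(warped)), "rank_sum")
    assert list(base["candidate_id"]) == list(moved["candidate_id"])


def test_no_complete_candidates_is_an_error():
    broken = {"A": dict(FIXTURE["A"])}
    del broken["A"]["ASP"]
    table = load_scores(long_table(broken))
    with pytest.raises(ValueError, match="no complete"):
        consensus(table)


def test_select_candidates_joins_rank_and_fit():
    ranking = consensus(load_scores(long_table(FIXTURE)))
    fits = {"A": 4.1, "B": 5.2, "C": 3.3}
    report = select_candidates(ranking, fits, top_n=2)
    assert list(report.columns) == ["candidate_id", "consensus", "rank", "fit"]
    assert list(report["candidate_id"]) == ["A", "B"]
    assert report.loc[0, "fit"] == pytest.approx(4.1)


def test_select_candidates_disjoint_ids_empty_report():
    ranking = consensus(load_scores(long_table(FIXTURE)))
    report = select_candidates(ranking, {"zzz": 1.0}, top_n=5)
    assert report.empty


def test_select_candidates_top_n_larger_than_join():
    ranking = consensus(load_scores(long_table(FIXTURE)))
    report = select_candidates(ranking, {"A": 1.0, "B": 2.0, "C": 3.0}, top_n=50)
    assert len(report) == 3
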