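"""Consensus aggregation of external docking scores.

Docking itself is out of scope: this module ingests score tables produced
by external docking programs (or by the synthetic fixtures) covering six
scoring functions — GoldScore, ChemScore, ASP, CHEMPLP (GOLD fitness
scores, higher-better), CDOCKER (an interaction energy, lower-better) and
LibDock (higher-better) — selects the direction-best pose per candidate
and score, and ranks candidates by either

* ``raw_sum``  — scores sign-normalized to higher-better (lower-better
  scores negated) and summed, or
* ``rank_sum`` — per-score ranks summed (lower sum is better); invariant
  under monotone rescaling of any single score column.

Candidates missing any of the six scores are flagged incomplete and
excluded from consensus by default.  The final report joins consensus
ranks with pharmacophore fit values so both selection criteria are
explicit side by side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Score name -> True when higher is better.  Versioned configuration.
SCORE_DIRECTIONS: dict[str, bool] = {
    "GoldScore": True,
    "ChemScore": True,
    "ASP": True,
    "CHEMPLP": True,
    "CDOCKER": False,
    "LibDock": True,
}
SCORE_NAMES = tuple(SCORE_DIRECTIONS)

__all__ = ["ScoreTable", "SCORE_DIRECTIONS", "SCORE_NAMES",
           "load_scores", "consensus", "select_candidates"]


@dataclass
class ScoreTable:
    """Best-pose score values per candidate, plus completeness flags.

    ``best`` is a wide DataFrame indexed by candidate_id with one column per
    score name; ``incomplete`` lists candidates missing at least one score.
    """

    best: pd.DataFrame
    incomplete: list[str] = field(default_factory=list)

    @property
    def complete(self) -> pd.DataFrame:
        return self.best.drop(index=self.incomplete)


def load_scores(path_or_frame: str | Path | pd.DataFrame,
                directions: dict[str, bool] = SCORE_DIRECTIONS) -> ScoreTable:
    """Load and validate a long-form docking score table.

    Expects columns candidate_id, pose_id, score_name, value.  Per candidate
    and score the direction-best pose value is retained.  Unknown score
    names are an error; candidates missing any score are flagged incomplete.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame)
    required = {"candidate_id", "pose_id", "score_name", "value"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"score table missing columns: {sorted(missing_cols)}")
    unknown = set(df["score_name"]) - set(directions)
    if unknown:
        raise ValueError(f"unknown score names: {sorted(unknown)}")

    def best_pose(group: pd.DataFrame) -> float:
        higher = directions[group.name[1]]
        return group["value"].max() if higher else group["value"].min()

    wide = (
        df.groupby(["candidate_id", "score_name"])
        .apply(best_pose, include_groups=False)
        .unstack("score_name")
        .reindex(columns=list(directions))
    )
    incomplete = sorted(wide.index[wide.isna().any(axis=1)])
    if incomplete:
        logger.warning("candidates with incomplete score coverage: %s", incomplete)
    return ScoreTable(best=wide, incomplete=incomplete)


def consensus(table: ScoreTable, method: str = "raw_sum",
              directions: dict[str, bool] = SCORE_DIRECTIONS) -> pd.DataFrame:
    """Rank complete candidates by consensus; ties broken by candidate id.

    Returns a DataFrame with columns candidate_id, consensus, rank.
    """
    data = table.complete
    if data.empty:
        raise ValueError("no complete candidates for consensus scoring")
    signed = data.copy()
    for name, higher in directions.items():
        if name in signed.columns and not higher:
            signed[name] = -signed[name]
    if method == "raw_sum":
        value = signed.sum(axis=1)
        ascending = False
    elif method == "rank_sum":
        # per-score rank, 1 = direction-best; 'min' keeps ranks integral
        value = signed.rank(ascending=False, method="min").sum(axis=1)
        ascending = True
    else:
        raise ValueError(f"unknown consensus method: {method}")
    out = pd.DataFrame({"candidate_id": value.index, "consensus": value.values})
    out = out.sort_values(["consensus", "candidate_id"],
                          ascending=[ascending, True], kind="mergesort")
    out["rank"] = range(1, len(out) + 1)
    return out.reset_index(drop=True)


def select_candidates(ranking: pd.DataFrame, fits: pd.DataFrame | dict,
                      top_n: int = 9) -> pd.DataFrame:
    """Join consensus ranks with pharmacophore fit values; keep top_n.

    ``fits`` maps candidate_id to fit value (dict, or DataFrame with
    candidate_id/fit columns).  A disjoint join yields an empty report with
    a warning.
    """
    if isinstance(fits, dict):
        fits = pd.DataFrame({"candidate_id": list(fits), "fit": list(fits.values())})
    report = ranking.merge(fits[["candidate_id", "fit"]], on="candidate_id", how="inner")
    if report.empty:
        logger.warning("consensus ranking and fit values share no candidates")
        return report
    report = report.sort_values("rank", kind="mergesort").head(top_n).reset_index(drop=True)
    return report[["candidate_id", "consensus", "rank", "fit"]]
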