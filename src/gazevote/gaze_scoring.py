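"""Gaze-bias indices, gaze "votes", prediction accuracy, and bias tests.

Monkeys look longer at the eventual *loser* of a race, so every vote rule maps
the less-looked-at candidate to the predicted winner:

* ``fixation_count`` — fewer in-box fixations wins,
* ``dwell_time`` — smaller summed in-box dwell wins,
* ``first_fixation`` — the candidate NOT fixated first wins.

Trials that cannot discriminate (equal counts/dwell, or no in-box fixation) are
ties and earn half credit in accuracy, keeping every race in the denominator and
chance at exactly 0.5.

Rank tests use the exact null distribution for small tie-free samples (n <= 12
per group) and the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError
from .gaze_io import (
    GazeTally,
    RaceRecord,
    SessionRecord,
    StimulusLayout,
    TrialRecord,
    assign_fixations,
)

VOTE_RULES = ("fixation_count", "dwell_time", "first_fixation")

#: Largest per-group sample size for which the exact rank-test null is used.
EXACT_RANK_N = 12


@dataclass(frozen=True)
class PredictionRecord:
    """One gaze 'vote': the predicted winner of one race, or a tie (None)."""

    session_id: str
    race_id: str
    rule: str
    predicted_winner_id: str | None


@dataclass(frozen=True)
class AccuracySummary:
    """Across-session accuracy with a one-sample t test against chance (0.5)."""

    per_session_accuracy: tuple[float, ...]
    mean: float
    sem: float
    t_statistic: float | None
    p_two_sided: float | None
    n_sessions: int


# ---------------------------------------------------------------------------
# Bias index and vote rules
# ---------------------------------------------------------------------------

def gaze_bias_index(
    tally: GazeTally, target_side: str = "left", rule: str = "fixation_count"
) -> float | None:
    """Signed looking bias toward ``target_side``: (target - other)/(target + other).

    Computed on fixation counts (``rule='fixation_count'``) or summed dwell times
    (``rule='dwell_time'``). Returns None (undefined) when both sides are zero.
    """
    if target_side not in ("left", "right"):
        raise ValueError(f"target_side must be 'left' or 'right', got {target_side!r}")
    if rule == "fixation_count":
        a, b = tally.left.n_fixations, tally.right.n_fixations
    elif rule == "dwell_time":
        a, b = tally.left.dwell_ms, tally.right.dwell_ms
    else:
        raise ValueError(f"gaze_bias_index is defined for count/dwell rules, got {rule!r}")
    if target_side == "right":
        a, b = b, a
    total = a + b
    if total == 0:
        return None
    return (a - b) / total


def cast_vote(tally: GazeTally, rule: str, trial: TrialRecord) -> PredictionRecord:
    """Map one trial's gaze tally to a predicted election winner.

    The predicted winner is the candidate the monkey looked at *less* (or did not
    fixate first). Equal counts/dwell — or no in-box fixation at all — yield a
    tie (``predicted_winner_id=None``).
    """
    if rule not in VOTE_RULES:
        raise ValueError(f"unknown vote rule {rule!r}")
    left_id, right_id = trial.left_candidate_id, trial.right_candidate_id
    winner: str | None
    if rule == "first_fixation":
        if tally.left.first_fixated:
            winner = right_id
        elif tally.right.first_fixated:
            winner = left_id
        else:
            winner = None
    else:
        if rule == "fixation_count":
            a, b = tally.left.n_fixations, tally.right.n_fixations
        else:
            a, b = tally.left.dwell_ms, tally.right.dwell_ms
        if a > b:
            winner = right_id
        elif b > a:
            winner = left_id
        else:
            winner = None
    return PredictionRecord(trial.session_id, trial.race_id, rule, winner)


def session_accuracy(
    predictions: Sequence[PredictionRecord],
    races: Iterable[RaceRecord] | Mapping[str, str],
) -> float:
    """Proportion of correct gaze votes in one session; ties earn half credit."""
    if not predictions:
        raise DataValidationError("session_accuracy requires at least one prediction")
    if isinstance(races, Mapping):
        winner_by_race = dict(races)
    else:
        winner_by_race = {r.race_id: r.winner_id for r in races}
    score = 0.0
    for p in predictions:
        if p.race_id not in winner_by_race:
            raise DataValidationError(f"prediction references unknown race {p.race_id}")
        if p.predicted_winner_id is None:
            score += 0.5
        elif p.predicted_winner_id == winner_by_race[p.race_id]:
            score += 1.0
    return score / len(predictions)


def accuracy_summary(per_session: Sequence[float]) -> AccuracySummary:
    """Mean +/- SEM of per-session accuracies and a two-sided t test vs 0.5.

    With zero variance across sessions the t statistic is undefined and both t
    and p are returned as None rather than fabricated.
    """
    vals = np.asarray(per_session, dtype=float)
    if vals.size < 2:
        raise DataValidationError("accuracy_summary requires at least 2 sessions")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    sem = sd / np.sqrt(vals.size)
    if sd == 0.0:
        t_stat, p = None, None
    else:
        res = stats.ttest_1samp(vals, popmean=0.5)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return AccuracySummary(tuple(vals.tolist()), mean, float(sem), t_stat, p, int(vals.size))


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def paired_gaze_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-race values.

    Zero differences are dropped (standard convention). If every difference is
    zero there is no evidence of a shift and p = 1 is returned with a warning.
    Uses the exact null for n <= 12 tie-free nonzero differences, the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise DataValidationError("paired test requires equal-length samples")
    d = a - b
    nonzero = d[d != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; returning p = 1", stacklevel=2)
        return 1.0
    ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= EXACT_RANK_N and not ties) else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.pvalue)


def unpaired_gaze_test(values_g1: Sequence[float], values_g2: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for two groups."""
    g1 = np.asarray(values_g1, dtype=float)
    g2 = np.asarray(values_g2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise DataValidationError("unpaired test requires two nonempty groups")
    pooled = np.concatenate([g1, g2])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(g1.size, g2.size) <= EXACT_RANK_N and not ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Table-level workhorses
# ---------------------------------------------------------------------------

def trial_tally_table(
    sessions: Iterable[SessionRecord],
    layouts: Mapping[str, StimulusLayout],
) -> pd.DataFrame:
    """One row per trial with per-side gaze tallies.

    Columns: session_id, monkey_id, office, trial_index, race_id,
    left/right_candidate_id, n_left, n_right, dwell_left, dwell_right,
    first_side ('left', 'right' or '').
    """
    rows = []
    for s in sessions:
        layout = layouts[s.session_id]
        for t in s.trials:
            tally = assign_fixations(t, layout)
            first = "left" if tally.left.first_fixated else (
                "right" if tally.right.first_fixated else "")
            rows.append((s.session_id, s.monkey_id, s.office, t.trial_index, t.race_id,
                         t.left_candidate_id, t.right_candidate_id,
                         tally.left.n_fixations, tally.right.n_fixations,
                         tally.left.dwell_ms, tally.right.dwell_ms, first))
    return pd.DataFrame(rows, columns=[
        "session_id", "monkey_id", "office", "trial_index", "race_id",
        "left_candidate_id", "right_candidate_id",
        "n_left", "n_right", "dwell_left", "dwell_right", "first_side",
    ])


def tally_table_from_frame(fix_df: pd.DataFrame, layout_df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized equivalent of :func:`trial_tally_table` on raw data frames.

    ``fix_df`` follows the fixations.csv schema (after the read-time truncation
    policy); ``layout_df`` follows layout.csv. Used for large simulated datasets;
    agrees exactly with the record-level route (tested).
    """
    df = fix_df.merge(layout_df, on="session_id", how="left", validate="many_to_one")
    if df[["left_x_min"]].isna().any().any():
        raise DataValidationError("fixation session without a layout row")
    in_left = ((df["x_px"] >= df["left_x_min"]) & (df["x_px"] < df["left_x_max"]) &
               (df["y_px"] >= df["left_y_min"]) & (df["y_px"] < df["left_y_max"]))
    in_right = ((df["x_px"] >= df["right_x_min"]) & (df["x_px"] < df["right_x_max"]) &
                (df["y_px"] >= df["right_y_min"]) & (df["y_px"] < df["right_y_max"]))
    dur = df["offset_ms"] - df["onset_ms"]
    df = df.assign(_left=in_left, _right=in_right,
                   _dwell_l=dur.where(in_left, 0.0), _dwell_r=dur.where(in_right, 0.0))
    keys = ["session_id", "monkey_id", "office", "trial_index", "race_id",
            "left_candidate_id", "right_candidate_id"]
    df = df.sort_values(["session_id", "trial_index", "onset_ms"], kind="stable")
    in_box = df["_left"] | df["_right"]
    first = (df[in_box]
             .groupby(["session_id", "trial_index"], sort=False)
             .first()["_left"]
             .map({True: "left", False: "right"}))
    agg = df.groupby(keys, sort=False).agg(
        n_left=("_left", "sum"), n_right=("_right", "sum"),
        dwell_left=("_dwell_l", "sum"), dwell_right=("_dwell_r", "sum"),
    ).reset_index()
    idx = pd.MultiIndex.from_arrays([agg["session_id"], agg["trial_index"]])
    agg["first_side"] = first.reindex(idx).fillna("").to_numpy()
    agg[["n_left", "n_right"]] = agg[["n_left", "n_right"]].astype(int)
    return agg


def predictions_from_tallies(tally_df: pd.DataFrame, rule: str) -> pd.DataFrame:
    """Vectorized gaze votes: adds ``predicted_winner_id`` (NaN = tie) to tallies."""
    if rule not in VOTE_RULES:
        raise ValueError(f"unknown vote rule {rule!r}")
    out = tally_df.copy()
    if rule == "first_fixation":
        pick_right = out["first_side"] == "left"
        pick_left = out["first_side"] == "right"
    else:
        a = out["n_left"] if rule == "fixation_count" else out["dwell_left"]
        b = out["n_right"] if rule == "fixation_count" else out["dwell_right"]
        pick_right = a > b
        pick_left = b > a
    out["predicted_winner_id"] = np.select(
        [pick_right.to_numpy(), pick_left.to_numpy()],
        [out["right_candidate_id"], out["left_candidate_id"]],
        default=None,
    )
    out["rule"] = rule
    return out


def accuracy_by_session(
    tally_df: pd.DataFrame,
    winner_by_race: Mapping[str, str],
    rule: str,
    session_key: str = "session_id",
) -> pd.Series:
    """Per-session accuracy (ties = half credit) from a tally table.

    ``session_key`` may be any column of the tally table; pass a derived
    monkey-day column to aggregate the two office blocks of one day together.
    """
    preds = predictions_from_tallies(tally_df, rule)
    true_winner = preds["race_id"].map(winner_by_race)
    if true_winner.isna().any():
        raise DataValidationError("tally table references a race without a recorded winner")
    score = np.where(preds["predicted_winner_id"].isna(), 0.5,
                     np.where(preds["predicted_winner_id"] == true_winner, 1.0, 0.0))
    return pd.Series(score).groupby(preds[session_key].to_numpy()).mean()


def monkey_day(session_id: str) -> str:
    """Monkey-day key for a session id of the form ``M1.d2.gub``.

    One monkey-day comprises one office-session per office; grouping accuracy by
    monkey-day pools the office blocks shown on the same day.
    """
    return session_id.rsplit(".", 1)[0]


def candidate_fixation_profile(
    sessions: Iterable[SessionRecord] | None = None,
    layouts: Mapping[str, StimulusLayout] | None = None,
    tally_df: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean in-box fixations per presentation, per candidate.

    Either pass ``sessions`` + ``layouts`` or a precomputed ``tally_df``. For each
    candidate the mean is taken over all trials in which that candidate appeared
    (the denominator is that candidate's presentation count). Also reports the
    mean per-trial looking bias toward the candidate, (own - other)/(own + other),
    over trials with at least one in-box fixation.
    """
    if tally_df is None:
        if sessions is None or layouts is None:
            raise ValueError("pass either tally_df or sessions and layouts")
        tally_df = trial_tally_table(sessions, layouts)
    left = tally_df[["left_candidate_id", "n_left", "n_right", "dwell_left"]].rename(
        columns={"left_candidate_id": "candidate_id", "n_left": "n_own",
                 "n_right": "n_other", "dwell_left": "dwell_own"})
    right = tally_df[["right_candidate_id", "n_right", "n_left", "dwell_right"]].rename(
        columns={"right_candidate_id": "candidate_id", "n_right": "n_own",
                 "n_left": "n_other", "dwell_right": "dwell_own"})
    long = pd.concat([left, right], ignore_index=True)
    total = long["n_own"] + long["n_other"]
    with np.errstate(invalid="ignore"):
        long["bias"] = np.where(total > 0, (long["n_own"] - long["n_other"]) / total, np.nan)
    prof = long.groupby("candidate_id", sort=False).agg(
        mean_fixations=("n_own", "mean"),
        mean_dwell_ms=("dwell_own", "mean"),
        mean_bias=("bias", "mean"),
        n_presentations=("n_own", "size"),
    ).reset_index()
    return prof
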