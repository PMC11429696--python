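"""Reading, validation, and structuring of gaze, election, landmark and layout tables.

The interchange format is plain CSV (UTF-8, one header row). Four tables make up a
dataset:

* ``fixations.csv`` — one row per fixation event, already parsed into events by the
  eye tracker (raw sample parsing is out of scope). Times are integer milliseconds
  relative to stimulus onset; pixel coordinates are 0-based with the origin at the
  top-left of the screen.
* ``elections.csv`` — one row per candidate, two rows per race, with vote shares,
  demographics and photo codes.
* ``layout.csv`` — one row per session giving the screen size and the two image
  rectangles (regions of interest). Rectangles are half-open on their max edges.
* ``landmarks.csv`` — facial landmark coordinates, handled by
  :mod:`gazevote.morphometrics`.

Fixations that straddle the end of the stimulus presentation are truncated at the
presentation duration; fixations starting after it are dropped. Ties in onset time
within a trial are kept in file order and flagged with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import isfinite
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, IntegrityError, ParseError, SchemaError

OFFICES = ("gubernatorial", "senatorial", "presidential")

FIXATION_COLUMNS = [
    "session_id", "monkey_id", "office", "trial_index", "race_id",
    "left_candidate_id", "right_candidate_id", "onset_ms", "offset_ms",
    "x_px", "y_px",
]

ELECTION_COLUMNS = [
    "race_id", "office", "year", "state", "candidate_id", "name", "gender",
    "birth_year", "party", "incumbent", "vote_share_pct", "winner",
    "ref_presidential_margin_pct", "smile", "bald", "facial_hair", "glasses",
]

LAYOUT_COLUMNS = [
    "session_id", "screen_w", "screen_h",
    "left_x_min", "left_y_min", "left_x_max", "left_y_max",
    "right_x_min", "right_y_min", "right_x_max", "right_y_max",
]

DEFAULT_STIMULUS_DURATION_MS = 2500


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Axis-aligned pixel rectangle, half-open on the max edges."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise DataValidationError(f"degenerate box: {self}")

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)


@dataclass(frozen=True)
class StimulusLayout:
    """Screen geometry for one session: two non-overlapping image boxes."""

    left_box: Box
    right_box: Box
    screen_w: int
    screen_h: int

    def __post_init__(self) -> None:
        for name, box in (("left", self.left_box), ("right", self.right_box)):
            if box.x_min < 0 or box.y_min < 0 or box.x_max > self.screen_w or box.y_max > self.screen_h:
                raise DataValidationError(f"{name} box extends beyond the screen: {box}")
        if self.left_box.x_max > self.right_box.x_min:
            raise DataValidationError("left and right boxes overlap or are swapped")


@dataclass(frozen=True)
class FixationEvent:
    """One fixation, in milliseconds from stimulus onset."""

    onset_ms: int
    offset_ms: int
    x_px: float
    y_px: float

    def __post_init__(self) -> None:
        if not (isfinite(self.x_px) and isfinite(self.y_px)):
            raise DataValidationError("non-finite fixation coordinates")
        if self.offset_ms <= self.onset_ms:
            raise DataValidationError(
                f"fixation offset ({self.offset_ms}) must exceed onset ({self.onset_ms})"
            )

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass
class TrialRecord:
    """One 2.5 s two-image presentation of a race within a session."""

    session_id: str
    monkey_id: str
    trial_index: int
    race_id: str
    left_candidate_id: str
    right_candidate_id: str
    stimulus_duration_ms: int = DEFAULT_STIMULUS_DURATION_MS
    fixations: list[FixationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.left_candidate_id == self.right_candidate_id:
            raise DataValidationError(
                f"trial {self.session_id}/{self.trial_index}: identical candidates on both sides"
            )


@dataclass
class SessionRecord:
    """All trials of one session; each race appears at most once."""

    session_id: str
    monkey_id: str
    office: str
    trials: list[TrialRecord] = field(default_factory=list)


@dataclass
class SideTally:
    n_fixations: int = 0
    dwell_ms: float = 0.0
    first_fixated: bool = False


@dataclass
class GazeTally:
    """Per-side gaze statistics for one trial."""

    left: SideTally = field(default_factory=SideTally)
    right: SideTally = field(default_factory=SideTally)

    @property
    def total_in_box(self) -> int:
        return self.left.n_fixations + self.right.n_fixations


@dataclass(frozen=True)
class CandidateRecord:
    """One candidate in one race. ``vote_share_pct`` is two-party normalized."""

    candidate_id: str
    race_id: str
    name: str
    gender: str
    birth_year: int
    party: str
    incumbent: bool
    vote_share_pct: float
    raw_vote_share_pct: float
    winner: bool
    smile: int
    bald: int
    facial_hair: int
    glasses: int
    competence: float | None = None


@dataclass(frozen=True)
class RaceRecord:
    race_id: str
    office: str
    year: int
    state: str
    ref_presidential_margin_pct: float
    candidate_ids: tuple[str, str]
    winner_id: str


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    extra = [c for c in df.columns if c not in required]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")
    if extra:
        raise SchemaError(f"{table}: unexpected column(s) {extra}")


def _numeric(df: pd.DataFrame, col: str, table: str) -> pd.Series:
    if df[col].isna().any():
        row = int(df.index[df[col].isna()][0]) + 2  # +2: header + 1-based
        raise ParseError(f"{table}: empty value in column '{col}' at row {row}")
    try:
        # numpy's parser is correctly rounded, so text -> float -> text round-trips
        return df[col].astype(float)
    except ValueError:
        def ok(v: str) -> bool:
            try:
                float(v)
                return True
            except ValueError:
                return False
        bad = ~df[col].map(ok)
        row = int(df.index[bad][0]) + 2
        raise ParseError(
            f"{table}: non-numeric value in column '{col}' at row {row}") from None


def read_fixation_table(
    path: str | Path,
    stimulus_duration_ms: int = DEFAULT_STIMULUS_DURATION_MS,
) -> list[SessionRecord]:
    """Read ``fixations.csv`` into session records.

    Rows are grouped into trials by (session_id, trial_index) and into sessions by
    session_id; fixations are sorted by onset (ties kept in file order, with a
    warning). Fixations whose offset exceeds the stimulus duration are truncated;
    fixations starting at or after the end of the presentation are dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, FIXATION_COLUMNS, path.name)
    for col in ("trial_index", "onset_ms", "offset_ms", "x_px", "y_px"):
        df[col] = _numeric(df, col, path.name)

    bad = df["offset_ms"] <= df["onset_ms"]
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise DataValidationError(
            f"{path.name}: fixation offset <= onset at row {row}"
        )
    if not np.isfinite(df[["x_px", "y_px"]].to_numpy()).all():
        raise DataValidationError(f"{path.name}: non-finite fixation coordinates")

    bad_office = ~df["office"].isin(OFFICES)
    if bad_office.any():
        raise DataValidationError(
            f"{path.name}: unknown office {df.loc[bad_office, 'office'].iloc[0]!r}"
        )

    # Presentation-window policy: truncate at offset, drop events entirely after it.
    df = df[df["onset_ms"] < stimulus_duration_ms].copy()
    df.loc[df["offset_ms"] > stimulus_duration_ms, "offset_ms"] = stimulus_duration_ms

    sessions: list[SessionRecord] = []
    for session_id, sdf in df.groupby("session_id", sort=False):
        monkeys = sdf["monkey_id"].unique()
        offices = sdf["office"].unique()
        if len(monkeys) > 1:
            raise IntegrityError(f"session {session_id}: multiple monkey_ids {list(monkeys)}")
        if len(offices) > 1:
            raise IntegrityError(f"session {session_id}: multiple offices {list(offices)}")
        session = SessionRecord(str(session_id), str(monkeys[0]), str(offices[0]))
        for trial_index, tdf in sdf.groupby("trial_index", sort=True):
            races = tdf["race_id"].unique()
            if len(races) > 1:
                raise IntegrityError(
                    f"session {session_id} trial {trial_index}: multiple race_ids {list(races)}"
                )
            lids = tdf["left_candidate_id"].unique()
            rids = tdf["right_candidate_id"].unique()
            if len(lids) > 1 or len(rids) > 1:
                raise IntegrityError(
                    f"session {session_id} trial {trial_index}: inconsistent candidate ids"
                )
            tdf = tdf.sort_values("onset_ms", kind="stable")
            if tdf["onset_ms"].duplicated().any():
                warnings.warn(
                    f"session {session_id} trial {trial_index}: tied fixation onsets, "
                    "keeping file order",
                    stacklevel=2,
                )
            trial = TrialRecord(
                session_id=str(session_id),
                monkey_id=str(monkeys[0]),
                trial_index=int(trial_index),
                race_id=str(races[0]),
                left_candidate_id=str(lids[0]),
                right_candidate_id=str(rids[0]),
                stimulus_duration_ms=stimulus_duration_ms,
                fixations=[
                    FixationEvent(int(r.onset_ms), int(r.offset_ms), float(r.x_px), float(r.y_px))
                    for r in tdf.itertuples()
                ],
            )
            session.trials.append(trial)
        sessions.append(session)
    return sessions


def read_election_table(
    path: str | Path, two_party_normalize: bool = True
) -> tuple[list[RaceRecord], list[CandidateRecord]]:
    """Read ``elections.csv`` into race and candidate records.

    Each race must reference exactly two candidates with exactly one winner whose
    raw vote share strictly exceeds the loser's. By default vote shares are
    two-party normalized at ingestion so the pair sums to 100; the raw share is
    retained on the record.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, ELECTION_COLUMNS, path.name)
    for col in ("year", "birth_year", "incumbent", "vote_share_pct", "winner",
                "ref_presidential_margin_pct", "smile", "bald", "facial_hair", "glasses"):
        df[col] = _numeric(df, col, path.name)

    if ((df["vote_share_pct"] < 0) | (df["vote_share_pct"] > 100)).any():
        raise DataValidationError(f"{path.name}: vote share outside [0, 100]")
    if (~df["gender"].isin(["F", "M"])).any():
        raise DataValidationError(f"{path.name}: gender must be 'F' or 'M'")
    if (~df["office"].isin(OFFICES)).any():
        raise DataValidationError(f"{path.name}: unknown office value")

    races: list[RaceRecord] = []
    candidates: list[CandidateRecord] = []
    for race_id, rdf in df.groupby("race_id", sort=False):
        if len(rdf) != 2:
            raise IntegrityError(f"race {race_id}: expected 2 candidates, found {len(rdf)}")
        winners = rdf[rdf["winner"] == 1]
        if len(winners) != 1:
            raise IntegrityError(f"race {race_id}: expected exactly one winner, found {len(winners)}")
        shares = rdf["vote_share_pct"].to_numpy(dtype=float)
        win_mask = (rdf["winner"] == 1).to_numpy()
        if shares[win_mask][0] <= shares[~win_mask][0]:
            raise IntegrityError(
                f"race {race_id}: winner's vote share does not exceed the loser's"
            )
        for col in ("office", "year", "state", "ref_presidential_margin_pct"):
            if rdf[col].nunique() != 1:
                raise IntegrityError(f"race {race_id}: inconsistent race-level column '{col}'")
        total = shares.sum()
        norm = shares / total * 100.0 if two_party_normalize and total > 0 else shares
        for (_, row), share_norm, share_raw in zip(rdf.iterrows(), norm, shares):
            candidates.append(CandidateRecord(
                candidate_id=str(row["candidate_id"]),
                race_id=str(race_id),
                name=str(row["name"]),
                gender=str(row["gender"]),
                birth_year=int(row["birth_year"]),
                party=str(row["party"]),
                incumbent=bool(int(row["incumbent"])),
                vote_share_pct=float(share_norm),
                raw_vote_share_pct=float(share_raw),
                winner=bool(int(row["winner"])),
                smile=int(row["smile"]),
                bald=int(row["bald"]),
                facial_hair=int(row["facial_hair"]),
                glasses=int(row["glasses"]),
            ))
        races.append(RaceRecord(
            race_id=str(race_id),
            office=str(rdf["office"].iloc[0]),
            year=int(rdf["year"].iloc[0]),
            state=str(rdf["state"].iloc[0]),
            ref_presidential_margin_pct=float(rdf["ref_presidential_margin_pct"].iloc[0]),
            candidate_ids=(str(rdf["candidate_id"].iloc[0]), str(rdf["candidate_id"].iloc[1])),
            winner_id=str(winners["candidate_id"].iloc[0]),
        ))
    return races, candidates


def read_layout_table(path: str | Path) -> dict[str, StimulusLayout]:
    """Read ``layout.csv`` into a session_id -> layout mapping."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, LAYOUT_COLUMNS, path.name)
    for col in LAYOUT_COLUMNS[1:]:
        df[col] = _numeric(df, col, path.name)
    layouts: dict[str, StimulusLayout] = {}
    for row in df.itertuples():
        layouts[str(row.session_id)] = StimulusLayout(
            left_box=Box(row.left_x_min, row.left_y_min, row.left_x_max, row.left_y_max),
            right_box=Box(row.right_x_min, row.right_y_min, row.right_x_max, row.right_y_max),
            screen_w=int(row.screen_w),
            screen_h=int(row.screen_h),
        )
    return layouts


def read_competence_table(path: str | Path) -> dict[str, float]:
    """Read optional ``competence.csv`` (candidate_id, competence)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, ["candidate_id", "competence"], path.name)
    df["competence"] = _numeric(df, "competence", path.name)
    return {str(r.candidate_id): float(r.competence) for r in df.itertuples()}


def attach_competence(
    candidates: Iterable[CandidateRecord], ratings: Mapping[str, float]
) -> list[CandidateRecord]:
    """Return candidates with competence ratings attached where available."""
    return [replace(c, competence=ratings.get(c.candidate_id)) for c in candidates]


# ---------------------------------------------------------------------------
# Fixation assignment and dataset validation
# ---------------------------------------------------------------------------

def assign_fixations(trial: TrialRecord, layout: StimulusLayout) -> GazeTally:
    """Score a trial's fixations by region-of-interest membership.

    A fixation counts for a side iff its (x, y) lies in that side's half-open box;
    fixations outside both boxes are ignored. ``first_fixated`` marks the side of
    the earliest in-box fixation (onset order; ties by list order).
    """
    tally = GazeTally()
    first_seen = False
    for fx in sorted(trial.fixations, key=lambda f: f.onset_ms):
        if layout.left_box.contains(fx.x_px, fx.y_px):
            side = tally.left
        elif layout.right_box.contains(fx.x_px, fx.y_px):
            side = tally.right
        else:
            continue
        side.n_fixations += 1
        side.dwell_ms += fx.duration_ms
        if not first_seen:
            side.first_fixated = True
            first_seen = True
    return tally


def validate_dataset(
    sessions: Iterable[SessionRecord],
    races: Iterable[RaceRecord],
    candidates: Iterable[CandidateRecord],
) -> list[str]:
    """Cross-check gaze sessions against election metadata.

    Returns a list of human-readable violations; an empty list means the dataset
    is clean. Checks: each race at most once per session; every trial references a
    known race and known candidates; the trial's candidate pair matches the race's.
    """
    race_by_id = {r.race_id: r for r in races}
    known_candidates = {c.candidate_id for c in candidates}
    violations: list[str] = []
    for session in sessions:
        seen: set[str] = set()
        for trial in session.trials:
            tag = f"session {session.session_id} trial {trial.trial_index}"
            if trial.race_id in seen:
                violations.append(f"{tag}: duplicate race {trial.race_id} in session")
            seen.add(trial.race_id)
            pair = {trial.left_candidate_id, trial.right_candidate_id}
            for cid in sorted(pair):
                if cid not in known_candidates:
                    violations.append(f"{tag}: unknown candidate {cid}")
            race = race_by_id.get(trial.race_id)
            if race is None:
                violations.append(f"{tag}: unknown race {trial.race_id}")
                continue
            if pair != set(race.candidate_ids):
                violations.append(
                    f"{tag}: candidate pair {sorted(pair)} does not match race "
                    f"{trial.race_id} ({sorted(race.candidate_ids)})"
                )
    return violations


# ---------------------------------------------------------------------------
# Writers (round-trip counterparts of the readers)
# ---------------------------------------------------------------------------

def write_fixation_table(sessions: Iterable[SessionRecord], path: str | Path) -> None:
    rows = []
    for s in sessions:
        for t in s.trials:
            for f in t.fixations:
                rows.append((s.session_id, s.monkey_id, s.office, t.trial_index,
                             t.race_id, t.left_candidate_id, t.right_candidate_id,
                             f.onset_ms, f.offset_ms, f.x_px, f.y_px))
    pd.DataFrame(rows, columns=FIXATION_COLUMNS).to_csv(path, index=False)


def write_election_table(
    races: Iterable[RaceRecord], candidates: Iterable[CandidateRecord], path: str | Path
) -> None:
    by_race: dict[str, list[CandidateRecord]] = {}
    for c in candidates:
        by_race.setdefault(c.race_id, []).append(c)
    rows = []
    for r in races:
        for c in by_race.get(r.race_id, []):
            rows.append((r.race_id, r.office, r.year, r.state, c.candidate_id, c.name,
                         c.gender, c.birth_year, c.party, int(c.incumbent),
                         c.raw_vote_share_pct, int(c.winner),
                         r.ref_presidential_margin_pct, c.smile, c.bald,
                         c.facial_hair, c.glasses))
    pd.DataFrame(rows, columns=ELECTION_COLUMNS).to_csv(path, index=False)


def write_layout_table(layouts: Mapping[str, StimulusLayout], path: str | Path) -> None:
    rows = []
    for sid, lay in layouts.items():
        lb, rb = lay.left_box, lay.right_box
        rows.append((sid, lay.screen_w, lay.screen_h,
                     lb.x_min, lb.y_min, lb.x_max, lb.y_max,
                     rb.x_min, rb.y_min, rb.x_max, rb.y_max))
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(path, index=False)
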