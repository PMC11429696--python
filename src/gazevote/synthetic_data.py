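"""Synthetic candidate rosters, faces, vote shares, and gaze sessions.

The generator emulates the statistical structure the analysis pipeline assumes,
so every stage is testable without any recorded data:

* a candidate roster with a fixed pair-gender composition per office (the
  default reproduces the study design: 124 gubernatorial + 149 senatorial races,
  201 male-male and 66 mixed-gender pairs, with 74 and 120 incumbents in running),
* faces built from a latent masculinity trait: the four base measurements (jaw
  width, cheekbone width, face height, lower face height, all IPD-normalized)
  load linearly on masculinity with independent Gaussian noise, giving sexual
  dimorphism in every metric; per-rater landmark tables are produced by
  inverting the measurement model (:func:`landmarks_from_metrics`) with rater
  noise on the normalized measurements,
* perceived competence ratings that load on jaw prominence,
* two-party vote shares that are a linear function of within-race differences in
  jaw prominence, competence, incumbency, and age, plus Gaussian noise, clipped
  and renormalized to sum to 100 per race,
* fixation-level gaze sessions: per trial the total in-box fixation count is
  Poisson, each fixation falls on a side with a logistic probability driven by
  loser status, jaw-prominence difference, gender, and age (the default uses the
  *emergent* route: gaze avoids prominent jaws and prominent jaws win, producing
  the loser-directed bias without a direct loser term), fixation durations are
  Gamma, and onsets are sequential with a fixed 30 ms saccade gap inside the
  2.5 s presentation window. Every trial starts with a central fixation (the
  trial-initiation spot), which lies outside both image boxes.

``analytic_pair_accuracy`` is the exact calibration oracle for the
fixation-count vote rule; ``solve_loser_allocation`` and
``calibrate_vote_betas`` invert it / the linear vote model so a configuration
can be pinned to a target accuracy or target correlation structure in closed
form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConfigError
from .facial_morphometrics import LANDMARK_COLUMNS, FaceLandmarks, FaceMetrics
from .gaze_io import ELECTION_COLUMNS, FIXATION_COLUMNS, LAYOUT_COLUMNS

US_STATES = (
    "AL AK AZ AR CA CO CT DE FL GA HI ID IL IN IA KS KY LA ME MD MA MI MN MS MO "
    "MT NE NV NH NJ NM NY NC ND OH OK OR PA RI SC SD TN TX UT VT VA WA WV WI WY"
).split()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class FeatureLoading(BaseModel):
    """Linear loading of one normalized measurement on latent masculinity."""

    intercept: float
    slope: float
    noise_sd: float = Field(ge=0)


class OfficeDesign(BaseModel):
    """Exact pair composition for one office's stimulus set."""

    n_mm: int = Field(ge=0)       # male-male pairs
    n_mixed: int = Field(ge=0)    # female-male pairs
    n_ff: int = Field(ge=0)       # female-female pairs
    n_incumbent_races: int = Field(ge=0)
    year_min: int
    year_max: int

    @property
    def n_races(self) -> int:
        return self.n_mm + self.n_mixed + self.n_ff

    @model_validator(mode="after")
    def _check(self) -> "OfficeDesign":
        if self.n_incumbent_races > self.n_races:
            raise ValueError("more incumbent races than races")
        if self.year_max < self.year_min:
            raise ValueError("year_max < year_min")
        return self


class GazeParams(BaseModel):
    """Stochastic gaze model: Poisson counts, logistic allocation, Gamma dwells."""

    mean_fixations: float = Field(default=8.0, gt=0)
    dwell_shape: float = Field(default=4.0, gt=0)
    dwell_mean_ms: float = Field(default=250.0, gt=0)
    side_bias: float = 0.0
    alloc_direct_loser: float = 0.0   # log-odds toward the losing candidate
    alloc_jaw: float = 6.0            # log-odds per unit opponent-minus-own jaw prominence
    alloc_female: float = 0.4         # log-odds toward a female candidate
    alloc_age: float = 0.1            # log-odds per decade of age advantage
    inter_fixation_gap_ms: float = Field(default=30.0, ge=0)
    initial_latency_ms: float = Field(default=200.0, gt=0)
    position_jitter_sd_px: float = Field(default=25.0, ge=0)


class VoteParams(BaseModel):
    """Linear two-party vote model on within-race feature differences.

    ``share_a = 50 + (beta . diff)/2 + noise`` with the pair renormalized to sum
    to 100. The jaw and competence coefficients default to values calibrated
    (via :func:`calibrate_vote_betas`) so the population correlation structure
    matches the study's: r(jaw, share) = 0.27 and r(competence, share) = 0.337
    (the marginal implied by the study's partial correlations 0.25/0.31 together
    with r(jaw, competence) = 0.14).
    """

    beta_jaw: float = 124.8           # percentage points per unit jaw prominence
    beta_competence: float = 5.25     # percentage points per rating unit
    beta_incumbent: float = 4.0       # pp advantage of an incumbent over a challenger
    beta_age: float = 1.0             # pp per decade of age advantage
    vote_noise_sd: float = Field(default=6.8, ge=0)


def _default_office_designs() -> dict[str, OfficeDesign]:
    # Study composition: 273 pairs total, 201 male-male, 66 mixed-gender.
    return {
        "gubernatorial": OfficeDesign(n_mm=90, n_mixed=32, n_ff=2,
                                      n_incumbent_races=74, year_min=1995, year_max=2006),
        "senatorial": OfficeDesign(n_mm=111, n_mixed=34, n_ff=4,
                                   n_incumbent_races=120, year_min=2000, year_max=2008),
    }


def _default_loadings() -> dict[str, FeatureLoading]:
    # Intercepts are typical adult values in IPD units; slopes give all four
    # measurements positive (widths) or negative (relative height) dimorphism.
    return {
        "jaw_width_norm": FeatureLoading(intercept=1.60, slope=0.060, noise_sd=0.045),
        "cheekbone_width_norm": FeatureLoading(intercept=2.20, slope=0.030, noise_sd=0.045),
        "face_height_norm": FeatureLoading(intercept=1.90, slope=-0.015, noise_sd=0.050),
        "lower_face_height_norm": FeatureLoading(intercept=0.76, slope=0.020, noise_sd=0.030),
    }


class SimConfig(BaseModel):
    """Full generative parameterization. Defaults are the study conditions."""

    seed: int = 0

    # Sessions: one monkey-day comprises one session per office in the roster.
    n_monkeys: int = Field(default=3, ge=1)
    sessions_per_monkey: int = Field(default=2, ge=1)

    # Roster: exact per-office design (default), or random mode via n_races.
    office_designs: dict[str, OfficeDesign] = Field(default_factory=_default_office_designs)
    n_races: int | None = Field(default=None, ge=1)
    office: str = "gubernatorial"
    p_female: float = Field(default=78 / 546, ge=0, le=1)
    p_incumbent_race: float = Field(default=194 / 273, ge=0, le=1)

    # Faces.
    masc_mean_m: float = 0.5
    masc_mean_f: float = -0.5
    masc_sd: float = Field(default=1.0, ge=0)
    loadings: dict[str, FeatureLoading] = Field(default_factory=_default_loadings)
    ipd_mean_px: float = Field(default=60.0, gt=0)
    ipd_sd_px: float = Field(default=5.0, ge=0)
    n_raters: int = Field(default=2, ge=1)
    rater_noise_sd: float = Field(default=0.025, ge=0)

    # Competence (rating-scale units, population SD ~= 1 at the defaults).
    competence_slope_on_jaw: float = 4.5
    competence_noise_sd: float = Field(default=0.99, ge=0)

    # Votes and gaze.
    vote: VoteParams = Field(default_factory=VoteParams)
    gaze: GazeParams = Field(default_factory=GazeParams)

    # Demographics and photo codes.
    age_mean: float = 52.0
    age_sd: float = Field(default=8.0, ge=0)
    age_min: int = 30
    age_max: int = 85
    margin_sd: float = Field(default=12.0, ge=0)
    smile_probs: tuple[float, float, float] = (0.077, 0.35, 0.573)
    p_bald: float = Field(default=0.12, ge=0, le=1)
    p_facial_hair: float = Field(default=0.10, ge=0, le=1)
    p_glasses: float = Field(default=0.15, ge=0, le=1)

    # Screen geometry.
    screen_w: int = 2560
    screen_h: int = 1440
    box_w: int = 600
    box_h: int = 600
    box_center_offset_x: int = 640
    stimulus_duration_ms: int = 2500

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if abs(sum(self.smile_probs) - 1.0) > 1e-9:
            raise ValueError("smile_probs must sum to 1")
        required = set(_default_loadings())
        if set(self.loadings) != required:
            raise ValueError(f"loadings must have exactly the keys {sorted(required)}")
        return self

    def null_config(self) -> "SimConfig":
        """Copy with every generative effect parameter set to zero."""
        return self.model_copy(update={
            "gaze": self.gaze.model_copy(update={
                "side_bias": 0.0, "alloc_direct_loser": 0.0, "alloc_jaw": 0.0,
                "alloc_female": 0.0, "alloc_age": 0.0}),
            "vote": self.vote.model_copy(update={
                "beta_jaw": 0.0, "beta_competence": 0.0,
                "beta_incumbent": 0.0, "beta_age": 0.0}),
            "competence_slope_on_jaw": 0.0,
        })

    @property
    def n_days(self) -> int:
        return self.n_monkeys * self.sessions_per_monkey

    def layout(self):
        from .gaze_io import Box, StimulusLayout

        cy = self.screen_h / 2
        lcx = self.screen_w / 2 - self.box_center_offset_x
        rcx = self.screen_w / 2 + self.box_center_offset_x
        return StimulusLayout(
            left_box=Box(lcx - self.box_w / 2, cy - self.box_h / 2,
                         lcx + self.box_w / 2, cy + self.box_h / 2),
            right_box=Box(rcx - self.box_w / 2, cy - self.box_h / 2,
                          rcx + self.box_w / 2, cy + self.box_h / 2),
            screen_w=self.screen_w, screen_h=self.screen_h,
        )


# ---------------------------------------------------------------------------
# Landmark synthesis (inverse of compute_metrics)
# ---------------------------------------------------------------------------

def landmarks_from_metrics(
    metrics: FaceMetrics | Mapping[str, float],
    ipd_px: float | None = None,
    center: tuple[float, float] = (400.0, 400.0),
) -> FaceLandmarks:
    """Construct a landmark set whose measurements reproduce the given metrics.

    The template fixes the arbitrary degrees of freedom: the face is upright
    (tilt 0) and centered at ``center``; bilateral points share a y coordinate,
    midline points share the center's x, so Euclidean distances reduce to the
    intended widths and heights exactly.
    """
    if isinstance(metrics, FaceMetrics):
        vals = {
            "jaw_width_norm": metrics.jaw_width_norm,
            "cheekbone_width_norm": metrics.cheekbone_width_norm,
            "face_height_norm": metrics.face_height_norm,
            "lower_face_height_norm": metrics.lower_face_height_norm,
        }
        if ipd_px is None:
            ipd_px = metrics.ipd_px
    else:
        vals = dict(metrics)
    if ipd_px is None or ipd_px <= 0:
        raise ConfigError("ipd_px must be positive")
    for k, v in vals.items():
        if v <= 0:
            raise ConfigError(f"non-positive metric {k} = {v}")
    H = vals["face_height_norm"] * ipd_px
    Hl = vals["lower_face_height_norm"] * ipd_px
    if Hl >= H:
        raise ConfigError("lower face height must be smaller than face height")
    Wc = vals["cheekbone_width_norm"] * ipd_px
    Wj = vals["jaw_width_norm"] * ipd_px
    cx, cy = center
    y_top = cy - H / 2
    return FaceLandmarks(
        pupil_left=(cx - ipd_px / 2, y_top + 0.30 * H),
        pupil_right=(cx + ipd_px / 2, y_top + 0.30 * H),
        zygion_left=(cx - Wc / 2, y_top + 0.45 * H),
        zygion_right=(cx + Wc / 2, y_top + 0.45 * H),
        gonion_left=(cx - Wj / 2, y_top + 0.80 * H),
        gonion_right=(cx + Wj / 2, y_top + 0.80 * H),
        face_top=(cx, y_top),
        lower_face_top=(cx, y_top + H - Hl),
        chin_bottom=(cx, y_top + H),
    )


# ---------------------------------------------------------------------------
# Roster simulation
# ---------------------------------------------------------------------------

BASE_FEATURES = ("jaw_width_norm", "cheekbone_width_norm",
                 "face_height_norm", "lower_face_height_norm")


@dataclass
class SimOutput:
    """All generated tables (gaze_io schemas) plus the generating truth."""

    elections: pd.DataFrame
    competence: pd.DataFrame
    landmarks: pd.DataFrame
    fixations: pd.DataFrame
    layouts: pd.DataFrame
    candidates: pd.DataFrame        # full internal truth, one row per candidate
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("elections", self.elections), ("competence", self.competence),
                         ("landmarks", self.landmarks), ("fixations", self.fixations),
                         ("layout", self.layouts)):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        p = out / "truth.json"
        p.write_text(json.dumps(self.truth, indent=2, default=float))
        paths["truth"] = p
        return paths


def _roster_design(config: SimConfig, rng: np.random.Generator):
    """Per-race office, pair genders (slot a, b), incumbency flags."""
    offices, genders_a, genders_b, incumbent_race, years = [], [], [], [], []
    if config.n_races is not None:
        n = config.n_races
        offices = [config.office] * n
        fem_a = rng.random(n) < config.p_female
        fem_b = rng.random(n) < config.p_female
        genders_a = np.where(fem_a, "F", "M")
        genders_b = np.where(fem_b, "F", "M")
        incumbent_race = rng.random(n) < config.p_incumbent_race
        design = config.office_designs.get(config.office)
        y0, y1 = (design.year_min, design.year_max) if design else (2000, 2008)
        years = rng.integers(y0, y1 + 1, size=n)
    else:
        for office, design in config.office_designs.items():
            kinds = (["mm"] * design.n_mm + ["mixed"] * design.n_mixed + ["ff"] * design.n_ff)
            kinds = list(rng.permutation(kinds))
            ga, gb = [], []
            for k in kinds:
                if k == "mm":
                    ga.append("M"); gb.append("M")
                elif k == "ff":
                    ga.append("F"); gb.append("F")
                else:
                    female_first = rng.random() < 0.5
                    ga.append("F" if female_first else "M")
                    gb.append("M" if female_first else "F")
            inc = np.zeros(design.n_races, dtype=bool)
            inc[rng.choice(design.n_races, size=design.n_incumbent_races, replace=False)] = True
            offices.extend([office] * design.n_races)
            genders_a.extend(ga)
            genders_b.extend(gb)
            incumbent_race.extend(inc.tolist())
            years.extend(rng.integers(design.year_min, design.year_max + 1,
                                      size=design.n_races).tolist())
        genders_a = np.asarray(genders_a)
        genders_b = np.asarray(genders_b)
        incumbent_race = np.asarray(incumbent_race)
        years = np.asarray(years)
    return (np.asarray(offices), genders_a, genders_b,
            np.asarray(incumbent_race, dtype=bool), np.asarray(years, dtype=int))


def simulate_election_roster(config: SimConfig, rng: np.random.Generator) -> SimOutput:
    """Generate the metadata portion: roster, faces, competence, vote shares.

    The returned :class:`SimOutput` has empty fixation/layout tables; pass the
    result through :func:`simulate_gaze_sessions` (or use
    :func:`simulate_dataset`) to add gaze.
    """
    offices, g_a, g_b, inc_race, years = _roster_design(config, rng)
    n_races = offices.size
    n_cand = 2 * n_races

    race_ids = np.array([f"{o[:3].upper()}-{i:04d}" for i, o in enumerate(offices)])
    slot = np.tile(["a", "b"], n_races)
    cand_race = np.repeat(race_ids, 2)
    cand_ids = np.char.add(np.char.add(cand_race.astype(str), "-"), slot)
    cand_office = np.repeat(offices, 2)
    cand_year = np.repeat(years, 2)
    gender = np.empty(n_cand, dtype="<U1")
    gender[0::2] = g_a
    gender[1::2] = g_b
    female = gender == "F"

    # Demographics.
    age = np.clip(np.rint(rng.normal(config.age_mean, config.age_sd, n_cand)),
                  config.age_min, config.age_max).astype(int)
    birth_year = cand_year - age
    inc_slot_a = rng.random(n_races) < 0.5
    incumbent = np.zeros(n_cand, dtype=bool)
    incumbent[0::2] = inc_race & inc_slot_a
    incumbent[1::2] = inc_race & ~inc_slot_a
    dem_first = rng.random(n_races) < 0.5
    party = np.empty(n_cand, dtype="<U5")
    party[0::2] = np.where(dem_first, "D", "R")
    party[1::2] = np.where(dem_first, "R", "D")
    state = rng.choice(US_STATES, size=n_races)
    margin = rng.normal(0.0, config.margin_sd, n_races)

    # Photo codes.
    smile = rng.choice([0, 1, 2], size=n_cand, p=list(config.smile_probs))
    bald = ((rng.random(n_cand) < config.p_bald) & ~female).astype(int)
    facial_hair = ((rng.random(n_cand) < config.p_facial_hair) & ~female).astype(int)
    glasses = (rng.random(n_cand) < config.p_glasses).astype(int)

    # Latent masculinity and facial measurements.
    masc_mean = np.where(female, config.masc_mean_f, config.masc_mean_m)
    masc = masc_mean + config.masc_sd * rng.standard_normal(n_cand)
    feats = {}
    for name in BASE_FEATURES:
        load = config.loadings[name]
        feats[name] = load.intercept + load.slope * masc + load.noise_sd * rng.standard_normal(n_cand)
        feats[name] = np.maximum(feats[name], 0.05)
    feats["lower_face_height_norm"] = np.minimum(
        feats["lower_face_height_norm"], 0.95 * feats["face_height_norm"])
    ipd = np.maximum(rng.normal(config.ipd_mean_px, config.ipd_sd_px, n_cand), 20.0)
    jaw_prom = feats["jaw_width_norm"] / feats["cheekbone_width_norm"]
    fwhr = feats["cheekbone_width_norm"] / feats["face_height_norm"]
    lfp = feats["lower_face_height_norm"] / feats["face_height_norm"]

    # Competence loads on jaw prominence (centered at the loading-implied mean).
    jaw_ref = (config.loadings["jaw_width_norm"].intercept
               / config.loadings["cheekbone_width_norm"].intercept)
    competence = (config.competence_slope_on_jaw * (jaw_prom - jaw_ref)
                  + config.competence_noise_sd * rng.standard_normal(n_cand))

    # Two-party vote shares from within-race differences.
    v = config.vote
    d_jaw = jaw_prom[0::2] - jaw_prom[1::2]
    d_comp = competence[0::2] - competence[1::2]
    d_inc = incumbent[0::2].astype(float) - incumbent[1::2].astype(float)
    d_age = (age[0::2] - age[1::2]) / 10.0
    diff = (v.beta_jaw * d_jaw + v.beta_competence * d_comp
            + v.beta_incumbent * d_inc + v.beta_age * d_age)
    share_a = 50.0 + diff / 2.0 + rng.normal(0.0, v.vote_noise_sd, n_races)
    n_clipped = int(((share_a < 0.5) | (share_a > 99.5)).sum())
    share_a = np.clip(share_a, 0.5, 99.5)
    share_a[share_a == 50.0] += 1e-6  # break exact ties
    share = np.empty(n_cand)
    share[0::2] = share_a
    share[1::2] = 100.0 - share_a
    winner = np.empty(n_cand, dtype=bool)
    winner[0::2] = share_a > 50.0
    winner[1::2] = ~winner[0::2]

    candidates = pd.DataFrame({
        "candidate_id": cand_ids, "race_id": cand_race, "office": cand_office,
        "year": cand_year, "state": np.repeat(state, 2),
        "ref_presidential_margin_pct": np.repeat(margin, 2),
        "name": [f"Candidate {c}" for c in cand_ids],
        "gender": gender, "birth_year": birth_year, "age": age, "party": party,
        "incumbent": incumbent.astype(int), "vote_share_pct": share,
        "winner": winner.astype(int), "smile": smile, "bald": bald,
        "facial_hair": facial_hair, "glasses": glasses,
        "masc": masc, "ipd_px": ipd,
        **feats,
        "jaw_prominence": jaw_prom, "fwhr": fwhr, "lfp": lfp,
        "competence": competence,
    })

    elections = candidates[ELECTION_COLUMNS].copy()
    competence_df = candidates[["candidate_id", "competence"]].copy()
    landmarks = _landmark_table(candidates, config, rng)

    truth = {
        "config": config.model_dump(),
        "n_races": int(n_races),
        "n_candidates": int(n_cand),
        "n_clipped_vote_shares": n_clipped,
        "jaw_reference": jaw_ref,
        "latent_masculinity": masc.tolist(),
        "true_jaw_prominence": jaw_prom.tolist(),
        "true_competence": competence.tolist(),
    }
    empty_fix = pd.DataFrame(columns=FIXATION_COLUMNS)
    empty_lay = pd.DataFrame(columns=LAYOUT_COLUMNS)
    return SimOutput(elections, competence_df, landmarks, empty_fix, empty_lay,
                     candidates, truth)


def _landmark_table(candidates: pd.DataFrame, config: SimConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Per-rater landmark rows: rater noise on normalized measurements."""
    rows = []
    base = candidates[list(BASE_FEATURES)].to_numpy()
    ipd = candidates["ipd_px"].to_numpy()
    ids = candidates["candidate_id"].to_numpy()
    for r in range(config.n_raters):
        noise = config.rater_noise_sd * rng.standard_normal(base.shape)
        noisy = np.maximum(base + noise, 0.05)
        noisy[:, 3] = np.minimum(noisy[:, 3], 0.95 * noisy[:, 2])
        for i in range(base.shape[0]):
            lm = landmarks_from_metrics(dict(zip(BASE_FEATURES, noisy[i])), ipd_px=ipd[i])
            row = [ids[i], f"rater{r + 1}"]
            for pname in ("pupil_left", "pupil_right", "zygion_left", "zygion_right",
                          "gonion_left", "gonion_right", "face_top", "lower_face_top",
                          "chin_bottom"):
                pt = getattr(lm, pname)
                row.extend([pt[0], pt[1]])
            rows.append(row)
    return pd.DataFrame(rows, columns=LANDMARK_COLUMNS)


# ---------------------------------------------------------------------------
# Gaze simulation
# ---------------------------------------------------------------------------

def _race_table(candidates: pd.DataFrame) -> pd.DataFrame:
    """One row per race with slot-a/slot-b attribute columns."""
    a = candidates.iloc[0::2].reset_index(drop=True)
    b = candidates.iloc[1::2].reset_index(drop=True)
    return pd.DataFrame({
        "race_id": a["race_id"].to_numpy(), "office": a["office"].to_numpy(),
        "id_a": a["candidate_id"].to_numpy(), "id_b": b["candidate_id"].to_numpy(),
        "jaw_a": a["jaw_prominence"].to_numpy(), "jaw_b": b["jaw_prominence"].to_numpy(),
        "fem_a": (a["gender"] == "F").to_numpy(), "fem_b": (b["gender"] == "F").to_numpy(),
        "age_a": a["age"].to_numpy(), "age_b": b["age"].to_numpy(),
        "winner_a": a["winner"].astype(bool).to_numpy(),
    })


def simulate_gaze_sessions(
    roster: SimOutput, config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate fixation and layout tables for every monkey-day session.

    Each monkey-day comprises one session per office in the roster; within a
    session each race is shown exactly once, in shuffled order with random side
    assignment. Returns ``(fixations, layouts)`` in the gaze_io schemas.
    """
    races = _race_table(roster.candidates)
    layout = config.layout()
    g = config.gaze

    # Per-trial metadata, session by session (vectorized within session).
    sess_ids, sess_rows = [], []
    trial_meta = []  # (session_idx arrays)
    race_idx_all, left_is_a_all, trial_index_all, session_idx_all = [], [], [], []
    monkey_of_session, id_of_session = [], []
    s_counter = 0
    for m in range(config.n_monkeys):
        for d in range(config.sessions_per_monkey):
            for office, odf in races.groupby("office", sort=False):
                sid = f"M{m + 1}.d{d + 1}.{office[:3]}"
                idx = odf.index.to_numpy()
                order = rng.permutation(idx.size)
                race_idx_all.append(idx[order])
                left_is_a_all.append(rng.random(idx.size) < 0.5)
                trial_index_all.append(np.arange(idx.size))
                session_idx_all.append(np.full(idx.size, s_counter))
                monkey_of_session.append(f"M{m + 1}")
                id_of_session.append(sid)
                s_counter += 1
    race_idx = np.concatenate(race_idx_all)
    left_is_a = np.concatenate(left_is_a_all)
    trial_index = np.concatenate(trial_index_all)
    session_idx = np.concatenate(session_idx_all)
    n_trials = race_idx.size

    jaw_a = races["jaw_a"].to_numpy()[race_idx]
    jaw_b = races["jaw_b"].to_numpy()[race_idx]
    fem_a = races["fem_a"].to_numpy()[race_idx]
    fem_b = races["fem_b"].to_numpy()[race_idx]
    age_a = races["age_a"].to_numpy()[race_idx]
    age_b = races["age_b"].to_numpy()[race_idx]
    win_a = races["winner_a"].to_numpy()[race_idx]

    jaw_l = np.where(left_is_a, jaw_a, jaw_b)
    jaw_r = np.where(left_is_a, jaw_b, jaw_a)
    fem_l = np.where(left_is_a, fem_a, fem_b)
    fem_r = np.where(left_is_a, fem_b, fem_a)
    age_l = np.where(left_is_a, age_a, age_b)
    age_r = np.where(left_is_a, age_b, age_a)
    loser_sign_left = np.where(left_is_a == win_a, -1.0, 1.0)

    logit = (g.side_bias + g.alloc_direct_loser * loser_sign_left
             + g.alloc_jaw * (jaw_r - jaw_l)
             + g.alloc_female * (fem_l.astype(float) - fem_r.astype(float))
             + g.alloc_age * (age_l - age_r) / 10.0)
    p_left = expit(logit)

    # Event-level generation.
    n_fix = rng.poisson(g.mean_fixations, n_trials)
    n_events = int(n_fix.sum())
    tr = np.repeat(np.arange(n_trials), n_fix)
    is_left = rng.random(n_events) < p_left[tr]
    dur = rng.gamma(g.dwell_shape, g.dwell_mean_ms / g.dwell_shape, n_events)
    cum = np.concatenate([[0.0], np.cumsum(dur + g.inter_fixation_gap_ms)])
    first_event = np.concatenate([[0], np.cumsum(n_fix)])[:-1]
    onset = g.initial_latency_ms + (cum[np.arange(n_events)] - cum[first_event[tr]])
    offset = onset + dur
    keep = onset < config.stimulus_duration_ms - 1
    tr, is_left, onset, offset = tr[keep], is_left[keep], onset[keep], offset[keep]
    onset_ms = np.floor(onset).astype(int)
    offset_ms = np.minimum(np.ceil(offset), config.stimulus_duration_ms).astype(int)
    offset_ms = np.maximum(offset_ms, onset_ms + 1)

    lcx, lcy = layout.left_box.center
    rcx, rcy = layout.right_box.center
    jit = rng.normal(0.0, g.position_jitter_sd_px, (tr.size, 2))
    half_w, half_h = config.box_w / 2 - 2, config.box_h / 2 - 2
    jit[:, 0] = np.clip(jit[:, 0], -half_w, half_w)
    jit[:, 1] = np.clip(jit[:, 1], -half_h, half_h)
    x = np.where(is_left, lcx, rcx) + jit[:, 0]
    y = np.where(is_left, lcy, rcy) + jit[:, 1]

    # Central trial-initiation fixation (outside both boxes) for every trial.
    gap_half = config.box_center_offset_x - config.box_w / 2 - 5
    cjit = np.clip(rng.normal(0.0, 10.0, (n_trials, 2)), -min(30, gap_half), min(30, gap_half))
    cx = config.screen_w / 2 + cjit[:, 0]
    cy0 = config.screen_h / 2 + cjit[:, 1]

    ev_session = session_idx[tr]
    id_arr = np.asarray(id_of_session)
    monkey_arr = np.asarray(monkey_of_session)
    race_id_by_trial = races["race_id"].to_numpy()[race_idx]
    left_id_by_trial = np.where(left_is_a, races["id_a"].to_numpy()[race_idx],
                                races["id_b"].to_numpy()[race_idx])
    right_id_by_trial = np.where(left_is_a, races["id_b"].to_numpy()[race_idx],
                                 races["id_a"].to_numpy()[race_idx])
    office_by_trial = races["office"].to_numpy()[race_idx]

    def _frame(trials, onset_v, offset_v, x_v, y_v):
        return pd.DataFrame({
            "session_id": id_arr[session_idx[trials]],
            "monkey_id": monkey_arr[session_idx[trials]],
            "office": office_by_trial[trials],
            "trial_index": trial_index[trials],
            "race_id": race_id_by_trial[trials],
            "left_candidate_id": left_id_by_trial[trials],
            "right_candidate_id": right_id_by_trial[trials],
            "onset_ms": onset_v, "offset_ms": offset_v,
            "x_px": x_v, "y_px": y_v,
        })

    central = _frame(np.arange(n_trials),
                     np.zeros(n_trials, dtype=int),
                     np.full(n_trials, int(g.initial_latency_ms) - int(g.inter_fixation_gap_ms)),
                     cx, cy0)
    events = _frame(tr, onset_ms, offset_ms, x, y)
    fix = pd.concat([central, events], ignore_index=True)
    fix = fix.sort_values(["session_id", "trial_index", "onset_ms"],
                          kind="stable").reset_index(drop=True)
    fix = fix[FIXATION_COLUMNS]

    lb, rb = layout.left_box, layout.right_box
    layouts = pd.DataFrame({
        "session_id": id_arr,
        "screen_w": layout.screen_w, "screen_h": layout.screen_h,
        "left_x_min": lb.x_min, "left_y_min": lb.y_min,
        "left_x_max": lb.x_max, "left_y_max": lb.y_max,
        "right_x_min": rb.x_min, "right_y_min": rb.y_min,
        "right_x_max": rb.x_max, "right_y_max": rb.y_max,
    })[LAYOUT_COLUMNS]
    return fix, layouts


def simulate_dataset(config: SimConfig) -> SimOutput:
    """Full deterministic simulation: roster + gaze, all from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    out = simulate_election_roster(config, rng)
    fix, layouts = simulate_gaze_sessions(out, config, rng)
    out.fixations = fix
    out.layouts = layouts
    out.truth["n_sessions"] = int(layouts.shape[0])
    out.truth["n_monkey_days"] = int(config.n_days)
    return out


# ---------------------------------------------------------------------------
# Analytic calibration oracle
# ---------------------------------------------------------------------------

def analytic_pair_accuracy(mean_fixations: float, p_loser: float,
                           tail: float = 1e-12) -> float:
    """Exact expected accuracy of the fixation-count rule for one race.

    The in-box fixation count is Poisson(``mean_fixations``); each fixation hits
    the losing candidate with probability ``p_loser``. The vote is correct when
    the loser receives strictly more fixations than the winner; equal counts
    (including zero fixations) score half. The Poisson sum is truncated once its
    remaining mass falls below ``tail`` (the remainder contributes its
    large-count limit).
    """
    lam = float(mean_fixations)
    p = float(p_loser)
    n_max = int(stats.poisson.ppf(1.0 - tail, lam)) + 1
    ns = np.arange(n_max + 1)
    pois = stats.poisson.pmf(ns, lam)
    acc = np.empty(ns.size)
    for i, n in enumerate(ns):
        k = np.arange(n + 1)
        pmf = stats.binom.pmf(k, n, p)
        acc[i] = pmf[2 * k > n].sum() + 0.5 * pmf[2 * k == n].sum()
    remainder = max(0.0, 1.0 - pois.sum())
    limit = 0.5 if p == 0.5 else (1.0 if p > 0.5 else 0.0)
    return float((pois * acc).sum() + remainder * limit)


def pair_p_loser(config: SimConfig, jaw_loser: float, jaw_winner: float,
                 female_loser: bool = False, female_winner: bool = False,
                 age_loser: float = 52.0, age_winner: float = 52.0) -> float:
    """Per-fixation probability of hitting the loser, from the allocation model."""
    g = config.gaze
    logit = (g.alloc_direct_loser
             + g.alloc_jaw * (jaw_winner - jaw_loser)
             + g.alloc_female * (float(female_loser) - float(female_winner))
             + g.alloc_age * (age_loser - age_winner) / 10.0)
    return float(expit(logit))


def expected_pair_accuracy(config: SimConfig, **pair_attrs) -> float:
    """Exact fixation-count-rule accuracy for a race with the given attributes."""
    p = pair_p_loser(config, **pair_attrs) if pair_attrs else float(
        expit(config.gaze.alloc_direct_loser))
    return analytic_pair_accuracy(config.gaze.mean_fixations, p)


def solve_loser_allocation(target_accuracy: float, mean_fixations: float = 8.0) -> float:
    """Direct-loser allocation coefficient whose expected accuracy hits the target."""
    if not 0.5 <= target_accuracy < 1.0:
        raise ConfigError("target accuracy must lie in [0.5, 1)")
    if target_accuracy == 0.5:
        return 0.0

    def f(a: float) -> float:
        return analytic_pair_accuracy(mean_fixations, float(expit(a))) - target_accuracy

    return float(brentq(f, 0.0, 20.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# Vote-model calibration
# ---------------------------------------------------------------------------

def calibrate_vote_betas(
    config: SimConfig,
    target_r_jaw: float = 0.27,
    target_r_comp: float = 0.337,
    probe_n_races: int = 20000,
    probe_seed: int = 202_401,
) -> SimConfig:
    """Solve beta_jaw and beta_competence for a target correlation structure.

    Population moments of jaw prominence and competence (their SDs and mutual
    correlation, plus the variance contributed by the incumbency and age terms)
    are estimated from a large probe roster; the two candidate-level correlations
    r(jaw, share) and r(competence, share) then determine the coefficients in
    closed form under the linear vote model.
    """
    probe_cfg = config.model_copy(update={
        "n_races": probe_n_races,
        "seed": probe_seed,
        "n_monkeys": 1, "sessions_per_monkey": 1,
    })
    rng = np.random.default_rng(probe_seed)
    roster = simulate_election_roster(probe_cfg, rng)
    cand = roster.candidates
    J = cand["jaw_prominence"].to_numpy()
    C = cand["competence"].to_numpy()
    sigma_j, sigma_c = float(J.std()), float(C.std())
    if sigma_c == 0:
        raise ConfigError("competence has zero variance; cannot calibrate")
    rho = float(np.corrcoef(J, C)[0, 1])
    d_inc = (cand["incumbent"].to_numpy()[0::2] - cand["incumbent"].to_numpy()[1::2]).astype(float)
    d_age = (cand["age"].to_numpy()[0::2] - cand["age"].to_numpy()[1::2]) / 10.0
    v = config.vote
    var_other = float(np.var(v.beta_incumbent * d_inc + v.beta_age * d_age))

    t1, t2 = float(target_r_jaw), float(target_r_comp)
    # u = beta_jaw * sigma_j, w = beta_competence * sigma_c;
    # r_jaw = (u + rho w) / (2 s_V), r_comp = (w + rho u) / (2 s_V),
    # s_V^2 = (u^2 + w^2 + 2 rho u w)/2 + k^2.
    a = (t1 / t2 - rho) / (1.0 - rho * t1 / t2)   # u = a * w
    k2 = v.vote_noise_sd ** 2 + var_other / 4.0
    m = 0.5 * (1.0 + rho * a)
    q = 0.5 * (a * a + 1.0 + 2.0 * rho * a)
    denom = m * m - t2 * t2 * q
    if denom <= 0:
        raise ConfigError("target correlations unattainable at this noise level")
    w = math.sqrt(t2 * t2 * k2 / denom)
    u = a * w
    new_vote = v.model_copy(update={"beta_jaw": u / sigma_j,
                                    "beta_competence": w / sigma_c})
    return config.model_copy(update={"vote": new_vote})
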