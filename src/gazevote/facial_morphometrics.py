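"""Landmark-based facial morphometrics.

Nine named pixel landmarks per face (pupils, zygions = widest cheekbone points,
gonions = widest jaw points, mid-brow ``face_top``, upper-lip ``lower_face_top``,
and ``chin_bottom``) are reduced to unitless masculinity metrics. All pixel
distances are Euclidean (robust to slight head tilt) and normalized against the
inter-pupillary distance (IPD), so the metrics are invariant to translation,
uniform scaling, and mirroring of the photograph:

* jaw prominence = jaw width / cheekbone width (the key masculinity cue),
* FWHR = cheekbone width / face height (face height = face_top to chin_bottom;
  note the classical FWHR uses upper-face height),
* LFP = lower face height / face height.

Faces are measured independently by two or more raters; per-feature metrics are
averaged across raters, and agreement is summarized as the mean pairwise
inter-rater Pearson correlation per feature, averaged over rater pairs and then
over features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError, IntegrityError, SchemaError

POINT_NAMES = (
    "pupil_left", "pupil_right",
    "zygion_left", "zygion_right",
    "gonion_left", "gonion_right",
    "face_top", "lower_face_top", "chin_bottom",
)

LANDMARK_COLUMNS = ["candidate_id", "rater_id"] + [
    f"{p}_{ax}" for p in POINT_NAMES for ax in ("x", "y")
]

#: Continuous per-face features entering averaging, concordance and contrasts.
METRIC_FEATURES = (
    "jaw_width_norm", "cheekbone_width_norm", "face_height_norm",
    "lower_face_height_norm", "jaw_prominence", "fwhr", "lfp",
)

METRICS_TABLE_COLUMNS = ["candidate_id", "ipd_px", *METRIC_FEATURES, "n_raters", "concordance"]

Point = tuple[float, float]


def _dist(a: Point, b: Point) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


@dataclass(frozen=True)
class FaceLandmarks:
    """Nine named pixel landmarks (0-based raster coordinates, y grows downward)."""

    pupil_left: Point
    pupil_right: Point
    zygion_left: Point
    zygion_right: Point
    gonion_left: Point
    gonion_right: Point
    face_top: Point
    lower_face_top: Point
    chin_bottom: Point

    def __post_init__(self) -> None:
        for pair in (("pupil_left", "pupil_right"),
                     ("zygion_left", "zygion_right"),
                     ("gonion_left", "gonion_right")):
            left, right = getattr(self, pair[0]), getattr(self, pair[1])
            if not left[0] < right[0]:
                raise DataValidationError(f"{pair[0]} must lie left of {pair[1]}")
        if _dist(self.pupil_left, self.pupil_right) <= 0:
            raise DataValidationError("pupil distance must be positive")
        if not self.face_top[1] < self.chin_bottom[1]:
            raise DataValidationError("face_top must lie above chin_bottom")
        if not self.face_top[1] < self.lower_face_top[1] < self.chin_bottom[1]:
            raise DataValidationError("lower_face_top must lie between face_top and chin_bottom")


@dataclass(frozen=True)
class FaceMetrics:
    """IPD-normalized widths/heights and the three derived masculinity ratios."""

    ipd_px: float
    jaw_width_norm: float
    cheekbone_width_norm: float
    face_height_norm: float
    lower_face_height_norm: float
    jaw_prominence: float
    fwhr: float
    lfp: float


def compute_metrics(landmarks: FaceLandmarks) -> FaceMetrics:
    """Reduce one landmark set to normalized facial metrics.

    Widths are Euclidean distances between bilateral pairs; heights between
    midline points (face_top to chin_bottom; lower_face_top to chin_bottom).
    """
    ipd = _dist(landmarks.pupil_left, landmarks.pupil_right)
    cheek = _dist(landmarks.zygion_left, landmarks.zygion_right)
    jaw = _dist(landmarks.gonion_left, landmarks.gonion_right)
    face_h = _dist(landmarks.face_top, landmarks.chin_bottom)
    lower_h = _dist(landmarks.lower_face_top, landmarks.chin_bottom)
    if cheek <= 0 or face_h <= 0:
        raise DataValidationError("degenerate landmarks: zero cheekbone width or face height")
    return FaceMetrics(
        ipd_px=ipd,
        jaw_width_norm=jaw / ipd,
        cheekbone_width_norm=cheek / ipd,
        face_height_norm=face_h / ipd,
        lower_face_height_norm=lower_h / ipd,
        jaw_prominence=jaw / cheek,
        fwhr=cheek / face_h,
        lfp=lower_h / face_h,
    )


# ---------------------------------------------------------------------------
# Landmark tables
# ---------------------------------------------------------------------------

def read_landmark_table(path: str | Path) -> pd.DataFrame:
    """Read ``landmarks.csv`` (one row per candidate x rater)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"candidate_id": str, "rater_id": str})
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in LANDMARK_COLUMNS]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    if extra:
        raise SchemaError(f"{path.name}: unexpected column(s) {extra}")
    coord_cols = LANDMARK_COLUMNS[2:]
    if not np.isfinite(df[coord_cols].to_numpy(dtype=float)).all():
        raise DataValidationError(f"{path.name}: non-finite landmark coordinates")
    return df


def landmarks_from_row(row) -> FaceLandmarks:
    """Build a :class:`FaceLandmarks` from one landmark-table row."""
    get = row.__getattr__ if hasattr(row, "__getattr__") else row.__getitem__
    pts = {}
    for name in POINT_NAMES:
        pts[name] = (float(getattr(row, f"{name}_x")), float(getattr(row, f"{name}_y")))
    return FaceLandmarks(**pts)


def metrics_table(landmark_df: pd.DataFrame) -> pd.DataFrame:
    """Per-rater metrics for every row of a landmark table."""
    rows = []
    for row in landmark_df.itertuples():
        m = compute_metrics(landmarks_from_row(row))
        rows.append((row.candidate_id, row.rater_id, m.ipd_px,
                     m.jaw_width_norm, m.cheekbone_width_norm, m.face_height_norm,
                     m.lower_face_height_norm, m.jaw_prominence, m.fwhr, m.lfp))
    return pd.DataFrame(rows, columns=["candidate_id", "rater_id", "ipd_px", *METRIC_FEATURES])


def rater_concordance(per_rater: pd.DataFrame, features: Sequence[str] = METRIC_FEATURES) -> float | None:
    """Mean pairwise inter-rater Pearson correlation, averaged over features.

    For every pair of raters, each feature is correlated across the candidates
    both raters measured (pairs with fewer than 3 common candidates are skipped).
    Returns None when fewer than 2 raters or no rater pair has enough overlap.
    """
    raters = sorted(per_rater["rater_id"].unique())
    if len(raters) < 2:
        return None
    wide = {r: per_rater[per_rater["rater_id"] == r].set_index("candidate_id") for r in raters}
    pair_means = []
    for r1, r2 in combinations(raters, 2):
        common = wide[r1].index.intersection(wide[r2].index)
        if len(common) < 3:
            continue
        rs = []
        for feat in features:
            a = wide[r1].loc[common, feat].to_numpy(dtype=float)
            b = wide[r2].loc[common, feat].to_numpy(dtype=float)
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            rs.append(float(np.corrcoef(a, b)[0, 1]))
        if rs:
            pair_means.append(float(np.mean(rs)))
    if not pair_means:
        return None
    return float(np.mean(pair_means))


def aggregate_raters(per_rater: pd.DataFrame) -> tuple[pd.DataFrame, float | None]:
    """Average per-rater metrics per candidate; summarize inter-rater agreement.

    Parameters
    ----------
    per_rater
        Output of :func:`metrics_table` (candidate_id, rater_id, ipd_px, features).

    Returns
    -------
    (aggregated, concordance)
        ``aggregated`` has one row per candidate with the per-feature arithmetic
        mean across raters, the rater count, and the global concordance repeated
        per row (the agreement statistic is defined across candidates, not per
        candidate). ``concordance`` is None with a single rater.
    """
    if per_rater.empty:
        raise IntegrityError("no rater metrics to aggregate")
    counts = per_rater.groupby("candidate_id")["rater_id"].nunique()
    dup = per_rater.duplicated(subset=["candidate_id", "rater_id"])
    if dup.any():
        raise IntegrityError("duplicate (candidate_id, rater_id) rows in rater metrics")
    conc = rater_concordance(per_rater)
    agg = (per_rater
           .groupby("candidate_id", sort=False)[["ipd_px", *METRIC_FEATURES]]
           .mean()
           .reset_index())
    agg["n_raters"] = agg["candidate_id"].map(counts).astype(int)
    agg["concordance"] = conc if conc is not None else np.nan
    return agg[METRICS_TABLE_COLUMNS], conc


# ---------------------------------------------------------------------------
# Group contrasts
# ---------------------------------------------------------------------------

def _rank_p(a: np.ndarray, b: np.ndarray, paired: bool) -> float:
    # Local import avoids a cycle (scoring imports nothing from here).
    from .gaze_scoring import paired_gaze_test, unpaired_gaze_test

    return paired_gaze_test(a, b) if paired else unpaired_gaze_test(a, b)


def group_contrast(
    metrics: pd.DataFrame,
    grouping: str,
    features: Sequence[str] = METRIC_FEATURES,
) -> pd.DataFrame:
    """Contrast facial metrics by candidate gender or by election outcome.

    Parameters
    ----------
    metrics
        One row per candidate with the feature columns plus ``gender`` (for
        ``grouping='gender'``) or ``winner`` and ``race_id`` (for
        ``grouping='outcome'``).
    grouping
        ``'gender'`` (unpaired; Wilcoxon rank-sum across candidates) or
        ``'outcome'`` (winner vs loser paired within race; Wilcoxon signed-rank).

    Returns
    -------
    DataFrame with one row per feature: group means with SEM, group sizes, the
    two-sided p-value, and — for the outcome contrast — the mean within-race
    percent difference 100 * (winner - loser) / loser.
    """
    if grouping not in ("gender", "outcome"):
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    if grouping == "gender":
        g1 = metrics[metrics["gender"] == "M"]
        g2 = metrics[metrics["gender"] == "F"]
        if len(g1) < 2 or len(g2) < 2:
            raise DataValidationError("need at least 2 candidates per gender group")
        for feat in features:
            a = g1[feat].to_numpy(dtype=float)
            b = g2[feat].to_numpy(dtype=float)
            rows.append({
                "feature": feat, "group_a": "M", "group_b": "F",
                "mean_a": a.mean(), "sem_a": stats.sem(a),
                "mean_b": b.mean(), "sem_b": stats.sem(b),
                "n_a": len(a), "n_b": len(b),
                "p": _rank_p(a, b, paired=False),
                "pct_diff": np.nan,
            })
        return pd.DataFrame(rows)

    winners = metrics[metrics["winner"].astype(bool)].set_index("race_id")
    losers = metrics[~metrics["winner"].astype(bool)].set_index("race_id")
    common = winners.index.intersection(losers.index)
    dropped = set(winners.index.symmetric_difference(losers.index))
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} race(s) missing one candidate's metrics",
            stacklevel=2,
        )
    if len(common) < 2:
        raise DataValidationError("need at least 2 complete races for the outcome contrast")
    for feat in features:
        w = winners.loc[common, feat].to_numpy(dtype=float)
        l = losers.loc[common, feat].to_numpy(dtype=float)
        rows.append({
            "feature": feat, "group_a": "winner", "group_b": "loser",
            "mean_a": w.mean(), "sem_a": stats.sem(w),
            "mean_b": l.mean(), "sem_b": stats.sem(l),
            "n_a": len(w), "n_b": len(l),
            "p": _rank_p(w, l, paired=True),
            "pct_diff": float(np.mean(100.0 * (w - l) / l)),
        })
    return pd.DataFrame(rows)
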