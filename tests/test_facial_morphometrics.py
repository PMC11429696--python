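"""Landmark metrics, rater aggregation/concordance, and group contrasts."""

import numpy as np
import pandas as pd
import pytest
from _oracles import exact_rank_sum_p
from hypothesis import given, settings
from hypothesis import strategies as st

from gazevote.errors import DataValidationError
from gazevote.facial_morphometrics import (
    METRIC_FEATURES,
    FaceLandmarks,
    aggregate_raters,
    compute_metrics,
    group_contrast,
    rater_concordance,
)
from gazevote.synthetic_data import SimConfig, landmarks_from_metrics, simulate_election_roster

# Hand-checked landmark set: ipd 60, cheekbone 120, jaw 90, face height 150,
# lower face height 60 -> jaw prominence 0.75, FWHR 0.8, LFP 0.4.
WORKED = FaceLandmarks(
    pupil_left=(40, 50), pupil_right=(100, 50),
    zygion_left=(10, 80), zygion_right=(130, 80),
    gonion_left=(25, 140), gonion_right=(115, 140),
    face_top=(70, 20), lower_face_top=(70, 110), chin_bottom=(70, 170),
)


def _transform(lm: FaceLandmarks, scale=1.0, dx=0.0, dy=0.0, mirror=False) -> FaceLandmarks:
    def tp(p):
        x, y = p
        if mirror:
            x = 200.0 - x
        return (x * scale + dx, y * scale + dy)
    pts = {name: tp(getattr(lm, name)) for name in (
        "pupil_left", "pupil_right", "zygion_left", "zygion_right",
        "gonion_left", "gonion_right", "face_top", "lower_face_top", "chin_bottom")}
    if mirror:  # mirroring swaps the bilateral labels
        for a, b in (("pupil_left", "pupil_right"), ("zygion_left", "zygion_right"),
                     ("gonion_left", "gonion_right")):
            pts[a], pts[b] = pts[b], pts[a]
    return FaceLandmarks(**pts)


class TestComputeMetrics:
    def test_worked_example(self):
        m = compute_metrics(WORKED)
        assert m.ipd_px == pytest.approx(60.0)
        assert m.jaw_width_norm == pytest.approx(90.0 / 60.0)
        assert m.cheekbone_width_norm == pytest.approx(120.0 / 60.0)
        assert m.face_height_norm == pytest.approx(150.0 / 60.0)
        assert m.lower_face_height_norm == pytest.approx(60.0 / 60.0)
        assert m.jaw_prominence == pytest.approx(0.75)
        assert m.fwhr == pytest.approx(0.8)
        assert m.lfp == pytest.approx(0.4)

    def test_simple_jaw_prominence_ratio(self):
        lm = _transform(WORKED)
        m = compute_metrics(lm)
        assert m.jaw_prominence == pytest.approx(90.0 / 120.0)

    @settings(max_examples=30, derandomize=True)
    @given(scale=st.floats(0.2, 8.0), dx=st.floats(-500, 500), dy=st.floats(-500, 500),
           mirror=st.booleans())
    def test_similarity_invariance(self, scale, dx, dy, mirror):
        """Ratios and normalized measures survive scaling, translation, mirroring."""
        base = compute_metrics(WORKED)
        m = compute_metrics(_transform(WORKED, scale, dx, dy, mirror))
        for feat in METRIC_FEATURES:
            assert getattr(m, feat) == pytest.approx(getattr(base, feat), rel=1e-9)

    def test_swapped_bilateral_points_rejected(self):
        with pytest.raises(DataValidationError):
            FaceLandmarks(pupil_left=(100, 50), pupil_right=(40, 50),
                          zygion_left=(10, 80), zygion_right=(130, 80),
                          gonion_left=(25, 140), gonion_right=(115, 140),
                          face_top=(70, 20), lower_face_top=(70, 110),
                          chin_bottom=(70, 170))

    def test_lower_face_top_outside_face_rejected(self):
        with pytest.raises(DataValidationError):
            FaceLandmarks(pupil_left=(40, 50), pupil_right=(100, 50),
                          zygion_left=(10, 80), zygion_right=(130, 80),
                          gonion_left=(25, 140), gonion_right=(115, 140),
                          face_top=(70, 20), lower_face_top=(70, 5),
                          chin_bottom=(70, 170))


class TestLandmarkSynthesis:
    @settings(max_examples=40, derandomize=True)
    @given(jaw=st.floats(1.2, 2.0), cheek=st.floats(1.8, 2.6),
           face=st.floats(1.5, 2.3), lfp=st.floats(0.2, 0.6),
           ipd=st.floats(40.0, 90.0))
    def test_roundtrip_identity(self, jaw, cheek, face, lfp, ipd):
        vals = {"jaw_width_norm": jaw, "cheekbone_width_norm": cheek,
                "face_height_norm": face, "lower_face_height_norm": lfp * face}
        m = compute_metrics(landmarks_from_metrics(vals, ipd_px=ipd))
        for k, v in vals.items():
            assert getattr(m, k) == pytest.approx(v, rel=1e-9)
        assert m.jaw_prominence == pytest.approx(jaw / cheek, rel=1e-9)
        assert m.fwhr == pytest.approx(cheek / face, rel=1e-9)
        assert m.lfp == pytest.approx(lfp, rel=1e-9)
        assert m.ipd_px == pytest.approx(ipd, rel=1e-9)

    def test_doubling_ipd_doubles_distances(self):
        vals = {"jaw_width_norm": 1.5, "cheekbone_width_norm": 1.875,
                "face_height_norm": 2.5, "lower_face_height_norm": 1.0}
        lm1 = landmarks_from_metrics(vals, ipd_px=60.0)
        lm2 = landmarks_from_metrics(vals, ipd_px=120.0)
        w1 = lm1.zygion_right[0] - lm1.zygion_left[0]
        w2 = lm2.zygion_right[0] - lm2.zygion_left[0]
        assert w2 == pytest.approx(2 * w1)
        assert compute_metrics(lm2).jaw_prominence == pytest.approx(
            compute_metrics(lm1).jaw_prominence, rel=1e-12)

    def test_worked_example_metrics_reconstruct(self):
        m = compute_metrics(WORKED)
        again = compute_metrics(landmarks_from_metrics(m))
        assert again.jaw_prominence == pytest.approx(0.75, rel=1e-12)
        assert again.fwhr == pytest.approx(0.8, rel=1e-12)
        assert again.lfp == pytest.approx(0.4, rel=1e-12)


def _per_rater_frame(values: dict[str, np.ndarray], candidates) -> pd.DataFrame:
    rows = []
    for rater, arr in values.items():
        for cid, jaw in zip(candidates, arr):
            row = {"candidate_id": cid, "rater_id": rater, "ipd_px": 60.0}
            for feat in METRIC_FEATURES:
                row[feat] = jaw if feat == "jaw_prominence" else jaw + hash(feat) % 5
            rows.append(row)
    return pd.DataFrame(rows)


class TestRaterAggregation:
    def test_identical_raters_concordance_one(self):
        cands = [f"c{i}" for i in range(10)]
        vals = np.linspace(0.7, 0.9, 10)
        df = _per_rater_frame({"r1": vals, "r2": vals}, cands)
        agg, conc = aggregate_raters(df)
        assert conc == pytest.approx(1.0)
        assert np.allclose(agg["jaw_prominence"], vals)
        assert (agg["n_raters"] == 2).all()

    def test_single_rater_concordance_null(self):
        df = _per_rater_frame({"r1": np.linspace(0.7, 0.9, 5)}, [f"c{i}" for i in range(5)])
        agg, conc = aggregate_raters(df)
        assert conc is None
        assert agg["concordance"].isna().all()

    def test_two_raters_match_hand_pearson(self):
        rng = np.random.default_rng(5)
        cands = [f"c{i}" for i in range(5)]
        base = rng.normal(0.8, 0.05, 5)
        r2 = base + rng.normal(0, 0.02, 5)
        rows = []
        for rater, arr in (("r1", base), ("r2", r2)):
            for cid, v in zip(cands, arr):
                row = {"candidate_id": cid, "rater_id": rater, "ipd_px": 60.0}
                # distinct per-feature values so each feature exercises Pearson
                for k, feat in enumerate(METRIC_FEATURES):
                    row[feat] = v * (1 + 0.1 * k)
                rows.append(row)
        df = pd.DataFrame(rows)
        _, conc = aggregate_raters(df)
        per_feature = []
        for k in range(len(METRIC_FEATURES)):
            a, b = base * (1 + 0.1 * k), r2 * (1 + 0.1 * k)
            n = 5
            num = np.sum((a - a.mean()) * (b - b.mean()))
            den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
            per_feature.append(num / den)
        assert conc == pytest.approx(float(np.mean(per_feature)), rel=1e-12)

    def test_aggregation_commutes_with_affine_rescale(self):
        rng = np.random.default_rng(8)
        cands = [f"c{i}" for i in range(8)]
        df = _per_rater_frame({"r1": rng.normal(0.8, 0.05, 8),
                               "r2": rng.normal(0.8, 0.05, 8)}, cands)
        agg, conc = aggregate_raters(df)
        df2 = df.copy()
        df2["jaw_prominence"] = 3.0 * df2["jaw_prominence"] + 1.0
        agg2, conc2 = aggregate_raters(df2)
        assert np.allclose(agg2["jaw_prominence"], 3.0 * agg["jaw_prominence"] + 1.0)
        assert conc2 == pytest.approx(conc, rel=1e-12)

    def test_concordance_on_simulated_raters_is_high(self, study_sim):
        from gazevote.facial_morphometrics import metrics_table
        per_rater = metrics_table(study_sim.landmarks)
        conc = rater_concordance(per_rater)
        assert 0.5 < conc < 1.0


class TestGroupContrast:
    def test_two_percent_jaw_difference(self):
        df = pd.DataFrame({
            "race_id": ["R1", "R1", "R2", "R2"],
            "winner": [1, 0, 1, 0],
            "jaw_prominence": [0.816, 0.80, 0.816, 0.80],
        })
        out = group_contrast(df, "outcome", features=("jaw_prominence",))
        assert out.iloc[0]["pct_diff"] == pytest.approx(2.0)

    def test_identical_outcome_distributions_p_one(self):
        df = pd.DataFrame({
            "race_id": [f"R{i}" for i in range(5)] * 2,
            "winner": [1] * 5 + [0] * 5,
            "jaw_prominence": list(np.linspace(0.7, 0.9, 5)) * 2,
        })
        with pytest.warns(UserWarning):
            out = group_contrast(df, "outcome", features=("jaw_prominence",))
        assert out.iloc[0]["p"] == 1.0

    def test_separated_gender_groups_match_enumeration(self):
        male = [0.80, 0.82, 0.84, 0.86]
        female = [0.70, 0.71, 0.72, 0.73]
        df = pd.DataFrame({"gender": ["M"] * 4 + ["F"] * 4,
                           "jaw_prominence": male + female})
        out = group_contrast(df, "gender", features=("jaw_prominence",))
        assert out.iloc[0]["p"] == pytest.approx(exact_rank_sum_p(male, female))

    def test_dimorphism_detected_in_all_masculinity_cues(self):
        """With positive dimorphism, every cue separates the sexes at n >= 50/group."""
        cfg = SimConfig(seed=42, n_races=120, p_female=0.5)
        roster = simulate_election_roster(cfg, np.random.default_rng(42))
        df = roster.candidates
        assert (df["gender"] == "F").sum() >= 50 and (df["gender"] == "M").sum() >= 50
        out = group_contrast(df, "gender",
                             features=("jaw_width_norm", "cheekbone_width_norm",
                                       "jaw_prominence", "fwhr", "lfp"))
        assert (out["p"] < 0.05).all()
        assert (out["mean_a"] > out["mean_b"]).all()  # male means larger
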