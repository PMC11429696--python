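"""Reading, validation, ROI assignment, and round-trip behavior of the data layer."""

import numpy as np
import pandas as pd
import pytest

from gazevote.errors import DataValidationError, IntegrityError, ParseError, SchemaError
from gazevote.gaze_io import (
    Box,
    FixationEvent,
    StimulusLayout,
    TrialRecord,
    assign_fixations,
    read_election_table,
    read_fixation_table,
    read_layout_table,
    validate_dataset,
    write_election_table,
    write_fixation_table,
)

LAYOUT = StimulusLayout(Box(100, 100, 300, 300), Box(500, 100, 700, 300), 800, 400)


def _fix_csv(tmp_path, rows, columns=None):
    cols = columns or ["session_id", "monkey_id", "office", "trial_index", "race_id",
                       "left_candidate_id", "right_candidate_id", "onset_ms",
                       "offset_ms", "x_px", "y_px"]
    path = tmp_path / "fixations.csv"
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


BASE_ROW = ("s1", "M1", "gubernatorial", 0, "R1", "c1", "c2")


class TestReadFixations:
    def test_two_rows_one_trial(self, tmp_path):
        path = _fix_csv(tmp_path, [(*BASE_ROW, 400, 600, 150, 150),
                                   (*BASE_ROW, 100, 300, 650, 250)])
        sessions = read_fixation_table(path)
        assert len(sessions) == 1 and len(sessions[0].trials) == 1
        trial = sessions[0].trials[0]
        # sorted by onset, not file order
        assert [f.onset_ms for f in trial.fixations] == [100, 400]

    def test_missing_column_names_it(self, tmp_path):
        path = _fix_csv(tmp_path, [BASE_ROW + (1, 2, 3)],
                        columns=["session_id", "monkey_id", "office", "trial_index",
                                 "race_id", "left_candidate_id", "right_candidate_id",
                                 "onset_ms", "offset_ms", "x_px"])
        with pytest.raises(SchemaError, match="y_px"):
            read_fixation_table(path)

    def test_non_numeric_cell_cites_row(self, tmp_path):
        path = _fix_csv(tmp_path, [(*BASE_ROW, 100, 300, 150, 150),
                                   (*BASE_ROW, 400, "oops", 150, 150)])
        with pytest.raises(ParseError, match="offset_ms.*row 3"):
            read_fixation_table(path)

    def test_zero_duration_rejected(self, tmp_path):
        path = _fix_csv(tmp_path, [(*BASE_ROW, 100, 100, 150, 150)])
        with pytest.raises(DataValidationError, match="row 2"):
            read_fixation_table(path)

    def test_presentation_window_truncation(self, tmp_path):
        # straddling fixation truncated at 2500; late fixation dropped entirely
        path = _fix_csv(tmp_path, [(*BASE_ROW, 2400, 2600, 150, 150),
                                   (*BASE_ROW, 2550, 2700, 150, 150)])
        sessions = read_fixation_table(path)
        fixes = sessions[0].trials[0].fixations
        assert len(fixes) == 1
        assert fixes[0].offset_ms == 2500

    def test_tied_onsets_warn(self, tmp_path):
        path = _fix_csv(tmp_path, [(*BASE_ROW, 100, 200, 150, 150),
                                   (*BASE_ROW, 100, 250, 650, 250)])
        with pytest.warns(UserWarning, match="tied"):
            read_fixation_table(path)

    def test_roundtrip_through_writer(self, tmp_path, study_sim, study_data_dir):
        sessions = read_fixation_table(study_data_dir / "fixations.csv")
        out = tmp_path / "rt.csv"
        write_fixation_table(sessions, out)
        again = read_fixation_table(out)
        assert again == sessions


class TestReadElections:
    def _elections(self, tmp_path, mutate=None):
        rows = []
        for i, (share, win) in enumerate([(60.0, 1), (40.0, 0), (45.0, 0), (55.0, 1)]):
            race = f"R{i // 2}"
            rows.append((race, "gubernatorial", 2000, "OH", f"c{i}", f"name{i}", "M",
                         1950, "D" if i % 2 == 0 else "R", 0, share, win, 5.0, 1, 0, 0, 0))
        from gazevote.gaze_io import ELECTION_COLUMNS
        df = pd.DataFrame(rows, columns=ELECTION_COLUMNS)
        if mutate is not None:
            df = mutate(df)
        path = tmp_path / "elections.csv"
        df.to_csv(path, index=False)
        return path

    def test_toy_table(self, tmp_path):
        races, cands = read_election_table(self._elections(tmp_path))
        assert len(races) == 2 and len(cands) == 4
        assert races[0].winner_id == "c0"

    def test_two_party_normalization_sums_to_100(self, tmp_path):
        def mutate(df):
            df.loc[0, "vote_share_pct"] = 55.0
            df.loc[1, "vote_share_pct"] = 35.0  # third-party remainder
            return df
        _, cands = read_election_table(self._elections(tmp_path, mutate))
        pair = [c for c in cands if c.race_id == "R0"]
        assert pair[0].vote_share_pct + pair[1].vote_share_pct == pytest.approx(100.0)
        assert pair[0].raw_vote_share_pct == 55.0

    def test_double_winner_rejected(self, tmp_path):
        def mutate(df):
            df.loc[1, "winner"] = 1
            return df
        with pytest.raises(IntegrityError, match="winner"):
            read_election_table(self._elections(tmp_path, mutate))

    def test_out_of_range_share_rejected(self, tmp_path):
        def mutate(df):
            df.loc[0, "vote_share_pct"] = 101.0
            return df
        with pytest.raises(DataValidationError, match="vote share"):
            read_election_table(self._elections(tmp_path, mutate))

    def test_three_candidate_race_rejected(self, tmp_path):
        def mutate(df):
            extra = df.iloc[[1]].copy()
            extra["candidate_id"] = "cX"
            return pd.concat([df, extra.assign(race_id="R0")], ignore_index=True)
        with pytest.raises(IntegrityError, match="2 candidates"):
            read_election_table(self._elections(tmp_path, mutate))

    def test_study_design_candidate_counts(self, study_data_dir):
        races, cands = read_election_table(study_data_dir / "elections.csv")
        by_office = {}
        for r in races:
            by_office[r.office] = by_office.get(r.office, 0) + 2
        assert by_office == {"gubernatorial": 248, "senatorial": 298}


class TestAssignFixations:
    def _trial(self, fixations):
        return TrialRecord("s1", "M1", 0, "R1", "c1", "c2", fixations=fixations)

    def test_center_of_left_box(self):
        t = self._trial([FixationEvent(0, 100, 200, 200)])
        tally = assign_fixations(t, LAYOUT)
        assert (tally.left.n_fixations, tally.right.n_fixations) == (1, 0)
        assert tally.left.first_fixated and not tally.right.first_fixated

    def test_half_open_boundary_counts_for_neither(self):
        t = self._trial([FixationEvent(0, 100, 300, 200)])  # exactly left x_max
        tally = assign_fixations(t, LAYOUT)
        assert tally.total_in_box == 0

    def test_first_fixated_skips_off_screen(self):
        t = self._trial([FixationEvent(0, 50, 10, 10),       # outside both
                         FixationEvent(60, 120, 600, 200),   # right box
                         FixationEvent(130, 200, 200, 200)])  # left box
        tally = assign_fixations(t, LAYOUT)
        assert tally.right.first_fixated and not tally.left.first_fixated
        assert (tally.left.n_fixations, tally.right.n_fixations) == (1, 1)

    def test_conservation_and_order_invariance(self):
        rng = np.random.default_rng(7)
        fixes = [FixationEvent(int(100 * i), int(100 * i) + 50,
                               float(rng.uniform(0, 800)), float(rng.uniform(0, 400)))
                 for i in range(40)]
        t = self._trial(fixes)
        tally = assign_fixations(t, LAYOUT)
        in_box = sum(1 for f in fixes
                     if LAYOUT.left_box.contains(f.x_px, f.y_px)
                     or LAYOUT.right_box.contains(f.x_px, f.y_px))
        assert tally.total_in_box == in_box
        shuffled = self._trial(list(rng.permutation(fixes)))
        t2 = assign_fixations(shuffled, LAYOUT)
        assert (t2.left.n_fixations, t2.right.n_fixations) == (
            tally.left.n_fixations, tally.right.n_fixations)
        assert t2.left.first_fixated == tally.left.first_fixated


class TestValidateDataset:
    def test_clean_synthetic_dataset(self, study_sim, study_data_dir):
        sessions = read_fixation_table(study_data_dir / "fixations.csv")
        races, cands = read_election_table(study_data_dir / "elections.csv")
        assert validate_dataset(sessions, races, cands) == []

    def test_duplicate_race_and_unknown_candidate(self, study_data_dir):
        sessions = read_fixation_table(study_data_dir / "fixations.csv")
        races, cands = read_election_table(study_data_dir / "elections.csv")
        s = sessions[0]
        dup = TrialRecord(s.session_id, s.monkey_id, 999, s.trials[0].race_id,
                          s.trials[0].left_candidate_id, s.trials[0].right_candidate_id)
        bad = TrialRecord(s.session_id, s.monkey_id, 1000, "NOPE", "ghost-a", "ghost-b")
        s.trials.extend([dup, bad])
        report = validate_dataset(sessions, races, cands)
        assert any("duplicate race" in v for v in report)
        assert any("unknown race" in v for v in report)
        assert any("unknown candidate" in v for v in report)


class TestGeometryTypes:
    def test_boxes_must_not_overlap(self):
        with pytest.raises(DataValidationError):
            StimulusLayout(Box(0, 0, 400, 300), Box(300, 0, 700, 300), 800, 400)

    def test_box_within_screen(self):
        with pytest.raises(DataValidationError):
            StimulusLayout(Box(0, 0, 400, 500), Box(500, 0, 700, 300), 800, 400)

    def test_layout_roundtrip(self, study_data_dir):
        layouts = read_layout_table(study_data_dir / "layout.csv")
        assert len(layouts) == 12
        lay = next(iter(layouts.values()))
        assert lay.left_box.x_max <= lay.right_box.x_min
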