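"""Trial-table validation, parceling and ordinal categorization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cogstab.data import (
    CategoryMap,
    DegeneracyError,
    IntegrityError,
    SchemaError,
    build_category_map,
    make_parcels,
    read_trial_table,
    validate_diary,
    validate_trials,
    write_trial_table,
)

from .conftest import make_trial_frame


def _toy_trials(task="quantity_discrimination", outcomes=(1, 0, 1, 1), phase=1):
    return make_trial_frame(
        [
            ("ape1", "bonobo", task, phase, 1, 1, i + 1, o, "2020-08-01")
            for i, o in enumerate(outcomes)
        ]
    )


class TestTrialTable:
    def test_identity_ingestion(self, tmp_path):
        df = _toy_trials()
        path = tmp_path / "trials.csv"
        df.to_csv(path, index=False)
        got = read_trial_table(path)
        assert len(got) == 4
        assert got["outcome"].tolist() == [1, 0, 1, 1]

    def test_schema_mapping_and_missing_column(self, tmp_path):
        df = _toy_trials().rename(columns={"subject_id": "ape"})
        path = tmp_path / "trials.csv"
        df.to_csv(path, index=False)
        got = read_trial_table(path, schema={"subject_id": "ape"})
        assert got["subject_id"].iloc[0] == "ape1"
        with pytest.raises(SchemaError, match="subject_id"):
            read_trial_table(path)

    def test_delay_task_rejected_in_phase_one(self):
        with pytest.raises(IntegrityError, match="phase 2"):
            validate_trials(_toy_trials(task="delay_of_gratification", phase=1))

    def test_trial_index_beyond_task_count_rejected(self):
        df = _toy_trials()
        df.loc[3, "trial_index"] = 13
        with pytest.raises(IntegrityError, match="trial count"):
            validate_trials(df)

    def test_duplicate_design_key_rejected(self):
        df = pd.concat([_toy_trials(), _toy_trials()], ignore_index=True)
        with pytest.raises(IntegrityError, match="duplicate"):
            validate_trials(df)

    def test_round_trip(self, tmp_path, small_cohort):
        trials = small_cohort["trials"]
        path = tmp_path / "out.csv"
        write_trial_table(trials, path)
        back = read_trial_table(path)
        lhs = validate_trials(trials).reset_index(drop=True)
        pd.testing.assert_frame_equal(lhs, back.reset_index(drop=True))


class TestParcels:
    def test_all_correct_split(self):
        trials = make_trial_frame(
            [
                ("a", "bonobo", "quantity_discrimination", 1, 1, 2, i + 1, 1, "2020-08-01")
                for i in range(12)
            ]
        )
        p = make_parcels(trials)
        assert len(p) == 2
        assert p["raw_sum"].tolist() == [6, 6]
        assert p["max_sum"].tolist() == [6, 6]

    def test_alternating_assignment(self):
        # first four outcomes (1,0,1,1), rest 0: half 1 holds odd trial
        # indices (1,3,...) -> sum 2; half 2 holds even -> sum 1
        outcomes = (1, 0, 1, 1) + (0,) * 8
        p = make_parcels(_toy_trials(outcomes=outcomes)).set_index("half")
        assert p.loc[1, "raw_sum"] == 2
        assert p.loc[2, "raw_sum"] == 1

    def test_session_balanced_gaze_following(self):
        trials = make_trial_frame(
            [
                ("a", "bonobo", "gaze_following", 1, 1, 1 if i < 4 else 2, i + 1, 1, "2020-08-01")
                for i in range(8)
            ]
        )
        t = trials.copy()
        p = make_parcels(t, scheme="session_balanced")
        # reconstruct assignment: each half should hold 2 trials per session
        t["half"] = np.where(t.groupby("session")["trial_index"].rank().astype(int) % 2 == 1, 1, 2)
        counts = t.groupby(["half", "session"]).size()
        assert set(counts) == {2}
        assert p["raw_sum"].tolist() == [4, 4]

    def test_incomplete_cell_flagged_missing(self):
        p = make_parcels(_toy_trials())  # 4 of 12 trials present
        assert (~p["complete"]).all()
        assert p["raw_sum"].isna().all()

    def test_parceling_conserves_totals(self, small_cohort):
        trials = small_cohort["trials"]
        p = make_parcels(trials)
        total = (
            p.dropna(subset=["raw_sum"])
            .groupby(["subject_id", "task", "phase", "time_point"])["raw_sum"]
            .sum()
        )
        expected = trials.groupby(["subject_id", "task", "phase", "time_point"])["outcome"].sum()
        aligned = total.astype(int).reindex(expected.index)
        assert (aligned == expected).all()


def _parcels_from_counts(counts: dict):
    rows = []
    i = 0
    for raw, n in counts.items():
        for _ in range(n):
            rows.append({"subject_id": f"s{i}", "task": "quantity_discrimination",
                         "half": 1, "raw_sum": raw})
            i += 1
    return pd.DataFrame(rows)


class TestCategoryMap:
    def test_tail_merge_hand_example(self):
        # frequencies .01/.04/.25/.30/.40 at min_prop .05: the deficient left
        # tail merges through level 2, leaving three categories
        cmap = build_category_map(
            _parcels_from_counts({0: 1, 1: 4, 2: 25, 3: 30, 4: 40}), min_prop=0.05
        )
        assert cmap.mapping == {0: 0, 1: 0, 2: 0, 3: 1, 4: 2}

    def test_uniform_distribution_identity(self):
        cmap = build_category_map(
            _parcels_from_counts({k: 10 for k in range(7)}), min_prop=0.05
        )
        assert cmap.mapping == {k: k for k in range(7)}
        assert cmap.n_categories == 7

    def test_two_levels_already_minimal(self):
        cmap = build_category_map(_parcels_from_counts({5: 50, 6: 50}))
        assert cmap.n_categories == 2
        assert cmap.mapping == {5: 0, 6: 1}

    def test_degenerate_single_level(self):
        with pytest.raises(DegeneracyError):
            build_category_map(_parcels_from_counts({6: 100}))

    def test_serialization_round_trip(self, tmp_path):
        cmap = build_category_map(_parcels_from_counts({0: 1, 1: 4, 2: 95}))
        path = tmp_path / "map.json"
        cmap.to_json(path)
        import json

        back = CategoryMap.from_dict(json.loads(path.read_text()))
        assert back == cmap

    @given(
        st.lists(st.integers(min_value=1, max_value=60), min_size=2, max_size=9)
    )
    def test_map_is_monotone_contiguous_and_idempotent(self, counts):
        parcels = _parcels_from_counts(dict(enumerate(counts)))
        cmap = build_category_map(parcels, min_prop=0.05)
        vals = [cmap.mapping[k] for k in sorted(cmap.mapping)]
        assert vals == sorted(vals)  # monotone
        assert set(vals) == set(range(max(vals) + 1))  # contiguous 0..K
        assert cmap.n_categories >= 2
        # applying the map to already-collapsed data changes nothing further
        collapsed = parcels.copy()
        collapsed["raw_sum"] = cmap.apply(parcels["raw_sum"].to_numpy()).astype(int)
        again = build_category_map(collapsed, min_prop=0.05)
        assert again.mapping == {k: k for k in range(cmap.n_categories)}


class TestDiary:
    def test_valid_diary_passes_and_tags_categories(self, small_cohort):
        out = validate_diary(small_cohort["diary"].drop(columns=["category"]))
        assert out.loc[out["predictor"] == "age", "category"].eq("stable_individual").all()

    def test_varying_stable_predictor_rejected(self, small_cohort):
        diary = small_cohort["diary"].copy()
        mask = (diary["predictor"] == "age") & (diary["time_point"] == 2)
        diary.loc[mask, "value"] = 99.0
        with pytest.raises(IntegrityError, match="stable"):
            validate_diary(diary)

    def test_incomplete_predictor_set_rejected(self, small_cohort):
        diary = small_cohort["diary"]
        drop = diary[(diary["predictor"] == "rank") & (diary["time_point"] == 1)].index[:1]
        with pytest.raises(IntegrityError, match="full predictor set"):
            validate_diary(diary.drop(index=drop))
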