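"""Cohort reading, scoring, imputation and episode extraction."""

import textwrap

import pytest
from hypothesis import given, strategies as st

from stroke_mdp import (
    build_episodes,
    compute_neuro_score,
    default_cohort_spec,
    extract_episodes,
    generate_cohort,
    impute_cohort,
    impute_missing,
    read_cohort,
    read_episodes,
    write_cohort,
    write_episodes,
)
from stroke_mdp.errors import (
    ConfigurationError,
    ImputationError,
    InputError,
    RecordRejected,
    ValidationError,
)

from conftest import greedy_items, make_record


class TestNeuroScore:
    def test_all_zero_items_score_zero(self, score_schema):
        items = {name: 0 for name in score_schema.item_names}
        assert compute_neuro_score(items, death=False, schema=score_schema) == 0

    def test_death_forces_maximum_regardless_of_items(self, score_schema):
        items = {name: 0 for name in score_schema.item_names}
        assert compute_neuro_score(items, death=True, schema=score_schema) == 29
        assert compute_neuro_score({}, death=True, schema=score_schema) == 29

    def test_item_above_maximum_rejected(self, score_schema):
        items = {name: 0 for name in score_schema.item_names}
        items["ataxia"] = 3  # max is 2
        with pytest.raises(ValidationError):
            compute_neuro_score(items, death=False, schema=score_schema)

    def test_missing_item_rejected(self, score_schema):
        items = {name: 0 for name in score_schema.item_names}
        items.pop("sensory")
        with pytest.raises(ValidationError):
            compute_neuro_score(items, death=False, schema=score_schema)

    @given(st.data())
    def test_monotone_in_every_item(self, data):
        from stroke_mdp import default_score_schema

        schema = default_score_schema()
        items = {
            name: data.draw(st.integers(0, cap), label=name)
            for name, cap in schema.item_max.items()
        }
        base = compute_neuro_score(items, death=False, schema=schema)
        name = data.draw(st.sampled_from(sorted(schema.item_names)), label="bump")
        if items[name] < schema.item_max[name]:
            bumped = dict(items, **{name: items[name] + 1})
            assert compute_neuro_score(bumped, death=False, schema=schema) >= base


class TestImputation:
    def test_identity_on_complete_data(self):
        assert impute_missing([1, 2, 3], span=2) == [1, 2, 3]

    def test_median_of_nearby_points(self):
        # median of the four neighbours {1, 2, 4, 5}
        assert impute_missing([1, 2, None, 4, 5], span=2) == [1, 2, 3.0, 4, 5]

    def test_window_limits_neighbours(self):
        # span 1: only {2, 4} are eligible
        assert impute_missing([1, 2, None, 4, 5], span=1) == [1, 2, 3.0, 4, 5]
        assert impute_missing([None, 5], span=1) == [5.0, 5]

    def test_all_missing_is_an_error(self):
        with pytest.raises(ImputationError):
            impute_missing([None, None, None], span=2)

    @given(
        st.lists(
            st.one_of(st.none(), st.integers(0, 29)), min_size=2, max_size=12
        ).filter(lambda v: any(x is not None for x in v))
    )
    def test_never_alters_observed_values_and_idempotent(self, values):
        try:
            filled = impute_missing(values, span=2)
        except ImputationError:
            return
        for old, new in zip(values, filled):
            if old is not None:
                assert new == old
        assert impute_missing(filled, span=2) == filled

    def test_cohort_imputation_rounds_to_integers(self, score_schema):
        records = [
            make_record(f"R{k}", (k, k, k), score_schema, admission_date=f"2005-05-{k+1:02d}")
            for k in range(4)
        ]
        records[1].item_scores[1]["ataxia"] = None
        records[1].characteristics["i2"] = None
        imputed, counts = impute_cohort(records, score_schema, span=2)
        assert counts == {"i2": 1, "ataxia_t1": 1}
        assert isinstance(records[1].item_scores[1]["ataxia"], int)
        assert records[1].characteristics["i2"] == 0


class TestEpisodes:
    def test_rewards_are_score_differences(self, score_schema):
        record = make_record("R1", (10, 6, 5), score_schema)
        e1, e2 = extract_episodes(record, score_schema)
        assert (e1.reward, e2.reward) == (4, 1)
        assert e1.state.endswith("3")  # score 10 -> level 3
        assert e1.next_state == e2.state

    def test_no_change_gives_zero_reward(self, score_schema):
        record = make_record("R1", (3, 3, 3), score_schema)
        e1, e2 = extract_episodes(record, score_schema)
        assert (e1.reward, e2.reward) == (0, 0)

    def test_death_at_discharge_forces_reward(self, score_schema):
        record = make_record("R1", (5, 5, 0), score_schema, death=(False, False, True))
        _e1, e2 = extract_episodes(record, score_schema)
        assert e2.reward == 5 - 29 == -24
        assert e2.next_state.endswith("5")

    def test_death_at_admission_rejected(self, score_schema):
        record = make_record("R1", (0, 0, 0), score_schema, death=(True, True, True))
        with pytest.raises(RecordRejected, match="death_at_admission"):
            extract_episodes(record, score_schema)

    def test_incomplete_actions_rejected(self, score_schema):
        record = make_record(
            "R1", (5, 5, 5), score_schema, actions=((1, 0, 0, 0, 1), (1, None, 0, 0, 1))
        )
        with pytest.raises(RecordRejected, match="incomplete_actions"):
            extract_episodes(record, score_schema)

    def test_rewards_telescope_across_stages(self, score_schema):
        spec = default_cohort_spec(n_patients=150, seed=21)
        records, _ = generate_cohort(spec)
        records, _ = impute_cohort(records, score_schema)
        episodes, exclusions = build_episodes(records, score_schema)
        by_record = {}
        for e in episodes:
            by_record.setdefault(e.record_id, {})[e.stage] = e
        assert by_record, "no episodes extracted"
        for rid, pair in by_record.items():
            record = next(r for r in records if r.record_id == rid)
            s1 = compute_neuro_score(record.item_scores[1], record.death[1], score_schema)
            s3 = compute_neuro_score(record.item_scores[3], record.death[3], score_schema)
            assert pair[1].reward + pair[2].reward == s1 - s3


class TestCohortIO:
    def test_round_trip(self, tmp_path, score_schema):
        spec = default_cohort_spec(n_patients=60, seed=9)
        records, _ = generate_cohort(spec)  # includes missing cells
        path = tmp_path / "cohort.csv"
        write_cohort(records, path, score_schema)
        back = read_cohort(path, score_schema)
        assert back == records

    def test_row_count_preserved(self, tmp_path, score_schema):
        records = [make_record("A", (1, 1, 1), score_schema), make_record("B", (2, 2, 2), score_schema)]
        path = tmp_path / "two.csv"
        write_cohort(records, path, score_schema)
        assert len(read_cohort(path, score_schema)) == 2

    def test_na_cell_becomes_missing(self, tmp_path, score_schema):
        records = [make_record("A", (1, 1, 1), score_schema)]
        path = tmp_path / "c.csv"
        write_cohort(records, path, score_schema)
        text = path.read_text().splitlines()
        header = text[0].split(",")
        idx = header.index("ataxia_t1")
        row = text[1].split(",")
        row[idx] = "NA"
        path.write_text("\n".join([text[0], ",".join(row)]) + "\n")
        back = read_cohort(path, score_schema)
        assert back[0].item_scores[1]["ataxia"] is None

    def test_action_flag_outside_alphabet_names_row_and_column(self, tmp_path, score_schema):
        records = [make_record("A", (1, 1, 1), score_schema)]
        path = tmp_path / "c.csv"
        write_cohort(records, path, score_schema)
        text = path.read_text().splitlines()
        header = text[0].split(",")
        idx = header.index("a3_s2")
        row = text[1].split(",")
        row[idx] = "2"
        path.write_text("\n".join([text[0], ",".join(row)]) + "\n")
        with pytest.raises(InputError, match=r"row 2.*a3_s2"):
            read_cohort(path, score_schema)

    def test_missing_mandatory_column(self, tmp_path, score_schema):
        path = tmp_path / "bad.csv"
        path.write_text("record_id,i1\nA,2\n")
        with pytest.raises(ConfigurationError, match="mandatory"):
            read_cohort(path, score_schema)

    def test_duplicate_record_id(self, tmp_path, score_schema):
        records = [make_record("A", (1, 1, 1), score_schema)]
        path = tmp_path / "c.csv"
        write_cohort(records + records, path, score_schema)
        with pytest.raises(InputError, match="duplicate"):
            read_cohort(path, score_schema)

    def test_episode_table_round_trip(self, tmp_path, score_schema):
        record = make_record("R1", (10, 6, 5), score_schema)
        episodes = list(extract_episodes(record, score_schema))
        path = tmp_path / "episodes.tsv"
        write_episodes(episodes, path)
        assert read_episodes(path) == episodes
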