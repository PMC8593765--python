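"""Reference-population rules, death-report dedup, descriptive statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from censusmrp import (
    SimConfig,
    annualized_mortality_rate,
    build_reference_population,
    deduplicate_death_reports,
    simulate_attrition,
    simulate_mortality,
    generate_population,
    tabulate_death_context,
    to_tables,
)
from censusmrp.census import ProcessingError, normalize_name, split_round
from conftest import (
    death_row,
    member_row,
    reach_rows,
    toy_census,
    toy_round_frame,
)


def test_name_normalization_strips_case_and_punctuation():
    assert normalize_name("Person-00017") == normalize_name("person 00017")
    assert normalize_name("  A. B-C ") == "abc"


class TestReferencePopulation:
    def test_toy_counts(self):
        """10 census-listed + 2 overlooked + 1 death-in-2019 + 3 joiners
        give a reference of 13 with 3 excluded joiners."""
        census = toy_census(10)
        r1 = toy_round_frame(
            reach_rows(range(5))
            + [member_row(0, 100, "Extra-1", 40, "overlooked"),
               member_row(1, 101, "Extra-2", 55, "overlooked"),
               member_row(2, 102, "New-1", 20, "joiner", entry_month=14),
               member_row(3, 103, "New-2", 25, "joiner", entry_month=15),
               death_row(4, "Gone-1", 70, 8)])
        r2 = toy_round_frame(
            reach_rows(range(5))
            + [member_row(4, 104, "New-3", 30, "joiner", entry_month=18)])
        ref = build_reference_population(census, r1, r2)
        assert ref.counts["reference_size"] == 13
        assert ref.counts["joiner"] == 3
        assert ref.counts["decedent_2019"] == 1
        assert ref.counts["overlooked"] == 2
        joiners = ref.persons[ref.persons["provenance"] == "joiner"]
        assert not joiners["in_reference"].any()

    def test_empty_rounds_leave_census_only(self):
        census = toy_census(6)
        empty = toy_round_frame(reach_rows(range(3), reached=False))
        ref = build_reference_population(census, empty, empty)
        assert ref.counts["reference_size"] == 6
        assert len(ref.unique_deaths) == 0

    def test_unknown_household_member_is_quarantined_not_dropped(self):
        census = toy_census(4, households=[0, 0, 1, 1])
        r1 = toy_round_frame(
            reach_rows([0, 1])
            + [member_row(99, 200, "Lost-1", 33, "overlooked")])
        r2 = toy_round_frame(reach_rows([0, 1]))
        ref = build_reference_population(census, r1, r2)
        assert len(ref.quarantine) == 1
        assert ref.quarantine.iloc[0]["reason"] == "unknown_household"
        assert 200 not in set(ref.persons["person_id"])

    def test_row_order_invariance(self, small_tables):
        rng = np.random.default_rng(0)
        shuffled = {
            k: v.sample(frac=1.0, random_state=1).reset_index(drop=True)
            for k, v in small_tables.items() if k != "econ"}
        a = build_reference_population(
            small_tables["census"], small_tables["round1"],
            small_tables["round2"])
        b = build_reference_population(
            shuffled["census"], shuffled["round1"], shuffled["round2"])
        assert a.counts == b.counts
        assert len(a.unique_deaths) == len(b.unique_deaths)
        assert (set(a.persons["person_id"][a.persons["in_reference"]])
                == set(b.persons["person_id"][b.persons["in_reference"]]))

    def test_reference_matches_generator_ground_truth(self):
        """Reference = census-listed + observed overlooked + observable
        2019 decedents, exactly (duplicates disabled)."""
        cfg = SimConfig(n_households=1200, duplicate_report_rate=0.0,
                        seed=13)
        pop = simulate_attrition(
            simulate_mortality(generate_population(cfg), cfg), cfg)
        tables = to_tables(pop)
        ref = build_reference_population(
            tables["census"], tables["round1"], tables["round2"])

        persons = pop.persons
        hh = pop.households.set_index("household_id")
        reached_any = (hh["reached_r1"] | hh["reached_r2"])
        reached_of = persons["household_id"].map(reached_any)
        listed = persons["provenance"] == "census_listed"
        overlooked_seen = (persons["provenance"] == "overlooked") & reached_of
        r1 = persons["household_id"].map(hh["reached_r1"])
        r2 = persons["household_id"].map(hh["reached_r2"])
        dm = persons["death_month"]
        dec19_seen = (persons["provenance"] == "decedent_2019") & (
            (r1 & (dm <= 16)) | r2)
        expected = int(listed.sum() + overlooked_seen.sum()
                       + dec19_seen.sum())
        assert ref.counts["reference_size"] == expected

    def test_unique_death_count_matches_generator_with_duplicates(self):
        cfg = SimConfig(n_households=1200, duplicate_report_rate=0.5,
                        seed=14)
        pop = simulate_attrition(
            simulate_mortality(generate_population(cfg), cfg), cfg)
        tables = to_tables(pop)
        ref = build_reference_population(
            tables["census"], tables["round1"], tables["round2"])
        true_unique = pop.death_reports["name"].map(normalize_name).nunique()
        assert len(pop.death_reports) > true_unique  # duplicates present
        assert len(ref.unique_deaths) == true_unique


class TestDeduplication:
    def test_three_reports_merge_into_one(self):
        reports = split_round(toy_round_frame([
            death_row(1, "Elder One", 81, 7),
            death_row(2, "elder-one", 82, 7),
            death_row(3, "ELDER ONE", 81, 8)]))["death"]
        unique, _ = deduplicate_death_reports(reports)
        assert len(unique) == 1
        assert unique.iloc[0]["reporting_households"] == (1, 2, 3)
        assert unique.iloc[0]["n_reports"] == 3

    def test_age_gate_keeps_distinct_people_apart(self):
        reports = split_round(toy_round_frame([
            death_row(1, "Shared Name", 40, 7),
            death_row(2, "Shared Name", 80, 7)]))["death"]
        unique, _ = deduplicate_death_reports(reports)
        assert len(unique) == 2

    def test_month_gate(self):
        reports = split_round(toy_round_frame([
            death_row(1, "Same Person", 70, 5),
            death_row(2, "Same Person", 70, 8)]))["death"]
        unique, _ = deduplicate_death_reports(reports)
        assert len(unique) == 2

    def test_cause_conflict_keeps_modal_and_logs(self):
        reports = split_round(toy_round_frame([
            death_row(1, "Case A", 60, 9, cause="cancer"),
            death_row(2, "Case A", 60, 9, cause="cancer"),
            death_row(3, "Case A", 61, 9, cause="liver")]))["death"]
        unique, conflicts = deduplicate_death_reports(reports)
        assert len(unique) == 1
        assert unique.iloc[0]["cause"] == "cancer"
        assert len(conflicts) == 1

    @settings(max_examples=40, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(1, 6),            # reporting household
                  st.sampled_from(["Name A", "name-a", "Name B"]),
                  st.integers(58, 64),          # age
                  st.integers(4, 9),            # month
                  st.sampled_from(["cancer", "liver", "other"])),
        min_size=0, max_size=12))
    def test_dedup_is_idempotent(self, raw):
        reports = split_round(toy_round_frame(
            [death_row(h, n, a, m, cause=c) for h, n, a, m, c in raw]
        ))["death"]
        once, _ = deduplicate_death_reports(reports)
        again_in = once.drop(
            columns=["name_norm", "reporting_households", "n_reports"])
        again_in = again_in.assign(
            reporting_household=[hs[0] for hs in
                                 once["reporting_households"]])
        twice, _ = deduplicate_death_reports(again_in)
        assert len(twice) == len(once)
        for col in ("name", "age", "death_month", "cause"):
            assert list(twice[col]) == list(once[col])


class TestRates:
    def test_printed_annualized_rate(self):
        assert round(annualized_mortality_rate(639, 58806, 22), 1) == 5.9

    @pytest.mark.parametrize("deaths,pop,months,expect", [
        (0, 1000, 12, 0.0),
        (12, 1000, 24, 6.0),
    ])
    def test_formula_cases(self, deaths, pop, months, expect):
        assert annualized_mortality_rate(deaths, pop, months) == pytest.approx(expect)

    def test_zero_population_is_an_error(self):
        with pytest.raises(ProcessingError):
            annualized_mortality_rate(1, 0, 12)


class TestDeathContext:
    def _deaths(self, year_months, consulted, lung, total):
        rows = []
        for i in range(total):
            rows.append({
                "name": f"P{i}", "name_norm": f"p{i}", "age": 60,
                "sex": "male", "death_month": year_months[i % len(year_months)],
                "cause": "lung" if i < lung else "other",
                "injury": False, "consulted_doctor": i < consulted,
                "died_in_hospital": False,
                "symptoms": "fever;cough" if i < lung else "",
                "reporting_households": (i,), "n_reports": 1})
        return pd.DataFrame(rows)

    def test_2019_consultation_percent(self):
        d = self._deaths([3, 7], consulted=339, lung=30, total=467)
        out = tabulate_death_context(d, 2019)
        assert out["n_deaths"] == 467
        assert out["consulted_doctor"]["percent_whole"] == 73
        assert out["causes"]["lung"]["percent_1dp"] == 6.4

    def test_2020_lung_percent(self):
        d = self._deaths([15, 20], consulted=240, lung=12, total=328)
        out = tabulate_death_context(d, 2020)
        assert out["causes"]["lung"]["percent_1dp"] == 3.7
        assert out["lung_symptom_mentions"] == 24

    def test_zero_category_preserves_denominator(self):
        d = self._deaths([4], consulted=0, lung=0, total=10)
        out = tabulate_death_context(d, 2019)
        assert out["causes"]["cancer"]["count"] == 0
        assert out["causes"]["cancer"]["denominator"] == 10
        assert out["causes"]["cancer"]["percent_whole"] == 0

    def test_yearly_counts_partition_unique_deaths(self, small_ref):
        d = small_ref.unique_deaths
        y19 = tabulate_death_context(d, 2019)["n_deaths"]
        y20 = tabulate_death_context(d, 2020)["n_deaths"]
        assert y19 + y20 == len(d)
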