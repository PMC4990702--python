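"""Survey assembly: visit definition, filters, aggregation, tensor build."""

import numpy as np
import pandas as pd
import pytest

from beepersist.surveys import (
    aggregate_species,
    assemble_detection_dataset,
    build_surveys,
    filter_cells,
    filter_species,
)


def _records(rows):
    return pd.DataFrame(rows, columns=["species", "date", "cell1km_id"])


@pytest.fixture
def toy_records():
    return _records(
        [
            # one visit with 3 species -> short list
            ("a", "1997-05-01", "S1_0"),
            ("b", "1997-05-01", "S1_0"),
            ("c", "1997-05-01", "S1_0"),
            # single-species visit
            ("a", "1997-06-01", "S1_0"),
            # long list (5 species)
            ("a", "2003-05-02", "S1_1"),
            ("b", "2003-05-02", "S1_1"),
            ("c", "2003-05-02", "S1_1"),
            ("d", "2003-05-02", "S1_1"),
            ("e", "2003-05-02", "S1_1"),
            # second year for cell S1_1
            ("b", "2004-05-02", "S1_1"),
        ]
    )


class TestBuildSurveys:
    def test_visit_is_unique_date_cell_combination(self, toy_records):
        sdata = build_surveys(toy_records)
        assert sdata.n_visits == 4
        v = sdata.visits.set_index(["cell1km_id", "date"])
        assert v.loc[("S1_0", pd.Timestamp("1997-05-01")), "list_length"] == 3

    def test_list_categories(self, toy_records):
        sdata = build_surveys(toy_records)
        v = sdata.visits.sort_values("date").reset_index()
        # 3-species -> short; 1-species -> neither; 5-species -> long
        assert v.loc[0, ["is_short", "is_long"]].tolist() == [1, 0]
        assert v.loc[1, ["is_short", "is_long"]].tolist() == [0, 0]
        assert v.loc[2, ["is_short", "is_long"]].tolist() == [0, 1]
        # partition: never both
        assert not ((v["is_short"] == 1) & (v["is_long"] == 1)).any()

    def test_coarse_records_excluded(self, toy_records):
        bad = _records([("a", "1997", "S1_0"), ("a", "1997-05-01", None)])
        sdata = build_surveys(pd.concat([toy_records, bad], ignore_index=True))
        assert sdata.n_visits == 4

    def test_duplicate_records_collapse(self):
        sdata = build_surveys(
            _records([("a", "1997-05-01", "S1_0")] * 3)
        )
        assert sdata.n_visits == 1
        assert sdata.visits.loc[0, "list_length"] == 1

    def test_cell_lookup_table(self, toy_records):
        lookup = pd.DataFrame(
            {"cell1km_id": ["S1_0", "S1_1"], "cell5km_id": ["P", "P"]}
        )
        sdata = build_surveys(toy_records, cell_lookup=lookup)
        assert set(sdata.visits["cell5km_id"]) == {"P"}
        with pytest.raises(ValueError, match="missing from cell_lookup"):
            build_surveys(toy_records, cell_lookup=lookup.iloc[:1])


class TestFilterCells:
    def test_cell_needs_two_distinct_years(self, toy_records):
        sdata = filter_cells(build_surveys(toy_records), min_years=2)
        # S1_0 surveyed only in 1997 (twice) -> dropped; S1_1 in 2003+2004 kept
        assert set(sdata.visits["cell1km_id"]) == {"S1_1"}

    def test_two_visits_same_year_insufficient(self):
        sdata = build_surveys(
            _records([("a", "1997-05-01", "c"), ("a", "1997-06-01", "c")])
        )
        assert filter_cells(sdata).n_visits == 0

    def test_empty_input_allowed(self, toy_records):
        sdata = filter_cells(build_surveys(toy_records), min_years=99)
        assert sdata.n_visits == 0

    def test_monotone_in_min_years(self, toy_records):
        sdata = build_surveys(toy_records)
        kept = [
            set(filter_cells(sdata, my).visits["cell1km_id"]) for my in (1, 2, 3)
        ]
        assert kept[0] >= kept[1] >= kept[2]


class TestAggregateSpecies:
    def test_both_members_collapse_and_length_drops(self):
        sdata = build_surveys(
            _records(
                [("terr", "1997-05-01", "c"), ("luco", "1997-05-01", "c"),
                 ("a", "1997-05-01", "c")]
            )
        )
        agg = aggregate_species(sdata, {"terr": "terr_agg", "luco": "terr_agg"})
        assert agg.visits.loc[0, "list_length"] == 2
        assert set(agg.detections["species"]) == {"terr_agg", "a"}

    def test_single_member_renamed_length_unchanged(self):
        sdata = build_surveys(_records([("terr", "1997-05-01", "c")]))
        agg = aggregate_species(sdata, {"terr": "terr_agg", "luco": "terr_agg"})
        assert agg.visits.loc[0, "list_length"] == 1

    def test_no_aggregates_is_identity(self, toy_records):
        sdata = build_surveys(toy_records)
        assert aggregate_species(sdata, None) is sdata

    def test_conflicting_mapping_rejected(self):
        sdata = build_surveys(_records([("x", "1997-05-01", "c")]))
        table = pd.DataFrame(
            {"species": ["x", "x"], "aggregate": ["agg_a", "agg_b"]}
        )
        with pytest.raises(ValueError, match="more than one aggregate"):
            aggregate_species(sdata, table)


class TestFilterSpecies:
    def test_threshold_boundary(self):
        rows = []
        for k in range(5):
            rows.append(("common", f"2000-01-{k+1:02d}", "c"))
        rows.append(("rare", "2000-01-01", "c"))
        sdata = build_surveys(_records(rows))
        assert filter_species(sdata, min_surveys=5) == ["common"]
        assert filter_species(sdata, min_surveys=6) == []

    def test_dropping_species_does_not_change_list_covariates(self, toy_records):
        sdata = build_surveys(toy_records)
        before = sdata.visits[["is_short", "is_long"]].copy()
        retained = filter_species(sdata, min_surveys=3)
        traits = pd.DataFrame(
            {"species": list("abcde"), "osr_forager": [1, 0, 1, 0, 1]}
        )
        ds = assemble_detection_dataset(sdata, traits, retained_species=retained)
        # the survey covariates are untouched by species retention
        pd.testing.assert_frame_equal(
            sdata.visits[["is_short", "is_long"]], before
        )
        assert ds.species == ["a", "b"]


class TestAssemble:
    def test_visits_pool_under_parent_5km_cell(self, toy_records):
        sdata = build_surveys(toy_records)
        traits = pd.DataFrame(
            {"species": list("abcde"), "osr_forager": [1, 0, 1, 0, 1]}
        )
        ds = assemble_detection_dataset(sdata, traits)
        assert ds.sites == ["S1"]
        assert ds.years.tolist() == list(range(1997, 2005))
        # conservation: every record incidence of retained species counted
        assert ds.det_counts.sum() == len(sdata.detections)

    def test_unsurveyed_interior_years_flagged(self, toy_records):
        sdata = build_surveys(toy_records)
        traits = pd.DataFrame(
            {"species": list("abcde"), "osr_forager": [1, 0, 1, 0, 1]}
        )
        ds = assemble_detection_dataset(sdata, traits)
        surveyed = ds.surveyed()[0]
        assert surveyed.tolist() == [True] + [False] * 5 + [True, True]

    def test_missing_trait_raises(self, toy_records):
        sdata = build_surveys(toy_records)
        traits = pd.DataFrame({"species": ["a"], "osr_forager": [1]})
        with pytest.raises(ValueError, match="forager flag"):
            assemble_detection_dataset(sdata, traits)

    def test_single_species_visits_counted_in_single_category(self, toy_records):
        sdata = build_surveys(toy_records)
        traits = pd.DataFrame(
            {"species": list("abcde"), "osr_forager": [1, 0, 1, 0, 1]}
        )
        ds = assemble_detection_dataset(sdata, traits)
        # 1997: one short and one single visit at site S1
        t1997 = 0
        assert ds.visit_counts[0, t1997].tolist() == [1, 1, 0]
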