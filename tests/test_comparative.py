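"""Regional overlap partitions, consensus scatter, and origin summaries."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethnosurvey.comparative import (
    VENN_CELLS,
    consensus_by_category,
    garden_wild_summary,
    region_overlap,
)

from conftest import make_dataset

_REGION_INF = {
    "SJ": ("I_sj", "SJ", "c1", 1200, "female", 40),
    "SR": ("I_sr", "SR", "c2", 900, "male", 55),
    "TK": ("I_tk", "TK", "c3", 2000, "female", 70),
}


def dataset_with_regional_species(sets: dict[str, list[str]], origin: str = "wild"):
    """One informant per region reporting the given species sets."""
    rows = []
    informants = []
    for region, species in sets.items():
        informants.append(_REGION_INF[region])
        for sp in species:
            rows.append((_REGION_INF[region][0], sp, "food", origin))
    return make_dataset(rows, informant_rows=informants)


class TestRegionOverlap:
    def test_enumerated_three_set_partition(self):
        ds = dataset_with_regional_species(
            {"SJ": ["S1", "S2"], "SR": ["S2", "S3"], "TK": ["S3", "S4"]}
        )
        part = region_overlap(ds, "species")
        assert part.partition_counts == {
            "sj_only": 1,
            "sr_only": 0,
            "tk_only": 1,
            "sj_sr": 1,
            "sj_tk": 0,
            "sr_tk": 1,
            "all": 0,
        }

    def test_identical_sets_all_in_triple_cell(self):
        ds = dataset_with_regional_species({r: ["S1", "S2"] for r in ("SJ", "SR", "TK")})
        counts = region_overlap(ds, "species").partition_counts
        assert counts["all"] == 2
        assert sum(counts.values()) == 2

    def test_disjoint_sets_only_single_cells(self):
        ds = dataset_with_regional_species({"SJ": ["S1"], "SR": ["S2"], "TK": ["S3"]})
        counts = region_overlap(ds, "species").partition_counts
        assert counts["sj_only"] == counts["sr_only"] == counts["tk_only"] == 1
        assert counts["all"] == counts["sj_sr"] == counts["sj_tk"] == counts["sr_tk"] == 0

    def test_use_items_are_species_category_pairs(self):
        rows = [
            ("I_sj", "S1", "food", "wild"),
            ("I_sj", "S1", "medicinal", "wild"),
            ("I_tk", "S1", "food", "wild"),
        ]
        ds = make_dataset(rows, informant_rows=[_REGION_INF["SJ"], _REGION_INF["TK"]])
        counts = region_overlap(ds, "use").partition_counts
        assert counts["sj_only"] == 1  # (S1, medicinal)
        assert counts["sj_tk"] == 1  # (S1, food)

    def test_partition_sums_and_region_totals(self, synth_dataset):
        for kind in ("species", "use"):
            part = region_overlap(synth_dataset, kind)
            union = set().union(*part.region_sets.values())
            assert sum(part.partition_counts.values()) == len(union)
            cells = part.cell_items()
            for region, four in (
                ("SJ", ("sj_only", "sj_sr", "sj_tk", "all")),
                ("SR", ("sr_only", "sj_sr", "sr_tk", "all")),
                ("TK", ("tk_only", "sj_tk", "sr_tk", "all")),
            ):
                assert part.region_total(region) == sum(len(cells[c]) for c in four)

    def test_garden_filter_never_increases_cells(self, synth_dataset):
        full = region_overlap(synth_dataset, "species").partition_counts
        garden = region_overlap(synth_dataset, "species", origin_filter="garden").partition_counts
        regional_full = {
            r: region_overlap(synth_dataset, "species").region_total(r) for r in ("SJ", "SR", "TK")
        }
        part_g = region_overlap(synth_dataset, "species", origin_filter="garden")
        for r in ("SJ", "SR", "TK"):
            assert part_g.region_total(r) <= regional_full[r]
        assert sum(garden.values()) <= sum(full.values())


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    sets=st.fixed_dictionaries(
        {
            r: st.sets(st.sampled_from([f"S{i}" for i in range(8)]), max_size=8)
            for r in ("SJ", "SR", "TK")
        }
    )
)
def test_partition_matches_exhaustive_set_algebra(sets):
    """The 7 exclusive cells are disjoint and reconstruct each region's set."""
    nonempty = {r: sorted(s) for r, s in sets.items() if s}
    if not nonempty:
        return
    ds = dataset_with_regional_species(nonempty)
    part = region_overlap(ds, "species")
    cells = part.cell_items()
    items = [item for c in VENN_CELLS for item in cells[c]]
    assert len(items) == len(set(items))  # disjoint
    for r, s in nonempty.items():
        assert part.region_sets[r] == set(s)


class TestConsensusByCategory:
    def test_nur_conservation_per_scope(self, synth_dataset):
        points = consensus_by_category(synth_dataset)
        for region in (None, "SJ", "SR", "TK"):
            label = region or "all"
            scope = points[points["region_scope"] == label]
            assert scope["nur"].sum() == len(synth_dataset.counting_reports(region))

    def test_category_present_in_one_region_only(self):
        rows = [
            ("I_sj", "S1", "cultural", "wild"),
            ("I_tk", "S1", "food", "wild"),
            ("I_tk", "S2", "food", "wild"),
        ]
        ds = make_dataset(rows, informant_rows=[_REGION_INF["SJ"], _REGION_INF["TK"]])
        pts = consensus_by_category(ds, include_overall=False)
        cultural = pts[pts["use_category"] == "cultural"]
        assert set(cultural["region_scope"]) == {"SJ"}

    def test_origin_split_emits_points_only_where_reports_exist(self):
        rows = [
            ("I_sj", "S1", "food", "garden"),
            ("I_sj", "S2", "food", "garden"),
            ("I_sj", "S1", "medicinal", "wild"),
            ("I_sj", "S2", "medicinal", "wild"),
        ]
        ds = make_dataset(rows, informant_rows=[_REGION_INF["SJ"]])
        pts = consensus_by_category(ds, split_by_origin=True)
        garden = pts[pts["origin_scope"] == "garden"]
        assert set(garden["use_category"]) == {"food"}

    def test_degenerate_category_flagged(self):
        ds = make_dataset([("I1", "S1", "food"), ("I1", "S2", "fuel")])
        pts = consensus_by_category(ds, include_overall=False)
        fuel = pts[pts["use_category"] == "fuel"].iloc[0]
        assert fuel["degenerate"] and fuel["fic"] == 0.0


class TestGardenWildSummary:
    def test_one_of_each_class(self):
        rows = [
            ("I1", "S1", "food", "wild"),
            ("I1", "S2", "food", "garden"),
            ("I1", "S3", "food", "garden"),
            ("I2", "S3", "food", "wild"),
        ]
        informants = [
            ("I1", "SJ", "c", 1000, "female", 40),
            ("I2", "SJ", "c", 1000, "male", 40),
        ]
        summary = garden_wild_summary(make_dataset(rows, informant_rows=informants))
        overall = summary[summary["region_scope"] == "all"].iloc[0]
        assert (
            overall["exclusively_wild"],
            overall["garden_only"],
            overall["both"],
        ) == (1, 1, 1)
        assert overall["classes_sum_to_total"]

    def test_region_without_garden_reports(self):
        ds = dataset_with_regional_species({"SJ": ["S1", "S2"], "TK": ["S1"]}, origin="wild")
        summary = garden_wild_summary(ds).set_index("region_scope")
        assert summary.loc["SJ", "garden_only"] == 0
        assert summary.loc["SJ", "both"] == 0

    def test_generator_truth_recovered_exactly(self, synth):
        dataset, truth = synth
        classes = {}
        known = dataset.origin_reports()
        for sp, grp in known.groupby("species_id"):
            origins = set(grp["origin"])
            classes[sp] = (
                "both"
                if origins == {"garden", "wild"}
                else ("garden_only" if origins == {"garden"} else "exclusively_wild")
            )
        summary = garden_wild_summary(dataset).set_index("region_scope")
        expected = {
            "exclusively_wild": sum(c == "exclusively_wild" for c in classes.values()),
            "garden_only": sum(c == "garden_only" for c in classes.values()),
            "both": sum(c == "both" for c in classes.values()),
        }
        for cls, count in expected.items():
            assert summary.loc["all", cls] == count
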