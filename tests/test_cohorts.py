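"""Band/bin assignment, cell tabulation, area aggregation, hemisphere splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleolbg.cohorts import (
    aggregate_nma,
    assign_lat_band,
    assign_lat_bands,
    assign_time_bin,
    genera_per_log_area,
    hemisphere_genus_counts,
    load_scheme,
    tabulate_cells,
)
from paleolbg.errors import ValidationError

from conftest import make_table

FIVE = load_scheme("five_bin")
THREE = load_scheme("three_bin")


class TestLatBands:
    @pytest.mark.parametrize(
        "lat,index",
        [
            (0.0, 0),      # equator in the 0-15N band
            (30.0, 2),     # boundary goes poleward: 30-45N
            (14.999, 0),
            (-76.0, -6),   # 75-90S, the southernmost band real data reach
            (-15.0, -2),   # mirrored convention: boundary poleward
            (-0.5, -1),
            (90.0, 5),     # poles closed
            (-90.0, -6),
        ],
    )
    def test_band_convention(self, lat, index):
        band = assign_lat_band(lat)
        assert band.index == index
        assert band.upper - band.lower == 15

    def test_out_of_range_latitude_rejected(self):
        with pytest.raises(ValidationError):
            assign_lat_band(90.5)

    @given(st.floats(min_value=-90, max_value=90, allow_nan=False))
    @settings(deadline=None, max_examples=200)
    def test_bands_partition_latitudes(self, lat):
        band = assign_lat_band(lat)
        assert -6 <= band.index <= 5
        # membership consistent with the half-open poleward convention
        if band.index >= 0:
            assert band.lower <= lat and (lat < band.upper or lat == 90)
        else:
            assert band.upper >= lat and (lat > band.lower or lat == -90)
        # scalar and vectorized paths agree
        assert assign_lat_bands(np.array([lat]))[0] == band.index


class TestTimeBins:
    @pytest.mark.parametrize(
        "max_ma,min_ma,scheme,expected",
        [
            (70.0, 68.0, FIVE, "Maas"),
            (150.0, 145.5, THREE, "Jurassic"),
            (146.0, 144.0, THREE, "Jurassic"),   # midpoint 145.0 on the boundary -> older bin
            (146.0, 144.0, FIVE, "Jur"),
            (60.0, 55.0, FIVE, None),            # Cenozoic midpoint: unbinned
            (300.0, 260.0, FIVE, None),
        ],
    )
    def test_midpoint_rule_with_older_bin_tie_break(self, max_ma, min_ma, scheme, expected):
        assert assign_time_bin(max_ma, min_ma, scheme) == expected

    def test_oldest_bin_upper_edge_closed(self):
        top = FIVE.bins[0].max_ma
        assert assign_time_bin(top, top, FIVE) == "Tr"

    def test_inverted_range_rejected(self):
        with pytest.raises(ValidationError):
            assign_time_bin(10.0, 20.0, FIVE)


class TestTabulateCells:
    def test_hand_counted_toy_cell(self, toy_cell_table):
        cells = tabulate_cells(toy_cell_table, FIVE)
        assert len(cells) == 1
        row = cells.iloc[0]
        assert (row["G"], row["O"], row["C"], row["TurtBF"]) == (3, 4, 2, 2)
        assert row["bin"] == "Camp" and row["band_index"] == 2

    def test_empty_cells_not_emitted_and_occurrences_accounted(self):
        table = make_table(
            [
                {"genus": "A", "palaeolat": 35.0},
                {"genus": "B", "palaeolat": -20.0},
                {"genus": "C", "max_ma": 30.0, "min_ma": 20.0},  # unbinned (Cenozoic)
            ]
        )
        cells = tabulate_cells(table, FIVE)
        assert len(cells) == 2
        assert cells["O"].sum() + 1 == table.n_occurrences
        assert any("unbinned" in line for line in table.filter_log)

    def test_tetbc_from_separate_tetrapod_table(self, toy_cell_table):
        tets = make_table(
            [
                {"genus": "TetA", "collection_id": "t1"},
                {"genus": "TetB", "collection_id": "t2"},
                {"genus": "TetC", "collection_id": "t2"},
            ]
        )
        cells = tabulate_cells(toy_cell_table, FIVE, tetrapods=tets)
        assert cells.iloc[0]["TetBC"] == 2
        absent = tabulate_cells(toy_cell_table, FIVE)
        assert np.isnan(absent.iloc[0]["TetBC"])

    def test_per_band_richness_bounded_by_bin_level_richness(self):
        rows = []
        rng = np.random.default_rng(3)
        for i in range(40):
            rows.append(
                {"genus": f"G{rng.integers(8)}", "collection_id": f"c{i}",
                 "palaeolat": float(rng.uniform(-60, 60))}
            )
        table = make_table(rows)
        cells = tabulate_cells(table, FIVE)
        bin_level = table.df["genus"].nunique()
        assert (cells["G"] <= bin_level).all()
        assert cells["G"].sum() >= bin_level


class TestHemisphereCounts:
    def test_genus_straddling_the_meridian_counts_in_both_halves(self):
        table = make_table(
            [
                {"genus": "A", "palaeolng": -10.0, "max_ma": 90.0, "min_ma": 88.0},
                {"genus": "A", "palaeolng": 10.0, "max_ma": 90.0, "min_ma": 88.0},
                {"genus": "B", "palaeolng": 120.0, "max_ma": 90.0, "min_ma": 88.0},
            ]
        )
        east, west = hemisphere_genus_counts(table, "Cretaceous")
        assert (east, west) == (2, 1)

    def test_southern_records_ignored(self):
        table = make_table(
            [{"genus": "A", "palaeolat": -10.0, "palaeolng": 5.0, "max_ma": 90.0, "min_ma": 88.0}]
        )
        assert hemisphere_genus_counts(table, "Cretaceous") == (0, 0)


def _area5(stage_rows):
    # stage_rows: (stage, max_ma, min_ma, {band_lower_5: area})
    rows = []
    for stage, hi, lo, areas in stage_rows:
        for lower, a in areas.items():
            rows.append(
                {"stage": stage, "stage_max_ma": hi, "stage_min_ma": lo,
                 "band_lower_5": lower, "area_km2": a}
            )
    return pd.DataFrame(rows)


class TestAggregateNMA:
    def test_single_stage_sums_constituent_bands(self):
        area5 = _area5([("s1", 80.0, 75.0, {0.0: 1e6, 5.0: 2e6, 10.0: 3e6})])
        out = aggregate_nma(area5, FIVE)
        assert out.loc[0, "nma_km2"] == pytest.approx(6e6)
        assert not out.loc[0, "degenerate"]

    def test_geometric_mean_across_stages(self):
        area5 = _area5(
            [
                ("s1", 80.0, 75.0, {0.0: 1e6, 5.0: 1e6, 10.0: 2e6}),  # sum 4e6
                ("s2", 75.0, 72.5, {0.0: 3e6, 5.0: 3e6, 10.0: 3e6}),  # sum 9e6
            ]
        )
        out = aggregate_nma(area5, FIVE)
        assert out.loc[0, "nma_km2"] == pytest.approx(6e6)  # sqrt(4e6 * 9e6)

    def test_zero_stage_area_degenerates_to_zero_with_flag(self):
        area5 = _area5(
            [
                ("s1", 80.0, 75.0, {0.0: 0.0, 5.0: 0.0, 10.0: 0.0}),
                ("s2", 75.0, 72.5, {0.0: 3e6, 5.0: 3e6, 10.0: 3e6}),
            ]
        )
        out = aggregate_nma(area5, FIVE)
        assert out.loc[0, "nma_km2"] == 0.0
        assert bool(out.loc[0, "degenerate"])

    def test_stage_permutation_invariance_and_scale_equivariance(self):
        stages = [
            ("s1", 80.0, 75.0, {0.0: 1e6, 5.0: 2e6, 10.0: 1e6}),
            ("s2", 75.0, 72.5, {0.0: 2e6, 5.0: 2e6, 10.0: 5e6}),
        ]
        out = aggregate_nma(_area5(stages), FIVE)
        flipped = aggregate_nma(_area5(stages[::-1]), FIVE)
        pd.testing.assert_frame_equal(out, flipped)
        doubled = _area5(stages)
        doubled["area_km2"] *= 2
        out2 = aggregate_nma(doubled, FIVE)
        assert np.allclose(out2["nma_km2"], 2 * out["nma_km2"])

    def test_missing_5deg_band_rejected(self):
        area5 = _area5([("s1", 80.0, 75.0, {0.0: 1e6, 5.0: 2e6})])
        with pytest.raises(ValidationError, match="missing"):
            aggregate_nma(area5, FIVE)


class TestGeneraPerLogArea:
    def test_closed_form(self):
        assert genera_per_log_area(5, 1e6) == pytest.approx(5 / 6)

    def test_zero_richness(self):
        assert genera_per_log_area(0, 1e4) == 0.0

    def test_area_of_one_km2_is_undefined(self):
        with pytest.raises(ValidationError):
            genera_per_log_area(3, 1.0)
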