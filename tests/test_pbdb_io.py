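"""Reading, validation, the non-marine filter, and formation-label resolution."""

import pandas as pd
import pytest

from paleolbg.cohorts import cell_keys, load_scheme
from paleolbg.errors import ConfigurationError, ValidationError
from paleolbg.pbdb_io import (
    ExclusionLists,
    apply_nonmarine_filter,
    classify_environment,
    normalize_genus,
    read_occurrence_table,
    resolve_formation_label,
    resolve_formation_labels,
)

from conftest import make_table


def _write_csv(tmp_path, rows, name="occ.csv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


BASE_ROW = {
    "occurrence_id": 1, "genus": "Testudo", "collection_id": 10, "reference_id": 5,
    "formation": "F1", "group": "", "collection_name": "loc", "palaeolat": 40.0,
    "palaeolng": 10.0, "max_ma": 80.0, "min_ma": 78.0,
    "environment_class": "non_marine", "taxon_category": "body_taxon",
}


class TestRead:
    def test_full_toy_table_parses_row_per_record(self, tmp_path):
        rows = [
            BASE_ROW,
            BASE_ROW | {"occurrence_id": 2, "genus": "Emys", "collection_id": 11},
            BASE_ROW | {"occurrence_id": 3, "genus": "Trionyx", "collection_id": 12},
        ]
        table = read_occurrence_table(_write_csv(tmp_path, rows))
        assert table.summary() == {"occurrences": 3, "genera": 3, "collections": 3}

    def test_row_missing_genus_is_excluded_and_logged(self, tmp_path):
        rows = [BASE_ROW, BASE_ROW | {"occurrence_id": 2, "genus": "", "collection_id": 11}]
        table = read_occurrence_table(_write_csv(tmp_path, rows))
        assert table.n_occurrences == 1
        assert any("missing genus" in line for line in table.filter_log)

    def test_malformed_latitude_goes_to_filter_log_not_crash(self, tmp_path):
        rows = [
            BASE_ROW,
            BASE_ROW | {"occurrence_id": 2, "palaeolat": 123.0, "collection_id": 11},
            BASE_ROW | {"occurrence_id": 3, "palaeolat": "north", "collection_id": 12},
        ]
        table = read_occurrence_table(_write_csv(tmp_path, rows))
        assert table.n_occurrences == 1
        assert sum("palaeolat" in line for line in table.filter_log) == 2

    def test_unmappable_required_column_names_the_column(self, tmp_path):
        rows = [{k: v for k, v in BASE_ROW.items() if k != "palaeolat"}]
        with pytest.raises(ConfigurationError, match="palaeolat"):
            read_occurrence_table(_write_csv(tmp_path, rows))

    def test_dialect_mapping_and_tsv(self, tmp_path):
        mapping = {"occurrence_id": "occ_no", "genus": "gen", "collection_id": "coll",
                   "palaeolat": "plat", "max_ma": "ma1", "min_ma": "ma2"}
        row = {"occ_no": 1, "gen": "Testudo", "coll": 2, "plat": 10.0, "ma1": 90.0, "ma2": 85.0}
        path = tmp_path / "t.tsv"
        pd.DataFrame([row]).to_csv(path, sep="\t", index=False)
        table = read_occurrence_table(path, format="tsv", column_map=mapping)
        assert table.n_occurrences == 1 and table.df.loc[0, "genus"] == "Testudo"

    def test_xlsx_sheet_roundtrip(self, tmp_path):
        path = tmp_path / "book.xlsx"
        pd.DataFrame([BASE_ROW]).to_excel(path, sheet_name="occurrences", index=False)
        table = read_occurrence_table(path, format="xlsx_sheet", sheet="occurrences")
        assert table.n_occurrences == 1

    def test_inconsistent_collection_coordinates_rejected(self, tmp_path):
        rows = [BASE_ROW, BASE_ROW | {"occurrence_id": 2, "palaeolat": -5.0}]
        with pytest.raises(ValidationError, match="inconsistent"):
            read_occurrence_table(_write_csv(tmp_path, rows))


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("cf. Testudo", "Testudo"),
        ("aff. Trionyx", "Trionyx"),
        ("?Emys", "Emys"),
        ('"Glyptops"', "Glyptops"),
        ("Testudo (Chersine) graeca", "Testudo"),
        ("  Adocus  ", "Adocus"),
    ],
)
def test_genus_normalization_strips_qualifiers(raw, expected):
    assert normalize_genus(raw) == expected


@pytest.mark.parametrize(
    "raw,expected",
    [("fluvial", "non_marine"), ("shallow marine", "marine"), ("", "unknown"),
     ("lacustrine - large", "non_marine"), ("reef", "marine")],
)
def test_environment_classification(raw, expected):
    assert classify_environment(raw) == expected


class TestNonmarineFilter:
    def test_marine_flagged_record_removed_others_untouched(self):
        table = make_table(
            [{"genus": "A"}, {"genus": "B", "environment_class": "marine"}, {"genus": "C"}]
        )
        out = apply_nonmarine_filter(table, ExclusionLists())
        assert sorted(out.df["genus"]) == ["A", "C"]

    def test_exclusion_lists_remove_by_name(self):
        table = make_table([{"genus": "Plesiochelys"}, {"genus": "Emys"}])
        out = apply_nonmarine_filter(table, ExclusionLists(marine_taxa={"Plesiochelys"}))
        assert list(out.df["genus"]) == ["Emys"]

    def test_identity_on_clean_table_with_empty_lists(self):
        table = make_table([{"genus": "A"}, {"genus": "B"}])
        out = apply_nonmarine_filter(table, ExclusionLists())
        assert out.df.equals(table.df)

    def test_filter_is_idempotent_and_monotone(self):
        table = make_table(
            [
                {"genus": "A"},
                {"genus": "Oolithes", "taxon_category": "ootaxon"},
                {"genus": "Track", "taxon_category": "ichnotaxon"},
                {"genus": "Marinus", "environment_class": "marine"},
            ]
        )
        excl = ExclusionLists(marine_taxa={"Marinus"})
        once = apply_nonmarine_filter(table, excl)
        twice = apply_nonmarine_filter(once, excl)
        assert once.df.equals(twice.df)
        assert once.n_occurrences <= table.n_occurrences
        assert once.n_genera <= table.n_genera

    def test_overlapping_exclusion_lists_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            ExclusionLists(marine_taxa={"X"}, ichnotaxa={"X"})

    def test_exclusion_lists_from_files(self, tmp_path):
        path = tmp_path / "marine.txt"
        path.write_text("# marine genera\nPlesiochelys\n  Thalassemys \n")
        excl = ExclusionLists.from_files(marine=path)
        assert excl.marine_taxa == frozenset({"Plesiochelys", "Thalassemys"})


class TestFormationResolution:
    def test_named_formation_wins(self):
        table = make_table([{"genus": "A", "formation": "F1"}])
        record = table.df.iloc[0]
        assert resolve_formation_label(record, table) == "F1"

    def test_group_substituted_when_group_has_no_named_formation(self):
        table = make_table(
            [
                {"genus": "A", "group": "G1"},
                {"genus": "B", "formation": "F2", "group": "G2"},
            ]
        )
        assert resolve_formation_label(table.df.iloc[0], table) == "G1"

    def test_group_not_substituted_when_it_would_inflate_the_count(self):
        # another record carries a named formation belonging to G1
        table = make_table(
            [
                {"genus": "A", "group": "G1"},
                {"genus": "B", "formation": "F1", "group": "G1"},
            ]
        )
        assert resolve_formation_label(table.df.iloc[0], table) is None

    def test_collection_name_only_for_lone_deposit_in_cell(self):
        scheme = load_scheme("five_bin")
        lone = make_table(
            [
                {"genus": "A", "collection_id": "c1", "collection_name": "Lone"},
                # different band (southern), so c1 stays alone in its cell
                {"genus": "B", "collection_id": "c2", "palaeolat": -20.0,
                 "collection_name": "Other"},
            ]
        )
        labels = resolve_formation_labels(lone, cell_keys=cell_keys(lone, scheme))
        assert labels.iloc[0] == "Lone"

        crowded = make_table(
            [
                {"genus": "A", "collection_id": "c1", "collection_name": "Lone"},
                {"genus": "B", "collection_id": "c2", "palaeolat": 36.0,
                 "collection_name": "Other"},
            ]
        )
        labels = resolve_formation_labels(crowded, cell_keys=cell_keys(crowded, scheme))
        assert pd.isna(labels.iloc[0])

    def test_resolved_group_labels_never_collide_with_formation_names(self):
        # a group named like an existing formation must not be substituted
        table = make_table(
            [
                {"genus": "A", "group": "F9"},
                {"genus": "B", "formation": "F9", "group": "Gother"},
            ]
        )
        labels = resolve_formation_labels(table)
        named = set(table.df["formation"].dropna())
        substituted = set(labels.dropna()) - named
        assert "F9" not in substituted
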