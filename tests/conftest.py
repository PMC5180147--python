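"""Shared fixtures: tiny hand-countable occurrence tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from paleolbg.pbdb_io import OccurrenceTable


def make_table(rows: list[dict]) -> OccurrenceTable:
    """Build a canonical OccurrenceTable from terse row dicts.

    Defaults: Late-Cretaceous-ish ages, 35N/10E, one collection per row
    unless given, body taxa in non-marine settings.
    """
    full = []
    for i, row in enumerate(rows):
        full.append(
            {
                "occurrence_id": row.get("occurrence_id", f"o{i}"),
                "genus": row.get("genus", f"G{i}"),
                "collection_id": row.get("collection_id", f"c{i}"),
                "reference_id": row.get("reference_id", f"r{i}"),
                "formation": row.get("formation", pd.NA),
                "group": row.get("group", pd.NA),
                "collection_name": row.get("collection_name", f"loc{i}"),
                "palaeolat": row.get("palaeolat", 35.0),
                "palaeolng": row.get("palaeolng", 10.0),
                "max_ma": row.get("max_ma", 80.0),
                "min_ma": row.get("min_ma", 78.0),
                "environment_class": row.get("environment_class", "non_marine"),
                "taxon_category": row.get("taxon_category", "body_taxon"),
            }
        )
    df = pd.DataFrame(full)
    # rows sharing a collection must share its coordinates/ages
    for col in ("palaeolat", "palaeolng", "max_ma", "min_ma"):
        df[col] = df.groupby("collection_id")[col].transform("first")
    return OccurrenceTable(df)


@pytest.fixture
def toy_cell_table() -> OccurrenceTable:
    """Four occurrences of genera A, A, B, C in 2 collections / 2 formations."""
    return make_table(
        [
            {"genus": "A", "collection_id": "c1", "formation": "F1"},
            {"genus": "A", "collection_id": "c1", "formation": "F1"},
            {"genus": "B", "collection_id": "c2", "formation": "F2"},
            {"genus": "C", "collection_id": "c2", "formation": "F2"},
        ]
    )
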