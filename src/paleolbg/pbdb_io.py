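"""Reading, validating and filtering Paleobiology-Database-style occurrence tables.

An *occurrence* is one taxon (here: genus) recorded in one fossil collection
(a locality sample), with palaeocoordinates and an age range attached.  This
module turns delimited-text or spreadsheet exports into a validated
:class:`OccurrenceTable`, applies the non-marine filter (marine taxa, ootaxa
and ichnotaxa removed), and resolves formation labels for the
turtle-bearing-formation (TurtBF) sampling proxy, substituting the geological
group or the collection name only where that cannot inflate the formation
count.

All name fields are NFC-normalized and whitespace-trimmed before any matching,
because these tables typically pass through spreadsheets.  Every dropped or
rewritten row is logged, never silently discarded.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

#: Canonical column set every OccurrenceTable carries.
CANONICAL_COLUMNS = [
    "occurrence_id",
    "genus",
    "collection_id",
    "reference_id",
    "formation",
    "group",
    "collection_name",
    "palaeolat",
    "palaeolng",
    "max_ma",
    "min_ma",
    "environment_class",
    "taxon_category",
]

REQUIRED_COLUMNS = [
    "occurrence_id",
    "genus",
    "collection_id",
    "palaeolat",
    "max_ma",
    "min_ma",
]

#: Column-name dictionaries for common export dialects.  Keys are canonical
#: names, values the header used by that dialect.  Export headers drift
#: between database versions, so these are defaults, not gospel: pass your
#: own mapping to ``read_occurrence_table`` when they do not match.
COLUMN_MAPS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in CANONICAL_COLUMNS},
    "pbdb": {
        "occurrence_id": "occurrence_no",
        "genus": "genus",
        "collection_id": "collection_no",
        "reference_id": "reference_no",
        "formation": "formation",
        "group": "stratgroup",
        "collection_name": "collection_name",
        "palaeolat": "paleolat",
        "palaeolng": "paleolng",
        "max_ma": "max_ma",
        "min_ma": "min_ma",
        "environment_class": "environment",
        "taxon_category": "pres_mode",
    },
    "fossilworks": {
        "occurrence_id": "occurrence_no",
        "genus": "occurrence.genus_name",
        "collection_id": "collection_no",
        "reference_id": "occurrence.reference_no",
        "formation": "collections.formation",
        "group": "collections.geological_group",
        "collection_name": "collection.name",
        "palaeolat": "collections.paleolatdec",
        "palaeolng": "collections.paleolngdec",
        "max_ma": "collections.ma_max",
        "min_ma": "collections.ma_min",
        "environment_class": "collections.environment",
        "taxon_category": "occurrence.preservation",
    },
}

# Open-nomenclature qualifiers stripped from genus strings: "cf. Xus",
# "aff. Xus", "?Xus", '"Xus"', "Xus (Subxus)" all normalize to "Xus".
_GENUS_QUALIFIERS = re.compile(r'\b(?:cf|aff|ex gr|sensu lato)\.?\s+|[?"“”\']')
_SUBGENUS = re.compile(r"\s*\([^)]*\)")

#: Environment strings treated as marine when no exclusion list catches the
#: genus first.  Matching is substring-based on the lower-cased field.
_MARINE_KEYWORDS = ("marine", "reef", "lagoon", "shoreface", "offshore")
_NONMARINE_KEYWORDS = (
    "fluvial", "lacustrine", "terrestrial", "alluvial", "floodplain",
    "channel", "pond", "swamp", "overbank", "eolian", "aeolian", "cave",
    "fissure", "wetland", "deltaic",
)


def _nfc(value: object) -> object:
    if isinstance(value, str):
        return unicodedata.normalize("NFC", value).strip()
    return value


def normalize_genus(raw: object) -> str:
    """Normalize a genus string: NFC, qualifier stripping, first token.

    Returns an empty string when nothing survives (treated as missing).
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ""
    name = unicodedata.normalize("NFC", str(raw))
    name = _SUBGENUS.sub("", name)
    name = _GENUS_QUALIFIERS.sub("", name)
    name = name.strip()
    if not name:
        return ""
    token = name.split()[0]
    return token[:1].upper() + token[1:]


def classify_environment(raw: object) -> str:
    """Map a free-text environment field to {marine, non_marine, unknown}."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "unknown"
    text = str(raw).strip().lower()
    if text in {"marine", "non_marine", "unknown"}:
        return text
    if text in {"non-marine", "nonmarine", "freshwater"}:
        return "non_marine"
    if any(k in text for k in _NONMARINE_KEYWORDS):
        return "non_marine"
    if any(k in text for k in _MARINE_KEYWORDS):
        return "marine"
    return "unknown"


def classify_taxon_category(raw: object) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "body_taxon"
    text = str(raw).strip().lower()
    if text in {"ootaxon", "egg", "eggshell", "oospecies"}:
        return "ootaxon"
    if text in {"ichnotaxon", "trace", "trackway", "footprint", "coprolite"}:
        return "ichnotaxon"
    return "body_taxon"


@dataclass
class ExclusionLists:
    """Genus-name exclusion sets for the non-marine filter.

    The three sets (marine taxa, ootaxa, other ichnotaxa) must be disjoint;
    list-driven exclusion takes precedence over the per-record environment
    flag, mirroring how published occurrence cleanups are specified.
    """

    marine_taxa: frozenset[str] = frozenset()
    ootaxa: frozenset[str] = frozenset()
    ichnotaxa: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        norm = lambda names: frozenset(normalize_genus(n) for n in names if str(n).strip())
        object.__setattr__(self, "marine_taxa", norm(self.marine_taxa))
        object.__setattr__(self, "ootaxa", norm(self.ootaxa))
        object.__setattr__(self, "ichnotaxa", norm(self.ichnotaxa))
        overlap = (self.marine_taxa & self.ootaxa) | (self.marine_taxa & self.ichnotaxa) | (
            self.ootaxa & self.ichnotaxa
        )
        if overlap:
            raise ValidationError(f"exclusion lists overlap: {sorted(overlap)}")

    @classmethod
    def from_files(
        cls,
        marine: str | Path | None = None,
        ootaxa: str | Path | None = None,
        ichnotaxa: str | Path | None = None,
    ) -> "ExclusionLists":
        """Build from plain-text files, one genus name per line, '#' comments."""

        def read(path):
            if path is None:
                return frozenset()
            lines = Path(path).read_text(encoding="utf-8").splitlines()
            return frozenset(
                ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")
            )

        return cls(read(marine), read(ootaxa), read(ichnotaxa))


@dataclass
class OccurrenceTable:
    """A validated occurrence table plus its provenance and filter log.

    ``df`` always carries :data:`CANONICAL_COLUMNS`.  The log is line
    oriented; every exclusion and substitution appends one line.
    """

    df: pd.DataFrame
    provenance: list[str] = field(default_factory=list)
    filter_log: list[str] = field(default_factory=list)

    @property
    def n_occurrences(self) -> int:
        return len(self.df)

    @property
    def n_genera(self) -> int:
        return int(self.df["genus"].nunique())

    @property
    def n_collections(self) -> int:
        return int(self.df["collection_id"].nunique())

    def summary(self) -> dict[str, int]:
        return {
            "occurrences": self.n_occurrences,
            "genera": self.n_genera,
            "collections": self.n_collections,
        }

    def log(self, message: str) -> None:
        self.filter_log.append(message)

    def to_csv(self, path: str | Path, filter_flag: pd.Series | None = None) -> None:
        out = self.df.copy()
        out["filter_flag"] = "retained" if filter_flag is None else filter_flag
        out.to_csv(path, index=False)

    def write_log(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.provenance + self.filter_log) + "\n", encoding="utf-8")


def _resolve_column_map(column_map: str | Mapping[str, str]) -> dict[str, str]:
    if isinstance(column_map, str):
        try:
            return dict(COLUMN_MAPS[column_map])
        except KeyError:
            raise ConfigurationError(
                f"unknown column-map dialect {column_map!r}; known: {sorted(COLUMN_MAPS)}"
            ) from None
    return dict(column_map)


def read_occurrence_table(
    path: str | Path,
    format: str = "csv",
    column_map: str | Mapping[str, str] = "canonical",
    sheet: str | int | None = None,
) -> OccurrenceTable:
    """Read a delimited or spreadsheet occurrence export into an OccurrenceTable.

    Parameters
    ----------
    path:
        File to read; must exist and carry a header row.
    format:
        One of ``csv``, ``tsv``, ``xlsx_sheet``.
    column_map:
        Dialect name from :data:`COLUMN_MAPS` or an explicit
        canonical-name -> header mapping.
    sheet:
        Sheet name or index, required for ``xlsx_sheet``.

    Rows missing a genus or a palaeolatitude, with an out-of-range or
    non-numeric latitude, or with an inverted/non-positive age range are
    excluded and logged row by row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        raw = pd.read_csv(path)
    elif format == "tsv":
        raw = pd.read_csv(path, sep="\t")
    elif format == "xlsx_sheet":
        raw = pd.read_excel(path, sheet_name=0 if sheet is None else sheet)
    else:
        raise ConfigurationError(f"unknown format {format!r}")

    mapping = _resolve_column_map(column_map)
    raw.columns = [str(c).strip() for c in raw.columns]
    missing = [mapping.get(c, c) for c in REQUIRED_COLUMNS if mapping.get(c, c) not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"required column(s) {missing} not found in {path.name}; "
            f"available: {list(raw.columns)}"
        )

    df = pd.DataFrame(index=raw.index)
    for canon in CANONICAL_COLUMNS:
        source = mapping.get(canon, canon)
        df[canon] = raw[source] if source in raw.columns else pd.NA

    table = OccurrenceTable(df, provenance=[f"source: {path} (format={format})"])

    # Normalize text fields before any matching.
    for col in ("formation", "group", "collection_name"):
        df[col] = df[col].map(_nfc)
        df.loc[df[col].astype("string").fillna("") == "", col] = pd.NA
    df["genus"] = df["genus"].map(normalize_genus)
    df["environment_class"] = df["environment_class"].map(classify_environment)
    df["taxon_category"] = df["taxon_category"].map(classify_taxon_category)
    for col in ("palaeolat", "palaeolng", "max_ma", "min_ma"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    keep = pd.Series(True, index=df.index)

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal keep
        bad = mask & keep
        for occ in df.loc[bad, "occurrence_id"]:
            table.log(f"excluded occurrence {occ}: {reason}")
        keep &= ~mask

    drop(df["genus"] == "", "missing genus")
    drop(df["palaeolat"].isna(), "missing palaeolatitude")
    drop((df["palaeolat"] < -90) | (df["palaeolat"] > 90), "palaeolatitude outside [-90, 90]")
    drop(df["max_ma"].isna() | df["min_ma"].isna(), "missing age bound")
    drop(df["max_ma"] < df["min_ma"], "inverted age range (max_ma < min_ma)")
    drop(df["min_ma"] <= 0, "non-positive age")

    dup = df["occurrence_id"].duplicated(keep="first")
    drop(dup, "duplicate occurrence_id")

    table.df = df[keep].reset_index(drop=True)
    _check_collection_consistency(table)
    table.log(
        f"read {table.n_occurrences} occurrences, {table.n_genera} genera, "
        f"{table.n_collections} collections ({int((~keep).sum())} rows excluded)"
    )
    return table


def _check_collection_consistency(table: OccurrenceTable) -> None:
    """Each collection must map to a single (palaeolat, palaeolng, max_ma, min_ma)."""
    geo = table.df.groupby("collection_id")[["palaeolat", "palaeolng", "max_ma", "min_ma"]].nunique()
    bad = geo[(geo > 1).any(axis=1)].index.tolist()
    if bad:
        raise ValidationError(
            f"collections with inconsistent coordinates or ages: {bad[:10]}"
        )


def apply_nonmarine_filter(table: OccurrenceTable, excl: ExclusionLists) -> OccurrenceTable:
    """Remove marine taxa, ootaxa and ichnotaxa (lists first, flags second).

    A record is removed when its genus is on any exclusion list, its taxon
    category is ootaxon/ichnotaxon, or its environment class is marine.
    Idempotent; removal counts are logged per category.
    """
    df = table.df
    in_marine = df["genus"].isin(excl.marine_taxa)
    in_oo = df["genus"].isin(excl.ootaxa) | (df["taxon_category"] == "ootaxon")
    in_ichno = df["genus"].isin(excl.ichnotaxa) | (df["taxon_category"] == "ichnotaxon")
    env_marine = (df["environment_class"] == "marine") & ~(in_marine | in_oo | in_ichno)
    removed = in_marine | in_oo | in_ichno | env_marine

    out = OccurrenceTable(
        df[~removed].reset_index(drop=True),
        provenance=list(table.provenance),
        filter_log=list(table.filter_log),
    )
    out.log(
        "non-marine filter: removed "
        f"{int(in_marine.sum())} listed-marine, {int(in_oo.sum())} ootaxon, "
        f"{int(in_ichno.sum())} ichnotaxon, {int(env_marine.sum())} marine-environment "
        f"records; {out.n_occurrences} occurrences retained"
    )
    return out


def resolve_formation_labels(
    table: OccurrenceTable,
    cell_keys: pd.DataFrame | None = None,
) -> pd.Series:
    """Resolve one formation label per record for the TurtBF proxy.

    Per record: the named formation when present; else the geological group
    name, but only if no record anywhere in the table carries a named
    formation belonging to that group and the group name does not itself
    duplicate a known formation name; else the collection name, but only if
    the record's collection is the only deposit in its (time bin x 15deg
    band) cell; else missing (the record contributes no formation count).

    ``cell_keys`` is a two-column frame (``bin``, ``band_index``) aligned to
    ``table.df`` (as produced by :func:`paleolbg.cohorts.cell_keys`); without
    it the collection-name fallback is never taken, since "same age and
    area" cannot be assessed.  Each substitution decision is logged.
    """
    df = table.df
    formation = df["formation"].astype("string")
    group = df["group"].astype("string")

    named_formations = set(formation.dropna())
    groups_with_formation = set(df.loc[formation.notna() & group.notna(), "group"])

    labels = formation.copy()
    need = labels.isna()

    # Group substitution: safe only when the group has no named formation in
    # the table and its name cannot collide with an existing formation label.
    group_ok = need & group.notna() & ~group.isin(groups_with_formation) & ~group.isin(
        named_formations
    )
    labels[group_ok] = group[group_ok]
    for occ, g in zip(df.loc[group_ok, "occurrence_id"], group[group_ok]):
        table.log(f"occurrence {occ}: formation label <- group {g!r} (no named formation in group)")

    still = labels.isna()
    if cell_keys is not None and still.any():
        keys = cell_keys.reset_index(drop=True)
        cell_id = keys["bin"].astype("string").fillna("<unbinned>") + "|" + keys[
            "band_index"
        ].astype(str)
        coll_per_cell = (
            pd.DataFrame({"cell": cell_id, "coll": df["collection_id"]})
            .groupby("cell")["coll"]
            .nunique()
        )
        lone = cell_id.map(coll_per_cell).eq(1) & still & df["collection_name"].notna()
        labels[lone] = df.loc[lone, "collection_name"]
        for occ, name in zip(df.loc[lone, "occurrence_id"], df.loc[lone, "collection_name"]):
            table.log(
                f"occurrence {occ}: formation label <- collection {name!r} "
                "(only deposit in its bin/band cell)"
            )
    for occ in df.loc[labels.isna(), "occurrence_id"]:
        table.log(f"occurrence {occ}: no defensible formation label; excluded from TurtBF")
    return labels


def resolve_formation_label(record: pd.Series, table: OccurrenceTable) -> str | None:
    """Single-record convenience wrapper around :func:`resolve_formation_labels`."""
    labels = resolve_formation_labels(table)
    hit = table.df["occurrence_id"] == record["occurrence_id"]
    if not hit.any():
        raise ValidationError(f"record {record['occurrence_id']!r} not in table")
    val = labels[hit].iloc[0]
    return None if pd.isna(val) else str(val)
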