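"""Temporal bins, 15-degree palaeolatitudinal bands, and per-cell tabulation.

The analytical unit downstream is the *cell*: one (time bin x 15deg band)
combination, carrying genus richness G, occurrence count O, collection count
C, the turtle-bearing-formation proxy TurtBF, the tetrapod-bearing-collection
proxy TetBC, and geometric-mean non-marine area (NMA).

Band convention (documented because it is load-bearing for reproducibility):
bands are half-open toward the poles — [lower, upper) in the north, mirrored
(lower, upper] in the south — so a boundary latitude belongs to the more
poleward band, 0deg sits in the 0-15N band, and +/-90 are closed.  Band
indices run -6 (75-90S) .. +5 (75-90N).

Time-bin assignment uses the collection's age-range midpoint; a midpoint
exactly on a bin boundary goes to the older bin.  Numeric stage boundaries
ship as an editable fixture table (GTS-2012 ages by default) rather than
being hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .errors import ConfigurationError, ValidationError
from .pbdb_io import OccurrenceTable

BAND_WIDTH = 15.0
FIVE_BIN_LABELS = ["Tr", "Jur", "rCret", "Camp", "Maas"]
THREE_BIN_LABELS = ["Jurassic", "Early Cretaceous", "Late Cretaceous"]


@dataclass(frozen=True)
class LatBand:
    """One 15-degree palaeolatitudinal band, index -6..+5."""

    index: int

    @property
    def lower(self) -> float:
        return self.index * BAND_WIDTH

    @property
    def upper(self) -> float:
        return (self.index + 1) * BAND_WIDTH

    @property
    def midpoint(self) -> float:
        return (self.lower + self.upper) / 2

    def __str__(self) -> str:
        lo, hi = abs(self.lower), abs(self.upper)
        if self.index >= 0:
            return f"{lo:g}-{hi:g}N"
        return f"{hi:g}-{lo:g}S"


@dataclass(frozen=True)
class TimeBin:
    label: str
    max_ma: float
    min_ma: float

    def __post_init__(self) -> None:
        if not self.max_ma > self.min_ma > 0:
            raise ValidationError(f"bad bin ages for {self.label}: {self.max_ma}..{self.min_ma}")


@dataclass(frozen=True)
class TimeBinScheme:
    """An ordered (old -> young), contiguous, non-overlapping set of bins."""

    name: str
    bins: tuple[TimeBin, ...]

    def __post_init__(self) -> None:
        for older, younger in zip(self.bins, self.bins[1:]):
            if not np.isclose(older.min_ma, younger.max_ma):
                raise ValidationError(
                    f"scheme {self.name}: bins {older.label}/{younger.label} not contiguous"
                )

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bins]

    @property
    def max_ma(self) -> float:
        return self.bins[0].max_ma

    @property
    def min_ma(self) -> float:
        return self.bins[-1].min_ma


def _load_bin_table(path: str | Path | None = None) -> pd.DataFrame:
    if path is not None:
        return pd.read_csv(path)
    with resources.files("paleolbg.data").joinpath("time_bins.csv").open("r") as fh:
        return pd.read_csv(fh)


def load_scheme(name: str, path: str | Path | None = None) -> TimeBinScheme:
    """Load a named binning scheme (``five_bin``, ``three_bin``, ``era``).

    ``path`` overrides the packaged boundary table with a user-edited CSV of
    the same layout (scheme, label, max_ma, min_ma).
    """
    table = _load_bin_table(path)
    rows = table[table["scheme"] == name]
    if rows.empty:
        raise ConfigurationError(f"no scheme {name!r} in bin table; have {sorted(table['scheme'].unique())}")
    bins = tuple(
        TimeBin(r.label, float(r.max_ma), float(r.min_ma))
        for r in rows.sort_values("max_ma", ascending=False).itertuples()
    )
    return TimeBinScheme(name, bins)


def assign_lat_band(palaeolat: float) -> LatBand:
    """Map a palaeolatitude to its 15-degree band (poleward-open convention)."""
    if not -90 <= palaeolat <= 90 or not np.isfinite(palaeolat):
        raise ValidationError(f"palaeolatitude {palaeolat} outside [-90, 90]")
    mag = min(int(abs(palaeolat) // BAND_WIDTH), 5)  # +/-90 closed into the polar band
    return LatBand(mag if palaeolat >= 0 else -mag - 1)


def assign_lat_bands(palaeolat: pd.Series | np.ndarray) -> np.ndarray:
    """Vectorized :func:`assign_lat_band`; returns integer band indices."""
    lat = np.asarray(palaeolat, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(np.abs(lat) > 90):
        raise ValidationError("palaeolatitude outside [-90, 90]")
    mag = np.minimum((np.abs(lat) // BAND_WIDTH).astype(int), 5)
    return np.where(lat >= 0, mag, -mag - 1)


def assign_time_bin(max_ma: float, min_ma: float, scheme: TimeBinScheme) -> str | None:
    """Bin containing the age-range midpoint; boundary ties go to the older bin.

    Returns ``None`` when the midpoint falls outside every bin.
    """
    if max_ma < min_ma:
        raise ValidationError(f"inverted age range {max_ma} < {min_ma}")
    mid = (max_ma + min_ma) / 2
    for i, b in enumerate(scheme.bins):
        upper_closed = i == 0  # oldest bin includes its older edge
        if (mid < b.max_ma or (upper_closed and mid == b.max_ma)) and mid >= b.min_ma:
            return b.label
    return None


def assign_time_bins(df: pd.DataFrame, scheme: TimeBinScheme) -> pd.Series:
    mid = (df["max_ma"] + df["min_ma"]) / 2
    edges = [b.max_ma for b in scheme.bins] + [scheme.min_ma]
    labels = pd.Series(pd.NA, index=df.index, dtype="string")
    for i, b in enumerate(scheme.bins):
        if i == 0:
            mask = (mid <= b.max_ma) & (mid >= b.min_ma)
        else:
            mask = (mid < b.max_ma) & (mid >= b.min_ma)
        labels[mask] = b.label
    return labels


def cell_keys(table: OccurrenceTable, scheme: TimeBinScheme) -> pd.DataFrame:
    """Per-record (bin, band_index) keys aligned to ``table.df``."""
    return pd.DataFrame(
        {
            "bin": assign_time_bins(table.df, scheme).values,
            "band_index": assign_lat_bands(table.df["palaeolat"]),
        },
        index=table.df.index,
    )


def tabulate_cells(
    turtles: OccurrenceTable,
    scheme: TimeBinScheme,
    tetrapods: OccurrenceTable | None = None,
    area15: pd.DataFrame | None = None,
    formation_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Tabulate one row per (bin, band) cell holding a turtle occurrence.

    Columns: bin, band_index, band_lower, band_upper, G (distinct genera),
    O (occurrences), C (distinct collections), TurtBF (distinct resolved
    formation labels), TetBC (distinct tetrapod collections in the cell; NaN
    when no tetrapod table is supplied), NMA and G_per_logNMA when a
    15-degree area table is supplied.  Unbinned occurrences (midpoint
    outside the scheme) are logged, and the cell rows account for every
    binned occurrence.
    """
    from .pbdb_io import resolve_formation_labels  # local to avoid cycle at import

    keys = cell_keys(turtles, scheme)
    if formation_labels is None:
        formation_labels = resolve_formation_labels(turtles, cell_keys=keys)

    df = turtles.df.assign(
        bin=keys["bin"], band_index=keys["band_index"], turtbf_label=formation_labels
    )
    unbinned = df["bin"].isna()
    if unbinned.any():
        turtles.log(f"{int(unbinned.sum())} occurrences outside {scheme.name} bins (unbinned)")
    df = df[~unbinned]

    grouped = df.groupby(["bin", "band_index"], observed=True)
    cells = grouped.agg(
        G=("genus", "nunique"),
        O=("occurrence_id", "size"),
        C=("collection_id", "nunique"),
        TurtBF=("turtbf_label", "nunique"),
    ).reset_index()

    if tetrapods is not None:
        tkeys = cell_keys(tetrapods, scheme)
        tdf = tetrapods.df.assign(bin=tkeys["bin"], band_index=tkeys["band_index"])
        tet = (
            tdf.dropna(subset=["bin"])
            .groupby(["bin", "band_index"], observed=True)["collection_id"]
            .nunique()
            .rename("TetBC")
            .reset_index()
        )
        cells = cells.merge(tet, on=["bin", "band_index"], how="left")
        cells["TetBC"] = cells["TetBC"].fillna(0).astype(int)
    else:
        cells["TetBC"] = np.nan

    cells["band_lower"] = cells["band_index"] * BAND_WIDTH
    cells["band_upper"] = cells["band_lower"] + BAND_WIDTH

    if area15 is not None:
        cells = cells.merge(
            area15[["bin", "band_index", "nma_km2"]], on=["bin", "band_index"], how="left"
        )
        cells = cells.rename(columns={"nma_km2": "NMA"})
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = genera_per_log_area_series(cells["G"], cells["NMA"])
        cells["G_per_logNMA"] = ratio
    else:
        cells["NMA"] = np.nan
        cells["G_per_logNMA"] = np.nan

    order = ["bin", "band_index", "band_lower", "band_upper", "G", "O", "C",
             "TurtBF", "TetBC", "NMA", "G_per_logNMA"]
    cells["bin"] = pd.Categorical(cells["bin"], categories=scheme.labels, ordered=True)
    return cells.sort_values(["bin", "band_index"]).reset_index(drop=True)[order]


def hemisphere_genus_counts(
    table: OccurrenceTable,
    era: str,
    scheme: TimeBinScheme | None = None,
    use_palaeolongitude: bool = True,
) -> tuple[int, int]:
    """Distinct Northern-Hemisphere genera east (lng >= 0) vs west (lng < 0).

    A genus recorded in both halves counts in both.  ``era`` is a label of
    the era scheme (Triassic / Jurassic / Cretaceous) by default.
    """
    scheme = scheme or load_scheme("era")
    if era not in scheme.labels:
        raise ConfigurationError(f"era {era!r} not in scheme {scheme.name}")
    df = table.df
    bins = assign_time_bins(df, scheme)
    lng = df["palaeolng"] if use_palaeolongitude else df.get("lng", df["palaeolng"])
    north = (df["palaeolat"] > 0) & (bins == era) & lng.notna()
    east = int(df.loc[north & (lng >= 0), "genus"].nunique())
    west = int(df.loc[north & (lng < 0), "genus"].nunique())
    return east, west


def aggregate_nma(area5: pd.DataFrame, scheme: TimeBinScheme) -> pd.DataFrame:
    """Aggregate 5-degree stage areas to 15-degree, per-bin geometric means.

    ``area5`` columns: ``stage``, ``stage_max_ma``, ``stage_min_ma`` (or a
    pre-assigned ``bin`` column), ``band_lower_5``, ``area_km2``.  Per 15deg
    band: sum the three constituent 5-degree areas within each stage, then
    take the geometric mean of the stage sums across the bin's stages.  A
    zero stage sum makes the geometric mean 0 and flags the cell degenerate.
    """
    df = area5.copy()
    if "bin" not in df.columns:
        if not {"stage_max_ma", "stage_min_ma"} <= set(df.columns):
            raise ConfigurationError(
                "area table needs either a 'bin' column or stage_max_ma/stage_min_ma"
            )
        df["bin"] = assign_time_bins(
            df.rename(columns={"stage_max_ma": "max_ma", "stage_min_ma": "min_ma"}), scheme
        )
    if df["area_km2"].lt(0).any():
        raise ValidationError("negative area")
    df = df.dropna(subset=["bin"])
    df["band_index"] = np.floor(df["band_lower_5"] / BAND_WIDTH + 1e-9).astype(int)

    per_band = df.groupby(["bin", "stage", "band_index"], observed=True).agg(
        stage_sum=("area_km2", "sum"), n5=("area_km2", "size")
    )
    if (per_band["n5"] != 3).any():
        incomplete = per_band[per_band["n5"] != 3].index.tolist()
        raise ValidationError(f"stages missing 5-degree bands for cells {incomplete[:5]}")

    def _gmean(values: pd.Series) -> float:
        if (values == 0).any():
            return 0.0
        return float(gmean(values))

    out = (
        per_band.reset_index()
        .groupby(["bin", "band_index"], observed=True)["stage_sum"]
        .agg(nma_km2=_gmean, degenerate=lambda v: bool((v == 0).any()))
        .reset_index()
    )
    return out


def genera_per_log_area(G: int, nma_km2: float) -> float:
    """Richness per decade of non-marine area: G / log10(NMA); needs NMA > 1 km2."""
    if not nma_km2 > 1:
        raise ValidationError(f"NMA must exceed 1 km2 (got {nma_km2})")
    if G < 0:
        raise ValidationError("negative richness")
    return float(G / np.log10(nma_km2))


def genera_per_log_area_series(G: pd.Series, nma: pd.Series) -> pd.Series:
    """Vectorized ratio; cells with NMA <= 1 km2 (undefined) come back NaN."""
    nma_vals = pd.to_numeric(nma, errors="coerce")
    out = pd.Series(np.nan, index=G.index, dtype=float)
    ok = nma_vals > 1
    out[ok] = G[ok] / np.log10(nma_vals[ok])
    return out
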