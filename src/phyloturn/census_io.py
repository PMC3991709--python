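"""Reading, validating and demographically classifying two-census stem tables.

A census is represented as a :class:`pandas.DataFrame` with the canonical
columns ``tag, species, x, y, dbh, status`` — one row per tagged stem.
Coordinates are in meters from the plot's lower-left corner, DBH in cm,
and ``status`` is one of ``alive``, ``dead`` or ``absent``.  A
:class:`CensusPair` holds the two aligned censuses plus plot dimensions, and
:func:`classify_demographics` partitions tags into survivors, deaths and
recruits — the raw material for the demographic null model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = ("tag", "species", "x", "y", "dbh", "status")
VALID_STATUS = ("alive", "dead", "absent")


class CensusError(ValueError):
    """Malformed or inconsistent census data."""


@dataclass(frozen=True)
class CensusPair:
    """Two aligned censuses of one mapped plot.

    Parameters
    ----------
    census1, census2
        Stem tables (canonical columns) for the first and second census.
    plot_dims
        ``(width, height)`` of the plot in meters.
    dates
        Labels for the two censuses (e.g. years).
    """

    census1: pd.DataFrame
    census2: pd.DataFrame
    plot_dims: tuple[float, float]
    dates: tuple[str, str] = ("t1", "t2")

    def __post_init__(self) -> None:
        for df in (self.census1, self.census2):
            missing = set(CANONICAL_COLUMNS) - set(df.columns)
            if missing:
                raise CensusError(f"census table missing columns: {sorted(missing)}")

    def species_pool(self) -> list[str]:
        """Sorted union of species alive in either census."""
        s1 = self.census1.loc[self.census1.status == "alive", "species"]
        s2 = self.census2.loc[self.census2.status == "alive", "species"]
        return sorted(set(s1) | set(s2))


@dataclass
class Demographics:
    """Exhaustive, disjoint partition of stem tags over the census interval."""

    survivors: np.ndarray
    deaths: np.ndarray
    recruits: np.ndarray
    log: dict = field(default_factory=dict)


def read_census_table(
    path: str | Path,
    plot_dims: tuple[float, float],
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read one census from a delimited text file and validate it.

    The file must be CSV or TSV (``.tsv``/``.txt`` extension, or gzip of
    either) with a header row providing the canonical column names, or names
    mapped to canonical via ``column_map`` (``{file_column: canonical}``).

    Raises
    ------
    CensusError
        On missing columns, duplicate tags, coordinates outside
        ``plot_dims``, unrecognized status codes, or an alive stem with
        missing DBH or DBH < 1 cm.
    """
    path = Path(path)
    name = path.name.removesuffix(".gz")
    sep = "\t" if name.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(CANONICAL_COLUMNS) - set(df.columns)
    if missing:
        raise CensusError(f"{path}: missing columns {sorted(missing)}")
    df = df.loc[:, list(CANONICAL_COLUMNS)].copy()
    df["tag"] = df["tag"].astype(str)
    df["species"] = df["species"].astype(str)
    return validate_census(df, plot_dims, source=str(path))


def validate_census(
    df: pd.DataFrame, plot_dims: tuple[float, float], source: str = "census"
) -> pd.DataFrame:
    """Validate a canonical-column census table in place and return it."""
    width, height = plot_dims
    dup = df["tag"].duplicated()
    if dup.any():
        raise CensusError(f"{source}: duplicate tags {df.loc[dup, 'tag'].tolist()[:5]}")
    df["status"] = df["status"].astype(str).str.strip().str.lower()
    bad_status = ~df["status"].isin(VALID_STATUS)
    if bad_status.any():
        rows = (df.index[bad_status] + 2).tolist()[:5]
        raise CensusError(f"{source}: unrecognized status at file line(s) {rows}")
    present = df["status"] != "absent"
    for axis, bound in (("x", width), ("y", height)):
        vals = df.loc[present, axis].to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals < 0) | (vals > bound)
        if bad.any():
            line = int(df.index[present][bad][0]) + 2
            raise CensusError(f"{source}: coordinate {axis} outside [0, {bound}] at file line {line}")
    alive = df["status"] == "alive"
    dbh = pd.to_numeric(df["dbh"], errors="coerce")
    df["dbh"] = dbh
    bad_dbh = alive & (dbh.isna() | (dbh < 1.0))
    if bad_dbh.any():
        line = int(df.index[bad_dbh][0]) + 2
        raise CensusError(f"{source}: alive stem with missing or <1 cm DBH at file line {line}")
    return df


def write_census_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a census in the canonical dialect (CSV, stable column order)."""
    df.loc[:, list(CANONICAL_COLUMNS)].to_csv(path, index=False)


def read_species_table(path: str | Path) -> pd.DataFrame:
    """Read the species table (CSV): ``species, growth_form`` + trait columns."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise CensusError(f"{path}: species table needs a 'species' column")
    df["species"] = df["species"].astype(str)
    if "growth_form" in df.columns:
        df["growth_form"] = df["growth_form"].str.strip().str.lower()
        bad = ~df["growth_form"].isin(["tree", "shrub"])
        if bad.any():
            raise CensusError(f"{path}: growth_form must be tree|shrub")
    return df.set_index("species")


def prune_to_species(pair: CensusPair, species: list[str] | set[str]) -> CensusPair:
    """Drop stems whose species is outside ``species`` (e.g. phylogeny tips).

    Silent pruning distorts abundances, so this is opt-in; the number of
    stems removed per census is recorded in the returned pair's tables'
    ``attrs['n_pruned']``.
    """
    keep = set(species)
    out = []
    for df in (pair.census1, pair.census2):
        mask = df["species"].isin(keep)
        sub = df.loc[mask].reset_index(drop=True)
        sub.attrs["n_pruned"] = int((~mask).sum())
        out.append(sub)
    return CensusPair(out[0], out[1], pair.plot_dims, pair.dates)


def classify_demographics(pair: CensusPair) -> Demographics:
    """Partition stems into survivors, deaths and recruits.

    survivors: alive in both censuses.  deaths: alive at census 1, dead or
    absent at census 2.  recruits: alive at census 2, absent from census 1
    (crossed the 1 cm DBH inclusion threshold during the interval).

    Raises
    ------
    CensusError
        If a stem is dead at census 1 but alive at census 2.
    """
    c1, c2 = pair.census1, pair.census2
    alive1 = set(c1.loc[c1.status == "alive", "tag"])
    dead1 = set(c1.loc[c1.status == "dead", "tag"])
    alive2 = set(c2.loc[c2.status == "alive", "tag"])
    zombies = dead1 & alive2
    if zombies:
        raise CensusError(f"stems dead at census 1 but alive at census 2: {sorted(zombies)[:5]}")
    survivors = np.array(sorted(alive1 & alive2))
    deaths = np.array(sorted(alive1 - alive2))
    recruits = np.array(sorted(alive2 - alive1 - dead1))
    return Demographics(
        survivors=survivors,
        deaths=deaths,
        recruits=recruits,
        log={"n_alive_c1": len(alive1), "n_alive_c2": len(alive2)},
    )
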