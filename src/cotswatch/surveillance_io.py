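"""Tabular input/output for the surveillance pipeline.

Canonical carriers are headered UTF-8 CSV files; in memory each table is a
validated :class:`pandas.DataFrame`.  This module owns the reef/sector
registry, the outbreak-threshold configuration, and the read/validate/write
paths used by every other stage.

CSV schemas
-----------
``tows.csv``      reef_id,sector_id,year,program,tow_index,cover_category,cots_count
``culls.csv``     reef_id,year,hours
``registry.csv``  reef_id,sector_id,sector_order,uses_established_inception
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PROGRAMS = ("LTMP", "RJFMP", "CONTROL")

TOW_COLUMNS = [
    "reef_id",
    "sector_id",
    "year",
    "program",
    "tow_index",
    "cover_category",
    "cots_count",
]
CULL_COLUMNS = ["reef_id", "year", "hours"]
REGISTRY_COLUMNS = [
    "reef_id",
    "sector_id",
    "sector_order",
    "uses_established_inception",
]

#: default manta-tow swath area in square metres (~200 m x ~10 m per tow)
DEFAULT_TOW_AREA_M2 = 2000.0


class SchemaError(ValueError):
    """A file does not match its declared schema or violates hard invariants."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Outbreak thresholds and window conventions.

    Densities are COTS per manta tow.  ``potential``/``established``/``severe``
    grade reef and sector status; an outbreak window requires persistence above
    the inception threshold for ``persistence_years`` consecutive years and is
    closed by ``decline_years`` consecutive years below ``potential``.
    ``depletion_fraction`` is the maximum tolerated relative coral-cover loss
    for culling to count as suppression rather than prey depletion.
    """

    potential: float = 0.11
    established: float = 0.22
    severe: float = 1.0
    persistence_years: int = 2
    decline_years: int = 2
    reef_outbreak_threshold: float = 0.11
    depletion_fraction: float = 0.25
    rounding: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.potential < self.established < self.severe):
            raise ValueError(
                "thresholds must satisfy 0 < potential < established < severe"
            )
        if self.persistence_years < 1 or self.decline_years < 1:
            raise ValueError("persistence_years and decline_years must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "ThresholdConfig":
        """Load a YAML key-value file; unknown keys are a hard error."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown threshold config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class Registry:
    """Reef-to-sector mapping plus per-sector wave ordering and overrides.

    ``sector_order`` positions sectors along the outbreak wave path (1..S).
    ``uses_established_inception`` marks sectors whose historically larger
    outbreaks make the established threshold the inception criterion.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in REGISTRY_COLUMNS if c not in t.columns]
        if missing:
            raise SchemaError(f"registry missing columns: {missing}")
        if t["reef_id"].duplicated().any():
            dupes = sorted(t.loc[t["reef_id"].duplicated(), "reef_id"].unique())
            raise SchemaError(f"reefs mapped to multiple sectors: {dupes}")
        orders = t.drop_duplicates("sector_id")["sector_order"].to_numpy()
        if sorted(orders) != list(range(1, len(orders) + 1)):
            raise SchemaError("sector_order values must be a permutation of 1..S")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Registry":
        table = pd.read_csv(path)
        if "uses_established_inception" in table.columns:
            table["uses_established_inception"] = table[
                "uses_established_inception"
            ].astype(bool)
        return cls(table=table)

    @property
    def reef_to_sector(self) -> dict:
        return dict(zip(self.table["reef_id"], self.table["sector_id"]))

    @property
    def sectors(self) -> list:
        """Sector ids in wave order."""
        t = self.table.drop_duplicates("sector_id").sort_values("sector_order")
        return list(t["sector_id"])

    def uses_established_inception(self, sector_id) -> bool:
        t = self.table
        rows = t.loc[t["sector_id"] == sector_id, "uses_established_inception"]
        if rows.empty:
            raise KeyError(f"unknown sector: {sector_id!r}")
        return bool(rows.iloc[0])

    def to_csv(self, path: str | Path) -> None:
        out = self.table.sort_values(["sector_order", "reef_id"])
        out.to_csv(path, index=False, columns=REGISTRY_COLUMNS)


def read_tow_records(path: str | Path, registry: Registry) -> pd.DataFrame:
    """Read and validate manta-tow records.

    Rows with an out-of-range cover category are rejected (counted and
    logged); an unknown reef or a duplicate (reef, year, program, tow_index)
    key is a hard error.  Returns the validated table with reefs resolved to
    sectors via the registry and a ``tow_area_m2`` column attached.
    """
    df = pd.read_csv(path)
    required = [c for c in TOW_COLUMNS if c != "sector_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing tow columns {missing}")

    unknown = sorted(set(df["reef_id"]) - set(registry.reef_to_sector))
    if unknown:
        raise SchemaError(f"{path}: unknown reef_id values {unknown}")

    bad_cat = ~df["cover_category"].isin(range(6))
    bad_count = df["cots_count"] < 0
    rejects = bad_cat | bad_count
    if rejects.any():
        logger.warning(
            "%s: rejected %d rows (cover_category outside 0-5: %d, "
            "negative cots_count: %d)",
            path,
            int(rejects.sum()),
            int(bad_cat.sum()),
            int(bad_count.sum()),
        )
    df = df.loc[~rejects].copy()

    key = ["reef_id", "year", "program", "tow_index"]
    if df.duplicated(key).any():
        dupes = df.loc[df.duplicated(key, keep=False), key].drop_duplicates()
        raise SchemaError(f"{path}: duplicate tow keys\n{dupes.to_string(index=False)}")
    bad_prog = sorted(set(df["program"]) - set(PROGRAMS))
    if bad_prog:
        raise SchemaError(f"{path}: unknown programs {bad_prog}")

    df["sector_id"] = df["reef_id"].map(registry.reef_to_sector)
    if "tow_area_m2" not in df.columns:
        df["tow_area_m2"] = DEFAULT_TOW_AREA_M2
    df.attrs["n_rejected"] = int(rejects.sum())
    cols = TOW_COLUMNS + ["tow_area_m2"]
    return df[cols].reset_index(drop=True)


def read_cull_log(path: str | Path, registry: Registry) -> pd.DataFrame:
    """Read diver bottom-hours and aggregate to one record per (reef, year).

    Totals are conserved by the aggregation.  Negative hours or an unknown
    reef are hard errors; an empty file yields an empty table with a warning.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=CULL_COLUMNS)
    missing = [c for c in CULL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing cull columns {missing}")
    if df.empty:
        logger.warning("%s: empty cull log", path)
        out = df.copy()
        out["sector_id"] = pd.Series(dtype=object)
        return out[["reef_id", "sector_id", "year", "hours"]]
    if (df["hours"] < 0).any():
        raise SchemaError(f"{path}: negative culling hours")
    unknown = sorted(set(df["reef_id"]) - set(registry.reef_to_sector))
    if unknown:
        raise SchemaError(f"{path}: unknown reef_id values {unknown}")
    out = (
        df.groupby(["reef_id", "year"], as_index=False)["hours"]
        .sum()
        .sort_values(["reef_id", "year"])
        .reset_index(drop=True)
    )
    out.insert(1, "sector_id", out["reef_id"].map(registry.reef_to_sector))
    return out


def write_table(
    records: pd.DataFrame,
    path: str | Path,
    *,
    sort_by: list[str] | None = None,
    rounding: int | None = None,
) -> None:
    """Write a result table deterministically.

    Rows are sorted by ``sort_by`` (default: all non-float columns in order),
    floats are rounded to ``rounding`` decimals, and an empty result produces
    a header-only file.
    """
    if records is None:
        raise ValueError("records must not be None")
    out = records.copy()
    if sort_by is None:
        sort_by = [
            c
            for c in out.columns
            if not pd.api.types.is_float_dtype(out[c])
        ]
    if sort_by and not out.empty:
        out = out.sort_values(sort_by, kind="mergesort")
    if rounding is not None:
        for c in out.columns:
            if pd.api.types.is_float_dtype(out[c]):
                out[c] = out[c].round(rounding)
    out.to_csv(path, index=False)
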