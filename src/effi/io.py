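"""Reading, validation and harmonization of department-year count tables.

The pipeline consumes four long-format CSV tables — births by maternal age
band, health-insurance affiliations by category, domestic-violence reports by
victim class, and deaths by cause — each with columns
``department, year, category, count``.  This module canonicalizes department
labels, pivots the tables onto a rectangular department x year grid of named
count aggregates, and fills missing cells by linear interpolation along the
year axis (nearest-value extension at the series edges).

Missing is never zero: a cell absent from the input is flagged ``missing``
and later ``imputed``; an explicit 0 count is data and stays observed.
"""

from __future__ import annotations

import re
import unicodedata
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DuplicateKeyError,
    ExclusionWarning,
    SchemaError,
    UnimputableError,
)

#: Count aggregates each source table must provide (category column values).
SOURCE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "births": ("births_le14", "births_15_19"),
    "affiliations": (
        "aff_women_10_14",
        "aff_women_15_19",
        "aff_women_total",
        "aff_indigenous",
        "aff_migrant",
        "aff_subsidized",
    ),
    "violence": ("dv_total", "dv_women_male_perp", "dv_children_le18"),
    "deaths": ("deaths_total", "deaths_suicide", "deaths_homicide_le19"),
}

ALL_AGGREGATES: tuple[str, ...] = tuple(
    c for cats in SOURCE_CATEGORIES.values() for c in cats
)

_REQUIRED_COLUMNS = ("department", "year", "category", "count")

OBSERVED, MISSING, IMPUTED = "observed", "missing", "imputed"


def canonical_department(name: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Canonicalize a department label: uppercase, strip diacritics, collapse
    whitespace, then apply the optional alias map (keys canonicalized too)."""
    s = unicodedata.normalize("NFKD", str(name))
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    s = re.sub(r"\s+", " ", s).strip().upper()
    if alias_map:
        canon_aliases = {
            canonical_department(k): v.upper() if isinstance(v, str) else v
            for k, v in alias_map.items()
        }
        s = canon_aliases.get(s, s)
    return s


@dataclass(frozen=True)
class RawRecordTable:
    """One validated long-format count table from a single source."""

    source: str
    records: pd.DataFrame  # columns: department, year, category, count

    def __post_init__(self) -> None:
        if self.source not in SOURCE_CATEGORIES:
            raise ConfigError(
                f"unknown source {self.source!r}; expected one of "
                f"{sorted(SOURCE_CATEGORIES)}"
            )


def as_record_table(
    frame: pd.DataFrame,
    source: str,
    column_map: Mapping[str, str] | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> RawRecordTable:
    """Validate an in-memory long-format frame and canonicalize departments.

    ``column_map`` maps the logical names (department/year/category/count) to
    the actual headers in ``frame``.
    """
    if source not in SOURCE_CATEGORIES:
        raise ConfigError(
            f"unknown source {source!r}; expected one of {sorted(SOURCE_CATEGORIES)}"
        )
    colmap = dict(column_map or {})
    rename = {colmap.get(k, k): k for k in _REQUIRED_COLUMNS}
    df = frame.rename(columns=rename)
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(
            f"{source} table is missing column(s): {', '.join(missing_cols)}"
        )
    df = df[list(_REQUIRED_COLUMNS)].copy()

    df["department"] = [canonical_department(d, alias_map) for d in df["department"]]
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    counts = pd.to_numeric(df["count"], errors="raise")
    bad = counts < 0
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"negative count in {source} table at row {row}: "
            f"{df.loc[row, 'department']} {df.loc[row, 'year']} "
            f"{df.loc[row, 'category']} -> {counts.loc[row]}"
        )
    df["count"] = counts.astype(float)

    dup = df.duplicated(subset=["department", "year", "category"], keep=False)
    if dup.any():
        keys = (
            df.loc[dup, ["department", "year", "category"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise DuplicateKeyError(
            f"duplicate (department, year, category) keys in {source} table: "
            + "; ".join(map(str, keys))
        )
    return RawRecordTable(source=source, records=df.reset_index(drop=True))


def read_record_table(
    path,
    source: str,
    column_map: Mapping[str, str] | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> RawRecordTable:
    """Read and validate one long-format CSV count table."""
    frame = pd.read_csv(path)
    return as_record_table(frame, source, column_map=column_map, alias_map=alias_map)


def write_record_table(table: RawRecordTable, path) -> None:
    table.records.to_csv(path, index=False)


@dataclass
class HarmonizedPanel:
    """Rectangular department x year grid of count aggregates.

    ``data`` holds the counts (NaN = missing); ``provenance`` holds a parallel
    grid of {observed, missing, imputed} flags.
    """

    data: pd.DataFrame
    provenance: pd.DataFrame

    @property
    def departments(self) -> list[str]:
        return list(self.data.index.get_level_values("department").unique())

    @property
    def years(self) -> list[int]:
        return list(self.data.index.get_level_values("year").unique())

    def to_csv(self, data_path, provenance_path=None) -> None:
        self.data.to_csv(data_path)
        if provenance_path is not None:
            self.provenance.to_csv(provenance_path)

    @classmethod
    def from_csv(cls, data_path, provenance_path=None) -> "HarmonizedPanel":
        data = pd.read_csv(data_path, index_col=["department", "year"])
        if provenance_path is not None:
            prov = pd.read_csv(provenance_path, index_col=["department", "year"])
        else:
            prov = data.notna().map(lambda ok: OBSERVED if ok else MISSING)
        return cls(data=data, provenance=prov)


def harmonize(
    tables: Iterable[RawRecordTable],
    departments: Sequence[str],
    years: Sequence[int],
    category_map: Mapping[str, str] | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> HarmonizedPanel:
    """Pivot validated record tables onto the configured department x year grid.

    Cells absent from the input are marked missing (NaN), never zero.
    Departments present in the data but not in the configured list are
    excluded with a warning; a required aggregate absent from every table is
    a schema error.
    """
    if not departments or not len(years):
        raise ConfigError("departments and years must be non-empty")
    departments = [canonical_department(d, alias_map) for d in departments]
    years = sorted(int(y) for y in years)
    catmap = dict(category_map or {})

    grid = pd.MultiIndex.from_product(
        [departments, years], names=["department", "year"]
    )
    data = pd.DataFrame(index=grid, columns=list(ALL_AGGREGATES), dtype=float)

    for table in tables:
        df = table.records.copy()
        df["category"] = df["category"].map(lambda c: catmap.get(c, c))
        known = df["category"].isin(SOURCE_CATEGORIES[table.source])
        if not known.all():
            unknown = sorted(df.loc[~known, "category"].unique())
            warnings.warn(
                f"{table.source}: ignoring unknown categories {unknown}",
                ExclusionWarning,
                stacklevel=2,
            )
            df = df[known]
        extra = ~df["department"].isin(departments)
        if extra.any():
            dropped = sorted(df.loc[extra, "department"].unique())
            warnings.warn(
                f"{table.source}: excluding departments not in configured list: "
                f"{dropped}",
                ExclusionWarning,
                stacklevel=2,
            )
            df = df[~extra]
        df = df[df["year"].isin(years)]
        wide = df.pivot_table(
            index=["department", "year"],
            columns="category",
            values="count",
            aggfunc="first",
        )
        for col in wide.columns:
            data.loc[wide.index, col] = wide[col]

    absent = [c for c in ALL_AGGREGATES if data[c].isna().all()]
    if absent:
        raise SchemaError(
            "required aggregates absent from all input tables: " + ", ".join(absent)
        )

    provenance = data.notna().map(lambda ok: OBSERVED if ok else MISSING)
    return HarmonizedPanel(data=data, provenance=provenance)


def impute_linear(panel: HarmonizedPanel) -> HarmonizedPanel:
    """Fill missing cells per (department, column) series along the year axis.

    Interior gaps are linearly interpolated against the year values; leading
    and trailing gaps take the nearest observed value (linear interpolation is
    undefined there).  Observed cells are never changed; filled cells are
    flagged ``imputed``.  A series with no observed value at all raises
    :class:`UnimputableError`.
    """
    data = panel.data.copy()
    prov = panel.provenance.copy()
    for dept in panel.departments:
        block = data.loc[dept]
        for col in data.columns:
            s = block[col]
            if not s.isna().any():
                continue
            if s.isna().all():
                raise UnimputableError(
                    f"department {dept!r}, column {col!r}: no observed values"
                )
            filled = (
                s.interpolate(method="index", limit_area="inside").ffill().bfill()
            )
            was_missing = s.isna()
            idx = pd.MultiIndex.from_product(
                [[dept], s.index], names=["department", "year"]
            )
            data.loc[idx, col] = filled.to_numpy()
            prov.loc[idx[np.asarray(was_missing)], col] = IMPUTED
    return HarmonizedPanel(data=data, provenance=prov)
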