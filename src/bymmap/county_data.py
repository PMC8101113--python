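"""County-level incidence tables: loading, validation, rates, expected counts.

The central container is :class:`CountyTable`, an ordered collection of
:class:`CountyRecord` objects — one per areal unit — holding the observed case
count ``Y_i``, the male population at risk, a named covariate vector, and
(once filled) the expected count ``E_i`` used as the Poisson offset in
disease-mapping models.

Expected counts use *internal (indirect) standardization*: every area is
assigned the pooled study rate, ``E_i = population_i * (sum Y) / (sum pop)``,
so that ``sum E_i == sum Y_i`` exactly and the standardized morbidity ratio
``SMR_i = Y_i / E_i`` averages to one when weighted by ``E_i``.

A transcription of the 2012-2016 Georgia county table (159 counties, male
population, mean annual prostate-cancer case counts, and eight socio-economic
covariates) ships with the package and is reachable through the fixture token
``"georgia_2012_2016"``.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "COVARIATE_COLUMNS",
    "PERCENT_COLUMNS",
    "GEORGIA_FIXTURE",
    "CountyRecord",
    "CountyTable",
    "crude_rate",
    "load_county_table",
    "write_csv",
    "with_period_totals",
    "compute_expected_counts",
    "smr",
    "summarize_table",
]

logger = logging.getLogger(__name__)

#: Covariate columns recognised in input CSVs, in canonical order.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "pct_65plus",
    "pct_black",
    "pct_bachelors",
    "pct_poverty",
    "pct_foreign_born",
    "pct_rural",
    "pct_unemployed",
    "median_family_income",
)

#: Covariates expressed as percentages (validated to lie in [0, 100]).
PERCENT_COLUMNS: tuple[str, ...] = COVARIATE_COLUMNS[:-1]

#: Token accepted by :func:`load_county_table` for the bundled Georgia table.
GEORGIA_FIXTURE = "georgia_2012_2016"

_REQUIRED_COLUMNS = ("area_id", "cases", "population")


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class ValidationError(ValueError):
    """A row violates a domain invariant (named in the message)."""


@dataclass
class CountyRecord:
    """One areal unit: identifiers, counts, covariates and offsets.

    ``cases`` is the observed count on whatever time basis the table uses
    (the Georgia fixture stores mean annual cases as printed; see
    :func:`with_period_totals`).  ``expected`` is ``None`` until
    :func:`compute_expected_counts` fills it.
    """

    area_id: str
    cases: float
    population: int
    covariates: dict[str, float] = field(default_factory=dict)
    crude_rate: float = 0.0
    expected: float | None = None
    missing_mask: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValidationError(
                f"non-positive population for area {self.area_id!r}: "
                f"{self.population}"
            )
        if self.cases < 0:
            raise ValidationError(
                f"negative case count for area {self.area_id!r}: {self.cases}"
            )
        for name in PERCENT_COLUMNS:
            val = self.covariates.get(name)
            if val is not None and not 0.0 <= val <= 100.0:
                raise ValidationError(
                    f"{name}={val} outside [0, 100] for area {self.area_id!r}"
                )


@dataclass
class CountyTable:
    """Ordered collection of :class:`CountyRecord` with period metadata."""

    records: list[CountyRecord]
    period_years: int = 1
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.area_id in seen:
                raise ValidationError(f"duplicate area_id {rec.area_id!r}")
            seen.add(rec.area_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CountyRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> CountyRecord:
        if isinstance(key, str):
            for rec in self.records:
                if rec.area_id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def area_ids(self) -> list[str]:
        return [rec.area_id for rec in self.records]

    def cases_array(self) -> np.ndarray:
        return np.array([rec.cases for rec in self.records], dtype=float)

    def population_array(self) -> np.ndarray:
        return np.array([rec.population for rec in self.records], dtype=float)

    def expected_array(self) -> np.ndarray:
        vals = [rec.expected for rec in self.records]
        if any(v is None for v in vals):
            raise ValidationError(
                "expected counts not filled; run compute_expected_counts first"
            )
        return np.array(vals, dtype=float)

    def covariate_matrix(
        self,
        names: Iterable[str],
        missing_policy: str = "impute_mean",
    ) -> tuple[np.ndarray, list[str]]:
        """Covariate design matrix (n, p) in record order.

        Missing cells are filled with the column mean over observed areas
        (``impute_mean``, with a logged warning) or rejected (``error``).
        Returns the matrix and the list of area_ids retained (always all of
        them under ``impute_mean``).
        """
        names = list(names)
        cols = []
        for name in names:
            vals = np.array(
                [rec.covariates.get(name, np.nan) for rec in self.records],
                dtype=float,
            )
            miss = np.isnan(vals)
            if miss.any():
                if miss.all():
                    raise ValidationError(
                        f"covariate {name} missing for every area"
                    )
                if missing_policy == "impute_mean":
                    fill = float(np.nanmean(vals))
                    offenders = [
                        self.records[i].area_id for i in np.flatnonzero(miss)
                    ]
                    logger.warning(
                        "covariate %s missing for %s; imputing column mean %.4g",
                        name, ", ".join(offenders), fill,
                    )
                    vals = np.where(miss, fill, vals)
                else:
                    raise ValidationError(
                        f"covariate {name} missing for "
                        f"{[self.records[i].area_id for i in np.flatnonzero(miss)]}"
                    )
            cols.append(vals)
        X = np.column_stack(cols) if cols else np.empty((self.n, 0))
        return X, self.area_ids

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "area_id": rec.area_id,
                "cases": rec.cases,
                "population": rec.population,
                "crude_rate": rec.crude_rate,
            }
            for name in COVARIATE_COLUMNS:
                row[name] = rec.covariates.get(name, np.nan)
            if rec.expected is not None:
                row["expected"] = rec.expected
            rows.append(row)
        return pd.DataFrame(rows)


def _covariate_columns(table: CountyTable) -> list[str]:
    """Covariate columns present anywhere in the table, canonical order first."""
    present = {c for r in table for c in (*r.covariates, *r.missing_mask)}
    ordered = [c for c in COVARIATE_COLUMNS if c in present]
    ordered += sorted(present - set(COVARIATE_COLUMNS))
    return ordered


def crude_rate(cases: float, population: float) -> float:
    """Crude incidence rate per 100,000 population.

    Raises ``ValidationError`` for non-positive population.  No rounding is
    applied; round at presentation time.
    """
    if population <= 0:
        raise ValidationError(f"population must be positive, got {population}")
    if cases < 0:
        raise ValidationError(f"cases must be non-negative, got {cases}")
    return cases / population * 100_000.0


def _parse_cell(raw: str) -> float | None:
    raw = raw.strip()
    if raw in ("", "."):
        return None
    return float(raw.replace("$", "").replace(",", ""))


def load_county_table(
    source: str | Path,
    period_years: int | None = None,
) -> CountyTable:
    """Read a county table from CSV, or the bundled fixture by token.

    The CSV must carry ``area_id``, ``cases`` and ``population`` columns;
    covariate columns are optional and blank or ``"."`` cells are recorded in
    each record's ``missing_mask``.  ``crude_rate`` is always recomputed from
    cases and population, never trusted from the file.

    Passing the token ``"georgia_2012_2016"`` loads the packaged Georgia
    transcription (mean annual cases; ``period_years`` defaults to 5).
    """
    if str(source) == GEORGIA_FIXTURE:
        ref = resources.files("bymmap.data").joinpath("georgia_2012_2016.csv")
        with resources.as_file(ref) as path:
            table = _read_csv(Path(path))
        table.period_years = 5 if period_years is None else period_years
        table.source_label = "Georgia counties 2012-2016 (SEER-derived transcription)"
        if table.n != 159:
            raise ValidationError(
                f"Georgia fixture corrupt: {table.n} rows, expected 159"
            )
        return table
    table = _read_csv(Path(source))
    if period_years is not None:
        table.period_years = period_years
    table.source_label = str(source)
    return table


def _read_csv(path: Path) -> CountyTable:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing_cols = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing_cols:
            raise SchemaError(
                f"{path}: missing required column(s) {missing_cols}"
            )
        reserved = {"area_id", "cases", "population", "crude_rate", "expected"}
        cov_cols = [c for c in header if c not in reserved]
        records = []
        for lineno, row in enumerate(reader, start=2):
            area_id = (row["area_id"] or "").strip()
            if not area_id:
                raise ValidationError(f"{path}:{lineno}: empty area_id")
            cases = _parse_cell(row["cases"])
            pop = _parse_cell(row["population"])
            if cases is None or pop is None:
                raise ValidationError(
                    f"{path}:{lineno} ({area_id}): cases/population missing"
                )
            if pop <= 0:
                raise ValidationError(
                    f"{path}:{lineno} ({area_id}): non-positive population {pop}"
                )
            covs: dict[str, float] = {}
            mask: set[str] = set()
            for name in cov_cols:
                val = _parse_cell(row.get(name, ""))
                if val is None:
                    mask.add(name)
                else:
                    covs[name] = val
            records.append(
                CountyRecord(
                    area_id=area_id,
                    cases=cases,
                    population=int(pop),
                    covariates=covs,
                    crude_rate=crude_rate(cases, pop),
                    missing_mask=frozenset(mask),
                )
            )
    if not records:
        raise ValidationError(f"{path}: no data rows")
    return CountyTable(records=records)


def write_csv(table: CountyTable, path: str | Path) -> None:
    """Write a table in the same CSV schema ``load_county_table`` reads.

    Missing covariates round-trip as ``"."`` cells.
    """
    cov_cols = _covariate_columns(table)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = ["area_id", "cases", "population", *cov_cols, "crude_rate"]
        has_expected = all(r.expected is not None for r in table)
        if has_expected:
            header.append("expected")
        writer.writerow(header)
        for rec in table:
            cells: list[object] = [rec.area_id, _fmt(rec.cases), rec.population]
            for name in cov_cols:
                val = rec.covariates.get(name)
                cells.append("." if val is None else _fmt(val))
            cells.append(repr(rec.crude_rate))
            if has_expected:
                cells.append(repr(rec.expected))
            writer.writerow(cells)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def with_period_totals(table: CountyTable) -> CountyTable:
    """Convert per-year mean case counts into period totals.

    Returns a new table with ``cases = round(cases * period_years)`` and
    ``period_years = 1``; a no-op copy when the table is already on a
    period-total basis.
    """
    if table.period_years == 1:
        return CountyTable(
            records=[replace(r) for r in table],
            period_years=1,
            source_label=table.source_label,
        )
    records = []
    for rec in table:
        cases = float(round(rec.cases * table.period_years))
        records.append(
            replace(rec, cases=cases, crude_rate=crude_rate(cases, rec.population))
        )
    return CountyTable(
        records=records,
        period_years=1,
        source_label=f"{table.source_label} [x{table.period_years} period totals]",
    )


def compute_expected_counts(table: CountyTable) -> CountyTable:
    """Fill ``E_i`` by internal standardization against the pooled rate.

    ``E_i = population_i * (sum_j cases_j / sum_j population_j)``, so that
    ``sum E_i == sum Y_i`` to machine precision.
    """
    if table.n == 0:
        raise ValidationError("cannot standardize an empty table")
    pooled = table.cases_array().sum() / table.population_array().sum()
    records = [
        replace(rec, expected=rec.population * pooled) for rec in table
    ]
    return CountyTable(
        records=records,
        period_years=table.period_years,
        source_label=table.source_label,
    )


def smr(table: CountyTable) -> np.ndarray:
    """Standardized morbidity ratios ``Y_i / E_i`` in record order."""
    expected = table.expected_array()
    if np.any(expected <= 0):
        raise ValidationError("SMR undefined: some expected counts are zero")
    return table.cases_array() / expected


def summarize_table(table: CountyTable) -> dict[str, dict[str, float]]:
    """Per-column descriptive summaries (the analogue of a table's All row).

    Every covariate column plus cases, population and crude_rate is
    aggregated by the unweighted mean over areas with observed values —
    including ``median_family_income``, whose cell is the mean of the county
    *medians*.  Each entry reports ``mean``, ``n`` (observed areas) and
    ``n_missing``.  JSON-serializable.
    """
    if table.n == 0:
        raise ValidationError("cannot summarize an empty table")
    out: dict[str, dict[str, float]] = {}
    for name in _covariate_columns(table):
        vals = [r.covariates[name] for r in table if name in r.covariates]
        out[name] = {
            "mean": float(np.mean(vals)) if vals else math.nan,
            "n": len(vals),
            "n_missing": table.n - len(vals),
        }
    for name, arr in (
        ("cases", table.cases_array()),
        ("population", table.population_array()),
        ("crude_rate", np.array([r.crude_rate for r in table])),
    ):
        out[name] = {"mean": float(arr.mean()), "n": table.n, "n_missing": 0}
    return out


def summary_to_json(summary: Mapping[str, Mapping[str, float]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
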