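"""Shared data model, configuration, and tabular I/O.

The canonical interchange format for every stage is long-format CSV
(UTF-8, header row): one row per (country, year, item) for supply tables,
one row per (crop, country, year) for nitrogen budgets, and so on.
Wide FAOSTAT-style layouts must be melted before ingest.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("nfootprint")

#: The ten aggregated food categories used throughout the analysis.
CATEGORIES: tuple[str, ...] = (
    "cereals",
    "starchy roots",
    "oil crops and pulses",
    "vegetables",
    "fruits",
    "other plant products",
    "meat and offal",
    "milk and dairy products",
    "eggs",
    "fish and seafood",
)

PLANT_CATEGORIES: tuple[str, ...] = CATEGORIES[:6]
ANIMAL_CATEGORIES: tuple[str, ...] = CATEGORIES[6:]

#: The five religious communities modelled.
RELIGIONS: tuple[str, ...] = ("Muslim", "Hindu", "Buddhist", "Christian", "Others")

#: Category-level dietary exclusions. Hindus are treated as
#: lacto-vegetarians (plant foods plus dairy); Buddhists as vegetarians
#: (plant foods only); Muslims, Christians and the residual "Others"
#: group carry no category-wide restriction.
RELIGION_EXCLUSIONS: dict[str, frozenset[str]] = {
    "Muslim": frozenset(),
    "Hindu": frozenset({"meat and offal", "eggs", "fish and seafood"}),
    "Buddhist": frozenset(
        {"meat and offal", "eggs", "fish and seafood", "milk and dairy products"}
    ),
    "Christian": frozenset(),
    "Others": frozenset(),
}

#: The six countries of the Indian Subcontinent plus the regional label.
ISC_COUNTRIES: tuple[str, ...] = (
    "Bangladesh",
    "India",
    "Pakistan",
    "Sri Lanka",
    "Nepal",
    "Bhutan",
)
REGION_LABEL = "ISC average"

#: Decade buckets. FAO series begin in 1961, so the 1960s bucket holds
#: nine years; the last bucket is truncated at the end of the data span.
DEFAULT_DECADES: dict[str, tuple[int, int]] = {
    "1960s": (1961, 1969),
    "1970s": (1970, 1979),
    "1980s": (1980, 1989),
    "1990s": (1990, 1999),
    "2000s": (2000, 2009),
    "2010s": (2010, 2013),
}

#: Jones factor: grams of N per gram of protein (1/6.25).
DEFAULT_PROTEIN_TO_N = 0.16


class SchemaError(ValueError):
    """A required column is missing or mistyped in an input table."""


class ValidationError(ValueError):
    """A row violates a documented bound; the message names the row."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoodItem:
    """One food item on a balance sheet, mapped to an aggregated category."""

    item_id: str
    name: str
    category: str
    protein_to_n: float = DEFAULT_PROTEIN_TO_N

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown category {self.category!r} for item {self.item_id!r}"
            )
        if not 0.0 < self.protein_to_n <= 0.25:
            raise ValidationError(
                f"protein_to_n must lie in (0, 0.25], got {self.protein_to_n} "
                f"for item {self.item_id!r}"
            )


@dataclass(frozen=True)
class ReligionProfile:
    """A community's category-level food permissions and population weight."""

    religion: str
    allowed_categories: frozenset[str]
    population_weight: float

    def __post_init__(self) -> None:
        if self.religion not in RELIGIONS:
            raise ValidationError(f"unknown religion {self.religion!r}")
        unknown = self.allowed_categories - set(CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown categories {sorted(unknown)!r}")
        if not 0.0 <= self.population_weight <= 1.0:
            raise ValidationError(
                f"population_weight outside [0, 1]: {self.population_weight}"
            )

    def permits(self, category: str) -> bool:
        if category not in CATEGORIES:
            raise ValidationError(f"unknown category {category!r}")
        return category in self.allowed_categories


def default_profile(religion: str, population_weight: float) -> ReligionProfile:
    """Build a ReligionProfile from the standard exclusion rules."""
    return ReligionProfile(
        religion=religion,
        allowed_categories=frozenset(CATEGORIES) - RELIGION_EXCLUSIONS[religion],
        population_weight=population_weight,
    )


@dataclass(frozen=True)
class SupplyRecord:
    """Per-capita protein supply of one item in one country-year.

    ``protein_supply`` is g protein per capita per day, as reported on
    food balance sheets. ``self_sufficiency`` above 1 (net exporters) is
    clamped to 1 on construction so the trade blend stays a convex
    combination.
    """

    country: str
    year: int
    item_id: str
    protein_supply: float
    food_waste: float = 0.0
    self_sufficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.protein_supply < 0:
            raise ValidationError(
                f"negative protein supply {self.protein_supply} "
                f"({self.country}, {self.year}, {self.item_id})"
            )
        if not 0.0 <= self.food_waste <= 1.0:
            raise ValidationError(
                f"food_waste outside [0, 1]: {self.food_waste} "
                f"({self.country}, {self.year}, {self.item_id})"
            )
        if self.self_sufficiency < 0:
            raise ValidationError(
                f"negative self_sufficiency {self.self_sufficiency} "
                f"({self.country}, {self.year}, {self.item_id})"
            )
        if self.self_sufficiency > 1.0:
            object.__setattr__(self, "self_sufficiency", 1.0)


@dataclass
class AnalysisConfig:
    """Run-level configuration shared by every stage."""

    countries: Sequence[str] = ISC_COUNTRIES
    years: tuple[int, int] = (1961, 2013)
    decade_buckets: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DECADES)
    )
    denitrification_ratio: float = 0.0
    protein_to_n_default: float = DEFAULT_PROTEIN_TO_N
    religion_weights_source: str | None = None
    redistribute_excluded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.denitrification_ratio <= 1.0:
            raise ValidationError(
                f"denitrification_ratio outside [0, 1]: {self.denitrification_ratio}"
            )
        lo, hi = self.years
        covered: list[int] = []
        for label, (a, b) in self.decade_buckets.items():
            if a > b:
                raise ValidationError(f"decade {label!r} has empty range {(a, b)}")
            covered.extend(range(a, b + 1))
        if len(covered) != len(set(covered)):
            raise ValidationError("decade buckets overlap")
        missing = set(range(lo, hi + 1)) - set(covered)
        if missing:
            raise ValidationError(
                f"decade buckets do not cover years {sorted(missing)}"
            )


def assign_decade(year: int, config: AnalysisConfig | None = None) -> str:
    """Map a year to its decade label (e.g. 2013 -> '2010s')."""
    config = config or AnalysisConfig()
    for label, (a, b) in config.decade_buckets.items():
        if a <= year <= b:
            return label
    lo, hi = config.years
    raise ValidationError(f"year {year} outside configured range [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

SUPPLY_COLUMNS = (
    "country",
    "year",
    "item_id",
    "protein_supply",
    "food_waste",
    "self_sufficiency",
)


def _require_columns(df: pd.DataFrame, columns: Iterable[str], path: object) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_supply_table(
    path: str | Path, config: AnalysisConfig | None = None
) -> list[SupplyRecord]:
    """Read a long-format supply CSV into validated SupplyRecords.

    Malformed rows raise with the offending (1-based data) row number.
    """
    df = pd.read_csv(path)
    _require_columns(df, SUPPLY_COLUMNS, path)
    records: list[SupplyRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                SupplyRecord(
                    country=str(row.country),
                    year=int(row.year),
                    item_id=str(row.item_id),
                    protein_supply=float(row.protein_supply),
                    food_waste=float(row.food_waste),
                    self_sufficiency=float(row.self_sufficiency),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, data row {i}: {exc}") from exc
    logger.info("read %d supply records from %s", len(records), path)
    return records


def write_supply_table(records: Iterable[SupplyRecord], path: str | Path) -> None:
    supply_frame(records).to_csv(path, index=False)


def supply_frame(records: Iterable[SupplyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.country, r.year, r.item_id, r.protein_supply, r.food_waste,
             r.self_sufficiency)
            for r in records
        ],
        columns=list(SUPPLY_COLUMNS),
    )


def read_items_table(path: str | Path) -> list[FoodItem]:
    df = pd.read_csv(path)
    _require_columns(df, ("item_id", "name", "category"), path)
    items = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            ptn = (
                float(row.protein_to_n)
                if "protein_to_n" in df.columns and pd.notna(row.protein_to_n)
                else DEFAULT_PROTEIN_TO_N
            )
            items.append(
                FoodItem(str(row.item_id), str(row.name), str(row.category), ptn)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, data row {i}: {exc}") from exc
    return items


def write_items_table(items: Iterable[FoodItem], path: str | Path) -> None:
    pd.DataFrame(
        [(it.item_id, it.name, it.category, it.protein_to_n) for it in items],
        columns=["item_id", "name", "category", "protein_to_n"],
    ).to_csv(path, index=False)


def read_religion_weights(path: str | Path) -> dict[str, list[ReligionProfile]]:
    """Read per-country religious population weights.

    Columns: country, religion, weight. Weights are time-constant per
    country; per country the five weights must sum to 1.
    Returns country -> list of ReligionProfile built from the standard
    exclusion rules.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("country", "religion", "weight"), path)
    out: dict[str, list[ReligionProfile]] = {}
    for country, grp in df.groupby("country"):
        total = grp["weight"].sum()
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"{path}: weights for {country!r} sum to {total}, expected 1"
            )
        out[str(country)] = [
            default_profile(str(r.religion), float(r.weight))
            for r in grp.itertuples(index=False)
        ]
    return out


def write_religion_weights(
    weights: Mapping[str, Sequence[ReligionProfile]], path: str | Path
) -> None:
    pd.DataFrame(
        [
            (country, p.religion, p.population_weight)
            for country, profiles in weights.items()
            for p in profiles
        ],
        columns=["country", "religion", "weight"],
    ).to_csv(path, index=False)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML; absent keys take defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "years" in kwargs:
        kwargs["years"] = tuple(kwargs["years"])
    if "decade_buckets" in kwargs:
        kwargs["decade_buckets"] = {
            k: tuple(v) for k, v in kwargs["decade_buckets"].items()
        }
    return AnalysisConfig(**kwargs)


def write_run_report(
    path: str | Path,
    config: AnalysisConfig,
    record_counts: Mapping[str, int],
    warnings: Sequence[str] = (),
) -> None:
    """Write a JSON run report: config echo, record counts, warnings."""
    payload = {
        "config": {
            "countries": list(config.countries),
            "years": list(config.years),
            "decade_buckets": {k: list(v) for k, v in config.decade_buckets.items()},
            "denitrification_ratio": config.denitrification_ratio,
            "protein_to_n_default": config.protein_to_n_default,
            "redistribute_excluded": config.redistribute_excluded,
            "seed": config.seed,
        },
        "record_counts": dict(record_counts),
        "warnings": list(warnings),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def configure_logging(verbosity: int = 0) -> None:
    """Route package logging to stderr; verbosity 0=WARNING, 1=INFO, 2=DEBUG."""
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (table convention), e.g. 0.125 -> 0.13."""
    import math

    factor = 10.0**ndigits
    scaled = x * factor
    return math.floor(scaled + 0.5) / factor if x >= 0 else math.ceil(scaled - 0.5) / factor


__all__ = [
    "CATEGORIES",
    "PLANT_CATEGORIES",
    "ANIMAL_CATEGORIES",
    "RELIGIONS",
    "RELIGION_EXCLUSIONS",
    "ISC_COUNTRIES",
    "REGION_LABEL",
    "DEFAULT_DECADES",
    "DEFAULT_PROTEIN_TO_N",
    "SchemaError",
    "ValidationError",
    "FoodItem",
    "ReligionProfile",
    "default_profile",
    "SupplyRecord",
    "AnalysisConfig",
    "assign_decade",
    "read_supply_table",
    "write_supply_table",
    "supply_frame",
    "read_items_table",
    "write_items_table",
    "read_religion_weights",
    "write_religion_weights",
    "load_config",
    "write_run_report",
    "configure_logging",
    "round_half_away",
    "replace",
]
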