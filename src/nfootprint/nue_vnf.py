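"""Nitrogen use efficiency budgets and virtual nitrogen factors.

Cultivation NUE is a mass-balance quotient over a crop N budget:
harvested crop N over the sum of fertilizer, manure, atmospheric
deposition, biological fixation and seed N. The domestic virtual
nitrogen factor (VNF, kg-N lost per kg-N of food N consumed) is the
reciprocal of the product of the cultivation, processing and
consumer-level NUEs of the chain. The trade-considered VNF blends the
domestic VNF with the regional average, weighted by the commodity's
self-sufficiency ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CATEGORIES,
    REGION_LABEL,
    AnalysisConfig,
    SchemaError,
    ValidationError,
    assign_decade,
    SupplyRecord,
    FoodItem,
)

logger = logging.getLogger("nfootprint.nue_vnf")


class DegenerateBudgetError(ValueError):
    """The pooled N-input denominator of a budget collection is zero."""


@dataclass(frozen=True)
class NBudget:
    """Per-crop nitrogen budget for one country-year (all terms kg-N)."""

    crop_id: str
    country: str
    year: int
    n_cont: float
    n_fert: float
    n_man: float
    n_adep: float
    n_bfix: float
    n_seed: float

    def __post_init__(self) -> None:
        for name in ("n_cont", "n_fert", "n_man", "n_adep", "n_bfix", "n_seed"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{name} < 0 in budget ({self.crop_id}, {self.country}, "
                    f"{self.year})"
                )

    @property
    def inputs(self) -> float:
        return self.n_fert + self.n_man + self.n_adep + self.n_bfix + self.n_seed


@dataclass(frozen=True)
class NUEComponents:
    """Chain-stage nitrogen use efficiencies, each in (0, 1]."""

    cultivation_nue: float
    processing_nue: float = 1.0
    consumer_nue: float = 1.0

    def validate(self) -> None:
        for name in ("cultivation_nue", "processing_nue", "consumer_nue"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} outside (0, 1]: {v}")


@dataclass(frozen=True)
class VNFRecord:
    """Domestic and trade-considered VNF for one country/category/decade."""

    country: str
    category: str
    decade: str
    domestic_vnf: float
    trade_vnf: float
    self_sufficiency: float


def cultivation_nue(budgets: Iterable[NBudget]) -> float:
    """Pooled cultivation NUE of a budget collection.

    Ratio of sums (total harvested N over total N inputs), the
    mass-balance-consistent aggregate, not the mean of per-crop ratios.
    Values above 1 are arithmetically possible (soil N mining) and are
    flagged with a warning rather than rejected.
    """
    budgets = list(budgets)
    if not budgets:
        raise DegenerateBudgetError("no budgets supplied")
    num = sum(b.n_cont for b in budgets)
    den = sum(b.inputs for b in budgets)
    if den <= 0:
        raise DegenerateBudgetError("pooled N-input denominator is zero")
    nue = num / den
    if nue > 1.0:
        logger.warning(
            "cultivation NUE %.3f exceeds 1 (soil N mining) for %d budgets",
            nue,
            len(budgets),
        )
    return nue


def domestic_vnf(components: NUEComponents) -> float:
    """Reciprocal of the product of the three chain NUEs (kg-N/kg-N)."""
    components.validate()
    return 1.0 / (
        components.cultivation_nue
        * components.processing_nue
        * components.consumer_nue
    )


def trade_considered_vnf(
    self_sufficiency: float, domestic: float, regional_avg: float
) -> float:
    """Self-sufficiency-weighted blend of domestic and regional VNFs."""
    if not 0.0 <= self_sufficiency <= 1.0:
        raise ValidationError(
            f"self_sufficiency outside [0, 1]: {self_sufficiency}"
        )
    if domestic <= 0 or regional_avg <= 0:
        raise ValidationError("VNF values must be positive")
    return self_sufficiency * domestic + (1.0 - self_sufficiency) * regional_avg


def regional_average_vnf(country_vnfs: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-country VNFs (full precision)."""
    values = np.asarray(list(country_vnfs), dtype=float)
    if values.size == 0:
        raise ValidationError("empty VNF collection")
    if (values <= 0).any():
        raise ValidationError("VNF values must be positive")
    return float(values.mean())


@dataclass
class VNFTable:
    """Result of :func:`build_vnf_table`: records plus unresolvable gaps."""

    records: list[VNFRecord]
    gaps: list[tuple[str, str, str]]

    def lookup(self) -> dict[tuple[str, str, str], VNFRecord]:
        return {(r.country, r.category, r.decade): r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.country, r.category, r.decade, r.domestic_vnf, r.trade_vnf,
                 r.self_sufficiency)
                for r in self.records
            ],
            columns=[
                "country", "category", "decade", "domestic_vnf", "trade_vnf",
                "self_sufficiency",
            ],
        )


def yearly_domestic_vnfs(
    budgets: Iterable[NBudget],
    components_by_category: Mapping[str, NUEComponents],
    crop_to_category: Mapping[str, str],
) -> pd.DataFrame:
    """Per (country, year, category) domestic VNFs.

    Plant-category cultivation NUEs come from the pooled budgets of the
    crops mapped to the category; animal-product categories take their
    full NUE chain directly from ``components_by_category`` (no feed-chain
    model is attempted).
    """
    rows = []
    by_key: dict[tuple[str, int, str], list[NBudget]] = {}
    for b in budgets:
        try:
            cat = crop_to_category[b.crop_id]
        except KeyError:
            raise SchemaError(f"crop {b.crop_id!r} has no category mapping")
        by_key.setdefault((b.country, b.year, cat), []).append(b)
    for (country, year, cat), blist in by_key.items():
        base = components_by_category.get(cat)
        if base is None:
            raise SchemaError(f"no NUE components for category {cat!r}")
        comp = NUEComponents(
            cultivation_nue=min(cultivation_nue(blist), 1.0),
            processing_nue=base.processing_nue,
            consumer_nue=base.consumer_nue,
        )
        rows.append((country, year, cat, domestic_vnf(comp)))
    return pd.DataFrame(rows, columns=["country", "year", "category", "domestic_vnf"])


def build_vnf_table(
    budgets: Iterable[NBudget],
    components_by_category: Mapping[str, NUEComponents],
    supply: Iterable[SupplyRecord],
    config: AnalysisConfig,
    crop_to_category: Mapping[str, str] | None = None,
    items: Sequence[FoodItem] | None = None,
) -> VNFTable:
    """Full VNF table: one record per (country, category, decade) plus the
    regional-average block.

    Plant categories derive yearly cultivation NUEs from the budgets;
    animal categories use the supplied NUE chain for every year of the
    span. Decadal values are equal-weight means of the yearly VNFs within
    the bucket. Self-sufficiency ratios are decade means over the supply
    records of the category's items. Missing (country, category, decade)
    cells are reported as gaps, never imputed.
    """
    crop_to_category = dict(crop_to_category or {})
    item_cat = {it.item_id: it.category for it in items} if items else {}

    budgets = list(budgets)
    supply = list(supply)
    lo, hi = config.years
    years = range(lo, hi + 1)

    dom = yearly_domestic_vnfs(budgets, components_by_category, crop_to_category)
    # categories with no mapped crop (animal products) take the supplied
    # chain directly, constant over the span
    budget_cats = set(crop_to_category.values())
    animal_rows = []
    for cat, comp in components_by_category.items():
        if cat in budget_cats or cat not in CATEGORIES:
            continue
        vnf = domestic_vnf(comp)
        for country in config.countries:
            for year in years:
                animal_rows.append((country, year, cat, vnf))
    if animal_rows:
        dom = pd.concat(
            [dom, pd.DataFrame(animal_rows, columns=dom.columns)], ignore_index=True
        )

    dom["decade"] = [assign_decade(y, config) for y in dom["year"]]
    decadal = (
        dom.groupby(["country", "category", "decade"])["domestic_vnf"]
        .mean()
        .reset_index()
    )

    # self-sufficiency per (country, category, decade): mean over records
    ss_lookup: dict[tuple[str, str, str], float] = {}
    if supply:
        sdf = pd.DataFrame(
            [
                (r.country, r.year, item_cat.get(r.item_id, r.item_id),
                 r.self_sufficiency)
                for r in supply
            ],
            columns=["country", "year", "category", "self_sufficiency"],
        )
        sdf["decade"] = [assign_decade(y, config) for y in sdf["year"]]
        grp = sdf.groupby(["country", "category", "decade"])["self_sufficiency"].mean()
        ss_lookup = grp.to_dict()

    decades = [
        d for d in config.decade_buckets
        if config.decade_buckets[d][0] <= hi and config.decade_buckets[d][1] >= lo
    ]
    dom_lookup = {
        (r.country, r.category, r.decade): r.domestic_vnf
        for r in decadal.itertuples(index=False)
    }

    requested_cats = set(decadal["category"])
    records: list[VNFRecord] = []
    gaps: list[tuple[str, str, str]] = []
    for cat in (c for c in CATEGORIES if c in requested_cats):
        for dec in decades:
            per_country = {
                c: dom_lookup.get((c, cat, dec)) for c in config.countries
            }
            present = {c: v for c, v in per_country.items() if v is not None}
            for c, v in per_country.items():
                if v is None:
                    gaps.append((c, cat, dec))
            if not present:
                continue
            avg = regional_average_vnf(list(present.values()))
            trade_values = []
            for c, v in present.items():
                ss = ss_lookup.get((c, cat, dec), 1.0)
                ss = min(ss, 1.0)
                tv = trade_considered_vnf(ss, v, avg)
                trade_values.append(tv)
                records.append(VNFRecord(c, cat, dec, v, tv, ss))
            records.append(
                VNFRecord(
                    REGION_LABEL, cat, dec, avg,
                    regional_average_vnf(trade_values),
                    float("nan"),
                )
            )
    if gaps:
        logger.warning("VNF table has %d (country, category, decade) gaps", len(gaps))
    return VNFTable(records=records, gaps=gaps)


def write_vnf_table(table: VNFTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_budgets_table(path) -> list[NBudget]:
    """Read a budgets CSV (crop_id, country, year, six N columns)."""
    df = pd.read_csv(path)
    needed = ("crop_id", "country", "year", "n_cont", "n_fert", "n_man",
              "n_adep", "n_bfix", "n_seed")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return [
        NBudget(
            str(r.crop_id), str(r.country), int(r.year), float(r.n_cont),
            float(r.n_fert), float(r.n_man), float(r.n_adep), float(r.n_bfix),
            float(r.n_seed),
        )
        for r in df.itertuples(index=False)
    ]


def write_budgets_table(budgets: Iterable[NBudget], path) -> None:
    pd.DataFrame(
        [
            (b.crop_id, b.country, b.year, b.n_cont, b.n_fert, b.n_man,
             b.n_adep, b.n_bfix, b.n_seed)
            for b in budgets
        ],
        columns=["crop_id", "country", "year", "n_cont", "n_fert", "n_man",
                 "n_adep", "n_bfix", "n_seed"],
    ).to_csv(path, index=False)


def read_components_table(path) -> dict[str, NUEComponents]:
    """Read NUE components CSV (category, cultivation, processing, consumer)."""
    df = pd.read_csv(path)
    needed = ("category", "cultivation_nue", "processing_nue", "consumer_nue")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out = {}
    for r in df.itertuples(index=False):
        comp = NUEComponents(
            float(r.cultivation_nue), float(r.processing_nue), float(r.consumer_nue)
        )
        comp.validate()
        out[str(r.category)] = comp
    return out


def write_components_table(components: Mapping[str, NUEComponents], path) -> None:
    pd.DataFrame(
        [
            (cat, c.cultivation_nue, c.processing_nue, c.consumer_nue)
            for cat, c in components.items()
        ],
        columns=["category", "cultivation_nue", "processing_nue", "consumer_nue"],
    ).to_csv(path, index=False)
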