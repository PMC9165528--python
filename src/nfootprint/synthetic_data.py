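"""Synthetic food-balance-sheet worlds with known ground truth.

Emulates the structure of FAO food balance sheets and fertilizer data
for the six countries of the Indian Subcontinent: per-capita protein
supplies with linear trends and multiplicative lognormal noise, crop N
budgets reverse-engineered from prescribed "true" cultivation NUE
trajectories (so the pipeline's NUE estimate recovers the truth
exactly), beta-distributed self-sufficiency ratios, and religious
population mixes. A closed-form GroundTruth record carries the analytic
VNFs and footprints implied by the generating parameters, which makes
end-to-end parameter-recovery tests possible without any downloads.

The packaged table fixtures (`table1_fixture`, `table2_fixture`)
transcribe the printed regional VNF and diet-share tables.

The generator captures trend + noise only; it does not emulate price
shocks, demographic change, reporting revisions, or item churn in real
balance sheets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    ANIMAL_CATEGORIES,
    CATEGORIES,
    ISC_COUNTRIES,
    PLANT_CATEGORIES,
    AnalysisConfig,
    FoodItem,
    ReligionProfile,
    SupplyRecord,
    ValidationError,
    default_profile,
)
from .diet_scenarios import BaselineInputs
from .footprint import FootprintResult, country_footprint
from .nue_vnf import (
    NBudget,
    NUEComponents,
    cultivation_nue,
    domestic_vnf,
    trade_considered_vnf,
)

#: Plausible national religious population shares (sum to 1 per country).
DEFAULT_RELIGION_MIX: dict[str, dict[str, float]] = {
    "Bangladesh": {"Muslim": 0.890, "Hindu": 0.085, "Buddhist": 0.010,
                   "Christian": 0.005, "Others": 0.010},
    "India": {"Hindu": 0.795, "Muslim": 0.140, "Christian": 0.025,
              "Buddhist": 0.010, "Others": 0.030},
    "Pakistan": {"Muslim": 0.960, "Hindu": 0.020, "Christian": 0.015,
                 "Buddhist": 0.001, "Others": 0.004},
    "Sri Lanka": {"Buddhist": 0.700, "Hindu": 0.125, "Muslim": 0.100,
                  "Christian": 0.070, "Others": 0.005},
    "Nepal": {"Hindu": 0.810, "Buddhist": 0.090, "Muslim": 0.045,
              "Christian": 0.015, "Others": 0.040},
    "Bhutan": {"Buddhist": 0.750, "Hindu": 0.225, "Muslim": 0.005,
               "Christian": 0.005, "Others": 0.015},
}

#: Baseline per-category protein supply, g/capita/day (cereal-dominated
#: regional diet, ~58 g/day total), and per-year linear trends.
DEFAULT_SUPPLY_BASE: dict[str, float] = {
    "cereals": 30.0, "starchy roots": 2.0, "oil crops and pulses": 6.0,
    "vegetables": 2.0, "fruits": 1.0, "other plant products": 7.0,
    "meat and offal": 1.5, "milk and dairy products": 6.0, "eggs": 0.5,
    "fish and seafood": 1.5,
}
DEFAULT_SUPPLY_TREND: dict[str, float] = {
    "cereals": 0.05, "starchy roots": 0.005, "oil crops and pulses": 0.02,
    "vegetables": 0.015, "fruits": 0.01, "other plant products": 0.02,
    "meat and offal": 0.01, "milk and dairy products": 0.03, "eggs": 0.005,
    "fish and seafood": 0.01,
}

#: Country cultivation-NUE trajectories: value in the first year and a
#: per-year drift (slow decline, consistent with sub-40% regional NUEs).
DEFAULT_NUE_START: dict[str, float] = {
    "Bangladesh": 0.46, "India": 0.42, "Pakistan": 0.50, "Sri Lanka": 0.36,
    "Nepal": 0.48, "Bhutan": 0.45,
}
DEFAULT_NUE_SLOPE: dict[str, float] = {
    "Bangladesh": -0.0012, "India": -0.0010, "Pakistan": -0.0020,
    "Sri Lanka": -0.0008, "Nepal": -0.0010, "Bhutan": -0.0009,
}

#: Relative cultivation-efficiency factors per plant category.
DEFAULT_CATEGORY_NUE_FACTOR: dict[str, float] = {
    "cereals": 1.00, "starchy roots": 1.05, "oil crops and pulses": 0.80,
    "vegetables": 0.70, "fruits": 0.60, "other plant products": 0.90,
}

#: Whole-chain production NUEs for animal products (no feed-chain model).
DEFAULT_ANIMAL_PRODUCTION_NUE: dict[str, float] = {
    "meat and offal": 0.30, "milk and dairy products": 0.11, "eggs": 0.28,
    "fish and seafood": 0.80,
}


@dataclass
class WorldSpec:
    """Declarative description of a synthetic world."""

    countries: tuple[str, ...] = ISC_COUNTRIES
    years: tuple[int, int] = (1961, 2013)
    items_per_category: int = 2
    religion_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_RELIGION_MIX
    )
    supply_base: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_SUPPLY_BASE
    )
    supply_trend: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_SUPPLY_TREND
    )
    noise_sigma: float = 0.05
    nue_start: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_NUE_START
    )
    nue_slope: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_NUE_SLOPE
    )
    category_nue_factor: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_CATEGORY_NUE_FACTOR
    )
    processing_nue: float = 0.90
    consumer_nue: float = 0.85
    animal_production_nue: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_ANIMAL_PRODUCTION_NUE
    )
    ss_beta: tuple[float, float] = (8.0, 2.0)
    waste: float = 0.10
    seed: int = 0

    def true_cultivation_nue(self, country: str, category: str, year: int) -> float:
        base = self.nue_start[country] + self.nue_slope[country] * (
            year - self.years[0]
        )
        nue = base * self.category_nue_factor[category]
        if not 0.0 < nue <= 1.0:
            raise ValidationError(
                f"infeasible true NUE {nue:.3f} for ({country}, {category}, {year})"
            )
        return nue


@dataclass
class GroundTruth:
    """Closed-form quantities implied by a WorldSpec (noiseless)."""

    domestic_vnf: dict[tuple[str, int, str], float]
    trade_vnf: dict[tuple[str, int, str], float]
    footprint: dict[tuple[str, int, str], float]  # (country, year, religion)


@dataclass
class World:
    """A generated input set plus its ground truth."""

    spec: WorldSpec
    items: list[FoodItem]
    supplies: list[SupplyRecord]
    budgets: list[NBudget]
    crop_to_category: dict[str, str]
    components_by_category: dict[str, NUEComponents]
    profiles: dict[str, list[ReligionProfile]]
    self_sufficiency: dict[tuple[str, str], float]  # (country, category)
    config: AnalysisConfig
    ground_truth: GroundTruth

    @property
    def items_by_id(self) -> dict[str, FoodItem]:
        return {it.item_id: it for it in self.items}


def generate_world(spec: WorldSpec) -> World:
    """Generate a reproducible world; see the module docstring.

    Budgets are solved from the target NUE (a Dirichlet draw fixes the
    input composition, the harvested N is the target ratio times the
    pooled inputs), so the pipeline's cultivation NUE recovers the true
    trajectory exactly. Supply noise is multiplicative lognormal with a
    fixed standard-normal draw per record, so shrinking ``noise_sigma``
    moves every record monotonically toward its noiseless value.
    """
    ss_rng, comp_rng, noise_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(3)
    )
    y0, y1 = spec.years
    years = range(y0, y1 + 1)
    config = AnalysisConfig(countries=spec.countries, years=spec.years, seed=spec.seed)

    items = [
        FoodItem(item_id=f"{cat}-{k}", name=f"{cat} item {k}", category=cat)
        for cat in CATEGORIES
        for k in range(1, spec.items_per_category + 1)
    ]
    profiles = {
        c: [default_profile(r, w) for r, w in spec.religion_mix[c].items()]
        for c in spec.countries
    }

    # self-sufficiency: one beta draw per (country, category), all its
    # items and years share it (the trade blend operates per category)
    a, b = spec.ss_beta
    self_sufficiency = {
        (c, cat): float(ss_rng.beta(a, b)) for c in spec.countries for cat in CATEGORIES
    }

    # budgets reverse-engineered from the true NUE trajectory
    budgets: list[NBudget] = []
    crop_to_category = {f"crop:{cat}": cat for cat in PLANT_CATEGORIES}
    comp_draw = {
        (c, cat): comp_rng.dirichlet(np.ones(5))
        for c in spec.countries
        for cat in PLANT_CATEGORIES
    }
    for c in spec.countries:
        for cat in PLANT_CATEGORIES:
            frac = comp_draw[(c, cat)]
            for year in years:
                nue = spec.true_cultivation_nue(c, cat, year)
                total_inputs = 100.0  # kt-N, arbitrary budget scale
                parts = frac * total_inputs
                budgets.append(
                    NBudget(
                        crop_id=f"crop:{cat}", country=c, year=year,
                        n_cont=nue * total_inputs, n_fert=parts[0],
                        n_man=parts[1], n_adep=parts[2], n_bfix=parts[3],
                        n_seed=parts[4],
                    )
                )

    components_by_category: dict[str, NUEComponents] = {}
    for cat in PLANT_CATEGORIES:
        components_by_category[cat] = NUEComponents(
            cultivation_nue=0.5,  # placeholder; budgets override it per year
            processing_nue=spec.processing_nue,
            consumer_nue=spec.consumer_nue,
        )
    for cat in ANIMAL_CATEGORIES:
        components_by_category[cat] = NUEComponents(
            cultivation_nue=spec.animal_production_nue[cat],
            processing_nue=spec.processing_nue,
            consumer_nue=spec.consumer_nue,
        )

    # supplies with fixed noise draws
    supplies: list[SupplyRecord] = []
    clean_supply: dict[tuple[str, int, str], float] = {}
    for c in spec.countries:
        for year in years:
            for it in items:
                cat = it.category
                clean = max(
                    (spec.supply_base[cat] + spec.supply_trend[cat] * (year - y0))
                    / spec.items_per_category,
                    0.0,
                )
                z = float(noise_rng.standard_normal())
                noisy = clean * float(np.exp(spec.noise_sigma * z))
                clean_supply[(c, year, it.item_id)] = clean
                supplies.append(
                    SupplyRecord(
                        country=c, year=year, item_id=it.item_id,
                        protein_supply=noisy, food_waste=spec.waste,
                        self_sufficiency=self_sufficiency[(c, cat)],
                    )
                )

    ground_truth = _closed_form_truth(spec, items, clean_supply, self_sufficiency)
    return World(
        spec=spec, items=items, supplies=supplies, budgets=budgets,
        crop_to_category=crop_to_category,
        components_by_category=components_by_category, profiles=profiles,
        self_sufficiency=self_sufficiency, config=config,
        ground_truth=ground_truth,
    )


def _closed_form_truth(
    spec: WorldSpec,
    items: list[FoodItem],
    clean_supply: dict[tuple[str, int, str], float],
    self_sufficiency: dict[tuple[str, str], float],
) -> GroundTruth:
    """Analytic VNFs and footprints, written as the direct formulas."""
    y0, y1 = spec.years
    dom: dict[tuple[str, int, str], float] = {}
    trade: dict[tuple[str, int, str], float] = {}
    fp: dict[tuple[str, int, str], float] = {}
    chain_tail = spec.processing_nue * spec.consumer_nue
    for year in range(y0, y1 + 1):
        for cat in CATEGORIES:
            for c in spec.countries:
                if cat in PLANT_CATEGORIES:
                    nue = spec.true_cultivation_nue(c, cat, year)
                else:
                    nue = spec.animal_production_nue[cat]
                dom[(c, year, cat)] = 1.0 / (nue * chain_tail)
            avg = sum(dom[(c, year, cat)] for c in spec.countries) / len(
                spec.countries
            )
            for c in spec.countries:
                ss = self_sufficiency[(c, cat)]
                trade[(c, year, cat)] = ss * dom[(c, year, cat)] + (1 - ss) * avg
    for c in spec.countries:
        for year in range(y0, y1 + 1):
            total = 0.0
            for religion, w in spec.religion_mix[c].items():
                excluded = {
                    "Hindu": {"meat and offal", "eggs", "fish and seafood"},
                    "Buddhist": {"meat and offal", "eggs", "fish and seafood",
                                 "milk and dairy products"},
                }.get(religion, set())
                value = 0.0
                for it in items:
                    if it.category in excluded:
                        continue
                    intake = (
                        clean_supply[(c, year, it.item_id)]
                        * 365.0 / 1000.0 * it.protein_to_n * (1.0 - spec.waste)
                    )
                    value += intake * (trade[(c, year, it.category)] + 1.0)
                fp[(c, year, religion)] = value
                total += w * value
            fp[(c, year, "all")] = total
    return GroundTruth(domestic_vnf=dom, trade_vnf=trade, footprint=fp)


def run_pipeline(
    world: World, years: range | None = None
) -> list[FootprintResult]:
    """Run the estimation pipeline on a world, year by year.

    Cultivation NUEs come from the generated budgets, domestic and
    trade-considered VNFs from the NUE chains, and footprints from the
    religion-weighted accounting — the same operations a real-data run
    would use, with yearly (not decadal) VNFs so results are comparable
    to the closed-form ground truth.
    """
    y0, y1 = world.spec.years
    years = years or range(y0, y1 + 1)
    items = world.items_by_id
    budgets_by = {}
    for bgt in world.budgets:
        cat = world.crop_to_category[bgt.crop_id]
        budgets_by.setdefault((bgt.country, bgt.year, cat), []).append(bgt)
    results: list[FootprintResult] = []
    for year in years:
        dom: dict[tuple[str, str], float] = {}
        for c in world.spec.countries:
            for cat in CATEGORIES:
                base = world.components_by_category[cat]
                if cat in PLANT_CATEGORIES:
                    nue = min(cultivation_nue(budgets_by[(c, year, cat)]), 1.0)
                    comp = NUEComponents(nue, base.processing_nue, base.consumer_nue)
                else:
                    comp = base
                dom[(c, cat)] = domestic_vnf(comp)
        for c in world.spec.countries:
            vnf_by_cat = {}
            for cat in CATEGORIES:
                avg = sum(dom[(cc, cat)] for cc in world.spec.countries) / len(
                    world.spec.countries
                )
                vnf_by_cat[cat] = trade_considered_vnf(
                    world.self_sufficiency[(c, cat)], dom[(c, cat)], avg
                )
            supplies = [
                s for s in world.supplies if s.country == c and s.year == year
            ]
            results.extend(
                country_footprint(
                    c, year, supplies, items, vnf_by_cat, world.profiles[c],
                    world.config,
                )
            )
    return results


def baseline_inputs(world: World, year: int = 2013) -> BaselineInputs:
    """Assemble a scenario baseline from one year of a world."""
    budgets_by: dict[tuple[str, str], list[NBudget]] = {}
    for bgt in world.budgets:
        if bgt.year != year:
            continue
        cat = world.crop_to_category[bgt.crop_id]
        budgets_by.setdefault((bgt.country, cat), []).append(bgt)
    components: dict[str, dict[str, NUEComponents]] = {}
    for c in world.spec.countries:
        components[c] = {}
        for cat in CATEGORIES:
            base = world.components_by_category[cat]
            if cat in PLANT_CATEGORIES:
                nue = min(cultivation_nue(budgets_by[(c, cat)]), 1.0)
                components[c][cat] = NUEComponents(
                    nue, base.processing_nue, base.consumer_nue
                )
            else:
                components[c][cat] = base
    return BaselineInputs(
        year=year,
        supplies=[s for s in world.supplies if s.year == year],
        items=world.items_by_id,
        components=components,
        profiles=world.profiles,
        config=world.config,
    )


# ---------------------------------------------------------------------------
# packaged table fixtures
# ---------------------------------------------------------------------------


def _data_rows(name: str) -> list[dict[str, str]]:
    with resources.files("nfootprint.data").joinpath(name).open(
        "r", encoding="utf-8"
    ) as fh:
        return list(csv.DictReader(fh))


def table1_fixture() -> dict[str, dict[str, dict[str, float]]]:
    """Printed regional trade-considered VNF table.

    Nested mapping country -> category -> decade -> VNF, including the
    "ISC average" block.
    """
    out: dict[str, dict[str, dict[str, float]]] = {}
    for row in _data_rows("table1_vnf.csv"):
        out.setdefault(row["country"], {}).setdefault(row["category"], {})[
            row["decade"]
        ] = float(row["trade_vnf"])
    return out


def table1_frame() -> pd.DataFrame:
    return pd.DataFrame(_data_rows("table1_vnf.csv")).astype({"trade_vnf": float})


@dataclass(frozen=True)
class Table2Cell:
    """One printed diet-share cell: target, actual, printed alteration.

    ``actual`` and ``alteration`` are ``None`` where the table prints a
    dash ("no change" / not applicable).
    """

    target: float
    actual: float | None
    alteration: float | None


def table2_fixture() -> dict[tuple[str, str], dict[str, Table2Cell]]:
    """Printed religion-sensitive diet shares and recommended alterations.

    Mapping (country, religion) -> category -> Table2Cell.
    """
    out: dict[tuple[str, str], dict[str, Table2Cell]] = {}
    for row in _data_rows("table2_diet.csv"):
        key = (row["country"], row["religion"])
        out.setdefault(key, {})[row["category"]] = Table2Cell(
            target=float(row["eat_lancet_target"]),
            actual=float(row["actual_share"]) if row["actual_share"] else None,
            alteration=(
                float(row["printed_alteration"])
                if row["printed_alteration"]
                else None
            ),
        )
    return out


def table2_frame() -> pd.DataFrame:
    return pd.DataFrame(_data_rows("table2_diet.csv"))
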