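"""Religion-weighted per-capita food nitrogen footprints.

The per-capita food N footprint of a country-year is the sum over food
items and religious communities of a production term (food N intake
times the item's trade-considered VNF) and a consumption term (food N
intake times one minus the denitrification ratio), weighted by each
community's population share. With the regional default denitrification
ratio of zero the consumption term equals the N intake itself.

National protein supplies are religion-invariant: religion specificity
enters only through category exclusions (an excluded category
contributes zero intake for that community). By default the excluded
protein is not redistributed to permitted categories; set
``AnalysisConfig.redistribute_excluded`` to renormalise a community's
diet to the national protein total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import (
    CATEGORIES,
    REGION_LABEL,
    AnalysisConfig,
    FoodItem,
    ReligionProfile,
    SupplyRecord,
    ValidationError,
)

DAYS_PER_YEAR = 365.0


class MissingVNFError(KeyError):
    """A consumed category has no trade-considered VNF."""


@dataclass(frozen=True)
class FootprintResult:
    """Per-capita N footprint (kg-N · capita⁻¹ · yr⁻¹) for one scope."""

    scope: str
    religion: str
    year: int
    production_nf: float
    consumption_nf: float
    total_nf: float
    per_category_breakdown: Mapping[str, float] = field(default_factory=dict)


def n_intake(
    protein_supply: float, protein_to_n: float, food_waste: float
) -> float:
    """Annual per-capita food N intake, kg-N/yr.

    ``protein_supply`` is g protein per capita per day; the Jones-type
    factor ``protein_to_n`` converts protein mass to N mass; the wasted
    fraction never reaches intake.
    """
    if protein_supply < 0 or protein_to_n < 0 or not 0.0 <= food_waste <= 1.0:
        raise ValidationError(
            f"inputs out of range: supply={protein_supply}, "
            f"protein_to_n={protein_to_n}, waste={food_waste}"
        )
    return protein_supply * DAYS_PER_YEAR / 1000.0 * protein_to_n * (1.0 - food_waste)


def production_nf_item(intake_n: float, trade_vnf: float) -> float:
    """Production-side footprint of one item: intake N times its VNF."""
    if intake_n < 0 or trade_vnf <= 0:
        raise ValidationError(
            f"need intake_n >= 0 and trade_vnf > 0, got {intake_n}, {trade_vnf}"
        )
    return intake_n * trade_vnf


def consumption_nf_item(intake_n: float, denitrification_ratio: float = 0.0) -> float:
    """Consumption-side footprint: intake N net of wastewater N removal."""
    if not 0.0 <= denitrification_ratio <= 1.0:
        raise ValidationError(
            f"denitrification_ratio outside [0, 1]: {denitrification_ratio}"
        )
    if intake_n < 0:
        raise ValidationError(f"negative intake_n: {intake_n}")
    return intake_n * (1.0 - denitrification_ratio)


def religion_filter(category: str, profile: ReligionProfile) -> bool:
    """True iff the community's dietary rules permit the category."""
    return profile.permits(category)


def country_footprint(
    country: str,
    year: int,
    supplies: Iterable[SupplyRecord],
    items: Mapping[str, FoodItem],
    vnf_by_category: Mapping[str, float],
    profiles: Sequence[ReligionProfile],
    config: AnalysisConfig | None = None,
) -> list[FootprintResult]:
    """Per-religion footprints plus the population-weighted national total.

    ``vnf_by_category`` maps each consumed category to its
    trade-considered VNF for this country and period. Returns one result
    per community and a final result with religion ``"all"``.
    """
    config = config or AnalysisConfig()
    supplies = [s for s in supplies if s.country == country and s.year == year]
    total_weight = sum(p.population_weight for p in profiles)
    if abs(total_weight - 1.0) > 1e-9:
        raise ValidationError(
            f"religion weights for {country!r} sum to {total_weight}, expected 1"
        )

    # per-item intake for the unrestricted (national) diet
    intakes: list[tuple[str, float]] = []  # (category, kg-N/yr)
    for s in supplies:
        item = items.get(s.item_id)
        if item is None:
            raise ValidationError(f"unknown item {s.item_id!r} in supply table")
        intakes.append(
            (item.category, n_intake(s.protein_supply, item.protein_to_n, s.food_waste))
        )
    national_total_n = sum(v for _, v in intakes)

    results: list[FootprintResult] = []
    agg_prod = agg_cons = 0.0
    agg_breakdown = {c: 0.0 for c in CATEGORIES}
    for profile in profiles:
        prod = cons = 0.0
        breakdown = {c: 0.0 for c in CATEGORIES}
        permitted_n = sum(v for c, v in intakes if profile.permits(c))
        scale = 1.0
        if config.redistribute_excluded and permitted_n > 0:
            scale = national_total_n / permitted_n
        for category, intake in intakes:
            if not religion_filter(category, profile):
                continue
            if intake == 0.0:
                continue
            if category not in vnf_by_category:
                raise MissingVNFError(
                    f"no trade VNF for ({country!r}, {category!r})"
                )
            eff = intake * scale
            p = production_nf_item(eff, vnf_by_category[category])
            q = consumption_nf_item(eff, config.denitrification_ratio)
            prod += p
            cons += q
            breakdown[category] += p + q
        results.append(
            FootprintResult(
                scope=country, religion=profile.religion, year=year,
                production_nf=prod, consumption_nf=cons, total_nf=prod + cons,
                per_category_breakdown=breakdown,
            )
        )
        w = profile.population_weight
        agg_prod += w * prod
        agg_cons += w * cons
        for c in CATEGORIES:
            agg_breakdown[c] += w * breakdown[c]
    results.append(
        FootprintResult(
            scope=country, religion="all", year=year,
            production_nf=agg_prod, consumption_nf=agg_cons,
            total_nf=agg_prod + agg_cons, per_category_breakdown=agg_breakdown,
        )
    )
    return results


def regional_footprint(
    country_results: Sequence[FootprintResult],
) -> list[FootprintResult]:
    """Unweighted country means, per religion label present in the input."""
    if not country_results:
        raise ValidationError("no country results to average")
    by_key: dict[tuple[str, int], list[FootprintResult]] = {}
    for r in country_results:
        by_key.setdefault((r.religion, r.year), []).append(r)
    out = []
    for (religion, year), rs in by_key.items():
        n = len(rs)
        breakdown = {
            c: sum(r.per_category_breakdown.get(c, 0.0) for r in rs) / n
            for c in CATEGORIES
        }
        prod = sum(r.production_nf for r in rs) / n
        cons = sum(r.consumption_nf for r in rs) / n
        out.append(
            FootprintResult(
                scope=REGION_LABEL, religion=religion, year=year,
                production_nf=prod, consumption_nf=cons, total_nf=prod + cons,
                per_category_breakdown=breakdown,
            )
        )
    return out


def footprint_frame(results: Iterable[FootprintResult]) -> pd.DataFrame:
    """Flatten results to a DataFrame with per-category breakdown columns."""
    rows = []
    for r in results:
        row = {
            "scope": r.scope, "religion": r.religion, "year": r.year,
            "production_nf": r.production_nf, "consumption_nf": r.consumption_nf,
            "total_nf": r.total_nf,
        }
        for c in CATEGORIES:
            row[f"nf[{c}]"] = r.per_category_breakdown.get(c, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_footprints(results: Iterable[FootprintResult], path) -> None:
    footprint_frame(results).to_csv(path, index=False)
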