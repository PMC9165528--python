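"""Diet and efficiency scenarios for 2014-2050.

Four scenarios transform the 2013 baseline:

* ``BAU`` — business as usual: diets and production efficiencies frozen
  at their 2013 values.
* ``NUE`` — crop cultivation NUEs raised 30% above 2013 (capped at 1);
  processing and consumer-level NUEs and diets unchanged.
* ``EAT_LANCET`` — religion-sensitive shift of 2013 protein supplies
  toward the EAT-Lancet planetary health diet shares, respecting each
  community's category exclusions, anchored at 51 g protein/day.
* ``INTEGRATED`` — both transformations combined. They act on disjoint
  inputs (efficiencies vs supplies), so composition is order-independent.

The alteration rule moves over-represented staple shares (cereals,
starchy roots, and dairy where not protected) down to their targets and
redistributes the freed share across the under-represented plant
categories (fruits, vegetables, oil crops and pulses, other plant
products) in proportion to their gaps. Meat, eggs and fish shares are
never altered, and categories a community excludes stay at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .core_io import (
    ANIMAL_CATEGORIES,
    CATEGORIES,
    AnalysisConfig,
    FoodItem,
    ReligionProfile,
    SupplyRecord,
    ValidationError,
)
from .footprint import FootprintResult, country_footprint, regional_footprint
from .nue_vnf import (
    NUEComponents,
    domestic_vnf,
    regional_average_vnf,
    trade_considered_vnf,
)

#: EAT-Lancet planetary health diet food-group shares (% of food share).
EAT_LANCET_SHARES: dict[str, float] = {
    "cereals": 32.0,
    "starchy roots": 2.0,
    "oil crops and pulses": 18.0,
    "vegetables": 3.0,
    "fruits": 5.0,
    "other plant products": 27.0,
    "meat and offal": 4.0,
    "milk and dairy products": 6.0,
    "eggs": 1.0,
    "fish and seafood": 2.0,
}

#: Staples whose shares are pulled down to target.
DECREASE_CATEGORIES = ("cereals", "starchy roots", "milk and dairy products")
#: Healthy plant categories that absorb the freed share.
INCREASE_CATEGORIES = (
    "oil crops and pulses",
    "vegetables",
    "fruits",
    "other plant products",
)

SCENARIO_NAMES = ("BAU", "NUE", "EAT_LANCET", "INTEGRATED")


class InfeasibleAlterationError(ValueError):
    """No redistribution satisfies the non-negativity/anchor constraints."""


@dataclass(frozen=True)
class DietShares:
    """Category shares (% of food share) of one community's diet."""

    country: str
    religion: str
    shares: Mapping[str, float]
    reference: str = "actual"  # or "eat_lancet_target"

    def __post_init__(self) -> None:
        for cat, v in self.shares.items():
            if cat not in CATEGORIES:
                raise ValidationError(f"unknown category {cat!r}")
            if v < 0:
                raise ValidationError(f"negative share for {cat!r}: {v}")


def eat_lancet_target(country: str = "", religion: str = "") -> DietShares:
    return DietShares(country, religion, dict(EAT_LANCET_SHARES),
                      reference="eat_lancet_target")


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one 2014-2050 scenario."""

    name: str
    nue_multiplier: float = 1.0
    diet_altered: bool = False
    baseline_year: int = 2013
    horizon: int = 2050
    calorie_anchor: float = 2500.0  # kcal/day, metadata only
    protein_anchor: float = 51.0  # g protein/day

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValidationError(f"unknown scenario {self.name!r}")
        want_mult = 1.3 if self.name in ("NUE", "INTEGRATED") else 1.0
        want_diet = self.name in ("EAT_LANCET", "INTEGRATED")
        if abs(self.nue_multiplier - want_mult) > 1e-12 or self.diet_altered != want_diet:
            raise ValidationError(
                f"scenario {self.name!r} requires nue_multiplier={want_mult}, "
                f"diet_altered={want_diet}"
            )


def scenario_spec(name: str, **overrides) -> ScenarioSpec:
    """Build the canonical spec for one of the four named scenarios."""
    if name not in SCENARIO_NAMES:
        raise ValidationError(f"unknown scenario {name!r}")
    return ScenarioSpec(
        name=name,
        nue_multiplier=1.3 if name in ("NUE", "INTEGRATED") else 1.0,
        diet_altered=name in ("EAT_LANCET", "INTEGRATED"),
        **overrides,
    )


def apply_nue_scenario(
    components: NUEComponents, multiplier: float
) -> NUEComponents:
    """Scale the cultivation NUE (capped at 1); other stages unchanged."""
    if multiplier < 1.0:
        raise ValidationError(f"multiplier must be >= 1, got {multiplier}")
    return NUEComponents(
        cultivation_nue=min(components.cultivation_nue * multiplier, 1.0),
        processing_nue=components.processing_nue,
        consumer_nue=components.consumer_nue,
    )


def diet_alteration(
    actual: DietShares,
    target: DietShares,
    profile: ReligionProfile,
    suppression_threshold: float = 2.0,
    dairy_protected_religions: Sequence[str] = ("Muslim", "Hindu"),
    integer_deltas: bool = True,
) -> dict[str, float]:
    """Share-point deltas moving a community's diet toward the target.

    Over-represented adjustable categories are pulled down to their
    targets (gaps at or below ``suppression_threshold`` share points are
    suppressed as "no change"); the freed share is spread over the
    under-represented healthy plant categories in proportion to their
    gaps, rounded to integer share points by largest remainder when
    ``integer_deltas`` is set. Dairy is frozen for the religions named in
    ``dairy_protected_religions`` (communities whose diets depend on
    dairy protein). Animal categories are never altered; excluded
    categories stay at zero.
    """
    a = {c: float(actual.shares.get(c, 0.0)) for c in CATEGORIES}
    t = {c: float(target.shares.get(c, 0.0)) for c in CATEGORIES}
    deltas = {c: 0.0 for c in CATEGORIES}

    adjustable = set(DECREASE_CATEGORIES) | set(INCREASE_CATEGORIES)
    if profile.religion in dairy_protected_religions:
        adjustable.discard("milk and dairy products")
    adjustable = {c for c in adjustable if profile.permits(c)}

    # decrease side: exact pull to target beyond the threshold
    freed = 0.0
    for c in sorted(adjustable):
        gap = t[c] - a[c]
        if gap < 0 and abs(gap) > suppression_threshold:
            deltas[c] = gap
            freed += -gap

    # increase side: distribute the freed share over positive gaps
    gaps = {
        c: max(t[c] - a[c], 0.0)
        for c in INCREASE_CATEGORIES
        if c in adjustable and deltas[c] == 0.0
    }
    total_gap = sum(gaps.values())
    if freed > 0:
        if total_gap > 0:
            raw = {c: freed * g / total_gap for c, g in gaps.items()}
        elif gaps:
            raw = {c: freed / len(gaps) for c in gaps}
        else:
            raise InfeasibleAlterationError(
                f"({actual.country}, {actual.religion}): freed share "
                f"{freed} has no permitted category to absorb it"
            )
        if integer_deltas:
            raw = _largest_remainder_round(raw, freed)
        deltas.update(raw)

    for c, d in deltas.items():
        if a[c] + d < -1e-9:
            raise InfeasibleAlterationError(
                f"({actual.country}, {actual.religion}, {c}): altered share "
                f"{a[c] + d} is negative"
            )
    return deltas


def _largest_remainder_round(raw: Mapping[str, float], total: float) -> dict[str, float]:
    """Round values to integers preserving their (integer) total."""
    floors = {c: float(int(v)) for c, v in raw.items()}
    remainder = round(total) - sum(floors.values())
    order = sorted(raw, key=lambda c: raw[c] - floors[c], reverse=True)
    out = dict(floors)
    for c in order[: int(remainder)]:
        out[c] += 1.0
    return out


def protein_shares(
    supplies: Iterable[SupplyRecord],
    items: Mapping[str, FoodItem],
    profile: ReligionProfile | None = None,
) -> tuple[dict[str, float], float]:
    """Category protein shares (%) and total g/day, optionally restricted
    to a community's permitted categories."""
    per_cat = {c: 0.0 for c in CATEGORIES}
    for s in supplies:
        cat = items[s.item_id].category
        if profile is not None and not profile.permits(cat):
            continue
        per_cat[cat] += s.protein_supply
    total = sum(per_cat.values())
    if total <= 0:
        raise ValidationError("no protein supply to compute shares from")
    return {c: 100.0 * v / total for c, v in per_cat.items()}, total


def altered_protein_supply(
    baseline: Sequence[SupplyRecord],
    items: Mapping[str, FoodItem],
    alteration: Mapping[str, float],
    profile: ReligionProfile | None = None,
    protein_anchor: float | None = 51.0,
    anchor_mode: str = "rescale",
) -> list[SupplyRecord]:
    """Apply share-point deltas to one country-year's supply records.

    New category shares are the actual shares plus the deltas; item
    supplies within a category scale proportionally. ``anchor_mode``:
    ``"rescale"`` sets total daily protein to ``protein_anchor``;
    ``"cap"`` only reduces totals above the anchor; ``"none"`` keeps the
    baseline total (each altered category scales by its share ratio,
    untouched categories keep their supplies exactly).
    """
    shares, total = protein_shares(baseline, items, profile)
    new_shares = {c: shares[c] + float(alteration.get(c, 0.0)) for c in CATEGORIES}
    for c, v in new_shares.items():
        if v < -1e-9:
            raise InfeasibleAlterationError(f"altered share for {c!r} is negative")
        new_shares[c] = max(v, 0.0)
    sum_new = sum(new_shares.values())
    if sum_new <= 0:
        raise InfeasibleAlterationError("altered shares sum to zero")

    if anchor_mode == "none" or protein_anchor is None:
        new_total_per_point = total / 100.0  # g/day per share point
    elif anchor_mode == "rescale":
        new_total_per_point = protein_anchor / sum_new
    elif anchor_mode == "cap":
        new_total_per_point = min(total * sum_new / 100.0, protein_anchor) / sum_new
    else:
        raise ValidationError(f"unknown anchor_mode {anchor_mode!r}")

    per_cat_old = {c: 0.0 for c in CATEGORIES}
    n_records = {c: 0 for c in CATEGORIES}
    for s in baseline:
        cat = items[s.item_id].category
        if profile is not None and not profile.permits(cat):
            continue
        per_cat_old[cat] += s.protein_supply
        n_records[cat] += 1
    factors: dict[str, float] = {}
    flat: dict[str, float] = {}  # g/day per record when the category was empty
    for c in CATEGORIES:
        new_cat_total = new_shares[c] * new_total_per_point
        if per_cat_old[c] > 0:
            factors[c] = new_cat_total / per_cat_old[c]
        elif new_cat_total > 1e-9:
            if n_records[c] == 0:
                raise InfeasibleAlterationError(
                    f"category {c!r} has no baseline items to carry its "
                    f"positive altered share"
                )
            # category newly introduced: split its protein evenly over items
            factors[c] = 0.0
            flat[c] = new_cat_total / n_records[c]
        else:
            factors[c] = 0.0

    out = []
    for s in baseline:
        cat = items[s.item_id].category
        if profile is not None and not profile.permits(cat):
            out.append(replace(s, protein_supply=0.0))
        else:
            out.append(
                replace(
                    s,
                    protein_supply=s.protein_supply * factors[cat] + flat.get(cat, 0.0),
                )
            )
    return out


# ---------------------------------------------------------------------------
# scenario input assembly
# ---------------------------------------------------------------------------


@dataclass
class BaselineInputs:
    """Complete 2013 input set: supplies, items, NUE chains, demographics."""

    year: int
    supplies: list[SupplyRecord]
    items: dict[str, FoodItem]
    components: dict[str, dict[str, NUEComponents]]  # country -> category
    profiles: dict[str, list[ReligionProfile]]  # country -> communities
    config: AnalysisConfig = field(default_factory=AnalysisConfig)
    nue_multiplier_applied: float = 1.0
    diet_altered_applied: bool = False


@dataclass
class ScenarioInputs:
    """Inputs for 2014-2050 produced by :func:`build_scenario_inputs`."""

    spec: ScenarioSpec
    years: range
    components: dict[str, dict[str, NUEComponents]]
    supplies: dict[tuple[str, str], list[SupplyRecord]]  # (country, religion)
    profiles: dict[str, list[ReligionProfile]]
    items: dict[str, FoodItem]
    config: AnalysisConfig


def build_scenario_inputs(
    spec: ScenarioSpec,
    baseline: BaselineInputs | ScenarioInputs,
    suppression_threshold: float = 2.0,
    dairy_protected_religions: Sequence[str] = ("Muslim", "Hindu"),
    anchor_mode: str = "rescale",
) -> ScenarioInputs:
    """Transform the 2013 baseline into scenario inputs for 2014-2050.

    The NUE multiplier applies to the cultivation stage of plant
    categories only (crop cultivation efficiency); diet alteration
    produces religion-specific supply sets. ``baseline`` may itself be a
    previously built ScenarioInputs: transformations already recorded on
    it are never applied twice, so builds are idempotent, and the NUE and
    diet transformations compose in either order (they act on disjoint
    inputs).
    """
    if isinstance(baseline, ScenarioInputs):
        prior = baseline
        baseline = BaselineInputs(
            year=prior.spec.baseline_year,
            supplies=[],
            items=prior.items,
            components=prior.components,
            profiles=prior.profiles,
            config=prior.config,
            nue_multiplier_applied=max(prior.spec.nue_multiplier, 1.0),
            diet_altered_applied=prior.spec.diet_altered,
        )
        supplies_source: dict[tuple[str, str], list[SupplyRecord]] = prior.supplies
        countries = sorted({c for c, _ in supplies_source})
    else:
        supplies_source = {}
        countries = sorted({s.country for s in baseline.supplies})
        for country in countries:
            base = [s for s in baseline.supplies if s.country == country]
            for profile in baseline.profiles[country]:
                supplies_source[(country, profile.religion)] = base
    if baseline.year != spec.baseline_year:
        raise ValidationError(
            f"baseline year {baseline.year} != spec baseline {spec.baseline_year}"
        )

    # efficiency transformation (plant cultivation only)
    need_mult = spec.nue_multiplier / baseline.nue_multiplier_applied
    components: dict[str, dict[str, NUEComponents]] = {}
    for country, per_cat in baseline.components.items():
        components[country] = {}
        for cat, comp in per_cat.items():
            if cat not in ANIMAL_CATEGORIES and need_mult > 1.0:
                components[country][cat] = apply_nue_scenario(comp, need_mult)
            else:
                components[country][cat] = comp

    # diet transformation (religion-specific supplies)
    supplies: dict[tuple[str, str], list[SupplyRecord]] = {}
    for country in countries:
        for profile in baseline.profiles[country]:
            key = (country, profile.religion)
            base = supplies_source[key]
            if spec.diet_altered and not baseline.diet_altered_applied:
                actual_shares, _ = protein_shares(base, baseline.items, profile)
                actual = DietShares(country, profile.religion, actual_shares)
                deltas = diet_alteration(
                    actual,
                    eat_lancet_target(country, profile.religion),
                    profile,
                    suppression_threshold=suppression_threshold,
                    dairy_protected_religions=dairy_protected_religions,
                    integer_deltas=False,
                )
                supplies[key] = altered_protein_supply(
                    base, baseline.items, deltas, profile,
                    protein_anchor=spec.protein_anchor, anchor_mode=anchor_mode,
                )
            else:
                supplies[key] = list(base)

    return ScenarioInputs(
        spec=spec,
        years=range(spec.baseline_year + 1, spec.horizon + 1),
        components=components,
        supplies=supplies,
        profiles=baseline.profiles,
        items=baseline.items,
        config=baseline.config,
    )

def scenario_trade_vnfs(
    inputs: ScenarioInputs,
) -> dict[str, dict[str, float]]:
    """Trade-considered VNFs per country and category under the scenario.

    Domestic VNFs follow from the scenario NUE chains; the regional
    average is the unweighted mean over the participating countries; the
    blend uses the mean baseline self-sufficiency of each country's
    category.
    """
    countries = sorted(inputs.components)
    doms = {
        country: {cat: domestic_vnf(comp) for cat, comp in per_cat.items()}
        for country, per_cat in inputs.components.items()
    }
    cats = sorted({cat for per_cat in doms.values() for cat in per_cat})
    avg = {
        cat: regional_average_vnf(
            [doms[c][cat] for c in countries if cat in doms[c]]
        )
        for cat in cats
    }
    trade: dict[str, dict[str, float]] = {}
    for country in countries:
        any_religion = next(
            recs for (c, _), recs in inputs.supplies.items() if c == country
        )
        ss_sum: dict[str, list[float]] = {}
        for s in any_religion:
            cat = inputs.items[s.item_id].category
            ss_sum.setdefault(cat, []).append(min(s.self_sufficiency, 1.0))
        trade[country] = {}
        for cat, dom in doms[country].items():
            ss = sum(ss_sum.get(cat, [1.0])) / len(ss_sum.get(cat, [1.0]))
            trade[country][cat] = trade_considered_vnf(ss, dom, avg[cat])
    return trade


def scenario_footprint(inputs: ScenarioInputs) -> list[FootprintResult]:
    """Per-capita footprints under a scenario's (frozen) annual inputs.

    Returns per-religion and population-weighted results per country plus
    the regional averages, evaluated at the scenario's representative
    year (inputs are constant over 2014-2050 by construction).
    """
    trade = scenario_trade_vnfs(inputs)
    year = inputs.spec.baseline_year
    results: list[FootprintResult] = []
    country_totals: list[FootprintResult] = []
    for country in sorted(inputs.components):
        profiles = inputs.profiles[country]
        agg_prod = agg_cons = 0.0
        agg_breakdown = {c: 0.0 for c in CATEGORIES}
        for profile in profiles:
            solo = replace(profile, population_weight=1.0)
            res = country_footprint(
                country, year, inputs.supplies[(country, profile.religion)],
                inputs.items, trade[country], [solo], inputs.config,
            )
            rel = res[0]
            results.append(rel)
            w = profile.population_weight
            agg_prod += w * rel.production_nf
            agg_cons += w * rel.consumption_nf
            for c in CATEGORIES:
                agg_breakdown[c] += w * rel.per_category_breakdown.get(c, 0.0)
        total = FootprintResult(
            scope=country, religion="all", year=year,
            production_nf=agg_prod, consumption_nf=agg_cons,
            total_nf=agg_prod + agg_cons, per_category_breakdown=agg_breakdown,
        )
        results.append(total)
        country_totals.append(total)
    results.extend(regional_footprint(results))
    return results
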