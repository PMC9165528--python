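"""Shared test utilities: brute-force oracles and random fixtures."""

import numpy as np

from nfootprint.core_io import CATEGORIES, FoodItem, SupplyRecord, default_profile


def oracle_country_footprint(country, year, supplies, items, vnfs, profiles,
                             denit=0.0):
    """Independent triple-loop evaluation of the footprint sums."""
    total = 0.0
    per_rel = {}
    for p in profiles:
        acc = 0.0
        for s in supplies:
            if s.country != country or s.year != year:
                continue
            it = items[s.item_id]
            if it.category not in p.allowed_categories:
                continue
            intake = (
                s.protein_supply * 365 / 1000 * it.protein_to_n * (1 - s.food_waste)
            )
            acc += intake * vnfs[it.category] + intake * (1 - denit)
        per_rel[p.religion] = acc
        total += p.population_weight * acc
    return per_rel, total


def random_fixture(rng, n_countries=3, n_items=10):
    """Random multi-country, multi-item, five-community footprint inputs."""
    countries = [f"country{i}" for i in range(n_countries)]
    cats = list(CATEGORIES)
    items = {}
    for i in range(n_items):
        cat = cats[i % len(cats)]
        items[f"item{i}"] = FoodItem(f"item{i}", f"item {i}", cat,
                                     protein_to_n=rng.uniform(0.1, 0.2))
    supplies = [
        SupplyRecord(c, 2013, iid, rng.uniform(0, 30), rng.uniform(0, 0.3),
                     rng.uniform(0, 1))
        for c in countries
        for iid in items
    ]
    vnfs = {cat: rng.uniform(1, 12) for cat in CATEGORIES}
    w = rng.dirichlet(np.ones(5))
    profiles = [
        default_profile(r, float(wi))
        for r, wi in zip(["Muslim", "Hindu", "Buddhist", "Christian", "Others"], w)
    ]
    profiles[-1] = default_profile(
        "Others", 1.0 - sum(p.population_weight for p in profiles[:-1])
    )
    return countries, items, supplies, vnfs, profiles
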