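# nfootprint

Religion-sensitive food nitrogen-footprint accounting for the Indian
Subcontinent (Bangladesh, India, Pakistan, Sri Lanka, Nepal, Bhutan), with
diet/efficiency reduction scenarios to 2050 and a from-scratch recurrent
forecaster.

## The problem

Most reactive nitrogen (Nr — every N species except inert N₂) released by
agro-food systems is lost during food production; the rest leaves with human
excreta. The per-capita **food N footprint** (kg-N·capita⁻¹·yr⁻¹) sums both:

```
NF_c = Σ_m Σ_n  W_nc · ( production NF_mnc + consumption NF_mnc )

production NF_mnc  = protein supply_mnc · N content_m · (1 − waste_mc) · trade VNF_mc
consumption NF_mnc = protein supply_mnc · N content_m · (1 − waste_mc) · (1 − denitrification)
```

where `m` indexes food items, `n` religious communities, and `W_nc` is the
population share of community `n` in country `c`. The region is the world's
most religiously diverse: Hindus are modelled as lacto-vegetarians (no meat,
eggs or fish), Buddhists as vegetarians (additionally no dairy), while
Muslims, Christians and other communities carry no category-wide
restriction. The denitrification ratio defaults to 0 (no N-removing sewage
treatment in the region), so the consumption term equals the food N intake.

The **virtual nitrogen factor** (VNF, kg-N lost per kg-N of food N consumed)
is the reciprocal of the chain's nitrogen use efficiencies,

```
VNF = 1 / (cultivation NUE · processing NUE · consumer NUE)
```

with the cultivation NUE a mass-balance quotient over crop N budgets
(harvested N over fertilizer + manure + deposition + fixation + seed N).
Imports are handled by blending each country's domestic VNF with the
regional average, weighted by the commodity's self-sufficiency ratio
(**trade-considered VNF**).

Four scenarios transform a 2013 baseline through 2050: business-as-usual
(**BAU**), a 30% increase of crop cultivation NUEs (**NUE**), a
religion-sensitive shift of protein supplies toward the EAT-Lancet
planetary health diet shares anchored at 51 g protein/day (**EAT_LANCET**),
and both combined (**INTEGRATED**). Annual series are projected with a
minimal LSTM cell (`h_t = o_t ⊙ tanh(C_t)`) implemented from scratch and
reported with its fit RMSE.

Because the historical FAO food-balance-sheet stack is not shipped, the
package includes a synthetic-data generator that emulates its structure
with known ground truth, plus packaged transcriptions of the published
regional VNF table and diet-share recommendations.

## Worked example

```python
import nfootprint as nf
from nfootprint.nue_vnf import regional_average_vnf

# regional average VNF recomputed from the packaged printed table
t1 = nf.table1_fixture()
vals = [t1[c]["milk and dairy products"]["1960s"] for c in nf.ISC_COUNTRIES]
print(f"regional milk/dairy VNF, 1960s: {regional_average_vnf(vals):.2f}")

# synthetic world -> 2013 baseline -> scenario footprints
world = nf.generate_world(nf.WorldSpec(seed=1))
base = nf.baseline_inputs(world, 2013)
for name in ("BAU", "NUE", "EAT_LANCET", "INTEGRATED"):
    inputs = nf.build_scenario_inputs(nf.scenario_spec(name), base)
    res = nf.scenario_footprint(inputs)
    total = [r for r in res
             if r.scope == "ISC average" and r.religion == "all"][0].total_nf
    print(f"{name:<11} {total:6.2f} kg-N per capita per year")
```

prints

```
regional milk/dairy VNF, 1960s: 12.07
BAU          17.62 kg-N per capita per year
NUE          15.17 kg-N per capita per year
EAT_LANCET   14.92 kg-N per capita per year
INTEGRATED   12.78 kg-N per capita per year
```

The first line is the unweighted six-country mean of the published
trade-considered VNFs for dairy in the 1960s. The scenario block shows the
population-weighted regional footprint of the synthetic world frozen at its
2013 inputs (BAU) and under each intervention: raising cultivation NUEs 30%
cuts the production side, the healthy-diet shift moves protein toward
lower-VNF plant categories and anchors intake at 51 g/day, and the combined
scenario is lowest. Absolute levels reflect the synthetic world's generating
parameters, not historical estimates.

A CLI mirrors the library: `nfootprint simulate | vnf | footprint |
scenario | forecast` (see `nfootprint --help`).

## Layout

- `nfootprint.core_io` — domain types, CSV/YAML readers and writers, decade buckets
- `nfootprint.nue_vnf` — NUE budgets, domestic/trade VNFs, decadal tables
- `nfootprint.footprint` — religion-weighted footprint accounting
- `nfootprint.diet_scenarios` — EAT-Lancet alteration rule and the four scenarios
- `nfootprint.forecast` — from-scratch LSTM, projection, RMSE
- `nfootprint.synthetic_data` — world generator, ground truth, packaged table fixtures

See `docs/methods.md` for model details, parameter defaults and limitations.
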