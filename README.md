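# reefspectra

Size-based, energy-flux modelling of coral-reef fish communities under
habitat degradation, mangrove-nursery subsidies and fishing.

## The problem

Structurally complex reefs are full of crevices in which fish hide from
their predators; degraded reefs are not.  Mangrove nurseries let juvenile
fish skip the most dangerous phase of reef life and migrate to the reef at
~16–18 cm body length.  How do these two habitat effects interact in
setting the standing stock and fisheries productivity of reef fish?
`reefspectra` addresses this with a mechanistic community model for
scientists studying reef fisheries and habitat management: predator,
herbivore and invertebrate **size spectra** coupled to turf-algae and
detritus pools, with predation routed through a size-preference kernel and
gated by refuge availability.

## The model in brief

Each trophic group's abundance density N(m) on a log body-mass grid obeys
the McKendrick–von Foerster equation

    ∂N/∂t = −∂(gN)/∂m − μ(m) N + sources,

with growth g(m) fuelled by ingestion (kernel-weighted vulnerable prey for
predators; algae or detritus for the other groups), and mortality μ from
predation, an allometric background rate, senescence and optional fishing
F on fish above the fished size limit.  A crevice census in 5-cm size
classes is mapped through the length–weight allometry W = 0.025 L³ onto
the mass grid; with N occupants and R refuges in a bin, only the surplus
V = max(0, (N−R)/N) is vulnerable to predation.  Habitat degradation
deletes the 5–30 cm crevices and halves the rest.  A mangrove nursery adds
a constant flux of predators and herbivores into the 16–18 cm bins.  Every
step closes an exact mass budget (growth, defecation, respiration, death,
catch, production), which the integrator verifies continuously.

The package follows the statsmodels model/results idiom:

```python
import reefspectra as rs

census  = rs.gen_crevice_sites(rs.SynthConfig(seed=1))[0]   # one reef
nursery = rs.NurserySupplement("mangrove", 0.96, 0.10)

model  = rs.ReefEcosystemModel(census, nursery=nursery)
result = model.fit()                  # integrate to equilibrium
print(result.summary())
```

## Worked example: the habitat × nursery factorial

The study design crosses 7 healthy-reef crevice censuses (and their 7
degraded counterparts) with 16 mangrove supplement sites and a no-nursery
arm — 238 scenarios per fishing level:

```python
import reefspectra as rs

cfg     = rs.SynthConfig(seed=1)
reefs   = rs.gen_crevice_sites(cfg)         # 7 healthy censuses
mangals = rs.gen_supplements(cfg)           # 16 supplement sites

scenarios = rs.build_factorial(reefs, mangals, F_levels=(0.0,))
results   = rs.run_all(scenarios, rs.ModelParams(), rs.SizeGrid.build())
summary   = rs.summarize(results)

for line in [
    ("mangrove effect, predator biomass, degraded reefs ",
     summary.mangrove_percent_change("biomass", "predators", "low")),
    ("mangrove effect, predator biomass, healthy reefs  ",
     summary.mangrove_percent_change("biomass", "predators", "high")),
    ("mangrove effect, herbivore biomass, healthy reefs ",
     summary.mangrove_percent_change("biomass", "herbivores", "high")),
    ("complexity effect, predator biomass (no nursery)  ",
     summary.complexity_percent_change("biomass", "predators", mangrove=False)),
    ("predator growth, degraded+mangrove vs healthy+mangrove",
     summary.growth_ratio_percent("predators")),
]:
    print(f"{line[0]}: {line[1]:+.1f}%")
```

With the shipped reference parameterisation this prints:

```
mangrove effect, predator biomass, degraded reefs : +46.6%
mangrove effect, predator biomass, healthy reefs  : +20.9%
mangrove effect, herbivore biomass, healthy reefs : -0.6%
complexity effect, predator biomass (no nursery)  : +148.6%
predator growth, degraded+mangrove vs healthy+mangrove: +292.8%
```

Read these as: nursery access raises equilibrium predator standing stock
(more strongly on degraded reefs), slightly depresses herbivores on
healthy reefs (their predators profit), structural complexity is the
dominant positive control on unfished predator biomass, and predators on
degraded-but-subsidised reefs grow roughly three times as fast per capita
as on healthy subsidised reefs because more of their prey is exposed.
With moderate fishing (F = 0.4 yr⁻¹) the balance shifts: the nursery gap
in predator biomass comes to rival and exceed the complexity gap, because
fishing removes the large predators that would otherwise consume the
subsidised immigrants.

A command-line interface mirrors the library
(`reefspectra synth | simulate | factorial | summarize | stats`).

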