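# Methods

## The model

`reefspectra` simulates a Caribbean fore-reef community as three coupled
body-size spectra — predatory fish, herbivorous fish, and detritivorous
invertebrates — together with two unstructured resource pools, turf algae
and detritus.  Abundance is resolved on a shared logarithmic body-mass grid
(120 bins from 0.1 mg to 20 kg by default, so that small invertebrate prey,
1-cm fish recruits and apex predators all live on one coordinate).  Each
spectrum obeys the McKendrick–von Foerster transport equation

    ∂N/∂t = −∂(g(m) N)/∂m − μ(m) N + sources,

where somatic growth g(m) moves individuals up the mass axis and mortality
μ(m) removes them.  The discretisation is first-order upwind in mass; in time, all per-capita
rates are evaluated once per step on the current state and the linear
update they imply (exponential removal by total mortality, upwind
transport, constant inflows, closed-form pool relaxation) is integrated in
automatic sub-steps sized so no bin turns over more than ~50% per
sub-step.  The number flux between adjacent bins is defined so that the
biomass created by transport equals the growth budget exactly (see *Mass
accounting*).

### Feeding

Predators feed on all three spectra through a log-normal size-preference
kernel centred on a preferred predator:prey mass ratio (default e^4.16 ≈ 64)
with width σ (default ≈ 2 ln units, a deliberately broad diet: reef
piscivores and invertivores take prey over several orders of magnitude of
body mass).  Per-capita encounter is the volumetric search rate
A(m) = γ m^q (q = 0.8) times the kernel-weighted *vulnerable* prey biomass.
Realised intake is bounded in two ways:

* a satiation ceiling I_max(m) = i_max m^q;
* Beddington–DeAngelis interference: encounter is divided by
  (1 + η B_pred), where B_pred is total predator standing stock.
  Interference represents contest behaviour among predators over the same
  prey field.  It is also the model's key dynamical stabiliser: without it
  the degraded-habitat (refuge-poor) scenarios relax onto maturation-delay
  predator–prey limit cycles rather than fixed points, and no equilibrium
  would exist to report.  We verified the cycles are dynamical rather than
  numerical (they persist under dt refinement) and that interference at the
  default η removes them in every scenario of the factorial design.

Herbivores graze the turf-algae pool and invertebrates consume detritus,
both with saturating (Michaelis–Menten) uptake in the pool size.  Within a
time step no prey bin can lose more than its vulnerable biomass and no pool
can go negative; when a cap binds, the affected consumers' realised intake
is scaled down consistently, so consumed biomass always equals realised
intake.

### Refuges and vulnerability

Reef structural complexity enters as the density and size distribution of
crevices, measured (or synthesised) in 5-cm size classes.  A fish shelters
in a crevice matching its own body length, so a class [L1, L2) cm protects
the body-mass range [0.025 L1³, 0.025 L2³) g via the length–weight
allometry W = 0.025 L³.  Crevice densities are apportioned over the mass
bins proportionally to overlap in log mass, conserving total refuge count.
At each step the vulnerable fraction of a fish bin with N occupants and R
refuges is V = max(0, (N − R)/N): refuges fill first, the surplus is
exposed.  Predators and herbivores compete for the *same* crevices — V is
computed from their combined occupancy and each group is exposed pro rata
— so a predator influx can displace herbivores from shelter on complex
reefs.  This makes vulnerability density dependent and is the only pathway
by which habitat quality affects the dynamics.  Invertebrates (cryptic
infauna) do not compete for fish crevices and are always fully exposed.
Fish below 5 cm are smaller than the smallest measured crevice class and
are never sheltered.

Habitat degradation is modelled as the loss of branching-coral structure:
crevice classes within [5, 30) cm are removed entirely and classes at or
above 30 cm are halved (larger holes in the underlying topography persist).

### Mortality, recruitment, subsidies, fishing

Total mortality is predation (each predator bin's realised intake is
distributed over prey bins proportionally to kernel-weighted vulnerable
biomass and converted to numbers by prey mass) plus an intrinsic background
rate μ_b = c m^(−1/4), plus a senescence term k_s (m / m_s) that closes each
spectrum at the group's characteristic maximum size (defaults: predators
5 kg, herbivores 2 kg, invertebrates 50 g), plus fishing mortality F applied
to fish above the fished size limit (default 15 cm, just below the nursery
migration size so that subsidised fish are immediately catchable).

Each group receives a constant larval/boundary recruitment flux into its
smallest bin: fish settle at 1 cm (0.025 g), invertebrates enter at the
grid base.  Recruitment is identical across scenarios so habitat and
nursery effects are never confounded with recruitment differences.

A mangrove nursery is a standing pool of juvenile fish measured as
densities per m² of mangrove.  Because the mangrove area around the study
reefs is roughly twice the reef area, densities are doubled, and the pool
emigrates onto the reef at a fixed per-capita rate (`replenishment_rate`),
entering the spectrum uniformly over the bins whose length falls in the
16–18 cm ontogenetic-migration window.  Expressing the subsidy as a rate
makes the annual flux independent of the integration step.  The default
rate (0.053 yr⁻¹) is part of the reference calibration below.

### Mass accounting

Every step closes an exact budget.  Ingested mass splits into growth
(conversion efficiency ε), defecation to detritus (δ), and respiration
(1 − ε − δ).  Non-predation deaths flow to detritus; fishing catch,
respiration, algal turnover losses and detrital burial are exports; algal
production, larval recruitment and nursery subsidies are imports.  The
integrator records the residual

    Δ(fish + algae + detritus) + exports − imports

at every step; it is zero to floating-point round-off (≲10⁻¹² g m⁻² in
practice), and the test suite asserts |residual| < 10⁻⁸ of system biomass
at every step of every run it performs.  Growth that cannot be realised as
transport (chiefly the top bin, which has nowhere to grow) is re-routed to
respiration, so the budget closes under all caps.

### Equilibrium

A run is declared at equilibrium when the within-window spread
(max − min)/mean of every group's standing stock over a trailing 10-year
window falls below `eq_tol` (default 10⁻⁶).  The spread criterion cannot be
satisfied momentarily by an oscillation passing through a turning point,
which a point-to-point change criterion can.  The default horizon is 400
years.  Because the sub-stepped update integrates the frozen-rate system
accurately within each step, the equilibrium is insensitive to dt (halving
dt moves equilibrium biomasses by ~0.1%); dt defaults to 0.05 yr.

## Reference parameterisation

The dynamical core's functional forms and rate constants are the package's
own reference parameterisation for an unfished Caribbean fore-reef.
Allometric exponents (q = 0.8 search/intake, −1/4 background mortality),
the log-normal mass-ratio kernel, and conversion efficiency ε = 0.285 follow
standard size-spectrum practice.  The remaining free coefficients — search
rate, satiation, interference, recruitment fluxes, benthic productivity and
the nursery replenishment rate — were calibrated once, jointly, so that the
factorial experiment (below) reproduces the documented community-level
behaviour of Caribbean reefs: fish standing stocks of order 10–100 g m⁻²,
herbivores outweighing predators, strong positive biomass responses of both
fish groups to structural complexity, moderate positive (predators) and
weak negative (herbivores) responses to nursery access, and faster
per-capita predator growth on refuge-poor reefs where more prey is exposed.
After calibration the defaults were frozen; all results in the README and
the acceptance script are computed with them.

## The factorial experiment

Seven healthy-reef crevice censuses define the high-complexity habitats;
applying the degradation transform to each yields the seven low-complexity
counterparts.  Sixteen mangrove supplement sites define the nursery arm.
Per fishing level the design is 14 non-nursery scenarios (7 habitats × 2
complexity levels) plus 224 nursery scenarios (16 supplements × 14), i.e.
238 scenarios, each integrated to equilibrium from the same initial state.
Summaries aggregate scenario-level equilibrium metrics into cells
(complexity × mangrove × fishing), reporting cell means, sample variances
(ddof = 1) and standard errors; headline percentage contrasts are ratios of
cell means, and the growth contrast is the ratio of abundance-weighted mean
specific growth over the fished size range between cells.  Standing stock
is Σ N m per group; fisheries productivity is Σ g(m) N(m) over bins above
the fished size limit — a production rate, not a stock.

## Synthetic inputs

The generators provide inputs with the structure the analysis assumes:

* **Crevice censuses** decline geometrically with class size (base density
  0.8 m⁻² in the 5–10 cm class, ratio 0.55 per class by default) with
  mean-one lognormal site noise — the qualitative shape of published
  crevice-size distributions, since the original census tables are not
  reproduced here.
* **Nursery supplements**: 16 sites, lognormal densities (CV 0.6) rescaled
  so the group means sit exactly at 0.96 predators and 0.10 herbivores per
  m² — nursery habitats in this region are strongly predator-dominated.
* **Field surveys**: six regions (three mangrove-rich, three
  mangrove-poor), ≥3 sites each; mangrove-poor sites follow
  log10(biomass) = 3.20 + 0.589 × rugosity plus region effects and
  lognormal site noise; mangrove-rich sites are flat in rugosity with
  site-level noise inflated 2.5-fold, anchored to the same expected biomass
  at mid-range rugosity so the treatments differ only in the effects under
  study.  Rugosity is drawn from a shared range, so the treatments are
  unconfounded by construction.

What the generators do *not* emulate: spatial autocorrelation among sites,
observation error in fish counts, seasonal pulses of migration, and any
correlation between crevice abundance and nursery quality.  Tests passing
on synthetic data therefore demonstrate correctness of the machinery and
internal consistency of the analysis, not agreement with any particular
real reef.

## Field-survey statistics

The survey module fits per-treatment OLS of log10(carnivore biomass) on
rugosity, compares biomass dispersion between treatments via standardised
z-scores (each site expressed in SDs from the shared mean of all sites;
|z| compared with a two-sided Mann–Whitney U), and checks for a rugosity
confound by comparing region-mean rugosity between treatments with Welch's
t-test.  The original analyses used linear mixed-effects models with region
as a random effect; aggregation to region means is a deliberate,
documented approximation that keeps every statistic verifiable against a
closed-form oracle.

## Numerical choices and degenerate inputs

* Bins are geometric-mean midpoints of log-spaced edges; transport moves
  individuals between adjacent midpoints, adding exactly the midpoint mass
  difference per individual.
* Vulnerability at an empty bin is 0 by convention (nothing is exposed).
* Within-step limits (pool exhaustion, per-sub-step transport bounds)
  scale realised rates rather than clipping state, so spectra never go
  negative and the budget stays closed; genuine clip events are counted
  and are zero in all converged reference runs.
* The regression on a constant response returns slope 0, R² = 0, p = 1
  rather than an error; a zero pooled SD in the dispersion contrast is an
  error (the statistic is undefined).
* Simulation sizes in the test-suite and acceptance script (400-year
  horizon, 120 mass bins, dt = 0.05 yr) are the package's reference
  problem sizes, chosen to resolve the crevice size classes and converge
  the factorial comfortably.

## Known limitations

* The three groups are aggregate spectra: no species identities, no
  taxonomy-specific diets or refuge preferences.
* Recruitment is a constant boundary flux — no stock–recruitment feedback,
  no larval supply variability.
* The nursery is a boundary flux only; mangrove internal dynamics, nursery
  quality and distance effects are outside the model.
* Interference is global (one η against total predator biomass) rather
  than local to each predator's prey field.
* Percentage contrasts depend quantitatively on the reference
  parameterisation; the original study's parameter tables are not
  reproduced here, so magnitudes should be read as the behaviour of this
  calibration, with the directions and orderings being the robust output.
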