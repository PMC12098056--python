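# Methods

This note documents the model implemented in `bombusim`: its assumptions,
the parameters that matter, the synthetic data it runs on, and the design
choices made where the design was genuinely open.

## Trip durations and the two handling-time engines

A nectar foraging trip lasts `F = 2·Δs/v + Th` — flight out and back at
speed `v` (default 5 m/s) plus the handling time `Th` for one crop load
(default crop 120 µl). Both engines scale with the patch **filling level**
`γ = nectar stock / daily capacity`, a volume-based proxy for the fraction
of flowers still filled, and both are capped at `Tmax` (default 3600 s) so
nearly-empty patches cannot generate unbounded trips.

**Mechanistic engine.** Per flower: access time `Ta = 0.3 + 0.04·C` s and
ingestion time from Harder's regression

`Ti = log10(V+1) / log10(0.3·W^(1/3)·G^1.41·(1−C/G)^0.4) − 0.3·Ta + 1`.

The typeset form of this regression is ambiguous in secondary sources; the
parse adopted here is the one that is finite at `C = 0` and has a vertical
asymptote where the log10 argument crosses 1 — for `G = 11.1` mm and
`W = 0.195` g the pole sits at `C ≈ 10.92` mm, just below the glossa
length, which matches the documented behaviour ("minor changes in the
corolla-depth/glossa-length ratio near the pole produce large handling-time
differences"). At or past the pole, and whenever `C ≥ G`, the engine
returns an unbounded sentinel that the `Tmax` cap absorbs; the same
happens for `γ = 0`. Total handling is
`Th = ((Tt + Ta)/γ + Ti) · ceil(crop/V)`; prose sources state that both
`Tt` and `Ta` scale with the filling level, fixing the `(Tt+Ta)/γ`
grouping.

**Fixed engine.** `Th = FixedHandlingTime_s/γ`, capped. By construction it
ignores all morphology (`C`, `V`, `W`, `G`); the test suite verifies that
perturbing corolla depths and glossa ranges leaves fixed-engine runs
byte-identical (these remain "dummy values" in the parameter files).

## Foraging mortality

Three built-in per-second hazards: high `1×10⁻⁵` (honeybee-derived, the
default), intermediate `2.14×10⁻⁶` (*Bombus lucorum* field estimate), low
`2.75×10⁻⁷` (multi-species, multi-site estimate). Survival of a trip of
duration `F` is `exp(−r·F)` — at these rates indistinguishable from
`(1−r)^F` (< 0.1 %) and additive in exposure. Mortality is applied once
per completed trip on the full duration; a forager that dies does **not**
deliver its load (the patch is still depleted — the load is lost en
route), a choice made explicit because the original description leaves it
open.

## Colony life cycle (simplified surrogate)

The colony model is a deliberately compact surrogate for the full
individual-based life cycle of the model family it emulates, with every
constant configuration-exposed (`ColonyParams`):

* **Calendar.** 365-day years. Queens emerge Mar 1 – Apr 15 (uniform per
  individual), search for nest sites (hedgerow/scrub patches; the
  landscape caps simultaneous colonies), and found with daily probability
  0.2. Sexual production runs from Jul 15; all colony activity stops
  Oct 31; overwinter survival (0.3) is applied to the year's hibernating
  queens on Dec 31. Census on the final Dec 31 is the population proxy.
* **Energetics.** Nectar (µl) is the single energy currency. Adults
  consume 40 µl/day (queen 60), larvae 20 µl/day plus 4 mg pollen/day
  over a 28-day aggregated development; workers live 30 days. Foraging
  itself costs 0.06 µl of nectar per second of trip time — approximately a
  0.6 W flight metabolic rate fuelled by nectar at ~10 J/µl. This single
  number fixes the break-even trip duration at `120/0.06 = 2000 s`, which
  is why 1800 s and 3600 s fixed handling times (trips ≥ ~2000–4300 s)
  starve every population regardless of the mortality model, while 900 s
  remains marginally viable — the extinction boundary emerges from
  energetics, not from a tuned mortality term.
* **Demand-driven foraging.** Each worker has a 28 800 s (8 h) daily
  foraging budget (founding queens 14 400 s, the rest incubation).
  Foragers choose nectar vs. pollen by the larger relative store deficit
  and stop when stores meet their targets (a reserve of three days'
  consumption, plus a queen-rearing hoard in the sexual phase). Patch
  choice maximises expected intake rate (expected load / expected trip
  duration at current γ) over memorised patches, with exploration
  probability 0.1 (forced when the memory is empty); ties break to the
  lowest patch id; foraging is abandoned when the best candidate's rate
  falls below 0.01 µl/s (nectar) or 10⁻⁵ g/s (pollen). The floor stops
  agents from grinding near-empty patches at `Tmax` per visit, yet is low
  enough that full-patch trips in the 3600 s scenarios (≈ 0.03 µl/s) are
  always taken.
* **Reproduction feedbacks.** Egg laying (≤ 2/day) is scaled by store
  fullness relative to the maintenance reserve, so brood demand tracks
  what the landscape actually supports; workers are reared through autumn,
  otherwise the 30-day lifespan would dissolve every colony weeks after
  the sexual switch. New queens are produced from the nectar surplus above
  the reserve at 1200 µl each, bounded by the worker population; the hoard
  target scales as 0.05 queens per worker per day, making seasonal queen
  output roughly proportional to workforce — the channel through which
  both foraging mortality and handling-time costs reach the population
  response. Colonies die after 2 consecutive days with an empty nectar
  store, or with their queen.
* **Pollen.** The pollen-trip mechanism is intentionally simple (it is not
  the subject of the experiment): duration `2Δs/v + 300 s/γ_pollen`,
  capped at `Tmax`, 0.1 g per load. Pollen is plentiful in the default
  landscape, so it constrains brood only transiently; simulated pollen
  trip means (≈ 420 s) sit in the plausible range and respond only weakly
  to the nectar handling engine.

## Synthetic landscape

`generate_landscape` draws a seeded, resource-poor mixed farm on a
4 × 4 km square: 32 point patches with habitats drawn from area fractions
(semi-improved pasture 0.30, permanent pasture 0.25, maize 0.20, hedgerow
0.10, scrub 0.10, flower-rich plot 0.05), each monospecific with a daily
nectar/pollen capacity (full daily reset within the species' flowering
window — there is no sub-daily secretion model, so the day's capacity is
the day's supply). Maize offers a brief pollen pulse and no nectar.
Distances are Euclidean; patches are points.

Two knobs set the ecological regime and were calibrated once, against the
declared target that the mechanistic baseline persists with year-end queen
counts in the hundreds (not thousands):

* `richness = 14` scales all capacities; it leaves enough slack that
  foragers mostly sample high filling levels, keeping mean trip durations
  cap-limited-linear in `FixedHandlingTime_s`, while the farm remains poor
  enough that populations stay in the hundreds.
* one nest site per hedgerow/scrub patch caps simultaneous colonies at
  ≈ 6 on the default map, in line with the handful of colonies such a farm
  supports.

What the generator does **not** emulate: real spatial autocorrelation of
habitats, within-day nectar secretion, weather, multi-year floral
turnover, or competing pollinator guilds. Passing behavioural tests on
this landscape therefore demonstrate the mechanisms (engine switching,
depletion scaling, mortality exposure, energetic extinction), not
site-specific predictions for any real farm.

## Experiment and statistics

The scenario grid is `ORG` (mechanistic engine, high mortality) plus
{LOW, MED, HIGH} × {112.5, 225, 450, 900, 1800, 3600} s — 19 scenarios,
run by default for 5 years (1825 daily steps) with 100 initial queens and
20 replicates (the shipped behavioural test suite uses 5 replicates to
keep its runtime near five minutes on one CPU). Replicate seeds derive
from (master seed, scenario name, replicate index) and are recorded in the
summary table. The "mean trip duration" statistic weights daily mean
durations by daily trip counts, which the tests verify equals the grand
mean of the per-trip log to machine precision; "colonies in the last
3 years" is the mean daily colony count over timesteps 731–1825.

## Numerical and design notes

* One master seed feeds named, independent RNG streams (placement,
  emergence, nest search, mortality, exploration, trait draws, scheduling
  order), so adding draws to one process never shifts another; agent
  iteration order is re-randomised daily.
* Degenerate inputs: zero patch capacity ⇒ filling level 0 ⇒ capped
  handling; depletion requests clamp at the stock and never go negative;
  zero-trip days carry no mean duration rather than a zero.
* Per-forager Harder terms (`Ta`, `Ti`, `Nflowers`) depend only on
  morphology and species constants and are cached per forager; patch
  choice is vectorised over candidate patches.
* Known limitations: cohort-free brood accounting (a list of ages), no
  male production, no badger predation, single bee species in the default
  tables (the table format supports several), and the pollen module is a
  stand-in. Population magnitudes are desk-scale: ordering and extinction
  patterns are the supported results, not absolute queen counts.
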