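# Methods

## Scope and model structure

`rhizoweed` simulates a non-spatial population of a perennial grass that
reproduces sexually (seeds) and clonally (rhizomes) on a single field,
under a fixed annual management program. One time step is one year; within
a year, events are ordered by days after the start of the season (DASS) but
the simulation is event-ordered, not day-stepped: dates matter only for
which applications a plant is exposed to and for its fecundity.

Seven life-history stages are represented: seeds (a pooled seedbank with
per-seed genetics, not scheduled as agents), seedlings, vegetative tillers
(including regrown tillers), adult plants, and primary / secondary /
tertiary rhizomes. All cohorts are stored as struct-of-arrays so a
replicate with tens of thousands of individuals runs in milliseconds.

The within-season schedule is:

1. primaries → Poisson-branched secondaries → one apical tiller per crown
   (Weibull emergence dates); spare nodes held as reserve meristems;
2. Bernoulli germination of the seedbank (26%) into seedlings (Weibull
   dates); non-germinating seeds are lost, not carried over (see below);
3. establishment survival draw for fitness-cost carriers;
4. clean-field removal of plants emerging strictly before sowing; removed
   tillers may regrow from reserves (emerging sowing + 21 d);
5. early POST application (30 d after sowing): foliar mortality on plants
   emerged by the application date, reduced mortality on rhizomes; killed
   apical tillers regrow 21 d later if their rhizome lives and reserves
   remain;
6. late POST application (30 d after early): foliar mortality on every
   plant of the season (its reduced efficacy folds in late emergers),
   rhizome mortality again;
7. census of standing live plants; control failure when density strictly
   exceeds 5 plants/m²;
8. if not failed: seed production into next season's seedbank, tertiary
   rhizome production (clones of adults), Bernoulli winter mortality of
   tertiaries → next season's primaries. Aboveground biomass and the
   spent primary/secondary rhizomes do not survive winter.

Intraspecific competition, explicit crop growth, spatial dispersal, and
herbicide decay kinetics are out of scope; interspecific competition with
the crop is represented solely by the exponential decline of fecundity
with emergence date.

## Resistance genetics

**Single dominant gene** (ACCase-inhibiting herbicides). A diploid nuclear
locus with alleles R/S; initialization is Hardy–Weinberg at allele
frequency *q* (so the initial resistant fraction ≈ 2*q* for rare alleles:
*q* = 10⁻⁵ ↔ 0.002%, *q* = 10⁻⁷ ↔ 0.00002%). Dominance is 1: RR and RS
survive applications with probability 1, SS escapes with probability
(1 − efficacy) per component. Seeds self with probability 0.95, otherwise
outcross to a father drawn uniformly from all adults alive at seed set;
segregation is Mendelian; clones copy the genotype verbatim.

**Quantitative** (glyphosate). Each individual carries Pz, the highest
dose it survives (g a.e./ha); an application is survived outright when
Pz ≥ rate (boundary inclusive). Initial Ln(Pz) ~ Normal(ln LD₅₀, 0.5087).
The printed value 0.5087 is interpreted as the *standard deviation* of
Ln(Pz): only that reading reproduces all three documented equivalences
between initial LD₅₀ (85 / 139 / 1,719) and initial resistant fraction
(0.00002% / 0.002% / 80%) at the 1,120 g a.e./ha rate.

Because the mating system is ~95% selfing, offspring Pz is not propagated
through the Breeder's equation. Instead the seeds of a season draw Ln(Pz)
iid from Normal(μ_parents, 1.18 × σ_parents), where μ and σ are the mean
and SD over the realized adult pool (unweighted by fecundity — emergence
date and Pz are independent, so weighting would only add noise). The
ratios (1, 1.18) come from an a-priori cross simulation, reimplemented in
`genetics.infinitesimal_cross_sim`: 20 unlinked additive diploid loci per
individual, allelic values iid Normal with variance σ²/(2·20), no
dominance, no mutation, no linkage. One generation of 95% selfing from
linkage equilibrium inflates the offspring SD by
√(0.95·1.5 + 0.05·1.0) ≈ 1.21 analytically; the simulation reports values
in that neighborhood, bracketing the adopted 1.18. The adopted ratios are
treated as fixed model constants.

**Fitness cost** (ACCase carriers only). Carriers (RR and RS equally —
the cost measurements exist for homozygotes only, and mirroring the
resistance dominance keeps the model to one assumption) suffer a single
establishment Bernoulli with survival 1 − 0.42 applied once to every new
aboveground individual (seedling, tiller, regrown tiller), and their seed
output is multiplied by 1 − 0.36. Presets: none (0, 0), literature
(0.42, 0.36), max (0.90, 0.90).

## Design decisions in the open parts of the design

* **Regrowth after the last application.** Tiller regrowth is triggered
  by the clean-field removal and by the early POST kill, not by the late
  POST kill. A replacement tiller therefore always faces at least one
  later control event. If post-late-POST regrowth matured into adults,
  every sensitive crown with spare meristems would contribute an
  untouched reproducing adult each year and chemical control could never
  suppress the population — contradicting the observed behavior that
  rare-allele scenarios stay controlled for 30 years in ~99.7% of
  replicates.
* **Rhizome mortality from applications** hits primary and secondary
  rhizomes at each POST event (tertiaries are created after the last
  event); rhizomes of resistant genets are immune, extending the
  per-architecture resistance contract to the whole genet.
* **Seedbank carryover.** Seeds failing the 26% germination draw are
  removed: the complement explicitly represents predation and loss of
  viability, not dormancy.
* **Mixtures.** A plant survives a multi-herbicide event only by
  surviving each component independently (no antagonism/synergy).
  `program_style` can instead rotate herbicides annually or split them
  between the two timings.
* **Census and classification.** The failure census counts standing live
  plants after the late application. A replicate chronicles evolved
  resistance to a herbicide when the resistant fraction of standing
  plants (per that herbicide's architecture) exceeds a threshold in any
  season with at least one plant. The threshold defaults to 0.20 of
  standing plants; it is a free operational definition — no published
  operationalization exists — and is recorded in every run manifest.
* **Tertiary rhizomes per adult** is not among the published parameters.
  Each adult clones itself into Poisson(`tertiary_rate`) tertiary
  rhizomes; the default is 2.75, in the plausible field range (2–3,
  comparable to the secondary-branching intensity) and calibrated once
  within that range against the baseline-scenario outcome (resistance
  probability ≈ 24%, failure near year 13), then frozen. It is exposed
  as a config knob and recorded in every run manifest.
* **Seedbank:tertiary-rhizome ratio.** Reported as the ratio of two
  state variables of the same season: the seedbank standing as the season
  opens (the previous season's seed production, before germination
  depletes it) and the tertiary rhizomes standing before winter. Seasons
  without tertiary rhizomes are excluded. The same-season flow ratio
  (new seeds ÷ tertiaries of the same year) is also derivable from the
  trajectories CSV but is several-fold smaller in declining populations;
  the state-variable reading is the one consistent with the published
  regional values (~5.1 South, ~11.9 North).

## Numerical choices

* Seed counts use stochastic rounding (floor plus Bernoulli on the
  fractional part): truncation would systematically zero out
  late-emerging plants whose expected fecundity is below one seed.
* Boundary conventions: strict `<` for the clean-field removal (a plant
  emerging exactly at sowing is kept); `≥` for Pz against the rate;
  strict `>` for the density threshold (exactly 5 plants/m² is not yet a
  failure).
* Degenerate inputs: σ = 0 gives a point mass at the LD₅₀; an empty
  adult pool produces no seeds or rhizomes; a replicate whose seedbank
  and rhizome bank are both empty is extinct and stops early (all later
  censuses are zero).
* RNG: one root seed spawns independent per-replicate PCG64 streams via
  `numpy.random.SeedSequence`; identical (config, seed) pairs give
  bit-identical replicates. The stream scheme is recorded in the run
  manifest.
* Weibull fitting uses least squares on the cumulative emergence curve,
  conditioned on emergence by the last evaluation date (plants emerging
  after the final survey are unobservable); an interval-censored
  maximum-likelihood option is provided. The exponential fecundity fit is
  ordinary least squares of ln(y) on x, with R² reported on that (log)
  scale.

## Sensitivity analysis

Eight ecological parameters (secondary-rhizome branching, nodes per
secondary, seed fecundity intercept+cap, initial seed and rhizome
densities, germination probability, winter mortality, emergence-date
shift) are perturbed ±10% (±1 day for emergence). All ensembles share one
root seed (common random numbers), so parameter deltas are paired
differences. A parameter is flagged sensitive when its probability delta
exceeds 5.8 percentage points or its failure-year delta exceeds 0.2 years
— the observed run-to-run variation of repeated 1,000-replicate baseline
ensembles.

## Synthetic data

`io.generate_emergence_fixture` emulates a quadrat emergence survey:
individual Weibull emergence dates binned at a handful of evaluation
dates, with plants emerging after the last visit unobserved. It does not
emulate spatial clustering between quadrats, observer error, or
within-season mortality before counting, so parameter-recovery tests
validate the estimator under sampling noise only, not under field
conditions. `generate_fecundity_fixture` produces exact or
log-normally-noised points from the exponential fecundity curve. Both
record their ground truth in a side-car JSON.

## Problem sizes

The test suite runs scenario ensembles of 250–500 replicates and the
acceptance script 1,000–9,000 per scenario (larger where the measured
probability is a fraction of a percent), sizes chosen so the whole suite
completes in minutes on a single CPU; the tolerances used alongside the
published values account for the binomial Monte-Carlo error at these
sizes. Distributional checks use 10⁴–10⁶ draws.

## Known limitations

* The glyphosate-solo pathway (low initial LD₅₀) depends strongly on how
  the offspring-SD ratio interacts with the clonal pathway: clones copy
  Pz exactly, so the adult pool's Ln(Pz) SD — dominated by tillers — does
  not compound the 1.18 seed-generation inflation. Populations under an
  effective solo program then go extinct before the tolerance tail
  reaches the application rate in most replicates, and the evolved-
  resistance probability for that configuration (~2–3%) sits below the
  published ~8%. The published model's bookkeeping of the offspring SD is
  not specified at this level of detail; this implementation follows the
  realized-parental-distribution contract.
* Fitness-cost dominance (RS vs RR) and the father-selection pool are
  modeling choices, not measurements.
* No multi-year seed dormancy, no density dependence below the ceiling,
  no herbicide-rate response curve (binary Pz threshold plus escape
  probability), one general ACCase locus rather than per-codon loci.
* The model is demographically faithful only up to the 5 plants/m²
  ceiling; beyond it the replicate stops, so trajectories never show
  saturation effects.
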