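# rhizoweed

Individual-based simulation of herbicide-resistance evolution in perennial
weeds that propagate by **both seeds and rhizomes**, parameterized for
Johnsongrass (*Sorghum halepense*) in Argentine soybean systems.

Annual weeds are well served by existing resistance models; perennials with
a clonal (rhizome) pathway are not. The clonal pathway changes the
evolutionary dynamics qualitatively: a resistant genet is copied verbatim
into next season's rhizomes, so a single resistant founder can sweep a
field without any further segregation. `rhizoweed` is aimed at weed
scientists and resistance modelers who want to ask when chemical programs
fail, how fast resistance evolves, and what tillage buys, for this kind of
life cycle.

## The model

Each simulated year (one time step) runs a full life cycle on a 10,000 m²
field until a ceiling density of 5 plants/m² is exceeded (control failure)
or a 30-year horizon ends:

1. Overwintered **primary rhizomes** branch into secondaries
   (Poisson, mean 2), each bearing Poisson(3) nodes; one apical tiller
   sprouts per crown (apical dominance), remaining nodes held in reserve.
2. A fixed fraction (26%) of the **seedbank** emerges as seedlings; the
   rest is lost to predation and loss of viability. Emergence dates *x*
   follow a two-parameter Weibull, *f(x) = (k/λ)(x/λ)^(k−1) e^−(x/λ)^k*.
3. A clean field is assumed at soybean sowing: earlier emergers are
   removed. Early and late **postemergence applications** (95% / 90%
   foliar efficacy) then remove sensitive plants; rhizomes are hit at
   reduced efficacy (25% no-till, 50% under tillage). Killed apical
   tillers regrow from reserve meristems three weeks after a kill.
4. Survivors mature, produce seeds — fecundity declines with emergence
   date, *f_i = a·e^{b·x}*, capped at a field maximum — and clone
   themselves into **tertiary rhizomes**, which face winter mortality and
   become next season's primaries.

Resistance is inherited under two architectures simultaneously:

* **single dominant gene** (ACCase-inhibiting herbicides): RR/RS/SS
  genotypes, Hardy–Weinberg initialization at allele frequency *q*,
  Mendelian segregation with 95% selfing, optional fitness cost on carrier
  survival (42%) and fecundity (36%);
* **quantitative** (glyphosate): each plant carries a tolerance phenotype
  *Pz* (the highest dose it survives), log-normal with median LD₅₀ and
  Ln-scale SD 0.5087; a plant with *Pz* ≥ the application rate survives.
  Seeds draw Ln(*Pz*) from a normal with the parental mean and 1.18× the
  parental SD (offspring/parent ratios from an a-priori 20-locus additive
  cross simulation, also included). Clones copy *Pz* exactly.

Scenario presets T1–T9 cover solo vs mixed programs, South/North regional
parameter sets, initial allele frequencies 10⁻⁷/10⁻⁵, three fitness-cost
levels, and tillage. See `docs/methods.md` for assumptions, parameter
tables, and design decisions.

## Worked example

Run a 200-replicate ensemble of the baseline scenario (T5: South, no-till,
glyphosate + ACCase mixture, q = 10⁻⁵, literature fitness cost):

```
$ rhizoweed run -s T5 -n 200 --seed 42 -o out/t5
running T5: 200 replicates, seed 42
{
  "n_replicates": 200,
  "accase_r_probability": 0.155,
  "glyphosate_r_probability": 1.0,
  "failure_probability": 0.155,
  "mean_failure_year": 13.32258064516129,
  "seedbank_rhizome_ratio": 4.686552470378272,
  "mean_accase_onset_year": 4.451612903225806,
  "mean_glyphosate_onset_year": 1.0
}
```

Reading: 15.5% of replicates evolved ACCase resistance (>20% of standing
plants resistant in some season; at 200 replicates the Monte-Carlo error
on this probability is about ±2.5 points), and in exactly those replicates
weed control failed, on average in year 13.3. The population counts as
glyphosate-resistant from year 1 because the baseline starts at 80%
resistant to glyphosate (initial LD₅₀ 1,719 g a.e./ha against a 1,120 g
a.e./ha rate) — which is why the program leans on the ACCase component.
The run directory contains `manifest.json` (full config + seed, enough to
reproduce the run exactly), per-replicate outcomes, yearly trajectories
(density, allele frequency, median Pz, seedbank, rhizome counts) as CSV,
and the JSON summary above.

Other entry points: `rhizoweed sensitivity` (±10% / ±1-day ecological
perturbations), `rhizoweed fit-emergence` / `fit-fecundity` (Weibull and
exponential fits from quadrat/plant tables), `rhizoweed fixtures`
(synthetic datasets with known truth), `rhizoweed presets`.

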