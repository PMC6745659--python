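"""Annual-cycle orchestration, 30-year replicates, and ensemble statistics.

One time step is one year. A season executes, in order: clonal sprouting
(primaries -> secondaries -> apical tillers), seedbank germination with
Weibull emergence, the clean-field removal at sowing, the early POST
application (foliar + rhizome effects), tiller regrowth three weeks later,
the late POST application, the density census against the 5 plants/m^2
control-failure threshold, then sexual reproduction into the next seedbank,
tertiary-rhizome production, and overwintering. A replicate stops at
control failure; an ensemble aggregates resistance probabilities, the mean
failure year among failing replicates, and the seedbank : tertiary-rhizome
density ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genetics import resistant_mask, sample_initial_genotypes, sample_initial_pz
from .lifecycle import (
    PlantCohort,
    RhizomeCohort,
    SeedbankPool,
    apply_foliar_herbicide,
    apply_rhizome_herbicide,
    establishment_cost_survival,
    germinate,
    overwinter,
    produce_secondary_rhizomes,
    produce_tertiary_rhizomes,
    regrow_tillers,
    remove_preplant,
    reproduce_sexually,
    sprout_tillers,
)
from .scenarios import ScenarioConfig


@dataclass
class SeasonState:
    """Between-season state: the seedbank and the overwintered primaries."""

    year: int
    seedbank: SeedbankPool
    primaries: RhizomeCohort


@dataclass
class SeasonRecord:
    """Per-season census and tallies recorded by :func:`run_season`."""

    year: int
    seedbank_start: int
    emerged: int
    adults: int
    density: float  # standing live plants / m^2 at the post-late-POST census
    accase_resistant_fraction: float
    glyphosate_resistant_fraction: float
    allele_frequency: float
    median_pz: float
    new_seeds: int
    tertiary_rhizomes: int
    failed: bool


@dataclass
class ReplicateResult:
    """Trajectories and outcome of a single 30-year replicate."""

    failure_year: int | None
    accase_resistance_year: int | None
    glyphosate_resistance_year: int | None
    seasons: list[SeasonRecord] = field(default_factory=list)

    @property
    def n_years_run(self) -> int:
        return len(self.seasons)

    def season_ratios(self) -> list[float]:
        """Seedbank:tertiary density ratios of the seasons where tertiary
        rhizomes exist.

        Both are state variables of the same season: the seedbank density as
        the season opens (before germination depletes it) and the
        tertiary-rhizome density before winter. Counts share the field
        area, so the count ratio equals the density ratio. Seasons without
        tertiary rhizomes are excluded (ratio undefined).
        """
        return [
            s.seedbank_start / s.tertiary_rhizomes
            for s in self.seasons
            if s.tertiary_rhizomes > 0
        ]


@dataclass
class SummaryStats:
    """Ensemble-level aggregation over replicates."""

    n_replicates: int
    accase_r_probability: float
    glyphosate_r_probability: float
    failure_probability: float
    mean_failure_year: float | None
    seedbank_rhizome_ratio: float | None
    mean_accase_onset_year: float | None = None
    mean_glyphosate_onset_year: float | None = None

    @classmethod
    def from_replicates(cls, results: list["ReplicateResult"]) -> "SummaryStats":
        n = len(results)
        failures = [r.failure_year for r in results if r.failure_year is not None]
        acc_years = [
            r.accase_resistance_year
            for r in results
            if r.accase_resistance_year is not None
        ]
        gly_years = [
            r.glyphosate_resistance_year
            for r in results
            if r.glyphosate_resistance_year is not None
        ]
        ratios: list[float] = []
        for r in results:
            ratios.extend(r.season_ratios())
        return cls(
            n_replicates=n,
            accase_r_probability=len(acc_years) / n,
            glyphosate_r_probability=len(gly_years) / n,
            failure_probability=len(failures) / n,
            mean_failure_year=(sum(failures) / len(failures)) if failures else None,
            seedbank_rhizome_ratio=(sum(ratios) / len(ratios)) if ratios else None,
            mean_accase_onset_year=(sum(acc_years) / len(acc_years)) if acc_years else None,
            mean_glyphosate_onset_year=(
                sum(gly_years) / len(gly_years) if gly_years else None
            ),
        )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize_state(cfg: ScenarioConfig, rng: np.random.Generator) -> SeasonState:
    """Year-0 seedbank and primary rhizomes with Hardy-Weinberg genotypes and
    log-normal Pz."""
    q = cfg.single_gene.initial_allele_freq
    n_seeds = int(round(cfg.initial_seedbank_density * cfg.field_area))
    n_rhiz = int(round(cfg.initial_rhizome_density * cfg.field_area))
    seedbank = SeedbankPool(
        genotype=sample_initial_genotypes(q, n_seeds, rng),
        ln_pz=np.log(sample_initial_pz(cfg.quant_trait, n_seeds, rng)),
    )
    primaries = RhizomeCohort(
        tier="primary",
        genotype=sample_initial_genotypes(q, n_rhiz, rng),
        pz=sample_initial_pz(cfg.quant_trait, n_rhiz, rng),
        meristems=np.zeros(n_rhiz, dtype=np.int64),
        alive=np.ones(n_rhiz, dtype=np.bool_),
    )
    return SeasonState(year=0, seedbank=seedbank, primaries=primaries)


# ---------------------------------------------------------------------------
# one season
# ---------------------------------------------------------------------------

def check_failure(density: float, threshold: float) -> bool:
    """Control failure when standing density strictly exceeds the threshold."""
    return density > threshold


def run_season(
    state: SeasonState, cfg: ScenarioConfig, rng: np.random.Generator
) -> SeasonRecord:
    """Advance the state through one season, mutating ``state`` in place.

    On control failure the replicate stops: reproduction and overwintering
    are skipped and the between-season state is emptied.
    """
    year = state.year + 1
    dom = cfg.single_gene.dominance
    cost = cfg.fitness_cost
    seedbank_start = state.seedbank.size

    # clonal sprouting
    secondaries = produce_secondary_rhizomes(
        state.primaries, cfg.rhizome_branch_mean, cfg.nodes_mean, rng
    )
    tillers = sprout_tillers(
        secondaries, cfg.tiller_emergence, rng, cfg.emergence_shift_days
    )

    # seedling emergence from the seedbank
    seedlings, state.seedbank = germinate(
        state.seedbank, cfg.p_germination, cfg.seedling_emergence, rng,
        cfg.emergence_shift_days,
    )
    plants = PlantCohort.concat(seedlings, tillers)
    emerged = plants.n
    establishment_cost_survival(plants, cost.survival_reduction, rng)

    # clean field at planting; removed tillers may regrow from reserves
    killed = remove_preplant(plants, cfg.sowing_date)
    regrown = regrow_tillers(
        secondaries, plants.source_rhizome[killed], cfg.sowing_date
    )
    establishment_cost_survival(regrown, cost.survival_reduction, rng)
    plants = PlantCohort.concat(plants, regrown)

    # POST applications; regrowth after every event except the last one,
    # so a replacement tiller always faces at least one later application
    events = cfg.events(year)
    for i, event in enumerate(events):
        killed = apply_foliar_herbicide(plants, event, dom, rng)
        apply_rhizome_herbicide(state.primaries, event, cfg.tillage, dom, rng)
        apply_rhizome_herbicide(secondaries, event, cfg.tillage, dom, rng)
        if i < len(events) - 1:
            regrown = regrow_tillers(
                secondaries, plants.source_rhizome[killed], event.date
            )
            establishment_cost_survival(regrown, cost.survival_reduction, rng)
            plants = PlantCohort.concat(plants, regrown)

    # census of standing live plants (the season's adults)
    alive = np.flatnonzero(plants.alive)
    n_adults = alive.size
    density = n_adults / cfg.field_area
    failed = check_failure(density, cfg.density_threshold)

    if n_adults:
        geno = plants.genotype[alive]
        pz = plants.pz[alive]
        acc_frac = float(resistant_mask(geno, dom).mean())
        gly_frac = float((pz >= cfg.quantitative_dose()).mean())
        allele_freq = float(geno.sum() / (2.0 * n_adults))
        median_pz = float(np.median(pz))
    else:
        acc_frac = gly_frac = allele_freq = 0.0
        median_pz = math.nan

    new_seeds = 0
    n_tertiary = 0
    if failed or n_adults == 0:
        state.seedbank = SeedbankPool.empty()
        state.primaries = RhizomeCohort(tier="primary")
    else:
        seedbank = reproduce_sexually(
            plants, cfg.single_gene.selfing_rate, cfg.quant_trait, cost,
            cfg.fecundity, rng,
        )
        tertiary = produce_tertiary_rhizomes(plants, cfg.tertiary_rate, rng)
        new_seeds = seedbank.size
        n_tertiary = tertiary.n
        state.seedbank = seedbank
        state.primaries = overwinter(tertiary, cfg.winter_mortality, rng)

    state.year = year
    return SeasonRecord(
        year=year,
        seedbank_start=seedbank_start,
        emerged=emerged,
        adults=n_adults,
        density=density,
        accase_resistant_fraction=acc_frac,
        glyphosate_resistant_fraction=gly_frac,
        allele_frequency=allele_freq,
        median_pz=median_pz,
        new_seeds=new_seeds,
        tertiary_rhizomes=n_tertiary,
        failed=failed,
    )


# ---------------------------------------------------------------------------
# replicates and ensembles
# ---------------------------------------------------------------------------

def classify_resistance(
    result: ReplicateResult, architecture: str, threshold_fraction: float
) -> tuple[bool, int | None]:
    """Whether (and first year) a replicate chronicles evolved resistance.

    A replicate is resistant to a herbicide when the resistant fraction of
    standing plants (per that herbicide's classification) exceeds the
    threshold fraction in any season with at least one standing plant.
    """
    attr = (
        "accase_resistant_fraction"
        if architecture == "single_gene"
        else "glyphosate_resistant_fraction"
    )
    for s in result.seasons:
        if s.adults > 0 and getattr(s, attr) > threshold_fraction:
            return True, s.year
    return False, None


def run_replicate(cfg: ScenarioConfig, rng: np.random.Generator) -> ReplicateResult:
    """Iterate seasons up to the 30-year horizon, control failure, or
    extinction; classify resistance from the recorded trajectories."""
    state = initialize_state(cfg, rng)
    seasons: list[SeasonRecord] = []
    failure_year: int | None = None
    for _ in range(cfg.n_years):
        rec = run_season(state, cfg, rng)
        seasons.append(rec)
        if rec.failed:
            failure_year = rec.year
            break
        if state.seedbank.size == 0 and state.primaries.n_alive == 0:
            break  # extinct: every later census is zero
    result = ReplicateResult(
        failure_year=failure_year,
        accase_resistance_year=None,
        glyphosate_resistance_year=None,
        seasons=seasons,
    )
    thr = cfg.classification_threshold
    _, result.accase_resistance_year = classify_resistance(result, "single_gene", thr)
    _, result.glyphosate_resistance_year = classify_resistance(
        result, "quantitative", thr
    )
    return result


def replicate_rngs(base_seed: int, n: int) -> list[np.random.Generator]:
    """Independent, reproducible per-replicate streams from one root seed."""
    ss = np.random.SeedSequence(base_seed)
    return [np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(n)]


def run_ensemble(
    cfg: ScenarioConfig,
    n_replicates: int | None = None,
    base_seed: int = 0,
    collect: bool = False,
):
    """Run independent replicates and aggregate them.

    Returns ``SummaryStats``; with ``collect=True`` returns
    ``(SummaryStats, list[ReplicateResult])``.
    """
    n = n_replicates if n_replicates is not None else cfg.n_replicates
    if n < 1:
        raise ValueError("n_replicates must be >= 1")
    results = [
        run_replicate(cfg, rng) for rng in replicate_rngs(base_seed, n)
    ]
    stats = SummaryStats.from_replicates(results)
    if collect:
        return stats, results
    return stats


def seedbank_rhizome_ratio(record: SeasonRecord) -> float:
    """Seedbank:tertiary density ratio of one season: the seedbank standing
    as the season opens over the tertiary rhizomes standing before winter."""
    if record.tertiary_rhizomes == 0:
        raise ZeroDivisionError(
            "ratio undefined in seasons without tertiary rhizomes"
        )
    return record.seedbank_start / record.tertiary_rhizomes
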