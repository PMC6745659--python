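"""Within-season demographic processes of a seed- and rhizome-propagated weed.

The annual cycle starts with overwintered primary rhizomes and the soil
seedbank. Primaries branch into secondary rhizomes; one apical tiller
sprouts per secondary crown (apical dominance) while the remaining nodes are
held as reserve meristems; a fixed fraction of the seedbank emerges as
seedlings. Emergence dates follow Weibull distributions fitted to field
data. A clean field is assumed at crop sowing; postemergence (POST)
herbicide applications then remove most sensitive aboveground plants and a
smaller fraction of the rhizomes. Killed apical tillers can be replaced
from reserve meristems three weeks after the kill. Surviving plants mature
to adults, produce seeds (fecundity declines exponentially with emergence
date -- a proxy for crop competition) and tertiary rhizomes; tertiary
rhizomes overwinter and become next season's primaries.

All cohorts are stored as struct-of-arrays (numpy) so a replicate of tens
of thousands of agents runs in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import resistant_mask

ORIGIN_SEEDLING: int = 0
ORIGIN_TILLER: int = 1
ORIGIN_REGROWN_TILLER: int = 2

TIMING_EARLY = "early_post"
TIMING_LATE = "late_post"

REGROWTH_DELAY_DAYS: float = 21.0  # replacement tillers emerge 3 weeks after the kill


@dataclass(frozen=True)
class EmergenceDistribution:
    """Two-parameter Weibull emergence phenology (days after season start)."""

    shape_k: float
    scale_lambda: float

    def __post_init__(self) -> None:
        if self.shape_k <= 0 or self.scale_lambda <= 0:
            raise ValueError("Weibull shape and scale must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.scale_lambda * rng.weibull(self.shape_k, n)

    def mean(self) -> float:
        from scipy.special import gamma

        return self.scale_lambda * float(gamma(1.0 + 1.0 / self.shape_k))

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.where(
            x <= 0, 0.0, 1.0 - np.exp(-((np.maximum(x, 0) / self.scale_lambda) ** self.shape_k))
        )


def sample_emergence_dates(
    dist: EmergenceDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` Weibull emergence dates (DASS >= 0)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return dist.sample(n, rng)


@dataclass(frozen=True)
class FecundityParams:
    """Exponential fecundity decline with emergence date: ``a * exp(b*x)``,
    capped at ``max_seeds`` seeds per plant."""

    a: float
    b: float
    max_seeds: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.max_seeds <= 0:
            raise ValueError("a and max_seeds must be positive")


@dataclass(frozen=True)
class HerbicideSpec:
    """One herbicide and its efficacies on aboveground biomass and rhizomes.

    ``resistance_architecture`` selects how resistant individuals are
    classified: ``"single_gene"`` (RR/RS survive) or ``"quantitative"``
    (Pz >= dose survives).
    """

    name: str
    resistance_architecture: str
    dose: float | None = None  # g a.e./ha; required for quantitative
    foliar_efficacy_early: float = 0.95
    foliar_efficacy_late: float = 0.90
    rhizome_efficacy_notill: float = 0.25
    rhizome_efficacy_till: float = 0.50

    def __post_init__(self) -> None:
        if self.resistance_architecture not in ("single_gene", "quantitative"):
            raise ValueError("unknown resistance_architecture")
        if self.resistance_architecture == "quantitative" and (
            self.dose is None or self.dose <= 0
        ):
            raise ValueError("quantitative herbicides need a positive dose")
        for e in (
            self.foliar_efficacy_early,
            self.foliar_efficacy_late,
            self.rhizome_efficacy_notill,
            self.rhizome_efficacy_till,
        ):
            if not 0.0 <= e <= 1.0:
                raise ValueError("efficacies must be in [0, 1]")

    def resistant(self, genotype: np.ndarray, pz: np.ndarray, dominance: float) -> np.ndarray:
        if self.resistance_architecture == "single_gene":
            return resistant_mask(genotype, dominance)
        return np.asarray(pz) >= self.dose


@dataclass(frozen=True)
class ApplicationEvent:
    """A POST application: date (DASS), timing, and the tank-mix components."""

    date: float
    timing: str
    herbicides: tuple[HerbicideSpec, ...]

    def __post_init__(self) -> None:
        if self.timing not in (TIMING_EARLY, TIMING_LATE):
            raise ValueError("timing must be early_post or late_post")


# ---------------------------------------------------------------------------
# cohort containers
# ---------------------------------------------------------------------------

def _empty(dtype) -> np.ndarray:
    return np.empty(0, dtype=dtype)


@dataclass
class PlantCohort:
    """Aboveground individuals (seedlings, tillers, regrown tillers)."""

    emergence_date: np.ndarray = field(default_factory=lambda: _empty(np.float64))
    genotype: np.ndarray = field(default_factory=lambda: _empty(np.int8))
    pz: np.ndarray = field(default_factory=lambda: _empty(np.float64))
    origin: np.ndarray = field(default_factory=lambda: _empty(np.int8))
    source_rhizome: np.ndarray = field(default_factory=lambda: _empty(np.int64))
    alive: np.ndarray = field(default_factory=lambda: _empty(np.bool_))

    @property
    def n(self) -> int:
        return self.emergence_date.size

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    @staticmethod
    def concat(*cohorts: "PlantCohort") -> "PlantCohort":
        return PlantCohort(
            emergence_date=np.concatenate([c.emergence_date for c in cohorts]),
            genotype=np.concatenate([c.genotype for c in cohorts]),
            pz=np.concatenate([c.pz for c in cohorts]),
            origin=np.concatenate([c.origin for c in cohorts]),
            source_rhizome=np.concatenate([c.source_rhizome for c in cohorts]),
            alive=np.concatenate([c.alive for c in cohorts]),
        )


@dataclass
class RhizomeCohort:
    """Belowground clonal organs of one tier."""

    tier: str = "primary"
    genotype: np.ndarray = field(default_factory=lambda: _empty(np.int8))
    pz: np.ndarray = field(default_factory=lambda: _empty(np.float64))
    meristems: np.ndarray = field(default_factory=lambda: _empty(np.int64))
    alive: np.ndarray = field(default_factory=lambda: _empty(np.bool_))

    @property
    def n(self) -> int:
        return self.genotype.size

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())


@dataclass
class SeedbankPool:
    """Soil seedbank: seeds carry genetics but are not scheduled as agents."""

    genotype: np.ndarray = field(default_factory=lambda: _empty(np.int8))
    ln_pz: np.ndarray = field(default_factory=lambda: _empty(np.float64))

    @property
    def size(self) -> int:
        return self.genotype.size

    @staticmethod
    def empty() -> "SeedbankPool":
        return SeedbankPool()


# ---------------------------------------------------------------------------
# emergence and establishment
# ---------------------------------------------------------------------------

def germinate(
    seedbank: SeedbankPool,
    p_germ: float,
    dist: EmergenceDistribution,
    rng: np.random.Generator,
    date_shift: float = 0.0,
) -> tuple[PlantCohort, SeedbankPool]:
    """Bernoulli germination of the seedbank into a seedling cohort.

    Seeds that fail the draw are lost to predation and loss of viability;
    the returned (depleted) seedbank is therefore empty. Emerged seeds
    become seedlings with Weibull emergence dates and genetics copied from
    their seed records.
    """
    if not 0.0 <= p_germ <= 1.0:
        raise ValueError("p_germ must be in [0, 1]")
    mask = rng.random(seedbank.size) < p_germ
    n = int(mask.sum())
    dates = np.maximum(sample_emergence_dates(dist, n, rng) + date_shift, 0.0)
    cohort = PlantCohort(
        emergence_date=dates,
        genotype=seedbank.genotype[mask].copy(),
        pz=np.exp(seedbank.ln_pz[mask]),
        origin=np.full(n, ORIGIN_SEEDLING, dtype=np.int8),
        source_rhizome=np.full(n, -1, dtype=np.int64),
        alive=np.ones(n, dtype=np.bool_),
    )
    return cohort, SeedbankPool.empty()


def establishment_cost_survival(
    plants: PlantCohort, survival_reduction: float, rng: np.random.Generator
) -> None:
    """One establishment Bernoulli per carrier seedling/tiller.

    Carriers of the single-gene resistance allele (RR or RS) survive
    establishment with probability ``1 - survival_reduction``; applied once
    per new aboveground individual, in place.
    """
    if survival_reduction <= 0.0 or plants.n == 0:
        return
    carriers = plants.alive & (plants.genotype > 0)
    idx = np.flatnonzero(carriers)
    if idx.size:
        die = rng.random(idx.size) < survival_reduction
        plants.alive[idx[die]] = False


def remove_preplant(plants: PlantCohort, sowing_date: float) -> np.ndarray:
    """Clean field at planting: kill plants emerging strictly before sowing.

    Returns the mask of individuals killed here (tiller-origin entries are
    eligible for regrowth from their rhizome's reserve meristems).
    """
    killed = plants.alive & (plants.emergence_date < sowing_date)
    plants.alive[killed] = False
    return killed


# ---------------------------------------------------------------------------
# chemical control
# ---------------------------------------------------------------------------

def _survives_components(
    genotype: np.ndarray,
    pz: np.ndarray,
    herbicides: tuple[HerbicideSpec, ...],
    efficacies: list[float],
    dominance: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Survival mask under a tank mix: each component must be survived.

    Resistant individuals (per that component's architecture) survive it
    with probability 1; sensitive individuals escape with probability
    ``1 - efficacy`` (independent Bernoulli per component)."""
    n = len(genotype)
    surv = np.ones(n, dtype=np.bool_)
    for herb, eff in zip(herbicides, efficacies):
        res = herb.resistant(genotype, pz, dominance)
        surv &= res | (rng.random(n) < 1.0 - eff)
    return surv


def apply_foliar_herbicide(
    plants: PlantCohort,
    event: ApplicationEvent,
    dominance: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply one POST event to the aboveground cohort, in place.

    Early POST targets plants emerged by the application date; late POST is
    assumed to cover every plant of the season (its reduced 90% efficacy
    folds in escapes of late emergers). Returns the mask of plants killed.
    """
    if event.timing == TIMING_EARLY:
        target = plants.alive & (plants.emergence_date <= event.date)
    else:
        target = plants.alive.copy()
    idx = np.flatnonzero(target)
    if idx.size == 0:
        return np.zeros(plants.n, dtype=np.bool_)
    effs = [
        h.foliar_efficacy_early if event.timing == TIMING_EARLY else h.foliar_efficacy_late
        for h in event.herbicides
    ]
    surv = _survives_components(
        plants.genotype[idx], plants.pz[idx], event.herbicides, effs, dominance, rng
    )
    killed = np.zeros(plants.n, dtype=np.bool_)
    killed[idx[~surv]] = True
    plants.alive[killed] = False
    return killed


def apply_rhizome_herbicide(
    rhizomes: RhizomeCohort,
    event: ApplicationEvent,
    tillage: bool,
    dominance: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Translocation of the POST application into the rhizomes, in place.

    Sensitive rhizomes die with the (lower) rhizome efficacy -- higher under
    tillage, where rhizomes are cut into shorter segments; resistant genets'
    rhizomes are unaffected. Returns the mask of rhizomes killed.
    """
    idx = np.flatnonzero(rhizomes.alive)
    if idx.size == 0:
        return np.zeros(rhizomes.n, dtype=np.bool_)
    effs = [
        h.rhizome_efficacy_till if tillage else h.rhizome_efficacy_notill
        for h in event.herbicides
    ]
    surv = _survives_components(
        rhizomes.genotype[idx], rhizomes.pz[idx], event.herbicides, effs, dominance, rng
    )
    killed = np.zeros(rhizomes.n, dtype=np.bool_)
    killed[idx[~surv]] = True
    rhizomes.alive[killed] = False
    return killed


def regrow_tillers(
    secondaries: RhizomeCohort,
    killed_sources: np.ndarray,
    kill_date: float,
) -> PlantCohort:
    """Replace killed apical tillers from reserve meristems (apical dominance).

    ``killed_sources`` are secondary-rhizome indices of tiller-origin plants
    that just died. Each source whose rhizome is still alive and has
    meristems remaining regrows exactly one tiller, emerging three weeks
    after the kill; meristem counts are decremented in place. Clone genetics.
    """
    src = np.asarray(killed_sources, dtype=np.int64)
    src = src[src >= 0]
    eligible = src[(secondaries.alive[src]) & (secondaries.meristems[src] > 0)]
    secondaries.meristems[eligible] -= 1
    n = eligible.size
    return PlantCohort(
        emergence_date=np.full(n, kill_date + REGROWTH_DELAY_DAYS, dtype=np.float64),
        genotype=secondaries.genotype[eligible].copy(),
        pz=secondaries.pz[eligible].copy(),
        origin=np.full(n, ORIGIN_REGROWN_TILLER, dtype=np.int8),
        source_rhizome=eligible.copy(),
        alive=np.ones(n, dtype=np.bool_),
    )


# ---------------------------------------------------------------------------
# reproduction
# ---------------------------------------------------------------------------

def seeds_per_plant(emergence_date: float, params: FecundityParams) -> int:
    """Deterministic seed count of one plant: ``round(min(a*e^(b*x), cap))``."""
    if emergence_date < 0:
        raise ValueError("emergence_date must be non-negative")
    return int(round(min(params.a * np.exp(params.b * emergence_date), params.max_seeds)))


def expected_seeds(dates: np.ndarray, params: FecundityParams) -> np.ndarray:
    """Vectorized capped exponential fecundity (real-valued expectation)."""
    return np.minimum(params.a * np.exp(params.b * np.asarray(dates)), params.max_seeds)


def sample_seed_counts(
    dates: np.ndarray,
    params: FecundityParams,
    fecundity_multiplier: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Integer seed counts with stochastic rounding (expectation-preserving).

    Truncation would bias low-fecundity (late-emerging) plants to zero;
    rounding up with probability equal to the fractional part keeps the
    expected seed output exact.
    """
    f = expected_seeds(dates, params) * fecundity_multiplier
    base = np.floor(f)
    frac = f - base
    return (base + (rng.random(f.size) < frac)).astype(np.int64)


def reproduce_sexually(
    adults: PlantCohort,
    selfing_rate: float,
    quant_model,
    fitness_cost,
    fecundity: FecundityParams,
    rng: np.random.Generator,
) -> SeedbankPool:
    """Seed production of the season's adults.

    Each adult mothers a fecundity-dependent number of seeds (reduced for
    resistance-allele carriers under a fitness cost). A seed is selfed with
    the selfing rate, otherwise outcrossed to a father drawn uniformly from
    all adults; the nuclear genotype follows Mendelian segregation. Seed
    Ln(Pz) is drawn iid from the normal with the offspring mean/SD obtained
    by scaling the realized parental Ln(Pz) mean and SD.
    """
    alive = np.flatnonzero(adults.alive)
    if alive.size == 0:
        return SeedbankPool.empty()
    dates = adults.emergence_date[alive]
    geno = adults.genotype[alive]
    carriers = geno > 0
    mult = np.where(carriers, 1.0 - fitness_cost.fecundity_reduction, 1.0)
    counts = sample_seed_counts(dates, fecundity, mult, rng)
    total = int(counts.sum())
    if total == 0:
        return SeedbankPool.empty()

    mothers_local = np.repeat(np.arange(alive.size), counts)
    selfed = rng.random(total) < selfing_rate
    fathers_local = rng.integers(0, alive.size, total)
    fathers_local[selfed] = mothers_local[selfed]

    from .genetics import mendelian_cross, offspring_pz_params

    seed_geno = mendelian_cross(geno[mothers_local], geno[fathers_local], rng)

    ln_pz = np.log(adults.pz[alive])
    mean_off, sd_off = offspring_pz_params(
        float(ln_pz.mean()), float(ln_pz.std()), quant_model
    )
    seed_ln_pz = rng.normal(mean_off, sd_off, total)
    return SeedbankPool(genotype=seed_geno, ln_pz=seed_ln_pz)


# ---------------------------------------------------------------------------
# clonal propagation
# ---------------------------------------------------------------------------

def produce_secondary_rhizomes(
    primaries: RhizomeCohort,
    mean_branches: float,
    mean_nodes: float,
    rng: np.random.Generator,
) -> RhizomeCohort:
    """Each overwintered primary branches into Poisson(mean) secondaries;
    each secondary bears Poisson(mean) nodes. Clonal genetics throughout."""
    idx = np.flatnonzero(primaries.alive)
    n_sec = rng.poisson(mean_branches, idx.size) if idx.size else np.empty(0, np.int64)
    parents = np.repeat(idx, n_sec)
    m = parents.size
    return RhizomeCohort(
        tier="secondary",
        genotype=primaries.genotype[parents].copy(),
        pz=primaries.pz[parents].copy(),
        meristems=rng.poisson(mean_nodes, m).astype(np.int64),
        alive=np.ones(m, dtype=np.bool_),
    )


def sprout_tillers(
    secondaries: RhizomeCohort,
    dist: EmergenceDistribution,
    rng: np.random.Generator,
    date_shift: float = 0.0,
) -> PlantCohort:
    """One apical tiller per secondary crown with at least one node.

    The sprouting node is consumed; the remaining nodes stay as reserve
    meristems for regrowth (apical dominance). Emergence dates are Weibull.
    """
    src = np.flatnonzero(secondaries.alive & (secondaries.meristems > 0))
    secondaries.meristems[src] -= 1
    n = src.size
    dates = np.maximum(sample_emergence_dates(dist, n, rng) + date_shift, 0.0)
    return PlantCohort(
        emergence_date=dates,
        genotype=secondaries.genotype[src].copy(),
        pz=secondaries.pz[src].copy(),
        origin=np.full(n, ORIGIN_TILLER, dtype=np.int8),
        source_rhizome=src.astype(np.int64),
        alive=np.ones(n, dtype=np.bool_),
    )


def produce_tertiary_rhizomes(
    adults: PlantCohort, rate_per_adult: float, rng: np.random.Generator
) -> RhizomeCohort:
    """Each season-end adult clones itself into Poisson(rate) tertiary rhizomes."""
    idx = np.flatnonzero(adults.alive)
    counts = rng.poisson(rate_per_adult, idx.size) if idx.size else np.empty(0, np.int64)
    parents = np.repeat(idx, counts)
    m = parents.size
    return RhizomeCohort(
        tier="tertiary",
        genotype=adults.genotype[parents].copy(),
        pz=adults.pz[parents].copy(),
        meristems=np.zeros(m, dtype=np.int64),
        alive=np.ones(m, dtype=np.bool_),
    )


def overwinter(
    tertiaries: RhizomeCohort, winter_mortality: float, rng: np.random.Generator
) -> RhizomeCohort:
    """Bernoulli winter survival of tertiary rhizomes; survivors become the
    next season's primaries. Aboveground biomass and the spent primary and
    secondary rhizomes do not survive winter."""
    if not 0.0 <= winter_mortality <= 1.0:
        raise ValueError("winter_mortality must be in [0, 1]")
    idx = np.flatnonzero(tertiaries.alive)
    keep = idx[rng.random(idx.size) >= winter_mortality]
    m = keep.size
    return RhizomeCohort(
        tier="primary",
        genotype=tertiaries.genotype[keep].copy(),
        pz=tertiaries.pz[keep].copy(),
        meristems=np.zeros(m, dtype=np.int64),
        alive=np.ones(m, dtype=np.bool_),
    )
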