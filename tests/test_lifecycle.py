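"""Lifecycle module: emergence, control events, regrowth, reproduction."""

import math

import numpy as np
import pytest
from scipy import stats

from rhizoweed.genetics import RR, RS, SS, FitnessCost, QuantTraitModel
from rhizoweed.lifecycle import (
    ORIGIN_REGROWN_TILLER,
    ORIGIN_SEEDLING,
    ORIGIN_TILLER,
    TIMING_EARLY,
    TIMING_LATE,
    ApplicationEvent,
    EmergenceDistribution,
    FecundityParams,
    HerbicideSpec,
    PlantCohort,
    RhizomeCohort,
    SeedbankPool,
    apply_foliar_herbicide,
    apply_rhizome_herbicide,
    germinate,
    overwinter,
    produce_secondary_rhizomes,
    produce_tertiary_rhizomes,
    regrow_tillers,
    remove_preplant,
    reproduce_sexually,
    sample_emergence_dates,
    sample_seed_counts,
    seeds_per_plant,
    sprout_tillers,
)

SOUTH_FEC = FecundityParams(a=298_660.0, b=-0.066, max_seeds=356.0)


def make_plants(dates, genotype=SS, pz=2000.0, origin=ORIGIN_SEEDLING, source=-1):
    n = len(dates)
    return PlantCohort(
        emergence_date=np.asarray(dates, dtype=float),
        genotype=np.full(n, genotype, dtype=np.int8),
        pz=np.full(n, pz, dtype=float),
        origin=np.full(n, origin, dtype=np.int8),
        source_rhizome=np.full(n, source, dtype=np.int64),
        alive=np.ones(n, dtype=bool),
    )


def make_rhizomes(n, genotype=SS, pz=2000.0, meristems=3, tier="secondary"):
    return RhizomeCohort(
        tier=tier,
        genotype=np.full(n, genotype, dtype=np.int8),
        pz=np.full(n, pz, dtype=float),
        meristems=np.full(n, meristems, dtype=np.int64),
        alive=np.ones(n, dtype=bool),
    )


class TestEmergence:
    @pytest.mark.parametrize("k, lam", [(10.5, 169.0), (6.5, 160.0), (4.1, 165.0), (5.2, 165.0)])
    def test_weibull_distribution(self, k, lam, rng):
        dist = EmergenceDistribution(k, lam)
        x = sample_emergence_dates(dist, 50_000, rng)
        assert np.all(x >= 0)
        ks = stats.kstest(x, stats.weibull_min(k, scale=lam).cdf)
        assert ks.pvalue > 1e-4
        se = x.std() / math.sqrt(x.size)
        assert x.mean() == pytest.approx(dist.mean(), abs=4 * se)

    def test_fraction_below_scale_is_1_minus_inv_e(self, rng):
        dist = EmergenceDistribution(10.5, 169.0)
        x = sample_emergence_dates(dist, 100_000, rng)
        assert np.mean(x <= 169.0) == pytest.approx(1 - math.exp(-1), abs=0.01)

    def test_shape_one_is_exponential(self, rng):
        x = sample_emergence_dates(EmergenceDistribution(1.0, 50.0), 50_000, rng)
        ks = stats.kstest(x, stats.expon(scale=50.0).cdf)
        assert ks.pvalue > 1e-4

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            EmergenceDistribution(0.0, 169.0)
        with pytest.raises(ValueError):
            EmergenceDistribution(10.5, -1.0)


class TestGermination:
    def test_binomial_mean(self, rng):
        n = 10_000
        bank = SeedbankPool(
            genotype=np.zeros(n, dtype=np.int8), ln_pz=np.full(n, 7.0)
        )
        cohort, depleted = germinate(bank, 0.26, EmergenceDistribution(10.5, 169.0), rng)
        se = math.sqrt(n * 0.26 * 0.74)
        assert cohort.n == pytest.approx(0.26 * n, abs=4 * se)
        assert depleted.size == 0  # the rest is lost to predation/viability
        assert np.all(cohort.origin == ORIGIN_SEEDLING)
        assert np.all(cohort.pz == pytest.approx(math.exp(7.0)))

    def test_extremes(self, rng):
        bank = SeedbankPool(genotype=np.zeros(50, dtype=np.int8), ln_pz=np.zeros(50))
        all_in, _ = germinate(bank, 1.0, EmergenceDistribution(10.5, 169.0), rng)
        assert all_in.n == 50
        empty, _ = germinate(SeedbankPool.empty(), 0.26, EmergenceDistribution(10.5, 169.0), rng)
        assert empty.n == 0


class TestPreplantRemoval:
    def test_strict_boundary(self):
        plants = make_plants([100.0, 138.0, 150.0])
        killed = remove_preplant(plants, 138.0)
        assert killed.tolist() == [True, False, False]
        assert plants.alive.tolist() == [False, True, True]


class TestFoliarHerbicide:
    def accase_event(self, timing=TIMING_EARLY, date=168.0):
        return ApplicationEvent(date, timing, (HerbicideSpec("accase", "single_gene"),))

    def test_sensitive_escape_rate_binomial(self, rng):
        n = 10_000
        plants = make_plants(np.full(n, 150.0), genotype=SS)
        apply_foliar_herbicide(plants, self.accase_event(), 1.0, rng)
        survivors = plants.n_alive
        se = math.sqrt(n * 0.05 * 0.95)
        assert survivors == pytest.approx(0.05 * n, abs=4 * se)

    def test_resistant_genotypes_always_survive(self, rng):
        for g in (RR, RS):
            plants = make_plants(np.full(500, 150.0), genotype=g)
            apply_foliar_herbicide(plants, self.accase_event(), 1.0, rng)
            assert plants.n_alive == 500

    def test_quantitative_resistance_is_dose_threshold(self, rng):
        ev = ApplicationEvent(
            168.0, TIMING_EARLY,
            (HerbicideSpec("glyphosate", "quantitative", dose=1120.0),),
        )
        above = make_plants(np.full(400, 150.0), pz=1500.0)
        apply_foliar_herbicide(above, ev, 1.0, rng)
        assert above.n_alive == 400
        at = make_plants(np.full(400, 150.0), pz=1120.0)
        apply_foliar_herbicide(at, ev, 1.0, rng)
        assert at.n_alive == 400  # Pz >= rate survives
        below = make_plants(np.full(4000, 150.0), pz=1000.0)
        apply_foliar_herbicide(below, ev, 1.0, rng)
        assert below.n_alive < 600

    def test_early_post_spares_later_emergers(self, rng):
        plants = make_plants([150.0, 200.0], genotype=SS)
        ev = ApplicationEvent(
            168.0, TIMING_EARLY,
            (HerbicideSpec("accase", "single_gene", foliar_efficacy_early=1.0),),
        )
        apply_foliar_herbicide(plants, ev, 1.0, rng)
        assert plants.alive.tolist() == [False, True]

    def test_late_post_covers_all_plants(self, rng):
        plants = make_plants([150.0, 250.0], genotype=SS)
        ev = ApplicationEvent(
            198.0, TIMING_LATE,
            (HerbicideSpec("accase", "single_gene", foliar_efficacy_late=1.0),),
        )
        apply_foliar_herbicide(plants, ev, 1.0, rng)
        assert plants.n_alive == 0

    def test_mixture_requires_surviving_each_component(self, rng):
        # SS genotype, high Pz: immune to glyphosate but not to the
        # single-gene component at full efficacy
        ev = ApplicationEvent(
            168.0, TIMING_EARLY,
            (
                HerbicideSpec("glyphosate", "quantitative", dose=1120.0),
                HerbicideSpec("accase", "single_gene", foliar_efficacy_early=1.0),
            ),
        )
        plants = make_plants(np.full(300, 150.0), genotype=SS, pz=5000.0)
        apply_foliar_herbicide(plants, ev, 1.0, rng)
        assert plants.n_alive == 0


class TestRhizomeHerbicide:
    def event(self):
        return ApplicationEvent(168.0, TIMING_EARLY, (HerbicideSpec("accase", "single_gene"),))

    @pytest.mark.parametrize("tillage, survival", [(False, 0.75), (True, 0.50)])
    def test_sensitive_mortality(self, tillage, survival, rng):
        rhiz = make_rhizomes(10_000, genotype=SS)
        apply_rhizome_herbicide(rhiz, self.event(), tillage, 1.0, rng)
        se = math.sqrt(10_000 * survival * (1 - survival))
        assert rhiz.n_alive == pytest.approx(survival * 10_000, abs=4 * se)

    def test_resistant_rhizomes_unaffected(self, rng):
        rhiz = make_rhizomes(500, genotype=RS)
        apply_rhizome_herbicide(rhiz, self.event(), True, 1.0, rng)
        assert rhiz.n_alive == 500


class TestTillerRegrowth:
    def test_replacement_three_weeks_after_kill(self):
        sec = make_rhizomes(5, meristems=3)
        regrown = regrow_tillers(sec, np.array([2]), kill_date=168.0)
        assert regrown.n == 1
        assert regrown.emergence_date[0] == pytest.approx(189.0)
        assert regrown.origin[0] == ORIGIN_REGROWN_TILLER
        assert sec.meristems[2] == 2

    def test_meristem_exhaustion_blocks_regrowth(self):
        sec = make_rhizomes(3, meristems=0)
        regrown = regrow_tillers(sec, np.array([0, 1]), kill_date=168.0)
        assert regrown.n == 0

    def test_dead_rhizome_cannot_regrow(self):
        sec = make_rhizomes(3, meristems=3)
        sec.alive[1] = False
        regrown = regrow_tillers(sec, np.array([1]), kill_date=168.0)
        assert regrown.n == 0

    def test_seedlings_never_regrow(self):
        sec = make_rhizomes(3, meristems=3)
        regrown = regrow_tillers(sec, np.array([-1, -1]), kill_date=140.0)
        assert regrown.n == 0

    def test_regrown_tiller_is_a_clone(self):
        sec = make_rhizomes(2, genotype=RS, pz=1234.5, meristems=2)
        regrown = regrow_tillers(sec, np.array([0]), kill_date=168.0)
        assert regrown.genotype[0] == RS
        assert regrown.pz[0] == 1234.5


class TestFecundity:
    def test_cap_binds_for_early_emergers(self):
        assert seeds_per_plant(0.0, SOUTH_FEC) == 356

    def test_exponential_decline(self):
        assert seeds_per_plant(168.0, SOUTH_FEC) == 5

    def test_flat_when_rate_zero(self):
        flat = FecundityParams(a=1000.0, b=0.0, max_seeds=356.0)
        assert seeds_per_plant(0.0, flat) == seeds_per_plant(200.0, flat) == 356

    def test_stochastic_rounding_preserves_expectation(self, rng):
        dates = np.full(200_000, 168.0)
        counts = sample_seed_counts(dates, SOUTH_FEC, np.ones(dates.size), rng)
        expected = 298_660.0 * math.exp(-0.066 * 168.0)
        assert counts.mean() == pytest.approx(expected, rel=0.02)


class TestSexualReproduction:
    def reproduce(self, adults, rng, selfing=0.95, cost=FitnessCost()):
        return reproduce_sexually(
            adults, selfing, QuantTraitModel(), cost, SOUTH_FEC, rng
        )

    def test_no_adults_no_seeds(self, rng):
        assert self.reproduce(make_plants([]), rng).size == 0

    def test_all_ss_adults_yield_all_ss_seeds(self, rng):
        seeds = self.reproduce(make_plants(np.full(50, 140.0), genotype=SS), rng)
        assert seeds.size > 0
        assert np.all(seeds.genotype == SS)

    def test_full_selfing_of_homozygotes_makes_no_heterozygotes(self, rng):
        adults = make_plants(np.full(100, 140.0), genotype=SS)
        adults.genotype[:50] = RR
        seeds = self.reproduce(adults, rng, selfing=1.0)
        assert not np.any(seeds.genotype == RS)

    def test_full_outcrossing_of_homozygotes_makes_half_heterozygotes(self, rng):
        adults = make_plants(np.full(100, 140.0), genotype=SS)
        adults.genotype[:50] = RR
        seeds = self.reproduce(adults, rng, selfing=0.0)
        # random fathers: P(RS) = 2 * 0.5 * 0.5
        assert np.mean(seeds.genotype == RS) == pytest.approx(0.5, abs=0.035)

    def test_fecundity_cost_reduces_carrier_seed_output(self, rng):
        adults = make_plants(np.full(200, 140.0), genotype=RS)
        no_cost = self.reproduce(adults, rng).size
        with_cost = self.reproduce(adults, rng, cost=FitnessCost.from_preset("literature")).size
        assert with_cost / no_cost == pytest.approx(0.64, abs=0.03)

    def test_seed_pz_follows_scaled_parent_distribution(self, rng):
        adults = make_plants(np.full(300, 140.0))
        adults.pz[:] = np.exp(rng.normal(7.0, 0.5, 300))
        seeds = self.reproduce(adults, rng)
        parent_ln = np.log(adults.pz)
        ratio = seeds.ln_pz.std() / parent_ln.std()
        assert ratio == pytest.approx(1.18, abs=0.05)
        assert seeds.ln_pz.mean() == pytest.approx(parent_ln.mean(), abs=0.05)


class TestClonalPropagation:
    def test_secondary_branching_means(self, rng):
        primaries = make_rhizomes(20_000, tier="primary")
        sec = produce_secondary_rhizomes(primaries, 2.0, 3.0, rng)
        assert sec.n / primaries.n == pytest.approx(2.0, rel=0.02)
        assert sec.meristems.mean() == pytest.approx(3.0, rel=0.02)

    def test_zero_branching(self, rng):
        sec = produce_secondary_rhizomes(make_rhizomes(100, tier="primary"), 0.0, 3.0, rng)
        assert sec.n == 0

    def test_one_apical_tiller_per_crown(self, rng):
        sec = make_rhizomes(200, meristems=3)
        sec.meristems[:10] = 0  # crowns without nodes cannot sprout
        tillers = sprout_tillers(sec, EmergenceDistribution(6.5, 160.0), rng)
        assert tillers.n == 190
        assert np.all(sec.meristems[10:] == 2)  # reserves held back
        assert np.all(tillers.origin == ORIGIN_TILLER)

    def test_tertiary_rhizomes_are_exact_clones(self, rng):
        adults = make_plants(np.full(2000, 150.0), genotype=RS)
        adults.pz[:] = rng.uniform(100.0, 5000.0, 2000)
        tert = produce_tertiary_rhizomes(adults, 1.0, rng)
        assert tert.n == pytest.approx(2000, abs=4 * math.sqrt(2000))
        # every clone's genotype and Pz occur verbatim in the parent cohort
        assert np.all(tert.genotype == RS)
        assert np.all(np.isin(tert.pz, adults.pz))

    def test_no_adults_no_tertiary(self, rng):
        assert produce_tertiary_rhizomes(make_plants([]), 1.0, rng).n == 0


class TestOverwintering:
    @pytest.mark.parametrize("mortality", [0.25, 0.50])
    def test_bernoulli_survival(self, mortality, rng):
        tert = make_rhizomes(20_000, tier="tertiary")
        prim = overwinter(tert, mortality, rng)
        p = 1 - mortality
        se = math.sqrt(20_000 * p * (1 - p))
        assert prim.n == pytest.approx(p * 20_000, abs=4 * se)
        assert prim.tier == "primary"

    def test_total_mortality_extinguishes_the_line(self, rng):
        assert overwinter(make_rhizomes(500, tier="tertiary"), 1.0, rng).n == 0

    def test_survivors_keep_clonal_genetics(self, rng):
        tert = make_rhizomes(1000, genotype=RR, pz=777.0, tier="tertiary")
        prim = overwinter(tert, 0.5, rng)
        assert np.all(prim.genotype == RR)
        assert np.all(prim.pz == 777.0)
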