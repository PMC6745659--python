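"""Inheritance of herbicide resistance.

Two architectures are modeled side by side:

* **Single dominant gene** (target-site resistance to ACCase-inhibiting
  herbicides such as haloxyfop/clethodim): each plant carries a diploid
  genotype RR / RS / SS at one nuclear locus; with full dominance both RR
  and RS survive applications.
* **Quantitative resistance** (non-target-site resistance to glyphosate):
  each plant carries a phenotype ``Pz`` -- the highest dose (g a.e./ha) it
  can survive -- drawn from a log-normal distribution whose median is the
  population LD50.

Because the species is ~95% self-pollinated, offspring Pz cannot come from
the Breeder's equation; instead the seeds of each season draw Ln(Pz) from a
normal whose mean and SD are the realized parental values multiplied by
fixed offspring/parent ratios (1 and 1.18), themselves obtained from an
a-priori 20-locus additive ("infinitesimal") cross simulation which is also
implemented here (:func:`infinitesimal_cross_sim`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

# Genotype encoding: number of resistance (R) alleles carried.
SS: int = 0
RS: int = 1
RR: int = 2
GENOTYPE_LABELS = {SS: "SS", RS: "RS", RR: "RR"}


@dataclass(frozen=True)
class SingleGeneModel:
    """Single-dominant-gene (target-site) resistance parameters.

    initial_allele_freq
        Initial frequency ``q`` of the resistance allele; genotypes are
        assigned under Hardy-Weinberg, so the initial resistant fraction is
        ``q**2 + 2*q*(1-q)`` (~``2q`` for rare alleles).
    dominance
        1.0 means heterozygotes are fully resistant (the setting used for
        ACCase target-site mutations).
    selfing_rate
        Proportion of seeds produced by self-pollination (0.95 for
        Johnsongrass; the remainder outcross to a random father).
    """

    initial_allele_freq: float = 1e-5
    dominance: float = 1.0
    selfing_rate: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.initial_allele_freq <= 1.0:
            raise ValueError("initial_allele_freq must be in [0, 1]")
        if not 0.0 <= self.dominance <= 1.0:
            raise ValueError("dominance must be in [0, 1]")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must be in [0, 1]")


@dataclass(frozen=True)
class QuantTraitModel:
    """Quantitative (log-normal Pz) resistance parameters.

    initial_ld50
        Median of the initial Pz distribution, g a.e./ha.
    sigma_log
        Standard deviation of Ln(Pz) (0.5087).
    mu_ratio, sigma_ratio
        Offspring/parent ratios of the mean and SD of Ln(Pz) applied each
        generation of sexual reproduction (1 and 1.18).
    """

    initial_ld50: float = 1719.0
    sigma_log: float = 0.5087
    mu_ratio: float = 1.0
    sigma_ratio: float = 1.18

    def __post_init__(self) -> None:
        if self.initial_ld50 <= 0:
            raise ValueError("initial_ld50 must be positive")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")
        if self.mu_ratio <= 0 or self.sigma_ratio <= 0:
            raise ValueError("offspring/parent ratios must be positive")


@dataclass(frozen=True)
class FitnessCost:
    """Fitness penalty of carrying the single-gene resistance allele.

    Expressed as fractional reductions applied to carrier (RR and RS)
    individuals: ``survival_reduction`` to the establishment survival of
    seedlings and tillers, ``fecundity_reduction`` to seed production.
    """

    survival_reduction: float = 0.0
    fecundity_reduction: float = 0.0

    PRESETS = {
        "none": (0.0, 0.0),
        "literature": (0.42, 0.36),  # black-grass ACCase D2078G measurements
        "max": (0.90, 0.90),
    }

    def __post_init__(self) -> None:
        for v in (self.survival_reduction, self.fecundity_reduction):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fitness-cost reductions must be in [0, 1]")

    @classmethod
    def from_preset(cls, name: str) -> "FitnessCost":
        try:
            s, f = cls.PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown fitness-cost preset {name!r}; "
                f"choose from {sorted(cls.PRESETS)}"
            ) from None
        return cls(survival_reduction=s, fecundity_reduction=f)


@dataclass(frozen=True)
class InfinitesimalConfig:
    """Configuration of the a-priori additive-loci cross simulation."""

    n_loci: int = 20
    population_size: int = 10_000
    selfing_rate: float = 0.95
    sigma_log: float = 0.5087
    baseline_ln_pz: float = math.log(1719.0)
    allelic_effect_sd: float | None = None  # default: sigma_log/sqrt(2*n_loci)

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")


# ---------------------------------------------------------------------------
# single-gene operations
# ---------------------------------------------------------------------------

def initial_genotype_probs(q: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities ``(p_RR, p_RS, p_SS)`` for
    resistance-allele frequency ``q``."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    return (q * q, 2.0 * q * (1.0 - q), (1.0 - q) ** 2)


def sample_initial_genotypes(q: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` genotypes (allele counts 0/1/2) under Hardy-Weinberg."""
    p_rr, p_rs, p_ss = initial_genotype_probs(q)
    u = rng.random(n)
    g = np.zeros(n, dtype=np.int8)
    g[u < p_rr + p_rs] = RS
    g[u < p_rr] = RR
    return g


def resistant_mask(genotypes: np.ndarray, dominance: float = 1.0) -> np.ndarray:
    """Boolean mask of phenotypically resistant individuals.

    RR is always resistant; RS is resistant under full dominance. Partial
    dominance values below 1 make heterozygotes sensitive (the model is only
    exercised at dominance 1).
    """
    g = np.asarray(genotypes)
    if dominance >= 1.0:
        return g >= RS
    return g == RR


def is_resistant(genotype: int, dominance: float = 1.0) -> bool:
    """Scalar convenience wrapper around :func:`resistant_mask`."""
    return bool(resistant_mask(np.asarray([genotype]), dominance)[0])


def mendelian_cross(
    mothers: np.ndarray, fathers: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized Mendelian cross of allele-count genotypes.

    Each offspring receives one allele drawn uniformly from each parent's
    two alleles; passing the same array twice realizes selfing.
    """
    g1 = rng.binomial(1, np.asarray(mothers, dtype=np.float64) / 2.0)
    g2 = rng.binomial(1, np.asarray(fathers, dtype=np.float64) / 2.0)
    return (g1 + g2).astype(np.int8)


def inherit_nuclear(
    mother: int, father: int | None, rng: np.random.Generator
) -> int:
    """Draw one offspring genotype; ``father=None`` signals selfing.

    Clonal (rhizome) propagation bypasses this entirely -- clones copy the
    maternal genotype verbatim.
    """
    f = mother if father is None else father
    return int(mendelian_cross(np.asarray([mother]), np.asarray([f]), rng)[0])


# ---------------------------------------------------------------------------
# quantitative-trait operations
# ---------------------------------------------------------------------------

def sample_initial_pz(
    model: QuantTraitModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` initial Pz values (g a.e./ha): Ln(Pz) ~ Normal(ln LD50, sigma)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return np.exp(rng.normal(math.log(model.initial_ld50), model.sigma_log, n))


def resistant_fraction_analytic(ld50: float, sigma_log: float, dose: float) -> float:
    """Upper-tail probability P(Pz >= dose) of the log-normal Pz model.

    This closed form is the oracle against which the sampler is checked; it
    also reproduces the printed equivalences between initial LD50 values and
    initial resistant fractions at the glyphosate label dose.
    """
    if ld50 <= 0 or dose <= 0:
        raise ValueError("ld50 and dose must be positive")
    if sigma_log == 0:
        return 1.0 if ld50 >= dose else 0.0
    return float(norm.cdf(math.log(ld50 / dose) / sigma_log))


def offspring_pz_params(
    parent_ln_pz_mean: float, parent_ln_pz_sd: float, model: QuantTraitModel
) -> tuple[float, float]:
    """Mean and SD of Ln(Pz) for the seeds of a season.

    The realized parental mean and SD are scaled by the fixed
    offspring/parent ratios; every seed then draws Ln(Pz) iid from the
    resulting normal.
    """
    if parent_ln_pz_sd < 0:
        raise ValueError("parent_ln_pz_sd must be non-negative")
    return (
        parent_ln_pz_mean * model.mu_ratio,
        parent_ln_pz_sd * model.sigma_ratio,
    )


def infinitesimal_cross_sim(
    cfg: InfinitesimalConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """A-priori additive-loci cross: estimate offspring/parent Ln(Pz) ratios.

    Each parent carries ``n_loci`` unlinked additive diploid loci whose
    allelic values sum (no dominance) to Ln(Pz) around a baseline. Mating
    follows the selfing rate; unlinked loci assort independently. Returns
    ``(mu_ratio_hat, sigma_ratio_hat)``: the ratios of offspring to parent
    mean and standard deviation of Ln(Pz).
    """
    n, loci = cfg.population_size, cfg.n_loci
    tau = (
        cfg.allelic_effect_sd
        if cfg.allelic_effect_sd is not None
        else cfg.sigma_log / math.sqrt(2.0 * loci)
    )
    alleles = rng.normal(0.0, tau, size=(n, loci, 2))
    parent_ln = cfg.baseline_ln_pz + alleles.sum(axis=(1, 2))

    selfed = rng.random(n) < cfg.selfing_rate
    fathers = rng.integers(0, n, n)
    fathers[selfed] = np.arange(n)[selfed]

    pick_m = rng.integers(0, 2, size=(n, loci))
    pick_f = rng.integers(0, 2, size=(n, loci))
    rows = np.arange(n)[:, None]
    cols = np.arange(loci)[None, :]
    gam_m = alleles[rows, cols, pick_m]
    gam_f = alleles[fathers[:, None], cols, pick_f]
    off_ln = cfg.baseline_ln_pz + (gam_m + gam_f).sum(axis=1)

    mu_ratio_hat = float(off_ln.mean() / parent_ln.mean())
    sigma_ratio_hat = float(off_ln.std() / parent_ln.std())
    return mu_ratio_hat, sigma_ratio_hat


# ---------------------------------------------------------------------------
# fitness cost
# ---------------------------------------------------------------------------

def apply_fitness_cost(
    base_rate: float, cost: FitnessCost, carrier: bool, which: str
) -> float:
    """Reduce a survival probability or seed count for R-allele carriers."""
    if base_rate < 0:
        raise ValueError("base_rate must be non-negative")
    if which not in ("survival", "fecundity"):
        raise ValueError("which must be 'survival' or 'fecundity'")
    if not carrier:
        return base_rate
    red = (
        cost.survival_reduction if which == "survival" else cost.fecundity_reduction
    )
    return base_rate * (1.0 - red)
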