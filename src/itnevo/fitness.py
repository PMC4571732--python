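"""Genotype fitnesses from the mosquito feeding cycle, and one generation
of the two-sex selection recursion.

Females are exposed to ITNs while repeatedly searching for blood meals;
their fitness is larval survival x fecundity x cost x expected adult
lifespan (in gonotrophic cycles).  Males never encounter nets, so their
fitness is larval survival x fertility cost.  Generations are discrete
and non-overlapping; mating is random, so offspring genotype proportions
are cross-products of male and female allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import (
    ConvergenceDomainError,
    DegenerateParametersError,
    PopulationExtinctError,
)
from .params import GENOTYPES, Genotype, ModelParameters, Sex

__all__ = [
    "AlleleFrequencies",
    "FitnessTable",
    "insecticide_survival",
    "larval_survival",
    "resistance_cost_factor",
    "single_attempt_success",
    "lifetime_feeding_success",
    "gonotrophic_cycle_survival",
    "expected_lifespan",
    "male_fitness",
    "female_fitness",
    "build_fitness_table",
    "mean_fitness",
    "genotype_frequencies_after_selection",
    "next_allele_frequencies",
]


@dataclass(frozen=True)
class AlleleFrequencies:
    """Resistance-allele frequency in males (p_m) and females (p_f).

    The sensitive-allele frequencies q_m = 1 - p_m and q_f = 1 - p_f are
    derived on access, never stored.
    """

    p_m: float
    p_f: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_m <= 1.0 and 0.0 <= self.p_f <= 1.0):
            raise ValueError(
                f"allele frequencies must lie in [0, 1], got "
                f"p_m={self.p_m!r}, p_f={self.p_f!r}"
            )

    @property
    def q_m(self) -> float:
        return 1.0 - self.p_m

    @property
    def q_f(self) -> float:
        return 1.0 - self.p_f

    @property
    def mean(self) -> float:
        """Sex-averaged resistance-allele frequency (p_m + p_f) / 2."""
        return 0.5 * (self.p_m + self.p_f)


def _dominance_weight(genotype: Genotype, h: float) -> float:
    # Fraction of the homozygote effect expressed: 0 (SS), h (RS), 1 (RR).
    if genotype is Genotype.SS:
        return 0.0
    if genotype is Genotype.RS:
        return h
    return 1.0


def insecticide_survival(genotype: Genotype, params: ModelParameters) -> float:
    """Probability of surviving insecticide exposure at a treated net.

    Sensitive mosquitoes survive with probability s; resistance reduces
    the kill probability (1-s) by rho (homozygotes) or h*rho
    (heterozygotes), giving s + rho(1-s) and s + h*rho*(1-s).
    """
    w = _dominance_weight(genotype, params.h)
    return params.s + w * params.rho * (1.0 - params.s)


def larval_survival(genotype: Genotype, params: ModelParameters) -> float:
    """Larval survival under larvicide coverage psi, standardized so all
    larvae in unexposed sites survive: 1 - psi*(1 - w*rho)."""
    w = _dominance_weight(genotype, params.h)
    return 1.0 - params.psi * (1.0 - w * params.rho)


def resistance_cost_factor(genotype: Genotype, params: ModelParameters) -> float:
    """Multiplicative fecundity/fertility cost: 1, 1-hZ, 1-Z."""
    return 1.0 - _dominance_weight(genotype, params.h) * params.Z


def single_attempt_success(params: ModelParameters, surv: float) -> float:
    """Probability Xi that one feeding attempt ends in a survived blood
    meal.

    A proportion 1-Q feeds on animals; Q attempts a human indoors, of
    which phi hit a protected house where the mosquito, if not repelled
    (prob. 1-r), must survive insecticide exposure with probability
    ``surv`` (the genotype's :func:`insecticide_survival`).  Every bite
    carries feeding-associated risk survived with probability sigma:

        Xi = sigma * (1 - Q*phi*(1 - (1-r)*surv))
    """
    return params.sigma * (
        1.0 - params.Q * params.phi * (1.0 - (1.0 - params.r) * surv)
    )


def lifetime_feeding_success(params: ModelParameters, surv: float) -> float:
    """Probability of eventually obtaining a blood meal over repeated,
    possibly repelled, host searches.

    Each repelled attempt recurs with probability Q*phi*r and survives
    the extra search risk with probability 1 - mu_r, so success sums the
    geometric series Xi * sum_n (Q*phi*r*(1-mu_r))^n with closed form
    Xi / (1 - Q*phi*r*(1-mu_r)).
    """
    ratio = params.Q * params.phi * params.r * (1.0 - params.mu_r)
    if ratio >= 1.0:
        raise ConvergenceDomainError(
            f"repeat-search series diverges: Q*phi*r*(1-mu_r) = {ratio} >= 1"
        )
    return single_attempt_success(params, surv) / (1.0 - ratio)


def gonotrophic_cycle_survival(params: ModelParameters, surv: float) -> float:
    """Probability of surviving one full gonotrophic cycle: feeding
    success times the feeding-independent survival 1 - mu_gt."""
    return (1.0 - params.effective_mu_gt) * lifetime_feeding_success(params, surv)


def expected_lifespan(genotype: Genotype, params: ModelParameters) -> float:
    """Expected adult female lifespan in multiples of the gonotrophic
    cycle: 1 / (1 - per-cycle survival), i.e. the mean of the geometric
    number of cycles completed."""
    p_cycle = gonotrophic_cycle_survival(
        params, insecticide_survival(genotype, params)
    )
    if p_cycle >= 1.0:
        raise DegenerateParametersError(
            f"per-cycle survival {p_cycle} >= 1: expected lifespan diverges"
        )
    return 1.0 / (1.0 - p_cycle)


def male_fitness(genotype: Genotype, params: ModelParameters) -> float:
    """Absolute male fitness: larval survival times the fertility cost.
    Males never encounter ITNs."""
    return larval_survival(genotype, params) * resistance_cost_factor(
        genotype, params
    )


def female_fitness(genotype: Genotype, params: ModelParameters) -> float:
    """Absolute female fitness: larval survival x fecundity kappa x
    fecundity cost x expected adult lifespan in gonotrophic cycles."""
    return (
        larval_survival(genotype, params)
        * params.kappa
        * resistance_cost_factor(genotype, params)
        * expected_lifespan(genotype, params)
    )


@dataclass(frozen=True)
class FitnessTable:
    """Absolute fitnesses of the six sex-genotype classes.

    Entries are indexed by ``table[sex, genotype]``.  Male fitnesses are
    dimensionless; female fitnesses carry the fecundity scale kappa.
    Both scales cancel in the recursion, which divides by mean fitness.
    """

    _w: dict[tuple[Sex, Genotype], float]

    def __post_init__(self) -> None:
        if set(self._w) != {(s, g) for s in Sex for g in Genotype}:
            raise ValueError("fitness table must have all six sex-genotype entries")
        if any(v < 0 for v in self._w.values()):
            raise ValueError("fitnesses must be non-negative")

    def __getitem__(self, key: tuple[Sex, Genotype]) -> float:
        return self._w[key]

    def by_sex(self, sex: Sex) -> tuple[float, float, float]:
        """Fitnesses (W_SS, W_RS, W_RR) for one sex, canonical order."""
        return tuple(self._w[sex, g] for g in GENOTYPES)  # type: ignore[return-value]


def build_fitness_table(params: ModelParameters) -> FitnessTable:
    """Evaluate all six absolute fitnesses for a parameter set."""
    w: dict[tuple[Sex, Genotype], float] = {}
    for g in GENOTYPES:
        w[Sex.MALE, g] = male_fitness(g, params)
        w[Sex.FEMALE, g] = female_fitness(g, params)
    return FitnessTable(w)


def mean_fitness(table: FitnessTable, freqs: AlleleFrequencies, sex: Sex) -> float:
    """Population mean fitness of one sex under random mating:

        Wbar = W_RR p_m p_f + W_RS (p_m q_f + p_f q_m) + W_SS q_m q_f
    """
    w_ss, w_rs, w_rr = table.by_sex(sex)
    het = freqs.p_m * freqs.q_f + freqs.p_f * freqs.q_m
    return (
        w_rr * freqs.p_m * freqs.p_f + w_rs * het + w_ss * freqs.q_m * freqs.q_f
    )


def genotype_frequencies_after_selection(
    table: FitnessTable, freqs: AlleleFrequencies, sex: Sex
) -> tuple[float, float, float]:
    """Post-selection genotype proportions (SS, RS, RR) in one sex:
    random-mating zygote proportions weighted by fitness and normalized
    by the sex's mean fitness."""
    w_ss, w_rs, w_rr = table.by_sex(sex)
    wbar = mean_fitness(table, freqs, sex)
    if wbar <= 0.0:
        raise PopulationExtinctError(
            f"mean {sex.value} fitness is zero; selection is undefined"
        )
    het = freqs.p_m * freqs.q_f + freqs.p_f * freqs.q_m
    return (
        w_ss * freqs.q_m * freqs.q_f / wbar,
        w_rs * het / wbar,
        w_rr * freqs.p_m * freqs.p_f / wbar,
    )


def next_allele_frequencies(
    table: FitnessTable, freqs: AlleleFrequencies
) -> AlleleFrequencies:
    """One generation of the two-sex recursion.

    The resistance-allele frequency transmitted by each sex is the
    post-selection RR proportion plus half the RS proportion:

        p_x(t+1) = [W_x,RR p_m p_f + 0.5 W_x,RS (p_m q_f + p_f q_m)] / Wbar_x
    """
    p_m, p_f = freqs.p_m, freqs.p_f
    q_m, q_f = freqs.q_m, freqs.q_f
    het = p_m * q_f + p_f * q_m
    out: dict[Sex, float] = {}
    for sex in Sex:
        w_ss, w_rs, w_rr = table.by_sex(sex)
        wbar = w_rr * p_m * p_f + w_rs * het + w_ss * q_m * q_f
        if wbar <= 0.0:
            raise PopulationExtinctError(
                f"mean {sex.value} fitness is zero; the recursion is undefined"
            )
        out[sex] = (w_rr * p_m * p_f + 0.5 * w_rs * het) / wbar
    # Guard floating-point overshoot at the boundaries.
    return AlleleFrequencies(
        p_m=min(1.0, max(0.0, out[Sex.MALE])),
        p_f=min(1.0, max(0.0, out[Sex.FEMALE])),
    )
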