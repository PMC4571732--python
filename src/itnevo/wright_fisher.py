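"""Finite-population sampling counterpart of the deterministic recursion.

The state holds post-selection adult genotype counts per sex.  Each
generation, the adults' allele frequencies define random-mating zygote
proportions; viability selection weights these by the sex-specific
fitnesses, giving each sex's post-selection genotype distribution, and
the next generation's adult counts are one multinomial draw per sex at
constant census sizes N_m and N_f (soft selection).  The expectation of
each sex's allele frequency therefore follows the deterministic
recursion exactly, making this a verification oracle for the
deterministic engine and a probe of drift at small N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fitness import (
    AlleleFrequencies,
    build_fitness_table,
    genotype_frequencies_after_selection,
    mean_fitness,
)
from .params import ModelParameters, Sex

__all__ = [
    "PopulationState",
    "stochastic_generation",
    "stochastic_trajectory",
    "StochasticTrajectory",
]

_GENOTYPE_COLS = ("SS", "RS", "RR")


@dataclass(frozen=True)
class PopulationState:
    """Genotype counts per sex, ordered (SS, RS, RR)."""

    male_counts: tuple[int, int, int]
    female_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        for counts in (self.male_counts, self.female_counts):
            if len(counts) != 3 or any(c < 0 for c in counts):
                raise ValueError("counts must be three non-negative integers")
        if self.n_m < 1 or self.n_f < 1:
            raise ValueError("population sizes must be at least 1 per sex")

    @property
    def n_m(self) -> int:
        return int(sum(self.male_counts))

    @property
    def n_f(self) -> int:
        return int(sum(self.female_counts))

    @property
    def allele_frequencies(self) -> AlleleFrequencies:
        ss_m, rs_m, rr_m = self.male_counts
        ss_f, rs_f, rr_f = self.female_counts
        return AlleleFrequencies(
            p_m=(2 * rr_m + rs_m) / (2 * self.n_m),
            p_f=(2 * rr_f + rs_f) / (2 * self.n_f),
        )

    @classmethod
    def from_allele_frequency(
        cls, p: float, n_m: int, n_f: int
    ) -> "PopulationState":
        """Deterministic Hardy-Weinberg seeding: rounded expected counts
        at allele frequency ``p`` in both sexes."""
        def counts(n: int) -> tuple[int, int, int]:
            rr = round(n * p * p)
            rs = round(n * 2 * p * (1 - p))
            rr, rs = min(rr, n), min(rs, n)
            if rr + rs > n:
                rs = n - rr
            return (n - rr - rs, rs, rr)

        return cls(counts(n_m), counts(n_f))


def _offspring_probabilities(
    state: PopulationState, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Post-selection genotype distributions (SS, RS, RR) per sex.

    Adults' allele frequencies give random-mating zygote proportions;
    weighting by the sex-specific fitnesses and normalizing yields each
    sex's adult genotype distribution in the next generation.
    """
    table = build_fitness_table(params)
    freqs = state.allele_frequencies
    return (
        np.array(genotype_frequencies_after_selection(table, freqs, Sex.MALE)),
        np.array(genotype_frequencies_after_selection(table, freqs, Sex.FEMALE)),
    )


def stochastic_generation(
    state: PopulationState,
    params: ModelParameters,
    rng: int | np.random.Generator,
) -> PopulationState:
    """One generation: random mating + deterministic selection define
    per-sex genotype distributions, then one multinomial draw of N_m
    adult males and one of N_f adult females."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    male_probs, female_probs = _offspring_probabilities(state, params)
    males = gen.multinomial(state.n_m, male_probs)
    females = gen.multinomial(state.n_f, female_probs)
    return PopulationState(tuple(int(c) for c in males), tuple(int(c) for c in females))


@dataclass
class StochasticTrajectory:
    """Record of a finite-population run, one row per generation
    (including the initial state)."""

    params: ModelParameters
    seed: int
    n_m: int
    n_f: int
    p_m: np.ndarray
    p_f: np.ndarray
    w_bar_m: np.ndarray
    w_bar_f: np.ndarray

    @property
    def p_mean(self) -> np.ndarray:
        return 0.5 * (self.p_m + self.p_f)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(len(self.p_m)),
                "p_m": self.p_m,
                "p_f": self.p_f,
                "p_mean": self.p_mean,
                "W_bar_m": self.w_bar_m,
                "W_bar_f": self.w_bar_f,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def run_record(self) -> dict:
        return {
            "parameters": self.params.to_dict(),
            "seed": self.seed,
            "N_m": self.n_m,
            "N_f": self.n_f,
            "generations_run": int(len(self.p_m) - 1),
            "final_p_m": float(self.p_m[-1]),
            "final_p_f": float(self.p_f[-1]),
        }

    def write_run_record(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.run_record(), indent=2))


def stochastic_trajectory(
    state: PopulationState,
    params: ModelParameters,
    generations: int,
    rng_seed: int,
) -> StochasticTrajectory:
    """Iterate :func:`stochastic_generation` for a fixed number of
    generations.  Replay is bit-identical under the same seed."""
    if generations < 1:
        raise ValueError("generations must be >= 1")
    gen = np.random.default_rng(rng_seed)
    table = build_fitness_table(params)
    p_ms, p_fs, wbms, wbfs = [], [], [], []

    def record(st: PopulationState) -> None:
        freqs = st.allele_frequencies
        p_ms.append(freqs.p_m)
        p_fs.append(freqs.p_f)
        wbms.append(mean_fitness(table, freqs, Sex.MALE))
        wbfs.append(mean_fitness(table, freqs, Sex.FEMALE))

    record(state)
    for _ in range(generations):
        state = stochastic_generation(state, params, gen)
        record(state)
    return StochasticTrajectory(
        params=params,
        seed=rng_seed,
        n_m=state.n_m,
        n_f=state.n_f,
        p_m=np.asarray(p_ms),
        p_f=np.asarray(p_fs),
        w_bar_m=np.asarray(wbms),
        w_bar_f=np.asarray(wbfs),
    )
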