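"""Deterministic dynamics: trajectories, outcome classification,
times-to-frequency, invasion growth factors and coverage thresholds."""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import (
    PopulationExtinctError,
    ResidentInviableError,
    UndefinedRatioError,
)
from .fitness import AlleleFrequencies, build_fitness_table
from .params import Genotype, ModelParameters, Sex

__all__ = [
    "OutcomeLabel",
    "Trajectory",
    "simulate_trajectory",
    "time_to_frequency",
    "invasion_growth_factor",
    "classify_outcome",
    "find_coverage_threshold",
    "evolution_time_ratio",
    "FIXATION_TOL",
    "ELIMINATION_TOL",
    "DEFAULT_MAX_GENERATIONS",
]

logger = logging.getLogger(__name__)

#: Mean frequency above 1 - FIXATION_TOL counts as fixation.
FIXATION_TOL = 1e-6
#: Mean frequency below ELIMINATION_TOL counts as elimination; sits well
#: below the customary 1e-5 initial frequency.
ELIMINATION_TOL = 1e-9
DEFAULT_MAX_GENERATIONS = 50_000

#: Default initial frequency used by the published scenarios.
DEFAULT_INIT = AlleleFrequencies(1e-5, 1e-5)


class OutcomeLabel(enum.Enum):
    FIXATION = "fixation"
    ELIMINATION = "elimination"
    NOT_CONVERGED = "not-converged"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _sex_fitnesses(params: ModelParameters) -> tuple[tuple[float, ...], tuple[float, ...]]:
    table = build_fitness_table(params)
    return table.by_sex(Sex.MALE), table.by_sex(Sex.FEMALE)


def _step(pm: float, pf: float, wm: tuple[float, ...], wf: tuple[float, ...]):
    # Scalar inner loop of the recursion; returns (pm', pf', Wbar_m, Wbar_f).
    qm, qf = 1.0 - pm, 1.0 - pf
    het = pm * qf + pf * qm
    hom_r = pm * pf
    hom_s = qm * qf
    wbar_m = wm[2] * hom_r + wm[1] * het + wm[0] * hom_s
    wbar_f = wf[2] * hom_r + wf[1] * het + wf[0] * hom_s
    if wbar_m <= 0.0 or wbar_f <= 0.0:
        raise PopulationExtinctError("mean fitness reached zero during iteration")
    pm_next = (wm[2] * hom_r + 0.5 * wm[1] * het) / wbar_m
    pf_next = (wf[2] * hom_r + 0.5 * wf[1] * het) / wbar_f
    return (
        min(1.0, max(0.0, pm_next)),
        min(1.0, max(0.0, pf_next)),
        wbar_m,
        wbar_f,
    )


@dataclass
class Trajectory:
    """Generation-indexed record of a deterministic run.

    Columns follow the CSV contract: generation, p_m, p_f, p_mean,
    W_bar_m, W_bar_f.  Mean fitnesses are those of the recorded
    generation's adults (the parents producing the next generation).
    """

    params: ModelParameters
    generation: np.ndarray
    p_m: np.ndarray
    p_f: np.ndarray
    w_bar_m: np.ndarray
    w_bar_f: np.ndarray
    outcome: OutcomeLabel
    fixation_tol: float = FIXATION_TOL
    elimination_tol: float = ELIMINATION_TOL
    extras: dict = field(default_factory=dict)

    @property
    def p_mean(self) -> np.ndarray:
        return 0.5 * (self.p_m + self.p_f)

    def __len__(self) -> int:
        return len(self.generation)

    @property
    def final(self) -> AlleleFrequencies:
        return AlleleFrequencies(float(self.p_m[-1]), float(self.p_f[-1]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
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
        """JSON-serializable record of parameters, tolerances and outcome."""
        rec = {
            "parameters": self.params.to_dict(),
            "fixation_tol": self.fixation_tol,
            "elimination_tol": self.elimination_tol,
            "generations_run": int(self.generation[-1]),
            "outcome": self.outcome.value,
            "final_p_m": float(self.p_m[-1]),
            "final_p_f": float(self.p_f[-1]),
        }
        rec.update(self.extras)
        return rec

    def write_run_record(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.run_record(), indent=2))


def simulate_trajectory(
    params: ModelParameters,
    init: AlleleFrequencies = DEFAULT_INIT,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
    fixation_tol: float = FIXATION_TOL,
    elimination_tol: float = ELIMINATION_TOL,
) -> Trajectory:
    """Iterate the recursion from ``init``, recording every generation.

    Stops early once the sex-averaged frequency exceeds
    ``1 - fixation_tol`` (fixation) or drops below ``elimination_tol``
    (elimination); otherwise runs ``max_generations`` generations and
    labels the run not-converged.
    """
    if max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    wm, wf = _sex_fitnesses(params)
    pm, pf = init.p_m, init.p_f
    gens = [0]
    pms = [pm]
    pfs = [pf]
    wbm0, wbf0 = _mean_fitnesses(pm, pf, wm, wf)
    wbms = [wbm0]
    wbfs = [wbf0]

    def _label(mean: float) -> OutcomeLabel:
        if mean > 1.0 - fixation_tol:
            return OutcomeLabel.FIXATION
        if mean < elimination_tol:
            return OutcomeLabel.ELIMINATION
        return OutcomeLabel.NOT_CONVERGED

    outcome = _label(0.5 * (pm + pf))
    if outcome is OutcomeLabel.NOT_CONVERGED:
        for t in range(1, max_generations + 1):
            pm, pf, _, _ = _step(pm, pf, wm, wf)
            wbar_m, wbar_f = _mean_fitnesses(pm, pf, wm, wf)
            gens.append(t)
            pms.append(pm)
            pfs.append(pf)
            wbms.append(wbar_m)
            wbfs.append(wbar_f)
            outcome = _label(0.5 * (pm + pf))
            if outcome is not OutcomeLabel.NOT_CONVERGED:
                break
    return Trajectory(
        params=params,
        generation=np.asarray(gens, dtype=int),
        p_m=np.asarray(pms, dtype=float),
        p_f=np.asarray(pfs, dtype=float),
        w_bar_m=np.asarray(wbms, dtype=float),
        w_bar_f=np.asarray(wbfs, dtype=float),
        outcome=outcome,
        fixation_tol=fixation_tol,
        elimination_tol=elimination_tol,
    )


def _mean_fitnesses(pm, pf, wm, wf):
    qm, qf = 1.0 - pm, 1.0 - pf
    het = pm * qf + pf * qm
    wbar_m = wm[2] * pm * pf + wm[1] * het + wm[0] * qm * qf
    wbar_f = wf[2] * pm * pf + wf[1] * het + wf[0] * qm * qf
    return wbar_m, wbar_f


def time_to_frequency(
    params: ModelParameters,
    init: AlleleFrequencies = DEFAULT_INIT,
    target: float = 0.5,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
) -> int | None:
    """First generation at which the sex-averaged frequency reaches
    ``target``; ``None`` ("never") if it is not reached within
    ``max_generations`` or the allele is eliminated first."""
    if not 0.0 < target < 1.0:
        raise ValueError("target must lie strictly between 0 and 1")
    wm, wf = _sex_fitnesses(params)
    pm, pf = init.p_m, init.p_f
    for t in range(max_generations + 1):
        mean = 0.5 * (pm + pf)
        if mean >= target:
            return t
        if mean < ELIMINATION_TOL:
            return None
        pm, pf, _, _ = _step(pm, pf, wm, wf)
    return None


def invasion_growth_factor(
    params: ModelParameters, invading_allele: Literal["R", "S"] = "R"
) -> float:
    """Per-generation growth factor of a rare allele against the
    monomorphic resident, from the linearized recursion.

    A rare allele appears almost exclusively in heterozygotes, so its
    summed frequency across sexes multiplies each generation by

        lambda = 0.5 * (W_m,RS / W_m,resident + W_f,RS / W_f,resident)

    with resident SS for invading R and resident RR for invading S.
    lambda > 1 means the allele increases when rare.
    """
    if invading_allele not in ("R", "S"):
        raise ValueError("invading_allele must be 'R' or 'S'")
    resident = Genotype.SS if invading_allele == "R" else Genotype.RR
    table = build_fitness_table(params)
    total = 0.0
    for sex in Sex:
        w_res = table[sex, resident]
        if w_res <= 0.0:
            raise ResidentInviableError(
                f"resident genotype {resident.value} has zero {sex.value} fitness"
            )
        total += table[sex, Genotype.RS] / w_res
    return 0.5 * total


def classify_outcome(
    params: ModelParameters,
    init: AlleleFrequencies = DEFAULT_INIT,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
) -> OutcomeLabel:
    """Terminal label of the deterministic trajectory from ``init``.

    ``NOT_CONVERGED`` is a legitimate return: a narrow larvicide-only
    coverage band lets both alleles invade when rare (protected
    polymorphism), and neutral parameters never move at all.
    """
    return simulate_trajectory(params, init, max_generations).outcome


def _growth_or_inf(params: ModelParameters, allele: Literal["R", "S"]) -> float:
    # A zero-fitness resident is instantly displaced by any viable
    # heterozygote: the growth factor diverges.
    try:
        return invasion_growth_factor(params, allele)
    except ResidentInviableError:
        return math.inf


def _criterion_holds(
    params: ModelParameters, criterion: Literal["invasion", "fixation"]
) -> bool:
    lam_r = _growth_or_inf(params, "R")
    if criterion == "invasion":
        return lam_r > 1.0
    return lam_r > 1.0 and _growth_or_inf(params, "S") < 1.0


def find_coverage_threshold(
    params: ModelParameters,
    vary: Literal["phi", "psi"] = "psi",
    criterion: Literal["invasion", "fixation"] = "invasion",
    tol: float = 1e-4,
    grid_points: int = 101,
) -> float | None:
    """Smallest coverage in [0, 1] of ``vary`` at which the criterion
    holds, all other parameters fixed.

    Criteria: ``invasion`` requires lambda_R > 1; ``fixation``
    additionally requires lambda_S < 1 (resistance both invades and
    cannot be re-invaded).  A ``grid_points``-point pre-scan brackets the
    lowest crossing, then bisection refines it to absolute tolerance
    ``tol``.  Returns ``None`` if the criterion holds nowhere on the grid.
    """
    if vary not in ("phi", "psi"):
        raise ValueError("vary must be 'phi' or 'psi'")
    grid = np.linspace(0.0, 1.0, grid_points)
    holds = [_criterion_holds(params.replace(**{vary: float(x)}), criterion) for x in grid]
    if not any(holds):
        return None
    first = next(i for i, h in enumerate(holds) if h)
    if sum(1 for a, b in zip(holds, holds[1:]) if a != b) > 1:
        logger.warning(
            "criterion %s changes state more than once along %s; "
            "reporting the smallest crossing",
            criterion,
            vary,
        )
    if first == 0:
        return float(grid[0])
    lo, hi = float(grid[first - 1]), float(grid[first])
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _criterion_holds(params.replace(**{vary: mid}), criterion):
            hi = mid
        else:
            lo = mid
    return hi


def round_percent(coverage: float) -> int:
    """Coverage as a whole percentage, rounded half-up (0.098 -> 10)."""
    return int(math.floor(coverage * 100.0 + 0.5))


def evolution_time_ratio(
    coverage: float,
    params: ModelParameters,
    target: float = 0.5,
    init: AlleleFrequencies = DEFAULT_INIT,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
) -> float:
    """Ratio of times to reach ``target`` under ITN-only versus
    larvicide-only deployment at the same coverage.

    Runs the recursion with (phi=coverage, psi=0) and (psi=coverage,
    phi=0) from the same initial frequencies.  Returns ``inf`` if only
    the ITN scenario never reaches the target; raises
    :class:`UndefinedRatioError` if the larvicide scenario never does.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    t_itn = time_to_frequency(
        params.replace(phi=coverage, psi=0.0), init, target, max_generations
    )
    t_larv = time_to_frequency(
        params.replace(psi=coverage, phi=0.0), init, target, max_generations
    )
    if t_larv is None or t_larv == 0:
        raise UndefinedRatioError(
            "larvicide-only scenario never reaches the target frequency; "
            "the ITN/larvicide time ratio is undefined"
        )
    if t_itn is None:
        return math.inf
    return t_itn / t_larv
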