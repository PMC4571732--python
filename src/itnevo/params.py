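"""Model parameters and basic enumerations.

The model tracks a single autosomal resistance locus with alleles R
(resistant) and S (sensitive) in a mosquito population exposed to two
insecticide pressures: insecticide-treated bed nets (ITNs), which act on
adult females during the feeding cycle, and larvicides, which act on the
aquatic larvae of both sexes.  All parameters are dimensionless
probabilities unless stated otherwise.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

from .exceptions import ParameterError

__all__ = ["Genotype", "Sex", "ModelParameters", "GENOTYPES", "load_parameters"]


class Genotype(enum.Enum):
    """Diploid genotype at the resistance locus. RS is the unordered
    heterozygote."""

    SS = "SS"
    RS = "RS"
    RR = "RR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical genotype ordering used for all tabulated output.
GENOTYPES = (Genotype.SS, Genotype.RS, Genotype.RR)


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_PROBABILITY_FIELDS = (
    "phi", "psi", "Q", "r", "s", "sigma", "mu", "mu_r", "h", "rho", "Z",
)

#: Config keys accepted by :func:`load_parameters`, in canonical order.
CONFIG_KEYS = (
    "phi", "psi", "Q", "r", "s", "sigma", "mu", "gt", "mu_gt", "mu_r",
    "h", "rho", "Z", "kappa",
)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the feeding-cycle resistance model.

    Parameters
    ----------
    phi : float
        ITN coverage: probability that a house targeted by a
        human-feeding mosquito is protected by a treated net.
    psi : float
        Larvicide coverage: proportion of larval sites treated with a
        lethal concentration of the insecticide (also a proxy for
        agricultural run-off exposure).
    Q : float
        Indoor human-feeding probability (anthropophily); a proportion
        1 - Q of feeding attempts target animals.
    r : float
        Repellency: probability that a mosquito contacting a treated net
        is deterred (or mechanically blocked) and restarts host search.
    s : float
        Probability that a *sensitive* mosquito survives ITN insecticide
        exposure while feeding in a protected house.
    sigma : float
        Probability of surviving feeding-associated risks, identical for
        human and animal hosts.
    mu : float
        Daily adult background mortality.
    gt : float
        Gonotrophic cycle length in days (blood meal to oviposition).
    mu_gt : float or None
        Per-cycle feeding-independent mortality.  When ``None`` it is
        derived exactly as ``1 - (1 - mu)**gt``; a numeric value
        overrides the derivation (e.g. to use a rounded published value).
    mu_r : float
        Additional mortality risk incurred per repeated host search
        after being repelled.
    h : float
        Dominance of the resistance allele: fraction of the homozygote
        resistance (and cost) expressed in heterozygotes.
    rho : float
        Resistance level: proportional reduction of insecticide-induced
        mortality in RR homozygotes.
    Z : float
        Fitness cost of resistance, paid through fecundity (females) or
        fertility/competitiveness (males).
    kappa : float
        Female fecundity (offspring per gonotrophic cycle lifetime unit);
        cancels out of the frequency recursion but is kept so female
        fitnesses are absolute reproductive outputs.

    Defaults are the model's typical field-derived values; ``phi`` and
    ``psi`` default to 0 (no intervention) and are set per scenario.
    """

    phi: float = 0.0
    psi: float = 0.0
    Q: float = 0.7
    r: float = 0.7
    s: float = 0.16
    sigma: float = 0.9
    mu: float = 0.1
    gt: float = 3.0
    mu_gt: float | None = None
    mu_r: float = 0.03
    h: float = 0.25
    rho: float = 0.95
    Z: float = 0.10
    kappa: float = 100.0

    def __post_init__(self) -> None:
        for name in _PROBABILITY_FIELDS:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ParameterError(
                    f"{name} must be a probability in [0, 1], got {value!r}"
                )
        if self.mu_gt is not None and not 0.0 <= self.mu_gt <= 1.0:
            raise ParameterError(
                f"mu_gt override must be in [0, 1], got {self.mu_gt!r}"
            )
        if self.gt <= 0:
            raise ParameterError(f"gt must be positive, got {self.gt!r}")
        if self.kappa <= 0:
            raise ParameterError(f"kappa must be positive, got {self.kappa!r}")
        # Strict bound guaranteeing convergence of the repeat-search
        # geometric series.
        if self.Q * self.phi * self.r * (1.0 - self.mu_r) >= 1.0:
            raise ParameterError(
                "Q*phi*r*(1-mu_r) must be < 1 for the repeat-search series "
                f"to converge; got {self.Q * self.phi * self.r * (1 - self.mu_r)}"
            )

    @property
    def effective_mu_gt(self) -> float:
        """Per-gonotrophic-cycle mortality: the override if set, else
        ``1 - (1 - mu)**gt``."""
        if self.mu_gt is not None:
            return self.mu_gt
        return 1.0 - (1.0 - self.mu) ** self.gt

    def replace(self, **changes: Any) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParameters":
        """Build parameters from a flat mapping; unknown keys are an error,
        absent keys fall back to the defaults."""
        unknown = set(data) - set(CONFIG_KEYS)
        if unknown:
            raise ParameterError(
                f"unknown parameter keys: {sorted(unknown)}; "
                f"valid keys are {list(CONFIG_KEYS)}"
            )
        return cls(**dict(data))


def load_parameters(path: str | Path) -> ModelParameters:
    """Read a flat TOML or JSON parameter file.

    Keys are exactly the field names of :class:`ModelParameters`; absent
    keys take the default values.  The format is chosen by extension
    (``.toml`` / ``.json``).
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    elif path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
    else:
        raise ParameterError(
            f"unsupported config format {path.suffix!r}: use .toml or .json"
        )
    return ModelParameters.from_dict(data)
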