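"""Sweep experiments: fixation boundaries, time-to-resistance curves and
larvicide-vs-ITN evolution-rate ratios, as tidy tables.

Each experiment walks a grid of coverages for a family of curves (one
curve per value of a secondary parameter such as repellency r or
human-feeding Q) and emits one row per (curve value, grid point).  The
tables, not plots, are the product; undefined quantities serialize as
the literal strings ``"never"``, ``"inf"`` and ``"undefined"`` rather
than sentinel numbers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .dynamics import (
    DEFAULT_MAX_GENERATIONS,
    ELIMINATION_TOL,
    FIXATION_TOL,
    AlleleFrequencies,
    evolution_time_ratio,
    find_coverage_threshold,
    time_to_frequency,
)
from .exceptions import UndefinedRatioError
from .params import ModelParameters

__all__ = [
    "SweepSpec",
    "fixation_boundary_experiment",
    "time_to_resistance_experiment",
    "larvicide_itn_ratio_experiment",
    "default_spec",
    "run_experiment",
    "write_table",
    "write_run_record",
    "EXPERIMENT_NAMES",
]

#: Published initial frequency for all time-based experiments.
SWEEP_INIT = AlleleFrequencies(1e-5, 1e-5)


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for one experiment.

    ``curve_param`` / ``curve_values`` define the curve family (e.g. r in
    {0, 0.2, ..., 1}); ``grid`` is the x-axis of coverages; ``base``
    carries every other parameter.
    """

    curve_param: str
    curve_values: tuple[float, ...]
    grid: tuple[float, ...]
    base: ModelParameters = field(default_factory=ModelParameters)

    def __post_init__(self) -> None:
        # Validate every curve/grid combination eagerly so errors carry
        # the offending value, not a mid-sweep traceback.
        for v in self.curve_values:
            self.base.replace(**{self.curve_param: float(v)})
        if any(not 0.0 <= x <= 1.0 for x in self.grid):
            raise ValueError("grid values must be coverages in [0, 1]")

    def curves(self):
        for v in self.curve_values:
            yield float(v), self.base.replace(**{self.curve_param: float(v)})


def _grid(n: int = 101) -> tuple[float, ...]:
    return tuple(np.round(np.linspace(0.0, 1.0, n), 10))


#: Default curve families, following the published figure captions.
_DEFAULT_SPECS = {
    "fixation-boundary-r": dict(curve_param="r", curve_values=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0)),
    "fixation-boundary-Q": dict(curve_param="Q", curve_values=(1.0, 0.8, 0.6, 0.4, 0.2, 0.0)),
    "time-to-resistance-psi": dict(curve_param="psi", curve_values=(0.0, 0.05, 0.10, 0.15, 0.20, 0.25)),
    "time-to-resistance-r": dict(curve_param="r", curve_values=(0.0, 0.2, 0.4, 0.6, 0.8)),
    "time-to-resistance-Q": dict(curve_param="Q", curve_values=(1.0, 0.9, 0.8, 0.7, 0.6)),
    "larvicide-itn-ratio": dict(curve_param="r", curve_values=(0.0, 0.2, 0.4, 0.6)),
}

EXPERIMENT_NAMES = tuple(_DEFAULT_SPECS)


def default_spec(
    name: str,
    base: ModelParameters | None = None,
    grid_points: int = 101,
) -> SweepSpec:
    """Build the default :class:`SweepSpec` for a named experiment."""
    if name not in _DEFAULT_SPECS:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENT_NAMES}")
    return SweepSpec(
        base=base if base is not None else ModelParameters(),
        grid=_grid(grid_points),
        **_DEFAULT_SPECS[name],
    )


def fixation_boundary_experiment(spec: SweepSpec) -> pd.DataFrame:
    """For each curve and each ITN coverage phi on the grid, the smallest
    larvicide coverage psi at which resistance is fixed (lambda_R > 1 and
    lambda_S < 1).  Missing boundaries (criterion holds nowhere) are NaN.
    """
    rows = []
    for value, params in spec.curves():
        for phi in spec.grid:
            psi_star = find_coverage_threshold(
                params.replace(phi=float(phi)), vary="psi", criterion="fixation"
            )
            rows.append(
                {
                    spec.curve_param: value,
                    "phi": float(phi),
                    "psi_fixation_boundary": math.nan if psi_star is None else psi_star,
                }
            )
    return pd.DataFrame(rows)


def time_to_resistance_experiment(
    spec: SweepSpec,
    target: float = 0.5,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
) -> pd.DataFrame:
    """Generations for the resistance allele to reach ``target`` from
    1e-5 in both sexes, per curve and ITN coverage.  Unreached targets
    are recorded as the string ``"never"``."""
    rows = []
    for value, params in spec.curves():
        for phi in spec.grid:
            t = time_to_frequency(
                params.replace(phi=float(phi)), SWEEP_INIT, target, max_generations
            )
            rows.append(
                {
                    spec.curve_param: value,
                    "phi": float(phi),
                    "generations_to_target": "never" if t is None else t,
                }
            )
    return pd.DataFrame(rows)


def larvicide_itn_ratio_experiment(
    spec: SweepSpec,
    target: float = 0.5,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
) -> pd.DataFrame:
    """Ratio of ITN-only to larvicide-only time to reach ``target`` at
    equal coverage, per curve.  Infinite ratios (ITN scenario never gets
    there) serialize as ``"inf"``; undefined ones (larvicide scenario
    never does, e.g. coverage 0 or neutral alleles) as ``"undefined"``."""
    rows = []
    for value, params in spec.curves():
        for cov in spec.grid:
            if cov <= 0.0:
                ratio: float | str = "undefined"
            else:
                try:
                    ratio = evolution_time_ratio(
                        float(cov), params, target, SWEEP_INIT, max_generations
                    )
                except UndefinedRatioError:
                    ratio = "undefined"
                else:
                    if math.isinf(ratio):
                        ratio = "inf"
            rows.append(
                {spec.curve_param: value, "coverage": float(cov), "time_ratio": ratio}
            )
    return pd.DataFrame(rows)


_RUNNERS = {
    "fixation-boundary-r": fixation_boundary_experiment,
    "fixation-boundary-Q": fixation_boundary_experiment,
    "time-to-resistance-psi": time_to_resistance_experiment,
    "time-to-resistance-r": time_to_resistance_experiment,
    "time-to-resistance-Q": time_to_resistance_experiment,
    "larvicide-itn-ratio": larvicide_itn_ratio_experiment,
}


def run_experiment(name: str, spec: SweepSpec | None = None, **kwargs) -> pd.DataFrame:
    """Run a named experiment with its default spec unless one is given."""
    if spec is None:
        spec = default_spec(name)
    return _RUNNERS[name](spec, **kwargs)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an experiment table as CSV (deterministic byte-for-byte for
    identical inputs)."""
    df.to_csv(path, index=False)


def write_run_record(
    spec: SweepSpec, name: str, path: str | Path, **extra
) -> None:
    """JSON run-record: parameters, grid, tolerances and tool version."""
    record = {
        "experiment": name,
        "tool_version": _version,
        "parameters": spec.base.to_dict(),
        "curve_param": spec.curve_param,
        "curve_values": list(spec.curve_values),
        "grid": list(spec.grid),
        "fixation_tol": FIXATION_TOL,
        "elimination_tol": ELIMINATION_TOL,
        "init_frequency": {"p_m": SWEEP_INIT.p_m, "p_f": SWEEP_INIT.p_f},
    }
    record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2))
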