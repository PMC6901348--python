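"""Canonical benchmark experiment protocols.

Each protocol names a benchmark task, the metric its headline number uses,
and the model configuration for desk-scale replication runs.  The search
budgets (GA population/generations, ICA population/iterations) are reduced
from the reference metaheuristic settings so that a ten-seed replication of
every protocol completes in minutes on one CPU; the selection rules, model
structure, initialisation and pruning are identical to the full-budget
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ica import ICAConfig
from .selection import GAConfig, SelectionConfig
from .training import InitConfig

__all__ = ["Protocol", "PROTOCOLS", "desk_selection", "desk_ica"]


def desk_ga() -> GAConfig:
    return GAConfig(population_size=150, generations=12)


def desk_selection(**kw) -> SelectionConfig:
    kw.setdefault("ga", desk_ga())
    return SelectionConfig(**kw)


def desk_ica(**kw) -> ICAConfig:
    kw.setdefault("population", 120)
    kw.setdefault("max_iterations", 40)
    return ICAConfig(**kw)


@dataclass
class Protocol:
    """One headline replication: benchmark, metric, model configuration."""

    benchmark: str
    metric: str  # key into the evaluate() dict, reported on the test split
    benchmark_kwargs: dict = field(default_factory=dict)
    selection: SelectionConfig = field(default_factory=desk_selection)
    ica: ICAConfig = field(default_factory=desk_ica)
    init: InitConfig = field(default_factory=InitConfig)
    runs: int = 10


#: headline benchmark protocols, keyed by a short experiment name.
#: ICA budgets scale with the per-evaluation cost of each task (sample count
#: and design width) so every ten-seed replication runs in about two minutes.
PROTOCOLS: dict[str, Protocol] = {
    "piecewise": Protocol(
        benchmark="example1", metric="rrse", ica=desk_ica(population=250, max_iterations=60)
    ),
    "plant2-1": Protocol(
        benchmark="plant2-1", metric="rmse", ica=desk_ica(population=220, max_iterations=60)
    ),
    "plant2-2": Protocol(
        benchmark="plant2-2", metric="rrse", ica=desk_ica(population=120, max_iterations=50)
    ),
    "plant2-4": Protocol(
        benchmark="plant2-4", metric="rrse", ica=desk_ica(population=200, max_iterations=55)
    ),
    "plant2-5": Protocol(
        benchmark="plant2-5", metric="rrse", ica=desk_ica(population=120, max_iterations=50)
    ),
    "mackey-glass-17": Protocol(
        benchmark="mackey-glass",
        metric="rmse",
        benchmark_kwargs={"tau": 17.0},
        ica=desk_ica(population=200, max_iterations=55),
    ),
    "mackey-glass-100": Protocol(
        benchmark="mackey-glass",
        metric="rmse",
        benchmark_kwargs={"tau": 100.0},
        ica=desk_ica(population=150, max_iterations=50),
    ),
}
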