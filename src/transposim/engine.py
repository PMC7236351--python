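"""Run a simulation to termination and classify its outcome.

A run starts from a founder host (built by :func:`transposim.model_core.init_genome`)
cloned to exactly the carrying capacity, then iterates cycles until one of
three terminal conditions: no active TEs remain anywhere (TE extinction),
no hosts remain (host extinction), or the cycle cap is reached with both
still present (TE accumulation).  The cap replaces a fixed walltime budget
and makes results machine-independent; it is recorded with every result.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .dynamics import CycleRecord, Population, population_record, run_cycle
from .model_core import Host, ParameterSet, init_genome

__all__ = [
    "CycleRecord",
    "ExperimentResult",
    "Outcome",
    "classify_outcome",
    "run_simulation",
]


class Outcome(str, enum.Enum):
    """The three terminal classes of a run."""

    TE_EXTINCTION = "te_extinction"
    HOST_EXTINCTION = "host_extinction"
    TE_ACCUMULATION = "te_accumulation"


def classify_outcome(hosts_alive: int, active_te_total: int) -> Outcome:
    """Label a terminated run.

    Host extinction takes precedence (TEs cannot persist in zero hosts);
    otherwise a run with no active TEs — inactive copies may remain — is TE
    extinction, and a run where both persist to the cycle cap is TE
    accumulation.
    """
    if hosts_alive == 0:
        return Outcome.HOST_EXTINCTION
    if active_te_total == 0:
        return Outcome.TE_EXTINCTION
    return Outcome.TE_ACCUMULATION


@dataclass
class ExperimentResult:
    """Outcome, trajectory and provenance of one simulation run.

    ``trajectory[0]`` is the initial population (cycle 0); one further record
    follows per executed cycle, so ``len(trajectory) == cycles_run + 1``.
    """

    outcome: Outcome
    trajectory: list[CycleRecord]
    params: ParameterSet
    seed: int | None
    cycles_run: int


def run_simulation(params: ParameterSet, seed: int | None = None) -> ExperimentResult:
    """Execute one run to termination.

    ``seed`` overrides ``params.seed``; all randomness flows through a single
    numpy Generator, so identical ``(params, seed)`` reproduce the trajectory
    bit for bit.  Termination is checked after the selection step of each
    cycle.
    """
    used_seed = params.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    founder = Host(init_genome(params, rng))
    hosts = [founder] + [founder.clone()
                         for _ in range(params.carrying_capacity - 1)]
    pop = Population(hosts, params.carrying_capacity)
    trajectory = [population_record(0, pop)]
    cycles_run = 0
    outcome = None
    for cycle in range(1, params.max_cycles + 1):
        pop, record = run_cycle(pop, params, rng, cycle)
        trajectory.append(record)
        cycles_run = cycle
        if len(pop.hosts) == 0:
            outcome = Outcome.HOST_EXTINCTION
            break
        if pop.total_active_te == 0:
            outcome = Outcome.TE_EXTINCTION
            break
    if outcome is None:
        outcome = classify_outcome(len(pop.hosts), pop.total_active_te)
    return ExperimentResult(outcome, trajectory, params, used_seed, cycles_run)
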