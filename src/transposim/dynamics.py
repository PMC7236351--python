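"""Per-cycle stochastic updates of the host population.

One cycle applies, in order: (1) every host is cloned, doubling the
population; (2) each clone may suffer one mutation-effect draw; (3) every
active TE may die (become permanently inactive); (4) every active TE may
excise, and (5-7) each excised TE reinserts 0-3 copies at positions drawn
from the TE insertion distribution, with insertions into genes hitting the
host's survival likelihood and insertions into other TEs deactivating the
destination; (8) hosts survive into the next cycle independently with
probability ``min(1, w_i / sum(w) * K)``, which makes the expected number of
survivors equal the carrying capacity ``K`` whenever no probability clamps.

Only clones are exposed to step 2; steps 3-7 apply to parents and clones
alike.  TE copies inserted during a cycle are not eligible for death or
excision until the next cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from .model_core import (
    ELEMENT_LENGTH,
    ElementKind,
    FitnessEffect,
    Host,
    ParameterSet,
    excise_te,
    insert_te,
    sample_position,
)


@dataclass
class Population:
    """The host population and the carrying capacity it trends toward."""

    hosts: list[Host]
    carrying_capacity: int

    def __len__(self) -> int:
        return len(self.hosts)

    @property
    def total_active_te(self) -> int:
        return sum(h.genome.n_active_te for h in self.hosts)


def clone_population(pop: Population) -> Population:
    """Double the population: parents first, then one deep-copied clone each."""
    clones = [h.clone() for h in pop.hosts]
    return Population(pop.hosts + clones, pop.carrying_capacity)


def apply_fitness_effect(host: Host, effect: FitnessEffect,
                         params: ParameterSet, rng: np.random.Generator) -> None:
    """Adjust a host's survival likelihood for one effect-category draw.

    Lethal sets the likelihood to exactly 0.  Deleterious and beneficial
    effects subtract or add ``U(0,1) * mutation_effect``, clamping at 0 from
    below; there is no upper cap.
    """
    if effect is FitnessEffect.LETHAL:
        host.survival_likelihood = 0.0
    elif effect is FitnessEffect.DELETERIOUS:
        host.survival_likelihood = max(
            0.0, host.survival_likelihood - rng.random() * params.mutation_effect)
    elif effect is FitnessEffect.BENEFICIAL:
        host.survival_likelihood += rng.random() * params.mutation_effect


def apply_host_mutation(host: Host, params: ParameterSet,
                        rng: np.random.Generator) -> Host:
    """Step 2: with probability ``host_mutation_rate``, one effect draw.

    At most one draw is made per host per cycle — the rate is the chance of
    the host being mutated at all, not a per-gene rate.
    """
    if rng.random() < params.host_mutation_rate:
        apply_fitness_effect(
            host, params.host_mutation_table.sample(rng), params, rng)
    return host


def apply_te_death(host: Host, params: ParameterSet,
                   rng: np.random.Generator) -> Host:
    """Step 3: each active TE independently dies with ``te_death_rate``.

    Death is permanent inactivation; inactive TEs never return to activity.
    """
    kinds = host.genome.kinds
    idx = np.flatnonzero(kinds == ElementKind.TE_ACTIVE)
    if idx.size:
        dead = idx[rng.random(idx.size) < params.te_death_rate]
        kinds[dead] = ElementKind.TE_INACTIVE
    return host


def excision_and_reinsertion(host: Host, params: ParameterSet,
                             rng: np.random.Generator) -> list[str]:
    """Steps 4-7: excise active TEs and reinsert their progeny.

    Each active TE independently excises with ``te_excision_rate``.  Excised
    TEs are processed one at a time, left to right: the TE is removed, a
    progeny count is drawn, and that many copies are inserted sequentially at
    positions drawn from the TE insertion distribution over the genome as
    already modified.  Insertions into genes trigger an insertion-effect draw
    against the host; insertions into TEs permanently deactivate the
    destination — including a still-pending excision candidate, which then
    loses its turn (only active TEs excise).  Copies inserted here are not
    themselves candidates this cycle.

    Returns the per-insertion site outcomes, in order.
    """
    genome = host.genome
    active_starts = genome.starts[genome.kinds == ElementKind.TE_ACTIVE]
    if active_starts.size == 0:
        return []
    mask = rng.random(active_starts.size) < params.te_excision_rate
    pending = [int(s) for s in active_starts[mask]]
    te_dist = params.te_distribution
    outcomes: list[str] = []
    while pending:
        start = pending.pop(0)
        excise_te(genome, start)
        pending = [s - ELEMENT_LENGTH if s > start else s for s in pending]
        n_copies = params.te_progeny.sample(rng)
        for _ in range(n_copies):
            pos = sample_position(te_dist, genome.length, rng)
            out = insert_te(genome, pos)
            outcomes.append(out.site)
            if out.site == "gene":
                apply_fitness_effect(
                    host, params.insertion_effect_table.sample(rng), params, rng)
            elif out.site == "te" and out.dest_start in pending:
                pending.remove(out.dest_start)
            pending = [s + ELEMENT_LENGTH if s >= out.shift_from else s
                       for s in pending]
    return outcomes


def select_survivors(pop: Population, rng: np.random.Generator) -> Population:
    """Step 8: independent survival draws normalized to the carrying capacity.

    Host ``i`` survives with probability ``min(1, w_i / sum(w) * K)``.  With
    no clamping the expected survivor count is exactly ``K``; the realized
    count varies.  If every likelihood is 0 the population goes extinct and
    an empty population is returned.
    """
    w = np.array([h.survival_likelihood for h in pop.hosts], dtype=float)
    total = w.sum()
    if total <= 0.0:
        return Population([], pop.carrying_capacity)
    p = np.minimum(1.0, w / total * pop.carrying_capacity)
    keep = rng.random(w.size) < p
    survivors = [h for h, k in zip(pop.hosts, keep) if k]
    return Population(survivors, pop.carrying_capacity)


@dataclass(frozen=True)
class CycleRecord:
    """Population metrics at the end of one cycle.

    ``mean_density`` is computed per host (active TEs divided by that host's
    genome length) and then averaged over hosts, so it is not in general the
    ratio of ``mean_active_te`` to ``mean_genome_bp``.  Metrics are NaN when
    no hosts remain.
    """

    cycle: int
    hosts_alive: int
    mean_active_te: float
    mean_genome_bp: float
    mean_density: float


def population_record(cycle: int, pop: Population) -> CycleRecord:
    """Summarize the population into a :class:`CycleRecord`."""
    n = len(pop.hosts)
    if n == 0:
        return CycleRecord(cycle, 0, math.nan, math.nan, math.nan)
    active = np.array([h.genome.n_active_te for h in pop.hosts], dtype=float)
    lengths = np.array([h.genome.length for h in pop.hosts], dtype=float)
    return CycleRecord(
        cycle=cycle,
        hosts_alive=n,
        mean_active_te=float(active.mean()),
        mean_genome_bp=float(lengths.mean()),
        mean_density=float((active / lengths).mean()),
    )


def run_cycle(pop: Population, params: ParameterSet, rng: np.random.Generator,
              cycle: int = 0) -> tuple[Population, CycleRecord]:
    """Apply one full cycle (steps 1-8) and summarize the survivors."""
    doubled = clone_population(pop)
    n_parents = len(pop.hosts)
    for clone in doubled.hosts[n_parents:]:
        apply_host_mutation(clone, params, rng)
    for host in doubled.hosts:
        apply_te_death(host, params, rng)
        excision_and_reinsertion(host, params, rng)
    survivors = select_survivors(doubled, rng)
    return survivors, population_record(cycle, survivors)
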