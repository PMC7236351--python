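"""The 2^8 High/Low factorial design, replicate execution and grid summaries.

Eight parameters are varied, each between a High and a Low level chosen to
favour high versus low TE proliferation.  Four are host-side properties —
carrying capacity, mutation-effect magnitude, non-coding background size,
and the coupled (gene count, host mutation rate) "corrected mutation rate"
factor — and four are TE-side properties: insertion bias, TE death rate, TE
excision rate, and the progeny distribution.  Note that the High
(pro-proliferation) level of the death rate is the numerically *smaller*
rate, 0.0005.

Every unique combination is one design point; the full grid has 256 points
and the reference experiment runs each 3 times (768 runs).  Desk-scale work
uses the Low-carrying-capacity half of the grid with a reduced cycle cap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .engine import ExperimentResult, Outcome, run_simulation
from .model_core import PROGENY_HIGH, PROGENY_LOW, ParameterSet

#: Factor order used everywhere: four host properties, then four TE properties.
FACTORS = (
    "carrying_capacity",
    "mutation_effect",
    "nc_bp",
    "corrected_mutation_rate",
    "insertion_bias",
    "te_death_rate",
    "te_excision_rate",
    "te_progeny",
)

#: High/Low values of each varied factor.  corrected_mutation_rate couples
#: (initial_genes, host_mutation_rate): the rate is per host, so ten-fold
#: more genes comes with a ten-fold higher rate.
FACTOR_LEVELS = {
    "carrying_capacity": {"H": 300, "L": 30},
    "mutation_effect": {"H": 0.1, "L": 0.01},
    "nc_bp": {"H": 14_000_000, "L": 1_400_000},
    "corrected_mutation_rate": {"H": (5000, 0.3), "L": (500, 0.03)},
    "insertion_bias": {"H": "H", "L": "L"},
    "te_death_rate": {"H": 0.0005, "L": 0.005},
    "te_excision_rate": {"H": 0.5, "L": 0.1},
    "te_progeny": {"H": PROGENY_HIGH, "L": PROGENY_LOW},
}

DEFAULT_MAX_CYCLES = 500
#: Desk preset: Low-capacity half-grid, one replicate, reduced cycle cap.
#: Persistent runs grow exponentially in TE count (and so in per-cycle cost),
#: so the desk cap is set where a full half-grid completes in minutes on one
#: CPU; borderline slow purges classify as accumulation at this cap.
DESK_MAX_CYCLES = 150


class DesignPoint(NamedTuple):
    """Eight H/L levels, in :data:`FACTORS` order."""

    carrying_capacity: str
    mutation_effect: str
    nc_bp: str
    corrected_mutation_rate: str
    insertion_bias: str
    te_death_rate: str
    te_excision_rate: str
    te_progeny: str

    @property
    def row_label(self) -> str:
        """Host-property label, e.g. ``"L.L.H.L."``."""
        return "".join(f"{v}." for v in self[:4])

    @property
    def col_label(self) -> str:
        """TE-property label, e.g. ``"H.L.H.H."``."""
        return "".join(f"{v}." for v in self[4:])

    @property
    def label(self) -> str:
        return self.row_label + "x" + self.col_label


def params_from_design(design: DesignPoint,
                       max_cycles: int = DEFAULT_MAX_CYCLES,
                       seed: int | None = None,
                       carrying_capacity: int | None = None) -> ParameterSet:
    """Instantiate the parameter set for one design point.

    ``carrying_capacity`` overrides the level-mapped value (used by desk-scale
    presets); all other parameters take their printed High/Low values.
    """
    genes, rate = FACTOR_LEVELS["corrected_mutation_rate"][design.corrected_mutation_rate]
    return ParameterSet(
        carrying_capacity=(FACTOR_LEVELS["carrying_capacity"][design.carrying_capacity]
                           if carrying_capacity is None else carrying_capacity),
        mutation_effect=FACTOR_LEVELS["mutation_effect"][design.mutation_effect],
        nc_bp=FACTOR_LEVELS["nc_bp"][design.nc_bp],
        initial_genes=genes,
        host_mutation_rate=rate,
        insertion_bias=FACTOR_LEVELS["insertion_bias"][design.insertion_bias],
        te_death_rate=FACTOR_LEVELS["te_death_rate"][design.te_death_rate],
        te_excision_rate=FACTOR_LEVELS["te_excision_rate"][design.te_excision_rate],
        te_progeny=FACTOR_LEVELS["te_progeny"][design.te_progeny],
        max_cycles=max_cycles,
        seed=seed,
        design=tuple(design),
    )


def all_designs() -> list[DesignPoint]:
    """The 256 design points, in deterministic row-major (H before L) order."""
    return [DesignPoint(*levels)
            for levels in itertools.product("HL", repeat=len(FACTORS))]


def desk_designs() -> list[DesignPoint]:
    """The Low-carrying-capacity half of the grid (128 points)."""
    return [d for d in all_designs() if d.carrying_capacity == "L"]


def build_grid(max_cycles: int = DEFAULT_MAX_CYCLES) -> list[ParameterSet]:
    """One :class:`ParameterSet` per design point — 256 in total."""
    return [params_from_design(d, max_cycles=max_cycles) for d in all_designs()]


def derive_seed(base_seed: int, design_index: int, replicate: int) -> int:
    """Stable per-run seed: independent of execution order, < 2^31."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(design_index, replicate))
    return int(ss.generate_state(1)[0] % (2 ** 31))


class RunSpec(NamedTuple):
    """One scheduled run of the grid."""

    design_index: int
    design: DesignPoint
    replicate: int
    seed: int


def grid_manifest(replicates: int, base_seed: int,
                  designs: Sequence[DesignPoint] | None = None) -> list[RunSpec]:
    """Schedule ``replicates`` seeded runs per design point.

    The manifest fixes every run's seed up front, so runs can be executed in
    any order (or on separate processes) without changing results.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if designs is None:
        designs = all_designs()
    return [RunSpec(i, d, r, derive_seed(base_seed, i, r))
            for i, d in enumerate(designs)
            for r in range(replicates)]


@dataclass
class RunFailure:
    """A run that raised instead of terminating; kept so it is never dropped."""

    spec: RunSpec
    error: str


@dataclass
class GridSummary:
    """Outcome tallies over a collection of grid runs."""

    n_runs: int
    outcome_counts: dict
    outcome_proportions: dict
    per_design: pd.DataFrame
    accumulation_factors: pd.DataFrame
    failures: list = field(default_factory=list)


def outcome_table(results: Iterable[ExperimentResult]) -> pd.DataFrame:
    """Tidy one-row-per-run table: factor levels, outcome, seed, cycles.

    This is the export consumed by external statistics packages (e.g. a
    binomial GLM of accumulation against the eight factors).
    """
    rows = []
    for i, res in enumerate(results):
        design = res.params.design
        row = {"run_id": i}
        if design is not None:
            row.update(dict(zip(FACTORS, design)))
        row.update({
            "outcome": res.outcome.value,
            "seed": res.seed,
            "cycles_run": res.cycles_run,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_accumulation_factors(
        results: Iterable[ExperimentResult]) -> pd.DataFrame:
    """Count High/Low levels per factor among TE-accumulation runs.

    Rows are levels ("H", "L"), columns the eight factors; each column sums
    to the total number of accumulation runs.  All-zero when no run
    accumulated.
    """
    counts = {f: {"H": 0, "L": 0} for f in FACTORS}
    for res in results:
        if res.outcome is not Outcome.TE_ACCUMULATION:
            continue
        design = res.params.design
        if design is None:
            raise ValueError("result has no design levels attached")
        for factor, level in zip(FACTORS, design):
            counts[factor][level] += 1
    return pd.DataFrame(counts, index=["H", "L"]).loc[["H", "L"], list(FACTORS)]


def summarize_grid(results: Sequence[ExperimentResult],
                   failures: Sequence[RunFailure] = ()) -> GridSummary:
    """Aggregate run outcomes into a :class:`GridSummary`."""
    n = len(results)
    counts = {o.value: 0 for o in Outcome}
    for res in results:
        counts[res.outcome.value] += 1
    proportions = {k: (v / n if n else 0.0) for k, v in counts.items()}
    table = outcome_table(results)
    if not table.empty and "carrying_capacity" in table:
        per_design = (table.groupby(list(FACTORS))["outcome"]
                      .value_counts().unstack(fill_value=0).reset_index())
    else:
        per_design = pd.DataFrame()
    acc = summarize_accumulation_factors(results)
    return GridSummary(n, counts, proportions, per_design, acc, list(failures))


def run_grid(replicates: int, max_cycles: int, base_seed: int,
             designs: Sequence[DesignPoint] | None = None,
             carrying_capacity: int | None = None,
             progress: bool = False) -> tuple[list[ExperimentResult], GridSummary]:
    """Execute the factorial grid.

    Runs every design point ``replicates`` times with seeds derived from
    ``base_seed`` via :func:`derive_seed`.  Individual run failures are
    captured in the summary's ``failures`` list rather than aborting the
    grid.
    """
    manifest = grid_manifest(replicates, base_seed, designs)
    if progress:
        from tqdm import tqdm
        manifest_iter = tqdm(manifest, desc="grid runs")
    else:
        manifest_iter = manifest
    results: list[ExperimentResult] = []
    failures: list[RunFailure] = []
    for spec in manifest_iter:
        params = params_from_design(spec.design, max_cycles=max_cycles,
                                    seed=spec.seed,
                                    carrying_capacity=carrying_capacity)
        try:
            results.append(run_simulation(params))
        except Exception as exc:  # noqa: BLE001 - recorded, never dropped
            failures.append(RunFailure(spec, repr(exc)))
    return results, summarize_grid(results, failures)
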