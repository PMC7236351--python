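"""Trajectory tables, density analysis, plateau detection, file I/O and plots.

The three plotted quantities of a run are the mean number of active TEs per
host, the mean host genome size, and the mean TE density (active TEs per bp,
computed per host and then averaged over hosts — not the ratio of the two
population means, although that variant is available).  The density series
is where the characteristic accumulation signature appears: in persistent
runs the absolute TE abundance keeps rising while the density flattens onto
a plateau, because each new active copy is matched by enough new inactive
copies to hold the ratio steady.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .dynamics import CycleRecord
from .engine import ExperimentResult, Outcome
from .experiments import outcome_table
from .model_core import ElementKind, Genome, ParameterSet

SCHEMA_VERSION = 1

TRAJECTORY_COLUMNS = [
    "run_id", "cycle", "hosts_alive", "mean_active_te",
    "mean_genome_bp", "mean_density",
]


def trajectory_table(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    """Long-format table: one row per (run, cycle), cycles contiguous from 0."""
    rows = []
    for run_id, res in enumerate(results):
        for rec in res.trajectory:
            rows.append((run_id, rec.cycle, rec.hosts_alive, rec.mean_active_te,
                         rec.mean_genome_bp, rec.mean_density))
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def compute_density_series(trajectory: Sequence[CycleRecord],
                           method: str = "per_host") -> np.ndarray:
    """TE density per cycle for one run's trajectory.

    ``per_host`` (default) takes the stored per-host-averaged density;
    ``ratio_of_means`` divides mean abundance by mean genome size instead.
    The series ends at the extinction cycle: trailing records with zero hosts
    are dropped.
    """
    if not trajectory:
        raise ValueError("trajectory is empty")
    recs = [r for r in trajectory if r.hosts_alive > 0]
    if method == "per_host":
        return np.array([r.mean_density for r in recs], dtype=float)
    if method == "ratio_of_means":
        return np.array([r.mean_active_te / r.mean_genome_bp for r in recs],
                        dtype=float)
    raise ValueError(f"unknown method {method!r}")


class PlateauVerdict(NamedTuple):
    """Result of :func:`detect_plateau`.

    ``plateau`` is ``None`` when the series is shorter than the window
    (insufficient data); otherwise True iff the trailing window satisfies the
    flatness criterion.  ``onset`` is the first cycle from which the
    criterion holds through the end of the series.
    """

    plateau: bool | None
    onset: int | None


def detect_plateau(series, window: int = 50,
                   tolerance: float = 0.05) -> PlateauVerdict:
    """Decide whether a density series has levelled off.

    The series is smoothed with a rolling mean of ``window`` cycles; the
    criterion compares each windowed mean with the mean of the window
    immediately before it and asks that their relative change be at most
    ``tolerance``.  Smoothing first makes the verdict about the level of the
    series, not its cycle-to-cycle noise.  The verdict is the criterion at
    the trailing window; the onset is the first cycle from which it holds
    through the end of the series.  A constant series plateaus at cycle 0; a
    steadily growing series never does.  Series shorter than two windows are
    insufficient data.
    """
    s = np.asarray(series, dtype=float)
    if window < 2:
        raise ValueError("window must be >= 2")
    if s.size < 2 * window:
        return PlateauVerdict(None, None)
    cs = np.concatenate([[0.0], np.cumsum(s)])
    means = (cs[window:] - cs[:-window]) / window  # means[i] = mean s[i:i+w]
    prev, cur = means[:-window], means[window:]
    denom = np.maximum(np.abs(prev), np.abs(cur))
    ok = (denom == 0.0) | (np.abs(cur - prev) <= tolerance * denom)
    if not ok[-1]:
        return PlateauVerdict(False, None)
    first = ok.size - 1
    while first > 0 and ok[first - 1]:
        first -= 1
    # onset reported as the start of the earlier window of the first
    # persistently flat comparison
    return PlateauVerdict(True, int(first))


# ---------------------------------------------------------------------------
# File output

OUTCOME_COLORS = {
    Outcome.TE_EXTINCTION.value: "#e8c832",   # yellow
    Outcome.HOST_EXTINCTION.value: "#7b3294",  # purple
    Outcome.TE_ACCUMULATION.value: "#1b9e8f",  # teal
}


def write_outputs(results: Sequence[ExperimentResult], out_dir,
                  plots: bool = False) -> dict:
    """Write a trajectory CSV, per-run JSONs and a grid summary CSV.

    Returns a mapping of artifact names to the paths written.  With
    ``plots=True``, an outcome mosaic (when results carry design levels) and
    trajectory panels are written as SVG.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        traj_path = out / "trajectory.csv"
        trajectory_table(results).to_csv(traj_path, index=False)
        paths["trajectory"] = traj_path
        runs_dir = out / "runs"
        runs_dir.mkdir(exist_ok=True)
        for i, res in enumerate(results):
            run_path = runs_dir / f"run_{i:04d}.json"
            run_path.write_text(json.dumps({
                "schema_version": SCHEMA_VERSION,
                "run_id": i,
                "outcome": res.outcome.value,
                "seed": res.seed,
                "cycles_run": res.cycles_run,
                "density_method": "per_host",
                "params": res.params.to_dict(),
            }, indent=2))
        paths["runs"] = runs_dir
        summary_path = out / "grid_summary.csv"
        outcome_table(results).to_csv(summary_path, index=False)
        paths["summary"] = summary_path
        if plots:
            import matplotlib
            matplotlib.use("Agg")
            if all(r.params.design is not None for r in results):
                fig = plot_outcome_mosaic(results)
                mosaic_path = out / "outcome_mosaic.svg"
                fig.savefig(mosaic_path)
                paths["mosaic"] = mosaic_path
            fig = plot_trajectory_panels(results)
            panels_path = out / "trajectories.svg"
            fig.savefig(panels_path)
            paths["trajectories"] = panels_path
        return paths
    except OSError as exc:
        raise OSError(f"failed writing outputs under {out}: {exc}") from exc


def read_trajectory(path) -> pd.DataFrame:
    """Re-read a trajectory CSV written by :func:`write_outputs`."""
    return pd.read_csv(path)


def read_run_json(path) -> dict:
    """Re-read one per-run JSON; ``params`` is rebuilt as a ParameterSet."""
    d = json.loads(Path(path).read_text())
    d["params"] = ParameterSet.from_dict(d["params"])
    return d


def genome_to_bed(genome: Genome, chrom: str = "chr1") -> str:
    """BED-like text snapshot (chrom, start, end, kind) for inspection."""
    names = {ElementKind.GENE: "gene", ElementKind.TE_ACTIVE: "te_active",
             ElementKind.TE_INACTIVE: "te_inactive"}
    lines = [f"{chrom}\t{e.start}\t{e.end}\t{names[e.kind]}"
             for e in genome.elements]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Plots

def plot_outcome_mosaic(results: Sequence[ExperimentResult]):
    """Fig-style outcome mosaic: rows = host-factor combos, cols = TE combos.

    Each cell is split vertically across that design point's replicates and
    colored by outcome (yellow TE extinction, purple host extinction, teal
    accumulation).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    by_cell: dict[tuple[str, str], list[str]] = {}
    for res in results:
        design = res.params.design
        row = "".join(f"{v}." for v in design[:4])
        col = "".join(f"{v}." for v in design[4:])
        by_cell.setdefault((row, col), []).append(res.outcome.value)
    rows = sorted({rc[0] for rc in by_cell})
    cols = sorted({rc[1] for rc in by_cell})
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(cols)),
                                    max(4, 0.35 * len(rows))))
    for yi, row in enumerate(rows):
        for xi, col in enumerate(cols):
            outcomes = by_cell.get((row, col), [])
            k = max(len(outcomes), 1)
            for j, oc in enumerate(outcomes):
                ax.add_patch(Rectangle((xi + j / k, yi), 1 / k, 1,
                                       facecolor=OUTCOME_COLORS[oc],
                                       edgecolor="white", linewidth=0.3))
    ax.set_xlim(0, len(cols))
    ax.set_ylim(0, len(rows))
    ax.set_xticks(np.arange(len(cols)) + 0.5, cols, rotation=90, fontsize=6)
    ax.set_yticks(np.arange(len(rows)) + 0.5, rows, fontsize=6)
    ax.set_xlabel("TE properties (bias.death.excision.progeny)")
    ax.set_ylabel("host properties (K.effect.ncbp.mutrate)")
    ax.invert_yaxis()
    fig.tight_layout()
    return fig


def plot_trajectory_panels(results: Sequence[ExperimentResult],
                           quantity: str = "mean_active_te",
                           factor: str | None = None):
    """One panel per outcome class, one line per run.

    With ``factor`` given, lines are colored purple (High) or yellow (Low)
    by that factor's level in the run's design.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .experiments import FACTORS

    classes = [o.value for o in Outcome]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for ax, oc in zip(axes, classes):
        ax.set_title(oc.replace("_", " "))
        ax.set_xlabel("cycle")
    axes[0].set_ylabel(quantity)
    for res in results:
        ax = axes[classes.index(res.outcome.value)]
        ys = [getattr(r, quantity) for r in res.trajectory if r.hosts_alive > 0]
        if factor is not None and res.params.design is not None:
            level = dict(zip(FACTORS, res.params.design))[factor]
            color = "#7b3294" if level == "H" else "#e8c832"
            style = "-" if level == "H" else "--"
        else:
            color, style = "#555555", "-"
        ax.plot(range(len(ys)), ys, style, color=color, linewidth=0.8, alpha=0.7)
    fig.tight_layout()
    return fig
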