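"""Scenario experiments: deep vs recent divergence, and the lineage-sorting sweep.

The two named scenarios bind the simulator to the study conditions: eleven
samples (10 ingroup + 1 outgroup), theta = 2.0, and a population join at
either 10 or 0.01 in 4*N0 units (40 or 0.04 N0 generations). Per replicate
the ingroup TMRCA is contrasted with the root height — the MRCA of ingroup
plus outgroup, the only per-replicate random quantity that estimates the
divergence date — and with the basal-node age, which is always strictly
younger than the root.

The sweep varies the join time on a grid in Ne generations (Ne = N0 here)
and records the fraction of replicates in which the ingroup is monophyletic,
locating the completion of lineage sorting.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import analytic_oracles
from .coalescent_core import Genealogy, SimulationConfig, simulate_genealogy
from .errors import InvalidParameterError
from .mutation_overlay import mutate_replicate
from .tree_metrics import basal_node_age, classify_sorting, root_height, tmrca

__all__ = [
    "SCENARIOS",
    "ReplicateSummary",
    "ScenarioSummary",
    "ScenarioResult",
    "SweepRow",
    "SweepResult",
    "run_scenario",
    "lineage_sorting_sweep",
    "compare_node_age_vs_tmrca",
]

#: Named study scenarios: join times in 4*N0 units with theta = 2.0, samples (1, 10).
SCENARIOS: dict[str, SimulationConfig] = {
    "deep": SimulationConfig(pop_sizes=(1, 10), theta=2.0, t_join=10.0, emit_trees=True),
    "recent": SimulationConfig(pop_sizes=(1, 10), theta=2.0, t_join=0.01, emit_trees=True),
}

#: Default replicate count: keeps every documented check fast while holding the
#: binomial standard error of a monophyly fraction below 0.007.
DEFAULT_N_REPS = 5000


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-genealogy record of the quantities the analysis contrasts."""

    replicate_index: int
    tmrca_ingroup: float
    root_height: float
    basal_node_age: float
    monophyletic: bool
    segsites: int

    def __post_init__(self) -> None:
        if self.tmrca_ingroup > self.root_height or self.basal_node_age >= self.root_height:
            raise InvalidParameterError("replicate violates age ordering invariants")


@dataclass
class ScenarioSummary:
    """Aggregate of a scenario run, including histogram data for plotting."""

    ms_command: str
    t_join_4N0: float
    n_reps: int
    seed: int
    monophyly_fraction: float
    tmrca_ingroup_mean: float
    root_height_mean: float
    tmrca_ingroup_quantiles: dict[str, float]
    root_height_quantiles: dict[str, float]
    tmrca_ingroup_hist: dict[str, list]
    root_height_hist: dict[str, list]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class ScenarioResult:
    summary: ScenarioSummary
    replicates: pd.DataFrame
    trees: list[Genealogy] = field(default_factory=list, repr=False)


_QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


def _quantiles(values: np.ndarray) -> dict[str, float]:
    return {f"q{int(q * 1000) / 10:g}": float(v) for q, v in zip(_QUANTILES, np.quantile(values, _QUANTILES))}


def _histogram(values: np.ndarray) -> dict[str, list]:
    # Freedman-Diaconis bin widths; edges recorded so output is reproducible.
    edges = np.histogram_bin_edges(values, bins="fd")
    counts, edges = np.histogram(values, bins=edges)
    return {"bin_edges": [float(e) for e in edges], "counts": [int(c) for c in counts]}


def run_scenario(
    scenario: Union[str, SimulationConfig],
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    out_dir: Optional[Union[str, Path]] = None,
    keep_trees: bool = False,
) -> ScenarioResult:
    """Run a named (``"deep"`` / ``"recent"``) or custom scenario.

    Deterministic given ``seed``. When ``out_dir`` is given, writes
    ``replicates.tsv`` (unit-annotated columns) and ``summary.json``.
    """
    from .io_cli import render_ms_command

    if isinstance(scenario, str):
        if scenario not in SCENARIOS:
            raise InvalidParameterError(
                f"unknown scenario {scenario!r}; valid names: {sorted(SCENARIOS)}"
            )
        base = SCENARIOS[scenario]
    else:
        base = scenario
    config = SimulationConfig(
        pop_sizes=base.pop_sizes,
        theta=base.theta,
        t_join=base.t_join,
        source_pop=base.source_pop,
        dest_pop=base.dest_pop,
        n_reps=n_reps,
        seed=seed,
        emit_trees=base.emit_trees,
    )
    ingroup = config.ingroup_labels
    if len(ingroup) < 2 or config.pop_sizes[0] < 1:
        raise InvalidParameterError("scenarios need >= 2 ingroup samples and >= 1 outgroup sample")

    records: list[ReplicateSummary] = []
    trees: list[Genealogy] = []
    for i in range(n_reps):
        tree = simulate_genealogy(config, i)
        matrix = mutate_replicate(config, tree, i)
        records.append(
            ReplicateSummary(
                replicate_index=i,
                tmrca_ingroup=tmrca(tree, ingroup),
                root_height=root_height(tree),
                basal_node_age=basal_node_age(tree),
                monophyletic=classify_sorting(tree, ingroup).is_monophyletic,
                segsites=matrix.n_sites,
            )
        )
        if keep_trees:
            trees.append(tree)

    frame = pd.DataFrame(
        {
            "replicate_index": [r.replicate_index for r in records],
            "tmrca_ingroup_4N0": [r.tmrca_ingroup for r in records],
            "root_height_4N0": [r.root_height for r in records],
            "basal_node_age_4N0": [r.basal_node_age for r in records],
            "monophyletic": [int(r.monophyletic) for r in records],
            "segsites_count": [r.segsites for r in records],
        }
    )
    t_ing = frame["tmrca_ingroup_4N0"].to_numpy()
    t_root = frame["root_height_4N0"].to_numpy()
    summary = ScenarioSummary(
        ms_command=render_ms_command(config),
        t_join_4N0=config.t_join,
        n_reps=n_reps,
        seed=seed,
        monophyly_fraction=float(frame["monophyletic"].mean()),
        tmrca_ingroup_mean=float(t_ing.mean()),
        root_height_mean=float(t_root.mean()),
        tmrca_ingroup_quantiles=_quantiles(t_ing),
        root_height_quantiles=_quantiles(t_root),
        tmrca_ingroup_hist=_histogram(t_ing),
        root_height_hist=_histogram(t_root),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "replicates.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(summary.to_json() + "\n")
    return ScenarioResult(summary=summary, replicates=frame, trees=trees)


# ---------------------------------------------------------------------------
# Lineage-sorting sweep
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepRow:
    """Monophyly fraction at one divergence time of the sweep grid."""

    t_ne: float  # join time in Ne (= N0) generations
    t_4N0: float
    n_reps: int
    monophyly_fraction: float
    binomial_se: float


@dataclass
class SweepResult:
    rows: list[SweepRow]
    threshold: float
    smallest_t_ne: Optional[float]  # None when the threshold is never reached

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_join_Ne_generations": [r.t_ne for r in self.rows],
                "t_join_4N0": [r.t_4N0 for r in self.rows],
                "n_reps": [r.n_reps for r in self.rows],
                "monophyly_fraction": [r.monophyly_fraction for r in self.rows],
                "binomial_se": [r.binomial_se for r in self.rows],
            }
        )


def lineage_sorting_sweep(
    t_values_ne: Sequence[float],
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    threshold: float = 0.9,
    n_ingroup: int = 10,
) -> SweepResult:
    """Monophyly fraction of the ingroup across a grid of divergence times.

    Grid values are in Ne generations (the unit in which lineage sorting is
    conventionally said to complete after 4-7 Ne generations) and are
    converted internally to the 4*N0 simulation unit (t/4). Each grid point
    runs fresh simulations of ``n_ingroup`` ingroup + 1 outgroup samples.
    Reports the smallest grid time whose fraction meets ``threshold``.
    """
    if len(t_values_ne) == 0:
        raise InvalidParameterError("sweep grid must be non-empty")
    if any(b < a for a, b in zip(t_values_ne, t_values_ne[1:])):
        raise InvalidParameterError("sweep grid must be ascending")
    if not 0.0 <= threshold <= 1.0:
        raise InvalidParameterError(f"threshold must be in [0, 1], got {threshold}")

    rows: list[SweepRow] = []
    smallest: Optional[float] = None
    for grid_index, t_ne in enumerate(t_values_ne):
        config = SimulationConfig(
            pop_sizes=(1, n_ingroup),
            theta=0.0,
            t_join=float(t_ne) / 4.0,
            n_reps=n_reps,
            # Distinct, order-independent seed per grid point.
            seed=(int(seed) * 100003 + grid_index * 7919) % (2**31),
            emit_trees=False,
        )
        ingroup = config.ingroup_labels
        hits = 0
        for i in range(n_reps):
            tree = simulate_genealogy(config, i)
            if classify_sorting(tree, ingroup).is_monophyletic:
                hits += 1
        frac = hits / n_reps
        rows.append(
            SweepRow(
                t_ne=float(t_ne),
                t_4N0=float(t_ne) / 4.0,
                n_reps=n_reps,
                monophyly_fraction=frac,
                binomial_se=math.sqrt(frac * (1.0 - frac) / n_reps),
            )
        )
        if smallest is None and frac >= threshold:
            smallest = float(t_ne)
    return SweepResult(rows=rows, threshold=threshold, smallest_t_ne=smallest)


def compare_node_age_vs_tmrca(trees: Sequence[Genealogy]) -> float:
    """Fraction of trees whose basal-node age is strictly below the root height.

    This is 1.0 on every valid input: the oldest non-root split is by
    construction younger than the root, i.e. node age never equals the TMRCA
    of the full sample.
    """
    if not trees:
        raise InvalidParameterError("at least one tree is required")
    hits = sum(1 for t in trees if basal_node_age(t) < root_height(t))
    return hits / len(trees)


def sweep_oracle_table(t_values_ne: Sequence[float], n_ingroup: int = 10) -> pd.DataFrame:
    """Exact monophyly probabilities on the same grid, for plotting against the sweep."""
    return pd.DataFrame(
        {
            "t_join_Ne_generations": list(t_values_ne),
            "monophyly_probability": [
                analytic_oracles.monophyly_probability(n_ingroup, float(t) / 4.0)
                for t in t_values_ne
            ],
        }
    )
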