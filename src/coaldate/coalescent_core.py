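"""Two-population isolation-model coalescent simulator.

Simulates rooted binary genealogies for samples drawn from two populations of
equal, constant size N0 that merge — looking backward in time — at a single
join time, with no migration before the join. Time is measured throughout in
units of 4*N0 generations (the ms convention), so while a population holds
k >= 2 lineages the waiting time to its next coalescence is exponential with
rate k*(k-1), and a single pair coalesces after mean 0.5 units.

Population 1 is the outgroup (leaves labelled ``Y1..Yn1``) and population 2
the ingroup (``X1..Xn2``), mirroring the ms ``-I`` sample ordering: samples
from population 1 come first in every output.

Reproducibility: every replicate draws from its own counter-based substream
derived from ``(seed, replicate_index, stream)``, so replicate i is identical
regardless of how many replicates are requested, and the genealogy stream is
independent of the mutation stream.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .errors import InvalidConfigError

__all__ = [
    "SimulationConfig",
    "GenealogyNode",
    "Genealogy",
    "simulate_genealogy",
    "simulate_replicates",
    "replicate_rng",
    "TREE_STREAM",
    "MUTATION_STREAM",
]

# Stream indices for the per-replicate RNG substreams.
TREE_STREAM = 0
MUTATION_STREAM = 1


def replicate_rng(seed: int, replicate_index: int, stream: int) -> np.random.Generator:
    """Counter-based substream: independent of n_reps and of the other streams."""
    entropy = (int(seed) % (2**63), int(replicate_index), int(stream))
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-population isolation model.

    Parameters
    ----------
    pop_sizes
        Sample counts ``(n1, n2)`` for population 1 (outgroup) and
        population 2 (ingroup) — the ms ``-I 2 n1 n2`` vector. Either entry
        may be zero (a zero outgroup with ``t_join=0`` gives the standard
        panmictic coalescent of ``n2`` lineages).
    theta
        Population-scaled mutation rate theta = 4*N0*mu per locus (``-t``).
    t_join
        Time of the backward population join in units of 4*N0 generations
        (``-ej``). 0 collapses the model to a single panmictic population.
    source_pop, dest_pop
        1-based indices of the merging populations; at ``t_join`` every
        lineage of ``source_pop`` moves into ``dest_pop``.
    n_reps
        Number of independent replicates.
    seed
        Master RNG seed; see :func:`replicate_rng`.
    emit_trees
        Whether ms-dialect output should include the Newick tree line (``-T``).
    """

    pop_sizes: tuple[int, int] = (1, 10)
    theta: float = 0.0
    t_join: float = 0.0
    source_pop: int = 1
    dest_pop: int = 2
    n_reps: int = 1
    seed: int = 0
    emit_trees: bool = True

    def __post_init__(self) -> None:
        if len(self.pop_sizes) != 2:
            raise InvalidConfigError(
                f"exactly two populations are supported, got {len(self.pop_sizes)}"
            )
        if any((not float(n).is_integer()) or n < 0 for n in self.pop_sizes):
            raise InvalidConfigError(f"pop_sizes must be non-negative integers: {self.pop_sizes}")
        object.__setattr__(self, "pop_sizes", tuple(int(n) for n in self.pop_sizes))
        if self.n_samples < 2:
            raise InvalidConfigError("at least 2 samples are required in total")
        if self.theta < 0:
            raise InvalidConfigError(f"theta must be >= 0, got {self.theta}")
        if self.t_join < 0:
            raise InvalidConfigError(f"t_join must be >= 0, got {self.t_join}")
        for idx in (self.source_pop, self.dest_pop):
            if idx not in (1, 2):
                raise InvalidConfigError(f"population index out of range: {idx}")
        if self.source_pop == self.dest_pop:
            raise InvalidConfigError("source_pop and dest_pop must differ")
        if self.n_reps < 1:
            raise InvalidConfigError(f"n_reps must be positive, got {self.n_reps}")

    @property
    def n_samples(self) -> int:
        return int(sum(self.pop_sizes))

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        """ms sample order: population 1 (Y) first, then population 2 (X)."""
        n1, n2 = self.pop_sizes
        return tuple(f"Y{i + 1}" for i in range(n1)) + tuple(f"X{i + 1}" for i in range(n2))

    @property
    def ingroup_labels(self) -> tuple[str, ...]:
        return tuple(f"X{i + 1}" for i in range(self.pop_sizes[1]))


class GenealogyNode:
    """Node of a rooted binary genealogy with an absolute age in 4*N0 units.

    Leaves carry a label and a population index and sit at age 0; internal
    nodes have exactly two children and are strictly older than both.
    """

    __slots__ = ("label", "age", "children", "population", "_min_leaf")

    def __init__(
        self,
        label: Optional[str] = None,
        age: float = 0.0,
        children: tuple = (),
        population: Optional[int] = None,
    ) -> None:
        self.label = label
        self.age = float(age)
        self.children = tuple(children)
        self.population = population
        # Smallest global sample index among descendant leaves; fixes the
        # deterministic label-sorted ordering used for pair selection.
        self._min_leaf = 0
        if self.children:
            self._min_leaf = min(c._min_leaf for c in self.children)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["GenealogyNode"]:
        stack: list[tuple[GenealogyNode, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaves(self) -> Iterator["GenealogyNode"]:
        for node in self.postorder():
            if node.is_leaf:
                yield node

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"GenealogyNode({self.label!r}, age={self.age})"
        return f"GenealogyNode(age={self.age}, children=2)"


@dataclass
class Genealogy:
    """A simulated (or parsed) rooted binary gene tree.

    ``t_join`` carries the generating model's population-join time for
    downstream truth comparisons; it is ``None`` for trees read from Newick.
    """

    root: GenealogyNode
    leaf_labels: tuple[str, ...] = field(default_factory=tuple)
    t_join: Optional[float] = None

    def __post_init__(self) -> None:
        found = [leaf.label for leaf in self.root.leaves()]
        if not self.leaf_labels:
            self.leaf_labels = tuple(found)
        if len(set(found)) != len(found):
            raise InvalidConfigError("leaf labels must be unique")
        if set(found) != set(self.leaf_labels):
            raise InvalidConfigError("leaf_labels do not match the tree's leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def root_age(self) -> float:
        return self.root.age


def _draw_pair(k: int, rng: np.random.Generator) -> tuple[int, int]:
    """Map a uniform draw over the k*(k-1)/2 index pairs to (i, j), i < j.

    Pairs are ordered (0,1),(0,2),...,(0,k-1),(1,2),... over the label-sorted
    lineage list, making the selection byte-reproducible.
    """
    m = int(rng.integers(k * (k - 1) // 2))
    i = 0
    row = k - 1
    while m >= row:
        m -= row
        i += 1
        row -= 1
    return i, i + 1 + m


def _coalesce(
    lineages: list[GenealogyNode],
    t: float,
    t_end: float,
    rng: np.random.Generator,
) -> float:
    """Coalesce ``lineages`` in place from time ``t`` until ``t_end`` or one remains."""
    while len(lineages) >= 2:
        k = len(lineages)
        wait = rng.exponential(1.0 / (k * (k - 1)))
        if t + wait > t_end:
            return t_end
        t += wait
        i, j = _draw_pair(k, rng)
        a, b = lineages[i], lineages[j]
        parent = GenealogyNode(age=t, children=(a, b))
        del lineages[j]
        del lineages[i]
        bisect.insort(lineages, parent, key=lambda node: node._min_leaf)
    return t


def simulate_genealogy(config: SimulationConfig, replicate_index: int = 0) -> Genealogy:
    """Simulate one genealogy under the two-population isolation model.

    The two populations coalesce independently on ``[0, t_join)``; at
    ``t_join`` the source population's surviving lineages move into the
    destination population, which then coalesces to a single root.
    Deterministic given ``(config.seed, replicate_index)``.
    """
    if replicate_index < 0:
        raise InvalidConfigError(f"replicate_index must be >= 0, got {replicate_index}")
    rng = replicate_rng(config.seed, replicate_index, TREE_STREAM)

    pops: list[list[GenealogyNode]] = [[], []]
    for sample_index, label in enumerate(config.leaf_labels):
        pop = 1 if label.startswith("Y") else 2
        leaf = GenealogyNode(label=label, age=0.0, population=pop)
        leaf._min_leaf = sample_index
        pops[pop - 1].append(leaf)

    # Independent within-population phase, truncated at the join.
    for lineages in pops:
        if len(lineages) >= 2:
            _coalesce(lineages, 0.0, config.t_join, rng)

    merged = pops[config.dest_pop - 1] + pops[config.source_pop - 1]
    merged.sort(key=lambda node: node._min_leaf)
    _coalesce(merged, config.t_join, np.inf, rng)
    (root,) = merged
    return Genealogy(root=root, leaf_labels=config.leaf_labels, t_join=config.t_join)


def simulate_replicates(config: SimulationConfig) -> list[Genealogy]:
    """Run ``config.n_reps`` independent replicates on counter-based substreams."""
    return [simulate_genealogy(config, i) for i in range(config.n_reps)]
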