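"""Infinite-sites mutation overlay and ms-dialect text output.

Mutations are superimposed on a fixed genealogy: the total count is Poisson
with mean theta * L where L is the tree's total branch length in 4*N0 units,
each mutation lands on a branch with probability proportional to branch
length, receives a fresh uniform(0,1) position, and sets the derived allele
(1) in exactly the leaves descending from that branch. Equivalent to
independent per-branch Poisson processes. Ancestral state is 0; there is no
back-mutation and no recombination, so every segregating site's derived set
is one branch's descendant leaf set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, TextIO

import numpy as np

from .coalescent_core import (
    MUTATION_STREAM,
    Genealogy,
    GenealogyNode,
    SimulationConfig,
    replicate_rng,
)
from .errors import InvalidParameterError, MsCommandError

__all__ = [
    "HaplotypeMatrix",
    "total_branch_length",
    "drop_mutations",
    "mutate_replicate",
    "write_ms_output",
    "read_ms_output",
]


@dataclass
class HaplotypeMatrix:
    """Binary leaves x segregating-sites matrix under the infinite-sites model.

    ``positions`` are decorative uniform marks in (0,1), strictly increasing;
    matrix entries are 0 (ancestral) / 1 (derived). Every column is variant:
    at least one 0 and one 1.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.labels), len(self.positions)):
            raise InvalidParameterError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.labels)} labels x {len(self.positions)} positions"
            )
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise InvalidParameterError("positions must be strictly increasing")
        if self.n_sites:
            col_sums = self.matrix.sum(axis=0)
            if np.any(col_sums == 0) or np.any(col_sums == self.matrix.shape[0]):
                raise InvalidParameterError("matrix contains an invariant column")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def row(self, label: str) -> np.ndarray:
        return self.matrix[self.labels.index(label)]


def _branches(tree: Genealogy) -> list[tuple[GenealogyNode, float]]:
    """(node, parent_age - node_age) for every non-root node, in postorder."""
    out: list[tuple[GenealogyNode, float]] = []

    def walk(node: GenealogyNode, parent_age: Optional[float]) -> None:
        for child in node.children:
            walk(child, node.age)
        if parent_age is not None:
            out.append((node, parent_age - node.age))

    walk(tree.root, None)
    return out


def total_branch_length(tree: Genealogy) -> float:
    """Sum of all branch lengths, in 4*N0 units."""
    return float(sum(length for _, length in _branches(tree)))


def drop_mutations(
    tree: Genealogy, theta: float, rng: np.random.Generator
) -> HaplotypeMatrix:
    """Overlay Poisson(theta * total length) infinite-sites mutations on ``tree``."""
    if theta < 0:
        raise InvalidParameterError(f"theta must be >= 0, got {theta}")
    branches = _branches(tree)
    lengths = np.array([length for _, length in branches])
    total = float(lengths.sum())
    label_index = {label: i for i, label in enumerate(tree.leaf_labels)}

    n_mut = 0 if (theta == 0.0 or total == 0.0) else int(rng.poisson(theta * total))
    if n_mut == 0:
        return HaplotypeMatrix(
            labels=tuple(tree.leaf_labels),
            positions=np.empty(0),
            matrix=np.empty((tree.n_leaves, 0), dtype=np.int8),
        )

    cum = np.cumsum(lengths)
    branch_idx = np.searchsorted(cum, rng.random(n_mut) * total, side="right")
    positions = rng.random(n_mut)
    order = np.argsort(positions, kind="stable")

    matrix = np.zeros((tree.n_leaves, n_mut), dtype=np.int8)
    for col, m in enumerate(order):
        node, _ = branches[int(branch_idx[m])]
        for leaf in node.leaves():
            matrix[label_index[leaf.label], col] = 1
    return HaplotypeMatrix(
        labels=tuple(tree.leaf_labels), positions=positions[order], matrix=matrix
    )


def mutate_replicate(
    config: SimulationConfig, tree: Genealogy, replicate_index: int
) -> HaplotypeMatrix:
    """Overlay mutations using the replicate's dedicated mutation substream.

    The mutation stream is separate from the genealogy stream, so the
    simulated trees are unchanged by toggling theta.
    """
    rng = replicate_rng(config.seed, replicate_index, MUTATION_STREAM)
    return drop_mutations(tree, config.theta, rng)


# ---------------------------------------------------------------------------
# ms-dialect text output
# ---------------------------------------------------------------------------


def write_ms_output(
    config: SimulationConfig,
    trees: Sequence[Genealogy],
    matrices: Sequence[HaplotypeMatrix],
    sink: TextIO,
) -> None:
    """Emit replicates in the ms output dialect.

    Layout: command echo, seed line, then per replicate a ``//`` separator,
    the Newick tree (when ``emit_trees``), ``segsites: S`` and, for S > 0, a
    4-decimal ``positions:`` line followed by one 0/1 row per sample in
    sample-label order.
    """
    from .io_cli import render_ms_command
    from .tree_metrics import write_newick

    if len(trees) != len(matrices):
        raise InvalidParameterError("trees and matrices must have matching lengths")
    sink.write(render_ms_command(config) + "\n")
    sink.write(f"{int(config.seed) % (2**63)}\n\n")
    for tree, mat in zip(trees, matrices):
        sink.write("//\n")
        if config.emit_trees:
            sink.write(write_newick(tree) + "\n")
        sink.write(f"segsites: {mat.n_sites}\n")
        if mat.n_sites:
            sink.write("positions: " + " ".join(f"{p:.4f}" for p in mat.positions) + "\n")
            for label in config.leaf_labels:
                sink.write("".join(str(int(v)) for v in mat.row(label)) + "\n")
        sink.write("\n")


def read_ms_output(text: str) -> tuple[SimulationConfig, list[tuple[Optional[str], HaplotypeMatrix]]]:
    """Parse the package's own ms-dialect output back into matrices.

    Returns the echoed configuration and, per replicate, the Newick line (or
    ``None``) and the haplotype matrix. Positions survive only to the printed
    4 decimals; the 0/1 matrix round-trips bit-exactly.
    """
    from .io_cli import parse_ms_command

    lines = text.splitlines()
    if not lines:
        raise MsCommandError("empty ms output")
    config = parse_ms_command(lines[0])
    labels = config.leaf_labels

    replicates: list[tuple[Optional[str], HaplotypeMatrix]] = []
    i = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        newick = None
        if i < len(lines) and lines[i].startswith("("):
            newick = lines[i].strip()
            i += 1
        if i >= len(lines) or not lines[i].startswith("segsites:"):
            raise MsCommandError(f"expected 'segsites:' at line {i + 1}")
        n_sites = int(lines[i].split(":", 1)[1])
        i += 1
        if n_sites == 0:
            mat = HaplotypeMatrix(
                labels=labels,
                positions=np.empty(0),
                matrix=np.empty((len(labels), 0), dtype=np.int8),
            )
        else:
            if not lines[i].startswith("positions:"):
                raise MsCommandError(f"expected 'positions:' at line {i + 1}")
            positions = np.array([float(x) for x in lines[i].split(":", 1)[1].split()])
            # 4-decimal printing can tie adjacent positions; nudge to keep them strict
            for k in range(1, positions.size):
                if positions[k] <= positions[k - 1]:
                    positions[k] = positions[k - 1] + 1e-9
            i += 1
            rows = []
            for _ in labels:
                rows.append([int(c) for c in lines[i].strip()])
                i += 1
            mat = HaplotypeMatrix(labels=labels, positions=positions, matrix=np.array(rows))
        replicates.append((newick, mat))
    return config, replicates
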