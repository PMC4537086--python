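"""Synthetic test fixtures: alignments with planted recombinant tracts, worked trees.

The alignment generator emulates the structure of a whole-genome alignment
after recombination: a shared reference sequence, independent per-column
background substitutions, designated tracts in which one taxon diverges at an
elevated rate (the "imported" recombinant segments), and sprinkled missing
data. Columns are independent — this is deliberately *not* a sequence
evolution simulator; it exists to exercise masking and SNP-culling logic with
a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .coalescent_core import Genealogy, GenealogyNode
from .errors import InvalidParameterError
from .recomb_mask import AlignmentMatrix, RecombinationInterval

__all__ = ["FixtureSpec", "PlantedTract", "generate_alignment", "write_fixture", "worked_trees"]

_ALPHABET = np.array(list("ACGT"), dtype="U1")


@dataclass(frozen=True)
class PlantedTract:
    """A recombinant segment: ``taxon`` diverges at ``rate`` on [begin, end] (1-based)."""

    taxon: str
    begin: int
    end: int
    rate: float = 0.5


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic alignment.

    Defaults give a small alignment (6 taxa x 2 kb) with a background
    substitution probability of 1% per column per taxon — enough variant
    columns to cull — and two planted tracts of strongly elevated divergence.
    """

    n_taxa: int = 6
    length: int = 2000
    background_rate: float = 0.01
    tracts: tuple[PlantedTract, ...] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.length < 1:
            raise InvalidParameterError("need >= 2 taxa and >= 1 column")
        if self.tracts is None:
            # Two tracts scaled to the alignment: 15-25% and 60-67.5% of its length.
            first = "t2"
            second = self.labels[min(4, self.n_taxa - 1)]
            object.__setattr__(
                self,
                "tracts",
                (
                    PlantedTract(first, int(0.15 * self.length) + 1, max(int(0.25 * self.length), int(0.15 * self.length) + 1), 0.5),
                    PlantedTract(second, int(0.6 * self.length) + 1, max(int(0.675 * self.length), int(0.6 * self.length) + 1), 0.5),
                ),
            )
        object.__setattr__(self, "tracts", tuple(self.tracts))
        for p in (self.background_rate, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"probability out of [0, 1]: {p}")
        labels = self.labels
        for tract in self.tracts:
            if not 0.0 <= tract.rate <= 1.0:
                raise InvalidParameterError(f"tract rate out of [0, 1]: {tract.rate}")
            if tract.taxon not in labels:
                raise InvalidParameterError(f"tract taxon {tract.taxon!r} not among {labels}")
            if not (1 <= tract.begin <= tract.end <= self.length):
                raise InvalidParameterError(
                    f"tract [{tract.begin}, {tract.end}] outside alignment of length {self.length}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"t{i + 1}" for i in range(self.n_taxa))


def generate_alignment(
    spec: FixtureSpec,
) -> tuple[AlignmentMatrix, list[RecombinationInterval]]:
    """Generate the alignment and return it with its ground-truth intervals.

    Taxon ``t1`` is the unmutated reference; every other taxon substitutes
    each column independently at the background rate, tract columns in the
    designated taxon at the tract's elevated rate, and missing characters (N)
    are sprinkled at the missing-data rate. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(spec.seed) % (2**63), 2)))
    reference = rng.choice(_ALPHABET, size=spec.length)
    data = np.tile(reference, (spec.n_taxa, 1)).astype("U1")

    def substitute(row: int, where: np.ndarray) -> None:
        # Replace with a uniformly chosen *different* base.
        idx = np.flatnonzero(where)
        if idx.size == 0:
            return
        current = data[row, idx]
        shift = rng.integers(1, 4, size=idx.size)
        base_idx = np.searchsorted(_ALPHABET, np.char.upper(current))
        data[row, idx] = _ALPHABET[(base_idx + shift) % 4]

    for row in range(1, spec.n_taxa):
        substitute(row, rng.random(spec.length) < spec.background_rate)
    for tract in spec.tracts:
        row = spec.labels.index(tract.taxon)
        where = np.zeros(spec.length, dtype=bool)
        where[tract.begin - 1 : tract.end] = rng.random(tract.end - tract.begin + 1) < tract.rate
        substitute(row, where)
    if spec.missing_rate > 0:
        miss = rng.random(data.shape) < spec.missing_rate
        data[miss] = "N"

    truth = [
        RecombinationInterval(taxon=t.taxon, begin=t.begin, end=t.end) for t in spec.tracts
    ]
    return AlignmentMatrix(labels=spec.labels, data=data), truth


def write_fixture(
    spec: FixtureSpec, out_dir: Union[str, Path]
) -> tuple[Path, Path]:
    """Write the fixture as FASTA plus a truth-interval TSV; returns both paths."""
    aln, truth = generate_alignment(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "alignment.fasta"
    with open(fasta, "w") as fh:
        for label in aln.labels:
            fh.write(f">{label}\n{aln.sequence(label)}\n")
    tsv = out / "intervals.tsv"
    with open(tsv, "w") as fh:
        fh.write("Node\tBeg\tEnd\n")
        for iv in truth:
            fh.write(f"{iv.taxon}\t{iv.begin}\t{iv.end}\n")
    return fasta, tsv


def _node(age: float, left: GenealogyNode, right: GenealogyNode) -> GenealogyNode:
    return GenealogyNode(age=age, children=(left, right))


def _leaf(label: str) -> GenealogyNode:
    return GenealogyNode(label=label, age=0.0)


def worked_trees() -> dict[str, Genealogy]:
    """Small hand-built genealogies with exact ages, used throughout the tests.

    - ``cherry3``: ((A:1,B:1):1,C:2)
    - ``ladder4``: (((A:1,B:1):1,C:2):1,D:3)
    - ``para3``: ((X1:1,Y1:1):1,X2:2) — X paraphyletic
    - ``mono3``: ((X1:1,X2:1):9,Y1:10) — X monophyletic, deep split
    """
    cherry3 = Genealogy(root=_node(2.0, _node(1.0, _leaf("A"), _leaf("B")), _leaf("C")))
    ladder4 = Genealogy(
        root=_node(
            3.0,
            _node(2.0, _node(1.0, _leaf("A"), _leaf("B")), _leaf("C")),
            _leaf("D"),
        )
    )
    para3 = Genealogy(root=_node(2.0, _node(1.0, _leaf("X1"), _leaf("Y1")), _leaf("X2")))
    mono3 = Genealogy(root=_node(10.0, _node(1.0, _leaf("X1"), _leaf("X2")), _leaf("Y1")))
    return {"cherry3": cherry3, "ladder4": ladder4, "para3": para3, "mono3": mono3}
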