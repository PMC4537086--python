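"""Recombination masking and SNP-matrix extraction from a whole-genome alignment.

Post-processing step between recombination detection and molecular dating:
alignment positions attributed to homologous recombination are removed (they
bias branch lengths and hence date estimates), positions containing ambiguous
or missing characters are excluded, and the remainder is culled to variant
positions, yielding the SNP matrix used for clock analyses.

Interval input follows the ClonalFrameML ``importation_status`` dialect: a
TSV with header ``Node  Beg  End``, 1-based inclusive alignment coordinates.
By default an interval masks the whole alignment column regardless of which
taxon it names; per-taxon masking (setting only that taxon's characters to N)
is available as an option. Intervals naming internal nodes of a supplied tree
are expanded to the node's descendant taxa; without a tree such intervals
fall back, with a warning, to whole-column masking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, IntervalError, InvalidParameterError

__all__ = [
    "AlignmentMatrix",
    "RecombinationInterval",
    "MaskReport",
    "load_alignment",
    "load_intervals",
    "mask_and_cull",
    "write_snp_matrix",
]

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"), dtype="U1")


@dataclass
class AlignmentMatrix:
    """Multi-taxon character matrix (taxa x columns) over nucleotide characters."""

    labels: tuple[str, ...]
    data: np.ndarray  # dtype '<U1', shape (n_taxa, length)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.data = np.asarray(self.data, dtype="U1")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise AlignmentError("data must be a 2-D taxa x columns character array")
        if len(set(self.labels)) != len(self.labels):
            raise AlignmentError("taxon labels must be unique")
        if self.data.shape[0] == 0:
            raise AlignmentError("alignment has no taxa")

    @classmethod
    def from_sequences(cls, labels: Sequence[str], sequences: Sequence[str]) -> "AlignmentMatrix":
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            bad = next(l for l, s in zip(labels, sequences) if len(s) != len(sequences[0]))
            raise AlignmentError(f"alignment is ragged: record {bad!r} has a different length")
        return cls(labels=tuple(labels), data=np.array([list(s) for s in sequences], dtype="U1"))

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def sequence(self, label: str) -> str:
        return "".join(self.data[self.labels.index(label)])


@dataclass(frozen=True)
class RecombinationInterval:
    """A masked tract: taxon (or internal-node) label with 1-based inclusive bounds."""

    taxon: str
    begin: int
    end: int
    row: Optional[int] = None  # source TSV row, for error messages

    def __post_init__(self) -> None:
        if self.begin < 1 or self.end < self.begin:
            where = f" (interval file row {self.row})" if self.row is not None else ""
            raise IntervalError(
                f"invalid interval {self.taxon} [{self.begin}, {self.end}]{where}"
            )


@dataclass
class MaskReport:
    """Exact column accounting of one mask-and-cull pass.

    Every original column lands in exactly one of: kept, masked-only,
    incomplete-only, invariant-only, or multiply-flagged (two or more of the
    removal reasons apply), so the five counts sum to the alignment length.
    """

    total_columns: int
    kept: int
    masked_only: int
    incomplete_only: int
    invariant_only: int
    multiply_flagged: int
    n_masked: int
    n_incomplete: int
    n_invariant: int
    recombination_fraction: float
    kept_coordinates: list[int] = field(default_factory=list)  # 1-based original positions

    def reconciles(self) -> bool:
        return (
            self.kept
            + self.masked_only
            + self.incomplete_only
            + self.invariant_only
            + self.multiply_flagged
            == self.total_columns
        )


def load_alignment(path: Union[str, Path]) -> AlignmentMatrix:
    """Read a multi-FASTA alignment; all records must have equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    length = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != length:
            raise AlignmentError(
                f"alignment is ragged: record {rec.id!r} has length {len(rec.seq)}, expected {length}"
            )
    return AlignmentMatrix.from_sequences(
        [rec.id for rec in records], [str(rec.seq) for rec in records]
    )


def load_intervals(path: Union[str, Path]) -> list[RecombinationInterval]:
    """Read a ClonalFrameML-style importation TSV (header ``Node  Beg  End``)."""
    frame = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in frame.columns}
    missing = [name for name in ("node", "beg", "end") if name not in cols]
    if missing:
        raise IntervalError(
            f"interval file must have columns Node, Beg, End; missing {missing} in {list(frame.columns)}"
        )
    out = []
    for i, rec in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, rec))
        out.append(
            RecombinationInterval(
                taxon=str(row[cols["node"]]),
                begin=int(row[cols["beg"]]),
                end=int(row[cols["end"]]),
                row=i + 2,  # 1-based file line, counting the header
            )
        )
    return out


def _expand_node_taxa(tree_newick: str, node_label: str) -> Optional[list[str]]:
    """Descendant taxa of a labelled internal node, or None if the label is absent."""
    import dendropy

    tree = dendropy.Tree.get(data=tree_newick, schema="newick", preserve_underscores=True)
    for node in tree.preorder_node_iter():
        if node.label == node_label or (node.taxon and node.taxon.label == node_label):
            return [leaf.taxon.label for leaf in node.leaf_iter()]
    return None


def mask_and_cull(
    aln: AlignmentMatrix,
    intervals: Iterable[RecombinationInterval],
    drop_incomplete: bool = True,
    per_taxon: bool = False,
    on_unknown_taxon: str = "warn",
    tree_newick: Optional[str] = None,
) -> tuple[AlignmentMatrix, MaskReport]:
    """Remove recombinant and incomplete positions, then cull to variant columns.

    Steps, in order: (1) every column intersecting any interval is removed
    entirely (or, with ``per_taxon=True``, only the named taxon's characters
    are set to N); (2) with ``drop_incomplete``, every column containing a
    character outside A/C/G/T (case-insensitive; gaps and IUPAC ambiguity
    codes count as missing) in any row is removed; (3) columns with at least
    two distinct A/C/G/T states among the remainder are kept, in original
    order. The report reconciles all columns exactly and records the 1-based
    original coordinates of the retained SNP columns.
    """
    if aln.length == 0:
        raise AlignmentError("alignment has zero columns")
    if on_unknown_taxon not in ("warn", "error"):
        raise InvalidParameterError("on_unknown_taxon must be 'warn' or 'error'")

    work = aln.data.copy()
    upper = np.char.upper(work)
    length = aln.length
    label_index = {label: i for i, label in enumerate(aln.labels)}

    masked = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.end > length:
            where = f" (interval file row {iv.row})" if iv.row is not None else ""
            raise IntervalError(
                f"interval {iv.taxon} [{iv.begin}, {iv.end}] exceeds alignment length {length}{where}"
            )
        targets: Optional[list[str]] = None
        if iv.taxon in label_index:
            targets = [iv.taxon]
        else:
            if tree_newick is not None:
                targets = _expand_node_taxa(tree_newick, iv.taxon)
            if targets is None:
                msg = (
                    f"interval taxon {iv.taxon!r} not in the alignment; "
                    "masking the whole column range"
                )
                if on_unknown_taxon == "error":
                    raise IntervalError(msg)
                warnings.warn(msg, stacklevel=2)
                logger.warning(msg)
                masked[iv.begin - 1 : iv.end] = True
                continue
        if per_taxon:
            for taxon in targets:
                upper[label_index[taxon], iv.begin - 1 : iv.end] = "N"
        else:
            masked[iv.begin - 1 : iv.end] = True

    is_base = np.isin(upper, _BASES)
    incomplete = ~is_base.all(axis=0)
    # Variant status judged on A/C/G/T characters only.
    present = np.stack([((upper == b) & is_base).any(axis=0) for b in _BASES])
    variant = present.sum(axis=0) >= 2
    invariant = ~variant

    if drop_incomplete:
        keep = ~masked & ~incomplete & variant
        flags = masked.astype(int) + incomplete.astype(int) + invariant.astype(int)
    else:
        keep = ~masked & variant
        flags = masked.astype(int) + invariant.astype(int)
        incomplete = np.zeros(length, dtype=bool)

    def only(flag: np.ndarray) -> int:
        return int((flag & (flags == 1)).sum())

    report = MaskReport(
        total_columns=length,
        kept=int(keep.sum()),
        masked_only=only(masked),
        incomplete_only=only(incomplete),
        invariant_only=only(invariant),
        multiply_flagged=int((flags >= 2).sum()),
        n_masked=int(masked.sum()),
        n_incomplete=int(incomplete.sum()),
        n_invariant=int(invariant.sum()),
        recombination_fraction=float(masked.sum()) / length,
        kept_coordinates=[int(i) + 1 for i in np.flatnonzero(keep)],
    )
    snp = AlignmentMatrix(labels=aln.labels, data=work[:, keep])
    return snp, report


def write_snp_matrix(
    matrix: AlignmentMatrix,
    path: Union[str, Path],
    fmt: str = "fasta",
    coordinates: Optional[Sequence[int]] = None,
) -> Path:
    """Write the SNP matrix as FASTA, NEXUS or TSV, plus a coordinate sidecar.

    When ``coordinates`` (1-based original positions, e.g.
    ``MaskReport.kept_coordinates``) is given, a ``<path>.coords.tsv`` sidecar
    maps each SNP column back to its original alignment position. A
    zero-column matrix is written as an empty-sequence stub with a warning.
    """
    path = Path(path)
    if fmt not in ("fasta", "nexus", "tsv"):
        raise InvalidParameterError(f"unknown format {fmt!r}; options: fasta, nexus, tsv")
    if matrix.length == 0:
        warnings.warn("writing a zero-column SNP matrix stub", stacklevel=2)

    with open(path, "w") as fh:
        if fmt == "fasta":
            for label in matrix.labels:
                fh.write(f">{label}\n{matrix.sequence(label)}\n")
        elif fmt == "nexus":
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.length};\n")
            fh.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
            for label in matrix.labels:
                fh.write(f"    {label}  {matrix.sequence(label)}\n")
            fh.write("  ;\nEND;\n")
        else:
            fh.write("taxon\t" + "\t".join(str(i + 1) for i in range(matrix.length)) + "\n")
            for label in matrix.labels:
                fh.write(label + "\t" + "\t".join(matrix.sequence(label)) + "\n")

    if coordinates is not None:
        sidecar = path.with_name(path.name + ".coords.tsv")
        with open(sidecar, "w") as fh:
            fh.write("snp_column\toriginal_position_1based\n")
            for i, pos in enumerate(coordinates):
                fh.write(f"{i + 1}\t{pos}\n")
    return path
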