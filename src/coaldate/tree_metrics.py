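"""Tree analytics: TMRCA, root height, basal-node age, monophyly; Newick I/O.

These are the quantities whose conflation motivates the package: the TMRCA of
a sampled taxon (the age at which its alleles coalesce) is a different random
variable from the taxon's divergence date from a sister lineage, and both
differ from the age of the "most basal node" of the taxon's subtree — the
oldest non-root internal node, which is always strictly younger than the root.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import dendropy
import pandas as pd

from .coalescent_core import Genealogy, GenealogyNode
from .errors import (
    InvalidQueryError,
    MissingTaxonError,
    NewickParseError,
    UndefinedQuantityError,
)

__all__ = [
    "CladeQuery",
    "Sorting",
    "SortingStatus",
    "tmrca",
    "root_height",
    "basal_node_age",
    "classify_sorting",
    "write_newick",
    "parse_newick",
    "metrics_dataframe",
]

#: Tolerance (in branch-length units) within which parsed trees must be ultrametric.
ULTRAMETRIC_TOL = 1e-6


@dataclass(frozen=True)
class CladeQuery:
    """A non-empty set of leaf labels whose MRCA is of interest."""

    leaf_label_set: frozenset[str]

    def __init__(self, labels: Iterable[str]) -> None:
        object.__setattr__(self, "leaf_label_set", frozenset(labels))
        if not self.leaf_label_set:
            raise InvalidQueryError("clade query must name at least one leaf")


class Sorting(enum.Enum):
    MONOPHYLETIC = "monophyletic"
    NON_MONOPHYLETIC = "non_monophyletic"


@dataclass(frozen=True)
class SortingStatus:
    """Lineage-sorting verdict for an ingroup query.

    ``n_intruders`` counts leaves under the ingroup's MRCA that are not part
    of the ingroup; the ingroup is monophyletic iff that count is zero.
    """

    status: Sorting
    n_query: int
    n_intruders: int

    def __post_init__(self) -> None:
        expected = Sorting.MONOPHYLETIC if self.n_intruders == 0 else Sorting.NON_MONOPHYLETIC
        if self.status is not expected:
            raise InvalidQueryError("status inconsistent with intruder count")

    @property
    def is_monophyletic(self) -> bool:
        return self.status is Sorting.MONOPHYLETIC


def _as_query(query: Union[CladeQuery, Iterable[str]]) -> frozenset[str]:
    if isinstance(query, CladeQuery):
        return query.leaf_label_set
    return CladeQuery(query).leaf_label_set


def _mrca(tree: Genealogy, labels: frozenset[str]) -> GenealogyNode:
    """Lowest node whose descendant leaf set contains ``labels``."""
    present = set(tree.leaf_labels)
    for label in sorted(labels):
        if label not in present:
            raise MissingTaxonError(f"leaf label not in tree: {label!r}")
    node = tree.root
    while True:
        step = None
        for child in node.children:
            below = {leaf.label for leaf in child.leaves()}
            if labels <= below:
                step = child
                break
        if step is None:
            return node
        node = step


def tmrca(tree: Genealogy, query: Union[CladeQuery, Iterable[str]]) -> float:
    """Age of the MRCA of the queried leaves, in 4*N0 units (0 for singletons)."""
    return _mrca(tree, _as_query(query)).age


def root_height(tree: Genealogy) -> float:
    """Root age — the TMRCA of the full sample, an upper bound on every clade TMRCA."""
    return tree.root.age


def basal_node_age(tree: Genealogy) -> float:
    """Age of the oldest non-root internal node.

    This formalizes the "most basal node" of a sampled clade: the deepest
    split *within* the sample, which is always strictly younger than the root
    (the sample's TMRCA). Undefined on two-leaf trees, whose only internal
    node is the root itself.
    """
    ages = [n.age for n in tree.root.postorder() if not n.is_leaf and n is not tree.root]
    if not ages:
        raise UndefinedQuantityError("basal node age is undefined for a two-leaf tree")
    return max(ages)


def classify_sorting(tree: Genealogy, ingroup: Union[CladeQuery, Iterable[str]]) -> SortingStatus:
    """Monophyly status of ``ingroup``: MONOPHYLETIC iff its MRCA contains no outsiders.

    With a single non-ingroup leaf this coincides with reciprocal monophyly.
    A singleton ingroup is vacuously monophyletic. Querying every leaf is
    rejected: monophyly of the full sample is not informative.
    """
    labels = _as_query(ingroup)
    if labels == set(tree.leaf_labels):
        raise InvalidQueryError("ingroup must be a proper subset of the leaves")
    node = _mrca(tree, labels)
    below = {leaf.label for leaf in node.leaves()}
    n_intruders = len(below - labels)
    status = Sorting.MONOPHYLETIC if n_intruders == 0 else Sorting.NON_MONOPHYLETIC
    return SortingStatus(status=status, n_query=len(labels), n_intruders=n_intruders)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def write_newick(tree: Union[Genealogy, GenealogyNode], precision: int = 9) -> str:
    """Serialize to rooted Newick with branch lengths (no root branch length)."""
    root = tree.root if isinstance(tree, Genealogy) else tree

    def render(node: GenealogyNode, parent_age: Optional[float]) -> str:
        if node.is_leaf:
            body = node.label or ""
        else:
            body = "(" + ",".join(render(c, node.age) for c in node.children) + ")"
        if parent_age is None:
            return body
        return f"{body}:{parent_age - node.age:.{precision}f}"

    return render(root, None) + ";"


def parse_newick(text: str) -> Genealogy:
    """Parse a rooted binary ultrametric Newick string into a :class:`Genealogy`.

    Node ages are recovered from root-to-tip distances; input whose leaves are
    not all equidistant from the root (within ``ULTRAMETRIC_TOL``) is rejected,
    as are non-binary trees and trees with missing branch lengths. Internal
    labels are ignored.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            terminating_semicolon_required=False,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        pos = ""
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        if line is not None:
            pos = f" (line {line}, column {col})"
        raise NewickParseError(f"malformed Newick{pos}: {exc}") from exc

    seed = dtree.seed_node
    depths: dict = {seed: 0.0}
    for nd in dtree.preorder_node_iter():
        if nd is seed:
            continue
        if nd.edge.length is None:
            raise NewickParseError("branch lengths are required on all non-root nodes")
        depths[nd] = depths[nd.parent_node] + float(nd.edge.length)

    leaf_depths = [depths[nd] for nd in dtree.leaf_node_iter()]
    height = max(leaf_depths)
    if max(leaf_depths) - min(leaf_depths) > ULTRAMETRIC_TOL:
        raise NewickParseError(
            f"tree is not ultrametric within {ULTRAMETRIC_TOL}: "
            f"leaf depths span [{min(leaf_depths):.6g}, {max(leaf_depths):.6g}]"
        )

    def convert(nd) -> GenealogyNode:
        children = nd.child_nodes()
        if not children:
            if nd.taxon is None or not nd.taxon.label:
                raise NewickParseError("every leaf must be labelled")
            return GenealogyNode(label=str(nd.taxon.label), age=0.0)
        if len(children) != 2:
            raise NewickParseError(
                f"tree must be strictly binary; found a node with {len(children)} children"
            )
        node = GenealogyNode(age=height - depths[nd], children=tuple(convert(c) for c in children))
        return node

    return Genealogy(root=convert(seed), t_join=None)


def metrics_dataframe(
    trees: Iterable[Genealogy],
    ingroup: Union[CladeQuery, Iterable[str]],
) -> pd.DataFrame:
    """Per-tree metric table (one row per genealogy), units annotated in headers."""
    rows = []
    labels = _as_query(ingroup)
    for i, tree in enumerate(trees):
        status = classify_sorting(tree, labels)
        rows.append(
            {
                "tree_index": i,
                "tmrca_ingroup_4N0": tmrca(tree, labels),
                "root_height_4N0": root_height(tree),
                "basal_node_age_4N0": basal_node_age(tree) if tree.n_leaves >= 3 else float("nan"),
                "sorting_status": status.status.value,
                "n_intruders": status.n_intruders,
            }
        )
    return pd.DataFrame(rows)
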