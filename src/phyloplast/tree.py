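"""Rooted phylogenies for comparative analysis.

This module owns the tree-side bookkeeping of the pipeline: Newick
ingestion (delegated to :mod:`dendropy`), Grafen-style ultrametric branch
lengths, the Brownian-motion covariance matrix among tips, soft-polytomy
counting for degrees-of-freedom corrections, and attachment of replicate
observations as near-zero-length tip clusters.

Trees are held in a deliberately small structure (:class:`Node` /
:class:`PhyloTree`) so that every transformation here is explicit and
auditable; parsing and serialisation of the Newick dialect are the only
parts backed by an external library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Optional, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "PhyloTree",
    "CovMatrix",
    "PolytomyReport",
    "TreeError",
    "NewickParseError",
    "CovarianceError",
    "parse_newick",
    "count_soft_polytomies",
    "grafen_branch_lengths",
    "phylo_covariance",
    "attach_replicates",
    "prune_to_tips",
]


class TreeError(ValueError):
    """Invalid tree structure or operation."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class CovarianceError(TreeError):
    """Covariance matrix cannot be built from the tree as given."""


class Node:
    """A single tree node; ``length`` is the edge to the parent (None at
    the root or when the input Newick carried no length)."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label or '?'} {kind} len={self.length}>"


class PhyloTree:
    """A rooted tree with optional branch lengths and unique tip labels."""

    def __init__(self, root: Node):
        self.root = root
        self.validate()

    # -- iteration ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.root.parent is not None:
            raise TreeError("root must not have a parent")
        labels = [t.label for t in self.tips()]
        if any(lbl is None for lbl in labels):
            raise TreeError("every tip must be labelled")
        seen: set[str] = set()
        dups = sorted({lbl for lbl in labels if lbl in seen or seen.add(lbl)})
        if dups:
            raise TreeError(f"duplicate tip labels: {', '.join(dups)}")
        for node in self.preorder():
            if node.length is not None and node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} at node {node.label or '<internal>'}"
                )
            for child in node.children:
                if child.parent is not node:
                    raise TreeError("inconsistent parent links")

    # -- geometry ----------------------------------------------------------

    def depths(self) -> dict[int, float]:
        """Distance from the root to every node, keyed by ``id(node)``.

        The root's own edge length (if any) is ignored.  Raises
        :class:`CovarianceError` when a non-root edge has no length.
        """
        depths = {id(self.root): 0.0}
        for node in self.preorder():
            for child in node.children:
                if child.length is None:
                    raise CovarianceError(
                        "tree has missing branch lengths; run grafen_branch_lengths first"
                    )
                depths[id(child)] = depths[id(node)] + child.length
        return depths

    def height(self) -> float:
        depths = self.depths()
        return max(depths[id(t)] for t in self.tips())

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                core = node.label
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.length is not None and node.parent is not None:
                core += f":{node.length:.12g}"
            return core

        return fmt(self.root) + ";"

    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            new = Node(label=node.label, length=node.length)
            for child in node.children:
                new.add_child(rec(child))
            return new

        return PhyloTree(rec(self.root))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree n_tips={self.n_tips}>"


@dataclass(frozen=True)
class PolytomyReport:
    """Count of internal nodes with more than two children.

    ``node_ids`` are preorder indices into the tree the report was
    computed from; each unresolved node costs one degree of freedom
    during hypothesis testing, regardless of how many extra children
    it carries.
    """

    n_soft_polytomies: int
    node_ids: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_soft_polytomies != len(self.node_ids):
            raise ValueError("n_soft_polytomies must equal len(node_ids)")

    def to_dict(self) -> dict:
        return {
            "n_soft_polytomies": self.n_soft_polytomies,
            "node_ids": list(self.node_ids),
        }


@dataclass
class CovMatrix:
    """Shared-path-length matrix among tips, ordered by ``labels``."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values).min())

    def reorder(self, labels: Sequence[str]) -> "CovMatrix":
        index = {lbl: i for i, lbl in enumerate(self.labels)}
        missing = [lbl for lbl in labels if lbl not in index]
        if missing:
            raise KeyError(f"labels not in covariance matrix: {missing}")
        idx = [index[lbl] for lbl in labels]
        return CovMatrix(list(labels), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    The dialect is plain Newick: optional branch lengths, optional
    internal-node labels (ignored), ``;``-terminated.  Parse failures
    raise :class:`NewickParseError` carrying dendropy's position
    diagnostics; duplicate tip labels raise :class:`TreeError`.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except TreeError:
        raise
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        node = Node(label=label if dnode.is_leaf() else None,
                    length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # root edge has no meaning here
    return PhyloTree(root)


def count_soft_polytomies(tree: PhyloTree) -> PolytomyReport:
    """Count internal nodes (root included) with more than two children."""
    ids = tuple(
        i for i, node in enumerate(tree.preorder()) if len(node.children) > 2
    )
    return PolytomyReport(n_soft_polytomies=len(ids), node_ids=ids)


def grafen_branch_lengths(tree: PhyloTree) -> PhyloTree:
    """Assign ultrametric branch lengths from the topology alone.

    Each node is given height ``(d - 1) / (n - 1)`` where ``d`` is the
    number of tips descending from it and ``n`` the total tip count;
    tips sit at height 0 and the root at height 1, so every root-to-tip
    path has length exactly 1.  Existing branch lengths are discarded.
    """
    n = tree.n_tips
    if n < 2:
        raise TreeError("Grafen heights are undefined for a tree with fewer than 2 tips")
    new = tree.copy()
    n_desc: dict[int, int] = {}
    for node in new.postorder():
        n_desc[id(node)] = 1 if node.is_tip else sum(
            n_desc[id(c)] for c in node.children
        )
    height: dict[int, float] = {
        id(node): (n_desc[id(node)] - 1) / (n - 1) for node in new.preorder()
    }
    for node in new.preorder():
        for child in node.children:
            child.length = height[id(node)] - height[id(child)]
    new.root.length = None
    return new


def phylo_covariance(tree: PhyloTree) -> CovMatrix:
    """Brownian-motion covariance matrix: entry (i, j) is the root-to-MRCA
    path length for tips i and j; the diagonal holds root-to-tip depths."""
    depths = tree.depths()  # raises CovarianceError on missing lengths
    tips = tree.tips()
    labels = [t.label for t in tips]
    index = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))
    # descendant-tip index sets per node, assigned at the MRCA
    desc: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            i = index[id(node)]
            desc[id(node)] = [i]
            V[i, i] = depths[id(node)]
            continue
        groups = [desc.pop(id(c)) for c in node.children]
        d = depths[id(node)]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        V[i, j] = V[j, i] = d
        desc[id(node)] = [i for g in groups for i in g]
    return CovMatrix(labels, V)


def attach_replicates(
    tree: PhyloTree,
    case_map: Mapping[str, Sequence[str]],
    epsilon: Optional[float] = None,
) -> tuple[PhyloTree, PolytomyReport]:
    """Attach replicate observations as tip clusters.

    Every species in ``case_map`` with a single case has its tip
    relabelled to the case id.  Species with ``k > 1`` cases have the tip
    turned into an internal node carrying ``k`` new case tips on branches
    of length ``epsilon``; the original terminal branch is shortened by
    ``epsilon`` so total tree height is unchanged.  Clusters with more
    than two cases count as soft polytomies in the returned report, which
    covers the whole augmented tree.

    ``epsilon`` defaults to ``1e-6 * tree.height()``.
    """
    new = tree.copy()
    if epsilon is None:
        epsilon = 1e-6 * new.height()
    if epsilon <= 0:
        raise TreeError("epsilon must be positive")
    tip_by_label = {t.label: t for t in new.tips()}
    missing = sorted(set(case_map) - set(tip_by_label))
    if missing:
        raise TreeError(f"species not in tree: {', '.join(missing)}")
    for species, case_ids in case_map.items():
        case_ids = list(case_ids)
        if len(case_ids) != len(set(case_ids)):
            raise TreeError(f"duplicate case ids for species {species!r}")
        tip = tip_by_label[species]
        if len(case_ids) == 1:
            tip.label = case_ids[0]
            continue
        if tip.length is None:
            raise TreeError(
                f"tip {species!r} has no branch length; run grafen_branch_lengths first"
            )
        if epsilon >= tip.length:
            raise TreeError(
                f"epsilon {epsilon} is not smaller than the terminal branch of "
                f"{species!r} ({tip.length}); would create a negative length"
            )
        tip.length -= epsilon
        tip.label = None
        for cid in case_ids:
            tip.add_child(Node(label=cid, length=epsilon))
    new.validate()
    return new, count_soft_polytomies(new)


def prune_to_tips(tree: PhyloTree, keep: Sequence[str]) -> PhyloTree:
    """Induced subtree on ``keep``; unifurcations are spliced out with
    their branch lengths summed (where present)."""
    keep_set = set(keep)
    missing = sorted(keep_set - set(tree.tip_labels()))
    if missing:
        raise TreeError(f"tips not in tree: {', '.join(missing)}")
    if not keep_set:
        raise TreeError("cannot prune to an empty tip set")

    def rec(node: Node) -> Optional[Node]:
        if node.is_tip:
            if node.label in keep_set:
                return Node(label=node.label, length=node.length)
            return None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if node.length is not None:
                child.length = (child.length or 0.0) + node.length
            return child
        new = Node(length=node.length)
        for k in kids:
            new.add_child(k)
        return new

    root = rec(tree.root)
    assert root is not None
    root.length = None
    root.parent = None
    return PhyloTree(root)
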