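"""Species-tree data model, Newick I/O, MRCA queries and branch classification.

The species tree is the coordinate system for every downstream analysis:
gene-family events (gains, duplications, losses) are mapped onto its
branches, and each branch carries a class label describing its position
relative to the designated trait-origin nodes (the "BCZ nodes" at which
hyphal multicellularity most plausibly arose).  Branches are identified
throughout the package by the id of the node they subtend (their child
end); the root has no subtending branch.
"""

from __future__ import annotations

import enum
import warnings
from typing import Iterable, Iterator, Optional

import dendropy
import pandas as pd

__all__ = [
    "BranchClass",
    "Node",
    "SpeciesTree",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "mrca",
    "classify_branches",
    "classification_to_frame",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


class BranchClass(enum.Enum):
    """Position of a species-tree branch relative to the trait origin."""

    PRE_ORIGIN = "PRE_ORIGIN"
    ORIGIN = "ORIGIN"
    POST_ORIGIN = "POST_ORIGIN"
    TERMINAL = "TERMINAL"
    EXCLUDED = "EXCLUDED"


class Node:
    """A rooted-tree node with a parent link and a subtending branch length."""

    __slots__ = ("id", "label", "length", "parent", "children", "support")

    def __init__(self, id: str, label: Optional[str] = None,
                 length: Optional[float] = None,
                 support: Optional[float] = None):
        self.id = id
        self.label = label
        self.length = length
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        # support is only meaningful on gene trees; species trees keep None
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def detach(self) -> None:
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.id!r} leaf={self.is_leaf}>"


class SpeciesTree:
    """Rooted tree with unique node ids and non-negative branch lengths.

    Also used as the underlying structure for gene trees (where internal
    ``support`` values are populated instead of treating labels as ids).
    """

    def __init__(self, root: Node):
        self.root = root
        self._index: dict[str, Node] = {}
        self._reindex()

    # -- construction / indexing -------------------------------------------

    def _reindex(self) -> None:
        self._index.clear()
        for node in self.preorder():
            if node.id in self._index:
                raise TreeValidationError(f"duplicate node id {node.id!r}")
            self._index[node.id] = node

    def validate(self) -> None:
        leaves = self.leaf_labels()
        if len(leaves) < 2:
            raise TreeValidationError("tree must have at least 2 leaves")
        if len(set(leaves)) != len(leaves):
            dups = sorted({x for x in leaves if leaves.count(x) > 1})
            raise TreeValidationError(f"duplicate leaf labels: {dups}")
        if any(not lbl for lbl in leaves):
            raise TreeValidationError("empty leaf label")
        for node in self.preorder():
            if node is not self.root and (node.length is None or node.length < 0):
                raise TreeValidationError(
                    f"branch to {node.id!r} has invalid length {node.length!r}")

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def node(self, node_id: str) -> Node:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"no node with id {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def nodes(self) -> list[Node]:
        return list(self.preorder())

    def branches(self) -> list[Node]:
        """All non-root nodes, each standing for its subtending branch."""
        return [n for n in self.preorder() if n is not self.root]

    def leaves_under(self, node: Node) -> list[Node]:
        stack, out = [node], []
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                out.append(nd)
            else:
                stack.extend(nd.children)
        return out

    def depth(self, node: Node) -> int:
        d = 0
        while node.parent is not None:
            node = node.parent
            d += 1
        return d

    def is_ancestor(self, anc: Node, node: Node) -> bool:
        """True if ``anc`` is ``node`` or an ancestor of ``node``."""
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    def path_to_root(self, node: Node) -> list[Node]:
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    # -- leaf lookup --------------------------------------------------------

    def leaf(self, label: str) -> Node:
        for nd in self.leaves():
            if nd.label == label:
                return nd
        raise KeyError(f"no leaf labelled {label!r}")

    # -- serialization ------------------------------------------------------

    def to_newick(self, *, lengths: bool = True, internal_labels: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label or node.id
            else:
                inner = ",".join(fmt(c) for c in node.children)
                lbl = ""
                if internal_labels:
                    if node.support is not None:
                        lbl = repr(node.support)
                    elif node.label is not None:
                        lbl = node.label
                s = f"({inner}){lbl}"
            if lengths and node.parent is not None and node.length is not None:
                s += f":{node.length!r}"
            return s

        return fmt(self.root) + ";"

    def copy(self) -> "SpeciesTree":
        def clone(node: Node) -> Node:
            c = Node(node.id, node.label, node.length, node.support)
            for ch in node.children:
                c.add_child(clone(ch))
            return c

        return SpeciesTree(clone(self.root))


def parse_newick(text: str, *, default_length: float = 1.0,
                 internal_labels_as: str = "id",
                 assume_rooted: bool = False) -> SpeciesTree:
    """Parse a rooted Newick string into a :class:`SpeciesTree`.

    Parameters
    ----------
    text:
        A single Newick tree.
    default_length:
        Substituted (with a warning) where a branch length is missing.
    internal_labels_as:
        ``"id"`` treats internal labels as node identifiers (species
        trees); ``"support"`` parses them as support values in [0, 1]
        (gene trees), leaving ids auto-generated.
    assume_rooted:
        When the basal node is a multifurcation the rooting is ambiguous;
        pass True to accept the tree as drawn instead of raising.
    """
    if internal_labels_as not in ("id", "support"):
        raise ValueError("internal_labels_as must be 'id' or 'support'")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy reports line/column in the message
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    counter = [0]
    missing = [0]

    def convert(dnode: dendropy.Node) -> Node:
        is_leaf = not dnode.child_nodes()
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        support = None
        if not is_leaf and internal_labels_as == "support" and label is not None:
            try:
                support = float(label)
            except ValueError:
                raise NewickParseError(
                    f"internal label {label!r} is not a numeric support value")
            if not 0.0 <= support <= 1.0:
                raise TreeValidationError(
                    f"support {support} outside [0, 1]")
            label = None
        if is_leaf:
            node_id = label
        elif internal_labels_as == "id" and label is not None:
            node_id = label
        else:
            node_id = f"N{counter[0]}"
            counter[0] += 1
        length = dnode.edge.length
        if length is None and dnode.parent_node is not None:
            missing[0] += 1
            length = default_length
        node = Node(node_id, label, length, support)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    if missing[0]:
        warnings.warn(
            f"{missing[0]} branch length(s) missing; defaulted to {default_length}",
            stacklevel=2)
    if len(root.children) > 2 and not assume_rooted:
        raise TreeValidationError(
            "basal multifurcation: rooting is ambiguous "
            "(pass assume_rooted=True to accept the tree as drawn)")
    tree = SpeciesTree(root)
    tree.validate()
    return tree


def mrca(tree: SpeciesTree, taxa: Iterable[str]) -> str:
    """Id of the most recent common ancestor of a set of leaf labels."""
    taxa = list(taxa)
    if not taxa:
        raise ValueError("taxa must be non-empty")
    leaf_by_label = {n.label: n for n in tree.leaves()}
    try:
        nodes = [leaf_by_label[t] for t in taxa]
    except KeyError as exc:
        raise KeyError(f"unknown taxon {exc.args[0]!r}") from None
    return mrca_nodes(tree, nodes).id


def mrca_nodes(tree: SpeciesTree, nodes: list[Node]) -> Node:
    anc = nodes[0]
    path = set(id(n) for n in tree.path_to_root(anc))
    current = anc
    for node in nodes[1:]:
        walker = node
        while id(walker) not in path:
            walker = walker.parent
        current = walker
        path = set(id(n) for n in tree.path_to_root(current))
    return current


def classify_branches(tree: SpeciesTree, origin_nodes: Iterable[str],
                      outgroup_root: Optional[str] = None
                      ) -> dict[str, BranchClass]:
    """Classify every branch by its position relative to the origin nodes.

    Returns a map from branch id (child-node id) to :class:`BranchClass`.
    Branches inside the outgroup clade, including its stem, are EXCLUDED;
    leaf branches are TERMINAL; branches subtending a designated origin
    node are ORIGIN; in-group internal branches ancestral to an origin
    node are PRE_ORIGIN; the remaining internal branches are POST_ORIGIN.
    """
    origin_nodes = set(origin_nodes)
    for oid in origin_nodes:
        if oid not in tree:
            raise KeyError(f"origin node {oid!r} not in tree")
        if tree.node(oid).is_leaf:
            raise TreeValidationError(f"origin node {oid!r} is a leaf")
    out_node = None
    if outgroup_root is not None:
        out_node = tree.node(outgroup_root)

    origin_set = {tree.node(oid) for oid in origin_nodes}
    result: dict[str, BranchClass] = {}
    for node in tree.branches():
        if out_node is not None and tree.is_ancestor(out_node, node):
            result[node.id] = BranchClass.EXCLUDED
        elif node.is_leaf:
            result[node.id] = BranchClass.TERMINAL
        elif node in origin_set:
            result[node.id] = BranchClass.ORIGIN
        elif any(tree.is_ancestor(node, o) and node is not o for o in origin_set):
            result[node.id] = BranchClass.PRE_ORIGIN
        else:
            result[node.id] = BranchClass.POST_ORIGIN
    return result


def classification_to_frame(tree: SpeciesTree,
                            classification: dict[str, BranchClass]) -> pd.DataFrame:
    """Tabulate a branch classification (child, parent, length, class)."""
    rows = []
    for node in tree.branches():
        rows.append({
            "child_node": node.id,
            "parent_node": node.parent.id,
            "length": node.length,
            "class": classification[node.id].value,
        })
    return pd.DataFrame(rows, columns=["child_node", "parent_node", "length", "class"])
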