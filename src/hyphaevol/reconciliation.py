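"""Gene-tree / species-tree reconciliation under the LCA mapping.

Duplication and loss events are inferred per gene family by mapping each
gene-tree node onto the most recent common ancestor (in the species tree)
of the species its leaves belong to.  A gene-tree node is a duplication
iff its mapping coincides with the mapping of at least one child; every
gene-tree edge whose endpoints map to different species nodes implies
losses in the sibling lineages skipped along the way.

Weakly supported gene-tree edges (support below a threshold, 0.9 for
SH-like supports) are contracted before reconciliation and the resulting
polytomies re-resolved so as to minimise the duplication count.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Optional
from dataclasses import dataclass, field
from .phylo_core import (
    Node,
    SpeciesTree,
    TreeValidationError,
    mrca_nodes,
    parse_newick,
)

__all__ = [
    "GeneTree",
    "ReconciledTree",
    "parse_gene_tree",
    "collapse_weak_edges",
    "resolve_polytomies_min_dup",
    "lca_reconcile",
]

SPECIES_SEP = "|"


class GeneTree(SpeciesTree):
    """Rooted gene tree whose leaves carry ``species|gene`` labels.

    Internal Newick labels are parsed as branch supports in [0, 1];
    a missing support is treated as full support (never collapsed).
    """

    def species_of(self, node: Node) -> str:
        if not node.is_leaf:
            raise ValueError("species_of is defined for leaves only")
        label = node.label or node.id
        if SPECIES_SEP not in label:
            raise TreeValidationError(
                f"gene-tree leaf {label!r} lacks a '{SPECIES_SEP}'-separated "
                "species prefix")
        return label.split(SPECIES_SEP, 1)[0]

    def species_set(self, node: Node) -> frozenset[str]:
        return frozenset(self.species_of(l) for l in self.leaves_under(node))

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.preorder() if not n.is_leaf)


def parse_gene_tree(text: str, *, assume_rooted: bool = True) -> GeneTree:
    tree = parse_newick(text, internal_labels_as="support",
                        assume_rooted=assume_rooted)
    gtree = GeneTree(tree.root)
    for leaf in gtree.leaves():
        gtree.species_of(leaf)  # validates the label convention
    return gtree


def collapse_weak_edges(gtree: GeneTree, threshold: float) -> GeneTree:
    """Contract internal edges whose support falls below ``threshold``.

    Children of a contracted node are re-attached to its parent, with the
    contracted edge length folded into theirs so root-to-leaf distances
    are preserved.  Leaf edges and edges without a support annotation are
    never contracted.  Returns a new (possibly multifurcating) tree.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = GeneTree(gtree.copy().root)
    changed = True
    while changed:
        changed = False
        for node in list(out.preorder()):
            if node.is_leaf or node.parent is None:
                continue
            if node.support is not None and node.support < threshold:
                parent = node.parent
                for child in list(node.children):
                    if node.length is not None and child.length is not None:
                        child.length += node.length
                    child.parent = parent
                    parent.children.append(child)
                node.children = []
                node.detach()
                changed = True
    out._reindex()
    return out


def _min_leaf_label(gtree: GeneTree, node: Node) -> str:
    return min((l.label or l.id) for l in gtree.leaves_under(node))


def resolve_polytomies_min_dup(gtree: GeneTree, stree: SpeciesTree) -> GeneTree:
    """Resolve multifurcations into binary subtrees minimising duplications.

    Each polytomy is resolved greedily: the pair of children whose joined
    species set has the deepest MRCA on the species tree is joined first
    (a deeper joint mapping defers coalescence, avoiding duplications);
    ties are broken lexicographically on the smallest leaf label in each
    subtree, making the output deterministic.
    """
    out = GeneTree(gtree.copy().root)
    species_leaf = {l.label: l for l in stree.leaves()}
    new_ids = itertools.count()

    def mapping(node: Node) -> Node:
        leaves = [species_leaf[out.species_of(l)] for l in out.leaves_under(node)]
        return mrca_nodes(stree, leaves)

    depth_cache = {id(n): stree.depth(n) for n in stree.preorder()}

    for node in list(out.postorder()):
        while len(node.children) > 2:
            best = None
            for a, b in itertools.combinations(node.children, 2):
                joined = mrca_nodes(stree, [mapping(a), mapping(b)])
                tie = tuple(sorted((_min_leaf_label(out, a),
                                    _min_leaf_label(out, b))))
                key = (-depth_cache[id(joined)], tie)
                if best is None or key < best[0]:
                    best = (key, a, b)
            _, a, b = best
            joint = Node(f"R{next(new_ids)}", None, 0.0)
            a.detach()
            b.detach()
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
    out._reindex()
    return out


@dataclass
class ReconciledTree:
    """LCA reconciliation of one gene tree against the species tree.

    ``duplications`` and ``losses`` count events per species branch,
    keyed by the id of the node the branch subtends (events mapped to
    the species root are keyed by the root id).
    """

    gene_tree: GeneTree
    mapping: dict[str, str]
    events: dict[str, str]  # internal gene node id -> SPECIATION | DUPLICATION
    duplications: Counter = field(default_factory=Counter)
    losses: Counter = field(default_factory=Counter)

    @property
    def n_duplications(self) -> int:
        return sum(self.duplications.values())

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())

    def copy_counts(self) -> Counter:
        """Observed extant copies per species (from the gene-tree leaves)."""
        return Counter(self.gene_tree.species_of(l)
                       for l in self.gene_tree.leaves())


def lca_reconcile(gtree: GeneTree, stree: SpeciesTree) -> ReconciledTree:
    """Reconcile a binary rooted gene tree with the species tree.

    Each gene node maps to the species-tree MRCA of its leaf species; a
    node is a DUPLICATION iff it maps to the same species node as one of
    its children.  For a gene edge whose parent maps to species node S
    and child to species node C (C inside S), one loss is recorded on the
    off-path child branch at every species node strictly between S and C,
    plus one at S itself when the parent is a duplication — the sibling
    lineages through which this copy left no descendants.
    """
    if not gtree.is_binary():
        raise TreeValidationError(
            "gene tree is not binary; resolve polytomies first")
    species_leaf = {l.label: l for l in stree.leaves()}
    for leaf in gtree.leaves():
        sp = gtree.species_of(leaf)
        if sp not in species_leaf:
            raise KeyError(f"gene-tree species {sp!r} absent from species tree")

    mapping_nodes: dict[str, Node] = {}
    events: dict[str, str] = {}
    for node in gtree.postorder():
        if node.is_leaf:
            mapping_nodes[node.id] = species_leaf[gtree.species_of(node)]
        else:
            kids = [mapping_nodes[c.id] for c in node.children]
            m = mrca_nodes(stree, kids)
            mapping_nodes[node.id] = m
            events[node.id] = (
                "DUPLICATION" if any(k is m for k in kids) else "SPECIATION")

    duplications: Counter = Counter()
    losses: Counter = Counter()
    for node_id, event in events.items():
        if event == "DUPLICATION":
            duplications[mapping_nodes[node_id].id] += 1

    for node in gtree.preorder():
        for child in node.children:
            m_parent = mapping_nodes[node.id]
            m_child = mapping_nodes[child.id]
            # species path child-mapping -> parent-mapping, walking up
            path = [m_child]
            while path[-1] is not m_parent:
                path.append(path[-1].parent)
            # off-path siblings at nodes strictly between the two mappings
            for below, at in zip(path[:-1], path[1:-1]):
                for sib in at.children:
                    if sib is not below:
                        losses[sib.id] += 1
            if events[node.id] == "DUPLICATION" and m_child is not m_parent:
                below = path[-2]
                for sib in m_parent.children:
                    if sib is not below:
                        losses[sib.id] += 1

    return ReconciledTree(
        gene_tree=gtree,
        mapping={k: v.id for k, v in mapping_nodes.items()},
        events=events,
        duplications=duplications,
        losses=losses,
    )
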