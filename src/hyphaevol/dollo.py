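"""Dollo-parsimony gain mapping, event aggregation and ancestral copy numbers.

Each gene family is assumed to have been gained exactly once (Dollo
parsimony): its origin is the MRCA of the species that retain it, and
every maximal retained-free clade below the origin accounts for one loss
on its stem branch.  Duplications and topology-implied losses come from
gene-tree reconciliation; families without a gene tree contribute gains
and Dollo losses only, with extra terminal copies booked as terminal
duplications.  Summing gains + duplications − losses down every
root-to-node path yields the ancestral copy number at each node.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .phylo_core import Node, SpeciesTree, mrca_nodes
from .reconciliation import GeneTree, ReconciledTree

__all__ = [
    "GeneFamily",
    "FamilyEvents",
    "EventMap",
    "ConsistencyError",
    "dollo_origin",
    "build_event_map",
    "ancestral_copy_numbers",
    "read_family_table",
]


class ConsistencyError(ValueError):
    """An event map implies a negative ancestral copy number."""


@dataclass
class GeneFamily:
    """A gene family: member genes with species assignments.

    ``category`` is an optional functional tag (e.g. "cell wall
    biogenesis"); it is carried through, never inferred.
    """

    id: str
    members: list[tuple[str, str]]  # (gene id, species)
    gene_tree: Optional[GeneTree] = None
    category: Optional[str] = None

    def copy_counts(self) -> Counter:
        return Counter(sp for _, sp in self.members)

    def present_species(self) -> set[str]:
        return {sp for _, sp in self.members}


@dataclass
class FamilyEvents:
    """Per-branch events of one family on the species tree.

    The single Dollo gain sits on the branch subtending ``origin`` (the
    origin node itself therefore has copy number >= 1); ``duplications``
    and ``losses`` are keyed by the id of the node each branch subtends.
    """

    family: str
    origin: str
    duplications: Counter = field(default_factory=Counter)
    losses: Counter = field(default_factory=Counter)
    category: Optional[str] = None

    @property
    def n_duplications(self) -> int:
        return sum(self.duplications.values())

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())


class EventMap:
    """Gains, duplications and losses for a set of families."""

    def __init__(self, families: dict[str, FamilyEvents]):
        self.families = families

    def __len__(self) -> int:
        return len(self.families)

    def __getitem__(self, family: str) -> FamilyEvents:
        return self.families[family]

    def __iter__(self):
        return iter(self.families.values())

    def subset(self, family_ids: Iterable[str]) -> "EventMap":
        ids = set(family_ids)
        return EventMap({f: e for f, e in self.families.items() if f in ids})

    def duplications_by_branch(self) -> Counter:
        total: Counter = Counter()
        for ev in self:
            total.update(ev.duplications)
        return total

    def losses_by_branch(self) -> Counter:
        total: Counter = Counter()
        for ev in self:
            total.update(ev.losses)
        return total

    def gains_by_branch(self) -> Counter:
        return Counter(ev.origin for ev in self)

    def total_duplications(self) -> int:
        return sum(ev.n_duplications for ev in self)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self:
            branches = {ev.origin} | set(ev.duplications) | set(ev.losses)
            for b in sorted(branches):
                rows.append({
                    "family": ev.family,
                    "branch": b,
                    "gain": int(b == ev.origin),
                    "duplications": ev.duplications.get(b, 0),
                    "losses": ev.losses.get(b, 0),
                })
        return pd.DataFrame(
            rows, columns=["family", "branch", "gain", "duplications", "losses"])


def dollo_origin(present: Iterable[str], stree: SpeciesTree
                 ) -> tuple[str, list[str]]:
    """Single-gain origin node and minimal loss branches for a presence set.

    The origin is the MRCA of the present species; each maximal clade
    below it containing no present species contributes one loss on its
    stem branch.  This is the minimum-loss solution under a single gain.
    """
    present = set(present)
    if not present:
        raise ValueError("family is absent from every species")
    leaves = {l.label: l for l in stree.leaves()}
    unknown = present - set(leaves)
    if unknown:
        raise KeyError(f"species not in tree: {sorted(unknown)}")
    origin = mrca_nodes(stree, [leaves[s] for s in present])

    losses: list[str] = []

    def walk(node: Node) -> None:
        if not any(l.label in present for l in stree.leaves_under(node)):
            losses.append(node.id)
            return
        for child in node.children:
            walk(child)

    for child in origin.children:
        walk(child)
    return origin.id, losses


def build_event_map(families: list[GeneFamily],
                    reconciliations: dict[str, ReconciledTree],
                    stree: SpeciesTree) -> EventMap:
    """Combine Dollo gains with reconciliation events for each family.

    Families with a reconciliation take duplications and losses from it
    (the LCA losses subsume the Dollo losses).  Presence-only families
    take losses from Dollo mapping and book k-1 terminal duplications for
    a species observed with k > 1 copies.  Every family is replayed down
    the tree and checked against its observed copy vector.
    """
    out: dict[str, FamilyEvents] = {}
    for fam in families:
        counts = fam.copy_counts()
        origin, dollo_losses = dollo_origin(set(counts), stree)
        rec = reconciliations.get(fam.id)
        if rec is not None:
            ev = FamilyEvents(fam.id, origin,
                              Counter(rec.duplications), Counter(rec.losses),
                              category=fam.category)
        else:
            dups: Counter = Counter()
            for leaf in stree.leaves():
                k = counts.get(leaf.label, 0)
                if k > 1:
                    dups[leaf.id] += k - 1
            ev = FamilyEvents(fam.id, origin, dups, Counter(dollo_losses),
                              category=fam.category)
        _check_replay(ev, counts, stree)
        out[fam.id] = ev
    return EventMap(out)


def _replay(ev: FamilyEvents, stree: SpeciesTree) -> dict[str, int]:
    copies: dict[str, int] = {}
    for node in stree.preorder():
        base = 0 if node.parent is None else copies[node.parent.id]
        c = (base + (node.id == ev.origin)
             + ev.duplications.get(node.id, 0) - ev.losses.get(node.id, 0))
        if c < 0:
            raise ConsistencyError(
                f"family {ev.family!r}: negative copy number {c} at node "
                f"{node.id!r}")
        copies[node.id] = c
    return copies


def _check_replay(ev: FamilyEvents, observed: Counter,
                  stree: SpeciesTree) -> None:
    copies = _replay(ev, stree)
    for leaf in stree.leaves():
        expect = observed.get(leaf.label, 0)
        if copies[leaf.id] != expect:
            raise ConsistencyError(
                f"family {ev.family!r}: replay gives {copies[leaf.id]} copies "
                f"in {leaf.label!r}, observed {expect}")


def ancestral_copy_numbers(events: EventMap, stree: SpeciesTree) -> pd.DataFrame:
    """Copy number of every family at every node (nodes x families).

    The copy number at a node is the running sum of gain + duplications
    − losses over the branches on the path from the root down to (and
    including) the node's own branch; e.g. a parent with 572 copies, 81
    duplications and 124 losses on the connecting branch leaves 529
    copies at the child.  Any negative intermediate raises
    :class:`ConsistencyError`.
    """
    node_ids = [n.id for n in stree.preorder()]
    data = {}
    for ev in events:
        copies = _replay(ev, stree)
        data[ev.family] = [copies[nid] for nid in node_ids]
    return pd.DataFrame(data, index=node_ids)


def read_family_table(path) -> list[GeneFamily]:
    """Read a TSV membership table (family, gene, species[, category])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family", "gene", "species"}
    if not required.issubset(df.columns):
        raise ValueError(f"family table must have columns {sorted(required)}")
    fams: dict[str, GeneFamily] = {}
    for row in df.itertuples(index=False):
        fam = fams.setdefault(
            row.family,
            GeneFamily(row.family, [],
                       category=getattr(row, "category", None)))
        fam.members.append((row.gene, row.species))
    return list(fams.values())
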