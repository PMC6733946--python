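"""Ground-truth simulators for every pipeline stage.

Gene families evolve by a single Dollo gain at a sampled origin node.
Along each branch the family accrues duplications as a Poisson count
with mean ``lambda_dup`` x branch length (x the elevation factor on the
designated origin ("BCZ") branches), each event splitting one uniformly
chosen live copy; independently, every live copy survives a loss clock
of rate ``lambda_loss`` per unit branch length.  Branch-level Poisson
duplications keep a family's per-branch duplication *rate* centred on
``lambda_dup`` x elevation regardless of how many copies it has
accumulated, which is the quantity the rate screen tests.  The
full event history is recorded, and alongside it the *observable* event
set — the parsimony-canonical reading of the pruned surviving gene tree,
in which a duplication erased by complementary losses is (provably)
unidentifiable and events are placed at their lowest consistent
position.  Reconciliation of the true gene tree must recover the
observable events exactly; the raw counts calibrate rate expectations.

Traits evolve by forward Brownian motion of a liability whose sign at
the tips gives the hyphal / non-hyphal state.  Gene structures and
domain tables are drawn with group-dependent length and count
distributions and written in the pipeline's own input formats.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .phylo_core import BranchClass, Node, SpeciesTree, mrca_nodes
from .reconciliation import GeneTree

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "SimulatedTruth",
    "simulate_species_tree",
    "designate_origin_nodes",
    "simulate_family_evolution",
    "simulate_trait",
    "simulate_features",
    "expected_duplications",
    "perturb_gene_tree",
    "write_simulation",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults describe a desk-scale fungal dataset: a 12-taxon tree with
    branch lengths around 0.2 substitutions/site, three nested origin
    nodes, roughly 0.1 expected duplications per family per background
    branch and a loss clock of 0.4 per copy per unit length.
    ``origin_elevation`` is 1 (no rate shift) unless a screen scenario
    raises it.
    """

    n_taxa: int = 12
    n_origin_nodes: int = 3
    branch_length_meanlog: float = math.log(0.2)
    branch_length_sdlog: float = 0.5
    lambda_dup: float = 0.5
    lambda_loss: float = 0.4
    origin_elevation: float = 1.0
    gain_nodes: Optional[list[str]] = None  # None = uniform over all nodes
    trait_root_liability: float = 0.0
    feature_params: dict = field(default_factory=lambda: {
        "unicellular": {"n_exons_mean": 4.0, "exon_length_mean": 300.0,
                        "intron_length_mean": 75.0},
        "multicellular": {"n_exons_mean": 5.0, "exon_length_mean": 300.0,
                          "intron_length_mean": 110.0},
    })
    domain_count_mean: dict = field(default_factory=lambda: {
        "unicellular": 2.0, "multicellular": 3.0})
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(n_taxa: int, seed: int,
                          meanlog: float = math.log(0.2),
                          sdlog: float = 0.5,
                          ultrametric: bool = False) -> SpeciesTree:
    """Random rooted binary tree with lognormal branch lengths.

    The topology comes from uniformly random pairwise joins (a pure-birth
    shape distribution).  In ultrametric mode internal-node heights are
    accumulated so every root-to-tip path has the same length.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))
    subtrees = [Node(f"sp{i + 1:0{width}d}", f"sp{i + 1:0{width}d}")
                for i in range(n_taxa)]
    counter = 0
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        counter += 1
        parent = Node(f"__tmp{counter}")
        parent.add_child(a)
        parent.add_child(b)
        subtrees.append(parent)
    root = subtrees[0]
    tree = SpeciesTree(root)

    # stable internal ids by preorder position
    internals = [n for n in tree.preorder() if not n.is_leaf]
    for k, node in enumerate(internals):
        node.id = f"N{k}"
        node.label = node.id
    tree._reindex()

    if ultrametric:
        height: dict[int, float] = {}
        for node in tree.postorder():
            if node.is_leaf:
                height[id(node)] = 0.0
            else:
                h = max(height[id(c)] for c in node.children)
                height[id(node)] = h + float(
                    rng.lognormal(meanlog, sdlog))
        for node in tree.preorder():
            if node.parent is not None:
                node.length = height[id(node.parent)] - height[id(node)]
    else:
        for node in tree.preorder():
            if node.parent is not None:
                node.length = float(rng.lognormal(meanlog, sdlog))
    tree.validate()
    return tree


def designate_origin_nodes(tree: SpeciesTree, k: int,
                           skip: int = 1) -> list[str]:
    """``k`` successive internal nodes down the heavy spine of the tree.

    Mirrors the nested arrangement of the BCZ nodes: consecutive
    backbone splits, each the parent of the next.  ``skip`` backbone
    nodes are left above the chain so that a pre-origin branch class
    exists (the earliest fungal splits precede the trait's origin).
    """
    spine = []
    node = tree.root
    while not node.is_leaf:
        node = max(node.children,
                   key=lambda c: (len(tree.leaves_under(c)), c.id))
        if not node.is_leaf:
            spine.append(node.id)
    if len(spine) < skip + k:
        raise ValueError(
            f"tree spine has only {len(spine)} internal nodes; "
            f"need {skip + k}")
    return spine[skip:skip + k]


# ---------------------------------------------------------------------------
# gene-family histories


class _Lin:
    """True-history lineage node: dup | spec | leaf | death."""

    __slots__ = ("kind", "sp", "children")

    def __init__(self, kind: str, sp: Node, children: Optional[list] = None):
        self.kind = kind
        self.sp = sp
        self.children = children or []


class _GNode:
    """Pruned (surviving) gene-tree node."""

    __slots__ = ("sp", "children")

    def __init__(self, sp: Optional[Node] = None,
                 children: Optional[list] = None):
        self.sp = sp  # species leaf for gene leaves
        self.children = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class SimulatedFamily:
    id: str
    origin: str
    members: list[tuple[str, str]]  # (gene id, species)
    gene_tree: Optional[GeneTree]
    raw_duplications: Counter
    raw_losses: Counter
    obs_duplications: Counter
    obs_losses: Counter

    def copy_counts(self) -> Counter:
        return Counter(sp for _, sp in self.members)


@dataclass
class SimulatedTruth:
    tree: SpeciesTree
    families: list[SimulatedFamily]
    n_redraws: int
    config: SimulationConfig


def _dup_rate(sp: Node, config: SimulationConfig,
              classification: Mapping[str, BranchClass]) -> float:
    factor = (config.origin_elevation
              if classification.get(sp.id) is BranchClass.ORIGIN else 1.0)
    return config.lambda_dup * factor


def _evolve_branch(sp: Node, entering: list[_Lin], config: SimulationConfig,
                   classification: Mapping[str, BranchClass],
                   rng, raw_dups: Counter, raw_losses: Counter) -> None:
    """Evolve all copies of one family along the branch subtending ``sp``.

    ``entering`` holds one stub lineage node per copy at the top of the
    branch; each stub is resolved in place into a death, a duplication
    (with two fresh stubs), a leaf, or a speciation passage, and the
    recursion continues into the child branches with the survivors.
    """
    L = sp.length
    rd = _dup_rate(sp, config, classification)
    rl = config.lambda_loss

    def death_time(t: float) -> float:
        return t + rng.exponential(1.0 / rl) if rl > 0 else math.inf

    live: list[list] = [[stub, death_time(0.0)] for stub in entering]
    dup_times = np.sort(rng.uniform(0.0, L, rng.poisson(rd * L))) \
        if rd > 0 else np.empty(0)

    def reap(until: float) -> None:
        for entry in list(live):
            if entry[1] < until:
                entry[0].kind = "death"
                raw_losses[sp.id] += 1
                live.remove(entry)

    for td in dup_times:
        reap(td)
        if not live:
            break  # no copy left for the event to act on
        entry = live[int(rng.integers(len(live)))]
        node = entry[0]
        node.kind = "dup"
        node.children = [_Lin("stub", sp), _Lin("stub", sp)]
        live.remove(entry)
        live.extend([[c, death_time(td)] for c in node.children])
        raw_dups[sp.id] += 1
    reap(L)

    if sp.is_leaf:
        for entry in live:
            entry[0].kind = "leaf"
        return
    for entry in live:
        node = entry[0]
        node.kind = "spec"
        node.children = [_Lin("stub", c) for c in sp.children]
    for i, child in enumerate(sp.children):
        stubs = [entry[0].children[i] for entry in live]
        if stubs:
            _evolve_branch(child, stubs, config, classification, rng,
                           raw_dups, raw_losses)


def _prune(lin: _Lin) -> Optional[_GNode]:
    """Drop extinct lineages and suppress unary passages."""
    if lin.kind == "leaf":
        return _GNode(sp=lin.sp)
    if lin.kind == "death":
        return None
    alive = [p for p in (_prune(c) for c in lin.children) if p is not None]
    if not alive:
        return None
    if len(alive) == 1:
        return alive[0]
    return _GNode(children=alive)


def _observable_events(root: _GNode, stree: SpeciesTree
                       ) -> tuple[Counter, Counter]:
    """Parsimony-canonical duplications and losses of a pruned history.

    Events are read off the surviving tree exactly as an LCA analysis
    would see them: a duplication is counted where a node and one of its
    children map to the same species node, and every species branch
    skipped along a gene edge contributes a loss on the off-path sibling.
    Implemented directly on simulator structures as an independent
    counterpart to the reconciliation module.
    """
    dups: Counter = Counter()
    losses: Counter = Counter()
    mapping: dict[int, Node] = {}

    def assign(g: _GNode) -> Node:
        if g.is_leaf:
            mapping[id(g)] = g.sp
            return g.sp
        kids = [assign(c) for c in g.children]
        m = mrca_nodes(stree, kids)
        mapping[id(g)] = m
        if any(k is m for k in kids):
            dups[m.id] += 1
        return m

    assign(root)

    def walk(g: _GNode) -> None:
        m_parent = mapping[id(g)]
        is_dup = any(mapping[id(c)] is m_parent for c in g.children)
        for child in g.children:
            m_child = mapping[id(child)]
            path = [m_child]
            while path[-1] is not m_parent:
                path.append(path[-1].parent)
            for below, at in zip(path[:-1], path[1:-1]):
                for sib in at.children:
                    if sib is not below:
                        losses[sib.id] += 1
            if is_dup and m_child is not m_parent:
                below = path[-2]
                for sib in m_parent.children:
                    if sib is not below:
                        losses[sib.id] += 1
            walk(child)

    walk(root)
    return dups, losses


def _to_gene_tree(root: _GNode, family: str) -> tuple[GeneTree,
                                                      list[tuple[str, str]]]:
    counters: Counter = Counter()
    members: list[tuple[str, str]] = []
    idx = [0]

    def build(g: _GNode) -> Node:
        if g.is_leaf:
            sp = g.sp.label
            counters[sp] += 1
            gene = f"{family}_g{counters[sp]}"
            members.append((gene, sp))
            return Node(f"{sp}|{gene}", f"{sp}|{gene}", 0.1)
        idx[0] += 1
        node = Node(f"{family}_i{idx[0]}", None, 0.1)
        for c in g.children:
            node.add_child(build(c))
        return node

    return GeneTree(build(root)), members


def simulate_family_evolution(stree: SpeciesTree,
                              classification: Mapping[str, BranchClass],
                              config: SimulationConfig,
                              n_families: int, seed: int) -> SimulatedTruth:
    """Simulate ``n_families`` single-gain birth–death family histories.

    Families whose copies all go extinct are redrawn (Dollo mapping
    needs at least one extant member); the number of redraws is kept as
    a record of the acquisition bias this introduces.  Families with a
    single surviving copy carry no gene tree (they are presence-only
    downstream).
    """
    rng = np.random.default_rng(seed)
    all_nodes = [n for n in stree.preorder()]
    if config.gain_nodes is not None:
        candidates = [stree.node(i) for i in config.gain_nodes]
    else:
        candidates = all_nodes
    families: list[SimulatedFamily] = []
    n_redraws = 0
    fam_width = len(str(max(n_families, 1)))
    for i in range(n_families):
        fam_id = f"fam{i + 1:0{fam_width}d}"
        while True:
            origin = candidates[int(rng.integers(len(candidates)))]
            raw_dups: Counter = Counter()
            raw_losses: Counter = Counter()
            if origin.is_leaf:
                lineage = _Lin("leaf", origin)
            else:
                lineage = _Lin("spec", origin,
                               [_Lin("stub", c) for c in origin.children])
                for stub, child in zip(lineage.children, origin.children):
                    _evolve_branch(child, [stub], config, classification,
                                   rng, raw_dups, raw_losses)
            pruned = _prune(lineage)
            if pruned is not None:
                break
            n_redraws += 1
        if pruned.is_leaf:
            sp = pruned.sp.label
            members = [(f"{fam_id}_g1", sp)]
            gtree = None
            obs_dups: Counter = Counter()
            obs_losses: Counter = Counter()
        else:
            obs_dups, obs_losses = _observable_events(pruned, stree)
            gtree, members = _to_gene_tree(pruned, fam_id)
        families.append(SimulatedFamily(
            id=fam_id, origin=origin.id, members=members, gene_tree=gtree,
            raw_duplications=raw_dups, raw_losses=raw_losses,
            obs_duplications=obs_dups, obs_losses=obs_losses))
    return SimulatedTruth(tree=stree, families=families,
                          n_redraws=n_redraws, config=config)


def expected_duplications(stree: SpeciesTree,
                          classification: Mapping[str, BranchClass],
                          config: SimulationConfig,
                          branch_ids: Sequence[str]) -> float:
    """Expected duplication count over a set of branches for a family
    whose lineage passes through them: sum of lambda_dup x elevation x
    length.  Exact when the loss rate is 0 (no chance of the family
    dying out before reaching a branch); an upper bound otherwise.
    """
    total = 0.0
    for bid in branch_ids:
        node = stree.node(bid)
        total += _dup_rate(node, config, classification) * node.length
    return total


def perturb_gene_tree(gtree: GeneTree, n_swaps: int, seed: int,
                      weak_support: float = 0.5) -> GeneTree:
    """Apply random NNI-style child swaps, marking touched edges with
    ``weak_support`` and all others with full support.

    Gives collapse_weak_edges something real to do in tests: collapsing
    the weak edges of a perturbed tree restores a topology that the
    minimum-duplication resolution can repair.
    """
    out = GeneTree(gtree.copy().root)
    rng = np.random.default_rng(seed)
    for node in out.preorder():
        if not node.is_leaf:
            node.support = 1.0
    internal_edges = [n for n in out.preorder()
                      if not n.is_leaf and n.parent is not None]
    for _ in range(n_swaps):
        if not internal_edges:
            break
        node = internal_edges[int(rng.integers(len(internal_edges)))]
        siblings = [c for c in node.parent.children if c is not node]
        if not siblings or not node.children:
            continue
        sib = siblings[int(rng.integers(len(siblings)))]
        child = node.children[int(rng.integers(len(node.children)))]
        child.detach()
        sib.detach()
        node.add_child(sib)
        node.parent.add_child(child)
        node.support = weak_support
    out._reindex()
    return out


# ---------------------------------------------------------------------------
# traits


def simulate_trait(stree: SpeciesTree, seed: int,
                   root_liability: float = 0.0
                   ) -> tuple[dict[str, str], dict[str, float]]:
    """Forward Brownian motion of the liability; tip state = its sign.

    Returns (tip states keyed by species, liabilities keyed by node id —
    internal nodes included, so ancestral reconstructions can be scored
    against the truth).
    """
    rng = np.random.default_rng(seed)
    lia: dict[str, float] = {stree.root.id: root_liability}
    for node in stree.preorder():
        if node.parent is None:
            continue
        if node.length is None or node.length <= 0:
            raise ValueError(f"branch to {node.id!r} must be positive")
        lia[node.id] = lia[node.parent.id] + float(
            rng.normal(0.0, math.sqrt(node.length)))
    states = {leaf.label: ("HYPHAL" if lia[leaf.id] > 0 else "NON_HYPHAL")
              for leaf in stree.leaves()}
    return states, lia


# ---------------------------------------------------------------------------
# gene structures and domain architectures


@dataclass
class FeatureSim:
    gff: dict[str, str]  # species -> GFF3 text
    domains: pd.DataFrame
    truth: pd.DataFrame  # per-gene sampled lengths


def simulate_features(groups: Mapping[str, Sequence[str]],
                      config: SimulationConfig, n_genes: int,
                      seed: int, n_domain_proteins: int = 50,
                      n_domain_families: int = 1) -> FeatureSim:
    """Group-dependent gene models (as GFF3) and domain tables.

    ``groups`` maps a cellularity group label to its species.  Exon and
    intron lengths and exon counts follow the per-group settings in
    ``config.feature_params``; per-protein domain counts are
    1 + Poisson(mean - 1) with the per-group mean from
    ``config.domain_count_mean``.
    """
    rng = np.random.default_rng(seed)
    gff: dict[str, str] = {}
    truth_rows = []
    for group, species_list in groups.items():
        params = config.feature_params[group]
        for sp in species_list:
            lines = ["##gff-version 3"]
            cursor = 1000
            for gi in range(n_genes):
                n_exons = 1 + int(rng.poisson(max(params["n_exons_mean"] - 1,
                                                  0.0)))
                exons = [3 + int(rng.poisson(params["exon_length_mean"] - 3))
                         for _ in range(n_exons)]
                introns = [4 + int(rng.poisson(params["intron_length_mean"]
                                               - 4))
                           for _ in range(n_exons - 1)]
                strand = "+" if rng.random() < 0.5 else "-"
                gene_id = f"{sp}_gene{gi + 1}"
                start = cursor
                segs = []
                pos = start
                for k, ex in enumerate(exons):
                    segs.append((pos, pos + ex - 1))
                    pos += ex
                    if k < len(introns):
                        pos += introns[k]
                end = segs[-1][1]
                lines.append("\t".join([
                    "chr1", "hyphaevol_sim", "gene", str(start), str(end),
                    ".", strand, ".", f"ID={gene_id}"]))
                mrna_id = f"{gene_id}.t1"
                lines.append("\t".join([
                    "chr1", "hyphaevol_sim", "mRNA", str(start), str(end),
                    ".", strand, ".", f"ID={mrna_id};Parent={gene_id}"]))
                for s, e in segs:
                    lines.append("\t".join([
                        "chr1", "hyphaevol_sim", "CDS", str(s), str(e),
                        ".", strand, "0", f"Parent={mrna_id}"]))
                truth_rows.append({
                    "species": sp, "group": group, "gene": gene_id,
                    "strand": strand,
                    "gene_length": end - start + 1,
                    "cds_length": sum(exons),
                    "n_exons": n_exons,
                    "intron_lengths": ",".join(map(str, introns)),
                })
                cursor = end + 500
            gff[sp] = "\n".join(lines) + "\n"

    pfam_pool = [f"PF{k:05d}" for k in range(1, 200)]
    domain_rows = []
    for fam_i in range(n_domain_families):
        family = f"dfam{fam_i + 1}"
        for group, species_list in groups.items():
            mean = config.domain_count_mean[group]
            for pi in range(n_domain_proteins):
                sp = species_list[pi % len(species_list)]
                count = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
                arch = list(rng.choice(pfam_pool, size=count, replace=False))
                domain_rows.append({
                    "protein": f"{family}_{group}_p{pi + 1}",
                    "species": sp, "group": group, "family": family,
                    "domains": ",".join(arch),
                })
    domains = pd.DataFrame(domain_rows)
    if not domains.empty:
        domains["architecture"] = domains["domains"].map(
            lambda s: tuple(s.split(",")))
    return FeatureSim(gff=gff, domains=domains,
                      truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# writers


def write_simulation(truth: SimulatedTruth, outdir,
                     trait_states: Optional[Mapping[str, str]] = None,
                     features: Optional[FeatureSim] = None) -> None:
    """Write a simulated dataset in the pipeline's own input formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "species_tree.nwk").write_text(truth.tree.to_newick() + "\n")
    fam_rows = []
    tree_dir = out / "gene_trees"
    tree_dir.mkdir(exist_ok=True)
    for fam in truth.families:
        for gene, sp in fam.members:
            fam_rows.append({"family": fam.id, "gene": gene, "species": sp})
        if fam.gene_tree is not None:
            (tree_dir / f"{fam.id}.nwk").write_text(
                fam.gene_tree.to_newick() + "\n")
    pd.DataFrame(fam_rows).to_csv(out / "families.tsv", sep="\t", index=False)
    truth_rows = []
    for fam in truth.families:
        branches = (set(fam.obs_duplications) | set(fam.obs_losses)
                    | {fam.origin})
        for b in sorted(branches):
            truth_rows.append({
                "family": fam.id, "branch": b,
                "gain": int(b == fam.origin),
                "duplications": fam.obs_duplications.get(b, 0),
                "losses": fam.obs_losses.get(b, 0),
            })
    pd.DataFrame(truth_rows).to_csv(out / "truth_events.tsv", sep="\t",
                                    index=False)
    if trait_states is not None:
        pd.DataFrame(
            [{"species": s, "state": st} for s, st in trait_states.items()]
        ).to_csv(out / "traits.tsv", sep="\t", index=False)
    if features is not None:
        gff_dir = out / "annotations"
        gff_dir.mkdir(exist_ok=True)
        for sp, text in features.gff.items():
            (gff_dir / f"{sp}.gff3").write_text(text)
        features.domains.drop(columns=["architecture"], errors="ignore"
                              ).to_csv(out / "domains.tsv", sep="\t",
                                       index=False)
    (out / "config.json").write_text(truth.config.to_json() + "\n")
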