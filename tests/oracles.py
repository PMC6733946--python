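"""Independent oracles used by the test suite.

Each function recomputes a quantity by a route deliberately different
from the package implementation: exact rational enumeration, textbook
closed forms, grid quadrature, or a dendropy-based reconstruction.
"""

from __future__ import annotations

import math
from fractions import Fraction

import dendropy
import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact enumeration with rational arithmetic.

    All tables with the observed margins are enumerated; p sums the
    hypergeometric probabilities of tables no more probable than the
    observed one.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x: int) -> Fraction:
        return (Fraction(math.comb(r1, x) * math.comb(r2, c1 - x),
                         math.comb(n, c1)))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = table_prob(a)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        px = table_prob(x)
        if px <= p_obs:
            total += px
    return float(total)


def bh_stepup_oracle(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values via the explicit step-up loop."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top  # 1-based rank of this p in ascending order
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return np.minimum(adj, 1.0)


def one_way_f_oracle(values, labels) -> float:
    """Textbook one-way ANOVA F: MS_between / MS_within."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    k = len(groups)
    n = values.size
    grand = values.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


def poisson_lrt_oracle(counts_a, counts_b) -> tuple[float, float]:
    """(group-b log rate ratio, LRT p) for a two-group Poisson model.

    The MLE of each group's mean is the sample mean, so the maximised
    log-likelihoods have closed forms.
    """
    from scipy.stats import chi2

    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    both = np.concatenate([a, b])

    def loglik(x, mu):
        if mu == 0:
            return 0.0 if np.all(x == 0) else -np.inf
        return float((x * math.log(mu) - mu).sum())

    ll_full = loglik(a, a.mean()) + loglik(b, b.mean())
    ll_null = loglik(both, both.mean())
    lr = 2.0 * (ll_full - ll_null)
    coef = (math.log(b.mean() / a.mean())
            if a.mean() > 0 and b.mean() > 0 else math.inf)
    return coef, float(chi2.sf(max(lr, 0.0), df=1))


def threshold_pp_quadrature(tree, traits, grid_n: int = 1201,
                            lim: float = 9.0) -> dict[str, float]:
    """P(liability > 0) per internal node by grid message passing.

    Liabilities live on a uniform grid; upward messages integrate the
    Brownian transition density against the child messages, the root
    takes a flat prior, and a downward pass yields every internal
    marginal.  Tips constrain their half-line (uncertain tips are
    uninformative).
    """
    xs = np.linspace(-lim, lim, grid_n)
    dx = xs[1] - xs[0]

    def kernel(t: float) -> np.ndarray:
        return (np.exp(-((xs[None, :] - xs[:, None]) ** 2) / (2 * t))
                / math.sqrt(2 * math.pi * t))

    up: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            state = traits[node.label]
            up[id(node)] = ((xs > 0).astype(float) if state == "HYPHAL"
                            else (xs <= 0).astype(float)
                            if state == "NON_HYPHAL" else np.ones_like(xs))
        else:
            m = np.ones_like(xs)
            for child in node.children:
                m = m * (kernel(child.length) @ up[id(child)]) * dx
            up[id(node)] = m

    down: dict[int, np.ndarray] = {id(tree.root): np.ones_like(xs)}
    pps: dict[str, float] = {}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        marginal = up[id(node)] * down[id(node)]
        marginal = marginal / (marginal.sum() * dx)
        pps[node.id] = float(marginal[xs > 0].sum() * dx)
        for child in node.children:
            sibs = np.ones_like(xs)
            for other in node.children:
                if other is not child:
                    sibs = sibs * (kernel(other.length) @ up[id(other)]) * dx
            parent_part = down[id(node)] * sibs
            down[id(child)] = (kernel(child.length).T @ parent_part) * dx
    return pps


def reconcile_oracle(gene_newick: str, species_newick: str
                     ) -> tuple[dict[str, int], int]:
    """LCA reconciliation rebuilt on dendropy structures.

    Returns (duplications per species-node label, total loss count).
    Losses use the path-length formula: for a gene edge with parent
    mapped to S and child to C, losses = depth(C) - depth(S) - 1, plus
    one more if the parent is a duplication and C != S.
    """
    stree = dendropy.Tree.get(data=species_newick, schema="newick",
                              preserve_underscores=True)
    gtree = dendropy.Tree.get(data=gene_newick, schema="newick",
                              preserve_underscores=True)

    clade: dict[int, frozenset] = {}
    depth: dict[int, int] = {}
    for nd in stree.postorder_node_iter():
        if nd.is_leaf():
            clade[id(nd)] = frozenset([nd.taxon.label])
        else:
            clade[id(nd)] = frozenset().union(
                *(clade[id(c)] for c in nd.child_nodes()))
    for nd in stree.preorder_node_iter():
        depth[id(nd)] = (0 if nd.parent_node is None
                         else depth[id(nd.parent_node)] + 1)

    def smallest_containing(species: frozenset):
        best = None
        for nd in stree.preorder_node_iter():
            if species <= clade[id(nd)]:
                if best is None or len(clade[id(nd)]) < len(clade[id(best)]):
                    best = nd
        return best

    mapping: dict[int, object] = {}
    species_below: dict[int, frozenset] = {}
    for nd in gtree.postorder_node_iter():
        if nd.is_leaf():
            sp = nd.taxon.label.split("|", 1)[0]
            species_below[id(nd)] = frozenset([sp])
        else:
            species_below[id(nd)] = frozenset().union(
                *(species_below[id(c)] for c in nd.child_nodes()))
        mapping[id(nd)] = smallest_containing(species_below[id(nd)])

    dups: dict[str, int] = {}
    losses = 0
    for nd in gtree.preorder_node_iter():
        if nd.is_leaf():
            continue
        is_dup = any(mapping[id(c)] is mapping[id(nd)]
                     for c in nd.child_nodes())
        if is_dup:
            m = mapping[id(nd)]
            label = m.taxon.label if m.is_leaf() else m.label
            dups[label] = dups.get(label, 0) + 1
        for child in nd.child_nodes():
            d = depth[id(mapping[id(child)])] - depth[id(mapping[id(nd)])]
            losses += max(d - 1, 0)
            if is_dup and d > 0:
                losses += 1
    return dups, losses


def dollo_min_losses_oracle(tree, present: set) -> int:
    """Minimum loss count over all single-gain origins, by exhaustion.

    For each candidate origin whose clade covers every present species,
    the forced loss count is the number of maximal absent clades below
    it; the oracle returns the minimum over all candidates.
    """
    best = None
    for origin in tree.preorder():
        leaves = {l.label for l in tree.leaves_under(origin)}
        if not present <= leaves:
            continue

        def absent_clades(node) -> int:
            sub = {l.label for l in tree.leaves_under(node)}
            if not sub & present:
                return 1
            return sum(absent_clades(c) for c in node.children)

        cost = sum(absent_clades(c) for c in origin.children)
        if best is None or cost < best:
            best = cost
    return best
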