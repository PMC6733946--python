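"""Bayesian ancestral state reconstruction under the threshold model.

A binary trait (hyphal / non-hyphal growth) is modelled as the sign of a
continuous latent liability that evolves along the tree by Brownian
motion.  Tip liabilities are constrained to the half-line matching the
observed state (tips coded uncertain are unconstrained); ancestral
liabilities are sampled by Metropolis-within-Gibbs — here the full
conditionals are conjugate normals, so every update is an exact Gibbs
draw.  The posterior probability of the hyphal state at a node ("PP")
is the fraction of post-burn-in samples with positive liability.

Because the liability scale of a binary trait is unidentifiable, the
diffusion rate is fixed at 1 and the threshold at 0.  The root carries
an improper flat prior, realised through its Gibbs conditional on its
children.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .phylo_core import SpeciesTree

__all__ = ["HYPHAL", "NON_HYPHAL", "UNCERTAIN", "ASRResult",
           "ancthresh_mcmc", "read_trait_table"]

HYPHAL = "HYPHAL"
NON_HYPHAL = "NON_HYPHAL"
UNCERTAIN = "UNCERTAIN"
_STATES = (HYPHAL, NON_HYPHAL, UNCERTAIN)


@dataclass
class ASRResult:
    """Posterior state probabilities per internal node, plus chain metadata."""

    pp: pd.DataFrame  # index: internal node id; columns: PP_hyphal, PP_nonhyphal
    generations: int
    burnin_fraction: float
    seed: int
    trace: np.ndarray  # per-generation joint log-density of the liabilities

    def pp_hyphal(self, node_id: str) -> float:
        return float(self.pp.loc[node_id, "PP_hyphal"])


def _sample_truncated_positive(mean: float, sd: float, rng) -> float:
    """Draw from N(mean, sd^2) conditioned on being > 0."""
    a = -mean / sd  # lower bound in standard units
    if a < 5.0:
        p = ndtr(a)
        z = ndtri(p + rng.random() * (1.0 - p))
        if math.isfinite(z):
            return mean + sd * z
        a = max(a, 5.0)
    # deep lower tail: exponential rejection (Robert 1995)
    alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
    while True:
        z = a + rng.standard_exponential() / alpha
        if rng.random() <= math.exp(-0.5 * (z - alpha) ** 2):
            return mean + sd * z


def ancthresh_mcmc(tree: SpeciesTree, traits: Mapping[str, str],
                   generations: int = 100_000, burnin_fraction: float = 0.2,
                   seed: int = 0,
                   root_prior: tuple[float, float] | None = None
                   ) -> ASRResult:
    """Sample ancestral liabilities and return per-node PPs.

    Each generation sweeps every node once.  An internal node's full
    conditional given its neighbours (parent and children, Brownian rate
    1) is normal with precision sum(1/t_i) and mean the precision-weighted
    average of neighbour liabilities; constrained tips are drawn from the
    correspondingly truncated normal given their parent.

    By default the root liability carries an improper flat prior,
    realised through its conditional on its children.  ``root_prior``
    = (mean, variance) substitutes a proper Gaussian prior instead —
    required, e.g., for calibration studies where the generative root
    liability is itself drawn from that Gaussian.
    """
    if generations < 1000:
        raise ValueError("generations must be >= 1000")
    if not 0.0 <= burnin_fraction < 1.0:
        raise ValueError("burnin_fraction must lie in [0, 1)")
    leaves = tree.leaves()
    for leaf in leaves:
        if leaf.label not in traits:
            raise KeyError(f"no trait entry for species {leaf.label!r}")
        if traits[leaf.label] not in _STATES:
            raise ValueError(
                f"state {traits[leaf.label]!r} for {leaf.label!r} not one of "
                f"{_STATES}")
    for node in tree.branches():
        if node.length is None or node.length <= 0:
            raise ValueError(
                f"branch to {node.id!r} must have positive length")

    nodes = list(tree.preorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    blen = np.ones(n)
    constraint = np.zeros(n, dtype=int)  # +1 positive, -1 non-positive
    neighbors: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, node in enumerate(nodes):
        if node.parent is not None:
            parent[i] = index[id(node.parent)]
            blen[i] = node.length
            neighbors[i].append((parent[i], node.length))
        for child in node.children:
            neighbors[i].append((index[id(child)], child.length))
        if node.is_leaf:
            state = traits[node.label]
            constraint[i] = {HYPHAL: 1, NON_HYPHAL: -1, UNCERTAIN: 0}[state]

    rng = np.random.default_rng(seed)
    lia = np.zeros(n)
    lia[constraint == 1] = 1.0
    lia[constraint == -1] = -1.0

    internal = [i for i, nd in enumerate(nodes) if not nd.is_leaf]
    burnin = int(round(burnin_fraction * generations))
    pos_counts = np.zeros(n, dtype=np.int64)
    trace = np.empty(generations)
    child_idx = np.array([i for i in range(n) if parent[i] >= 0])
    child_par = parent[child_idx]
    child_len = blen[child_idx]

    root_prec = root_mean_term = 0.0
    if root_prior is not None:
        mu0, var0 = root_prior
        if var0 <= 0:
            raise ValueError("root_prior variance must be positive")
        root_prec = 1.0 / var0
        root_mean_term = mu0 / var0

    for g in range(generations):
        for i in range(n):
            nbrs = neighbors[i]
            prec = 0.0
            wsum = 0.0
            if parent[i] < 0:
                prec = root_prec
                wsum = root_mean_term
            for j, t in nbrs:
                w = 1.0 / t
                prec += w
                wsum += w * lia[j]
            mean = wsum / prec
            sd = math.sqrt(1.0 / prec)
            c = constraint[i]
            if c == 0:
                lia[i] = mean + sd * rng.standard_normal()
            elif c == 1:
                lia[i] = _sample_truncated_positive(mean, sd, rng)
            else:
                lia[i] = -_sample_truncated_positive(-mean, sd, rng)
        if g >= burnin:
            pos_counts[lia > 0] += 1
        diffs = lia[child_idx] - lia[child_par]
        trace[g] = -0.5 * float(
            np.sum(diffs * diffs / child_len + np.log(2 * math.pi * child_len)))

    kept = generations - burnin
    rows = {}
    for i in internal:
        pp = pos_counts[i] / kept
        rows[nodes[i].id] = (pp, 1.0 - pp)
    ppf = pd.DataFrame.from_dict(
        rows, orient="index", columns=["PP_hyphal", "PP_nonhyphal"])
    return ASRResult(pp=ppf, generations=generations,
                     burnin_fraction=burnin_fraction, seed=seed, trace=trace)


def read_trait_table(path) -> dict[str, str]:
    """Read a TSV trait file with columns (species, state)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"species", "state"}.issubset(df.columns):
        raise ValueError("trait table must have columns: species, state")
    return dict(zip(df["species"], df["state"].str.upper()))
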