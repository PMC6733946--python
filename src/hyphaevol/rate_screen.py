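"""Genome-wide screen for gene families whose duplication dynamics track
the origin of hyphal multicellularity.

For each family, duplications per branch are converted to rates (events
per unit branch length) on the pre-origin / origin / post-origin
partition of internal branches; terminal branches and the excluded
outgroup are never counted.  A permutation ANOVA (one-way across the
three node classes, treatment df = 2) asks whether the family's rate on
origin branches departs from exchangeability; a family is a screen
candidate when it is conserved in most filamentous taxa AND either its
Dollo origin maps to an origin node or its origin-branch rate is both
significantly non-exchangeable and strictly the largest class mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .phylo_core import BranchClass, SpeciesTree
from .dollo import EventMap
from .contrasts import bh_adjust

__all__ = [
    "RateTable",
    "ScreenResult",
    "branch_duplication_rates",
    "permutation_anova",
    "conservation_filter",
    "run_screen",
]

_INCLUDED = (BranchClass.PRE_ORIGIN, BranchClass.ORIGIN, BranchClass.POST_ORIGIN)

ORIGIN_IN_BCZ = "ORIGIN_IN_BCZ"
ELEVATED_RATE = "ELEVATED_RATE"


@dataclass
class RateTable:
    """Per-family duplication rates on the included internal branches."""

    branches: list[str]
    lengths: np.ndarray
    classes: list[BranchClass]
    rates: pd.DataFrame  # families x branches

    def class_labels(self) -> np.ndarray:
        return np.array([c.value for c in self.classes])


@dataclass
class ScreenResult:
    family: str
    F: float
    p: float
    q: float
    mean_rates: dict[str, float]
    conserved: bool
    origin_node: str
    candidate: bool
    reason: Optional[str]


def branch_duplication_rates(events: EventMap, stree: SpeciesTree,
                             classification: Mapping[str, BranchClass]
                             ) -> RateTable:
    """Duplications / branch length for every included internal branch.

    Terminal branches and the excluded outgroup clade are dropped before
    any rate is formed.  A zero-length included branch is an error: a
    rate is undefined there and silently flooring the length would bias
    the screen, so the user must resolve it explicitly.
    """
    branches = [n for n in stree.branches()
                if classification[n.id] in _INCLUDED]
    zero = [n.id for n in branches if not n.length or n.length <= 0]
    if zero:
        raise ValueError(
            f"included branches with non-positive length: {sorted(zero)}; "
            "collapse them or assign an explicit floor before screening")
    lengths = np.array([n.length for n in branches], dtype=float)
    ids = [n.id for n in branches]
    data = {}
    for ev in events:
        dups = np.array([ev.duplications.get(b, 0) for b in ids], dtype=float)
        data[ev.family] = dups / lengths
    rates = pd.DataFrame(data, index=ids).T
    return RateTable(branches=ids, lengths=lengths,
                     classes=[classification[b] for b in ids], rates=rates)


def _one_way_f(values: np.ndarray, codes: np.ndarray, n_groups: int
               ) -> float:
    """Closed-form one-way ANOVA F (between-class MS / within-class MS)."""
    n = values.size
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        grp = values[codes == g]
        if grp.size == 0:
            continue
        m = grp.mean()
        ss_between += grp.size * (m - grand) ** 2
        ss_within += float(((grp - m) ** 2).sum())
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within == 0.0:
        return 0.0 if ss_between == 0.0 else np.inf
    return (ss_between / df_b) / (ss_within / df_w)


def permutation_anova(rates: Sequence[float], classes: Sequence[str],
                      n_perm: int = 999, seed: int = 0
                      ) -> tuple[float, float]:
    """One-way permutation ANOVA of branch rates across node classes.

    F is the usual between/within mean-square ratio (three classes give
    treatment df = 2); its null distribution is obtained by uniformly
    permuting class labels across branches.  p uses the add-one
    estimator (1 + #{F* >= F}) / (1 + n_perm), so it can never be 0.
    Empty classes are dropped with a warning (df adjusts); identical
    rates short-circuit to F = 0, p = 1.
    """
    values = np.asarray(rates, dtype=float)
    labels = np.asarray(classes)
    if values.size != labels.size:
        raise ValueError("rates and classes must have equal length")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    present = pd.unique(labels)
    if present.size < 2 or values.size < 2:
        raise ValueError("need >= 2 branches in >= 2 classes")
    levels = {lab: i for i, lab in enumerate(present)}
    codes = np.array([levels[l] for l in labels])
    if np.all(values == values[0]):
        return 0.0, 1.0
    n_groups = len(levels)
    f_obs = _one_way_f(values, codes, n_groups)
    rng = np.random.default_rng(seed)
    # permutations leave the total SS fixed, so only the between-class SS
    # needs recomputing: SSW = SST - SSB
    grand = values.mean()
    sst = float(((values - grand) ** 2).sum())
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    ssb = np.zeros(n_perm)
    for g in range(n_groups):
        mask = perms == g
        n_g = mask.sum(axis=1)
        s_g = mask @ values
        ssb += np.where(n_g > 0, (s_g - n_g * grand) ** 2 / np.maximum(n_g, 1),
                        0.0)
    df_b = n_groups - 1
    df_w = values.size - n_groups
    ssw = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore"):
        f_perm = (ssb / df_b) / (ssw / df_w)
    exceed = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (1 + exceed) / (1 + n_perm)
    return float(f_obs), float(p)


def conservation_filter(copy_matrix: pd.DataFrame,
                        filamentous_taxa: Iterable[str],
                        stree: SpeciesTree,
                        threshold: float = 0.7) -> pd.Series:
    """Is each family retained (>= 1 copy) in >= threshold of the
    filamentous taxa?  The boundary is inclusive: exactly 70% passes."""
    taxa = list(filamentous_taxa)
    if not taxa:
        raise ValueError("filamentous taxon set is empty")
    leaf_ids = {l.label: l.id for l in stree.leaves()}
    missing = [t for t in taxa if t not in leaf_ids]
    if missing:
        raise KeyError(f"filamentous taxa not in tree: {missing}")
    rows = [leaf_ids[t] for t in taxa]
    frac = (copy_matrix.loc[rows] >= 1).mean(axis=0)
    return frac >= threshold


def run_screen(events: EventMap, copy_matrix: pd.DataFrame,
               stree: SpeciesTree,
               classification: Mapping[str, BranchClass],
               filamentous_taxa: Iterable[str],
               alpha: float = 0.05, n_perm: int = 999, seed: int = 0,
               conservation_threshold: float = 0.7) -> pd.DataFrame:
    """Run the full candidate screen and return one row per family.

    candidate = conserved AND (origin in BCZ nodes OR (permutation
    p < alpha AND the origin-class mean rate strictly exceeds both other
    class means)).  Raw p drives the rule; BH q is reported alongside.
    Each family's permutation stream is derived from ``seed`` and the
    family's rank, so results are reproducible family-by-family.
    """
    table = branch_duplication_rates(events, stree, classification)
    labels = table.class_labels()
    conserved = conservation_filter(copy_matrix, filamentous_taxa, stree,
                                    conservation_threshold)
    origin_ids = {b for b, c in classification.items()
                  if c is BranchClass.ORIGIN}
    rng = np.random.default_rng(seed)
    rows = []
    for fam in table.rates.index:
        rates = table.rates.loc[fam].to_numpy()
        fam_seed = int(rng.integers(0, 2**31 - 1))
        F, p = permutation_anova(rates, labels, n_perm=n_perm, seed=fam_seed)
        means = {c.value: float(rates[labels == c.value].mean())
                 for c in _INCLUDED if (labels == c.value).any()}
        ev = events[fam]
        is_cons = bool(conserved.get(fam, False))
        bcz_mean = means.get(BranchClass.ORIGIN.value, 0.0)
        others = [v for k, v in means.items()
                  if k != BranchClass.ORIGIN.value]
        elevated = p < alpha and bool(others) and all(bcz_mean > v for v in others)
        in_bcz = ev.origin in origin_ids
        reason = None
        if is_cons and in_bcz:
            reason = ORIGIN_IN_BCZ
        elif is_cons and elevated:
            reason = ELEVATED_RATE
        rows.append({
            "family": fam, "F": F, "p": p,
            "mean_PRE_ORIGIN": means.get("PRE_ORIGIN", np.nan),
            "mean_ORIGIN": means.get("ORIGIN", np.nan),
            "mean_POST_ORIGIN": means.get("POST_ORIGIN", np.nan),
            "conserved": is_cons, "origin_node": ev.origin,
            "candidate": reason is not None, "reason": reason,
        })
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"])
    cols = ["family", "F", "p", "q", "mean_PRE_ORIGIN", "mean_ORIGIN",
            "mean_POST_ORIGIN", "conserved", "origin_node", "candidate",
            "reason"]
    return df[cols]
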