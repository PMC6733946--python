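"""Exact-test contrasts: duplication enrichment at the trait origin and
loss depletion in secondarily simplified (yeast-like) clades.

Both analyses reduce to two-sided Fisher exact tests on 2x2 tables of
event counts, with Benjamini–Hochberg correction applied within each
test battery.  The focal unit (family or functional category) is always
subtracted from the genome-wide background before testing, so a unit is
never compared against a background that contains it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .phylo_core import BranchClass, SpeciesTree
from .dollo import EventMap

__all__ = [
    "ContingencyResult",
    "fisher_exact_2x2",
    "bh_adjust",
    "bcz_duplication_enrichment",
    "yeast_loss_depletion",
]

ENRICHED = "ENRICHED"
DEPLETED = "DEPLETED"
NONE = "NONE"


@dataclass
class ContingencyResult:
    """A two-sided Fisher exact test on a 2x2 table.

    The odds ratio carries a 0.5 continuity correction (applied to the
    reported OR only, never to the p-value) so it stays finite with zero
    cells.  ``degenerate`` marks tables with a zero margin, for which no
    association is testable and p is 1 by convention.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    p: float
    odds_ratio: float
    direction: str
    degenerate: bool = False


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """Two-sided Fisher exact test: p sums hypergeometric probabilities of
    all tables (margins fixed) no more probable than the observed one."""
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    degenerate = (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0)
    if degenerate:
        p = 1.0
    else:
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        p = min(p, 1.0)
    oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    if degenerate or oddsr == 1.0:
        direction = NONE
    else:
        direction = ENRICHED if oddsr > 1.0 else DEPLETED
    return ContingencyResult(((a, b), (c, d)), p, oddsr, direction, degenerate)


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _branch_sets(classification: Mapping[str, BranchClass]
                 ) -> tuple[set[str], set[str]]:
    """(origin branches, all counted branches) — excluded branches dropped."""
    origin = {b for b, c in classification.items() if c is BranchClass.ORIGIN}
    counted = {b for b, c in classification.items()
               if c is not BranchClass.EXCLUDED}
    return origin, counted


def bcz_duplication_enrichment(events: EventMap,
                               classification: Mapping[str, BranchClass],
                               by: str = "family") -> pd.DataFrame:
    """Test each unit for duplication enrichment/depletion at the origin.

    For every family (or functional category, ``by="category"``) the
    duplications mapped to origin ("BCZ") branches are compared with the
    unit's duplications elsewhere, against the same split for all other
    families.  Units with no duplications anywhere are reported as NA.
    Returns one row per unit with the table cells, two-sided p, BH q and
    direction.
    """
    if by not in ("family", "category"):
        raise ValueError("by must be 'family' or 'category'")
    origin_branches, counted = _branch_sets(classification)

    def unit_counts(fams) -> tuple[int, int]:
        bcz = other = 0
        for ev in fams:
            for branch, k in ev.duplications.items():
                if branch not in counted and branch not in origin_branches:
                    continue
                if branch in origin_branches:
                    bcz += k
                else:
                    other += k
        return bcz, other

    if by == "family":
        units = {ev.family: [ev] for ev in events}
    else:
        units = {}
        for ev in events:
            if ev.category is not None:
                units.setdefault(ev.category, []).append(ev)

    genome_bcz, genome_other = unit_counts(list(events))
    rows = []
    for name in sorted(units):
        a, b = unit_counts(units[name])
        if a + b == 0:
            rows.append({"unit": name, "a": 0, "b": 0, "c": np.nan, "d": np.nan,
                         "p": np.nan, "direction": "NA",
                         "note": "no duplications"})
            continue
        c, d = genome_bcz - a, genome_other - b
        res = fisher_exact_2x2([[a, b], [c, d]])
        rows.append({"unit": name, "a": a, "b": b, "c": c, "d": d,
                     "p": res.p, "direction": res.direction, "note": ""})
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    tested = df["p"].notna()
    if tested.any():
        df.loc[tested, "q"] = bh_adjust(df.loc[tested, "p"])
    return df[["unit", "a", "b", "c", "d", "p", "q", "direction", "note"]]


def yeast_loss_depletion(events: EventMap, copy_matrix: pd.DataFrame,
                         stree: SpeciesTree,
                         clades: Sequence[tuple[str, str]],
                         categories: Mapping[str, Iterable[str]],
                         ) -> pd.DataFrame:
    """Loss depletion of gene categories in secondarily simplified clades.

    For each (clade, category): the ancestral copy count is read from the
    copy matrix at the node preceding the clade's stem node (the state
    prior to the clade's emergence); losses are summed over all branches
    of the clade including its stem.  Two percent-lost summaries are
    reported — against the ancestral count and against the mean extant
    copy number of the clade's terminals — and depletion/enrichment is
    tested on [[category losses, category retained], [background losses,
    background retained]] with the category removed from the background.
    """
    rows = []
    all_fams = [ev.family for ev in events]
    for clade_name, stem_id in clades:
        stem = stree.node(stem_id)
        if stem.parent is None:
            raise ValueError(f"clade stem {stem_id!r} must be a non-root node")
        anc_node = stem.parent.id
        clade_branches = {n.id for n in stree.preorder()
                          if stree.is_ancestor(stem, n)}
        clade_leaves = [l.id for l in stree.leaves_under(stem)]

        def stats_for(fams: list[str]) -> tuple[float, int, float]:
            anc = float(copy_matrix.loc[anc_node, fams].sum())
            losses = sum(k for ev in (events[f] for f in fams)
                         for br, k in ev.losses.items() if br in clade_branches)
            extant = float(copy_matrix.loc[clade_leaves, fams].sum(axis=1).mean())
            return anc, losses, extant

        genome_anc, genome_losses, _ = stats_for(all_fams)
        for cat_name, fam_ids in categories.items():
            fams = [f for f in fam_ids if f in events.families]
            anc, losses, extant = stats_for(fams)
            if anc == 0:
                rows.append({"clade": clade_name, "category": cat_name,
                             "ancestral": 0, "losses": losses,
                             "note": "zero ancestral copies"})
                continue
            bg_anc = genome_anc - anc
            bg_losses = genome_losses - losses
            retained = max(int(anc) - losses, 0)
            bg_retained = max(int(bg_anc) - bg_losses, 0)
            res = fisher_exact_2x2([[losses, retained],
                                    [bg_losses, bg_retained]])
            rows.append({
                "clade": clade_name, "category": cat_name,
                "ancestral": anc, "losses": losses,
                "percent_lost": 100.0 * losses / anc,
                "percent_retained_extant": 100.0 * extant / anc,
                "p": res.p, "direction": res.direction, "note": "",
            })
    df = pd.DataFrame(rows)
    if "p" in df.columns:
        tested = df["p"].notna()
        df["q"] = np.nan
        df.loc[tested, "q"] = bh_adjust(df.loc[tested, "p"])
    return df
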