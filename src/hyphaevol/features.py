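"""Gene-structure and domain-architecture statistics.

Gene models (gene / CDS / intron lengths) are extracted from GFF3
annotations, introns being the gaps between consecutive CDS segments in
genomic order.  Length contrasts between plesiomorphically unicellular
and multicellular fungi use Welch's (unpooled-variance) t-test.  Domain
architectures — the ordered tuple of domain accessions along a protein —
are inventoried per family and group with a conservation cutoff, and
per-protein domain counts are compared between groups with a Poisson
GLM and a likelihood-ratio test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import gffutils
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "GeneModel",
    "extract_gene_structures",
    "welch_t_test",
    "architecture_inventory",
    "domain_count_glm",
    "read_domain_table",
]


@dataclass
class GeneModel:
    """One gene model: 1-based inclusive coordinates, CDS in genomic order."""

    gene_id: str
    species: Optional[str]
    strand: str
    span: tuple[int, int]
    cds: list[tuple[int, int]]

    @property
    def gene_length(self) -> int:
        return self.span[1] - self.span[0] + 1

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            out.append((e1 + 1, s2 - 1))
        return out

    @property
    def intron_lengths(self) -> list[int]:
        """Intron lengths in genomic order."""
        return [e - s + 1 for s, e in self.introns]

    def intron_lengths_transcript_order(self) -> list[int]:
        """Intron lengths in transcript (5'->3') order."""
        lengths = self.intron_lengths
        return lengths[::-1] if self.strand == "-" else lengths


def extract_gene_structures(gff: str, *, from_string: bool = False,
                            species: Optional[str] = None) -> list[GeneModel]:
    """Parse a GFF3 annotation into gene models, one per gene.

    For genes with several mRNAs the longest (by genomic span, ties by
    id) is kept.  CDS features lacking a resolvable mRNA parent are
    skipped with a warning; overlapping CDS segments within one mRNA are
    an error.
    """
    db = gffutils.create_db(
        gff, dbfn=":memory:", from_string=from_string, force=True,
        merge_strategy="create_unique", keep_order=True)
    orphans = 0
    for cds in db.features_of_type("CDS"):
        if not cds.attributes.get("Parent"):
            orphans += 1
    if orphans:
        warnings.warn(f"{orphans} CDS feature(s) without Parent skipped")

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue
        mrnas.sort(key=lambda m: (-(m.end - m.start + 1), m.id))
        mrna = mrnas[0]
        segs = sorted((c.start, c.end)
                      for c in db.children(mrna, featuretype="CDS"))
        if not segs:
            continue
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping CDS segments in mRNA {mrna.id!r}: "
                    f"({s1},{e1}) and ({s2},{e2})")
        models.append(GeneModel(
            gene_id=gene.id, species=species, strand=gene.strand,
            span=(gene.start, gene.end), cds=segs))
    return models


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]
                 ) -> tuple[float, float, float]:
    """Welch's two-sided t-test: (t, Welch–Satterthwaite df, p).

    Variances are never pooled.  Two identical constant groups return
    (0, df, 1) rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both variances zero with unequal means: t undefined")
    se2a, se2b = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (se2a ** 2 / (a.size - 1)
                               + se2b ** 2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def read_domain_table(path) -> pd.DataFrame:
    """Read a TSV domain-annotation table.

    Columns: protein, species, group, family, domains (ordered,
    comma-separated accessions).  An ``architecture`` tuple column is
    derived.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein", "species", "group", "family", "domains"}
    if not required.issubset(df.columns):
        raise ValueError(f"domain table needs columns {sorted(required)}")
    df["architecture"] = df["domains"].map(
        lambda s: tuple(s.split(",")) if isinstance(s, str) and s else ())
    return df


def architecture_inventory(arch: pd.DataFrame,
                           conservation_threshold: float = 0.7
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(family, group) architecture frequencies with a conservation rule.

    An architecture is retained within its group only when it occurs in
    at least ``conservation_threshold`` of that group's species carrying
    the family (the boundary is inclusive).  Architectures are
    order-sensitive: (A,B) and (B,A) are distinct.  Returns the retained
    frequency table and a per-family indicator of architecture change
    (a retained architecture present in one group but not the other).
    """
    if "architecture" not in arch.columns:
        arch = arch.assign(architecture=arch["domains"].map(
            lambda s: tuple(s.split(",")) if isinstance(s, str) and s else ()))
    arch = arch[arch["architecture"].map(len) > 0]
    rows = []
    changes = []
    for family, fam_df in arch.groupby("family", sort=True):
        if fam_df.empty:
            warnings.warn(f"family {family!r} has no annotated proteins")
            continue
        retained_by_group: dict[str, set] = {}
        for group, grp_df in fam_df.groupby("group", sort=True):
            n_species = grp_df["species"].nunique()
            by_arch = grp_df.groupby("architecture")["species"].nunique()
            for architecture, n_sp in by_arch.items():
                frac = n_sp / n_species
                if frac >= conservation_threshold:
                    retained_by_group.setdefault(group, set()).add(architecture)
                    rows.append({
                        "family": family, "group": group,
                        "architecture": ",".join(architecture),
                        "n_species": int(n_sp), "fraction": frac,
                    })
        groups = sorted(retained_by_group)
        changed = False
        if len(groups) == 2:
            s1, s2 = (retained_by_group[g] for g in groups)
            changed = bool(s1 ^ s2)
        changes.append({"family": family, "architecture_change": changed})
    freq = pd.DataFrame(
        rows, columns=["family", "group", "architecture", "n_species",
                       "fraction"])
    return freq, pd.DataFrame(changes, columns=["family",
                                                "architecture_change"])


def domain_count_glm(arch: pd.DataFrame, *, group_order: Optional[
        Sequence[str]] = None) -> pd.DataFrame:
    """Per-family Poisson regression of domain count on group.

    Fits log E[count] = b0 + b1 * group for every family with at least
    two proteins per group and tests b1 = 0 by likelihood ratio against
    the intercept-only model.  The coefficient is positive when the
    second group (multicellular, by default the lexicographically later
    label) carries more domains.  Families with no count variation are
    reported with a degenerate flag and p = 1, never a crash.
    """
    if "architecture" not in arch.columns:
        arch = arch.assign(architecture=arch["domains"].map(
            lambda s: tuple(s.split(",")) if isinstance(s, str) and s else ()))
    rows = []
    for family, fam_df in arch.groupby("family", sort=True):
        counts = fam_df["architecture"].map(len).to_numpy(dtype=float)
        groups = fam_df["group"].to_numpy()
        labels = (list(group_order) if group_order is not None
                  else sorted(pd.unique(groups)))
        if len(labels) != 2:
            continue
        n0 = int((groups == labels[0]).sum())
        n1 = int((groups == labels[1]).sum())
        if n0 < 2 or n1 < 2:
            continue
        x = (groups == labels[1]).astype(float)
        if np.all(counts == counts[0]):
            rows.append({"family": family, "coef": 0.0, "p": 1.0,
                         "n": n0 + n1, "degenerate": True})
            continue
        exog = sm.add_constant(x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = sm.GLM(counts, exog,
                              family=sm.families.Poisson()).fit()
                null = sm.GLM(counts, np.ones((counts.size, 1)),
                              family=sm.families.Poisson()).fit()
            lr = 2.0 * (full.llf - null.llf)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            coef = float(full.params[1])
            degenerate = not np.isfinite(coef) or abs(coef) > 20
            if degenerate:
                p = 1.0
        except Exception:
            coef, p, degenerate = 0.0, 1.0, True
        rows.append({"family": family, "coef": coef, "p": p,
                     "n": n0 + n1, "degenerate": degenerate})
    return pd.DataFrame(rows, columns=["family", "coef", "p", "n",
                                       "degenerate"])
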