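"""Config-driven orchestration of the full analysis.

Stages: branch classification -> reconciliation -> Dollo event mapping ->
ancestral copy numbers -> threshold-model ASR -> enrichment contrasts ->
rate screen -> feature statistics.  Every stage that has its inputs
configured runs and writes a TSV; a run log captures the configuration,
seed, package versions and stage timings, and a summary records the
headline counts (families per origin epoch, the share with origin-node
duplications, screen candidates).  Any stage failure aborts with the
stage name attached.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .phylo_core import (BranchClass, classification_to_frame,
                         classify_branches, parse_newick)
from .reconciliation import (collapse_weak_edges, lca_reconcile,
                             parse_gene_tree, resolve_polytomies_min_dup)
from .dollo import (EventMap, ancestral_copy_numbers, build_event_map,
                    read_family_table)
from .threshold_asr import ancthresh_mcmc, read_trait_table
from .contrasts import bcz_duplication_enrichment, yeast_loss_depletion
from .rate_screen import conservation_filter, run_screen
from .features import (architecture_inventory, domain_count_glm,
                       extract_gene_structures, read_domain_table)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "fraction_pct",
           "origin_epoch_summary"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    """Inputs, constants and thresholds for one pipeline run.

    The defaults mirror the analysis constants: support threshold 0.9
    for collapsing weak gene-tree edges, conservation in at least 70% of
    filamentous taxa, and alpha = 0.05 throughout.
    """

    species_tree: str = ""
    families: str = ""
    gene_trees_dir: Optional[str] = None
    traits: Optional[str] = None
    gff_dir: Optional[str] = None
    domains: Optional[str] = None
    origin_nodes: list = field(default_factory=list)
    outgroup_root: Optional[str] = None
    filamentous_taxa: list = field(default_factory=list)
    yeast_clades: dict = field(default_factory=dict)  # name -> stem node id
    alpha: float = 0.05
    support_threshold: float = 0.9
    conservation_threshold: float = 0.7
    mcmc_generations: int = 100_000
    burnin_fraction: float = 0.2
    n_perm: int = 999
    seed: int = 0
    outdir: str = "hyphaevol_out"

    def __post_init__(self):
        for name in ("support_threshold", "conservation_threshold",
                     "burnin_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def fraction_pct(part: float, total: float, decimals: int = 1) -> float:
    """A share as a percentage, rounded as printed (one decimal)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * part / total, decimals)


def origin_epoch_summary(events: EventMap, classification, stree
                         ) -> dict[str, int]:
    """Families per origin epoch relative to the designated origin nodes.

    ``pre``: origin at the root or on a pre-origin branch; ``origin``:
    at a designated origin node; ``post``: anywhere else in the in-group.
    """
    counts = {"pre": 0, "origin": 0, "post": 0}
    root_id = stree.root.id
    for ev in events:
        if ev.origin == root_id:
            counts["pre"] += 1
            continue
        cls = classification.get(ev.origin)
        if cls is BranchClass.ORIGIN:
            counts["origin"] += 1
        elif cls is BranchClass.PRE_ORIGIN:
            counts["pre"] += 1
        else:
            counts["post"] += 1
    return counts


def _require(path: Optional[str], what: str) -> Path:
    if not path:
        raise PipelineError(f"config missing required input: {what}")
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"{what} not found: {p}")
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns the summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    summary: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage {name!r} failed: {exc}") \
                        from exc
        return _Timer()

    with stage("load"):
        tree = parse_newick(_require(config.species_tree,
                                     "species tree").read_text())
        families = read_family_table(_require(config.families,
                                              "family table"))
        classification = classify_branches(tree, config.origin_nodes,
                                           config.outgroup_root)
        classification_to_frame(tree, classification).to_csv(
            out / "classification.tsv", sep="\t", index=False)

    with stage("reconcile"):
        reconciliations = {}
        if config.gene_trees_dir:
            tree_dir = _require(config.gene_trees_dir, "gene tree directory")
            for fam in families:
                path = tree_dir / f"{fam.id}.nwk"
                if not path.exists():
                    continue
                gtree = parse_gene_tree(path.read_text())
                gtree = collapse_weak_edges(gtree, config.support_threshold)
                gtree = resolve_polytomies_min_dup(gtree, tree)
                reconciliations[fam.id] = lca_reconcile(gtree, tree)

    with stage("dollo"):
        events = build_event_map(families, reconciliations, tree)
        events.to_frame().to_csv(out / "events.tsv", sep="\t", index=False)
        copy_matrix = ancestral_copy_numbers(events, tree)
        copy_matrix.to_csv(out / "copy_matrix.tsv", sep="\t")

    if config.traits:
        with stage("asr"):
            traits = read_trait_table(_require(config.traits, "trait table"))
            asr = ancthresh_mcmc(tree, traits,
                                 generations=config.mcmc_generations,
                                 burnin_fraction=config.burnin_fraction,
                                 seed=config.seed)
            asr.pp.rename_axis("node").to_csv(out / "asr.tsv", sep="\t")
            origin_pps = {n: round(asr.pp_hyphal(n), 3)
                          for n in config.origin_nodes if n in asr.pp.index}
            summary["asr_pp_hyphal_origin_nodes"] = origin_pps

    with stage("enrich"):
        fam_enrich = bcz_duplication_enrichment(events, classification,
                                                by="family")
        fam_enrich.to_csv(out / "enrichment_family.tsv", sep="\t",
                          index=False)
        if any(f.category for f in families):
            cat_enrich = bcz_duplication_enrichment(events, classification,
                                                    by="category")
            cat_enrich.to_csv(out / "enrichment_category.tsv", sep="\t",
                              index=False)

    if config.yeast_clades:
        with stage("losses"):
            categories: dict[str, list[str]] = {}
            for fam in families:
                if fam.category:
                    categories.setdefault(fam.category, []).append(fam.id)
            if categories:
                report = yeast_loss_depletion(
                    events, copy_matrix, tree,
                    list(config.yeast_clades.items()), categories)
                report.to_csv(out / "loss_report.tsv", sep="\t", index=False)

    screen = None
    if config.filamentous_taxa:
        with stage("screen"):
            screen = run_screen(events, copy_matrix, tree, classification,
                                config.filamentous_taxa, alpha=config.alpha,
                                n_perm=config.n_perm, seed=config.seed,
                                conservation_threshold=(
                                    config.conservation_threshold))
            screen.to_csv(out / "screen.tsv", sep="\t", index=False)

    if config.gff_dir or config.domains:
        with stage("features"):
            if config.gff_dir:
                gff_dir = _require(config.gff_dir, "annotation directory")
                rows = []
                for path in sorted(gff_dir.glob("*.gff3")):
                    for gm in extract_gene_structures(str(path),
                                                      species=path.stem):
                        rows.append({
                            "species": gm.species, "gene": gm.gene_id,
                            "gene_length": gm.gene_length,
                            "cds_length": gm.cds_length,
                            "n_introns": len(gm.introns),
                            "total_intron_length": sum(gm.intron_lengths),
                        })
                pd.DataFrame(rows).to_csv(out / "gene_structures.tsv",
                                          sep="\t", index=False)
            if config.domains:
                arch = read_domain_table(_require(config.domains,
                                                  "domain table"))
                freq, changes = architecture_inventory(
                    arch, config.conservation_threshold)
                freq.to_csv(out / "architectures.tsv", sep="\t", index=False)
                changes.to_csv(out / "architecture_changes.tsv", sep="\t",
                               index=False)
                domain_count_glm(arch).to_csv(out / "domain_glm.tsv",
                                              sep="\t", index=False)

    with stage("summary"):
        n_fam = len(events)
        epochs = origin_epoch_summary(events, classification, tree)
        origin_ids = {b for b, c in classification.items()
                      if c is BranchClass.ORIGIN}
        with_bcz_dups = sum(
            1 for ev in events
            if any(b in origin_ids for b in ev.duplications))
        summary.update({
            "n_families": n_fam,
            "families_pre_origin": epochs["pre"],
            "families_origin": epochs["origin"],
            "families_post_origin": epochs["post"],
            "pct_pre_origin": fraction_pct(epochs["pre"], n_fam),
            "pct_origin": fraction_pct(epochs["origin"], n_fam),
            "pct_post_origin": fraction_pct(epochs["post"], n_fam),
            "families_with_origin_duplications": with_bcz_dups,
            "pct_with_origin_duplications": fraction_pct(with_bcz_dups,
                                                         n_fam),
        })
        if config.filamentous_taxa:
            conserved = conservation_filter(
                copy_matrix, config.filamentous_taxa, tree,
                config.conservation_threshold)
            born_conserved = sum(
                1 for ev in events
                if ev.origin in origin_ids and bool(conserved.get(ev.family)))
            summary["families_origin_born_conserved"] = born_conserved
            summary["pct_origin_born_conserved"] = fraction_pct(
                born_conserved, n_fam)
        if screen is not None:
            summary["screen_candidates"] = int(screen["candidate"].sum())
            summary["screen_origin_in_bcz"] = int(
                (screen["reason"] == "ORIGIN_IN_BCZ").sum())
            summary["screen_elevated_rate"] = int(
                (screen["reason"] == "ELEVATED_RATE").sum())

    log = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "timings_s": timings,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
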