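from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from scipy import stats as sps

from hyphaevol.dollo import EventMap, FamilyEvents, GeneFamily, \
    ancestral_copy_numbers, build_event_map
from hyphaevol.phylo_core import BranchClass, classify_branches, parse_newick
from hyphaevol.rate_screen import (branch_duplication_rates,
                                   conservation_filter, permutation_anova,
                                   run_screen)
from hyphaevol.reconciliation import lca_reconcile
from hyphaevol.synthetic_data import (SimulationConfig,
                                      designate_origin_nodes,
                                      simulate_family_evolution,
                                      simulate_species_tree)

from oracles import one_way_f_oracle

TREE = "((((A:1,B:1)AB:0.5,C:1)ABC:0.5,D:1)ABCD:0.5,E:2)R;"


def _screen_inputs(elevation, lambda_dup, n_families, seed, n_taxa=16):
    tree = simulate_species_tree(n_taxa, seed=5)
    origins = designate_origin_nodes(tree, 3, skip=2)
    classification = classify_branches(tree, origins)
    config = SimulationConfig(origin_elevation=elevation,
                              lambda_dup=lambda_dup,
                              gain_nodes=[tree.root.id])
    truth = simulate_family_evolution(tree, classification, config,
                                      n_families, seed)
    families = [GeneFamily(f.id, f.members, f.gene_tree)
                for f in truth.families]
    recs = {f.id: lca_reconcile(f.gene_tree, tree)
            for f in truth.families if f.gene_tree is not None}
    events = build_event_map(families, recs, tree)
    copies = ancestral_copy_numbers(events, tree)
    return tree, classification, events, copies


class TestBranchRates:
    def test_rate_arithmetic_and_exclusions(self):
        tree = parse_newick(TREE)
        classification = classify_branches(tree, {"ABC", "AB"})
        ev = FamilyEvents("f", "R", Counter({"ABC": 4, "A": 7}))
        table = branch_duplication_rates(EventMap({"f": ev}), tree,
                                         classification)
        assert table.rates.loc["f", "ABC"] == pytest.approx(4 / 0.5)
        assert "A" not in table.branches  # terminal dups never rated
        assert set(table.branches) == {"ABCD", "ABC", "AB"}

    def test_excluded_outgroup_absent(self):
        tree = parse_newick(TREE)
        classification = classify_branches(tree, {"AB"},
                                           outgroup_root="ABC")
        ev = FamilyEvents("f", "R")
        table = branch_duplication_rates(EventMap({"f": ev}), tree,
                                         classification)
        assert set(table.branches) == {"ABCD"}

    def test_zero_length_branch_is_an_error(self):
        tree = parse_newick("(((A:1,B:1)AB:0,C:1)ABC:1,D:1)R;")
        classification = classify_branches(tree, {"ABC"})
        ev = FamilyEvents("f", "R")
        with pytest.raises(ValueError, match="non-positive length"):
            branch_duplication_rates(EventMap({"f": ev}), tree,
                                     classification)


class TestPermutationAnova:
    def test_identical_rates_null(self):
        F, p = permutation_anova([1.0] * 9, ["a", "b", "c"] * 3,
                                 n_perm=199, seed=0)
        assert F == 0.0
        assert p == 1.0

    def test_perfect_separation_attains_minimum(self):
        rates = [0.0, 0.0, 0.0, 10.0, 10.0, 10.0, 20.0, 20.0, 20.0]
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        F, p = permutation_anova(rates, labels, n_perm=999, seed=1)
        # of the 9!/(3!3!3!) = 1680 label arrangements only the observed
        # one (up to class renaming) maximises F; with the add-one
        # estimator and finite resampling p lands near its floor
        assert p < 0.02

    def test_f_matches_closed_form(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            values = rng.gamma(2.0, 2.0, size=12)
            labels = rng.choice(["pre", "origin", "post"], size=12)
            if len(set(labels)) < 2:
                continue
            F, _ = permutation_anova(values, labels, n_perm=99, seed=3)
            assert F == pytest.approx(one_way_f_oracle(values, labels),
                                      rel=1e-10)
            groups = [values[labels == g] for g in np.unique(labels)]
            assert F == pytest.approx(sps.f_oneway(*groups).statistic,
                                      rel=1e-9)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(11)
        values = rng.exponential(1.0, size=10)
        labels = (["pre"] * 3 + ["origin"] * 3 + ["post"] * 4)
        _, p1 = permutation_anova(values, labels, n_perm=499, seed=5)
        _, p2 = permutation_anova(values * 1000.0, labels, n_perm=499,
                                  seed=5)
        assert p1 == p2

    def test_type_one_error_under_exchangeable_null(self):
        """i.i.d. rates with arbitrary labels reject at about alpha."""
        rng = np.random.default_rng(23)
        labels = ["pre"] * 2 + ["origin"] * 3 + ["post"] * 7
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            values = rng.gamma(1.5, 1.0, size=len(labels))
            _, p = permutation_anova(values, labels, n_perm=199,
                                     seed=int(rng.integers(2**31 - 1)))
            if p < 0.05:
                rejections += 1
        rate = rejections / n_rep
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < half_width + 1e-9


class TestConservationFilter:
    def _copies(self, fractions, tree):
        import pandas as pd
        leaves = [l.id for l in tree.leaves()]
        data = {}
        for fam, frac in fractions.items():
            k = round(frac * len(leaves))
            data[fam] = [1 if i < k else 0 for i in range(len(leaves))]
        return pd.DataFrame(data, index=leaves)

    def test_inclusive_boundary(self):
        tree = simulate_species_tree(10, seed=9)
        copies = self._copies({"at70": 0.7, "below": 0.6, "full": 1.0},
                              tree)
        out = conservation_filter(copies, tree.leaf_labels(), tree, 0.7)
        assert bool(out["at70"]) is True
        assert bool(out["below"]) is False
        assert bool(out["full"]) is True

    def test_zero_threshold_always_passes(self):
        tree = simulate_species_tree(10, seed=9)
        copies = self._copies({"rare": 0.1}, tree)
        out = conservation_filter(copies, tree.leaf_labels(), tree, 0.0)
        assert bool(out["rare"]) is True

    def test_empty_taxon_set_rejected(self):
        tree = simulate_species_tree(10, seed=9)
        copies = self._copies({"f": 1.0}, tree)
        with pytest.raises(ValueError, match="empty"):
            conservation_filter(copies, [], tree)


class TestRunScreen:
    def test_origin_family_candidate_without_duplications(self):
        tree = parse_newick(TREE)
        classification = classify_branches(tree, {"ABC", "AB"})
        fams = {
            "born": FamilyEvents("born", "ABC"),
            "bg": FamilyEvents("bg", "R", Counter({"ABCD": 1})),
        }
        events = EventMap(fams)
        copies = ancestral_copy_numbers(events, tree)
        out = run_screen(events, copies, tree, classification,
                         ["A", "B", "C", "D"], n_perm=99, seed=2)
        row = out.set_index("family").loc["born"]
        assert row["candidate"]
        assert row["reason"] == "ORIGIN_IN_BCZ"

    def test_unconserved_family_never_candidate(self):
        tree = parse_newick(TREE)
        classification = classify_branches(tree, {"ABC", "AB"})
        fams = {"born": FamilyEvents("born", "AB",
                                     losses=Counter({"A": 1}))}
        events = EventMap(fams)
        copies = ancestral_copy_numbers(events, tree)
        out = run_screen(events, copies, tree, classification,
                         ["A", "B"], n_perm=99, seed=2)
        assert not out["candidate"].any()

    def test_deterministic_given_seed(self):
        _, classification, events, copies = _screen_inputs(1.0, 0.5, 30, 71)
        tree = simulate_species_tree(16, seed=5)
        taxa = tree.leaf_labels()
        s1 = run_screen(events, copies, tree, classification, taxa,
                        n_perm=199, seed=13)
        s2 = run_screen(events, copies, tree, classification, taxa,
                        n_perm=199, seed=13)
        assert s1.equals(s2)

    def test_power_under_origin_elevation(self):
        """Ten-fold origin elevation sized to 20 expected origin events
        is recovered as ELEVATED_RATE for at least 80% of families."""
        tree = simulate_species_tree(16, seed=5)
        origins = designate_origin_nodes(tree, 3, skip=2)
        classification = classify_branches(tree, origins)
        origin_len = sum(tree.node(b).length for b, c in
                         classification.items()
                         if c is BranchClass.ORIGIN)
        lam = 20.0 / (10.0 * origin_len)
        _, classification, events, copies = _screen_inputs(
            10.0, lam, 200, 81)
        out = run_screen(events, copies, tree, classification,
                         tree.leaf_labels(), n_perm=999, seed=82)
        power = (out["reason"] == "ELEVATED_RATE").mean()
        assert power >= 0.8

    def test_null_families_rarely_candidates(self):
        """Without elevation the rate route fires at most at alpha."""
        tree = simulate_species_tree(16, seed=5)
        _, classification, events, copies = _screen_inputs(
            1.0, 3.0, 400, 91)
        out = run_screen(events, copies, tree, classification,
                         tree.leaf_labels(), n_perm=199, seed=92)
        by_rate = (out["reason"] == "ELEVATED_RATE").mean()
        assert by_rate <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / len(out))
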