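from __future__ import annotations

import pytest

from hyphaevol import (GeneFamily, ancestral_copy_numbers, build_event_map,
                       classify_branches, lca_reconcile, parse_newick)
from hyphaevol.synthetic_data import (SimulationConfig,
                                      designate_origin_nodes,
                                      simulate_family_evolution,
                                      simulate_species_tree)


@pytest.fixture
def three_taxon_tree():
    return parse_newick("((A:1,B:1)AB:1,C:2)R;")


@pytest.fixture
def balanced_four_tree():
    return parse_newick("((a:1,b:1)AB:1,(c:1,d:1)CD:1)R;")


@pytest.fixture(scope="session")
def sim_bundle():
    """A 12-taxon simulated dataset shared across tests.

    Returns (tree, origin node ids, classification, truth, event map,
    copy matrix) built from simulated families under default conditions.
    """
    tree = simulate_species_tree(12, seed=101)
    origins = designate_origin_nodes(tree, 3)
    classification = classify_branches(tree, origins)
    config = SimulationConfig()
    truth = simulate_family_evolution(tree, classification, config,
                                      n_families=200, seed=102)
    families = [GeneFamily(f.id, f.members, f.gene_tree)
                for f in truth.families]
    reconciliations = {f.id: lca_reconcile(f.gene_tree, tree)
                       for f in truth.families if f.gene_tree is not None}
    events = build_event_map(families, reconciliations, tree)
    copies = ancestral_copy_numbers(events, tree)
    return tree, origins, classification, truth, events, copies
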