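from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hyphaevol.features import (architecture_inventory, domain_count_glm,
                                extract_gene_structures, welch_t_test)
from hyphaevol.synthetic_data import SimulationConfig, simulate_features

from oracles import poisson_lrt_oracle

GFF = """##gff-version 3
chr1\ttest\tgene\t100\t400\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t100\t400\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\ttest\tCDS\t100\t200\t.\t+\t0\tParent=g1.t1
chr1\ttest\tCDS\t301\t400\t.\t+\t0\tParent=g1.t1
chr1\ttest\tgene\t1000\t1200\t.\t-\t.\tID=g2
chr1\ttest\tmRNA\t1000\t1200\t.\t-\t.\tID=g2.t1;Parent=g2
chr1\ttest\tCDS\t1000\t1200\t.\t-\t0\tParent=g2.t1
"""


class TestGeneStructures:
    def test_cds_and_intron_arithmetic(self):
        models = {m.gene_id: m for m in
                  extract_gene_structures(GFF, from_string=True)}
        g1 = models["g1"]
        assert g1.cds_length == 101 + 100
        assert g1.introns == [(201, 300)]
        assert g1.intron_lengths == [100]
        assert g1.gene_length == 301

    def test_single_cds_gene_has_no_introns(self):
        models = {m.gene_id: m for m in
                  extract_gene_structures(GFF, from_string=True)}
        assert models["g2"].intron_lengths == []

    def test_minus_strand_reverses_transcript_order_only(self):
        gff = GFF.replace(
            "ID=g1\n", "ID=g1\n").replace("\t+\t.\tID=g1",
                                          "\t-\t.\tID=g1").replace(
            "\t+\t.\tID=g1.t1", "\t-\t.\tID=g1.t1").replace(
            "\t+\t0\tParent=g1.t1", "\t-\t0\tParent=g1.t1")
        models = {m.gene_id: m for m in
                  extract_gene_structures(gff, from_string=True)}
        g1 = models["g1"]
        assert g1.introns == [(201, 300)]  # genomic coordinates unchanged
        assert g1.intron_lengths_transcript_order() == [100]

    def test_overlapping_cds_rejected(self):
        bad = GFF.replace("CDS\t301\t400", "CDS\t150\t400")
        with pytest.raises(ValueError, match="overlapping"):
            extract_gene_structures(bad, from_string=True)

    def test_invariants_on_simulated_annotations(self):
        config = SimulationConfig()
        sim = simulate_features({"unicellular": ["u1"]}, config, 30,
                                seed=5)
        for gm in extract_gene_structures(sim.gff["u1"], from_string=True):
            assert len(gm.introns) == len(gm.cds) - 1
            assert gm.gene_length == gm.cds_length + sum(gm.intron_lengths)

    def test_round_trip_of_sampled_lengths(self):
        """Parsing the generated GFF3 returns the exact sampled lengths."""
        config = SimulationConfig()
        sim = simulate_features({"multicellular": ["m1"]}, config, 40,
                                seed=6)
        models = {m.gene_id: m for m in
                  extract_gene_structures(sim.gff["m1"], from_string=True)}
        truth = sim.truth.set_index("gene")
        assert len(models) == len(truth)
        for gene, row in truth.iterrows():
            gm = models[gene]
            assert gm.gene_length == row["gene_length"]
            assert gm.cds_length == row["cds_length"]
            expected = ([int(x) for x in row["intron_lengths"].split(",")]
                        if row["intron_lengths"] else [])
            assert gm.intron_lengths == expected


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_textbook_example(self):
        t, df, p = welch_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.2879, abs=1e-3)

    def test_matches_scipy_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a = rng.normal(0, 1, size=rng.integers(3, 30))
            b = rng.normal(0.5, 2, size=rng.integers(3, 30))
            t, df, p = welch_t_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_power_against_simulated_shift(self):
        """A clear simulated group shift in CDS length is detected."""
        config = SimulationConfig()
        sim = simulate_features(
            {"unicellular": ["u1", "u2"], "multicellular": ["m1", "m2"]},
            config, 60, seed=8)
        models = []
        for sp, text in sim.gff.items():
            models += extract_gene_structures(text, from_string=True,
                                              species=sp)
        truth_groups = sim.truth.set_index("gene")["group"]
        uni = [sum(m.intron_lengths) for m in models
               if truth_groups[m.gene_id] == "unicellular"
               and m.intron_lengths]
        multi = [sum(m.intron_lengths) for m in models
                 if truth_groups[m.gene_id] == "multicellular"
                 and m.intron_lengths]
        t, _, p = welch_t_test(uni, multi)
        assert p < 0.01
        assert t < 0  # multicellular introns are longer by construction


class TestArchitectureInventory:
    def _table(self):
        rows = []
        for i in range(10):
            rows.append({"protein": f"u{i}", "species": f"us{i}",
                         "group": "unicellular", "family": "fam1",
                         "domains": "PF1,PF2"})
        for i in range(10):
            arch = "PF1,PF2,PF3" if i < 8 else "PF9"
            rows.append({"protein": f"m{i}", "species": f"ms{i}",
                         "group": "multicellular", "family": "fam1",
                         "domains": arch})
        return pd.DataFrame(rows)

    def test_conservation_rule_and_change_flag(self):
        freq, changes = architecture_inventory(self._table(), 0.7)
        kept = set(zip(freq["group"], freq["architecture"]))
        assert ("unicellular", "PF1,PF2") in kept
        assert ("multicellular", "PF1,PF2,PF3") in kept
        assert ("multicellular", "PF9") not in kept  # 10% < 70%
        assert bool(changes.set_index("family").loc[
            "fam1", "architecture_change"]) is True

    def test_order_sensitivity(self):
        rows = [{"protein": f"p{i}", "species": f"s{i}",
                 "group": "unicellular", "family": "f",
                 "domains": "A,B" if i < 5 else "B,A"} for i in range(10)]
        freq, _ = architecture_inventory(pd.DataFrame(rows), 0.4)
        archs = set(freq["architecture"])
        assert archs == {"A,B", "B,A"}


class TestDomainCountGlm:
    def _table(self, counts_uni, counts_multi):
        rows = []
        for i, k in enumerate(counts_uni):
            rows.append({"protein": f"u{i}", "species": f"us{i % 4}",
                         "group": "unicellular", "family": "fam",
                         "domains": ",".join(f"PF{j}" for j in range(k))})
        for i, k in enumerate(counts_multi):
            rows.append({"protein": f"m{i}", "species": f"ms{i % 4}",
                         "group": "multicellular", "family": "fam",
                         "domains": ",".join(f"PF{j}" for j in range(k))})
        return pd.DataFrame(rows)

    def test_clear_shift_detected_and_matches_lrt_oracle(self):
        table = self._table([2] * 10 + [3], [3] * 10 + [4])
        out = domain_count_glm(
            table, group_order=["unicellular", "multicellular"])
        row = out.set_index("family").loc["fam"]
        coef_oracle, p_oracle = poisson_lrt_oracle(
            [2] * 10 + [3], [3] * 10 + [4])
        assert row["coef"] == pytest.approx(coef_oracle, abs=1e-6)
        assert row["p"] == pytest.approx(p_oracle, abs=1e-6)
        assert row["coef"] > 0

    def test_equal_groups_null(self):
        table = self._table([2, 3, 2, 3, 2], [3, 2, 3, 2, 3])
        out = domain_count_glm(
            table, group_order=["unicellular", "multicellular"])
        row = out.set_index("family").loc["fam"]
        assert abs(row["coef"]) < 0.2
        assert row["p"] > 0.5

    def test_constant_counts_degenerate(self):
        table = self._table([2] * 6, [2] * 6)
        out = domain_count_glm(table)
        row = out.set_index("family").loc["fam"]
        assert bool(row["degenerate"]) is True
        assert row["p"] == 1.0

    def test_simulated_shift_recovered(self):
        """delta = 1 on a baseline of 2 domains is significant at
        n = 50 per group."""
        config = SimulationConfig()
        sim = simulate_features(
            {"unicellular": ["u1", "u2"], "multicellular": ["m1", "m2"]},
            config, 5, seed=10, n_domain_proteins=50)
        out = domain_count_glm(
            sim.domains, group_order=["unicellular", "multicellular"])
        row = out.iloc[0]
        assert row["coef"] > 0
        assert row["p"] < 0.05
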