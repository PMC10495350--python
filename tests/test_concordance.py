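"""Concordance mapping, quartet/triplet frequencies, topology spectra."""

import math

import numpy as np
import pytest

from phylodiscord import concordance as C
from phylodiscord import msc
from phylodiscord import trees as T

from conftest import all_unrooted_binary_trees


class TestMapConcordance:
    def test_identical_gene_trees_all_concordant(self):
        sp = T.read_newick("(((A,B),(C,D)),E);")[0]
        gts = [T.read_newick("(((A,B),(C,D)),E);")[0] for _ in range(3)]
        summary = C.map_concordance(sp, gts)
        for b in summary.branches:
            assert b.concordant == 3
            assert b.total == 3

    def test_hand_counts_with_conflict(self):
        sp = T.read_newick("(((A,B),(C,D)),O);")[0]
        gts = T.read_newick(
            "(((A,B),(C,D)),O);(((A,B),(C,D)),O);(((A,C),(B,D)),O);"
        )
        summary = C.map_concordance(sp, gts)
        ab = summary.by_clade({"A", "B"})
        assert ab.concordant == 2
        assert ab.top_conflict == 1
        assert ab.other_conflict == 0
        assert ab.uninformative == 0

    def test_missing_taxa_counted(self):
        sp = T.read_newick("(((A,B),(C,D)),E);")[0]
        gts = [T.read_newick("((A,C),(D,E));")[0]]  # B missing
        summary = C.map_concordance(sp, gts)
        ab = summary.by_clade({"A", "B"})
        assert ab.missing == 1

    def test_collapsed_conflict_becomes_uninformative(self):
        sp = T.read_newick("(((A,B),(C,D)),E);")[0]
        gts = [T.read_newick("((((A,C)5,B),D),E);")[0]]
        hard = C.map_concordance(sp, gts, support_threshold=0.0)
        soft = C.map_concordance(sp, gts, support_threshold=10.0)
        ab_hard = hard.by_clade({"A", "B"})
        ab_soft = soft.by_clade({"A", "B"})
        assert ab_hard.top_conflict == 1
        assert ab_soft.top_conflict == 0
        assert ab_soft.uninformative == 1

    def test_counts_sum_invariant(self, seven_taxon_scenario, seven_taxon_gene_trees):
        sc = seven_taxon_scenario
        gts = seven_taxon_gene_trees.trees[:100]
        # knock random taxa out of some gene trees
        rng = np.random.default_rng(0)
        pruned = []
        for t in gts:
            if rng.random() < 0.3:
                keep = sorted(T.tip_labels(t) - {rng.choice(sorted(T.tip_labels(t)))})
                pruned.append(T.restrict(t, keep))
            else:
                pruned.append(t)
        summary = C.map_concordance(sc.species_tree, pruned)
        for b in summary.branches:
            assert b.total == len(pruned)

    def test_against_brute_force_compatibility_oracle(self):
        """Conflict decisions match an oracle that declares two splits
        incompatible iff no binary tree on the shared taxa contains both."""
        sp = T.read_newick("(((A,B),(C,D)),(E,F));")[0]
        gts = T.read_newick(
            "(((A,B),(C,D)),(E,F));"
            "(((A,C),(B,D)),(E,F));"
            "(((A,E),(C,D)),(B,F));"
            "((((A,B),C),D),(E,F));"
        )
        labels = sorted(T.tip_labels(sp))
        universe = all_unrooted_binary_trees(labels)
        tree_bips = [T.bipartitions(t) for t in universe]

        def oracle_compatible(b1, b2):
            return any(b1 in bips and b2 in bips for bips in tree_bips)

        summary = C.map_concordance(sp, gts)
        for branch in summary.branches:
            for gt in gts:
                gbips = T.bipartitions(gt)
                rs = branch.bipartition  # full taxon set here
                oracle_conflict = any(not oracle_compatible(rs, gb) for gb in gbips)
                mine_conflict = any(not gb.is_compatible_with(rs) for gb in gbips)
                assert oracle_conflict == mine_conflict


class TestQuartetFreqs:
    def test_concordant_only(self):
        sp = T.read_newick("(((A,B),(C,D)),E);")[0]
        gts = [T.read_newick("(((A,B),(C,D)),E);")[0] for _ in range(4)]
        qc = C.branch_quartet_freqs(sp, gts, {"A", "B"})
        assert qc.q == pytest.approx((1.0, 0.0, 0.0))
        assert qc.exact

    def test_uniform_over_resolutions(self):
        sp = T.read_newick("(((A,B),(C,D)),E);")[0]
        gts = T.read_newick(
            "(((A,B),(C,D)),E);(((A,C),(B,D)),E);(((A,D),(B,C)),E);"
        )
        qc = C.branch_quartet_freqs(sp, gts, {"A", "B"})
        assert qc.q == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_msc_simulation_matches_closed_form(self):
        # a quartet is discordant only when BOTH root-adjacent cherries fail
        # to coalesce, so P(ab|cd) = 1 - (2/3) exp(-(T_AB + T_CD)); branch
        # lengths/thetas chosen so T_AB = T_CD = 0.5 coalescent units
        sp = T.read_newick(
            "((A:0.3,B:0.3):0.2,(C:0.5,D:0.5):0.3);", units="substitutions_per_site"
        )[0]
        table = msc.BranchTable.from_constant(
            sp, 0.8, overrides={frozenset("CD"): 1.2}
        )
        sample = msc.simulate_gene_trees(sp, table, n=2000, seed=17)
        qc = C.branch_quartet_freqs(sp, sample.trees, {"A", "B"})
        p = 1 - (2 / 3) * math.exp(-1)
        se = math.sqrt(p * (1 - p) / 2000)
        assert abs(qc.q[0] - p) < 3 * se

    def test_sampling_matches_enumeration(self, seven_taxon_scenario, seven_taxon_gene_trees):
        sc = seven_taxon_scenario
        gts = seven_taxon_gene_trees.trees
        clade = frozenset({"Pras1", "Pras2", "Chlo1", "Chlo2"})
        exact = C.branch_quartet_freqs(sc.species_tree, gts, clade)
        sampled = C.branch_quartet_freqs(sc.species_tree, gts, clade, max_quartets=4, seed=1)
        assert exact.exact and not sampled.exact
        tot_e = sum(exact.counts)
        tot_s = sum(sampled.counts)
        for qe, qs in zip(np.array(exact.counts) / tot_e, np.array(sampled.counts) / tot_s):
            se = math.sqrt(max(qe * (1 - qe), 1e-6) / 434)
            assert abs(qe - qs) < 4 * se

    def test_minor_symmetry_under_pure_msc(self, seven_taxon_scenario):
        from scipy import stats

        sc = seven_taxon_scenario
        sample = msc.simulate_gene_trees(sc.species_tree, sc.branch_table, n=3000, seed=23)
        qc = C.branch_quartet_freqs(sc.species_tree, sample.trees, frozenset({"Pras1", "Pras2", "Chlo1", "Chlo2"}))
        e2, e3 = qc.minor_effective_counts()
        res = stats.chisquare([e2, e3])
        assert res.pvalue > 0.01

    def test_nonbranch_rejected(self):
        sp = T.read_newick("(((A,B),(C,D)),E);")[0]
        with pytest.raises(T.TreeValidationError):
            C.branch_quartet_freqs(sp, [], {"A", "C"})


class TestTripletFreqs:
    def test_single_gene_tree(self):
        gts = [T.read_newick("(((A,B),C),O);")[0]]
        table = C.triplet_freqs(gts, ["A", "B", "C"], "O")
        row = table[(table.triplet == "A|B|C") & (table.resolution == "A,B|C")]
        assert row.freq.iloc[0] == 1.0

    def test_row_counts(self, seven_taxon_gene_trees):
        gts = seven_taxon_gene_trees.trees[:50]
        ingroup = ["Pras1", "Pras2", "Chlo1", "Chlo2", "Stre1", "Stre2"]
        table = C.triplet_freqs(gts, ingroup, "Glau")
        assert table.triplet.nunique() == 20  # C(6,3)
        assert len(table) == 60
        sums = table.groupby("triplet").freq.sum()
        assert np.allclose(sums, 1.0)

    def test_matches_analytic_probs(self, seven_taxon_scenario):
        sc = seven_taxon_scenario
        sample = msc.simulate_gene_trees(sc.species_tree, sc.branch_table, n=3000, seed=31)
        table = C.triplet_freqs(sample.trees, ["Pras1", "Chlo1", "Stre1"], "Glau")
        p1, p2, p3 = msc.expected_triplet_probs(
            sc.species_tree, sc.branch_table, ["Pras1", "Chlo1", "Stre1"]
        )
        row = table[table.resolution == "Chlo1,Pras1|Stre1"]
        se = math.sqrt(p1 * (1 - p1) / 3000)
        assert abs(row.freq.iloc[0] - p1) < 3 * se

    def test_outgroup_in_ingroup_rejected(self):
        gts = [T.read_newick("(((A,B),C),O);")[0]]
        with pytest.raises(T.TreeValidationError):
            C.triplet_freqs(gts, ["A", "B", "O"], "O")


class TestTopologySpectrum:
    def test_counts(self):
        gts = T.read_newick(
            "((A,B),(C,D));((B,A),(D,C));((A,B),(C,D));((A,C),(B,D));"
        )
        spec = C.topology_spectrum(gts)
        assert spec.total == 4
        assert sorted(spec.counts.values()) == [1, 3]

    def test_rotation_invariant_key(self):
        t1 = T.read_newick("((A,B),(C,D));")[0]
        t2 = T.read_newick("((D,C),(B,A));")[0]
        assert C.canonical_topology(t1) == C.canonical_topology(t2)

    def test_top_entry_is_species_topology(self, seven_taxon_scenario):
        sc = seven_taxon_scenario
        sample = msc.simulate_gene_trees(sc.species_tree, sc.branch_table, n=2000, seed=37)
        spec = C.topology_spectrum(sample.trees)
        top_key, _ = spec.most_common(1)[0]
        assert top_key == C.canonical_topology(sc.species_tree)

    def test_tipset_mismatch_rejected(self):
        gts = T.read_newick("((A,B),(C,D));((A,B),(C,E));")
        with pytest.raises(T.TreeValidationError):
            C.topology_spectrum(gts)
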