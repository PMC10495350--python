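"""Tree model: Newick I/O, bipartitions, RF, collapsing, restriction."""

import itertools

import numpy as np
import pytest
from dendropy.calculate import treecompare

from phylodiscord import trees as T

from conftest import all_unrooted_binary_trees, random_rooted_tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

class TestReadNewick:
    def test_lengths_parsed(self):
        t = T.read_newick("((A:1,B:1):1,C:2);")[0]
        lengths = sorted(
            nd.edge.length for nd in t.preorder_node_iter() if nd is not t.seed_node
        )
        assert lengths == [1.0, 1.0, 1.0, 2.0]
        assert sorted(T.tip_labels(t)) == ["A", "B", "C"]

    def test_support_parsed(self):
        t = T.read_newick("((A,B)95,C);")[0]
        sups = [nd.support for nd in t.preorder_internal_node_iter() if nd is not t.seed_node]
        assert sups == [95.0]

    def test_lpp_rescaled(self):
        t = T.read_newick("((A,B)0.97,C);", support_as_fraction=True)[0]
        sups = [nd.support for nd in t.preorder_internal_node_iter() if nd is not t.seed_node]
        assert sups == [97.0]

    def test_duplicate_tip_rejected(self):
        with pytest.raises(T.TreeValidationError):
            T.read_newick("((A,B),(A,C));")

    def test_malformed_rejected(self):
        with pytest.raises(T.NewickParseError):
            T.read_newick("((A,B,C);")

    def test_negative_length_rejected(self):
        with pytest.raises(T.TreeValidationError):
            T.read_newick("((A:-1,B:1):1,C:2);")

    def test_read_write_read_fixpoint(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 12))
            labels = [f"t{i}" for i in range(n)]
            t1 = random_rooted_tree(labels, rng)
            t2 = T.read_newick(T.write_newick(t1))[0]
            t3 = T.read_newick(T.write_newick(t2))[0]
            assert T.bipartitions(t2) == T.bipartitions(t1)
            assert T.write_newick(t2) == T.write_newick(t3)


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

class TestBipartitions:
    def test_single_internal_edge(self):
        t = T.read_newick("((A,B),(C,D));")[0]
        assert T.bipartitions(t) == {T.Bipartition("AB", "CD")}

    def test_star_has_none(self):
        t = T.read_newick("(A,B,C,D,E);")[0]
        assert T.bipartitions(t) == set()

    def test_caterpillar_count(self):
        t = T.read_newick("(A,(B,(C,(D,E))));")[0]
        assert len(T.bipartitions(t)) == 2  # n - 3

    def test_unordered_equality(self):
        assert T.Bipartition("AB", "CD") == T.Bipartition("DC", "BA")

    def test_compatibility(self):
        a = T.Bipartition("AB", "CDE")
        b = T.Bipartition("ABC", "DE")
        c = T.Bipartition("AC", "BDE")
        assert a.is_compatible_with(b)
        assert not a.is_compatible_with(c)

    def test_restriction(self):
        bip = T.Bipartition("AB", "CDE")
        assert bip.restrict("ABC") == T.Bipartition("AB", "C")
        assert bip.restrict("CDE") is None


# ---------------------------------------------------------------------------
# Robinson–Foulds
# ---------------------------------------------------------------------------

class TestRF:
    def test_identity(self):
        t = T.read_newick("((A,B),(C,(D,E)));")[0]
        assert T.rf_distance(t, t) == 0.0

    def test_single_nni(self):
        t1 = T.read_newick("(((A,B),C),(D,E));")[0]
        t2 = T.read_newick("(((A,C),B),(D,E));")[0]
        assert T.rf_distance(t1, t2) == 2.0

    def test_tipset_mismatch_names_taxa(self):
        t1 = T.read_newick("((A,B),(C,D));")[0]
        t2 = T.read_newick("((A,B),(C,E));")[0]
        with pytest.raises(T.TreeValidationError, match="[DE]"):
            T.rf_distance(t1, t2)

    def test_against_dendropy_oracle_all_five_tip_trees(self):
        """RF on every pair of the 15 unrooted 5-tip binary trees matches
        dendropy's symmetric difference, and behaves as a metric."""
        import dendropy

        topologies = all_unrooted_binary_trees(list("ABCDE"))
        assert len(topologies) == 15
        newicks = [t.as_string(schema="newick", suppress_rooting=True) for t in topologies]
        tns = dendropy.TaxonNamespace()
        oracle = [
            dendropy.Tree.get(data=nw, schema="newick", taxon_namespace=tns)
            for nw in newicks
        ]
        for o in oracle:
            o.encode_bipartitions()
        n = len(topologies)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                d[i, j] = T.rf_distance(topologies[i], topologies[j])
                expected = treecompare.symmetric_difference(oracle[i], oracle[j])
                assert d[i, j] == expected
        # metric properties
        assert np.allclose(d, d.T)
        assert all(d[i, i] == 0 for i in range(n))
        assert all(d[i, j] > 0 for i in range(n) for j in range(n) if i != j)
        for i, j, k in itertools.combinations(range(n), 3):
            assert d[i, k] <= d[i, j] + d[j, k]

    def test_normalized_maximum(self):
        rng = np.random.default_rng(3)
        labels = list("ABCDEFG")
        found = False
        for _ in range(200):
            t1 = random_rooted_tree(labels, rng)
            t2 = random_rooted_tree(labels, rng)
            if T.rf_distance(t1, t2) == 8.0:  # 2(n-3) for n=7
                assert T.rf_distance(t1, t2, normalized=True) == 1.0
                found = True
                break
        assert found


# ---------------------------------------------------------------------------
# Support collapsing
# ---------------------------------------------------------------------------

class TestCollapse:
    def test_noop_when_all_supported(self):
        t = T.read_newick("(((A,B)80,C)90,(D,E)99);")[0]
        c = T.collapse_low_support(t, 10)
        assert T.bipartitions(c) == T.bipartitions(t)

    def test_full_collapse_to_star(self):
        t = T.read_newick("(((A,B)0,C)0,(D,E)0);")[0]
        c = T.collapse_low_support(t, 10)
        assert T.bipartitions(c) == set()
        assert T.tip_labels(c) == T.tip_labels(t)

    def test_strict_inequality_at_threshold(self):
        t = T.read_newick("(((A,B)9.9,C)10,(D,E)10);")[0]
        c = T.collapse_low_support(t, 10)
        assert T.Bipartition("AB", "CDE") not in T.bipartitions(c)
        assert T.Bipartition("ABC", "DE") in T.bipartitions(c)

    def test_absent_support_never_collapsed(self):
        t = T.read_newick("(((A,B)5,(C,D)),E);")[0]
        c = T.collapse_low_support(t, 10)
        assert T.Bipartition("AB", "CDE") not in T.bipartitions(c)
        assert T.Bipartition("CD", "ABE") in T.bipartitions(c)

    def test_idempotent(self):
        t = T.read_newick("(((A,B)5,C)50,(D,E)20);")[0]
        once = T.collapse_low_support(t, 30)
        twice = T.collapse_low_support(once, 30)
        assert T.bipartitions(once) == T.bipartitions(twice)
        assert T.tip_labels(once) == T.tip_labels(t)


# ---------------------------------------------------------------------------
# Restriction and patristic distances
# ---------------------------------------------------------------------------

class TestRestrict:
    def test_induced_topology(self):
        t = T.read_newick("(((A,B),C),D);")[0]
        r = T.restrict(t, {"A", "B", "C"})
        assert T.tip_labels(r) == frozenset("ABC")
        assert T.Bipartition("AB", "C").restrict(T.tip_labels(r)) is not None

    def test_identity_on_full_set(self):
        t = T.read_newick("(((A:1,B:2):1,C:1):1,D:4);")[0]
        r = T.restrict(t, T.tip_labels(t))
        assert T.bipartitions(r) == T.bipartitions(t)

    def test_lengths_additive(self):
        t = T.read_newick("(((A:0.1,B:0.1):0.2,C:0.1):0.1,D:0.5);")[0]
        r = T.restrict(t, {"A", "C", "D"})
        labels, m = T.patristic_matrix(r)
        # A's path to C: 0.1 (pendant) + 0.2 (suppressed) + 0.1
        assert m[labels.index("A"), labels.index("C")] == pytest.approx(0.4)

    def test_unknown_taxon_rejected(self):
        t = T.read_newick("((A,B),(C,D));")[0]
        with pytest.raises(T.TreeValidationError):
            T.restrict(t, {"A", "Z"})

    def test_restrict_commutes_with_patristic(self):
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(8)]
        t = random_rooted_tree(labels, rng)
        keep = ["t0", "t2", "t5", "t7"]
        full_labels, full = T.patristic_matrix(t)
        sub_labels, sub = T.patristic_matrix(T.restrict(t, keep))
        for a in keep:
            for b in keep:
                assert sub[sub_labels.index(a), sub_labels.index(b)] == pytest.approx(
                    full[full_labels.index(a), full_labels.index(b)]
                )


class TestPatristic:
    def test_hand_example(self):
        t = T.read_newick("((A:0.1,B:0.1):0.1,C:0.2);")[0]
        labels, m = T.patristic_matrix(t)
        a, b, c = (labels.index(x) for x in "ABC")
        assert m[a, b] == pytest.approx(0.2)
        assert m[a, c] == pytest.approx(0.4)
        assert m[b, c] == pytest.approx(0.4)
        assert np.allclose(np.diag(m), 0.0)

    def test_ultrametric_tips_equidistant(self):
        t = T.read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")[0]
        depths = T.root_to_tip_lengths(t)
        assert len(set(round(v, 9) for v in depths.values())) == 1

    def test_missing_length_names_edge(self):
        t = T.read_newick("((A:1,B),C:2);")[0]
        with pytest.raises(T.TreeValidationError, match="B"):
            T.patristic_matrix(t)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

class TestConsensus:
    def test_identical_trees(self):
        ts = T.read_newick("((A,B),(C,D));((A,B),(C,D));((A,B),(C,D));")
        cons = T.consensus_tree(ts, 0.5)
        assert T.bipartitions(cons) == {T.Bipartition("AB", "CD")}

    def test_no_shared_bipartitions_gives_star(self):
        ts = T.read_newick("((A,B),(C,D),E);((A,C),(B,E),D);")
        cons = T.consensus_tree(ts, 0.51)
        assert T.bipartitions(cons) == set()

    def test_two_of_three_included(self):
        ts = T.read_newick("((A,B),(C,D),E);((A,B),C,(D,E));((A,C),B,(D,E));")
        cons = T.consensus_tree(ts, 0.5)
        assert T.Bipartition("AB", "CDE") in T.bipartitions(cons)

    def test_tipset_mismatch_rejected(self):
        ts = T.read_newick("((A,B),(C,D));((A,B),(C,E));")
        with pytest.raises(T.TreeValidationError):
            T.consensus_tree(ts, 0.5)
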