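"""Delta-lnL signal classification, pruning likelihood, diagnostics."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from phylodiscord import signal as G
from phylodiscord import synthetic_data as S
from phylodiscord import trees as T
from phylodiscord.alignments import Alignment


class TestClassifyGeneSupport:
    def test_strong_and_weak(self):
        lnl = pd.DataFrame(
            {
                "lnl_T1": [-1000.0, -1000.0, -1010.0],
                "lnl_T2": [-1003.0, -1001.0, -1000.0],
                "lnl_T3": [-1005.0, -1003.0, -1004.0],
            }
        )
        labels, summary = G.classify_gene_support(lnl)
        assert list(labels) == ["strong_T1", "weak_T1", "strong_T2"]
        assert summary["strong_T1"] == pytest.approx(1 / 3)
        assert summary["weak_T1"] == pytest.approx(1 / 3)
        assert summary["strong_T2"] == pytest.approx(1 / 3)

    def test_tie_is_unclassifiable(self):
        lnl = pd.DataFrame({"lnl_T1": [-5.0], "lnl_T2": [-5.0], "lnl_T3": [-9.0]})
        labels, summary = G.classify_gene_support(lnl)
        assert list(labels) == ["unclassifiable"]
        assert sum(v for k, v in summary.items() if k != "unclassifiable") == 0.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame(rng.normal(-1000, 5, size=(30, 3)), columns=["lnl_T1", "lnl_T2", "lnl_T3"])
        shifted = base.add(rng.normal(0, 100, size=(30, 1)))
        l1, _ = G.classify_gene_support(base)
        l2, _ = G.classify_gene_support(shifted)
        assert list(l1) == list(l2)

    def test_fractions_sum_to_at_most_one(self):
        rng = np.random.default_rng(2)
        lnl = pd.DataFrame(rng.normal(-1000, 2, size=(50, 3)), columns=["lnl_T1", "lnl_T2", "lnl_T3"])
        _, summary = G.classify_gene_support(lnl)
        assert sum(v for k, v in summary.items() if k != "unclassifiable") <= 1.0 + 1e-12


class TestGeneLogLikelihood:
    def test_zero_branch_limit(self):
        model = G.SubstModel.poisson()
        aln = Alignment(["A", "B"], ["ACDE", "ACDE"])
        tree = T.read_newick("(A:0.0,B:0.0);")[0]
        assert G.gene_log_likelihood(aln, tree, model) == pytest.approx(4 * math.log(1 / 20))

    def test_two_taxon_closed_form(self):
        # equal-frequency k-state model: P(same) = 1/k + (k-1)/k * exp(-k t/(k-1))
        model = G.SubstModel.poisson()
        k = 20
        t = 0.3
        tree = T.read_newick(f"(A:{t/2},B:{t/2});")[0]
        p_same = 1 / k + (k - 1) / k * math.exp(-k * t / (k - 1))
        p_diff = (1 - p_same) / (k - 1)
        aln = Alignment(["A", "B"], ["AC", "AD"])  # one match, one mismatch
        expected = math.log(p_same / k) + math.log(p_diff / k)
        assert G.gene_log_likelihood(aln, tree, model) == pytest.approx(expected, abs=1e-10)

    def test_root_invariance(self):
        # same unrooted tree, root placed on different edges
        model = G.SubstModel.poisson()
        rng = np.random.default_rng(5)
        tree1 = T.read_newick("(((A:0.2,B:0.3):0.1,C:0.4):0.0,D:0.3);")[0]
        tree2 = T.read_newick("((A:0.2,B:0.3):0.05,(C:0.4,D:0.3):0.05);")[0]
        aln = Alignment(
            ["A", "B", "C", "D"],
            ["".join(rng.choice(list("ACDEFG"), 30)) for _ in range(4)],
        )
        l1 = G.gene_log_likelihood(aln, tree1, model)
        l2 = G.gene_log_likelihood(aln, tree2, model)
        assert l1 == pytest.approx(l2, abs=1e-9)

    def test_matches_exhaustive_summation(self):
        """Pruning equals brute-force summation over all ancestral states
        on 4-tip trees under a 4-state model with unequal frequencies."""
        states = "ACGT"
        k = 4
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        s = np.ones((k, k))
        np.fill_diagonal(s, 0.0)
        s[0, 1] = s[1, 0] = 3.0
        model = G.SubstModel(states, s, freqs)
        q = model.rate_matrix()
        tree = T.read_newick("((A:0.3,B:0.4):0.2,(C:0.5,D:0.1):0.3);")[0]
        aln = Alignment(["A", "B", "C", "D"], ["AC", "AG", "C-", "TT"])

        def brute_force():
            total_log = 0.0
            pmat = {}
            for nd in tree.preorder_node_iter():
                if nd is not tree.seed_node:
                    pmat[nd] = expm(q * nd.edge.length)
            internal = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
            for site in range(aln.length):
                obs = {l: aln.sequence(l)[site] for l in aln.labels}
                total = 0.0
                for assign in product(range(k), repeat=len(internal)):
                    amap = dict(zip(internal, assign))
                    p = freqs[amap[tree.seed_node]]
                    for nd in tree.preorder_node_iter():
                        if nd is tree.seed_node:
                            continue
                        ps = amap[nd.parent_node]
                        if nd.is_leaf():
                            ch = obs[nd.taxon.label]
                            if ch == "-":
                                p *= 1.0  # marginalize: sum over child states = row sum = 1
                            else:
                                p *= pmat[nd][ps, states.index(ch)]
                        else:
                            p *= pmat[nd][ps, amap[nd]]
                    total += p
                total_log += math.log(total)
            return total_log

        assert G.gene_log_likelihood(aln, tree, model) == pytest.approx(
            brute_force(), abs=1e-8
        )

    def test_gamma_rates_average(self):
        model = G.SubstModel.poisson(gamma_shape=0.5)
        rates = model.category_rates()
        assert len(rates) == 4
        assert rates.mean() == pytest.approx(1.0)
        assert rates[0] < rates[-1]

    def test_taxon_mismatch_rejected(self):
        model = G.SubstModel.poisson()
        aln = Alignment(["A", "B"], ["AA", "CC"])
        tree = T.read_newick("((A:1,B:1):1,C:1);")[0]
        with pytest.raises(T.TreeValidationError):
            G.gene_log_likelihood(aln, tree, model)


class TestRecovery:
    def test_true_topology_wins_on_long_alignments(self):
        """Sequences evolved on T1 yield strong T1 signal with 1000 sites."""
        model = G.SubstModel.poisson()
        t1 = T.read_newick("(((A:0.2,B:0.2):0.1,C:0.3):0.1,D:0.4);")[0]
        t2 = T.read_newick("(((A:0.2,C:0.2):0.1,B:0.3):0.1,D:0.4);")[0]
        t3 = T.read_newick("(((A:0.2,D:0.2):0.1,C:0.3):0.1,B:0.4);")[0]
        rows = []
        for g in range(5):
            aln = S.evolve_sequences(t1, model, length=1000, seed=100 + g)
            rows.append(
                {
                    "lnl_T1": G.gene_log_likelihood(aln, t1, model),
                    "lnl_T2": G.gene_log_likelihood(aln, t2, model),
                    "lnl_T3": G.gene_log_likelihood(aln, t3, model),
                }
            )
        _, summary = G.classify_gene_support(pd.DataFrame(rows))
        assert summary["strong_T1"] > summary["strong_T2"]
        assert summary["strong_T1"] > summary["strong_T3"]


class TestDiagnostics:
    def test_informative_site_definitions(self):
        aln = Alignment(["w", "x", "y", "z"], ["AAA", "AAA", "BBA", "BCB"])
        # col0 AABB? -> A,A,B,B informative; col1 A,A,B,C not; col2 A,A,A,B not
        aln = Alignment(["w", "x", "y", "z"], ["AAA", "AAA", "BBA", "BCB"])
        assert G.count_informative_sites(aln) == 1

    def test_rate_is_mean_patristic(self):
        tree = T.read_newick("((A:0.1,B:0.1):0.1,C:0.2);")[0]
        aln = Alignment(["A", "B", "C"], ["AAAA", "AAAA", "AAAA"])
        d = G.alignment_diagnostics(aln, tree)
        assert d.rate == pytest.approx((0.2 + 0.4 + 0.4) / 3)
        assert math.isnan(d.saturation_slope)  # <4 sequences

    def test_slope_near_one_at_low_divergence_and_below_under_saturation(self):
        model = G.SubstModel.poisson()
        rng = np.random.default_rng(11)
        labels = [f"t{i}" for i in range(8)]
        from conftest import random_rooted_tree

        base = random_rooted_tree(labels, rng)
        for nd in base.preorder_node_iter():
            if nd is not base.seed_node:
                nd.edge.length = rng.uniform(0.002, 0.008)
        aln_low = S.evolve_sequences(base, model, length=10000, seed=1)
        slope_low = G.alignment_diagnostics(aln_low, base).saturation_slope
        assert slope_low == pytest.approx(1.0, abs=0.05)

        saturated = T.read_newick(T.write_newick(base))[0]
        for nd in saturated.preorder_node_iter():
            if nd is not saturated.seed_node:
                nd.edge.length = nd.edge.length * 150
        aln_high = S.evolve_sequences(saturated, model, length=4000, seed=2)
        slope_high = G.alignment_diagnostics(aln_high, saturated).saturation_slope
        assert slope_high < 0.5
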