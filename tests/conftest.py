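"""Shared fixtures and small tree-enumeration helpers."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from phylodiscord import msc, synthetic_data, trees


def _fresh_copy(tree: dendropy.Tree) -> dendropy.Tree:
    out = trees.read_newick(tree.as_string(schema="newick", suppress_rooting=True))[0]
    return out


def all_unrooted_binary_trees(labels: list[str]) -> list[dendropy.Tree]:
    """Enumerate unrooted binary topologies by stepwise tip insertion."""
    first = trees.read_newick(f"({labels[0]},{labels[1]},{labels[2]});")[0]
    current = [first]
    for label in labels[3:]:
        nxt = []
        for tree in current:
            n_edges = sum(1 for nd in tree.preorder_node_iter() if nd is not tree.seed_node)
            for i in range(n_edges):
                work = _fresh_copy(tree)
                targets = [nd for nd in work.preorder_node_iter() if nd is not work.seed_node]
                target = targets[i]
                parent = target.parent_node
                mid = dendropy.Node()
                parent.remove_child(target)
                parent.add_child(mid)
                mid.add_child(target)
                taxon = dendropy.Taxon(label=label)
                work.taxon_namespace.add_taxon(taxon)
                mid.add_child(dendropy.Node(taxon=taxon))
                work.update_taxon_namespace()
                nxt.append(_fresh_copy(work))
        current = nxt
    return current


def all_rooted_binary_trees(labels: list[str]) -> list[dendropy.Tree]:
    """Enumerate rooted binary topologies ((2n-3)!! of them)."""
    first = trees.read_newick(f"({labels[0]},{labels[1]});")[0]
    current = [first]
    for label in labels[2:]:
        nxt = []
        for tree in current:
            # insertion on every edge, plus above the root
            n_edges = sum(1 for nd in tree.preorder_node_iter() if nd is not tree.seed_node)
            for i in range(n_edges + 1):
                work = _fresh_copy(tree)
                taxon = dendropy.Taxon(label=label)
                work.taxon_namespace.add_taxon(taxon)
                if i == n_edges:  # new root above the old one
                    new_root = dendropy.Node()
                    new_root.add_child(work.seed_node)
                    new_root.add_child(dendropy.Node(taxon=taxon))
                    work.seed_node = new_root
                else:
                    targets = [nd for nd in work.preorder_node_iter() if nd is not work.seed_node]
                    target = targets[i]
                    parent = target.parent_node
                    mid = dendropy.Node()
                    parent.remove_child(target)
                    parent.add_child(mid)
                    mid.add_child(target)
                    mid.add_child(dendropy.Node(taxon=taxon))
                work.update_taxon_namespace()
                nxt.append(_fresh_copy(work))
        current = nxt
    for t in current:
        t.is_rooted = True
    return current


def random_rooted_tree(labels: list[str], rng: np.random.Generator) -> dendropy.Tree:
    """Random rooted binary tree with uniform-ish random branch lengths."""
    nodes = [dendropy.Node(taxon=dendropy.Taxon(label=l)) for l in labels]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.update_taxon_namespace()
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        if nd is not tree.seed_node:
            nd.edge.length = float(np.round(rng.uniform(0.01, 2.0), 6))
        nd.support = None
    tree.length_units = "unitless"
    return tree


@pytest.fixture(scope="session")
def focal_clade():
    return frozenset({"Pras1", "Pras2", "Chlo1", "Chlo2"})


@pytest.fixture(scope="session")
def seven_taxon_scenario():
    return synthetic_data.make_scenario(synthetic_data.ScenarioConfig(seed=0))


@pytest.fixture(scope="session")
def seven_taxon_gene_trees(seven_taxon_scenario):
    return synthetic_data.generate_gene_trees(seven_taxon_scenario, n=434)


@pytest.fixture(scope="session")
def triplet_species_tree():
    tree = trees.read_newick(
        "((A:0.3,B:0.3):0.2,C:0.5);", units="substitutions_per_site"
    )[0]
    tree.is_rooted = True
    return tree


@pytest.fixture(scope="session")
def triplet_theta(triplet_species_tree):
    return msc.BranchTable.from_constant(triplet_species_tree, 0.4)
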