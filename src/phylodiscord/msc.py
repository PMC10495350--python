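"""Multispecies-coalescent machinery.

Gene trees are simulated within a rooted binary species tree whose branch
lengths are in mutational units (expected substitutions per site, the
product muT of mutation rate and time).  Each species-tree branch carries a
population-size parameter theta on the 4*N*mu scale, so that with j
uncoalesced lineages inside a branch the waiting time to the next
coalescence is exponential with rate j(j-1)/theta in mutational-time units.
This is the convention used by Phybase's ``sim.coaltree.sp``; with a single
relevant internal branch of length b the probability that a rooted triplet
matches the species tree is the classic 1 - (2/3) exp(-2 b / theta).

theta itself is estimated per internal branch as the ratio of the
mutational branch length (from a constrained ML tree) to the coalescent
branch length (from a summary-coalescent species tree): theta = muT / tau.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .trees import (
    Bipartition,
    TreeValidationError,
    bipartitions,
    is_binary,
    is_rooted_binary_root,
    leafset_below,
    tip_labels,
)

__all__ = [
    "BranchRecord",
    "BranchTable",
    "GeneTreeSample",
    "simulate_gene_trees",
    "expected_triplet_probs",
    "estimate_theta",
]


# ---------------------------------------------------------------------------
# Branch table
# ---------------------------------------------------------------------------

@dataclass
class BranchRecord:
    """One internal species-tree branch with its paired length estimates."""

    branch_id: str
    bipartition: Bipartition
    clade: frozenset            # leaf set below the branch in the rooted tree
    mu_t: float | None = None   # substitutions/site
    tau: float | None = None    # coalescent units
    theta: float | None = None  # muT / tau, 4*N*mu scale


@dataclass
class BranchTable:
    """Per-branch theta map for a rooted species tree.

    ``terminal_theta`` applies to all pendant branches; ``root_theta`` to the
    ancestral population above the root (it affects coalescence times there
    but never gene-tree topology frequencies at internal branches).
    """

    records: list[BranchRecord] = field(default_factory=list)
    terminal_theta: float = 1.0
    root_theta: float | None = None

    def __post_init__(self):
        self._by_clade = {r.clade: r for r in self.records}

    @property
    def mean_internal_theta(self) -> float:
        vals = [r.theta for r in self.records if r.theta is not None]
        if not vals:
            raise ValueError("no internal branch has a defined theta")
        return float(np.mean(vals))

    def record_for_clade(self, clade: frozenset) -> BranchRecord | None:
        return self._by_clade.get(frozenset(clade))

    def theta_for_clade(self, clade: frozenset) -> float | None:
        clade = frozenset(clade)
        if len(clade) == 1:
            return self.terminal_theta
        rec = self._by_clade.get(clade)
        return rec.theta if rec is not None else None

    def with_override(self, clade: Iterable[str], theta: float) -> "BranchTable":
        """Copy of the table with theta replaced on the branch above ``clade``."""
        clade = frozenset(clade)
        if clade not in self._by_clade:
            raise KeyError(f"no internal branch subtends clade {sorted(clade)}")
        recs = [
            BranchRecord(r.branch_id, r.bipartition, r.clade, r.mu_t, r.tau,
                         theta if r.clade == clade else r.theta)
            for r in self.records
        ]
        return BranchTable(recs, self.terminal_theta, self.root_theta)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            small = min(r.bipartition.sides, key=lambda s: (len(s), sorted(s)))
            rows.append(
                {
                    "branch_id": r.branch_id,
                    "clade": "|".join(sorted(r.clade)),
                    "bipartition_small_side": "|".join(sorted(small)),
                    "muT": r.mu_t,
                    "tau": r.tau,
                    "theta": r.theta,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_constant(
        cls,
        species_tree: dendropy.Tree,
        internal_theta: float,
        terminal_theta: float = 1.0,
        overrides: Mapping[frozenset, float] | None = None,
        root_theta: float | None = None,
    ) -> "BranchTable":
        """Constant theta on every internal branch, with optional per-clade overrides."""
        all_taxa = tip_labels(species_tree)
        records = []
        idx = 0
        for node in species_tree.preorder_internal_node_iter():
            if node is species_tree.seed_node:
                continue
            clade = leafset_below(node)
            idx += 1
            records.append(
                BranchRecord(
                    branch_id=f"br{idx}",
                    bipartition=Bipartition(clade, all_taxa - clade),
                    clade=clade,
                    mu_t=node.edge.length,
                    theta=internal_theta,
                )
            )
        table = cls(records, terminal_theta=terminal_theta, root_theta=root_theta)
        if overrides:
            for clade, th in overrides.items():
                table = table.with_override(clade, th)
        return table


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class GeneTreeSample:
    """A batch of simulated gene trees, one sampled lineage per species."""

    trees: list[dendropy.Tree]
    seed: int
    theta_description: str
    count: int
    source_labels: list[str] | None = None  # e.g. "base" / "introgressed"

    def __post_init__(self):
        if len(self.trees) != self.count:
            raise ValueError("count does not match number of trees")


def _resolve_theta(theta, species_tree) -> BranchTable:
    if isinstance(theta, BranchTable):
        return theta
    if isinstance(theta, (int, float)):
        return BranchTable.from_constant(species_tree, float(theta))
    if isinstance(theta, Mapping):
        table = BranchTable.from_constant(species_tree, float("nan"))
        for rec in table.records:
            if rec.clade in theta:
                rec.theta = float(theta[rec.clade])
            else:
                raise ValueError(f"theta missing for clade {sorted(rec.clade)}")
        return BranchTable(table.records, table.terminal_theta, table.root_theta)
    raise TypeError("theta must be a BranchTable, a number, or a clade->theta mapping")


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise TreeValidationError("species tree has a missing branch length")
        depths[node] = depths[node.parent_node] + node.edge.length
    return depths


def simulate_gene_trees(
    species_tree: dendropy.Tree,
    theta,
    n: int,
    seed: int,
    terminal_theta: float | None = None,
) -> GeneTreeSample:
    """Simulate ``n`` coalescent gene trees inside a species tree.

    Per-gene random streams are derived from the master seed by index, so
    gene tree i is the same regardless of ``n`` or evaluation order.  Output
    gene trees carry coalescence times in the species tree's mutational-time
    units; tip depths match the species-tree tip depths.
    """
    if not is_rooted_binary_root(species_tree) or not is_binary(species_tree):
        raise TreeValidationError("species tree must be rooted and binary")
    table = _resolve_theta(theta, species_tree)
    if terminal_theta is not None:
        table = BranchTable(table.records, terminal_theta, table.root_theta)
    for rec in table.records:
        if rec.theta is None or not rec.theta > 0:
            raise ValueError(
                f"theta must be > 0 on every internal branch (branch {rec.branch_id})"
            )
    if not table.terminal_theta > 0:
        raise ValueError("terminal theta must be > 0")
    root_theta = table.root_theta if table.root_theta is not None else table.terminal_theta

    depths = _node_depths(species_tree)
    taxon_namespace = dendropy.TaxonNamespace(sorted(tip_labels(species_tree)))
    taxa = {t.label: t for t in taxon_namespace}

    trees = []
    for i in range(n):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(i,))))
        gt = _simulate_one(species_tree, table, root_theta, depths, rng, taxon_namespace, taxa)
        trees.append(gt)
    return GeneTreeSample(
        trees=trees,
        seed=seed,
        theta_description=repr(
            {"|".join(sorted(r.clade)): r.theta for r in table.records}
        ),
        count=n,
    )


def _coalesce_in_interval(lineages, pos, floor, theta, rng):
    """Coalesce lineages between positions ``pos`` (tipward) and ``floor``.

    Positions are depths from the species-tree root and decrease rootward;
    ``floor=-inf`` for the ancestral population above the root.
    """
    while len(lineages) > 1:
        j = len(lineages)
        rate = j * (j - 1) / theta
        wait = rng.exponential(1.0 / rate)
        if pos - wait <= floor:
            return lineages, floor
        pos -= wait
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = lineages[i1], lineages[i2]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = a.sim_pos - pos
        b.edge.length = b.sim_pos - pos
        parent.sim_pos = pos
        lineages = [l for k, l in enumerate(lineages) if k not in (i1, i2)]
        lineages.append(parent)
    return lineages, pos


def _simulate_one(species_tree, table, root_theta, depths, rng, tns, taxa):
    active: dict = {}

    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            leaf = dendropy.Node(taxon=taxa[node.taxon.label])
            leaf.sim_pos = depths[node]
            active[node] = [leaf]
            continue
        lineages = []
        for child in node.child_nodes():
            lins = active.pop(child)
            if child.is_leaf():
                theta_b = table.terminal_theta
            else:
                theta_b = table.theta_for_clade(leafset_below(child))
            lins, _ = _coalesce_in_interval(
                lins, depths[child], depths[node], theta_b, rng
            )
            lineages.extend(lins)
        active[node] = lineages

    lineages = active[species_tree.seed_node]
    # ancestral population above the root: coalesce to a single lineage
    pos = depths[species_tree.seed_node]
    lineages, _ = _coalesce_in_interval(lineages, pos, -math.inf, root_theta, rng)
    root = lineages[0]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    tree.length_units = "substitutions_per_site"
    for nd in tree.preorder_node_iter():
        nd.support = None
    return tree


# ---------------------------------------------------------------------------
# Analytic triplet probabilities
# ---------------------------------------------------------------------------

def expected_triplet_probs(
    species_tree: dendropy.Tree,
    theta,
    triplet: Sequence[str],
) -> tuple[float, float, float]:
    """Exact rooted-triplet resolution probabilities under the MSC.

    Requires the triplet to be separated by a single internal branch of
    length b with parameter theta; then the species-tree resolution has
    probability 1 - (2/3) exp(-2 b / theta) and each minor resolution
    (1/3) exp(-2 b / theta).
    """
    if len(set(triplet)) != 3:
        raise ValueError("triplet must contain three distinct taxa")
    if not is_rooted_binary_root(species_tree):
        raise TreeValidationError("species tree must be rooted")
    species_tree.is_rooted = True
    table = _resolve_theta(theta, species_tree)
    labeled = {}
    for leaf in species_tree.leaf_node_iter():
        labeled[leaf.taxon.label] = leaf
    try:
        nodes = [labeled[t] for t in triplet]
    except KeyError as exc:
        raise TreeValidationError(f"taxon {exc} not in species tree") from exc

    mrca_all = species_tree.mrca(taxa=[n.taxon for n in nodes])
    pair_mrcas = []
    names = list(triplet)
    for i in range(3):
        for j in range(i + 1, 3):
            m = species_tree.mrca(taxa=[nodes[i].taxon, nodes[j].taxon])
            pair_mrcas.append(((names[i], names[j]), m))
    depths = _node_depths(species_tree)
    cherry = max(pair_mrcas, key=lambda t: depths[t[1]])
    cherry_node = cherry[1]
    if cherry_node is mrca_all:
        raise TreeValidationError("species tree does not resolve the triplet")
    # path from the cherry MRCA up to the triplet MRCA must be a single edge
    if cherry_node.parent_node is not mrca_all:
        raise TreeValidationError(
            "triplet spans more than one internal branch; use simulation instead"
        )
    b = cherry_node.edge.length
    th = table.theta_for_clade(leafset_below(cherry_node))
    if th is None or not th > 0:
        raise ValueError("theta undefined or non-positive on the relevant branch")
    minor = math.exp(-2.0 * b / th) / 3.0
    return (1.0 - 2.0 * minor, minor, minor)


# ---------------------------------------------------------------------------
# theta estimation
# ---------------------------------------------------------------------------

def _internal_edge_lengths(tree: dendropy.Tree) -> dict[Bipartition, float]:
    """Length per non-trivial unrooted bipartition; the two edges incident
    to a bifurcating root contribute to a single (summed) edge."""
    all_taxa = tip_labels(tree)
    out: dict[Bipartition, float] = {}
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        clade = leafset_below(node)
        bip = Bipartition(clade, all_taxa - clade)
        if bip.is_trivial:
            continue
        length = node.edge.length if node.edge.length is not None else 0.0
        out[bip] = out.get(bip, 0.0) + length
    return out


def estimate_theta(
    ml_tree: dendropy.Tree,
    coal_tree: dendropy.Tree,
    terminal_theta: float = 1.0,
) -> BranchTable:
    """theta = muT / tau per internal branch, matched by bipartition.

    ``ml_tree`` carries mutational lengths (substitutions/site), ``coal_tree``
    coalescent-unit lengths; the trees must agree on internal-branch
    topology for every branch to be matched.  Branches present in only one
    tree, or with tau = 0, are recorded with theta undefined.
    """
    if tip_labels(ml_tree) != tip_labels(coal_tree):
        raise TreeValidationError("theta estimation requires identical tip sets")
    mu = _internal_edge_lengths(ml_tree)
    tau = _internal_edge_lengths(coal_tree)
    all_taxa = tip_labels(ml_tree)

    # clade orientation follows the ML tree's rooting when rooted
    clade_of: dict[Bipartition, frozenset] = {}
    for node in ml_tree.preorder_internal_node_iter():
        if node is ml_tree.seed_node:
            continue
        clade = leafset_below(node)
        bip = Bipartition(clade, all_taxa - clade)
        clade_of.setdefault(bip, clade)

    records = []
    for idx, (bip, mu_len) in enumerate(sorted(mu.items(), key=lambda kv: repr(kv[0])), 1):
        rec = BranchRecord(
            branch_id=f"br{idx}",
            bipartition=bip,
            clade=clade_of.get(bip, min(bip.sides, key=lambda s: (len(s), sorted(s)))),
            mu_t=mu_len,
        )
        if bip not in tau:
            warnings.warn(f"bipartition unmatched in coalescent tree: {bip}", stacklevel=2)
        else:
            rec.tau = tau[bip]
            if rec.tau > 0:
                rec.theta = mu_len / rec.tau
            else:
                warnings.warn(f"tau = 0, theta undefined for {bip}", stacklevel=2)
        records.append(rec)
    for bip in tau:
        if bip not in mu:
            warnings.warn(f"bipartition unmatched in ML tree: {bip}", stacklevel=2)
    return BranchTable(records, terminal_theta=terminal_theta)
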