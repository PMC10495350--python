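"""Gene-tree / species-tree concordance analyses.

Three complementary summaries of discordance around species-tree branches:

* :func:`map_concordance` — per-branch counts of concordant, conflicting
  (with the single most common conflict tracked separately), uninformative
  and missing gene trees, in the style of PhyParts pie charts.
* :func:`branch_quartet_freqs` — normalized frequencies (q1, q2, q3) of the
  three quartet resolutions around an internal branch, in the style of
  ASTRAL's per-branch quartet support.  Under pure incomplete lineage
  sorting the two minor frequencies are symmetric (q2 = q3 in expectation);
  skew is the signature of gene flow.
* :func:`triplet_freqs` / :func:`topology_spectrum` — rooted-triplet and
  whole-topology frequency spectra used to correlate empirical gene trees
  with coalescent simulations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations, product

import dendropy
import numpy as np
import pandas as pd

from .trees import (
    Bipartition,
    TreeValidationError,
    bipartitions,
    collapse_low_support,
    leafset_below,
    tip_labels,
)

__all__ = [
    "ConcordanceSummary",
    "QuartetCounts",
    "TopologySpectrum",
    "map_concordance",
    "branch_quartet_freqs",
    "triplet_freqs",
    "topology_spectrum",
    "canonical_topology",
]


# ---------------------------------------------------------------------------
# PhyParts-style concordance mapping
# ---------------------------------------------------------------------------

@dataclass
class BranchConcordance:
    branch_id: str
    bipartition: Bipartition
    concordant: int = 0
    top_conflict: int = 0
    other_conflict: int = 0
    uninformative: int = 0
    missing: int = 0
    top_conflict_bipartition: Bipartition | None = None

    @property
    def total(self) -> int:
        return (self.concordant + self.top_conflict + self.other_conflict
                + self.uninformative + self.missing)


@dataclass
class ConcordanceSummary:
    branches: list[BranchConcordance]
    n_gene_trees: int

    def by_clade(self, clade) -> BranchConcordance:
        clade = frozenset(clade)
        for b in self.branches:
            if clade in b.bipartition.sides:
                return b
        raise KeyError(f"no species-tree branch subtends {sorted(clade)}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.branches:
            small = min(b.bipartition.sides, key=lambda s: (len(s), sorted(s)))
            rows.append(
                {
                    "branch_id": b.branch_id,
                    "clade": "|".join(sorted(small)),
                    "concordant": b.concordant,
                    "top_conflict": b.top_conflict,
                    "other_conflict": b.other_conflict,
                    "uninformative": b.uninformative,
                    "missing": b.missing,
                }
            )
        return pd.DataFrame(rows)


def map_concordance(
    species_tree: dendropy.Tree,
    gene_trees: list[dendropy.Tree],
    support_threshold: float = 0.0,
) -> ConcordanceSummary:
    """Map gene trees onto species-tree branches, PhyParts style.

    Gene trees are first collapsed at ``support_threshold`` (percent), so
    only supported conflict counts as conflict.  For each species-tree
    internal branch, each gene tree is classified exactly once:

    * *missing* — after restriction to the gene tree's taxa, either side of
      the branch bipartition has fewer than 2 taxa;
    * *concordant* — the restricted bipartition occurs in the gene tree;
    * *conflicting* — some gene-tree bipartition is incompatible with the
      restricted bipartition (the single most frequent conflicting
      bipartition across genes is tallied separately);
    * *uninformative* — otherwise (the gene tree, typically a polytomy
      after collapsing, neither contains nor contradicts the branch).
    """
    all_taxa = tip_labels(species_tree)
    branches = []
    idx = 0
    for node in species_tree.preorder_internal_node_iter():
        if node is species_tree.seed_node:
            continue
        clade = leafset_below(node)
        bip = Bipartition(clade, all_taxa - clade)
        if bip.is_trivial:
            continue
        idx += 1
        branches.append(BranchConcordance(branch_id=f"br{idx}", bipartition=bip))

    prepared = []
    for gt in gene_trees:
        gt2 = collapse_low_support(gt, support_threshold) if support_threshold > 0 else gt
        gtaxa = tip_labels(gt2)
        if not gtaxa <= all_taxa:
            raise TreeValidationError(
                f"gene tree has taxa outside the species tree: {sorted(gtaxa - all_taxa)}"
            )
        prepared.append((gtaxa, bipartitions(gt2)))

    for branch in branches:
        conflict_counter: Counter[Bipartition] = Counter()
        n_conflicting = 0
        for gtaxa, gbips in prepared:
            rs = branch.bipartition.restrict(gtaxa)
            if rs is None or rs.is_trivial:
                branch.missing += 1
                continue
            if rs in gbips:
                branch.concordant += 1
                continue
            conflicts = {gb for gb in gbips if not gb.is_compatible_with(rs)}
            if conflicts:
                n_conflicting += 1
                conflict_counter.update(conflicts)
            else:
                branch.uninformative += 1
        if conflict_counter:
            top_bip, top_n = conflict_counter.most_common(1)[0]
            branch.top_conflict = top_n
            branch.other_conflict = n_conflicting - top_n
            branch.top_conflict_bipartition = top_bip
    return ConcordanceSummary(branches=branches, n_gene_trees=len(gene_trees))


# ---------------------------------------------------------------------------
# Quartet frequencies around a branch
# ---------------------------------------------------------------------------

@dataclass
class QuartetCounts:
    """Quartet resolution tallies around one internal species-tree branch.

    ``counts`` and ``effective_counts`` are in a *fixed* topology order —
    (species resolution, first alternative, second alternative) — so that
    empirical and simulated tallies can be compared resolution by
    resolution.  ``effective_counts`` weight each gene tree equally (each
    gene's resolved quartets are averaged before summing), putting the
    tallies on a number-of-genes scale suitable for count-based tests.
    ``q`` holds the normalized frequencies with the two minor entries
    sorted descending (q2 >= q3), the usual reporting convention.
    """

    branch_clade: frozenset
    topologies: tuple[str, str, str]
    counts: tuple[float, float, float]
    effective_counts: tuple[float, float, float]
    genes_counted: int
    n_quartets_per_gene: int
    exact: bool

    @property
    def q(self) -> tuple[float, float, float]:
        c = np.asarray(self.counts, dtype=float)
        tot = c.sum()
        if tot == 0:
            return (float("nan"),) * 3
        q1 = c[0] / tot
        minors = sorted(c[1:] / tot, reverse=True)
        return (q1, minors[0], minors[1])

    def minor_effective_counts(self) -> tuple[float, float]:
        """Minor-resolution tallies, gene-scale, in fixed topology order."""
        return (self.effective_counts[1], self.effective_counts[2])


def _neighbor_clades(species_tree, clade):
    """The four clades around the internal branch above ``clade``."""
    clade = frozenset(clade)
    all_taxa = tip_labels(species_tree)
    target = None
    for node in species_tree.preorder_internal_node_iter():
        if node is species_tree.seed_node:
            continue
        if leafset_below(node) == clade:
            target = node
            break
    if target is None:
        raise TreeValidationError(f"no internal branch subtends {sorted(clade)}")
    kids = target.child_nodes()
    if len(kids) != 2:
        raise TreeValidationError("branch must sit in a binary region of the tree")
    a = leafset_below(kids[0])
    b = leafset_below(kids[1])
    parent = target.parent_node
    siblings = [c for c in parent.child_nodes() if c is not target]
    if parent is species_tree.seed_node:
        if len(siblings) == 1 and not siblings[0].is_leaf():
            sibs = siblings[0].child_nodes()
            if len(sibs) != 2:
                raise TreeValidationError("branch must sit in a binary region of the tree")
            c, d = leafset_below(sibs[0]), leafset_below(sibs[1])
        elif len(siblings) == 2:
            c, d = leafset_below(siblings[0]), leafset_below(siblings[1])
        else:
            raise TreeValidationError(
                "branch has fewer than four neighboring clades (root-adjacent cherry)"
            )
    else:
        c = leafset_below(siblings[0])
        d = all_taxa - clade - leafset_below(siblings[0])
        if not d:
            raise TreeValidationError("branch has fewer than four neighboring clades")
    return a, b, c, d


def branch_quartet_freqs(
    species_tree: dendropy.Tree,
    gene_trees: list[dendropy.Tree],
    branch_clade,
    max_quartets: int = 100_000,
    seed: int = 0,
) -> QuartetCounts:
    """Quartet resolution frequencies around a species-tree internal branch.

    For every quartet (a, b, c, d) drawn from the four neighboring clades
    A, B, C, D of the branch, the induced resolution in each gene tree is
    tallied: ab|cd matches the species tree; ac|bd and ad|bc are the two
    alternatives.  All quartets are enumerated when |A||B||C||D| <=
    ``max_quartets``; beyond that, quartets are sampled uniformly (seeded).
    """
    A, B, C, D = _neighbor_clades(species_tree, branch_clade)
    n_quartets = len(A) * len(B) * len(C) * len(D)
    if n_quartets <= max_quartets:
        quartets = list(product(sorted(A), sorted(B), sorted(C), sorted(D)))
        exact = True
    else:
        rng = np.random.default_rng(seed)
        sa, sb, sc, sd = sorted(A), sorted(B), sorted(C), sorted(D)
        quartets = [
            (sa[rng.integers(len(sa))], sb[rng.integers(len(sb))],
             sc[rng.integers(len(sc))], sd[rng.integers(len(sd))])
            for _ in range(max_quartets)
        ]
        exact = False

    raw = np.zeros(3)
    eff = np.zeros(3)
    genes_counted = 0
    for gt in gene_trees:
        gtaxa = tip_labels(gt)
        gbips = bipartitions(gt)
        gene_counts = np.zeros(3)
        for a, b, c, d in quartets:
            if not {a, b, c, d} <= gtaxa:
                continue
            res = _quartet_resolution(gbips, a, b, c, d)
            if res is not None:
                gene_counts[res] += 1
        r = gene_counts.sum()
        if r > 0:
            genes_counted += 1
            raw += gene_counts
            eff += gene_counts / r
    return QuartetCounts(
        branch_clade=frozenset(branch_clade),
        topologies=("AB|CD", "AC|BD", "AD|BC"),
        counts=tuple(raw),
        effective_counts=tuple(eff),
        genes_counted=genes_counted,
        n_quartets_per_gene=len(quartets),
        exact=exact,
    )


def _quartet_resolution(gbips, a, b, c, d):
    """0 = ab|cd, 1 = ac|bd, 2 = ad|bc, None = unresolved in the gene tree."""
    for bip in gbips:
        if bip.separates((a, b), (c, d)):
            return 0
        if bip.separates((a, c), (b, d)):
            return 1
        if bip.separates((a, d), (b, c)):
            return 2
    return None


# ---------------------------------------------------------------------------
# Rooted triplets
# ---------------------------------------------------------------------------

def triplet_freqs(
    gene_trees: list[dendropy.Tree],
    ingroup,
    outgroup: str,
) -> pd.DataFrame:
    """Rooted-triplet resolution frequencies across gene trees.

    For each combination of three ingroup taxa {x, y, z}, rooted with the
    outgroup, a gene tree supports the resolution xy|z when some
    bipartition separates {x, y} from {z, outgroup}.  Frequencies are over
    the gene trees containing all four taxa; each row sums to 1.
    """
    ingroup = sorted(set(ingroup))
    if outgroup in ingroup:
        raise TreeValidationError("outgroup must not be in the ingroup set")
    prepared = [(tip_labels(gt), bipartitions(gt)) for gt in gene_trees]
    for gtaxa, _ in prepared:
        if outgroup not in gtaxa:
            raise TreeValidationError(f"outgroup {outgroup!r} missing from a gene tree")
    rows = []
    for x, y, z in combinations(ingroup, 3):
        counts = {f"{x},{y}|{z}": 0, f"{x},{z}|{y}": 0, f"{y},{z}|{x}": 0}
        keys = list(counts)
        n_used = 0
        for gtaxa, gbips in prepared:
            if not {x, y, z} <= gtaxa:
                continue
            res = _quartet_resolution(gbips, x, y, z, outgroup)
            if res is None:
                continue
            # res: 0 -> xy|z-o, 1 -> xz|y-o, 2 -> xo|yz i.e. cherry (y,z)
            counts[keys[res]] += 1
            n_used += 1
        total = n_used if n_used else 1
        for key in keys:
            rows.append(
                {
                    "triplet": f"{x}|{y}|{z}",
                    "resolution": key,
                    "count": counts[key],
                    "freq": counts[key] / total,
                    "n_gene_trees": n_used,
                }
            )
    return pd.DataFrame(rows)


def triplet_freq_vector(table: pd.DataFrame) -> dict[str, float]:
    """Flatten a triplet_freqs table to {'triplet:resolution': freq}."""
    return {
        f"{r.triplet}:{r.resolution}": r.freq for r in table.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# Topology spectrum
# ---------------------------------------------------------------------------

def canonical_topology(tree: dendropy.Tree) -> str:
    """Rotation-invariant rooted topology string (lengths/supports ignored)."""

    def canon(node):
        if node.is_leaf():
            return node.taxon.label
        return "(" + ",".join(sorted(canon(c) for c in node.child_nodes())) + ")"

    return canon(tree.seed_node) + ";"


@dataclass
class TopologySpectrum:
    counts: dict[str, int]
    total: int

    def freqs(self) -> dict[str, float]:
        return {k: v / self.total for k, v in self.counts.items()}

    def most_common(self, n: int = 1):
        return Counter(self.counts).most_common(n)


def topology_spectrum(trees: list[dendropy.Tree]) -> TopologySpectrum:
    """Count distinct rooted topologies in a set of same-taxon trees."""
    ref = tip_labels(trees[0])
    counts: Counter[str] = Counter()
    for t in trees:
        if tip_labels(t) != ref:
            raise TreeValidationError("topology spectrum requires identical tip sets")
        counts[canonical_topology(t)] += 1
    return TopologySpectrum(counts=dict(counts), total=len(trees))
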