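"""Core tree model and operations.

Trees are :class:`dendropy.Tree` objects.  Two lightweight conventions are
layered on top:

* ``node.support`` — per-internal-node support on a 0–100 percent scale
  (bootstrap or local posterior probability rescaled on read), or ``None``
  when absent.
* ``tree.length_units`` — a tag in ``{"substitutions_per_site",
  "coalescent", "unitless"}`` recording what the branch lengths mean.

Bipartitions are represented explicitly as pairs of taxon-label sets
(:class:`Bipartition`) rather than bitmasks, because most downstream
analyses (concordance mapping, quartet counting) need to restrict them to
arbitrary taxon subsets.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np

UNIT_TAGS = ("substitutions_per_site", "coalescent", "unitless")


class NewickParseError(ValueError):
    pass


class TreeValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

class Bipartition:
    """An unordered split of a taxon set into two non-empty sides."""

    __slots__ = ("_sides",)

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise TreeValidationError("both sides of a bipartition must be non-empty")
        if a & b:
            raise TreeValidationError(f"bipartition sides overlap: {sorted(a & b)}")
        # canonical order for repr stability; equality ignores order
        self._sides = tuple(sorted((a, b), key=lambda s: (len(s), sorted(s))))

    @property
    def sides(self) -> tuple[frozenset, frozenset]:
        return self._sides

    @property
    def taxa(self) -> frozenset:
        return self._sides[0] | self._sides[1]

    @property
    def is_trivial(self) -> bool:
        return min(len(self._sides[0]), len(self._sides[1])) == 1

    def __eq__(self, other) -> bool:
        return isinstance(other, Bipartition) and self._sides == other._sides

    def __hash__(self) -> int:
        return hash(self._sides)

    def __repr__(self) -> str:
        a, b = self._sides
        return f"Bipartition({'|'.join(sorted(a))} -- {'|'.join(sorted(b))})"

    def restrict(self, taxa: Iterable[str]) -> "Bipartition | None":
        """Induced bipartition on a taxon subset; ``None`` if a side empties."""
        taxa = frozenset(taxa)
        a = self._sides[0] & taxa
        b = self._sides[1] & taxa
        if not a or not b:
            return None
        return Bipartition(a, b)

    def separates(self, pair1: Iterable[str], pair2: Iterable[str]) -> bool:
        """True if one side contains all of pair1 and the other all of pair2."""
        p1, p2 = frozenset(pair1), frozenset(pair2)
        a, b = self._sides
        return (p1 <= a and p2 <= b) or (p1 <= b and p2 <= a)

    def is_compatible_with(self, other: "Bipartition") -> bool:
        """Split compatibility on a shared taxon set.

        Two splits A|B and C|D can co-occur in one tree iff at least one of
        the four cross-intersections is empty.
        """
        if self.taxa != other.taxa:
            raise TreeValidationError("compatibility requires identical taxon sets")
        a, b = self._sides
        c, d = other._sides
        return not (a & c) or not (a & d) or not (b & c) or not (b & d)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _parse_support(label: str | None, as_fraction: bool) -> float | None:
    if label is None:
        return None
    try:
        val = float(label)
    except ValueError:
        return None
    return val * 100.0 if as_fraction else val


def read_newick(
    text: str,
    units: str = "unitless",
    support_as_fraction: bool = False,
) -> list[dendropy.Tree]:
    """Parse one or more Newick trees from a string.

    Internal node labels that parse as numbers are interpreted as support
    values; with ``support_as_fraction=True`` they are taken as posterior
    probabilities in [0, 1] and rescaled to the common 0–100 percent scale.
    """
    if units not in UNIT_TAGS:
        raise ValueError(f"units must be one of {UNIT_TAGS}")
    try:
        trees = dendropy.TreeList.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(str(exc)) from exc
    out = []
    for tree in trees:
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dups}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length on edge above {_edge_name(edge)}"
                )
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                node.support = None
            else:
                node.support = _parse_support(node.label, support_as_fraction)
        tree.length_units = units
        out.append(tree)
    return out


def read_newick_file(path, units: str = "unitless", support_as_fraction: bool = False):
    with open(path) as fh:
        return read_newick(fh.read(), units=units, support_as_fraction=support_as_fraction)


def _edge_name(edge) -> str:
    head = edge.head_node
    if head.is_leaf():
        return head.taxon.label
    return "{" + ",".join(sorted(l.taxon.label for l in head.leaf_iter())) + "}"


def _sync_support_labels(tree: dendropy.Tree) -> None:
    for node in tree.preorder_internal_node_iter():
        sup = getattr(node, "support", None)
        if sup is not None:
            node.label = format(sup, "g")


def write_newick(trees: Sequence[dendropy.Tree] | dendropy.Tree, path=None) -> str:
    """Serialize trees to Newick, one per line, supports as node labels."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    buf = io.StringIO()
    for tree in trees:
        _sync_support_labels(tree)
        buf.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
        )
        buf.write("\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Basic accessors
# ---------------------------------------------------------------------------

def tip_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def leafset_below(node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def is_rooted_binary_root(tree: dendropy.Tree) -> bool:
    return len(tree.seed_node.child_nodes()) == 2


def is_binary(tree: dendropy.Tree) -> bool:
    for node in tree.preorder_internal_node_iter():
        if len(node.child_nodes()) != 2:
            return False
    return True


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter() if e.tail_node is not None)


def root_to_tip_lengths(tree: dendropy.Tree) -> dict[str, float]:
    depths = {}

    def _walk(node, depth):
        for child in node.child_nodes():
            d = depth + (child.edge.length or 0.0)
            if child.is_leaf():
                depths[child.taxon.label] = d
            else:
                _walk(child, d)

    _walk(tree.seed_node, 0.0)
    return depths


def clone(tree: dendropy.Tree) -> dendropy.Tree:
    new = tree.clone(depth=1)
    new.length_units = getattr(tree, "length_units", "unitless")
    return new


# ---------------------------------------------------------------------------
# Bipartition extraction
# ---------------------------------------------------------------------------

def bipartitions(tree: dendropy.Tree, include_trivial: bool = False) -> set[Bipartition]:
    """Unrooted bipartitions of the tree, one per internal edge.

    The root edge of a rooted tree is not double-counted: the two edges
    incident to a bifurcating root induce the same split and appear once.
    """
    all_taxa = tip_labels(tree)
    if len(all_taxa) < 3:
        warnings.warn("fewer than 3 tips: no bipartitions", stacklevel=2)
        return set()
    out: set[Bipartition] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = leafset_below(node)
        above = all_taxa - below
        if not above:
            continue
        if node.is_leaf():
            if include_trivial:
                out.add(Bipartition(below, above))
            continue
        bip = Bipartition(below, above)
        if bip.is_trivial and not include_trivial:
            continue
        out.add(bip)
    return out


# ---------------------------------------------------------------------------
# Robinson–Foulds
# ---------------------------------------------------------------------------

def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree, normalized: bool = False) -> float:
    """Unweighted Robinson–Foulds distance (non-trivial splits only).

    Rooted trees are compared on their unrooted bipartition sets.  The
    normalized variant divides by 2(n-3), the maximum for binary unrooted
    trees on n tips.
    """
    taxa1, taxa2 = tip_labels(t1), tip_labels(t2)
    if taxa1 != taxa2:
        only1 = sorted(taxa1 - taxa2)
        only2 = sorted(taxa2 - taxa1)
        raise TreeValidationError(
            f"tip sets differ: only in first {only1}, only in second {only2}"
        )
    b1 = bipartitions(t1)
    b2 = bipartitions(t2)
    dist = float(len(b1 ^ b2))
    if normalized:
        n = len(taxa1)
        denom = 2.0 * (n - 3)
        return dist / denom if denom > 0 else 0.0
    return dist


# ---------------------------------------------------------------------------
# Support-based collapsing
# ---------------------------------------------------------------------------

def collapse_low_support(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Contract internal edges whose support is strictly below ``threshold``.

    Edges lacking a support value are never collapsed (absence is not
    evidence of low support).  Tips are untouched.
    """
    new = clone(tree)
    to_collapse = []
    for node in new.preorder_internal_node_iter():
        if node is new.seed_node:
            continue
        sup = getattr(node, "support", None)
        if sup is not None and sup < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return new


# ---------------------------------------------------------------------------
# Taxon restriction
# ---------------------------------------------------------------------------

def restrict(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on a taxon subset.

    Degree-2 nodes created by pruning are suppressed with branch lengths
    summed, so patristic distances among retained taxa are preserved.
    """
    taxa = frozenset(taxa)
    present = tip_labels(tree)
    unknown = taxa - present
    if unknown:
        raise TreeValidationError(f"taxa not in tree: {sorted(unknown)}")
    if len(taxa) < 2:
        raise TreeValidationError("need at least 2 taxa to restrict to")
    new = clone(tree)
    new.retain_taxa_with_labels(sorted(taxa))
    # retain_taxa suppresses internal unifurcations; make sure a chain at the
    # root is fully suppressed too
    new.suppress_unifurcations()
    new.seed_node.edge.length = None
    return new


# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------

def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Pairwise path-length matrix; labels returned sorted."""
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            raise TreeValidationError(
                f"missing branch length on edge above {_edge_name(edge)}"
            )
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(tip_labels(tree))
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in labels}
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return labels, mat


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def consensus_tree(trees: Sequence[dendropy.Tree], min_freq: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus containing splits with frequency >= min_freq."""
    ref = tip_labels(trees[0])
    for t in trees[1:]:
        if tip_labels(t) != ref:
            raise TreeValidationError("consensus requires identical tip sets")
    # re-read into a common taxon namespace
    text = "".join(
        t.as_string(schema="newick", suppress_rooting=True) for t in trees
    )
    tl = dendropy.TreeList.get(data=text, schema="newick")
    # dendropy treats min_freq as a strict ">" cutoff in places; nudge down so
    # a split at exactly min_freq is included, matching the >= convention
    cons = tl.consensus(min_freq=max(min_freq - 1e-9, 0.0))
    cons.length_units = getattr(trees[0], "length_units", "unitless")
    for node in cons.preorder_node_iter():
        node.support = None
    return cons
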