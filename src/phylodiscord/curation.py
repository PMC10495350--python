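"""Dataset-assembly filters and clock-likeness ranking.

Upstream orthology inference, alignment and trimming are assumed done;
this module applies the final keep/drop rules before tree building —
minimum taxon occupancy against a reference panel, minimum alignment
length, and a pairwise-identity floor — and ranks gene trees by
clock-likeness (bipartition support to the species tree, then root-to-tip
variance, then total tree length) in the manner of SortaDate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

from .alignments import GAP_CHARS, Alignment
from .trees import (
    Bipartition,
    TreeValidationError,
    bipartitions,
    root_to_tip_lengths,
    tip_labels,
    total_tree_length,
)

__all__ = ["filter_alignments", "rank_clocklike", "pairwise_identity"]


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Fraction identical over mutually non-gap columns (NaN if none)."""
    used = same = 0
    for a, b in zip(seq1, seq2):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        used += 1
        if a == b:
            same += 1
    return same / used if used else float("nan")


@dataclass
class FilterReport:
    frame: pd.DataFrame          # one row per input gene
    sequences_removed: int
    genes_dropped: int


def filter_alignments(
    alns: list[Alignment],
    reference_taxa,
    min_occupancy: float = 0.5,
    min_len: int = 100,
    min_pairwise_identity: float = 0.2,
    identity_per_alignment: bool = False,
) -> tuple[list[Alignment], FilterReport]:
    """Apply the occupancy / length / identity filters.

    Per gene, in order:

    1. identity — with ``identity_per_alignment=False`` (default) each
       sequence whose *maximum* identity to any other row falls below
       ``min_pairwise_identity`` is removed; with the flag set, the whole
       alignment is dropped when its mean pairwise identity is below the
       threshold;
    2. occupancy — the gene is dropped when the fraction of the reference
       taxon panel present is below ``min_occupancy``;
    3. length — the gene is dropped when shorter than ``min_len`` columns.

    Both occupancy and length use strict "below threshold" semantics, so a
    gene exactly at either threshold is retained.
    """
    if not alns:
        raise ValueError("no alignments given")
    reference_taxa = frozenset(reference_taxa)
    if not reference_taxa:
        raise ValueError("reference taxon set is empty")

    retained: list[Alignment] = []
    rows = []
    seqs_removed_total = 0
    for aln in alns:
        row = {
            "gene": aln.name,
            "n_taxa_in": aln.n_taxa,
            "length": aln.length,
            "sequences_removed": 0,
            "kept": False,
            "reason": "",
        }
        work = aln
        if identity_per_alignment:
            idents = [
                pairwise_identity(a, b)
                for a, b in combinations(work.rows, 2)
            ]
            idents = [x for x in idents if np.isfinite(x)]
            if idents and float(np.mean(idents)) < min_pairwise_identity:
                row["reason"] = "mean_identity"
                rows.append(row)
                continue
        else:
            keep_labels = []
            for label in work.labels:
                others = [l for l in work.labels if l != label]
                if not others:
                    keep_labels.append(label)
                    continue
                best = max(
                    (pairwise_identity(work.sequence(label), work.sequence(o)) for o in others),
                    default=float("nan"),
                )
                if np.isnan(best) or best >= min_pairwise_identity:
                    keep_labels.append(label)
            removed = work.n_taxa - len(keep_labels)
            row["sequences_removed"] = removed
            seqs_removed_total += removed
            if not keep_labels:
                row["reason"] = "empty_after_identity"
                rows.append(row)
                continue
            if removed:
                work = work.subset(keep_labels)

        occupancy = len(set(work.labels) & reference_taxa) / len(reference_taxa)
        row["occupancy"] = occupancy
        if occupancy < min_occupancy:
            row["reason"] = "occupancy"
            rows.append(row)
            continue
        if work.length < min_len:
            row["reason"] = "length"
            rows.append(row)
            continue
        row["kept"] = True
        rows.append(row)
        retained.append(work)
    frame = pd.DataFrame(rows)
    report = FilterReport(
        frame=frame,
        sequences_removed=seqs_removed_total,
        genes_dropped=int((~frame["kept"]).sum()),
    )
    return retained, report


def rank_clocklike(
    gene_trees: list[dendropy.Tree],
    species_bipartitions: set[Bipartition],
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Rank genes by clock-likeness, SortaDate style.

    Per gene tree: the fraction of its non-trivial bipartitions found in
    the species tree ("bipartition support"), the variance of root-to-tip
    path lengths, and the total tree length.  Genes are sorted
    lexicographically — support descending, then variance ascending, then
    length ascending — and the 1-based ``rank`` column records the result.
    Trees must be rooted (root-to-tip depths are meaningless otherwise).
    """
    if names is None:
        names = [f"gene{i + 1}" for i in range(len(gene_trees))]
    rows = []
    for name, tree in zip(names, gene_trees):
        if len(tree.seed_node.child_nodes()) != 2:
            raise TreeValidationError(
                f"gene tree {name!r} is unrooted; root with an outgroup first"
            )
        gbips = bipartitions(tree)
        if gbips:
            support = sum(1 for b in gbips if b in species_bipartitions) / len(gbips)
        else:
            support = 0.0
        depths = np.array(list(root_to_tip_lengths(tree).values()))
        rows.append(
            {
                "gene": name,
                "bipartition_support": support,
                "root_to_tip_variance": float(np.var(depths)),
                "tree_length": total_tree_length(tree),
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        by=["bipartition_support", "root_to_tip_variance", "tree_length", "gene"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
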