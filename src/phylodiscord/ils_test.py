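"""ILS-versus-gene-flow decision procedure.

Under the multispecies coalescent without gene flow, the two minor quartet
resolutions around a branch are equally probable.  Two statistics probe
departures from that expectation:

* a Pearson chi-square test of homogeneity comparing the empirical minor
  tallies (N2, N3) against tallies from gene trees simulated under the
  fitted MSC (M2, M3) — a small P-value means the empirical minor-topology
  balance differs from what ILS alone produces;
* the Quartet Differential, QD = 1 - |N2 - N3| / (N2 + N3), which is 1 for
  perfectly symmetric discordance and 0 for fully skewed discordance.

The decision rule (thresholds 0.1 and 0.8 by default): a branch is
ILS-consistent when P > 0.1 and QD > 0.8; gene flow is suspected when both
fall at or below their thresholds; anything else is ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

from .concordance import QuartetCounts, branch_quartet_freqs
from .trees import TreeValidationError, rf_distance, tip_labels

__all__ = [
    "BranchVerdict",
    "minor_quartet_chi2",
    "quartet_differential",
    "freq_correlation",
    "rf_overlap",
    "classify_branch",
    "test_branch",
]


@dataclass
class BranchVerdict:
    branch_clade: frozenset | None
    chi2: float
    p_value: float
    qd: float | None
    label: str  # "ILS-consistent" | "gene-flow-suspected" | "ambiguous"
    p_threshold: float
    qd_threshold: float


def minor_quartet_chi2(
    empirical: tuple[float, float],
    simulated: tuple[float, float],
) -> tuple[float, float]:
    """Pearson chi-square of homogeneity on [[N2, N3], [M2, M3]].

    df = 1, no continuity correction.  Counts may be non-integral (e.g.
    gene-scale effective counts).  A zero row is an error; a zero column
    yields statistic 0 and P = 1 with a warning.
    """
    n2, n3 = empirical
    m2, m3 = simulated
    table = np.array([[n2, n3], [m2, m3]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("each row of the 2x2 table must have a positive total")
    if (table.sum(axis=0) == 0).any():
        warnings.warn("a minor topology is absent from both sets", stacklevel=2)
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def quartet_differential(n2: float, n3: float) -> float | None:
    """QD = 1 - |N2 - N3| / (N2 + N3); ``None`` when no minor quartets."""
    if n2 < 0 or n3 < 0:
        raise ValueError("counts must be non-negative")
    total = n2 + n3
    if total == 0:
        return None
    return 1.0 - abs(n2 - n3) / total


def freq_correlation(
    empirical: dict[str, float],
    simulated: dict[str, float],
) -> tuple[float, float, float]:
    """Pearson correlation of two frequency vectors aligned by key.

    Keys absent from one vector contribute 0.  Returns (r, r^2, two-sided
    P); all NaN when either aligned vector has zero variance.
    """
    keys = sorted(set(empirical) | set(simulated))
    if len(keys) < 3:
        raise ValueError("need at least 3 aligned frequencies")
    x = np.array([empirical.get(k, 0.0) for k in keys])
    y = np.array([simulated.get(k, 0.0) for k in keys])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan"), float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def rf_overlap(
    empirical: list[dendropy.Tree],
    simulated: list[dendropy.Tree],
    reference: dendropy.Tree,
) -> float:
    """Overlap of the two RF-to-reference distance distributions.

    Each tree set yields a discrete distribution of unweighted RF distances
    to the reference topology; the overlap coefficient
    sum_d min(f_emp(d), f_sim(d)) in [0, 1] measures how much of the
    empirical tree-to-species-tree variation the simulated (pure-ILS) set
    reproduces.
    """
    ref_taxa = tip_labels(reference)
    for t in empirical + simulated:
        if tip_labels(t) != ref_taxa:
            raise TreeValidationError("all trees must share the reference tip set")
    d_emp = [rf_distance(t, reference) for t in empirical]
    d_sim = [rf_distance(t, reference) for t in simulated]
    values = sorted(set(d_emp) | set(d_sim))
    f_emp = np.array([d_emp.count(v) / len(d_emp) for v in values])
    f_sim = np.array([d_sim.count(v) / len(d_sim) for v in values])
    return float(np.minimum(f_emp, f_sim).sum())


def classify_branch(
    p_value: float,
    qd: float | None,
    p_threshold: float = 0.1,
    qd_threshold: float = 0.8,
) -> str:
    """Apply the P/QD decision rule; QD undefined always yields ambiguous."""
    for thr in (p_threshold, qd_threshold):
        if not 0.0 < thr < 1.0:
            raise ValueError("thresholds must be in (0, 1)")
    if qd is None or np.isnan(qd):
        return "ambiguous"
    if p_value > p_threshold and qd > qd_threshold:
        return "ILS-consistent"
    if p_value <= p_threshold and qd <= qd_threshold:
        return "gene-flow-suspected"
    return "ambiguous"


def test_branch(
    species_tree: dendropy.Tree,
    empirical_gene_trees: list[dendropy.Tree],
    simulated_gene_trees: list[dendropy.Tree],
    branch_clade,
    p_threshold: float = 0.1,
    qd_threshold: float = 0.8,
    support_threshold: float = 0.0,
    max_quartets: int = 100_000,
    seed: int = 0,
) -> BranchVerdict:
    """End-to-end decision for one branch.

    Minor tallies on both sides are gene-scale effective counts in matching
    topology order; QD is computed from the empirical tallies.  Gene trees
    are optionally collapsed at ``support_threshold`` before counting.
    """
    from .trees import collapse_low_support

    if support_threshold > 0:
        empirical_gene_trees = [
            collapse_low_support(t, support_threshold) for t in empirical_gene_trees
        ]
    emp = branch_quartet_freqs(
        species_tree, empirical_gene_trees, branch_clade,
        max_quartets=max_quartets, seed=seed,
    )
    sim = branch_quartet_freqs(
        species_tree, simulated_gene_trees, branch_clade,
        max_quartets=max_quartets, seed=seed,
    )
    chi2, p = minor_quartet_chi2(emp.minor_effective_counts(), sim.minor_effective_counts())
    n2, n3 = emp.minor_effective_counts()
    qd = quartet_differential(n2, n3)
    label = classify_branch(p, qd, p_threshold, qd_threshold)
    return BranchVerdict(
        branch_clade=frozenset(branch_clade),
        chi2=chi2,
        p_value=p,
        qd=qd,
        label=label,
        p_threshold=p_threshold,
        qd_threshold=qd_threshold,
    )
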