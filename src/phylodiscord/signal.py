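"""Gene-wise phylogenetic signal and per-gene alignment diagnostics.

The central statistic is the gene-wise log-likelihood difference among
candidate topologies: a gene strongly supports topology Ti when lnL(Ti)
exceeds the log-likelihood of *both* alternatives by at least a margin
(default 2 log units); it weakly supports Ti when Ti is the unique maximum
but some margin falls short.  The module consumes externally computed
log-likelihood tables and also provides a self-contained Felsenstein
pruning evaluator (fixed branch lengths, time-reversible models, optional
discrete-gamma rates) so that the classification can be exercised end to
end on simulated alignments.

Per-gene diagnostics follow the TreSpEx conventions: parsimony-informative
site counts, substitution saturation as the OLS slope of uncorrected
p-distance on patristic distance (slope near 1 = unsaturated, well below
1 = saturated), and evolutionary rate as the mean patristic distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .alignments import AMBIGUOUS_CHARS, GAP_CHARS, Alignment
from .trees import TreeValidationError, patristic_matrix, tip_labels

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "SubstModel",
    "classify_gene_support",
    "gene_log_likelihood",
    "alignment_diagnostics",
    "GeneDiagnostics",
]


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------

@dataclass
class SubstModel:
    """Time-reversible CTMC: exchangeabilities + equilibrium frequencies.

    The generator Q[i, j] = s[i, j] * pi[j] (i != j) is normalized to one
    expected substitution per unit branch length.  ``gamma_shape`` switches
    on discrete-gamma among-site rate variation with ``gamma_ncat``
    mean-per-category rates.
    """

    states: str
    exchangeabilities: np.ndarray
    freqs: np.ndarray
    gamma_shape: float | None = None
    gamma_ncat: int = 4

    def __post_init__(self):
        k = len(self.states)
        if k < 2:
            raise ValueError("model needs at least two states")
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.freqs, dtype=float)
        if s.shape != (k, k) or pi.shape != (k,):
            raise ValueError("inconsistent model dimensions")
        if not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if not np.isclose(pi.sum(), 1.0):
            raise ValueError("equilibrium frequencies must sum to 1")
        self.exchangeabilities = s
        self.freqs = pi

    @property
    def n_states(self) -> int:
        return len(self.states)

    def rate_matrix(self) -> np.ndarray:
        k = self.n_states
        q = self.exchangeabilities * self.freqs[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -(self.freqs * np.diag(q)).sum()
        return q / mean_rate

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.gamma_ncat)

    @classmethod
    def poisson(cls, states: str = AMINO_ACIDS, **kw) -> "SubstModel":
        """Equal exchangeabilities and equal frequencies (Poisson model)."""
        k = len(states)
        s = np.ones((k, k))
        np.fill_diagonal(s, 0.0)
        return cls(states, s, np.full(k, 1.0 / k), **kw)


def discrete_gamma_rates(shape: float, ncat: int) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability gamma categories (mean 1)."""
    # X ~ Gamma(shape, scale=1/shape); E[X | bin] via the Gamma(shape+1) CDF
    bounds = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), shape, scale=1.0 / shape)
    upper_cdf = gamma_dist.cdf(bounds, shape + 1, scale=1.0 / shape)
    rates = ncat * np.diff(upper_cdf)
    return rates / rates.mean()


# ---------------------------------------------------------------------------
# Delta-lnL classification
# ---------------------------------------------------------------------------

def classify_gene_support(
    lnl: pd.DataFrame,
    margin: float = 2.0,
) -> tuple[pd.Series, dict[str, float]]:
    """Classify each gene's support among candidate topologies.

    ``lnl`` has one row per gene and one column of log-likelihoods per
    topology (e.g. ``lnl_T1``, ``lnl_T2``, ``lnl_T3``).  A gene is
    ``strong_Ti`` when Ti beats every alternative by at least ``margin``
    log units, ``weak_Ti`` when Ti is the unique maximum but at least one
    margin falls short, and ``unclassifiable`` on an exact tie for the
    maximum (excluded from the summary fractions).

    Returns the per-gene label series and a dict of summary fractions over
    all genes.
    """
    values = lnl.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("log-likelihoods must be finite")
    names = [c.removeprefix("lnl_") for c in lnl.columns]
    labels = []
    for row in values:
        order = np.argsort(row)[::-1]
        best, second = order[0], order[1]
        if row[best] == row[second]:
            labels.append("unclassifiable")
            continue
        margins = row[best] - np.delete(row, best)
        kind = "strong" if (margins >= margin).all() else "weak"
        labels.append(f"{kind}_{names[best]}")
    label_series = pd.Series(labels, index=lnl.index, name="signal_class")
    n = len(labels)
    summary = {}
    for name in names:
        for kind in ("strong", "weak"):
            key = f"{kind}_{name}"
            summary[key] = labels.count(key) / n if n else float("nan")
    summary["unclassifiable"] = labels.count("unclassifiable") / n if n else float("nan")
    return label_series, summary


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _transition_matrices(q, pi, lengths):
    """P(t) for every branch length via the reversible-symmetrization trick."""
    sq = np.sqrt(pi)
    b = (q * sq[:, None]) / sq[None, :]
    b = (b + b.T) / 2.0  # symmetric for reversible q; average kills roundoff
    w, v = np.linalg.eigh(b)
    # P(t) = diag(1/sq) V exp(w t) V' diag(sq)
    left = v / sq[:, None]
    right = (v * sq[:, None]).T
    t = np.asarray(lengths)[:, None]
    expwt = np.exp(w[None, :] * t)  # (nbr, k)
    return np.einsum("ik,bk,kj->bij", left, expwt, right)


def _encode_column(chars, states):
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    out = np.zeros((len(chars), k))
    for r, ch in enumerate(chars):
        if ch in GAP_CHARS or ch in AMBIGUOUS_CHARS:
            out[r, :] = 1.0
        else:
            if ch not in idx:
                raise ValueError(f"character {ch!r} not in model states")
            out[r, idx[ch]] = 1.0
    return out


def gene_log_likelihood(
    aln: Alignment,
    tree: dendropy.Tree,
    model: SubstModel,
) -> float:
    """Felsenstein pruning log-likelihood with fixed branch lengths.

    Sites are independent; gaps and ambiguity codes contribute all-ones
    partials (missing data); the root is closed with the model's
    equilibrium frequencies (the likelihood is root-invariant for these
    reversible models).  With discrete-gamma rates the per-site likelihood
    averages over equally probable rate categories.
    """
    taxa = tip_labels(tree)
    missing = taxa - set(aln.labels)
    if missing:
        raise TreeValidationError(f"alignment lacks tree taxa: {sorted(missing)}")
    pi = model.freqs
    q = model.rate_matrix()
    k = model.n_states
    nsites = aln.length
    rates = model.category_rates()

    nodes = list(tree.postorder_node_iter())
    branch_nodes = [nd for nd in nodes if nd is not tree.seed_node]
    lengths = []
    for nd in branch_nodes:
        if nd.edge.length is None:
            raise TreeValidationError("tree has a missing branch length")
        lengths.append(nd.edge.length)
    lengths = np.asarray(lengths)

    # tip partials (k x nsites per leaf)
    tip_partials = {}
    for leaf in tree.leaf_node_iter():
        seq = aln.sequence(leaf.taxon.label)
        tip_partials[leaf] = _encode_column(seq, model.states).T  # (k, nsites)

    site_like = np.zeros(nsites)
    for rate in rates:
        pmats = _transition_matrices(q, pi, np.maximum(lengths * rate, 0.0))
        pmat_of = dict(zip(branch_nodes, pmats))
        partial = {}
        scale_log = {}
        for nd in nodes:
            if nd.is_leaf():
                partial[nd] = tip_partials[nd]
                scale_log[nd] = np.zeros(nsites)
                continue
            prod = np.ones((k, nsites))
            logs = np.zeros(nsites)
            for child in nd.child_nodes():
                prod *= pmat_of[child] @ partial[child]
                logs += scale_log[child]
            mx = prod.max(axis=0)
            mx[mx == 0.0] = 1.0
            partial[nd] = prod / mx
            scale_log[nd] = logs + np.log(mx)
        root = tree.seed_node
        site_like += np.exp(
            scale_log[root] + np.log(np.maximum(pi @ partial[root], 1e-300))
        ) / len(rates)
    return float(np.log(site_like).sum())


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

@dataclass
class GeneDiagnostics:
    informative_sites: int
    saturation_slope: float  # NaN when undefined
    rate: float              # mean patristic distance
    n_taxa: int
    alignment_length: int


def count_informative_sites(aln: Alignment) -> int:
    """Parsimony-informative columns: >=2 states each in >=2 sequences."""
    count = 0
    for i in range(aln.length):
        col = [c for c in aln.column(i) if c not in GAP_CHARS and c not in AMBIGUOUS_CHARS]
        tallies = {}
        for c in col:
            tallies[c] = tallies.get(c, 0) + 1
        if sum(1 for v in tallies.values() if v >= 2) >= 2:
            count += 1
    return count


def p_distance(seq1: str, seq2: str) -> float:
    """Uncorrected distance over mutually determined (non-gap) columns."""
    used = diffs = 0
    for a, b in zip(seq1, seq2):
        if a in GAP_CHARS or b in GAP_CHARS or a in AMBIGUOUS_CHARS or b in AMBIGUOUS_CHARS:
            continue
        used += 1
        if a != b:
            diffs += 1
    return diffs / used if used else float("nan")


def alignment_diagnostics(aln: Alignment, tree: dendropy.Tree) -> GeneDiagnostics:
    """Informative sites, saturation slope, and mean-patristic rate.

    The saturation regression puts p-distance on the y-axis and patristic
    distance on the x-axis (with intercept); an unsaturated gene has slope
    near 1 and saturation pulls the slope toward 0.  Undefined (NaN) with
    fewer than 4 sequences.
    """
    taxa = sorted(tip_labels(tree))
    missing = set(taxa) - set(aln.labels)
    if missing:
        raise TreeValidationError(f"alignment lacks tree taxa: {sorted(missing)}")
    labels, pd_mat = patristic_matrix(tree)
    pairs = list(combinations(range(len(labels)), 2))
    patristic = np.array([pd_mat[i, j] for i, j in pairs])
    rate = float(patristic.mean())
    informative = count_informative_sites(aln)
    if len(labels) < 4:
        slope = float("nan")
    else:
        pdist = np.array(
            [p_distance(aln.sequence(labels[i]), aln.sequence(labels[j])) for i, j in pairs]
        )
        ok = np.isfinite(pdist)
        if ok.sum() < 3 or np.allclose(patristic[ok], patristic[ok][0]):
            slope = float("nan")
        else:
            slope = float(np.polyfit(patristic[ok], pdist[ok], 1)[0])
    return GeneDiagnostics(
        informative_sites=informative,
        saturation_slope=slope,
        rate=rate,
        n_taxa=len(labels),
        alignment_length=aln.length,
    )
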