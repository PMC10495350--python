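"""Ancestral-state estimation for discrete characters.

An all-rates-different (ARD) continuous-time Markov chain is fitted by
maximum likelihood on a time-scaled tree — every ordered state pair gets
its own rate, k(k-1) free parameters optimized as log-rates by
quasi-Newton from several seeded starts, with a uniform root prior.
Ancestral states are then summarized two ways:

* :func:`marginal_asr` — exact per-node marginal posteriors by a
  standard up/down pass of the pruning algorithm;
* :func:`stochastic_maps` — full character histories sampled conditional
  on the tip data (joint node states by recursive conditioning, then
  within-branch paths by uniformization), whose per-node state frequencies
  converge to the marginal posteriors as the number of maps grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .trees import TreeValidationError, leafset_below, tip_labels

__all__ = [
    "make_generator",
    "validate_generator",
    "transition_probs",
    "fit_ard",
    "marginal_asr",
    "stochastic_maps",
    "ArdFit",
    "SimmapSet",
]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_generator(rates: np.ndarray, k: int) -> np.ndarray:
    """Build a k x k generator from k(k-1) off-diagonal rates (row-major)."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (k * (k - 1),):
        raise ValueError(f"expected {k * (k - 1)} rates for k={k}")
    if (rates < 0).any():
        raise ValueError("rates must be non-negative")
    q = np.zeros((k, k))
    idx = 0
    for i in range(k):
        for j in range(k):
            if i != j:
                q[i, j] = rates[idx]
                idx += 1
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def validate_generator(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    k = q.shape[0]
    if q.shape != (k, k):
        raise ValueError("generator must be square")
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < -1e-12).any():
        raise ValueError("off-diagonal rates must be non-negative")
    if not np.allclose(q.sum(axis=1), 0.0, atol=1e-8):
        raise ValueError("generator rows must sum to zero")
    return q


def transition_probs(q: np.ndarray, t: float) -> np.ndarray:
    """exp(Q t): a proper stochastic matrix for t >= 0."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return expm(validate_generator(q) * t)


def _propagators(q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """exp(Q t) for many t at once (eigendecomposition, expm fallback)."""
    k = q.shape[0]
    lengths = np.asarray(lengths, dtype=float)
    try:
        w, v = np.linalg.eig(q)
        vinv = np.linalg.inv(v)
        expwt = np.exp(w[None, :] * lengths[:, None])
        p = np.einsum("ik,bk,kj->bij", v, expwt, vinv)
        p = np.real(p)
        check = expm(q * lengths.max()) if lengths.size else None
        if check is not None and not np.allclose(
            p[int(np.argmax(lengths))], check, atol=1e-8
        ):
            raise np.linalg.LinAlgError("eig reconstruction inaccurate")
    except np.linalg.LinAlgError:
        p = np.stack([expm(q * t) for t in lengths])
    return np.clip(p, 0.0, None)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def _tip_likelihoods(tree, tip_states, k):
    taxa = tip_labels(tree)
    missing = taxa - set(tip_states)
    if missing:
        raise TreeValidationError(f"states missing for tips: {sorted(missing)}")
    out = {}
    for leaf in tree.leaf_node_iter():
        s = tip_states[leaf.taxon.label]
        vec = np.ones(k) if s is None else None
        if vec is None:
            s = int(s)
            if not 0 <= s < k:
                raise ValueError(f"state {s} out of range for k={k}")
            vec = np.zeros(k)
            vec[s] = 1.0
        out[leaf] = vec
    return out


def _branch_setup(tree):
    nodes = list(tree.postorder_node_iter())
    branch_nodes = [nd for nd in nodes if nd is not tree.seed_node]
    lengths = []
    for nd in branch_nodes:
        bl = nd.edge.length
        if bl is None or bl <= 0:
            raise TreeValidationError("all branch lengths must be present and > 0")
        lengths.append(bl)
    return nodes, branch_nodes, np.asarray(lengths)


def _up_pass(nodes, pmat_of, tip_like, k):
    """Partial likelihoods L_v(i) = P(data below v | state i), log-scaled."""
    partial, log_scale = {}, {}
    for nd in nodes:
        if nd.is_leaf():
            partial[nd] = tip_like[nd]
            log_scale[nd] = 0.0
            continue
        vec = np.ones(k)
        ls = 0.0
        for child in nd.child_nodes():
            vec = vec * (pmat_of[child] @ partial[child])
            ls += log_scale[child]
        mx = vec.max()
        if mx <= 0:
            raise ValueError("tip data have zero likelihood under this generator")
        partial[nd] = vec / mx
        log_scale[nd] = ls + np.log(mx)
    return partial, log_scale


def _loglik(tree, tip_states, q, prior=None):
    k = q.shape[0]
    nodes, branch_nodes, lengths = _branch_setup(tree)
    pmats = _propagators(q, lengths)
    pmat_of = dict(zip(branch_nodes, pmats))
    tip_like = _tip_likelihoods(tree, tip_states, k)
    partial, log_scale = _up_pass(nodes, pmat_of, tip_like, k)
    root = tree.seed_node
    pi = np.full(k, 1.0 / k) if prior is None else np.asarray(prior)
    like = float(pi @ partial[root])
    if like <= 0:
        return -np.inf
    return np.log(like) + log_scale[root]


def _parsimony_changes(tree, tip_states, k: int) -> int:
    """Fitch parsimony count of state changes (ambiguous tips = full set)."""
    changes = 0
    state_sets = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            s = tip_states[nd.taxon.label]
            state_sets[nd] = frozenset(range(k)) if s is None else frozenset({int(s)})
            continue
        sets = [state_sets[c] for c in nd.child_nodes()]
        inter = frozenset.intersection(*sets)
        if inter:
            state_sets[nd] = inter
        else:
            state_sets[nd] = frozenset.union(*sets)
            changes += 1
    return changes


@dataclass
class ArdFit:
    q: np.ndarray
    log_likelihood: float
    converged: bool
    n_states: int
    unobserved_states: list[int]


def fit_ard(
    tree: dendropy.Tree,
    tip_states: dict,
    k: int,
    nstarts: int = 3,
    seed: int = 0,
    root_prior: np.ndarray | None = None,
) -> ArdFit:
    """Maximum-likelihood ARD generator for one discrete character.

    Optimizes the k(k-1) log-rates with L-BFGS-B from ``nstarts`` seeded
    starting points and keeps the best.  States never observed at the tips
    are reported: rates into them are unidentifiable (the likelihood is
    flat in those directions).  Raises with the best-found generator
    attached when no start converges.
    """
    observed = {int(s) for s in tip_states.values() if s is not None}
    unobserved = sorted(set(range(k)) - observed)
    if unobserved:
        warnings.warn(
            f"states never observed at tips: {unobserved}; "
            "their incoming rates are unidentifiable",
            stacklevel=2,
        )
    _, _, lengths = _branch_setup(tree)
    # initialize at the parsimony-implied change rate; starting orders of
    # magnitude too low risks capture by the infinite-rate plateau
    changes = _parsimony_changes(tree, tip_states, k)
    base_rate = max(changes, 1) / max(lengths.sum(), 1e-9)
    rng = np.random.default_rng(seed)
    npar = k * (k - 1)

    def objective(log_rates):
        q = make_generator(np.exp(log_rates), k)
        return -_loglik(tree, tip_states, q, root_prior)

    best = None
    any_success = False
    for start in range(nstarts):
        x0 = np.log(base_rate) + (rng.normal(0.0, 1.0, npar) if start else np.zeros(npar))
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(-18.0, 8.0)] * npar,
        )
        # a flat (unidentifiable) direction can abort the line search at the
        # optimum; a near-zero gradient is still convergence
        converged = bool(res.success) or float(np.abs(res.jac).max()) < 1e-3
        any_success = any_success or converged
        if best is None or res.fun < best.fun:
            best = res
    q = make_generator(np.exp(best.x), k)
    fit = ArdFit(
        q=q,
        log_likelihood=-float(best.fun),
        converged=any_success,
        n_states=k,
        unobserved_states=unobserved,
    )
    if not any_success:
        err = RuntimeError("ARD optimization did not converge from any start")
        err.best_fit = fit
        raise err
    return fit


# ---------------------------------------------------------------------------
# Marginal ancestral states
# ---------------------------------------------------------------------------

def _node_key(node) -> str:
    return "|".join(sorted(leafset_below(node)))


def marginal_asr(
    tree: dendropy.Tree,
    tip_states: dict,
    q: np.ndarray,
    root_prior: np.ndarray | None = None,
) -> pd.DataFrame:
    """Exact marginal posterior state probabilities at every internal node.

    Up/down pass: outside partials O_v(i) combine the prior, the data not
    below v, and the transition into v; the marginal at v is proportional
    to O_v * L_v.  Nodes are keyed by the sorted labels of their subtended
    clade.
    """
    q = validate_generator(q)
    k = q.shape[0]
    nodes, branch_nodes, lengths = _branch_setup(tree)
    pmats = _propagators(q, lengths)
    pmat_of = dict(zip(branch_nodes, pmats))
    tip_like = _tip_likelihoods(tree, tip_states, k)
    partial, _ = _up_pass(nodes, pmat_of, tip_like, k)
    pi = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)

    outside = {tree.seed_node: pi.copy()}
    for nd in tree.preorder_node_iter():
        for child in nd.child_nodes():
            acc = outside[nd].copy()
            for sib in nd.child_nodes():
                if sib is child:
                    continue
                acc = acc * (pmat_of[sib] @ partial[sib])
            outside[child] = acc @ pmat_of[child]

    rows = []
    for nd in nodes:
        if nd.is_leaf():
            continue
        post = outside[nd] * partial[nd]
        post = post / post.sum()
        rows.append({"node": _node_key(nd), **{f"state_{i}": post[i] for i in range(k)}})
    return pd.DataFrame(rows).set_index("node")


# ---------------------------------------------------------------------------
# Stochastic mapping
# ---------------------------------------------------------------------------

@dataclass
class SimmapSet:
    """A set of sampled character histories and their node-state summary."""

    node_states: np.ndarray            # nsim x n_internal_nodes
    node_keys: list[str]
    transition_counts: np.ndarray      # nsim (real state changes per map)
    branch_histories: list | None      # per map: {node_key: [(state, duration), ...]}
    seed: int
    n_states: int
    resampled_maps: int = 0
    node_posteriors: pd.DataFrame = field(init=False)

    def __post_init__(self):
        nsim = self.node_states.shape[0]
        freq = np.zeros((len(self.node_keys), self.n_states))
        for j in range(len(self.node_keys)):
            for s in range(self.n_states):
                freq[j, s] = np.mean(self.node_states[:, j] == s)
        self.node_posteriors = pd.DataFrame(
            freq,
            index=pd.Index(self.node_keys, name="node"),
            columns=[f"state_{i}" for i in range(self.n_states)],
        )
        self.nsim = nsim


def _sample_path(a, b, t, q, omega, r_mat, p_ab, rng, max_jumps=10_000):
    """Uniformized CTMC path from state a to b over duration t.

    Returns (segments, n_real_transitions); segments are (state, duration)
    pairs covering [0, t].
    """
    if omega == 0.0:
        return [(a, t)], 0
    mu = omega * t
    # sample the number of uniformized jumps given the endpoints
    u = rng.random()
    log_pois = -mu
    rn = np.eye(r_mat.shape[0])
    pois = np.exp(log_pois)
    cum = pois * rn[a, b] / p_ab
    n = 0
    rn_powers = [rn]
    while cum < u:
        n += 1
        if n > max_jumps:
            return None
        rn = rn @ r_mat
        rn_powers.append(rn)
        log_pois += np.log(mu) - np.log(n)
        cum += np.exp(log_pois) * rn[a, b] / p_ab
    if n == 0:
        return [(a, t)], 0
    # jump states: forward sampling conditioned on the endpoint
    states = [a]
    for step in range(1, n):
        prev = states[-1]
        weights = r_mat[prev, :] * rn_powers[n - step][:, b]
        weights = np.clip(weights, 0.0, None)
        total = weights.sum()
        if total <= 0:
            return None
        states.append(int(rng.choice(len(weights), p=weights / total)))
    states.append(b)
    times = np.sort(rng.random(n)) * t
    segments = []
    changes = 0
    cur_state, cur_start = states[0], 0.0
    for jump_time, new_state in zip(times, states[1:]):
        if new_state != cur_state:
            segments.append((cur_state, jump_time - cur_start))
            cur_state, cur_start = new_state, jump_time
            changes += 1
    segments.append((cur_state, t - cur_start))
    return segments, changes


def stochastic_maps(
    tree: dendropy.Tree,
    tip_states: dict,
    q: np.ndarray,
    nsim: int = 1000,
    seed: int = 0,
    root_prior: np.ndarray | None = None,
    keep_histories: bool = False,
    retry_cap: int = 100,
) -> SimmapSet:
    """Sample ``nsim`` stochastic character maps conditional on tip data.

    Each map draws the root state from its conditional posterior, node
    states down the tree by recursive conditioning on the pruning partials,
    and within-branch histories by uniformization (rejection-free given the
    endpoints; a map is resampled, counted and logged if path sampling
    fails numerically ``retry_cap`` times).  Deterministic given the seed.
    """
    q = validate_generator(q)
    k = q.shape[0]
    nodes, branch_nodes, lengths = _branch_setup(tree)
    pmats = _propagators(q, lengths)
    pmat_of = dict(zip(branch_nodes, pmats))
    tip_like = _tip_likelihoods(tree, tip_states, k)
    partial, _ = _up_pass(nodes, pmat_of, tip_like, k)
    pi = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)

    internal = [nd for nd in nodes if not nd.is_leaf()]
    node_keys = [_node_key(nd) for nd in internal]
    node_index = {nd: i for i, nd in enumerate(internal)}
    length_of = dict(zip(branch_nodes, lengths))

    omega = float(max(-np.diag(q).min() * 1.05, 0.0))
    r_mat = np.eye(k) + q / omega if omega > 0 else np.eye(k)

    rng_master = np.random.default_rng(seed)
    node_states = np.zeros((nsim, len(internal)), dtype=int)
    transition_counts = np.zeros(nsim, dtype=int)
    histories = [] if keep_histories else None
    resampled = 0

    for m in range(nsim):
        attempts = 0
        while True:
            attempts += 1
            if attempts > retry_cap:
                raise RuntimeError("stochastic map resampling exceeded the retry cap")
            ok, states, changes, hist = _sample_one_map(
                tree, internal, node_index, partial, pmat_of, length_of,
                pi, q, omega, r_mat, rng_master, keep_histories, k,
            )
            if ok:
                break
            resampled += 1
            warnings.warn("path sampling failed on a branch; map resampled", stacklevel=2)
        node_states[m] = states
        transition_counts[m] = changes
        if keep_histories:
            histories.append(hist)

    return SimmapSet(
        node_states=node_states,
        node_keys=node_keys,
        transition_counts=transition_counts,
        branch_histories=histories,
        seed=seed,
        n_states=k,
        resampled_maps=resampled,
    )


def _sample_one_map(tree, internal, node_index, partial, pmat_of, length_of,
                    pi, q, omega, r_mat, rng, keep_histories, k):
    state_of = {}
    root = tree.seed_node
    w = pi * partial[root]
    w = w / w.sum()
    state_of[root] = int(rng.choice(k, p=w))
    states = np.zeros(len(internal), dtype=int)
    states[node_index[root]] = state_of[root]
    changes = 0
    hist = {} if keep_histories else None

    for nd in tree.preorder_node_iter():
        for child in nd.child_nodes():
            i = state_of[nd]
            w = pmat_of[child][i, :] * partial[child]
            total = w.sum()
            if total <= 0:
                return False, None, None, None
            j = int(rng.choice(k, p=w / total))
            state_of[child] = j
            if not child.is_leaf():
                states[node_index[child]] = j
            p_ab = pmat_of[child][i, j]
            path = _sample_path(i, j, length_of[child], q, omega, r_mat, p_ab, rng)
            if path is None:
                return False, None, None, None
            segments, n_changes = path
            changes += n_changes
            if keep_histories:
                key = (
                    child.taxon.label if child.is_leaf()
                    else "|".join(sorted(l.taxon.label for l in child.leaf_iter()))
                )
                hist[key] = segments
    return True, states, changes, hist
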