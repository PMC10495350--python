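"""Synthetic study-scenario generator.

Produces every input the discordance pipeline consumes: a species tree
with per-branch theta (a compact seven-taxon design by default — two
Prasinodermophyta-like, two Chlorophyta-like and two Streptophyta-like
ingroup taxa plus a glaucophyte-like outgroup, with a short, high-theta
focal branch uniting the first two pairs), MSC gene trees with optional
introgression, amino-acid alignments evolved along gene trees, and
discrete characters evolved under an arbitrary-rate CTMC.

Introgression is modeled as species-tree switching: independently for each
gene, with probability m the gene tree is simulated on a modified species
tree in which the recipient is regrafted as sister to the donor.  This is
the simplest generative mechanism that skews the minor-quartet balance the
decision rule keys on; it is not a migration-rate model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import dendropy
import numpy as np

from . import msc
from .alignments import Alignment
from .signal import SubstModel
from .trees import (
    TreeValidationError,
    leafset_below,
    read_newick,
    tip_labels,
    write_newick,
)

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "IntrogressionEvent",
    "make_scenario",
    "generate_gene_trees",
    "generate_alignments",
    "generate_characters",
    "evolve_sequences",
    "evolve_characters",
    "yule_tree",
    "DEFAULT_SPECIES_NEWICK",
]

# Seven-taxon study design: pendant and internal lengths in expected
# substitutions/site; the focal branch (above Pras+Chlo) is short.
DEFAULT_SPECIES_NEWICK = (
    "((((Pras1:0.45,Pras2:0.45):0.25,(Chlo1:0.5,Chlo2:0.5):0.2):0.2,"
    "(Stre1:0.55,Stre2:0.55):0.35):0.4,Glau:1.3);"
)
DEFAULT_FOCAL_CLADE = ("Pras1", "Pras2", "Chlo1", "Chlo2")


@dataclass
class IntrogressionEvent:
    donor: str
    recipient: str
    m: float  # per-gene probability of following the modified tree

    def __post_init__(self):
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("introgression fraction m must be in [0, 1]")


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic experiment.

    Defaults encode the seven-taxon study design: internal theta 0.2
    (matching a typical internal-branch estimate), a focal-branch override
    of 0.4 (high ILS; its mutational length of 0.2 gives 2b/theta = 1),
    terminal theta 1, and 434 genes.
    """

    species_newick: str = DEFAULT_SPECIES_NEWICK
    n_taxa: int | None = None          # used only when yule_birth_rate is set
    yule_birth_rate: float | None = None
    internal_theta: float = 0.2
    focal_clade: tuple = DEFAULT_FOCAL_CLADE
    focal_theta: float = 0.4
    terminal_theta: float = 1.0
    introgression: list = field(default_factory=list)  # IntrogressionEvent dicts
    n_genes: int = 434
    seq_length: int = 300
    seq_gamma_shape: float | None = None
    char_k: int = 3
    char_rates: list | None = None     # flat k(k-1) rate list, row-major
    seed: int = 0

    def events(self) -> list[IntrogressionEvent]:
        out = []
        for ev in self.introgression:
            if isinstance(ev, IntrogressionEvent):
                out.append(ev)
            else:
                out.append(IntrogressionEvent(**ev))
        return out

    def to_json(self) -> str:
        d = asdict(self)
        d["introgression"] = [asdict(e) for e in self.events()]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        d = json.loads(text)
        if "focal_clade" in d and d["focal_clade"] is not None:
            d["focal_clade"] = tuple(d["focal_clade"])
        return cls(**d)


@dataclass
class Scenario:
    config: ScenarioConfig
    species_tree: dendropy.Tree
    branch_table: msc.BranchTable
    modified_trees: list          # (event, species_tree, branch_table)
    manifest: dict


def yule_tree(n_taxa: int, birth_rate: float, seed: int, prefix: str = "t") -> dendropy.Tree:
    """Ultrametric pure-birth tree on ``n_taxa`` tips, depth in time units."""
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    # record (birth_time, parent_index) per lineage; lineage 0/1 from the root
    birth = [0.0, 0.0]
    parent = [-1, -1]
    alive = [0, 1]
    t = 0.0
    while len(alive) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(alive)))
        idx = int(rng.integers(len(alive)))
        split = alive[idx]
        a, b = len(birth), len(birth) + 1
        birth += [t, t]
        parent += [split, split]
        alive[idx] = a
        alive.append(b)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(alive)))

    nodes = {}
    root = dendropy.Node()
    for i in range(len(birth)):
        nodes[i] = dendropy.Node()
    tns = dendropy.TaxonNamespace()
    for i in (0, 1):
        root.add_child(nodes[i])
    for i in range(2, len(birth)):
        nodes[parent[i]].add_child(nodes[i])
    tip_counter = 0
    end_time = {i: None for i in range(len(birth))}
    children_of = {}
    for i in range(2, len(birth)):
        children_of.setdefault(parent[i], []).append(i)
    for i in range(len(birth)):
        kids = children_of.get(i, [])
        end_time[i] = birth[kids[0]] if kids else t_end
    for i in sorted(range(len(birth)), key=lambda x: birth[x]):
        nodes[i].edge.length = end_time[i] - birth[i]
        if not children_of.get(i):
            tip_counter += 1
            taxon = dendropy.Taxon(label=f"{prefix}{tip_counter}")
            tns.add_taxon(taxon)
            nodes[i].taxon = taxon
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    tree.length_units = "unitless"
    for nd in tree.preorder_node_iter():
        nd.support = None
    return tree


def _regraft_recipient(species_tree, table, event):
    """Species tree with the recipient moved to be sister to the donor.

    The donor's pendant branch is split in half; the recipient re-attaches
    at the split with a pendant of the same length.  theta on branches
    whose subtended clade is unchanged carries over; new or altered
    branches get the table's mean internal theta (the new donor+recipient
    branch is the exception: it is below the species level, so it gets the
    terminal theta).
    """
    donor, recipient = event.donor, event.recipient
    taxa = tip_labels(species_tree)
    for name in (donor, recipient):
        if name not in taxa:
            raise TreeValidationError(f"introgression taxon {name!r} not in species tree")
    newick = write_newick(species_tree)
    mod = read_newick(newick, units=getattr(species_tree, "length_units", "unitless"))[0]
    mod.is_rooted = True
    leaf_r = next(l for l in mod.leaf_node_iter() if l.taxon.label == recipient)
    mod.prune_taxa([leaf_r.taxon], suppress_unifurcations=True)
    mod.suppress_unifurcations()
    leaf_d = next(l for l in mod.leaf_node_iter() if l.taxon.label == donor)
    d_len = leaf_d.edge.length or 0.0
    parent = leaf_d.parent_node
    junction = dendropy.Node()
    parent.remove_child(leaf_d)
    parent.add_child(junction)
    junction.edge.length = d_len / 2.0
    junction.add_child(leaf_d)
    leaf_d.edge.length = d_len / 2.0
    new_r = dendropy.Node(taxon=dendropy.Taxon(label=recipient))
    mod.taxon_namespace.add_taxon(new_r.taxon)
    junction.add_child(new_r)
    new_r.edge.length = d_len / 2.0
    mod.update_taxon_namespace()
    for nd in mod.preorder_node_iter():
        nd.support = None

    fallback = table.mean_internal_theta
    all_mod = tip_labels(mod)
    records = []
    idx = 0
    for node in mod.preorder_internal_node_iter():
        if node is mod.seed_node:
            continue
        clade = leafset_below(node)
        idx += 1
        old = table.record_for_clade(clade)
        if old is not None:
            theta = old.theta
        elif clade == frozenset({donor, recipient}):
            theta = table.terminal_theta
        else:
            theta = fallback
        from .trees import Bipartition

        records.append(
            msc.BranchRecord(
                branch_id=f"br{idx}",
                bipartition=Bipartition(clade, all_mod - clade),
                clade=clade,
                mu_t=node.edge.length,
                theta=theta,
            )
        )
    mod_table = msc.BranchTable(records, table.terminal_theta, table.root_theta)
    return mod, mod_table


def make_scenario(config: ScenarioConfig) -> Scenario:
    """Build the species tree, theta table and reproducibility manifest."""
    if config.yule_birth_rate is not None:
        if not config.n_taxa:
            raise ValueError("n_taxa required for a Yule species tree")
        tree_seed = int(
            np.random.SeedSequence(config.seed, spawn_key=(0,)).generate_state(1)[0]
            % (2**31)
        )
        species_tree = yule_tree(config.n_taxa, config.yule_birth_rate, tree_seed)
    else:
        species_tree = read_newick(config.species_newick, units="substitutions_per_site")[0]
        species_tree.is_rooted = True
        tree_seed = None

    overrides = {}
    if config.focal_clade:
        overrides[frozenset(config.focal_clade)] = config.focal_theta
    try:
        table = msc.BranchTable.from_constant(
            species_tree,
            config.internal_theta,
            terminal_theta=config.terminal_theta,
            overrides=overrides,
        )
    except KeyError as exc:
        raise TreeValidationError(
            f"focal clade does not match any internal branch: {exc}"
        ) from exc

    modified = []
    for ev in config.events():
        mod_tree, mod_table = _regraft_recipient(species_tree, table, ev)
        modified.append((ev, mod_tree, mod_table))

    manifest = {
        "config": json.loads(config.to_json()),
        "species_newick": write_newick(species_tree).strip(),
        "species_tree_seed": tree_seed,
        "theta": {"|".join(sorted(r.clade)): r.theta for r in table.records},
        "terminal_theta": config.terminal_theta,
        "modified_newicks": [write_newick(t).strip() for _, t, _ in modified],
        "gene_seed_scheme": "SeedSequence(seed, spawn_key=(1, gene_index))",
    }
    return Scenario(
        config=config,
        species_tree=species_tree,
        branch_table=table,
        modified_trees=modified,
        manifest=manifest,
    )


def generate_gene_trees(scenario: Scenario, n: int | None = None) -> msc.GeneTreeSample:
    """Simulate gene trees, per gene switching to an introgressed tree.

    Gene i draws its own random stream from the master seed by counter;
    with probability m (per event, in order) the gene follows the
    corresponding regrafted species tree, otherwise the base tree.  The
    generating class of every gene is recorded in ``source_labels``.
    """
    cfg = scenario.config
    n = cfg.n_genes if n is None else n
    events = scenario.modified_trees
    base = (scenario.species_tree, scenario.branch_table)

    depths_cache = {}
    setups = {}
    for key, (tree, table) in {"base": base, **{
        f"introgressed_{i}": (t, tb) for i, (_, t, tb) in enumerate(events)
    }}.items():
        depths_cache[key] = msc._node_depths(tree)
        tns = dendropy.TaxonNamespace(sorted(tip_labels(tree)))
        setups[key] = (tree, table, tns, {t.label: t for t in tns})

    trees = []
    labels = []
    for i in range(n):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(cfg.seed, spawn_key=(1, i)))
        )
        key = "base"
        for j, (ev, _, _) in enumerate(events):
            if rng.random() < ev.m:
                key = f"introgressed_{j}"
                break
        tree, table, tns, taxa = setups[key]
        root_theta = table.root_theta if table.root_theta is not None else table.terminal_theta
        gt = msc._simulate_one(tree, table, root_theta, depths_cache[key], rng, tns, taxa)
        trees.append(gt)
        labels.append(key)
    return msc.GeneTreeSample(
        trees=trees,
        seed=cfg.seed,
        theta_description="scenario",
        count=n,
        source_labels=labels,
    )


def generate_alignments(
    scenario: Scenario,
    sample: msc.GeneTreeSample,
    n: int | None = None,
) -> list[Alignment]:
    """Amino-acid alignments evolved along the sampled gene trees.

    Uses the scenario's sequence model (length, optional gamma shape);
    per-gene seeds are spawned from the master seed by counter.
    """
    cfg = scenario.config
    model = SubstModel.poisson(gamma_shape=cfg.seq_gamma_shape)
    trees = sample.trees if n is None else sample.trees[:n]
    out = []
    for i, tree in enumerate(trees):
        seed = int(
            np.random.SeedSequence(cfg.seed, spawn_key=(2, i)).generate_state(1)[0]
            % (2**31)
        )
        aln = evolve_sequences(tree, model, cfg.seq_length, seed)
        aln.name = f"gene{i + 1}"
        out.append(aln)
    return out


def generate_characters(scenario: Scenario, n_characters: int = 1):
    """Discrete characters evolved on the species tree under the config's Q.

    Returns a list of (tip_states, true_node_states) pairs.  When the
    config gives no rates, a symmetric unit-rate generator on ``char_k``
    states is used.
    """
    from .asr import make_generator

    cfg = scenario.config
    k = cfg.char_k
    rates = (
        np.asarray(cfg.char_rates, dtype=float)
        if cfg.char_rates is not None
        else np.ones(k * (k - 1))
    )
    q = make_generator(rates, k)
    out = []
    for i in range(n_characters):
        seed = int(
            np.random.SeedSequence(cfg.seed, spawn_key=(3, i)).generate_state(1)[0]
            % (2**31)
        )
        out.append(evolve_characters(scenario.species_tree, q, seed))
    return out


def evolve_sequences(
    tree: dendropy.Tree,
    model: SubstModel,
    length: int,
    seed: int,
) -> Alignment:
    """I.i.d. sites evolved along the tree under a reversible CTMC.

    The root sequence is drawn from the equilibrium frequencies; each
    branch applies exp(Q * t * r) with r the site's discrete-gamma rate
    multiplier (all 1 without gamma).  Branch lengths are expected
    substitutions per site.
    """
    if model.n_states == 0:
        raise ValueError("model has no states")
    rng = np.random.default_rng(seed)
    q = model.rate_matrix()
    pi = model.freqs
    k = model.n_states
    rates = model.category_rates()
    site_cat = rng.integers(len(rates), size=length)

    states_of = {}
    root_states = rng.choice(k, size=length, p=pi)
    states_of[tree.seed_node] = root_states
    from scipy.linalg import expm

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        parent_states = states_of[node.parent_node]
        child_states = np.empty(length, dtype=int)
        for ci, r in enumerate(rates):
            mask = site_cat == ci
            if not mask.any():
                continue
            p = expm(q * t * r)
            p = np.clip(p, 0.0, None)
            p = p / p.sum(axis=1, keepdims=True)
            ps = parent_states[mask]
            u = rng.random(ps.size)
            cdf = np.cumsum(p, axis=1)
            child_states[mask] = np.argmax(cdf[ps] > u[:, None], axis=1)
        states_of[node] = child_states

    labels, rows = [], []
    for leaf in tree.leaf_node_iter():
        labels.append(leaf.taxon.label)
        rows.append("".join(model.states[s] for s in states_of[leaf]))
    order = np.argsort(labels)
    return Alignment([labels[i] for i in order], [rows[i] for i in order])


def evolve_characters(
    tree: dendropy.Tree,
    q: np.ndarray,
    seed: int,
    root_prior: np.ndarray | None = None,
) -> tuple[dict, dict]:
    """One discrete character evolved by CTMC; true node states retained.

    Returns (tip_states, node_states): tip states keyed by label, internal
    (and root) states keyed by the sorted labels of the subtended clade —
    matching the keys used by the ancestral-state module, so recovery can
    be scored directly.
    """
    from .asr import validate_generator, _node_key

    q = validate_generator(q)
    k = q.shape[0]
    rng = np.random.default_rng(seed)
    pi = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)
    from scipy.linalg import expm

    state_of = {tree.seed_node: int(rng.choice(k, p=pi))}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        p = expm(q * t)[state_of[node.parent_node]]
        p = np.clip(p, 0.0, None)
        state_of[node] = int(rng.choice(k, p=p / p.sum()))
    tips = {}
    internals = {}
    for node, s in state_of.items():
        if node.is_leaf():
            tips[node.taxon.label] = s
        else:
            internals[_node_key(node)] = s
    return tips, internals
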