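# Methods

This note records the models, conventions, numerical choices and known
limitations behind `phylodiscord`, in the order a user meets them.

## Trees and conventions

Trees are dendropy objects with two package conventions: `node.support`
on a 0–100 percent scale (local posterior probabilities in [0,1] are
rescaled ×100 on read when requested), and `tree.length_units` tagging
branch lengths as substitutions/site, coalescent units, or unitless.
Support-based collapsing contracts internal edges with support **strictly
below** the threshold; edges with *absent* support are never collapsed —
absence of a value is not evidence of low support. Robinson–Foulds
distances count non-trivial bipartitions on the unrooted tree; rooted
inputs are compared on their unrooted split sets, and the normalized
variant divides by 2(n−3). Majority-rule consensus includes splits at
frequency ≥ the cutoff (inclusive at the boundary).

## The multispecies coalescent simulator

Branch lengths are mutational (μT, substitutions/site) and θ is on the
4Nμ scale, the Phybase `sim.coaltree.sp` convention: within a species
branch of length b, j uncoalesced lineages coalesce at rate j(j−1)/θ per
unit of mutational time, so a two-lineage branch is "b in mutational
units = 2b/θ in coalescent units". One lineage is sampled per species.
Lineages surviving to the root keep coalescing in an ancestral population
whose θ defaults to the terminal-branch θ (it shifts root-ward node times
but can never change topology frequencies at internal branches). Gene
trees carry coalescence times in the species tree's time units, so node
ages are always at or above the corresponding speciation.

Per-gene random streams are spawned from the master seed by gene index
(`SeedSequence(seed, spawn_key=(i,))`): gene i is identical no matter how
many genes are simulated or in what order.

θ estimation divides the mutational length of each internal branch by its
coalescent-unit length, matching branches across the two trees by
unrooted bipartition; the two edges at a bifurcating root are merged into
the single unrooted edge they represent. Unmatched branches and τ = 0
leave θ undefined (recorded, warned) rather than guessed. The division is
exact arithmetic, so recovery from consistent inputs has zero error.

## Concordance accounting

`map_concordance` restricts each species-tree bipartition to the gene
tree's taxa. A gene is *missing* at a branch when either restricted side
has <2 taxa; *concordant* when the restricted split occurs in the gene
tree; *conflicting* when some gene-tree split (surviving the support
collapse) is incompatible with it — two splits on the same taxon set are
compatible iff one of their four cross-intersections is empty; otherwise
*uninformative* (polytomies spanning the branch). Each conflicting gene
contributes once to the conflict total; the single most frequent
conflicting split across genes is reported separately, so "top conflict"
never exceeds the number of conflicting genes.

Quartet frequencies around a branch enumerate one tip from each of the
four neighboring clades (all combinations up to `max_quartets = 1e5`,
seeded uniform sampling beyond, with the exactness recorded). Counts are
kept in a fixed topology order (species resolution, then the two
alternatives) so empirical and simulated tallies can be compared
resolution-by-resolution; the reported q1/q2/q3 sort the minors
descending, the usual display convention.

**Count scale.** For count-based tests the package uses *gene-scale
effective counts*: each gene's resolved quartets are averaged before
summing, so the tallies total the number of informative gene trees (the
same scale as ASTRAL's effective number). The quartets within one gene
around a deep branch are very strongly correlated (measured intra-gene
correlation ≈ 0.9 on the default scenario), so raw quartet tallies would
overstate the information roughly eight-fold and wreck the calibration of
any test built on them.

## The ILS / gene-flow decision rule

The chi-square is the Pearson homogeneity statistic on the 2×2 table of
minor tallies [[N2, N3], [M2, M3]] (empirical vs simulated, df = 1, no
continuity correction), with the simulated arm at its actual size
(20,000 genes by default). QD = 1 − |N2−N3|/(N2+N3) is computed from the
gene-tree quartet tallies directly — a deliberate approximation of
Quartet Sampling's score that preserves the statistic's definition while
avoiding per-replicate ML evaluation of resampled alignments. The label
rule: ILS-consistent iff P > 0.1 **and** QD > 0.8; gene-flow-suspected
iff P ≤ 0.1 **and** QD ≤ 0.8; otherwise ambiguous (including QD
undefined). Thresholds are parameters; these defaults follow common
practice for this test.

A calibration note: under a true null (pure MSC), a correctly calibrated
level-0.1 test yields P > 0.1 about 90% of the time *by construction*;
per-gene averaging makes this implementation mildly conservative
(~92% joint ILS-consistent rate in replicate studies). Any procedure
claiming a materially higher positive-control rate at these thresholds is
either mis-calibrated or testing something else. The negative control is
far from the boundary: with a 30% introgression pulse, QD at the focal
branch collapses to ~0.5 and the rule flags gene flow essentially always.

"Variation accounted for" by the coalescent model is operationalized as
the overlap coefficient Σ_d min(f_emp(d), f_sim(d)) between the two
discrete distributions of unweighted RF distance to the species tree.

## Gene-wise signal

A gene strongly supports topology Ti when lnL(Ti) beats **both**
alternatives by ≥ 2 log units; it weakly supports Ti when Ti is the
strict maximum but a margin falls short; exact ties for the maximum are
unclassifiable and excluded from the summary fractions rather than
arbitrarily assigned. The built-in likelihood is Felsenstein pruning with
fixed branch lengths over reversible models (default: 20-state
equal-frequency Poisson; discrete-gamma rates by mean-per-category
discretization), with per-node partial rescaling for numerical safety. It
exists so the classification can be exercised end-to-end on simulated
alignments; it does not attempt site-heterogeneous profile-mixture models,
and production lnL tables are expected to come from an external ML engine.

Saturation is reported as the OLS slope of uncorrected p-distance
(response) on patristic distance (predictor), with intercept — slope near
1 means unsaturated. The slope is divergence-sensitive: even without
rate variation it falls below 1 once mean distances are large, because
p-distance saturates; the package follows the TreSpEx orientation of the
regression. The evolutionary rate proxy is the mean patristic distance;
informative sites are columns with ≥2 states each present in ≥2
sequences (gaps and ambiguity excluded).

## Tree landscapes

The Kendall–Colijn vector of a rooted tree lists, for each tip pair, the
root-to-MRCA measure blended by λ between edge count (λ=0) and path
length (λ=1), plus one pendant entry per tip; the metric is the
Euclidean distance between vectors. λ defaults to 0 — the question here
is topological. Embedding is classical MDS (PCoA by eigendecomposition:
deterministic, no initialization); clustering is Ward linkage on the
retained axes (default nf = 4) cut into a fixed k (default 3, no
automatic selection), with cluster ids renumbered by first appearance so
identical inputs give identical labelings. The cluster summary is the
member tree minimizing the summed KC distance to its cluster (ties to the
lowest index) plus a majority consensus; no Bayesian clade-credibility
machinery is involved.

## Ancestral states

The ARD model gives every ordered state pair its own rate: k(k−1) free
parameters, optimized as log-rates (bounds e±[−18, 8]) by L-BFGS-B from
multiple seeded starts. The starting rate is the Fitch-parsimony change
count divided by total tree length — starting orders of magnitude too low
risks capture by the infinite-rate plateau, where the likelihood degrades
to the product of stationary frequencies. A near-zero final gradient is
accepted as convergence even when the line search aborts on a flat
(unidentifiable) direction; states absent from the tips are flagged as
having unidentifiable incoming rates. The root prior is uniform (the
`make.simmap` default); a custom prior can be supplied.

Stochastic maps are sampled exactly: node states jointly from the pruning
partials (root from its conditional posterior, children conditioned on
the parent), then within-branch histories by uniformization — the number
of virtual jumps drawn from its endpoint-conditioned distribution, jump
states by forward sampling against powers of the uniformized kernel, jump
times as sorted uniforms. Numerical failure on a branch (vanishing
endpoint probability) resamples the whole map, counted and warned, with a
retry cap of 100. Node posterior frequencies converge to the exact
marginal posteriors (up/down pass), which the package also exposes; at
5,000 maps the maximum deviation on the bundled 6-tip / 3-state check is
≈ 0.01.

## Synthetic scenarios

The default scenario is a seven-taxon design: pairs standing in for
Prasinodermophyta, Chlorophyta and Streptophyta plus one outgroup, with a
short focal branch (μT = 0.2) uniting the first two pairs. Defaults:
internal θ = 0.2 (a typical internal-branch estimate), focal θ = 0.4
(high ILS: 2b/θ = 1), terminal θ = 1, 434 genes — the scale of the
reduced empirical dataset this kind of analysis is run on. A low-ILS
variant (focal θ = 0.1) is one config field away.

Introgression is species-tree switching: per gene, with probability m the
gene tree is simulated on a modified species tree in which the recipient
is regrafted as sister to the donor (donor pendant split in half, θ
carried over for unchanged clades, the new donor+recipient branch at the
terminal θ, altered branches at the mean internal θ). This is the
simplest generative mechanism that skews minor-quartet symmetry — the
feature the decision rule keys on — and is not a migration-rate model:
no per-gene partial ancestry, no continuous gene flow, no timing of the
pulse. Sequence evolution is i.i.d.-site CTMC (default equal-frequency
20-state Poisson; an empirical exchangeability matrix can be supplied but
is never bundled silently); character evolution draws node states
hierarchically from exact transition probabilities and keeps the true
internal states for recovery scoring.

What passing on these data does and does not show: the generator matches
the pipeline's model assumptions (MSC, i.i.d. sites, no alignment error,
no gene-tree estimation error except what support-collapsing emulates),
so green tests certify correctness of the implementations and the
internal consistency of the decision rule — not robustness to model
violations in empirical data (estimation error, missing data structure,
selection, rate heterogeneity across lineages).

## Problem sizes used in the test suite

The suite runs the closed-form simulator check at n = 20,000 gene trees;
replicate operating-characteristic checks at 100 replicates × 434 genes
against a 20,000-tree simulated reference; ARD recovery at 50 replicates
of 500-tip trees; stochastic-map accuracy at 5,000 maps; and exhaustive
oracle checks on all 15 five-tip unrooted (or four-tip rooted)
topologies. Unit tests use smaller sizes of the same designs with wider,
pre-stated statistical tolerances (3–4 standard errors).
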