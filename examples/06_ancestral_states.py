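"""Fit an all-rates-different model and sample stochastic character maps.

Evolves a 3-state character (think habitat: marine / freshwater /
terrestrial) along a 200-tip time tree, fits the ARD generator by maximum
likelihood, and summarizes 1000 stochastic maps into per-node posterior
state frequencies, cross-checked against the exact marginal posteriors.
"""

import numpy as np

from phylodiscord import asr, synthetic_data

tree = synthetic_data.yule_tree(200, birth_rate=1.0, seed=3)
q_true = asr.make_generator(np.array([0.4, 0.1, 0.2, 0.3, 0.1, 0.5]), 3)
tips, true_nodes = synthetic_data.evolve_characters(tree, q_true, seed=4)

fit = asr.fit_ard(tree, tips, k=3, nstarts=2, seed=5)
print("fitted generator (rows sum to 0):")
print(np.round(fit.q, 3))
print(f"log-likelihood: {fit.log_likelihood:.2f}  converged: {fit.converged}")

maps = asr.stochastic_maps(tree, tips, fit.q, nsim=1000, seed=6)
marginal = asr.marginal_asr(tree, tips, fit.q)
dev = float((maps.node_posteriors.loc[marginal.index] - marginal).abs().to_numpy().max())
root_key = "|".join(sorted(tips))
print(f"\nroot state posterior (from 1000 maps): "
      f"{np.round(maps.node_posteriors.loc[root_key].to_numpy(), 3)}")
print(f"true root state: {true_nodes[root_key]}")
print(f"max |simmap - marginal| over all nodes/states: {dev:.3f}")
# The simmap frequencies track the exact marginals to ~0.05 at 1000 maps
# (Monte Carlo error shrinks as 1/sqrt(nsim)); the number of state changes
# per sampled history is in maps.transition_counts.
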