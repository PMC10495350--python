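"""Dissect gene-wise log-likelihood signal among candidate topologies.

Evolves 30 amino-acid alignments along topology T1, evaluates each under
the three candidate placements with the built-in pruning likelihood, and
classifies every gene as strongly/weakly supporting one topology (margin:
2 log units beats both alternatives).
"""

import pandas as pd

from phylodiscord import signal, synthetic_data, trees

model = signal.SubstModel.poisson()
t1 = trees.read_newick("(((A:0.2,B:0.2):0.1,C:0.3):0.1,D:0.4);")[0]
t2 = trees.read_newick("(((A:0.2,C:0.2):0.1,B:0.3):0.1,D:0.4);")[0]
t3 = trees.read_newick("(((A:0.2,D:0.2):0.1,C:0.3):0.1,B:0.4);")[0]

rows = []
for gene in range(30):
    aln = synthetic_data.evolve_sequences(t1, model, length=500, seed=1000 + gene)
    rows.append(
        {
            "lnl_T1": signal.gene_log_likelihood(aln, t1, model),
            "lnl_T2": signal.gene_log_likelihood(aln, t2, model),
            "lnl_T3": signal.gene_log_likelihood(aln, t3, model),
        }
    )
labels, summary = signal.classify_gene_support(pd.DataFrame(rows))
for key, frac in summary.items():
    if frac > 0:
        print(f"{key}: {100 * frac:.1f}%")

aln = synthetic_data.evolve_sequences(t1, model, length=500, seed=1)
diag = signal.alignment_diagnostics(aln, t1)
print(
    f"\ndiagnostics of one gene: {diag.informative_sites} informative sites, "
    f"saturation slope {diag.saturation_slope:.2f}, rate {diag.rate:.3f}"
)
# Genes evolved on T1 overwhelmingly land in strong_T1.  The saturation
# slope is scale-sensitive: near 1 for shallow alignments, and well below
# 1 here because a mean pairwise distance of ~0.67 substitutions/site
# already hides repeat substitutions.
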