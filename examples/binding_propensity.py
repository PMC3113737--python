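"""Per-amino-acid binding propensities with bootstrap error bars.

Builds a synthetic ATP-binding dataset, pools binding/total counts over
all proteins, computes P(i) = (N_b(i)/N(i)) / (N_b(all)/N(all)) and
attaches 500-replicate bootstrap error bars from protein-level
resampling.  P(i) > 1 means amino acid i is enriched at binding sites.
"""

import numpy as np

from nucsite import (
    AA_ORDER,
    BindingCounts,
    FixtureSpec,
    bootstrap_errors,
    compare_propensities,
    compute_propensity,
    counts_from_labels,
    make_ligand_dataset,
)

spec = FixtureSpec(n_proteins=30, chain_length=80, n_binding=8,
                   ligand_het="ATP", seed=101)
dataset = make_ligand_dataset(spec)

per_protein = [counts_from_labels(e.chain, e.labels) for e in dataset.entries]
pooled = sum(per_protein, BindingCounts.zero())
table = compute_propensity(pooled, ligand_het="ATP")
table.err = bootstrap_errors(per_protein, n_replicates=500, seed=17)

print(f"ATP dataset: {pooled.n_binding_all} binding / "
      f"{pooled.n_total_all} residues pooled over {len(dataset)} proteins")
print("aa     P    err   Nb    N")
for i, aa in enumerate(AA_ORDER):
    print(f"{aa}  {table.p[i]:5.2f}  {table.err[i]:5.2f}  "
          f"{pooled.n_binding[i]:3d}  {pooled.n_total[i]:4d}")

weighted = np.nansum(table.p * pooled.n_total) / pooled.n_total_all
print(f"\nweighted mean of P over residue counts: {weighted:.6f} "
      "(exactly 1 by construction of the ratio)")

# compare against an independently generated GTP dataset: with random
# sequences, binding-site composition carries no residue preference, so
# the correlation between the two propensity tables should be weak
gtp = make_ligand_dataset(FixtureSpec(n_proteins=30, chain_length=80,
                                      n_binding=8, ligand_het="GTP", seed=202))
gtp_pooled = sum((counts_from_labels(e.chain, e.labels) for e in gtp.entries),
                 BindingCounts.zero())
r, r2 = compare_propensities(table, compute_propensity(gtp_pooled, "GTP"))
print(f"ATP vs GTP propensity correlation: R = {r:.2f}, R^2 = {r2:.2f} "
      "(weak: toy binding sites are placed without residue preference)")
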