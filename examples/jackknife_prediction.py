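"""Blind binding-site prediction under leave-one-protein-out jackknife.

Builds a planted-signal dataset (binding residues' profile rows shifted
by +6 on 3 dims over unit noise), scores every protein with a model that
never saw it, and reports threshold metrics at the best-F cutoff plus
the pooled ROC AUC.
"""

from nucsite import FixtureSpec, jackknife_evaluate, make_ligand_dataset

spec = FixtureSpec(n_proteins=20, chain_length=60, n_binding=6,
                   ligand_het="ATP", signal_dims=(0, 1, 2),
                   signal_shift=6.0, noise_sd=1.0, seed=303)
dataset = make_ligand_dataset(spec)
print(f"dataset: {len(dataset)} proteins, {dataset.n_binding} binding / "
      f"{dataset.n_nonbinding} non-binding residues")

scores = jackknife_evaluate(dataset)
report = scores.report()
print(f"\nmetrics at the best F-measure cutoff ({report.cutoff:.3f}):")
print(f"  accuracy    {report.accuracy:5.1f} %")
print(f"  sensitivity {report.sensitivity:5.1f} %")
print(f"  specificity {report.specificity:5.1f} %")
print(f"  F-measure   {report.f_measure:5.1f} %")
print(f"  AUC         {100 * scores.auc('pooled'):5.1f} %  (pooled residues)")
print(f"  AUC         {100 * scores.auc('per_protein'):5.1f} %  (per-protein average)")
print("\nan AUC near 100% means the planted profile signal is recovered "
      "blind; a random predictor would sit near 50%")
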