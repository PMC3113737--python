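# Methods

## Scope and model

`nucsite` treats protein–nucleotide recognition at single-residue
resolution for eight adenine/guanine phosphates (HET codes CMP, PCG, AMP,
ADP, ATP, 5GP, GDP, GTP; the code maps each to its base, phosphate count
and cyclic flag). Two complementary analyses share one labelling
definition:

* **descriptive** — per-amino-acid binding propensities with bootstrap
  error bars, comparable across ligands by Pearson correlation;
* **predictive** — a per-ligand support vector regression that scores
  every residue from local sequence-profile context, evaluated blind by
  leave-one-protein-out jackknife and across ligands by an AUC matrix.

## Curation

PDB text is parsed with gemmi. Only the first model of multi-model (NMR)
files is used; for alternate locations the highest-occupancy conformer
wins, ties going to the lowest altloc character. Modified residues that
have a standard parent (e.g. MSE) map to the parent one-letter code;
anything else becomes X and is excluded from propensity counts while
remaining in the sequence.

Filters: chains with a resolution value numerically greater than 2.5 Å are
discarded ("worse than 2.5 Å" in the crystallographic sense; the boundary
value is retained, and NMR chains, which carry no resolution, pass).
Chains shorter than 30 residues are discarded. Redundancy is removed
greedily: chains are visited by decreasing length (ties by identifier) and
kept only if their global-alignment identity to every kept chain is ≤ 0.30,
where identity = identical aligned positions / length of the shorter
sequence under match +1, mismatch 0, linear gap −1 scoring
(Bio.Align.PairwiseAligner). The greedy order and the
shorter-sequence denominator are conventions chosen for reproducibility;
the cutoff and scoring are configurable.

## Contact labelling

A residue binds a ligand copy if any non-hydrogen atom pair is within
4.5 Å (inclusive; hydrogens can be included via a flag but are absent from
typical ≤ 2.5 Å X-ray structures). With several copies of the same ligand
in one structure, binding to any copy counts. Four channels refine the
overall label: protein main chain (N, CA, C, O, OXT; CB is side chain,
OXT main chain) × ligand base or phosphate group, using a deterministic
name table per HET code (purine ring + exocyclic substituents → base;
P/PA/PB/PG and their bonded O1A…O3G / O1P…O3P / OP1-3 oxygens → phosphate;
primed sugar atoms, including the ester O3'/O5', → ribose). Ribose
contacts set the overall label but no channel, so the channel union is a
subset of the overall label by construction.

## Propensity

For amino acid *i* within one ligand category, counts are pooled over all
proteins and

    P(i) = (N_b(i) / N(i)) / (N_b(all) / N(all)).

The weighted-mean identity Σᵢ P(i)·N(i) = N(all) holds exactly whenever
any binding residue exists, and is asserted in the tests. Amino acids
absent from a dataset give NaN, never 0 — a 0 would fake depletion.
Channel propensities normalise by the channel's own binding totals, so
each channel is internally calibrated (an overall-denominator variant is a
flag away).

Error bars: 500 pseudo-copies of the dataset are drawn by sampling whole
proteins with replacement (protein-level resampling respects the
correlation of residues within a protein); the error bar is the population
standard deviation of P(i) over pseudo-copies. Population vs sample SD is
immaterial at 500 replicates; population was chosen. Replicates with no
binding residues are excluded with a logged count, and columns whose
replicates are bit-identical (e.g. a single-protein dataset) report exactly
zero rather than mean-subtraction round-off. The generator is
`numpy.random.default_rng(seed)`; the seed is recorded in CLI output.

## Features

Each residue is encoded from a centred 5-residue window (2 on each side —
the field's convention for an unspecified window) over the chain's L×20
PSSM, columns in the canonical alphabet ARNDCQEGHILKMFPSTWYV. Every slot
contributes 21 dims: the 20 scores, plus a terminal flag that is 1 (with
zeroed scores) when the slot falls beyond either terminus — 105 dims in
all. Raw integer PSSM scores are used by default: the SVR operates on
unscaled inputs unless told otherwise, and this choice materially affects
reproduction, so it is stated here prominently; a logistic rescaling
1/(1+e^(−x/10)) is available and every trained model records which mode
produced its features.

Profiles come from PSI-BLAST ASCII PSSM files (the parser re-orders the
file's own column order to the canonical alphabet and cross-checks row
letters against the chain), from plain TSV, or from the synthetic
generator. An adapter can invoke an external `psiblast` executable
(3 iterations by default, the convention for profile building); it is
dependency-injected, raises a structured error when the tool is absent,
and nothing in the package requires it.

## Model and evaluation

An RBF-kernel SVR (scikit-learn) is fitted on all residues of a ligand
dataset with targets 1/0. Defaults — C = 1, ε = 0.1, γ = "scale" — are the
package's documented configuration; γ="scale" ≈ 1/(105·Var(X)) is close to
the classical 1/n_features default of other SVM implementations on
unit-variance profiles. Fitting is deterministic given the fixed data
order sorted by (structure_id, chain_id, seq_index).

Jackknife: each protein is scored by a model trained on all others; every
residue is scored exactly once and a leakage check is implicit in the
key-based fold construction. Metrics are computed on pooled residues by
default; a per-protein-average mode exists and reports name the mode. A
fold with single-class training data scores the base rate, with a warning.

Cross-prediction: models trained on the *full* dataset of ligand A score
dataset B for all ordered pairs, reported as AUC in percent; the diagonal
deliberately reuses training data and sits at the over-learning ceiling
(100% on separable data). SVR outputs may leave [0,1]; ROC analysis uses
raw scores (monotone-invariant), clipping is display-only.

Metrics: binary calls use the strict rule positive ⇔ score > cutoff.
Accuracy, sensitivity, specificity and precision follow the standard
definitions; the F-measure is the harmonic mean of precision and recall by
default with a geometric-mean variant (`f_mode="geometric"`) for users who
define it that way. Reported operating points maximise the F-measure over
all distinct score cutoffs (ties → lowest cutoff), and the report labels
the cutoff. AUC is the trapezoid area over all distinct cutoffs, equal to
the normalised Mann–Whitney U with ties counted ½ (verified against an
exhaustive pair-counting oracle to 1e−12).

## Synthetic fixtures

The generator emulates exactly what the pipeline consumes: complexes in
PDB text and L×20 profiles. The chain lies on an idealised helix (2.3 Å
radius, 1.5 Å rise, 100°/residue); the ligand template carries the correct
atom names per HET code in schematic geometry and is translated 30 Å off
the helix axis. Each requested binding residue reaches the ligand with a
planted pseudo side-chain atom 3.5 Å from the nearest ligand atom; a rigid
translation alone cannot make an arbitrary scatter of residues touch one
small molecule, so the reach-atom construction is used instead. Margins
(binding ≤ 4.0 Å, non-binding ≥ 6.0 Å) straddle the 4.5 Å cutoff so
round-off cannot flip labels, the generator verifies its own geometry, and
dataset assembly re-derives labels through the contacts module — geometry,
not the requested positions, is the ground truth.

Profiles are Normal(0, noise_sd) with `signal_shift` added on
`signal_dims` of binding rows. Default study conditions: 40 proteins of
60 residues, 6 binding residues each, shift +6 on 3 dims, unit noise —
strong enough that blind recovery is expected, and a label permutation
restores chance performance.

For cross-prediction pairs, each dataset can also plant *decoy* shifts:
the same magnitude on the partner's signal dims, applied to
label-independent non-binding rows (one decoy per binding residue by
default). Without decoys, an RBF model scores any feature vector far from
all its support vectors near the regression intercept, so a dataset whose
positives are shifted on dims the model never saw is still partially
separable by sheer novelty (measured here as cross-AUC ≈ 0.87). Decoys
equalise the marginal feature distributions of the paired datasets, so the
orthogonal-signal cross-AUC sits near chance and the same-vs-orthogonal
contrast isolates transfer of the learned signal.

What the fixtures do **not** emulate: real backbone stereochemistry,
side-chain packing, binding-pocket geometry, sequence composition bias,
or evolutionary correlation between profile columns and structure.
Passing tests therefore certify the correctness of the pipeline's
machinery and statistics, not the attainable accuracy on real PDB-derived
datasets with database-built PSSMs.

## Problem sizes and numerical choices

The test and acceptance runs use 40-protein datasets (2 400 residues,
105 features) for signal recovery, self-prediction and cross-prediction,
and a 12-protein × 40-residue dataset for the 10-seed jackknife
permutation null — sizes chosen so the full suite completes in well under
a minute of SVR fitting while keeping ≥ 200 positives per dataset.
Distance checks run on exact coordinates with an inclusive cutoff;
bootstrap and fixture randomness always flow from named integer seeds
(`SeedSequence((seed, protein_index, stream))`), so every artefact is
bit-reproducible.

## Known limitations

* Real-data headline numbers (propensity correlations between actual
  ligand pairs, jackknife AUCs per ligand, the 8×8 cross-prediction
  matrix) require the curated PDB datasets and database-built PSSMs;
  the package computes them given such inputs but ships no structures.
* The greedy redundancy-removal convention is one of several reasonable
  choices; kept sets can differ from other clustering tools near the
  cutoff.
* Ribose-mediated contacts are deliberately channel-less; an analysis
  needing a ribose channel must extend the channel table.
* SVR hyperparameters are not tuned; the defaults are part of the method
  definition, not an optimised operating point.
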