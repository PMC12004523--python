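# Methods

`cypscreen` implements a ligand-based virtual-screening workflow for
aromatase (CYP19A1) inhibitor discovery: curation of bioactivity records
from two differently-annotated sources, chemical-space characterization,
random-forest classification validated under similarity-constrained
cross-validation with early-enrichment (BEDROC) model selection, and a
multi-stage triage funnel that reduces a screening library to a diverse,
novel shortlist. Everything runs on synthetic libraries carrying a planted
structure–activity rule, so the full workflow is testable without any
database access.

## Curation model

Raw records are (id, SMILES, source, activity) rows. Standardization keeps
the largest organic fragment (salt/solvent stripping), neutralizes charges
where chemically valid, selects the canonical tautomer, removes all
stereochemistry, and emits canonical SMILES. The fixed order —
strip → neutralize → tautomer → de-stereo → canonicalize — makes tautomer
selection independent of counter-ions, and the composite transform is
idempotent (verified property). A pluggable pre-standardization hook exists
for site-specific washing rules.

Filters and labels:

* element filter: H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I only;
* molecular weight: average MW of the parent in the inclusive range
  250–900 Da;
* potency source: active iff the pIC50-like value ≥ 6 (potency ≤ 1 µM);
* score source: score 0 → inactive, 40–100 → active, anything else
  excluded. The full complement of the two stated intervals is excluded
  (not just the 5–30 band), which is the safer superset reading of the
  ambiguous mid-band;
* deduplication on canonical SMILES: concordant groups keep the first
  record in id-sort order, conflicting groups are dropped entirely.

Cross-source label conflicts are *not* auto-resolved; a consistency report
lists structures labeled differently in the two sources for manual review.

## Featurization

* `ecfp4_2048`: Morgan radius-2 fingerprints folded to 2048 bits.
* `physchem_2d`: a pinned panel of 209 RDKit 2D descriptors, shipped as a
  manifest file. The count is toolkit-version dependent, so consistency
  with the manifest, not a literal count, is the contract. `Ipc` is
  excluded because it overflows to inf for large molecules; non-finite
  descriptor values are imputed with training-set column medians, and the
  medians travel with the trained model.
* `pca_panel_13`: the 13 interpretable properties used for chemical-space
  maps (N/O counts, chiral centers, MW, heavy atoms, HBA/HBD, logP, TPSA,
  aromatic atoms, net charge, ring count, fraction Csp3).

PCA z-scores columns before decomposition (constant columns dropped):
mixing raw counts with logP-scale quantities would otherwise let MW
dominate every component. Tanimoto similarity between two all-zero
fingerprints is defined as 1.0 (identical absence of features), and 0.0
against any non-empty fingerprint. Murcko scaffolds are plain frameworks
(ring systems plus linkers, no atom/bond abstraction); acyclic molecules
map to the empty scaffold.

## Validation scheme

The question a screening model must answer is whether it ranks *novel
chemotypes* early, so random CV splits (which place close analogs on both
sides) overestimate performance. Instead:

1. **Butina sphere-exclusion clustering** of the training set at a
   Tanimoto floor of 0.3: candidate centroids ranked by neighbor count
   (ties: input order), each claiming unassigned neighbors. "Floor 0.3" is
   read as: compounds with similarity ≥ 0.3 to a centroid belong to its
   cluster and therefore stay *together* in one fold.
2. **Greedy fold assignment**: clusters are shuffled with the seeded
   generator and assigned, in that order, to the currently smallest of
   k=5 folds. The fold-size spread is provably bounded by the largest
   cluster size. The same fold plan is shared across the whole
   hyperparameter grid so settings are compared on identical splits.
3. **SMOTE inside training folds only**: the minority class is augmented
   by linear interpolation between a minority sample and one of its k=5
   nearest minority neighbors until the classes balance. Originals are
   preserved verbatim; validation and test folds are never touched.
   Interpolated fingerprint features may be fractional; tree ensembles
   are indifferent to this, so they are used as-is. A nominal-aware
   `binary` mode (each synthetic feature copied from one of the two
   parents) is available for strictly-binary workflows.
4. **Random forest**: 1000 trees, `min_samples_split=2`, model seed 42;
   `max_features` tuned over {None, sqrt, 0.2, 0.4, 0.8} by maximizing
   mean per-fold BEDROC (ties → earlier grid entry). The reported
   probability is the forest's averaged per-tree class probability, which
   for fully-grown trees coincides with the fraction of trees voting
   active.

Cluster-constrained folds on imbalanced data can leave a fold without one
class; such folds cannot be trained on or scored and are recorded as NaN,
with the grid mean taken over scoreable folds. If no fold is scoreable the
dataset is too small or imbalanced for the scheme and an error is raised.

### BEDROC

With N compounds, n actives at descending-score ranks r_i (stable ties on
input order) and weight α:

    RIE    = ( Σ_i exp(−α·r_i/N) ) / ( (n/N)·(1−e^{−α})/(e^{α/N}−1) )
    BEDROC = (RIE − RIE_min) / (RIE_max − RIE_min),  clamped to [0, 1]

where RIE_max/RIE_min place the actives at the top/bottom n ranks. α
defaults to 20 (≈ the top 8% of the list carries 80% of the weight); it is
exposed because BEDROC values are only comparable at a fixed α and active
fraction. Tie handling is documented because BEDROC is rank-sensitive:
equal scores are ranked in input order. ROC-AUC is the Mann–Whitney
probability that a random active outranks a random inactive, ties worth
one half.

The train/test split is 4:1 (test = ⌊0.2·n⌋, shuffled, seed 42). After
held-out evaluation, test and training sets are recombined and the final
screening models are trained on the full dataset (oversampled), one per
source × feature panel — four bundles in total. A bundle's manifest
(panel, hyperparameters, seeds, dataset hash) suffices to retrain it
bit-identically, which is how models are persisted and reloaded.

## Triage funnel

Stages, in order, each recording survivors and first-failure reasons:

1. rule of five in its original "at most one violation" form
   (MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10);
2. CYP motif: an aromatic imidazole, 1,2,3-/1,2,4-triazole or pyridine
   ring — the canonical heme-iron-coordinating substructures;
3. ensemble gate: kept iff ranked in the top N (default 10,000) by *any*
   of the four models and max probability strictly > 0.7; rank ties break
   on compound id;
4. novelty: maximum Tanimoto to any known active strictly below 0.7 — a
   candidate at exactly 0.7 is removed;
5. liabilities: PAINS (families A/B/C), net positive charge, ≥ 7
   consecutive unbranched sp3 carbons ("long alkane" is not quantified in
   the protocol; 7 is this package's choice), Br or I, nitro groups, basic
   aliphatic amines, and more than 8 rotatable bonds. The basic-amine
   SMARTS exempts amides, anilines and aromatic azole nitrogens so the
   mandatory CYP motif can never trigger it;
6. diversity: Butina clustering at centroid similarity 0.6, one
   representative per cluster (highest ensemble probability, ties →
   lowest id).

The funnel ends with a probability-ranked shortlist; docking and visual
inspection are manual steps outside this package's scope and are
represented only by that exported sheet.

## Synthetic data

Molecules are assembled from a grammar: two-slot ring-system cores
(azole-bearing actives; plain aromatic inactives; pyridine-bearing
"motif decoys") × small acyclic substituents, zipped with RDKit and
passed through the standardizer at generation time. This guarantees
validity, canonical-form stability (curation is a no-op), clearance of
the 250–900 Da window, and a controllable Murcko-scaffold census (many
analogs per scaffold, as real SAR datasets show).

A molecule is truly active iff it matches the planted SMARTS (default:
aromatic imidazole, so planted actives also pass the funnel's motif
gate). Observed labels flip with probability `label_noise`; activity
payloads are drawn consistently with the observed label — potency values
from Normal(7.0, 0.7) truncated ≥ 6 for actives and Normal(5.0, 0.6)
truncated < 6 for inactives; scores of 0 / uniform 40–100, with an
optional fraction pushed into the excluded 5–30 band. Two source profiles
mirror the real class balances: `balanced_potency` ≈ 1.2:1 and
`imbalanced_score` ≈ 1:11. A `foreign` variant draws substituents from a
shifted pool to emulate cross-source chemical-space drift; screening
libraries use it so planted library actives are analogs, not copies, of
training actives. Ground truth lives in a sidecar mapping, never on the
records.

What the generator does *not* emulate: real chemistry distributions
beyond class ratio, scaffold clustering and label semantics — no assay
noise structure, no activity cliffs, no property drift with scaffold
size. Passing tests therefore demonstrate that the machinery is correct
and that a genuine substructure signal is recovered under the stated
noise, not that any particular real-data performance will be reached.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which the statistical claims are meaningful: labeled sets of
n = 600 (the scale of the curated potency source), screening libraries of
5,050 with 50 planted actives (≈ 1% base rate), and demo pipelines around
n = 120–200 per source. The enrichment claim is assessed on the top-100
ensemble-ranked gate survivors against a ten-fold improvement over base
rate. Unit tests use smaller forests (50–100 trees) where only mechanics,
not performance, are under test; performance claims always use the
protocol's 1000 trees.

Degenerate inputs are defined, not left to chance: single-class
oversampling and single-class metric calls raise; a lone minority sample
is replicated rather than interpolated; empty libraries produce all-zero
funnels; unparseable SMILES are rejected with reasons during curation and
raise structured errors in featurization.

## Known limitations

* The exact standardization rule set of the original washing tools is not
  fully recoverable; the pre-standardization hook is the extension point
  for exact parity.
* Whether to z-score before PCA is a package decision (yes), not a claim
  of parity with any particular study.
* The manual "steric hindrance" substructure screen and docking/visual
  inspection stages are out of scope; the funnel's output is the input to
  those human steps.
* BEDROC on very small or very imbalanced validation folds is dominated
  by a handful of top-ranked molecules; the NaN-fold policy above
  mitigates but does not remove this.
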