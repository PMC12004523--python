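# cypscreen

Ligand-based virtual screening for aromatase (CYP19A1) inhibitor
discovery: bioactivity curation, chemical-space analysis, random-forest
classification under similarity-constrained cross-validation with
BEDROC-driven model selection, and a multi-stage compound-triage funnel.

Aromatase converts androgens to estrogens; inhibiting it is a mainstay of
hormone-receptor-positive breast-cancer therapy, and the canonical
inhibition mode is coordination of an azole nitrogen to the heme iron.
`cypscreen` is aimed at computational chemists who want a tested,
reproducible harness for this style of campaign: it curates potency- and
score-annotated bioactivity records into clean labeled datasets, trains
classifier ensembles whose validation respects chemical-series structure,
and triages a screening library down to a novel, diverse shortlist with a
full audit trail. The entire workflow runs on synthetic libraries
carrying a planted structure–activity rule, so every stage is exercised
end to end without any database downloads.

## The core method

Compounds are featurized as ECFP4 fingerprints (radius 2, 2048 bits) or a
pinned panel of ~209 RDKit 2D descriptors. Model validation uses Butina
sphere-exclusion clustering at Tanimoto floor 0.3 — compounds more
similar than 0.3 stay in one cluster — and whole clusters are assigned to
five cross-validation folds (greedy, to the smallest fold), so no fold
sees close analogs of another fold's molecules. Inside each training fold
SMOTE balances the classes; validation folds are untouched. A random
forest (1000 trees, seed 42) is tuned over
`max_features ∈ {None, sqrt, 0.2, 0.4, 0.8}` by maximizing the mean
per-fold BEDROC,

    RIE    = ( Σ_actives e^(−α·rᵢ/N) ) / ( (n/N)·(1−e^(−α))/(e^(α/N)−1) )
    BEDROC = (RIE − RIE_min) / (RIE_max − RIE_min),    α = 20

an exponentially rank-weighted enrichment metric that rewards ranking
actives *early* — the quantity that actually matters when only the top of
a ranked library will ever be looked at.

Screening applies, in order: rule-of-five, a CYP-motif requirement
(aromatic imidazole / triazole / pyridine), a rank-and-probability
ensemble gate over four models (two sources × two feature panels), a
novelty filter (Tanimoto < 0.7 to all known actives), PAINS and
structural-liability exclusions, and diversity clustering at 0.6 with one
representative per cluster. Full details and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

Run the demo pipeline (synthetic sources, four models, screening funnel):

```bash
cypscreen run-all --outdir runs/demo
```

which logs the funnel as machine-readable JSON plus a per-stage summary:

```
{"funnel": [["ro5", 510, 510], ["cyp_motif", 510, 160], ["ensemble_gate", 160, 10], ["novelty", 10, 10], ["liability", 10, 10], ["diversity", 10, 10]]}
ro5: 510 -> 510
cyp_motif: 510 -> 160
ensemble_gate: 160 -> 10
novelty: 10 -> 10
liability: 10 -> 10
diversity: 10 -> 10
```

Reading the funnel: the 510-molecule demo library is drug-like by
construction, so the rule of five removes nothing; the CYP-motif gate
keeps the 160 molecules bearing an azole or pyridine ring (the 10 planted
actives plus the pyridine-carrying decoys); the ensemble gate keeps only
the compounds some model ranks highly with probability > 0.7 — here
exactly the 10 planted actives; none is a near-copy of a training active
(the library draws from a shifted substituent distribution, so the
novelty filter passes all 10), none carries a structural liability, and
all 10 fall in distinct diversity clusters, so the final shortlist is the
complete planted set. `runs/demo/` contains the curated datasets,
curation reports, CV tables, per-bundle manifests, the funnel report with
per-compound failure reasons, and the ranked shortlist.

The library layer is equally usable directly:

```python
from cypscreen.synthetic import SyntheticConfig, generate_labeled_dataset
from cypscreen.curation import curate
from cypscreen import chemspace, modeling

records, truth = generate_labeled_dataset(SyntheticConfig.balanced(600, label_noise=0.1, seed=1))
curated, report = curate(records)
train, test = modeling.split_train_test(curated, seed=42)
fps = chemspace.ecfp4_block(train).matrix
y = [int(r.label.value == "active") for r in train]
cv = modeling.cv_select(fps, y, fps, compound_ids=[r.compound_id for r in train])
print(cv.chosen, round(cv.chosen_mean_bedroc, 2))   # 0.8 0.71
```

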