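# ppiscreen

Structure-based screening of protein–protein interactions from predicted
complex models.

Structure predictors will happily return a model for *any* pair of protein
sequences, whether or not the two proteins interact in a cell. `ppiscreen`
is for researchers who want to use those models as a screening instrument:
given predicted complex structures plus their confidence data (per-residue
pLDDT, the N×N predicted-aligned-error matrix, pTM/iPTM), it decides whether
a candidate pair is an *active* (interacting) pairing or a *decoy*
(non-interacting) pairing, and evaluates selectivity across whole
ligand/receptor families.

## The method

A gradient-boosted classifier is trained to separate predicted models of
active pairs from predicted models of **compelling decoys** — complexes
between proteins that structurally resemble true binding partners but are
presumed not to interact. The pieces:

* **Decoy construction.** For each active complex, both component proteins
  are replaced by their closest structural analog (ranked by TM-score,
  TM = (1/L_ref) Σ 1/(1+(dᵢ/d₀)²) with d₀ = 1.24(L_ref−15)^⅓ − 1.8) and
  rigidly superposed onto the components they replace. If the two chosen
  analogs would jointly reconstitute an active pairing, second-best analogs
  are substituted.
* **Features (57, versioned manifest).** A residue is interfacial when its
  Cβ (Cα for glycine) is within 12 Å of a representative atom on the other
  entity. Three blocks: 7 predictor-confidence features — including
  `ipae_top_quarter` (mean of the worst quarter of PAE values over
  interacting pairs) and `tpae_top_quarter` (mean of the best quarter over
  all cross-entity pairs); 33 structural counting features (interface
  residue/class/contact counts, interface secondary-structure composition —
  none may scale with total protein size); 17 interface energy features
  (split Lennard-Jones attraction/repulsion, distance-dependent-dielectric
  electrostatics, Gaussian-occlusion solvation, backbone hydrogen bonds —
  self-contained analogs of the classic molecular-mechanics terms).
* **Training protocol.** Complex-level (grouped) 60/20/20
  train/validation/test split — all models of one pairing stay together;
  training actives are filtered to models with DockQ ≥ 0.23 against the
  native structure (DockQ = (Fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²))/3);
  stratified grouped 5-fold cross-validation; optional sequential backward
  feature selection and hyperparameter tuning on train+validation only.
* **Screening rule.** A complex is scored by the **maximum** classifier
  score over its (up to five) predicted models. Reference discriminators
  (iPTM, pDockQ) are computed for comparison, and a threshold table reports
  FPR/TPR/precision/recall/F1 per operating point.
* **Family screens.** All ligand×receptor pairings of a conserved family are
  scored into a complete grid (multi-chain entities supported, e.g. three
  copies of a trimeric ligand as entity 1), evaluated by per-ligand top-k
  hits and a flattened-grid ROC.

## Worked example

Train a screening classifier on a synthetic study — docked complexes with
confident interfaces as actives, separated poses with uncertain confidence
as decoys — end to end through structure generation and feature extraction:

```python
import pandas as pd
from ppiscreen import PPIScreenModel
from ppiscreen.extract import feature_vector
from ppiscreen.manifest import ID_COLUMNS, all_features
from ppiscreen.synth import make_chain, make_complex, make_confidence

rows = []
for c in range(20):
    active = c % 2 == 0
    cid = f"cpx{c:02d}"
    for rank in (1, 2):
        seed = 100 * c + rank
        a = make_chain(20, "H", seed=seed, chain_id="A")
        b = make_chain(20, "H", seed=seed + 1, chain_id="B")
        model = make_complex([a, b], "docked" if active else "separated",
                             seed=seed, complex_id=cid, model_rank=rank)
        conf = make_confidence(
            model, "confident_interface" if active else "uncertain_interface",
            seed=seed)
        rows.append(feature_vector(model, conf,
                                   label="active" if active else "decoy"))
table = pd.DataFrame(rows, columns=ID_COLUMNS + all_features())

results = PPIScreenModel(table, seed=1, folds=4).fit()
print(results.summary())
```

This prints:

```
PPI screening classifier
====================================================
classifier:        xgboost
manifest version:  1.0
features used:     57
seed:              1
folds:             4
complexes (train/val/test): 12/4/4
cross-fold AUC:    1.000
test AUC (max-of-models, per complex): 1.000

operating points (threshold / FPR / TPR / precision / F1):
   0.98  0.00  0.00  1.00  0.00
   0.95  0.00  0.00  1.00  0.00
   0.90  0.00  1.00  1.00  1.00
   ...
   0.05  1.00  1.00  0.50  0.67
   0.00  1.00  1.00  0.50  0.67
```

Reading it: the grouped split put 12 complexes in training, 4 in validation
folds, 4 in test; the pooled cross-fold AUC and the held-out test AUC (one
max-of-models score per complex) are both 1.0 because the synthetic signal
is strong. In the threshold table, a very high cutoff (0.98) predicts no
positives (TPR 0, precision reported 1.0 by convention); at threshold 0
everything is called positive, so FPR = TPR = 1 and precision equals the
test-set prevalence (0.50 here, F1 = 0.67).

The same pipeline runs from the shell:

```bash
ppiscreen simulate --out sim --n-complexes 20 --seed 7
ppiscreen extract  --index sim/index.csv --out features.csv
ppiscreen train    --features features.csv --out run --seed 7
ppiscreen screen   --features features.csv --model run/model.pkl --out scores.tsv
```

Other subcommands: `decoys` (analog-swap decoy recipes + FASTA for
re-prediction), `dockq` (model-vs-native quality), `family-screen`
(ligand×receptor selectivity grid, top-k report, ROC).

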