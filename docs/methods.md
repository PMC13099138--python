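# Methods

This note documents the models and procedures implemented in `ppiscreen`,
the assumptions behind them, the tunable constants, and what the synthetic
fixtures do and do not establish about real data.

## Problem setting and entities

The screening question is binary: given one or more predicted structural
models of a candidate protein pairing plus the predictor's confidence
output, is the pairing an interacting (*active*) pair or a non-interacting
(*decoy*) pair? Every structure is partitioned into exactly two **entities**
(chain groups). An entity may hold several chains — the canonical case is a
trimeric ligand screened against a single receptor chain (3:1 grouping) —
and every "interchain" notion in the package (interface, PAE statistics,
energy terms, native contacts) is defined **across entities**, never across
raw chains. Residues are indexed positionally (0-based, concatenated chain
order) internally because PAE matrices are positional; author numbering is
kept for reporting and for model↔native correspondence.

Parsing conventions (deterministic by construction): highest-occupancy
altloc conformer kept per atom name; insertion-coded residues ordered after
their base residue; hydrogen atoms ignored everywhere. Confidence files are
JSON with canonical keys `plddt`/`pae`/`ptm`/`iptm`; an adapter maps common
score-file variants. Missing pTM/iPTM are imputed as 0 with a warning
(older score files omit them); a missing pLDDT or PAE key, or any dimension
mismatch with the paired structure, is an error.

## Interface definition

A residue is interfacial when its representative atom — Cβ, or Cα for
glycine — lies within **12.0 Å (inclusive)** of a representative atom on
the other entity. A non-glycine residue lacking Cβ falls back to Cα with a
warning rather than rebuilding an ideal Cβ: simplest deterministic behavior,
and isolated in one function so it can be swapped. The inclusive boundary
is fixed for reproducibility.

## Secondary structure

Labels {H, E, C} come from backbone hydrogen-bond patterns using the
Kabsch–Sander electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond if
E < −0.5. The amide hydrogen is placed 1.01 Å from N along the bisector of
the N−C(prev) and N−Cα directions (undefined at chain starts and for
proline). Helix: runs of ≥2 consecutive i→i+4 bonds label residues
i+1…i+5. Strand: residues in parallel/antiparallel bridge ladders of
length ≥2. Everything else, including residues with missing backbone,
degrades to C. This is a self-contained assignment, not a wrapper around an
external program; it agrees with the ideal-geometry fixtures (≥14/20 H on an
ideal helix, central E labels on a constructed two-strand sheet) but has not
been benchmarked against reference assignments on experimental structures.

## Confidence features (7)

Pair PAE values average the two matrix directions, (pae[i,j]+pae[j,i])/2 —
a symmetric statistic avoids an arbitrary orientation choice. The "quarter"
is k = ceil(n/4), minimum 1, so the selection is never empty.

* `ipae_top_quarter`: mean of the *highest* quarter of PAE values over
  interacting (interface) pairs — penalizes interfaces whose worst contacts
  are uncertain.
* `tpae_top_quarter`: mean of the *lowest* quarter over all N₁×N₂
  cross-entity pairs — rewards confident relative placement anywhere.
* plus `mean_interchain_pae`, `mean_iface_plddt`, `min_entity_mean_plddt`,
  `ptm`, `iptm`.

Contact-free models get sentinels: 31.75 Å (the conventional PAE ceiling)
for PAE statistics, 0 for interface-pLDDT statistics. The sentinel pushes
no-contact models toward decoy-like feature values instead of dropping them;
decoys with no contact are informative negatives.

## Counting features (33)

Counts of interface residues (total, per entity), per-class counts
(charged = {D,E,K,R}; histidine is polar, not charged; aromatic = {F,W,Y,H};
special = {G,P}), unordered class-pair contact counts over a single-class
assignment (charged > special > hydrophobic > polar precedence), interface
secondary-structure proportions per entity, `prop_iface_beta` (fraction of
interface residues labeled E), contact-pair totals and density, and charged/
hydrophobic/polar proportions. Every feature is a function of the interface
alone: the decoy construction slightly favors larger analogs, and any
feature scaling with total protein size would let the classifier exploit
that artifact. A dedicated test appends remote residues and asserts no
feature moves.

## Energy features (17)

Self-contained analogs of the classic molecular-mechanics interface terms —
original functional forms and parameters, not a port of any external scorer
(an external scorer can be plugged in for parity studies):

* **Lennard-Jones**, split: LJ(d) = ε[(σ/d)¹² − 2(σ/d)⁶]; attractive part
  = LJ(d) for d ≥ σ and −ε below σ; repulsive part = LJ(d)+ε below σ, else
  0. Clashes therefore register purely as repulsion. Cutoff 6.0 Å with a
  linear switch over the last 0.5 Å. Combining rules: arithmetic mean σ,
  geometric mean ε.
* **Electrostatics**: 332·qᵢqⱼ/(ε(d)·d) with distance-dependent dielectric
  ε(d) = d, hard cutoff 10 Å. Partial charges: backbone dipole
  (N −0.35, Cα +0.35, C +0.35, O −0.35) plus charged side-chain termini
  (Lys NZ +1; Arg NH1/NH2 +0.5 each; Asp/Glu carboxylate oxygens −0.5 each).
* **Solvation**: Lazaridis–Karplus-style Gaussian occlusion — each
  neighboring heavy atom within 6 Å desolvates an atom by
  (ΔG_free/(2π^1.5 λ d²))·exp(−((d−r)/λ)²)·V_occluder. ΔG_free is negative
  for apolar carbons (burial favorable) and positive for polar/charged N and
  O. Parameters ship as JSON (`data/energy_params.json`).
* **Hydrogen bonds**: cross-entity Kabsch–Sander energies below −0.5
  kcal/mol, split half/half between donor and acceptor residues so totals
  count each bond once.

Per-residue energies sum an interfacial residue's atoms against the *other*
entity only. The 17-member block aggregates the five terms as totals and
per-interface-residue means (totals consequently count an atom pair once
per participating interfacial residue), a weighted composite (repulsion
down-weighted ×0.55, matching the usual practice of softening clash terms),
per-contact-pair means, and two extremes (best residue composite, worst
residue repulsion). Empty interface → all 17 features are 0.

## Docking quality (DockQ)

DockQ = (Fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²))/3 with Fnat over 5 Å
heavy-atom cross-entity contacts, iRMS the backbone RMSD over native
interface residues (10 Å heavy-atom definition) after interface
superposition, and LRMS the ligand backbone RMSD after receptor
superposition (receptor = larger entity; entity 1 on ties). The
acceptable-model filter is **inclusive ≥ 0.23**. Superposition is Kabsch
(SVD, proper rotation enforced; collinear inputs rejected). Training
actives below the threshold are dropped from the *training* partition only:
in a prospective screen no native exists, so validation/test sets keep
mis-docked actives.

## TM-score and decoy generation

TM = (1/L_ref)·Σ 1/(1+(dᵢ/d₀)²), d₀ = 1.24(L_ref−15)^⅓ − 1.8 floored at
0.5 Å, normalized by the **template** (replaced) protein's length — the
ranking is *for* a template slot. The alignment is a self-contained
heuristic: gapless Cα-window seeds (length 20, stride 5, deduplicated by
diagonal offset) plus a secondary-structure-string Needleman–Wunsch seed,
each refined by iterative superpose/re-align (distance cutoff max(4.5, d₀),
≤20 iterations), best seed kept. Bit-parity with dedicated structural
alignment programs is a non-goal; self-identity is exactly 1 and rigid
invariance holds to 1e-6, which is what analog *ranking* needs. TM ties are
broken at 1e-6 resolution by lexicographically smaller id.

Analog selection excludes the protein itself and its own binding partners.
When the best analogs of both slots jointly reconstitute an active pairing
(or coincide), candidate combinations are tried in order of total rank,
then slot-1 rank — the second-best rule, generalized so the
no-reconstitution invariant is always satisfiable on small libraries. The
emitted decoy *structure* is the crude superposition product, for
inspection; the canonical decoy for screening is a re-predicted model of
the emitted sequence pair (outside this package — synthetic confidence
bundles stand in during tests). `size_bias_report` tracks the
analog/template length-ratio distribution and can flag manifest features
correlating with total length (|r| ≥ 0.5) on a decoy feature table.

## Classifier and evaluation

Unit of information is the complex: the 60/20/20 split and the stratified
5-fold cross-validation assign whole complexes (all their model rows) to one
partition/fold; a hard leakage guard asserts this on every run. Rounding of
partition sizes: n_val = round(0.2n), n_test = round(0.2n), remainder to
train; fewer than 5 complexes is a configuration error.

The default classifier is XGBoost (gradient-boosted trees) with
`tree_method="exact"`: exact split finding places thresholds mid-gap
between observed feature values, which generalizes better than histogram
bin edges on small tables with well-separated features. Defaults:
100 estimators, depth 4, learning rate 0.2, `n_jobs=1`, seeded. A logistic
baseline (standardized features) ships for framework comparisons.
Backward selection removes, at each step, the feature whose removal
maximizes cross-fold AUC (stop at target size, or when AUC falls more than
a tolerance below the full model). Hyperparameter tuning grids over
max_depth, n_estimators, learning_rate, gamma, reg_lambda,
min_child_weight (extensible), scored by cross-fold AUC; neither ever sees
test rows. All seeds default to 42 and are surfaced in config and logs.

ROC AUC is rank-based with half credit for ties (Mann–Whitney U / n⁺n⁻).
The threshold table uses prediction = score ≥ threshold; at zero predicted
positives precision is reported as 1.0 with recall 0 (and F1 = 0 when
precision+recall is 0). Complex scores are max over model scores (first
index on ties). Baselines: iPTM read from the bundle; pDockQ =
0.724/(1+exp(−0.052(x−152.611)))+0.018 with x = mean interface pLDDT ×
log₁₀(#interface contacts), x = 0 at zero contacts (constants pinned in
`config.py`).

Family screens score every ligand×receptor pairing (missing pairings are an
error — a selectivity grid is only interpretable complete), with top-k hits
per ligand (score ties broken by receptor id) against a curated
known-interaction mask supplied as input, and a flattened-grid ROC.

## Synthetic fixtures: what they emulate and what they don't

`synth` builds idealized chains from ideal bond geometry and per-residue
φ/ψ (helix −57/−47, strand −139/135, coil sampled in a polyproline-II-like
region that forms no hydrogen-bond ladders), poly-alanine by default with
optional sequence motifs. Complex poses satisfy asserted predicates:
docked (min cross-entity representative distance in [4, 8] Å, no heavy-atom
overlap < 2.5 Å), clashed (≥5 heavy-atom pairs < 2.0 Å), separated
(> 30 Å). Confidence bundles center intra-entity PAE at 2 Å and
cross-entity PAE at 4 Å (confident interface) or 25 Å (uncertain), clipped
to [0, 31.75]; pLDDT 85–95; iPTM 0.8/0.2. Feature tables draw informative
columns class-conditionally at a stated standardized mean difference with a
shared within-complex effect (sd 0.5) and label-independent nuisance
columns. All generators are seed-deterministic.

These fixtures exercise every code path with controllable ground truth, but
they are *easier* than real screening data: class-conditional distributions
are cleanly separated, confidence signals are consistent with geometry by
construction, and sequences are compositionally trivial. Passing tests
demonstrate correctness of the machinery (definitions, invariants,
protocol, leakage guards), not the discrimination performance obtainable on
real predicted complexes — benchmark AUCs on thousands of externally
predicted models are out of scope. Accordingly the acceptance study's AUCs
(≈1.0 for the classifier and the iPTM baseline at the default conditions)
characterize the synthetic conditions; pDockQ scores lower there because
synthetic pLDDT carries no class signal, leaving it only the contact count.

Null-calibration checks use the mean cross-fold AUC over 20 seeds (band
[0.4, 0.6]); single-seed AUCs on small tables are quantized and individually
bounded only loosely ([0.2, 0.8]).

## Numerical choices and degenerate inputs

* Distance ties at cutoffs: inclusive (≤) everywhere.
* Empty interface: PAE sentinel 31.75 Å, pLDDT/count/proportion sentinels 0,
  all energy terms 0; never dropped.
* top-quarter k = ceil(n/4) ≥ 1; empty value sets are an error.
* Superposition requires ≥3 non-collinear points.
* d₀ floor 0.5 Å; chains shorter than 15 residues are outside the TM
  formula's domain and rejected.
* Argmax/selection ties: first candidate in iteration order (features),
  lexicographic id (analogs, receptors).
* Exit codes: 0 success, 2 configuration, 3 data, 4 computation errors.

## Problem sizes used by the shipped runs

The test suite and acceptance script run on synthetic studies sized for
stable statistics: the screening study uses 60 complexes × 5 models,
the family screen a 5×6 grid, decoy libraries 8 proteins, classifier
recovery 30 complexes × 5 models × 20 seeds, and the split-leakage guard
1000 random draws. These are the package's chosen study conditions.

## Known limitations

* The energy terms are coarse analogs: no side chains beyond Cβ are built
  for synthetic fixtures, hydrogens are ignored, and parameters are a small
  original table — adequate for discriminative features, not for
  thermodynamics.
* The TM alignment heuristic can underestimate similarity between folds
  related by large insertions (window seeds are gapless; only the SS seed
  introduces gaps).
* Secondary-structure assignment is untested against reference assignments
  on experimental structures.
* The 57-feature roster is a declared reconstruction, shipped as a
  versioned manifest so it can be revised without code changes; trained
  models embed the manifest version and refuse mismatched tables.
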