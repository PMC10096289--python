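# Methods

This note records the models the package implements, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic studies do and do not demonstrate.

## Consensus signature aggregation

Each perturbational signature is a z-score vector over a fixed, ordered
landmark gene panel (unitless; the real L1000 panel has 978 genes, synthetic
studies default to 50).  Signatures are never imputed onto a panel: readers
reorder columns to the panel and fail on missing genes.

Replicates are combined by correlation weighting.  For signatures
`x_1 … x_n`, the pairwise Spearman matrix `R` (average ranks for ties;
constant vectors correlate 0 by convention, so a flat profile is treated as
uninformative rather than undefined) yields weights proportional to the
off-diagonal row sums of `R`, normalized to sum to one, and the consensus is
the weighted mean.  Two numerical choices:

* **Correlation floor** (`floor`, default **0.01**): each off-diagonal entry
  is floored at a small positive value before the row sums.  Anti-correlated
  replicate sets can otherwise produce zero or negative weight mass, which
  has no meaningful convex interpretation.  The floor keeps every weight
  strictly positive, so the consensus always lies in the convex hull of its
  inputs.  With the floor in place, `n = 1` reduces to the identity and
  `n = 2` to the simple mean; both are implemented as explicit fast paths,
  and a set of bit-identical replicates returns the replicate exactly.
* **Stage order**: condition-level replicates are collapsed *within* each
  cell line first, and the per-cell-line consensus vectors are then combined.
  This keeps a cell line with many replicates from dominating the target's
  representative vector; single-stage pooling is available only as a
  diagnostic flag, and the tests assert it is measurably worse under
  replicate-count skew.

All floating-point comparisons in the tests are at 1e-9 absolute unless the
assertion is about exactness (replicate idempotence, noise-free recovery),
which is exact by construction.

## PPI-based target inference

Targets without measured signatures get inferred vectors: the
correlation-weighted average (same machinery as above, each neighbour vector
acting as one replicate) of the measured vectors of their **direct**
neighbours in a high-confidence PPI graph.  Parameters:

* **Edge threshold**: strictly greater than 0.9 on the unit scale (900 on
  the STRING 0–1000 combined-score scale; both scales are accepted with an
  explicit declaration, since silently mixing them is a classic failure).
* **`min_neighbors` = 3**: genes with fewer covered neighbours stay absent.
  Support is monotone — removing a neighbour can only move a gene toward
  absent.
* **One hop, self excluded**: no propagation or iteration, and a gene's own
  measured vector never joins its neighbour pool, so inferred-vs-measured
  comparisons for the same gene are honest validation pairs.

A store may hold measured and inferred entries for the same gene; plain
lookups prefer measured.  Validation compares within-gene correlations
(inferred vs measured, same gene) against between-gene correlations with a
one-sided Mann–Whitney rank-sum test.

## Compound featurization

Molecules are parsed from SMILES; the largest covalent fragment is kept
(salts and counterions carry no embedding information) and atoms are
renumbered canonically, so every spelling of the same molecule yields the
same token sentence.  The sentence emits, per heavy atom, the Morgan
environment identifier at each radius in `{0, 1}` (configurable), and the
compound vector is the exact sum of the per-token embeddings — duplicates
counted with multiplicity.  Unknown tokens are skipped by default (a
zero-vector policy is available); a sentence with no known token embeds to
the zero vector with a warning.  The embedding table itself is an input
artifact (default dimension 300 in real use; synthetic studies use 16) —
training it is out of scope.  Hashed Morgan bit vectors (2048 bits, radius
2) and MACCS keys are provided as binary baselines; RDKit's MACCS output
pads an unused bit 0, which is dropped to honour the 166-key contract.

## Dataset assembly

Positive pairs come from a curated (compound, target gene, mode-of-action
term) table; `activator`/`agonist` map to the activatory mode and
`inhibitor`/`antagonist` to the inhibitory mode, case-insensitively;
anything else is dropped and counted.  Feature rows are the compound vector
followed by the target vector.  Tiers follow target provenance: `original`
(measured vectors), `additional` (inferred-only), `integrated` (either);
when no gene holds both provenances the original and additional tiers
partition the integrated one.

Negative pairs are drawn uniformly without replacement from the compound ×
target grid of the positive set, excluding same-mode positives only — an
activatory positive may legitimately be sampled as an inhibitory negative,
since the two modes are separate classification problems.  The sampling
universe is the *full* dataset's grid even when sampling for one CV fold;
fold-restricted grids would both bias the negatives toward the fold's
compounds and make 1:10 test sampling infeasible at small scale.

## Classifiers

The cascade deep forest trains levels of `n_estimators_per_level` forests
(half `RandomForestClassifier`, half `ExtraTreesClassifier`, each with
`n_trees` trees; defaults **8** and **500**).  Level `t > 1` receives the
original features plus the previous level's out-of-fold class-probability
vectors (`n_estimators_per_level × 2` extra columns).  Out-of-fold
probabilities come from an internal stratified k-fold
(`cv_folds_internal = 3`); each forest is then refit on the full level input
for prediction time.  The per-level validation score is out-of-fold AUPR by
default (AUROC and accuracy are available) — AUPR because it is the more
informative metric under the class imbalance this problem runs at.  Training
stops when a level fails to beat the best score by more than
`stop_tolerance` (default 1e-4) or at `max_levels` (20), keeping the
best-scoring prefix; since every metric is bounded by 1, training also stops
as soon as no attainable score could clear the tolerance, which makes an
infinite tolerance train exactly one level.  Prediction averages the last
level's positive-class probabilities.

Baselines (logistic regression, random forest, MLP) share the
`predict_scores` contract.  Tree models see raw features; logit and the MLP
get z-scaling fit on the training data only.  The MLP uses two hidden
layers (256, 64), ReLU, and early stopping on a 10 % validation split — a
conventional configuration recorded here as a package default, not a claim
about any reference architecture.  Hyperparameter search is greedy
coordinate descent over a declared grid, one axis at a time, scored by CV
AUPR, ties breaking to the first-listed value.

## Evaluation protocol

Repeated k-fold CV (defaults k = 5, 5 repeats) partitions the *positives*;
per fold the model trains on held-in positives plus 1:1 sampled negatives
and is tested on held-out positives plus `test_negative_ratio` (1 or 10)
times as many fresh negatives.  All seeds derive from one master seed via
named `SeedSequence` derivations (repeat, fold, role), so a run is
reproducible to the byte and no global RNG state exists anywhere in the
package.

Enrichment factor EFx% is precision at an operating point divided by
positive prevalence.  The printed-formula denominator is read as the total
sample size, which is the only reading consistent with "enrichment over
chance".  The operating point is the largest calling set whose false
positive rate does not exceed the budget (the conservative side of the
discrete ROC); linear ROC interpolation at exactly the budget is available
as `method="interpolate"`.  Two edge cases: if no non-empty calling set fits
the budget (the top-scored items are all negatives), EF is 0 with a warning;
if the score vector is entirely tied it carries no ranking information and
is scored at chance level (EF = 1) via the diagonal ROC — the two cases are
distinct because the first is an informative ranking that fails at the
budget, the second is no ranking at all.

Reference ranking counts reference scores strictly greater than the query
(optimistic rank, query assumed a member of the pool) and reports
`100 · rank / size`.  Rediscovery at a threshold uses a strict inequality:
a score exactly at the threshold does not count.

## Synthetic studies

The generator emulates the statistical structure the method assumes, not the
technology: per target a true vector drawn from N(0, I); replicates =
truth + N(0, noise_sd²·I) on a cells × conditions grid; PPI neighbourhoods
whose vectors are correlated copies of the truth plus decoy low-degree
nodes; a random token embedding table with compounds as random token
multisets; and DTI labels planted by thresholding a noisy pair propensity.
Defaults (the study conditions for all tests): 50-gene panel, 30 targets,
3 cell lines × 3 conditions at noise SD 0.5, PPI degree 4, 16-dimensional
embeddings over 200 compounds, 500 positives.

The planted propensity is `slope · s · z + ε` with `ε ~ N(0, 1)`, slope 4,
signal strength `s ∈ [0, 1]`, and `z` the standardized mix of **additive
main effects** (compound and target linear scores) and a **bilinear
interaction** `cᵀW t`, mixed 70 / 30.  The additive component is essential:
a purely bilinear interaction is invisible in expectation to any linear
model on concatenated `[c, t]` features (the best additive approximation of
`cᵀWt` under isotropic inputs is zero), so a pure-interaction plant would
make the logistic baseline a coin flip and leave the cascade nothing
linear-comparable to beat.  The mixed plant gives a linear model a provable
foothold while still rewarding interaction-capable models.  Positives are
the top pairs by noisy propensity, so labels carry both signal and noise.

What passing tests on these studies show: the formulas and protocol are
implemented correctly, planted structure of the assumed kind is recovered,
and the machinery is deterministic.  What they do not show: performance on
real perturbational data — the generator has no beadset effects,
dose–response shapes, cell-line biology, chemical series structure, or
curation biases in the positive labels.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: formula-level
checks at n ∈ 2…6, G ∈ 5…30; aggregation studies at 50 targets × 3 seeds;
inference validation at 30 targets; classifier benchmarks at 500 positives
(1,000 rows, 66 features) with a 70/30 split over 3 seeds; the CV protocol
at 150 positives over 15 targets × 120 compounds, k = 5 × 2 repeats.  These
sizes make every planted effect comfortably detectable while keeping a full
run in minutes.

## Known limitations

* The cascade follows the published cascade-forest idea, not any specific
  library's internals; per-level forest composition and the stopping metric
  are package choices.
* GCT support is the 1.2/1.3 text dialect only; binary GCTX is not read.
* Identifier normalization (PubChem CIDs, HGNC symbols) is the caller's
  job; compound ids and gene symbols are opaque strings here.
* Mode-of-action vocabulary is the four-term map above; richer pharmacology
  (partial agonism, allosteric modulation) is out of scope.
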