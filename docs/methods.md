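# Methods

`dpicdf` predicts whether a protein is druggable — able to bind drug-like
small molecules with therapeutic effect — from its amino-acid sequence
alone. A sequence is mapped into three complementary feature views, the
views are fused by serial concatenation, and a cascade deep-forest
classifier produces the final class probability. This note records the
model, its parameters, and the design choices made where published
descriptions of this family of methods leave the details open.

## Feature encoders

### HOG-PSSM (evolutionary view, 256-D)

The evolutionary profile of a protein is an L x 20 position-specific
scoring matrix (PSSM) of log-odds conservation scores, as produced by
iterative PSI-BLAST search. Each raw score *a* is squashed with the
logistic function f(a) = 1 / (1 + exp(-a)), giving a matrix of values in
(0, 1) that is then treated as a grayscale image and summarized with a
histogram-of-oriented-gradients descriptor:

1. **Gradients.** Central differences along both axes; at the first and
   last index of an axis, one-sided differences against an implicit zero
   border (`P(next) - 0` and `0 - P(prev)`). `Gx` runs along the 20
   amino-acid columns, `Gy` along the sequence. Magnitude is
   `sqrt(Gx^2 + Gy^2)`; direction is the two-argument arctangent
   `atan2(Gx, Gy)`. The two-argument form is a deliberate choice: the
   plain ratio `Gx / Gy` is undefined when `Gy = 0` and loses the sign
   quadrant, while `atan2` agrees with it wherever the ratio is defined.
2. **Cells.** The matrix is tiled into a 4 x 4 grid: the 20 columns split
   into four blocks of 5 residue columns; the L positions split into four
   blocks of floor(L/4), the last block absorbing the remainder (no
   padding, no truncation — every position contributes). Sequences must
   have L >= 8 so each cell holds at least two positions.
3. **Histograms.** Each cell accumulates a 16-bin orientation histogram
   over equal angular bins covering the full circle (left-closed bins,
   with +pi folded into the last bin), each vote weighted by the gradient
   magnitude — the standard HOG convention, chosen over unweighted counts.
   Each cell histogram is L2-normalized; a cell with no gradient mass
   (norm below epsilon = 1e-12) stays all-zero rather than being divided.
   No block-overlap normalization is applied.

16 cells x 16 bins = 256 dimensions. The grid geometry is configurable
(`HOGConfig`); published index bounds for this construction are mutually
inconsistent, and the 4 x 4 grid is the only tiling consistent with a
256-D output over a 20-column profile, so it is the default here.

### NQLC (physicochemical composition/transition/distribution, 147-D)

Seven attributes — hydrophobicity, normalized van der Waals volume,
polarity, polarizability, charge, secondary-structure propensity, solvent
accessibility — each partition the 20 residues into three groups
(Dubchak-style CTD tables, shipped as editable TSV under `dpicdf/data/`).
Per attribute the sequence becomes a string over {1,2,3} and yields:

- **C** (3): fraction of residues per group,
- **T** (3): fraction of the L-1 adjacent pairs whose members lie in two
  different groups, per unordered group pair,
- **D** (15): for each group, the position (percent of L) of its first
  occurrence and of the residues completing 25%, 50%, 75% and 100% of the
  group's occurrences; absent groups report zeros. Five landmarks per
  group is the only reading consistent with the 105-D distribution block.

7 x (3 + 3 + 15) = 147. Feature matrices are standardized column-wise with
a z-score y = (x - mean) / std using the sample standard deviation
(denominator n - 1), fitted on training data only and applied to test
data; a min-max [0, 1] mode exists behind `mode="minmax"`. Zero-variance
columns are flagged and mapped to 0 with a warning.

### CPSR (composite compositional view, 71-D)

Concatenation, in order: amino-acid composition (20), raw sequence length
(1, z-scored later with the rest of the matrix), ordered bigram
frequencies over the six Dayhoff exchange groups {HRK} {DENQ} {C} {STPAG}
{MILV} {FYW} normalized by L-1 (36), electron donor/acceptor class
frequencies (6), mean per-residue rigidity, flexibility and
irreplaceability (1 each), and side-chain R-group family frequencies (5).
Group blocks are length-normalized frequencies by default
(`count_mode="count"` restores raw counts). Bigrams are ordered
(e1e2 != e2e1), which is what makes the block exactly 6^2 = 36 wide.

The scalar scales shipped as defaults are literature stand-ins, stored in
the same editable TSV config: flexibility is the Vihinen normalized
B-factor scale; rigidity is that scale mirrored about 1 (higher = stiffer
backbone); irreplaceability is the reciprocal of Dayhoff relative
mutability, scaled so alanine = 1 — a residue that mutates rarely is hard
to replace. Users with preferred scales can substitute them without
touching code.

### Fusion

Serial concatenation in the fixed order CPSR, NQLC, HOG-PSSM:
Hybrid1 = CPSR+HOG (327), Hybrid2 = NQLC+HOG (403), Hybrid3 = all three
(474). Tree ensembles are order-invariant, but a fixed order keeps block
schemas and feature-attribution audits reproducible. Standardization is
applied matrix-wide after fusion in training mode.

## Cascade deep forest

Each layer holds four tree learners — one gradient-boosted ensemble
(XGBoost), one random forest, two extra-trees forests — a mix matching
the "four learners" gcForest-style design while covering the three named
families. Forests sample sqrt(d) candidate features per node split; the
boosted learner subsamples columns per tree at the same sqrt(d)/d rate.

A layer's class probabilities are estimated **out-of-fold** via internal
3-fold stratified cross-fitting, so no sample is scored by a model that
saw it; without this, stacked layers overfit trivially. Layer t >= 2
consumes the original features concatenated with layer t-1's eight
probability columns (d + n_estimators x 2). A layer's validation score is
the accuracy of its averaged out-of-fold probabilities; growth stops after
`patience` (default 1) consecutive layers without a new best, or at
`max_layers` (default 20), and layers beyond the best are discarded. At
inference the input is propagated through full-data refits of each
layer's learners and the final probability is the mean of the last
layer's four probability vectors; an exact 0.5/0.5 tie resolves to the
negative class.

Defaults: 100 trees per learner (a practical default; the tree budget is
config-owned and the degenerate single-forest configuration is covered by
an exact equivalence test), `internal_cv_folds=3`, binary classes only.
All randomness derives from one master seed via `numpy.random.SeedSequence`
(per-layer, per-estimator, per-fold), so a full fit/predict run is
bit-reproducible; serialization via joblib round-trips predictions
bit-identically.

## Evaluation

ACC, SEN, SPE and MCC from the confusion table, with the druggable class
positive. MCC is 0 when its denominator vanishes; SEN/SPE are 0 when no
member of the relevant class was evaluated (documented conventions —
stratification makes them unreachable in practice). AUC is the
Mann-Whitney rank statistic (ties counted 1/2), equal to the trapezoidal
integral of the empirical ROC curve. Cross-validation is stratified
k-fold (per-class fold sizes differ by at most 1); standardization and
all model fitting happen strictly inside the training folds. Headline
numbers are means over folds; a pooled-confusion variant and the AUC of
the pooled out-of-fold scores are also reported.

## Synthetic data

`generate_synthetic_dataset` draws residues i.i.d. from per-class
composition profiles, lengths uniform on [50, 300] by default. Negatives
use the uniform profile; positives are enriched 2:1 in hydrophobic
residues (ACFILMVWY), a coarse emulation of the compositional bias that
separates druggable from non-druggable proteins. `synthesize_pssm` stands
in for a PSI-BLAST search: row i gets +sharpness (default 8) at the column
of residue i plus rounded Gaussian noise (sd 1), i.e. a conservation
profile of a non-divergent family.

What this does **not** emulate: positional motifs, domain architecture,
realistic alignment-depth-dependent PSSM structure, length/composition
confounds, or homology between train and test sequences. Passing tests
therefore demonstrate that the encoders, fusion, classifier and CV
protocol are implemented correctly and are leakage-free — not that the
method attains any particular accuracy on real druggability benchmarks,
which additionally require curated datasets and PSI-BLAST profiles
against Swiss-Prot.

## Numerical choices and problem sizes

- Logistic normalization is exact `scipy.special.expit`; non-finite PSSM
  entries are rejected rather than silently propagated.
- Orientation binning is left-closed with +pi folded into the final bin;
  a zero-gradient position votes with weight 0 and cannot shift any bin.
- CTD distribution landmark for quantile q of a group with n_g members is
  the ceil(q * n_g)-th occurrence (at least the 1st).
- Exact reproducibility requires single-threaded estimators; all base
  learners are constructed with `n_jobs=1`.
- Test and acceptance runs use deliberately modest problem sizes — 200
  synthetic sequences, 40-50 trees per learner, at most 2-3 layers — as
  the package's own defaults for its self-checks; the classifier defaults
  themselves are larger.

## Known limitations

- The shipped CTD group tables and CPSR scales are standard literature
  versions; method variants published with private supplementary tables
  will differ numerically until those tables are substituted via the TSV
  config.
- Inference re-propagates through full-data refits while growth was
  scored on out-of-fold probabilities; layer-2+ inputs therefore have a
  slightly different distribution at train and test time. This is the
  standard cascade-forest trade-off.
- Binary classification only; no multi-grained scanning front-end; PSSM
  generation itself (PSI-BLAST against Swiss-Prot) is out of scope — the
  package parses the ASCII output or synthesizes profiles.
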