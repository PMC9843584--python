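# Methods

This note documents the models, procedures and numerical choices behind
`ntaug` in enough detail to reason about what a passing test does — and does
not — establish.

## Nucleotide augmentation

A protein sequence over the 20 canonical residues maps to
∏ᵢ dᵢ synonymous coding sequences, where dᵢ ∈ {1,…,6} is the codon
degeneracy of residue *i* in the active codon table. Augmentation samples
this space; every emitted nucleotide sequence inherits the parent's label
unchanged, and the package enforces (and property-tests) that every output
translates back to its parent under the configured table.

**Offline iterative.** The base sequence takes the lexicographically first
codon of every residue — "the same codon every time", so identical proteins
always map to identical DNA. Augmentations 1…n−1 then walk the cartesian
product of per-position codon choices as a mixed-radix counter with the
*leftmost* codon position as the fastest digit: the first few augmentations
differ from the base only near the sequence start, concentrating
modifications in one region. Which end varies fastest is an arbitrary
convention; leftmost was fixed here for reproducibility. When n_aug exceeds
the synonym capacity the output is capped at capacity with a warning —
enumeration cannot mint new distinct sequences.

**Offline random.** Each of the n_aug outputs draws every residue's codon
uniformly and independently. Duplicates are possible and are kept (with a
warning): that is what uniform sampling of a finite space produces, and
deduplicating would silently change the effective augmentation factor.

**Online probabilistic.** Per mini-batch sequence a fresh p_aug ~ U(0,1) is
drawn; modification fires when p_aug strictly exceeds the threshold t_aug
(default 0.5). The substitution count k is drawn uniformly from
{1, …, max(1, ⌊NumSubs·L⌋)} (NumSubs default 0.25, L = codon count);
positions are chosen uniformly without replacement among positions with
degeneracy ≥ 2, and each chosen codon is replaced by a uniform draw over its
synonyms *excluding itself*, so a firing modification actually changes the
sequence whenever any degenerate position exists. The exact step-level
schedule (k distribution, exclusion of the current codon) is this package's
design choice; it guarantees the codon-Hamming bound 1 ≤ d ≤ max(1,⌊NumSubs·L⌋)
that the tests assert. p_aug is redrawn every time a batch is formed, i.e.
fresh per epoch.

## Codon tables

- **natural** — the standard genetic code restricted to its 61 sense
  codons. Stop codons are excluded everywhere: the method augments coding
  sequence only, so reverse translation can never emit a stop and
  translation treats one as an untranslatable codon.
- **balanced** — exactly 3 codons per residue (60 codons used). Published
  balance tables for this construction live in supplementary material not
  bundled here, so the package builds its own: residues with ≥ 3 natural
  codons keep their 3 lexicographically smallest; the rest keep all of
  theirs and are topped up from the pool of unassigned sense codons by a
  seeded shuffle. This honors the 3-per-residue constraint deterministically
  while staying close to the natural relationship. A user with a published
  table can load it verbatim via the plain-text serialization
  (`CodonTable.from_text`).
- **shuffled** — a seeded permutation of the 61 sense codons dealt back out
  in the natural per-residue degeneracy counts (residues iterated
  alphabetically), destroying codon identity while conserving the
  degeneracy multiset {6,6,6,4,4,4,4,4,3,2,…,2,1,1}.

Every table is a function in both directions: each codon belongs to at most
one residue, so translation is reverse lookup.

## Encodings

Vocabularies are closed and alphabet-derived, never fitted: 4 nucleotide
unigrams, 64 trigrams, 68 tri+unigrams, 21 amino-acid unigrams (20 canonical
+ UNK). Token ids start at 1; id 0 is a reserved PAD id outside the content
vocabulary, marked by a boolean mask rather than a vocabulary entry. The
tri+unigram token list is the trigram list followed by the unigram list
(L/3 + L tokens). One-hot tensors have content_size columns; PAD rows are
zero. The amino-acid one-hot carries a 21st UNK column but has support on
only 20 columns for clean sequences, reconciling a 21-token vocabulary with
an L×20 one-hot for canonical input. UNK is an encoder-level token only;
codon operations reject non-canonical residues outright.

## Data protocols

- **Edit distance** is Levenshtein (unit-cost substitution/insertion/
  deletion; coincides with Hamming for equal-length pairs), implemented as a
  Wagner–Fischer DP because no edit-distance library ships in the target
  environment.
- **Splitting**: records within `ed_threshold` of the wild type form
  train+validation (default 20% validation, stratified by class or by
  10-quantile fitness bin); records beyond it form the test set — training
  near the wild type and testing far from it measures extrapolation, the
  regime these libraries are actually used in.
- **Stratified truncation** bins fitness into 10 quantile bins (duplicate
  edges merged) and apportions per-bin quotas by the largest-remainder
  method, so the subset size is exactly ⌈fraction·n⌉ and bin proportions are
  preserved to ±1 record. Bin count and rounding rule are package decisions;
  quantile bins keep quotas populated under skewed fitness distributions.
- **Class imbalance** down-samples positives to round(ratio · n_negatives),
  seeded, negatives untouched. **Minority-class augmentation** expands only
  the minority class n_aug-fold; the majority class is reverse translated
  once per record (random codon sampling). A tie in class counts makes
  "minority" ambiguous and must be resolved explicitly by the caller.
- **Test replicates**: nucleotide models are evaluated on 5 independent
  reverse translations of the test set (replicate i seeded base_seed + i),
  because random codon sampling makes the test representation itself
  stochastic. Deterministic (iterative-style) sampling yields 5 identical
  replicates by construction, mirroring the training condition's sampling.
  In the experiment driver the validation split is taken *before* imposing
  class imbalance, so validation stays balanced while training is
  imbalanced; this differs from re-splitting after imbalance and makes the
  validation metric comparable across imbalance ratios.

## Synthetic data (what a green test establishes)

The generators produce desk-scale stand-ins with the *shape* of real
combinatorial libraries, not their biology:

- **Landscape**: 9-residue wild type, 4 fully mutable positions (19
  alternatives each — a 20⁴ = 160,000-variant space), fitness =
  Σ additive effects + Σ sparse pairwise epistasis (30 random residue-pairs
  per position pair, N(0, 0.5)) + N(0, 0.1) noise; additive effects
  N(0, 1). ~3,000 variants are sampled across edit distances 1–4 with
  √-of-availability weighting — linear weighting would starve the
  near-wild-type strata that form the training side of the split, and the
  √ rule lands near the ~1:2 near/far proportions of real benchmark splits.
- **Binder library**: all 9 positions mutable over a reduced 8-residue
  alphabet; the same latent-fitness form thresholded at an empirical
  quantile to hit a target positive fraction (default 0.5).

Both are deterministic in their seed. What green tests establish: the
pipeline's algebra (synonymy, shapes, counts, determinism) and the
directional claim that augmentation helps when training data are scarce
*on this landscape family*. They do not establish benchmark-level metric
values on real mutagenesis data, which require the external datasets and
much longer training.

## Models and training

The reference models follow the published architectures but run on a small
in-repo numpy reverse-mode autodiff engine (`ntaug.nn`) because no deep
learning framework is available in the target environment; all primitive
gradients are verified against central finite differences in the test
suite.

- **Transformer**: token ids → embedding → sinusoidal positional encoding →
  post-norm encoder layer (multi-head self-attention with key padding mask,
  feed-forward, residual + layer norm, dropout 0.3) → PAD positions zeroed →
  flatten → linear → ReLU → dropout → linear(1). Paper preset: embedding
  256/32, heads 8/2, feed-forward hidden 1024/128, penultimate linear
  1024/512 (regression/classification); the "hidden dimension" is read as
  the encoder layer's feed-forward width.
- **CNN**: one-hot input → [conv1d (same padding) → batch norm → ReLU → max
  pool 2] per layer → flatten → linear → ReLU → dropout → linear(1). Paper
  preset: kernels 5,3 with 1024,512 filters (regression); kernel 5 with 64
  filters (classification).
- The **desk** preset keeps layer structure and shrinks widths (transformer
  32/2/64/64 and 16/2/32/32; CNN 64,32/64 and 16/32) so a full grid trains
  on one CPU in minutes. Models are built to a fixed token length and every
  batch is padded to it, which makes predictions provably invariant to the
  amount of right-padding an input batch carries.

Training: SGD with momentum 0.9; MSE (regression) or binary cross entropy
(classification); batch size 32; learning rate 0.01 by default (unstated in
the source work; chosen once from the desk-scale smoke runs). Offline runs
early-stop on the validation metric (Spearman ρ / MCC) with patience 10 and
restore the best epoch; online runs train a fixed epoch count so augmented
and baseline models see equally many gradient steps. Class-weighted
sampling draws mini-batch indices with replacement with probability
∝ 1/class frequency. Three independent seeded streams (batch order, dropout,
online augmentation) derive from the training seed, so disabling online
augmentation (t_aug = 1.0) reproduces the un-augmented run bit for bit.
Gradient clipping (global norm, max 1.0) is an optional flag; the desk
transformer uses it — without clipping, post-norm transformer + SGD at this
scale either diverges or collapses to constant output, the same instability
that motivates clipping on long-input tasks. Classification decisions
threshold the sigmoid output at 0.5.

## Evaluation

Spearman's ρ is computed via scipy (average ranks, Pearson on ranks) and
MCC via scikit-learn, both wrapped with explicit domain checks: a constant
vector makes ρ undefined and raises rather than returning 0, while MCC's
zero-denominator cases return 0 by the standard convention (keeping
imbalance sweeps plottable). Both implementations are cross-checked against
independent brute-force oracles (sorting-based ranks; explicit confusion
counts) to 1e-12 in the tests. Aggregation is nested: mean over the 5 test
replicates within a seed, then mean / sd / normal-approximation 95% CI
(mean ± 1.96·sd/√n) across seeds; the CI is omitted for a single seed. The
nesting order is declared, not inferred.

## Known limitations

- The balanced/shuffled tables are seeded constructions satisfying the
  published constraints, not the published tables themselves.
- The synthetic landscape is additive + pairwise; real landscapes contain
  higher-order epistasis and measurement artifacts.
- The numpy engine is CPU-only and unbatched across epochs; the paper-size
  presets are provided for completeness but are impractical without real
  data and hardware.
- No significance testing between conditions beyond the seed-level CI.
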