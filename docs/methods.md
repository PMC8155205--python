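# Methods

## Molecular graphs and token/atom alignment

A molecule is the heavy-atom graph of its SMILES string: implicit hydrogens
are excluded, atoms are indexed in SMILES appearance order, and the
adjacency matrix **A** is binary and bond-order-agnostic (a single, double
or aromatic bond all contribute A[i,j] = 1). This is the standard
molecular-graph convention and it makes the alignment between the tokenizer
and the graph trivial: the k-th atomic token of the tokenized string is the
k-th atom of the parsed molecule, so row k of **A**'s embedding is added at
that token's position and nowhere else. Whether bond order or aromaticity
should enter **A** is genuinely open; binary was chosen as the minimal
reading, and the embedding layer is agnostic to the matrix's contents if a
richer encoding is ever substituted.

The tokenizer is a greedy atom-level splitter: bracket atoms `[...]` are
single tokens; `Cl`/`Br` match before `C`/`B` (outside brackets SMILES only
permits the organic subset, so no other bare two-letter element can occur —
matching, say, `Sn` greedily would mis-split aromatic sequences such as
`CSn1nco1`, which is sulfur followed by aromatic nitrogen); aromatic
lowercase atoms, ring-closure digits and `%nn` pairs, bond symbols, branch
parentheses and the dot separator are one token each. Concatenating the
tokens reproduces the input exactly, which the tests use as a round-trip
invariant. Sequences that would exceed the model's maximum length (256 by
default, with START and END added) are skipped rather than truncated,
because truncation can orphan ring-closure digits and silently change the
molecule. Out-of-vocabulary tokens at fine-tuning time map to `<UNK>`.

## Matrix embedding

The embedding of the adjacency matrix is the affine map
`E(A) = (A W_a) W_e + b` with `W_a` of shape (max_atoms × d_model), `W_e`
(d_model × d_model) and bias `b` (d_model), producing one vector per atom
row. Among the possible shape readings of this layer, this is the one that
yields per-atom vectors M_1…M_n to add at atomic positions; a
single-global-vector reading was rejected because it could not be applied
per atom. `max_atoms` defaults to 128 (tiny profile: 32); molecules with
more heavy atoms are rejected at encoding time.

Batches are cropped to the longest real sequence and largest molecule they
contain before the forward pass. The cropped regions are all PAD tokens and
zero adjacency padding, so outputs are bit-identical to the fully padded
computation (a tested invariant) while attention cost drops quadratically.

## Encoder and numerical engine

The encoder is a post-norm Transformer: per layer, multi-head scaled
dot-product self-attention (PAD keys receive a −1e9 score bias before the
softmax, so they get zero weight), an output projection, a residual
connection and layer normalization, then a GELU (exact erf form)
feed-forward block with its own residual and normalization. Dropout is
fixed at zero. Position embeddings are learned absolute (BERT-style); the
residual-plus-layer-norm arrangement is the conventional choice where the
block structure was otherwise unspecified.

All tensors run on a small reverse-mode autodiff engine written on NumPy
(`chemlm.autograd`): elementwise arithmetic with broadcasting, batched
matmul, exp/log/erf/tanh/sigmoid, reductions, reshape/transpose and
integer-array gathers. Gradients are verified against central finite
differences in the test suite. Two numerical details matter in practice:
softmax is computed with a max-shift treated as a constant (the gradient
flows through the shifted logits, which is exact), and every op output is
forced C-contiguous — elementwise work on transposed views is an order of
magnitude slower once arrays exceed cache. Float64 is used throughout;
determinism is exact for fixed seeds because the operation order is fixed.

## Pre-training

Each sequence contributes `max(1, round(0.15 n))` corrupted positions drawn
uniformly without replacement from its n real (non-special) tokens — an
exact-proportion rule rather than i.i.d. Bernoulli selection, with the
minimum of one guaranteeing a learning signal on very short SMILES. The
rounding floor(x + 0.5) is half-up, so the corpus-level selected fraction
sits slightly above 15 % (the min-1 rule biases short sequences upward; the
measured value at desk scale is ≈ 15.4 %). Each selected position becomes
`<MASK>` with probability 0.8, a uniformly random non-special vocabulary
token with 0.1, or stays unchanged with 0.1; all selected positions enter
the cross-entropy. Because the random redraw can coincide with the original
token, a sliver of the random mass is observed as "unchanged" when
classifying outcomes after the fact.

The loss is the unweighted sum (weighting configurable) of the mean
cross-entropy over corrupted positions and the squared error of the QED
prediction, a sigmoid-squashed affine readout of the first encoder output —
QED lies in (0,1], so the squashing stabilizes the regression without
changing the affine form of the head. The learning rate follows
`0.1 · d_model^-0.5 · min(step^-0.5, step·warmup^-1.5)` with Adam;
`warmup = 10,000` steps at full scale. The tiny profile uses `warmup = 100`
— with d_model = 64 and only hundreds of optimization steps, a 10,000-step
warmup would keep the learning rate below 1e-5 for the entire run.

A held-out fraction of the corpus (default 10 %) is evaluated every epoch
under corruptions drawn once and frozen, so the validation series is
comparable across epochs; the checkpoint with the best validation loss is
returned. Training histories are bit-identical across runs with the same
seed.

## Fine-tuning

Classification datasets are split by canonical Bemis–Murcko scaffold:
groups sorted by descending size (ties by scaffold string), filled greedily
into train, then valid, then test at 80:10:10, so no scaffold spans two
partitions and the test set is out-of-distribution. Regression uses a
seeded random shuffle with contiguous cuts. Multi-task datasets are learned
jointly in one model; missing labels are excluded from the per-task sigmoid
cross-entropy by a 0/1 observation mask. Regression targets are z-scored on
the training partition only and predictions de-standardized before RMSE.
Early stopping is checkpoint selection: the validation metric (mean ROC-AUC
over tasks with both classes present, or RMSE) is tracked every epoch and
the best epoch's weights are restored for the single test evaluation. Runs
repeat over 5 seeds (weight init and batch order vary; scaffold splits are
deterministic) and report mean ± std. ROC-AUC is the rank-sum estimator
with average ranks, i.e. the probability that a random positive outranks a
random negative with ties counted one half. Tasks whose evaluation
partition contains a single class are dropped from the ROC-AUC average with
a warning. The full-scale defaults mirror the published protocol
(lr ∈ {1e-5, 5e-5}, batch {64, 128}, 15 epochs classification / 40
regression); the desk-scale experiments below use larger learning rates
because the tiny model sees only hundreds of gradient steps. The QED head
is detached during fine-tuning (not kept as an auxiliary loss); whether to
keep it is an open choice.

## Synthetic data

The generator grows random trees over {C, N, O, S, F, Cl, Br} under the
valence budget C:4, N:3, O:2, S:2, halogens:1, optionally closes one ring
and optionally upgrades one bond to a double bond where spare valence
allows, then emits the SMILES through RDKit (which may aromatize suitable
rings), guaranteeing chemical validity without a rejection loop. Molecules
have 4–12 heavy atoms by default and are deduplicated; generation is
deterministic per seed. Toy tasks label these molecules by structural rules
(ring presence, heteroatom counts, halogen presence) or by heavy-atom count
plus seeded Gaussian noise. The corpus emulates none of the property
distributions, size range or scaffold diversity of a real screening
library, so passing desk-scale checks demonstrates that the machinery
learns and transfers on well-posed signals — not that it reaches published
benchmark accuracy on real assays.

## Desk-scale experiment design

All experiments (`chemlm.experiments`) use the tiny configuration
(2 layers, 4 heads, d_model 64, max_len 64, max_atoms 32) and sizes chosen
so each procedure completes in seconds to a couple of minutes on one CPU
core:

- **Memorization**: 10 molecules, 500 epochs; masked accuracy on the same
  molecules under fresh corruptions reaches ~100 %, a capacity/optimization
  sanity check. (At 200 epochs the tiny model reaches only ~75 %.)
- **Pre-training gains**: 2,000-molecule corpus, 15 epochs; evaluation on
  300 freshly generated molecules (filtered against the corpus). Held-out
  masked accuracy (~68 %) is compared against an untrained encoder (~2 %,
  near 1/|vocab|) and held-out QED MAE (~0.08) against the constant-mean
  predictor (~0.086). The QED margin is real but modest at this scale — the
  cross-entropy dominates the 1:1 loss sum, and the head recovers roughly
  0.4 correlation with the true QED.
- **Separable classification**: ring presence on 200 molecules, random
  split, lr 1e-3, 8 epochs, 3 seeds, trained from scratch; the ring-closure
  digits make the task near-linearly separable and test ROC-AUC exceeds
  0.9. A random split is used because the ring label is a deterministic
  function of the Murcko scaffold: scaffold splitting necessarily yields
  single-class validation/test partitions for this label.
- **Noisy regression**: heavy-atom count + N(0, 0.5²) on 300 molecules from
  the pre-trained encoder, lr 3e-4, 25 epochs; test RMSE (~0.64) lands
  within twice the injected noise floor.
- **Transfer**: heteroatom-count ≥ 3 classification (a label overlapping
  the chemistry the QED objective rewards through the HBA/PSA
  desirabilities), 300 molecules, random split, lr 5e-4, 15 epochs,
  5 matched seeds. For each seed the scratch model's best validation
  ROC-AUC defines a target; the pre-trained encoder reaches it in a median
  of ~2–4 epochs versus ~8–15 for scratch. Smaller datasets (150 molecules,
  i.e. 15-molecule validation sets) or lr ≤ 2e-4 leave both models at
  chance within the epoch budget and measure nothing.

## Known limitations

- The engine is single-threaded NumPy; the full-scale 8×16×1024
  configuration is expressed but not practical to pre-train here.
- The adjacency matrix ignores bond order, aromaticity and stereochemistry;
  3D structure is out of scope.
- The synthetic corpus is narrow (4–12 heavy atoms, 7 elements, at most one
  ring), so vocabulary and scaffold diversity are far below real corpora.
- QED desirability parameters come from RDKit's implementation; the
  geometric mean is computed in-repo and tested against it.
- Greedy scaffold splitting can over-fill the training partition by up to
  one scaffold group; ratios are exact only in expectation.
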