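# chemlm

A Transformer encoder for molecular property prediction that reads SMILES
strings but does not rely on SMILES alone: the input embedding of every
*atomic* token is augmented with a learned embedding of the molecule's
heavy-atom adjacency matrix, and the encoder is pre-trained with a dual
self-supervised objective — masked-token recovery plus regression of the QED
drug-likeness score — before being fine-tuned on downstream
classification/regression tasks.

The package is aimed at cheminformatics practitioners who want a
property-prediction model that can be pre-trained on an unlabeled SMILES
corpus and fine-tuned on small labeled datasets (single- or multi-task, with
missing labels allowed), entirely from the command line or from Python.
The neural network and its training loop run on a small NumPy reverse-mode
autodiff engine included in the package, so a CPU is all that is required at
desk scale; the full-size configuration (8 layers, 16 heads, 1024-d) is
expressed by the same code.

## Model

For a molecule with heavy-atom adjacency matrix **A** (binary, symmetric,
zero diagonal, atoms in SMILES appearance order), the input representation
at token position *p* is

```
h_p = TokEmb(x_p) + PosEmb(p) + [p is the k-th atomic token] · E(A)_k
E(A) = (A · W_a) · W_e + b            (one d_model vector per atom row)
```

Non-atomic tokens (bonds, ring digits, parentheses, specials) receive no
matrix term. The encoder is a standard stack of multi-head scaled
dot-product self-attention blocks,

```
Attention(Q, K, V) = softmax(Q Kᵀ / √d_k) V ,   Q = H W^Q, K = H W^K, V = H W^V,
```

with GELU feed-forward networks, residual connections, layer normalization,
no dropout, and PAD positions excluded from every attention row.

Pre-training corrupts 15 % of the real tokens of each sequence
(80 % → `<MASK>`, 10 % → random chemistry token, 10 % unchanged) and
minimizes the sum of the masked-token cross-entropy and the squared error of
the QED prediction read from the first (START) output, where

```
QED = exp( (1/n) Σ ln d_i )
```

is the geometric mean of the eight standard property desirabilities
(computed through RDKit). Optimization is Adam under the warmup schedule

```
lr(step) = 0.1 · d_model^-0.5 · min(step^-0.5, step · warmup^-1.5)
```

Fine-tuning replaces the output layers with a per-task affine head on the
first output, splits data 80:10:10 (Bemis–Murcko scaffold split for
classification, random split for regression), applies early stopping on the
validation metric, and reports mean ± std of test ROC-AUC or RMSE over
5 seeds.

## Worked example

Everything below runs on one CPU in about a minute, using the built-in
synthetic molecule generator (valence-respecting random molecular graphs)
instead of a downloaded corpus:

```
$ chemlm make-fixtures --n 300 --seed 0 --out fixtures
wrote 300 molecules to fixtures

$ chemlm pretrain --corpus fixtures/corpus.smi --profile tiny \
      --epochs 10 --seed 0 --out pretrain_run
...
INFO epoch 10: train_loss=2.1050 val_loss=2.0222 acc=0.321 mae=0.0692
best epoch: 10 masked_accuracy=0.321 qed_mae=0.0692

$ chemlm finetune --data fixtures/classification.csv --task classification \
      --checkpoint pretrain_run/checkpoint --split random \
      --epochs 8 --lr 1e-3 --seeds 5 --seed 0 --out finetune_run
...
test roc_auc: 0.9982 +/- 0.0036 over 5 seeds
```

The pre-training log shows the two self-supervised signals improving
(masked-token accuracy rising from chance ≈ 4 % to 32 % after ten epochs on
270 training molecules; held-out QED mean absolute error falling to 0.069),
and the fine-tuned model separates ring-containing from acyclic molecules
almost perfectly on the held-out test split (ROC-AUC 0.998 averaged over
five seeds). `finetune_run/report.json` records the seed, configuration,
split sizes, per-epoch validation curves and test metrics;
`chemlm predict --checkpoint finetune_run/model --data new.csv --out scores.csv`
scores new molecules with the saved model.

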