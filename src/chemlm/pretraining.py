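"""Dual-objective self-supervised pre-training.

Two tasks are trained simultaneously on unlabeled SMILES: recovery of
corrupted tokens (masked-language-model objective) and regression of the QED
drug-likeness value read off the first encoder output. The loss is the
unweighted sum of the mean cross-entropy over corrupted positions and the
squared error on QED. Optimization is Adam under the inverse-square-root
warmup schedule

    lr(step) = base_factor * d_model^{-1/2} * min(step^{-1/2}, step * warmup^{-3/2})

which rises linearly to its peak at ``step == warmup_steps`` and decays as
step^{-1/2} afterwards.

Masking recipe: 15% of the real (non-special) token positions of each
sequence are selected — exactly round(0.15 n), at least one — and each
selected position independently becomes the MASK token with probability 0.8,
a uniformly random chemistry token with probability 0.1, or stays unchanged
with probability 0.1. All selected positions contribute recovery targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import mol_io
from .autograd import Tensor
from .model import ModelConfig, MolecularEncoder, prepare_batch
from .nn import Adam, mean_squared_error, softmax_cross_entropy
from .tokenizer import (EncodedInput, SequenceLengthError, Vocabulary,
                        build_vocab, encode, tokenize)

logger = logging.getLogger(__name__)

__all__ = [
    "MaskedExample", "LrScheduleConfig", "PretrainConfig", "PretrainResult",
    "apply_masking", "pretrain_loss", "lr_schedule", "run_pretraining",
    "evaluate_masked", "masking_rate", "encode_corpus",
]

MASK_FRACTION = 0.15
P_MASK, P_RANDOM, P_KEEP = 0.8, 0.1, 0.1


@dataclass(frozen=True)
class MaskedExample:
    corrupted_ids: np.ndarray       # (L,) ids after corruption
    target_ids: np.ndarray          # (m,) original ids at corrupted positions
    positions: np.ndarray           # (m,) corrupted position indices


def masking_rate(n_tokens: int) -> int:
    """Number of positions selected for an n-token sequence: round-half-up of
    15%, never fewer than one."""
    if n_tokens < 1:
        raise ValueError("sequence has no maskable tokens")
    return max(1, int(np.floor(MASK_FRACTION * n_tokens + 0.5)))


def apply_masking(enc: EncodedInput, vocab: Vocabulary,
                  rng: np.random.Generator) -> MaskedExample:
    """Corrupt a fixed 15% of the real token positions of one sequence.

    START, END and PAD are never selected. Raises if the sequence holds no
    real tokens.
    """
    n_real_tokens = enc.n_real - 2  # exclude START and END
    if n_real_tokens < 1:
        raise ValueError("cannot mask a sequence with zero non-special tokens")
    candidates = np.arange(1, enc.n_real - 1)
    m = masking_rate(n_real_tokens)
    positions = np.sort(rng.choice(candidates, size=m, replace=False))
    corrupted = enc.ids.copy()
    targets = enc.ids[positions].copy()
    chem_ids = vocab.chemistry_ids()
    u = rng.random(m)
    for i, p in enumerate(positions):
        if u[i] < P_MASK:
            corrupted[p] = vocab.mask_id
        elif u[i] < P_MASK + P_RANDOM:
            corrupted[p] = rng.choice(chem_ids)
        # else: unchanged, still a recovery target
    return MaskedExample(corrupted_ids=corrupted, target_ids=targets,
                         positions=positions)


def pretrain_loss(mlm_logits: Tensor, mlm_targets: np.ndarray,
                  qed_pred: Tensor, qed_true: np.ndarray) -> Tensor:
    """Sum of mean cross-entropy on corrupted positions and MSE on QED.

    ``mlm_logits``: (m, V) logits gathered at the corrupted positions of the
    batch; ``mlm_targets``: (m,) original ids; ``qed_pred``/``qed_true``: (B,).
    """
    if mlm_logits.shape[0] == 0:
        raise ValueError("no corrupted positions to recover")
    ce = softmax_cross_entropy(mlm_logits, mlm_targets)
    mse = mean_squared_error(qed_pred, qed_true)
    return ce + mse


@dataclass(frozen=True)
class LrScheduleConfig:
    d_model: int
    warmup_steps: int = 10_000
    base_factor: float = 0.1

    def __post_init__(self):
        if self.warmup_steps < 1:
            raise ValueError("warmup_steps must be >= 1")


def lr_schedule(step_num: int, cfg: LrScheduleConfig) -> float:
    """Warmup/decay learning rate; peak base_factor/(sqrt(d_model*warmup))."""
    if step_num < 1:
        raise ValueError("step_num must be >= 1")
    return (cfg.base_factor * cfg.d_model ** -0.5
            * min(step_num ** -0.5, step_num * cfg.warmup_steps ** -1.5))


# -- corpus preparation ------------------------------------------------------

@dataclass
class EncodedMolecule:
    smiles: str
    enc: EncodedInput
    adj: np.ndarray
    qed: float


def encode_corpus(corpus: list[str], vocab: Vocabulary,
                  cfg: ModelConfig) -> list[EncodedMolecule]:
    """Tokenize, encode and label a SMILES corpus; over-length or oversized
    molecules are skipped with a logged count (never truncated, which would
    corrupt ring-closure bookkeeping)."""
    out: list[EncodedMolecule] = []
    n_skipped = 0
    for smiles in corpus:
        try:
            mol = mol_io.parse_smiles(smiles)
            if mol.n_atoms > cfg.max_atoms:
                raise SequenceLengthError(f"{mol.n_atoms} atoms > {cfg.max_atoms}")
            enc = encode(tokenize(smiles), vocab, cfg.max_len)
            out.append(EncodedMolecule(
                smiles=smiles, enc=enc, adj=mol_io.adjacency(mol),
                qed=mol_io.qed_label(mol)))
        except (mol_io.ParseError, SequenceLengthError):
            n_skipped += 1
    if n_skipped:
        logger.warning("skipped %d molecules (unparseable or over-length)", n_skipped)
    return out


@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 10
    batch_size: int = 64
    seed: int = 0
    val_fraction: float = 0.1
    warmup_steps: int = 10_000
    base_factor: float = 0.1


@dataclass
class PretrainResult:
    model: MolecularEncoder
    vocab: Vocabulary
    history: list[dict] = field(default_factory=list)

    @property
    def best_epoch(self) -> dict:
        return min(self.history, key=lambda row: row["val_loss"])


def _batches(n: int, batch_size: int, order: np.ndarray):
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _forward_masked(model: MolecularEncoder, data: list[EncodedMolecule],
                    masked: list[MaskedExample], idx: np.ndarray):
    """Forward pass on corrupted ids; returns gathered logits, targets, QED."""
    encs = [data[i].enc for i in idx]
    adjs = [data[i].adj for i in idx]
    ids, a, scatter, pad_mask = prepare_batch(encs, adjs, model.cfg)
    l_eff = ids.shape[1]
    corrupted = np.stack([masked[i].corrupted_ids for i in idx])[:, :l_eff]
    outputs = model.forward(corrupted, a, scatter, pad_mask)
    logits = model.mlm_head(outputs)
    flat = logits.reshape(len(idx) * l_eff, model.vocab_size)
    rows, targets = [], []
    for b, i in enumerate(idx):
        rows.extend(b * l_eff + masked[i].positions)
        targets.extend(masked[i].target_ids)
    gathered = flat[np.asarray(rows, dtype=np.intp)]
    qed_pred = model.qed_head(outputs)
    qed_true = np.array([data[i].qed for i in idx])
    return gathered, np.asarray(targets, dtype=np.intp), qed_pred, qed_true


def evaluate_masked(model: MolecularEncoder, data: list[EncodedMolecule],
                    masked: list[MaskedExample],
                    batch_size: int = 64) -> dict:
    """Masked-token accuracy, QED MAE and validation loss on fixed corruptions."""
    n_correct = n_total = 0
    abs_err = 0.0
    loss_sum = 0.0
    n_batches = 0
    order = np.arange(len(data))
    for idx in _batches(len(data), batch_size, order):
        logits, targets, qed_pred, qed_true = _forward_masked(
            model, data, masked, idx)
        pred = logits.data.argmax(axis=-1)
        n_correct += int((pred == targets).sum())
        n_total += len(targets)
        abs_err += float(np.abs(qed_pred.data - qed_true).sum())
        loss_sum += float(pretrain_loss(logits, targets, qed_pred, qed_true).data)
        n_batches += 1
    return {
        "masked_accuracy": n_correct / n_total,
        "qed_mae": abs_err / len(data),
        "val_loss": loss_sum / n_batches,
    }


def run_pretraining(corpus: list[str], model_cfg: ModelConfig,
                    train_cfg: PretrainConfig) -> PretrainResult:
    """Pre-train an encoder on a SMILES corpus; fully reproducible per seed.

    A held-out fraction of the corpus is used for per-epoch validation with
    corruptions fixed once, so the metric series is comparable across epochs.
    The returned model carries the weights of the best-validation-loss epoch.
    """
    if not corpus:
        raise ValueError("empty pre-training corpus")
    vocab = build_vocab(corpus)
    data = encode_corpus(corpus, vocab, model_cfg)
    if not data:
        raise ValueError("no encodable molecules in corpus")

    rng = np.random.default_rng(train_cfg.seed)
    order = rng.permutation(len(data))
    if train_cfg.val_fraction > 0 and len(data) > 1:
        n_val = max(1, int(round(train_cfg.val_fraction * len(data))))
    else:
        n_val = 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = val_idx, train_idx

    train_data = [data[i] for i in train_idx]
    val_data = [data[i] for i in val_idx]
    val_rng = np.random.default_rng(train_cfg.seed + 1)
    val_masked = [apply_masking(d.enc, vocab, val_rng) for d in val_data]

    model = MolecularEncoder(model_cfg, len(vocab), seed=train_cfg.seed)
    opt = Adam(model.parameters())
    lr_cfg = LrScheduleConfig(d_model=model_cfg.d_model,
                              warmup_steps=train_cfg.warmup_steps,
                              base_factor=train_cfg.base_factor)

    history: list[dict] = []
    best_loss = np.inf
    best_state = model.state_dict()
    step = 0
    for epoch in range(1, train_cfg.epochs + 1):
        epoch_order = rng.permutation(len(train_data))
        masked = [apply_masking(d.enc, vocab, rng) for d in train_data]
        epoch_loss = 0.0
        n_batches = 0
        lr = 0.0
        for idx in _batches(len(train_data), train_cfg.batch_size, epoch_order):
            logits, targets, qed_pred, qed_true = _forward_masked(
                model, train_data, masked, idx)
            loss = pretrain_loss(logits, targets, qed_pred, qed_true)
            opt.zero_grad()
            loss.backward()
            step += 1
            lr = lr_schedule(step, lr_cfg)
            opt.step(lr)
            epoch_loss += float(loss.data)
            n_batches += 1
        row = {"epoch": epoch, "train_loss": epoch_loss / n_batches, "lr": lr}
        if val_data:
            row.update(evaluate_masked(model, val_data, val_masked,
                                       train_cfg.batch_size))
        else:
            row.update({"masked_accuracy": np.nan, "qed_mae": np.nan,
                        "val_loss": row["train_loss"]})
        history.append(row)
        logger.info("epoch %d: train_loss=%.4f val_loss=%.4f acc=%.3f mae=%.4f",
                    epoch, row["train_loss"], row["val_loss"],
                    row["masked_accuracy"], row["qed_mae"])
        if row["val_loss"] < best_loss:
            best_loss = row["val_loss"]
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return PretrainResult(model=model, vocab=vocab, history=history)
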