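"""Desk-scale study protocols: reproducible CPU-sized training experiments.

These procedures exercise the full pipeline at sizes a single CPU core
handles in minutes: a memorization run, a small-corpus pre-training with
held-out evaluation against untrained and constant-predictor baselines,
separable classification and noisy regression fine-tuning checks, and a
transfer comparison measuring how quickly a pre-trained encoder reaches the
best validation score of a model trained from scratch. Every function is
deterministic given its seed.
"""

from __future__ import annotations

import numpy as np

from . import synthetic
from .finetuning import FinetuneConfig, TaskSpec, run_finetuning
from .model import ModelConfig, MolecularEncoder, save_checkpoint
from .pretraining import (PretrainConfig, PretrainResult, apply_masking,
                          encode_corpus, evaluate_masked, run_pretraining)

__all__ = [
    "memorization_experiment", "pretrain_experiment",
    "classification_experiment", "regression_experiment",
    "transfer_experiment", "epochs_to_reach",
]

TINY = ModelConfig.tiny()


def memorization_experiment(seed: int, n_molecules: int = 10,
                            epochs: int = 500) -> dict:
    """Overfit a tiny encoder on a handful of molecules and report masked
    accuracy on those same molecules under fresh corruptions."""
    mols = synthetic.generate_molecules(
        synthetic.GeneratorConfig(n_molecules=n_molecules, seed=seed + 11))
    res = run_pretraining(mols, TINY, PretrainConfig(
        epochs=epochs, seed=seed, warmup_steps=100, val_fraction=0.0))
    data = encode_corpus(mols, res.vocab, TINY)
    rng = np.random.default_rng(seed + 1)
    masked = [apply_masking(d.enc, res.vocab, rng) for d in data]
    ev = evaluate_masked(res.model, data, masked)
    return {"masked_accuracy": ev["masked_accuracy"], "n_molecules": n_molecules}


def pretrain_experiment(seed: int, n_molecules: int = 2000,
                        epochs: int = 15, n_eval: int = 300) -> dict:
    """Pre-train on a synthetic corpus; evaluate masked accuracy and QED MAE
    on freshly generated held-out molecules against an untrained encoder and
    a constant-mean QED predictor."""
    corpus = synthetic.generate_molecules(
        synthetic.GeneratorConfig(n_molecules=n_molecules, seed=seed + 21))
    res = run_pretraining(corpus, TINY, PretrainConfig(
        epochs=epochs, seed=seed, warmup_steps=100))

    pool = synthetic.generate_molecules(
        synthetic.GeneratorConfig(n_molecules=n_eval + 200, seed=seed + 22))
    known = set(corpus)
    eval_smiles = [s for s in pool if s not in known][:n_eval]
    data = encode_corpus(eval_smiles, res.vocab, TINY)
    rng = np.random.default_rng(seed + 23)
    masked = [apply_masking(d.enc, res.vocab, rng) for d in data]

    trained = evaluate_masked(res.model, data, masked)
    untrained_model = MolecularEncoder(TINY, len(res.vocab), seed=seed + 24)
    untrained = evaluate_masked(untrained_model, data, masked)

    corpus_qed = np.array([d.qed for d in
                           encode_corpus(corpus, res.vocab, TINY)])
    eval_qed = np.array([d.qed for d in data])
    const_mae = float(np.abs(eval_qed - corpus_qed.mean()).mean())
    return {
        "result": res,
        "heldout_masked_accuracy": trained["masked_accuracy"],
        "untrained_masked_accuracy": untrained["masked_accuracy"],
        "accuracy_ratio": trained["masked_accuracy"]
        / max(untrained["masked_accuracy"], 1e-9),
        "heldout_qed_mae": trained["qed_mae"],
        "constant_mean_qed_mae": const_mae,
        "n_corpus": len(corpus),
        "n_eval": len(eval_smiles),
    }


def classification_experiment(seed: int, n_molecules: int = 200,
                              epochs: int = 8, n_seeds: int = 3) -> dict:
    """Separable task: predict ring presence, which the token sequence
    reveals through ring-closure digits. Random split — the label is a
    deterministic function of the scaffold, so scaffold splitting would
    leave single-class partitions."""
    df = synthetic.generate_classification_dataset(
        synthetic.GeneratorConfig(n_molecules=n_molecules, seed=seed + 31),
        "has_ring")
    spec = TaskSpec(task_type="classification", label_columns=("has_ring",))
    cfg = FinetuneConfig(epochs=epochs, lr=1e-3, n_seeds=n_seeds, seed=seed,
                         split="random")
    res = run_finetuning(df, spec, None, cfg)
    return {"test_roc_auc": res.metrics.mean,
            "per_seed": res.metrics.per_seed_test, "n": len(df)}


def regression_experiment(seed: int, checkpoint_path, n_molecules: int = 300,
                          noise_sd: float = 0.5, epochs: int = 25) -> dict:
    """Noisy heavy-atom-count regression from a pre-trained encoder; the
    injected noise floor bounds the achievable RMSE from below."""
    mols = synthetic.generate_molecules(
        synthetic.GeneratorConfig(n_molecules=n_molecules, seed=seed + 41))
    df = synthetic.make_regression_task(mols, noise_sd=noise_sd,
                                        seed=seed + 42)
    spec = TaskSpec(task_type="regression", label_columns=("target",))
    cfg = FinetuneConfig(epochs=epochs, lr=3e-4, n_seeds=1, seed=seed,
                         split="random")
    res = run_finetuning(df, spec, checkpoint_path, cfg)
    return {"test_rmse": res.metrics.mean, "noise_sd": noise_sd,
            "n": len(df)}


def epochs_to_reach(trace: list[float], target: float) -> int:
    """1-based first epoch at which a validation trace attains ``target``;
    one past the last epoch if it never does."""
    for i, v in enumerate(trace):
        if v >= target:
            return i + 1
    return len(trace) + 1


def transfer_experiment(seed: int, checkpoint_path, n_molecules: int = 300,
                        epochs: int = 15, lr: float = 5e-4,
                        n_seeds: int = 5) -> dict:
    """Convergence-speed comparison on a heteroatom-counting task.

    For each seed, the scratch model's best validation ROC-AUC defines the
    target; we record how many epochs the scratch model needed to first
    reach its own best versus how many the pre-trained model needed to reach
    that same value, and compare the medians over seeds. Heteroatom counting
    is used because it overlaps the chemistry the QED objective rewards
    (HBA/PSA desirabilities), so pre-training has signal to transfer.
    """
    df = synthetic.generate_classification_dataset(
        synthetic.GeneratorConfig(n_molecules=n_molecules, seed=seed + 51),
        "heteroatom_ge_3")
    spec = TaskSpec(task_type="classification",
                    label_columns=("heteroatom_ge_3",))
    cfg = FinetuneConfig(epochs=epochs, lr=lr, n_seeds=n_seeds, seed=seed,
                         split="random")
    scratch = run_finetuning(df, spec, None, cfg)
    pretrained = run_finetuning(df, spec, checkpoint_path, cfg)

    scratch_epochs, pretrained_epochs = [], []
    for s_trace, p_trace in zip(scratch.metrics.per_seed_val_traces,
                                pretrained.metrics.per_seed_val_traces):
        target = max(s_trace)
        scratch_epochs.append(epochs_to_reach(s_trace, target))
        pretrained_epochs.append(epochs_to_reach(p_trace, target))
    return {
        "scratch_epochs": scratch_epochs,
        "pretrained_epochs": pretrained_epochs,
        "median_scratch_epochs": float(np.median(scratch_epochs)),
        "median_pretrained_epochs": float(np.median(pretrained_epochs)),
        "n": len(df),
    }


def save_pretrained(result: PretrainResult, directory) -> str:
    """Write a checkpoint bundle for downstream experiments; returns path."""
    path = str(directory)
    save_checkpoint(path, result.model, result.vocab)
    return path
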