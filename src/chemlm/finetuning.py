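"""Downstream fine-tuning: splits, metrics, multi-task training, 5-seed runs.

Classification datasets are split by Bemis–Murcko scaffold (out-of-
distribution evaluation), regression datasets by seeded random shuffle, both
at 80:10:10. Multi-task datasets are learned jointly in one model with
missing labels excluded from the loss. Validation is tracked every epoch;
the weights of the best-validation epoch are restored for test evaluation
(early stopping by checkpoint selection), and the whole run is repeated over
several seeds to report mean ± std.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy.stats import rankdata

from . import mol_io
from .autograd import Tensor
from .model import (ModelConfig, MolecularEncoder, TaskHead, load_checkpoint,
                    prepare_batch)
from .nn import Adam, mean_squared_error, sigmoid_cross_entropy
from .pretraining import EncodedMolecule, encode_corpus
from .tokenizer import Vocabulary, build_vocab

logger = logging.getLogger(__name__)

__all__ = [
    "SplitResult", "TaskSpec", "FinetuneConfig", "TaskMetrics",
    "UndefinedMetricError", "murcko_scaffold", "scaffold_split",
    "random_split", "roc_auc", "rmse", "select_best_epoch",
    "run_finetuning", "FinetunedModel",
]


# -- splitting ---------------------------------------------------------------

@dataclass(frozen=True)
class SplitResult:
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray
    method: str
    seed: int | None = None

    def __post_init__(self):
        n = len(self.train) + len(self.valid) + len(self.test)
        combined = np.concatenate([self.train, self.valid, self.test])
        if len(np.unique(combined)) != n:
            raise ValueError("split partitions overlap or repeat indices")


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis–Murcko framework; acyclic molecules map to ''."""
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise mol_io.ParseError(f"invalid SMILES: {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=rd)


def scaffold_split(smiles_list: list[str],
                   ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
                   ) -> SplitResult:
    """Deterministic greedy scaffold split: group molecules by scaffold, sort
    groups by descending size (ties by scaffold string), fill train, then
    valid, then test. No scaffold ever spans two partitions."""
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(smiles_list):
        groups.setdefault(murcko_scaffold(s), []).append(i)
    if len(groups) < 3:
        raise ValueError(
            f"need at least 3 scaffold groups for a 3-way split, got {len(groups)}"
        )
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n = len(smiles_list)
    n_train = ratios[0] * n
    n_valid = ratios[1] * n
    train: list[int] = []
    valid: list[int] = []
    test: list[int] = []
    for _, idx in ordered:
        if len(train) < n_train:
            train.extend(idx)
        elif len(valid) < n_valid:
            valid.extend(idx)
        else:
            test.extend(idx)
    return SplitResult(np.array(train), np.array(valid), np.array(test),
                       method="scaffold")


def random_split(n: int, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                 seed: int = 0) -> SplitResult:
    """Seeded uniform shuffle with contiguous cuts at the ratio boundaries."""
    if n < 3:
        raise ValueError("need at least 3 molecules to split three ways")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    c1 = int(round(ratios[0] * n))
    c2 = int(round((ratios[0] + ratios[1]) * n))
    return SplitResult(perm[:c1], perm[c1:c2], perm[c2:],
                       method="random", seed=seed)


# -- metrics -----------------------------------------------------------------

class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. single-class ROC-AUC)."""


def roc_auc(scores, labels) -> float:
    """Probability that a random positive outranks a random negative, ties 1/2.

    Computed from the rank-sum (Mann–Whitney) statistic with average ranks,
    equivalent to trapezoidal integration of the ROC curve.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC-AUC undefined with a single class")
    ranks = rankdata(scores)
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def rmse(predictions, targets) -> float:
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if predictions.size == 0 or predictions.shape != targets.shape:
        raise ValueError("predictions and targets must be equal-length, non-empty")
    return float(np.sqrt(np.mean((predictions - targets) ** 2)))


def mean_roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average ROC-AUC over tasks; single-class tasks dropped with a warning."""
    values = []
    for t in range(labels.shape[1]):
        observed = ~np.isnan(labels[:, t])
        try:
            values.append(roc_auc(scores[observed, t], labels[observed, t]))
        except UndefinedMetricError:
            warnings.warn(f"task {t} has a single class; dropped from the average")
    if not values:
        raise UndefinedMetricError("no task had both classes present")
    return float(np.mean(values))


def select_best_epoch(trace: list[float], mode: str) -> int:
    """Index of the best validation value: max for 'max' (ROC-AUC),
    min for 'min' (RMSE). First occurrence wins on ties."""
    arr = np.asarray(trace, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty validation trace")
    return int(arr.argmax() if mode == "max" else arr.argmin())


# -- fine-tuning -------------------------------------------------------------

@dataclass(frozen=True)
class TaskSpec:
    task_type: str                      # "classification" | "regression"
    label_columns: tuple[str, ...]
    smiles_column: str = "smiles"

    def __post_init__(self):
        if self.task_type not in ("classification", "regression"):
            raise ValueError(f"unknown task_type {self.task_type!r}")
        if len(self.label_columns) < 1:
            raise ValueError("need at least one label column")

    @property
    def n_tasks(self) -> int:
        return len(self.label_columns)


@dataclass(frozen=True)
class FinetuneConfig:
    epochs: int | None = None           # default: 15 classification, 40 regression
    batch_size: int = 64
    lr: float = 5e-5
    n_seeds: int = 5
    seed: int = 0
    split: str | None = None            # default: scaffold cls, random reg
    model_config: ModelConfig | None = None  # used when training from scratch

    def resolved_epochs(self, task_type: str) -> int:
        if self.epochs is not None:
            return self.epochs
        return 15 if task_type == "classification" else 40

    def resolved_split(self, task_type: str) -> str:
        if self.split is not None:
            return self.split
        return "scaffold" if task_type == "classification" else "random"


@dataclass
class TaskMetrics:
    metric_name: str
    per_seed_test: list[float]
    per_seed_best_epoch: list[int]
    per_seed_val_traces: list[list[float]]

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_seed_test))

    @property
    def std(self) -> float:
        return float(np.std(self.per_seed_test))

    def summary(self) -> dict:
        return {"metric": self.metric_name, "mean": self.mean, "std": self.std,
                "per_seed": self.per_seed_test,
                "best_epochs": self.per_seed_best_epoch}


@dataclass
class FinetunedModel:
    encoder: MolecularEncoder
    head: TaskHead
    vocab: Vocabulary
    spec: TaskSpec
    target_mean: np.ndarray | None = None   # regression de-standardization
    target_std: np.ndarray | None = None

    def predict(self, smiles_list: list[str],
                batch_size: int = 64) -> pd.DataFrame:
        """Per-task scores (sigmoid probabilities) or de-standardized values."""
        data = encode_corpus(smiles_list, self.vocab, self.encoder.cfg)
        preds = _predict_encoded(self.encoder, self.head, data, batch_size)
        if self.spec.task_type == "classification":
            from scipy.special import expit
            preds = expit(preds)
        else:
            preds = preds * self.target_std + self.target_mean
        out = pd.DataFrame({self.spec.smiles_column: [d.smiles for d in data]})
        for t, col in enumerate(self.spec.label_columns):
            out[col] = preds[:, t]
        return out


    def save(self, path) -> None:
        """Persist the fine-tuned bundle: encoder checkpoint, head weights,
        task description and regression normalization."""
        from .model import save_checkpoint

        path = Path(path)
        save_checkpoint(path / "encoder", self.encoder, self.vocab)
        np.savez(path / "head.npz", **self.head.state_dict())
        task = asdict(self.spec)
        if self.target_mean is not None:
            task["target_mean"] = self.target_mean.tolist()
            task["target_std"] = self.target_std.tolist()
        import json
        (path / "task.json").write_text(json.dumps(task, indent=2))

    @classmethod
    def load(cls, path) -> "FinetunedModel":
        import json

        path = Path(path)
        encoder, vocab = load_checkpoint(path / "encoder")
        task = json.loads((path / "task.json").read_text())
        target_mean = task.pop("target_mean", None)
        target_std = task.pop("target_std", None)
        task["label_columns"] = tuple(task["label_columns"])
        spec = TaskSpec(**task)
        head = TaskHead(encoder.cfg.d_model, spec.n_tasks,
                        np.random.default_rng(0))
        with np.load(path / "head.npz") as npz:
            head.load_state_dict(dict(npz))
        return cls(encoder=encoder, head=head, vocab=vocab, spec=spec,
                   target_mean=None if target_mean is None
                   else np.asarray(target_mean),
                   target_std=None if target_std is None
                   else np.asarray(target_std))


def _predict_encoded(encoder: MolecularEncoder, head: TaskHead,
                     data: list[EncodedMolecule], batch_size: int) -> np.ndarray:
    rows = []
    for start in range(0, len(data), batch_size):
        chunk = data[start:start + batch_size]
        ids, a, scatter, mask = prepare_batch(
            [d.enc for d in chunk], [d.adj for d in chunk], encoder.cfg)
        outputs = encoder.forward(ids, a, scatter, mask)
        rows.append(head(outputs).data)
    return np.concatenate(rows, axis=0)


def _metric(spec: TaskSpec, preds: np.ndarray, labels: np.ndarray,
            target_mean, target_std) -> float:
    if spec.task_type == "classification":
        return mean_roc_auc(preds, labels)
    de_std = preds * target_std + target_mean
    true = labels * target_std + target_mean
    return rmse(de_std.ravel(), true.ravel())


def _train_one_seed(df: pd.DataFrame, spec: TaskSpec, cfg: FinetuneConfig,
                    split: SplitResult, checkpoint_path, run_seed: int):
    if checkpoint_path is not None:
        encoder, vocab = load_checkpoint(checkpoint_path)
    else:
        model_cfg = cfg.model_config or ModelConfig.tiny()
        vocab = build_vocab(df[spec.smiles_column].tolist())
        encoder = MolecularEncoder(model_cfg, len(vocab), seed=run_seed)

    smiles = df[spec.smiles_column].tolist()
    labels = df[list(spec.label_columns)].to_numpy(dtype=np.float64)
    data = encode_corpus(smiles, vocab, encoder.cfg)
    if len(data) != len(smiles):
        raise ValueError("dataset contains molecules the model cannot encode; "
                         "filter before splitting")

    rng = np.random.default_rng(run_seed)
    head = TaskHead(encoder.cfg.d_model, spec.n_tasks, rng)
    params = encoder.parameters() + head.parameters()
    opt = Adam(params, lr=cfg.lr)

    train_idx, valid_idx, test_idx = split.train, split.valid, split.test
    y = labels.copy()
    target_mean = target_std = None
    if spec.task_type == "regression":
        target_mean = np.nanmean(labels[train_idx], axis=0)
        target_std = np.nanstd(labels[train_idx], axis=0)
        target_std = np.where(target_std > 0, target_std, 1.0)
        y = (labels - target_mean) / target_std

    mode = "max" if spec.task_type == "classification" else "min"
    epochs = cfg.resolved_epochs(spec.task_type)
    val_trace: list[float] = []
    best_state = None
    for _epoch in range(epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            chunk = [data[i] for i in idx]
            ids, a, scatter, mask = prepare_batch(
                [d.enc for d in chunk], [d.adj for d in chunk], encoder.cfg)
            logits = head(encoder.forward(ids, a, scatter, mask))
            batch_y = y[idx]
            observed = (~np.isnan(batch_y)).astype(np.float64)
            if spec.task_type == "classification":
                loss = sigmoid_cross_entropy(logits, batch_y, weight=observed)
            else:
                diff = (logits - Tensor(np.nan_to_num(batch_y))) * Tensor(observed)
                loss = (diff ** 2.0).sum() * (1.0 / observed.sum())
            opt.zero_grad()
            loss.backward()
            opt.step()
        val_preds = _predict_encoded(
            encoder, head, [data[i] for i in valid_idx], cfg.batch_size)
        val_metric = _metric(spec, val_preds, y[valid_idx],
                             target_mean, target_std)
        val_trace.append(val_metric)
        if select_best_epoch(val_trace, mode) == len(val_trace) - 1:
            best_state = {"enc": encoder.state_dict(), "head": head.state_dict()}
    best_epoch = select_best_epoch(val_trace, mode)
    encoder.load_state_dict(best_state["enc"])
    head.load_state_dict(best_state["head"])
    test_preds = _predict_encoded(
        encoder, head, [data[i] for i in test_idx], cfg.batch_size)
    test_metric = _metric(spec, test_preds, y[test_idx], target_mean, target_std)
    model = FinetunedModel(encoder=encoder, head=head, vocab=vocab, spec=spec,
                           target_mean=target_mean, target_std=target_std)
    return test_metric, best_epoch, val_trace, model


def _filter_encodable(df: pd.DataFrame, spec: TaskSpec,
                      model_cfg: ModelConfig) -> pd.DataFrame:
    """Drop rows whose SMILES cannot be parsed or do not fit the model's
    length/atom capacity, with a logged count."""
    from .tokenizer import tokenize

    keep = []
    for s in df[spec.smiles_column]:
        try:
            mol = mol_io.parse_smiles(str(s))
            ok = (mol.n_atoms <= model_cfg.max_atoms
                  and len(tokenize(str(s)).tokens) + 2 <= model_cfg.max_len)
        except (mol_io.ParseError, ValueError):
            ok = False
        keep.append(ok)
    keep = np.array(keep)
    if not keep.all():
        logger.warning("dropped %d rows that cannot be encoded", (~keep).sum())
    return df.loc[keep].reset_index(drop=True)


@dataclass
class FinetuneResult:
    metrics: TaskMetrics
    model: FinetunedModel          # model of the best-validation seed
    split: SplitResult


def run_finetuning(df: pd.DataFrame, spec: TaskSpec,
                   checkpoint_path=None,
                   cfg: FinetuneConfig = FinetuneConfig()) -> FinetuneResult:
    """Train and evaluate a downstream task over ``cfg.n_seeds`` runs.

    The split is computed once (scaffold splits are deterministic; random
    splits use ``cfg.seed``); seed-to-seed variation comes from weight
    initialization, batch order and, for scratch models, the vocabulary RNG.
    """
    if checkpoint_path is not None:
        probe_cfg = load_checkpoint(checkpoint_path)[0].cfg
    else:
        probe_cfg = cfg.model_config or ModelConfig.tiny()
    df = _filter_encodable(df, spec, probe_cfg)

    method = cfg.resolved_split(spec.task_type)
    smiles = df[spec.smiles_column].tolist()
    if method == "scaffold":
        split = scaffold_split(smiles)
    elif method == "random":
        split = random_split(len(smiles), seed=cfg.seed)
    else:
        raise ValueError(f"unknown split method {method!r}")

    mode = "max" if spec.task_type == "classification" else "min"
    tests, best_epochs, traces, models, best_vals = [], [], [], [], []
    for k in range(cfg.n_seeds):
        run_seed = cfg.seed + 1000 * k
        test_metric, best_epoch, trace, model = _train_one_seed(
            df, spec, cfg, split, checkpoint_path, run_seed)
        logger.info("seed %d: best_epoch=%d test=%.4f", run_seed,
                    best_epoch, test_metric)
        tests.append(test_metric)
        best_epochs.append(best_epoch)
        traces.append(trace)
        models.append(model)
        best_vals.append(trace[best_epoch])
    metric_name = "roc_auc" if spec.task_type == "classification" else "rmse"
    metrics = TaskMetrics(metric_name=metric_name, per_seed_test=tests,
                          per_seed_best_epoch=best_epochs,
                          per_seed_val_traces=traces)
    best_seed = int(np.argmax(best_vals) if mode == "max"
                    else np.argmin(best_vals))
    return FinetuneResult(metrics=metrics, model=models[best_seed], split=split)
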