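"""Merged-embedding Transformer encoder for SMILES.

The input representation of a molecule is the sum of three embeddings:
token embeddings, learned absolute position embeddings, and a matrix
embedding E(A) = (A W_a) W_e + b computed from the heavy-atom adjacency
matrix A. The matrix embedding contributes one vector per atom and is added
only at atomic token positions; special tokens, bonds, ring digits and
parentheses receive token + position embeddings alone.

The encoder stack is a standard post-norm Transformer: multi-head scaled
dot-product self-attention plus a GELU feed-forward network, with residual
connections and layer normalization, and PAD key positions masked out of
every attention row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .nn import Embedding, LayerNorm, Linear, Module, init_normal
from .tokenizer import EncodedInput, Vocabulary

__all__ = [
    "ModelConfig", "MatrixEmbedding", "EncoderLayer", "MolecularEncoder",
    "scaled_dot_attention", "pad_adjacency", "atom_scatter_matrix",
    "prepare_batch", "save_checkpoint", "load_checkpoint",
]

CHECKPOINT_FORMAT = "chemlm-checkpoint-v1"


@dataclass(frozen=True)
class ModelConfig:
    """Encoder hyperparameters.

    Defaults are the full-scale configuration (8 layers, 16 heads, 1024-d
    hidden units, GELU activation, no dropout, 256-token inputs); ``tiny()``
    gives a CPU-scale profile used for tests and desk-scale experiments.
    """

    n_layers: int = 8
    n_heads: int = 16
    d_model: int = 1024
    d_feedforward: int = 4096
    max_len: int = 256
    max_atoms: int = 128
    dropout: float = 0.0
    activation: str = "gelu"

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.dropout != 0.0:
            raise ValueError("dropout is fixed at 0 for this model")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        base = cls(n_layers=2, n_heads=4, d_model=64, d_feedforward=128,
                   max_len=64, max_atoms=32)
        return replace(base, **overrides) if overrides else base


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         key_mask: np.ndarray | None = None) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V with PAD keys excluded.

    ``q, k, v``: (..., L, d_k). ``key_mask``: boolean, True at real key
    positions, broadcastable to the (..., L_q, L_k) score shape.
    """
    d_k = q.shape[-1]
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) \
        * (1.0 / np.sqrt(d_k))
    if key_mask is not None:
        bias = np.where(key_mask, 0.0, -1e9)
        scores = scores + Tensor(bias)
    return scores.softmax(axis=-1) @ v


class MatrixEmbedding(Module):
    """Affine map from the padded adjacency matrix to per-atom vectors.

    E(A) = (A W_a) W_e + b with W_a of shape (max_atoms, d_model) and W_e of
    shape (d_model, d_model), yielding one d_model vector per atom row.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.w_a = init_normal(rng, cfg.max_atoms, cfg.d_model)
        self.w_e = init_normal(rng, cfg.d_model, cfg.d_model)
        self.bias = Tensor(np.zeros(cfg.d_model), requires_grad=True)
        self.max_atoms = cfg.max_atoms

    def __call__(self, a_padded: np.ndarray) -> Tensor:
        a = np.asarray(a_padded, dtype=np.float64)
        m = a.shape[-1]
        if a.shape[-2] != m or m > self.max_atoms:
            raise ValueError(
                f"adjacency must be square and padded to at most "
                f"{self.max_atoms}x{self.max_atoms}, got {a.shape}"
            )
        # batches may be cropped below max_atoms; the unused W_a rows would
        # only ever meet zero-padding, so slicing them off is exact
        w_a = self.w_a if m == self.max_atoms else self.w_a[:m]
        return (Tensor(a) @ w_a) @ self.w_e + self.bias


class EncoderLayer(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.d_model
        self.n_heads = cfg.n_heads
        self.d_k = cfg.d_k
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.norm1 = LayerNorm(d)
        self.ff1 = Linear(d, cfg.d_feedforward, rng)
        self.ff2 = Linear(cfg.d_feedforward, d, rng)
        self.norm2 = LayerNorm(d)

    def _split_heads(self, x: Tensor, batch: int, length: int) -> Tensor:
        return x.reshape(batch, length, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def __call__(self, h: Tensor, pad_mask: np.ndarray) -> Tensor:
        batch, length, d = h.shape
        q = self._split_heads(self.wq(h), batch, length)
        k = self._split_heads(self.wk(h), batch, length)
        v = self._split_heads(self.wv(h), batch, length)
        key_mask = pad_mask[:, None, None, :]  # (B, 1, 1, L_k)
        attended = scaled_dot_attention(q, k, v, key_mask)
        merged = attended.transpose(0, 2, 1, 3).reshape(batch, length, d)
        h = self.norm1(h + self.wo(merged))
        ff = self.ff2(self.ff1(h).gelu())
        return self.norm2(h + ff)


class MolecularEncoder(Module):
    """Token + position + selective matrix embedding, followed by the encoder
    stack, with masked-token and QED heads on top."""

    def __init__(self, cfg: ModelConfig, vocab_size: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.vocab_size = vocab_size
        self.tok_emb = Embedding(vocab_size, cfg.d_model, rng)
        self.pos_emb = Embedding(cfg.max_len, cfg.d_model, rng)
        self.matrix_emb = MatrixEmbedding(cfg, rng)
        self.layers = [EncoderLayer(cfg, rng) for _ in range(cfg.n_layers)]
        self.mlm_proj = Linear(cfg.d_model, vocab_size, rng)
        self.qed_proj = Linear(cfg.d_model, 1, rng)

    # -- embedding ----------------------------------------------------------
    def embed(self, ids: np.ndarray, a_padded: np.ndarray,
              scatter: np.ndarray) -> Tensor:
        """Sum token, position, and (selectively) matrix embeddings.

        ``scatter`` is the constant (B, L, max_atoms) selection matrix with
        scatter[b, p, k] = 1 iff position p holds the k-th atomic token of
        molecule b; multiplying it into E(A) places each atom vector at its
        token position and nothing anywhere else.
        """
        batch, length = ids.shape
        h = self.tok_emb(ids) + self.pos_emb.weight[np.arange(length)]
        matrix_vectors = self.matrix_emb(a_padded)
        return h + Tensor(scatter) @ matrix_vectors

    # -- encoder ------------------------------------------------------------
    def encoder_forward(self, hidden: Tensor, pad_mask: np.ndarray) -> Tensor:
        for layer in self.layers:
            hidden = layer(hidden, pad_mask)
        return hidden

    def forward(self, ids: np.ndarray, a_padded: np.ndarray,
                scatter: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        return self.encoder_forward(self.embed(ids, a_padded, scatter), pad_mask)

    # -- heads --------------------------------------------------------------
    def mlm_head(self, outputs: Tensor) -> Tensor:
        """Per-position vocabulary logits for masked-token recovery."""
        return self.mlm_proj(outputs)

    def qed_head(self, outputs: Tensor) -> Tensor:
        """Scalar drug-likeness prediction from the first (START) output,
        squashed to (0, 1) by a sigmoid."""
        first = outputs[:, 0, :]
        return self.qed_proj(first).sigmoid().reshape(outputs.shape[0])


class TaskHead(Module):
    """Per-task affine map of the first encoder output (fine-tuning head)."""

    def __init__(self, d_model: int, n_tasks: int, rng: np.random.Generator):
        if n_tasks < 1:
            raise ValueError("n_tasks must be >= 1")
        self.proj = Linear(d_model, n_tasks, rng)
        self.n_tasks = n_tasks

    def __call__(self, outputs: Tensor) -> Tensor:
        return self.proj(outputs[:, 0, :])


# -- batching helpers --------------------------------------------------------

def pad_adjacency(a: np.ndarray, max_atoms: int) -> np.ndarray:
    n = a.shape[0]
    if n > max_atoms:
        raise ValueError(f"molecule with {n} atoms exceeds max_atoms={max_atoms}")
    out = np.zeros((max_atoms, max_atoms), dtype=np.float64)
    out[:n, :n] = a
    return out


def atom_scatter_matrix(enc: EncodedInput, n_atoms: int,
                        max_len: int, max_atoms: int) -> np.ndarray:
    """(L, max_atoms) one-hot placement of atom k at its token position."""
    if len(enc.atom_positions) != n_atoms:
        raise ValueError(
            f"token/graph misalignment: {len(enc.atom_positions)} atomic tokens "
            f"vs {n_atoms} atoms"
        )
    s = np.zeros((max_len, max_atoms), dtype=np.float64)
    for k, p in enumerate(enc.atom_positions):
        s[p, k] = 1.0
    return s


def prepare_batch(encoded: list[EncodedInput], adjacencies: list[np.ndarray],
                  cfg: ModelConfig, crop: bool = True):
    """Stack encoded molecules into (ids, A_padded, scatter, pad_mask) arrays.

    With ``crop`` (default) the batch is trimmed to the longest real sequence
    and largest molecule it contains; the removed regions are all PAD / zero
    padding, so results are identical and attention cost drops quadratically.
    """
    ids = np.stack([e.ids for e in encoded])
    a = np.stack([pad_adjacency(adj, cfg.max_atoms) for adj in adjacencies])
    scatter = np.stack([
        atom_scatter_matrix(e, adj.shape[0], cfg.max_len, cfg.max_atoms)
        for e, adj in zip(encoded, adjacencies)
    ])
    pad_mask = np.stack([e.padding_mask for e in encoded])
    if crop:
        l_eff = max(e.n_real for e in encoded)
        m_eff = max(1, max(adj.shape[0] for adj in adjacencies))
        ids = ids[:, :l_eff]
        a = a[:, :m_eff, :m_eff]
        scatter = scatter[:, :l_eff, :m_eff]
        pad_mask = pad_mask[:, :l_eff]
    return ids, a, scatter, pad_mask


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(path, model: MolecularEncoder, vocab: Vocabulary) -> None:
    """Write a checkpoint bundle: config JSON, vocabulary JSON, weight arrays."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {"format": CHECKPOINT_FORMAT,
            "config": asdict(model.cfg),
            "vocab_size": model.vocab_size}
    (path / "config.json").write_text(json.dumps(meta, indent=2))
    vocab.to_json(path / "vocab.json")
    np.savez(path / "weights.npz", **model.state_dict())


def load_checkpoint(path) -> tuple[MolecularEncoder, Vocabulary]:
    path = Path(path)
    meta = json.loads((path / "config.json").read_text())
    if meta.get("format") != CHECKPOINT_FORMAT:
        raise ValueError(f"unrecognized checkpoint format in {path}")
    cfg = ModelConfig(**meta["config"])
    vocab = Vocabulary.from_json(path / "vocab.json")
    if len(vocab) != meta["vocab_size"]:
        raise ValueError("checkpoint vocabulary size mismatch")
    model = MolecularEncoder(cfg, meta["vocab_size"])
    with np.load(path / "weights.npz") as npz:
        model.load_state_dict(dict(npz))
    return model, vocab
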