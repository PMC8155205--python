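"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module", "Linear", "Embedding", "LayerNorm", "Adam", "init_normal",
    "softmax_cross_entropy", "sigmoid_cross_entropy", "mean_squared_error",
]


def init_normal(rng: np.random.Generator, *shape, std: float = 0.02) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Module:
    """Base class: recursively collects parameters from attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _params_of(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        _collect_state(self, "", out)
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        mine = {}
        _collect_tensors(self, "", mine)
        missing = set(mine) - set(state)
        extra = set(state) - set(mine)
        if missing or extra:
            raise ValueError(
                f"state mismatch: missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        for name, tensor in mine.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != tensor.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {tensor.data.shape}"
                )
            tensor.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _params_of(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _params_of(v)


def _named_children(obj):
    for name, value in vars(obj).items():
        if isinstance(value, (Tensor, Module)):
            yield name, value
        elif isinstance(value, (list, tuple)):
            for i, v in enumerate(value):
                if isinstance(v, (Tensor, Module)):
                    yield f"{name}.{i}", v


def _collect_state(obj, prefix, out):
    for name, value in _named_children(obj):
        key = f"{prefix}{name}"
        if isinstance(value, Tensor):
            if value.requires_grad:
                out[key] = value.data.copy()
        else:
            _collect_state(value, key + ".", out)


def _collect_tensors(obj, prefix, out):
    for name, value in _named_children(obj):
        key = f"{prefix}{name}"
        if isinstance(value, Tensor):
            if value.requires_grad:
                out[key] = value
        else:
            _collect_tensors(value, key + ".", out)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, std: float = 0.02):
        self.weight = init_normal(rng, d_in, d_out, std=std)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_embeddings: int, d_model: int, rng: np.random.Generator, std: float = 0.02):
        self.weight = init_normal(rng, n_embeddings, d_model, std=std)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, d_model: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d_model), requires_grad=True)
        self.beta = Tensor(np.zeros(d_model), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2.0).mean(axis=-1, keepdims=True)
        norm = centered * (var + self.eps) ** -0.5
        return norm * self.gamma + self.beta


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer targets under row-wise softmax.

    ``logits``: (N, V) Tensor; ``targets``: (N,) integer array.
    """
    targets = np.asarray(targets, dtype=np.intp)
    n, v = logits.shape
    shift = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    log_z = shift.exp().sum(axis=-1).log()
    onehot = np.zeros((n, v))
    onehot[np.arange(n), targets] = 1.0
    picked = (shift * Tensor(onehot)).sum(axis=-1)
    return (log_z - picked).mean()


def sigmoid_cross_entropy(logits: Tensor, targets: np.ndarray,
                          weight: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy with logits; `weight` zeroes out missing labels.

    Uses the stable form max(x,0) - x*t + log(1 + exp(-|x|)).
    """
    t = Tensor(np.nan_to_num(np.asarray(targets, dtype=np.float64)))
    x = logits
    relu_x = (x + Tensor(np.abs(x.data))) * 0.5          # max(x, 0)
    softplus = ((Tensor(-np.abs(x.data))).exp() + 1.0).log()
    loss = relu_x - x * t + softplus
    if weight is not None:
        w = np.asarray(weight, dtype=np.float64)
        total = w.sum()
        if total <= 0:
            raise ValueError("no observed labels in batch")
        return (loss * Tensor(w)).sum() * (1.0 / total)
    return loss.mean()


def mean_squared_error(pred: Tensor, targets: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(targets, dtype=np.float64))
    return (diff ** 2.0).mean()


class Adam:
    """Adam optimizer with an optional externally supplied per-step learning rate."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = m / (1.0 - b1 ** self.t)
            v_hat = v / (1.0 - b2 ** self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
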