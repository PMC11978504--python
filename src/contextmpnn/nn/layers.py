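"""Layer primitives: linear, layer norm, dropout, embedding, feed-forward.

A tiny ``Module`` system tracks named parameters for counting, checkpointing
and optimization. Initialization is Xavier-uniform for weight matrices, zeros
for biases and ones/zeros for normalization affine parameters, drawn from a
seeded generator so model construction is reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = False

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def _apply_mode(self, training: bool):
        self.training = training
        for value in vars(self).values():
            if isinstance(value, Module):
                value._apply_mode(training)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._apply_mode(training)

    def train(self):
        self._apply_mode(True)
        return self

    def eval(self):
        self._apply_mode(False)
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(unexpected)}")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.astype(np.float64).copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Tensor(rng.uniform(-bound, bound, (out_features, in_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def __call__(self, x):
        return T.linear(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x):
        return T.layer_norm(x, self.gamma, self.beta, self.eps)


class Dropout(Module):
    """Inverted dropout: active only in training mode, identity in eval."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x):
        if not self.training or self.p <= 0.0:
            return x
        x = T.as_tensor(x)
        mask = (self.rng.random(x.shape) >= self.p).astype(np.float64)
        return x * (mask / (1.0 - self.p))


class Embedding(Module):
    def __init__(self, num_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (num_tokens + dim))
        self.weight = Tensor(rng.uniform(-bound, bound, (num_tokens, dim)),
                             requires_grad=True)

    def __call__(self, tokens: np.ndarray):
        return T.gather_rows(self.weight, np.asarray(tokens, dtype=np.int64))


class PositionWiseFeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.w_in = Linear(dim, hidden, rng)
        self.w_out = Linear(hidden, dim, rng)

    def __call__(self, x):
        return self.w_out(T.gelu(self.w_in(x)))


class Adam:
    """Adam with bias correction; state round-trips through ``state_dict``."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.98), eps: float = 1e-9):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.step_count = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.step_count += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.step_count
        bc2 = 1.0 - b2 ** self.step_count
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        return {
            "step_count": self.step_count,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict):
        self.step_count = int(state["step_count"])
        self.m = [np.asarray(m, dtype=np.float64).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64).copy() for v in state["v"]]


def save_checkpoint(path, model: Module, config: dict,
                    optimizer: Adam | None = None, extra: dict | None = None):
    """Write weights as an .npz archive plus a JSON manifest next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        opt = optimizer.state_dict()
        arrays["opt/step_count"] = np.array(opt["step_count"])
        for i, m in enumerate(opt["m"]):
            arrays[f"opt/m/{i}"] = m
        for i, v in enumerate(opt["v"]):
            arrays[f"opt/v/{i}"] = v
    np.savez(path, **arrays)
    manifest = {"format_version": 1, "config": config, "extra": extra or {}}
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path, model: Module, optimizer: Adam | None = None) -> dict:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        params = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
        model.load_state_dict(params)
        if optimizer is not None and "opt/step_count" in data.files:
            n = len(optimizer.params)
            optimizer.load_state_dict({
                "step_count": data["opt/step_count"][()],
                "m": [data[f"opt/m/{i}"] for i in range(n)],
                "v": [data[f"opt/v/{i}"] for i in range(n)],
            })
    manifest_path = Path(str(path) + ".json")
    if manifest_path.exists():
        return json.loads(manifest_path.read_text())
    return {}
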