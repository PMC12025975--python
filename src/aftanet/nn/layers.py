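"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, Parameter, gelu, layer_norm, softmax

__all__ = ["Module", "Linear", "LayerNorm", "MLP", "MultiHeadAttention",
           "Dropout"]


class Module:
    """Minimal container with recursive named-parameter collection."""

    def parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                out[name] = val
            elif isinstance(val, Module):
                for k, v in val.parameters().items():
                    out[f"{name}.{k}"] = v
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for k, v in item.parameters().items():
                            out[f"{name}.{i}.{k}"] = v
                    elif isinstance(item, Parameter):
                        out[f"{name}.{i}"] = item
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"parameter tree mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.array(state[k], dtype=np.float64)

    def state(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}


def _init_weight(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    # truncated-normal-free Xavier; adequate at these depths
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = Parameter(_init_weight(rng, d_in, d_out))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, eps=self.eps)


class Dropout(Module):
    """Inverted dropout; a no-op unless `training` and rate > 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, training: bool,
                 rng: np.random.Generator | None = None) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(np.float64) / keep
        return x * mask


class MLP(Module):
    """Two-layer feed-forward block with GELU, the Transformer FFN."""

    def __init__(self, d_model: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, hidden, rng)
        self.fc2 = Linear(hidden, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class MultiHeadAttention(Module):
    """Scaled dot-product self-attention with an optional per-token value gate.

    The gate `g` (length n_tokens, mean approximately 1) rescales the value
    vectors before aggregation: A · diag(g) · V.  With g = 1 this is exactly
    standard multi-head attention.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError(
                f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.w_q = Linear(d_model, d_model, rng)
        self.w_k = Linear(d_model, d_model, rng)
        self.w_v = Linear(d_model, d_model, rng)
        self.w_o = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, n: int) -> Tensor:
        # (..., n, d_model) -> (..., heads, n, d_k)
        lead = x.shape[:-2]
        x = x.reshape(*lead, n, self.n_heads, self.d_k)
        axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
        return x.transpose(axes)

    def __call__(self, x: Tensor, gate: Tensor | None = None,
                 context: Tensor | None = None) -> Tensor:
        """Self-attention over `x`, or cross-attention of `x` onto `context`.

        The gate applies to tokens of the attended-to sequence.
        """
        src = x if context is None else context
        n_q = x.shape[-2]
        n_kv = src.shape[-2]
        q = self._split(self.w_q(x), n_q)
        k = self._split(self.w_k(src), n_kv)
        v = self._split(self.w_v(src), n_kv)
        if gate is not None:
            v = v * gate.reshape(*gate.shape[:-1], 1, gate.shape[-1], 1)
        scores = q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)
        a = softmax(scores * (1.0 / np.sqrt(self.d_k)), axis=-1)
        out = a @ v
        lead = out.shape[:-3]
        axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
        out = out.transpose(axes).reshape(*lead, n_q, self.d_model)
        return self.w_o(out)
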