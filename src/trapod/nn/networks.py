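"""Network architectures for the perioperative model zoo.

All networks map a batch of inputs to one pre-sigmoid logit per surgery.
Sequence inputs are arrays of shape (m, n, k): surgeries x time steps x
channels.  Tabular inputs are (m, d).  Hidden MLP layers use the logistic
sigmoid activation throughout.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, softmax

__all__ = [
    "Adam",
    "HybridNet",
    "LSTMNet",
    "MLPNet",
    "TransformerNet",
]


class Module:
    """Base class: named parameters, checkpointing, counting."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def add_param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array)
        self._params[name] = t
        return t

    def add_child(self, name: str, child: "Module") -> "Module":
        self._children[name] = child
        return child

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.named_parameters(prefix + name + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        if set(state) != set(params):
            missing = set(params) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for k, v in state.items():
            params[k].data = np.array(v, dtype=np.float64)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def describe(self) -> dict[str, int]:
        """Parameter counts per top-level component."""
        counts: dict[str, int] = {}
        for name, p in self.named_parameters().items():
            top = name.split(".")[0]
            counts[top] = counts.get(top, 0) + p.data.size
        counts["total"] = sum(counts.values())
        return counts


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int):
        super().__init__()
        self.W = self.add_param("W", _glorot(rng, d_in, d_out, (d_in, d_out)))
        self.b = self.add_param("b", np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLPNet(Module):
    """Fully connected net, sigmoid hidden activations, scalar logit output."""

    def __init__(self, rng, d_in: int, hidden: list[int]):
        super().__init__()
        self.layers: list[Linear] = []
        prev = d_in
        for i, h in enumerate(hidden):
            self.layers.append(self.add_child(f"hidden{i}", Linear(rng, prev, h)))
            prev = h
        self.out = self.add_child("out", Linear(rng, prev, 1))

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x).sigmoid()
        return self.out(x).reshape(-1)


class LSTMLayer(Module):
    """One LSTM layer unrolled over time (gate order: input, forget, cell, output)."""

    def __init__(self, rng, d_in: int, d_hidden: int):
        super().__init__()
        self.h = d_hidden
        self.Wx = self.add_param("Wx", _glorot(rng, d_in, 4 * d_hidden, (d_in, 4 * d_hidden)))
        self.Wh = self.add_param("Wh", _glorot(rng, d_hidden, 4 * d_hidden, (d_hidden, 4 * d_hidden)))
        b = np.zeros(4 * d_hidden)
        b[d_hidden : 2 * d_hidden] = 1.0  # forget-gate bias
        self.b = self.add_param("b", b)

    def __call__(self, steps: list[Tensor]) -> list[Tensor]:
        m = steps[0].shape[0]
        h = Tensor(np.zeros((m, self.h)), requires_grad=False)
        c = Tensor(np.zeros((m, self.h)), requires_grad=False)
        hs: list[Tensor] = []
        for x in steps:
            z = x @ self.Wx + h @ self.Wh + self.b
            i = z[:, 0 : self.h].sigmoid()
            f = z[:, self.h : 2 * self.h].sigmoid()
            g = z[:, 2 * self.h : 3 * self.h].tanh()
            o = z[:, 3 * self.h : 4 * self.h].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h)
        return hs


class LSTMNet(Module):
    """Stacked LSTM; the last hidden state feeds a sigmoid-MLP head."""

    def __init__(self, rng, d_in: int, d_hidden: int, n_layers: int, head: list[int]):
        super().__init__()
        self.cells: list[LSTMLayer] = []
        prev = d_in
        for i in range(n_layers):
            self.cells.append(self.add_child(f"lstm{i}", LSTMLayer(rng, prev, d_hidden)))
            prev = d_hidden
        self.head = self.add_child("head", MLPNet(rng, d_hidden, head))

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[1]
        steps = [x[:, t, :] for t in range(n)]
        for cell in self.cells:
            steps = cell(steps)
        return self.head(steps[-1])


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = self.add_param("gamma", np.ones(d))
        self.beta = self.add_param("beta", np.zeros(d))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class EncoderLayer(Module):
    """Post-norm transformer encoder block with self-attention and feed-forward."""

    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.dk = d_model // n_heads
        self.Wq = self.add_child("Wq", Linear(rng, d_model, d_model))
        self.Wk = self.add_child("Wk", Linear(rng, d_model, d_model))
        self.Wv = self.add_child("Wv", Linear(rng, d_model, d_model))
        self.Wo = self.add_child("Wo", Linear(rng, d_model, d_model))
        self.ff1 = self.add_child("ff1", Linear(rng, d_model, d_ff))
        self.ff2 = self.add_child("ff2", Linear(rng, d_ff, d_model))
        self.ln1 = self.add_child("ln1", LayerNorm(d_model))
        self.ln2 = self.add_child("ln2", LayerNorm(d_model))
        self.last_attention: np.ndarray | None = None  # (m, heads, n, n)

    def _split(self, x: Tensor, m: int, n: int) -> Tensor:
        return x.reshape(m, n, self.h, self.dk).swapaxes(1, 2)

    def __call__(self, x: Tensor) -> Tensor:
        m, n, d = x.shape
        q = self._split(self.Wq(x), m, n)
        k = self._split(self.Wk(x), m, n)
        v = self._split(self.Wv(x), m, n)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dk))
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data.copy()
        ctx = (attn @ v).swapaxes(1, 2).reshape(m, n, d)
        x = self.ln1(x + self.Wo(ctx))
        ff = self.ff2(self.ff1(x).sigmoid())
        return self.ln2(x + ff)


def sinusoidal_encoding(n_steps: int, d_model: int) -> np.ndarray:
    pos = np.arange(n_steps)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


class TransformerNet(Module):
    """Encoder-only transformer: linear projection of each time step into a
    learnable d-dimensional space, positional encoding, a stack of
    self-attention encoder blocks, time pooling, and a sigmoid-MLP head."""

    def __init__(
        self,
        rng,
        d_in: int,
        n_steps: int,
        d_model: int = 32,
        n_heads: int = 1,
        n_layers: int = 1,
        d_ff: int | None = None,
        head: list[int] | None = None,
        positional: str = "sinusoidal",
        pool: str = "mean",
    ):
        super().__init__()
        if pool not in ("mean", "flatten"):
            raise ValueError(f"unknown pooling {pool!r}")
        self.pool = pool
        self.n_steps = n_steps
        self.proj = self.add_child("proj", Linear(rng, d_in, d_model))
        if positional == "sinusoidal":
            self.pos = Tensor(sinusoidal_encoding(n_steps, d_model), requires_grad=False)
        elif positional == "learnable":
            self.pos = self.add_param("pos", 0.01 * rng.standard_normal((n_steps, d_model)))
        else:
            raise ValueError(f"unknown positional encoding {positional!r}")
        d_ff = d_ff or 2 * d_model
        self.blocks: list[EncoderLayer] = []
        for i in range(n_layers):
            self.blocks.append(
                self.add_child(f"enc{i}", EncoderLayer(rng, d_model, n_heads, d_ff))
            )
        head_in = d_model if pool == "mean" else d_model * n_steps
        self.head = self.add_child("head", MLPNet(rng, head_in, head or [8]))

    def __call__(self, x: Tensor) -> Tensor:
        m, n, _ = x.shape
        if n != self.n_steps:
            raise ValueError(f"expected {self.n_steps} time steps, got {n}")
        z = self.proj(x) + self.pos
        for block in self.blocks:
            z = block(z)
        pooled = z.mean(axis=1) if self.pool == "mean" else z.reshape(m, -1)
        return self.head(pooled)

    def attention_weights(self) -> np.ndarray:
        """Attention of the last encoder block from the latest forward pass,
        averaged over heads: (m, n, n)."""
        a = self.blocks[-1].last_attention
        if a is None:
            raise RuntimeError("run a forward pass before requesting attention")
        return a.mean(axis=1)

    def input_projection_weights(self) -> np.ndarray:
        """(k, d) linear projection weights mapping channels into model space."""
        return self.proj.W.data


class HybridNet(Module):
    """Fuse a sequence branch and a tabular MLP branch.

    Each branch emits a pre-sigmoid logit; a linear combiner (two weights and
    a bias) merges them into one logit per surgery.
    """

    def __init__(self, rng, seq_net: Module, tab_net: Module):
        super().__init__()
        self.seq = self.add_child("seq", seq_net)
        self.tab = self.add_child("tab", tab_net)
        self.combine = self.add_child("combine", Linear(rng, 2, 1))

    def __call__(self, inputs: tuple[Tensor, Tensor]) -> Tensor:
        x_seq, x_tab = inputs
        z_seq = self.seq(x_seq).reshape(-1, 1)
        z_tab = self.tab(x_tab).reshape(-1, 1)
        return self.combine(concat([z_seq, z_tab], axis=1)).reshape(-1)


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
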