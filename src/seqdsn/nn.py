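"""Neural-network layers and optimizer built on :mod:`seqdsn.autograd`.

Layers follow the usual module contract: parameters are
``Tensor(requires_grad=True)``, ``train()``/``eval()`` toggle batch
statistics, ``state_dict``/``load_state_dict`` round-trip weights as
plain numpy arrays (so checkpoints are portable ``.npz`` archives).
Initialization is Glorot-uniform drawn from an explicit
``numpy.random.Generator`` so that model construction is a pure
function of the seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Linear", "Conv1d", "BatchNorm", "LSTM", "SGD", "Adam"]


class Module:
    """Base class; discovers parameters and submodules by attribute scan."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def _named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                state[key] = v.data
            elif isinstance(v, np.ndarray):
                state[key] = v
            elif isinstance(v, Module):
                state.update(v._named_state(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item._named_state(prefix=f"{key}.{i}."))
        return state

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._named_state().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        current = self._named_state()
        missing = set(current) - set(state)
        if missing:
            raise KeyError(f"state_dict missing keys: {sorted(missing)}")
        for key, arr in state.items():
            if key not in current:
                raise KeyError(f"unexpected state_dict key: {key}")
            if current[key].shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {key}: "
                    f"{current[key].shape} vs {arr.shape}")
            current[key][...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_glorot(rng, in_features, out_features,
                                     (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """1-D convolution over (batch, channels, length) with symmetric padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 padding: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel
        self.weight = Tensor(_glorot(rng, fan_in, out_channels,
                                     (out_channels, in_channels, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, self.padding)


class BatchNorm(Module):
    """Batch normalization over the feature axis.

    Accepts (B, F) or (B, C, L) input; for the latter, statistics pool
    over batch and length. Running statistics (momentum 0.1) are used
    in eval mode — the standard train/eval contract.
    """

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        bshape = (1, -1) if x.ndim == 2 else (1, -1, 1)

        def _pool(t: Tensor) -> Tensor:
            # mean over batch (and length for 3-D input) per feature
            return t.mean(axis=0) if t.ndim == 2 else t.mean(axis=2).mean(axis=0)

        if self.training:
            mean = _pool(x)
            centered = x - mean.reshape(*bshape)
            var = _pool(centered ** 2.0)
            n = x.shape[0] if x.ndim == 2 else x.shape[0] * x.shape[2]
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data * n / max(n - 1, 1))
            inv_std = (var + self.eps) ** -0.5
            xhat = centered * inv_std.reshape(*bshape)
        else:
            mean = Tensor(self.running_mean.reshape(bshape))
            std = Tensor(np.sqrt(self.running_var + self.eps).reshape(bshape))
            xhat = (x - mean) / std
        return xhat * self.gamma.reshape(*bshape) + self.beta.reshape(*bshape)


class LSTM(Module):
    """Single-layer LSTM returning the final hidden state (B, H)."""

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator):
        super().__init__()
        H = hidden_size
        self.wx = Tensor(_glorot(rng, input_size, H, (input_size, 4 * H)),
                         requires_grad=True)
        self.wh = Tensor(_glorot(rng, H, H, (H, 4 * H)), requires_grad=True)
        bias = np.zeros(4 * H)
        bias[H:2 * H] = 1.0  # forget-gate bias 1: standard stability trick
        self.bias = Tensor(bias, requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.lstm(self.wx, self.wh, self.bias)


class SGD:
    """SGD with classical momentum and optional gradient-norm clipping."""

    def __init__(self, params: list[Tensor], lr: float,
                 momentum: float = 0.9, clip_norm: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p.data) for p in params]

    def _clip(self):
        if self.clip_norm is None:
            return
        total = np.sqrt(sum(float((p.grad ** 2).sum())
                            for p in self.params if p.grad is not None))
        if total > self.clip_norm and total > 0:
            scale = self.clip_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale

    def step(self):
        self._clip()
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class Adam:
    def __init__(self, params: list[Tensor], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
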