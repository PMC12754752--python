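"""Neural network layers built on the autodiff Tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, conv2d, stack_rows, upsample2

__all__ = ["Module", "Parameter", "Linear", "Conv2d", "BatchNorm2d",
           "Dropout", "LSTM", "set_seed", "get_rng"]

_rng = np.random.default_rng(0)


def set_seed(seed: int) -> None:
    """Seed parameter initialization and dropout."""
    global _rng
    _rng = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _rng


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery by attribute walk, train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
        walk(self)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = []

        def walk(obj):
            if isinstance(obj, Module):
                mods.append(obj)
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
        walk(self)
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = np.array(s, dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(fan_in: int, fan_out: int, shape) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return _rng.uniform(-lim, lim, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int):
        super().__init__()
        self.weight = Parameter(_glorot(in_features, out_features, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0):
        super().__init__()
        fan_in = in_channels * kernel_size ** 2
        self.weight = Parameter(_glorot(fan_in, out_channels,
                                        (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones((1, num_channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, num_channels, 1, 1)))
        self.running_mean = np.zeros((1, num_channels, 1, 1))
        self.running_var = np.ones((1, num_channels, 1, 1))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float = 0.2):
        super().__init__()
        self.p = p

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (_rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LSTM(Module):
    """(Optionally stacked) LSTM over an explicit Python time loop.

    Input/hidden size are equal by construction in the LSTM-Conv cell
    (hidden size matches the scanned row length).
    """

    def __init__(self, size: int, n_layers: int = 1):
        super().__init__()
        self.size = size
        self.n_layers = n_layers
        self.wx = [Parameter(_glorot(size, 4 * size, (size, 4 * size))) for _ in range(n_layers)]
        self.wh = [Parameter(_glorot(size, 4 * size, (size, 4 * size))) for _ in range(n_layers)]
        self.b = [Parameter(np.zeros(4 * size)) for _ in range(n_layers)]

    def init_state(self, batch: int) -> list[tuple[Tensor, Tensor]]:
        z = lambda: Tensor(np.zeros((batch, self.size)))
        return [(z(), z()) for _ in range(self.n_layers)]

    def step(self, x_t: Tensor, state: list[tuple[Tensor, Tensor]]):
        new_state = []
        inp = x_t
        for layer in range(self.n_layers):
            h, c = state[layer]
            z = inp @ self.wx[layer] + h @ self.wh[layer] + self.b[layer]
            n = self.size
            i = z[:, :n].sigmoid()
            f = z[:, n:2 * n].sigmoid()
            g = z[:, 2 * n:3 * n].tanh()
            o = z[:, 3 * n:].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            new_state.append((h_new, c_new))
            inp = h_new
        return inp, new_state

    def forward(self, xs: list[Tensor], state=None):
        """Run over a list of (B, size) inputs; returns outputs + final state."""
        if state is None:
            state = self.init_state(xs[0].shape[0])
        outs = []
        for x_t in xs:
            y, state = self.step(x_t, state)
            outs.append(y)
        return outs, state
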