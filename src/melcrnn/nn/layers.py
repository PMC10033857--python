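"""Network layers built on the autodiff core.

The convolution and pooling layers implement their own backward rules
(chunked im2col + GEMM in channels-last layout) because these dominate run
time; everything else is composed from primitive ``Tensor`` ops.  2-D
feature maps flow through the CNN as (batch, height, width, channels).

All parameters are float32; layer state lives in ``Parameter`` tensors
collected recursively through ``Module.parameters()``.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "AvgPool2d",
    "Dropout",
    "BiRNN",
    "xavier_normal_",
]


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal container with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            for m in _collect_modules(v):
                mods.extend(m.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(v):
    if isinstance(v, Parameter):
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)


def _collect_modules(v):
    if isinstance(v, Module):
        yield v
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect_modules(item)


def xavier_normal_(param: Parameter, fan_in: int, fan_out: int, rng: np.random.Generator) -> None:
    """Fill ``param`` in place with N(0, 2/(fan_in+fan_out)) draws."""
    std = np.sqrt(2.0 / (fan_in + fan_out))
    param.data[...] = rng.normal(0.0, std, size=param.data.shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(np.zeros((in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def init(self, rng: np.random.Generator) -> None:
        xavier_normal_(self.weight, self.in_features, self.out_features, rng)
        self.bias.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


# ---------------------------------------------------------------------------
# Convolution: 3x3, stride 1, padding 1 (the only case the model uses).
# Feature maps are channels-last (N, H, W, C): im2col is then a set of nine
# contiguous-run copies and every GEMM has a healthy K = 9*C inner dimension.
# The column matrix is built in batch chunks (and rebuilt in backward) so its
# peak size stays bounded.
# ---------------------------------------------------------------------------

_COL_BUDGET = 2.0e7  # floats per column-matrix chunk (~80 MB float32)


def _build_col(xp: np.ndarray, h: int, w: int) -> np.ndarray:
    """Padded chunk (m, h+2, w+2, c) -> column matrix (m*h*w, 9*c)."""
    m, _, _, c = xp.shape
    col = np.empty((m, h, w, 9, c), dtype=xp.dtype)
    for di in range(3):
        for dj in range(3):
            col[:, :, :, di * 3 + dj, :] = xp[:, di : di + h, dj : dj + w, :]
    return col.reshape(m * h * w, 9 * c)


def _chunk_size(h: int, w: int, c: int) -> int:
    return max(1, int(_COL_BUDGET // max(1, h * w * 9 * c)))


def _conv3x3(x: np.ndarray, w2: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """x (N,H,W,C), w2 (9C, F) -> (N,H,W,F); stride 1, pad 1."""
    n, h, wd, c = x.shape
    f = w2.shape[1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.empty((n, h, wd, f), dtype=x.dtype)
    step = _chunk_size(h, wd, c)
    for i in range(0, n, step):
        m = min(step, n - i)
        col = _build_col(xp[i : i + m], h, wd)
        out[i : i + m] = (col @ w2).reshape(m, h, wd, f)
    if b is not None:
        out += b
    return out


def _conv3x3_backward(x: np.ndarray, w2: np.ndarray, gy: np.ndarray,
                      need_gx: bool) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Gradients of _conv3x3: returns (gx, gw2, gb)."""
    n, h, wd, c = x.shape
    f = w2.shape[1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    gw2 = np.zeros_like(w2)
    gxp = np.zeros_like(xp) if need_gx else None
    step = _chunk_size(h, wd, c)
    for i in range(0, n, step):
        m = min(step, n - i)
        gy_flat = gy[i : i + m].reshape(m * h * wd, f)
        col = _build_col(xp[i : i + m], h, wd)
        gw2 += col.T @ gy_flat
        if need_gx:
            gcol = (gy_flat @ w2.T).reshape(m, h, wd, 9, c)
            gslab = gxp[i : i + m]
            for di in range(3):
                for dj in range(3):
                    gslab[:, di : di + h, dj : dj + wd, :] += gcol[:, :, :, di * 3 + dj, :]
    gx = gxp[:, 1:-1, 1:-1, :] if need_gx else None
    return gx, gw2, gy.sum(axis=(0, 1, 2))


class Conv2d(Module):
    """3x3 convolution, stride 1, padding 1, with bias; channels-last maps.

    The kernel parameter keeps the conventional (F, C, 3, 3) shape; it is
    flattened to the (9C, F) GEMM operand on the fly."""

    def __init__(self, in_channels: int, out_channels: int):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(np.zeros((out_channels, in_channels, 3, 3)))
        self.bias = Parameter(np.zeros(out_channels))

    def init(self, rng: np.random.Generator) -> None:
        xavier_normal_(self.weight, self.in_channels * 9, self.out_channels * 9, rng)
        self.bias.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        # (F, C, 3, 3) -> (3, 3, C, F) -> (9C, F), matching _build_col order
        w2 = np.ascontiguousarray(w.data.transpose(2, 3, 1, 0)).reshape(-1, w.data.shape[0])
        out_data = _conv3x3(x.data, w2, b.data)

        def backward(gy):
            gx, gw2, gb = _conv3x3_backward(x.data, w2, gy, x.requires_grad)
            if w.requires_grad:
                c, f = w.data.shape[1], w.data.shape[0]
                w._accumulate(gw2.reshape(3, 3, c, f).transpose(3, 2, 0, 1))
            if b.requires_grad:
                b._accumulate(gb)
            if gx is not None:
                x._accumulate(gx)

        return Tensor._make(out_data, (x, w, b), backward)


class BatchNorm2d(Module):
    """Per-channel batch normalisation over (N, H, W); channels-last input."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.weight, self.bias
        xd = x.data
        axes = (0, 1, 2)
        if self.training:
            mean = xd.mean(axis=axes)
            var = xd.var(axis=axes)
            m = self.momentum
            n = xd.shape[0] * xd.shape[1] * xd.shape[2]
            unbiased = var * n / max(1, n - 1)
            self.running_mean = (1 - m) * self.running_mean + m * mean.astype(np.float32)
            self.running_var = (1 - m) * self.running_var + m * unbiased.astype(np.float32)
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(xd.dtype)
        xhat = (xd - mean.astype(xd.dtype)) * inv_std
        out_data = xhat * gamma.data + beta.data
        training = self.training

        def backward(gy):
            if gamma.requires_grad:
                gamma._accumulate((gy * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accumulate(gy.sum(axis=axes))
            if x.requires_grad:
                gxhat = gy * gamma.data
                istd = inv_std
                if training:
                    gx = (
                        gxhat
                        - gxhat.mean(axis=axes, keepdims=True)
                        - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)
                    ) * istd
                else:
                    gx = gxhat * istd
                x._accumulate(gx)

        return Tensor._make(out_data, (x, gamma, beta), backward)


class AvgPool2d(Module):
    """2x2 average pooling, stride 2, floor mode.

    A spatial axis of size < 2 is left untouched (so sequences that have
    already collapsed to height 1 keep pooling along time only); trailing
    odd rows/columns are cropped.  Channels-last input (N, H, W, C).
    """

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.data.shape
        kh = 2 if h >= 2 else 1
        kw = 2 if w >= 2 else 1
        ho, wo = h // kh, w // kw
        xc = x.data[:, : ho * kh, : wo * kw, :]
        out_data = xc.reshape(n, ho, kh, wo, kw, c).mean(axis=(2, 4))
        scale = 1.0 / (kh * kw)

        def backward(gy):
            gx = np.zeros_like(x.data)
            up = np.repeat(np.repeat(gy, kh, axis=1), kw, axis=2) * scale
            gx[:, : ho * kh, : wo * kw, :] = up
            x._accumulate(gx)

        return Tensor._make(out_data, (x,), backward)


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = np.random.default_rng(0)

    def seed(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.data.shape, dtype=np.float32) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


# ---------------------------------------------------------------------------
# Recurrent layers
# ---------------------------------------------------------------------------


class _RNNCellBase(Module):
    def __init__(self, input_size: int, hidden_size: int, gates: int):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.w_ih = Parameter(np.zeros((input_size, gates * hidden_size)))
        self.w_hh = Parameter(np.zeros((hidden_size, gates * hidden_size)))
        self.bias = Parameter(np.zeros(gates * hidden_size))

    def init(self, rng: np.random.Generator) -> None:
        xavier_normal_(self.w_ih, self.input_size, self.hidden_size, rng)
        xavier_normal_(self.w_hh, self.hidden_size, self.hidden_size, rng)
        self.bias.data[...] = 0.0


class ElmanCell(_RNNCellBase):
    """s_t = tanh(U x_t + W s_{t-1} + b)."""

    def __init__(self, input_size: int, hidden_size: int):
        super().__init__(input_size, hidden_size, 1)

    def step(self, x: Tensor, state):
        h = state
        return (x @ self.w_ih + h @ self.w_hh + self.bias).tanh()

    def initial_state(self, batch: int):
        return Tensor(np.zeros((batch, self.hidden_size), dtype=np.float32))

    @staticmethod
    def output(state):
        return state


class GRUCell(_RNNCellBase):
    def __init__(self, input_size: int, hidden_size: int):
        super().__init__(input_size, hidden_size, 3)

    def step(self, x: Tensor, state):
        h = state
        hs = self.hidden_size
        zi = x @ self.w_ih + self.bias
        zh = h @ self.w_hh
        r = (zi[:, :hs] + zh[:, :hs]).sigmoid()
        z = (zi[:, hs : 2 * hs] + zh[:, hs : 2 * hs]).sigmoid()
        n = (zi[:, 2 * hs :] + r * zh[:, 2 * hs :]).tanh()
        one = Tensor(np.ones((1, hs), dtype=np.float32))
        return (one - z) * n + z * h

    initial_state = ElmanCell.initial_state
    output = staticmethod(ElmanCell.output)


class LSTMCell(_RNNCellBase):
    def __init__(self, input_size: int, hidden_size: int):
        super().__init__(input_size, hidden_size, 4)

    def step(self, x: Tensor, state):
        h, c = state
        hs = self.hidden_size
        z = x @ self.w_ih + h @ self.w_hh + self.bias
        i = z[:, :hs].sigmoid()
        f = z[:, hs : 2 * hs].sigmoid()
        g = z[:, 2 * hs : 3 * hs].tanh()
        o = z[:, 3 * hs :].sigmoid()
        c_new = f * c + i * g
        return (o * c_new.tanh(), c_new)

    def initial_state(self, batch: int):
        z = np.zeros((batch, self.hidden_size), dtype=np.float32)
        return (Tensor(z), Tensor(z.copy()))

    @staticmethod
    def output(state):
        return state[0]


_CELLS = {"elman_tanh": ElmanCell, "gru": GRUCell, "lstm": LSTMCell}


class BiRNN(Module):
    """Stacked bidirectional recurrent network over a short patch sequence.

    Each layer runs one cell forward and an independent cell backward over
    the sequence; their per-step outputs are concatenated (width 2*hidden)
    and fed to the next layer.  ``forward`` returns the full output
    sequence as a list of (batch, 2*hidden) tensors in temporal order.
    """

    def __init__(self, input_size: int, hidden_size: int, num_layers: int = 2,
                 cell: str = "elman_tanh"):
        super().__init__()
        if cell not in _CELLS:
            raise ValueError(f"unknown RNN cell {cell!r}; choose from {sorted(_CELLS)}")
        self.hidden_size = hidden_size
        cls = _CELLS[cell]
        self.fwd_cells = []
        self.bwd_cells = []
        for layer in range(num_layers):
            in_size = input_size if layer == 0 else 2 * hidden_size
            self.fwd_cells.append(cls(in_size, hidden_size))
            self.bwd_cells.append(cls(in_size, hidden_size))

    def init(self, rng: np.random.Generator) -> None:
        for cell in self.fwd_cells + self.bwd_cells:
            cell.init(rng)

    def forward(self, xs: list[Tensor]) -> list[Tensor]:
        batch = xs[0].shape[0]
        seq = xs
        for fwd, bwd in zip(self.fwd_cells, self.bwd_cells):
            f_states = []
            state = fwd.initial_state(batch)
            for x in seq:
                state = fwd.step(x, state)
                f_states.append(fwd.output(state))
            b_states = []
            state = bwd.initial_state(batch)
            for x in reversed(seq):
                state = bwd.step(x, state)
                b_states.append(bwd.output(state))
            b_states.reverse()
            seq = [concat([f, b], axis=1) for f, b in zip(f_states, b_states)]
        return seq
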