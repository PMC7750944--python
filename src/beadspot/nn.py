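"""Minimal CPU neural-network engine for the seed detector.

A small, self-contained set of layers (3x3/1x1 convolution, batch norm,
ReLU, 2x2 max-pool, nearest-neighbour 2x upsampling) with explicit forward
and backward passes over NumPy, plus an Adam optimizer.  Convolutions use
an im2col layout so the inner loop is a single BLAS matmul; tensors are
kept channels-last (N, H, W, C) internally so the column matrices are
built from contiguous slices without transposes.  Everything runs in
float32.  The scale is deliberately modest: the networks trained here have
1e4-1e6 parameters and images are a few hundred px across, for which this
is fast enough on one CPU core and fully deterministic.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


_OFFSETS = [(i, j) for i in range(3) for j in range(3)]


class Conv2d(Layer):
    """Same-padded convolution, kernel 3 or 1, stride 1, zero padding.

    Weight layout is (kernel*kernel*C_in, C_out) so that the forward pass
    is ``cols @ weight`` with ``cols`` of shape (N*H*W, k*k*C_in).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        assert kernel in (1, 3)
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out)))
        self.bias = Param(np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        n, h, w, c = x.shape
        self._shape = (n, h, w, c)
        if self.k == 1:
            cols = x.reshape(n * h * w, c)
        else:
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
            cols = np.concatenate(
                [xp[:, i : i + h, j : j + w, :] for i, j in _OFFSETS], axis=3
            ).reshape(n * h * w, 9 * c)
        self._cols = cols if train else None
        out = cols @ self.weight.value + self.bias.value
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout):
        n, h, w, c = self._shape
        dflat = dout.reshape(n * h * w, self.c_out)
        self.weight.grad += self._cols.T @ dflat
        self.bias.grad += dflat.sum(axis=0)
        dcols = dflat @ self.weight.value.T
        if self.k == 1:
            return dcols.reshape(n, h, w, c)
        dcols = dcols.reshape(n, h, w, 9, c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=F32)
        for idx, (i, j) in enumerate(_OFFSETS):
            dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, idx, :]
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv)
        return (self.gamma.value * xhat + self.beta.value).astype(F32)

    def backward(self, dout):
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma.value
        # standard batch-norm backward over the (N, H, W) axes
        t1 = dxhat - dxhat.mean(axis=(0, 1, 2))
        t2 = xhat * ((dxhat * xhat).sum(axis=(0, 1, 2)) / m)
        return ((t1 - t2) * inv).astype(F32)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input H, W must be even."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(n, h // 2, w // 2, 4, c)
        self._argmax = xr.argmax(axis=3)
        self._shape = (n, h, w, c)
        return np.take_along_axis(xr, self._argmax[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        n, h, w, c = self._shape
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=F32)
        np.put_along_axis(dxr, self._argmax[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dxr = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(dxr.reshape(n, h, w, c))


class UpsampleNearest2(Layer):
    def forward(self, x, train):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout):
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(F32)


class ConvBlock(Layer):
    """[3x3 conv -> batch norm -> ReLU] x 2."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.layers = [
            Conv2d(c_in, c_out, 3, rng),
            BatchNorm2d(c_out),
            ReLU(),
            Conv2d(c_out, c_out, 3, rng),
            BatchNorm2d(c_out),
            ReLU(),
        ]

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class UNet:
    """Encoder-decoder with skip connections and a single-logit head.

    ``depth`` encoder levels with channel widths ``base * 2**level``, a
    bottleneck at ``base * 2**depth``, nearest-neighbour upsampling in the
    decoder with channel concatenation of the matching encoder output, and
    a 1x1 convolution producing one logit per pixel.  ``sigmoid(logits)``
    is the seed probability.  Spatial input size must be divisible by
    ``2**depth``.  The public interface uses (N, 1, H, W) batches; the
    channels-last internal layout is an implementation detail.
    """

    def __init__(self, depth: int = 3, base_channels: int = 32, rng_seed: int = 0):
        rng = np.random.default_rng(rng_seed)
        self.depth = depth
        self.base = base_channels
        self.enc = []
        c_prev = 1
        for level in range(depth):
            c = base_channels * 2**level
            self.enc.append(ConvBlock(c_prev, c, rng))
            c_prev = c
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = ConvBlock(c_prev, base_channels * 2**depth, rng)
        self.ups = [UpsampleNearest2() for _ in range(depth)]
        self.dec = []
        c_deep = base_channels * 2**depth
        for level in reversed(range(depth)):
            c_skip = base_channels * 2**level
            self.dec.append(ConvBlock(c_deep + c_skip, c_skip, rng))
            c_deep = c_skip
        self.head = Conv2d(base_channels, 1, 1, rng)
        # seeds cover well under 1% of the pixels; starting the head at a
        # negative logit matches that prior and speeds up convergence
        self.head.bias.value[...] = -4.0

    def params(self) -> list[Param]:
        out = []
        for block in [*self.enc, self.bottleneck, *self.dec, self.head]:
            out.extend(block.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 1, H, W) image batch -> (N, 1, H, W) logits."""
        x = np.ascontiguousarray(np.asarray(x, dtype=F32).transpose(0, 2, 3, 1))
        h, w = x.shape[1], x.shape[2]
        if h % 2**self.depth or w % 2**self.depth:
            raise ValueError(f"input size {h}x{w} not divisible by {2 ** self.depth}")
        skips = []
        for level in range(self.depth):
            x = self.enc[level].forward(x, train)
            skips.append(x)
            x = self.pools[level].forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for i, level in enumerate(reversed(range(self.depth))):
            x = self.ups[i].forward(x, train)
            skip = skips[level]
            self._skip_channels.append(skip.shape[3])
            x = np.concatenate([skip, x], axis=3)
            x = self.dec[i].forward(x, train)
        out = self.head.forward(x, train)
        return out.transpose(0, 3, 1, 2)

    def backward(self, dlogits: np.ndarray) -> None:
        d = np.ascontiguousarray(np.asarray(dlogits, dtype=F32).transpose(0, 2, 3, 1))
        d = self.head.backward(d)
        dskips = {}
        for j in reversed(range(self.depth)):  # dec[j] serves encoder level depth-1-j
            d = self.dec[j].backward(d)
            c_skip = self._skip_channels[j]
            dskip, d = d[:, :, :, :c_skip], d[:, :, :, c_skip:]
            d = self.ups[j].backward(np.ascontiguousarray(d))
            dskips[self.depth - 1 - j] = dskip
        d = self.bottleneck.backward(d)
        for level in reversed(range(self.depth)):
            d = self.pools[level].backward(d)
            d = d + dskips[level]
            d = self.enc[level].backward(d)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    def state(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.params()]
        for block in self._bn_layers():
            arrays.append(block.running_mean.copy())
            arrays.append(block.running_var.copy())
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        ps = self.params()
        for p, a in zip(ps, arrays[: len(ps)]):
            p.value[...] = a
        rest = arrays[len(ps) :]
        for i, block in enumerate(self._bn_layers()):
            block.running_mean[...] = rest[2 * i]
            block.running_var[...] = rest[2 * i + 1]

    def _bn_layers(self):
        for block in [*self.enc, self.bottleneck, *self.dec]:
            for layer in block.layers:
                if isinstance(layer, BatchNorm2d):
                    yield layer


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
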