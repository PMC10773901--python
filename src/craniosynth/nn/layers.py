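"""Neural-network layers built on the autodiff primitives.

Convolutions are expressed as gather (im2col) + matmul, transposed
convolutions as zero-dilation + convolution, and nearest-neighbour
upsampling as a gather. Every forward pass is therefore a composition of
differentiable primitives, which is what makes the gradient penalty's
double backprop work.
"""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor, _node, concat, leaky_relu, matmul, reshape, sum_, take, tanh, transpose


def pad4d(x: Tensor, pads: tuple[int, int, int, int]) -> Tensor:
    """Zero-pad the two trailing axes by (top, bottom, left, right)."""
    t, b, l, r = pads
    if t == b == l == r == 0:
        return x
    out = np.pad(x.data, ((0, 0), (0, 0), (t, b), (l, r)))
    return _node(out, (x,), (lambda g: slice4d(g, pads),))


def slice4d(x: Tensor, cuts: tuple[int, int, int, int]) -> Tensor:
    """Crop the two trailing axes by (top, bottom, left, right)."""
    t, b, l, r = cuts
    if t == b == l == r == 0:
        return x
    h, w = x.shape[2], x.shape[3]
    out = x.data[:, :, t : h - b, l : w - r].copy()
    return _node(out, (x,), (lambda g: pad4d(g, cuts),))


def dilate2d(x: Tensor, stride: int) -> Tensor:
    """Insert stride-1 zeros between entries of the two trailing axes."""
    if stride == 1:
        return x
    n, c, h, w = x.shape
    out = np.zeros((n, c, (h - 1) * stride + 1, (w - 1) * stride + 1), dtype=DTYPE)
    out[:, :, ::stride, ::stride] = x.data
    return _node(out, (x,), (lambda g: downsample2d(g, stride),))


def downsample2d(x: Tensor, stride: int) -> Tensor:
    """Keep every stride-th entry of the two trailing axes."""
    if stride == 1:
        return x
    out = x.data[:, :, ::stride, ::stride].copy()
    return _node(out, (x,), (lambda g: dilate2d(g, stride),))


def _flip_swap(w: Tensor) -> Tensor:
    """rot180 spatially and swap in/out channel axes: (F,C,kh,kw)->(C,F,kh,kw)."""
    f, c, kh, kw = w.shape
    idx = np.arange(f * c * kh * kw).reshape(f, c, kh, kw)
    idx = idx[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
    return take(w, np.ascontiguousarray(idx))


def _conv_forward(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    kh, kw = w.shape[2], w.shape[3]
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, oh, ow, kh, kw)
    out = np.tensordot(win, w, axes=((1, 4, 5), (1, 2, 3)))  # (n, oh, ow, f)
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def conv_nobias(x: Tensor, w: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation as a differentiable primitive.

    The input-gradient is the full convolution of the (dilated) output
    gradient with the rotated kernel; the weight-gradient is a correlation
    of the padded input with the dilated output gradient. Both are built
    from primitives, so the op supports double backprop.
    """
    n, c, h, w_in = x.shape
    f, _, kh, kw = w.shape
    hp, wp = h + 2 * pad, w_in + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    # rows/cols beyond the last window (when stride does not divide evenly)
    rh = hp - ((oh - 1) * stride + kh)
    rw = wp - ((ow - 1) * stride + kw)
    out = _conv_forward(x.data, w.data, stride, pad)

    def vjp_x(g):
        gd = dilate2d(g, stride)
        gd = pad4d(gd, (kh - 1, kh - 1 + rh, kw - 1, kw - 1 + rw))
        gx = conv_nobias(gd, _flip_swap(w), stride=1, pad=0)  # (n, c, hp, wp)
        return slice4d(gx, (pad, pad, pad, pad))

    def vjp_w(g):
        xp = pad4d(x, (pad, pad, pad, pad))
        gd = dilate2d(g, stride)
        gw = conv_nobias(transpose(xp, (1, 0, 2, 3)), transpose(gd, (1, 0, 2, 3)), 1, 0)
        gw = slice4d(gw, (0, rh, 0, rw))  # (c, f, kh, kw)
        return transpose(gw, (1, 0, 2, 3))

    return _node(out, (x, w), (vjp_x, vjp_w))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """x: (N,C,H,W); weight: (F,C,kh,kw); bias: (F,)."""
    return conv_nobias(x, weight, stride, pad) + reshape(bias, (1, -1, 1, 1))


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 2, pad: int = 1) -> Tensor:
    """Transposed convolution: zero-dilate by ``stride`` then convolve.

    Output size: (H-1)*stride - 2*pad + kh.
    """
    kh = weight.shape[2]
    xd = dilate2d(x, stride)
    return conv_nobias(xd, weight, stride=1, pad=kh - 1 - pad) + reshape(bias, (1, -1, 1, 1))


_IDX_CACHE: dict[tuple, np.ndarray] = {}


def _upsample_indices(n, c, h, w):
    key = ("up2", n, c, h, w)
    if key not in _IDX_CACHE:
        ni, ci, hi, wi = np.meshgrid(
            np.arange(n), np.arange(c), np.arange(2 * h), np.arange(2 * w), indexing="ij"
        )
        _IDX_CACHE[key] = (((ni * c + ci) * h + hi // 2) * w + wi // 2).astype(np.intp)
    return _IDX_CACHE[key]


def upsample_nearest2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    return take(x, _upsample_indices(n, c, h, w))


# -- parameterized layers -----------------------------------------------------


class Layer:
    kind = "layer"

    def parameters(self) -> list[Tensor]:
        return []

    def __call__(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    kind = "dense"

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        s = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0, s, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + reshape(self.bias, (1, -1))

    def parameters(self):
        return [self.weight, self.bias]


class Conv2d(Layer):
    kind = "conv"

    def __init__(self, c_in, c_out, k, stride, pad, rng: np.random.Generator):
        s = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Tensor(rng.normal(0, s, (c_out, c_in, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)

    def parameters(self):
        return [self.weight, self.bias]


class ConvTranspose2d(Layer):
    kind = "convtranspose"

    def __init__(self, c_in, c_out, k, stride, pad, rng: np.random.Generator):
        s = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Tensor(rng.normal(0, s, (c_out, c_in, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.pad)

    def parameters(self):
        return [self.weight, self.bias]


class Upsample2(Layer):
    kind = "upsample"

    def __call__(self, x):
        return upsample_nearest2(x)


class LeakyReLU(Layer):
    kind = "leaky_relu"

    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def __call__(self, x):
        return leaky_relu(x, self.alpha)


class Tanh(Layer):
    kind = "tanh"

    def __call__(self, x):
        return tanh(x)


class Reshape(Layer):
    kind = "reshape"

    def __init__(self, shape):
        self.shape = shape

    def __call__(self, x):
        return reshape(x, (x.shape[0],) + tuple(self.shape))


class Flatten(Layer):
    kind = "flatten"

    def __call__(self, x):
        return reshape(x, (x.shape[0], -1))


class Embedding(Layer):
    kind = "embedding"

    def __init__(self, n_classes: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0, 0.1, (n_classes, dim)), requires_grad=True)
        self.dim = dim

    def __call__(self, labels: np.ndarray) -> Tensor:
        labels = np.asarray(labels, dtype=np.intp)
        idx = labels[:, None] * self.dim + np.arange(self.dim)[None, :]
        return take(self.weight, idx)

    def parameters(self):
        return [self.weight]


class Sequential(Layer):
    kind = "sequential"

    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    @property
    def kinds(self) -> list[str]:
        return [l.kind for l in self.layers]


class Adam:
    """Adaptive-moment optimizer; ``betas=(0.0, 0.9)`` is the WGAN-GP convention."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(p.shape) for p in self.params]
        self.v = [np.zeros(p.shape) for p in self.params]

    def step(self, grads: list[Tensor]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data
            m *= self.b1
            m += (1 - self.b1) * gd
            v *= self.b2
            v += (1 - self.b2) * gd * gd
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
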