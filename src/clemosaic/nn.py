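"""Minimal reverse-mode autodiff engine for small convolutional networks.

Implements exactly the operations the segmentation network needs: 3x3/1x1
convolutions (im2col + BLAS matmul), fixed separable Gaussian smoothing with
reflective padding, 2x2 max pooling, 2x bilinear upsampling, batch
normalization, ReLU/sigmoid, channel concatenation and binary cross-entropy
on logits, plus an Adam optimizer.  All tensors are NCHW ``float32``.

Gradients are exact (the test suite checks them against central finite
differences), including through the reflective padding of the Gaussian
layers, whose adjoint is realized by scatter-adding along the same gather
indices used in the forward pass.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """A numpy array plus the closure needed to backpropagate into parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=DTYPE)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g


# ---------------------------------------------------------------- primitives

def _corr(a: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Raw stride-1 cross-correlation as a sum of per-tap GEMMs.

    One tensordot per kernel tap avoids the expensive 6-D im2col transpose
    while doing the same FLOPs through BLAS.
    """
    n, cin, h, wd = a.shape
    cout, _, kh, kw = w.shape
    ap = np.pad(a, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else a
    ho, wo = ap.shape[2] - kh + 1, ap.shape[3] - kw + 1
    out = np.zeros((cout, n, ho, wo), dtype=a.dtype)
    for i in range(kh):
        for j in range(kw):
            out += np.tensordot(w[:, :, i, j], ap[:, :, i : i + ho, j : j + wo],
                                axes=(1, 1))
    return out.transpose(1, 0, 2, 3)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, pad: int) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) with zero padding."""
    cout, cin, kh, kw = w.data.shape
    out = _corr(x.data, w.data, pad)
    if b is not None:
        out = out + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if w.requires_grad:
            ap = (np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
                  if pad else x.data)
            ho, wo = g.shape[2], g.shape[3]
            gT = np.ascontiguousarray(g.transpose(1, 0, 2, 3))
            dw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    dw[:, :, i, j] = np.tensordot(
                        gT, ap[:, :, i : i + ho, j : j + wo],
                        axes=([1, 2, 3], [0, 2, 3]))
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # input gradient = transposed convolution: correlate g with the
            # channel-transposed, spatially flipped kernel
            wt = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            x._accum(_corr(g, wt, kh - 1 - pad))

    return Tensor(out, parents=parents, backward=bwd)


def _reflect_indices(n: int, p: int) -> np.ndarray:
    """Gather indices realizing numpy 'reflect' padding of width p
    (handles p >= n via repeated reflection)."""
    if n == 1:
        return np.zeros(2 * p + 1, dtype=int)
    return np.pad(np.arange(n), p, mode="reflect")


def gaussian_smooth_op(x: Tensor, k1d: np.ndarray) -> Tensor:
    """Depthwise separable correlation with a fixed 1-D kernel, reflect pad.

    The kernel carries no gradient; the input gradient is exact, including
    the fold-back through the reflective border.
    """
    k1d = np.asarray(k1d, dtype=DTYPE)
    k = k1d.size
    p = (k - 1) // 2
    n, c, h, w = x.data.shape
    iy = _reflect_indices(h, p)
    ix = _reflect_indices(w, p)

    def corr(a):
        ap = a[:, :, iy, :][:, :, :, ix]
        out = np.zeros((n, c, h, w + 2 * p), dtype=DTYPE)
        for j in range(k):  # vertical pass
            out += k1d[j] * ap[:, :, j : j + h, :]
        res = np.zeros((n, c, h, w), dtype=DTYPE)
        for j in range(k):  # horizontal pass
            res += k1d[j] * out[:, :, :, j : j + w]
        return res

    out = corr(x.data)

    def bwd(g):
        if not x.requires_grad:
            return
        # adjoint of horizontal pass: scatter into padded width
        gp = np.zeros((n, c, h, w + 2 * p), dtype=DTYPE)
        for j in range(k):
            gp[:, :, :, j : j + w] += k1d[j] * g
        # adjoint of vertical pass
        gpp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for j in range(k):
            gpp[:, :, j : j + h, :] += k1d[j] * gp
        # adjoint of the gather = scatter-add along the same indices
        gx_cols = np.zeros((n, c, h + 2 * p, w), dtype=DTYPE)
        np.add.at(gx_cols, (slice(None), slice(None), slice(None), ix), gpp)
        gx = np.zeros((n, c, h, w), dtype=DTYPE)
        np.add.at(gx, (slice(None), slice(None), iy, slice(None)), gx_cols)
        x._accum(gx)

    return Tensor(out, parents=(x,), backward=bwd)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "max-pool needs even dims"
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    arg = r.argmax(axis=-1)
    out = np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]

    def bwd(g):
        if not x.requires_grad:
            return
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
        gx = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gx.reshape(n, c, h, w))

    return Tensor(out, parents=(x,), backward=bwd)


def _upsample_axis_weights(n_out: int, n_in: int):
    """Bilinear sample positions for 2x upsampling (half-pixel centers)."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = (src - i0).astype(DTYPE)
    return i0, i1, (1 - w1), w1


def upsample2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    y0, y1, wy0, wy1 = _upsample_axis_weights(2 * h, h)
    x0, x1, wx0, wx1 = _upsample_axis_weights(2 * w, w)

    a = x.data
    rows = a[:, :, y0, :] * wy0[None, None, :, None] + a[:, :, y1, :] * wy1[None, None, :, None]
    out = rows[:, :, :, x0] * wx0 + rows[:, :, :, x1] * wx1

    def bwd(g):
        if not x.requires_grad:
            return
        grows = np.zeros((n, c, 2 * h, w), dtype=DTYPE)
        np.add.at(grows, (slice(None), slice(None), slice(None), x0), g * wx0)
        np.add.at(grows, (slice(None), slice(None), slice(None), x1), g * wx1)
        gx = np.zeros_like(a)
        np.add.at(gx, (slice(None), slice(None), y0, slice(None)),
                  grows * wy0[None, None, :, None])
        np.add.at(gx, (slice(None), slice(None), y1, slice(None)),
                  grows * wy1[None, None, :, None])
        x._accum(gx)

    return Tensor(out, parents=(x,), backward=bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def bwd(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor(out, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -30, 30)))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * s * (1 - s))

    return Tensor(s, parents=(x,), backward=bwd)


def concat(xs, axis=1) -> Tensor:
    out = np.concatenate([t.data for t in xs], axis=axis)
    sizes = [t.data.shape[axis] for t in xs]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(xs, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor(out, parents=tuple(xs), backward=bwd)


def bce_with_logits(z: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits."""
    t = np.asarray(target, dtype=DTYPE)
    zd = z.data
    loss = np.maximum(zd, 0) - zd * t + np.log1p(np.exp(-np.abs(zd)))
    out = loss.mean()

    def bwd(g):
        if z.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(zd, -30, 30)))
            z._accum(g * (s - t) / zd.size)

    return Tensor(out, parents=(z,), backward=bwd)


# ------------------------------------------------------------------ modules

class Module:
    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        out.extend(m.parameters())
        return out

    def modules(self):
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        out.extend(m.modules())
        return out

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    # state dict: flat name -> array, for npz checkpoints
    def state_dict(self, prefix=""):
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                out[prefix + k] = v.data
            elif isinstance(v, np.ndarray) and k.startswith("running_"):
                out[prefix + k] = v
            elif isinstance(v, Module):
                out.update(v.state_dict(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        out.update(m.state_dict(f"{prefix}{k}.{i}."))
        return out

    def load_state_dict(self, state, prefix=""):
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                v.data = np.asarray(state[prefix + k], dtype=DTYPE)
            elif isinstance(v, np.ndarray) and k.startswith("running_"):
                setattr(self, k, np.asarray(state[prefix + k], dtype=DTYPE))
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        m.load_state_dict(state, f"{prefix}{k}.{i}.")


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, pad=None):
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(rng.normal(0, std, (cout, cin, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.pad = (k - 1) // 2 if pad is None else pad

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        out = xhat * self.gamma.data[None, :, None, None] + self.beta.data[None, :, None, None]
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        training = self.training

        def bwd(g):
            if self.gamma.requires_grad:
                self.gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if self.beta.requires_grad:
                self.beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gh = g * self.gamma.data[None, :, None, None]
                if training:
                    t1 = gh.sum(axis=(0, 2, 3))[None, :, None, None]
                    t2 = (gh * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
                    gx = (gh - t1 / m - xhat * t2 / m) * inv[None, :, None, None]
                else:
                    gx = gh * inv[None, :, None, None]
                x._accum(gx.astype(DTYPE))

        return Tensor(out, parents=(x, self.gamma, self.beta), backward=bwd)


class Adam:
    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
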