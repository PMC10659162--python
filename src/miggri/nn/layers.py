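"""Neural-network building blocks on top of the autodiff core.

Convolutions are implemented with im2col/col2im so the heavy lifting is a
single matrix product per layer; the transposed convolution is the exact
adjoint of the forward convolution (same helpers, roles swapped).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "LSTMCell",
    "conv2d",
    "conv_transpose2d",
]


# ---------------------------------------------------------------------------
# im2col / col2im


def _im2col(xp: np.ndarray, kh: int, kw: int, s: int, ho: int, wo: int) -> np.ndarray:
    """Padded input (N,C,Hp,Wp) -> patches (N, C, kh, kw, ho, wo)."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
    return cols


def _col2im(cols: np.ndarray, hp: int, wp: int, s: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back onto (N,C,hp,wp)."""
    n, c, kh, kw, ho, wo = cols.shape
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + s * ho : s, j : j + s * wo : s] += cols[:, :, i, j]
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation). x:(N,Ci,H,W), w:(Co,Ci,kh,kw)."""
    n, ci, h, wd = x.shape
    co, ci_w, kh, kw = w.shape
    if ci != ci_w:
        raise ValueError(f"channel mismatch: input {ci}, weight {ci_w}")
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (wd + 2 * pad - kw) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = _im2col(xp, kh, kw, stride, ho, wo).reshape(n, ci * kh * kw, ho * wo)
    w2 = w.data.reshape(co, ci * kh * kw)
    out = np.matmul(w2[None], cols).reshape(n, co, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1)

    def backward(g):
        gf = g.reshape(n, co, ho * wo)
        if w.requires_grad:
            w._accum(np.tensordot(gf, cols, axes=([0, 2], [0, 2])).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w2.T[None], gf).reshape(n, ci, kh, kw, ho, wo)
            dxp = _col2im(dcols, h + 2 * pad, wd + 2 * pad, stride)
            x._accum(dxp[:, :, pad : pad + h, pad : pad + wd])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def conv_transpose2d(
    x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0
) -> Tensor:
    """Transposed 2-D convolution. x:(N,Ci,H,W), w:(Ci,Co,kh,kw).

    Output spatial size is ``(H-1)*stride - 2*pad + k``; with k=4, stride=2,
    pad=1 this exactly doubles the resolution.
    """
    n, ci, h, wd = x.shape
    ci_w, co, kh, kw = w.shape
    if ci != ci_w:
        raise ValueError(f"channel mismatch: input {ci}, weight {ci_w}")
    ho = (h - 1) * stride - 2 * pad + kh
    wo = (wd - 1) * stride - 2 * pad + kw
    w2 = w.data.reshape(ci, co * kh * kw)
    xf = x.data.reshape(n, ci, h * wd)
    cols = np.matmul(w2.T[None], xf).reshape(n, co, kh, kw, h, wd)
    outp = _col2im(cols, ho + 2 * pad, wo + 2 * pad, stride)
    out = outp[:, :, pad : pad + ho, pad : pad + wo]
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1)

    def backward(g):
        gp = np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        gcols = _im2col(gp, kh, kw, stride, h, wd).reshape(n, co * kh * kw, h * wd)
        if w.requires_grad:
            w._accum(np.tensordot(xf, gcols, axes=([0, 2], [0, 2])).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(np.matmul(w2[None], gcols).reshape(x.shape))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


# ---------------------------------------------------------------------------
# modules


class Module:
    """Tiny parameter container with recursive discovery and state dicts."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for _, value in self._named(prefix=""):
            params.append(value)
        return params

    def _named(self, prefix: str):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value._named(prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named(prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._named(prefix="")}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self._named(prefix=""))
        if set(own) != set(state):
            raise KeyError(
                f"state mismatch: missing {set(own) - set(state)}, "
                f"unexpected {set(state) - set(own)}"
            )
        for k, v in own.items():
            v.data = np.asarray(state[k], dtype=np.float64).reshape(v.data.shape).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _param(rng: np.random.Generator, shape, std: float) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _param(rng, (n_in, n_out), std=np.sqrt(2.0 / n_in))
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in, c_out, k, rng, stride=1, pad=0):
        self.stride, self.pad = stride, pad
        self.w = _param(rng, (c_out, c_in, k, k), std=np.sqrt(2.0 / (c_in * k * k)))
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    def __init__(self, c_in, c_out, k, rng, stride=1, pad=0):
        self.stride, self.pad = stride, pad
        self.w = _param(rng, (c_in, c_out, k, k), std=np.sqrt(2.0 / (c_in * k * k)))
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class LSTMCell(Module):
    """Single-layer LSTM cell; gate order i, f, g, o. Forget bias starts at 1."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        std = 1.0 / np.sqrt(n_hidden)
        self.wx = _param(rng, (n_in, 4 * n_hidden), std=std)
        self.wh = _param(rng, (n_hidden, 4 * n_hidden), std=std)
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        """One recurrence step on a batch: x (B,n_in), h/c (B,n_hidden)."""
        nh = self.n_hidden
        gates = x @ self.wx + h @ self.wh + self.b
        gd = np.clip(gates.data, -500, 500)
        i_s = 1.0 / (1.0 + np.exp(-gd[:, :nh]))
        f_s = 1.0 / (1.0 + np.exp(-gd[:, nh : 2 * nh]))
        g_t = np.tanh(gd[:, 2 * nh : 3 * nh])
        o_s = 1.0 / (1.0 + np.exp(-gd[:, 3 * nh :]))
        c_old = c.data
        c_new_d = f_s * c_old + i_s * g_t
        tanh_c = np.tanh(c_new_d)
        h_new_d = o_s * tanh_c

        def _push(gh, gc):
            # shared adjoint for both outputs; contributions are additive
            if gh is not None:
                gc = (gc if gc is not None else 0.0) + gh * o_s * (1.0 - tanh_c**2)
                d_o = gh * tanh_c * o_s * (1.0 - o_s)
            else:
                d_o = np.zeros_like(o_s)
            d_i = gc * g_t * i_s * (1.0 - i_s)
            d_f = gc * c_old * f_s * (1.0 - f_s)
            d_g = gc * i_s * (1.0 - g_t**2)
            if gates.requires_grad:
                gates._backward(np.concatenate([d_i, d_f, d_g, d_o], axis=1))
            if c.requires_grad:
                c._accum(gc * f_s)

        h_new = Tensor._make(h_new_d, (gates, c), lambda g: _push(g, None))
        c_new = Tensor._make(c_new_d, (gates, c), lambda g: _push(None, g))
        return h_new, c_new

    def run(self, xs: Tensor) -> Tensor:
        """Run over one sequence (T, n_in); returns the final hidden state (n_hidden,)."""
        h = Tensor(np.zeros((1, self.n_hidden)))
        c = Tensor(np.zeros((1, self.n_hidden)))
        for t in range(xs.shape[0]):
            h, c = self.step(xs.gather_rows([t]), h, c)
        return h.reshape((self.n_hidden,))
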