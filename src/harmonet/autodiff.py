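"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This engine exists to train the dual generative networks on CPU at the
volume sizes this package targets.  It supports higher-order derivatives:
each op's backward pass is itself expressed through recorded ops, so the
gradient-penalty term of the Wasserstein critic (a function of the critic's
input gradient) can be differentiated with respect to the critic weights.

Convolutions are built from a closed triple of primitives --

    conv(x, w)              forward cross-correlation
    conv_input_grad(g, w)   gradient w.r.t. the input  (== transposed conv)
    conv_weight_grad(x, g)  gradient w.r.t. the kernel

-- whose backward passes only use members of the same triple, which is what
makes double backprop through a convolutional critic exact rather than
approximate.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording inside the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An array with an optional autodiff graph node."""

    __slots__ = ("data", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(astensor(other), -1.0))

    def __rsub__(self, other):
        return add(astensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, power(other, -1.0))

    def __pow__(self, p):
        return power(self, p)


def astensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _tracked(*inputs):
    return _GRAD_ENABLED and any(t.requires_grad for t in inputs)


def _make(data, inputs, backward):
    if _tracked(*inputs):
        return Tensor(data, requires_grad=True, parents=tuple(inputs),
                      backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------

def sum_to(x, shape):
    """Sum ``x`` down to ``shape`` (inverse of NumPy broadcasting)."""
    x = astensor(x)
    if tuple(x.shape) == tuple(shape):
        return x
    lead = x.ndim - len(shape)
    axes = tuple(range(lead)) + tuple(
        lead + i for i, s in enumerate(shape) if s == 1 and x.shape[lead + i] != 1
    )
    out = tsum(x, axis=axes, keepdims=True) if axes else x
    return reshape(out, shape)


def broadcast_to(x, shape):
    x = astensor(x)
    if tuple(x.shape) == tuple(shape):
        return x
    data = np.broadcast_to(x.data, shape)

    def backward(g):
        return (sum_to(g, x.shape),)

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = astensor(a), astensor(b)
    data = a.data + b.data

    def backward(g):
        return sum_to(g, a.shape), sum_to(g, b.shape)

    return _make(data, (a, b), backward)


def mul(a, b):
    a, b = astensor(a), astensor(b)
    data = a.data * b.data

    def backward(g):
        return sum_to(mul(g, b), a.shape), sum_to(mul(g, a), b.shape)

    return _make(data, (a, b), backward)


def power(x, p):
    x = astensor(x)
    p = float(p)
    data = x.data ** p

    def backward(g):
        return (mul(g, mul(power(x, p - 1.0), p)),)

    return _make(data, (x,), backward)


def sqrt(x):
    return power(x, 0.5)


def absval(x):
    x = astensor(x)
    data = np.abs(x.data)
    sign = Tensor(np.sign(x.data))  # constant w.r.t. the graph

    def backward(g):
        return (mul(g, sign),)

    return _make(data, (x,), backward)


def leaky_relu(x, slope=0.2):
    x = astensor(x)
    mask = np.where(x.data > 0, 1.0, slope).astype(x.dtype)
    data = x.data * mask
    mask_t = Tensor(mask)

    def backward(g):
        return (mul(g, mask_t),)

    return _make(data, (x,), backward)


def tsum(x, axis=None, keepdims=False):
    x = astensor(x)
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gd = g
        if not keepdims and axis is not None:
            axes = axis if isinstance(axis, tuple) else (axis,)
            shp = list(g.shape)
            for ax in sorted(a % x.ndim for a in axes):
                shp.insert(ax, 1)
            gd = reshape(g, tuple(shp))
        elif not keepdims and axis is None:
            gd = reshape(g, (1,) * x.ndim)
        return (broadcast_to(gd, x.shape),)

    return _make(data, (x,), backward)


def tmean(x, axis=None, keepdims=False):
    x = astensor(x)
    n = x.data.size if axis is None else np.prod(
        [x.shape[a % x.ndim] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(x, shape):
    x = astensor(x)
    data = x.data.reshape(shape)
    orig = x.shape

    def backward(g):
        return (reshape(g, orig),)

    return _make(data, (x,), backward)


def concat(tensors, axis):
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]

    def backward(g):
        outs, start = [], 0
        for sz in sizes:
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + sz)
            outs.append(getslice(g, tuple(sl)))
            start += sz
        return tuple(outs)

    return _make(data, tensors, backward)


def getslice(x, slices):
    x = astensor(x)
    data = x.data[slices]
    orig_shape = x.shape

    def backward(g):
        return (scatter(g, slices, orig_shape),)

    return _make(data, (x,), backward)


def scatter(g, slices, shape):
    """Place ``g`` into a zero array of ``shape`` at ``slices``."""
    g = astensor(g)
    data = np.zeros(shape, dtype=g.dtype)
    data[slices] = g.data

    def backward(gg):
        return (getslice(gg, slices),)

    return _make(data, (g,), backward)


def batchnorm(x, gamma, beta, mean, var, batch_stats, eps=1e-5):
    """Fused batch normalization over (batch, *spatial) per channel.

    ``mean``/``var`` are per-channel arrays (batch statistics when
    ``batch_stats`` is true, running statistics otherwise).  The backward
    pass is hand-fused for speed and is first-order only; nothing in this
    package differentiates twice through batch norm (the critics, which the
    gradient penalty double-differentiates, contain none).
    """
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    axes = (0,) + tuple(range(2, x.ndim))
    cshape = (1, x.shape[1]) + (1,) * (x.ndim - 2)
    xd = x.data
    inv = 1.0 / np.sqrt(var.reshape(cshape) + eps)
    xhat = (xd - mean.reshape(cshape)) * inv
    gdat = gamma.data.reshape(cshape)
    data = xhat * gdat + beta.data.reshape(cshape)

    def backward(g):
        gd = g.data
        dgamma = (gd * xhat).sum(axis=axes)
        dbeta = gd.sum(axis=axes)
        if batch_stats:
            m = float(np.prod([xd.shape[a] for a in axes]))
            dx = (gdat * inv) * (gd - dbeta.reshape(cshape) / m
                                 - xhat * (dgamma.reshape(cshape) / m))
        else:
            dx = gd * (gdat * inv)
        return Tensor(dx), Tensor(dgamma), Tensor(dbeta)

    return _make(data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# convolution primitives (N spatial dims, valid padding handled internally)
# ---------------------------------------------------------------------------

def _norm_tuple(v, n):
    return tuple(v) if isinstance(v, (tuple, list)) else (int(v),) * n


def _out_spatial(in_sp, k, s, p):
    return tuple((i + 2 * pi - ki) // si + 1 for i, ki, si, pi in zip(in_sp, k, s, p))


def _pad_cl(xt, pad):
    """Pad the spatial axes of a channels-last array."""
    if not any(pad):
        return xt
    width = [(0, 0)] + [(pi, pi) for pi in pad] + [(0, 0)]
    return np.pad(xt, width)


def _offset_slice(idx, s, out_sp):
    """Spatial slices selecting x[k + s*o] for one kernel offset."""
    return tuple(slice(ki, ki + si * oi, si)
                 for ki, si, oi in zip(idx, s, out_sp))


def _conv_fwd(x, w, stride, pad):
    # channels-last accumulation over kernel offsets: each offset is one
    # large matmul on a strided view, avoiding the k^d im2col blow-up
    nd = w.ndim - 2
    k = w.shape[2:]
    s, p = _norm_tuple(stride, nd), _norm_tuple(pad, nd)
    out_sp = _out_spatial(x.shape[2:], k, s, p)
    xt = _pad_cl(np.moveaxis(x, 1, -1), p)
    y = np.zeros((x.shape[0],) + out_sp + (w.shape[0],), dtype=x.dtype)
    for idx in np.ndindex(*k):
        wk = np.ascontiguousarray(w[(slice(None), slice(None)) + idx].T)
        xsl = xt[(slice(None),) + _offset_slice(idx, s, out_sp) + (slice(None),)]
        y += xsl @ wk
    return np.ascontiguousarray(np.moveaxis(y, -1, 1))


def _conv_wgrad(x, g, stride, pad, kshape):
    nd = len(kshape)
    s, p = _norm_tuple(stride, nd), _norm_tuple(pad, nd)
    out_sp = g.shape[2:]
    xt = _pad_cl(np.moveaxis(x, 1, -1), p)
    gmove = np.ascontiguousarray(np.moveaxis(g, 1, -1))  # (B, *out, Cout)
    lead = tuple(range(nd + 1))
    dw = np.empty((g.shape[1], x.shape[1]) + tuple(kshape), dtype=x.dtype)
    for idx in np.ndindex(*kshape):
        xsl = xt[(slice(None),) + _offset_slice(idx, s, out_sp) + (slice(None),)]
        dw[(slice(None), slice(None)) + idx] = np.tensordot(
            gmove, xsl, axes=(lead, lead))
    return dw


def _conv_igrad(g, w, stride, pad, in_spatial):
    # one GEMM produces all kernel-offset contributions; the scatter-add is
    # grouped by stride parity so each accumulation hits contiguous runs
    nd = w.ndim - 2
    k = w.shape[2:]
    s, p = _norm_tuple(stride, nd), _norm_tuple(pad, nd)
    B, Cout = g.shape[:2]
    Cin = w.shape[1]
    out_sp = g.shape[2:]
    padded = tuple(i + 2 * pi for i, pi in zip(in_spatial, p))
    gmove = np.ascontiguousarray(np.moveaxis(g, 1, -1))  # (B, *out, Cout)
    worder = (0,) + tuple(range(2, 2 + nd)) + (1,)
    wmat = np.ascontiguousarray(w.transpose(worder)).reshape(Cout, -1)
    cols = (gmove.reshape(-1, Cout) @ wmat).reshape(
        (B,) + tuple(out_sp) + tuple(k) + (Cin,))
    dxp = np.zeros((B,) + padded + (Cin,), dtype=g.dtype)  # channels last
    for parity in np.ndindex(*s):
        sub = dxp[(slice(None),) + tuple(
            slice(r, None, si) for r, si in zip(parity, s)) + (slice(None),)]
        buf = np.zeros(sub.shape, dtype=g.dtype)
        hit = False
        for idx in np.ndindex(*k):
            if any(ki % si != ri for ki, si, ri in zip(idx, s, parity)):
                continue
            q = tuple(ki // si for ki, si in zip(idx, s))
            tgt = (slice(None),) + tuple(
                slice(qi, qi + oi) for qi, oi in zip(q, out_sp)) + (slice(None),)
            buf[tgt] += cols[(slice(None),) + (slice(None),) * nd + idx
                             + (slice(None),)]
            hit = True
        if hit:
            sub += buf
    core = (slice(None),) + tuple(
        slice(pi, pi + i) for pi, i in zip(p, in_spatial)) + (slice(None),)
    return np.ascontiguousarray(np.moveaxis(dxp[core], -1, 1))


def conv(x, w, stride=1, pad=0):
    """N-d strided cross-correlation: x (B,Cin,*S), w (Cout,Cin,*K)."""
    x, w = astensor(x), astensor(w)
    data = _conv_fwd(x.data, w.data, stride, pad)
    in_sp = x.shape[2:]

    def backward(g):
        gx = conv_input_grad(g, w, stride, pad, in_sp) if x.requires_grad else None
        gw = conv_weight_grad(x, g, stride, pad, w.shape[2:]) \
            if w.requires_grad else None
        return gx, gw

    return _make(data, (x, w), backward)


def conv_input_grad(g, w, stride, pad, in_spatial):
    """Adjoint of ``conv`` w.r.t. its input; also the transposed convolution."""
    g, w = astensor(g), astensor(w)
    data = _conv_igrad(g.data, w.data, stride, pad, tuple(in_spatial))

    def backward(gg):
        dg = conv(gg, w, stride, pad) if g.requires_grad else None
        dw = conv_weight_grad(gg, g, stride, pad, w.shape[2:]) \
            if w.requires_grad else None
        return dg, dw

    return _make(data, (g, w), backward)


def conv_weight_grad(x, g, stride, pad, kshape):
    """Adjoint of ``conv`` w.r.t. the kernel."""
    x, g = astensor(x), astensor(g)
    data = _conv_wgrad(x.data, g.data, stride, pad, tuple(kshape))
    in_sp = x.shape[2:]

    def backward(gu):
        dx = conv_input_grad(g, gu, stride, pad, in_sp) if x.requires_grad else None
        dg = conv(x, gu, stride, pad) if g.requires_grad else None
        return dx, dg

    return _make(data, (x, g), backward)


# ---------------------------------------------------------------------------
# graph traversal
# ---------------------------------------------------------------------------

def _topo(root):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def grad(output, inputs, grad_output=None, create_graph=False):
    """Gradients of a scalar (or seeded) ``output`` w.r.t. ``inputs``.

    Returns a list aligned with ``inputs``; entries are ``None`` where the
    output does not depend on the input.  With ``create_graph=True`` the
    returned gradients are themselves differentiable.
    """
    if grad_output is None:
        if output.data.size != 1:
            raise ValueError("grad() needs a scalar output or an explicit seed")
        grad_output = Tensor(np.ones_like(output.data))
    grads = {id(output): astensor(grad_output)}

    def run():
        for node in reversed(_topo(output)):
            g = grads.get(id(node))
            if g is None or node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = add(grads[id(p)], pg)
                else:
                    grads[id(p)] = pg
        return [grads.get(id(t)) for t in inputs]

    if create_graph:
        return run()
    with no_grad():
        out = run()
    return [None if g is None else g.detach() for g in out]
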