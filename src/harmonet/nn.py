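"""Network building blocks: U-Net generators, Markovian patch critics, RMSProp.

Everything runs on the NumPy autodiff engine in :mod:`harmonet.autodiff`.
Networks are dimension-generic (2D slices or 3D volumes); all tensors are
channel-first, ``(batch, channel, *spatial)``, float32.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: tracks parameters and train/eval mode."""

    def __init__(self):
        self._params = {}
        self._modules = {}
        self.training = True

    def register(self, name, array):
        t = Tensor(np.asarray(array, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        return t

    def add_module(self, name, mod):
        self._modules[name] = mod
        return mod

    def parameters(self):
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix=""):
        for k, v in self._params.items():
            yield prefix + k, v
        for mk, m in self._modules.items():
            yield from m.named_parameters(prefix + mk + ".")

    def train(self, mode=True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self):
        d = {k: v.data for k, v in self.named_parameters()}
        for mk, m in self._modules.items():
            for bk, bv in getattr(m, "_buffers", {}).items():
                d[f"{mk}.{bk}"] = bv
        for bk, bv in getattr(self, "_buffers", {}).items():
            d[bk] = bv
        return d

    def load_state_dict(self, d):
        for k, v in self.named_parameters():
            v.data[...] = d[k]
        mods = [("", self)] + [(mk + ".", m) for mk, m in self._modules.items()]
        for pre, m in mods:
            for bk in getattr(m, "_buffers", {}):
                m._buffers[bk][...] = d[pre + bk]

    def __call__(self, x):
        return self.forward(x)


class Conv(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, rng=None, w_scale=None):
        super().__init__()
        nd = len(kernel) if isinstance(kernel, (tuple, list)) else None
        if nd is None:
            raise ValueError("kernel must be a tuple, one entry per spatial dim")
        self.stride, self.pad, self.kernel = stride, pad, tuple(kernel)
        rng = rng or np.random.default_rng()
        fan_in = in_ch * int(np.prod(kernel))
        scale = w_scale if w_scale is not None else np.sqrt(2.0 / fan_in)
        self.w = self.register("w", rng.normal(0.0, scale, (out_ch, in_ch) + self.kernel))
        self.b = self.register("b", np.zeros(out_ch))

    def forward(self, x):
        y = ad.conv(x, self.w, stride=self.stride, pad=self.pad)
        bshape = (1, self.b.shape[0]) + (1,) * (y.ndim - 2)
        return y + ad.reshape(self.b, bshape)


class ConvTranspose(Module):
    """Transposed convolution via the conv input-gradient primitive."""

    def __init__(self, in_ch, out_ch, kernel, stride, pad, output_padding=0,
                 rng=None):
        super().__init__()
        self.stride = _tup(stride, len(kernel))
        self.pad = _tup(pad, len(kernel))
        self.output_padding = _tup(output_padding, len(kernel))
        self.kernel = tuple(kernel)
        rng = rng or np.random.default_rng()
        fan_in = in_ch * int(np.prod(kernel))
        # weight layout matches conv with in_ch playing the Cout role
        self.w = self.register(
            "w", rng.normal(0.0, np.sqrt(2.0 / fan_in), (in_ch, out_ch) + self.kernel))
        self.b = self.register("b", np.zeros(out_ch))

    def out_spatial(self, in_spatial):
        return tuple(
            s * (i - 1) + k - 2 * p + op
            for i, k, s, p, op in zip(in_spatial, self.kernel, self.stride,
                                      self.pad, self.output_padding)
        )

    def forward(self, x):
        out_sp = self.out_spatial(x.shape[2:])
        y = ad.conv_input_grad(x, self.w, self.stride, self.pad, out_sp)
        bshape = (1, self.b.shape[0]) + (1,) * (y.ndim - 2)
        return y + ad.reshape(self.b, bshape)


class BatchNorm(Module):
    """Batch normalization over (batch, *spatial), per channel."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = self.register("gamma", np.ones(channels))
        self.beta = self.register("beta", np.zeros(channels))
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }

    def forward(self, x):
        x = ad.astensor(x)
        axes = (0,) + tuple(range(2, x.ndim))
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        return ad.batchnorm(x, self.gamma, self.beta, mu, var,
                            batch_stats=self.training, eps=self.eps)


def _tup(v, n):
    return tuple(v) if isinstance(v, (tuple, list)) else (int(v),) * n


# ---------------------------------------------------------------------------
# U-Net generator
# ---------------------------------------------------------------------------

class UNetGenerator(Module):
    """Encoder/decoder with stride-2 convolutions and concatenation skips.

    The output head is a linear convolution added to the input (residual),
    so an untrained network is close to the identity map -- appropriate for
    harmonization, where the learned transform is a modest correction of an
    already-valid metric map.  Outputs are unbounded during training; the
    caller clips to the metric range at inference.
    """

    def __init__(self, ndim=2, depth=3, base_channels=16, in_channels=1,
                 kernel_size=5, lrelu_slope=0.2, batch_norm=True,
                 skip_connections=True, residual=True, seed=0):
        super().__init__()
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.ndim, self.depth = ndim, depth
        self.skip_connections = skip_connections
        self.residual = residual
        self.lrelu_slope = lrelu_slope
        rng = np.random.default_rng(seed)
        k = (kernel_size,) * ndim
        pad = kernel_size // 2

        chans = [base_channels * 2 ** i for i in range(depth)]
        self.enc, self.enc_bn = [], []
        c_in = in_channels
        for i, c in enumerate(chans):
            self.enc.append(self.add_module(f"enc{i}", Conv(c_in, c, k, 2, pad, rng)))
            self.enc_bn.append(self.add_module(f"enc_bn{i}", BatchNorm(c)) if batch_norm else None)
            c_in = c

        self.dec, self.dec_bn = [], []
        self.decoder_in_channels = []
        for i in range(depth - 1, -1, -1):
            c_out = chans[i - 1] if i > 0 else base_channels
            self.decoder_in_channels.append(c_in)
            self.dec.append(self.add_module(
                f"dec{i}", ConvTranspose(c_in, c_out, k, 2, pad, output_padding=1, rng=rng)))
            self.dec_bn.append(self.add_module(f"dec_bn{i}", BatchNorm(c_out)) if batch_norm else None)
            c_in = c_out + (chans[i - 1] if (skip_connections and i > 0) else 0)
        # small-scale init keeps the residual head near the identity map;
        # the head is a cheap 3^nd correction layer on top of the U-Net
        self.head = self.add_module(
            "head", Conv(c_in, in_channels, (3,) * ndim, 1, 1, rng, w_scale=1e-4))

    def check_input(self, spatial):
        f = 2 ** self.depth
        for s in spatial:
            if s % f != 0:
                raise ValueError(
                    f"spatial dims {tuple(spatial)} must be divisible by "
                    f"2**depth = {f}; reduce depth or pad the input")

    def forward(self, x):
        x = ad.astensor(x)
        self.check_input(x.shape[2:])
        feats = []
        h = x
        for convl, bn in zip(self.enc, self.enc_bn):
            h = ad.leaky_relu(convl(h), self.lrelu_slope)
            if bn is not None:
                h = bn(h)
            feats.append(h)
        for j, (deconv, bn) in enumerate(zip(self.dec, self.dec_bn)):
            h = ad.leaky_relu(deconv(h), self.lrelu_slope)
            if bn is not None:
                h = bn(h)
            enc_level = self.depth - 2 - j  # encoder feature with matching size
            if self.skip_connections and enc_level >= 0:
                h = ad.concat([h, feats[enc_level]], axis=1)
        out = self.head(h)
        return (x + out) if self.residual else out


# ---------------------------------------------------------------------------
# Markovian (patch) discriminator
# ---------------------------------------------------------------------------

#: default layer plans: (kernel, stride, out_channels); analytic receptive
#: fields are exactly 30x30 (2D) and 30x30x8 (3D).
PLAN_2D = [((4, 4), (2, 2), 16), ((4, 4), (2, 2), 32),
           ((4, 4), (1, 1), 64), ((3, 3), (1, 1), 1)]
PLAN_3D = [((4, 4, 3), (2, 2, 1), 16), ((4, 4, 3), (2, 2, 1), 32),
           ((4, 4, 3), (1, 1, 1), 64), ((3, 3, 2), (1, 1, 1), 1)]


def analytic_receptive_field(plan):
    """Per-side receptive field from kernel/stride arithmetic."""
    nd = len(plan[0][0])
    r = [1] * nd
    j = [1] * nd
    for kernel, stride, _ in plan:
        for d in range(nd):
            r[d] += (kernel[d] - 1) * j[d]
            j[d] *= stride[d]
    return tuple(r)


class PatchDiscriminator(Module):
    """Fully convolutional critic scoring overlapping local patches.

    No batch normalization anywhere; LeakyReLU after every layer except the
    final scoring convolution.  ``forward`` returns the mean of the score
    map (the overall critic output); ``score_map`` exposes the spatial map.
    The analytic receptive field of the plan is verified against
    ``target_receptive_field`` at construction.
    """

    def __init__(self, ndim=2, plan=None, in_channels=1,
                 target_receptive_field=None, lrelu_slope=0.2, seed=0):
        super().__init__()
        if plan is None:
            plan = PLAN_2D if ndim == 2 else PLAN_3D
        if target_receptive_field is None:
            target_receptive_field = (30, 30) if ndim == 2 else (30, 30, 8)
        self.plan = plan
        self.lrelu_slope = lrelu_slope
        rf = analytic_receptive_field(plan)
        if tuple(rf) != tuple(target_receptive_field):
            raise ValueError(
                f"layer plan has receptive field {tuple(rf)}, required "
                f"{tuple(target_receptive_field)}")
        self.receptive_field_target = tuple(target_receptive_field)
        rng = np.random.default_rng(seed)
        self.layers = []
        c_in = in_channels
        for i, (kernel, stride, c_out) in enumerate(plan):
            self.layers.append(self.add_module(
                f"conv{i}", Conv(c_in, c_out, kernel, stride, 0, rng)))
            c_in = c_out

    def score_map(self, x):
        h = ad.astensor(x)
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i < len(self.layers) - 1:
                h = ad.leaky_relu(h, self.lrelu_slope)
        return h

    def forward(self, x):
        return ad.tmean(self.score_map(x))

    def min_input(self):
        """Smallest input spatial size producing a 1x..x1 score map."""
        nd = len(self.plan[0][0])
        size = [1] * nd
        for kernel, stride, _ in reversed(self.plan):
            size = [stride[d] * (size[d] - 1) + kernel[d] for d in range(nd)]
        return tuple(size)


def receptive_field(disc, input_spatial=None, seed=0):
    """Empirical per-side receptive field of a patch discriminator.

    Backpropagates a unit seed from one central score-map unit and measures
    the bounding box of nonzero input sensitivity.
    """
    nd = len(disc.plan[0][0])
    if input_spatial is None:
        input_spatial = tuple(3 * m for m in disc.min_input())
    rng = np.random.default_rng(seed)
    x = Tensor(rng.uniform(0.1, 1.0, (1, 1) + tuple(input_spatial)).astype(np.float32),
               requires_grad=True)
    smap = disc.score_map(x)
    seed_arr = np.zeros_like(smap.data)
    center = tuple(s // 2 for s in smap.shape)
    seed_arr[center] = 1.0
    (gx,) = ad.grad(smap, [x], grad_output=Tensor(seed_arr))
    nz = np.argwhere(np.abs(gx.data[0, 0]) > 1e-12)
    if nz.size == 0:
        return (0,) * nd
    return tuple(int(nz[:, d].max() - nz[:, d].min() + 1) for d in range(nd))


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class RMSProp:
    """RMSProp with running mean-square gradient normalization."""

    def __init__(self, params, lr=5e-5, alpha=0.99, eps=1e-8):
        self.params = list(params)
        self.lr, self.alpha, self.eps = lr, alpha, eps
        self.sq = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads):
        for p, s, g in zip(self.params, self.sq, grads):
            if g is None:
                continue
            gd = g.data if isinstance(g, Tensor) else g
            s *= self.alpha
            s += (1 - self.alpha) * gd * gd
            p.data -= self.lr * gd / (np.sqrt(s) + self.eps)
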