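"""Dual-GAN harmonization: cycle-consistent Wasserstein translation of
metric maps between two sites.

Two U-Net generators (G_A: site1 -> site2, G_B: site2 -> site1) are trained
against two Markovian patch critics with the Wasserstein objective plus a
gradient penalty, and an L1 cycle-reconstruction loss weighted by
``lambda_recon``:

    L = L_adv + lambda * L_recon,
    L_adv = E[D(real)] - E[D(fake)] - lambda_gp * E[(||grad D(xhat)|| - 1)^2]

with xhat sampled uniformly on the segment between paired real and generated
samples.  Training is unpaired: each update samples independent batches from
both cohorts.  In 2D mode, training samples are slices of the configured
orientation pooled over subjects; slices with almost no mask coverage are
excluded, and at inference out-of-mask voxels are restored from the input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .metric_io import SiteDataset, extract_slices, restack_slices

log = logging.getLogger("harmonet")


@dataclass
class GeneratorConfig:
    kernel_style: str = "2D"          # "2D" | "3D"
    orientation: str = "axial"        # 2D only
    kernel_size: int = 5
    stride: int = 2
    depth: int = 3
    base_channels: int = 16
    lrelu_slope: float = 0.2
    batch_norm: bool = True
    skip_connections: bool = True
    residual_output: bool = True      # linear head added to the input

    @property
    def ndim(self):
        return 2 if self.kernel_style.upper() == "2D" else 3


@dataclass
class DiscriminatorConfig:
    kernel_style: str = "2D"
    plan: list = None                 # [(kernel, stride, channels), ...]
    target_receptive_field: tuple = None
    lrelu_slope: float = 0.2

    @property
    def ndim(self):
        return 2 if self.kernel_style.upper() == "2D" else 3

    def resolved_target(self):
        if self.target_receptive_field is not None:
            return tuple(self.target_receptive_field)
        return (30, 30) if self.ndim == 2 else (30, 30, 8)


@dataclass
class TrainConfig:
    lambda_recon: float = 20.0
    lambda_gp: float = 10.0
    epochs: int = 300
    learning_rate: float = 5e-5    # critic learning rate
    gen_learning_rate: float = None  # defaults to learning_rate / 4
    batch_size: int = 16
    critic_steps: int = 5
    critic_warmup: int = 30           # critic-only iterations before the
                                      # generators move (critics first)
    lr_decay: bool = True             # linear decay over the 2nd half of training
    gen_ema_decay: float = 0.98      # Polyak average of generator weights
                                      # used at inference (0 disables)
    seed: int = 0
    min_mask_coverage: float = 0.01   # background-slice exclusion threshold

    def __post_init__(self):
        if self.lambda_recon < 0 or self.lambda_gp < 0:
            raise ValueError("loss weights must be >= 0")
        if min(self.epochs, self.batch_size, self.critic_steps) < 1:
            raise ValueError("epochs, batch_size and critic_steps must be >= 1")


@dataclass
class LossHistory:
    adversarial: list = field(default_factory=list)   # E[D(real)] - E[D(fake)]
    reconstruction: list = field(default_factory=list)
    gradient_penalty: list = field(default_factory=list)
    epoch: list = field(default_factory=list)

    def epoch_mean(self, values, epoch):
        vals = [v for v, e in zip(values, self.epoch) if e == epoch]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class HarmonizationModel:
    G_A: nn.UNetGenerator             # site1 -> site2
    G_B: nn.UNetGenerator             # site2 -> site1
    D_A: nn.PatchDiscriminator        # judges the site-2 domain
    D_B: nn.PatchDiscriminator        # judges the site-1 domain
    gen_cfg: GeneratorConfig
    disc_cfg: DiscriminatorConfig
    train_cfg: TrainConfig
    site1: str
    site2: str
    mask: np.ndarray
    loss_history: LossHistory = field(default_factory=LossHistory)


def build_generator(config, seed=0):
    return nn.UNetGenerator(
        ndim=config.ndim, depth=config.depth, base_channels=config.base_channels,
        kernel_size=config.kernel_size, lrelu_slope=config.lrelu_slope,
        batch_norm=config.batch_norm, skip_connections=config.skip_connections,
        residual=config.residual_output, seed=seed)


def build_discriminator(config, seed=0):
    return nn.PatchDiscriminator(
        ndim=config.ndim, plan=config.plan,
        target_receptive_field=config.resolved_target(),
        lrelu_slope=config.lrelu_slope, seed=seed)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def adversarial_loss(D, real_batch, fake_batch):
    """E[D(real)] - E[D(fake)], means taken over batch and score map.

    The critic ascends this quantity; the generator descends its negation.
    Returns (loss, breakdown) with per-term values.
    """
    real_batch, fake_batch = ad.astensor(real_batch), ad.astensor(fake_batch)
    if real_batch.data.size == 0 or fake_batch.data.size == 0:
        raise ValueError("empty batch")
    d_real = D(real_batch)
    d_fake = D(fake_batch)
    loss = d_real - d_fake
    return loss, {"d_real": float(d_real.item()), "d_fake": float(d_fake.item())}


def gradient_penalty(D, real_batch, fake_batch, rng=None, alpha=None):
    """E[(||grad_xhat D(xhat)||_2 - 1)^2] on per-pair interpolates.

    ``alpha`` (per-sample, in [0,1]) can be forced for testing; otherwise it
    is drawn uniformly per real/fake pair.
    """
    real = ad.astensor(real_batch).data
    fake = ad.astensor(fake_batch).data
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must share a shape")
    b = real.shape[0]
    if alpha is None:
        rng = rng or np.random.default_rng()
        alpha = rng.uniform(0.0, 1.0, size=b)
    a = np.asarray(alpha, dtype=real.dtype).reshape((b,) + (1,) * (real.ndim - 1))
    xhat = Tensor(a * real + (1 - a) * fake, requires_grad=True)
    smap = D.score_map(xhat)
    # mean over the score map per sample, summed over the batch, so the
    # input gradient of sample i is exactly d(mean score_i)/d(xhat_i)
    score_sum = ad.tsum(smap) * (1.0 / float(np.prod(smap.shape[1:])))
    (gin,) = ad.grad(score_sum, [xhat], create_graph=True)
    axes = tuple(range(1, real.ndim))
    norms = ad.sqrt(ad.tsum(gin * gin, axis=axes) + 1e-12)
    return ad.tmean((norms - 1.0) ** 2.0)


def reconstruction_loss(x, x_recon, y, y_recon):
    """Symmetric per-element L1 cycle loss."""
    x, x_recon = ad.astensor(x), ad.astensor(x_recon)
    y, y_recon = ad.astensor(y), ad.astensor(y_recon)
    if x.shape != x_recon.shape or y.shape != y_recon.shape:
        raise ValueError("reconstruction shapes must match their originals")
    return ad.tmean(ad.absval(x - x_recon)) + ad.tmean(ad.absval(y - y_recon))


def total_loss(adv, recon, lam):
    """L = L_adv + lambda * L_recon."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if isinstance(adv, Tensor) or isinstance(recon, Tensor):
        return ad.astensor(adv) + ad.astensor(recon) * float(lam)
    return adv + lam * recon


# ---------------------------------------------------------------------------
# training data preparation
# ---------------------------------------------------------------------------

def _training_pool(dataset, gen_cfg, mask, min_cov):
    """Stack training samples: masked slices (2D) or whole volumes (3D)."""
    if gen_cfg.ndim == 2:
        mstack, _ = extract_slices(mask.astype(float), gen_cfg.orientation)
        cov = mstack.mean(axis=(1, 2))
        keep = cov >= min_cov
        samples = []
        for v in dataset.volumes:
            stack, _ = extract_slices(v, gen_cfg.orientation)
            samples.append(stack[keep])
        pool = np.concatenate(samples).astype(np.float32)[:, None]
        return pool
    vols = dataset.stack().astype(np.float32)[:, None]
    return vols


def _check_pool(pool, gen, disc):
    gen.check_input(pool.shape[2:])
    min_in = disc.min_input()
    if any(s < m for s, m in zip(pool.shape[2:], min_in)):
        raise ValueError(
            f"sample spatial size {pool.shape[2:]} smaller than the critic's "
            f"minimum input {min_in}")


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _freeze(net, frozen):
    for p in net.parameters():
        p.requires_grad = not frozen

def train(site1, site2, gen_cfg=None, disc_cfg=None, train_cfg=None, mask=None,
          epoch_callback=None):
    """Train the dual translation model on two unpaired cohorts.

    Per iteration: ``critic_steps`` updates of both critics (each maximizing
    the penalized Wasserstein objective on an independent batch), then one
    joint update of both generators (adversarial + cycle loss).  Critics are
    updated before generators.  Fully reproducible from ``train_cfg.seed``.
    """
    gen_cfg = gen_cfg or GeneratorConfig()
    disc_cfg = disc_cfg or DiscriminatorConfig(kernel_style=gen_cfg.kernel_style)
    train_cfg = train_cfg or TrainConfig()
    if len(site1) == 0 or len(site2) == 0:
        raise ValueError("both cohorts must be non-empty")
    mask = mask if mask is not None else site1.mask
    if mask is None:
        raise ValueError("a white-matter mask is required")

    rng = np.random.default_rng(train_cfg.seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=4)
    G_A = build_generator(gen_cfg, seed=int(seeds[0]))
    G_B = build_generator(gen_cfg, seed=int(seeds[1]))
    D_A = build_discriminator(disc_cfg, seed=int(seeds[2]))
    D_B = build_discriminator(disc_cfg, seed=int(seeds[3]))

    pool1 = _training_pool(site1, gen_cfg, mask, train_cfg.min_mask_coverage)
    pool2 = _training_pool(site2, gen_cfg, mask, train_cfg.min_mask_coverage)
    _check_pool(pool1, G_A, D_A)
    _check_pool(pool2, G_B, D_B)

    lr = train_cfg.learning_rate
    # the critics move faster than the generators so the Wasserstein
    # estimate stays ahead of the translation they are scoring
    gen_lr = train_cfg.gen_learning_rate
    gen_lr = lr / 4.0 if gen_lr is None else gen_lr
    opt_DA = nn.RMSProp(D_A.parameters(), lr=lr)
    opt_DB = nn.RMSProp(D_B.parameters(), lr=lr)
    gen_params = G_A.parameters() + G_B.parameters()
    opt_G = nn.RMSProp(gen_params, lr=gen_lr)

    bs = train_cfg.batch_size
    history = LossHistory()
    iters_per_epoch = max(1, int(np.ceil(max(len(pool1), len(pool2)) / bs)))
    ema = None
    if train_cfg.gen_ema_decay > 0:
        ema = [p.data.copy() for p in gen_params]

    def batch(pool):
        idx = rng.integers(0, len(pool), size=min(bs, len(pool)))
        return pool[idx]

    def critic_update(D, opt, G, pool_real, pool_src):
        x_real = batch(pool_real)
        with ad.no_grad():
            fake = G(batch(pool_src)).data
        adv, _ = adversarial_loss(D, x_real, fake)
        gp = gradient_penalty(D, x_real, fake, rng=rng)
        # critic descends -(adv) + lambda_gp * gp
        loss = total_loss(-adv, gp, train_cfg.lambda_gp)
        grads = ad.grad(loss, D.parameters())
        opt.step(grads)
        return float(adv.item()), float(gp.item())

    for _ in range(train_cfg.critic_warmup):
        critic_update(D_A, opt_DA, G_A, pool2, pool1)
        critic_update(D_B, opt_DB, G_B, pool1, pool2)

    step = 0
    for epoch in range(train_cfg.epochs):
        if train_cfg.lr_decay and train_cfg.epochs > 1:
            # constant through the first half, then linear decay to ~0
            frac = epoch / (train_cfg.epochs - 1)
            scale = 1.0 if frac <= 0.5 else max(2.0 * (1.0 - frac), 0.05)
            opt_DA.lr = opt_DB.lr = lr * scale
            opt_G.lr = gen_lr * scale
        for _ in range(iters_per_epoch):
            for _ in range(train_cfg.critic_steps):
                adv_a, gp_a = critic_update(D_A, opt_DA, G_A, pool2, pool1)
                adv_b, gp_b = critic_update(D_B, opt_DB, G_B, pool1, pool2)

            x = Tensor(batch(pool1))
            y = Tensor(batch(pool2))
            _freeze(D_A, True)
            _freeze(D_B, True)
            fake_y = G_A(x)
            fake_x = G_B(y)
            recon = reconstruction_loss(x, G_B(fake_y), y, G_A(fake_x))
            g_adv = -(D_A(fake_y) + D_B(fake_x))
            loss_G = total_loss(g_adv, recon, train_cfg.lambda_recon)
            _freeze(D_A, False)
            _freeze(D_B, False)
            if not np.isfinite(loss_G.item()):
                raise FloatingPointError(
                    f"non-finite generator loss at iteration {step}")
            grads = ad.grad(loss_G, gen_params)
            opt_G.step(grads)
            if ema is not None:
                d = train_cfg.gen_ema_decay
                for e, p in zip(ema, gen_params):
                    e *= d
                    e += (1 - d) * p.data

            history.adversarial.append(0.5 * (adv_a + adv_b))
            history.reconstruction.append(float(recon.item()))
            history.gradient_penalty.append(0.5 * (gp_a + gp_b))
            history.epoch.append(epoch)
            step += 1
        log.info("epoch %d: adv=%.4f recon=%.4f", epoch,
                 history.epoch_mean(history.adversarial, epoch),
                 history.epoch_mean(history.reconstruction, epoch))
        if epoch_callback is not None:
            epoch_callback(epoch, G_A, G_B)

    if ema is not None:
        # inference uses the Polyak average, which sits at the center of the
        # adversarial limit cycle rather than wherever the last step landed
        for e, p in zip(ema, gen_params):
            p.data[...] = e

    model = HarmonizationModel(G_A.eval(), G_B.eval(), D_A.eval(), D_B.eval(),
                               gen_cfg, disc_cfg, train_cfg,
                               site1.site, site2.site, np.asarray(mask, bool),
                               history)
    return model


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

DIRECTIONS = ("1to2", "2to1")


def harmonize(model, volume, direction):
    """Translate one volume across sites; geometry and covariates preserved.

    2D models translate each slice of the configured orientation and
    restack; 3D models translate the whole volume.  Outputs are clipped to
    the metric's valid range and out-of-mask voxels are restored from the
    input.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    G = model.G_A if direction == "1to2" else model.G_B
    if model.mask.shape != volume.shape:
        raise ValueError("model/volume geometry mismatch")
    G.eval()
    if model.gen_cfg.ndim == 2:
        stack, meta = extract_slices(volume, model.gen_cfg.orientation)
        with ad.no_grad():
            out = G(Tensor(stack.astype(np.float32)[:, None])).data[:, 0]
        data = restack_slices(out.astype(float), meta)
    else:
        with ad.no_grad():
            data = G(Tensor(volume.data.astype(np.float32)[None, None])).data[0, 0]
        data = data.astype(float)
    lo, hi = volume.valid_range()
    data = np.clip(data, lo, hi)
    data[~model.mask] = volume.data[~model.mask]
    return volume.with_data(data)


def harmonize_dataset(model, dataset, direction):
    return SiteDataset(dataset.site,
                       [harmonize(model, v, direction) for v in dataset.volumes],
                       dataset.mask)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model, out_dir):
    """Persist weights (npz per network) plus a JSON config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("G_A", "G_B", "D_A", "D_B"):
        np.savez(out / f"{name}.npz", **getattr(model, name).state_dict())
    cfg = {
        "gen_cfg": asdict(model.gen_cfg),
        "disc_cfg": asdict(model.disc_cfg),
        "train_cfg": asdict(model.train_cfg),
        "site1": model.site1, "site2": model.site2,
    }
    (out / "config.json").write_text(json.dumps(cfg, indent=2))
    np.savez(out / "mask.npz", mask=model.mask)
    hist = model.loss_history
    np.savetxt(out / "loss_history.csv",
               np.column_stack([hist.epoch, hist.adversarial,
                                hist.reconstruction, hist.gradient_penalty]),
               delimiter=",", header="epoch,adversarial,reconstruction,gp",
               comments="")


def load_model(model_dir):
    d = Path(model_dir)
    cfg = json.loads((d / "config.json").read_text())
    gen_cfg = GeneratorConfig(**cfg["gen_cfg"])
    disc_cfg = DiscriminatorConfig(**cfg["disc_cfg"])
    disc_cfg.plan = ([tuple(map(tuple, p[:2])) + (p[2],) for p in disc_cfg.plan]
                     if disc_cfg.plan else None)
    train_cfg = TrainConfig(**cfg["train_cfg"])
    nets = {}
    for name in ("G_A", "G_B", "D_A", "D_B"):
        net = build_generator(gen_cfg) if name.startswith("G") else \
            build_discriminator(disc_cfg)
        with np.load(d / f"{name}.npz") as z:
            net.load_state_dict(dict(z.items()))
        nets[name] = net.eval()
    mask = np.load(d / "mask.npz")["mask"]
    return HarmonizationModel(nets["G_A"], nets["G_B"], nets["D_A"], nets["D_B"],
                              gen_cfg, disc_cfg, train_cfg,
                              cfg["site1"], cfg["site2"], mask)
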