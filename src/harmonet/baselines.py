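"""Conventional harmonization baselines: scaling and voxel-level ComBat.

Three comparators are provided:

* global scaling   - one factor equalizing whole-white-matter cohort means;
* voxel scaling    - a per-voxel factor equalizing per-voxel group means;
* ComBat           - per-voxel location/scale (gamma/delta) batch model with
                     age and sex covariates and optional parametric
                     empirical-Bayes shrinkage.

Scaling factors always map the TARGET site onto the REFERENCE site.  ComBat
supports a reference-site mode in which the reference cohort defines the
standardization (and passes through unchanged), matching a harmonization
protocol where one site is the anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .metric_io import SiteDataset

log = logging.getLogger("harmonet")


@dataclass
class ScalingModel:
    mode: str                      # "global" | "voxel"
    factor: object                 # scalar or 3D array (1 outside mask)
    mask: np.ndarray
    reference_site: str
    target_site: str
    degenerate_voxels: np.ndarray = None  # indices (n, 3) of passed-through voxels

    def __post_init__(self):
        if self.mode not in ("global", "voxel"):
            raise ValueError("mode must be 'global' or 'voxel'")
        f = np.asarray(self.factor)
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("scaling factors must be finite and > 0")


@dataclass
class CombatModel:
    """Fitted location/scale batch model.

    ``delta`` entries are multiplicative scale factors on the standard
    deviation (the square root of the location/scale model's variance
    parameter).  ``gamma``/``delta`` rows follow ``sites`` order.
    """

    sites: list
    grand_mean: np.ndarray          # alpha(v), masked voxels flattened
    beta_cov: np.ndarray            # (2, V): age, sex-male coefficients
    sigma: np.ndarray               # pooled residual SD per voxel
    gamma: np.ndarray               # (n_sites, V) additive site parameters
    delta: np.ndarray               # (n_sites, V) multiplicative (SD) factors
    mask: np.ndarray
    voxel_index: tuple              # flat index of fitted voxels inside mask
    degenerate_voxels: np.ndarray
    empirical_bayes: bool
    reference_site: str = None

    def site_row(self, site):
        if site not in self.sites:
            raise ValueError(f"site {site!r} was not seen during fitting; "
                             f"known sites: {self.sites}")
        return self.sites.index(site)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def _check_geometry(target, reference, mask):
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    shapes = {target.volumes[0].shape, reference.volumes[0].shape, mask.shape}
    if len(shapes) != 1:
        raise ValueError(f"datasets/mask geometry mismatch: {shapes}")
    return mask


def fit_global_scaling(target, reference, mask):
    """One factor: reference cohort WM mean over target cohort WM mean."""
    mask = _check_geometry(target, reference, mask)
    t_mean = target.stack()[:, mask].mean()
    r_mean = reference.stack()[:, mask].mean()
    if t_mean == 0:
        raise ValueError("target cohort mean over the mask is zero")
    return ScalingModel("global", float(r_mean / t_mean), mask,
                        reference.site, target.site)


def fit_voxel_scaling(target, reference, mask):
    """Per-voxel factor: ratio of per-voxel group means inside the mask.

    Voxels whose target group mean is zero cannot be scaled; they pass
    through with factor 1 and are reported in ``degenerate_voxels``.
    """
    mask = _check_geometry(target, reference, mask)
    t_mean = target.stack().mean(axis=0)
    r_mean = reference.stack().mean(axis=0)
    factor = np.ones(mask.shape)
    valid = mask & (t_mean != 0)
    factor[valid] = r_mean[valid] / t_mean[valid]
    degen = np.argwhere(mask & (t_mean == 0))
    if len(degen):
        log.warning("voxel scaling: %d masked voxels with zero target mean "
                    "pass through unchanged", len(degen))
    return ScalingModel("voxel", factor, mask, reference.site, target.site,
                        degenerate_voxels=degen)


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------

def _covariate_matrix(ages, sexes):
    return np.column_stack([np.asarray(ages, dtype=float),
                            (np.asarray(sexes) == "male").astype(float)])


def _eb_priors(gamma_hat, delta_hat_var):
    g_bar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1)
    m, s2 = delta_hat_var.mean(), delta_hat_var.var(ddof=1)
    a = (2 * s2 + m ** 2) / s2
    b = (m * s2 + m ** 3) / s2
    return g_bar, t2, a, b


def _eb_iterate(s_site, gamma_hat, delta_hat_var, conv=1e-4, max_iter=100):
    """Parametric empirical-Bayes shrinkage (normal / inverse-gamma priors)."""
    g_bar, t2, a, b = _eb_priors(gamma_hat, delta_hat_var)
    n = s_site.shape[0]
    g_old, d_old = gamma_hat.copy(), delta_hat_var.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * gamma_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((s_site - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1)
        change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                     np.max(np.abs(d_new - d_old) / d_old))
        g_old, d_old = g_new, d_new
        if change <= conv:
            break
    return g_old, d_old


def fit_combat(datasets, mask, empirical_bayes=True, reference_site=None):
    """Fit the per-voxel location/scale batch model on one or more cohorts.

    Covariates are each subject's age (weeks) and sex.  With
    ``reference_site`` set, the standardization (grand mean, covariate fit,
    residual scale) is anchored on that site and its data are left unchanged
    by ``apply_harmonization``.
    """
    if isinstance(datasets, SiteDataset):
        datasets = [datasets]
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    sites = [ds.site for ds in datasets]
    if len(set(sites)) != len(sites):
        raise ValueError("duplicate site labels")
    for ds in datasets:
        if len(ds) < 3 and len(datasets) > 1:
            raise ValueError(f"site {ds.site!r} has {len(ds)} subjects; "
                             "ComBat needs at least 3 per site")
    if reference_site is not None and reference_site not in sites:
        raise ValueError(f"reference site {reference_site!r} not among {sites}")

    Y = np.concatenate([ds.stack()[:, mask] for ds in datasets])  # (n, V)
    n_per = [len(ds) for ds in datasets]
    n, V = Y.shape
    site_of = np.repeat(np.arange(len(sites)), n_per)
    ages = np.concatenate([ds.ages() for ds in datasets])
    sexes = np.concatenate([np.asarray(ds.sexes()) for ds in datasets])
    Xcov = _covariate_matrix(ages, sexes)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), Xcov])) < 3:
        raise ValueError("covariate design (age, sex) is rank deficient")

    batch = np.zeros((n, len(sites)))
    batch[np.arange(n), site_of] = 1.0
    ref_idx = sites.index(reference_site) if reference_site is not None else None
    if ref_idx is not None:
        batch[:, ref_idx] = 1.0  # reference column doubles as the intercept
    X = np.column_stack([batch, Xcov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (covariate "
                         "confounded with site?)")

    # degenerate voxels: zero variance within any site -> pass through
    flat_ok = np.ones(V, dtype=bool)
    for i in range(len(sites)):
        sub = Y[site_of == i]
        if len(sub) > 1:
            flat_ok &= sub.var(axis=0) > 0
    degen = np.argwhere(mask)[~flat_ok]
    if len(degen):
        log.warning("ComBat: %d masked voxels have zero within-site variance "
                    "and pass through unchanged", len(degen))
    Yf = Y[:, flat_ok]

    B = np.linalg.lstsq(X, Yf, rcond=None)[0]           # (p, Vf)
    n_sites = len(sites)
    if ref_idx is not None:
        grand = B[ref_idx]
        resid_ref = Yf[site_of == ref_idx] - X[site_of == ref_idx] @ B
        var_pooled = (resid_ref ** 2).mean(axis=0)
    else:
        grand = (np.array(n_per) / n) @ B[:n_sites]
        var_pooled = ((Yf - X @ B) ** 2).mean(axis=0)
    if np.any(var_pooled <= 0):
        bad = np.argwhere(mask)[flat_ok][var_pooled <= 0]
        degen = np.vstack([degen, bad]) if len(degen) else bad
        keep = var_pooled > 0
        idx_ok = np.flatnonzero(flat_ok)[keep]
        flat_ok = np.zeros(V, dtype=bool)
        flat_ok[idx_ok] = True
        Yf, B, grand, var_pooled = Yf[:, keep], B[:, keep], grand[keep], var_pooled[keep]
    beta_cov = B[n_sites:]
    sigma = np.sqrt(var_pooled)
    stand_mean = grand[None, :] + Xcov @ beta_cov
    S = (Yf - stand_mean) / sigma[None, :]

    gamma = np.zeros((n_sites, Yf.shape[1]))
    delta_var = np.ones_like(gamma)
    single_site = n_sites == 1
    for i in range(n_sites):
        s_i = S[site_of == i]
        g_hat = s_i.mean(axis=0)
        d_hat = s_i.var(axis=0, ddof=1)
        if single_site:
            g_hat, d_hat = np.zeros_like(g_hat), np.ones_like(d_hat)
        elif empirical_bayes:
            g_hat, d_hat = _eb_iterate(s_i, g_hat, d_hat)
        gamma[i], delta_var[i] = g_hat, d_hat
    if ref_idx is not None:
        gamma[ref_idx] = 0.0
        delta_var[ref_idx] = 1.0

    return CombatModel(
        sites=sites, grand_mean=grand, beta_cov=beta_cov, sigma=sigma,
        gamma=gamma, delta=np.sqrt(delta_var), mask=mask,
        voxel_index=np.flatnonzero(flat_ok), degenerate_voxels=degen,
        empirical_bayes=empirical_bayes, reference_site=reference_site)


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def apply_harmonization(model, volume):
    """Transform one volume through a fitted scaling or ComBat model."""
    if isinstance(model, ScalingModel):
        if np.asarray(model.mask).shape != volume.shape:
            raise ValueError("model/volume geometry mismatch")
        out = volume.data * model.factor if model.mode == "voxel" else \
            volume.data * float(model.factor)
    elif isinstance(model, CombatModel):
        if model.mask.shape != volume.shape:
            raise ValueError("model/volume geometry mismatch")
        row = model.site_row(volume.site)
        flat = volume.data[model.mask]
        vi = model.voxel_index
        cov = _covariate_matrix([volume.age_weeks], [volume.sex])[0]
        stand = model.grand_mean + cov @ model.beta_cov
        s = (flat[vi] - stand) / model.sigma
        s = (s - model.gamma[row]) / model.delta[row]
        flat[vi] = s * model.sigma + stand
        out = volume.data.copy()
        out[model.mask] = flat
    else:
        raise TypeError(f"unknown model type {type(model)!r}")
    lo, hi = volume.valid_range()
    n_clip = int(np.sum((out < lo) | (out > hi)))
    if n_clip:
        log.info("harmonization clipped %d voxels to [%g, %g]", n_clip, lo, hi)
    return volume.with_data(np.clip(out, lo, hi))


def harmonize_dataset(model, dataset):
    return SiteDataset(dataset.site,
                       [apply_harmonization(model, v) for v in dataset.volumes],
                       dataset.mask)
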