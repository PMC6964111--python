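"""FA-like phantom cohorts with known covariate structure and site effects.

The phantoms have no anatomy; they carry exactly the statistical structure
the harmonization problem is about: a template of white-matter FA with
elongated high-FA tracts, cohorts of subjects varying by age, sex and
subject-level offsets, and a spatially smooth, optionally nonlinear site
transformation with known ground truth, so every downstream stage can be
scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .metric_io import MetricVolume, SiteDataset

#: nominal white-matter FA used to express fractional site-effect
#: magnitudes in additive FA units
NOMINAL_WM_FA = 0.25

SITE_EFFECT_KINDS = ("identity", "multiplicative", "additive", "nonlinear", "mixed")


@dataclass
class TemplateAtlas:
    """Baseline FA map, white-matter mask and named tract tubes."""

    base_map: np.ndarray
    wm_mask: np.ndarray
    tract_masks: dict          # name -> binary array
    tract_directions: dict     # name -> unit 3-vector (principal axis)
    shape: tuple
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)

    def validate(self):
        assert self.base_map.shape == self.shape == self.wm_mask.shape
        inside = self.base_map[self.wm_mask]
        assert inside.size and inside.min() > 0 and inside.max() < 1
        assert np.all(self.base_map[~self.wm_mask] == 0)
        for name, m in self.tract_masks.items():
            assert m.shape == self.shape
            assert not np.any(m & ~self.wm_mask), f"tract {name} leaves the WM mask"
        return self


@dataclass
class CovariateModel:
    """Generative covariate structure of a neonatal FA cohort.

    Defaults emulate term-neonate cohorts scanned around 41 weeks
    postmenstrual age: a positive age effect on tract FA, a small additive
    sex effect (male-positive) on tract FA, and between-subject and voxel
    noise on white matter.
    """

    age_range_weeks: tuple = (38.3, 43.7)
    male_fraction: float = 2.0 / 3.0
    beta_age: float = 0.006      # FA per week, inside tract masks
    beta_sex: float = 0.007      # additive FA for males, inside tract masks
    subject_sd: float = 0.015    # between-subject FA SD, whole white matter
    noise_sd: float = 0.01       # within-image voxel noise SD, white matter

    def __post_init__(self):
        lo, hi = self.age_range_weeks
        if not lo < hi:
            raise ValueError("age range must satisfy low < high")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        if min(self.subject_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")

    @property
    def age_mid(self):
        return 0.5 * (self.age_range_weeks[0] + self.age_range_weeks[1])


@dataclass
class SiteEffectField:
    """Ground-truth site transformation: x -> clip((g*x + a)^gamma + noise)."""

    mult_field: np.ndarray
    add_field: np.ndarray
    gamma_nl: float = 1.0
    noise_sd_site: float = 0.0
    smoothness_mm: float = 0.0
    seed: int = 0
    kind: str = "identity"
    magnitude: float = 0.0

    def __post_init__(self):
        if np.any(self.mult_field <= 0):
            raise ValueError("multiplicative field must be strictly positive")
        if self.gamma_nl <= 0:
            raise ValueError("gamma_nl must be positive")
        if self.noise_sd_site < 0:
            raise ValueError("noise_sd_site must be >= 0")

    @property
    def shape(self):
        return self.mult_field.shape

    def is_identity(self):
        return (np.all(self.mult_field == 1.0) and np.all(self.add_field == 0.0)
                and self.gamma_nl == 1.0 and self.noise_sd_site == 0.0)

    def params_text(self):
        return (f"kind={self.kind}\nmagnitude={self.magnitude}\n"
                f"gamma_nl={self.gamma_nl}\nnoise_sd_site={self.noise_sd_site}\n"
                f"smoothness_mm={self.smoothness_mm}\nseed={self.seed}\n")


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------

def _ellipsoid(shape, scale=0.42):
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    c = [(s - 1) / 2.0 for s in shape]
    r = [max(scale * s, 1.5) for s in shape]
    d2 = sum(((g - ci) / ri) ** 2 for g, ci, ri in zip(grids, c, r))
    return d2 <= 1.0


def make_template(shape=(64, 64, 16), n_tracts=3, seed=0,
                  voxel_size_mm=(2.0, 2.0, 2.0)):
    """Build a phantom FA template with ``n_tracts`` parallel tract tubes.

    The white matter is an ellipsoid with base FA ~0.22 plus smooth spatial
    variation; tracts are tubes running along the Y axis with base FA raised
    by ~0.12, mimicking coherent fiber bundles standing out of surrounding
    white matter.
    """
    shape = tuple(int(s) for s in shape)
    if n_tracts < 1:
        raise ValueError("n_tracts must be >= 1")
    if any(s < m for s, m in zip(shape, (32, 32, 8))):
        raise ValueError(f"shape {shape} too small; minimum is (32, 32, 8)")
    rng = np.random.default_rng(seed)
    wm = _ellipsoid(shape)

    base = np.zeros(shape)
    noise = gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    noise /= max(noise[wm].std(), 1e-12)
    base[wm] = 0.22 + 0.02 * noise[wm]

    # tract tubes along Y, spread across X at mid-Z
    radius = 2.2
    x0, x1 = shape[0] * 0.25, shape[0] * 0.75
    if (x1 - x0) < (n_tracts - 1) * 2 * (radius + 1):
        raise ValueError(
            f"shape {shape} cannot hold {n_tracts} non-overlapping tracts "
            f"spaced > {2 * (radius + 1):.0f} voxels apart along X")
    xs = np.linspace(x0, x1, n_tracts) if n_tracts > 1 else [shape[0] / 2.0]
    zc = (shape[2] - 1) / 2.0
    gx, gy, gz = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    ylo, yhi = shape[1] * 0.1, shape[1] * 0.9
    tract_masks, tract_dirs = {}, {}
    for t, xc in enumerate(xs):
        tube = (((gx - xc) ** 2 + (gz - zc) ** 2) <= radius ** 2) & \
               (gy >= ylo) & (gy <= yhi)
        tube &= wm
        if not tube.any():
            raise ValueError("tract tube fell outside the white-matter mask")
        name = f"tract{t}"
        tract_masks[name] = tube
        tract_dirs[name] = np.array([0.0, 1.0, 0.0])
        base[tube] += 0.12
    base[wm] = np.clip(base[wm], 0.05, 0.95)
    return TemplateAtlas(base_map=base, wm_mask=wm, tract_masks=tract_masks,
                         tract_directions=tract_dirs, shape=shape,
                         voxel_size_mm=voxel_size_mm).validate()


# ---------------------------------------------------------------------------
# site effects
# ---------------------------------------------------------------------------

def _smooth_unit_field(shape, smoothness_mm, voxel_size_mm, rng):
    """Seeded white noise smoothed to `smoothness_mm`, standardized to
    zero mean / unit SD over the volume."""
    sigma = [max(smoothness_mm / v, 0.5) for v in voxel_size_mm]
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    f -= f.mean()
    f /= max(f.std(), 1e-12)
    return f


def make_site_effect(shape, kind, magnitude=0.0, smoothness_mm=12.0, seed=0,
                     voxel_size_mm=(2.0, 2.0, 2.0), noise_sd_site=0.0):
    """Construct a ground-truth site transformation of the given kind.

    ``magnitude`` is the fractional shift of the white-matter mean the field
    induces (0.05 = a 5% effect) for every kind; spatial variation of the
    smooth fields scales with the magnitude.
    """
    shape = tuple(int(s) for s in shape)
    if kind not in SITE_EFFECT_KINDS:
        raise ValueError(f"unknown site-effect kind {kind!r}; valid kinds: "
                         f"{SITE_EFFECT_KINDS}")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    ones, zeros = np.ones(shape), np.zeros(shape)
    if kind == "identity":
        return SiteEffectField(ones, zeros, 1.0, 0.0, smoothness_mm, seed, kind, 0.0)
    rng = np.random.default_rng(seed)
    g, a, gamma = ones.copy(), zeros.copy(), 1.0
    if kind in ("multiplicative", "mixed"):
        m = magnitude if kind == "multiplicative" else magnitude / 2.0
        z = _smooth_unit_field(shape, smoothness_mm, voxel_size_mm, rng)
        g = np.maximum((1.0 + m) + 0.3 * m * z, 0.05)
    if kind in ("additive", "mixed"):
        m = magnitude if kind == "additive" else magnitude / 2.0
        z = _smooth_unit_field(shape, smoothness_mm, voxel_size_mm, rng)
        a = NOMINAL_WM_FA * m * (1.0 + 0.3 * z)
    if kind == "nonlinear":
        # power < 1 raises FA values in (0, 1), emulating a site that
        # reads systematically higher
        gamma = 1.0 / (1.0 + magnitude)
    return SiteEffectField(g, a, gamma, noise_sd_site, smoothness_mm, seed,
                           kind, magnitude)


def apply_site_effect(volume, fld, seed=0):
    """Transform a volume through a site effect; keeps the truth attached."""
    if volume.shape != fld.shape:
        raise ValueError(
            f"volume shape {volume.shape} != field shape {fld.shape}")
    x = fld.mult_field * volume.data + fld.add_field
    x = np.clip(x, 0.0, None) ** fld.gamma_nl
    if fld.noise_sd_site > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, fld.noise_sd_site, x.shape)
    lo, hi = volume.valid_range()
    x = np.clip(x, lo, hi)
    out = volume.with_data(x)
    return replace(out, site_effect=fld)


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

def sample_subject(template, covariates, age, sex, seed=0, subject_id="sub",
                   site="site1"):
    """Draw one site-free subject from the covariate model.

    Tract FA = base + beta_age * (age - range midpoint) + beta_sex * [male];
    the subject-level offset and voxel noise act on the whole white matter.
    """
    lo, hi = covariates.age_range_weeks
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside the model range [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    data = template.base_map.copy()
    effect = covariates.beta_age * (age - covariates.age_mid)
    effect += covariates.beta_sex if sex == "male" else 0.0
    for m in template.tract_masks.values():
        data[m] += effect
    wm = template.wm_mask
    if covariates.subject_sd > 0:
        data[wm] += rng.normal(0.0, covariates.subject_sd)
    if covariates.noise_sd > 0:
        data[wm] += rng.normal(0.0, covariates.noise_sd, int(wm.sum()))
    data = np.clip(data, 0.0, 1.0)
    return MetricVolume(data=data, voxel_size_mm=template.voxel_size_mm,
                        subject_id=subject_id, site=site, age_weeks=float(age),
                        sex=sex, metric_name="FA")


def generate_cohort(template, n_subjects, covariates, fld=None, seed=0,
                    site="site1"):
    """Generate a site cohort passed through the given site effect.

    Sex follows the deterministic-proportion rule: exactly
    ``floor(n * male_fraction)`` males, order shuffled by the seed, so a
    42-subject cohort at male_fraction 2/3 reproduces a 28:14 split exactly.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = covariates.age_range_weeks
    ages = rng.uniform(lo, hi, n_subjects)
    n_male = int(np.floor(n_subjects * covariates.male_fraction))
    sexes = np.array(["male"] * n_male + ["female"] * (n_subjects - n_male))
    sexes = sexes[rng.permutation(n_subjects)]
    if fld is None:
        fld = make_site_effect(template.shape, "identity")
    vols = []
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=(n_subjects, 2))
    for i in range(n_subjects):
        v = sample_subject(template, covariates, ages[i], str(sexes[i]),
                           seed=int(child_seeds[i, 0]),
                           subject_id=f"{site}_s{i:03d}", site=site)
        vols.append(apply_site_effect(v, fld, seed=int(child_seeds[i, 1])))
    return SiteDataset(site=site, volumes=vols, mask=template.wm_mask.copy())
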