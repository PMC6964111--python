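"""Evaluation statistics: inter-site error, effect sizes, tract profiles,
age correlations and voxel-wise group tests.

RMSE is computed per held-out subject against the REFERENCE site's
voxel-wise group mean over the analysis mask and summarized by the median;
the absolute-error map is between group means.  The voxel-wise group test is
a mass-univariate two-sample comparison with either Benjamini-Hochberg FDR
(Mann-Whitney per voxel) or max-statistic permutation FWER control -- a
deliberately simplified substitute for skeleton-based TBSS, and labeled as
such in every report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metric_io import MetricVolume

NOT_TBSS = "voxelwise (not TBSS)"


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------

def absolute_error_map(site_a, site_b, mask):
    """|group-mean A - group-mean B| inside the mask, 0 outside."""
    mask = np.asarray(mask, bool)
    if site_a.volumes[0].shape != site_b.volumes[0].shape or \
            mask.shape != site_a.volumes[0].shape:
        raise ValueError("geometry mismatch between cohorts and mask")
    out = np.zeros(mask.shape)
    out[mask] = np.abs(site_a.stack()[:, mask].mean(axis=0)
                       - site_b.stack()[:, mask].mean(axis=0))
    return out


def rmse(subject, reference, mask):
    """Root mean square deviation of one subject from the reference
    cohort's per-voxel group mean, over masked voxels."""
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    if subject.shape != reference.volumes[0].shape:
        raise ValueError("geometry mismatch")
    ref_mean = reference.stack()[:, mask].mean(axis=0)
    return float(np.sqrt(np.mean((subject.data[mask] - ref_mean) ** 2)))


@dataclass
class ErrorReport:
    abs_error_map: np.ndarray
    per_subject_rmse: pd.DataFrame        # subject_id, rmse
    method: str
    fold_averaged: bool = False
    rmse_definition: str = ("per held-out subject vs the reference site's "
                            "voxel-wise group mean (re-interpretation)")
    abs_error_definition: str = "between per-site group means (re-interpretation)"

    @property
    def summary(self):
        r = self.per_subject_rmse["rmse"]
        return {"median": float(r.median()),
                "q1": float(r.quantile(0.25)), "q3": float(r.quantile(0.75))}


def error_report(target, reference, mask, method="none"):
    amap = absolute_error_map(target, reference, mask)
    rows = [{"subject_id": v.subject_id, "rmse": rmse(v, reference, mask)}
            for v in target.volumes]
    return ErrorReport(amap, pd.DataFrame(rows), method)


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------

@dataclass
class EffectSizeResult:
    d: float
    M_f: float
    M_m: float
    S_f: float
    S_m: float
    n_f: int
    n_m: int
    S_pooled: float


def cohens_d(values_f, values_m):
    """Standardized mean difference (female - male) with pooled SD.

    Sample SDs use n-1.  A zero pooled SD with equal means gives d = 0 by
    rule; with unequal means it is an error (the effect is not expressible
    on that scale).
    """
    f = np.asarray(values_f, dtype=float)
    m = np.asarray(values_m, dtype=float)
    if len(f) < 2 or len(m) < 2:
        raise ValueError("need at least 2 observations per group")
    s_f, s_m = f.std(ddof=1), m.std(ddof=1)
    n_f, n_m = len(f), len(m)
    s_pooled = np.sqrt(((n_f - 1) * s_f ** 2 + (n_m - 1) * s_m ** 2)
                       / (n_f + n_m - 2))
    diff = f.mean() - m.mean()
    if s_pooled == 0:
        if diff != 0:
            raise ValueError("zero pooled SD with unequal means")
        d = 0.0
    else:
        d = diff / s_pooled
    return EffectSizeResult(float(d), float(f.mean()), float(m.mean()),
                            float(s_f), float(s_m), n_f, n_m, float(s_pooled))


def tract_cohens_d(dataset, tract_mask):
    """Cohen's d between sexes on per-subject tract-mean metric values."""
    tract_mask = np.asarray(tract_mask, bool)
    means = dataset.stack()[:, tract_mask].mean(axis=1)
    sexes = np.asarray(dataset.sexes())
    return cohens_d(means[sexes == "female"], means[sexes == "male"])


# ---------------------------------------------------------------------------
# tract profiles
# ---------------------------------------------------------------------------

@dataclass
class TractProfile:
    tract: str
    values: np.ndarray     # length n_levels, ordered from the low-projection end
    n_levels: int


def tract_profile(volume, tract_mask, axis_direction=None, n_levels=100,
                  tract_name="tract"):
    """Mean metric on equally spaced bins along the tract axis.

    Tract voxels are projected onto ``axis_direction`` (default: the
    principal axis of the voxel coordinates); the projected extent is split
    into ``n_levels`` equal bins and the metric averaged per bin.  An empty
    bin is an error naming the bin -- reduce ``n_levels`` for short tracts.
    """
    tract_mask = np.asarray(tract_mask, bool)
    coords = np.argwhere(tract_mask)
    if coords.size == 0:
        raise ValueError("tract mask is empty")
    if axis_direction is None:
        centered = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis_direction = vt[0]
    axis = np.asarray(axis_direction, dtype=float)
    axis = axis / np.linalg.norm(axis)
    proj = coords @ axis
    lo, hi = proj.min(), proj.max()
    edges = np.linspace(lo, hi, n_levels + 1)
    which = np.clip(np.searchsorted(edges, proj, side="right") - 1, 0, n_levels - 1)
    data = volume.data if isinstance(volume, MetricVolume) else np.asarray(volume)
    vals = data[tract_mask]
    out = np.empty(n_levels)
    for b in range(n_levels):
        sel = which == b
        if not sel.any():
            raise ValueError(
                f"tract-profile bin {b + 1}/{n_levels} contains no voxels; "
                "reduce n_levels for this tract")
        out[b] = vals[sel].mean()
    return TractProfile(tract_name, out, n_levels)


@dataclass
class ProfileCorrelation:
    r: np.ndarray            # per-location Pearson r (nan where undefined)
    p: np.ndarray
    significant: np.ndarray  # p < alpha, False where undefined
    undefined: np.ndarray    # zero-variance locations
    n_subjects: int
    alpha: float = 0.05


def profile_age_correlation(profiles, ages, alpha=0.05):
    """Per-location Pearson correlation of profile values with age."""
    ages = np.asarray(ages, dtype=float)
    if len(profiles) < 3:
        raise ValueError("need at least 3 subjects")
    lengths = {p.n_levels for p in profiles}
    names = {p.tract for p in profiles}
    if len(lengths) != 1 or len(names) != 1:
        raise ValueError("profiles must share one tract and length")
    mat = np.stack([p.values for p in profiles])   # (n_subjects, n_levels)
    n_loc = mat.shape[1]
    r = np.full(n_loc, np.nan)
    p = np.full(n_loc, np.nan)
    undefined = np.zeros(n_loc, bool)
    for j in range(n_loc):
        col = mat[:, j]
        if col.std() == 0 or ages.std() == 0:
            undefined[j] = True
            continue
        r[j], p[j] = stats.pearsonr(col, ages)
    sig = np.where(undefined, False, p < alpha)
    return ProfileCorrelation(r, p, sig, undefined, len(profiles), alpha)


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def wm_histogram(dataset, mask, bins=50, value_range=None):
    """Per-subject and pooled histograms of metric values in the mask."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    mask = np.asarray(mask, bool)
    if value_range is None:
        value_range = dataset.volumes[0].valid_range()
    per_subject = {}
    pooled = None
    edges = None
    for v in dataset.volumes:
        counts, edges = np.histogram(v.data[mask], bins=bins, range=value_range)
        per_subject[v.subject_id] = counts
        pooled = counts if pooled is None else pooled + counts
    return {"per_subject": per_subject, "pooled": pooled, "edges": edges}


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def mannwhitney_u(group_a, group_b):
    """Two-sided Mann-Whitney U (U of group A, tie-corrected).

    Exact enumeration for small untied samples (n <= 20 per group); normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class GroupTestResult:
    p_map: np.ndarray
    significance: np.ndarray
    direction: np.ndarray      # +1 where site B higher, -1 where A higher
    method: str
    mask: np.ndarray
    alpha: float
    provenance: str = NOT_TBSS

    def n_significant(self):
        return int(self.significance.sum())


def _welch_t(A, B):
    """Vectorized two-sample t statistic over columns (voxels)."""
    na, nb = len(A), len(B)
    va = A.var(axis=0, ddof=1) / na
    vb = B.var(axis=0, ddof=1) / nb
    denom = np.sqrt(va + vb)
    denom[denom == 0] = np.inf
    return (B.mean(axis=0) - A.mean(axis=0)) / denom


def voxelwise_group_test(site_a, site_b, mask, method="permutation_maxstat",
                         n_permutations=1000, seed=0, alpha=0.05):
    """Mass-univariate two-sample test with multiplicity correction.

    ``permutation_maxstat``: Welch t per voxel, FWER controlled by the
    permutation distribution of the maximum |t| over the mask (identity
    permutation included).  ``mannwhitney_fdr``: Mann-Whitney per voxel with
    Benjamini-Hochberg correction.
    """
    mask = np.asarray(mask, bool)
    if len(site_a) < 3 or len(site_b) < 3:
        raise ValueError("need at least 3 subjects per site")
    A = site_a.stack()[:, mask]
    B = site_b.stack()[:, mask]
    direction_flat = np.sign(B.mean(axis=0) - A.mean(axis=0))

    if method == "permutation_maxstat":
        if n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        rng = np.random.default_rng(seed)
        X = np.concatenate([A, B])
        na = len(A)
        obs = np.abs(_welch_t(A, B))
        max_null = np.empty(n_permutations + 1)
        max_null[0] = obs.max()  # identity permutation keeps the test valid
        for i in range(n_permutations):
            perm = rng.permutation(len(X))
            max_null[i + 1] = np.abs(_welch_t(X[perm[:na]], X[perm[na:]])).max()
        # identity term always counts once, keeping p >= 1/(B+1) and the test valid
        p_flat = np.sum(max_null[None, :] >= obs[:, None], axis=1) \
            / (n_permutations + 1)
        sig_flat = p_flat <= alpha
    elif method == "mannwhitney_fdr":
        res = stats.mannwhitneyu(A, B, alternative="two-sided", axis=0,
                                 method="asymptotic")
        p_flat = np.minimum(res.pvalue, 1.0)
        p_flat = np.nan_to_num(p_flat, nan=1.0)
        adj = stats.false_discovery_control(p_flat, method="bh")
        sig_flat = adj < alpha
        p_flat = adj
    else:
        raise ValueError(f"unknown method {method!r}")

    p_map = np.ones(mask.shape)
    p_map[mask] = p_flat
    sig = np.zeros(mask.shape, bool)
    sig[mask] = sig_flat
    direction = np.zeros(mask.shape)
    direction[mask] = direction_flat
    return GroupTestResult(p_map, sig, direction, method, mask, alpha)


def union_over_folds(results):
    """Overlay per-fold group tests: union of significance, min p per voxel."""
    if not results:
        raise ValueError("no results")
    methods = {r.method for r in results}
    shapes = {r.p_map.shape for r in results}
    if len(methods) != 1:
        raise ValueError(f"cannot union mixed methods {methods}")
    if len(shapes) != 1:
        raise ValueError("geometry mismatch across folds")
    p = np.minimum.reduce([r.p_map for r in results])
    sig = np.logical_or.reduce([r.significance for r in results])
    direction = results[0].direction.copy()
    for r in results[1:]:
        take = (direction == 0) & (r.direction != 0)
        direction[take] = r.direction[take]
    return GroupTestResult(p, sig, direction, results[0].method,
                           results[0].mask, results[0].alpha)
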