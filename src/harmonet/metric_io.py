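"""Reading, writing and organizing scalar metric volumes (FA / MD).

Volumes are assumed pre-registered to a common template space; array
indices are (X, Y, Z) and no world-space resampling happens here.  Cohorts
are described by a CSV manifest with columns
``subject_id, site, age_weeks, sex, path``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger("harmonet")

#: valid value range per metric; FA is dimensionless, MD in mm^2/s
METRIC_RANGES = {"FA": (0.0, 1.0), "MD": (0.0, 4e-3)}

#: values farther outside the range than this (relative to range width) are
#: rejected rather than clipped
HARD_REJECT_FACTOR = 1.5

MANIFEST_COLUMNS = ["subject_id", "site", "age_weeks", "sex", "path"]


@dataclass
class MetricVolume:
    """One subject's 3D scalar map with geometry and covariates."""

    data: np.ndarray
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    subject_id: str = ""
    site: str = ""
    age_weeks: float = float("nan")
    sex: str = ""
    metric_name: str = "FA"
    site_effect: object = None  # ground-truth field, kept for evaluation

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"metric volume must be 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("metric volume contains non-finite values")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self):
        return self.data.shape

    def with_data(self, data):
        return replace(self, data=np.asarray(data, dtype=float))

    def valid_range(self):
        return METRIC_RANGES[self.metric_name]


@dataclass
class SiteDataset:
    """An ordered cohort of volumes from one site sharing a mask."""

    site: str
    volumes: list
    mask: np.ndarray = None

    def __post_init__(self):
        if self.volumes:
            shape = self.volumes[0].shape
            metric = self.volumes[0].metric_name
            ids = set()
            for v in self.volumes:
                if v.shape != shape:
                    raise ValueError("all volumes in a site must share one shape")
                if v.metric_name != metric:
                    raise ValueError("all volumes must share the metric name")
                if v.subject_id in ids:
                    raise ValueError(f"duplicate subject_id {v.subject_id!r}")
                ids.add(v.subject_id)
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)

    def __len__(self):
        return len(self.volumes)

    def __iter__(self):
        return iter(self.volumes)

    def stack(self):
        """(n_subjects, X, Y, Z) array of voxel data."""
        return np.stack([v.data for v in self.volumes])

    def subject_ids(self):
        return [v.subject_id for v in self.volumes]

    def subset(self, subject_ids):
        keep = set(subject_ids)
        return SiteDataset(self.site, [v for v in self.volumes if v.subject_id in keep],
                           self.mask)

    def ages(self):
        return np.array([v.age_weeks for v in self.volumes])

    def sexes(self):
        return [v.sex for v in self.volumes]


@dataclass
class FoldSplit:
    """Per-site partition of subject ids into k folds."""

    k: int
    folds: dict = field(default_factory=dict)  # site -> list of k id-lists

    def train_ids(self, site, fold):
        return [s for i, f in enumerate(self.folds[site]) if i != fold for s in f]

    def test_ids(self, site, fold):
        return list(self.folds[site][fold])

    def to_frame(self):
        rows = [
            {"subject_id": sid, "site": site, "fold": i}
            for site, folds in self.folds.items()
            for i, fold in enumerate(folds)
            for sid in fold
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI and manifest I/O
# ---------------------------------------------------------------------------

def validate_metric_data(data, metric_name, mask=None, policy="clip"):
    """Clip values marginally outside the metric range; reject gross ones.

    Registration interpolation can push FA slightly past [0, 1]; those are
    clipped with a warning.  Values beyond ``HARD_REJECT_FACTOR`` times the
    range width are treated as a corrupt file.
    """
    lo, hi = METRIC_RANGES[metric_name]
    width = hi - lo
    region = data[mask] if mask is not None else data
    worst = max(lo - region.min(), region.max() - hi, 0.0)
    if worst > (HARD_REJECT_FACTOR - 1.0) * width:
        raise ValueError(
            f"{metric_name} values out of range by {worst:.3g} "
            f"(> {(HARD_REJECT_FACTOR - 1) * width:.3g}); refusing to clip")
    if worst > 0:
        n = int(np.sum((data < lo) | (data > hi)))
        if policy == "raise":
            raise ValueError(f"{n} voxels outside the {metric_name} range")
        log.warning("clipped %d voxels marginally outside the %s range",
                    n, metric_name)
        data = np.clip(data, lo, hi)
    return data


def read_metric_volume(path, manifest_row=None, metric_name="FA", policy="clip"):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D: {path}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    row = manifest_row if manifest_row is not None else {}
    if manifest_row is not None:
        missing = [c for c in ("subject_id", "site", "age_weeks", "sex") if c not in row
                   or pd.isna(row[c])]
        if missing:
            raise ValueError(f"manifest row missing covariates: {missing}")
    data = validate_metric_data(data, metric_name, policy=policy)
    return MetricVolume(
        data=data, voxel_size_mm=zooms,
        subject_id=str(row.get("subject_id", "")), site=str(row.get("site", "")),
        age_weeks=float(row.get("age_weeks", np.nan)),
        sex=str(row.get("sex", "")), metric_name=metric_name)


def write_metric_volume(volume, path):
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))


def write_mask(mask, path, voxel_size_mm=(2.0, 2.0, 2.0)):
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def read_mask(path):
    return np.asarray(nib.load(str(path)).dataobj) > 0


def read_manifest(path):
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df


def load_cohort(manifest, site, mask=None, metric_name="FA"):
    """Load one site's volumes in manifest order."""
    df = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
    df = df[df["site"].astype(str) == str(site)]
    vols = [read_metric_volume(r["path"], r, metric_name) for _, r in df.iterrows()]
    if not vols:
        raise ValueError(f"no subjects for site {site!r} in manifest")
    return SiteDataset(str(site), vols, mask)


def write_cohort(dataset, out_dir, manifest_path=None):
    """Write each volume as NIfTI plus a cohort manifest CSV."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for v in dataset.volumes:
        p = out_dir / f"{v.subject_id}.nii.gz"
        write_metric_volume(v, p)
        rows.append({"subject_id": v.subject_id, "site": v.site,
                     "age_weeks": v.age_weeks, "sex": v.sex, "path": str(p)})
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if manifest_path is None:
        manifest_path = out_dir / "manifest.csv"
    df.to_csv(manifest_path, index=False)
    return manifest_path


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

def kfold_split(datasets, k, seed=0):
    """Seeded per-site partition into k folds of near-equal size.

    Stratifying by site guarantees every training fold contains subjects of
    both domains, which the adversarial training requires.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    folds = {}
    for ds in datasets:
        ids = ds.subject_ids()
        if k > len(ids):
            raise ValueError(
                f"k={k} exceeds the {len(ids)} subjects of site {ds.site!r}")
        perm = list(np.array(ids, dtype=object)[rng.permutation(len(ids))])
        folds[ds.site] = [list(chunk) for chunk in np.array_split(perm, k)]
    return FoldSplit(k=k, folds=folds)


# ---------------------------------------------------------------------------
# orientation-specific slice stacks
# ---------------------------------------------------------------------------

#: slicing axis per orientation (array axes are X, Y, Z)
ORIENTATION_AXIS = {"axial": 2, "coronal": 1, "sagittal": 0}


def extract_slices(volume, orientation):
    """Return (stack, meta): stack[i] is the i-th slice along the axis.

    axial -> Z slices of (X, Y); coronal -> Y slices of (X, Z);
    sagittal -> X slices of (Y, Z).
    """
    if orientation not in ORIENTATION_AXIS:
        raise ValueError(
            f"unknown orientation {orientation!r}; expected one of "
            f"{sorted(ORIENTATION_AXIS)}")
    data = volume.data if isinstance(volume, MetricVolume) else np.asarray(volume)
    axis = ORIENTATION_AXIS[orientation]
    stack = np.moveaxis(data, axis, 0)
    meta = {"orientation": orientation, "axis": axis, "shape": data.shape}
    return stack, meta


def restack_slices(stack, meta):
    """Inverse of :func:`extract_slices`; exact round trip."""
    data = np.moveaxis(np.asarray(stack), 0, meta["axis"])
    if data.shape != tuple(meta["shape"]):
        raise ValueError("slice stack inconsistent with original shape")
    return data
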