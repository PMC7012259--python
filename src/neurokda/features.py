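"""Feature extraction from registered gray-matter density volumes.

The classifier consumes voxel-wise gray-matter (GM) density maps that have
already been bias-corrected, skull-stripped, segmented and spatially
normalized upstream.  This module covers the in-package steps: Gaussian
smoothing, integer-factor block-mean downsampling, vectorization into
column feature vectors, training-only two-sample t-test screening, and
mapping screening results back into a volume for biomarker inspection.

Conventions
-----------
* Feature vectors are **columns**: a feature matrix is ``M x N`` with one
  column per subject.
* Vectorization uses C-order raster scan (last axis fastest), fixed
  everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "Volume3D",
    "FeatureMatrix",
    "ScreenResult",
    "smooth_volume",
    "downsample",
    "vectorize",
    "unvectorize",
    "ttest_screen",
    "biomarker_map",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_matrix",
    "write_matrix",
]


@dataclass
class Volume3D:
    """A 3D grid of nonnegative density values with physical voxel size."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.values.ndim}")
        if any(s < 1 for s in self.values.shape):
            raise ValueError(f"all axis extents must be >= 1, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")
        if np.any(self.values < 0):
            raise ValueError("density values must be nonnegative")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class FeatureMatrix:
    """Column-per-subject feature matrix with class labels.

    ``X`` is ``M x N`` (M features, N subjects); ``labels`` holds class
    indices ``0..C-1``; ``feature_index_map`` optionally maps each row to
    its 3D voxel coordinate.
    """

    X: np.ndarray
    labels: np.ndarray
    feature_index_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D (features x subjects)")
        if self.labels.shape != (self.X.shape[1],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match subject count {self.X.shape[1]}"
            )
        if self.feature_index_map is not None:
            self.feature_index_map = np.asarray(self.feature_index_map, dtype=int)
            if self.feature_index_map.shape != (self.X.shape[0], 3):
                raise ValueError("feature_index_map must be (M, 3)")

    @property
    def n_features(self) -> int:
        return self.X.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, columns: np.ndarray) -> "FeatureMatrix":
        """Column (subject) subset, preserving the row index map."""
        return FeatureMatrix(self.X[:, columns], self.labels[columns], self.feature_index_map)


@dataclass
class ScreenResult:
    """Outcome of per-feature two-sample t-test screening."""

    selected: np.ndarray      # sorted retained row indices
    pvalues: np.ndarray       # length-M two-sided p-values
    threshold: float


def _gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = int(np.ceil(truncate * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_volume(v: Volume3D, sigma_vox: float, truncate: float = 4.0) -> Volume3D:
    """Separable Gaussian smoothing with a truncated, normalized kernel.

    Boundaries use symmetric (reflect) extension, which leaves constant
    volumes unchanged and conserves the total density exactly.
    """
    if sigma_vox <= 0:
        raise ValueError(f"sigma_vox must be > 0, got {sigma_vox}")
    kernel = _gaussian_kernel_1d(sigma_vox, truncate)
    out = v.values
    for axis in range(3):
        out = ndimage.convolve1d(out, kernel, axis=axis, mode="reflect")
    # reflect convolution can produce tiny negative values from roundoff
    out = np.clip(out, 0.0, None)
    return Volume3D(out, v.voxel_size_mm)


def downsample(v: Volume3D, factor: int) -> Volume3D:
    """Block-mean downsampling by an integer factor per axis.

    Each output voxel is the mean of its ``factor**3`` input block; the
    physical voxel size grows by ``factor``.  Axis extents must divide
    evenly -- no silent cropping.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    shape = v.values.shape
    if any(s % factor != 0 for s in shape):
        raise ValueError(
            f"volume shape {shape} is not divisible by downsampling factor {factor}"
        )
    n0, n1, n2 = (s // factor for s in shape)
    blocks = v.values.reshape(n0, factor, n1, factor, n2, factor)
    out = blocks.mean(axis=(1, 3, 5))
    voxel = tuple(s * factor for s in v.voxel_size_mm)
    return Volume3D(out, voxel)  # type: ignore[arg-type]


def vectorize(
    v: Volume3D, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a volume to a feature vector plus its row->voxel index map.

    Raster order is C order (axis 2 fastest).  With a boolean ``mask`` of
    the volume's shape only the True voxels are kept, in the same order.
    """
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != v.values.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume shape {v.values.shape}"
            )
        vec = v.values[mask]
        index_map = np.argwhere(mask)
    else:
        vec = v.values.ravel(order="C").copy()
        index_map = np.argwhere(np.ones(v.values.shape, dtype=bool))
    return vec, index_map


def unvectorize(
    vec: np.ndarray,
    index_map: np.ndarray,
    shape: tuple[int, int, int],
    fill: float = 0.0,
) -> Volume3D:
    """Inverse of :func:`vectorize`: scatter a vector back onto a grid."""
    vec = np.asarray(vec, dtype=float)
    index_map = np.asarray(index_map, dtype=int)
    if vec.shape[0] != index_map.shape[0]:
        raise ValueError("vector length does not match index map")
    out = np.full(shape, fill, dtype=float)
    out[index_map[:, 0], index_map[:, 1], index_map[:, 2]] = vec
    return Volume3D(out)


def ttest_screen(
    train: FeatureMatrix, threshold: float, equal_var: bool = True
) -> ScreenResult:
    """Two-sample t-test screening of feature rows, training data only.

    Runs a two-sided two-sample t-test (pooled variance by default; Welch
    with ``equal_var=False``) on every row and retains rows with
    ``p < threshold``.  Degenerate rows: equal means with zero pooled
    variance carry no signal (p = 1, dropped); unequal means with zero
    pooled variance are infinitely significant (p = 0, retained).
    """
    if train.n_classes != 2:
        raise ValueError(f"t-test screening requires exactly 2 classes, got {train.n_classes}")
    counts = train.class_counts()
    if np.any(counts < 2):
        raise ValueError(f"each class needs >= 2 training subjects, got counts {counts}")
    a = train.X[:, train.labels == 0]
    b = train.X[:, train.labels == 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        pvalues = np.asarray(res.pvalue, dtype=float)
    # zero-variance rows come back NaN from the t statistic
    bad = ~np.isfinite(pvalues)
    if np.any(bad):
        mean_diff = a.mean(axis=1) - b.mean(axis=1)
        pvalues[bad & (mean_diff == 0)] = 1.0
        pvalues[bad & (mean_diff != 0)] = 0.0
    selected = np.flatnonzero(pvalues < threshold)
    return ScreenResult(selected=selected, pvalues=pvalues, threshold=float(threshold))


def biomarker_map(
    screen: ScreenResult,
    shape: tuple[int, int, int],
    feature_index_map: np.ndarray | None,
) -> Volume3D:
    """Render selected features as a -log10(p) significance volume.

    Voxels of retained features get ``-log10(p)``; everything else 0.
    Supports the before/after-decomposition biomarker comparison.
    """
    if feature_index_map is None:
        raise ValueError("biomarker_map requires a feature_index_map onto the volume shape")
    out = np.zeros(shape, dtype=float)
    if screen.selected.size:
        coords = np.asarray(feature_index_map, dtype=int)[screen.selected]
        p = np.clip(screen.pvalues[screen.selected], 1e-300, None)
        out[coords[:, 0], coords[:, 1], coords[:, 2]] = -np.log10(p)
    return Volume3D(out)


# ---------------------------------------------------------------------------
# IO helpers (NIfTI volumes, delimited matrices, label CSVs)
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> Volume3D:
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()[:3]
    return Volume3D(values, tuple(float(z) for z in zooms))  # type: ignore[arg-type]


def write_volume(v: Volume3D, path: str | Path) -> None:
    affine = np.diag(list(v.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(v.values, affine), str(path))


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"subject_id", "label"}.issubset(df.columns):
        raise ValueError("labels CSV must have columns subject_id,label")
    return df


def write_labels(subject_ids: Sequence[str], labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"subject_id": subject_ids, "label": np.asarray(labels, dtype=int)}).to_csv(
        path, index=False
    )


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_matrix(x: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(x, dtype=float), delimiter="\t")
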