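"""Subject-level weighted functional connectome construction.

The pipeline mirrors the standard weighted (threshold-free) construction:
mean BOLD signal inside a 4 mm sphere around each ROI centre, Pearson
correlation between every ROI pair, Fisher z-transform, and zeroing of
negative weights.  No sparsity or correlation-strength thresholding is
applied at any stage; downstream graph metrics operate directly on the
Fisher-z weights (which may exceed 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .confounds import VolumeSeries

__all__ = [
    "RoiTable",
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "extract_roi_timeseries",
    "correlation_matrix",
    "fisher_z",
    "zero_negatives",
    "build_connectome",
    "regress_confounds",
]

DEFAULT_SPHERE_RADIUS = 4.0  # mm
_CLIP = 1.0 - 1e-7


@dataclass
class RoiTable:
    """ROI labels and centre coordinates in world (scanner/MNI) millimetres."""

    table: pd.DataFrame  # columns: label, x, y, z

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        required = {"label", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"ROI table missing columns: {sorted(missing)}")
        if df["label"].duplicated().any():
            raise ValueError("ROI labels must be unique")
        self.table = df.reset_index(drop=True)

    @property
    def labels(self) -> list[str]:
        return self.table["label"].astype(str).tolist()

    @property
    def centers(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RoiTimeSeries:
    """Frames x ROIs matrix of mean BOLD signal."""

    data: np.ndarray
    tr: float
    labels: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValueError("ROI time series must be 2D (frames x ROIs)")
        if len(self.labels) != d.shape[1]:
            raise ValueError("label count must match ROI count")
        if self.tr <= 0:
            raise ValueError("repetition time must be positive")
        self.data = d

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


STAGES = ("pearson_r", "fisher_z", "fisher_z_nonneg")


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI matrix with a pipeline stage tag."""

    values: np.ndarray
    stage: str
    labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if np.max(np.abs(v - v.T), initial=0.0) > 1e-10:
            raise ValueError("connectivity matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if self.stage == "fisher_z_nonneg" and np.any(v < 0):
            raise ValueError("fisher_z_nonneg stage requires nonnegative entries")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count must match matrix size")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def _voxel_world_coordinates(volumes: VolumeSeries) -> np.ndarray:
    """World (mm) coordinates of every voxel centre, via the NIfTI affine."""
    nx, ny, nz = volumes.spatial_shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    ijk = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4)
    world = ijk @ volumes.affine.T
    return world[:, :3].reshape(nx, ny, nz, 3)


def extract_roi_timeseries(
    volumes: VolumeSeries, rois: RoiTable, radius: float = DEFAULT_SPHERE_RADIUS
) -> RoiTimeSeries:
    """Mean signal over voxels whose centre lies within ``radius`` mm of each ROI.

    The sphere is a closed ball (distance <= radius) over voxel centres in
    world coordinates; voxels outside the brain mask (when present) are
    excluded.  An ROI whose sphere captures no voxels raises an error naming
    the ROI.
    """
    if radius <= 0:
        raise ValueError("sphere radius must be positive")
    world = _voxel_world_coordinates(volumes)
    flat_world = world.reshape(-1, 3)
    flat_data = volumes.data.reshape(-1, volumes.n_frames)
    in_brain = (
        volumes.mask.reshape(-1)
        if volumes.mask is not None
        else np.ones(flat_world.shape[0], dtype=bool)
    )
    out = np.empty((volumes.n_frames, len(rois)))
    for idx, (label, center) in enumerate(zip(rois.labels, rois.centers)):
        dist2 = ((flat_world - center) ** 2).sum(axis=1)
        sel = (dist2 <= radius**2) & in_brain
        if not sel.any():
            raise ValueError(f"ROI {label!r}: sphere of radius {radius} mm contains no voxels")
        out[:, idx] = flat_data[sel].mean(axis=0)
    return RoiTimeSeries(data=out, tr=volumes.tr, labels=rois.labels)


def correlation_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every ROI pair; diagonal forced to zero.

    Zero-variance ROI columns yield zero rows/columns with a degeneracy
    warning rather than aborting the subject.
    """
    if ts.n_frames < 3:
        raise ValueError("need at least 3 frames to correlate")
    X = ts.data
    sd = X.std(axis=0)
    # relative tolerance: a constant column stored in floats has sd ~ eps*|mean|
    degenerate = sd <= 1e-12 * np.maximum(np.abs(X).max(axis=0), 1.0)
    if degenerate.any():
        bad = [ts.labels[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(f"zero-variance ROI columns set to zero connectivity: {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(values=r, stage="pearson_r", labels=ts.labels)


def fisher_z(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Entrywise Fisher z-transform (arctanh); |r| clipped at 1 - 1e-7 first."""
    if matrix.stage != "pearson_r":
        raise ValueError(f"fisher_z expects stage 'pearson_r', got {matrix.stage!r}")
    r = np.clip(matrix.values, -_CLIP, _CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(values=z, stage="fisher_z", labels=matrix.labels)


def zero_negatives(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Replace negative weights by zero; nonnegative entries pass unchanged."""
    if matrix.stage != "fisher_z":
        raise ValueError(f"zero_negatives expects stage 'fisher_z', got {matrix.stage!r}")
    v = matrix.values.copy()
    v[v < 0] = 0.0
    return ConnectivityMatrix(values=v, stage="fisher_z_nonneg", labels=matrix.labels)


def build_connectome(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Full construction: Pearson r -> Fisher z -> negatives zeroed.

    The order is fixed (z-transform before zeroing) and no thresholding is
    ever applied.
    """
    return zero_negatives(fisher_z(correlation_matrix(ts)))


def regress_confounds(ts: RoiTimeSeries, confounds: np.ndarray) -> RoiTimeSeries:
    """Project confound columns (plus an intercept) out of each ROI series.

    Optional preprocessing step; the default pipeline does not apply it.
    """
    C = np.atleast_2d(np.asarray(confounds, dtype=float))
    if C.shape[0] != ts.n_frames:
        C = C.T
    if C.shape[0] != ts.n_frames:
        raise ValueError("confound rows must match the number of frames")
    X = np.column_stack([np.ones(ts.n_frames), C])
    coef, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    return RoiTimeSeries(data=ts.data - X @ coef, tr=ts.tr, labels=ts.labels)
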