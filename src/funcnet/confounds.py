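"""Per-frame motion and intensity confounds for 4D BOLD series.

Implements the standard resting-state nuisance battery: framewise
displacement in the Power (absolute sum of relative motions) and Jenkinson
(RMS displacement between affines over a head-sized sphere) formulations,
standardized DVARS, tissue global signals, discrete-cosine high-pass
filtering, temporal and anatomical CompCor, confound expansion with
derivatives and quadratics, and motion-outlier annotation at the
0.5 mm FD / 1.5 standardized-DVARS thresholds.

Frame 0 of every differenced quantity (FD, DVARS, derivatives) is 0 by
convention: it has no predecessor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MotionTrace",
    "VolumeSeries",
    "TissueMask",
    "ConfoundTable",
    "CompCorResult",
    "fd_power",
    "fd_jenkinson",
    "dvars_standardized",
    "global_signals",
    "dct_highpass",
    "tcompcor",
    "acompcor",
    "retain_components",
    "expand_confounds",
    "annotate_outliers",
]

#: Field-standard sphere radius (mm) converting rotations to displacement
#: in the Power FD formulation.
DEFAULT_POWER_RADIUS = 50.0
#: Head-sized sphere radius (mm) in the original Jenkinson RMS formulation.
DEFAULT_JENKINSON_RADIUS = 80.0
DEFAULT_FD_THRESHOLD = 0.5
DEFAULT_DVARS_THRESHOLD = 1.5
DEFAULT_DCT_CUTOFF = 128.0
DEFAULT_TCOMPCOR_FRACTION = 0.02
DEFAULT_ACOMPCOR_BINARIZE = 0.99
DEFAULT_VARIANCE_TARGET = 0.50
DEFAULT_GLOBAL_SIGNAL_BINARIZE = 0.5


@dataclass
class MotionTrace:
    """Per-frame rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray  # T x 6, order (tx, ty, tz, rx, ry, rz)
    tr: float

    def __post_init__(self) -> None:
        p = np.asarray(self.params, dtype=float)
        if p.ndim != 2 or p.shape[1] != 6:
            raise ValueError("motion parameters must be a T x 6 array")
        if p.shape[0] < 1:
            raise ValueError("motion trace needs at least one frame")
        if not np.all(np.isfinite(p)):
            raise ValueError("motion parameters contain non-finite values")
        if np.any(np.abs(p[:, 3:]) >= np.pi):
            raise ValueError("rotation magnitudes must be < pi radians")
        if self.tr <= 0:
            raise ValueError("repetition time must be positive")
        self.params = p

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass
class VolumeSeries:
    """4D BOLD grid (x, y, z, frame) with geometry and timing metadata."""

    data: np.ndarray
    voxel_size: float | tuple[float, float, float]
    tr: float
    affine: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4:
            raise ValueError(f"expected a 4D volume series, got {d.ndim}D")
        if min(d.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        vz = self.voxel_size
        if np.isscalar(vz):
            vz = (float(vz),) * 3
        vz = tuple(float(v) for v in vz)
        if any(v <= 0 for v in vz):
            raise ValueError("voxel size must be positive")
        if self.tr <= 0:
            raise ValueError("repetition time must be positive")
        if self.affine is None:
            aff = np.diag([*vz, 1.0])
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4 x 4")
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != d.shape[:3]:
                raise ValueError("mask shape must match the spatial grid")
            self.mask = m
        self.data = d
        self.voxel_size = vz
        self.affine = aff

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class TissueMask:
    """3D probability map in [0, 1] with a tissue label."""

    probabilities: np.ndarray
    label: str

    _ALLOWED = {"CSF", "WM", "CSF+WM", "whole-brain", "GM"}

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 3:
            raise ValueError("tissue mask must be a 3D grid")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.label not in self._ALLOWED:
            raise ValueError(
                f"unknown tissue label {self.label!r}; allowed: {sorted(self._ALLOWED)}"
            )
        self.probabilities = p

    def binarize(self, threshold: float) -> np.ndarray:
        return self.probabilities >= threshold


@dataclass
class ConfoundTable:
    """Per-frame confound regressors plus column lineage metadata.

    ``lineage`` maps each column name to one of ``raw``, ``derivative``,
    ``quadratic`` or ``derivative_quadratic``.
    """

    frame: "pd.DataFrame"
    lineage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import pandas as pd  # deferred; keeps numpy-only callers light

        if not isinstance(self.frame, pd.DataFrame):
            self.frame = pd.DataFrame(self.frame)
        for col in self.frame.columns:
            self.lineage.setdefault(col, "raw")


def _check_motion(motion: MotionTrace) -> np.ndarray:
    return motion.params


def fd_power(
    motion: MotionTrace, rotation_radius: float = DEFAULT_POWER_RADIUS
) -> np.ndarray:
    """Power framewise displacement: absolute sum of relative motions (mm).

    Rotations (radians) are converted to arc length on a sphere of
    ``rotation_radius`` mm before summation.  FD[0] = 0.
    """
    if rotation_radius <= 0:
        raise ValueError("rotation radius must be positive")
    p = _check_motion(motion)
    fd = np.zeros(p.shape[0])
    if p.shape[0] > 1:
        diff = np.abs(np.diff(p, axis=0))
        fd[1:] = diff[:, :3].sum(axis=1) + rotation_radius * diff[:, 3:].sum(axis=1)
    return fd


def _rigid_affine(params: np.ndarray) -> np.ndarray:
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    A = np.eye(4)
    A[:3, :3] = Rz @ Ry @ Rx
    A[:3, 3] = (tx, ty, tz)
    return A


def fd_jenkinson(
    motion: MotionTrace, sphere_radius: float = DEFAULT_JENKINSON_RADIUS
) -> np.ndarray:
    """Jenkinson framewise displacement: RMS displacement between affines (mm).

    For the relative rigid transform M between consecutive frames, the RMS
    displacement of points distributed uniformly through a solid sphere of
    radius R centred at the origin has the closed form
    ``sqrt(R^2/5 * trace(A.T A) + |b|^2)`` with ``A = M[:3,:3] - I`` and
    ``b = M[:3,3]``.  FD[0] = 0.
    """
    if sphere_radius <= 0:
        raise ValueError("sphere radius must be positive")
    p = _check_motion(motion)
    T = p.shape[0]
    fd = np.zeros(T)
    if T == 1:
        return fd
    affines = [_rigid_affine(row) for row in p]
    for t in range(1, T):
        M = affines[t] @ np.linalg.inv(affines[t - 1]) - np.eye(4)
        A = M[:3, :3]
        b = M[:3, 3]
        fd[t] = np.sqrt(sphere_radius**2 / 5.0 * np.trace(A.T @ A) + b @ b)
    return fd


def _mask_voxels(volumes: VolumeSeries, mask: np.ndarray) -> np.ndarray:
    """Frames x voxels matrix of in-mask time series."""
    if mask.shape != volumes.spatial_shape:
        raise ValueError("mask shape must match the volume grid")
    if not mask.any():
        raise ValueError("mask selects no voxels")
    return volumes.data[mask].T  # (T, n_voxels)


def dvars_standardized(
    volumes: VolumeSeries, mask: TissueMask, binarize_at: float = DEFAULT_GLOBAL_SIGNAL_BINARIZE
) -> np.ndarray:
    """Standardized DVARS: RMS frame-to-frame intensity change, median-scaled.

    Raw DVARS[t] is the RMS over in-mask voxels of the backward temporal
    difference; DVARS[0] = 0.  The series is divided by its median over
    frames 1..T-1 so the nonzero entries have median 1.  A constant series
    returns all zeros with a degenerate-scale warning (no division by 0).
    """
    if volumes.n_frames < 2:
        raise ValueError("DVARS needs at least 2 frames")
    ts = _mask_voxels(volumes, mask.binarize(binarize_at))
    raw = np.zeros(volumes.n_frames)
    diff = np.diff(ts, axis=0)
    raw[1:] = np.sqrt((diff**2).mean(axis=1))
    scale = np.median(raw[1:])
    if scale == 0.0:
        warnings.warn("constant volume series: DVARS scale is degenerate, returning zeros")
        return raw
    return raw / scale


def global_signals(
    volumes: VolumeSeries,
    masks: list[TissueMask],
    binarize_at: float = DEFAULT_GLOBAL_SIGNAL_BINARIZE,
) -> dict[str, np.ndarray]:
    """Per-frame mean signal within each binarized tissue mask."""
    out: dict[str, np.ndarray] = {}
    for mask in masks:
        binary = mask.binarize(binarize_at)
        if not binary.any():
            raise ValueError(f"{mask.label} mask is empty after binarization at {binarize_at}")
        out[mask.label] = volumes.data[binary].mean(axis=0)
    return out


def _dct_drop_basis(n_frames: int, tr: float, cutoff_period: float) -> np.ndarray:
    """Constant + DCT-II regressors with period strictly above the cutoff."""
    total_duration = 2.0 * n_frames * tr
    # component k has period 2*T*tr/k; drop all k with period > cutoff
    n_drop = int(np.ceil(total_duration / cutoff_period)) - 1
    t = np.arange(n_frames)
    basis = [np.ones(n_frames)]
    for k in range(1, n_drop + 1):
        basis.append(np.cos(np.pi * k * (t + 0.5) / n_frames))
    return np.column_stack(basis)


def dct_highpass(
    series: np.ndarray, cutoff_period: float = DEFAULT_DCT_CUTOFF, tr: float = 1.0
) -> np.ndarray:
    """Project the constant and sub-cutoff discrete-cosine drift basis out.

    Removes every DCT-II basis function with period > ``cutoff_period``
    seconds (plus the constant) by least-squares projection, i.e. a
    high-pass filter at 1/cutoff Hz.  Idempotent.
    """
    X = np.atleast_2d(np.asarray(series, dtype=float))
    if X.shape[0] == 1 and X.size > 1 and np.asarray(series).ndim == 1:
        X = X.T
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 frames to filter")
    if cutoff_period <= 2 * tr:
        raise ValueError("cutoff period must exceed twice the repetition time")
    basis = _dct_drop_basis(n, tr, cutoff_period)
    if basis.shape[1] >= n:
        warnings.warn("cutoff removes all temporal variation; returning zeros")
        out = np.zeros_like(X)
    else:
        coef, *_ = np.linalg.lstsq(basis, X, rcond=None)
        out = X - basis @ coef
    if np.asarray(series).ndim == 1:
        return out.ravel()
    return out


@dataclass
class CompCorResult:
    """Principal components of a nuisance voxel set."""

    components: np.ndarray  # frames x k, unit-normed columns
    singular_values: np.ndarray
    n_voxels: int


def _principal_components(ts: np.ndarray) -> CompCorResult:
    """Unit-normed temporal principal components of a frames x voxels matrix.

    Columns are demeaned first; the sign of each component is fixed so its
    largest-magnitude voxel loading is positive (determinism).
    """
    X = ts - ts.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    if not keep.any():
        raise ValueError("all voxels are constant: no variance to decompose")
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    for i in range(s.size):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    return CompCorResult(components=U, singular_values=s, n_voxels=ts.shape[1])


def tcompcor(
    volumes: VolumeSeries,
    mask: TissueMask,
    top_fraction: float = DEFAULT_TCOMPCOR_FRACTION,
    binarize_at: float = DEFAULT_GLOBAL_SIGNAL_BINARIZE,
) -> CompCorResult:
    """Temporal CompCor: PCA of the highest-variance in-mask voxels.

    Selects the ``ceil(top_fraction * n_voxels)`` voxels with the largest
    temporal standard deviation (ties broken by linear voxel index) and
    returns their principal components ordered by singular value.  The
    caller is expected to high-pass filter the series first (128 s DCT in
    the standard pipeline).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    ts = _mask_voxels(volumes, mask.binarize(binarize_at))
    sd = ts.std(axis=0)
    n_keep = int(np.ceil(top_fraction * ts.shape[1]))
    order = np.argsort(-sd, kind="stable")  # stable: ties keep linear-index order
    selected = np.sort(order[:n_keep])
    return _principal_components(ts[:, selected])


def acompcor(
    volumes: VolumeSeries,
    prob_masks: list[TissueMask],
    binarize_at: float = DEFAULT_ACOMPCOR_BINARIZE,
) -> dict[str, CompCorResult]:
    """Anatomical CompCor: per-tissue PCA of voxels inside thresholded masks."""
    if not 0 < binarize_at < 1:
        raise ValueError("binarization threshold must lie in (0, 1)")
    out: dict[str, CompCorResult] = {}
    for mask in prob_masks:
        binary = mask.binarize(binarize_at)
        if not binary.any():
            raise ValueError(f"{mask.label} mask is empty after thresholding at {binarize_at}")
        out[mask.label] = _principal_components(_mask_voxels(volumes, binary))
    return out


def retain_components(
    singular_values: np.ndarray, variance_target: float = DEFAULT_VARIANCE_TARGET
) -> int:
    """Smallest k whose cumulative squared-singular-value share meets the target."""
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0:
        raise ValueError("no singular values supplied")
    if np.any(s <= 0):
        raise ValueError("singular values must be positive")
    if np.any(np.diff(s) > 0):
        raise ValueError("singular values must be sorted descending")
    if not 0 < variance_target <= 1:
        raise ValueError("variance target must lie in (0, 1]")
    shares = np.cumsum(s**2) / np.sum(s**2)
    return int(np.searchsorted(shares, variance_target - 1e-12) + 1)


def expand_confounds(table: ConfoundTable, columns: list[str]) -> ConfoundTable:
    """Add temporal-derivative and quadratic expansions of selected columns.

    Each selected column gains ``_derivative1`` (backward difference, first
    frame 0), ``_power2`` (square of the raw), and ``_derivative1_power2``
    (square of the derivative): m columns become 4m lineage columns.
    """
    df = table.frame.copy()
    lineage = dict(table.lineage)
    for col in columns:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not present")
        new = {
            f"{col}_derivative1": "derivative",
            f"{col}_power2": "quadratic",
            f"{col}_derivative1_power2": "derivative_quadratic",
        }
        for name in new:
            if name in df.columns:
                raise ValueError(f"derived column {name!r} already exists")
        x = df[col].to_numpy(dtype=float)
        dx = np.zeros_like(x)
        dx[1:] = np.diff(x)
        df[f"{col}_derivative1"] = dx
        df[f"{col}_power2"] = x**2
        df[f"{col}_derivative1_power2"] = dx**2
        lineage.update(new)
    return ConfoundTable(frame=df, lineage=lineage)


def annotate_outliers(
    fd: np.ndarray,
    dvars_std: np.ndarray,
    fd_threshold: float = DEFAULT_FD_THRESHOLD,
    dvars_threshold: float = DEFAULT_DVARS_THRESHOLD,
) -> np.ndarray:
    """Flag frames strictly exceeding either threshold (FD mm, DVARS unitless).

    Strict inequality: a frame exactly at a threshold is not flagged.
    """
    fd = np.asarray(fd, dtype=float)
    dv = np.asarray(dvars_std, dtype=float)
    if fd.shape != dv.shape:
        raise ValueError("FD and DVARS series must have equal length")
    if fd_threshold <= 0 or dvars_threshold <= 0:
        raise ValueError("thresholds must be positive")
    return (fd > fd_threshold) | (dv > dvars_threshold)
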