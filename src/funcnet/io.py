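"""Readers/writers for on-disk formats and the pipeline configuration.

Formats: NIfTI-1 volumes and masks (voxel size and TR read from the
header), whitespace/tab-delimited motion parameters (6 columns,
translations mm then rotations radians by default), tab-separated ROI
tables and connectivity matrices with label headers, CSV/TSV cohort
tables, and JSON sidecars carrying stage parameters and provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .confounds import (
    DEFAULT_ACOMPCOR_BINARIZE,
    DEFAULT_DCT_CUTOFF,
    DEFAULT_DVARS_THRESHOLD,
    DEFAULT_FD_THRESHOLD,
    DEFAULT_JENKINSON_RADIUS,
    DEFAULT_POWER_RADIUS,
    DEFAULT_TCOMPCOR_FRACTION,
    DEFAULT_VARIANCE_TARGET,
    ConfoundTable,
    MotionTrace,
    VolumeSeries,
)
from .connectome import ConnectivityMatrix, RoiTable, RoiTimeSeries
from .stats import RECENCY_CATEGORIES

__all__ = [
    "PipelineConfig",
    "read_nifti_series",
    "write_nifti_series",
    "read_motion_params",
    "read_roi_table",
    "read_cohort_table",
    "read_timeseries",
    "write_timeseries",
    "read_matrix",
    "write_matrix",
    "write_confounds",
]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their standard defaults."""

    roi_table: str | None = None
    data_dir: str | None = None
    covariates: str | None = None
    output_dir: str = "funcnet-out"
    sphere_radius_mm: float = 4.0
    fd_power_radius_mm: float = DEFAULT_POWER_RADIUS
    fd_jenkinson_radius_mm: float = DEFAULT_JENKINSON_RADIUS
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD
    dvars_threshold: float = DEFAULT_DVARS_THRESHOLD
    dct_cutoff_s: float = DEFAULT_DCT_CUTOFF
    tcompcor_fraction: float = DEFAULT_TCOMPCOR_FRACTION
    compcor_variance_target: float = DEFAULT_VARIANCE_TARGET
    acompcor_binarize: float = DEFAULT_ACOMPCOR_BINARIZE
    alpha: float = 0.05
    alpha_remove: float = 0.05
    tr_override: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sphere_radius_mm",
            "fd_power_radius_mm",
            "fd_jenkinson_radius_mm",
            "fd_threshold_mm",
            "dvars_threshold",
            "dct_cutoff_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def read_nifti_series(path: str | Path, tr_override: float | None = None) -> VolumeSeries:
    """Load a 4D NIfTI file; voxel size and TR come from the header."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D NIfTI series, got {data.ndim}D: {path}")
    zooms = img.header.get_zooms()
    tr = tr_override if tr_override is not None else (float(zooms[3]) if len(zooms) > 3 else 0.0)
    if tr <= 0:
        raise ValueError(
            f"no repetition time in the header of {path}; supply tr_override in the config"
        )
    return VolumeSeries(
        data=data, voxel_size=tuple(float(z) for z in zooms[:3]), tr=tr, affine=img.affine
    )


def write_nifti_series(volumes: VolumeSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(volumes.data, volumes.affine)
    zooms = (*volumes.voxel_size, volumes.tr)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_motion_params(
    path: str | Path, tr: float, rotations_first: bool = False
) -> MotionTrace:
    """Whitespace-delimited 6-column motion parameters.

    Default column order is (tx, ty, tz, rx, ry, rz); ``rotations_first``
    accepts the rotations-leading dialect.
    """
    arr = np.loadtxt(str(path), ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"motion file must have 6 columns, found {arr.shape[1]}: {path}")
    if rotations_first:
        arr = arr[:, [3, 4, 5, 0, 1, 2]]
    return MotionTrace(params=arr, tr=tr)


def read_roi_table(path: str | Path) -> RoiTable:
    """Tab-separated ROI table with header columns label, x, y, z (mm)."""
    df = pd.read_csv(str(path), sep="\t")
    if df.empty:
        raise ValueError(f"ROI table is empty: {path}")
    df.columns = [c.lower() for c in df.columns]
    return RoiTable(table=df)


_BOOL_MAP = {"yes": True, "no": False, "1": True, "0": False, "true": True, "false": False}


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Cohort covariates (CSV or TSV): subject_id, age, mtbi_history, ...

    Booleans are accepted as yes/no or 1/0.  Unknown recency categories are
    rejected with the allowed values listed.  Extra columns pass through.
    """
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"cohort table is empty: {path}")
    df.columns = [c.lower() for c in df.columns]
    required = {"subject_id", "age", "mtbi_history"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")

    def to_bool(v):
        s = str(v).strip().lower()
        if s not in _BOOL_MAP:
            raise ValueError(f"unrecognized boolean value {v!r} in mtbi_history")
        return _BOOL_MAP[s]

    df["mtbi_history"] = df["mtbi_history"].map(to_bool)
    if "mtbi_recency" in df.columns:
        vals = df["mtbi_recency"].dropna()
        bad = set(vals) - set(RECENCY_CATEGORIES)
        if bad:
            raise ValueError(
                f"unknown recency categories {sorted(bad)}; allowed: {list(RECENCY_CATEGORIES)}"
            )
        rec_no_hist = df.loc[~df["mtbi_history"], "mtbi_recency"].notna()
        if rec_no_hist.any():
            raise ValueError("recency present for subjects without mTBI history")
    if "mtbi_count" in df.columns:
        neg = pd.to_numeric(df["mtbi_count"], errors="coerce") < 0
        if neg.any():
            raise ValueError("negative mTBI counts are invalid")
        hist_false = ~df["mtbi_history"]
        nonzero = pd.to_numeric(df["mtbi_count"], errors="coerce").fillna(0) > 0
        if (hist_false & nonzero).any():
            raise ValueError("nonzero mTBI count for subjects without history")
    return df


def read_timeseries(path: str | Path, tr: float) -> RoiTimeSeries:
    """Tab-separated frames x ROIs matrix with a label header row."""
    df = pd.read_csv(str(path), sep="\t")
    return RoiTimeSeries(data=df.to_numpy(dtype=float), tr=tr, labels=list(df.columns))


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.data, columns=ts.labels).to_csv(str(path), sep="\t", index=False)


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    """Square TSV with label header row/column plus a JSON stage sidecar."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    df.to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"stage": matrix.stage, "n_rois": matrix.n_rois}))


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = path.with_suffix(path.suffix + ".json")
    stage = "fisher_z_nonneg"
    if sidecar.exists():
        stage = json.loads(sidecar.read_text())["stage"]
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float), stage=stage, labels=[str(c) for c in df.columns]
    )


def write_confounds(
    table: ConfoundTable, path: str | Path, parameters: dict | None = None
) -> None:
    """TSV confound table plus a JSON sidecar with thresholds and lineage."""
    path = Path(path)
    table.frame.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"parameters": parameters or {}, "lineage": table.lineage}, indent=2)
    )
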