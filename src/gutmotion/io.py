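"""File I/O: 4D NIfTI cine volumes, centerline CSV/JSON, segment tables, configs.

World coordinates follow the NIfTI affine; only axis-aligned affines
with positive spacing are accepted (anything else is rejected rather
than silently reinterpreted).  The first ``frames_to_discard`` volumes
of a cine acquisition are dropped on read, matching the protocol of
discarding the initial contrast-artifact frames.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .classify import SegmentRecord
from .errors import FormatError, InvalidCenterlineError
from .geometry import CineVolume

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_cine",
    "write_cine",
    "read_centerline",
    "write_centerline",
    "records_from_csv",
    "records_to_csv",
    "write_json",
]


@dataclass
class RunConfig:
    """Resolved settings of one analysis run; serialises losslessly to YAML."""

    volume: Optional[str] = None
    centerline: Optional[str] = None
    backend: str = "inr"
    frames_to_discard: int = 2
    dt: float = 1.0
    tube_diameter: float = 40.0
    inner_diameter: float = 0.5
    outer_diameter: float = 30.0
    spatial_window: float = 8.0
    temporal_window: float = 3.0
    resample_step: float = 1.0
    reduced_profile: bool = True
    iterations: Optional[int] = None
    min_length_mm: float = 40.0
    folds: int = 5
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _check_affine(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rot = affine[:3, :3]
    spacing = np.abs(np.diag(rot))
    off = rot - np.diag(np.diag(rot))
    if np.any(np.abs(off) > 1e-4 * max(spacing.max(), 1.0)):
        raise FormatError("only axis-aligned (no rotation/shear) affines are supported")
    if np.any(np.diag(rot) <= 0):
        raise FormatError("affine must have positive spacing on the diagonal")
    return spacing, affine[:3, 3].astype(float)


def read_cine(path, frames_to_discard: int = 2, dt: Optional[float] = None) -> list[CineVolume]:
    """Load a 4D NIfTI cine series as a list of frames (in acquisition order).

    ``dt`` falls back to the NIfTI time-axis zoom when present, else 1 s.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"expected a 4D cine volume, got {data.ndim}D data in {path}")
    spacing, origin = _check_affine(img.affine)
    if dt is None:
        zooms = img.header.get_zooms()
        dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if frames_to_discard >= data.shape[3]:
        raise FormatError(
            f"cannot discard {frames_to_discard} of {data.shape[3]} frames"
        )
    if frames_to_discard:
        log.info("discarding first %d of %d frames", frames_to_discard, data.shape[3])
    return [
        CineVolume(data[..., k].astype(float), spacing, origin, time_index=i, dt=dt)
        for i, k in enumerate(range(frames_to_discard, data.shape[3]))
    ]


def write_cine(frames: Sequence[CineVolume], path) -> None:
    """Write frames as one 4D NIfTI file (affine from spacing/origin, dt in zooms)."""
    if not frames:
        raise FormatError("no frames to write")
    ref = frames[0]
    data = np.stack([f.voxels for f in frames], axis=-1)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(ref.spacing)
    affine[:3, 3] = ref.origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((*ref.spacing, ref.dt))
    nib.save(img, str(path))


def read_centerline(path, volume: Optional[CineVolume] = None) -> np.ndarray:
    """Ordered centerline points (world mm) from CSV (x_mm,y_mm,z_mm) or JSON.

    Warns when points fall outside the bounds of ``volume`` (if given).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            raw = json.loads(path.read_text())
            pts = np.asarray(raw, dtype=float)
        except (json.JSONDecodeError, ValueError) as e:
            raise FormatError(f"malformed centerline JSON {path}: {e}") from e
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise FormatError(f"centerline JSON must be a list of [x, y, z], got {pts.shape}")
    else:
        try:
            df = pd.read_csv(path)
        except Exception as e:  # pandas raises several parser error types
            raise FormatError(f"malformed centerline CSV {path}: {e}") from e
        cols = ["x_mm", "y_mm", "z_mm"]
        if not all(c in df.columns for c in cols):
            raise FormatError(f"centerline CSV needs columns {cols}, got {list(df.columns)}")
        numeric = df[cols].apply(pd.to_numeric, errors="coerce")
        if numeric.isna().any().any():
            raise FormatError(f"centerline CSV {path} contains missing/non-numeric rows")
        pts = numeric.to_numpy(dtype=float)
    if len(pts) < 2:
        raise InvalidCenterlineError(f"centerline {path} has fewer than 2 points")
    if volume is not None and not volume.in_bounds(pts).all():
        log.warning("centerline %s has points outside the image bounds", path)
    return pts


def write_centerline(points: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(points, dtype=float), columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        path, index=False
    )


_RECORD_COLUMNS = [
    "segment_id",
    "subject_id",
    "cohort",
    "length_mm",
    "extraction_failed",
    "duplicate_of",
    "reference_motility",
    "reference_direction",
    "mean_velocity",
    "mean_absolute_velocity",
    "predicted_class",
]


def records_from_csv(path) -> list[SegmentRecord]:
    """Segment table reader (one SegmentRecord per row)."""
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise FormatError(f"malformed segment table {path}: {e}") from e
    required = {"segment_id", "subject_id", "cohort", "length_mm"}
    if not required.issubset(df.columns):
        raise FormatError(f"segment table needs columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        def get(col, default=None):
            if col not in df.columns or pd.isna(row[col]):
                return default
            return row[col]

        records.append(
            SegmentRecord(
                segment_id=str(row["segment_id"]),
                subject_id=str(row["subject_id"]),
                cohort=str(row["cohort"]),
                length_mm=float(row["length_mm"]),
                extraction_failed=bool(get("extraction_failed", False)),
                duplicate_of=(None if get("duplicate_of") is None else str(get("duplicate_of"))),
                reference_motility=get("reference_motility"),
                reference_direction=get("reference_direction"),
                mean_velocity=(None if get("mean_velocity") is None else float(get("mean_velocity"))),
                mean_absolute_velocity=(
                    None
                    if get("mean_absolute_velocity") is None
                    else float(get("mean_absolute_velocity"))
                ),
                predicted_class=get("predicted_class"),
            )
        )
    return records


def records_to_csv(records: Sequence[SegmentRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records], columns=_RECORD_COLUMNS).to_csv(
        path, index=False
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")
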