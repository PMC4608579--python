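"""Reading and writing the pipeline's external data.

Time-lapse stacks are multi-page grayscale TIFFs; rosette annotations and
simulation configurations are JSON; per-rosette measures, per-ring profiles
and per-observation velocity dumps are CSV.

Coordinate convention: pixel coordinates are 0-based with x increasing to
the right and y increasing downwards, exactly as stored in the image array
(``frame[y, x]``).  All angles elsewhere in the package are reported in the
mathematical convention (degrees counter-clockwise from the +x axis) after
flipping y; that conversion happens in exactly one place,
:func:`rosettepiv.motion.displacement_to_velocity`.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Point, Polygon


class DataError(ValueError):
    """Raised when an input file violates a documented precondition."""


@dataclasses.dataclass(frozen=True)
class Calibration:
    """Acquisition calibration and analysis thresholds.

    Defaults are the acquisition constants of the imaging setup the
    pipeline was designed around: 0.64 um square pixels, one frame every
    5 minutes, 13 px (8.3 um) square patches, a 15 um/hr motile threshold
    and a 120 um/hr maximal expected speed (which bounds the matching
    search radius).
    """

    pixel_size_um: float = 0.64
    frame_interval_min: float = 5.0
    patch_px: int = 13
    min_speed_um_hr: float = 15.0
    max_speed_um_hr: float = 120.0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "frame_interval_min", "patch_px",
                     "min_speed_um_hr", "max_speed_um_hr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"Calibration.{name} must be strictly positive")

    @property
    def px_per_frame_to_um_hr(self) -> float:
        """Conversion factor from px/frame to um/hr."""
        return self.pixel_size_um * 60.0 / self.frame_interval_min


@dataclasses.dataclass
class TimeLapse:
    """A calibrated multi-frame grayscale stack.

    ``frames`` has shape (n_frames, height, width); all frames share the
    same shape and all intensities are finite.
    """

    frames: np.ndarray
    channel_label: str = "GFP"
    calibration: Calibration = dataclasses.field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DataError(
                "a time-lapse needs a (frames, height, width) stack; "
                "at least 2 frames required"
            )
        if self.frames.shape[0] < 2:
            raise DataError("at least 2 frames required")
        if not np.all(np.isfinite(self.frames)):
            raise DataError("pixel intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclasses.dataclass
class RosetteAnnotation:
    """Manual annotation of one rosette: center point + closed contour.

    The contour is a simple (non-self-intersecting) polygon of >= 3
    vertices in pixel coordinates; the vertex list is implicitly closed.
    The center must lie strictly inside the contour.
    """

    rosette_id: str
    center_px: tuple[float, float]
    contour_px: np.ndarray
    stage: str = "unknown"

    def __post_init__(self) -> None:
        self.contour_px = np.asarray(self.contour_px, dtype=float)
        self.center_px = (float(self.center_px[0]), float(self.center_px[1]))
        if self.contour_px.ndim != 2 or self.contour_px.shape[1] != 2 \
                or self.contour_px.shape[0] < 3:
            raise DataError(
                f"rosette {self.rosette_id!r}: contour needs at least 3 (x, y) vertices"
            )
        poly = Polygon(self.contour_px)
        if not poly.is_valid:
            raise DataError(
                f"rosette {self.rosette_id!r}: contour polygon is self-intersecting"
            )
        if not poly.contains(Point(self.center_px)):
            raise DataError(f"rosette {self.rosette_id!r}: center outside contour")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.contour_px)


def read_timelapse(path: str | Path, calibration: Calibration | None = None,
                   channel_label: str = "GFP") -> TimeLapse:
    """Read a multi-page grayscale TIFF as a :class:`TimeLapse`.

    Frames are ordered by page (acquisition time).  Raises
    :class:`DataError` for a missing file, a single-frame stack, or pages
    of inconsistent shape.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"stack file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    if len(pages) < 2:
        raise DataError("at least 2 frames required")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise DataError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
    if pages[0].ndim != 2:
        raise DataError(f"expected grayscale pages, got shape {pages[0].shape}")
    return TimeLapse(np.stack(pages), channel_label=channel_label,
                     calibration=calibration or Calibration())


def write_timelapse(stack: TimeLapse | np.ndarray, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF (one page per frame)."""
    frames = stack.frames if isinstance(stack, TimeLapse) else np.asarray(stack)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, frames, photometric="minisblack")


def read_annotations(path: str | Path) -> list[RosetteAnnotation]:
    """Read rosette annotations from a JSON file.

    The file holds a list of records, each with ``rosette_id``,
    ``center_px`` ([x, y]), ``contour_px`` ([[x, y], ...]) and ``stage``.
    Every returned annotation satisfies the annotation invariants; a
    violating record raises :class:`DataError` naming the rosette.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"annotation file not found: {path}")
    with open(path) as fh:
        records = json.load(fh)
    if isinstance(records, dict):
        records = records.get("rosettes", [records])
    return [
        RosetteAnnotation(
            rosette_id=str(rec["rosette_id"]),
            center_px=tuple(rec["center_px"]),
            contour_px=np.asarray(rec["contour_px"], dtype=float),
            stage=str(rec.get("stage", "unknown")),
        )
        for rec in records
    ]


def write_annotations(annotations: Sequence[RosetteAnnotation],
                      path: str | Path) -> None:
    records = [
        {
            "rosette_id": a.rosette_id,
            "center_px": list(a.center_px),
            "contour_px": a.contour_px.tolist(),
            "stage": a.stage,
        }
        for a in annotations
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


#: Column order of the per-rosette measures table.
MEASURES_COLUMNS = [
    "rosette_id", "stage", "size_um",
    "rs_deg", "rs_apical_deg", "rs_basal_deg",
    "ba_ratio",
    "speed_um_hr", "speed_apical_um_hr", "speed_basal_um_hr",
    "motile_fraction", "n_motile_obs",
]


def write_measures_table(records: Sequence, path: str | Path) -> None:
    """Write per-rosette measures as CSV, one row per rosette.

    Undefined measures (e.g. B/A with zero apical motions) are written as
    the sentinel text "NA".  Numeric fields survive a write/read round
    trip to within 1e-9.
    """
    if len(records) == 0:
        raise DataError("write_measures_table: empty record list")
    rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records]
    df = pd.DataFrame(rows)[MEASURES_COLUMNS]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="NA", float_format="%.12g")


def read_measures_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"measures table not found: {path}")
    return pd.read_csv(path, na_values=["NA"], keep_default_na=False)
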