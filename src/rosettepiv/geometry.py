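"""Rosette geometry: circle fit, patch grid, radial angles, circular rings.

"Rosette size" is the diameter of the least-squares circle fit to the
annotated contour.  The sub-cellular patch grid tiles the contour's
bounding box with non-overlapping square patches (side = ``patch_px``);
a patch is retained iff its center lies inside the contour and its bounds
lie inside the image.  Expected radial angles are computed from the
manually annotated center; rings are computed from the fitted circle.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from shapely.geometry import Point, Polygon

from .io import Calibration, RosetteAnnotation


@dataclasses.dataclass
class RosetteGeometry:
    """Fitted circle ("rosette size") plus the original annotation."""

    center_px: tuple[float, float]       # fitted circle center
    diameter_px: float
    diameter_um: float
    contour_px: np.ndarray
    annotation: RosetteAnnotation | None = None


@dataclasses.dataclass
class PatchGrid:
    """Retained patches of one rosette, as parallel arrays over patches."""

    side: int
    patch_ids: np.ndarray          # (n,) int, row-major over the candidate grid
    bounds_px: np.ndarray          # (n, 2) int: top-left (x0, y0); side is shared
    centers_px: np.ndarray         # (n, 2) float: patch center (x, y)
    outward_angle_deg: np.ndarray  # (n,) in [0, 360): center -> patch direction
    orientation_deg: np.ndarray    # (n,) in [0, 180): outward mod 180
    ring_index: np.ndarray         # (n,) int in {1..n_rings}

    @property
    def n_patches(self) -> int:
        return len(self.patch_ids)


def fit_rosette_circle(annotation: RosetteAnnotation,
                       calibration: Calibration) -> RosetteGeometry:
    """Least-squares (Kasa) circle fit to the contour vertices.

    The algebraic fit minimizes sum((x-a)^2 + (y-b)^2 - r^2)^2 and is
    exact (zero residual) when the vertices lie on a true circle.
    Raises ``ValueError`` on degenerate (collinear) contours.
    """
    pts = np.asarray(annotation.contour_px, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("degenerate contour: vertices are collinear")
    cx, cy, c = sol
    r = float(np.sqrt(c + cx ** 2 + cy ** 2))
    return RosetteGeometry(
        center_px=(float(cx), float(cy)),
        diameter_px=2.0 * r,
        diameter_um=2.0 * r * calibration.pixel_size_um,
        contour_px=pts,
        annotation=annotation,
    )


def expected_radial_angle(patch_center: tuple[float, float],
                          rosette_center: tuple[float, float],
                          ) -> tuple[float, float]:
    """Outward angle (center -> patch) and its orientation (mod 180).

    Angles are degrees in the mathematical convention (counter-clockwise
    from +x, y flipped from image coordinates).  Raises ``ValueError`` if
    the patch center coincides with the rosette center.
    """
    dx = patch_center[0] - rosette_center[0]
    dy = patch_center[1] - rosette_center[1]
    if dx == 0 and dy == 0:
        raise ValueError("patch center coincides with rosette center")
    outward = float(np.degrees(np.arctan2(-dy, dx))) % 360.0
    return outward, outward % 180.0


def assign_rings(patch_center: tuple[float, float],
                 geometry: RosetteGeometry, n_rings: int = 5) -> int:
    """Ring index in {1..n_rings} at growing distances from the center.

    Rings have equal width (fitted radius / n_rings).  Patches beyond the
    fitted radius but still inside the contour fall in the last ring,
    which is confined by the contour rather than the circle.
    """
    radius = geometry.diameter_px / 2.0
    w = radius / n_rings
    d = float(np.hypot(patch_center[0] - geometry.center_px[0],
                       patch_center[1] - geometry.center_px[1]))
    return min(int(d // w) + 1, n_rings)


def build_patch_grid(geometry: RosetteGeometry, image_shape: tuple[int, int],
                     calibration: Calibration, n_rings: int = 5) -> PatchGrid:
    """Tile the contour with non-overlapping square patches.

    The candidate grid is anchored at the top-left of the contour's
    bounding box with stride = side = ``calibration.patch_px``; patch ids
    are row-major over the candidates.  A candidate is retained iff its
    center lies inside the contour polygon and its bounds lie inside the
    image.  Radial angles use the manually annotated center; ring indices
    use the fitted circle.
    """
    side = int(calibration.patch_px)
    h, w = image_shape
    contour = geometry.contour_px
    poly = Polygon(contour)
    ann_center = (geometry.annotation.center_px if geometry.annotation is not None
                  else geometry.center_px)

    x_min = int(np.floor(contour[:, 0].min()))
    y_min = int(np.floor(contour[:, 1].min()))
    x_max = float(contour[:, 0].max())
    y_max = float(contour[:, 1].max())
    nx = max(int(np.ceil((x_max - x_min) / side)), 0)
    ny = max(int(np.ceil((y_max - y_min) / side)), 0)

    ids, bounds, centers, outward, orient, rings = [], [], [], [], [], []
    half = (side - 1) / 2.0
    pid = 0
    for iy in range(ny):
        for ix in range(nx):
            x0 = x_min + ix * side
            y0 = y_min + iy * side
            this_id = pid
            pid += 1
            cx, cy = x0 + half, y0 + half
            if x0 < 0 or y0 < 0 or x0 + side > w or y0 + side > h:
                continue
            if not poly.contains(Point(cx, cy)):
                continue
            if cx == ann_center[0] and cy == ann_center[1]:
                continue  # radial angle undefined exactly at the center
            out, ori = expected_radial_angle((cx, cy), ann_center)
            ids.append(this_id)
            bounds.append((x0, y0))
            centers.append((cx, cy))
            outward.append(out)
            orient.append(ori)
            rings.append(assign_rings((cx, cy), geometry, n_rings))

    if not ids:
        raise ValueError("contour smaller than one patch: no patches retained")
    return PatchGrid(
        side=side,
        patch_ids=np.asarray(ids, dtype=int),
        bounds_px=np.asarray(bounds, dtype=int),
        centers_px=np.asarray(centers, dtype=float),
        outward_angle_deg=np.asarray(outward, dtype=float),
        orientation_deg=np.asarray(orient, dtype=float),
        ring_index=np.asarray(rings, dtype=int),
    )
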