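"""Patch-based motion estimation by maximal local cross-correlation.

For every patch and every consecutive frame pair, the integer displacement
within a speed-bounded search radius that maximizes the zero-mean
normalized cross-correlation (Pearson correlation on pixels) between the
patch at time t and the shifted window at time t+1 is recorded.  The
displacement is converted to a calibrated speed and a velocity angle, and
the observation is flagged motile iff the speed reaches the calibration's
minimum (slower motions are retained for audit but excluded from every
downstream measure, because small displacements over-quantize the
velocity angle).

Tie-breaking among equally correlated displacements is a documented total
order: smaller squared magnitude first (bias toward "no motion" under
ambiguity), then smaller velocity angle in [0, 360) with the zero
displacement ordered first.  Frames are replicate-padded by the search
radius so boundary patches have complete search windows.  Displacements
are integer pixels only; no sub-pixel refinement is attempted, matching
the quantized-motion design of the measures.
"""
from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd

from .geometry import PatchGrid
from .io import Calibration, TimeLapse


@dataclasses.dataclass
class VelocityField:
    """Per-patch, per-frame-pair displacement observations.

    All arrays have shape (n_patches, n_pairs) where
    n_pairs = n_frames - 1.  ``angle_deg`` is the velocity angle in the
    mathematical convention, NaN where dx = dy = 0.
    """

    dx_px: np.ndarray
    dy_px: np.ndarray
    speed_um_hr: np.ndarray
    angle_deg: np.ndarray
    motile: np.ndarray
    calibration: Calibration

    @property
    def n_pairs(self) -> int:
        return self.dx_px.shape[1]

    @property
    def n_observations(self) -> int:
        return int(self.dx_px.size)

    def to_dataframe(self, grid: PatchGrid | None = None) -> pd.DataFrame:
        """Long-format per-observation table (optionally with patch ids)."""
        n_patches, n_pairs = self.dx_px.shape
        pidx = np.repeat(np.arange(n_patches), n_pairs)
        df = pd.DataFrame({
            "patch_id": (grid.patch_ids[pidx] if grid is not None else pidx),
            "frame": np.tile(np.arange(n_pairs), n_patches),
            "dx_px": self.dx_px.ravel(),
            "dy_px": self.dy_px.ravel(),
            "speed_um_hr": self.speed_um_hr.ravel(),
            "angle_deg": self.angle_deg.ravel(),
            "motile": self.motile.ravel(),
        })
        return df


def search_radius_px(calibration: Calibration) -> int:
    """Search radius from the maximal expected speed.

    Smallest integer r with r >= max_speed_um_hr * dt / (60 * pixel_size),
    never below 1 px.
    """
    r = math.ceil(calibration.max_speed_um_hr * calibration.frame_interval_min
                  / (60.0 * calibration.pixel_size_um))
    return max(int(r), 1)


def displacement_to_velocity(dx_px: np.ndarray, dy_px: np.ndarray,
                             calibration: Calibration,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Convert integer pixel displacements to (speed um/hr, angle deg).

    This is the single place where image coordinates (y down) are flipped
    into the mathematical angle convention: the angle is atan2(-dy, dx)
    in [0, 360), NaN for zero displacement.
    """
    dx = np.asarray(dx_px, dtype=float)
    dy = np.asarray(dy_px, dtype=float)
    speed = np.hypot(dx, dy) * calibration.px_per_frame_to_um_hr
    with np.errstate(invalid="ignore"):
        angle = np.degrees(np.arctan2(-dy, dx)) % 360.0
    angle = np.where((dx == 0) & (dy == 0), np.nan, angle)
    return speed, angle


def _candidate_order_keys(r: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flattened (dy, dx) grids plus the tie-break keys for radius r.

    The tie-break key rows are (squared magnitude, angle); candidates
    outside the Euclidean disk |d| <= r get magnitude key infinity so
    they are never selected (the speed bound is radial, not square).
    """
    dys, dxs = np.mgrid[-r:r + 1, -r:r + 1]
    dxs = dxs.ravel()
    dys = dys.ravel()
    mag2 = (dxs ** 2 + dys ** 2).astype(float)
    ang = np.degrees(np.arctan2(-dys.astype(float), dxs.astype(float))) % 360.0
    ang[mag2 == 0] = -1.0  # zero displacement sorts first
    return dxs, dys, np.stack([mag2, ang])


def _select_best(corr_flat: np.ndarray, keys: np.ndarray) -> int:
    """Index of the max correlation; ties by (magnitude, angle) keys."""
    best = corr_flat.max()
    tied = np.flatnonzero(corr_flat == best)
    if len(tied) == 1:
        return int(tied[0])
    order = np.lexsort((keys[1, tied], keys[0, tied]))
    return int(tied[order[0]])


def _match_in_padded(frame_t: np.ndarray, padded_t1: np.ndarray,
                     x0: int, y0: int, side: int, r: int,
                     dxs: np.ndarray, dys: np.ndarray, keys: np.ndarray,
                     ) -> tuple[int, int] | None:
    """NCC argmax for one patch against an already r-padded next frame.

    Returns None for a zero-variance (flat) patch.
    """
    patch = frame_t[y0:y0 + side, x0:x0 + side]
    p = patch - patch.mean()
    p_norm = float(np.sqrt((p * p).sum()))
    if p_norm == 0.0:
        return None
    region = padded_t1[y0:y0 + side + 2 * r, x0:x0 + side + 2 * r]
    windows = np.lib.stride_tricks.sliding_window_view(region, (side, side))
    wm = windows.mean(axis=(2, 3))
    num = np.einsum("ijkl,kl->ij", windows, p)  # p is zero-mean
    wss = np.einsum("ijkl,ijkl->ij", windows, windows) - side * side * wm ** 2
    w_norm = np.sqrt(np.maximum(wss, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = num / (p_norm * w_norm)
    corr = corr.ravel()
    corr[w_norm.ravel() == 0.0] = -2.0  # flat windows lose to textured ones
    corr[keys[0] > r * r] = -3.0        # outside the speed disk
    k = _select_best(corr, keys)
    return int(dxs[k]), int(dys[k]), float(corr[k])


def match_patch(frame_t: np.ndarray, frame_t1: np.ndarray,
                patch_bounds: tuple[int, int, int], r: int) -> tuple[int, int]:
    """Best integer displacement of one patch between two frames.

    ``patch_bounds`` is (x0, y0, side).  Frames are replicate-padded by r
    so every candidate window exists.  Returns (dx, dy) maximizing the
    zero-mean normalized cross-correlation; a zero-variance (flat) patch
    returns (0, 0).  Candidate windows with zero variance are never
    selected over a textured one.
    """
    x0, y0, side = patch_bounds
    padded = np.pad(np.asarray(frame_t1, dtype=float), r, mode="edge")
    dxs, dys, keys = _candidate_order_keys(r)
    res = _match_in_padded(np.asarray(frame_t, dtype=float), padded,
                           x0, y0, side, r, dxs, dys, keys)
    return (0, 0) if res is None else (res[0], res[1])


#: Minimum acceptable peak correlation for a displacement observation.
#: Matches below it carry no evidence of coherent local motion (the peak
#: of a signal-free patch against ~1000 candidate windows stays well
#: below this) and are treated like flat patches: (0, 0), non-motile.
MIN_PEAK_CORR = 0.5


def compute_velocity_field(stack: TimeLapse, grid: PatchGrid,
                           min_corr: float = MIN_PEAK_CORR) -> VelocityField:
    """One displacement observation per (patch, consecutive frame pair).

    Observations whose correlation peak falls below ``min_corr`` — the
    standard particle-image-velocimetry quality gate against spurious
    peaks — are recorded as (0, 0) and non-motile.
    """
    cal = stack.calibration
    r = search_radius_px(cal)
    n_patches = grid.n_patches
    n_pairs = stack.n_frames - 1
    dx = np.zeros((n_patches, n_pairs), dtype=int)
    dy = np.zeros((n_patches, n_pairs), dtype=int)
    n_flat = 0
    n_low = 0
    frames = np.asarray(stack.frames, dtype=float)
    side = grid.side
    dxs, dys, keys = _candidate_order_keys(r)
    for t in range(n_pairs):
        f0 = frames[t]
        padded = np.pad(frames[t + 1], r, mode="edge")
        for i in range(n_patches):
            x0, y0 = grid.bounds_px[i]
            res = _match_in_padded(f0, padded, x0, y0, side, r, dxs, dys, keys)
            if res is None:
                n_flat += 1
                continue
            if res[2] < min_corr:
                n_low += 1
                continue
            dx[i, t], dy[i, t] = res[0], res[1]
    if n_flat:
        warnings.warn(f"{n_flat} flat (zero-variance) patch observations "
                      "marked non-motile", stacklevel=2)
    if n_low:
        warnings.warn(f"{n_low} low-confidence matches (peak correlation < "
                      f"{min_corr}) marked non-motile", stacklevel=2)
    speed, angle = displacement_to_velocity(dx, dy, cal)
    motile = speed >= cal.min_speed_um_hr
    return VelocityField(dx_px=dx, dy_px=dy, speed_um_hr=speed,
                         angle_deg=angle, motile=motile, calibration=cal)
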