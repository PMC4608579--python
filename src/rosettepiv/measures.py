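"""Rosette-level readouts of interkinetic nuclear migration.

Three core measures summarize one rosette movie:

* **Radial Score (RS)** — the mean angular alignment gamma between each
  motile patch velocity and its expected radial orientation, pooled over
  all patches and frame pairs.  gamma folds the angle difference into
  [0, 90] degrees, so apically and basally directed radial motion both
  score 0 and uniformly random motion averages 45.  Lower RS = more
  radially organized.
* **B/A ratio** — the count of basally directed motile observations
  (velocity within 90 degrees of the outward radial direction) divided by
  the apically directed count; 1 means equal numbers, > 1 more motion
  toward the periphery.
* **Speed** — the mean velocity magnitude (um/hr) over motile
  observations, overall and split by direction class.

Observations slower than the calibrated motile threshold are excluded
from every measure.  Undefined measures (empty subsets, zero apical
count) are NaN and serialize as "NA".  Temporal profiles recompute each
measure per frame pair and record the sample variance ("functional
instability") and the least-squares slope over time; ring profiles
recompute them per circular ring.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import PatchGrid, RosetteGeometry
from .motion import VelocityField


@dataclasses.dataclass
class RosetteMeasures:
    """One scalar record per rosette; NaN encodes undefined ("NA")."""

    rosette_id: str
    stage: str
    size_um: float
    rs_deg: float
    rs_apical_deg: float
    rs_basal_deg: float
    ba_ratio: float
    speed_um_hr: float
    speed_apical_um_hr: float
    speed_basal_um_hr: float
    motile_fraction: float
    n_motile_obs: int


@dataclasses.dataclass
class TemporalProfile:
    """Per-frame-pair measure series with variance and trend slope."""

    per_frame: pd.DataFrame     # columns: frame, rs_deg, ba_ratio, speed_um_hr, n_motile
    variance_rs: float
    variance_ba: float
    variance_speed: float
    slope_rs: float
    slope_ba: float
    slope_speed: float


def angular_alignment(velocity_angle_deg, expected_orientation_deg):
    """Angular alignment gamma in [0, 90] degrees.

    gamma = fold(|velocity - orientation| mod 180) with
    fold(a) = min(a, 180 - a), so parallel and anti-parallel radial
    motion both score 0 and perpendicular motion scores 90.
    """
    a = np.abs(np.asarray(velocity_angle_deg, dtype=float)
               - np.asarray(expected_orientation_deg, dtype=float)) % 180.0
    return np.minimum(a, 180.0 - a)


def classify_direction(velocity_angle_deg, outward_angle_deg):
    """Classify motile velocities as basal (outward) or apical (inward).

    A velocity within 90 degrees of the outward radial direction is
    basal, beyond 90 apical; exactly 90 is basal (fixed tie-break).
    Returns a boolean array (or scalar) that is True for basal.
    """
    d = np.abs(np.asarray(velocity_angle_deg, dtype=float)
               - np.asarray(outward_angle_deg, dtype=float)) % 360.0
    delta = np.minimum(d, 360.0 - d)
    return delta <= 90.0


def _obs_arrays(field: VelocityField, grid: PatchGrid):
    """Per-observation (gamma, basal, speed, motile, frame, ring) arrays."""
    n_patches, n_pairs = field.dx_px.shape
    orient = np.repeat(grid.orientation_deg[:, None], n_pairs, axis=1)
    outward = np.repeat(grid.outward_angle_deg[:, None], n_pairs, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gamma = angular_alignment(field.angle_deg, orient)
        basal = classify_direction(field.angle_deg, outward)
    return gamma, basal


def radial_score(field: VelocityField, grid: PatchGrid,
                 subset: str = "all") -> float:
    """Mean angular alignment over motile observations (pooled over time).

    ``subset`` selects all motile observations or only the apically /
    basally directed ones.  NaN when the subset is empty.
    """
    gamma, basal = _obs_arrays(field, grid)
    mask = field.motile.copy()
    if subset == "apical":
        mask &= ~basal
    elif subset == "basal":
        mask &= basal
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if not mask.any():
        return float("nan")
    return float(gamma[mask].mean())


def ba_ratio(field: VelocityField, grid: PatchGrid) -> float:
    """Basal over apical motile observation counts; NaN if no apical."""
    _, basal = _obs_arrays(field, grid)
    n_basal = int((field.motile & basal).sum())
    n_apical = int((field.motile & ~basal).sum())
    if n_apical == 0:
        warnings.warn("B/A ratio undefined: zero apical motile observations",
                      stacklevel=2)
        return float("nan")
    return n_basal / n_apical


def mean_speed(field: VelocityField, grid: PatchGrid | None = None,
               subset: str = "all") -> float:
    """Mean speed (um/hr) over motile observations in the subset."""
    mask = field.motile.copy()
    if subset in ("apical", "basal"):
        if grid is None:
            raise ValueError("grid required for direction subsets")
        _, basal = _obs_arrays(field, grid)
        mask &= basal if subset == "basal" else ~basal
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if not mask.any():
        return float("nan")
    return float(field.speed_um_hr[mask].mean())


def motile_fraction(field: VelocityField) -> float:
    """Fraction of all observations at or above the motile threshold."""
    if field.n_observations == 0:
        raise ValueError("empty velocity field")
    return float(field.motile.mean())


def compute_measures(field: VelocityField, grid: PatchGrid,
                     geometry: RosetteGeometry, rosette_id: str,
                     stage: str = "unknown") -> RosetteMeasures:
    """All scalar per-rosette measures in one record."""
    gamma, basal = _obs_arrays(field, grid)
    return RosetteMeasures(
        rosette_id=rosette_id,
        stage=stage,
        size_um=geometry.diameter_um,
        rs_deg=radial_score(field, grid, "all"),
        rs_apical_deg=radial_score(field, grid, "apical"),
        rs_basal_deg=radial_score(field, grid, "basal"),
        ba_ratio=ba_ratio(field, grid),
        speed_um_hr=mean_speed(field, grid, "all"),
        speed_apical_um_hr=mean_speed(field, grid, "apical"),
        speed_basal_um_hr=mean_speed(field, grid, "basal"),
        motile_fraction=motile_fraction(field),
        n_motile_obs=int(field.motile.sum()),
    )


def _series_variance_slope(frames: np.ndarray, values: np.ndarray,
                           ) -> tuple[float, float]:
    """Sample variance and OLS slope of a series; NaN-valued frames skipped."""
    ok = np.isfinite(values)
    if ok.sum() < 2:
        return float("nan"), float("nan")
    v = float(np.var(values[ok], ddof=1))
    slope = float(sps.linregress(frames[ok], values[ok]).slope) \
        if len(np.unique(frames[ok])) > 1 else float("nan")
    return v, slope


def temporal_profile(field: VelocityField, grid: PatchGrid) -> TemporalProfile:
    """Per-frame measures, their temporal variance and trend slope.

    Each measure is recomputed independently for every frame pair from
    that pair's motile observations; frames with no motile observations
    (or, for B/A, no apical ones) carry NaN and are skipped in the
    variance and slope.  Variance is the sample (n-1) variance; the slope
    is the least-squares slope of measure vs frame index, a stationarity
    check for the imaging course.
    """
    gamma, basal = _obs_arrays(field, grid)
    n_pairs = field.n_pairs
    rs = np.full(n_pairs, np.nan)
    ba = np.full(n_pairs, np.nan)
    sp = np.full(n_pairs, np.nan)
    n_mot = np.zeros(n_pairs, dtype=int)
    for t in range(n_pairs):
        m = field.motile[:, t]
        n_mot[t] = int(m.sum())
        if n_mot[t] == 0:
            continue
        rs[t] = gamma[m, t].mean()
        sp[t] = field.speed_um_hr[m, t].mean()
        n_ap = int((m & ~basal[:, t]).sum())
        if n_ap > 0:
            ba[t] = int((m & basal[:, t]).sum()) / n_ap
    frames = np.arange(n_pairs)
    var_rs, slope_rs = _series_variance_slope(frames, rs)
    var_ba, slope_ba = _series_variance_slope(frames, ba)
    var_sp, slope_sp = _series_variance_slope(frames, sp)
    per_frame = pd.DataFrame({"frame": frames, "rs_deg": rs, "ba_ratio": ba,
                              "speed_um_hr": sp, "n_motile": n_mot})
    return TemporalProfile(per_frame=per_frame,
                           variance_rs=var_rs, variance_ba=var_ba,
                           variance_speed=var_sp, slope_rs=slope_rs,
                           slope_ba=slope_ba, slope_speed=slope_sp)


def ring_profile(field: VelocityField, grid: PatchGrid,
                 n_rings: int = 5) -> pd.DataFrame:
    """RS, B/A and speed per circular ring, pooled over time.

    Returns one row per ring index 1..n_rings with NaN for empty rings.
    """
    gamma, basal = _obs_arrays(field, grid)
    rows = []
    for ring in range(1, n_rings + 1):
        sel = grid.ring_index == ring
        m = field.motile[sel]
        g = gamma[sel]
        b = basal[sel]
        s = field.speed_um_hr[sel]
        n_mot = int(m.sum())
        rs = float(g[m].mean()) if n_mot else float("nan")
        speed = float(s[m].mean()) if n_mot else float("nan")
        n_ap = int((m & ~b).sum())
        ba = (int((m & b).sum()) / n_ap) if n_ap > 0 else float("nan")
        rows.append({"ring_index": ring, "rs_deg": rs, "ba_ratio": ba,
                     "speed_um_hr": speed, "n_motile": n_mot})
    return pd.DataFrame(rows)
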