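"""Synthetic rosette movies with known ground truth.

The generator emulates the statistical structure the analysis assumes:
granule-textured nuclei packed inside a circular rosette, a configurable
fraction of which performs interkinetic nuclear migration along fixed
radial rays — synchronized apical excursions at the apical speed
followed by slower basal returns — while the rest, a contiguous wedge of
differentiated-like cells, stays put.  Because the basal return of each
excursion is slower than its apical leg, basally directed observations
outnumber apical ones by the speed ratio, reproducing the mild basal
excess seen in rosette recordings; an optional antiphase sub-wedge pulls
that ratio toward 1.  A ``random_motion`` mode instead redraws each
motile nucleus's direction uniformly on [0, 360) every frame, the
non-rosette negative control.

Phase-coherent migration keeps the relative geometry of the tissue
frozen in polar coordinates, so the texture inside any analysis patch
translates rigidly between frames — the assumption patch correlation
relies on, and the 2-D stand-in for the third dimension in which a real
pseudostratified epithelium resolves counter-migrating nuclei.  Angular
noise enters as a bounded tangential wobble shared by the migrating
cohort, with the radial step scaled so the full step magnitude always
equals the configured speed.

Each nucleus is rendered as a fixed, distinctive constellation of small
Gaussian granules (chromatin-like speckle) bounded by a radially
elongated ellipse, plus per-frame additive background noise.  The
internal texture matters: normalized cross-correlation is invariant to
brightness, so featureless identical blobs would be mutually
indistinguishable within the search radius, which real fluorescence
texture never is.

All randomness derives from the single config seed in a documented
order (placement, motility wedge, brightness, granules, then per-frame
phase, wobble and pixel noise), so output is bit-reproducible.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Calibration, RosetteAnnotation, TimeLapse


@dataclasses.dataclass
class SimulationConfig:
    """Generative parameters of one synthetic rosette movie.

    Speeds are in um/hr and must not exceed the calibration's maximal
    speed; the default speeds and motile fraction are early-radial-glial
    (E-RG)-like.  ``brightness_jitter`` spreads per-nucleus blob
    amplitudes uniformly in [1 - j, 1 + j], which keeps patch dominance
    unambiguous where blobs overlap.
    """

    image_size_px: int = 192
    center_px: tuple[float, float] = (96.0, 96.0)
    rosette_radius_px: float = 60.0
    lumen_radius_px: float = 12.0
    n_nuclei: int = 250
    nucleus_sigma_px: float = 2.5
    radial_exclusion_px: float = 14.0
    tangential_exclusion_px: float = 8.0
    blocking_distance_px: float = 10.0
    motile_fraction: float = 0.6
    apical_speed_um_hr: float = 38.81
    basal_speed_um_hr: float = 35.27
    antiphase_fraction: float = 0.0
    angular_noise_sd_deg: float = 35.0
    background_noise_sd: float = 0.02
    background_texture_amp: float = 0.0
    brightness_jitter: float = 0.4
    n_frames: int = 50
    calibration: Calibration = dataclasses.field(default_factory=Calibration)
    mode: str = "rosette"
    stage: str = "E-RG-like"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.motile_fraction <= 1.0:
            raise ValueError("motile_fraction must be in [0, 1]")
        if not 0.0 <= self.antiphase_fraction <= 1.0:
            raise ValueError("antiphase_fraction must be in [0, 1]")
        if self.angular_noise_sd_deg < 0:
            raise ValueError("angular_noise_sd_deg must be >= 0")
        for name in ("apical_speed_um_hr", "basal_speed_um_hr"):
            if getattr(self, name) > self.calibration.max_speed_um_hr:
                raise ValueError(f"{name} exceeds calibration.max_speed_um_hr")
        if self.mode not in ("rosette", "random_motion"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.lumen_radius_px < self.rosette_radius_px:
            raise ValueError("need 0 < lumen_radius_px < rosette_radius_px")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["calibration"] = dataclasses.asdict(self.calibration)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["calibration"] = Calibration(**d["calibration"])
        d["center_px"] = tuple(d["center_px"])
        return cls(**d)


@dataclasses.dataclass
class GroundTruth:
    """True per-nucleus, per-frame state of a generated movie.

    ``table`` has one row per (nucleus, frame) with columns nucleus_id,
    frame, x, y, direction and true_speed_um_hr.  ``direction``
    (apical/basal/none) and ``true_speed_um_hr`` describe the step taken
    from this frame to the next; the last frame and static nuclei carry
    "none" and speed 0.
    """

    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False, float_format="%.6f")


#: Granules per nucleus and their geometry relative to nucleus_sigma_px.
N_GRANULES = 18
_GRANULE_RADIAL_SEMI = 2.8       # ellipse semi-axis along the radial axis
_GRANULE_TANGENTIAL_SEMI = 1.8   # ellipse semi-axis across it
_GRANULE_SIGMA_RANGE = (0.32, 0.64)  # x nucleus_sigma_px


def _sample_granules(cfg: SimulationConfig, positions: np.ndarray,
                     rng: np.random.Generator,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed per-nucleus internal texture: granule offsets, amplitudes, sizes.

    Each nucleus is a cloud of small Gaussian granules placed uniformly
    in an ellipse elongated along the nucleus's radial axis, emulating
    the radially oriented nuclei of a pseudostratified epithelium.  The
    granules are spread wider than their individual size, so each
    nucleus presents a distinctive multi-point constellation to the
    correlator: granules tighter than their own width would blur into
    one featureless blob, and any blob matches any other blob almost
    perfectly under normalized cross-correlation.  The offsets are
    hard-bounded by the ellipse, which keeps one nucleus's texture from
    flooding its neighbours' territory.
    """
    sig = cfg.nucleus_sigma_px
    rr = np.sqrt(rng.random((cfg.n_nuclei, N_GRANULES)))
    th = rng.uniform(0.0, 2 * np.pi, (cfg.n_nuclei, N_GRANULES))
    if cfg.mode == "random_motion":
        # non-rosette texture carries no radial anisotropy (an elongated
        # pattern self-correlates along its axis and would bias the
        # estimated directions toward it)
        semi_along = semi_across = np.sqrt(_GRANULE_RADIAL_SEMI
                                           * _GRANULE_TANGENTIAL_SEMI)
    else:
        semi_along = _GRANULE_RADIAL_SEMI
        semi_across = _GRANULE_TANGENTIAL_SEMI
    along = semi_along * sig * rr * np.cos(th)
    across = semi_across * sig * rr * np.sin(th)
    cx, cy = cfg.center_px
    ang = np.arctan2(positions[:, 1] - cy, positions[:, 0] - cx)
    cos, sin = np.cos(ang)[:, None], np.sin(ang)[:, None]
    offsets = np.stack([along * cos - across * sin,
                        along * sin + across * cos], axis=-1)
    g_amps = rng.uniform(0.4, 1.6, size=(cfg.n_nuclei, N_GRANULES))
    g_sigmas = rng.uniform(*_GRANULE_SIGMA_RANGE,
                           size=(cfg.n_nuclei, N_GRANULES)) * cfg.nucleus_sigma_px
    return offsets, g_amps, g_sigmas


def _static_background(cfg: SimulationConfig,
                       rng: np.random.Generator) -> np.ndarray | None:
    """Fixed dim background texture (out-of-focus autofluorescence).

    A smooth random field that does not move between frames; it anchors
    patches without nuclear signal to zero displacement, as stationary
    background does in real recordings.
    """
    if cfg.background_texture_amp <= 0:
        return None
    from scipy.ndimage import gaussian_filter
    n = cfg.image_size_px
    field = gaussian_filter(rng.normal(size=(n, n)), 1.5)
    return field * (cfg.background_texture_amp / field.std())


def _render(positions: np.ndarray, amps: np.ndarray,
            granule_offsets: np.ndarray, granule_amps: np.ndarray,
            granule_sigmas: np.ndarray, static_bg: np.ndarray | None,
            cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """One frame: granule-textured nuclei plus background texture + noise."""
    n = cfg.image_size_px
    frame = np.zeros((n, n), dtype=float)
    if static_bg is not None:
        frame += static_bg
    for i, ((x, y), amp) in enumerate(zip(positions, amps)):
        for (ox, oy), ga, gs in zip(granule_offsets[i], granule_amps[i],
                                    granule_sigmas[i]):
            gx, gy = x + ox, y + oy
            ext = int(np.ceil(4 * gs))
            x0 = max(int(np.floor(gx)) - ext, 0)
            x1 = min(int(np.ceil(gx)) + ext + 1, n)
            y0 = max(int(np.floor(gy)) - ext, 0)
            y1 = min(int(np.ceil(gy)) + ext + 1, n)
            if x0 >= x1 or y0 >= y1:
                continue
            ys = np.arange(y0, y1)[:, None]
            xs = np.arange(x0, x1)[None, :]
            frame[y0:y1, x0:x1] += amp * ga * np.exp(
                -((xs - gx) ** 2 + (ys - gy) ** 2) / (2 * gs ** 2))
    if cfg.background_noise_sd > 0:
        frame += rng.normal(0.0, cfg.background_noise_sd, size=frame.shape)
    return frame.astype(np.float32)


def _place_nuclei(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing placement with an anisotropic exclusion zone.

    Candidates are drawn uniformly by area between the lumen and the
    rosette radius and accepted only if outside every accepted nucleus's
    elliptical exclusion zone — elongated along the radial axis
    (``radial_exclusion_px``) and tight across it
    (``tangential_exclusion_px``) — matching the packing of elongated,
    radially oriented nuclei in a pseudostratified epithelium.  The
    radial exclusion keeps radial neighbours, which move against each
    other during interkinetic migration, from overlapping inside one
    analysis patch.  Placement stops at ``n_nuclei`` accepted or at
    saturation, so the realized count can be smaller than requested.
    """
    cx, cy = cfg.center_px
    accepted: list[tuple[float, float]] = []
    ra = cfg.radial_exclusion_px
    ta = cfg.tangential_exclusion_px
    attempts = 0
    since_last = 0
    max_attempts = 300 * max(cfg.n_nuclei, 1)
    while len(accepted) < cfg.n_nuclei and attempts < max_attempts \
            and since_last < 1500:  # saturation: stop when nothing fits
        attempts += 1
        since_last += 1
        r = np.sqrt(rng.uniform(cfg.lumen_radius_px ** 2,
                                cfg.rosette_radius_px ** 2))
        th = rng.uniform(0.0, 2 * np.pi)
        x, y = cx + r * np.cos(th), cy + r * np.sin(th)
        ur = (np.cos(th), np.sin(th))
        ok = True
        for ax, ay in accepted:
            dx, dy = ax - x, ay - y
            dr = dx * ur[0] + dy * ur[1]
            dt = -dx * ur[1] + dy * ur[0]
            if (dr / ra) ** 2 + (dt / ta) ** 2 < 1.0:
                ok = False
                break
        if ok:
            accepted.append((x, y))
            since_last = 0
    if not accepted:
        raise ValueError("could not place any nuclei")
    return np.asarray(accepted, dtype=float)


def _blocked(candidate: np.ndarray, others: np.ndarray, i: int,
             blocking_distance: float) -> bool:
    """True if the candidate position sits within blocking distance of
    any other nucleus (steric exclusion maintained throughout the movie)."""
    d = np.hypot(others[:, 0] - candidate[0], others[:, 1] - candidate[1])
    d[i] = np.inf
    return bool((d < blocking_distance).any())


class _RosetteDynamics:
    """Synchronized interkinetic migration waves on fixed rays.

    Each nucleus lives on a fixed ray through the rosette center.  All
    motile nuclei migrate in phase: an apical leg at the apical speed
    down to a per-cycle excursion amplitude, then a basal leg at the
    basal speed back out.  Because the basal leg is slower, it spans
    more frames than the apical leg of the same excursion, so basally
    directed observations outnumber apical ones by the speed ratio —
    the emergent basal-to-apical ratio.  Excursion amplitudes are
    redrawn each cycle so leg durations are not locked to one frame
    count.  Angular noise is a shared, bounded tangential wobble; the
    radial step is scaled so the full step magnitude always equals the
    configured speed.  Phase-coherent motion freezes the relative
    geometry of the tissue in polar coordinates: nuclei never collide,
    and the texture inside any analysis patch translates rigidly — the
    assumption the patch correlator relies on.  (A pseudostratified
    epithelium resolves counter-migrating nuclei in the third
    dimension, which a 2-D simulator cannot; phase coherence is the
    2-D analogue that preserves the observable statistics.)
    """

    EXCURSION_RANGE = (10.0, 16.0)  # px, redrawn every cycle

    def __init__(self, cfg: SimulationConfig, pos: np.ndarray,
                 ap_px: float, ba_px: float) -> None:
        cx, cy = cfg.center_px
        self.cfg = cfg
        self.cx, self.cy = cx, cy
        self.theta = np.arctan2(pos[:, 1] - cy, pos[:, 0] - cx)
        self.radius = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy)
        self.ux, self.uy = np.cos(self.theta), np.sin(self.theta)
        self.tx, self.ty = -self.uy, self.ux
        self.ap_px, self.ba_px = ap_px, ba_px
        self.wobble = 0.0            # shared tangential offset
        self.wob_max = cfg.tangential_exclusion_px / 2.0
        self.tan_noise = np.tan(np.deg2rad(min(cfg.angular_noise_sd_deg,
                                               60.0)))
        self.leg = 0                 # start on an apical leg
        self.u = 0.0                 # radial phase offset (<= 0)
        self.amplitude = 0.0         # drawn on first step

    def positions(self, motile: np.ndarray | None = None) -> np.ndarray:
        w = self.wobble if motile is None else np.where(motile, self.wobble,
                                                        0.0)
        return np.column_stack([
            self.cx + self.radius * self.ux + w * self.tx,
            self.cy + self.radius * self.uy + w * self.ty])

    def step(self, motile: np.ndarray, rng: np.random.Generator,
             antiphase: np.ndarray | None = None,
             ) -> tuple[np.ndarray, np.ndarray]:
        """Advance one frame; returns (direction labels, true speeds).

        ``antiphase`` marks motile nuclei migrating in opposite phase
        (basal while the majority is apical and vice versa); a nonzero
        antiphase share pulls the emergent basal-to-apical ratio from
        the speed ratio toward 1.
        """
        cfg = self.cfg
        n = cfg.n_nuclei
        if antiphase is None:
            antiphase = np.zeros(n, dtype=bool)
        main = motile & ~antiphase
        anti = motile & antiphase
        if self.amplitude == 0.0:
            self.amplitude = rng.uniform(*self.EXCURSION_RANGE)
        sp = self.ba_px if self.leg == 1 else self.ap_px
        sp_anti = self.ap_px if self.leg == 1 else self.ba_px
        dw_raw = float(np.clip(rng.normal(0.0, 1.0) * self.tan_noise * sp,
                               -0.9 * min(sp, sp_anti),
                               0.9 * min(sp, sp_anti)))
        new_w = float(np.clip(self.wobble + dw_raw, -self.wob_max,
                              self.wob_max))
        dw = new_w - self.wobble
        dr = float(np.sqrt(max(sp ** 2 - dw ** 2, 0.0)))
        dr_anti = float(np.sqrt(max(sp_anti ** 2 - dw ** 2, 0.0)))
        sgn = 1.0 if self.leg == 1 else -1.0

        self.radius[main] += sgn * dr
        self.radius[anti] -= sgn * dr_anti
        self.wobble = new_w
        self.u += sgn * dr
        direction = np.array(["none"] * n, dtype=object)
        true_speed = np.zeros(n)
        direction[main] = "basal" if self.leg == 1 else "apical"
        direction[anti] = "apical" if self.leg == 1 else "basal"
        true_speed[main] = sp * cfg.calibration.px_per_frame_to_um_hr
        true_speed[anti] = sp_anti * cfg.calibration.px_per_frame_to_um_hr

        # phase turnaround: apical until the excursion amplitude is
        # reached (or the innermost migrating nucleus touches the
        # center), basal until back at the home radius, then a new cycle
        r_min = self.radius[main].min() if main.any() else np.inf
        if self.leg == 0 and (self.u <= -self.amplitude or r_min - dr < 2.0):
            self.leg = 1
        elif self.leg == 1 and self.u >= 0.0:
            self.leg = 0
            self.amplitude = rng.uniform(*self.EXCURSION_RANGE)
        return direction, true_speed


def _motile_wedge(cfg: SimulationConfig, theta: np.ndarray,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(motile, antiphase) masks; non-motile nuclei form one wedge.

    Non-migrating (differentiated) cells cluster spatially rather than
    scatter among migrating ones; a contiguous static domain also keeps
    the motile/static interface — where patch observations mix moving
    and resting texture — as small as possible.  The wedge size realizes
    ``motile_fraction`` to the nearest nucleus, and the antiphase
    sub-wedge ``antiphase_fraction`` of the motile nuclei.
    """
    n = cfg.n_nuclei
    n_static = int(round((1.0 - cfg.motile_fraction) * n))
    start = rng.uniform(0.0, 2 * np.pi)
    order = np.argsort((theta - start) % (2 * np.pi))
    motile = np.ones(n, dtype=bool)
    motile[order[:n_static]] = False
    antiphase = np.zeros(n, dtype=bool)
    n_anti = int(round(cfg.antiphase_fraction * (n - n_static)))
    # antiphase sub-wedge sits right after the static wedge, so it adds
    # only one extra motile/antiphase interface
    antiphase[order[n_static:n_static + n_anti]] = True
    return motile, antiphase


def _contour_polygon(cfg: SimulationConfig, n_vertices: int = 24) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    cx, cy = cfg.center_px
    return np.column_stack([cx + cfg.rosette_radius_px * np.cos(theta),
                            cy + cfg.rosette_radius_px * np.sin(theta)])


def generate_rosette_movie(config: SimulationConfig,
                           ) -> tuple[TimeLapse, RosetteAnnotation, GroundTruth]:
    """Simulate one movie; dispatches on ``config.mode``.

    Returns the rendered stack, the matching annotation (contour = regular
    polygon on the rosette circle, center = rosette center) and the
    ground-truth trajectory table.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cal = cfg.calibration
    um_hr_to_px_frame = 1.0 / cal.px_per_frame_to_um_hr

    # initialization order is part of the reproducibility contract
    cx, cy = cfg.center_px
    pos = _place_nuclei(cfg, rng)
    cfg = dataclasses.replace(cfg, n_nuclei=len(pos))
    if cfg.mode == "rosette":
        theta = np.arctan2(pos[:, 1] - cfg.center_px[1],
                           pos[:, 0] - cfg.center_px[0])
        motile, antiphase = _motile_wedge(cfg, theta, rng)
    else:
        motile = rng.random(cfg.n_nuclei) < cfg.motile_fraction
        antiphase = np.zeros(cfg.n_nuclei, dtype=bool)
    amps = rng.uniform(1.0 - cfg.brightness_jitter, 1.0 + cfg.brightness_jitter,
                       cfg.n_nuclei)
    granule_offsets, granule_amps, granule_sigmas = _sample_granules(cfg, pos,
                                                                     rng)
    static_bg = _static_background(cfg, rng)
    ap_px = cfg.apical_speed_um_hr * um_hr_to_px_frame
    ba_px = cfg.basal_speed_um_hr * um_hr_to_px_frame

    frames = []
    rows = []
    dyn = (_RosetteDynamics(cfg, pos, ap_px, ba_px)
           if cfg.mode == "rosette" else None)
    if dyn is not None:
        pos = dyn.positions(motile)
    for f in range(cfg.n_frames):
        frames.append(_render(pos, amps, granule_offsets, granule_amps,
                              granule_sigmas, static_bg, cfg, rng))
        last = f == cfg.n_frames - 1
        # decide the step from frame f to f+1 (direction/speed recorded
        # on frame f's ground-truth row; the last frame takes no step)
        new_pos = pos.copy()
        direction = np.array(["none"] * cfg.n_nuclei, dtype=object)
        true_speed = np.zeros(cfg.n_nuclei)
        if not last and cfg.mode == "random_motion":
            step_dirs = rng.uniform(0.0, 2 * np.pi, cfg.n_nuclei)
            for i in range(cfg.n_nuclei):
                if not motile[i]:
                    continue
                ang = step_dirs[i]
                step = ap_px * np.array([np.cos(ang), np.sin(ang)])
                new = pos[i] + step
                if np.hypot(new[0] - cx, new[1] - cy) > cfg.rosette_radius_px:
                    new = pos[i] - step  # reflect back inside
                if _blocked(new, new_pos, i, cfg.blocking_distance_px):
                    continue  # crowded: stay put this frame
                new_pos[i] = new
                true_speed[i] = cfg.apical_speed_um_hr
        elif not last:
            direction, true_speed = dyn.step(motile, rng, antiphase)
            new_pos = dyn.positions(motile)
        for i in range(cfg.n_nuclei):
            rows.append((i, f, pos[i, 0], pos[i, 1], direction[i],
                         true_speed[i]))
        pos = new_pos

    stack = TimeLapse(np.stack(frames), channel_label="synthetic-GFP",
                      calibration=cal)
    annotation = RosetteAnnotation(
        rosette_id=f"sim-{cfg.seed}",
        center_px=cfg.center_px,
        contour_px=_contour_polygon(cfg),
        stage=cfg.stage,
    )
    gt = GroundTruth(pd.DataFrame(
        rows, columns=["nucleus_id", "frame", "x", "y", "direction",
                       "true_speed_um_hr"]))
    return stack, annotation, gt


def generate_random_motion_movie(config: SimulationConfig,
                                 ) -> tuple[TimeLapse, RosetteAnnotation, GroundTruth]:
    """Non-rosette control: directions redrawn uniformly every frame."""
    if config.mode != "random_motion":
        config = dataclasses.replace(config, mode="random_motion")
    return generate_rosette_movie(config)


_PRESETS: dict[str, dict] = {
    # Stage-like cohorts: the speeds and motile fractions are the
    # published stage means the recovery experiments are run against.
    "e_rg": dict(stage="E-RG-like", motile_fraction=0.6,
                 apical_speed_um_hr=38.81, basal_speed_um_hr=35.27,
                 angular_noise_sd_deg=35.0),
    "m_rg": dict(stage="M-RG-like", motile_fraction=0.3,
                 apical_speed_um_hr=30.25, basal_speed_um_hr=27.12,
                 angular_noise_sd_deg=50.0),
    # Sparse so independently wandering blobs rarely collide and every
    # textured patch tracks exactly one of them.
    "non_rosette": dict(stage="non-rosette", mode="random_motion",
                        motile_fraction=1.0, apical_speed_um_hr=30.0,
                        basal_speed_um_hr=30.0, n_nuclei=30),
    # Perturbation presets, relative to control (= E-RG-like):
    # blebbistatin-like degrades organization and the outward bias but
    # keeps speed; cytochalasin-like degrades organization, the
    # basal-to-apical ratio, motility and speed.
    "control": dict(stage="treated-control", motile_fraction=0.6,
                    apical_speed_um_hr=38.81, basal_speed_um_hr=35.27,
                    angular_noise_sd_deg=35.0),
    "blebbistatin_like": dict(stage="treated-blebbistatin",
                              motile_fraction=0.6,
                              apical_speed_um_hr=38.81,
                              basal_speed_um_hr=35.27,
                              antiphase_fraction=0.45,
                              angular_noise_sd_deg=60.0),
    "cytochalasin_like": dict(stage="treated-cytochalasin",
                              motile_fraction=0.45,
                              apical_speed_um_hr=28.0,
                              basal_speed_um_hr=26.0,
                              antiphase_fraction=0.5,
                              angular_noise_sd_deg=65.0),
}


def perturbation_preset(name: str, **overrides) -> SimulationConfig:
    """Named generator preset (stage-like or perturbation-like cohort)."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; "
                         f"choose from {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def write_simulation(config: SimulationConfig, out_dir: str | Path,
                     ) -> dict[str, Path]:
    """Generate a movie and write stack/annotation/ground-truth/config."""
    from .io import write_annotations, write_timelapse

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, annotation, gt = generate_rosette_movie(config)
    paths = {
        "stack": out / "stack.tif",
        "annotation": out / "annotation.json",
        "ground_truth": out / "ground_truth.csv",
        "config": out / "config.json",
    }
    write_timelapse(stack, paths["stack"])
    write_annotations([annotation], paths["annotation"])
    gt.to_csv(paths["ground_truth"])
    config.to_json(paths["config"])
    return paths
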