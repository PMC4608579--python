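# rosettepiv

Patch cross-correlation velocimetry and interkinetic nuclear migration
(INM) measures for neural rosette time-lapse microscopy.

Neural rosettes are in vitro multicellular structures of radially
arranged neural stem cells whose apical ends adjoin a central lumen — a
dish model of the embryonic ventricular zone. Their nuclei shuttle
between the apical (luminal) and basal (peripheral) ends of the cells,
and the degree to which this motion is fast, radially organized and
biased outward is a quantitative readout of tissue state. `rosettepiv`
turns an annotated time-lapse movie (multi-page TIFF + a center point
and contour polygon per rosette) into those readouts, for developmental
biologists and image analysts quantifying rosette cultures or testing
perturbations.

## Method

Each rosette is tiled with non-overlapping 13 × 13 px (8.3 µm) patches.
For every patch and consecutive frame pair the integer displacement
(dx, dy) maximizing the zero-mean normalized cross-correlation within a
search radius set by a 120 µm/hr speed bound is recorded, converted to a
speed |d|·(60·Δx/Δt) µm/hr, and kept only if it reaches the 15 µm/hr
motile threshold (≈ 2 px/frame; slower motions over-quantize the angle).
From the motile observations the package computes, per rosette:

- **Radial Score (RS)** — the mean angular alignment γ ∈ [0°, 90°]
  between each velocity and its expected radial orientation (the
  direction from the annotated center to the patch, mod 180°),
  γ = min(a, 180° − a) with a = |θ_v − θ_r| mod 180°. Lower = more
  radially organized; uniformly random motion averages 45°.
- **B/A ratio** — basally directed motile observations (velocity within
  90° of outward) over apically directed ones.
- **Speed** — mean motile speed, overall and split by direction class.
- **Motile fraction** — motile observations over all observations.
- **Ring profiles** — the same measures in five equal-width circular
  rings from the center, and **temporal profiles** — per-frame series
  with their sample variance ("functional instability") and trend slope.
- **Rosette size** — the diameter of the least-squares circle through
  the annotated contour.

Cohort statistics (Wilcoxon rank-sum and signed-rank, Pearson
correlation, least-squares fits and signed residuals from a reference
group's RS-vs-size fit) live in `rosettepiv.stats`.

A fully ground-truthed synthetic rosette-movie generator
(`rosettepiv.synthetic`) emulates the assumed data structure —
granule-textured nuclei migrating radially inside a circular rosette,
plus a random-motion non-rosette control — so every stage of the
pipeline is testable without microscopy data. See `docs/methods.md` for
the generative model and its limits.

## Worked example

```python
import rosettepiv as rp
from rosettepiv.pipeline import analyze_rosette

config = rp.perturbation_preset("e_rg", seed=1)   # early-stage-like rosette
stack, annotation, truth = rp.generate_rosette_movie(config)
result = analyze_rosette(stack, annotation)
m = result.measures
print(f"rosette size   : {m.size_um:.1f} um")
print(f"radial score   : {m.rs_deg:.1f} deg")
print(f"B/A ratio      : {m.ba_ratio:.2f}")
print(f"speed          : {m.speed_um_hr:.1f} um/hr")
print(f"motile fraction: {m.motile_fraction:.2f}")
```

prints

```
rosette size   : 76.8 um
radial score   : 22.9 deg
B/A ratio      : 1.16
speed          : 40.7 um/hr
motile fraction: 0.62
```

i.e. a 76.8 µm rosette whose motion is strongly radial (22.9° is far
below the 45° random baseline), mildly basally biased, fast, and with
62% of patch observations above the motile threshold — recovering the
generator's settings (motile fraction 0.6, apical/basal speeds
38.8/35.3 µm/hr) up to pixel quantization.

The same pipeline runs from the shell:

```
rosettepiv simulate --preset e_rg --seed 1 --out sim/
rosettepiv analyze  --stack sim/stack.tif --annotations sim/annotation.json --out out/
rosettepiv compare  --measures out/measures.csv --out cmp/   # needs >= 2 stages
```

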