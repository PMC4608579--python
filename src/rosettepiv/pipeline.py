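"""End-to-end convenience: annotation + stack -> velocity field + measures."""
from __future__ import annotations

import dataclasses

from .geometry import PatchGrid, RosetteGeometry, build_patch_grid, \
    fit_rosette_circle
from .io import RosetteAnnotation, TimeLapse
from .measures import RosetteMeasures, compute_measures
from .motion import VelocityField, compute_velocity_field


@dataclasses.dataclass
class RosetteResult:
    """Everything computed for one rosette in one channel."""

    measures: RosetteMeasures
    field: VelocityField
    grid: PatchGrid
    geometry: RosetteGeometry


def analyze_rosette(stack: TimeLapse, annotation: RosetteAnnotation,
                    ) -> RosetteResult:
    """Run the full pipeline for one rosette on one channel.

    Fits the rosette circle, builds the patch grid, estimates per-patch
    displacements by cross-correlation and aggregates the motile
    observations into the scalar measures.
    """
    geometry = fit_rosette_circle(annotation, stack.calibration)
    grid = build_patch_grid(geometry, stack.shape, stack.calibration)
    field = compute_velocity_field(stack, grid)
    measures = compute_measures(field, grid, geometry,
                                rosette_id=annotation.rosette_id,
                                stage=annotation.stage)
    return RosetteResult(measures=measures, field=field, grid=grid,
                         geometry=geometry)
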