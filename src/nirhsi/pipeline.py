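"""End-to-end scan processing: cube -> per-particle table.

Ties the stages together in the shipboard order: flatten, find the scale
bar, segment, measure, pool each particle's spectrum, encode it, and score
it against a trained forest with an FPR-constrained threshold policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import CLASS_ORDER, ForestModel, ThresholdPolicy, assign_class, score
from .features import (
    DEFAULT_PROMINENCE_MIN,
    FeatureSchema,
    encode_spectrum,
    extract_mean_spectrum,
)
from .hypercube import Hypercube
from .morphometry import geometry_frame, measure_particles
from .segmentation import (
    CalibrationMissingError,
    ScaleCalibration,
    detect_scale_bar,
    flatten_cube,
    segment_particles,
)

__all__ = ["process_cube"]


def process_cube(
    cube: Hypercube,
    model: ForestModel,
    policy: ThresholdPolicy,
    schema: FeatureSchema | None = None,
    min_area_px: int = 20,
    prominence_min: float = DEFAULT_PROMINENCE_MIN,
    mm_per_pixel: float | None = None,
    bar_edge: str = "bottom",
    invert_contrast: bool = False,
):
    """Process one reflectance cube into a per-particle results table.

    If ``mm_per_pixel`` is given it overrides scale-bar detection (for scans
    without a bar). Returns ``(DataFrame, ScaleCalibration, label_map)``;
    the frame has one row per particle with geometry, the assigned class,
    and P_rf per class.
    """
    schema = schema or FeatureSchema.default()
    flat = flatten_cube(cube)

    exclude = None
    if mm_per_pixel is None:
        scale = detect_scale_bar(flat, edge=bar_edge)
        exclude = scale.bar_mask
    else:
        scale = ScaleCalibration(mm_per_pixel=mm_per_pixel, bar_extent_px=2)
        try:  # still mask a bar out of segmentation if one happens to be present
            exclude = detect_scale_bar(flat, edge=bar_edge).bar_mask
        except RuntimeError:
            exclude = None

    labels = segment_particles(
        flat, min_area_px=min_area_px, exclude=exclude, invert_contrast=invert_contrast
    )
    geoms = measure_particles(labels, scale)
    frame = geometry_frame(geoms)

    classes, scores_per_class = [], {c: [] for c in model.classes}
    for g in geoms:
        pixels = np.argwhere(labels == g.label)
        spectrum = extract_mean_spectrum(cube, pixels)
        bits = encode_spectrum(spectrum, schema, prominence_min)
        s = score(model, bits)
        classes.append(assign_class(s, policy))
        for c in model.classes:
            scores_per_class[c].append(s.get(c, 0.0))

    frame["class"] = classes
    for c in model.classes:
        frame[f"p_rf_{c}"] = scores_per_class[c]
    return frame, scale, labels
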