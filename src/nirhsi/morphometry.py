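"""Particle morphometry: length, width, area, and perimeter in millimetres.

Length and width are caliper extents along the two principal directions of
the particle's pixel-coordinate cloud, obtained from a singular value
decomposition of the centred coordinates. The extent along each direction is
(max - min projection + 1 pixel) so that a single pixel has a one-pixel
extent and an axis-aligned N-pixel row has extent N. Area is the pixel count
times the squared pitch; perimeter is the length of the sub-pixel
marching-squares contour of the mask, which converges to the true perimeter
for smooth shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .segmentation import ScaleCalibration

__all__ = [
    "ParticleGeometry",
    "principal_axes",
    "area_perimeter",
    "measure_particles",
    "geometry_frame",
]


@dataclass
class ParticleGeometry:
    """Measured geometry of one segmented particle."""

    label: int
    length_mm: float
    width_mm: float
    area_mm2: float
    perimeter_mm: float
    centroid: tuple[float, float]  # (line, sample) in pixels

    def __post_init__(self) -> None:
        if not (self.length_mm >= self.width_mm > 0):
            raise ValueError("need length_mm >= width_mm > 0")


def _coords(region_pixels) -> np.ndarray:
    coords = np.asarray(list(region_pixels), dtype=float)
    if coords.size == 0:
        raise ValueError("empty particle region")
    return coords.reshape(-1, 2)


def principal_axes(region_pixels, scale: ScaleCalibration) -> tuple[float, float]:
    """(length_mm, width_mm): caliper extents along the SVD principal axes."""
    coords = _coords(region_pixels)
    centred = coords - coords.mean(axis=0)
    if len(coords) == 1:
        ext = np.array([1.0, 1.0])
    else:
        # Right singular vectors = principal directions of the pixel cloud.
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        proj = centred @ vt.T
        ext = proj.max(axis=0) - proj.min(axis=0) + 1.0
    length, width = sorted(ext * scale.mm_per_pixel, reverse=True)
    return float(length), float(width)


def area_perimeter(
    region_pixels, scale: ScaleCalibration, smooth_sigma: float = 1.0
) -> tuple[float, float]:
    """(area_mm2, perimeter_mm) of the region.

    Area counts pixels. Perimeter measures the 0.5-level marching-squares
    contour of the binary mask after a light Gaussian anti-aliasing
    (``smooth_sigma`` pixels; 0 disables): on a raw binary mask the contour
    is a staircase that overestimates smooth boundaries by ~6-9%, while the
    anti-aliased contour tracks a rasterised circle to within ~0.5%.
    """
    from scipy.ndimage import gaussian_filter

    coords = _coords(region_pixels).astype(int)
    s = scale.mm_per_pixel
    area = coords.shape[0] * s * s

    origin = coords.min(axis=0)
    extent = coords.max(axis=0) - origin + 1
    pad = 1 + int(np.ceil(3 * smooth_sigma))
    mask = np.zeros(extent + 2 * pad, dtype=float)
    mask[coords[:, 0] - origin[0] + pad, coords[:, 1] - origin[1] + pad] = 1.0
    if smooth_sigma > 0:
        mask = gaussian_filter(mask, smooth_sigma)

    perim_px = 0.0
    for contour in measure.find_contours(mask, 0.5):
        perim_px += np.sum(np.hypot(*np.diff(contour, axis=0).T))
    return float(area), float(perim_px * s)


def measure_particles(labels: np.ndarray, scale: ScaleCalibration) -> list[ParticleGeometry]:
    """Geometry for every labelled region of a segmentation label map."""
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        pixels = np.argwhere(labels == lab)
        length, width = principal_axes(pixels, scale)
        area, perim = area_perimeter(pixels, scale)
        centroid = tuple(pixels.mean(axis=0))
        out.append(
            ParticleGeometry(
                label=int(lab),
                length_mm=length,
                width_mm=width,
                area_mm2=area,
                perimeter_mm=perim,
                centroid=centroid,
            )
        )
    return out


def geometry_frame(geometries: list[ParticleGeometry]):
    """Per-particle geometry table with the standard export columns."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id": g.label,
                "length_mm": g.length_mm,
                "width_mm": g.width_mm,
                "area_mm2": g.area_mm2,
                "perimeter_mm": g.perimeter_mm,
                "centroid_line": g.centroid[0],
                "centroid_sample": g.centroid[1],
            }
            for g in geometries
        ]
    )
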