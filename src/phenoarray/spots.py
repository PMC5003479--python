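"""Printed-spot extraction from the tracer channel and registration to the grid.

Pixel convention: 0-based (row, col) indices, y increasing downward. A pixel
index maps to physical um as ``field_origin + index * um_per_pixel`` (pixel
centres, matching the rendering convention of :mod:`phenoarray.synth`).

Registration is translation-only: printed arrays and scanner axes are treated
as mechanically aligned; rotation is a documented limitation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .layout import GridLayout

__all__ = ["SpotDetection", "detect_spots", "register_to_layout"]

log = logging.getLogger(__name__)

DEFAULT_MIN_DIAMETER_UM = 150.0
DEFAULT_MAX_DIAMETER_UM = 600.0


@dataclass
class SpotDetection:
    """One tracer-channel detection; centroid in (row, col) pixels."""

    detection_id: int
    centroid_row: float
    centroid_col: float
    area_px: int
    equivalent_diameter_um: float
    mean_tracer_intensity: float
    matched_spot_id: int | None = None

    def center_um(self, um_per_pixel: float, field_origin: tuple[float, float]) -> tuple[float, float]:
        ox, oy = field_origin
        return (ox + self.centroid_col * um_per_pixel, oy + self.centroid_row * um_per_pixel)


def _threshold_value(img: np.ndarray, strategy) -> float:
    if isinstance(strategy, (int, float)) and not isinstance(strategy, bool):
        return float(strategy)
    if strategy == "otsu":
        return float(threshold_otsu(img))
    raise ValueError(f"unknown threshold strategy {strategy!r}; use 'otsu' or a fixed value")


def detect_spots(
    tracer: np.ndarray,
    um_per_pixel: float,
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    max_diameter_um: float = DEFAULT_MAX_DIAMETER_UM,
    threshold="otsu",
) -> list[SpotDetection]:
    """Threshold, label, hole-fill and size-gate tracer spots.

    Components whose equivalent diameter (``2 * sqrt(area / pi) * um_per_pixel``)
    falls outside ``[min_diameter_um, max_diameter_um]`` are discarded. The
    result is sorted row-major by centroid. An all-constant image yields an
    empty list.
    """
    if tracer.size == 0:
        raise ValueError("empty tracer image")
    if not min_diameter_um < max_diameter_um:
        raise ValueError("min_diameter_um must be below max_diameter_um")
    img = np.asarray(tracer, dtype=np.float64)
    if np.ptp(img) == 0:
        return []
    thr = _threshold_value(img, threshold)
    # opening removes speckle that would otherwise percolate into spot-sized
    # blobs on noise-only images; spots are far larger than the 3x3 element
    mask = ndi.binary_opening(img > thr, structure=np.ones((3, 3)))
    mask = ndi.binary_fill_holes(mask)
    labels = label(mask)
    detections: list[SpotDetection] = []
    for region in regionprops(labels, intensity_image=img):
        diameter = 2.0 * math.sqrt(region.area / math.pi) * um_per_pixel
        if not min_diameter_um <= diameter <= max_diameter_um:
            continue
        r, c = region.centroid
        detections.append(
            SpotDetection(
                detection_id=-1,
                centroid_row=float(r),
                centroid_col=float(c),
                area_px=int(region.area),
                equivalent_diameter_um=diameter,
                mean_tracer_intensity=float(region.intensity_mean),
            )
        )
    # row-major: bin rows at half the minimum diameter so centroid jitter
    # within one grid row cannot reorder it
    row_bin = max(min_diameter_um / 2.0 / um_per_pixel, 1.0)
    detections.sort(key=lambda d: (int(d.centroid_row / row_bin), d.centroid_col))
    for i, d in enumerate(detections):
        d.detection_id = i
    return detections


def register_to_layout(
    detections: list[SpotDetection],
    layout: GridLayout,
    field_origin: tuple[float, float],
    um_per_pixel: float,
    max_displacement_um: float = 150.0,
) -> tuple[list[SpotDetection], tuple[float, float]]:
    """Match detections to expected grid positions; translation-only.

    The global translation is the component-wise median of (detection - nearest
    expected centre) offsets. Matching is then greedy nearest-first and
    one-to-one within ``max_displacement_um``; when two detections claim one
    spot the farther one is left unmatched and logged.

    Returns the (mutated) detections and the estimated (dx, dy) translation in um.
    """
    expected = layout.centers()
    if len(expected) == 0:
        raise ValueError("layout has no spots")
    if not detections:
        return detections, (0.0, 0.0)

    det_xy = np.array([d.center_um(um_per_pixel, field_origin) for d in detections])
    d2 = ((det_xy[:, None, :] - expected[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    offsets = det_xy - expected[nearest]
    translation = (float(np.median(offsets[:, 0])), float(np.median(offsets[:, 1])))

    shifted = det_xy - np.array(translation)
    dist = np.sqrt(((shifted[:, None, :] - expected[None, :, :]) ** 2).sum(axis=2))
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    used_det: set[int] = set()
    used_spot: set[int] = set()
    for di, si in order:
        if dist[di, si] > max_displacement_um:
            break
        if di in used_det:
            continue
        if si in used_spot:
            log.warning(
                "detection %d also claims spot %d (%.1f um away); left unmatched",
                detections[di].detection_id,
                layout.spots[si].spot_id,
                dist[di, si],
            )
            continue
        detections[di].matched_spot_id = layout.spots[si].spot_id
        used_det.add(int(di))
        used_spot.add(int(si))
    return detections, translation
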