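"""Nucleus segmentation, per-cell phenotype measurement and classification.

Per-cell "intensity per pixel" is the MEAN phenotype intensity over the
measurement region; the region is the nucleus mask dilated by a bounded
perinuclear ring (default 3 um), with dilated regions of neighbouring cells
kept disjoint by nearest-label assignment. Integrated (summed) intensity is
available as a config alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, watershed

__all__ = [
    "CellRecord",
    "segment_nuclei",
    "measure_phenotype",
    "classify_expressing",
    "resolve_threshold",
]

DEFAULT_MIN_AREA_UM2 = 25.0
DEFAULT_MAX_AREA_UM2 = 800.0
DEFAULT_DILATION_UM = 3.0


@dataclass
class CellRecord:
    """One detected cell; centroid in (row, col) pixels."""

    cell_id: int
    centroid_row: float
    centroid_col: float
    nucleus_area_px: int
    phenotype_intensity: float | None = None
    expressing: bool | None = None
    assigned_spot_id: int | None = None

    def center_um(self, um_per_pixel: float, field_origin: tuple[float, float] = (0.0, 0.0)):
        ox, oy = field_origin
        return (ox + self.centroid_col * um_per_pixel, oy + self.centroid_row * um_per_pixel)


def segment_nuclei(
    nuclei: np.ndarray,
    um_per_pixel: float,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    max_area_um2: float = DEFAULT_MAX_AREA_UM2,
    smoothing_sigma_um: float = 1.5,
    min_peak_distance_um: float = 4.0,
    exclude_border: bool = False,
) -> tuple[np.ndarray, list[CellRecord]]:
    """Segment the nuclei channel into one label per cell.

    Pipeline: Gaussian smoothing, Otsu threshold, hole filling, then a
    distance-transform watershed to split touching nuclei, then an area gate
    in physical units. Nuclei touching the field border are kept by default.

    Returns the (relabelled, consecutive) label grid and one record per label.
    """
    if nuclei.size == 0:
        raise ValueError("empty nuclei image")
    img = np.asarray(nuclei, dtype=np.float64)
    empty = np.zeros(img.shape, dtype=np.int32)
    if np.ptp(img) == 0:
        return empty, []
    smoothed = ndi.gaussian_filter(img, sigma=smoothing_sigma_um / um_per_pixel)
    mask = ndi.binary_fill_holes(smoothed > threshold_otsu(smoothed))
    if not mask.any():
        return empty, []

    distance = ndi.gaussian_filter(ndi.distance_transform_edt(mask), sigma=1.0)
    min_dist_px = max(2, int(round(min_peak_distance_um / um_per_pixel)))
    peaks = peak_local_max(distance, min_distance=min_dist_px, labels=mask, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask)

    if exclude_border:
        border = np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        )
        labels[np.isin(labels, border[border > 0])] = 0

    min_px = min_area_um2 / um_per_pixel**2
    max_px = max_area_um2 / um_per_pixel**2
    out = np.zeros(img.shape, dtype=np.int32)
    records: list[CellRecord] = []
    next_id = 1
    for region in regionprops(labels):
        if not min_px <= region.area <= max_px:
            continue
        out[labels == region.label] = next_id
        r, c = region.centroid
        records.append(
            CellRecord(
                cell_id=next_id,
                centroid_row=float(r),
                centroid_col=float(c),
                nucleus_area_px=int(region.area),
            )
        )
        next_id += 1
    return out, records


def measure_phenotype(
    cells: list[CellRecord],
    labels: np.ndarray,
    phenotype: np.ndarray,
    um_per_pixel: float,
    dilation_radius_um: float = DEFAULT_DILATION_UM,
    statistic: str = "mean",
) -> list[CellRecord]:
    """Set each cell's phenotype_intensity from the (dilated) nucleus region.

    ``statistic`` is "mean" (per-pixel intensity, the default) or "integrated"
    (summed intensity over the region).
    """
    if labels.shape != phenotype.shape:
        raise ValueError(f"label grid {labels.shape} and phenotype grid {phenotype.shape} differ")
    if statistic not in ("mean", "integrated"):
        raise ValueError("statistic must be 'mean' or 'integrated'")
    if not cells:
        return cells
    region = labels
    if dilation_radius_um > 0:
        region = expand_labels(labels, distance=dilation_radius_um / um_per_pixel)
    img = np.asarray(phenotype, dtype=np.float64)
    ids = [c.cell_id for c in cells]
    if statistic == "mean":
        values = ndi.mean(img, labels=region, index=ids)
    else:
        values = ndi.sum_labels(img, labels=region, index=ids)
    for cell, v in zip(cells, values):
        cell.phenotype_intensity = float(v)
    return cells


def resolve_threshold(
    cells: list[CellRecord],
    strategy: str = "otsu",
    value: float | None = None,
    control_intensities=None,
    control_percentile: float = 5.0,
) -> float:
    """Compute the expressing/non-expressing intensity cutoff.

    Strategies: "fixed" (use ``value``), "otsu" (Otsu over the pooled per-cell
    intensity distribution), "control_percentile" (a low percentile of the
    per-cell intensities observed on negative controls of the same batch,
    default the 5th).
    """
    if strategy == "fixed":
        if value is None:
            raise ValueError("fixed strategy requires a threshold value")
        return float(value)
    if strategy == "otsu":
        intensities = np.array([c.phenotype_intensity for c in cells], dtype=np.float64)
        if intensities.size == 0:
            raise ValueError("cannot derive an Otsu threshold from zero cells")
        if np.ptp(intensities) == 0:
            return float(intensities[0])
        return float(threshold_otsu(intensities, nbins=256))
    if strategy == "control_percentile":
        ctrl = np.asarray(control_intensities, dtype=np.float64) if control_intensities is not None else None
        if ctrl is None or ctrl.size == 0:
            raise ValueError("control_percentile strategy requires control cell intensities")
        return float(np.percentile(ctrl, control_percentile))
    raise ValueError(f"unknown threshold strategy {strategy!r}")


def classify_expressing(
    cells: list[CellRecord],
    strategy: str = "otsu",
    value: float | None = None,
    control_intensities=None,
    control_percentile: float = 5.0,
) -> tuple[list[CellRecord], float]:
    """Flag each cell as expressing iff its phenotype intensity exceeds the threshold.

    Returns the (mutated) records and the threshold actually applied. An empty
    cell list yields an empty result (threshold NaN).
    """
    if not cells:
        return cells, math.nan
    if any(c.phenotype_intensity is None for c in cells):
        raise ValueError("phenotype_intensity must be set on all cells before classification")
    thr = resolve_threshold(
        cells,
        strategy=strategy,
        value=value,
        control_intensities=control_intensities,
        control_percentile=control_percentile,
    )
    for c in cells:
        c.expressing = bool(c.phenotype_intensity > thr)
    return cells, thr
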