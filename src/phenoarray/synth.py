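"""Ground-truthed synthetic multi-channel fluorescence scenes.

Renders three co-registered channels of a cell monolayer seeded over a printed
spot array (or a plain well): a tracer channel showing the printed spots, a
nuclei channel with one blob per cell, and a phenotype channel whose per-cell
intensity is drawn from an "expressing" or a "silenced" distribution according
to a per-spot silenced fraction. Everything is deterministic given the seed,
and the sampled ground truth (cell positions, radii, flags, spot membership)
is returned alongside the images.

Noise model: the noise-free signal is Gaussian-smoothed (1 px) to soften disc
edges, Poisson shot noise is applied to the signal, then an additive Gaussian
background is added and the result is clipped into the 16-bit range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage as ndi

from .layout import GridLayout

__all__ = [
    "SceneParams",
    "MultiChannelField",
    "GroundTruthCell",
    "GroundTruth",
    "render_field",
    "render_well",
    "BIT_DEPTH_MAX",
]

BIT_DEPTH_MAX = 65535


@dataclass
class MultiChannelField:
    """One imaged field: three co-registered channels plus physical metadata.

    ``field_origin`` is the (x, y) um offset of pixel (0, 0) into the slide.
    """

    tracer: np.ndarray
    phenotype: np.ndarray
    nuclei: np.ndarray
    um_per_pixel: float
    field_origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.tracer.shape == self.phenotype.shape == self.nuclei.shape):
            raise ValueError("the three channels must share one shape")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tracer.shape


@dataclass
class GroundTruthCell:
    center_x: float  # um, field-local
    center_y: float
    nucleus_radius: float  # um
    expressing: bool
    spot_id: int | None = None
    phenotype_value: float = 0.0


@dataclass
class GroundTruth:
    cells: list[GroundTruthCell] = field(default_factory=list)
    per_spot_silenced_fraction: dict[int, float] = field(default_factory=dict)

    def realized_silenced_fraction(self, spot_id: int | None) -> float:
        members = [c for c in self.cells if c.spot_id == spot_id]
        if not members:
            return float("nan")
        return sum(not c.expressing for c in members) / len(members)


@dataclass
class SceneParams:
    layout: GridLayout | None = None
    field_origin: tuple[float, float] = (0.0, 0.0)
    field_width_um: float = 1700.0
    field_height_um: float = 1700.0
    um_per_pixel: float = 1.33
    cell_density: float = 1500.0  # cells per mm^2
    nucleus_radius_mean: float = 6.0  # um
    nucleus_radius_sd: float = 0.8
    nucleus_intensity: float = 3000.0
    expressing_intensity_mean: float = 1000.0
    silenced_intensity_mean: float = 150.0
    intensity_sd: float = 80.0
    per_spot_silenced_fraction: dict[int, float] = field(default_factory=dict)
    off_spot_silenced_fraction: float = 0.0
    tracer_spot_intensity: float = 4000.0
    tracer_gradient: float = 0.0  # optional linear intensity fall-off across a spot, fraction
    background_level: float = 100.0
    background_noise_sd: float = 8.0
    phenotype_dilation_um: float = 3.0
    # minimum centre separation as a fraction of the two nuclei's summed radii;
    # placement is dart-throwing with a bounded retry budget, so crowding
    # degrades gracefully to overlaps at very high densities
    min_separation_factor: float = 0.95
    placement_attempts: int = 30
    seed: int = 0

    def validate(self) -> None:
        fracs = list(self.per_spot_silenced_fraction.values()) + [self.off_spot_silenced_fraction]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("silenced fractions must lie in [0, 1]")
        if self.expressing_intensity_mean <= self.silenced_intensity_mean:
            raise ValueError("expressing_intensity_mean must exceed silenced_intensity_mean")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
        if self.cell_density < 0 or self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("density must be >= 0 and field dimensions positive")
        if not 0.0 <= self.tracer_gradient <= 1.0:
            raise ValueError("tracer_gradient must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("layout")
        d["per_spot_silenced_fraction"] = {int(k): float(v) for k, v in self.per_spot_silenced_fraction.items()}
        return d

    def without_layout(self) -> "SceneParams":
        return replace(self, layout=None)


def _paint_disc(img: np.ndarray, cx: float, cy: float, radius: float, value: float) -> None:
    """Set img to max(img, value) inside a disc given in pixel coordinates."""
    h, w = img.shape
    r0 = max(int(math.floor(cy - radius)), 0)
    r1 = min(int(math.ceil(cy + radius)) + 1, h)
    c0 = max(int(math.floor(cx - radius)), 0)
    c1 = min(int(math.ceil(cx + radius)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    patch = img[r0:r1, c0:c1]
    np.maximum(patch, np.where(inside, value, 0.0), out=patch)


def _spots_in_field(params: SceneParams) -> list:
    """Layout spots whose disc intersects the field rectangle."""
    assert params.layout is not None
    ox, oy = params.field_origin
    r = params.layout.spot_radius
    out = []
    for s in params.layout.spots:
        if (
            s.center_x + r >= ox
            and s.center_x - r <= ox + params.field_width_um
            and s.center_y + r >= oy
            and s.center_y - r <= oy + params.field_height_um
        ):
            out.append(s)
    return out


def _place_with_repulsion(
    params: SceneParams, rng: np.random.Generator, radii: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throwing placement with a soft minimum-separation constraint.

    Each cell gets up to ``placement_attempts`` uniform draws; a draw is
    accepted when it sits at least ``min_separation_factor * (r_i + r_j)`` from
    every already-placed cell. When the budget runs out the last draw is kept,
    so the requested density is always realized (overlaps appear instead).
    Uses a coarse occupancy grid to keep neighbourhood queries local.
    """
    n = len(radii)
    xs = np.empty(n)
    ys = np.empty(n)
    if n == 0:
        return xs, ys
    cell_size = max(2.0 * float(np.max(radii)) * params.min_separation_factor, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        for _ in range(max(params.placement_attempts, 1)):
            x = rng.uniform(0.0, params.field_width_um)
            y = rng.uniform(0.0, params.field_height_um)
            gx, gy = int(x / cell_size), int(y / cell_size)
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for j in grid.get((gx + dx, gy + dy), ()):
                        min_d = params.min_separation_factor * (radii[i] + radii[j])
                        if (x - xs[j]) ** 2 + (y - ys[j]) ** 2 < min_d**2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                break
        xs[i], ys[i] = x, y
        grid.setdefault((int(x / cell_size), int(y / cell_size)), []).append(i)
    return xs, ys


def _sample_cells(params: SceneParams, rng: np.random.Generator, spots) -> list[GroundTruthCell]:
    area_mm2 = params.field_width_um * params.field_height_um / 1e6
    n_cells = int(rng.poisson(params.cell_density * area_mm2))
    if n_cells == 0:
        return []
    radii = np.clip(
        rng.normal(params.nucleus_radius_mean, params.nucleus_radius_sd, n_cells),
        2.0,
        None,
    )
    xs, ys = _place_with_repulsion(params, rng, radii)
    ox, oy = params.field_origin
    spot_r = params.layout.spot_radius if params.layout is not None else 0.0
    centers = (
        np.array([[s.center_x - ox, s.center_y - oy] for s in spots]) if spots else np.empty((0, 2))
    )
    cells: list[GroundTruthCell] = []
    for i in range(n_cells):
        spot_id: int | None = None
        if len(centers):
            d2 = (centers[:, 0] - xs[i]) ** 2 + (centers[:, 1] - ys[i]) ** 2
            j = int(np.argmin(d2))
            if d2[j] <= spot_r**2:
                spot_id = spots[j].spot_id
        if spot_id is not None:
            frac = params.per_spot_silenced_fraction.get(spot_id, params.off_spot_silenced_fraction)
        else:
            frac = params.off_spot_silenced_fraction
        silenced = bool(rng.random() < frac)
        mean = params.silenced_intensity_mean if silenced else params.expressing_intensity_mean
        value = max(float(rng.normal(mean, params.intensity_sd)), 0.0)
        cells.append(
            GroundTruthCell(
                center_x=float(xs[i]),
                center_y=float(ys[i]),
                nucleus_radius=float(radii[i]),
                expressing=not silenced,
                spot_id=spot_id,
                phenotype_value=value,
            )
        )
    return cells


def _finish_channel(signal: np.ndarray, params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    smoothed = ndi.gaussian_filter(signal, sigma=1.0)
    noisy = rng.poisson(np.clip(smoothed, 0.0, None)).astype(np.float64)
    noisy += params.background_level
    noisy += rng.normal(0.0, params.background_noise_sd, signal.shape)
    return np.clip(np.rint(noisy), 0, BIT_DEPTH_MAX).astype(np.uint16)


def _render(params: SceneParams, spots) -> tuple[MultiChannelField, GroundTruth]:
    params.validate()
    rng = np.random.default_rng(params.seed)
    upp = params.um_per_pixel
    shape = (
        max(int(round(params.field_height_um / upp)), 1),
        max(int(round(params.field_width_um / upp)), 1),
    )
    ox, oy = params.field_origin

    tracer = np.zeros(shape, dtype=np.float64)
    spot_r_px = (params.layout.spot_radius / upp) if params.layout is not None else 0.0
    for s in spots:
        cx = (s.center_x - ox) / upp
        cy = (s.center_y - oy) / upp
        _paint_disc(tracer, cx, cy, spot_r_px, params.tracer_spot_intensity)
    if params.tracer_gradient > 0 and spots:
        # optional linear fall-off left-to-right across the field
        ramp = 1.0 - params.tracer_gradient * (np.arange(shape[1]) / max(shape[1] - 1, 1))
        tracer *= ramp[None, :]

    cells = _sample_cells(params, rng, spots)
    nuclei = np.zeros(shape, dtype=np.float64)
    phenotype = np.zeros(shape, dtype=np.float64)
    for c in cells:
        cx, cy = c.center_x / upp, c.center_y / upp
        _paint_disc(nuclei, cx, cy, c.nucleus_radius / upp, params.nucleus_intensity)
        _paint_disc(
            phenotype,
            cx,
            cy,
            (c.nucleus_radius + params.phenotype_dilation_um) / upp,
            c.phenotype_value,
        )

    fld = MultiChannelField(
        tracer=_finish_channel(tracer, params, rng),
        phenotype=_finish_channel(phenotype, params, rng),
        nuclei=_finish_channel(nuclei, params, rng),
        um_per_pixel=upp,
        field_origin=params.field_origin,
    )
    truth = GroundTruth(cells=cells, per_spot_silenced_fraction=dict(params.per_spot_silenced_fraction))
    return fld, truth


def render_field(params: SceneParams) -> tuple[MultiChannelField, GroundTruth]:
    """Render a field over a printed array; requires a layout intersecting the field."""
    if params.layout is None:
        raise ValueError("render_field requires a layout; use render_well for well mode")
    spots = _spots_in_field(params)
    if not spots:
        raise ValueError("field does not intersect any layout spot")
    return _render(params, spots)


def render_well(params: SceneParams) -> tuple[MultiChannelField, GroundTruth]:
    """Render a well-format field: no tracer spots, one silenced fraction for all cells."""
    if params.layout is not None:
        params = params.without_layout()
    return _render(params, [])
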