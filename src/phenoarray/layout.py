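"""Printable grid layouts, slide capacity, control allocation and library partitioning.

All physical coordinates are in micrometres. The origin is the top-left
corner of the slide; ``x`` runs along the long (76 mm) axis, ``y`` along the
short (26 mm) axis. Spots are indexed row-major, 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SpotSpec",
    "GridLayout",
    "LibraryPlan",
    "ZeroCapacityError",
    "CapacityExceededError",
    "plan_grid",
    "allocate_controls",
    "partition_library",
    "round_half_up",
    "DEFAULT_SLIDE_WIDTH_UM",
    "DEFAULT_SLIDE_HEIGHT_UM",
    "DEFAULT_SPOT_DIAMETER_UM",
    "DEFAULT_EDGE_GAP_UM",
    "DEFAULT_MARGIN_UM",
]

# Standard 26 x 76 mm microscope slide, 300 um spots with 200 um edge gaps
# (500 um pitch) and a 2 mm unprintable border on every side.
DEFAULT_SLIDE_WIDTH_UM = 76_000.0
DEFAULT_SLIDE_HEIGHT_UM = 26_000.0
DEFAULT_SPOT_DIAMETER_UM = 300.0
DEFAULT_EDGE_GAP_UM = 200.0
DEFAULT_MARGIN_UM = 2_000.0

ROLES = ("test", "negative_control", "blank")


class ZeroCapacityError(ValueError):
    """The printable region cannot hold a single spot."""


class CapacityExceededError(ValueError):
    """More reagent labels than available test positions."""


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going away from zero (for x >= 0)."""
    return int(math.floor(x + 0.5))


@dataclass
class SpotSpec:
    """One planned spot: id, physical centre, reagent and role."""

    spot_id: int
    center_x: float
    center_y: float
    reagent_label: str = ""
    role: str = "test"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.role in ("test", "negative_control") and not self.reagent_label:
            raise ValueError(f"spot {self.spot_id}: role {self.role!r} requires a reagent_label")


@dataclass
class GridLayout:
    """A planned row-major grid of printed spots on a slide."""

    slide_width: float
    slide_height: float
    spot_diameter: float
    edge_gap: float
    margin: float
    n_rows: int
    n_cols: int
    spots: list[SpotSpec] = field(default_factory=list)

    @property
    def pitch(self) -> float:
        """Centre-to-centre distance, identical in both axes."""
        return self.spot_diameter + self.edge_gap

    @property
    def capacity(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def spot_radius(self) -> float:
        return self.spot_diameter / 2.0

    def spot_by_id(self, spot_id: int) -> SpotSpec:
        return self._index()[spot_id]

    def _index(self) -> dict[int, SpotSpec]:
        if not hasattr(self, "_by_id") or len(self._by_id) != len(self.spots):
            self._by_id = {s.spot_id: s for s in self.spots}
        return self._by_id

    def centers(self) -> np.ndarray:
        """(n, 2) array of spot centres as (x, y) um, in spot order."""
        return np.array([[s.center_x, s.center_y] for s in self.spots], dtype=float)

    def validate(self) -> None:
        if self.n_rows * self.n_cols != len(self.spots):
            raise ValueError(
                f"n_rows * n_cols = {self.n_rows * self.n_cols} but {len(self.spots)} spots present"
            )
        ids = [s.spot_id for s in self.spots]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate spot ids")
        r = self.spot_radius
        for s in self.spots:
            if not (
                self.margin + r - 1e-6 <= s.center_x <= self.slide_width - self.margin - r + 1e-6
                and self.margin + r - 1e-6 <= s.center_y <= self.slide_height - self.margin - r + 1e-6
            ):
                raise ValueError(f"spot {s.spot_id} extends outside the printable region")
        pts = self.centers()
        if len(pts) > 1:
            # overlapping spots: any pair closer than one diameter
            from scipy.spatial import cKDTree

            tree = cKDTree(pts)
            pairs = tree.query_pairs(self.spot_diameter - 1e-6)
            if pairs:
                i, j = sorted(pairs)[0]
                raise ValueError(
                    f"spots {self.spots[i].spot_id} and {self.spots[j].spot_id} overlap"
                )


def _axis_count(usable: float, diameter: float, pitch: float) -> int:
    if usable < diameter:
        return 0
    return int(math.floor((usable - diameter) / pitch + 1e-9)) + 1


def plan_grid(
    slide_width: float = DEFAULT_SLIDE_WIDTH_UM,
    slide_height: float = DEFAULT_SLIDE_HEIGHT_UM,
    spot_diameter: float = DEFAULT_SPOT_DIAMETER_UM,
    edge_gap: float = DEFAULT_EDGE_GAP_UM,
    margin: float = DEFAULT_MARGIN_UM,
) -> GridLayout:
    """Plan the densest row-major grid fitting the printable region.

    The pitch is ``spot_diameter + edge_gap`` in both axes and every spot must
    lie entirely inside the slide minus its margins.

    Raises
    ------
    ZeroCapacityError
        If the printable region is smaller than one spot in either axis.
    """
    if slide_width <= 0 or slide_height <= 0 or spot_diameter <= 0:
        raise ValueError("slide dimensions and spot diameter must be positive")
    if edge_gap < 0 or margin < 0:
        raise ValueError("edge_gap and margin must be non-negative")

    usable_w = slide_width - 2.0 * margin
    usable_h = slide_height - 2.0 * margin
    pitch = spot_diameter + edge_gap
    n_cols = _axis_count(usable_w, spot_diameter, pitch)
    n_rows = _axis_count(usable_h, spot_diameter, pitch)
    if n_cols == 0 or n_rows == 0:
        raise ZeroCapacityError(
            f"printable region {max(usable_w, 0):.0f} x {max(usable_h, 0):.0f} um "
            f"cannot hold a {spot_diameter:.0f} um spot"
        )

    r = spot_diameter / 2.0
    spots = []
    sid = 0
    for row in range(n_rows):
        cy = margin + r + row * pitch
        for col in range(n_cols):
            cx = margin + r + col * pitch
            spots.append(SpotSpec(spot_id=sid, center_x=cx, center_y=cy, reagent_label="", role="blank"))
            sid += 1
    return GridLayout(
        slide_width=slide_width,
        slide_height=slide_height,
        spot_diameter=spot_diameter,
        edge_gap=edge_gap,
        margin=margin,
        n_rows=n_rows,
        n_cols=n_cols,
        spots=spots,
    )


def allocate_controls(spots_per_array: int, control_fraction: float, seed: int) -> dict[int, str]:
    """Assign roles to spot ids 0..spots_per_array-1.

    Exactly ``round_half_up(spots_per_array * control_fraction)`` spots become
    ``negative_control``; placement is a seeded uniform scatter, the rest are
    ``test``.
    """
    if not 0.0 <= control_fraction <= 1.0:
        raise ValueError("control_fraction must lie in [0, 1]")
    if spots_per_array < 0:
        raise ValueError("spots_per_array must be non-negative")
    n_controls = round_half_up(spots_per_array * control_fraction)
    rng = np.random.default_rng(seed)
    control_ids = set(rng.choice(spots_per_array, size=n_controls, replace=False).tolist())
    return {
        i: ("negative_control" if i in control_ids else "test") for i in range(spots_per_array)
    }


@dataclass
class LibraryPlan:
    """Partition of a reagent library over a set of identical arrays."""

    n_arrays: int
    spots_per_array: int
    control_fraction: float
    assignments: dict[int, list[str]]

    @property
    def controls_per_array(self) -> int:
        return round_half_up(self.spots_per_array * self.control_fraction)

    @property
    def test_positions_per_array(self) -> int:
        return self.spots_per_array - self.controls_per_array

    @property
    def total_test_positions(self) -> int:
        return self.n_arrays * self.test_positions_per_array


def partition_library(
    reagent_labels: Sequence[str],
    n_arrays: int,
    spots_per_array: int,
    control_fraction: float,
) -> LibraryPlan:
    """Fill arrays in order with test labels; unused test positions become blanks.

    Every test label appears exactly once across the whole plan. Each array's
    assignment list has length ``spots_per_array - controls_per_array`` (the
    controls occupy the remaining positions); blanks are recorded as ``""``.

    Raises
    ------
    CapacityExceededError
        If more labels are supplied than available test positions; the message
        names the shortfall.
    """
    labels = list(reagent_labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate reagent labels in library")
    n_controls = round_half_up(spots_per_array * control_fraction)
    per_array = spots_per_array - n_controls
    capacity = n_arrays * per_array
    if len(labels) > capacity:
        raise CapacityExceededError(
            f"{len(labels)} labels exceed {capacity} available test positions "
            f"({n_arrays} arrays x {per_array}); shortfall {len(labels) - capacity}"
        )
    assignments: dict[int, list[str]] = {}
    for a in range(n_arrays):
        chunk = labels[a * per_array : (a + 1) * per_array]
        chunk = chunk + [""] * (per_array - len(chunk))
        assignments[a] = chunk
    return LibraryPlan(
        n_arrays=n_arrays,
        spots_per_array=spots_per_array,
        control_fraction=control_fraction,
        assignments=assignments,
    )


def apply_roles(
    layout: GridLayout,
    roles: dict[int, str],
    test_labels: Sequence[str] | None = None,
    control_label: str = "NC",
) -> GridLayout:
    """Stamp roles (and optionally per-test reagent labels) onto a planned grid.

    Test labels are consumed in spot-id order; surplus test positions become
    blanks. Returns the same layout object, mutated.
    """
    it = iter(test_labels) if test_labels is not None else None
    for spot in layout.spots:
        role = roles.get(spot.spot_id, "blank")
        if role == "negative_control":
            spot.role = role
            spot.reagent_label = control_label
        elif role == "test":
            if it is None:
                spot.role = "test"
                spot.reagent_label = f"reagent_{spot.spot_id}"
            else:
                label = next(it, None)
                if label:
                    spot.role = "test"
                    spot.reagent_label = label
                else:
                    spot.role = "blank"
                    spot.reagent_label = ""
        else:
            spot.role = "blank"
            spot.reagent_label = ""
    return layout
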