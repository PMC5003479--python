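"""Shared fixtures: small printed layouts and rendered synthetic fields.

Expensive renders are session-scoped and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from phenoarray import SceneParams, plan_grid, render_field, render_well
from phenoarray.layout import apply_roles


def make_small_array(silenced_test: float = 0.8, silenced_control: float = 0.0):
    """A 3 x 3 spot grid on a tiny slide with alternating control/test roles.

    Returns (layout, per_spot_silenced_fraction). Controls are labelled "NC",
    tests "miR".
    """
    layout = plan_grid(2300, 2300, 300, 200, 300)
    roles = {
        s.spot_id: ("negative_control" if i % 2 == 0 else "test")
        for i, s in enumerate(layout.spots)
    }
    apply_roles(layout, roles, control_label="NC")
    for s in layout.spots:
        if s.role == "test":
            s.reagent_label = "miR"
    fractions = {
        s.spot_id: (silenced_control if s.role == "negative_control" else silenced_test)
        for s in layout.spots
    }
    return layout, fractions


def greedy_match_recall(truth_xy: np.ndarray, found_xy: np.ndarray, tol_um: float = 6.0) -> float:
    """Fraction of ground-truth points matched one-to-one within tolerance."""
    if len(truth_xy) == 0:
        return 1.0
    if len(found_xy) == 0:
        return 0.0
    d, idx = cKDTree(found_xy).query(truth_xy)
    used: set[int] = set()
    matched = 0
    for gi in np.argsort(d):
        if d[gi] <= tol_um and idx[gi] not in used:
            used.add(int(idx[gi]))
            matched += 1
    return matched / len(truth_xy)


@pytest.fixture(scope="session")
def small_array():
    return make_small_array()


@pytest.fixture(scope="session")
def array_scene(small_array):
    """One rendered array field (controls silenced 0, tests 0.8) plus its truth."""
    layout, fractions = small_array
    params = SceneParams(
        layout=layout,
        field_width_um=2300,
        field_height_um=2300,
        per_spot_silenced_fraction=fractions,
        seed=7,
    )
    field, truth = render_field(params)
    return params, field, truth


@pytest.fixture(scope="session")
def well_scene():
    """One small well-mode field, 30% silenced, for segmentation tests."""
    params = SceneParams(
        layout=None,
        field_width_um=800,
        field_height_um=800,
        off_spot_silenced_fraction=0.3,
        seed=11,
    )
    field, truth = render_well(params)
    return params, field, truth
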