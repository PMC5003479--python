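"""Cell-to-spot association, percent-expressing scoring, control normalization,
knockdown statistics, and the end-to-end array quantification pipeline.

Association uses the NOMINAL spot disc (registered layout centre plus nominal
radius), not the thresholded tracer component; this is robust to tracer
intensity variation. The replicate unit on arrays is one spot; percents are
computed per replicate and then aggregated per condition.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats as sps

from .cells import (
    CellRecord,
    classify_expressing,
    measure_phenotype,
    segment_nuclei,
)
from .layout import GridLayout
from .spots import detect_spots, register_to_layout
from .synth import MultiChannelField

__all__ = [
    "SpotResult",
    "NormalizedCondition",
    "AnalysisConfig",
    "UndefinedPercentError",
    "NormalizationError",
    "StageError",
    "assign_cells_to_spots",
    "percent_expressing",
    "normalize_to_control",
    "knockdown_test",
    "quantify_array",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_CELLS_PER_SPOT = 20


class UndefinedPercentError(ValueError):
    """Percent expressing is undefined for an empty cell group."""


class NormalizationError(ValueError):
    """Control-based normalization is undefined (zero/absent control)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class SpotResult:
    spot_id: int | None
    reagent_label: str
    role: str
    n_cells: int
    n_expressing: int
    percent_expressing: float
    low_count: bool = False


@dataclass
class NormalizedCondition:
    condition: str
    replicate_values: list[float]
    mean_normalized_expression: float
    sd: float
    n: int
    knockdown_percent: float
    t_statistic: float | None = None
    p_value: float | None = None


@dataclass
class AnalysisConfig:
    """All knobs of the quantification pipeline, with bench defaults."""

    # spot detection / registration
    spot_threshold: str | float = "otsu"
    min_spot_diameter_um: float = 150.0
    max_spot_diameter_um: float = 600.0
    max_registration_displacement_um: float = 150.0
    # segmentation
    min_nucleus_area_um2: float = 25.0
    max_nucleus_area_um2: float = 800.0
    smoothing_sigma_um: float = 1.5
    min_peak_distance_um: float = 4.0
    exclude_border_nuclei: bool = False
    # phenotype measurement / classification
    dilation_radius_um: float = 3.0
    intensity_statistic: str = "mean"
    classify_strategy: str = "control_percentile"
    classify_fixed_value: float | None = None
    control_percentile: float = 5.0
    control_condition: str = "NC"
    # association and reporting
    association_radius_factor: float = 1.0
    min_cells_per_spot: int = DEFAULT_MIN_CELLS_PER_SPOT

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def assign_cells_to_spots(
    cells: list[CellRecord],
    spot_centers: dict[int, tuple[float, float]],
    spot_diameter_um: float,
    um_per_pixel: float,
    field_origin: tuple[float, float] = (0.0, 0.0),
    association_radius_factor: float = 1.0,
) -> list[CellRecord]:
    """Assign each cell to the nearest spot centre within the cutoff radius.

    A cell belongs to spot ``s`` iff its nucleus centroid lies within
    ``association_radius_factor * spot_diameter / 2`` of s's centre; among
    spots in range the nearer centre wins and exact ties go to the lower spot
    id. Cells out of range stay unassigned.

    ``spot_centers`` maps spot id to (x, y) um in slide coordinates (use the
    registered layout centres).
    """
    if not spot_centers:
        for c in cells:
            c.assigned_spot_id = None
        return cells
    ids = sorted(spot_centers)  # ascending ids: ties resolve to the lower id
    centers = np.array([spot_centers[i] for i in ids], dtype=float)
    cutoff = association_radius_factor * spot_diameter_um / 2.0
    for c in cells:
        x, y = c.center_um(um_per_pixel, field_origin)
        d = np.hypot(centers[:, 0] - x, centers[:, 1] - y)
        j = int(np.argmin(d))  # argmin returns the first (lowest-id) minimum
        c.assigned_spot_id = ids[j] if d[j] <= cutoff else None
    return cells


def percent_expressing(
    cells_in_group: list[CellRecord],
    spot_id: int | None = None,
    reagent_label: str = "",
    role: str = "test",
    min_cells: int = DEFAULT_MIN_CELLS_PER_SPOT,
) -> SpotResult:
    """Tally a group of classified cells into a SpotResult.

    Raises :class:`UndefinedPercentError` on an empty group; groups smaller
    than ``min_cells`` are flagged low-count, not dropped.
    """
    n = len(cells_in_group)
    if n == 0:
        raise UndefinedPercentError(
            f"percent expressing undefined for empty group (spot {spot_id!r})"
        )
    if any(c.expressing is None for c in cells_in_group):
        raise ValueError("expressing flags must be set before scoring")
    n_expr = sum(bool(c.expressing) for c in cells_in_group)
    return SpotResult(
        spot_id=spot_id,
        reagent_label=reagent_label,
        role=role,
        n_cells=n,
        n_expressing=n_expr,
        percent_expressing=100.0 * n_expr / n,
        low_count=n < min_cells,
    )


def knockdown_test(test_values, control_values) -> tuple[float, float]:
    """Two-sample Student's t-test (equal variance, two-sided).

    Warns when the group variances differ by more than 4x.
    """
    t_vals = np.asarray(test_values, dtype=float)
    c_vals = np.asarray(control_values, dtype=float)
    if len(t_vals) < 2 or len(c_vals) < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    v1, v2 = np.var(t_vals, ddof=1), np.var(c_vals, ddof=1)
    if v1 > 0 and v2 > 0 and max(v1, v2) / min(v1, v2) > 4.0:
        warnings.warn(
            f"group variances differ by more than 4x ({v1:.3g} vs {v2:.3g}); "
            "the equal-variance t-test may be inappropriate",
            stacklevel=2,
        )
    res = sps.ttest_ind(t_vals, c_vals, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def normalize_to_control(
    results_by_condition: dict[str, list[float]],
    control_condition: str,
    run_tests: bool = True,
) -> list[NormalizedCondition]:
    """Normalize per-replicate raw percents so the control condition means 100.

    Each replicate value becomes ``100 * raw / mean(raw control)``; knockdown
    is ``100 - mean(normalized)``. When both groups have >= 2 replicates a
    Student's t-test against the control's normalized values is attached.
    """
    if control_condition not in results_by_condition:
        raise NormalizationError(f"control condition {control_condition!r} absent")
    ctrl_raw = np.asarray(results_by_condition[control_condition], dtype=float)
    if ctrl_raw.size == 0:
        raise NormalizationError("control condition has no replicates")
    ctrl_mean = float(np.mean(ctrl_raw))
    if ctrl_mean == 0:
        raise NormalizationError("control mean is zero; normalization undefined")

    ctrl_norm = (100.0 * ctrl_raw / ctrl_mean).tolist()
    out: list[NormalizedCondition] = []
    for condition, raw in results_by_condition.items():
        vals = [100.0 * v / ctrl_mean for v in raw]
        n = len(vals)
        if condition == control_condition:
            mean = 100.0  # exact by construction
        else:
            mean = float(np.mean(vals)) if n else float("nan")
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        t_stat = p_val = None
        if run_tests and condition != control_condition and n >= 2 and len(ctrl_norm) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t_stat, p_val = knockdown_test(vals, ctrl_norm)
        out.append(
            NormalizedCondition(
                condition=condition,
                replicate_values=vals,
                mean_normalized_expression=mean,
                sd=sd,
                n=n,
                knockdown_percent=100.0 - mean,
                t_statistic=t_stat,
                p_value=p_val,
            )
        )
    return out


@dataclass
class ArrayQuantification:
    """Everything the end-to-end pipeline produces for one field."""

    cells: list[CellRecord]
    spot_results: list[SpotResult]
    conditions: list[NormalizedCondition]
    threshold: float
    translation_um: tuple[float, float]
    stage_timings: dict[str, float] = dc_field(default_factory=dict)


def _timed(timings: dict[str, float], stage: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except (UndefinedPercentError, NormalizationError, StageError):
        raise
    except Exception as exc:  # label the failing stage
        raise StageError(stage, exc) from exc
    timings[stage] = time.perf_counter() - t0
    log.info("stage %s: %.3f s", stage, timings[stage])
    return result


def quantify_array(
    field: MultiChannelField,
    layout: GridLayout,
    config: AnalysisConfig | None = None,
) -> ArrayQuantification:
    """Run detect -> register -> segment -> measure -> assign -> classify ->
    score -> normalize -> test on one field.

    Conditions are reagent labels; the control condition is the one named in
    ``config.control_condition`` (the reagent label of negative-control spots).
    Note cells are assigned to spots before classification because the default
    control-percentile threshold needs the control cells' intensities.
    """
    cfg = config or AnalysisConfig()
    timings: dict[str, float] = {}

    detections = _timed(
        timings,
        "detect_spots",
        detect_spots,
        field.tracer,
        field.um_per_pixel,
        min_diameter_um=cfg.min_spot_diameter_um,
        max_diameter_um=cfg.max_spot_diameter_um,
        threshold=cfg.spot_threshold,
    )
    detections, translation = _timed(
        timings,
        "register",
        register_to_layout,
        detections,
        layout,
        field.field_origin,
        field.um_per_pixel,
        max_displacement_um=cfg.max_registration_displacement_um,
    )

    labels, cells = _timed(
        timings,
        "segment_nuclei",
        segment_nuclei,
        field.nuclei,
        field.um_per_pixel,
        min_area_um2=cfg.min_nucleus_area_um2,
        max_area_um2=cfg.max_nucleus_area_um2,
        smoothing_sigma_um=cfg.smoothing_sigma_um,
        min_peak_distance_um=cfg.min_peak_distance_um,
        exclude_border=cfg.exclude_border_nuclei,
    )
    cells = _timed(
        timings,
        "measure_phenotype",
        measure_phenotype,
        cells,
        labels,
        field.phenotype,
        field.um_per_pixel,
        dilation_radius_um=cfg.dilation_radius_um,
        statistic=cfg.intensity_statistic,
    )

    # registered centres = planned centres + estimated translation
    matched_ids = {d.matched_spot_id for d in detections if d.matched_spot_id is not None}
    centers = {
        s.spot_id: (s.center_x + translation[0], s.center_y + translation[1])
        for s in layout.spots
        if s.spot_id in matched_ids
    }
    cells = _timed(
        timings,
        "assign",
        assign_cells_to_spots,
        cells,
        centers,
        layout.spot_diameter,
        field.um_per_pixel,
        field.field_origin,
        association_radius_factor=cfg.association_radius_factor,
    )

    control_ids = {s.spot_id for s in layout.spots if s.role == "negative_control"}
    control_intensities = [
        c.phenotype_intensity for c in cells if c.assigned_spot_id in control_ids
    ]
    cells, threshold = _timed(
        timings,
        "classify",
        classify_expressing,
        cells,
        strategy=cfg.classify_strategy,
        value=cfg.classify_fixed_value,
        control_intensities=control_intensities or None,
        control_percentile=cfg.control_percentile,
    )

    spot_results: list[SpotResult] = []
    by_spot: dict[int, list[CellRecord]] = {}
    for c in cells:
        if c.assigned_spot_id is not None:
            by_spot.setdefault(c.assigned_spot_id, []).append(c)
    for sid in sorted(by_spot):
        spot_spec = layout.spot_by_id(sid)
        spot_results.append(
            percent_expressing(
                by_spot[sid],
                spot_id=sid,
                reagent_label=spot_spec.reagent_label,
                role=spot_spec.role,
                min_cells=cfg.min_cells_per_spot,
            )
        )
    timings["score"] = 0.0

    by_condition: dict[str, list[float]] = {}
    for r in spot_results:
        if r.role == "blank":
            continue
        by_condition.setdefault(r.reagent_label, []).append(r.percent_expressing)
    conditions = _timed(
        timings,
        "normalize",
        normalize_to_control,
        by_condition,
        cfg.control_condition,
    )

    return ArrayQuantification(
        cells=cells,
        spot_results=spot_results,
        conditions=conditions,
        threshold=threshold,
        translation_um=translation,
        stage_timings=timings,
    )
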