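"""Readers/writers for every artifact surface.

Conventions
-----------
* Channel TIFFs are grayscale 8- or 16-bit, one file per channel, named
  ``<run>_<field>_<tag>.tif`` with tags 560 (tracer), 488 (phenotype) and
  635 (nuclei) echoing the acquisition wavelengths.
* A field manifest is a JSON file tying the three channel files to the pixel
  scale and the field origin.
* Layouts round-trip through a tab-delimited array-list file in the GenePix
  Array List (GAL) dialect: an ATF preamble, ``Key=Value`` header records
  carrying the grid geometry, then Block/Row/Column/X/Y/ID/Name records. The
  spot role rides in the Name field as ``<role>|<reagent label>``. A JSON
  form is provided for exact metadata round-trips.
* CSV tables are comma-separated, UTF-8, mandatory header row, '.' decimal.
  Coordinates are written to 0.1 um precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cells import CellRecord
from .layout import GridLayout, SpotSpec
from .spots import SpotDetection
from .stats import NormalizedCondition, SpotResult
from .synth import GroundTruth, MultiChannelField

__all__ = [
    "CHANNEL_TAGS",
    "FieldManifest",
    "write_field",
    "read_field",
    "write_layout",
    "read_layout",
    "layout_to_json",
    "layout_from_json",
    "write_cell_table",
    "read_cell_table",
    "write_spot_results",
    "write_conditions",
    "write_detections",
    "write_ground_truth",
    "read_ground_truth",
    "GalFormatError",
]

CHANNEL_TAGS = {"tracer": "560", "phenotype": "488", "nuclei": "635"}


class GalFormatError(ValueError):
    """Malformed array-list file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# fields


@dataclass
class FieldManifest:
    field_id: str
    channels: dict[str, str]  # channel name -> file path
    um_per_pixel: float
    field_origin: tuple[float, float] = (0.0, 0.0)

    def validate(self) -> None:
        missing = [ch for ch in CHANNEL_TAGS if ch not in self.channels]
        if missing:
            raise ValueError(f"manifest missing channels: {missing}")
        for ch, path in self.channels.items():
            if not Path(path).is_file():
                raise FileNotFoundError(f"channel {ch!r}: no such file {path}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "field_id": self.field_id,
                    "channels": self.channels,
                    "um_per_pixel": self.um_per_pixel,
                    "field_origin": list(self.field_origin),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "FieldManifest":
        with open(path) as fh:
            d = json.load(fh)
        base = Path(path).parent
        channels = {
            ch: str((base / p)) if not Path(p).is_absolute() else p
            for ch, p in d["channels"].items()
        }
        return cls(
            field_id=d["field_id"],
            channels=channels,
            um_per_pixel=float(d["um_per_pixel"]),
            field_origin=tuple(d.get("field_origin", (0.0, 0.0))),
        )


def write_field(field: MultiChannelField, outdir, run: str = "run", field_id: str = "f000") -> FieldManifest:
    """Write one TIFF per channel plus a JSON manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    channels = {}
    for ch, tag in CHANNEL_TAGS.items():
        path = outdir / f"{run}_{field_id}_{tag}.tif"
        tifffile.imwrite(path, getattr(field, ch))
        channels[ch] = path.name
    manifest = FieldManifest(
        field_id=field_id,
        channels={ch: str(outdir / name) for ch, name in channels.items()},
        um_per_pixel=field.um_per_pixel,
        field_origin=field.field_origin,
    )
    manifest.to_json(outdir / f"{run}_{field_id}_manifest.json")
    return manifest


def read_field(manifest: FieldManifest) -> MultiChannelField:
    """Load the three channels; 8-bit images are promoted to uint16 without rescaling."""
    manifest.validate()
    arrays = {}
    shapes = {}
    for ch in CHANNEL_TAGS:
        img = tifffile.imread(manifest.channels[ch])
        if img.ndim != 2:
            raise ValueError(f"channel {ch!r}: expected a 2-D grayscale image, got {img.shape}")
        if img.dtype == np.uint8:
            img = img.astype(np.uint16)
        elif img.dtype != np.uint16:
            raise ValueError(f"channel {ch!r}: unsupported dtype {img.dtype}; expected 8/16-bit")
        arrays[ch] = img
        shapes[ch] = img.shape
    first = next(iter(shapes.values()))
    for ch, shp in shapes.items():
        if shp != first:
            raise ValueError(f"channel {ch!r} shape {shp} differs from {first}")
    return MultiChannelField(
        tracer=arrays["tracer"],
        phenotype=arrays["phenotype"],
        nuclei=arrays["nuclei"],
        um_per_pixel=manifest.um_per_pixel,
        field_origin=tuple(manifest.field_origin),
    )


# ---------------------------------------------------------------------------
# layouts (GAL dialect)

_GEOMETRY_KEYS = {
    "SlideWidth": "slide_width",
    "SlideHeight": "slide_height",
    "SpotDiameter": "spot_diameter",
    "EdgeGap": "edge_gap",
    "Margin": "margin",
    "Rows": "n_rows",
    "Cols": "n_cols",
}


def write_layout(layout: GridLayout, path) -> None:
    """Write a GridLayout as a GAL-dialect tab-delimited array list."""
    header_records = [
        '"Type=GenePix ArrayList V1.0"',
        '"BlockCount=1"',
        f'"SlideWidth={layout.slide_width:.1f}"',
        f'"SlideHeight={layout.slide_height:.1f}"',
        f'"SpotDiameter={layout.spot_diameter:.1f}"',
        f'"EdgeGap={layout.edge_gap:.1f}"',
        f'"Margin={layout.margin:.1f}"',
        f'"Rows={layout.n_rows}"',
        f'"Cols={layout.n_cols}"',
    ]
    lines = ["ATF\t1.0", f"{len(header_records)}\t7"]
    lines.extend(header_records)
    lines.append("Block\tRow\tColumn\tX\tY\tID\tName")
    for s in layout.spots:
        row = s.spot_id // layout.n_cols + 1
        col = s.spot_id % layout.n_cols + 1
        name = f"{s.role}|{s.reagent_label}"
        lines.append(f"1\t{row}\t{col}\t{s.center_x:.1f}\t{s.center_y:.1f}\t{s.spot_id}\t{name}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_layout(path) -> GridLayout:
    """Parse a GAL-dialect array list back into a validated GridLayout."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    if not text or not text[0].startswith("ATF"):
        raise GalFormatError("missing ATF signature", line=1)
    try:
        n_headers = int(text[1].split("\t")[0])
    except (IndexError, ValueError) as exc:
        raise GalFormatError(f"bad header-count record: {exc}", line=2) from exc
    geometry: dict[str, float] = {}
    for i in range(2, 2 + n_headers):
        try:
            record = text[i].strip().strip('"')
        except IndexError as exc:
            raise GalFormatError("file truncated inside header block", line=i + 1) from exc
        if "=" not in record:
            raise GalFormatError(f"header record without '=': {record!r}", line=i + 1)
        key, _, value = record.partition("=")
        if key in _GEOMETRY_KEYS:
            try:
                geometry[_GEOMETRY_KEYS[key]] = float(value)
            except ValueError as exc:
                raise GalFormatError(f"bad value for {key}: {value!r}", line=i + 1) from exc
    missing = [k for k in _GEOMETRY_KEYS.values() if k not in geometry]
    if missing:
        raise GalFormatError(f"missing geometry headers: {missing}")

    col_line = 2 + n_headers
    expected_cols = ["Block", "Row", "Column", "X", "Y", "ID", "Name"]
    if text[col_line].split("\t") != expected_cols:
        raise GalFormatError(
            f"unexpected column header {text[col_line]!r}; expected {expected_cols}",
            line=col_line + 1,
        )
    spots = []
    for i, line in enumerate(text[col_line + 1 :], start=col_line + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise GalFormatError(f"expected 7 fields, got {len(parts)}", line=i)
        try:
            x, y, sid = float(parts[3]), float(parts[4]), int(parts[5])
        except ValueError as exc:
            raise GalFormatError(str(exc), line=i) from exc
        role, _, label = parts[6].partition("|")
        spots.append(SpotSpec(spot_id=sid, center_x=x, center_y=y, reagent_label=label, role=role))
    layout = GridLayout(
        slide_width=geometry["slide_width"],
        slide_height=geometry["slide_height"],
        spot_diameter=geometry["spot_diameter"],
        edge_gap=geometry["edge_gap"],
        margin=geometry["margin"],
        n_rows=int(geometry["n_rows"]),
        n_cols=int(geometry["n_cols"]),
        spots=spots,
    )
    layout.validate()
    return layout


def layout_to_json(layout: GridLayout, path) -> None:
    d = {
        "slide_width": layout.slide_width,
        "slide_height": layout.slide_height,
        "spot_diameter": layout.spot_diameter,
        "edge_gap": layout.edge_gap,
        "margin": layout.margin,
        "n_rows": layout.n_rows,
        "n_cols": layout.n_cols,
        "spots": [
            {
                "spot_id": s.spot_id,
                "center_x": s.center_x,
                "center_y": s.center_y,
                "reagent_label": s.reagent_label,
                "role": s.role,
            }
            for s in layout.spots
        ],
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def layout_from_json(path) -> GridLayout:
    with open(path) as fh:
        d = json.load(fh)
    spots = [SpotSpec(**s) for s in d.pop("spots")]
    layout = GridLayout(spots=spots, **d)
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# tables


def write_cell_table(cells: list[CellRecord], path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "x_px": [round(c.centroid_col, 2) for c in cells],
            "y_px": [round(c.centroid_row, 2) for c in cells],
            "area_px": [c.nucleus_area_px for c in cells],
            "intensity": [c.phenotype_intensity for c in cells],
            "expressing": [c.expressing for c in cells],
            "spot_id": [c.assigned_spot_id for c in cells],
        }
    )
    df.to_csv(path, index=False)


def read_cell_table(path) -> list[CellRecord]:
    df = pd.read_csv(path)
    cells = []
    for row in df.itertuples(index=False):
        spot = None if pd.isna(row.spot_id) else int(row.spot_id)
        expressing = None if pd.isna(row.expressing) else bool(row.expressing)
        intensity = None if pd.isna(row.intensity) else float(row.intensity)
        cells.append(
            CellRecord(
                cell_id=int(row.cell_id),
                centroid_row=float(row.y_px),
                centroid_col=float(row.x_px),
                nucleus_area_px=int(row.area_px),
                phenotype_intensity=intensity,
                expressing=expressing,
                assigned_spot_id=spot,
            )
        )
    return cells


def write_detections(detections: list[SpotDetection], path) -> None:
    pd.DataFrame(
        {
            "detection_id": [d.detection_id for d in detections],
            "x_px": [round(d.centroid_col, 2) for d in detections],
            "y_px": [round(d.centroid_row, 2) for d in detections],
            "area_px": [d.area_px for d in detections],
            "diameter_um": [round(d.equivalent_diameter_um, 1) for d in detections],
            "intensity": [round(d.mean_tracer_intensity, 2) for d in detections],
            "matched_spot_id": [d.matched_spot_id for d in detections],
        }
    ).to_csv(path, index=False)


def write_spot_results(results: list[SpotResult], path) -> None:
    pd.DataFrame(
        {
            "spot_id": [r.spot_id for r in results],
            "reagent_label": [r.reagent_label for r in results],
            "role": [r.role for r in results],
            "n_cells": [r.n_cells for r in results],
            "n_expressing": [r.n_expressing for r in results],
            "percent_expressing": [round(r.percent_expressing, 3) for r in results],
            "low_count": [r.low_count for r in results],
        }
    ).to_csv(path, index=False)


def write_conditions(conditions: list[NormalizedCondition], path) -> None:
    pd.DataFrame(
        {
            "condition": [c.condition for c in conditions],
            "n": [c.n for c in conditions],
            "mean_normalized_expression": [round(c.mean_normalized_expression, 3) for c in conditions],
            "sd": [round(c.sd, 3) for c in conditions],
            "knockdown_percent": [round(c.knockdown_percent, 3) for c in conditions],
            "t_statistic": [c.t_statistic for c in conditions],
            "p_value": [c.p_value for c in conditions],
        }
    ).to_csv(path, index=False)


def write_ground_truth(truth: GroundTruth, path) -> None:
    pd.DataFrame(
        {
            "x_um": [round(c.center_x, 2) for c in truth.cells],
            "y_um": [round(c.center_y, 2) for c in truth.cells],
            "nucleus_radius_um": [round(c.nucleus_radius, 2) for c in truth.cells],
            "expressing": [c.expressing for c in truth.cells],
            "spot_id": [c.spot_id for c in truth.cells],
            "phenotype_value": [round(c.phenotype_value, 2) for c in truth.cells],
        }
    ).to_csv(path, index=False)


def read_ground_truth(path) -> GroundTruth:
    from .synth import GroundTruthCell

    df = pd.read_csv(path)
    cells = [
        GroundTruthCell(
            center_x=float(r.x_um),
            center_y=float(r.y_um),
            nucleus_radius=float(r.nucleus_radius_um),
            expressing=bool(r.expressing),
            spot_id=None if pd.isna(r.spot_id) else int(r.spot_id),
            phenotype_value=float(r.phenotype_value),
        )
        for r in df.itertuples(index=False)
    ]
    return GroundTruth(cells=cells)
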