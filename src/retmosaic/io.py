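"""Readers and writers for the package's plain-text formats.

Soma fields travel as CSV (id, x_um, y_um, diameter_um, labels with
semicolon-joined tags), arbor territories and clone columns as JSON vertex
lists, DRP profiles as tidy per-bin TSV. See docs/FORMATS.md for the full
format reference. Saving then loading reproduces a field exactly: floats are
written with repr-level precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enclosure import ArborTerritory
from .errors import InputError
from .geometry import SimplePolygon, SomaField, SomaPoint, Window
from .mosaic_stats import DRPResult

__all__ = [
    "load_soma_csv",
    "save_soma_csv",
    "load_polygons_json",
    "save_polygons_json",
    "drp_to_frame",
    "save_drp_tsv",
]

_REQUIRED_COLUMNS = ("id", "x_um", "y_um")


def load_soma_csv(path, window: Window, field_id: str | None = None) -> SomaField:
    """Read a soma-centre table; validates bounds against ``window``.

    Requires columns id, x_um, y_um; optional diameter_um (default 10.0) and
    labels (semicolon-joined tags). Errors name the offending row.
    """
    df = pd.read_csv(
        path, dtype={"id": str, "labels": str}, float_precision="round_trip"
    )
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    points = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        x, y = getattr(row, "x_um"), getattr(row, "y_um")
        if not (np.isfinite(x) and np.isfinite(y)):
            raise InputError(f"{path}: non-numeric coordinate at row {row_no}")
        if not window.contains(x, y):
            raise InputError(
                f"{path}: soma {row.id!r} at row {row_no} lies outside the window"
            )
        diameter = float(getattr(row, "diameter_um", 10.0))
        if not np.isfinite(diameter):
            raise InputError(f"{path}: non-numeric diameter at row {row_no}")
        raw = getattr(row, "labels", "")
        labels = frozenset(
            tag for tag in str(raw).split(";") if tag and tag.lower() != "nan"
        )
        points.append(SomaPoint(str(row.id), float(x), float(y), diameter, labels))
    return SomaField(window, points, field_id=field_id or Path(path).stem)


def save_soma_csv(field: SomaField, path) -> None:
    df = pd.DataFrame(
        {
            "id": [p.id for p in field.points],
            "x_um": [repr(float(p.x_um)) for p in field.points],
            "y_um": [repr(float(p.y_um)) for p in field.points],
            "diameter_um": [repr(float(p.diameter_um)) for p in field.points],
            "labels": [";".join(sorted(p.labels)) for p in field.points],
        }
    )
    df.to_csv(path, index=False)


def load_polygons_json(path) -> list:
    """Read arbor territories from a JSON array of
    ``{"reference_id", "vertices_um", ["source_field_id"]}`` records.

    Self-intersecting or degenerate vertex lists raise a validation error
    naming the reference_id.
    """
    with open(path) as fh:
        data = json.load(fh)
    arbors = []
    for rec in data:
        try:
            poly = SimplePolygon(tuple(map(tuple, rec["vertices_um"])))
        except InputError as exc:
            raise InputError(
                f"{path}: invalid polygon for reference "
                f"{rec.get('reference_id')!r}: {exc}"
            ) from exc
        arbors.append(
            ArborTerritory(
                str(rec["reference_id"]), poly, rec.get("source_field_id")
            )
        )
    return arbors


def save_polygons_json(arbors: list, path) -> None:
    data = [
        {
            "reference_id": a.reference_id,
            "source_field_id": a.source_field_id,
            "vertices_um": [list(v) for v in a.polygon.vertices_um],
        }
        for a in arbors
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


def drp_to_frame(drp: DRPResult) -> pd.DataFrame:
    """Tidy per-bin DRP table (one annulus per row)."""
    return pd.DataFrame(
        {
            "bin_mid_um": drp.bin_mids_um,
            "count": drp.counts,
            "corrected_area_um2": drp.corrected_areas_um2,
            "density_cells_per_mm2": drp.densities_per_mm2,
        }
    )


def save_drp_tsv(drp: DRPResult, path) -> None:
    drp_to_frame(drp).to_csv(path, sep="\t", index=False)
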