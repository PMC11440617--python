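"""Windowed planar geometry primitives for mosaic spatial statistics.

All coordinates are micrometres (μm) inside an axis-aligned rectangular
observation window [0, width] × [0, height] with the origin at one corner.
Densities are reported in cells/mm²; the μm²→mm² constant is pinned in
:data:`UM2_PER_MM2`. Distances are Euclidean and coordinates continuous
(no pixel grid).

The annulus–window intersection area used for density-recovery-profile edge
correction is computed analytically (difference of two circle–rectangle
intersection areas) rather than numerically, so the O(n·K) DRP loop stays
exact and fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon as _ShapelyPolygon, box

from .errors import InputError

#: conversion constant: 1 mm² = 10⁶ μm²
UM2_PER_MM2 = 1.0e6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular field of view, [0, width] × [0, height] μm."""

    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        if not (self.width_um > 0 and self.height_um > 0):
            raise InputError("window dimensions must be positive")

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / UM2_PER_MM2

    def contains(self, x: float, y: float) -> bool:
        """Boundary-inclusive membership test."""
        return 0.0 <= x <= self.width_um and 0.0 <= y <= self.height_um

    def as_box(self) -> _ShapelyPolygon:
        return box(0.0, 0.0, self.width_um, self.height_um)


@dataclass(frozen=True)
class SomaPoint:
    """A soma centre with its diameter and free-form tags.

    The default diameter, 10.0 μm, is the mean starburst soma size used as the
    hard-core distance throughout; tags carry population / genotype / reporter
    flags (e.g. ``{"ON", "reference"}``).
    """

    id: str
    x_um: float
    y_um: float
    diameter_um: float = 10.0
    labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise InputError(f"soma {self.id!r}: diameter must be positive")
        object.__setattr__(self, "x_um", float(self.x_um))
        object.__setattr__(self, "y_um", float(self.y_um))
        object.__setattr__(self, "diameter_um", float(self.diameter_um))
        object.__setattr__(self, "labels", frozenset(self.labels))

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0


@dataclass
class SomaField:
    """A windowed 2D point set of soma centres — the substrate of every statistic."""

    window: Window
    points: list
    field_id: str | None = None

    def __post_init__(self) -> None:
        self.points = list(self.points)
        ids = [p.id for p in self.points]
        if len(set(ids)) != len(ids):
            raise InputError("soma ids must be unique within a field")
        for p in self.points:
            if not self.window.contains(p.x_um, p.y_um):
                raise InputError(
                    f"soma {p.id!r} at ({p.x_um}, {p.y_um}) lies outside the window"
                )

    def __len__(self) -> int:
        return len(self.points)

    def coords(self) -> np.ndarray:
        """(n, 2) array of centre coordinates in μm."""
        if not self.points:
            return np.empty((0, 2))
        return np.array([[p.x_um, p.y_um] for p in self.points], dtype=float)

    def diameters(self) -> np.ndarray:
        return np.array([p.diameter_um for p in self.points], dtype=float)

    @property
    def density_per_mm2(self) -> float:
        """Global density D = n / window area, in cells/mm²."""
        return len(self.points) / self.window.area_mm2

    def subset(self, label: str) -> "SomaField":
        """Field restricted to somata carrying ``label``."""
        return SomaField(
            self.window,
            [p for p in self.points if label in p.labels],
            field_id=self.field_id,
        )


@dataclass(frozen=True)
class SimplePolygon:
    """A closed, non-self-intersecting polygon given by its vertex ring (μm)."""

    vertices_um: tuple

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices_um)
        object.__setattr__(self, "vertices_um", verts)
        if len(verts) < 3:
            raise InputError("polygon needs at least 3 vertices")
        poly = _ShapelyPolygon(verts)
        if (not poly.is_valid) or poly.area <= 0:
            raise InputError("polygon must be simple (non-self-intersecting) with positive area")

    @cached_property
    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices_um)

    @property
    def area_um2(self) -> float:
        return self.shapely.area


# ---------------------------------------------------------------------------
# annulus-window intersection (DRP edge correction)
# ---------------------------------------------------------------------------

def _disk_quadrant_area(a: float, b: float, r: float) -> float:
    """Area of the disk x²+y²≤r² inside the box [0, a] × [0, b] (a, b may be ≤0)."""
    if a <= 0.0 or b <= 0.0 or r <= 0.0:
        return 0.0
    a = min(a, r)
    b = min(b, r)
    if a * a + b * b <= r * r:
        return a * b
    # the box corner (a, b) pokes outside the circle
    x1 = math.sqrt(max(r * r - b * b, 0.0))

    def antiderivative(x: float) -> float:
        # ∫ sqrt(r² − x²) dx
        x = min(max(x, -r), r)
        return 0.5 * (x * math.sqrt(max(r * r - x * x, 0.0)) + r * r * math.asin(x / r))

    return b * x1 + antiderivative(a) - antiderivative(x1)


def circle_window_area(cx: float, cy: float, r: float, window: Window) -> float:
    """Exact area of the disk of radius ``r`` about (cx, cy) clipped to the window."""
    if r <= 0.0:
        return 0.0
    return (
        _disk_quadrant_area(window.width_um - cx, window.height_um - cy, r)
        + _disk_quadrant_area(cx, window.height_um - cy, r)
        + _disk_quadrant_area(window.width_um - cx, cy, r)
        + _disk_quadrant_area(cx, cy, r)
    )


def annulus_window_area(
    center: Sequence[float], r_inner: float, r_outer: float, window: Window
) -> float:
    """Exact area of {p : r_inner ≤ |p − center| < r_outer} ∩ window, in μm².

    The annulus is half-open, but the boundary circle has measure zero so the
    area equals the difference of two clipped disk areas.
    """
    cx, cy = float(center[0]), float(center[1])
    if not window.contains(cx, cy):
        raise InputError(f"annulus centre ({cx}, {cy}) lies outside the window")
    if not (0.0 <= r_inner < r_outer):
        raise InputError("require 0 <= r_inner < r_outer")
    return circle_window_area(cx, cy, r_outer, window) - circle_window_area(
        cx, cy, r_inner, window
    )


# ---------------------------------------------------------------------------
# disk-in-polygon containment
# ---------------------------------------------------------------------------

def disk_fully_inside(soma: SomaPoint, polygon: SimplePolygon) -> bool:
    """True iff the closed soma disk lies entirely within the polygon.

    Equivalent to: centre strictly inside AND distance from centre to the
    polygon boundary ≥ soma radius.
    """
    poly = polygon.shapely
    pt = Point(soma.x_um, soma.y_um)
    if not poly.contains(pt):
        return False
    return poly.exterior.distance(pt) >= soma.radius_um


# ---------------------------------------------------------------------------
# clipped Voronoi tessellation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoronoiDomain:
    id: str
    polygon: _ShapelyPolygon
    area_um2: float
    is_border: bool


def voronoi_domains(field: SomaField) -> list:
    """Voronoi cell of every soma, clipped to the window.

    Implemented by mirroring the point set across the four window edges before
    triangulating, which makes every original cell finite and clips it exactly
    at the window boundary. Domains whose boundary touches the window edge are
    flagged ``is_border`` (the regularity-index consumer decides exclusion);
    clipped areas tile the window exactly.
    """
    pts = field.coords()
    n = len(pts)
    if n < 4:
        raise InputError("Voronoi tessellation needs at least 4 points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
        raise InputError("points are collinear; Voronoi domains are degenerate")
    w, h = field.window.width_um, field.window.height_um

    mirrored = np.vstack(
        [
            pts,
            np.column_stack([-pts[:, 0], pts[:, 1]]),          # across x = 0
            np.column_stack([2 * w - pts[:, 0], pts[:, 1]]),   # across x = w
            np.column_stack([pts[:, 0], -pts[:, 1]]),          # across y = 0
            np.column_stack([pts[:, 0], 2 * h - pts[:, 1]]),   # across y = h
        ]
    )
    vor = Voronoi(mirrored)
    window_box = field.window.as_box()
    tol = 1e-7 * max(w, h)

    domains = []
    for i, soma in enumerate(field.points):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:  # pragma: no cover - mirrors prevent this
            raise InputError(f"unbounded Voronoi cell for soma {soma.id!r}")
        verts = vor.vertices[region]
        cell = _ShapelyPolygon(verts)
        clipped = cell.intersection(window_box)
        is_border = bool(
            np.any(
                (np.abs(verts[:, 0]) < tol)
                | (np.abs(verts[:, 0] - w) < tol)
                | (np.abs(verts[:, 1]) < tol)
                | (np.abs(verts[:, 1] - h) < tol)
            )
        )
        domains.append(VoronoiDomain(soma.id, clipped, clipped.area, is_border))
    return domains


# ---------------------------------------------------------------------------
# flip transform (chance-rate controls)
# ---------------------------------------------------------------------------

def flip_points(xy: np.ndarray, window: Window) -> np.ndarray:
    """Reflect points about both window axes: (x, y) → (width − x, height − y).

    Order is preserved; applying the flip twice restores the input.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise InputError("expected an (n, 2) coordinate array")
    if xy.size and (
        xy[:, 0].min() < 0
        or xy[:, 1].min() < 0
        or xy[:, 0].max() > window.width_um
        or xy[:, 1].max() > window.height_um
    ):
        raise InputError("points must lie inside the window")
    return np.column_stack([window.width_um - xy[:, 0], window.height_um - xy[:, 1]])


def flip_field(field: SomaField) -> SomaField:
    """Field with every soma reflected about both axes (labels preserved)."""
    flipped = flip_points(field.coords(), field.window)
    points = [
        SomaPoint(p.id, float(x), float(y), p.diameter_um, p.labels)
        for p, (x, y) in zip(field.points, flipped)
    ]
    return SomaField(field.window, points, field_id=field.field_id)
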