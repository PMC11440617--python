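"""Seeded generators for every input the analysis pipeline consumes.

Four point-pattern regimes emulate the phenotypes under study:

* ``hardcore_random`` — somata dropped one-by-one uniformly at random,
  rejecting any candidate whose centre comes closer than one soma diameter
  to an existing cell (the random-array reference; also the mutant-OFF
  phenotype).
* ``exclusion_mosaic`` — sequential insertion additionally rejects candidates
  falling inside any existing cell's dendritic-territory polygon, the
  dendrite–soma exclusion mechanism that regularises wild-type mosaics.
* ``clustered`` — a Thomas (Poisson cluster) process with the hard core
  retained, for the aggregated mutant phenotypes.
* ``clone_field`` — radial clone columns plus a known fraction of tangentially
  dispersed cells with a known displacement distribution.

Arbor polygons are jittered regular n-gons in three regimes: ``coordinated``
(radius scaled to the nearest homotypic neighbour, the wild-type anatomy),
``independent`` (size drawn blind to neighbours), and ``overgrown`` (reaching
past the first neighbour ring, the later-stage anatomy). Dendritic-tip fields
with a controllable true contact rate complete the inputs.

All randomness flows through one pinned generator (numpy PCG64) seeded from
the config, so a fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.ops import unary_union
from shapely.prepared import prep

from .enclosure import ArborTerritory
from .errors import ConfigError, InputError, SaturationError
from .geometry import SimplePolygon, SomaField, SomaPoint, Window, disk_fully_inside

__all__ = [
    "ON_WT_DENSITY_PER_MM2",
    "OFF_WT_DENSITY_PER_MM2",
    "ArborParams",
    "ClusterParams",
    "CloneParams",
    "SimConfig",
    "CloneField",
    "simulate_hardcore",
    "simulate_exclusion_mosaic",
    "simulate_clustered",
    "generate_arbors",
    "generate_tip_field",
    "generate_clone_field",
]

#: printed wild-type densities (cells/mm²) used as presets
ON_WT_DENSITY_PER_MM2 = 1290.0
OFF_WT_DENSITY_PER_MM2 = 1495.0

#: side of the standard 40x field of view, μm
DEFAULT_WINDOW_SIDE_UM = 353.55


@dataclass(frozen=True)
class ArborParams:
    """Dendritic-territory polygon parameters.

    ``alpha`` scales coordinated radii relative to the nearest-neighbour
    distance (0.9: the arbor stops just short of the nearest homotypic soma);
    ``overgrow_alpha`` scales overgrown radii relative to the
    ``neighbor_rank``-th neighbour (1.1 × 2nd neighbour: past the first ring).
    """

    arbor_mode: str = "coordinated"
    alpha: float = 0.9
    radius_mean_um: float = 15.0
    radius_sd_um: float = 3.0
    n_vertices: int = 12
    vertex_jitter_frac: float = 0.1
    overgrow_alpha: float = 1.1
    neighbor_rank: int = 2

    def __post_init__(self) -> None:
        if self.arbor_mode not in ("coordinated", "independent", "overgrown"):
            raise ConfigError(f"unknown arbor_mode {self.arbor_mode!r}")
        if self.n_vertices < 3:
            raise ConfigError("arbors need at least 3 vertices")
        if not (0 <= self.vertex_jitter_frac < 1):
            raise ConfigError("vertex_jitter_frac must be in [0, 1)")
        if min(self.alpha, self.radius_mean_um, self.radius_sd_um, self.overgrow_alpha) <= 0:
            raise ConfigError("arbor scale parameters must be positive")
        if self.neighbor_rank < 2:
            raise ConfigError("overgrown arbors must reference the 2nd neighbour or beyond")


@dataclass(frozen=True)
class ClusterParams:
    """Thomas-process parameters: parent intensity κ (per mm²), Poisson
    offspring mean μ per parent, isotropic Gaussian offspring scatter σ (μm)."""

    parent_intensity_per_mm2: float = 350.0
    offspring_mean: float = 4.0
    offspring_sd_um: float = 10.0
    max_offspring_retries: int = 100

    def __post_init__(self) -> None:
        if min(self.parent_intensity_per_mm2, self.offspring_mean, self.offspring_sd_um) <= 0:
            raise ConfigError("cluster parameters must be positive")


@dataclass(frozen=True)
class CloneParams:
    """Clone-column field parameters: column disk radius and areal density,
    dispersed fraction p, and the |Normal| displacement of dispersed cells
    beyond the column boundary (μm)."""

    column_radius_um: float = 15.0
    column_density_per_mm2: float = 100.0
    dispersed_fraction: float = 0.3
    displacement_mean_um: float = 15.0
    displacement_sd_um: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dispersed_fraction <= 1.0):
            raise ConfigError("dispersed_fraction must be in [0, 1]")
        if min(
            self.column_radius_um,
            self.column_density_per_mm2,
            self.displacement_mean_um,
            self.displacement_sd_um,
        ) <= 0:
            raise ConfigError("clone parameters must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one synthetic-mosaic run."""

    mode: str = "hardcore_random"
    window: Window = Window(DEFAULT_WINDOW_SIDE_UM, DEFAULT_WINDOW_SIDE_UM)
    target_density_per_mm2: float = 1400.0
    soma_diameter_um: float = 10.0
    arbor_params: ArborParams = dc_field(default_factory=ArborParams)
    cluster_params: ClusterParams = dc_field(default_factory=ClusterParams)
    clone_params: CloneParams = dc_field(default_factory=CloneParams)
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.mode not in ("hardcore_random", "exclusion_mosaic", "clustered", "clone_field"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.target_density_per_mm2 <= 0 or self.soma_diameter_um <= 0:
            raise ConfigError("density and soma diameter must be positive")
        # packing feasibility: soma-disk area fraction must stay below 0.5
        area_fraction = (
            self.target_density_per_mm2
            / 1e6
            * math.pi
            * (self.soma_diameter_um / 2.0) ** 2
        )
        if area_fraction >= 0.5:
            raise ConfigError(
                f"infeasible packing: soma area fraction {area_fraction:.2f} >= 0.5"
            )

    @property
    def n_target(self) -> int:
        return int(round(self.target_density_per_mm2 * self.window.area_mm2))

    @classmethod
    def off_wildtype(cls, seed: int = 0, **kwargs) -> "SimConfig":
        """Exclusion-mosaic preset at the printed OFF wild-type density."""
        return cls(
            mode="exclusion_mosaic",
            target_density_per_mm2=OFF_WT_DENSITY_PER_MM2,
            seed=seed,
            **kwargs,
        )

    @classmethod
    def on_wildtype(cls, seed: int = 0, **kwargs) -> "SimConfig":
        """Exclusion-mosaic preset at the printed ON wild-type density."""
        return cls(
            mode="exclusion_mosaic",
            target_density_per_mm2=ON_WT_DENSITY_PER_MM2,
            seed=seed,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# arbor polygon machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ArborProfile:
    """Per-cell polygon shape (rotation + per-vertex jitter multipliers),
    separated from the radius so an arbor can be rescaled deterministically."""

    rotation: float
    multipliers: tuple

    def polygon(self, cx: float, cy: float, radius: float) -> SimplePolygon:
        n = len(self.multipliers)
        angles = self.rotation + 2.0 * math.pi * np.arange(n) / n
        r = radius * np.asarray(self.multipliers)
        verts = np.column_stack([cx + r * np.cos(angles), cy + r * np.sin(angles)])
        return SimplePolygon(tuple(map(tuple, verts)))


def _draw_profile(rng: np.random.Generator, params: ArborParams) -> _ArborProfile:
    for _ in range(50):
        rotation = float(rng.uniform(0.0, 2.0 * math.pi))
        mult = 1.0 + params.vertex_jitter_frac * rng.uniform(-1.0, 1.0, params.n_vertices)
        profile = _ArborProfile(rotation, tuple(mult))
        try:
            profile.polygon(0.0, 0.0, 1.0)
        except InputError:
            continue  # jitter produced a self-intersection; redraw
        return profile
    raise RuntimeError("could not draw a simple jittered polygon")  # pragma: no cover


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) redrawn until strictly positive."""
    for _ in range(1000):
        v = float(rng.normal(mean, sd))
        if v > 0:
            return v
    raise RuntimeError("truncated-normal draw failed")  # pragma: no cover


def _arbor_with_floor(
    soma: SomaPoint, profile: _ArborProfile, radius: float, source_field_id: str | None
) -> ArborTerritory:
    """Build the arbor, enforcing that the reference soma disk fits inside.

    Radii too small for the disk are regenerated at the floor radius
    1.2 × soma radius, then nudged up until containment holds (vertex jitter
    can pull the inradius below the nominal radius).
    """
    radius = max(radius, 1.2 * soma.radius_um)
    for _ in range(100):
        arbor = ArborTerritory(
            soma.id, profile.polygon(soma.x_um, soma.y_um, radius), source_field_id
        )
        if disk_fully_inside(soma, arbor.polygon):
            return arbor
        radius *= 1.05
    raise RuntimeError("failed to fit reference soma inside its arbor")  # pragma: no cover


# ---------------------------------------------------------------------------
# point-pattern generators
# ---------------------------------------------------------------------------

def _uniform_candidate(rng: np.random.Generator, window: Window) -> np.ndarray:
    return rng.uniform((0.0, 0.0), (window.width_um, window.height_um))


def _make_field(config: SimConfig, coords: np.ndarray, field_id: str | None) -> SomaField:
    points = [
        SomaPoint(f"c{i:04d}", float(x), float(y), config.soma_diameter_um)
        for i, (x, y) in enumerate(coords)
    ]
    return SomaField(config.window, points, field_id=field_id)


def simulate_hardcore(config: SimConfig, field_id: str | None = None) -> SomaField:
    """Sequential random placement with a hard core at the soma diameter.

    Candidates are uniform on the window; a candidate whose centre falls
    within one soma diameter of an existing cell is cancelled and redrawn,
    until exactly ``round(density × area)`` cells are placed. Exhausting
    ``max_attempts`` consecutive rejections raises :class:`SaturationError`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_target
    d = config.soma_diameter_um
    pts = np.empty((n, 2))
    k = 0
    attempts = 0
    while k < n:
        if attempts >= config.max_attempts:
            raise SaturationError(k, n)
        c = _uniform_candidate(rng, config.window)
        if k and np.min(np.hypot(pts[:k, 0] - c[0], pts[:k, 1] - c[1])) < d:
            attempts += 1
            continue
        pts[k] = c
        k += 1
        attempts = 0
    return _make_field(config, pts, field_id)


def simulate_exclusion_mosaic(
    config: SimConfig, field_id: str | None = None
) -> tuple:
    """Mosaic built by dendrite–soma exclusion.

    Cells are inserted sequentially; a candidate is rejected if it violates
    the hard core *or* its centre falls inside any existing cell's arbor
    polygon, so each territory carves out an exclusion zone. Each accepted
    cell receives a jittered n-gon arbor with radius ~ N(mean, sd) truncated
    positive; in ``coordinated`` mode the radii are then rescaled to
    alpha × nearest-neighbour distance (``overgrown``: overgrow_alpha × k-th
    neighbour). Returns ``(field, arbors)``.
    """
    rng = np.random.default_rng(config.seed)
    params = config.arbor_params
    n = config.n_target
    d = config.soma_diameter_um
    centers: list = []
    radii: list = []
    profiles: list = []
    polys: list = []
    max_r: list = []

    attempts = 0
    while len(centers) < n:
        if attempts >= config.max_attempts:
            raise SaturationError(len(centers), n)
        c = _uniform_candidate(rng, config.window)
        ok = True
        if centers:
            arr = np.asarray(centers)
            dist = np.hypot(arr[:, 0] - c[0], arr[:, 1] - c[1])
            if dist.min() < d:
                ok = False
            else:
                pt = Point(c)
                for j in np.nonzero(dist < np.asarray(max_r))[0]:
                    if polys[j].contains(pt):
                        ok = False
                        break
        if not ok:
            attempts += 1
            continue
        radius = _truncated_normal(rng, params.radius_mean_um, params.radius_sd_um)
        profile = _draw_profile(rng, params)
        poly = profile.polygon(c[0], c[1], radius)
        centers.append(c)
        radii.append(radius)
        profiles.append(profile)
        polys.append(poly.shapely)
        max_r.append(radius * (1.0 + params.vertex_jitter_frac))
        attempts = 0

    field = _make_field(config, np.asarray(centers), field_id)
    final_radii = _mode_radii(field.coords(), np.asarray(radii), params)
    arbors = [
        _arbor_with_floor(soma, profile, float(r), field_id)
        for soma, profile, r in zip(field.points, profiles, final_radii)
    ]
    return field, arbors


def _mode_radii(coords: np.ndarray, base_radii: np.ndarray, params: ArborParams) -> np.ndarray:
    """Arbor radii for the requested regime, from base draws and neighbour geometry."""
    if params.arbor_mode == "independent" or len(coords) < params.neighbor_rank + 1:
        return base_radii
    tree = cKDTree(coords)
    k = 2 if params.arbor_mode == "coordinated" else params.neighbor_rank + 1
    dist, _ = tree.query(coords, k=k)
    if params.arbor_mode == "coordinated":
        return params.alpha * dist[:, 1]
    return params.overgrow_alpha * dist[:, -1]


def simulate_clustered(config: SimConfig, field_id: str | None = None) -> SomaField:
    """Thomas cluster process with the hard core retained.

    Parent centres form a Poisson process at intensity κ; each parent spawns
    Poisson(μ) offspring displaced by an isotropic Gaussian of scale σ.
    Offspring landing outside the window or violating the hard core are
    redrawn a bounded number of times, then dropped, so clumps touch without
    merging. Warns when the realised density falls below 80% of κ·μ.
    """
    rng = np.random.default_rng(config.seed)
    cp = config.cluster_params
    area_mm2 = config.window.area_mm2
    d = config.soma_diameter_um
    n_parents = int(rng.poisson(cp.parent_intensity_per_mm2 * area_mm2))
    accepted: list = []
    for _ in range(n_parents):
        parent = _uniform_candidate(rng, config.window)
        n_off = int(rng.poisson(cp.offspring_mean))
        for _ in range(n_off):
            for _ in range(cp.max_offspring_retries):
                pos = parent + rng.normal(0.0, cp.offspring_sd_um, 2)
                if not config.window.contains(pos[0], pos[1]):
                    continue
                if accepted:
                    arr = np.asarray(accepted)
                    if np.min(np.hypot(arr[:, 0] - pos[0], arr[:, 1] - pos[1])) < d:
                        continue
                accepted.append(pos)
                break
    expected = cp.parent_intensity_per_mm2 * area_mm2 * cp.offspring_mean
    if expected > 0 and len(accepted) < 0.8 * expected:
        warnings.warn(
            f"clustered field realised {len(accepted)} cells "
            f"(< 80% of the expected {expected:.0f}); clumps may be over-packed",
            stacklevel=2,
        )
    coords = np.asarray(accepted) if accepted else np.empty((0, 2))
    return _make_field(config, coords, field_id)


# ---------------------------------------------------------------------------
# arbors, tips, clone fields
# ---------------------------------------------------------------------------

def generate_arbors(
    field: SomaField,
    arbor_params: ArborParams,
    seed: int,
    reference_ids: list | None = None,
) -> list:
    """Arbor polygon for each requested reference soma (default: all somata).

    ``coordinated`` radii follow alpha × nearest-neighbour distance,
    ``independent`` radii are N(mean, sd) draws blind to neighbours, and
    ``overgrown`` radii follow overgrow_alpha × k-th-neighbour distance.
    Every polygon fully contains its reference soma disk.
    """
    if not field.points:
        raise InputError("field is empty")
    rng = np.random.default_rng(seed)
    coords = field.coords()
    base = np.array(
        [
            _truncated_normal(rng, arbor_params.radius_mean_um, arbor_params.radius_sd_um)
            for _ in range(len(field))
        ]
    )
    radii = _mode_radii(coords, base, arbor_params)
    wanted = set(reference_ids) if reference_ids is not None else None
    arbors = []
    for soma, r in zip(field.points, radii):
        profile = _draw_profile(rng, arbor_params)
        if wanted is not None and soma.id not in wanted:
            continue
        arbors.append(_arbor_with_floor(soma, profile, float(r), field.field_id))
    return arbors


def generate_tip_field(
    field: SomaField,
    true_contact_fraction: float,
    n_tips: int,
    seed: int,
) -> pd.DataFrame:
    """Dendritic-tip point table with a controllable true contact rate.

    A fraction ``true_contact_fraction`` of tips is placed on soma rims
    (soma chosen uniformly, rim angle uniform); the remainder are uniform in
    the window outside all soma disks. Columns: tip_id, parent_cell_id,
    x_um, y_um.
    """
    if n_tips <= 0:
        raise InputError("n_tips must be positive")
    if not (0.0 <= true_contact_fraction <= 1.0):
        raise InputError("true_contact_fraction must be in [0, 1]")
    if not field.points:
        raise InputError("field is empty")
    rng = np.random.default_rng(seed)
    coords = field.coords()
    radii = field.diameters() / 2.0
    n_contact = int(round(true_contact_fraction * n_tips))
    rows = []
    for t in range(n_contact):
        for _ in range(1000):
            j = int(rng.integers(len(field)))
            theta = rng.uniform(0.0, 2.0 * math.pi)
            rim = radii[j] - 1e-9  # a nanometre inside, robust to FP rounding
            x = coords[j, 0] + rim * math.cos(theta)
            y = coords[j, 1] + rim * math.sin(theta)
            if field.window.contains(x, y):
                rows.append((f"t{t:04d}", field.points[j].id, x, y))
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place a rim tip inside the window")
    for t in range(n_contact, n_tips):
        for _ in range(10_000):
            c = _uniform_candidate(rng, field.window)
            if np.all(np.hypot(coords[:, 0] - c[0], coords[:, 1] - c[1]) > radii):
                rows.append((f"t{t:04d}", "scatter", float(c[0]), float(c[1])))
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place a non-contact tip outside all somata")
    return pd.DataFrame(rows, columns=["tip_id", "parent_cell_id", "x_um", "y_um"])


@dataclass
class CloneField:
    """Clone-column polygons, the cell field, and the generation ground truth
    (per-cell dispersed flag and displacement distance)."""

    columns: list
    cells: SomaField
    truth: pd.DataFrame


def _circle_polygon(cx: float, cy: float, r: float, n: int = 64) -> SimplePolygon:
    ang = 2.0 * math.pi * np.arange(n) / n
    return SimplePolygon(tuple(zip(cx + r * np.cos(ang), cy + r * np.sin(ang))))


def generate_clone_field(config: SimConfig, field_id: str | None = None) -> CloneField:
    """Radial clone columns with a known dispersed fraction.

    Column disks (polygonised circles) come from a Poisson process whose
    centres keep one column radius clear of the window edge. A fraction
    1 − p of cells is placed uniformly inside random columns; a fraction p is
    displaced from a column boundary by |N(mean, sd)| along the outward
    radial direction. A dispersed placement is redrawn if it lands inside any
    column, outside the window, or nearer to another column than its own
    displacement — so the origin column is always the nearest one and the
    measured boundary distance recovers the generative displacement. The true
    dispersed flag and displacement are stored per cell.
    """
    rng = np.random.default_rng(config.seed)
    cp = config.clone_params
    win = config.window
    R = cp.column_radius_um
    if 2 * R >= min(win.width_um, win.height_um):
        raise ConfigError("column radius too large for the window")
    n_cols = max(1, int(rng.poisson(cp.column_density_per_mm2 * win.area_mm2)))
    centers = rng.uniform((R, R), (win.width_um - R, win.height_um - R), (n_cols, 2))
    columns = [_circle_polygon(cx, cy, R) for cx, cy in centers]
    union = unary_union([c.shapely for c in columns])
    if union.area > 0.8 * win.area_um2:
        raise ConfigError(
            "columns cover more than 80% of the window; "
            "the dispersed fraction is unidentifiable"
        )
    prepared = [prep(c.shapely) for c in columns]

    n_cells = config.n_target
    n_disp = int(round(cp.dispersed_fraction * n_cells))
    rows = []
    points = []
    for i in range(n_cells - n_disp):  # column-resident cells
        for _ in range(10_000):
            j = int(rng.integers(n_cols))
            rad = R * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            x = centers[j, 0] + rad * math.cos(theta)
            y = centers[j, 1] + rad * math.sin(theta)
            if prepared[j].contains(Point(x, y)) and win.contains(x, y):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place a column cell")
        cid = f"c{i:04d}"
        points.append(SomaPoint(cid, x, y, config.soma_diameter_um, {"column"}))
        rows.append((cid, False, math.nan))
    for i in range(n_cells - n_disp, n_cells):  # dispersed cells
        for _ in range(10_000):
            j = int(rng.integers(n_cols))
            theta = rng.uniform(0.0, 2.0 * math.pi)
            dist = abs(rng.normal(cp.displacement_mean_um, cp.displacement_sd_um))
            x = centers[j, 0] + (R + dist) * math.cos(theta)
            y = centers[j, 1] + (R + dist) * math.sin(theta)
            if not win.contains(x, y):
                continue
            pt = Point(x, y)
            if any(p.contains(pt) for p in prepared):
                continue
            d_centers = np.hypot(centers[:, 0] - x, centers[:, 1] - y)
            d_centers[j] = math.inf
            if d_centers.min() - R > dist:  # origin column stays the nearest
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place a dispersed cell")
        cid = f"c{i:04d}"
        points.append(SomaPoint(cid, x, y, config.soma_diameter_um, {"dispersed"}))
        rows.append((cid, True, dist))

    cells = SomaField(win, points, field_id=field_id)
    truth = pd.DataFrame(rows, columns=["id", "dispersed", "displacement_um"])
    return CloneField(columns, cells, truth)
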