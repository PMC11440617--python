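"""Arbor-territory enclosure analysis with the unmatched-transposition null.

Each reference cell owns a dendritic-territory polygon. The analysis counts
homotypic somata whose disks are fully contained in that polygon (the
reference cell's own soma always counts), then builds a resampling null by
transposing the identical polygon — same coordinates — onto the soma arrays
of every *other* field in the dataset ("unmatched" images). Because a real
image always contains at least the reference soma, unmatched images enclosing
zero somata are excluded before averaging; the enclosed cell index (ECI) is

    ECI = mean(unmatched counts > 0) − real count,

zero when real and unmatched images enclose equally, positive when chance
placement encloses more. The per-dataset median ECI is compared to zero with
a one-sample Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats

from .errors import InputError, InsufficientDataError
from .geometry import SimplePolygon, SomaField, SomaPoint, disk_fully_inside

__all__ = [
    "ArborTerritory",
    "EnclosureRecord",
    "DistributionReport",
    "LeveneResult",
    "count_enclosed",
    "build_unmatched",
    "enclosed_cell_index",
    "eci_median_test",
    "enclosure_distributions",
    "size_filter",
    "variance_equality_test",
]


@dataclass(frozen=True)
class ArborTerritory:
    """A dendritic territory polygon tied to one reference soma."""

    reference_id: str
    polygon: SimplePolygon
    source_field_id: str | None = None

    @property
    def area_um2(self) -> float:
        return self.polygon.area_um2


@dataclass
class EnclosureRecord:
    """One arbor's real enclosed count, its unmatched-null counts, and its ECI."""

    arbor: ArborTerritory
    real_count: int
    unmatched_counts: list
    unmatched_mean_zero_excluded: float = math.nan
    eci: float = math.nan

    @property
    def eci_defined(self) -> bool:
        return not math.isnan(self.eci)

    @property
    def unmatched_mean_full(self) -> float:
        """Mean over the full unmatched family, zeros retained (box-plot dataset)."""
        if not self.unmatched_counts:
            return math.nan
        return float(np.mean(self.unmatched_counts))


def count_enclosed(
    arbor: ArborTerritory,
    field: SomaField,
    population_filter: str | None = None,
    nucleus_diameter_um: float | None = None,
) -> int:
    """Number of somata whose disks are fully contained in the arbor polygon.

    ``population_filter`` restricts counting to somata carrying that label.
    ``nucleus_diameter_um`` overrides the per-soma diameter for the containment
    disk (the marker's nuclear extent need not equal the soma hard core).
    A polygon extending outside the window is flagged with a warning and
    counting proceeds on the in-window somata.
    """
    poly = arbor.polygon.shapely
    minx, miny, maxx, maxy = poly.bounds
    if (
        minx < -1e-9
        or miny < -1e-9
        or maxx > field.window.width_um + 1e-9
        or maxy > field.window.height_um + 1e-9
    ):
        warnings.warn(
            f"arbor {arbor.reference_id!r} extends outside the window; "
            "counting in-window somata only",
            stacklevel=2,
        )
    somata = field.points
    if population_filter is not None:
        somata = [p for p in somata if population_filter in p.labels]
    if not somata:
        return 0
    xy = np.array([[p.x_um, p.y_um] for p in somata])
    radii = (
        np.array([p.radius_um for p in somata])
        if nucleus_diameter_um is None
        else np.full(len(somata), nucleus_diameter_um / 2.0)
    )
    # bounding-box prefilter before the exact disk-containment test
    near = (
        (xy[:, 0] >= minx - radii)
        & (xy[:, 0] <= maxx + radii)
        & (xy[:, 1] >= miny - radii)
        & (xy[:, 1] <= maxy + radii)
    )
    count = 0
    for idx in np.nonzero(near)[0]:
        p = somata[idx]
        probe = (
            p
            if nucleus_diameter_um is None
            else SomaPoint(p.id, p.x_um, p.y_um, nucleus_diameter_um, p.labels)
        )
        if disk_fully_inside(probe, arbor.polygon):
            count += 1
    return count


def _fill_eci(record: EnclosureRecord) -> EnclosureRecord:
    nonzero = [c for c in record.unmatched_counts if c > 0]
    if nonzero:
        record.unmatched_mean_zero_excluded = float(np.mean(nonzero))
        record.eci = record.unmatched_mean_zero_excluded - record.real_count
    else:
        record.unmatched_mean_zero_excluded = math.nan
        record.eci = math.nan
    return record


def build_unmatched(
    arbors: list,
    fields: list,
    population_filter: str | None = None,
    nucleus_diameter_um: float | None = None,
) -> list:
    """Real counts plus unmatched-transposition counts for every arbor.

    Each arbor is scored on its own source field, then the identical polygon
    (same coordinates; windows must match) is scored on every other field,
    yielding a family of unmatched counts of size ``len(fields) − 1``.
    """
    if len(fields) < 2:
        raise InputError("need at least 2 fields to build unmatched controls")
    dims = {(f.window.width_um, f.window.height_um) for f in fields}
    if len(dims) != 1:
        raise InputError("all fields must share identical window dimensions")
    by_id = {f.field_id: f for f in fields}
    if len(by_id) != len(fields):
        raise InputError("fields must carry unique field_id values")

    records = []
    for arbor in arbors:
        if arbor.source_field_id not in by_id:
            raise InputError(
                f"arbor {arbor.reference_id!r}: unknown source field "
                f"{arbor.source_field_id!r}"
            )
        source = by_id[arbor.source_field_id]
        real = count_enclosed(arbor, source, population_filter, nucleus_diameter_um)
        unmatched = [
            count_enclosed(arbor, f, population_filter, nucleus_diameter_um)
            for f in fields
            if f.field_id != arbor.source_field_id
        ]
        records.append(_fill_eci(EnclosureRecord(arbor, real, unmatched)))
    return records


def enclosed_cell_index(record: EnclosureRecord) -> float:
    """ECI = mean of the arbor's nonzero unmatched counts minus its real count.

    NaN (undefined) when every unmatched image enclosed zero somata; such
    records are retained but excluded from the median test.
    """
    return _fill_eci(record).eci


def eci_median_test(records: list) -> tuple:
    """Two-sided one-sample Wilcoxon signed-rank of the ECIs against 0.

    Exact null distribution for n ≤ 25 (no ties/zeros), normal approximation
    with continuity correction otherwise; zero ECIs are dropped before
    ranking, and an all-zero sample reports p = 1 with the degenerate flag.

    Returns ``(median, p_value, degenerate)``.
    """
    values = np.array(
        [r.eci if isinstance(r, EnclosureRecord) else float(r) for r in records],
        dtype=float,
    )
    values = values[~np.isnan(values)]
    if len(values) < 6:
        raise InsufficientDataError("need at least 6 defined ECIs for the median test")
    median = float(np.median(values))
    nonzero = values[values != 0]
    if len(nonzero) == 0:
        return median, 1.0, True
    exact_ok = len(nonzero) <= 25 and len(np.unique(np.abs(nonzero))) == len(nonzero)
    if exact_ok:
        res = stats.wilcoxon(nonzero, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            nonzero, alternative="two-sided", method="approx", correction=True
        )
    return median, float(min(res.pvalue, 1.0)), False


@dataclass
class DistributionReport:
    """Real vs unmatched frequency-of-enclosing-n curves with their chi² test."""

    ns: np.ndarray
    real_freq: np.ndarray
    unmatched_mean_freq: np.ndarray
    unmatched_sem_freq: np.ndarray
    chi2_stat: float
    chi2_p: float
    chi2_df: int


def enclosure_distributions(records: list, max_n: int | None = None) -> DistributionReport:
    """Frequency curves of enclosing exactly n somata, real vs unmatched.

    The real curve is the fraction of arbors with real count n. The unmatched
    curve averages per-arbor frequency vectors computed over each arbor's
    nonzero unmatched counts (zero-count images excluded, as for the ECI).
    The chi-squared test compares observed real arbor counts per bin against
    expected counts = unmatched proportions × number of real arbors, pooling
    upper-tail bins until every expected count is ≥ 5.
    """
    if len(records) < 2:
        raise InsufficientDataError("need at least 2 records")
    real_counts = np.array([r.real_count for r in records])
    per_arbor = []
    for r in records:
        nonzero = np.array([c for c in r.unmatched_counts if c > 0])
        if len(nonzero):
            per_arbor.append(nonzero)
    if not per_arbor:
        raise InsufficientDataError("no nonzero unmatched counts in any record")
    if max_n is None:
        max_n = int(max(real_counts.max(), max(v.max() for v in per_arbor)))
    ns = np.arange(1, max_n + 1)

    real_freq = np.array([(real_counts == n).mean() for n in ns])
    freq_rows = np.array([[(v == n).mean() for n in ns] for v in per_arbor])
    unmatched_mean = freq_rows.mean(axis=0)
    unmatched_sem = (
        freq_rows.std(axis=0, ddof=1) / math.sqrt(len(freq_rows))
        if len(freq_rows) > 1
        else np.zeros_like(unmatched_mean)
    )

    observed = real_freq * len(records)
    expected = unmatched_mean * len(records)
    stat, p, df = _chi2_pooled(observed, expected)
    return DistributionReport(ns, real_freq, unmatched_mean, unmatched_sem, stat, p, df)


def _chi2_pooled(observed: np.ndarray, expected: np.ndarray) -> tuple:
    """Chi-squared with upper-tail pooling so every expected count is ≥ 5."""
    obs = list(observed.astype(float))
    exp = list(expected.astype(float))
    while len(exp) > 1 and exp[-1] < 5.0:
        tail_e, tail_o = exp.pop(), obs.pop()
        exp[-1] += tail_e
        obs[-1] += tail_o
    obs_a, exp_a = np.array(obs), np.array(exp)
    keep = ~((obs_a == 0) & (exp_a == 0))
    obs_a, exp_a = obs_a[keep], exp_a[keep]
    if len(obs_a) <= 1 or exp_a.sum() <= 0:
        return 0.0, 1.0, 0
    exp_a = exp_a * obs_a.sum() / exp_a.sum()  # match totals for the test
    if np.any(exp_a == 0):
        return math.inf, 0.0, len(obs_a) - 1
    stat, p = stats.chisquare(obs_a, f_exp=exp_a)
    if np.allclose(obs_a, exp_a):
        return 0.0, 1.0, len(obs_a) - 1
    return float(stat), float(p), len(obs_a) - 1


def size_filter(reference_arbors: list, comparison_arbors: list) -> tuple:
    """Keep only arbors within 1 SD of the reference-set mean area.

    Bounds [mean − SD, mean + SD] are computed from the reference (wild-type)
    areas and applied, boundary-inclusive, to both datasets. Returns
    ``(filtered_reference, filtered_comparison, (low, high))``.
    """
    if len(reference_arbors) < 3:
        raise InsufficientDataError("need at least 3 reference arbors for the size filter")
    areas = np.array([a.area_um2 for a in reference_arbors])
    low = float(areas.mean() - areas.std(ddof=1))
    high = float(areas.mean() + areas.std(ddof=1))
    ref_f = [a for a in reference_arbors if low <= a.area_um2 <= high]
    comp_f = [a for a in comparison_arbors if low <= a.area_um2 <= high]
    if not ref_f or (comparison_arbors and not comp_f):
        warnings.warn("size filter produced an empty dataset", stacklevel=2)
    return ref_f, comp_f, (low, high)


@dataclass(frozen=True)
class LeveneResult:
    f_ratio: float
    p_value: float
    degenerate: bool


def variance_equality_test(group_a_areas, group_b_areas) -> LeveneResult:
    """Levene's test of equal variances with mean centring."""
    a = np.asarray(group_a_areas, dtype=float)
    b = np.asarray(group_b_areas, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError("need at least 3 observations per group")
    if np.all(a == a[0]) and np.all(b == b[0]):
        return LeveneResult(math.nan, math.nan, True)
    stat, p = stats.levene(a, b, center="mean")
    return LeveneResult(float(stat), float(p), bool(math.isnan(stat)))
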