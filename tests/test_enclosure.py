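"""Enclosure counting, the unmatched-transposition null, the enclosed cell
index and its Wilcoxon test, frequency distributions, the 1-SD size filter
and Levene's variance test."""

import itertools
import math
import warnings

import numpy as np
import pytest
from scipy import stats

from retmosaic import (
    ArborParams,
    ArborTerritory,
    EnclosureRecord,
    InputError,
    InsufficientDataError,
    SimConfig,
    SimplePolygon,
    SomaField,
    SomaPoint,
    Window,
    build_unmatched,
    count_enclosed,
    disk_fully_inside,
    eci_median_test,
    enclosed_cell_index,
    enclosure_distributions,
    generate_arbors,
    simulate_hardcore,
    size_filter,
    variance_equality_test,
)

W = 353.55


def _square_arbor(cx, cy, half, reference_id="ref", source=None):
    poly = SimplePolygon(
        ((cx - half, cy - half), (cx + half, cy - half),
         (cx + half, cy + half), (cx - half, cy + half))
    )
    return ArborTerritory(reference_id, poly, source)


class TestCountEnclosed:
    def test_isolated_reference_counts_one(self, window):
        field = SomaField(window, [SomaPoint("ref", 100.0, 100.0)])
        assert count_enclosed(_square_arbor(100, 100, 30), field) == 1

    def test_straddling_soma_excluded_by_full_containment(self, window):
        pts = [
            SomaPoint("ref", 100.0, 100.0),
            SomaPoint("in1", 110.0, 110.0),
            SomaPoint("in2", 90.0, 92.0),
            SomaPoint("straddle", 128.0, 100.0),  # disk crosses the boundary
        ]
        field = SomaField(window, pts)
        assert count_enclosed(_square_arbor(100, 100, 30), field) == 3

    def test_population_filter_restricts_counting(self, window):
        pts = [
            SomaPoint("a", 100.0, 100.0, labels={"ON"}),
            SomaPoint("b", 110.0, 100.0, labels={"OFF"}),
        ]
        field = SomaField(window, pts)
        arbor = _square_arbor(105, 100, 40)
        assert count_enclosed(arbor, field, population_filter="ON") == 1
        assert count_enclosed(arbor, field) == 2

    def test_matches_per_soma_brute_force_oracle(self, window):
        """100 random arbor/field pairs: prefiltered counting equals a plain
        loop of disk_fully_inside over every soma."""
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(20, 60))
            pts = [
                SomaPoint(f"p{i}", *rng.uniform(0, W, 2), rng.uniform(4, 14))
                for i in range(n)
            ]
            field = SomaField(window, pts)
            cx, cy = rng.uniform(60, W - 60, 2)
            ang = np.sort(rng.uniform(0, 2 * math.pi, 7))
            rad = rng.uniform(20, 55, 7)
            try:
                poly = SimplePolygon(
                    tuple(zip(cx + rad * np.cos(ang), cy + rad * np.sin(ang)))
                )
            except InputError:
                continue
            arbor = ArborTerritory("a", poly)
            oracle = sum(disk_fully_inside(p, poly) for p in pts)
            assert count_enclosed(arbor, field) == oracle


class TestBuildUnmatched:
    def _fields_and_arbors(self, n_fields=4, seed0=400):
        fields, arbors = [], []
        for i in range(n_fields):
            f = simulate_hardcore(SimConfig(seed=seed0 + i), field_id=f"f{i}")
            fields.append(f)
            p = next(
                q for q in f.points if 60 < q.x_um < W - 60 and 60 < q.y_um < W - 60
            )
            arbors.append(_square_arbor(p.x_um, p.y_um, 25, p.id, f"f{i}"))
        return fields, arbors

    def test_identity_transposition_reproduces_real_count(self, window):
        field = simulate_hardcore(SimConfig(seed=7), field_id="src")
        twin = SomaField(window, field.points, field_id="copy")
        p = next(q for q in field.points if 60 < q.x_um < W - 60 and 60 < q.y_um < W - 60)
        arbor = _square_arbor(p.x_um, p.y_um, 30, p.id, "src")
        records = build_unmatched([arbor], [field, twin])
        assert records[0].unmatched_counts == [records[0].real_count]
        assert records[0].eci == 0.0

    def test_family_size_is_fields_minus_one(self):
        fields, arbors = self._fields_and_arbors(5)
        for rec in build_unmatched(arbors, fields):
            assert len(rec.unmatched_counts) == 4

    def test_mismatched_windows_rejected(self):
        fields, arbors = self._fields_and_arbors(2)
        odd = SomaField(Window(100, 100), [SomaPoint("x", 5, 5)], field_id="odd")
        with pytest.raises(InputError):
            build_unmatched(arbors, fields + [odd])

    def test_mean_unmatched_count_matches_eroded_area_oracle(self, window):
        """On CSR fields the expected transposed count is D × (polygon eroded
        by the soma radius): within 3 SE over 20 fields."""
        rho = 5.0
        arbor = _square_arbor(170.0, 170.0, 40.0, "a", "src")
        eroded = arbor.polygon.shapely.buffer(-rho).area
        rng = np.random.default_rng(31)
        n = 175
        counts = []
        for i in range(20):
            xy = rng.uniform(0, W, (n, 2))
            f = SomaField(
                window,
                [SomaPoint(f"p{j}", x, y, 2 * rho) for j, (x, y) in enumerate(xy)],
                field_id=f"t{i}",
            )
            counts.append(count_enclosed(arbor, f))
        D = n / window.area_um2
        expected = D * eroded
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) <= 3 * se


class TestEnclosedCellIndex:
    def test_printed_formula_arithmetic(self):
        rec = EnclosureRecord(_square_arbor(50, 50, 20), 1, [2, 2, 3, 2, 3])
        assert enclosed_cell_index(rec) == pytest.approx(2.4 - 1)

    def test_zero_exclusion_rule(self):
        rec = EnclosureRecord(_square_arbor(50, 50, 20), 2, [0, 2, 2])
        assert enclosed_cell_index(rec) == 0.0
        assert rec.unmatched_mean_zero_excluded == 2.0
        assert rec.unmatched_mean_full == pytest.approx(4 / 3)

    def test_zero_exclusion_never_decreases_the_unmatched_mean(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            counts = rng.poisson(1.0, 10).tolist()
            rec = EnclosureRecord(_square_arbor(50, 50, 20), 1, counts)
            enclosed_cell_index(rec)
            if not math.isnan(rec.unmatched_mean_zero_excluded):
                assert rec.unmatched_mean_zero_excluded >= rec.unmatched_mean_full

    def test_all_zero_family_is_undefined(self):
        rec = EnclosureRecord(_square_arbor(50, 50, 20), 1, [0, 0, 0])
        assert math.isnan(enclosed_cell_index(rec))
        assert not rec.eci_defined


def _exact_wilcoxon_enumeration(values):
    """Two-sided one-sample Wilcoxon p by enumerating all 2^n sign flips."""
    v = np.array([x for x in values if x != 0], dtype=float)
    ranks = stats.rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    mu = ranks.sum() / 2
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(v)):
        w = ranks[np.array(signs, dtype=bool)].sum()
        total += 1
        count += abs(w - mu) >= abs(w_obs - mu) - 1e-12
    return count / total


class TestEciMedianTest:
    def test_symmetric_values_give_p_one(self):
        med, p, degen = eci_median_test([1, -1, 2, -2, 3, -3])
        assert med == 0.0
        assert p == pytest.approx(1.0)
        assert not degen

    def test_all_zero_values_degenerate(self):
        med, p, degen = eci_median_test([0.0] * 8)
        assert (med, p, degen) == (0.0, 1.0, True)

    def test_all_positive_n8_exact_tail(self):
        values = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
        _, p, _ = eci_median_test(values)
        assert p == pytest.approx(2 * (1 / 2**8))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_full_enumeration_at_small_n(self, seed):
        rng = np.random.default_rng(seed)
        values = np.round(rng.normal(0.2, 1.0, 9), 3)
        values = values[values != 0]
        _, p, _ = eci_median_test(list(values) + [0.0] * 2)  # zeros dropped
        assert p == pytest.approx(_exact_wilcoxon_enumeration(values), rel=1e-9)

    def test_too_few_defined_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            eci_median_test([1.0, 2.0, 3.0])


class TestEnclosureDistributions:
    def _rec(self, real, unmatched):
        return EnclosureRecord(_square_arbor(50, 50, 20), real, list(unmatched))

    def test_identical_curves_give_chi2_zero(self):
        recs = [self._rec(1, [1, 1, 1]) for _ in range(10)]
        rep = enclosure_distributions(recs)
        assert rep.chi2_stat == 0.0 and rep.chi2_p == 1.0

    def test_curves_are_normalised(self):
        rng = np.random.default_rng(2)
        recs = [
            self._rec(int(rng.integers(1, 4)), rng.poisson(1.2, 8).tolist())
            for _ in range(25)
        ]
        rep = enclosure_distributions(recs)
        assert rep.real_freq.sum() == pytest.approx(1.0)
        assert rep.unmatched_mean_freq.sum() == pytest.approx(1.0)

    def test_power_against_shifted_unmatched(self):
        """Real counts of 1 vs unmatched counts in {2, 3}: detected at
        p < 0.01 with 30 arbors."""
        rng = np.random.default_rng(3)
        recs = [
            self._rec(1, rng.choice([2, 3], 10).tolist()) for _ in range(30)
        ]
        rep = enclosure_distributions(recs)
        assert rep.chi2_p < 0.01


class TestSizeFilter:
    def _arbors_with_areas(self, areas, source="src"):
        out = []
        for i, area in enumerate(areas):
            half = math.sqrt(area) / 2
            out.append(_square_arbor(100, 100, half, f"a{i}", source))
        return out

    def test_inclusive_bounds(self):
        # stub arbors with exactly representable areas: mean 100, SD 20
        class _Stub:
            def __init__(self, area):
                self.area_um2 = area

        ref = [_Stub(80.0), _Stub(100.0), _Stub(120.0)]
        comp = [_Stub(80.0), _Stub(120.0), _Stub(79.9), _Stub(120.1)]
        ref_f, comp_f, (lo, hi) = size_filter(ref, comp)
        assert (lo, hi) == (80.0, 120.0)
        assert len(ref_f) == 3  # boundary members retained (inclusive)
        assert [a.area_um2 for a in comp_f] == [80.0, 120.0]

    def test_definition_on_reference_set(self):
        rng = np.random.default_rng(4)
        ref = self._arbors_with_areas(rng.normal(900, 150, 40))
        areas = np.array([a.area_um2 for a in ref])
        lo, hi = areas.mean() - areas.std(ddof=1), areas.mean() + areas.std(ddof=1)
        ref_f, _, _ = size_filter(ref, [])
        assert {a.reference_id for a in ref_f} == {
            a.reference_id for a in ref if lo <= a.area_um2 <= hi
        }

    def test_filtering_shrinks_between_group_size_gap(self):
        """Smaller mutant-like arbors: the 1-SD filter reduces the mean-area
        difference between groups."""
        rng = np.random.default_rng(6)
        wt = self._arbors_with_areas(rng.normal(1000, 200, 60))
        mut = self._arbors_with_areas(rng.normal(700, 200, 60), "mut")
        wt_f, mut_f, _ = size_filter(wt, mut)
        gap_before = np.mean([a.area_um2 for a in wt]) - np.mean(
            [a.area_um2 for a in mut]
        )
        gap_after = np.mean([a.area_um2 for a in wt_f]) - np.mean(
            [a.area_um2 for a in mut_f]
        )
        assert 0 < gap_after < gap_before


class TestVarianceEqualityTest:
    def test_identical_groups_degenerate(self):
        res = variance_equality_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert res.degenerate

    def test_type_one_error_calibrated(self):
        """Equal-variance normal samples, n = 30/group, 1,000 simulations:
        rejection rate at α = 0.05 within [0.03, 0.07]."""
        rng = np.random.default_rng(8)
        rejections = 0
        for _ in range(1000):
            a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
            rejections += variance_equality_test(a, b).p_value < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_power_against_tripled_spread(self):
        rng = np.random.default_rng(9)
        rejections = 0
        for _ in range(200):
            a, b = rng.normal(0, 1, 30), rng.normal(0, 3, 30)
            rejections += variance_equality_test(a, b).p_value < 0.05
        assert rejections / 200 > 0.9


class TestEciNullBehaviour:
    def test_independent_arbors_have_centred_eci(self):
        """Independent arbors on hard-core fields, sized so the
        zero-exclusion inflation balances the reference-soma conditioning:
        median ECI is 0 in most replicates and the grand mean is within 3 SE
        of 0."""
        params = ArborParams(
            arbor_mode="independent", radius_mean_um=15.0, radius_sd_um=3.0
        )
        medians, all_eci = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(6):
                fields, arbors = [], []
                for i in range(12):
                    f = simulate_hardcore(
                        SimConfig(seed=5000 + 100 * rep + i), field_id=f"f{i}"
                    )
                    fields.append(f)
                    ids = [
                        p.id
                        for p in f.points
                        if 30 < p.x_um < W - 30 and 30 < p.y_um < W - 30
                    ][:9]
                    arbors += generate_arbors(
                        f, params, seed=6000 + 100 * rep + i, reference_ids=ids
                    )
                records = build_unmatched(arbors, fields)
                med, _, _ = eci_median_test(records)
                medians.append(med)
                all_eci += [r.eci for r in records if r.eci_defined]
        assert np.median(medians) == pytest.approx(0.0, abs=0.1)
        se = np.std(all_eci, ddof=1) / math.sqrt(len(all_eci))
        assert abs(np.mean(all_eci)) <= 3 * se
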