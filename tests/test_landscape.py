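"""Property-space analytics: histograms, KDEs, shifts, topography, hulls, regions."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aromap import (
    MoleculeEntry,
    PropertyRecord,
    SynthConfig,
    TopographyConfig,
    convex_hull2d,
    histogram2d,
    kde1d,
    parse_constraints,
    region_count,
    ring_count_distributions,
    simulate_properties,
    substituent_shifts,
    topography,
)
from aromap.enumeration import Library
from aromap.landscape import Hull2D

record_strategy = st.builds(
    PropertyRecord,
    st.uuids().map(str),
    st.floats(-12, -2),
    st.floats(-6, 1),
    st.floats(0.1, 8),
)


def make_records(points, axes=("minus_ip", "minus_ea")):
    out = []
    for k, (x, y) in enumerate(points):
        values = {"minus_ip": -7.0, "minus_ea": -2.0, "optical_gap": 4.0}
        values[axes[0]] = x
        values[axes[1]] = y
        out.append(PropertyRecord(f"r{k}", **values))
    return out


class TestHistogram2D:
    def test_single_record_single_cell(self):
        counts, _, _ = histogram2d(make_records([(-7.0, -2.0)]), bins=5)
        assert counts.sum() == 1
        assert (counts == 1).sum() == 1

    @given(st.lists(record_strategy, min_size=1, max_size=100), st.integers(2, 20))
    @settings(max_examples=30, derandomize=True)
    def test_counts_conserved_for_any_binning(self, records, bins):
        counts, _, _ = histogram2d(records, bins=bins)
        assert counts.sum() == len(records)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform([-12, -6], [-2, 1], size=(100, 2))
        records = make_records(pts)
        counts, xe, ye = histogram2d(records, bins=7)
        naive = np.zeros_like(counts)
        for x, y in pts:
            i = min(np.searchsorted(xe, x, side="right") - 1, len(xe) - 2)
            j = min(np.searchsorted(ye, y, side="right") - 1, len(ye) - 2)
            naive[i, j] += 1
        assert np.array_equal(counts, naive)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            histogram2d([])


class TestKDE:
    def test_standard_normal_density_at_zero(self):
        """At the origin the KDE estimates the N(0, 1+h^2) density, i.e.
        1/sqrt(2*pi) up to known kernel smoothing; check within ~3 SE."""
        rng = np.random.default_rng(0)
        h = 0.1
        x = rng.standard_normal(10000)
        grid, density = kde1d(x, bandwidth=h)
        d0 = np.interp(0.0, grid, density)
        expected = 1 / np.sqrt(2 * np.pi * (1 + h**2))
        se = np.sqrt(expected * 0.2821 / (10000 * h))  # R(K)=1/(2*sqrt(pi))
        assert abs(d0 - expected) < 3 * se

    @pytest.mark.parametrize("seed", range(5))
    def test_integral_is_one(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.2, 3), size=200)
        grid, density = kde1d(x)
        assert density.min() >= 0
        assert np.trapezoid(density, grid) == pytest.approx(1.0, abs=1e-3)

    def test_identical_values_fixed_bandwidth_peak_at_value(self):
        grid, density = kde1d([2.5, 2.5], bandwidth=0.3)
        assert grid[np.argmax(density)] == pytest.approx(2.5, abs=0.02)
        assert np.trapezoid(density, grid) == pytest.approx(1.0, abs=1e-3)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            kde1d([1.0])


class TestSubstituentShifts:
    def _library_and_records(self):
        entries, records = [], []
        for s, base in (("A", -8.0), ("B", -6.0)):
            entries.append(MoleculeEntry(f"{s}0", f"p{s}", s))
            records.append(PropertyRecord(f"{s}0", base, -2.0, 4.0))
            entries.append(MoleculeEntry(f"{s}1", f"m{s}", s, substituents=("NO2",)))
            records.append(PropertyRecord(f"{s}1", base - 0.5, -2.8, 4.1))
        return Library(entries=entries), records

    def test_unsubstituted_entries_shift_zero(self):
        lib, recs = self._library_and_records()
        df = substituent_shifts(lib, recs)
        parents = df[df.n_substituents == 0]
        assert (parents.d_minus_ip == 0).all()
        assert (parents.d_minus_ea == 0).all()

    def test_shift_is_difference_to_parent(self):
        lib, recs = self._library_and_records()
        df = substituent_shifts(lib, recs).set_index("id")
        assert df.loc["A1", "d_minus_ip"] == pytest.approx(-0.5)
        assert df.loc["A1", "d_minus_ea"] == pytest.approx(-0.8)

    def test_missing_parent_record_skips_and_reports(self):
        lib, recs = self._library_and_records()
        recs = [r for r in recs if r.molecule_id != "B0"]
        df = substituent_shifts(lib, recs)
        # B0 lacks its own record, B1 its parent's — both are reported
        assert set(df.attrs["skipped"]) == {"B0", "B1"}
        assert set(df.id) == {"A0", "A1"}

    def test_synthetic_attenuation_shows_sublinear_growth(self):
        """With attenuation < 1, two-substituent shifts are larger than one-
        substituent shifts but by less than a factor of two (generator echo)."""
        from test_synth_data import CLASSES, synthetic_library

        lib = synthetic_library(n_skeletons=40, subs_per_entry=(1, 2), per_skeleton=10, homo=True)
        cheap, _ = simulate_properties(lib, SynthConfig(seed=21), CLASSES)
        df = substituent_shifts(lib, cheap, CLASSES)
        one = df[df.n_substituents == 1]
        two = df[df.n_substituents == 2]
        m1 = np.abs(np.concatenate([one.d_minus_ip, one.d_minus_ea])).mean()
        m2 = np.abs(np.concatenate([two.d_minus_ip, two.d_minus_ea])).mean()
        assert m1 < m2 < 2 * m1

    def test_synthetic_donor_acceptor_signs(self):
        from test_synth_data import CLASSES, synthetic_library

        lib = synthetic_library(n_skeletons=40, subs_per_entry=(1,), per_skeleton=9)
        cheap, _ = simulate_properties(lib, SynthConfig(seed=22), CLASSES)
        df = substituent_shifts(lib, cheap, CLASSES)
        acc = df[df.classes == "strong_acceptor"]
        don = df[df.classes == "strong_donor"]
        assert acc.d_minus_ea.mean() < 0 < don.d_minus_ea.mean()


class TestTopography:
    def test_single_skeleton_wins_every_cell(self):
        entries = [MoleculeEntry(f"m{i}", f"s{i}", "A") for i in range(4)]
        recs = make_records([(-7.2, -2.2), (-7.3, -2.1), (-6.1, -1.2), (-6.2, -1.1)])
        recs = [PropertyRecord(e.id, r.minus_ip, r.minus_ea, r.optical_gap) for e, r in zip(entries, recs)]
        topo = topography(recs, Library(entries=entries))
        for sid, prev, occ in topo.cells.values():
            assert sid == "A"
            assert prev == pytest.approx(occ / 4)

    def test_concentrated_small_family_beats_large_family(self):
        """A: 10/10 molecules in the cell (prevalence 1.0) beats
        B: 20/100 in the cell (prevalence 0.2)."""
        entries, recs = [], []
        for i in range(10):
            entries.append(MoleculeEntry(f"a{i}", f"a{i}", "A"))
            recs.append(PropertyRecord(f"a{i}", -7.2, -2.2, 4.0))
        for i in range(100):
            entries.append(MoleculeEntry(f"b{i}", f"b{i}", "B"))
            in_cell = i < 20
            recs.append(PropertyRecord(f"b{i}", -7.1 if in_cell else -3.2, -2.3 if in_cell else -0.2, 4.0))
        topo = topography(recs, Library(entries=entries))
        cell = topo.config.cell_of(-7.2, -2.2)
        sid, prev, occ = topo.cells[cell]
        assert sid == "A"
        assert prev == pytest.approx(1.0)
        assert occ == 30

    def test_origin_shift_by_full_increment_preserves_membership(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform([-12, -6], [-2, 1], size=(50, 2))
        entries = [MoleculeEntry(f"m{i}", f"s{i}", f"sk{i % 5}") for i in range(50)]
        recs = [PropertyRecord(f"m{i}", x, y, 4.0) for i, (x, y) in enumerate(pts)]
        lib = Library(entries=entries)
        base = topography(recs, lib, TopographyConfig(0.5, 0.5, origin=(0.0, 0.0)))
        shifted = topography(recs, lib, TopographyConfig(0.5, 0.5, origin=(-0.5, -1.0)))
        # lowering the origin by (1, 2) increments raises every index by (1, 2)
        remapped = {(i - 1, j - 2): v for (i, j), v in shifted.cells.items()}
        assert remapped == base.cells

    def test_record_order_invariance_and_bounded_prevalence(self, small_library, small_records):
        topo_a = topography(small_records, small_library)
        topo_b = topography(list(reversed(small_records)), small_library)
        assert topo_a.cells == topo_b.cells
        assert all(0 < prev <= 1 for _, prev, _ in topo_a.cells.values())

    def test_bad_increments_rejected(self):
        with pytest.raises(ValueError):
            TopographyConfig(ip_increment=0.0)


def hull_area_oracle(points: np.ndarray) -> float:
    """O(n^3)+ convex-hull area: a point is a vertex iff no triangle of
    other points strictly contains it; order vertices by angle, shoelace."""

    def in_triangle(p, a, b, c):
        d = np.array([a, b, c])
        signs = []
        for i in range(3):
            u, v = d[i], d[(i + 1) % 3]
            signs.append((v[0] - u[0]) * (p[1] - u[1]) - (v[1] - u[1]) * (p[0] - u[0]))
        signs = np.array(signs)
        return np.all(signs > 1e-12) or np.all(signs < -1e-12)

    vertices = []
    for i, p in enumerate(points):
        others = [q for j, q in enumerate(points) if j != i]
        inside = any(
            in_triangle(p, a, b, c) for a, b, c in combinations(others, 3)
        )
        if not inside:
            vertices.append(p)
    vertices = np.unique(np.array(vertices), axis=0)
    centroid = vertices.mean(axis=0)
    angles = np.arctan2(vertices[:, 1] - centroid[1], vertices[:, 0] - centroid[0])
    v = vertices[np.argsort(angles)]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestConvexHull:
    def test_triangle_is_its_own_hull(self):
        recs = make_records([(0.0, 0.1), (1.0, 0.1), (0.5, 1.1)])
        hull = convex_hull2d(recs)
        assert not hull.degenerate
        assert len(hull.vertices) == 3
        assert hull.area == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_area_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, size=(20, 2))
        hull = convex_hull2d(make_records(pts))
        assert hull.area == pytest.approx(hull_area_oracle(pts), rel=1e-9)

    def test_subset_hull_nested_in_superset_hull(self):
        rng = np.random.default_rng(17)
        pts = rng.uniform([-12, -6], [-2, 1], size=(60, 2))
        all_recs = make_records(pts)
        subset = all_recs[:20]
        big = convex_hull2d(all_recs, subset_label="all")
        small = convex_hull2d(subset, subset_label="subset")
        assert big.contains(small.vertices).all()
        assert big.contains(pts).all()

    def test_degenerate_hulls_flagged(self):
        one = convex_hull2d(make_records([(0.0, 0.0)]))
        assert one.degenerate
        collinear = convex_hull2d(make_records([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)]))
        assert collinear.degenerate
        assert collinear.contains([(1.0, 1.0)])[0]
        assert not collinear.contains([(1.0, 0.0)])[0]

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            convex_hull2d([], subset_label="nothing")


class TestRingCountGroups:
    def test_group_sizes_conserve_library(self, small_library, small_records):
        df = ring_count_distributions(small_library, small_records)
        assert len(df) == len(small_records)
        assert df.groupby("n_aromatic_rings").size().sum() == len(small_records)

    def test_azulene_derivatives_group_at_zero_rings(self, small_library, small_records):
        df = ring_count_distributions(small_library, small_records)
        by_id = small_library.by_id()
        az = df[df.id.map(lambda i: by_id[i].skeleton_id) == "azulene"]
        assert len(az) > 0
        assert (az.n_aromatic_rings == 0).all()


class TestRegionCount:
    def test_empty_constraints_count_everything(self):
        recs = make_records([(-7.0, -2.0), (-6.0, -1.0)])
        assert region_count(recs, []) == 2

    def test_constraint_string_parsing(self):
        parsed = parse_constraints("minus_ip>-6, minus_ea<-4")
        assert parsed == [("minus_ip", ">", -6.0), ("minus_ea", "<", -4.0)]
        with pytest.raises(ValueError):
            parse_constraints("minus_ip >= -6")

    def test_strict_inequalities(self):
        recs = make_records([(-6.0, -4.0)])  # exactly on both bounds
        assert region_count(recs, "minus_ip>-6, minus_ea<-4") == 0

    @given(st.lists(record_strategy, min_size=0, max_size=200))
    @settings(max_examples=30, derandomize=True)
    def test_matches_naive_filter_oracle(self, records):
        constraints = [("minus_ip", ">", -6.0), ("minus_ea", "<", -2.0)]
        naive = sum(1 for r in records if r.minus_ip > -6.0 and r.minus_ea < -2.0)
        assert region_count(records, constraints) == naive

    def test_unknown_property_rejected(self):
        with pytest.raises(KeyError):
            region_count([], [("homo", ">", 0.0)])
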