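"""Layer assignment, sulcal/gyral partition, vessel association, heatmaps."""

import math

import numpy as np
import pytest
from scipy import stats
from shapely.geometry import Point, Polygon

from stereopath.annotations import (
    LayerRegion,
    MarkerPoint,
    SulcusAnnotation,
    Vessel,
)
from stereopath.spatial import (
    UNASSIGNED,
    assign_markers_to_layers,
    density_heatmap,
    partition_sulcal_gyral,
    regional_density,
    vessel_association,
)
from stereopath.stereology import SamplingDesign

from conftest import pip_even_odd, rect


def mk(x, y, sid="s1", st="neuropil_thread"):
    return MarkerPoint(float(x), float(y), sid, st)


class TestLayerAssignment:
    def test_marker_at_polygon_centroid_gets_that_layer(self, tiny_set):
        layer2 = next(lr for lr in tiny_set.layer_regions
                      if lr.layer == "II" and lr.section_id == "sec1")
        c = layer2.polygon.centroid
        labels = assign_markers_to_layers(
            [mk(c.x, c.y, "sec1")], tiny_set.layer_regions)
        assert labels[0].label == "II"

    def test_marker_outside_cortex_unassigned(self, tiny_set):
        labels = assign_markers_to_layers(
            [mk(-500, 500, "sec1")], tiny_set.layer_regions)
        assert labels[0].label == UNASSIGNED

    def test_assignment_restricted_to_own_section(self, tiny_set):
        # only sec1 polygons exist for this marker's section
        regions = [lr for lr in tiny_set.layer_regions
                   if lr.section_id == "sec1"]
        labels = assign_markers_to_layers([mk(100, -100, "sec2")], regions)
        assert labels[0].label == UNASSIGNED

    def test_matches_brute_force_point_in_polygon_oracle(self):
        """10⁴ random points against an even–odd crossing-number oracle."""
        rng = np.random.default_rng(42)
        # irregular non-convex, non-overlapping layer polygons
        polys = {
            "I": Polygon([(0, 0), (4000, 0), (4000, -300), (2000, -150),
                          (0, -300)]),
            "II": Polygon([(0, -300), (2000, -150), (4000, -300),
                           (4000, -700), (0, -700)]),
            "III": Polygon([(0, -700), (4000, -700), (3500, -1200),
                            (500, -1200)]),
        }
        regions = [LayerRegion("s1", name, p) for name, p in polys.items()]
        xs = rng.uniform(-100, 4100, 10_000)
        ys = rng.uniform(-1300, 100, 10_000)
        markers = [mk(x, y) for x, y in zip(xs, ys)]
        labels = assign_markers_to_layers(markers, regions)
        expected = np.full(len(markers), UNASSIGNED, dtype=object)
        for name in ("I", "II", "III"):  # superficial-first tie-break
            inside = pip_even_odd(polys[name], xs, ys)
            unset = expected == UNASSIGNED
            expected[inside & unset] = name
        got = np.array([l.label for l in labels], dtype=object)
        assert (got == expected).all()


class TestSulcalPartition:
    def _slot(self, depth=300.0):
        """Straight slot sulcus: fundus at origin, mouths ±depth in x."""
        ribbon = rect(-2000, -400, 2000, 400)
        sulcus = SulcusAnnotation("s1", (0.0, 0.0), (-depth, 0.0),
                                  (depth, 0.0))
        return ribbon, sulcus

    def test_third_rule_marks_near_fundus_markers_sulcal(self):
        ribbon, sulcus = self._slot(300.0)
        labels, _ = partition_sulcal_gyral(
            [mk(50, 0), mk(150, 0)], ribbon, sulcus)
        assert labels[0].label == "sulcal"     # 50 <= 300/3
        assert labels[1].label == "gyral"      # 150 > 100
        assert labels[0].distance_to_fundus == pytest.approx(50.0)

    def test_depth_fraction_one_extends_to_full_depth(self):
        ribbon, sulcus = self._slot(300.0)
        labels, _ = partition_sulcal_gyral(
            [mk(299, 0), mk(301, 0)], ribbon, sulcus, depth_fraction=1.0)
        assert labels[0].label == "sulcal"
        assert labels[1].label == "gyral"

    def test_out_of_ribbon_marker_unassigned(self):
        ribbon, sulcus = self._slot()
        labels, _ = partition_sulcal_gyral([mk(0, 900)], ribbon, sulcus)
        assert labels[0].label == UNASSIGNED

    def test_degenerate_sulcus_rejected(self):
        ribbon = rect(-100, -100, 100, 100)
        sulcus = SulcusAnnotation("s1", (0.0, 0.0), (0.0, 0.0), (0.0, 0.0))
        with pytest.raises(ValueError, match="degenerate|depth"):
            partition_sulcal_gyral([], ribbon, sulcus)

    def test_partition_is_complete_and_disjoint(self):
        ribbon, sulcus = self._slot()
        rng = np.random.default_rng(8)
        markers = [mk(x, y) for x, y in
                   rng.uniform([-2000, -400], [2000, 400], size=(500, 2))]
        labels, _ = partition_sulcal_gyral(markers, ribbon, sulcus)
        cls = [l.label for l in labels]
        assert all(c in ("sulcal", "gyral") for c in cls)  # all in ribbon
        assert cls.count("sulcal") + cls.count("gyral") == len(markers)

    def test_sulcal_area_matches_fine_grid_oracle(self):
        """Sinusoidal ribbon: sulcal area fraction vs numerical
        integration on a fine grid, within 1%."""
        xs = np.linspace(0, 4000, 400)
        top = 200 * np.sin(xs / 4000 * 2 * math.pi)
        band = Polygon(
            list(zip(xs, top)) + list(zip(xs[::-1], top[::-1] - 600.0)))
        fundus = (1000.0, 200.0)
        sulcus = SulcusAnnotation("s1", fundus, (400.0, 100.0),
                                  (1600.0, 100.0))
        _, areas = partition_sulcal_gyral([], band, sulcus)
        radius = sulcus.depth() / 3.0
        # oracle: dense grid point-count
        gx, gy = np.meshgrid(np.arange(0, 4000, 4.0),
                             np.arange(-800, 400, 4.0))
        gx, gy = gx.ravel(), gy.ravel()
        inside = pip_even_odd(band, gx, gy)
        near = np.hypot(gx - fundus[0], gy - fundus[1]) <= radius
        cell = 16.0
        oracle_sulcal = float(np.count_nonzero(inside & near)) * cell
        oracle_total = float(np.count_nonzero(inside)) * cell
        assert areas["sulcal"] == pytest.approx(oracle_sulcal, rel=0.01)
        assert areas["sulcal"] + areas["gyral"] == pytest.approx(
            oracle_total, rel=0.01)


class TestRegionalDensity:
    def test_hand_arithmetic_chain(self):
        """10 sulcal markers in 0.5 mm² × 10 sections at 500 µm period:
        estimate 136.36, volume 2.5 mm³, density 54.5 per mm³."""
        design = SamplingDesign()
        counts = {"sulcal": [1] * 10}
        areas = {"sulcal": [0.5e6] * 10}
        (rec,) = regional_density(counts, areas, design, "neuropil_thread")
        assert rec.density_value == pytest.approx(10 * 10 * 15 / 11 / 2.5,
                                                  rel=1e-9)
        assert rec.density_value == pytest.approx(54.545, abs=0.01)

    def test_zero_markers_zero_density(self):
        (rec,) = regional_density({"gyral": [0] * 10},
                                  {"gyral": [1e6] * 10},
                                  SamplingDesign(), "neuron")
        assert rec.density_value == 0.0

    def test_doubling_areas_halves_densities(self):
        design = SamplingDesign()
        counts = {"sulcal": [2] * 10, "gyral": [5] * 10}
        areas = {"sulcal": [0.4e6] * 10, "gyral": [2e6] * 10}
        base = regional_density(counts, areas, design)
        doubled = regional_density(
            counts, {k: [2 * a for a in v] for k, v in areas.items()},
            design)
        for b, d in zip(base, doubled):
            assert d.density_value == pytest.approx(b.density_value / 2)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            regional_density({"sulcal": [1]}, {"sulcal": [0.0]},
                             SamplingDesign())


class TestVesselAssociation:
    @staticmethod
    def build_set(n_vessels, n_associated, spacing=1000.0):
        """n eligible vessels in a row; the first n_associated get a
        marker 50 µm from their edge, the rest none within reach."""
        vessels = [Vessel(i * spacing, 0.0, "s1", 50.0)
                   for i in range(n_vessels)]
        markers = [mk(i * spacing + 25.0 + 50.0, 0.0)
                   for i in range(n_associated)]
        return markers, vessels

    @pytest.mark.parametrize("n,k,pct", [
        (202, 9, 4.5),
        (260, 60, 23.1),
        (94, 58, 61.7),
    ])
    def test_percentage_from_constructed_counts(self, n, k, pct):
        markers, vessels = self.build_set(n, k)
        s = vessel_association(markers, vessels)
        assert s.n_vessels == n
        assert s.n_associated == k
        assert round(s.pct_associated, 1) == pct
        assert s.mean_distance == pytest.approx(50.0)

    def test_small_vessel_excluded_by_diameter_rule(self):
        s = vessel_association([mk(0, 0)], [Vessel(0, 0, "s1", 25.0)])
        assert s.n_vessels == 0
        assert s.pct_associated is None

    def test_diameter_rule_is_strict_inequality(self):
        s = vessel_association([mk(0, 0)], [Vessel(0, 0, "s1", 30.0)])
        assert s.n_vessels == 0
        s = vessel_association([mk(0, 0)], [Vessel(0, 0, "s1", 30.001)])
        assert s.n_vessels == 1

    def test_marker_inside_lumen_floors_distance_at_zero(self):
        s = vessel_association([mk(5, 0)], [Vessel(0, 0, "s1", 60.0)])
        assert s.n_associated == 1
        assert s.mean_distance == 0.0

    def test_threshold_is_inclusive(self):
        # vessel edge at 25; marker exactly 100 from edge
        s = vessel_association([mk(125.0, 0)], [Vessel(0, 0, "s1", 50.0)])
        assert s.n_associated == 1

    def test_markers_matched_within_sections_only(self):
        s = vessel_association([mk(0, 0, sid="s2")],
                               [Vessel(0, 0, "s1", 60.0)])
        assert s.n_associated == 0

    def test_matches_all_pairs_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        vessels = [Vessel(x, y, f"s{s}", d) for x, y, s, d in zip(
            rng.uniform(0, 5000, 1000), rng.uniform(0, 5000, 1000),
            rng.integers(0, 3, 1000), rng.uniform(10, 80, 1000))]
        markers = [mk(x, y, sid=f"s{s}") for x, y, s in zip(
            rng.uniform(0, 5000, 800), rng.uniform(0, 5000, 800),
            rng.integers(0, 3, 800))]
        got = vessel_association(markers, vessels)
        # oracle: plain all-pairs scan
        elig = [v for v in vessels if v.diameter > 30.0]
        dists = []
        for v in elig:
            best = math.inf
            for m in markers:
                if m.section_id != v.section_id:
                    continue
                best = min(best, max(
                    0.0, math.hypot(m.x - v.x, m.y - v.y) - v.diameter / 2))
            dists.append(best)
        assoc = [d for d in dists if d <= 100.0]
        assert got.n_vessels == len(elig)
        assert got.n_associated == len(assoc)
        assert got.mean_distance == pytest.approx(np.mean(assoc), rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(17)
        vessels = [Vessel(x, y, "s1", d) for x, y, d in zip(
            rng.uniform(0, 2000, 50), rng.uniform(0, 2000, 50),
            rng.uniform(20, 90, 50))]
        markers = [mk(x, y) for x, y in
                   rng.uniform(0, 2000, size=(70, 2))]
        a = vessel_association(markers, vessels)
        b = vessel_association(markers[::-1], vessels[::-1])
        assert a == b


class TestHeatmap:
    def test_single_marker_fills_exactly_one_bin(self):
        grid = density_heatmap([mk(120, 80)], grid_cell=100.0)
        assert grid.counts.sum() == 1
        assert (grid.counts == 1).sum() == 1

    def test_counts_conserve_marker_number(self):
        rng = np.random.default_rng(12)
        markers = [mk(x, y) for x, y in
                   rng.uniform(0, 3000, size=(777, 2))]
        grid = density_heatmap(markers, grid_cell=250.0, bandwidth=250.0)
        assert grid.total == 777
        # smoothing lives in a separate matrix, counts untouched
        assert grid.smoothed is not None
        assert grid.counts.sum() == 777

    def test_structure_filter(self):
        markers = [mk(10, 10), mk(20, 20, st="neuron")]
        grid = density_heatmap(markers, 100.0, structure="neuron")
        assert grid.total == 1

    def test_nonpositive_cell_rejected(self):
        with pytest.raises(ValueError):
            density_heatmap([], grid_cell=0.0)

    def test_invariant_under_rigid_shift_of_markers_and_origin(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 2000, size=(300, 2))
        markers = [mk(x, y) for x, y in pts]
        shifted = [mk(x + 12345.0, y - 678.0) for x, y in pts]
        g1 = density_heatmap(markers, 250.0,
                             bounds=(0, 0, 2000, 2000))
        g2 = density_heatmap(shifted, 250.0,
                             bounds=(12345.0, -678.0, 14345.0, 1322.0))
        assert (g1.counts == g2.counts).all()

    def test_uniform_markers_pass_chi_square_uniformity(self):
        """Binned uniform points look uniform: chi-square not rejected
        at α = 0.001 in ≥ 95% of seeded runs."""
        passes = 0
        n_runs = 40
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            markers = [mk(x, y) for x, y in
                       rng.uniform(0, 2000, size=(2000, 2))]
            grid = density_heatmap(markers, 250.0,
                                   bounds=(0, 0, 2000, 2000))
            _, p = stats.chisquare(grid.counts.ravel())
            if p > 0.001:
                passes += 1
        assert passes >= 0.95 * n_runs
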