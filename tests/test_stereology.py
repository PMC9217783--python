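"""Fractionator, Gundersen CE, Cavalieri volumes, densities."""

import math

import numpy as np
import pytest

from stereopath.stereology import (
    DesignError,
    SamplingDesign,
    cavalieri_volume,
    fractionator_estimate,
    frame_grid_counts,
    gundersen_ce,
    layer_density,
    sample_slab_population,
    sampling_fractions,
)


class TestSamplingFractions:
    def test_serial_exhaustive_design(self):
        """50 µm sections every 500 µm, full grid, 11 µm dissector in a
        15 µm mounted section."""
        ssf, asf, tsf = sampling_fractions(SamplingDesign())
        assert ssf == pytest.approx(0.1)
        assert asf == pytest.approx(1.0)
        assert tsf == pytest.approx(11.0 / 15.0)

    def test_fully_exhaustive_design_gives_unit_fractions(self):
        d = SamplingDesign(cut_thickness=500.0, section_period=500.0,
                           mounted_thickness=500.0, dissector_height=500.0,
                           guard_top=0.0, guard_bottom=0.0)
        assert sampling_fractions(d) == pytest.approx((1.0, 1.0, 1.0))

    def test_grid_fraction_passes_through_as_asf(self):
        d = SamplingDesign(grid_fraction=0.25)
        assert sampling_fractions(d).asf == 0.25

    @pytest.mark.parametrize("bad", [
        dict(grid_fraction=0.0),
        dict(grid_fraction=1.5),
        dict(mounted_thickness=10.0),   # < dissector + guards
        dict(mounted_thickness=60.0),   # > cut thickness
        dict(section_period=40.0),      # < cut thickness
    ])
    def test_invalid_designs_rejected(self, bad):
        with pytest.raises(DesignError):
            SamplingDesign(**bad).validate()


class TestFractionator:
    def test_zero_counts_give_zero_estimate(self):
        est = fractionator_estimate([0] * 10, SamplingDesign())
        assert est.raw_count == 0
        assert est.estimate == 0.0
        assert est.ce is None

    def test_estimate_is_count_over_product_of_fractions(self):
        est = fractionator_estimate([5] * 10, SamplingDesign())
        assert est.raw_count == 50
        assert est.estimate == pytest.approx(50 * 10 * 15 / 11)
        assert est.estimate == pytest.approx(681.8181818, abs=1e-6)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fractionator_estimate([3, -1, 2], SamplingDesign())

    def test_adding_a_marker_never_decreases_the_estimate(self):
        design = SamplingDesign()
        rng = np.random.default_rng(5)
        counts = list(rng.integers(0, 20, size=10))
        base = fractionator_estimate(counts, design).estimate
        for i in range(len(counts)):
            bumped = list(counts)
            bumped[i] += 1
            assert fractionator_estimate(bumped, design).estimate > base

    def test_random_phase_sampling_is_unbiased(self):
        """Mean fractionator estimate over random phases recovers the
        true population size (checked against its own Monte-Carlo s.e.)."""
        design = SamplingDesign()
        rng = np.random.default_rng(99)
        n_true = 1000
        pts = rng.uniform([0, 0, 0], [3000, 3000, 5000], size=(n_true, 3))
        estimates = []
        for _ in range(150):
            counts = sample_slab_population(pts, design, rng)
            estimates.append(fractionator_estimate(counts, design).estimate)
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(mean - n_true) < 3 * se + 1e-9
        assert abs(mean - n_true) / n_true < 0.05

    def test_subsampled_grid_is_also_unbiased(self):
        design = SamplingDesign(grid_fraction=0.25, frame_w=300.0,
                                frame_h=300.0)
        rng = np.random.default_rng(7)
        n_true = 800
        pts = rng.uniform([0, 0, 0], [4000, 4000, 4000], size=(n_true, 3))
        estimates = []
        for _ in range(300):
            counts = sample_slab_population(pts, design, rng)
            estimates.append(fractionator_estimate(counts, design).estimate)
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(mean - n_true) < 3 * se


class TestGundersenCE:
    def test_uniform_series_reduces_to_poisson_noise_term(self):
        """A perfectly even series has no systematic variance left; the
        smoothness term clamps at zero and CE = sqrt(n)/n."""
        ce = gundersen_ce([5] * 10, m=1)
        assert ce == pytest.approx(math.sqrt(50) / 50, abs=1e-12)

    def test_long_unit_series(self):
        assert gundersen_ce([1] * 100, m=1) == pytest.approx(0.1, abs=1e-12)

    def test_all_zero_series_is_undefined_not_zero(self):
        assert gundersen_ce([0, 0, 0]) is None

    def test_fewer_than_three_sections_undefined(self):
        assert gundersen_ce([5, 5]) is None

    def test_m0_uses_smaller_denominator(self):
        counts = [2, 9, 4, 7, 1, 8, 3]
        q = np.array(counts, dtype=float)
        a = float(q @ q)
        b = float(q[:-1] @ q[1:])
        c = float(q[:-2] @ q[2:])
        noise = q.sum()
        for m, denom in ((0, 12.0), (1, 240.0)):
            var = max((3 * (a - noise) - 4 * b + c) / denom, 0.0)
            expected = math.sqrt(noise + var) / noise
            assert gundersen_ce(counts, m=m) == pytest.approx(expected,
                                                              abs=1e-12)

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_scaling_counts_changes_ce_exactly_as_formula(self, k):
        counts = [3, 1, 4, 1, 5, 9, 2, 6]
        scaled = [k * c for c in counts]
        q = np.array(scaled, dtype=float)
        a, b, c = float(q @ q), float(q[:-1] @ q[1:]), float(q[:-2] @ q[2:])
        noise = q.sum()
        var = max((3 * (a - noise) - 4 * b + c) / 240.0, 0.0)
        assert gundersen_ce(scaled, m=1) == pytest.approx(
            math.sqrt(noise + var) / noise, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            gundersen_ce([1, -2, 3])


class TestCavalieri:
    def test_serial_sections_of_one_mm2(self):
        areas = [(f"s{i}", 1e6) for i in range(10)]
        v = cavalieri_volume(areas, 500.0)
        assert v.volume == pytest.approx(5e9)  # 5 mm³

    def test_single_section(self):
        assert cavalieri_volume([("s0", 1234.0)], 10.0).volume == 12340.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            cavalieri_volume([], 500.0)

    def test_sliced_cylinder_recovers_closed_form_volume(self):
        """Cylinder of radius r and length L sliced every 500 µm: the
        Cavalieri sum converges to πr²L for L >> spacing."""
        rng = np.random.default_rng(11)
        r, length, spacing = 5000.0, 60000.0, 500.0
        rel_errors = []
        for _ in range(20):
            phase = rng.uniform(0, spacing)
            zs = np.arange(phase, length, spacing)
            areas = [(f"s{i}", math.pi * r * r) for i in range(len(zs))]
            v = cavalieri_volume(areas, spacing).volume
            rel_errors.append(abs(v - math.pi * r * r * length)
                              / (math.pi * r * r * length))
        assert max(rel_errors) < 0.05


class TestDensity:
    def _estimate(self):
        return fractionator_estimate([5] * 10, SamplingDesign())

    def test_density_per_mm3(self):
        vol = cavalieri_volume([(f"s{i}", 1e6) for i in range(10)], 500.0)
        rec = layer_density(self._estimate(), vol, "per_mm3")
        assert rec.density_value == pytest.approx(681.8181818 / 5.0,
                                                  rel=1e-9)

    def test_per_cm3_is_thousandfold_per_mm3(self):
        vol = cavalieri_volume([(f"s{i}", 1e6) for i in range(10)], 500.0)
        a = layer_density(self._estimate(), vol, "per_mm3")
        b = layer_density(self._estimate(), vol, "per_cm3")
        assert b.density_value == pytest.approx(1000.0 * a.density_value)
        assert a.converted("per_cm3").density_value == pytest.approx(
            b.density_value)

    def test_zero_estimate_gives_zero_density(self):
        vol = cavalieri_volume([("s0", 1e6)], 500.0)
        est = fractionator_estimate([0, 0, 0], SamplingDesign())
        assert layer_density(est, vol).density_value == 0.0

    def test_zero_volume_rejected(self):
        vol = cavalieri_volume([("s0", 0.0)], 500.0)
        with pytest.raises(ValueError):
            layer_density(self._estimate(), vol)


class TestFrameGrid:
    def test_full_grid_counts_everything(self):
        pts = np.random.default_rng(0).uniform(0, 5000, size=(500, 2))
        assert frame_grid_counts(pts, SamplingDesign(), (0, 0)) == 500

    def test_quarter_grid_counts_quarter_on_average(self):
        design = SamplingDesign(grid_fraction=0.25, frame_w=350.0,
                                frame_h=350.0)
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 7000, size=(2000, 2))
        fractions = []
        for _ in range(200):
            off = rng.uniform(0, 700, size=2)
            fractions.append(
                frame_grid_counts(pts, design, tuple(off)) / len(pts))
        assert np.mean(fractions) == pytest.approx(0.25, abs=0.01)

    def test_forbidden_edge_convention(self):
        """Inclusion edges (lower-left) count; exclusion edges do not."""
        design = SamplingDesign(grid_fraction=0.25, frame_w=100.0,
                                frame_h=100.0)
        # grid step is 200; frame occupies [0, 100) x [0, 100)
        assert frame_grid_counts(np.array([[0.0, 0.0]]), design, (0, 0)) == 1
        assert frame_grid_counts(np.array([[100.0, 50.0]]), design,
                                 (0, 0)) == 0
        assert frame_grid_counts(np.array([[50.0, 100.0]]), design,
                                 (0, 0)) == 0
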