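"""Gel densitometry calibration: band detection, standard curves, anchor
interpolation, the primer-extension one-base correction, and per-base
resampling round trips through the lane simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nucmap as nm
from nucmap.gelcal import CalibrationError, _interp_with_ends


def gaussian_trace(centers, heights, sigma=1.5, lo=0.0, hi=100.0, n=2001):
    x = np.linspace(lo, hi, n)
    y = np.zeros_like(x)
    for c, h in zip(centers, heights):
        y += h * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    return nm.LaneTrace(x, y)


class TestDetectBands:
    def test_two_well_separated_bumps(self):
        trace = gaussian_trace([30.0, 70.0], [1.0, 0.8])
        bands = nm.detect_bands(trace, min_prominence=0.1)
        assert len(bands) == 2
        step = trace.x[1] - trace.x[0]
        assert abs(bands[0].center - 30.0) <= step
        assert abs(bands[1].center - 70.0) <= step

    def test_flat_trace_yields_no_bands(self):
        trace = nm.LaneTrace(np.linspace(0, 10, 50), np.full(50, 3.0))
        assert nm.detect_bands(trace, min_prominence=0.1) == []

    def test_single_bump_with_huge_separation(self):
        trace = gaussian_trace([50.0], [1.0])
        bands = nm.detect_bands(trace, min_prominence=0.1, min_separation=1000.0)
        assert len(bands) == 1

    def test_thinning_keeps_higher_peak(self):
        trace = gaussian_trace([48.0, 52.0], [1.0, 0.5], sigma=1.0)
        bands = nm.detect_bands(trace, min_prominence=0.05, min_separation=10.0)
        assert len(bands) == 1
        assert abs(bands[0].center - 48.0) < 1.0

    @given(st.integers(0, 19))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_recovers_band_count_on_simulated_lanes(self, seed):
        """n well-separated simulated bands yield exactly n calls."""
        rng = np.random.default_rng(seed)
        n_bands = int(rng.integers(1, 6))
        # geometric ladder: adjacent migrations differ by ~7 a.u. >> 6 sigma,
        # so every drawn band is resolvable by construction
        ladder = np.geomspace(100, 2000, 8)
        sizes = np.sort(rng.choice(ladder, n_bands, replace=False))
        lane = nm.simulate_gel_lane([(s, 1.0) for s in sizes], nm.GelModel(), seed=seed)
        bands = nm.detect_bands(lane.trace, min_prominence=0.2)
        assert len(bands) == n_bands


class TestSizeCurve:
    def test_log_linear_midpoint(self):
        curve = nm.fit_size_curve(nm.SizeStandard([(1000, 10.0), (100, 20.0)]))
        mid = curve.migration_to_size(15.0)
        assert mid.value == pytest.approx(10 ** 2.5, rel=1e-9)
        assert not mid.extrapolated

    def test_interpolation_passes_through_knots(self):
        curve = nm.fit_size_curve(nm.SizeStandard([(1000, 10.0), (500, 14.0), (100, 20.0)]))
        assert curve.migration_to_size(14.0).value == pytest.approx(500.0)

    def test_extrapolation_is_flagged(self):
        curve = nm.fit_size_curve(nm.SizeStandard([(1000, 10.0), (100, 20.0)]))
        beyond = curve.migration_to_size(25.0)
        assert beyond.value == pytest.approx(10 ** 1.5, rel=1e-9)
        assert beyond.extrapolated

    def test_non_monotone_standard_rejected(self):
        with pytest.raises(CalibrationError, match="monotone"):
            nm.SizeStandard([(100, 20.0), (500, 25.0), (1000, 10.0)])

    def test_size_to_migration_round_trip(self):
        gel = nm.GelModel()
        curve = nm.fit_size_curve(gel.size_standard([100, 300, 1000, 2000]))
        for s in (150.0, 450.0, 1500.0):
            m = curve.size_to_migration(s)
            assert curve.migration_to_size(m.value).value == pytest.approx(s, rel=1e-6)


class TestCalibrateBases:
    anchors = nm.AnchorSet([(10.0, 100), (20.0, 110)])

    @pytest.mark.parametrize("x,expected,extrap", [(15.0, 105.0, False),
                                                   (12.0, 102.0, False),
                                                   (25.0, 115.0, True)])
    def test_linear_interpolation_and_flagged_extrapolation(self, x, expected, extrap):
        got = nm.calibrate_bases(self.anchors, x)
        assert got.value == pytest.approx(expected)
        assert got.extrapolated is extrap

    def test_anchor_migrations_reproduce_anchor_bases_exactly(self):
        anchors = nm.AnchorSet([(5.0, 50), (9.0, 80), (14.0, 120), (30.0, 200)])
        for m, b in anchors.anchors:
            assert nm.calibrate_bases(anchors, m).value == b

    @given(st.floats(5.0, 30.0), st.floats(5.0, 30.0))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_between_anchors(self, x1, x2):
        anchors = nm.AnchorSet([(5.0, 50), (9.0, 80), (14.0, 120), (30.0, 200)])
        lo, hi = sorted((x1, x2))
        assert nm.calibrate_bases(anchors, lo).value <= nm.calibrate_bases(anchors, hi).value

    def test_descending_base_orientation_supported(self):
        anchors = nm.AnchorSet([(10.0, 200), (20.0, 100)])
        assert nm.calibrate_bases(anchors, 15.0).value == pytest.approx(150.0)


class TestTaqCorrection:
    def test_primer_extension_shifts_one_base_shorter(self):
        assert nm.apply_taq_correction(500, "primer_extension") == 499

    def test_ladder_and_indirect_lanes_unchanged(self):
        assert nm.apply_taq_correction(500, "sequencing_ladder") == 500
        assert nm.apply_taq_correction(500, "indirect_end_label") == 500

    def test_wraps_at_circular_origin(self, trp1_map):
        assert nm.apply_taq_correction(1, "primer_extension", trp1_map) == 1453

    def test_bijection_on_circular_map(self, trp1_map):
        for b in (1, 2, 700, 1453):
            corrected = nm.apply_taq_correction(b, "primer_extension", trp1_map)
            assert trp1_map.wrap(corrected + 1) == b


class TestTraceToBaseGrid:
    def test_constant_trace_gives_constant_grid(self):
        x = np.linspace(0, 50, 501)
        trace = nm.LaneTrace(x, np.full_like(x, 2.0))
        anchors = nm.AnchorSet([(0.0, 100), (50.0, 150)])
        grid = nm.trace_to_base_grid(trace, anchors)
        assert np.allclose(grid.values, 2.0)

    def test_round_trip_recovers_per_base_intensities(self, rng):
        bases = np.arange(1100, 1161)
        truth = rng.gamma(2.0, 1.0, size=bases.size)
        trace, anchors = nm.simulate_primer_extension_lane(
            bases, truth, lane_kind="primer_extension", seed=5
        )
        grid = nm.trace_to_base_grid(trace, anchors)
        common = np.isin(grid.bases, bases)
        got = grid.values[common]
        want = truth[np.isin(bases, grid.bases[common])]
        r = np.corrcoef(got, want)[0, 1]
        assert r >= 0.99

    def test_delta_band_peaks_at_assigned_base(self):
        bases = np.arange(1100, 1161)
        truth = np.zeros(bases.size)
        truth[bases.tolist().index(1132)] = 5.0
        trace, anchors = nm.simulate_primer_extension_lane(
            bases, truth, lane_kind="sequencing_ladder", seed=6
        )
        grid = nm.trace_to_base_grid(trace, anchors)
        assert int(grid.bases[np.argmax(grid.values)]) == 1132

    def test_signal_conservation_within_two_percent(self, rng):
        bases = np.arange(200, 241)
        truth = rng.gamma(2.0, 1.0, size=bases.size) + 0.2
        trace, anchors = nm.simulate_primer_extension_lane(
            bases, truth, lane_kind="sequencing_ladder", samples_per_base=25, seed=8
        )
        grid = nm.trace_to_base_grid(trace, anchors)
        width_per_base = 0.5  # migration_per_base of the simulator
        binned = float(np.sum(grid.values) * width_per_base)
        integral = float(np.trapezoid(trace.y, trace.x))
        assert abs(binned - integral) / integral <= 0.02

    def test_anchors_fully_outside_trace_error(self):
        x = np.linspace(0, 10, 100)
        trace = nm.LaneTrace(x, np.ones_like(x))
        anchors = nm.AnchorSet([(50.0, 100), (60.0, 120)])
        with pytest.raises(CalibrationError):
            nm.trace_to_base_grid(trace, anchors)


class TestCorrelateWithTrack:
    def _track(self, smap, values):
        return nm.StrandedTrack(smap, np.array(values, float),
                                np.zeros(smap.length), nm.TrackKind.CLEAVAGE)

    def test_identical_signal_correlates_perfectly(self, toy_circle):
        values = np.zeros(500)
        values[99:110] = np.arange(1, 12)
        grid = nm.gelcal.BaseGrid(np.arange(100, 111), values[99:110].astype(float),
                                  np.zeros(11, bool))
        res = nm.correlate_with_track(grid, self._track(toy_circle, values),
                                      strand="plus", window=(100, 110))
        assert res.pearson == pytest.approx(1.0)
        assert res.spearman == pytest.approx(1.0)

    def test_negated_signal_anticorrelates(self, toy_circle):
        values = np.zeros(500)
        values[99:110] = np.arange(1, 12)
        grid = nm.gelcal.BaseGrid(np.arange(100, 111),
                                  12.0 - values[99:110], np.zeros(11, bool))
        res = nm.correlate_with_track(grid, self._track(toy_circle, values),
                                      strand="plus", window=(100, 110))
        assert res.pearson == pytest.approx(-1.0)

    def test_zero_variance_reports_nan_not_exception(self, toy_circle):
        grid = nm.gelcal.BaseGrid(np.arange(100, 111), np.full(11, 2.0),
                                  np.zeros(11, bool))
        res = nm.correlate_with_track(grid, self._track(toy_circle, np.zeros(500)),
                                      strand="plus", window=(100, 110))
        assert np.isnan(res.pearson) and np.isnan(res.spearman)

    def test_gel_and_sequencing_views_of_one_nucleosome_agree(self, trp1):
        """A gel lane rendered from a simulated cleavage track correlates
        strongly with that track over the nucleosome window."""
        smap = trp1.map
        spec = nm.ChromatinSpec(map=smap, dyads=[nm.Dyad(1132)])
        reads = nm.simulate_chemical_reads(spec, n=4000, seed=42)
        cleavage = nm.to_cleavage_sites(nm.five_prime_track(reads, smap))
        combined = nm.combine_strands(cleavage)
        window = np.arange(1100, 1166)
        trace, anchors = nm.simulate_primer_extension_lane(
            window, combined[window - 1], lane_kind="sequencing_ladder", seed=43
        )
        grid = nm.trace_to_base_grid(trace, anchors)
        track = nm.StrandedTrack(smap, combined, np.zeros(smap.length),
                                 nm.TrackKind.CLEAVAGE)
        res = nm.correlate_with_track(grid, track, strand="plus", window=(1105, 1160))
        assert res.pearson >= 0.9
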