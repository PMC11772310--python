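"""Chromatography tests: XIC/TIC construction, peak detection and integration
against analytic oracles, and the quantitative readout arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import gaussian_area
from lupin_miner import chromquant as cq
from lupin_miner.chromquant import (
    Chromatogram,
    MsRun,
    MzWindow,
    Peak,
    QuantConfig,
    Scan,
)
from lupin_miner.errors import (
    BlankContradictionError,
    ConfigError,
    MissingInternalStandardError,
)


def make_run(times, centroids):
    """centroids: per scan list of (mz, intensity) tuples."""
    scans = [
        Scan(
            time=t,
            mz=np.array([c[0] for c in cs], dtype=float),
            intensity=np.array([c[1] for c in cs], dtype=float),
        )
        for t, cs in zip(times, centroids)
    ]
    return MsRun(scans=scans).validate()


def gaussian_chrom(amp, sigma, rt=5.0, step=None, span=5.0):
    step = step or sigma / 10
    t = np.arange(rt - span * sigma, rt + span * sigma + step / 2, step)
    return Chromatogram(t, amp * np.exp(-0.5 * ((t - rt) / sigma) ** 2))


class TestXicTic:
    def test_window_containment(self):
        run = make_run([0.0, 0.1, 0.2], [[(235.225, 100.0)]] * 3)
        xic = cq.extract_xic(run, MzWindow(235.22, 0.01))
        np.testing.assert_array_equal(xic.intensities, [100.0, 100.0, 100.0])

    def test_adjacent_window_excludes(self):
        run = make_run([0.0, 0.1, 0.2], [[(235.225, 100.0)]] * 3)
        xic = cq.extract_xic(run, MzWindow(235.18, 0.01))
        assert xic.intensities.max() == 0.0

    def test_closed_boundaries_inclusive(self):
        run = make_run([0.0, 0.1], [[(235.23, 7.0)], [(235.21, 3.0)]])
        xic = cq.extract_xic(run, MzWindow(235.22, 0.01))
        np.testing.assert_array_equal(xic.intensities, [7.0, 3.0])

    def test_tic_sums_scans(self):
        run = make_run([0.0, 0.1], [[(100.0, 3.0), (200.0, 4.0)], [(150.0, 7.0)]])
        tic = cq.total_ion_chromatogram(run)
        np.testing.assert_array_equal(tic.intensities, [7.0, 7.0])

    def test_tic_equals_xic_partition(self):
        rng = np.random.default_rng(5)
        times = np.arange(0, 1.0, 0.1)
        cents = [
            [(float(rng.uniform(50, 450)), float(rng.uniform(0, 100))) for _ in range(6)]
            for _ in times
        ]
        run = make_run(times, cents)
        tic = cq.total_ion_chromatogram(run)
        total = sum(
            cq.extract_xic(run, MzWindow(c, 50.0)).intensities
            for c in (100.0, 200.0, 300.0, 400.0)  # closed cover of [50, 450]
        )
        np.testing.assert_allclose(total, tic.intensities, rtol=1e-12)

    def test_empty_scans_are_zero(self):
        run = make_run([0.0, 0.1], [[], []])
        assert cq.total_ion_chromatogram(run).intensities.tolist() == [0.0, 0.0]


class TestDetectAndIntegrate:
    def test_single_noiseless_gaussian(self):
        chrom = gaussian_chrom(1e5, 0.05)
        peaks = cq.detect_peaks(chrom, noise_sd=0.0)
        assert len(peaks) == 1
        assert abs(peaks[0].apex_time - 5.0) <= 0.005 + 1e-9
        assert peaks[0].area == pytest.approx(gaussian_area(1e5, 0.05), rel=0.01)

    def test_all_zero_input(self):
        chrom = Chromatogram(np.arange(10.0), np.zeros(10))
        assert cq.detect_peaks(chrom) == []

    def test_flat_nonzero_input(self):
        chrom = Chromatogram(np.arange(10.0), np.full(10, 5.0))
        assert cq.detect_peaks(chrom) == []

    def test_two_separated_gaussians(self):
        t = np.arange(0, 10, 0.005)
        y = 1e4 * np.exp(-0.5 * ((t - 3.0) / 0.05) ** 2) + 2e4 * np.exp(
            -0.5 * ((t - 3.6) / 0.05) ** 2
        )
        peaks = cq.detect_peaks(Chromatogram(t, y), noise_sd=0.0)
        assert len(peaks) == 2
        assert peaks[0].right_time <= peaks[1].left_time  # valley separates them
        assert peaks[0].area == pytest.approx(gaussian_area(1e4, 0.05), rel=0.01)
        assert peaks[1].area == pytest.approx(gaussian_area(2e4, 0.05), rel=0.01)

    def test_rectangle_integration(self):
        t = np.arange(0, 5.0, 0.1)
        y = np.where((t >= 1.0) & (t <= 3.0), 10.0, 0.0)
        chrom = Chromatogram(t, y)
        peak = Peak(apex_time=2.0, left_time=1.0, right_time=3.0, height=10.0, area=0.0)
        assert cq.integrate_peak(chrom, peak) == pytest.approx(20.0)

    def test_integration_linearity(self):
        chrom = gaussian_chrom(1e4, 0.05)
        peak = cq.detect_peaks(chrom, noise_sd=0.0)[0]
        doubled = Chromatogram(chrom.times, 2 * chrom.intensities)
        assert cq.integrate_peak(doubled, peak) == pytest.approx(
            2 * cq.integrate_peak(chrom, peak)
        )

    def test_time_translation_invariance(self):
        chrom = gaussian_chrom(1e4, 0.05)
        peak = cq.detect_peaks(chrom, noise_sd=0.0)[0]
        shifted = Chromatogram(chrom.times + 2.5, chrom.intensities)
        speak = cq.detect_peaks(shifted, noise_sd=0.0)[0]
        assert speak.area == pytest.approx(peak.area, rel=1e-9)

    def test_inverted_boundaries_rejected(self):
        chrom = gaussian_chrom(1e4, 0.05)
        bad = Peak(apex_time=5.0, left_time=4.5, right_time=5.5, height=1.0, area=0.0)
        bad.left_time, bad.right_time = 5.5, 4.5
        with pytest.raises(ValueError):
            cq.integrate_peak(chrom, bad)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cq.detect_peaks(Chromatogram(np.arange(3.0), np.zeros(3)))


class TestMatchPeak:
    def _peak(self, rt, area=10.0):
        return Peak(rt, rt - 0.1, rt + 0.1, 5.0, area)

    def test_nearest_wins(self):
        peaks = [self._peak(5.0), self._peak(8.0)]
        assert cq.match_peak(peaks, 5.1, 0.3) is peaks[0]

    def test_no_match(self):
        peaks = [self._peak(5.0), self._peak(8.0)]
        assert cq.match_peak(peaks, 6.5, 0.3) is None

    def test_equidistant_tie_goes_to_larger_area(self):
        peaks = [self._peak(4.9, area=1.0), self._peak(5.1, area=9.0)]
        assert cq.match_peak(peaks, 5.0, 0.3) is peaks[1]


class TestNormalizationAndComparison:
    def test_arithmetic(self):
        assert cq.normalized_abundance(1000.0, 100.0, 20.0) == pytest.approx(0.5)
        assert cq.normalized_abundance(0.0, 100.0, 20.0) == 0.0

    def test_gain_invariance(self):
        a = cq.normalized_abundance(1000.0, 100.0, 20.0)
        b = cq.normalized_abundance(3000.0, 300.0, 20.0)
        assert a == pytest.approx(b)

    def test_missing_internal_standard(self):
        with pytest.raises(MissingInternalStandardError):
            cq.normalized_abundance(1000.0, 0.0, 20.0)

    def test_residual_percent(self):
        assert cq.residual_percent([100.0], [0.6]) == pytest.approx(0.6)
        assert cq.residual_percent([3.0, 5.0], [3.0, 5.0]) == pytest.approx(100.0)

    def test_fold_change_and_consistency(self):
        assert cq.fold_change([2.0], [26.0]) == pytest.approx(13.0)
        wt, ko = [2.0, 3.0, 4.0], [1.0, 0.5, 0.2]
        assert cq.fold_change(wt, ko) == pytest.approx(
            cq.residual_percent(wt, ko) / 100.0
        )

    def test_zero_wild_type_rejected(self):
        with pytest.raises(ValueError):
            cq.residual_percent([0.0, 0.0], [1.0])


class TestPurityAndFractions:
    def _peak(self, rt, area):
        return Peak(rt, rt - 0.1, rt + 0.1, area, area)

    def test_blank_exclusion_arithmetic(self):
        sample = [
            ("analyte", self._peak(8.0, 98.0)),
            (None, self._peak(5.0, 2.0)),
            (None, self._peak(3.0, 50.0)),  # column bleed, present in blank
        ]
        blank = [self._peak(3.0, 48.0)]
        assert cq.area_percent_purity(sample, blank, "analyte", 0.2) == pytest.approx(98.0)

    def test_no_contaminants_is_pure(self):
        sample = [("analyte", self._peak(8.0, 42.0))]
        assert cq.area_percent_purity(sample, [], "analyte", 0.2) == pytest.approx(100.0)

    def test_analyte_matching_blank_contradicts(self):
        sample = [("analyte", self._peak(8.0, 98.0))]
        blank = [self._peak(8.05, 10.0)]
        with pytest.raises(BlankContradictionError):
            cq.area_percent_purity(sample, blank, "analyte", 0.2)

    def test_intensity_rescaling_invariance(self):
        sample = [("analyte", self._peak(8.0, 98.0)), (None, self._peak(5.0, 2.0))]
        scaled = [(n, self._peak(p.apex_time, p.area * 7.0)) for n, p in sample]
        assert cq.area_percent_purity(sample, [], "analyte", 0.2) == pytest.approx(
            cq.area_percent_purity(scaled, [], "analyte", 0.2)
        )

    def test_alkaloid_fraction(self):
        peaks = [("sparteine", self._peak(8.0, 96.0))] + [
            (f"minor{i}", self._peak(9.0 + i, 0.8)) for i in range(5)
        ]
        assert cq.alkaloid_fraction(peaks, "sparteine") == pytest.approx(96.0)
        assert sum(cq.alkaloid_fraction(peaks, n) for n, _ in peaks) == pytest.approx(100.0)
        assert cq.alkaloid_fraction([("x", self._peak(1.0, 5.0))], "x") == 100.0

    def test_absent_analyte_rejected(self):
        with pytest.raises(LookupError):
            cq.alkaloid_fraction([("a", self._peak(1.0, 5.0))], "b")


class TestEnantiomericExcess:
    @pytest.mark.parametrize(
        "target, antipode, expected",
        [(199.0, 1.0, 99.0), (5.0, 5.0, 0.0), (0.0, 7.0, -100.0)],
    )
    def test_values(self, target, antipode, expected):
        assert cq.enantiomeric_excess(target, antipode) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            cq.enantiomeric_excess(0.0, 0.0)

    @given(
        st.floats(0.0, 1e6),
        st.floats(0.0, 1e6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry_and_range(self, a, b):
        if a + b == 0:
            return
        ee = cq.enantiomeric_excess(a, b)
        assert -100.0 <= ee <= 100.0
        assert cq.enantiomeric_excess(b, a) == pytest.approx(-ee, abs=1e-9)


class TestConfigAndIo:
    def test_overlapping_windows_rejected(self):
        from lupin_miner.chromquant import AnalyteDef

        with pytest.raises(ConfigError):
            QuantConfig(
                analytes={
                    "a": AnalyteDef("a", MzWindow(100.0, 0.5), 1.0),
                    "b": AnalyteDef("b", MzWindow(100.3, 0.5), 2.0),
                }
            )

    def test_default_config_valid_and_round_trips(self, tmp_path):
        qc = QuantConfig.default()
        qc.to_yaml(tmp_path / "q.yaml")
        back = QuantConfig.from_yaml(tmp_path / "q.yaml")
        assert set(back.analytes) == set(qc.analytes)
        assert back.analytes["sparteine"].window.center == 235.22

    def test_msrun_csv_round_trip(self, tmp_path):
        run = make_run([0.0, 0.1, 0.2], [[(100.0, 5.0)], [], [(101.0, 7.0)]])
        run.to_csv(tmp_path / "run.csv")
        back = MsRun.from_csv(tmp_path / "run.csv")
        assert [s.time for s in back.scans] == [0.0, 0.1, 0.2]
        assert len(back.scans[1].mz) == 0
        np.testing.assert_allclose(back.scans[2].intensity, [7.0])
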