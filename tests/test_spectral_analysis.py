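import math

import numpy as np
import pytest

from fibrilshift.habit_model import Habit, habit_report
from fibrilshift.nmr_forward import (
    Peak1D,
    apply_water_edit,
    default_water_edit_profile,
    make_axis,
    peaks_from_table,
    simulate_1d,
    simulate_inadequate,
    simulate_pdsd,
)
from fibrilshift.pipeline import simulate_is_ratio
from fibrilshift.reference_data import CARBONS, ReferenceSet, SiteShifts
from fibrilshift.spectral_analysis import (
    crystallinity_index,
    enhancement_factors,
    fit_c1_region,
    integrate_window,
    interior_surface_ratio,
    pick_peaks_1d,
    trace_spin_systems,
)


class TestPickPeaks:
    def test_single_lorentzian_recovered_subgrid(self):
        sp = simulate_1d([Peak1D("c", 6, 66.0, 0.5, 1.0)])
        positions = pick_peaks_1d(sp)
        assert len(positions) == 1
        assert positions[0] == pytest.approx(66.0, abs=0.01)

    def test_c1_region_of_majors_recovered(self, poplar, majors):
        # resolved linewidth: peaks 0.3–0.7 ppm apart need fwhm below ~0.3
        peaks = peaks_from_table(poplar, carbons=(1,), fwhm=0.15)
        sp = simulate_1d(peaks, axis=make_axis(100, 110, 0.01))
        found = pick_peaks_1d(sp, min_height=0.1, min_separation=0.1)
        expected = sorted((s.shift(1) for s in majors), reverse=True)
        assert len(found) == len(expected)
        assert np.allclose(found, expected, atol=0.05)

    def test_all_zero_spectrum_gives_no_peaks(self):
        axis = make_axis()
        from fibrilshift.nmr_forward import Spectrum1D

        sp = Spectrum1D(axis=axis, intensity=np.zeros_like(axis))
        assert pick_peaks_1d(sp).size == 0


class TestIntegrateWindow:
    def test_lorentzian_window_area_matches_closed_form(self):
        gamma = 0.25  # fwhm 0.5
        sp = simulate_1d([Peak1D("x", 4, 85.0, 2 * gamma, 1.0)])
        area = integrate_window(sp, 80.0, 90.0)
        expected = gamma * 2 * math.atan(5.0 / gamma)  # ∫ unit Lorentzian over ±5
        assert area == pytest.approx(expected, rel=0.01)

    def test_half_window_of_symmetric_peak(self):
        sp = simulate_1d([Peak1D("x", 4, 85.0, 0.5, 1.0)])
        half = integrate_window(sp, 85.0, 90.0)
        full = integrate_window(sp, 80.0, 90.0)
        assert half == pytest.approx(full / 2, rel=0.02)

    def test_zero_spectrum_integrates_to_zero(self):
        axis = make_axis()
        from fibrilshift.nmr_forward import Spectrum1D

        sp = Spectrum1D(axis=axis, intensity=np.zeros_like(axis))
        assert integrate_window(sp, 60.0, 70.0) == 0.0

    def test_window_outside_axis_rejected(self):
        sp = simulate_1d([Peak1D("x", 4, 85.0)])
        with pytest.raises(ValueError):
            integrate_window(sp, 10.0, 20.0)


class TestTraceSpinSystems:
    def test_six_major_systems_traced_exactly(self, poplar, majors):
        peaks = simulate_inadequate(majors)
        systems = trace_spin_systems(peaks, tol=0.1, table=poplar)
        assert len(systems) == 6 and all(s.complete for s in systems)
        by_site = {s.site_id: s.shifts for s in systems}
        assert set(by_site) == {"a", "b", "c", "f", "g", "j"}
        for site in majors:
            assert by_site[site.site_id] == pytest.approx(site.shifts, abs=1e-9)

    def test_single_site_gives_one_system(self, poplar):
        systems = trace_spin_systems(simulate_inadequate([poplar.get("a")]))
        assert len(systems) == 1 and systems[0].complete

    def test_shared_c2_resolved_between_a_and_c(self, poplar):
        # a and c have identical C2 at 71.8 ppm; DQ coordinates still split them
        pair = [poplar.get("a"), poplar.get("c")]
        systems = trace_spin_systems(simulate_inadequate(pair), tol=0.1, table=poplar)
        assert {s.site_id for s in systems} == {"a", "c"}
        assert all(s.complete for s in systems)

    def test_exact_inverse_on_random_separated_tables(self):
        # forward-then-trace is the identity when every carbon's shifts are
        # pairwise separated by more than the tolerance
        rng = np.random.default_rng(42)
        windows = [(103, 108), (69, 74), (74, 79), (81, 91), (69, 74), (60, 66)]
        for _ in range(20):
            shifts = []
            for lo, hi in windows:
                vals = lo + (hi - lo) * np.sort(rng.random(4))
                while np.min(np.diff(vals)) < 0.3:
                    vals = lo + (hi - lo) * np.sort(rng.random(4))
                shifts.append(np.round(vals, 2))
            sites = tuple(
                SiteShifts(f"s{k}", tuple(float(shifts[c][k]) for c in range(6)))
                for k in range(4)
            )
            systems = trace_spin_systems(simulate_inadequate(sites), tol=0.1)
            assert len(systems) == 4 and all(s.complete for s in systems)
            traced = {s.shifts for s in systems}
            assert traced == {s.shifts for s in sites}


class TestCrystallinityIndex:
    def test_symmetric_domains_give_half(self):
        peaks = [Peak1D("x", 4, p, 0.4, 1.0) for p in (88.0, 88.7, 89.4)]
        peaks += [Peak1D("y", 4, p, 0.4, 1.0) for p in (85.0, 84.3, 83.6)]
        result = crystallinity_index(simulate_1d(peaks))
        assert result.ci == pytest.approx(0.5, abs=0.01)

    def test_domain1_only_gives_one(self):
        # Gaussian lineshape: no heavy tail leaking into the D2 window
        sp = simulate_1d([Peak1D("x", 4, 89.0, 0.4, 1.0)], lineshape="gaussian")
        result = crystallinity_index(sp)
        assert result.ci == pytest.approx(1.0, abs=0.01)

    def test_zero_spectrum_flagged_undefined(self):
        from fibrilshift.nmr_forward import Spectrum1D

        axis = make_axis()
        result = crystallinity_index(Spectrum1D(axis=axis, intensity=np.zeros_like(axis)))
        assert not result.defined and math.isnan(result.ci)

    def test_invariant_under_global_scaling(self, poplar):
        peaks = peaks_from_table(poplar, carbons=(4,))
        scaled = [Peak1D(p.site_id, p.carbon, p.position, p.fwhm, 7.5 * p.amplitude) for p in peaks]
        assert crystallinity_index(simulate_1d(peaks)).ci == pytest.approx(
            crystallinity_index(simulate_1d(scaled)).ci
        )

    def test_overestimates_interior_fraction_for_habit_weights(self, poplar):
        # site b sits on the domain-1 side, so CI exceeds i/(i+s) = 1/3
        from fibrilshift.nmr_forward import site_multiplicities

        counts = site_multiplicities(habit_report(Habit.from_string("234432")))
        sp = simulate_1d(peaks_from_table(poplar, carbons=(4,), amplitudes=counts))
        result = crystallinity_index(sp)
        assert result.ci > 1 / 3


class TestC1Fit:
    def test_noiseless_amplitudes_recovered(self, poplar, majors):
        amps = {"a": 3.0, "b": 2.0, "c": 3.0, "f": 4.0, "g": 2.5, "j": 3.5}
        sp = simulate_1d(
            peaks_from_table(poplar, carbons=(1,), amplitudes=amps),
            axis=make_axis(98, 112, 0.02),
        )
        positions = {s.site_id: s.shift(1) for s in majors}
        fit = fit_c1_region(sp, positions)
        for site, expected in amps.items():
            assert fit.amplitudes[site] == pytest.approx(expected, rel=0.01)

    def test_zero_spectrum_gives_zero_amplitudes(self, majors):
        from fibrilshift.nmr_forward import Spectrum1D

        axis = make_axis(98, 112, 0.02)
        sp = Spectrum1D(axis=axis, intensity=np.zeros_like(axis))
        fit = fit_c1_region(sp, {s.site_id: s.shift(1) for s in majors})
        assert all(v == 0 for v in fit.amplitudes.values())

    def test_noisy_amplitudes_within_five_percent(self, poplar, majors):
        amps = {"a": 3.0, "b": 2.0, "c": 3.0, "f": 4.0, "g": 2.5, "j": 3.5}
        peaks = peaks_from_table(poplar, carbons=(1,), amplitudes=amps)
        axis = make_axis(98, 112, 0.02)
        clean = simulate_1d(peaks, axis=axis)
        sigma = 0.01 * clean.intensity.max()
        sp = simulate_1d(peaks, axis=axis, noise_sigma=sigma, seed=11)
        fit = fit_c1_region(sp, {s.site_id: s.shift(1) for s in majors})
        for site, expected in amps.items():
            assert fit.amplitudes[site] == pytest.approx(expected, rel=0.05)

    def test_positions_outside_c1_region_rejected(self):
        sp = simulate_1d([Peak1D("x", 1, 106.0)], axis=make_axis(98, 112, 0.02))
        with pytest.raises(ValueError):
            fit_c1_region(sp, {"x": 89.0})


class TestInteriorSurfaceRatio:
    def test_234432_multiplicities_give_half(self):
        amps = {"a": 3.0, "c": 3.0, "b": 2.0, "f": 10 / 3, "g": 10 / 3, "j": 10 / 3}
        result = interior_surface_ratio(amps)
        assert result.ratio == pytest.approx(0.5)

    def test_zero_surface_flagged_undefined(self):
        amps = {"a": 3.0, "c": 3.0, "b": 0.0, "f": 0.0, "g": 0.0, "j": 0.0}
        result = interior_surface_ratio(amps)
        assert not result.defined

    def test_core_rich_composition_exceeds_half(self):
        # cotton-like: larger fibrils have relatively more core than surface
        amps = {"a": 8.0, "c": 8.0, "b": 2.0, "f": 4.0, "g": 3.0, "j": 3.0}
        assert interior_surface_ratio(amps).ratio > 0.5

    def test_missing_site_rejected(self):
        with pytest.raises(KeyError):
            interior_surface_ratio({"a": 1.0, "c": 1.0})


class TestRoundTrip:
    @pytest.mark.parametrize("habit_str", ["234432", "34443", "44444"])
    def test_noiseless_recovery_within_two_percent(self, poplar, habit_str):
        report = habit_report(Habit.from_string(habit_str))
        result = simulate_is_ratio(poplar, report)
        assert result.ratio == pytest.approx(report.is_ratio, rel=0.02)

    def test_noisy_recovery_within_ten_percent_over_seeds(self, poplar):
        report = habit_report(Habit.from_string("234432"))
        ratios = [
            simulate_is_ratio(poplar, report, noise_sigma=0.01, seed=seed).ratio
            for seed in range(20)
        ]
        assert np.mean(ratios) == pytest.approx(0.5, rel=0.10)


class TestEnhancementFactors:
    def test_identity_when_unedited(self, majors):
        std = simulate_pdsd(majors, 30)
        report = enhancement_factors(std, std)
        assert all(f == pytest.approx(1.0) for f in report.factors.values())
        assert not any(report.hydrated.values())

    def test_default_profile_classification(self, majors):
        std = simulate_pdsd(majors, 30)
        edited = apply_water_edit(std, default_water_edit_profile())
        report = enhancement_factors(std, edited)
        for site in "bfgj":
            assert report.site_hydrated(site, carbon=4)
        for site in "ac":
            assert not report.site_hydrated(site, carbon=4)

    def test_b_c6_less_enhanced_than_b_c4(self, majors):
        std = simulate_pdsd(majors, 30)
        edited = apply_water_edit(std, default_water_edit_profile())
        report = enhancement_factors(std, edited)
        assert report.factor("b", 6) < report.factor("b", 4)
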