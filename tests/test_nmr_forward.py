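import math

import numpy as np
import pytest

from fibrilshift.habit_model import Habit, habit_report
from fibrilshift.nmr_forward import (
    BONDED_PAIRS,
    Peak1D,
    apply_water_edit,
    default_contact_map,
    default_water_edit_profile,
    make_axis,
    peaks_from_table,
    simulate_1d,
    simulate_inadequate,
    simulate_pdsd,
    site_multiplicities,
)


@pytest.fixture(scope="module")
def hr_234432():
    return habit_report(Habit.from_string("234432"))


class TestSiteMultiplicities:
    def test_234432_default_split(self, hr_234432):
        counts = site_multiplicities(hr_234432)
        assert counts["a"] == 3 and counts["c"] == 3
        assert counts["b"] == pytest.approx(2.0)
        assert counts["f"] + counts["g"] + counts["j"] == pytest.approx(10.0)
        assert sum(counts.values()) == pytest.approx(18.0)

    def test_single_sheet_habit_all_surface(self):
        counts = site_multiplicities(habit_report(Habit((6,))))
        assert counts["a"] == counts["c"] == 0
        assert sum(counts.values()) == pytest.approx(6.0)

    def test_24_chain_equal_split(self):
        report = habit_report(Habit.from_string("6666"))
        assert (report.n_interior, report.n_surface) == (8, 16)
        counts = site_multiplicities(report, {s: 0.25 for s in "bfgj"})
        assert counts["a"] == counts["c"] == 4
        assert all(counts[s] == 4 for s in "bfgj")

    def test_bad_split_rejected(self, hr_234432):
        with pytest.raises(ValueError):
            site_multiplicities(hr_234432, {"b": 0.5, "f": 0.6})


class TestSimulate1D:
    def test_single_peak_argmax(self):
        sp = simulate_1d([Peak1D("a", 4, 89.2, 0.5, 1.0)])
        assert sp.axis[np.argmax(sp.intensity)] == pytest.approx(89.2, abs=0.02)

    def test_major_c4_region_splits_into_two_clusters(self, poplar):
        sp = simulate_1d(peaks_from_table(poplar, carbons=(4,)))
        mask_d1 = (sp.axis > 86.5) & (sp.axis < 92)
        mask_d2 = (sp.axis > 80) & (sp.axis < 86.5)
        top_d1 = sp.axis[mask_d1][np.argmax(sp.intensity[mask_d1])]
        top_d2 = sp.axis[mask_d2][np.argmax(sp.intensity[mask_d2])]
        assert 88.5 < top_d1 < 89.5
        assert 83.5 <= top_d2 < 85.0

    def test_domain2_c4_shows_both_peaks(self, poplar):
        amps = {"f": 1.0, "g": 1.0, "j": 1.0}
        sp = simulate_1d(peaks_from_table(poplar, carbons=(4,), amplitudes=amps))
        from fibrilshift.spectral_analysis import pick_peaks_1d

        positions = pick_peaks_1d(sp, min_height=0.2, min_separation=0.3)
        assert len(positions) == 2
        assert positions[0] == pytest.approx(84.5, abs=0.15)
        assert positions[1] == pytest.approx(83.5, abs=0.15)

    def test_same_seed_is_bit_identical(self):
        peaks = [Peak1D("a", 1, 106.1)]
        sp1 = simulate_1d(peaks, noise_sigma=0.05, seed=7)
        sp2 = simulate_1d(peaks, noise_sigma=0.05, seed=7)
        assert np.array_equal(sp1.intensity, sp2.intensity)
        sp3 = simulate_1d(peaks, noise_sigma=0.05, seed=8)
        assert not np.array_equal(sp1.intensity, sp3.intensity)

    def test_linearity_without_noise(self, poplar):
        p1 = peaks_from_table(poplar, carbons=(1,))
        p2 = peaks_from_table(poplar, carbons=(4,))
        combined = simulate_1d(p1 + p2)
        separate = simulate_1d(p1).intensity + simulate_1d(p2).intensity
        assert np.allclose(combined.intensity, separate)

    def test_lorentzian_integral_matches_closed_form(self):
        amp, fwhm, pos = 2.0, 0.5, 85.0
        sp = simulate_1d([Peak1D("x", 4, pos, fwhm, amp)])
        area = -np.trapezoid(sp.intensity, sp.axis)  # axis descending
        expected = amp * math.pi * fwhm / 2  # unit-height Lorentzian area
        assert area == pytest.approx(expected, rel=0.01)

    def test_out_of_axis_peak_warned_and_skipped(self):
        axis = make_axis(80, 95)
        with pytest.warns(UserWarning, match="skipped"):
            sp = simulate_1d([Peak1D("x", 1, 106.1)], axis=axis)
        assert sp.intensity.max() == 0


class TestInadequate:
    def test_single_site_emits_ten_peaks(self, poplar):
        peaks = simulate_inadequate([poplar.get("c")])
        assert len(peaks) == 10
        dq_values = {round(p.dim2, 4) for p in peaks}
        assert round(75.4 + 88.4, 4) in dq_values  # C3–C4 pair of site c

    def test_six_major_sites_emit_sixty_peaks(self, majors):
        assert len(simulate_inadequate(majors)) == 60

    def test_zero_amplitude_site_contributes_nothing(self, majors):
        amps = {s.site_id: 1.0 for s in majors}
        amps["b"] = 0.0
        peaks = simulate_inadequate(majors, amplitudes=amps)
        assert len(peaks) == 50
        assert all(p.site_i != "b" for p in peaks)

    def test_dq_is_sum_of_bonded_sq_shifts(self, majors):
        for p in simulate_inadequate(majors):
            site = next(s for s in majors if s.site_id == p.site_i)
            assert p.dim2 == pytest.approx(site.shift(p.carbon_i) + site.shift(p.carbon_j))
            assert (
                (p.carbon_i, p.carbon_j) in BONDED_PAIRS
                or (p.carbon_j, p.carbon_i) in BONDED_PAIRS
            )


class TestPdsd:
    def test_short_mixing_is_intra_residue_only(self, majors):
        peaks = simulate_pdsd(majors, 30)
        assert all(p.site_i == p.site_j for p in peaks)

    def test_200ms_c1_contacts_are_a_c_only(self, majors):
        inter = [p for p in simulate_pdsd(majors, 200) if p.site_i != p.site_j]
        assert inter and {frozenset((p.site_i, p.site_j)) for p in inter} == {
            frozenset(("a", "c"))
        }
        assert all(p.carbon_i == p.carbon_j == 1 for p in inter)

    def test_400ms_c4_contacts_with_weaker_c_peaks(self, majors):
        inter = [p for p in simulate_pdsd(majors, 400) if p.site_i != p.site_j]
        c4 = [p for p in inter if p.carbon_i == 4 and p.carbon_j == 4]
        sources = {p.site_i for p in c4} | {p.site_j for p in c4}
        assert {"a", "b", "c", "f", "g", "j"} <= sources
        amp_from = lambda s: max(
            p.amplitude for p in c4 if s in (p.site_i, p.site_j)
        )
        assert amp_from("c") < amp_from("a") == amp_from("b")

    def test_symmetric_about_diagonal(self, majors):
        peaks = simulate_pdsd(majors, 400)
        coords = {(round(p.dim1, 6), round(p.dim2, 6), round(p.amplitude, 9)) for p in peaks}
        assert coords == {(d2, d1, a) for d1, d2, a in coords}


class TestWaterEdit:
    def test_unit_profile_is_identity(self, majors):
        from fibrilshift.nmr_forward import WaterEditProfile

        peaks = simulate_pdsd(majors, 30)
        unit = WaterEditProfile({s.site_id: 1.0 for s in majors})
        edited = apply_water_edit(peaks, unit)
        assert [p.amplitude for p in edited] == [p.amplitude for p in peaks]

    def test_default_profile_ordering(self):
        profile = default_water_edit_profile()
        w = profile.factor
        assert w("a", 4) == w("c", 4) == 1.0
        for site in "fgj":
            assert w(site, 4) > 1.0
        assert w("b", 4) > w("a", 4)
        assert w("b", 6) < w("b", 4)
        assert w("g", 6) > max(w("f", 6), w("j", 6))  # g marginally closest to water

    def test_missing_site_raises(self, majors):
        from fibrilshift.nmr_forward import WaterEditProfile

        profile = WaterEditProfile({"a": 1.0})
        with pytest.raises(KeyError):
            apply_water_edit(simulate_pdsd(majors, 30), profile)

    def test_contact_map_defaults_valid(self):
        contacts = default_contact_map()
        assert all(c.min_mixing_ms > 0 and 0 < c.relative_amplitude <= 1 for c in contacts)
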