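import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from specbind import (DomainError, FretConfig, Spectrum, WindowError,
                      distance_from_efficiency, efficiency_from_distance,
                      efficiency_from_intensity, forster_radius,
                      forster_window_check, fret_analysis,
                      generate_overlap_pair, overlap_integral)


class TestOverlapIntegral:
    def test_zero_acceptor_gives_zero_overlap(self, gaussian_spectrum):
        donor = gaussian_spectrum(340, 15)
        eps = Spectrum(donor.wavelengths_nm, np.zeros(len(donor)),
                       "molar_absorptivity")
        j = overlap_integral(donor, eps, (300, 400))
        assert j.j_nm4_M_inv_cm_inv == 0.0

    def test_narrow_donor_limit_is_epsilon_lambda_fourth(self):
        # donor mass concentrated at 340 nm, flat epsilon
        wl = np.arange(300.0, 400.0, 0.05)
        donor = Spectrum(wl, np.exp(-0.5 * ((wl - 340) / 0.2) ** 2),
                         "emission")
        eps = Spectrum(wl, np.full(wl.size, 500.0), "molar_absorptivity")
        j = overlap_integral(donor, eps, (300, 400))
        assert j.j_nm4_M_inv_cm_inv == pytest.approx(500.0 * 340**4,
                                                     rel=1e-4)

    def test_matches_fine_grid_oracle_within_five_hundredths_percent(self):
        donor, eps, oracle = generate_overlap_pair(
            donor_center_nm=340, donor_sigma_nm=15,
            acceptor_center_nm=330, acceptor_sigma_nm=12,
            epsilon_peak_M_inv_cm_inv=4000, grid_step_nm=1.0)
        j = overlap_integral(donor, eps, (265, 415))
        assert j.j_nm4_M_inv_cm_inv == pytest.approx(oracle, rel=5e-4)

    def test_invariant_to_donor_rescaling(self, gaussian_spectrum):
        donor = gaussian_spectrum(340, 15)
        eps = gaussian_spectrum(330, 12, peak=4000,
                                kind="molar_absorptivity")
        j1 = overlap_integral(donor, eps, (300, 400))
        j2 = overlap_integral(donor.with_signal(donor.signal * 137.0), eps,
                              (300, 400))
        assert j2.j_nm4_M_inv_cm_inv == pytest.approx(
            j1.j_nm4_M_inv_cm_inv, rel=1e-12)

    def test_quadrature_error_shrinks_with_the_grid_step(self):
        # narrow bands so the step is coarse relative to the bandwidth;
        # wide Gaussians hit the error floor at any realistic step
        errors = []
        for step in (4.0, 2.0, 1.0):
            donor, eps, oracle = generate_overlap_pair(
                donor_center_nm=340, donor_sigma_nm=2.5,
                acceptor_center_nm=336, acceptor_sigma_nm=2.5,
                grid_step_nm=step)
            j = overlap_integral(donor, eps, donor.range_nm)
            errors.append(abs(j.j_nm4_M_inv_cm_inv / oracle - 1.0))
        assert errors[0] > errors[1] > errors[2]
        # at least second-order convergence per halving
        assert errors[1] / errors[2] > 3.0

    def test_disjoint_range_raises_window_error(self, gaussian_spectrum):
        donor = gaussian_spectrum(340, 15, lo=300, hi=400)
        eps = gaussian_spectrum(330, 12, kind="molar_absorptivity",
                                lo=300, hi=400)
        with pytest.raises(WindowError):
            overlap_integral(donor, eps, (500, 600))

    def test_all_zero_donor_raises(self, gaussian_spectrum):
        eps = gaussian_spectrum(330, 12, kind="molar_absorptivity")
        donor = Spectrum(eps.wavelengths_nm, np.zeros(len(eps)), "emission")
        with pytest.raises(DomainError):
            overlap_integral(donor, eps, (300, 400))

    def test_absorbance_acceptor_rejected(self, gaussian_spectrum):
        donor = gaussian_spectrum(340, 15)
        absorb = gaussian_spectrum(330, 12, kind="absorbance")
        with pytest.raises(DomainError, match="molar absorptivity"):
            overlap_integral(donor, absorb, (300, 400))


class TestForsterRadius:
    def test_zero_overlap_gives_zero_radius(self):
        assert forster_radius(0.0) == 0.0

    def test_value_for_tabulated_overlap_integral(self):
        # direct evaluation of the R0^6 relation with the 1e-28 conversion
        assert forster_radius(2.11e13) == pytest.approx(1.9687, abs=2e-3)

    def test_sixth_root_homogeneity(self):
        j = 3.3e12
        assert forster_radius(64 * j) == pytest.approx(2 * forster_radius(j),
                                                       rel=1e-12)

    def test_negative_overlap_rejected(self):
        with pytest.raises(DomainError):
            forster_radius(-1.0)


class TestEfficiencyAndDistance:
    def test_no_quenching_means_zero_efficiency(self):
        assert efficiency_from_intensity(100.0, 100.0) == 0.0

    @pytest.mark.parametrize("frac,expected", [(0.29, 0.71), (0.38, 0.62)])
    def test_intensity_ratio_maps_to_efficiency(self, frac, expected):
        assert efficiency_from_intensity(frac * 1000, 1000) == \
            pytest.approx(expected)

    def test_f_larger_than_f0_rejected(self):
        with pytest.raises(DomainError):
            efficiency_from_intensity(101.0, 100.0)

    def test_efficiency_is_half_at_the_forster_radius(self):
        assert efficiency_from_distance(1.89, 1.89) == 0.5

    def test_efficiency_tends_to_one_at_contact(self):
        assert efficiency_from_distance(1e-6, 1.89) == pytest.approx(1.0)

    def test_distance_at_half_efficiency_is_r0(self):
        assert distance_from_efficiency(0.5, 1.89) == pytest.approx(1.89)

    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_distance_efficiency_round_trip(self, r):
        r0 = 1.89
        e = efficiency_from_distance(r, r0)
        assert distance_from_efficiency(e, r0) == pytest.approx(r,
                                                                rel=1e-12)

    @given(r=st.floats(0.05, 20.0), r0=st.floats(0.5, 10.0))
    def test_efficiency_strictly_decreasing_in_distance(self, r, r0):
        assert efficiency_from_distance(r * 1.01, r0) < \
            efficiency_from_distance(r, r0)
        assert 0 < efficiency_from_distance(r, r0) < 1

    @pytest.mark.parametrize("e", [0.0, 1.0])
    def test_degenerate_efficiencies_rejected(self, e):
        with pytest.raises(DomainError):
            distance_from_efficiency(e, 1.89)


class TestForsterWindow:
    def test_reported_distances_fall_inside_the_window(self):
        assert forster_window_check(1.43, 1.89)
        assert forster_window_check(1.51, 1.89)

    def test_boundaries_are_strict(self):
        assert not forster_window_check(0.5 * 1.89, 1.89)
        assert not forster_window_check(1.5 * 1.89, 1.89)

    def test_far_outside_is_false(self):
        assert not forster_window_check(3 * 1.89, 1.89)


class TestFretAnalysis:
    def test_full_chain_is_consistent(self):
        donor, eps, _ = generate_overlap_pair()
        res = fret_analysis(donor, eps, f=290.0, f0=1000.0,
                            range_nm=(265, 415))
        assert res.efficiency == pytest.approx(0.71)
        assert res.j_cm3_M_inv == pytest.approx(
            res.j_nm4_M_inv_cm_inv * 1e-28, rel=1e-15)
        # r back-computed from E and R0 closes the loop
        assert efficiency_from_distance(res.r_nm, res.r0_nm) == \
            pytest.approx(res.efficiency, rel=1e-12)
        assert res.forster_window_ok == forster_window_check(res.r_nm,
                                                             res.r0_nm)

    def test_r0_invariant_to_donor_intensity_units(self):
        donor, eps, _ = generate_overlap_pair()
        res1 = fret_analysis(donor, eps, 290.0, 1000.0, range_nm=(265, 415))
        res2 = fret_analysis(donor.with_signal(donor.signal * 1e3), eps,
                             290.0, 1000.0, range_nm=(265, 415))
        assert res2.r0_nm == pytest.approx(res1.r0_nm, rel=1e-12)


def test_fret_config_validation():
    with pytest.raises(DomainError):
        FretConfig(kappa_squared=5.0)
    with pytest.raises(DomainError):
        FretConfig(refractive_index=0.9)
    with pytest.raises(DomainError):
        FretConfig(quantum_yield=0.0)
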