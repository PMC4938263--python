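import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from specbind import (ConfigurationError, DomainError, InsufficientDataError,
                      TitrationSeries, classify_mechanism,
                      displacement_analysis, modified_sv_fit, read_titration,
                      stern_volmer_fit, write_titration)

from conftest import ols_oracle

Q_GRID = np.arange(0, 55e-6, 5e-6)


def linear_quench_series(ksv, f0=1000.0, q=Q_GRID, **meta):
    """Noiseless series following F = F0 / (1 + Ksv [Q])."""
    f = f0 / (1.0 + ksv * q)
    return TitrationSeries(q, f, f0, **meta)


def binding_series(kb, n, f0=1000.0, q=Q_GRID):
    """Noiseless static-quenching series with F0/F − 1 = Kb [Q]^n."""
    with np.errstate(divide="ignore"):
        ratio = np.where(q > 0, kb * q**n, 0.0)
    return TitrationSeries(q, f0 / (1.0 + ratio), f0)


class TestTitrationSeries:
    def test_zero_point_must_match_f0(self):
        with pytest.raises(DomainError, match="f0"):
            TitrationSeries(Q_GRID, np.full(Q_GRID.size, 900.0), 1000.0)

    def test_non_increasing_q_rejected(self):
        with pytest.raises(DomainError):
            TitrationSeries([0, 1e-5, 1e-5], [100, 90, 80], 100)

    def test_round_trip_through_file(self, tmp_path):
        series = linear_quench_series(5.03e4, temperature_K=298.0)
        path = tmp_path / "titration.csv"
        write_titration(series, path)
        back = read_titration(path, temperature_K=298.0)
        np.testing.assert_allclose(back.q_M, series.q_M)
        np.testing.assert_allclose(back.f_au, series.f_au, rtol=1e-8)


class TestSternVolmerFit:
    def test_recovers_printed_hsa_constant_from_noiseless_data(self):
        fit = stern_volmer_fit(linear_quench_series(5.03e4))
        assert fit.ksv_M_inv == pytest.approx(5.03e4, rel=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.kq_M_inv_s_inv == pytest.approx(5.03e13, rel=1e-12)
        assert not fit.intercept_flagged
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_fluorescence_gives_zero_ksv(self):
        series = TitrationSeries(Q_GRID, np.full(Q_GRID.size, 1000.0), 1000.0)
        fit = stern_volmer_fit(series)
        assert fit.ksv_M_inv == pytest.approx(0.0, abs=1e-6)

    def test_two_point_series_is_insufficient(self):
        series = TitrationSeries([0, 5e-6, 1e-5], [1000, 900, 800], 1000)
        with pytest.raises(InsufficientDataError):
            stern_volmer_fit(series)

    def test_agrees_with_exact_normal_equations_oracle(self):
        series = linear_quench_series(3.2e4)
        fit = stern_volmer_fit(series)
        mask = series.q_M > 0
        slope, intercept = ols_oracle(series.q_M[mask],
                                      series.f0 / series.f_au[mask])
        assert fit.ksv_M_inv == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)

    @given(tau0=st.floats(1e-10, 1e-7))
    def test_kq_over_ksv_is_exactly_inverse_lifetime(self, tau0):
        fit = stern_volmer_fit(linear_quench_series(2.3e4), tau0_s=tau0)
        assert fit.kq_M_inv_s_inv * tau0 == pytest.approx(fit.ksv_M_inv,
                                                          rel=1e-15)


class TestModifiedSvFit:
    def test_recovers_kb_and_n_to_machine_precision(self):
        fit = modified_sv_fit(binding_series(3.14e5, 1.1))
        assert fit.kb_M_inv == pytest.approx(3.14e5, rel=1e-9)
        assert fit.n_sites == pytest.approx(1.1, rel=1e-12)
        assert fit.kb_M_inv == pytest.approx(10**fit.log10_kb, rel=1e-15)

    def test_agrees_with_exact_normal_equations_oracle(self):
        series = binding_series(3.14e5, 1.1)
        fit = modified_sv_fit(series)
        mask = series.q_M > 0
        slope, intercept = ols_oracle(
            np.log10(series.q_M[mask]),
            np.log10(series.f0 / series.f_au[mask] - 1))
        assert fit.n_sites == pytest.approx(slope, rel=1e-9)
        assert fit.log10_kb == pytest.approx(intercept, rel=1e-9)

    def test_doubling_concentrations_shifts_log_ratio_by_log2(self):
        kb, f0 = 1e3, 1000.0
        s1 = binding_series(kb, 1.0, q=Q_GRID)
        s2 = binding_series(kb, 1.0, q=2 * Q_GRID)
        r1 = np.log10(f0 / s1.f_au[1:] - 1)
        r2 = np.log10(f0 / s2.f_au[1:] - 1)
        np.testing.assert_allclose(r2 - r1, np.log10(2), rtol=1e-9)

    def test_unquenched_point_is_excluded_and_recorded(self):
        f = 1000.0 / (1.0 + 2e5 * Q_GRID)
        f[1] = 1000.0  # first titration point shows no quenching
        series = TitrationSeries(Q_GRID, f, 1000.0)
        fit = modified_sv_fit(series)
        assert fit.excluded_points == (1,)
        assert fit.n_points_used == Q_GRID.size - 2

    def test_too_few_surviving_points_is_insufficient(self):
        q = np.array([0, 5e-6, 1e-5, 1.5e-5])
        f = np.array([1000.0, 1000.0, 1000.0, 900.0])
        with pytest.raises(InsufficientDataError):
            modified_sv_fit(TitrationSeries(q, f, 1000.0))

    def test_coincides_with_stern_volmer_when_n_is_one(self):
        """With a single site the two linearisations are the same model."""
        series = linear_quench_series(7.7e4)
        sv = stern_volmer_fit(series)
        binding = modified_sv_fit(series)
        assert binding.kb_M_inv == pytest.approx(sv.ksv_M_inv, rel=1e-6)
        assert binding.n_sites == pytest.approx(1.0, rel=1e-9)


class TestMechanismClassifier:
    def _fits(self, ksvs, tau0=1e-9):
        return [stern_volmer_fit(linear_quench_series(k), tau0_s=tau0)
                for k in ksvs]

    def test_decreasing_ksv_with_high_kq_is_static(self):
        fits = self._fits([5.03e4, 3.20e4, 2.30e4])
        call = classify_mechanism(fits, [298, 303, 310])
        assert call.call == "static"
        assert call.ksv_temperature_trend == "decreasing"
        assert call.kq_exceeds_diffusion_limit

    def test_increasing_ksv_with_low_kq_is_dynamic(self):
        # kq below the diffusion limit needs a long lifetime
        fits = self._fits([1e2, 2e2, 3e2], tau0=1e-7)
        call = classify_mechanism(fits, [298, 303, 310])
        assert call.call == "dynamic"

    def test_mixed_evidence_is_ambiguous(self):
        fits = self._fits([3e2, 2e2, 1e2], tau0=1e-7)  # decreasing, low kq
        assert classify_mechanism(fits, [298, 303, 310]).call == "ambiguous"

    def test_duplicate_temperatures_rejected(self):
        fits = self._fits([5e4, 3e4])
        with pytest.raises(DomainError):
            classify_mechanism(fits, [298, 298])


class TestDisplacement:
    SITE_MAP = {"WAR": "site I", "PBZ": "site I", "DIA": "site II"}

    def _report(self, ksv_free, marker_ksv):
        free = stern_volmer_fit(linear_quench_series(ksv_free))
        markers = {m: stern_volmer_fit(linear_quench_series(k))
                   for m, k in marker_ksv.items()}
        return displacement_analysis(free, markers, self.SITE_MAP)

    def test_diazepam_displacement_calls_site_two_primary(self):
        rep = self._report(5.03e4,
                           {"DIA": 6.3e3, "PBZ": 1.20e4, "WAR": 1.7e4})
        assert rep.primary_site_call == "site II"
        assert rep.primary_marker == "DIA"
        # frozen arithmetic: 1 − ksv_with/ksv_free on the marker constants
        decreases = {m: d["fractional_decrease"]
                     for m, d in rep.markers.items()}
        assert decreases["DIA"] == pytest.approx(0.8748, abs=5e-4)
        assert decreases["PBZ"] == pytest.approx(0.7614, abs=5e-4)
        assert decreases["WAR"] == pytest.approx(0.6620, abs=5e-4)
        assert rep.secondary_sites == ("site I",)

    def test_no_competition_yields_no_call(self):
        rep = self._report(5.0e4, {"DIA": 5.0e4, "WAR": 5.0e4})
        assert rep.primary_site_call == "none"
        for d in rep.markers.values():
            assert d["fractional_decrease"] == pytest.approx(0.0, abs=1e-9)

    def test_single_marker_is_the_primary_call(self):
        rep = self._report(5.0e4, {"WAR": 5.0e3})
        assert rep.primary_site_call == "site I"
        assert rep.primary_marker == "WAR"

    def test_marker_missing_from_site_map_is_configuration_error(self):
        free = stern_volmer_fit(linear_quench_series(5e4))
        other = stern_volmer_fit(linear_quench_series(1e4))
        with pytest.raises(ConfigurationError):
            displacement_analysis(free, {"XYZ": other}, self.SITE_MAP)
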