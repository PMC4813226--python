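"""(ratio)_A efficiencies, overlap integrals, Förster radii and geometry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ionfold.binding_models import TitrationSeries
from ionfold.exceptions import (
    AcceptorSignalAbsentError,
    EfficiencyRangeError,
    GeometryError,
    GridMismatchError,
    IncompatibleSpectraError,
    InvalidLabelingFractionError,
    InvalidPhotophysicsError,
)
from ionfold.fret_core import (
    FORSTER_PREFACTOR_A6,
    DyePhotophysics,
    ForsterParams,
    JunctionGeometry,
    Spectrum,
    SpectrumRole,
    distance_from_efficiency,
    donor_normalize,
    efficiency_from_distance,
    efficiency_from_ratio_a,
    forster_radius,
    interduplex_angle,
    overlap_integral,
    ratio_a,
    ratio_a_from_efficiency,
)


class TestRatioA:
    def test_identical_spectra_give_unity(self, gaussian_spectrum_factory):
        s = gaussian_spectrum_factory(600, 20, 100, 570, 700)
        assert ratio_a(s, s) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("scale,expected", [(0.5, 0.5), (1.2, 1.2)])
    def test_amplitude_scaling(self, gaussian_spectrum_factory, scale, expected):
        # two bands with the same center/width: the ratio is the amplitude ratio
        a = gaussian_spectrum_factory(600, 15, 100 * scale, 540, 700)
        b = gaussian_spectrum_factory(600, 15, 100, 540, 700)
        band = (600 - 30, 600 + 30)  # center +/- 2 sigma
        assert ratio_a(a, b, band) == pytest.approx(expected, rel=1e-12)

    def test_scaled_gaussian_matches_quadrature_oracle(self):
        # independent oracle: dense-grid trapezoid of each band separately
        wl = np.arange(540.0, 700.0, 2.0)
        dense = np.arange(560.0, 640.0001, 0.001)
        f = lambda x, amp: amp * np.exp(-0.5 * ((x - 600.0) / 15.0) ** 2)
        oracle = np.trapezoid(f(dense, 120.0), dense) / np.trapezoid(f(dense, 100.0), dense)
        got = ratio_a(
            Spectrum(wl, f(wl, 120.0)), Spectrum(wl, f(wl, 100.0)), (560, 640)
        )
        assert got == pytest.approx(oracle, rel=1e-6)
        assert got == pytest.approx(1.2, rel=1e-9)

    def test_zero_acceptor_signal_raises(self, gaussian_spectrum_factory):
        s = gaussian_spectrum_factory(600, 20, 100, 570, 700)
        zero = Spectrum(s.wavelength_nm, np.zeros_like(s.intensity))
        with pytest.raises(AcceptorSignalAbsentError):
            ratio_a(s, zero)

    def test_band_outside_spectrum_raises(self, gaussian_spectrum_factory):
        s = gaussian_spectrum_factory(600, 20, 100, 580, 650)
        with pytest.raises(IncompatibleSpectraError):
            ratio_a(s, s, band=(570, 700))


class TestEfficiencyFromRatioA:
    def test_direct_excitation_only_gives_zero(self):
        dyes = DyePhotophysics(eps_acceptor_at_donor_ex=20_000.0,
                               fraction_donor_labeled=0.8)
        r = dyes.eps_acceptor_at_donor_ex / dyes.eps_acceptor_at_acceptor_ex
        assert efficiency_from_ratio_a(r, dyes) == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluated_value(self, dyes):
        # r = 0.1, eps_A(dEx) = 0, f_D = 1: E = 0.1 * 89100/78000
        assert efficiency_from_ratio_a(0.1, dyes) == pytest.approx(0.11423, abs=5e-6)

    def test_round_trip_through_inverse(self, dyes):
        # low initial-state efficiency typical of the open junction
        for e in (0.05, 0.35):
            r = ratio_a_from_efficiency(e, dyes)
            assert efficiency_from_ratio_a(r, dyes) == pytest.approx(e, rel=1e-12)

    @given(st.floats(0.0, 3.0), st.floats(0.0, 3.0))
    def test_affine_in_ratio_with_known_slope(self, r1, r2):
        dyes = DyePhotophysics(eps_acceptor_at_donor_ex=15_000.0,
                               fraction_donor_labeled=0.9)
        slope = dyes.eps_acceptor_at_acceptor_ex / (
            dyes.fraction_donor_labeled * dyes.eps_donor_at_donor_ex
        )
        de = efficiency_from_ratio_a(r2, dyes) - efficiency_from_ratio_a(r1, dyes)
        assert de == pytest.approx(slope * (r2 - r1), rel=1e-9, abs=1e-12)

    def test_invalid_labeling_fraction_raises(self):
        with pytest.raises(InvalidLabelingFractionError):
            DyePhotophysics(fraction_donor_labeled=0.0)


class TestDonorNormalize:
    @staticmethod
    def _series(values, conc=None):
        conc = np.logspace(-6, -3, len(values)) if conc is None else conc
        return TitrationSeries(concentration_M=conc, signal=np.asarray(values, float))

    def test_constant_donor_leaves_series_unchanged(self):
        s = self._series([1.0, 1.2, 1.5, 1.9, 2.0])
        donor = self._series([7.0] * 5)
        np.testing.assert_allclose(donor_normalize(s, donor).signal, s.signal)

    def test_uniform_donor_loss_divides_out(self):
        s = self._series([1.0, 1.2, 1.5, 1.9, 2.0])
        donor = self._series([10.0, 9.0, 9.0, 9.0, 9.0])
        out = donor_normalize(s, donor)
        np.testing.assert_allclose(out.signal[1:], s.signal[1:] / 0.9, rtol=1e-14)
        assert out.signal[0] == s.signal[0]

    def test_linear_bleach_correction_recovers_clean_curve(self):
        # 5% linear donor bleach across the titration, imposed then divided out
        conc = np.logspace(-6, -3, 12)
        clean = 0.05 + 0.3 * conc / (22e-6 + conc)
        bleach = np.linspace(1.0, 0.95, 12)
        observed = self._series(clean * bleach, conc)
        donor = self._series(100.0 * bleach, conc)
        np.testing.assert_allclose(
            donor_normalize(observed, donor).signal, clean, rtol=1e-12
        )

    def test_mismatched_grids_raise(self):
        s = self._series([1, 2, 3, 4, 5.0])
        donor = self._series([1, 2, 3, 4, 5.0], conc=np.logspace(-5, -2, 5))
        with pytest.raises(GridMismatchError):
            donor_normalize(s, donor)


class TestOverlapIntegral:
    def test_zero_extinction_gives_zero(self, gaussian_spectrum_factory):
        donor = gaussian_spectrum_factory(520, 15, 100, 480, 600)
        acc = Spectrum(donor.wavelength_nm, np.zeros_like(donor.intensity),
                       SpectrumRole.ACCEPTOR_ABSORPTION)
        assert overlap_integral(donor, acc) == 0.0

    def test_delta_like_donor_limit(self):
        # very narrow donor band at 550 nm against flat extinction eps0
        wl = np.arange(500.0, 600.0001, 0.01)
        donor = Spectrum(wl, np.exp(-0.5 * ((wl - 550.0) / 0.05) ** 2))
        acc = Spectrum(wl, np.full_like(wl, 89_100.0),
                       SpectrumRole.ACCEPTOR_ABSORPTION)
        assert overlap_integral(donor, acc) == pytest.approx(
            89_100.0 * 550.0**4, rel=1e-5
        )

    def test_converges_under_grid_refinement(self):
        def make(step):
            wl = np.arange(450.0, 700.0 + step, step)
            donor = Spectrum(wl, 100 * np.exp(-0.5 * ((wl - 520) / 15) ** 2))
            acc = Spectrum(wl, 89_100 * np.exp(-0.5 * ((wl - 555) / 15) ** 2),
                           SpectrumRole.ACCEPTOR_ABSORPTION)
            return overlap_integral(donor, acc)

        coarse, fine, dense = make(2.0), make(1.0), make(0.05)
        assert abs(fine - coarse) / dense < 1e-3
        assert abs(fine - dense) / dense < 1e-3

    def test_disjoint_ranges_warn_and_return_zero(self, gaussian_spectrum_factory):
        donor = gaussian_spectrum_factory(520, 10, 100, 500, 540)
        acc = gaussian_spectrum_factory(600, 10, 89_100, 560, 650,
                                        role=SpectrumRole.ACCEPTOR_ABSORPTION)
        with pytest.warns(UserWarning):
            assert overlap_integral(donor, acc) == 0.0


class TestForsterRadius:
    def test_sixth_root_scaling_in_quantum_yield(self):
        base = ForsterParams(overlap_integral_J=1e15, donor_quantum_yield=0.4)
        doubled = ForsterParams(overlap_integral_J=1e15, donor_quantum_yield=0.8)
        assert forster_radius(doubled) / forster_radius(base) == pytest.approx(
            2 ** (1 / 6), rel=1e-12
        )

    def test_algebraic_identity_r0_sixth(self):
        fp = ForsterParams(overlap_integral_J=3.2e15, donor_quantum_yield=0.6,
                           kappa_squared=2 / 3, refractive_index=1.4)
        r0 = forster_radius(fp)
        expected = (FORSTER_PREFACTOR_A6 * fp.kappa_squared
                    * fp.refractive_index**-4 * fp.donor_quantum_yield
                    * fp.overlap_integral_J)
        assert r0**6 == pytest.approx(expected, rel=1e-9)

    def test_depends_only_on_product_of_factors(self):
        # swap factors between kappa^2 and Q_D keeping the product fixed
        a = ForsterParams(overlap_integral_J=1e15, donor_quantum_yield=0.9,
                          kappa_squared=0.3, refractive_index=1.33)
        b = ForsterParams(overlap_integral_J=1e15, donor_quantum_yield=0.3,
                          kappa_squared=0.9, refractive_index=1.33)
        assert forster_radius(a) == pytest.approx(forster_radius(b), rel=1e-12)

    def test_round_trip_through_50_A(self):
        # solve J for R0 = 50 A, then recompute
        fp0 = ForsterParams(overlap_integral_J=1.0, donor_quantum_yield=0.6)
        j = (50.0 / forster_radius(fp0)) ** 6
        fp = ForsterParams(overlap_integral_J=j, donor_quantum_yield=0.6)
        assert forster_radius(fp) == pytest.approx(50.0, rel=1e-12)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(InvalidPhotophysicsError):
            forster_radius(ForsterParams(overlap_integral_J=0.0,
                                         donor_quantum_yield=0.5))


class TestDistanceFromEfficiency:
    def test_half_transfer_at_forster_radius(self):
        assert distance_from_efficiency(0.5, 50.0, 1.0) == pytest.approx(50.0)

    def test_conformer_corrected_hand_value(self):
        # E_obs 0.35 with 77% folded-conformer population: E_corr = 0.4545
        assert distance_from_efficiency(0.35, 50.0, 0.77) == pytest.approx(
            51.5, abs=0.05
        )

    def test_observed_efficiency_window_maps_into_50_60_A(self):
        for e_obs in np.linspace(0.25, 0.35, 7):
            r = distance_from_efficiency(float(e_obs), 50.0, 0.77)
            assert 50.0 <= r <= 60.0

    @given(st.floats(0.011, 0.989))
    def test_inverse_of_forward_map(self, frac):
        r0, f = 50.0, 0.77
        e_obs = frac * f
        r = distance_from_efficiency(e_obs, r0, f)
        assert efficiency_from_distance(r, r0, f) == pytest.approx(e_obs, rel=1e-9)

    def test_out_of_range_raises_unless_clamped(self):
        with pytest.raises(EfficiencyRangeError):
            distance_from_efficiency(0.8, 50.0, 0.77)
        assert distance_from_efficiency(0.8, 50.0, 0.77, clamp=True) > 0


class TestInterduplexAngle:
    def test_equilateral_gives_60_degrees(self):
        geom = JunctionGeometry()
        assert interduplex_angle(geom.arm_length_A, geom) == pytest.approx(60.0)

    def test_right_angle_at_sqrt2(self):
        geom = JunctionGeometry()
        assert interduplex_angle(geom.arm_length_A * np.sqrt(2), geom) == pytest.approx(90.0)

    def test_17bp_arms_at_50_A(self):
        # a = b = 17 bp x 3.4 A = 57.8 A
        assert interduplex_angle(50.0, JunctionGeometry()) == pytest.approx(51.3, abs=0.05)

    @given(st.floats(1.0, 114.0))
    def test_strictly_increasing_in_separation(self, c):
        geom = JunctionGeometry()
        lo = max(c, 1.0)
        hi = min(lo + 1.0, 2 * geom.arm_length_A - 1e-6)
        if hi <= lo:
            return
        assert interduplex_angle(hi, geom) > interduplex_angle(lo, geom)

    def test_triangle_violation_raises(self):
        with pytest.raises(GeometryError):
            interduplex_angle(120.0, JunctionGeometry())


class TestSpectrumValidation:
    def test_rejects_non_monotone_grid(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([500.0, 499.0, 501.0]), np.ones(3))

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([500.0, 501.0]), np.array([1.0, -0.1]))
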