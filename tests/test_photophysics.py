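import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecmfluor.photophysics import (
    AcquisitionSettings,
    Spectrum,
    contrast_dff,
    excitation_coefficient,
    renormalize_emission,
    signal_at_settings,
)
from ecmfluor.synthetic import make_default_dye


class TestSpectrum:
    def test_validation(self):
        with pytest.raises(ValueError):
            Spectrum([500.0, 499.0, 501.0], [1.0, 1.0, 1.0], "emission")
        with pytest.raises(ValueError):
            Spectrum([500.0, 501.0], [1.0, -0.1], "emission")
        with pytest.raises(TypeError):
            Spectrum([500.0, 501.0], [1.0, 1.0], "fluorescence")

    def test_interpolation_is_linear_and_bounded(self):
        s = Spectrum([500.0, 510.0], [0.0, 1.0], "absorbance")
        assert s.value_at(505.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            s.value_at(499.0)
        with pytest.raises(ValueError):
            s.value_at(511.0)

    def test_longpass_band_integrates_to_grid_end(self):
        w = np.linspace(500, 600, 101)
        s = Spectrum(w, np.ones_like(w), "emission")
        assert s.integrate_band(550.0, None) == pytest.approx(50.0)
        assert s.integrate_band(550.0, 1e9) == pytest.approx(50.0)
        assert s.integrate_band(650.0, None) == 0.0


class TestExcitationCoefficient:
    @pytest.mark.parametrize(
        "phi,a,expected",
        [
            (1.0, 0.0, 0.0),  # no absorption, no excitation
            (0.5, 1.0, 0.45),
            (0.9, 2.0, 0.891),
        ],
    )
    def test_hand_evaluated_values(self, phi, a, expected):
        assert excitation_coefficient(phi, a) == pytest.approx(expected, abs=1e-12)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            excitation_coefficient(-0.1, 1.0)
        with pytest.raises(ValueError):
            excitation_coefficient(1.5, 1.0)
        with pytest.raises(ValueError):
            excitation_coefficient(0.5, -1.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        phi=st.floats(0.0, 1.0),
        a1=st.floats(0.0, 5.0),
        a2=st.floats(0.0, 5.0),
    )
    def test_monotone_in_absorbance_and_bounded_by_phi(self, phi, a1, a2):
        lo, hi = sorted((a1, a2))
        e_lo = excitation_coefficient(phi, lo)
        e_hi = excitation_coefficient(phi, hi)
        assert 0.0 <= e_lo <= e_hi <= phi

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(p1=st.floats(0.0, 1.0), p2=st.floats(0.0, 1.0), a=st.floats(0.0, 5.0))
    def test_monotone_in_quantum_yield(self, p1, p2, a):
        lo, hi = sorted((p1, p2))
        assert excitation_coefficient(lo, a) <= excitation_coefficient(hi, a)


class TestRenormalizeEmission:
    def setup_method(self):
        w = np.linspace(550, 650, 201)
        self.em = Spectrum(w, np.exp(-0.5 * ((w - 590) / 15) ** 2), "emission")

    def test_zero_absorbance_gives_zero_spectrum(self):
        out = renormalize_emission(self.em, 0.8, 0.0)
        assert np.all(out.values == 0.0)

    def test_scaling_is_uniform_and_equals_coefficient(self):
        out = renormalize_emission(self.em, 0.5, 1.0)
        ratio = out.values / self.em.values
        assert np.allclose(ratio, 0.45)

    def test_pointwise_monotone_in_absorbance(self):
        hi = renormalize_emission(self.em, 0.5, 2.0)
        lo = renormalize_emission(self.em, 0.5, 0.3)
        assert np.all(hi.values >= lo.values)

    def test_rejects_wrong_kind(self):
        absorb = Spectrum([500.0, 600.0], [0.1, 0.2], "absorbance")
        with pytest.raises(TypeError):
            renormalize_emission(absorb, 0.5, 1.0)


class TestMixtureSignal:
    def test_endpoints_and_midpoint(self, default_dye, red_settings):
        s0 = signal_at_settings(default_dye, 0.0, red_settings)
        s1 = signal_at_settings(default_dye, 1.0, red_settings)
        s_half = signal_at_settings(default_dye, 0.5, red_settings)
        assert s_half == pytest.approx(0.5 * (s0 + s1), rel=1e-12)
        assert s1 > s0 > 0

    def test_affine_in_fraction_bound(self, default_dye, red_settings):
        s0 = signal_at_settings(default_dye, 0.0, red_settings)
        s1 = signal_at_settings(default_dye, 1.0, red_settings)
        for f in np.linspace(0, 1, 11):
            expected = s0 + f * (s1 - s0)
            assert signal_at_settings(default_dye, f, red_settings) == pytest.approx(
                expected, rel=1e-12
            )

    def test_fraction_outside_unit_interval_rejected(self, default_dye, red_settings):
        with pytest.raises(ValueError):
            signal_at_settings(default_dye, -0.01, red_settings)
        with pytest.raises(ValueError):
            signal_at_settings(default_dye, 1.01, red_settings)


class TestContrast:
    @pytest.mark.parametrize(
        "bound,unbound,expected",
        [(5.0, 5.0, 0.0), (8.3, 1.0, 7.3), (1.0, 2.0, -0.5)],
    )
    def test_arithmetic(self, bound, unbound, expected):
        assert contrast_dff(bound, unbound) == pytest.approx(expected)

    def test_nonpositive_unbound_rejected(self):
        with pytest.raises(ValueError):
            contrast_dff(1.0, 0.0)
        with pytest.raises(ValueError):
            contrast_dff(1.0, -1.0)

    def test_default_dye_reproduces_configured_contrast(self, default_dye, red_settings):
        """The generator dye round-trips its configured dF/F of 7.3 at 561/575LP."""
        bound = signal_at_settings(default_dye, 1.0, red_settings)
        unbound = signal_at_settings(default_dye, 0.0, red_settings)
        assert contrast_dff(bound, unbound) == pytest.approx(7.3, rel=0.01)

    def test_red_excitation_beats_green_for_contrast(
        self, default_dye, red_settings, green_settings
    ):
        """Longer-wavelength excitation preferentially excites the red-shifted
        bound state, so 561/575LP contrast exceeds 488/500-545 contrast."""
        dff_red = contrast_dff(
            signal_at_settings(default_dye, 1.0, red_settings),
            signal_at_settings(default_dye, 0.0, red_settings),
        )
        dff_green = contrast_dff(
            signal_at_settings(default_dye, 1.0, green_settings),
            signal_at_settings(default_dye, 0.0, green_settings),
        )
        assert dff_red > dff_green


class TestDefaultDyeConstruction:
    def test_red_shifts_on_half_nm_grid(self, default_dye):
        shift_abs = default_dye.bound.absorbance.peak_nm - default_dye.unbound.absorbance.peak_nm
        shift_em = default_dye.bound.emission.peak_nm - default_dye.unbound.emission.peak_nm
        assert shift_abs == pytest.approx(13.0, abs=1e-9)
        assert shift_em == pytest.approx(14.0, abs=1e-9)

    def test_zero_target_contrast_equalizes_signals(self, red_settings):
        dye = make_default_dye(target_contrast=0.0)
        s0 = signal_at_settings(dye, 0.0, red_settings)
        s1 = signal_at_settings(dye, 1.0, red_settings)
        assert s1 == pytest.approx(s0, rel=1e-9)

    def test_unreachable_contrast_raises(self):
        with pytest.raises(ValueError):
            make_default_dye(target_contrast=-1.5)
        with pytest.raises(ValueError):
            # detection band entirely beyond the stored emission grid
            make_default_dye(
                settings=AcquisitionSettings(excitation_nm=561.0, emission_band=(705.0, 720.0))
            )
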