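"""SLR design, multiband synthesis, RF spoiling, and the Bloch oracle."""

import math

import numpy as np
import pytest

from smsepi.events import SystemLimits
from smsepi.rf import (
    PulseShape,
    SLRSpec,
    SMSSpec,
    bloch_simulate,
    count_bands,
    design_slr_pulse,
    design_slr_rf,
    default_fatsat_spec,
    forward_slr,
    inverse_slr,
    make_fatsat_pulse,
    optimize_band_phases,
    profile_fwhm,
    rf_spoiling_phase,
    synthesize_sms_pulse,
)
from smsepi.units import GAMMA_HZ_PER_T

THICKNESS = 2.4e-3


@pytest.fixture(scope="module")
def ex_spec():
    return SLRSpec(duration=3.2e-3, time_bandwidth=4, flip_angle=math.pi / 2)


@pytest.fixture(scope="module")
def ex_pulse(ex_spec, limits):
    return design_slr_pulse(ex_spec, THICKNESS, limits)


def _profile(pulse, grad_amp, z):
    g = np.full(pulse.samples.size, grad_amp)
    M = bloch_simulate(pulse, g, positions=z)
    return M[:, 0] + 1j * M[:, 1]


class TestBlochOracle:
    def test_zero_rf_leaves_magnetization_unchanged(self):
        M = bloch_simulate(np.zeros(50, complex), raster=1e-5,
                           positions=np.linspace(-0.01, 0.01, 11))
        assert np.allclose(M, [0, 0, 1])

    @pytest.mark.parametrize("flip_deg", [10, 45, 90, 150])
    def test_constant_pulse_gives_closed_form_flip(self, flip_deg):
        alpha = math.radians(flip_deg)
        n, dt = 200, 5e-6
        b1 = np.full(n, alpha / (2 * np.pi * n * dt), dtype=complex)
        M = bloch_simulate(b1, raster=dt)
        assert M[0, 2] == pytest.approx(math.cos(alpha), abs=1e-6)

    def test_magnetization_magnitude_conserved(self, ex_pulse):
        pulse, grad = ex_pulse
        z = np.linspace(-0.01, 0.01, 101)
        M = bloch_simulate(pulse, np.full(pulse.samples.size, grad.amplitude), z)
        assert np.abs(np.linalg.norm(M, axis=1) - 1).max() < 1e-9

    def test_small_tip_profile_is_fourier_transform_of_envelope(self, limits):
        spec = SLRSpec(duration=3.2e-3, time_bandwidth=4,
                       flip_angle=math.radians(5))
        pulse = design_slr_rf(spec, limits)
        n = pulse.samples.size
        freqs = np.linspace(-2 * spec.bandwidth, 2 * spec.bandwidth, 201)
        prof = np.array([
            bloch_simulate(pulse, off_resonance=f)[0] for f in freqs
        ])
        mxy = np.abs(prof[:, 0] + 1j * prof[:, 1])
        ft = np.abs(
            np.exp(-2j * np.pi * np.outer(freqs, pulse.t)) @ pulse.samples
        )
        corr = np.corrcoef(mxy, ft)[0, 1]
        assert corr > 0.99

    def test_mismatched_waveform_lengths_error(self):
        with pytest.raises(ValueError, match="lengths differ"):
            bloch_simulate(np.zeros(10, complex), grad=np.zeros(9), raster=1e-5)


class TestSLRTransform:
    def test_forward_inverse_roundtrip(self):
        rng = np.random.default_rng(3)
        rf = 0.2 * (rng.standard_normal(48) + 1j * rng.standard_normal(48))
        a, b = forward_slr(rf)
        assert np.abs(inverse_slr(a, b) - rf).max() < 1e-12

    def test_unitarity_of_forward_transform(self):
        rng = np.random.default_rng(4)
        rf = 0.3 * rng.standard_normal(32).astype(complex)
        a, b = forward_slr(rf)
        # |A|^2 + |B|^2 = 1 on the unit circle
        w = np.exp(2j * np.pi * np.linspace(0, 1, 64, endpoint=False))
        A = np.polyval(a[::-1], 1 / w) * 1.0
        B = np.polyval(b[::-1], 1 / w)
        assert np.abs(np.abs(A) ** 2 + np.abs(B) ** 2 - 1).max() < 1e-9


class TestSLRDesign:
    @pytest.mark.parametrize("ftype", ["linear_phase", "minimum_phase"])
    def test_slice_profile_fwhm_within_5_percent(self, limits, ftype):
        spec = SLRSpec(duration=3.2e-3, time_bandwidth=4,
                       flip_angle=math.pi / 2, filter_type=ftype)
        pulse, grad = design_slr_pulse(spec, THICKNESS, limits)
        z = np.linspace(-4 * THICKNESS, 4 * THICKNESS, 1601)
        fwhm = profile_fwhm(z, _profile(pulse, grad.amplitude, z))
        assert fwhm == pytest.approx(THICKNESS, rel=0.05)

    def test_out_of_band_excitation_below_stopband_level(self, ex_pulse):
        pulse, grad = ex_pulse
        z = np.linspace(-4 * THICKNESS, 4 * THICKNESS, 1601)
        mxy = np.abs(_profile(pulse, grad.amplitude, z))
        far = np.abs(z) > 2 * THICKNESS
        assert mxy[far].max() < 0.02

    def test_zero_flip_returns_zero_waveform(self, limits):
        spec = SLRSpec(duration=3.2e-3, time_bandwidth=4, flip_angle=0.0)
        pulse = design_slr_rf(spec, limits)
        assert np.all(pulse.samples == 0)

    def test_minimum_phase_concentrates_energy_late(self, limits):
        spec = SLRSpec(duration=3.2e-3, time_bandwidth=4,
                       flip_angle=math.pi / 2, filter_type="minimum_phase")
        pulse = design_slr_rf(spec, limits)
        peak_frac = np.argmax(np.abs(pulse.samples)) / pulse.samples.size
        assert peak_frac > 0.55  # shorter effective isodelay than linear phase

    def test_infeasible_gradient_suggests_longer_duration(self, limits):
        spec = SLRSpec(duration=0.2e-3, time_bandwidth=8, flip_angle=math.pi / 2)
        with pytest.raises(ValueError, match="duration"):
            design_slr_pulse(spec, 0.4e-3, limits)

    def test_on_resonance_mz_decreases_monotonically_with_flip(self, limits):
        mz = []
        for deg in (10, 30, 50, 70, 90):
            spec = SLRSpec(duration=3.2e-3, time_bandwidth=4,
                           flip_angle=math.radians(deg))
            pulse = design_slr_rf(spec, limits)
            mz.append(bloch_simulate(pulse)[0, 2])
        assert np.all(np.diff(mz) < 0)


class TestFatSat:
    def test_frequency_offset_matches_chemical_shift_arithmetic(self):
        spec = default_fatsat_spec()
        pulse = make_fatsat_pulse(spec, fat_shift_ppm=-3.45, field_strength=3.0)
        expected = -3.45 * GAMMA_HZ_PER_T * 3.0 / 1e6
        assert pulse.freq_offset == pytest.approx(expected, rel=1e-12)
        assert pulse.freq_offset < 0

    def test_saturates_fat_and_spares_water(self):
        spec = default_fatsat_spec()
        pulse = make_fatsat_pulse(spec)
        m_fat = bloch_simulate(pulse, off_resonance=pulse.freq_offset)
        m_water = bloch_simulate(pulse, off_resonance=0.0)
        assert abs(m_fat[0, 2]) < 0.1  # >= 90% saturation of Mz
        assert m_water[0, 2] >= 0.95

    def test_zero_field_strength_rejected(self):
        with pytest.raises(ValueError, match="field_strength"):
            make_fatsat_pulse(default_fatsat_spec(), field_strength=0.0)

    def test_bandwidth_overlapping_water_rejected(self):
        wide = SLRSpec(duration=1e-3, time_bandwidth=2, flip_angle=math.pi / 2,
                       filter_type="minimum_phase")
        with pytest.raises(ValueError, match="water"):
            make_fatsat_pulse(wide)


@pytest.fixture(scope="module")
def base52(limits):
    spec = SLRSpec(duration=3.2e-3, time_bandwidth=4,
                   flip_angle=math.radians(52))
    return design_slr_pulse(spec, THICKNESS, limits)


class TestMultiband:
    def test_single_band_is_identity(self, base52, limits):
        base, grad = base52
        sms = SMSSpec(n_bands=1, band_separation=0.024, slice_thickness=THICKNESS)
        out = synthesize_sms_pulse(base, sms, grad.amplitude, limits)
        np.testing.assert_array_equal(out.samples, base.samples)

    def test_optimized_phases_beat_zero_phases_for_six_bands(self, base52, limits):
        base, grad = base52
        zero = synthesize_sms_pulse(
            base,
            SMSSpec(6, 0.024, THICKNESS, phase_offsets=np.zeros(6)),
            grad.amplitude, limits,
        )
        opt = synthesize_sms_pulse(
            base, SMSSpec(6, 0.024, THICKNESS), grad.amplitude, limits
        )
        assert opt.peak < zero.peak

    def test_six_band_profile_has_six_bands_at_requested_positions(
        self, base52, limits
    ):
        base, grad = base52
        sep = 0.024
        mb = synthesize_sms_pulse(base, SMSSpec(6, sep, THICKNESS),
                                  grad.amplitude, limits)
        z = np.linspace(-0.08, 0.08, 3201)
        mxy = _profile(mb, grad.amplitude, z)
        assert count_bands(z, mxy) == 6
        mag = np.abs(mxy)
        for b in range(6):
            zc = (b - 2.5) * sep
            sel = np.abs(z - zc) < sep / 2
            zb = z[sel]
            prof = mag[sel]
            # band present, centered, and near nominal thickness
            assert prof.max() > 0.5 * mag.max()
            assert abs(zb[np.argmax(prof)] - zc) < THICKNESS
            assert profile_fwhm(zb, prof) == pytest.approx(THICKNESS, rel=0.05)

    def test_multiband_profile_superposes_single_band_profiles_small_tip(
        self, limits
    ):
        spec = SLRSpec(duration=3.2e-3, time_bandwidth=4,
                       flip_angle=math.radians(5))
        base, grad = design_slr_pulse(spec, THICKNESS, limits)
        sep = 0.012
        mb = synthesize_sms_pulse(base, SMSSpec(3, sep, THICKNESS),
                                  grad.amplitude, limits)
        z = np.linspace(-0.03, 0.03, 1201)
        mb_prof = np.abs(_profile(mb, grad.amplitude, z))
        phis = optimize_band_phases(base, grad.amplitude * np.array([-sep, 0, sep]))
        single = np.zeros_like(z, dtype=complex)
        for zc, phi in zip((-sep, 0, sep), phis):
            shifted = PulseShape(
                base.samples * np.exp(
                    1j * (2 * np.pi * grad.amplitude * zc * base.t + phi)
                ),
                base.raster, base.bandwidth,
            )
            single += _profile(shifted, grad.amplitude, z)
        corr = np.corrcoef(mb_prof, np.abs(single))[0, 1]
        assert corr > 0.99

    def test_peak_above_rf_limit_suggests_stretching(self, base52):
        base, grad = base52
        tight = SystemLimits(max_rf_amplitude=base.peak * 1.5)
        with pytest.raises(ValueError, match="stretch"):
            synthesize_sms_pulse(base, SMSSpec(6, 0.024, THICKNESS),
                                 grad.amplitude, tight)


class TestRFSpoiling:
    def test_zero_index_gives_zero_phase(self):
        assert rf_spoiling_phase(0) == 0.0

    def test_closed_form_at_n_2(self):
        # 117 * 3 mod 360 = 351 degrees
        assert math.degrees(rf_spoiling_phase(2)) == pytest.approx(351.0)

    def test_second_differences_constant_at_increment(self):
        phases = np.unwrap([rf_spoiling_phase(n) for n in range(50)])
        # reconstruct the quadratic schedule without the 2 pi wrap
        inc = math.radians(117.0)
        full = np.array([inc * n * (n + 1) / 2 for n in range(50)])
        d2 = np.diff(full, 2)
        assert np.allclose(d2, inc)
        # and the wrapped values match the schedule mod 2 pi
        assert np.allclose(
            np.mod([rf_spoiling_phase(n) for n in range(50)], 2 * np.pi),
            np.mod(full, 2 * np.pi), atol=1e-9,
        )

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            rf_spoiling_phase(-1)
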