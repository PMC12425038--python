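"""Reconstruction chain: phase correction, regridding, slice GRAPPA,
SENSE, partial Fourier, coil combination, and the end-to-end oracle."""

import numpy as np
import pytest

from smsepi.events import SystemLimits
from smsepi.protocol import ci_params, design_epi_readout
from smsepi.recon import (
    ImageTimeSeries,
    PhaseCorrection,
    RampRegridder,
    ReconError,
    apply_phase_correction,
    apply_slice_grappa,
    calibrate_slice_grappa,
    coil_combine_rss,
    estimate_phase_correction,
    ifft2_centered,
    pf_zerofill,
    reconstruct_timeseries,
    sense_unalias,
)
from smsepi.recon import _grid_calibration, _shifts_from_phase, _consts_from_phase
from smsepi.simulator import (
    AcqNoiseModel,
    DigitalPhantom,
    make_ball_phantom,
    make_coil_maps,
    simulate_acquisition,
)


def _nrmse(a, b, mask):
    return np.linalg.norm((a - b)[mask]) / np.linalg.norm(b[mask])


class TestPhaseCorrection:
    def test_injected_parameters_recovered_within_1_percent(
        self, ci_protocol, ci_readout, ci_phantom, ci_maps, limits
    ):
        raw, cal = simulate_acquisition(
            ci_phantom, ci_maps, ci_protocol, ci_readout,
            AcqNoiseModel(theta0=0.15, theta1=0.002), limits,
        )
        pc = estimate_phase_correction(cal)
        assert pc.theta0 == pytest.approx(0.15, rel=0.01)
        assert pc.theta1 == pytest.approx(0.002, rel=0.01)

    def test_null_case_estimates_are_near_zero(self, ci_noiseless):
        _, cal = ci_noiseless
        pc = estimate_phase_correction(cal)
        assert abs(pc.theta0) < 1e-6
        assert abs(pc.theta1) < 1e-8

    def test_recovery_robust_to_noise(
        self, ci_protocol, ci_readout, ci_phantom, ci_maps, limits
    ):
        raw, cal = simulate_acquisition(
            ci_phantom, ci_maps, ci_protocol, ci_readout,
            AcqNoiseModel(sigma=0.3, theta0=0.15, theta1=0.002, seed=5), limits,
        )
        pc = estimate_phase_correction(cal)
        assert pc.theta0 == pytest.approx(0.15, rel=0.01)
        assert pc.theta1 == pytest.approx(0.002, rel=0.01)

    def test_all_zero_navigators_rejected(self, ci_noiseless):
        raw, cal = ci_noiseless
        import dataclasses

        dead = dataclasses.replace(cal, nav=np.zeros_like(cal.nav))
        with pytest.raises(ReconError, match="all-zero"):
            estimate_phase_correction(dead)

    def test_correction_inverts_injection_exactly(self, ci_noiseless, ci_protocol,
                                                  ci_readout, ci_phantom, ci_maps,
                                                  limits):
        clean, _ = ci_noiseless
        dirty, _ = simulate_acquisition(
            ci_phantom, ci_maps, ci_protocol, ci_readout,
            AcqNoiseModel(theta0=0.15, theta1=0.002), limits,
        )
        fixed = apply_phase_correction(
            dirty.data[0, 0], dirty.polarity, PhaseCorrection(0.15, 0.002)
        )
        np.testing.assert_allclose(fixed, clean.data[0, 0], atol=1e-9)

    def test_excessive_linear_term_rejected(self):
        with pytest.raises(ValueError, match="theta1"):
            PhaseCorrection(0.0, 2.0)


class TestRampRegridding:
    def test_flat_top_grid_samples_pass_through_unchanged(self, limits):
        p = ci_params(n_volumes=1, n_dummy=0, ramp_sampling=False,
                      partial_fourier=1.0, tr=0.96)
        ro = design_epi_readout(p, limits)
        rg = RampRegridder(ro.kx_of_sample, p.matrix[0], p.fov[0])
        np.testing.assert_allclose(rg.R_pos, np.eye(p.matrix[0]), atol=1e-12)

    def test_single_voxel_object_regrids_to_analytic_dft_line(
        self, ci_readout, ci_protocol
    ):
        nx = ci_protocol.matrix[0]
        vx = ci_protocol.fov[0] / nx
        x0 = (7 - nx // 2) * vx  # an off-center point source
        kx = ci_readout.kx_of_sample
        samples = np.exp(-2j * np.pi * kx * x0) / np.sqrt(nx)
        rg = RampRegridder(kx, nx, ci_protocol.fov[0])
        line = rg.apply(samples[None, None, :], np.array([1]))[0, 0]
        grid = (np.arange(nx) - nx // 2) / ci_protocol.fov[0]
        analytic = np.exp(-2j * np.pi * grid * x0) / np.sqrt(nx)
        assert np.abs(line - analytic).max() < 1e-3 * np.abs(analytic).max()

    def test_energy_preserved_for_band_limited_content(
        self, ci_readout, ci_protocol
    ):
        rng = np.random.default_rng(2)
        nx = ci_protocol.matrix[0]
        vx = ci_protocol.fov[0] / nx
        xpos = (np.arange(nx) - nx // 2) * vx
        obj = rng.standard_normal(nx) + 1j * rng.standard_normal(nx)
        E = np.exp(-2j * np.pi * np.outer(ci_readout.kx_of_sample, xpos)) / np.sqrt(nx)
        samples = E @ obj
        rg = RampRegridder(ci_readout.kx_of_sample, nx, ci_protocol.fov[0])
        line = rg.apply(samples[None, None, :], np.array([1]))[0, 0]
        assert np.sum(np.abs(line) ** 2) == pytest.approx(
            np.sum(np.abs(obj) ** 2), rel=0.01
        )

    def test_grid_beyond_sampled_extent_rejected(self, ci_readout, ci_protocol):
        with pytest.raises(ReconError, match="extent"):
            RampRegridder(ci_readout.kx_of_sample * 0.5, ci_protocol.matrix[0],
                          ci_protocol.fov[0])


@pytest.fixture(scope="module")
def gridded_cal(ci_noiseless):
    raw, cal = ci_noiseless
    pc = estimate_phase_correction(cal)
    rg = RampRegridder(raw.kx, raw.matrix[0], raw.fov[0])
    return raw, _grid_calibration(cal, pc, rg), rg, pc


class TestSliceGrappa:
    def test_single_band_kernels_reproduce_input(self, gridded_cal):
        raw, cal_k, rg, pc = gridded_cal
        nz = cal_k.shape[0]
        bands = np.arange(nz)[:, None]
        phases = np.ones((cal_k.shape[2], 1), dtype=complex)
        kern = calibrate_slice_grappa(cal_k, bands, phases)
        assert max(max(r) for r in kern.residual) < 1e-5
        out = apply_slice_grappa(cal_k[3], kern, group=3)
        rel = np.linalg.norm(out[0] - cal_k[3]) / np.linalg.norm(cal_k[3])
        assert rel < 1e-4

    def test_noiseless_calibration_residual_below_1e3(self, gridded_cal):
        raw, cal_k, rg, pc = gridded_cal
        kern = calibrate_slice_grappa(cal_k, raw.band_slices, raw.caipi_phase)
        assert max(max(r) for r in kern.residual) < 1e-3

    def test_kernels_independent_of_noise_seed_when_noiseless(
        self, ci_protocol, ci_readout, ci_phantom, ci_maps, limits
    ):
        kerns = []
        for seed in (1, 2):
            _, cal = simulate_acquisition(
                ci_phantom, ci_maps, ci_protocol, ci_readout,
                AcqNoiseModel(seed=seed), limits,
            )
            pc = estimate_phase_correction(cal)
            rg = RampRegridder(cal.kx, cal.matrix[0], cal.fov[0])
            cal_k = _grid_calibration(cal, pc, rg)
            bands = np.stack(
                [ci_protocol.slices_of_shot(s)
                 for s in range(ci_protocol.n_shots_per_volume)]
            )
            from smsepi.protocol import caipi_phase_table

            kerns.append(
                calibrate_slice_grappa(cal_k, bands,
                                       caipi_phase_table(ci_protocol))
            )
        for g in range(len(kerns[0].kernels)):
            for b in range(len(kerns[0].kernels[g])):
                np.testing.assert_array_equal(
                    kerns[0].kernels[g][b], kerns[1].kernels[g][b]
                )

    def test_underdetermined_calibration_rejected(self, gridded_cal):
        raw, cal_k, rg, pc = gridded_cal
        tiny = cal_k[:, :4, :4, :]
        with pytest.raises(ReconError, match="underdetermined"):
            calibrate_slice_grappa(tiny, raw.band_slices, raw.caipi_phase[:4])

    def test_even_kernel_dims_rejected(self, gridded_cal):
        raw, cal_k, rg, pc = gridded_cal
        with pytest.raises(ValueError, match="odd"):
            calibrate_slice_grappa(cal_k, raw.band_slices, raw.caipi_phase,
                                   kernel_size=(4, 4))

    def test_zero_input_gives_zero_output(self, gridded_cal):
        raw, cal_k, rg, pc = gridded_cal
        kern = calibrate_slice_grappa(cal_k, raw.band_slices, raw.caipi_phase)
        out = apply_slice_grappa(np.zeros_like(cal_k[0]), kern, group=0)
        assert np.all(out == 0)

    def test_interslice_leakage_below_5_percent(
        self, ci_protocol, ci_readout, ci_maps, limits
    ):
        """A band simulated empty must stay (nearly) empty after
        separation: leakage < 5% of the source band energy."""
        ph = make_ball_phantom(ci_protocol)
        hollow = ph.data.copy()
        shot = 0
        bands = ci_protocol.slices_of_shot(shot)
        empty_slice = int(bands[1])
        hollow[:, :, empty_slice] = 0.0
        phant = DigitalPhantom(hollow, ph.voxel_size)
        raw, cal = simulate_acquisition(
            phant, ci_maps, ci_protocol, ci_readout, AcqNoiseModel(), limits
        )
        ts = reconstruct_timeseries(raw, cal, method="slice_grappa")
        vol = ts.data[..., 0]
        src = int(bands[0])
        leak = np.linalg.norm(vol[:, :, empty_slice])
        source = np.linalg.norm(vol[:, :, src])
        assert leak < 0.05 * source


class TestSense:
    def test_single_band_unit_coil_is_identity(self):
        nx = ny = 16
        img = np.arange(nx * ny, dtype=complex).reshape(nx, ny, 1)
        maps = np.ones((1, nx, ny, 1), dtype=complex)
        out, g = sense_unalias(img, maps, np.array([0]), np.zeros(1),
                               np.ones(1, dtype=complex))
        np.testing.assert_allclose(out[0], img[:, :, 0], atol=1e-12)

    def test_well_conditioned_recovery_is_exact(self, ci_fullfourier, limits):
        p, ph, maps, ro = ci_fullfourier
        raw, cal = simulate_acquisition(ph, maps, p, ro, AcqNoiseModel(), limits)
        ny = p.matrix[1]
        shifts = _shifts_from_phase(raw.caipi_phase, ny)
        consts = _consts_from_phase(raw.caipi_phase, raw.ky_index, shifts, ny)
        bands = raw.band_slices[0]
        coil = np.zeros((p.matrix[0], ny, maps.ncoils), dtype=complex)
        for b, z in enumerate(bands):
            prod = ph.data[:, :, z, None] * np.moveaxis(maps.maps[:, :, :, z], 0, -1)
            coil += consts[b] * np.roll(prod, -int(shifts[b]), axis=1)
        out, g = sense_unalias(coil, maps.maps, bands, shifts, consts)
        for b, z in enumerate(bands):
            err = np.abs(np.abs(out[b]) - ph.data[:, :, z]).max()
            assert err < 1e-6 * ph.data.max()

    def test_g_factor_at_least_one(self, ci_fullfourier, limits):
        p, ph, maps, ro = ci_fullfourier
        raw, cal = simulate_acquisition(ph, maps, p, ro, AcqNoiseModel(), limits)
        ny = p.matrix[1]
        shifts = _shifts_from_phase(raw.caipi_phase, ny)
        consts = _consts_from_phase(raw.caipi_phase, raw.ky_index, shifts, ny)
        bands = raw.band_slices[0]
        coil = np.zeros((p.matrix[0], ny, maps.ncoils), dtype=complex)
        _, g = sense_unalias(coil, maps.maps, bands, shifts, consts)
        assert g.min() >= 1.0 - 1e-9

    def test_rank_deficient_voxels_flagged_zero(self):
        nx = ny = 8
        img = np.ones((nx, ny, 2), dtype=complex)
        maps = np.zeros((2, nx, ny, 2), dtype=complex)  # all-zero sensitivities
        out, g = sense_unalias(img, maps, np.array([0, 1]), np.zeros(2),
                               np.ones(2, dtype=complex))
        assert np.all(out == 0)

    def test_fractional_shift_rejected(self):
        img = np.ones((8, 8, 2), dtype=complex)
        maps = np.ones((2, 8, 8, 2), dtype=complex)
        with pytest.raises(ReconError, match="integer"):
            sense_unalias(img, maps, np.array([0, 1]), np.array([0.0, 2.5]),
                          np.ones(2, dtype=complex))


class TestPartialFourier:
    def test_full_fraction_is_identity(self):
        rng = np.random.default_rng(0)
        ny = 16
        lines = rng.standard_normal((ny, 3, 8)) + 0j
        kyi = np.arange(ny) - ny // 2
        out = pf_zerofill(lines, kyi, ny)
        np.testing.assert_array_equal(out, lines)

    def test_missing_early_lines_zero_filled_to_full_matrix(self):
        ny, ne = 90, 72
        kyi = np.arange(ny - ne, ny) - ny // 2
        lines = np.ones((ne, 2, 4), dtype=complex)
        out = pf_zerofill(lines, kyi, ny)
        assert out.shape[0] == 90
        assert np.all(out[: ny - ne] == 0)
        assert np.all(out[ny - ne :] == 1)

    def test_point_source_psf_broadening_matches_truncation_oracle(self):
        """Zero-filling the early 20% of ky broadens the PSF main lobe by
        the analytic truncated-Fourier factor."""
        ny = 90
        ne = 72
        kyi = np.arange(ny - ne, ny) - ny // 2
        # point source at the center: unit k-space
        full = np.ones((ny, 1, 1), dtype=complex)
        part = pf_zerofill(np.ones((ne, 1, 1), dtype=complex), kyi, ny)

        def psf_fwhm(window):
            # dense analytic PSF: |sum_m w_m e^{2 pi i m y}| on a fine grid
            m = np.arange(ny) - ny // 2
            y = np.linspace(-0.5, 0.5, 20001)
            psf = np.abs(np.exp(2j * np.pi * np.outer(y, m)) @ window)
            half = psf.max() / 2
            above = psf >= half
            return y[above].max() - y[above].min()

        w_full = psf_fwhm(full[:, 0, 0])
        w_part = psf_fwhm(part[:, 0, 0])
        assert w_part / w_full == pytest.approx(ny / ne, rel=0.05)


class TestCoilCombine:
    def test_single_coil_gives_magnitude(self):
        img = (np.random.default_rng(0).standard_normal((5, 5, 1))
               + 1j * np.random.default_rng(1).standard_normal((5, 5, 1)))
        np.testing.assert_allclose(coil_combine_rss(img), np.abs(img[..., 0]))

    def test_invariant_to_per_coil_global_phase(self):
        rng = np.random.default_rng(2)
        img = rng.standard_normal((6, 6, 4)) + 1j * rng.standard_normal((6, 6, 4))
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, 4))
        np.testing.assert_allclose(
            coil_combine_rss(img * phases), coil_combine_rss(img), rtol=1e-12
        )

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        img = rng.standard_normal((4, 4, 8)) + 1j * rng.standard_normal((4, 4, 8))
        brute = np.sqrt(sum(np.abs(img[..., c]) ** 2 for c in range(8)))
        np.testing.assert_allclose(coil_combine_rss(img), brute, atol=1e-12)


class TestFullChain:
    def test_noiseless_recovery_both_methods(self, ci_noiseless, ci_phantom):
        raw, cal = ci_noiseless
        mask = ci_phantom.data > 0.5 * ci_phantom.data.max()
        vols = {}
        for method in ("slice_grappa", "sense"):
            ts = reconstruct_timeseries(raw, cal, method=method)
            vols[method] = ts.data[..., 0]
            assert _nrmse(vols[method], ci_phantom.data, mask) < 0.05
        assert _nrmse(vols["slice_grappa"], vols["sense"], mask) < 0.05

    def test_degenerate_single_band_full_fourier_recovery(self, limits):
        p = ci_params(sms_factor=1, partial_fourier=1.0, ramp_sampling=False,
                      n_volumes=1, n_dummy=0, tr=0.96)
        ph = make_ball_phantom(p)
        maps = make_coil_maps(p, 6, seed=1, phantom=ph)
        ro = design_epi_readout(p, limits)
        raw, cal = simulate_acquisition(ph, maps, p, ro, AcqNoiseModel(), limits)
        mask = ph.data > 0.5 * ph.data.max()
        for method in ("slice_grappa", "sense"):
            ts = reconstruct_timeseries(raw, cal, method=method)
            assert _nrmse(ts.data[..., 0], ph.data, mask) < 1e-3

    def test_dummy_volumes_dropped_from_output(self, ci_readout, ci_phantom,
                                               ci_maps, limits):
        p = ci_params(n_volumes=2, n_dummy=1)
        raw, cal = simulate_acquisition(ci_phantom, ci_maps, p, ci_readout,
                                        AcqNoiseModel(), limits)
        ts = reconstruct_timeseries(raw, cal, method="slice_grappa")
        assert ts.data.shape[-1] == 2

    def test_bit_identical_output_for_identical_input(self, ci_noiseless):
        raw, cal = ci_noiseless
        a = reconstruct_timeseries(raw, cal, method="slice_grappa")
        b = reconstruct_timeseries(raw, cal, method="slice_grappa")
        np.testing.assert_array_equal(a.data, b.data)

    def test_missing_calibration_error_names_requirement(self, ci_noiseless):
        raw, _ = ci_noiseless
        with pytest.raises(ReconError, match="slice_grappa requires"):
            reconstruct_timeseries(raw, None, method="slice_grappa")
        with pytest.raises(ReconError, match="sense requires"):
            reconstruct_timeseries(raw, None, method="sense")

    def test_increasing_noise_strictly_decreases_in_mask_snr(
        self, ci_protocol, ci_readout, ci_phantom, ci_maps, limits
    ):
        mask = ci_phantom.data > 0.99 * ci_phantom.data.max()
        snrs = []
        for sigma in (0.5, 2.0, 8.0):
            raw, cal = simulate_acquisition(
                ci_phantom, ci_maps, ci_protocol, ci_readout,
                AcqNoiseModel(sigma=sigma, seed=21), limits,
            )
            ts = reconstruct_timeseries(raw, cal, method="slice_grappa")
            vol = ts.data[..., 0]
            err = vol[mask] - ci_phantom.data[mask]
            snrs.append(ci_phantom.data[mask].mean() / err.std())
        assert snrs[0] > snrs[1] > snrs[2]

    def test_nifti_roundtrip_preserves_geometry(self, ci_noiseless, tmp_path):
        raw, cal = ci_noiseless
        ts = reconstruct_timeseries(raw, cal, method="slice_grappa")
        path = str(tmp_path / "bold.nii.gz")
        ts.to_nifti(path)
        back = ImageTimeSeries.from_nifti(path)
        assert back.data.shape == ts.data.shape
        assert back.tr == pytest.approx(ts.tr, rel=1e-6)
        np.testing.assert_allclose(
            back.voxel_size, ts.voxel_size, rtol=1e-5
        )
        np.testing.assert_allclose(back.data, ts.data, rtol=1e-5, atol=1e-4)
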