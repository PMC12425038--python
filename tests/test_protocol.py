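"""Protocol assembly: EPI readout design, fat sat, timing, CAIPI pattern."""

import math

import numpy as np
import pytest

from smsepi.events import SystemLimits, TrapGradient
from smsepi.protocol import (
    ProtocolParams,
    build_fatsat_block,
    build_protocol,
    caipi_phase_table,
    ci_params,
    design_epi_readout,
    protocol_report,
)
from smsepi.safety import predict_pns
from smsepi.sequence import compute_kspace, validate_sequence


@pytest.fixture(scope="module")
def abcd():
    return ProtocolParams(n_volumes=1, n_dummy=0)


@pytest.fixture(scope="module")
def abcd_readout(abcd, limits):
    return design_epi_readout(abcd, limits)


@pytest.fixture(scope="module")
def abcd_sequence(abcd, limits):
    return build_protocol(abcd, limits)


class TestProtocolParams:
    def test_abcd_echo_count_is_72(self, abcd):
        assert abcd.n_echoes == 72  # ceil(0.8 * 90)

    def test_slices_must_divide_by_sms_factor(self):
        with pytest.raises(ValueError, match="divisible"):
            ProtocolParams(n_slices=61)

    def test_partial_fourier_range_enforced(self):
        with pytest.raises(ValueError, match="partial_fourier"):
            ProtocolParams(partial_fourier=0.4)

    def test_slab_thickness_consistency_enforced(self):
        with pytest.raises(ValueError, match="fov z"):
            ProtocolParams(fov=(0.216, 0.216, 0.15))

    def test_partial_fourier_omits_early_ky_lines(self, abcd):
        kyi = abcd.ky_indices()
        assert kyi.size == 72
        assert kyi[0] == -27 and kyi[-1] == 44  # later 80% of -45..44

    def test_shot_slices_are_maximally_separated(self, abcd):
        slices = abcd.slices_of_shot(0)
        assert np.all(np.diff(slices) == abcd.n_shots_per_volume)
        all_slices = np.concatenate(
            [abcd.slices_of_shot(s) for s in range(abcd.n_shots_per_volume)]
        )
        assert sorted(all_slices) == list(range(60))


class TestEPIReadoutDesign:
    def test_readout_moment_spans_full_kx_extent(self, abcd, abcd_readout):
        assert abcd_readout.readout.area == pytest.approx(
            abcd.matrix[0] / abcd.fov[0], rel=1e-9
        )

    def test_ramp_samples_cover_ramps_and_flat_top(self, abcd_readout):
        ro, adc = abcd_readout.readout, abcd_readout.adc
        assert adc.delay < ro.rise_time  # sampling starts on the ramp
        assert adc.end_time > ro.rise_time + ro.flat_time  # and ends on one

    def test_adc_window_symmetric_about_trapezoid_center(self, abcd_readout):
        ro, adc = abcd_readout.readout, abcd_readout.adc
        kx = abcd_readout.kx_of_sample
        np.testing.assert_allclose(kx, -kx[::-1], atol=1e-9)

    def test_predicted_pns_within_derated_bound(self, abcd, abcd_sequence):
        rep = protocol_report(abcd_sequence)
        assert rep["pns_peak_percent"] <= abcd.pns_derate * 100.0

    def test_infeasible_pns_target_raises(self, abcd, limits):
        from smsepi.safety import PNSParams

        # absurdly strict rheobase: no slew can satisfy the bound
        strict = PNSParams(rheobase=0.1)
        with pytest.raises(ValueError, match="infeasible"):
            design_epi_readout(abcd, limits, strict)


class TestFatSat:
    def test_block_holds_one_rf_and_one_z_spoiler(self, abcd, limits):
        blk = build_fatsat_block(abcd, limits)
        assert blk.rf is not None and blk.gz is not None
        assert blk.gx is None and blk.gy is None and blk.adc is None

    def test_spoiler_dephases_at_least_4pi_across_slice(self, abcd, limits):
        blk = build_fatsat_block(abcd, limits)
        assert abs(blk.gz.area) >= 2.0 / abcd.slice_thickness - 1e-9

    def test_fat_offset_negative_at_3t(self, abcd, limits):
        blk = build_fatsat_block(abcd, limits)
        assert blk.rf.freq_offset < 0


class TestBuildProtocol:
    def test_ten_sms_shots_per_volume(self, abcd_sequence):
        vols = {}
        for s in abcd_sequence.sms_shots:
            vols.setdefault(s.volume, []).append(s)
        assert all(len(v) == 10 for v in vols.values())  # 60 / 6

    def test_reference_segment_covers_every_slice_single_band(self, abcd_sequence):
        refs = abcd_sequence.reference_shots
        assert len(refs) == 60
        assert all(r.slices.size == 1 for r in refs)
        assert sorted(int(r.slices[0]) for r in refs) == list(range(60))

    def test_block_durations_in_one_volume_sum_to_tr(self, abcd, abcd_sequence):
        seq = abcd_sequence.seq
        vol0 = [s for s in abcd_sequence.sms_shots if s.volume == 0]
        i0 = vol0[0].excite_block - 1  # fatsat block opens the shot
        last = vol0[-1].echo_blocks[-1]
        while last + 1 < len(seq.blocks) and seq.blocks[last + 1].label == "tr_fill":
            last += 1
        total = sum(b.duration for b in seq.blocks[i0 : last + 1])
        assert total == pytest.approx(abcd.tr, abs=1e-9)

    def test_assembled_sequence_passes_validation(self, abcd_sequence):
        assert validate_sequence(abcd_sequence.seq) == []

    def test_shot_phases_follow_rf_spoiling_schedule(self, abcd_sequence):
        from smsepi.rf import rf_spoiling_phase

        seq = abcd_sequence.seq
        for i, shot in enumerate(abcd_sequence.shots[:25]):
            expected = rf_spoiling_phase(i)
            rf = seq.blocks[shot.excite_block].rf
            adc = seq.blocks[shot.echo_blocks[0]].adc
            assert rf.phase_offset == pytest.approx(expected)
            assert adc.phase_offset == pytest.approx(expected)

    def test_incommensurate_tr_rejected(self, limits):
        with pytest.raises(ValueError, match="multiple"):
            build_protocol(ci_params(tr=0.250033), limits)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(matrix=(24, 24), n_slices=8, sms_factor=2, tr=0.2,
                 fov=(0.216, 0.216, 8 * 0.0024)),
            dict(matrix=(30, 30), n_slices=9, sms_factor=3, tr=0.3,
                 fov=(0.216, 0.216, 9 * 0.0024), partial_fourier=0.75),
        ],
    )
    def test_tr_fill_holds_for_other_feasible_parameter_sets(self, kw, limits):
        p = ProtocolParams(n_volumes=1, n_dummy=0, **kw)
        ps = build_protocol(p, limits)
        seq = ps.seq
        vol0 = [s for s in ps.sms_shots if s.volume == 0]
        i0 = vol0[0].excite_block - 1
        last = vol0[-1].echo_blocks[-1]
        while last + 1 < len(seq.blocks) and seq.blocks[last + 1].label == "tr_fill":
            last += 1
        total = sum(b.duration for b in seq.blocks[i0 : last + 1])
        assert total == pytest.approx(p.tr, abs=1e-9)


class TestKSpaceCoverage:
    def test_one_shot_visits_partial_fourier_ky_window(
        self, ci_sequence, ci_protocol
    ):
        shot = ci_sequence.sms_shots[0]
        trajs = compute_kspace(
            ci_sequence.seq, block_range=(shot.excite_block, shot.echo_blocks[-1] + 1)
        )
        echoes = trajs[ci_protocol.n_navigators :]
        ky = np.array([t.k[:, 1].mean() for t in echoes])
        dky = 1.0 / ci_protocol.fov[1]
        idx = np.round(ky / dky).astype(int)
        assert list(idx) == list(ci_protocol.ky_indices())
        assert len(set(idx)) == ci_protocol.n_echoes

    def test_caipi_blip_trajectory_matches_encoding_table(
        self, ci_sequence, ci_protocol
    ):
        """The kz excursion of the z blips reproduces the phase table:
        phase(e, b) = exp(2 pi i z_b (kz_e - kz_0)) for relative band
        offsets z_b = b * band_separation."""
        shot = ci_sequence.sms_shots[0]
        trajs = compute_kspace(
            ci_sequence.seq, block_range=(shot.excite_block, shot.echo_blocks[-1] + 1)
        )
        echoes = trajs[ci_protocol.n_navigators :]
        kz = np.array([t.k[:, 2].mean() for t in echoes])
        kz_rel = kz - kz[0]
        tab = caipi_phase_table(ci_protocol)
        band_sep = ci_protocol.fov[2] / ci_protocol.sms_factor
        for b in range(ci_protocol.sms_factor):
            predicted = np.exp(2j * np.pi * b * band_sep * kz_rel)
            np.testing.assert_allclose(predicted, tab[:, b], atol=1e-9)

    def test_navigators_sample_ky_zero(self, ci_sequence, ci_protocol):
        shot = ci_sequence.sms_shots[0]
        trajs = compute_kspace(
            ci_sequence.seq, block_range=(shot.excite_block, shot.echo_blocks[-1] + 1)
        )
        for t in trajs[: ci_protocol.n_navigators]:
            assert np.allclose(t.k[:, 1], 0.0, atol=1e-9)


class TestProtocolReport:
    def test_total_duration_is_reference_plus_volumes(self, abcd, abcd_sequence):
        rep = protocol_report(abcd_sequence)
        expected = rep["reference_duration_s"] + (
            abcd.n_dummy + abcd.n_volumes
        ) * abcd.tr
        assert rep["total_duration_s"] == pytest.approx(expected, abs=1e-9)

    def test_echo_spacing_equals_adc_start_difference(self, abcd_sequence):
        rep = protocol_report(abcd_sequence)
        assert rep["echo_spacing_s"] == pytest.approx(
            abcd_sequence.readout.echo_spacing, abs=1e-12
        )

    def test_reported_pns_consistent_with_safety_module(self, abcd_sequence):
        rep = protocol_report(abcd_sequence)
        seq = abcd_sequence.seq
        tr = float(seq.definitions["TR"])
        res = predict_pns(seq, t_range=(seq.duration - tr, seq.duration),
                          periodic=True)
        assert res.peak == pytest.approx(rep["pns_peak_percent"], rel=1e-9)
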