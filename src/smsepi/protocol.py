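"""ABCD-matched SMS-EPI protocol assembly.

One shot consists of: fat saturation (minimum-phase SLR with spoiler),
multiband SLR excitation with slice-select gradient and rephaser, readout/
phase-encode prewinders, three phase-correction navigator echoes (phase-
encode blips off), and the CAIPI-blipped ramp-sampled EPI train covering
the acquired partial-Fourier fraction of ky.  Shots are RF-spoiled.  The
full sequence is a single-band reference segment (one 2D-EPI shot per
slice, used for slice-GRAPPA calibration and coil maps) followed by the
SMS time series (dummy volumes first, then the output volumes), each
volume lasting exactly one TR.

Default acquisition geometry matches the ABCD study protocol: 2.4 mm
isotropic, 90 x 90 matrix, 60 slices, SMS factor 6, TR 0.8 s, partial
Fourier 0.8, FOV 21.6 x 21.6 x 14.4 cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .events import (
    ADCEvent,
    Block,
    RFEvent,
    SystemLimits,
    TrapGradient,
    make_trapezoid,
)
from .rf import (
    PulseShape,
    SLRSpec,
    SMSSpec,
    bloch_simulate,
    default_fatsat_spec,
    design_slr_pulse,
    make_fatsat_pulse,
    rf_spoiling_phase,
    synthesize_sms_pulse,
)
from .safety import (
    PNSParams,
    PNSResult,
    pns_impulse_response,
    predict_pns,
    rf_energy_report,
)
from .sequence import SequenceObject, compute_kspace
from .units import hzm_to_mtm, mtm_to_hzm, tms_to_hzms


@dataclass(frozen=True)
class ProtocolParams:
    """Acquisition parameters of the SMS-EPI protocol."""

    fov: Tuple[float, float, float] = (0.216, 0.216, 0.144)  # m
    matrix: Tuple[int, int] = (90, 90)
    n_slices: int = 60
    slice_thickness: float = 0.0024  # m
    sms_factor: int = 6
    tr: float = 0.8  # s
    partial_fourier: float = 0.8
    flip_angle: float = math.radians(52.0)
    n_volumes: int = 5
    caipi_shift: int = 3
    pns_derate: float = 0.8  # fraction of the stimulation limit
    n_dummy: int = 2
    # pulse-design defaults (the source protocol does not print these)
    rf_duration: float = 3.2e-3
    rf_tbw: float = 4.0
    readout_amplitude: float = mtm_to_hzm(24.0)  # Hz/m, pre-derating target
    initial_slew: float = tms_to_hzms(120.0)  # Hz/m/s, pre-derating
    n_navigators: int = 3
    ramp_sampling: bool = True

    def __post_init__(self) -> None:
        if self.n_slices % self.sms_factor != 0:
            raise ValueError("ProtocolParams: n_slices must be divisible by sms_factor")
        if not (0.5 < self.partial_fourier <= 1.0):
            raise ValueError("ProtocolParams: partial_fourier must be in (0.5, 1]")
        if abs(self.fov[2] - self.n_slices * self.slice_thickness) > 1e-9:
            raise ValueError(
                "ProtocolParams: fov z must equal n_slices * slice_thickness"
            )
        if self.caipi_shift < 1:
            raise ValueError("ProtocolParams: caipi_shift must be >= 1")

    @property
    def n_shots_per_volume(self) -> int:
        return self.n_slices // self.sms_factor

    @property
    def n_echoes(self) -> int:
        return math.ceil(self.partial_fourier * self.matrix[1])

    @property
    def voxel_size(self) -> Tuple[float, float, float]:
        return (
            self.fov[0] / self.matrix[0],
            self.fov[1] / self.matrix[1],
            self.slice_thickness,
        )

    def ky_indices(self) -> np.ndarray:
        """Acquired ky indices (ky=0 at matrix center, index nx//2).

        Partial Fourier omits the early (most negative) ky lines; the
        acquired window runs from -(n_echoes - ny/2) up to ny/2 - 1 in
        units of 1/fov_y.
        """
        ny = self.matrix[1]
        return np.arange(ny - self.n_echoes, ny) - ny // 2

    def slices_of_shot(self, shot: int) -> np.ndarray:
        """Slice indices excited by `shot` (0-based, interleaved shot order:
        even shots first, then odd)."""
        ns = self.n_shots_per_volume
        order = list(range(0, ns, 2)) + list(range(1, ns, 2))
        s = order[shot % ns]
        return s + ns * np.arange(self.sms_factor)

    def slice_positions(self, indices: np.ndarray) -> np.ndarray:
        """Slice-center z positions (m) for slice indices."""
        return (np.asarray(indices) - (self.n_slices - 1) / 2) * self.slice_thickness


def ci_params(**overrides) -> ProtocolParams:
    """Reduced test geometry: 36 x 36 matrix, 12 slices, SMS 3.

    The matrix is chosen divisible by the CAIPI shift so the inter-band
    FOV/3 displacement is an integer voxel count, as in the full protocol
    (90/3 = 30 voxels)."""
    kw = dict(
        fov=(0.216, 0.216, 12 * 0.0024),
        matrix=(36, 36),
        n_slices=12,
        sms_factor=3,
        tr=0.25,
        n_volumes=4,
        n_dummy=1,
    )
    kw.update(overrides)
    return ProtocolParams(**kw)


def caipi_phase_table(p: ProtocolParams) -> np.ndarray:
    """Complex CAIPI encoding phase per (echo, band).

    The z blips step kz through the cycle c_e = (ky_e mod S) - (ky_0 mod S)
    in units of 1/(S * band_separation), S = caipi_shift.  Referenced to
    the lowest band of the group, band b (offset b * band_separation)
    acquires the phase exp(2 pi i * b * c_e / S), i.e. an exact in-plane
    shift of band b by b * ny / S voxels.  The same table drives the
    simulator's encoding and the reconstruction's bookkeeping.
    """
    kyi = p.ky_indices()
    S = p.caipi_shift
    cyc = (kyi % S) - (kyi[0] % S)
    b = np.arange(p.sms_factor)
    if p.sms_factor == 1 or S == 1:
        return np.ones((kyi.size, p.sms_factor), dtype=complex)
    return np.exp(2j * np.pi * np.outer(cyc, b) / S)


def caipi_band_shift_voxels(p: ProtocolParams) -> np.ndarray:
    """In-plane shift (voxels along y) of each band in the collapsed image."""
    if p.sms_factor == 1 or p.caipi_shift == 1:
        return np.zeros(p.sms_factor)
    return np.arange(p.sms_factor) * p.matrix[1] / p.caipi_shift


def caipi_band_const(p: ProtocolParams) -> np.ndarray:
    """Constant per-band phase left after absorbing the pure ky ramp.

    phase(e, b) = exp(2 pi i b ky_e / S) * const_b with
    const_b = exp(-2 pi i b (ky_0 mod S) / S); the ramp part is the
    circular shift by b * ny / S voxels.
    """
    kyi = p.ky_indices()
    S = p.caipi_shift
    b = np.arange(p.sms_factor)
    if p.sms_factor == 1 or S == 1:
        return np.ones(p.sms_factor, dtype=complex)
    return np.exp(-2j * np.pi * b * (int(kyi[0]) % S) / S)


@dataclass
class EPIReadout:
    """Designed EPI readout: gradients, ADC, and bookkeeping."""

    readout: TrapGradient  # positive-polarity readout trapezoid
    prewinder_x: TrapGradient
    prewinder_y: TrapGradient
    blip_y: TrapGradient
    caipi_blips: List[TrapGradient]  # per transition pattern index
    adc: ADCEvent
    echo_spacing: float
    n_echoes: int
    ramp_sampling: bool
    derated_slew: float  # Hz/m/s actually used
    kx_of_sample: np.ndarray  # kx (1/m) at each ADC sample, positive polarity
    gap_time: float  # post-readout gap holding the blips


def _round_raster(t: float, raster: float, up: bool = True) -> float:
    n = t / raster
    return (math.ceil(round(n, 9)) if up else math.floor(round(n, 9))) * raster


def design_epi_readout(
    p: ProtocolParams,
    limits: SystemLimits,
    pns_params: Optional[PNSParams] = None,
) -> EPIReadout:
    """Design the ramp-sampled EPI readout with PNS-derated slew.

    The readout trapezoid has zeroth moment exactly nx/fov_x.  The ADC
    window is symmetric about the trapezoid center; with ramp sampling it
    spans ramps and flat top at a dwell giving ~2x oversampling on the
    flat top, otherwise it covers the flat top only with one sample per
    Cartesian kx step.  The slew rate is reduced iteratively until the
    impulse-response PNS prediction of the echo train stays below
    ``p.pns_derate`` of the stimulation limit.
    """
    pns_params = pns_params or PNSParams()
    nx = p.matrix[0]
    area = nx / p.fov[0]  # 1/m
    slew = min(p.initial_slew, limits.max_slew)
    g_target = min(p.readout_amplitude, limits.max_gradient)
    graster = limits.grad_raster_time

    for _ in range(60):
        ro, adc, kx = _design_single_echo(p, limits, g_target, slew)
        # blips are short; they may use up to twice the (derated) readout
        # slew, capped by the hardware limit, and still scale down with it
        blip_slew = min(limits.max_slew, 2 * slew)
        blip_y = make_trapezoid("y", limits, area=1.0 / p.fov[1], max_slew=blip_slew)
        band_sep = p.fov[2] / p.sms_factor
        dkz = 1.0 / (p.caipi_shift * band_sep)
        # z-blip areas follow the CAIPI cycle: shift-1 steps then a rewind
        caipi_blips = [
            make_trapezoid("z", limits, area=dkz, max_slew=blip_slew),
            make_trapezoid(
                "z", limits, area=-(p.caipi_shift - 1) * dkz, max_slew=blip_slew
            ),
        ]
        gap = max(
            blip_y.end_time,
            max(b.end_time for b in caipi_blips) if p.sms_factor > 1 else 0.0,
        )
        gap = _round_raster(gap, graster)
        es = _round_raster(ro.end_time + gap, limits.block_duration_raster)
        # PNS of the periodic echo train with the true blip pattern
        train = _echo_train_waveform(
            ro, blip_y, caipi_blips, p.ky_indices(), p.caipi_shift,
            p.sms_factor, es, limits,
        )
        res = pns_impulse_response(
            train, limits.grad_raster_time, pns_params, periodic=True
        )
        if res.peak <= p.pns_derate * 100.0:
            return EPIReadout(
                readout=ro,
                prewinder_x=make_trapezoid("x", limits, area=-ro.area / 2, max_slew=slew),
                prewinder_y=make_trapezoid(
                    "y", limits, area=p.ky_indices()[0] / p.fov[1], max_slew=slew
                ),
                blip_y=blip_y,
                caipi_blips=caipi_blips,
                adc=adc,
                echo_spacing=es,
                n_echoes=p.n_echoes,
                ramp_sampling=p.ramp_sampling,
                derated_slew=slew,
                kx_of_sample=kx,
                gap_time=gap,
            )
        slew *= 0.95
        if slew < tms_to_hzms(5.0):
            break
    raise ValueError(
        "design_epi_readout: echo spacing infeasible at minimum slew under "
        "the PNS derating target"
    )


def _design_single_echo(
    p: ProtocolParams, limits: SystemLimits, g_target: float, slew: float
) -> Tuple[TrapGradient, ADCEvent, np.ndarray]:
    """One readout trapezoid + symmetric ADC; returns kx at sample centers."""
    nx = p.matrix[0]
    area = nx / p.fov[0]
    graster = limits.grad_raster_time
    araster = limits.adc_raster_time

    if p.ramp_sampling:
        # dwell for ~2x flat-top oversampling, on an even 200 ns grid so the
        # symmetric ADC delay lands on the ADC raster
        dwell = max(
            2 * araster,
            math.ceil(1.0 / (2 * p.fov[0] * g_target) / (2 * araster)) * 2 * araster,
        )
        g = 1.0 / (2 * p.fov[0] * dwell)
        rise = max(_round_raster(g / slew, graster), graster)
        flat = max(_round_raster(area / g - rise, graster), 0.0)
        amp = area / (rise + flat)  # exact zeroth moment
        ro = TrapGradient("x", amp, rise, flat, rise)
        dur = ro.end_time
        # keep the ADC clear of the dead time at both ends (symmetric window)
        nsamp = int(math.floor(round((dur - 2 * limits.adc_dead_time) / dwell, 9)))
        delay = (dur - nsamp * dwell) / 2
    else:
        # flat-top-only sampling on the Cartesian grid: one sample per kx
        # step; pick the dwell so rise+flat lands on the gradient raster
        dwell_min = max(2 * araster, 1.0 / (p.fov[0] * g_target))
        dwell = math.ceil(dwell_min / (2 * araster)) * 2 * araster
        for _ in range(200):
            if abs((nx * dwell) / graster - round(nx * dwell / graster)) < 1e-6:
                break
            dwell += 2 * araster
        g = 1.0 / (p.fov[0] * dwell)
        rise = max(
            _round_raster(g / slew, graster),
            graster,
            _round_raster(limits.adc_dead_time + dwell, graster),
        )
        flat = nx * dwell
        amp = g
        ro = TrapGradient("x", amp, rise, flat, rise)
        nsamp = nx
        # sample centers on the integer Cartesian kx grid: first center at
        # the ramp/flat corner, so kx_i = (i - nx/2) / fov_x exactly
        delay = rise - dwell / 2
    adc = ADCEvent(num_samples=nsamp, dwell=dwell, delay=delay)
    kx = np.asarray(ro.integral(adc.sample_times)) - ro.area / 2
    return ro, adc, kx


def _echo_train_waveform(
    ro: TrapGradient,
    blip_y: TrapGradient,
    caipi_blips: List[TrapGradient],
    ky_indices: np.ndarray,
    caipi_shift: int,
    sms_factor: int,
    echo_spacing: float,
    limits: SystemLimits,
) -> np.ndarray:
    """Raster-sampled (3, nt) gradient waveform of the alternating train,
    with the y blips and the actual CAIPI z-blip step/rewind pattern."""
    raster = limits.grad_raster_time
    n_echoes = len(ky_indices)
    nt_es = int(round(echo_spacing / raster))
    nt = nt_es * n_echoes
    t = (np.arange(nt) + 0.5) * raster
    g = np.zeros((3, nt))
    for e in range(n_echoes):
        t0 = e * echo_spacing
        local = t - t0
        sign = 1.0 if e % 2 == 0 else -1.0
        g[0] += sign * ro.value(local)
        if e < n_echoes - 1:
            g[1] += blip_y.value(local - ro.end_time)
            if sms_factor > 1 and caipi_shift > 1:
                step = int(ky_indices[e + 1]) % caipi_shift - int(
                    ky_indices[e]
                ) % caipi_shift
                bz = caipi_blips[0] if step == 1 else caipi_blips[1]
                g[2] += bz.value(local - ro.end_time)
    return g


def build_fatsat_block(
    p: ProtocolParams,
    limits: SystemLimits,
    field_strength: float = 3.0,
    max_slew: Optional[float] = None,
) -> Block:
    """Fat-saturation block: spectrally selective RF plus a z spoiler with
    at least 4 pi dephasing across one slice thickness."""
    spec = default_fatsat_spec(field_strength=field_strength)
    pulse = make_fatsat_pulse(spec, field_strength=field_strength, limits=limits)
    rf = RFEvent(
        signal=pulse.samples,
        t=pulse.t,
        delay=max(limits.rf_dead_time, 0.0),
        freq_offset=pulse.freq_offset,
        dead_time=limits.rf_dead_time,
        ringdown_time=limits.rf_ringdown_time,
    )
    spoil_area = 2.0 / p.slice_thickness  # 4 pi rad = 2 cycles across a voxel
    spoiler = make_trapezoid(
        "z", limits, area=spoil_area,
        delay=_round_raster(rf.end_time, limits.grad_raster_time),
        max_slew=max_slew,
    )
    return Block(rf=rf, gz=spoiler, label="fatsat")


@dataclass
class _Excitation:
    pulse: PulseShape
    grad: TrapGradient
    rephaser: TrapGradient
    base: PulseShape
    slice_grad_amplitude: float


def _design_excitation(
    p: ProtocolParams,
    limits: SystemLimits,
    n_bands: int,
    max_slew: Optional[float] = None,
) -> _Excitation:
    spec = SLRSpec(
        duration=p.rf_duration,
        time_bandwidth=p.rf_tbw,
        flip_angle=p.flip_angle,
        filter_type="linear_phase",
    )
    base, grad = design_slr_pulse(spec, p.slice_thickness, limits)
    if max_slew is not None:
        raster = limits.grad_raster_time
        rise = math.ceil(grad.amplitude / max_slew / raster) * raster
        grad = replace(grad, rise_time=rise, fall_time=rise)
    if n_bands > 1:
        sms = SMSSpec(
            n_bands=n_bands,
            band_separation=p.fov[2] / p.sms_factor,
            slice_thickness=p.slice_thickness,
        )
        pulse = synthesize_sms_pulse(base, sms, grad.amplitude, limits)
    else:
        pulse = base
    # rephase the slice-select gradient from the RF center to the end
    rf_delay = max(limits.rf_dead_time, grad.rise_time)
    grad = replace(grad, delay=rf_delay - grad.rise_time)
    center_t = rf_delay + pulse.duration / 2
    reph_area = -(
        float(grad.integral(grad.end_time)) - float(grad.integral(center_t))
    )
    rephaser = make_trapezoid("z", limits, area=reph_area, max_slew=max_slew)
    return _Excitation(pulse, grad, rephaser, base, grad.amplitude)


def _excitation_block(
    exc: _Excitation,
    p: ProtocolParams,
    limits: SystemLimits,
    freq_offset: float,
    phase_offset: float,
) -> Block:
    rf_delay = max(limits.rf_dead_time, exc.grad.rise_time)
    rf = RFEvent(
        signal=exc.pulse.samples,
        t=exc.pulse.t,
        delay=rf_delay,
        freq_offset=freq_offset,
        phase_offset=phase_offset,
        dead_time=limits.rf_dead_time,
        ringdown_time=limits.rf_ringdown_time,
    )
    return Block(rf=rf, gz=exc.grad, label="excite")


@dataclass
class ShotMap:
    """Block-index bookkeeping for one shot in the assembled sequence."""

    kind: str  # "reference" or "sms"
    volume: int  # -1 for reference; dummy volumes are negative after -1
    shot: int
    slices: np.ndarray
    excite_block: int
    echo_blocks: List[int]
    nav_blocks: List[int]
    rf_phase: float


def _shot_blocks(
    seq: SequenceObject,
    p: ProtocolParams,
    limits: SystemLimits,
    fatsat: Block,
    exc: _Excitation,
    readout: EPIReadout,
    shot_index: int,
    slices: np.ndarray,
    shot_duration: float,
    kind: str,
    volume: int,
    shot: int,
) -> ShotMap:
    """Append one complete shot; returns its block map."""
    phi = rf_spoiling_phase(shot_index)
    t_start = seq.duration
    seq.add_block(Block(rf=fatsat.rf, gz=fatsat.gz, label="fatsat"))
    # multiband excitation is synthesized symmetric about z=0; shift the
    # band comb to this shot's slices with a frequency offset
    zc = float(np.mean(p.slice_positions(slices)))
    freq = exc.slice_grad_amplitude * zc
    exc_block_idx = len(seq.blocks)
    pulse = exc.pulse if kind == "sms" else exc.base
    rf_delay = max(limits.rf_dead_time, exc.grad.rise_time)
    rf = RFEvent(
        signal=pulse.samples,
        t=pulse.t,
        delay=rf_delay,
        freq_offset=freq,
        phase_offset=phi,
        dead_time=limits.rf_dead_time,
        ringdown_time=limits.rf_ringdown_time,
    )
    seq.add_block(Block(rf=rf, gz=exc.grad, label="excite"))
    # slice rephaser + readout prewinder (x); ky prewinder comes after the
    # navigators so they sample ky = 0
    seq.add_block(
        Block(gz=exc.rephaser, gx=readout.prewinder_x, label="prewind_x")
    )
    ro = readout.readout
    nav_blocks: List[int] = []
    adc = replace(readout.adc, phase_offset=phi)
    for nav in range(p.n_navigators):
        sign = 1.0 if nav % 2 == 0 else -1.0
        nav_blocks.append(len(seq.blocks))
        seq.add_block(
            Block(
                gx=replace(ro, amplitude=sign * ro.amplitude),
                adc=adc,
                label="nav",
            ),
            duration=_round_raster(readout.echo_spacing, limits.block_duration_raster),
        )
    start_polarity = 1.0 if p.n_navigators % 2 == 0 else -1.0
    seq.add_block(Block(gy=readout.prewinder_y, label="prewind_y"))
    echo_blocks: List[int] = []
    kyi = p.ky_indices()
    for e in range(p.n_echoes):
        sign = start_polarity * (1.0 if e % 2 == 0 else -1.0)
        blk = Block(
            gx=replace(ro, amplitude=sign * ro.amplitude),
            adc=adc,
            label="echo",
        )
        if e < p.n_echoes - 1:
            blk.gy = replace(readout.blip_y, delay=ro.end_time)
            if kind == "sms" and p.sms_factor > 1:
                cyc = int(kyi[e]) % p.caipi_shift
                nxt = int(kyi[e + 1]) % p.caipi_shift
                step = nxt - cyc
                zb = (
                    readout.caipi_blips[0]
                    if step == 1
                    else readout.caipi_blips[1]
                )
                blk.gz = replace(zb, delay=ro.end_time)
        echo_blocks.append(len(seq.blocks))
        seq.add_block(
            blk,
            duration=_round_raster(readout.echo_spacing, limits.block_duration_raster),
        )
    # fill to the nominal shot duration
    elapsed = seq.duration - t_start
    fill = shot_duration - elapsed
    if fill < -1e-9:
        raise ValueError(
            f"shot duration {elapsed * 1e3:.2f} ms exceeds the budget "
            f"{shot_duration * 1e3:.2f} ms (TR too short for this protocol)"
        )
    if fill > 1e-9:
        seq.add_block(
            Block(label="tr_fill"),
            duration=_round_raster(fill, limits.block_duration_raster, up=False),
        )
    return ShotMap(
        kind=kind,
        volume=volume,
        shot=shot,
        slices=slices,
        excite_block=exc_block_idx,
        echo_blocks=echo_blocks,
        nav_blocks=nav_blocks,
        rf_phase=phi,
    )


@dataclass
class ProtocolSequence:
    """Assembled sequence plus shot bookkeeping."""

    seq: SequenceObject
    params: ProtocolParams
    readout: EPIReadout
    shots: List[ShotMap]
    excitation: _Excitation

    @property
    def reference_shots(self) -> List[ShotMap]:
        return [s for s in self.shots if s.kind == "reference"]

    @property
    def sms_shots(self) -> List[ShotMap]:
        return [s for s in self.shots if s.kind == "sms"]


def build_protocol(
    p: ProtocolParams,
    limits: Optional[SystemLimits] = None,
    pns_params: Optional[PNSParams] = None,
) -> ProtocolSequence:
    """Assemble the full protocol sequence.

    Layout: [reference segment: n_slices single-band 2D-EPI shots] then
    [(n_dummy + n_volumes) volumes of n_slices/sms_factor SMS shots]; each
    volume sums to exactly one TR of block durations.
    """
    limits = limits or SystemLimits()
    pns = pns_params or PNSParams()
    shot_duration = _round_raster(
        p.tr / p.n_shots_per_volume, limits.block_duration_raster, up=False
    )
    if abs(shot_duration * p.n_shots_per_volume - p.tr) > 1e-9:
        raise ValueError(
            "build_protocol: tr must be a multiple of "
            "n_shots_per_volume * block_duration_raster for exact volume timing"
        )

    # outer derating loop: the EPI-train design already limits the train's
    # prediction, but spoilers, rephasers and prewinders add to the peak;
    # rebuild with a reduced slew budget until one full TR (periodic, the
    # steady-state train) stays within the derating target
    p_iter = p
    for _ in range(30):
        seq = SequenceObject(system=limits)
        seq.definitions["Name"] = "smsepi"
        seq.definitions["FOV"] = tuple(p.fov)
        seq.definitions["TR"] = p.tr
        readout = design_epi_readout(p_iter, limits, pns_params)
        # auxiliary gradients get half the readout slew so simultaneous
        # multi-axis ramps cannot dominate the root-sum-of-squares
        aux_slew = readout.derated_slew / 2
        fatsat = build_fatsat_block(p, limits, max_slew=aux_slew)
        exc = _design_excitation(p, limits, p.sms_factor, max_slew=aux_slew)
        shots: List[ShotMap] = []
        shot_index = 0
        # single-band reference segment: one shot per slice
        for sl in range(p.n_slices):
            shots.append(
                _shot_blocks(
                    seq, p, limits, fatsat, exc, readout, shot_index,
                    np.array([sl]), shot_duration, "reference", -1, sl,
                )
            )
            shot_index += 1
        for v in range(p.n_dummy + p.n_volumes):
            vol = v - p.n_dummy  # dummies are negative
            for s in range(p.n_shots_per_volume):
                shots.append(
                    _shot_blocks(
                        seq, p, limits, fatsat, exc, readout, shot_index,
                        p.slices_of_shot(s), shot_duration, "sms", vol, s,
                    )
                )
                shot_index += 1
        ps = ProtocolSequence(seq, p, readout, shots, exc)
        res = predict_pns(
            seq, pns, t_range=(seq.duration - p.tr, seq.duration), periodic=True
        )
        if res.peak <= p.pns_derate * 100.0:
            return ps
        p_iter = replace(p_iter, initial_slew=readout.derated_slew * 0.95)
    raise ValueError(
        "build_protocol: could not satisfy the PNS derating target at any slew"
    )


def protocol_report(ps: ProtocolSequence, pns_params: Optional[PNSParams] = None) -> Dict[str, float]:
    """Summary quantities recomputed from the assembled event data."""
    seq, p = ps.seq, ps.params
    first = ps.sms_shots[0] if ps.sms_shots else ps.shots[0]
    # echo spacing from ADC start-time differences
    t = 0.0
    starts = {}
    for i, b in enumerate(seq.blocks):
        if b.adc is not None and i in first.echo_blocks:
            starts[i] = t + b.adc.delay
        t += b.duration
    times = [starts[i] for i in first.echo_blocks[:2]]
    echo_spacing = times[1] - times[0] if len(times) == 2 else float("nan")
    # TE: excitation RF center to the ky=0 echo center
    kyi = p.ky_indices()
    izero = int(np.argmin(np.abs(kyi)))
    t = 0.0
    te = float("nan")
    center = None
    for i, b in enumerate(seq.blocks):
        if i == first.excite_block and b.rf is not None:
            center = t + b.rf.center
        if i == first.echo_blocks[izero] and center is not None:
            mid = t + b.adc.delay + b.adc.num_samples * b.adc.dwell / 2
            te = mid - center
        t += b.duration
    adc = seq.blocks[first.echo_blocks[0]].adc
    # PNS over the final TR (a steady-state SMS volume), periodic wrap
    pns = predict_pns(
        seq, pns_params, t_range=(seq.duration - p.tr, seq.duration),
        periodic=True,
    )
    energy = rf_energy_report(seq, tr=p.tr)
    n_ref = len(ps.reference_shots)
    return {
        "te_s": te,
        "echo_spacing_s": echo_spacing,
        "readout_bandwidth_hz": 1.0 / adc.dwell,
        "total_duration_s": seq.duration,
        "reference_duration_s": n_ref * p.tr / p.n_shots_per_volume,
        "pns_peak_percent": pns.peak,
        "rf_energy_relative": energy["relative_to_reference"],
        "derated_slew_tms": ps.readout.derated_slew / tms_to_hzms(1.0),
        "flip_angle_deg": math.degrees(p.flip_angle),
        "n_echoes": float(p.n_echoes),
    }
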