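"""RF pulse design: SLR pulses, fat saturation, multiband (SMS) synthesis,
RF-spoiling phase schedule, and a Bloch simulator.

The Shinnar-Le Roux (SLR) transform maps RF pulse design onto the design
of two complex polynomials (A, B) with |A|^2 + |B|^2 = 1 on the unit
circle.  B is designed as an FIR filter whose magnitude response is the
target excitation profile (scaled by sin(flip/2)); A is obtained as the
minimum-phase spectral factor of 1 - |B|^2; the hard-pulse recursion is
then inverted to recover the RF waveform.  The Bloch simulator integrates
the rotation operators sample by sample and serves as the module's
independent oracle: a designed pulse is only trusted through its simulated
profile.

Multiband pulses are synthesized by frequency-modulating the single-band
pulse to each slice position and summing, with per-band phase offsets
chosen to minimize the peak amplitude (Wong-style phase schedule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .events import SystemLimits, TrapGradient, make_trapezoid
from .units import GAMMA_HZ_PER_T


@dataclass(frozen=True)
class SLRSpec:
    """Design parameters for an SLR pulse."""

    duration: float  # s
    time_bandwidth: float
    flip_angle: float  # rad
    filter_type: str = "linear_phase"  # or "minimum_phase"
    passband_ripple: float = 0.01
    stopband_ripple: float = 0.01

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("SLRSpec: duration must be > 0")
        if self.time_bandwidth < 1:
            raise ValueError("SLRSpec: time_bandwidth must be >= 1")
        if not (0 <= self.flip_angle <= math.pi):
            raise ValueError("SLRSpec: flip_angle must be in [0, pi]")
        if self.filter_type not in ("linear_phase", "minimum_phase"):
            raise ValueError("SLRSpec: unknown filter_type")

    @property
    def bandwidth(self) -> float:
        return self.time_bandwidth / self.duration


@dataclass
class PulseShape:
    """Complex RF samples (Hz) on a uniform raster."""

    samples: np.ndarray  # complex, Hz
    raster: float  # s
    bandwidth: float  # Hz, nominal
    freq_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)

    @property
    def duration(self) -> float:
        return self.samples.size * self.raster

    @property
    def t(self) -> np.ndarray:
        """Sample-center times."""
        return (np.arange(self.samples.size) + 0.5) * self.raster

    @property
    def peak(self) -> float:
        return float(np.abs(self.samples).max())

    def energy(self) -> float:
        """Integral of |b1|^2 dt, in Hz^2 s."""
        return float(np.sum(np.abs(self.samples) ** 2) * self.raster)


@dataclass
class SMSSpec:
    """Simultaneous-multislice excitation geometry."""

    n_bands: int
    band_separation: float  # m, center-to-center
    slice_thickness: float  # m
    phase_offsets: Optional[np.ndarray] = None  # rad per band

    def __post_init__(self) -> None:
        if self.n_bands < 1:
            raise ValueError("SMSSpec: n_bands must be >= 1")
        if self.band_separation < self.slice_thickness:
            raise ValueError("SMSSpec: band_separation must be >= slice_thickness")
        if self.phase_offsets is not None:
            self.phase_offsets = np.asarray(self.phase_offsets, dtype=float)
            if self.phase_offsets.size != self.n_bands:
                raise ValueError("SMSSpec: need one phase offset per band")

    def band_positions(self) -> np.ndarray:
        """Band centers in m, symmetric about 0."""
        b = np.arange(self.n_bands)
        return (b - (self.n_bands - 1) / 2) * self.band_separation


# ---------------------------------------------------------------------------
# SLR transform
# ---------------------------------------------------------------------------

def forward_slr(rf_rad: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Hard-pulse recursion: RF samples (complex radians) -> (a, b) coeffs.

    Polynomials are in powers of z^{-1}, ascending coefficient order.
    """
    rf_rad = np.asarray(rf_rad, dtype=complex)
    n = rf_rad.size
    a = np.zeros(n, dtype=complex)
    b = np.zeros(n, dtype=complex)
    a[0] = 1.0
    for j in range(n):
        theta = abs(rf_rad[j])
        C = math.cos(theta / 2)
        S = 1j * np.exp(1j * np.angle(rf_rad[j])) * math.sin(theta / 2)
        # free precession shifts b by z^{-1}, then rotation mixes
        b_shift = np.roll(b, 1)
        b_shift[0] = 0.0
        if j == 0:
            b_shift = b  # no precession before the first sample
        a_new = C * a - np.conj(S) * b_shift
        b_new = S * a + C * b_shift
        a, b = a_new, b_new
    return a, b


def inverse_slr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Invert the hard-pulse recursion: (a, b) -> RF samples (complex rad)."""
    a = np.asarray(a, dtype=complex).copy()
    b = np.asarray(b, dtype=complex).copy()
    n = a.size
    rf = np.zeros(n, dtype=complex)
    for j in range(n - 1, -1, -1):
        # lowest-order coefficients determine the j-th rotation
        theta = 2 * math.atan2(abs(b[0]), abs(a[0]))
        phi = np.angle(b[0] / a[0]) - math.pi / 2 if abs(a[0]) > 0 else 0.0
        rf[j] = theta * np.exp(1j * phi)
        C = math.cos(theta / 2)
        S = 1j * np.exp(1j * phi) * math.sin(theta / 2)
        a_prev = C * a + np.conj(S) * b
        b_prev = -S * a + C * b
        if j > 0:
            # undo the z^{-1} precession: b_prev must have zero constant term
            b_prev = np.roll(b_prev, -1)
            b_prev[-1] = 0.0
        a, b = a_prev, b_prev
    return rf


def _dinf(d1: float, d2: float) -> float:
    """Empirical transition-width factor for equiripple filters."""
    a1, a2, a3 = 5.309e-3, 7.114e-2, -4.761e-1
    a4, a5, a6 = -2.66e-3, -5.941e-1, -4.278e-1
    l1, l2 = math.log10(d1), math.log10(d2)
    return (a1 * l1**2 + a2 * l1 + a3) * l2 + (a4 * l1**2 + a5 * l1 + a6)


def _beta_filter(n: int, tbw: float, d1: float, d2: float, minimum_phase: bool) -> np.ndarray:
    """Design the SLR beta polynomial (unit passband) of length n."""
    if minimum_phase:
        # design |B|^2 as a linear-phase prototype of length 2n-1, then
        # spectral-factorize; the squared response carries doubled passband
        # and squared stopband ripples and achieves half the transition
        n2 = 2 * n - 1
        d1sq, d2sq = 2 * d1, (d2**2) / 2
        w = 0.5 * _dinf(d1sq, d2sq) / tbw
        fp = (1 - w) * tbw / (2 * n)
        fs = (1 + w) * tbw / (2 * n)
        h = _equiripple(n2, fp, fs, d1sq, d2sq)
        # ensure nonnegative response before factorization
        wgrid, resp = sps.freqz(h, worN=8 * 2 ** int(math.ceil(math.log2(n2))))
        resp = np.real(resp * np.exp(1j * wgrid * (n2 - 1) / 2))
        h = h / np.abs(resp).max()
        resp_min = resp.min() / np.abs(resp).max()
        if resp_min < 0:
            h = h * (1 / (1 - resp_min))
            h[(n2 - 1) // 2] += -resp_min / (1 - resp_min)
        b = _min_phase_factor(h, n)
        return b / np.abs(np.fft.fft(b, 16 * n)).max()
    w = _dinf(d1, d2) / tbw
    fp = (1 - w) * tbw / n / 2
    fs = (1 + w) * tbw / n / 2
    return _equiripple(n, fp, fs, d1, d2)


def _equiripple(n: int, fp: float, fs: float, d1: float, d2: float) -> np.ndarray:
    """Parks-McClellan bandpass design with least-squares fallback."""
    bands = [0.0, max(fp, 1e-4), min(fs, 0.5 - 1e-4), 0.5]
    try:
        h = sps.remez(n, bands, [1, 0], weight=[1 / d1, 1 / d2], fs=1.0, maxiter=100)
        if np.all(np.isfinite(h)):
            return h
    except Exception:
        pass
    return sps.firls(n if n % 2 == 1 else n + 1, bands, [1, 1, 0, 0], fs=1.0)[:n]


def _min_phase_factor(h: np.ndarray, n: int) -> np.ndarray:
    """Minimum-phase spectral factor of the nonnegative response of `h`
    (a linear-phase FIR of length 2n-1), via the cepstral method."""
    nfft = 4 * 2 ** int(math.ceil(math.log2(h.size * 8)))
    wgrid = np.arange(nfft) * 2 * np.pi / nfft
    resp = np.fft.fft(h, nfft) * np.exp(1j * wgrid * (h.size - 1) / 2)
    mag2 = np.maximum(np.real(resp), 1e-12)
    log_mag = 0.5 * np.log(mag2)
    cep = np.fft.ifft(log_mag)
    fold = cep.copy()
    fold[1 : nfft // 2] *= 2
    fold[nfft // 2 + 1 :] = 0
    min_spec = np.exp(np.fft.fft(fold))
    bmin = np.fft.ifft(min_spec)[:n]
    return np.real_if_close(bmin, tol=1e6).astype(complex)


# ---------------------------------------------------------------------------
# pulse design
# ---------------------------------------------------------------------------

def _design_raster(duration: float, limits: SystemLimits, n_target: int = 400) -> float:
    """Pick a design raster: a multiple of the RF raster giving ~n_target samples."""
    k = max(1, round(duration / (limits.rf_raster_time * n_target)))
    return k * limits.rf_raster_time


def design_slr_rf(spec: SLRSpec, limits: Optional[SystemLimits] = None) -> PulseShape:
    """Design an SLR excitation/saturation pulse (no gradient context)."""
    limits = limits or SystemLimits()
    raster = _design_raster(spec.duration, limits)
    n = max(8, round(spec.duration / raster))
    if spec.flip_angle == 0:
        return PulseShape(np.zeros(n, dtype=complex), raster, spec.bandwidth)
    # effective B-polynomial ripples for an excitation pulse
    d1 = math.sqrt(spec.passband_ripple / 2)
    d2 = spec.stopband_ripple / math.sqrt(2)
    b = _beta_filter(n, spec.time_bandwidth, d1, d2, spec.filter_type == "minimum_phase")
    b = np.asarray(b, dtype=complex)
    # normalize passband response to sin(flip/2)
    nfft = 32 * 2 ** int(math.ceil(math.log2(n)))
    bresp = np.abs(np.fft.fft(b, nfft))
    b = b * math.sin(spec.flip_angle / 2) / bresp.max()
    a = _a_from_b(b)
    rf_rad = inverse_slr(a, b)
    if spec.filter_type == "linear_phase":
        # a linear-phase design yields a (nearly) symmetric pulse; remove the
        # residual global phase so the waveform is real-valued on resonance
        rf_rad = rf_rad * np.exp(-1j * np.angle(rf_rad[np.argmax(np.abs(rf_rad))]))
    rf_hz = rf_rad / (2 * np.pi * raster)
    return PulseShape(rf_hz, raster, spec.bandwidth)


def _a_from_b(b: np.ndarray) -> np.ndarray:
    """Minimum-phase A polynomial with |A|^2 = 1 - |B|^2 on the unit circle."""
    n = b.size
    nfft = 16 * 2 ** int(math.ceil(math.log2(n)))
    Bw = np.fft.fft(b, nfft)
    mag2 = np.maximum(1.0 - np.abs(Bw) ** 2, 1e-12)
    log_mag = 0.5 * np.log(mag2)
    cep = np.fft.ifft(log_mag)
    fold = cep.copy()
    fold[1 : nfft // 2] *= 2
    fold[nfft // 2 + 1 :] = 0
    Aw = np.exp(np.fft.fft(fold))
    a = np.fft.ifft(Aw)[:n]
    return a


def design_slr_pulse(
    spec: SLRSpec, thickness: float, limits: Optional[SystemLimits] = None
) -> Tuple[PulseShape, TrapGradient]:
    """Design a slice-selective SLR pulse and its slice-select trapezoid.

    The gradient amplitude is bandwidth/thickness; the returned trapezoid
    has its flat top covering the RF shape (the caller sets delays when
    placing both into a block).  Raises if the required gradient exceeds
    the hardware limit.
    """
    if thickness <= 0:
        raise ValueError("design_slr_pulse: thickness must be > 0")
    limits = limits or SystemLimits()
    g_nominal = spec.bandwidth / thickness  # Hz/m
    if g_nominal > limits.max_gradient:
        raise ValueError(
            f"slice-select gradient {g_nominal:.3g} Hz/m exceeds max_gradient "
            f"{limits.max_gradient:.3g} Hz/m; increase the pulse duration "
            "or the slice thickness"
        )
    pulse = design_slr_rf(spec, limits)
    # calibrate the gradient to the *delivered* excitation bandwidth: the
    # filter recipe's half-max width differs slightly from the nominal
    # time-bandwidth, so measure it with the Bloch oracle and set
    # g = FWHM_freq / thickness, making the slice width exact by design
    g_amp = g_nominal
    if spec.flip_angle > 0:
        freqs = np.linspace(-1.5 * spec.bandwidth, 1.5 * spec.bandwidth, 241)
        # a unit gradient with "positions" equal to the frequencies sweeps
        # the off-resonance axis in a single vectorized call
        prof = bloch_simulate(
            pulse, grad=np.ones(pulse.samples.size), positions=freqs
        )
        mxy = prof[:, 0] + 1j * prof[:, 1]
        fwhm_hz = profile_fwhm(freqs, mxy)
        if 0.5 * spec.bandwidth < fwhm_hz < 1.5 * spec.bandwidth:
            g_amp = fwhm_hz / thickness
    if g_amp > limits.max_gradient:
        raise ValueError(
            "calibrated slice-select gradient exceeds max_gradient; "
            "increase the pulse duration"
        )
    raster = limits.grad_raster_time
    rise = math.ceil(g_amp / limits.max_slew / raster) * raster
    flat = math.ceil(round(pulse.duration / raster, 9)) * raster
    grad = TrapGradient("z", g_amp, rise, flat, rise)
    return pulse, grad


def make_fatsat_pulse(
    spec: SLRSpec,
    fat_shift_ppm: float = -3.45,
    field_strength: float = 3.0,
    limits: Optional[SystemLimits] = None,
) -> PulseShape:
    """Spectrally selective fat-saturation pulse (minimum-phase SLR).

    The pulse is played with a frequency offset at the fat resonance; its
    bandwidth must keep water (0 ppm) in the stopband.
    """
    if field_strength <= 0:
        raise ValueError("make_fatsat_pulse: field_strength must be > 0")
    offset = fat_shift_ppm * GAMMA_HZ_PER_T * field_strength / 1e6
    bw = spec.bandwidth
    # water must lie beyond the stopband edge of the shifted profile
    w = _dinf(spec.passband_ripple, spec.stopband_ripple) / spec.time_bandwidth
    stop_edge = (1 + w) * bw / 2
    if abs(offset) <= stop_edge:
        raise ValueError(
            f"fat-sat bandwidth {bw:.1f} Hz overlaps the water resonance "
            f"(offset {offset:.1f} Hz); narrow the bandwidth"
        )
    pulse = design_slr_rf(spec, limits)
    pulse.freq_offset = offset
    return pulse


def default_fatsat_spec(
    fat_shift_ppm: float = -3.45, field_strength: float = 3.0
) -> SLRSpec:
    """Fat-sat design defaults: 90 deg minimum-phase pulse whose bandwidth
    is 35% of the fat-water separation."""
    sep = abs(fat_shift_ppm) * GAMMA_HZ_PER_T * field_strength / 1e6
    bw = 0.35 * sep
    tbw = 2.0
    return SLRSpec(
        duration=tbw / bw,
        time_bandwidth=tbw,
        flip_angle=math.pi / 2,
        filter_type="minimum_phase",
    )


# ---------------------------------------------------------------------------
# multiband synthesis
# ---------------------------------------------------------------------------

def optimize_band_phases(
    base: PulseShape, freqs: Sequence[float], n_restarts: int = 12, seed: int = 12345
) -> np.ndarray:
    """Per-band phase offsets minimizing the peak of the synthesized pulse.

    Bounded random-restart Nelder-Mead over the (n_bands - 1) free phases
    (the first band's phase is fixed at 0).  Deterministic for a given seed.
    """
    from scipy.optimize import minimize

    freqs = np.asarray(freqs, dtype=float)
    nb = freqs.size
    if nb < 2:
        return np.zeros(nb)
    t = base.t

    def peak(phis_free: np.ndarray) -> float:
        phis = np.concatenate([[0.0], phis_free])
        mod = np.exp(1j * (2 * np.pi * freqs[:, None] * t[None, :] + phis[:, None]))
        return float(np.abs(base.samples[None, :] * mod).sum(axis=0).max())

    rng = np.random.default_rng(seed)
    best = np.zeros(nb - 1)
    best_val = peak(best)
    for _ in range(n_restarts):
        x0 = rng.uniform(0, 2 * np.pi, nb - 1)
        res = minimize(peak, x0, method="Nelder-Mead",
                       options={"maxiter": 400 * nb, "fatol": 1e-6})
        if res.fun < best_val:
            best_val = res.fun
            best = res.x
    return np.concatenate([[0.0], np.mod(best, 2 * np.pi)])


def synthesize_sms_pulse(
    base: PulseShape,
    sms: SMSSpec,
    slice_grad_amplitude: float,
    limits: Optional[SystemLimits] = None,
) -> PulseShape:
    """Sum frequency-shifted copies of `base` to excite `n_bands` slices.

    result(t) = sum_b base(t) * exp(i (2 pi f_b t + phi_b)), with
    f_b = g_ss * z_b the per-band frequency offsets.  Phase offsets default
    to the peak-minimizing schedule.  Raises if the synthesized peak
    exceeds the RF amplitude limit.
    """
    limits = limits or SystemLimits()
    if sms.n_bands == 1:
        return PulseShape(base.samples.copy(), base.raster, base.bandwidth,
                          base.freq_offset)
    freqs = slice_grad_amplitude * sms.band_positions()
    phis = (
        sms.phase_offsets
        if sms.phase_offsets is not None
        else optimize_band_phases(base, freqs)
    )
    t = base.t
    mod = np.exp(1j * (2 * np.pi * freqs[:, None] * t[None, :] + np.asarray(phis)[:, None]))
    samples = (base.samples[None, :] * mod).sum(axis=0)
    peak = float(np.abs(samples).max())
    if peak > limits.max_rf_amplitude:
        raise ValueError(
            f"multiband peak {peak:.1f} Hz exceeds max_rf_amplitude "
            f"{limits.max_rf_amplitude:.1f} Hz; stretch the pulse duration"
        )
    return PulseShape(samples, base.raster, base.bandwidth, base.freq_offset)


# ---------------------------------------------------------------------------
# RF spoiling
# ---------------------------------------------------------------------------

RF_SPOIL_INCREMENT = math.radians(117.0)


def rf_spoiling_phase(n: int, increment: float = RF_SPOIL_INCREMENT) -> float:
    """Quadratic RF-spoiling phase of shot n: phi_n = inc * n(n+1)/2 mod 2pi.

    The same phase must be applied to the excitation pulse and to the
    receiver (ADC) of that shot.
    """
    if n < 0:
        raise ValueError("rf_spoiling_phase: n must be >= 0")
    tri = (n * (n + 1)) // 2
    return float(math.fmod(increment * tri, 2 * math.pi))


# ---------------------------------------------------------------------------
# Bloch simulation (test oracle)
# ---------------------------------------------------------------------------

def bloch_simulate(
    rf: PulseShape | np.ndarray,
    grad: Optional[np.ndarray] = None,
    positions: np.ndarray = np.array([0.0]),
    off_resonance: float = 0.0,
    raster: Optional[float] = None,
    m0: Tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> np.ndarray:
    """Integrate the Bloch equations (no relaxation) through an RF shape.

    `rf` supplies complex B1 samples in Hz; `grad` is the slice gradient in
    Hz/m on the same raster (scalar per sample), or None for zero.  Returns
    magnetization (npos, 3) after the pulse for each position (m).
    """
    if isinstance(rf, PulseShape):
        b1 = rf.samples
        dt = rf.raster
        df0 = rf.freq_offset
    else:
        b1 = np.asarray(rf, dtype=complex)
        if raster is None:
            raise ValueError("bloch_simulate: raster required for raw arrays")
        dt = raster
        df0 = 0.0
    n = b1.size
    if grad is None:
        grad = np.zeros(n)
    grad = np.asarray(grad, dtype=float)
    if grad.size != n:
        raise ValueError("bloch_simulate: rf and gradient waveform lengths differ")
    positions = np.atleast_1d(np.asarray(positions, dtype=float))
    npos = positions.size
    M = np.tile(np.asarray(m0, dtype=float), (npos, 1))
    for j in range(n):
        bx = np.full(npos, b1[j].real)
        by = np.full(npos, b1[j].imag)
        bz = grad[j] * positions + off_resonance - df0
        # rotate about the effective field; RF plays in the rotating frame
        bmag = np.sqrt(bx**2 + by**2 + bz**2)
        angle = -2 * np.pi * bmag * dt
        nonzero = bmag > 0
        if not np.any(nonzero):
            continue
        ax = np.zeros(npos)
        ay = np.zeros(npos)
        az = np.zeros(npos)
        ax[nonzero] = bx[nonzero] / bmag[nonzero]
        ay[nonzero] = by[nonzero] / bmag[nonzero]
        az[nonzero] = bz[nonzero] / bmag[nonzero]
        c = np.cos(angle)
        s = np.sin(angle)
        axis = np.stack([ax, ay, az], axis=1)
        dot = (axis * M).sum(axis=1)
        cross = np.cross(axis, M)
        M = (
            M * c[:, None]
            + cross * s[:, None]
            + axis * (dot * (1 - c))[:, None]
        )
    return M


def profile_fwhm(z: np.ndarray, mxy: np.ndarray) -> float:
    """Full width at half maximum of |Mxy(z)| by linear interpolation."""
    mag = np.abs(mxy)
    half = mag.max() / 2
    above = mag >= half
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return 0.0
    i0, i1 = idx[0], idx[-1]

    def edge(i_out, i_in):
        if i_out < 0 or i_out >= mag.size:
            return z[i_in]
        f = (half - mag[i_out]) / (mag[i_in] - mag[i_out])
        return z[i_out] + f * (z[i_in] - z[i_out])

    left = edge(i0 - 1, i0)
    right = edge(i1 + 1, i1)
    return float(abs(right - left))


def count_bands(z: np.ndarray, mxy: np.ndarray, rel_height: float = 0.5) -> int:
    """Count distinct excitation bands above `rel_height` of the peak."""
    mag = np.abs(mxy)
    above = mag >= rel_height * mag.max()
    transitions = np.diff(above.astype(int))
    rising = int((transitions == 1).sum()) + int(above[0])
    return rising
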