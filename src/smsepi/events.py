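"""Sequence event data model: hardware limits, RF, gradient and ADC events.

A pulse sequence is a list of non-overlapping blocks executed back to back.
Each block holds at most one RF pulse, one gradient per axis, and one ADC
window.  Events are plain dataclasses; they carry physical values
(gamma-normalized gradient units, Hz for RF amplitude) and validate only
their intrinsic invariants at construction.  Validation against a
particular hardware profile is a separate step (`sequence.validate_sequence`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .units import GAMMA_HZ_PER_T, mtm_to_hzm, tms_to_hzms

CHANNELS = ("x", "y", "z")

#: Common denominator for all raster times (100 ns).
RASTER_UNIT = 100e-9


def _on_raster(value: float, raster: float, tol: float = 1e-6) -> bool:
    """True if `value` is an integer multiple of `raster` (relative tol)."""
    if raster <= 0:
        return False
    n = value / raster
    return abs(n - round(n)) <= tol * max(1.0, abs(n))


@dataclass(frozen=True)
class SystemLimits:
    """Hardware capability profile a sequence is designed against.

    All gradient quantities are gamma-normalized (Hz/m, Hz/m/s).  Raster
    times must be integer multiples of 100 ns, matching the granularity of
    current vendor waveform memories.
    """

    max_rf_amplitude: float = 25e-6 * GAMMA_HZ_PER_T  # Hz (25 uT)
    rf_dead_time: float = 100e-6
    rf_ringdown_time: float = 60e-6
    rf_raster_time: float = 1e-6
    max_gradient: float = mtm_to_hzm(50.0)  # Hz/m
    max_slew: float = tms_to_hzms(200.0)  # Hz/m/s
    grad_raster_time: float = 10e-6
    adc_dead_time: float = 20e-6
    adc_raster_time: float = 100e-9
    block_duration_raster: float = 10e-6

    def __post_init__(self) -> None:
        for name in (
            "max_rf_amplitude",
            "rf_dead_time",
            "rf_ringdown_time",
            "rf_raster_time",
            "max_gradient",
            "max_slew",
            "grad_raster_time",
            "adc_dead_time",
            "adc_raster_time",
            "block_duration_raster",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SystemLimits.{name} must be strictly positive")
        for name in (
            "rf_raster_time",
            "grad_raster_time",
            "adc_raster_time",
            "block_duration_raster",
        ):
            if not _on_raster(getattr(self, name), RASTER_UNIT):
                raise ValueError(
                    f"SystemLimits.{name} must be an integer multiple of 100 ns"
                )


@dataclass
class RFEvent:
    """A shaped RF pulse.

    `signal` holds complex amplitude samples in Hz; `t` their times in
    seconds relative to the start of the pulse (after `delay`).
    """

    signal: np.ndarray
    t: np.ndarray
    delay: float = 0.0
    freq_offset: float = 0.0
    ppm_offset: float = 0.0
    phase_offset: float = 0.0
    dead_time: float = 0.0
    ringdown_time: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=complex)
        self.t = np.asarray(self.t, dtype=float)
        if self.signal.shape != self.t.shape:
            raise ValueError("RFEvent: signal and t must have equal length")
        if self.t.size == 0:
            raise ValueError("RFEvent: empty waveform")
        if self.t[0] < 0 or np.any(np.diff(self.t) <= 0):
            raise ValueError("RFEvent: t must be strictly increasing and start >= 0")
        if self.delay < self.dead_time:
            raise ValueError("RFEvent: delay must be >= dead_time")

    @property
    def shape_duration(self) -> float:
        return float(self.t[-1])

    @property
    def end_time(self) -> float:
        """End of the event within its block, including ringdown."""
        return self.delay + self.shape_duration + self.ringdown_time

    @property
    def center(self) -> float:
        """Effective center (time of peak |signal|) relative to block start."""
        mag = np.abs(self.signal)
        peak = mag.max()
        idx = np.flatnonzero(mag >= peak * (1 - 1e-9))
        return self.delay + float(self.t[idx[len(idx) // 2]])


@dataclass
class TrapGradient:
    """Trapezoidal gradient: ramp up, flat top, ramp down.  Starts/ends at 0."""

    channel: str
    amplitude: float  # Hz/m
    rise_time: float
    flat_time: float
    fall_time: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"TrapGradient: channel must be one of {CHANNELS}")
        if min(self.rise_time, self.flat_time, self.fall_time, self.delay) < 0:
            raise ValueError("TrapGradient: times must be nonnegative")
        if (self.rise_time == 0) != (self.fall_time == 0) and self.amplitude != 0:
            # zero-time ramps on a nonzero trapezoid would be an infinite slew
            pass
        if self.amplitude != 0 and (self.rise_time == 0 or self.fall_time == 0):
            raise ValueError("TrapGradient: nonzero amplitude requires nonzero ramps")

    @property
    def area(self) -> float:
        """Zeroth moment in 1/m (k-space displacement)."""
        return self.amplitude * (self.rise_time / 2 + self.flat_time + self.fall_time / 2)

    @property
    def flat_area(self) -> float:
        return self.amplitude * self.flat_time

    @property
    def end_time(self) -> float:
        return self.delay + self.rise_time + self.flat_time + self.fall_time

    @property
    def first(self) -> float:
        return 0.0

    @property
    def last(self) -> float:
        return 0.0

    def value(self, t):
        """Gradient value (Hz/m) at block-local time(s) t."""
        t = np.asarray(t, dtype=float)
        tt = t - self.delay
        r, f_, d = self.rise_time, self.flat_time, self.fall_time
        out = np.zeros_like(tt)
        if self.amplitude != 0:
            up = (tt >= 0) & (tt < r)
            out[up] = self.amplitude * tt[up] / r
            flat = (tt >= r) & (tt <= r + f_)
            out[flat] = self.amplitude
            down = (tt > r + f_) & (tt <= r + f_ + d)
            out[down] = self.amplitude * (r + f_ + d - tt[down]) / d
        return out

    def integral(self, t):
        """Cumulative integral of the waveform from block start to time(s) t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        tt = np.clip(t - self.delay, 0.0, self.rise_time + self.flat_time + self.fall_time)
        r, f_, d = self.rise_time, self.flat_time, self.fall_time
        a = self.amplitude
        out = np.zeros_like(tt)
        if a != 0:
            m1 = tt <= r
            out[m1] = a * tt[m1] ** 2 / (2 * r)
            m2 = (tt > r) & (tt <= r + f_)
            out[m2] = a * r / 2 + a * (tt[m2] - r)
            m3 = tt > r + f_
            td = tt[m3] - r - f_
            out[m3] = a * r / 2 + a * f_ + a * td - a * td**2 / (2 * d)
        return out if out.size > 1 else float(out[0])


@dataclass
class ArbGradient:
    """Arbitrary gradient waveform sampled on the gradient raster.

    Samples are taken to sit at raster-center times
    ``delay + (i + 1/2) * raster``; the waveform is piecewise linear
    between samples and holds `first`/`last` edge values at its ends so
    continuity across block boundaries is well defined.
    """

    channel: str
    waveform: np.ndarray  # Hz/m
    raster: float
    delay: float = 0.0
    first: float = 0.0
    last: float = 0.0

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"ArbGradient: channel must be one of {CHANNELS}")
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.size == 0:
            raise ValueError("ArbGradient: empty waveform")
        if self.raster <= 0 or self.delay < 0:
            raise ValueError("ArbGradient: raster must be > 0 and delay >= 0")

    @property
    def shape_duration(self) -> float:
        return self.waveform.size * self.raster

    @property
    def end_time(self) -> float:
        return self.delay + self.shape_duration

    @property
    def area(self) -> float:
        times, values = self._times_and_values()
        return float(np.trapezoid(values, times))

    def _times_and_values(self):
        n = self.waveform.size
        tc = self.delay + (np.arange(n) + 0.5) * self.raster
        times = np.concatenate([[self.delay], tc, [self.delay + n * self.raster]])
        values = np.concatenate([[self.first], self.waveform, [self.last]])
        return times, values

    def value(self, t):
        times, values = self._times_and_values()
        t = np.asarray(t, dtype=float)
        out = np.interp(t, times, values, left=0.0, right=0.0)
        return out

    def integral(self, t):
        """Cumulative trapezoidal integral from block start to time(s) t."""
        times, values = self._times_and_values()
        cum = np.concatenate([[0.0], np.cumsum(np.diff(times) * (values[1:] + values[:-1]) / 2)])
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.interp(t, times, cum, left=0.0, right=cum[-1])
        return out if out.size > 1 else float(out[0])


Gradient = Union[TrapGradient, ArbGradient]


@dataclass
class ADCEvent:
    """Data acquisition window with `num_samples` samples of width `dwell`.

    Sample *centers* sit at ``delay + (i + 1/2) * dwell``.
    """

    num_samples: int
    dwell: float
    delay: float = 0.0
    freq_offset: float = 0.0
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.num_samples <= 0:
            raise ValueError("ADCEvent: num_samples must be > 0")
        if self.dwell <= 0:
            raise ValueError("ADCEvent: dwell must be > 0")
        if self.delay < 0:
            raise ValueError("ADCEvent: delay must be >= 0")

    @property
    def sample_times(self) -> np.ndarray:
        return self.delay + (np.arange(self.num_samples) + 0.5) * self.dwell

    @property
    def end_time(self) -> float:
        return self.delay + self.num_samples * self.dwell


@dataclass
class Block:
    """One sequence block: at most one RF, one gradient per axis, one ADC."""

    rf: Optional[RFEvent] = None
    gx: Optional[Gradient] = None
    gy: Optional[Gradient] = None
    gz: Optional[Gradient] = None
    adc: Optional[ADCEvent] = None
    duration: float = 0.0
    label: str = ""

    def gradient(self, channel: str) -> Optional[Gradient]:
        return {"x": self.gx, "y": self.gy, "z": self.gz}[channel]

    @property
    def events_end(self) -> float:
        ends = [0.0]
        if self.rf is not None:
            ends.append(self.rf.end_time)
        for ch in CHANNELS:
            g = self.gradient(ch)
            if g is not None:
                ends.append(g.end_time)
        if self.adc is not None:
            ends.append(self.adc.end_time)
        return max(ends)


def make_trapezoid(
    channel: str,
    limits: SystemLimits,
    *,
    area: Optional[float] = None,
    amplitude: Optional[float] = None,
    flat_time: Optional[float] = None,
    rise_time: Optional[float] = None,
    duration: Optional[float] = None,
    delay: float = 0.0,
    max_slew: Optional[float] = None,
    max_grad: Optional[float] = None,
) -> TrapGradient:
    """Design a trapezoid on the gradient raster.

    Mirrors the usual toolbox helper: specify either (`area`,) possibly with
    a `duration`, or (`amplitude`, `flat_time`).  Ramps are rounded up to
    the raster; when rounding, the amplitude is rescaled so the requested
    area is hit exactly.
    """
    smax = max_slew if max_slew is not None else limits.max_slew
    gmax = max_grad if max_grad is not None else limits.max_gradient
    raster = limits.grad_raster_time

    def ceil_raster(t: float) -> float:
        return math.ceil(round(t / raster, 9)) * raster

    if amplitude is not None and flat_time is not None:
        rise = rise_time if rise_time is not None else abs(amplitude) / smax
        rise = max(ceil_raster(rise), raster)
        return TrapGradient(channel, amplitude, rise, ceil_raster(flat_time), rise, delay)

    if area is None:
        raise ValueError("make_trapezoid: specify area or (amplitude, flat_time)")
    if area == 0:
        return TrapGradient(channel, 0.0, 0.0, 0.0, 0.0, delay)

    sign = 1.0 if area > 0 else -1.0
    a = abs(area)
    # triangle feasible?
    g_tri = math.sqrt(a * smax)
    if g_tri <= gmax:
        rise = max(ceil_raster(g_tri / smax), raster)
        flat = 0.0
        amp = a / rise  # triangle: area = amp * rise (rise == fall)
        while amp / rise > smax * (1 + 1e-9):
            rise += raster
            amp = a / rise
    else:
        rise = max(ceil_raster(gmax / smax), raster)
        flat = ceil_raster(a / gmax - rise)
        amp = a / (rise + flat)
        while amp > gmax * (1 + 1e-9):
            flat += raster
            amp = a / (rise + flat)
    if duration is not None:
        total = ceil_raster(duration)
        if total < 2 * rise + flat - 1e-12:
            raise ValueError("make_trapezoid: requested duration too short")
        flat = total - 2 * rise
        amp = a / (rise + flat)
    return TrapGradient(channel, sign * amp, rise, flat, rise, delay)


def scale_trapezoid(g: TrapGradient, factor: float) -> TrapGradient:
    return replace(g, amplitude=g.amplitude * factor)
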