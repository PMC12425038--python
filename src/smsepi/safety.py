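"""Design-phase safety estimation: peripheral nerve stimulation (PNS) and
relative RF energy.

Two PNS predictors are provided, both driven by the per-axis gradient slew
rate on the gradient raster:

* the nerve impulse-response convolution model (the form used on GE
  systems): each axis' slew rate (converted to an effective coil dB/dt via
  an effective coil length) is convolved with the normalized nerve impulse
  response h(t) = c / (c + t)^2, where c is the chronaxie; the response is
  expressed as a percentage of the rheobase.
* the SAFE filter model (the form used on Siemens systems): a weighted
  cascade of three first-order low-pass responses to the rectified slew
  rate per axis.

Axis responses are combined by root-sum-of-squares.  Both models are
linear or positively homogeneous in the gradient amplitude, so derating
the slew scales the prediction proportionally.

Default impulse-response constants are the published GE whole-body
gradient values (rheobase 23.4 T/s, chronaxie 334 us, effective coil
length 0.333 m), which correspond to an effective slew-rate rheobase of
~70 T/m/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .events import CHANNELS, SystemLimits
from .sequence import SequenceObject
from .units import GAMMA_HZ_PER_T


@dataclass(frozen=True)
class PNSParams:
    """Nerve stimulation model constants.

    `rheobase` is in T/s (coil dB/dt), `chronaxie` in s, and
    `effective_length` in m converts gradient slew (T/m/s) to dB/dt.
    For the SAFE model, `safe_weights` and `safe_taus` give the three
    filter weights (summing to ~1) and time constants per cascade stage;
    they are applied identically on each axis.
    """

    model: str = "impulse_response"
    rheobase: float = 23.4  # T/s
    chronaxie: float = 334e-6  # s
    effective_length: float = 0.333  # m
    # SAFE cascade constants: 3-exponential least-squares approximation of
    # the chronaxie impulse response c/(c+t)^2, so both predictors share a
    # common physiological scale.  The shortest stage filters the
    # rectified slew; the slower stages filter the signed slew and are
    # taken in magnitude (published SAFE cascade structure).
    safe_weights: Tuple[float, float, float] = (0.153, 0.453, 0.340)
    safe_taus: Tuple[float, float, float] = (0.109e-3, 0.336e-3, 1.472e-3)

    def __post_init__(self) -> None:
        if self.rheobase <= 0 or self.chronaxie <= 0 or self.effective_length <= 0:
            raise ValueError("PNSParams: rheobase, chronaxie, effective_length > 0")
        if any(w < 0 for w in self.safe_weights):
            raise ValueError("PNSParams: SAFE weights must be nonnegative")
        if self.model not in ("impulse_response", "safe"):
            raise ValueError("PNSParams: model must be impulse_response or safe")


@dataclass
class PNSResult:
    """Per-sample stimulation prediction as % of the limit."""

    time: np.ndarray  # s
    pns_percent: np.ndarray  # combined, % of limit
    per_axis: np.ndarray  # (3, nt) % of limit

    @property
    def peak(self) -> float:
        return float(self.pns_percent.max()) if self.pns_percent.size else 0.0

    @property
    def time_of_peak(self) -> float:
        if not self.pns_percent.size:
            return 0.0
        return float(self.time[int(np.argmax(self.pns_percent))])


def gradient_waveforms(
    seq: SequenceObject,
    t_range: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sample all three gradient channels on the raster over `t_range`.

    Returns (t, g) with g of shape (3, nt) in Hz/m; samples are taken at
    raster centers.
    """
    raster = seq.system.grad_raster_time
    t0, t1 = (0.0, seq.duration) if t_range is None else t_range
    nt = int(round((t1 - t0) / raster))
    t = t0 + (np.arange(nt) + 0.5) * raster
    g = np.zeros((3, nt))
    start = 0.0
    for b in seq.blocks:
        end = start + b.duration
        if end > t0 and start < t1:
            sel = (t >= start) & (t < end)
            if np.any(sel):
                local = t[sel] - start
                for a, ch in enumerate(CHANNELS):
                    ev = b.gradient(ch)
                    if ev is not None:
                        g[a, sel] += ev.value(local)
        start = end
        if start >= t1:
            break
    return t, g


def _slew_tms(g: np.ndarray, dt: float, periodic: bool) -> np.ndarray:
    """Per-axis slew rate in T/m/s from gamma-normalized waveforms."""
    g_t = g / GAMMA_HZ_PER_T
    if periodic:
        prev = np.roll(g_t, 1, axis=-1)
    else:
        prev = np.concatenate([np.zeros((g.shape[0], 1)), g_t[:, :-1]], axis=-1)
    return (g_t - prev) / dt


def pns_impulse_response(
    grads: np.ndarray,
    dt: float,
    params: Optional[PNSParams] = None,
    periodic: bool = False,
) -> PNSResult:
    """Nerve impulse-response PNS prediction.

    `grads` is (3, nt) in Hz/m on the raster `dt`.  The per-axis response
    is the convolution of the slew rate with h(t) = c/(c+t)^2 (normalized
    to unit integral), scaled by the effective coil length and expressed
    as % of the rheobase; axes combine as root-sum-of-squares.  With
    ``periodic=True`` the waveform is treated as one period of a steady-
    state train (circular convolution).
    """
    p = params or PNSParams()
    grads = np.atleast_2d(np.asarray(grads, dtype=float))
    nt = grads.shape[1]
    slew = _slew_tms(grads, dt, periodic)
    c = p.chronaxie
    nh = min(max(int(50 * c / dt), 16), 4 * nt)
    th = (np.arange(nh)) * dt
    h = c / (c + th) ** 2 * dt  # discrete density, sums to ~1
    per_axis = np.zeros_like(slew)
    for a in range(slew.shape[0]):
        if periodic:
            x = np.concatenate([slew[a][-min(nh, nt):], slew[a]])
            full = np.convolve(x, h)[: x.size]
            per_axis[a] = full[-nt:]
        else:
            per_axis[a] = np.convolve(slew[a], h)[:nt]
    scale = 100.0 * p.effective_length / p.rheobase
    per_axis = per_axis * scale
    combined = np.sqrt((per_axis**2).sum(axis=0))
    t = (np.arange(nt) + 0.5) * dt
    return PNSResult(t, combined, np.abs(per_axis))


def pns_safe(
    grads: np.ndarray,
    dt: float,
    params: Optional[PNSParams] = None,
    periodic: bool = False,
) -> PNSResult:
    """SAFE-style PNS prediction.

    Per axis, a weighted cascade of three first-order low-pass stages: the
    fastest stage filters the rectified slew rate, the two slower stages
    filter the signed slew and contribute their magnitude (preserving the
    partial cancellation of bipolar gradient trains), summed and expressed
    as % of the limit.
    """
    from scipy.signal import lfilter

    p = params or PNSParams()
    grads = np.atleast_2d(np.asarray(grads, dtype=float))
    nt = grads.shape[1]
    slew = _slew_tms(grads, dt, periodic)
    if periodic:
        npad = min(nt, int(50 * max(p.safe_taus) / dt))
        slew = np.concatenate([slew[:, nt - npad:], slew], axis=1)
    order = np.argsort(p.safe_taus)
    fast = order[0]
    per_axis = np.zeros((slew.shape[0], slew.shape[1]))
    for i, (w, tau) in enumerate(zip(p.safe_weights, p.safe_taus)):
        alpha = dt / (tau + dt)
        x = np.abs(slew) if i == fast else slew
        filt = lfilter([alpha], [1, -(1 - alpha)], x, axis=1)
        per_axis += w * filt if i == fast else w * np.abs(filt)
    if periodic:
        per_axis = per_axis[:, -nt:]
    scale = 100.0 * p.effective_length / p.rheobase
    per_axis = per_axis * scale
    combined = np.sqrt((per_axis**2).sum(axis=0))
    t = (np.arange(nt) + 0.5) * dt
    return PNSResult(t, combined, per_axis)


def predict_pns(
    seq: SequenceObject,
    params: Optional[PNSParams] = None,
    t_range: Optional[Tuple[float, float]] = None,
    periodic: bool = True,
) -> PNSResult:
    """Evaluate the selected PNS model on a sequence's gradient waveforms."""
    p = params or PNSParams()
    t, g = gradient_waveforms(seq, t_range)
    fn = pns_impulse_response if p.model == "impulse_response" else pns_safe
    res = fn(g, seq.system.grad_raster_time, p, periodic=periodic)
    res.time = res.time + (t[0] - res.time[0])
    return res


# ---------------------------------------------------------------------------
# relative RF energy
# ---------------------------------------------------------------------------

#: Reference: a 1 ms, 180 degree hard pulse (amplitude 500 Hz).
REFERENCE_PULSE_ENERGY = 500.0**2 * 1e-3  # Hz^2 s


def rf_energy_report(seq: SequenceObject, tr: Optional[float] = None) -> Dict[str, float]:
    """Total RF energy of the sequence and per TR, relative to a reference.

    Energy is the integral of |b1|^2 over time (Hz^2 s), additive over
    blocks.  The reference is one 1 ms, 180 degree hard pulse per TR.
    """
    total = 0.0
    n_rf = 0
    for b in seq.blocks:
        if b.rf is not None:
            dt = np.diff(b.rf.t)
            dt = np.concatenate([dt, dt[-1:]]) if dt.size else np.array([0.0])
            total += float(np.sum(np.abs(b.rf.signal) ** 2 * dt))
            n_rf += 1
    if n_rf == 0:
        raise ValueError("rf_energy_report: sequence contains no RF events")
    duration = seq.duration
    tr_eff = tr if tr is not None else duration
    per_tr = total * (tr_eff / duration) if duration > 0 else 0.0
    return {
        "total_energy_hz2_s": total,
        "energy_per_tr_hz2_s": per_tr,
        "relative_to_reference": per_tr / REFERENCE_PULSE_ENERGY,
        "n_rf_events": float(n_rf),
    }
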