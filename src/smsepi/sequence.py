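"""Sequence container, hardware validation, and k-space trajectory.

The sequence is an ordered list of blocks; block order is execution order
and blocks play back to back without gaps.  Gradient waveforms must be
continuous across block boundaries (a gradient ending at a nonzero value
must be picked up at that value by the next block).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence as Seq

import numpy as np

from .events import (
    CHANNELS,
    ADCEvent,
    ArbGradient,
    Block,
    Gradient,
    RFEvent,
    SystemLimits,
    TrapGradient,
    _on_raster,
)


class SequenceError(ValueError):
    """Raised when a block or event violates the sequence data model."""


@dataclass
class Violation:
    """One hardware-limit or raster-rule violation found by validation."""

    block_index: int
    rule: str
    measured: float
    limit: float

    def __str__(self) -> str:
        return (
            f"block {self.block_index}: {self.rule} "
            f"(measured {self.measured:.6g}, limit {self.limit:.6g})"
        )


@dataclass
class SequenceObject:
    """Ordered block list plus the hardware profile it was designed for."""

    system: SystemLimits = field(default_factory=SystemLimits)
    blocks: List[Block] = field(default_factory=list)
    definitions: Dict[str, object] = field(default_factory=dict)
    unknown_sections: Dict[str, str] = field(default_factory=dict)

    # continuity tolerance as a fraction of max_gradient
    CONTINUITY_TOL = 1e-6

    @property
    def duration(self) -> float:
        return float(sum(b.duration for b in self.blocks))

    def _boundary_value(self, block: Optional[Block], channel: str, side: str) -> float:
        if block is None:
            return 0.0
        g = block.gradient(channel)
        if g is None:
            return 0.0
        if side == "last":
            # a gradient ending before the block end leaves the channel at `last`
            return g.last
        return g.first

    def add_block(self, *events, duration: Optional[float] = None, label: str = "") -> None:
        """Append a block assembled from `events` (or a ready-made Block).

        Enforces the one-event-per-channel rule and gradient continuity
        with the previous block; the block duration is the latest event
        end rounded up to the block-duration raster unless given.
        """
        if len(events) == 1 and isinstance(events[0], Block):
            block = events[0]
            if duration is not None:
                block.duration = duration
            elif block.duration <= 0:
                raster = self.system.block_duration_raster
                block.duration = float(
                    np.ceil(round(block.events_end / raster, 9)) * raster
                )
            if label:
                block.label = label
        else:
            block = Block(label=label)
            for ev in events:
                if isinstance(ev, RFEvent):
                    if block.rf is not None:
                        raise SequenceError("multiple RF events in one block")
                    block.rf = ev
                elif isinstance(ev, (TrapGradient, ArbGradient)):
                    attr = f"g{ev.channel}"
                    if getattr(block, attr) is not None:
                        raise SequenceError(
                            f"multiple gradient events on channel {ev.channel} in one block"
                        )
                    setattr(block, attr, ev)
                elif isinstance(ev, ADCEvent):
                    if block.adc is not None:
                        raise SequenceError("multiple ADC events in one block")
                    block.adc = ev
                else:
                    raise SequenceError(f"unsupported event type {type(ev).__name__}")
            raster = self.system.block_duration_raster
            end = block.events_end
            block.duration = (
                duration
                if duration is not None
                else float(np.ceil(round(end / raster, 9)) * raster)
            )
        if block.duration + 1e-12 < block.events_end:
            raise SequenceError(
                f"block duration {block.duration:.6g} s shorter than latest "
                f"event end {block.events_end:.6g} s"
            )
        # gradient continuity at the boundary with the previous block
        prev = self.blocks[-1] if self.blocks else None
        tol = self.CONTINUITY_TOL * self.system.max_gradient
        for ch in CHANNELS:
            v_prev = self._boundary_value(prev, ch, "last")
            v_new = self._boundary_value(block, ch, "first")
            if abs(v_prev - v_new) > tol:
                raise SequenceError(
                    f"gradient discontinuity on channel {ch} at block boundary: "
                    f"previous ends at {v_prev:.6g} Hz/m, new starts at {v_new:.6g} Hz/m"
                )
        self.blocks.append(block)


def validate_sequence(
    seq: SequenceObject, limits: Optional[SystemLimits] = None
) -> List[Violation]:
    """Check every event against hardware limits and raster rules.

    Violations are returned as data; an empty list means the sequence fits
    the profile.  Design specifications must be equal to or lower than the
    actual capabilities of the target scanner.
    """
    lim = limits if limits is not None else seq.system
    out: List[Violation] = []

    def add(i, rule, measured, bound):
        out.append(Violation(i, rule, float(measured), float(bound)))

    for i, b in enumerate(seq.blocks):
        if b.rf is not None:
            rf = b.rf
            peak = float(np.abs(rf.signal).max())
            if peak > lim.max_rf_amplitude * (1 + 1e-9):
                add(i, "rf amplitude", peak, lim.max_rf_amplitude)
            if rf.delay + 1e-12 < lim.rf_dead_time:
                add(i, "rf delay < rf_dead_time", rf.delay, lim.rf_dead_time)
            if not all(_on_raster(t, lim.rf_raster_time) for t in np.diff(rf.t)):
                add(i, "rf raster", float(np.diff(rf.t)[0]), lim.rf_raster_time)
        for ch in CHANNELS:
            g = b.gradient(ch)
            if g is None:
                continue
            if isinstance(g, TrapGradient):
                if abs(g.amplitude) > lim.max_gradient * (1 + 1e-9):
                    add(i, f"g{ch} amplitude", abs(g.amplitude), lim.max_gradient)
                for name, t in (
                    ("rise", g.rise_time),
                    ("flat", g.flat_time),
                    ("fall", g.fall_time),
                ):
                    if t > 0 and not _on_raster(t, lim.grad_raster_time):
                        add(i, f"g{ch} {name} raster", t, lim.grad_raster_time)
                for name, t in (("rise", g.rise_time), ("fall", g.fall_time)):
                    if g.amplitude != 0 and t > 0:
                        slew = abs(g.amplitude) / t
                        if slew > lim.max_slew * (1 + 1e-9):
                            add(i, f"g{ch} slew", slew, lim.max_slew)
            else:
                w = np.concatenate([[g.first], g.waveform, [g.last]])
                peak = float(np.abs(w).max())
                if peak > lim.max_gradient * (1 + 1e-9):
                    add(i, f"g{ch} amplitude", peak, lim.max_gradient)
                slews = np.abs(np.diff(w)) / g.raster
                if slews.size and slews.max() > lim.max_slew * (1 + 1e-9):
                    add(i, f"g{ch} slew", float(slews.max()), lim.max_slew)
                if not _on_raster(g.raster, lim.grad_raster_time):
                    add(i, f"g{ch} raster", g.raster, lim.grad_raster_time)
        if b.adc is not None:
            adc = b.adc
            if not _on_raster(adc.dwell, lim.adc_raster_time):
                add(i, "adc dwell raster", adc.dwell, lim.adc_raster_time)
            if adc.delay + 1e-12 < lim.adc_dead_time:
                add(i, "adc delay < adc_dead_time", adc.delay, lim.adc_dead_time)
        if not _on_raster(b.duration, lim.block_duration_raster):
            add(i, "block duration raster", b.duration, lim.block_duration_raster)
        if b.duration + 1e-12 < b.events_end:
            add(i, "block duration < events end", b.duration, b.events_end)
    # boundary continuity
    tol = SequenceObject.CONTINUITY_TOL * lim.max_gradient
    for i in range(1, len(seq.blocks)):
        for ch in CHANNELS:
            v0 = seq._boundary_value(seq.blocks[i - 1], ch, "last")
            v1 = seq._boundary_value(seq.blocks[i], ch, "first")
            if abs(v0 - v1) > tol:
                add(i, f"g{ch} boundary continuity", abs(v0 - v1), tol)
    return out


@dataclass
class AdcTrajectory:
    """k-space sample positions for one ADC window."""

    block_index: int
    time: np.ndarray  # absolute sample-center times, s
    k: np.ndarray  # (num_samples, 3) in 1/m


def compute_kspace(
    seq: SequenceObject, block_range: Optional[Seq[int]] = None
) -> List[AdcTrajectory]:
    """k-vector at every ADC sample time.

    k(t) is the cumulative integral of the gamma-normalized gradients,
    reset to zero at the center of each RF excitation pulse.  Raises if an
    ADC occurs before any excitation.

    `block_range` restricts evaluation to ``range(start, stop)`` blocks
    (k-state is still tracked from the sequence start).
    """
    lo, hi = (0, len(seq.blocks)) if block_range is None else block_range
    k = np.zeros(3)
    excited = False
    t0 = 0.0
    out: List[AdcTrajectory] = []
    for i, b in enumerate(seq.blocks):
        grads = [b.gradient(ch) for ch in CHANNELS]
        rf_center = b.rf.center if b.rf is not None else None

        def integral(t):
            t = np.atleast_1d(np.asarray(t, dtype=float))
            vals = np.zeros((t.size, 3))
            for a, g in enumerate(grads):
                if g is not None:
                    vals[:, a] = np.atleast_1d(g.integral(t))
            return vals

        if b.adc is not None and lo <= i < hi:
            if not excited and rf_center is None:
                raise SequenceError(f"block {i}: ADC with no preceding RF excitation")
            ts = b.adc.sample_times
            vals = integral(ts)
            if rf_center is not None:
                ref = integral(np.array([rf_center]))[0]
                k_s = np.where(
                    (ts >= rf_center)[:, None], vals - ref, k + vals
                )
            else:
                k_s = k + vals
            out.append(AdcTrajectory(i, t0 + ts, k_s))
        end_val = integral(np.array([b.duration]))[0]
        if rf_center is not None:
            excited = True
            k = end_val - integral(np.array([rf_center]))[0]
        else:
            k = k + end_val
        t0 += b.duration
        if i >= hi and block_range is not None:
            break
    return out
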