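"""Reader/writer for the Pulseq v1.4 text sequence format.

The writer emits the sections [VERSION], [DEFINITIONS], [BLOCKS], [RF],
[GRADIENTS], [TRAP], [ADC] and [SHAPES].  Event IDs are content-hashed so
identical waveforms share a single library entry, which keeps multi-volume
EPI files small.  Two dialect notes relative to the published v1.4 format:
delays are written as (possibly fractional) microseconds, and arbitrary-
gradient lines carry two trailing columns with the boundary values used
for continuity checking.  Files carrying a [SIGNATURE] section are
accepted; unknown sections are preserved verbatim and re-emitted on write.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

import numpy as np

from .events import (
    ADCEvent,
    ArbGradient,
    Block,
    RFEvent,
    SystemLimits,
    TrapGradient,
)
from .sequence import SequenceObject

_FMT = "%.10g"


class SeqParseError(ValueError):
    """Malformed .seq content; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


# ---------------------------------------------------------------------------
# shape run-length compression (derivative encoding per the public format)
# ---------------------------------------------------------------------------

def compress_shape(samples: np.ndarray) -> Tuple[int, np.ndarray]:
    """Derivative + run-length encode a shape.

    Returns ``(num_samples, data)``.  If compression does not shrink the
    shape the raw samples are returned instead (recognizable because then
    ``len(data) == num_samples``).
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    deriv = np.round(np.concatenate([[samples[0]], np.diff(samples)]), 10)
    out: List[float] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and deriv[j + 1] == deriv[i]:
            j += 1
        run = j - i + 1
        if run >= 2:
            # a pair of equal values is always followed by the count of
            # additional repeats (0 for a run of exactly two)
            out.extend([deriv[i], deriv[i], float(run - 2)])
        else:
            out.append(deriv[i])
        i = j + 1
    data = np.array(out)
    if data.size >= n:
        return n, np.round(samples, 10)
    return n, data


def decompress_shape(num_samples: int, data: np.ndarray) -> np.ndarray:
    """Inverse of :func:`compress_shape`."""
    data = np.asarray(data, dtype=float)
    if data.size == num_samples:
        return data.copy()
    deriv: List[float] = []
    i = 0
    while i < data.size:
        v = data[i]
        if len(deriv) >= 2 and deriv[-1] == deriv[-2]:
            # v is a repeat count of additional occurrences
            count = int(round(v))
            if count < 0:
                raise SeqParseError("negative repeat count in compressed shape")
            deriv.extend([deriv[-1]] * count)
            i += 1
            # reset run detection
            if i < data.size:
                deriv.append(data[i])
                i += 1
            continue
        deriv.append(v)
        i += 1
    if len(deriv) != num_samples:
        raise SeqParseError(
            f"decompressed shape has {len(deriv)} samples, expected {num_samples}"
        )
    return np.cumsum(deriv)


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

class _Library:
    """Insertion-ordered content-addressed event/shape library."""

    def __init__(self) -> None:
        self._ids: Dict[tuple, int] = {}
        self.entries: List[tuple] = []

    def insert(self, key: tuple) -> int:
        if key not in self._ids:
            self._ids[key] = len(self._ids) + 1
            self.entries.append(key)
        return self._ids[key]


def _shape_key(samples: np.ndarray) -> tuple:
    return tuple(np.round(np.asarray(samples, dtype=float), 10).tolist())


def write_seq(seq: SequenceObject, path: str) -> None:
    """Serialize `seq` to a Pulseq text file.  Deterministic: the same
    object always produces byte-identical output."""
    shapes = _Library()
    rf_lib = _Library()
    grad_lib = _Library()  # traps and arbitrary gradients share one id space
    adc_lib = _Library()

    sys = seq.system
    block_rows = []
    for b in seq.blocks:
        rf_id = gx_id = gy_id = gz_id = adc_id = 0
        if b.rf is not None:
            rf = b.rf
            if rf.ppm_offset != 0:
                raise ValueError("write_seq: ppm_offset is not representable in v1.4")
            mag = np.abs(rf.signal)
            peak = mag.max()
            mag_n = mag / peak if peak > 0 else mag
            phase_n = np.mod(np.angle(rf.signal) / (2 * np.pi), 1.0)
            time_n = rf.t / sys.rf_raster_time
            mag_id = shapes.insert(_shape_key(mag_n))
            phase_id = shapes.insert(_shape_key(phase_n))
            time_id = shapes.insert(_shape_key(time_n))
            rf_id = rf_lib.insert(
                (
                    round(peak, 10),
                    mag_id,
                    phase_id,
                    time_id,
                    round(rf.delay * 1e6, 4),
                    round(rf.freq_offset, 10),
                    round(rf.phase_offset, 10),
                )
            )
        ids = {}
        for ch in "xyz":
            g = b.gradient(ch)
            if g is None:
                ids[ch] = 0
            elif isinstance(g, TrapGradient):
                ids[ch] = grad_lib.insert(
                    (
                        "trap",
                        round(g.amplitude, 10),
                        round(g.rise_time * 1e6, 4),
                        round(g.flat_time * 1e6, 4),
                        round(g.fall_time * 1e6, 4),
                        round(g.delay * 1e6, 4),
                    )
                )
            else:
                if not math.isclose(g.raster, sys.grad_raster_time, rel_tol=1e-9):
                    raise ValueError(
                        "write_seq: arbitrary gradient raster must equal the "
                        "system gradient raster"
                    )
                peak = np.abs(g.waveform).max()
                wav_n = g.waveform / peak if peak > 0 else g.waveform
                sid = shapes.insert(_shape_key(wav_n))
                ids[ch] = grad_lib.insert(
                    (
                        "arb",
                        round(float(peak), 10),
                        sid,
                        round(g.delay * 1e6, 4),
                        round(g.first, 10),
                        round(g.last, 10),
                    )
                )
        gx_id, gy_id, gz_id = ids["x"], ids["y"], ids["z"]
        if b.adc is not None:
            adc_id = adc_lib.insert(
                (
                    b.adc.num_samples,
                    round(b.adc.dwell * 1e9, 4),
                    round(b.adc.delay * 1e6, 4),
                    round(b.adc.freq_offset, 10),
                    round(b.adc.phase_offset, 10),
                )
            )
        dur_units = int(round(b.duration / sys.block_duration_raster))
        block_rows.append((dur_units, rf_id, gx_id, gy_id, gz_id, adc_id))

    lines: List[str] = []
    lines.append("# Pulseq sequence file")
    lines.append("# Created by smsepi")
    lines.append("")
    lines.append("[VERSION]")
    lines.append("major 1")
    lines.append("minor 4")
    lines.append("revision 0")
    lines.append("")
    lines.append("[DEFINITIONS]")
    defs = dict(seq.definitions)
    defs.setdefault("AdcRasterTime", sys.adc_raster_time)
    defs.setdefault("BlockDurationRaster", sys.block_duration_raster)
    defs.setdefault("GradientRasterTime", sys.grad_raster_time)
    defs.setdefault("RadiofrequencyRasterTime", sys.rf_raster_time)
    defs.setdefault("MaxGradient", sys.max_gradient)
    defs.setdefault("MaxSlew", sys.max_slew)
    defs.setdefault("MaxRfAmplitude", sys.max_rf_amplitude)
    defs.setdefault("RfDeadTime", sys.rf_dead_time)
    defs.setdefault("RfRingdownTime", sys.rf_ringdown_time)
    defs.setdefault("AdcDeadTime", sys.adc_dead_time)
    for key in sorted(defs):
        val = defs[key]
        if isinstance(val, (tuple, list, np.ndarray)):
            sval = " ".join(_FMT % float(v) for v in val)
        elif isinstance(val, (int, float, np.floating, np.integer)):
            sval = _FMT % float(val)
        else:
            sval = str(val)
        lines.append(f"{key} {sval}")
    lines.append("")
    lines.append("# Format of blocks:")
    lines.append("# NUM DUR RF  GX  GY  GZ  ADC  EXT")
    lines.append("[BLOCKS]")
    for i, (dur, rf_id, gx, gy, gz, adc_id) in enumerate(block_rows, start=1):
        lines.append(f"{i} {dur} {rf_id} {gx} {gy} {gz} {adc_id} 0")
    if rf_lib.entries:
        lines.append("")
        lines.append("# Format of RF events:")
        lines.append("# id amplitude mag_id phase_id time_id delay freq phase")
        lines.append("# ..        Hz   ....     ....    ....    us   Hz   rad")
        lines.append("[RF]")
        for i, (amp, mid, pid, tid, delay, freq, phase) in enumerate(
            rf_lib.entries, start=1
        ):
            lines.append(
                f"{i} {_FMT % amp} {mid} {pid} {tid} {_FMT % delay} "
                f"{_FMT % freq} {_FMT % phase}"
            )
    arb_entries = [
        (i, e) for i, e in enumerate(grad_lib.entries, start=1) if e[0] == "arb"
    ]
    trap_entries = [
        (i, e) for i, e in enumerate(grad_lib.entries, start=1) if e[0] == "trap"
    ]
    if arb_entries:
        lines.append("")
        lines.append("# Format of arbitrary gradients:")
        lines.append("# id amplitude shape_id time_id delay first last")
        lines.append("[GRADIENTS]")
        for i, (_tag, amp, sid, delay, first, last) in arb_entries:
            lines.append(
                f"{i} {_FMT % amp} {sid} 0 {_FMT % delay} {_FMT % first} {_FMT % last}"
            )
    if trap_entries:
        lines.append("")
        lines.append("# Format of trapezoid gradients:")
        lines.append("# id amplitude rise flat fall delay")
        lines.append("# ..      Hz/m   us   us   us    us")
        lines.append("[TRAP]")
        for i, (_tag, amp, rise, flat, fall, delay) in trap_entries:
            lines.append(
                f"{i} {_FMT % amp} {_FMT % rise} {_FMT % flat} {_FMT % fall} "
                f"{_FMT % delay}"
            )
    if adc_lib.entries:
        lines.append("")
        lines.append("# Format of ADC events:")
        lines.append("# id num dwell delay freq phase")
        lines.append("# ..  ..    ns    us   Hz   rad")
        lines.append("[ADC]")
        for i, (num, dwell, delay, freq, phase) in enumerate(adc_lib.entries, start=1):
            lines.append(
                f"{i} {num} {_FMT % dwell} {_FMT % delay} {_FMT % freq} {_FMT % phase}"
            )
    if shapes.entries:
        lines.append("")
        lines.append("[SHAPES]")
        for i, key in enumerate(shapes.entries, start=1):
            n, data = compress_shape(np.array(key))
            lines.append("")
            lines.append(f"shape_id {i}")
            lines.append(f"num_samples {n}")
            for v in data:
                lines.append(_FMT % v)
    for name, text in seq.unknown_sections.items():
        lines.append("")
        lines.append(f"[{name}]")
        lines.append(text.rstrip("\n"))
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


# ---------------------------------------------------------------------------
# reader
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {
    "VERSION",
    "DEFINITIONS",
    "BLOCKS",
    "RF",
    "GRADIENTS",
    "TRAP",
    "ADC",
    "SHAPES",
}


def read_seq(path: str) -> SequenceObject:
    """Parse a .seq file into a :class:`SequenceObject`.

    Raises :class:`SeqParseError` (with a line number) on malformed section
    headers, dangling event/shape references, or an unsupported version.
    Unknown sections are kept verbatim in ``seq.unknown_sections``.
    """
    with open(path) as fh:
        raw_lines = fh.read().splitlines()

    sections: Dict[str, List[Tuple[int, str]]] = {}
    unknown: Dict[str, str] = {}
    current: Optional[str] = None
    for ln, line in enumerate(raw_lines, start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if stripped.startswith("["):
            if not stripped.endswith("]") or len(stripped) < 3:
                raise SeqParseError(f"malformed section header {stripped!r}", ln)
            current = stripped[1:-1]
            sections.setdefault(current, [])
            continue
        if current is None:
            raise SeqParseError("content before first section header", ln)
        sections[current].append((ln, stripped))

    for name in list(sections):
        if name not in _KNOWN_SECTIONS:
            unknown[name] = "\n".join(s for _, s in sections.pop(name))

    # version
    if "VERSION" not in sections:
        raise SeqParseError("missing [VERSION] section")
    ver = {}
    for ln, s in sections["VERSION"]:
        parts = s.split()
        if len(parts) != 2:
            raise SeqParseError(f"malformed version line {s!r}", ln)
        ver[parts[0]] = parts[1]
    if ver.get("major") != "1":
        raise SeqParseError(f"unsupported version major={ver.get('major')}")

    # definitions
    defs: Dict[str, object] = {}
    for ln, s in sections.get("DEFINITIONS", []):
        parts = s.split()
        key, vals = parts[0], parts[1:]
        parsed = []
        numeric = True
        for v in vals:
            try:
                parsed.append(float(v))
            except ValueError:
                numeric = False
                break
        if numeric and len(parsed) == 1:
            defs[key] = parsed[0]
        elif numeric and parsed:
            defs[key] = tuple(parsed)
        else:
            defs[key] = " ".join(vals)

    def fdef(key: str, default: float) -> float:
        v = defs.get(key, default)
        return float(v) if isinstance(v, (int, float)) else default

    sysdefaults = SystemLimits()
    system = SystemLimits(
        max_rf_amplitude=fdef("MaxRfAmplitude", sysdefaults.max_rf_amplitude),
        rf_dead_time=fdef("RfDeadTime", sysdefaults.rf_dead_time),
        rf_ringdown_time=fdef("RfRingdownTime", sysdefaults.rf_ringdown_time),
        rf_raster_time=fdef("RadiofrequencyRasterTime", sysdefaults.rf_raster_time),
        max_gradient=fdef("MaxGradient", sysdefaults.max_gradient),
        max_slew=fdef("MaxSlew", sysdefaults.max_slew),
        grad_raster_time=fdef("GradientRasterTime", sysdefaults.grad_raster_time),
        adc_dead_time=fdef("AdcDeadTime", sysdefaults.adc_dead_time),
        adc_raster_time=fdef("AdcRasterTime", sysdefaults.adc_raster_time),
        block_duration_raster=fdef(
            "BlockDurationRaster", sysdefaults.block_duration_raster
        ),
    )

    # shapes
    shapes: Dict[int, np.ndarray] = {}
    cur_id = None
    cur_n = None
    cur_data: List[float] = []
    shape_lines = sections.get("SHAPES", []) + [(0, "shape_id -1")]
    for ln, s in shape_lines:
        parts = s.split()
        if parts[0].lower() == "shape_id":
            if cur_id is not None:
                if cur_n is None:
                    raise SeqParseError(f"shape {cur_id} missing num_samples", ln)
                shapes[cur_id] = decompress_shape(cur_n, np.array(cur_data))
            if int(parts[1]) == -1:
                break
            cur_id = int(parts[1])
            cur_n = None
            cur_data = []
        elif parts[0].lower() == "num_samples":
            cur_n = int(parts[1])
        else:
            try:
                cur_data.append(float(parts[0]))
            except ValueError:
                raise SeqParseError(f"bad shape sample {parts[0]!r}", ln)

    def get_shape(sid: int, ln: int) -> np.ndarray:
        if sid not in shapes:
            raise SeqParseError(f"reference to undefined shape id {sid}", ln)
        return shapes[sid]

    # event libraries
    rf_events: Dict[int, RFEvent] = {}
    for ln, s in sections.get("RF", []):
        p = s.split()
        if len(p) != 8:
            raise SeqParseError(f"malformed RF line ({len(p)} columns, expected 8)", ln)
        rid = int(p[0])
        amp = float(p[1])
        mag = get_shape(int(p[2]), ln)
        phase = get_shape(int(p[3]), ln)
        t = get_shape(int(p[4]), ln) * system.rf_raster_time
        if mag.size != phase.size or mag.size != t.size:
            raise SeqParseError(f"RF event {rid}: inconsistent shape lengths", ln)
        signal = amp * mag * np.exp(2j * np.pi * phase)
        rf_events[rid] = RFEvent(
            signal=signal,
            t=t,
            delay=float(p[5]) * 1e-6,
            freq_offset=float(p[6]),
            phase_offset=float(p[7]),
        )

    trap_events: Dict[int, TrapGradient] = {}
    trap_rows: Dict[int, tuple] = {}
    for ln, s in sections.get("TRAP", []):
        p = s.split()
        if len(p) != 6:
            raise SeqParseError(f"malformed TRAP line ({len(p)} columns, expected 6)", ln)
        trap_rows[int(p[0])] = tuple(float(v) for v in p[1:])

    grad_rows: Dict[int, tuple] = {}
    for ln, s in sections.get("GRADIENTS", []):
        p = s.split()
        if len(p) != 7:
            raise SeqParseError(
                f"malformed GRADIENTS line ({len(p)} columns, expected 7)", ln
            )
        grad_rows[int(p[0])] = (
            float(p[1]),
            int(p[2]),
            int(p[3]),
            float(p[4]),
            float(p[5]),
            float(p[6]),
            ln,
        )

    adc_events: Dict[int, ADCEvent] = {}
    for ln, s in sections.get("ADC", []):
        p = s.split()
        if len(p) != 6:
            raise SeqParseError(f"malformed ADC line ({len(p)} columns, expected 6)", ln)
        adc_events[int(p[0])] = ADCEvent(
            num_samples=int(p[1]),
            dwell=float(p[2]) * 1e-9,
            delay=float(p[3]) * 1e-6,
            freq_offset=float(p[4]),
            phase_offset=float(p[5]),
        )

    def make_grad(ch: str, gid: int, trap: bool, ln: int):
        if trap:
            if gid not in trap_rows:
                raise SeqParseError(f"reference to undefined TRAP id {gid}", ln)
            amp, rise, flat, fall, delay = trap_rows[gid]
            return TrapGradient(ch, amp, rise * 1e-6, flat * 1e-6, fall * 1e-6, delay * 1e-6)
        if gid not in grad_rows:
            raise SeqParseError(f"reference to undefined GRADIENTS id {gid}", ln)
        amp, sid, _tid, delay, first, last, row_ln = grad_rows[gid]
        wav = get_shape(sid, row_ln) * amp
        return ArbGradient(
            ch, wav, raster=system.grad_raster_time, delay=delay * 1e-6,
            first=first, last=last,
        )

    seq = SequenceObject(system=system, definitions=defs, unknown_sections=unknown)
    for ln, s in sections.get("BLOCKS", []):
        p = s.split()
        if len(p) != 8:
            raise SeqParseError(
                f"malformed BLOCKS line ({len(p)} columns, expected 8)", ln
            )
        _num, dur, rf_id, gx, gy, gz, adc_id, _ext = (int(v) for v in p)
        block = Block(duration=dur * system.block_duration_raster)
        if rf_id:
            if rf_id not in rf_events:
                raise SeqParseError(f"reference to undefined RF id {rf_id}", ln)
            block.rf = rf_events[rf_id]
        for ch, gid in (("x", gx), ("y", gy), ("z", gz)):
            if gid:
                # negative ids in our writer denote traps; files use disjoint
                # libraries so try TRAP first, then GRADIENTS
                g = make_grad(ch, gid, gid in trap_rows, ln)
                setattr(block, f"g{ch}", g)
        if adc_id:
            if adc_id not in adc_events:
                raise SeqParseError(f"reference to undefined ADC id {adc_id}", ln)
            block.adc = adc_events[adc_id]
        seq.blocks.append(block)
    return seq
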