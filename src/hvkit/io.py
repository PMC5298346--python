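"""Trace file format and JSON configuration.

The native trace format is plain TSV: a header block of ``# key<TAB>value``
lines followed by a data block with columns

    sweep_index  step_voltage_mV  time_ms  current_pA  segment

``segment`` is ``step`` or ``tail``; during tail rows the voltage column
holds the command voltage of the tail segment, so tail-scan protocols
round-trip without extra columns. Floats are written with ``repr`` so that
write -> read -> write is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np

from .biophysics import Cation, SolutionConditions
from .simulate import (GatingParams, NoiseModel, Sweep, TraceFamily,
                       VoltageProtocol)

__all__ = [
    "TraceParseError",
    "GENERATOR_VERSION",
    "write_trace_family",
    "read_trace_family",
    "RunConfig",
    "AnalysisOptions",
    "config_hash",
]

GENERATOR_VERSION = "hvkit-trace-1"

REQUIRED_HEADER_KEYS = (
    "ph_o", "ph_i", "temperature_c", "cation", "zn_um", "junction_mv",
    "holding_mv", "tail_mv", "sample_interval_ms", "seed",
    "generator_version",
)

_COLUMNS = ("sweep_index", "step_voltage_mV", "time_ms", "current_pA",
            "segment")


class TraceParseError(ValueError):
    """Malformed trace file; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _fmt(x) -> str:
    return repr(float(x))


def write_trace_family(family: TraceFamily, path) -> None:
    """Serialize a family to the trace TSV dialect."""
    c, p, g, n = family.conditions, family.protocol, family.gating, family.noise
    header = {
        "ph_o": _fmt(c.pH_o), "ph_i": _fmt(c.pH_i),
        "temperature_c": _fmt(c.temperature_C),
        "cation": c.main_cation.value, "zn_um": _fmt(c.zn_uM),
        "junction_mv": _fmt(c.junction_potential_mV),
        "holding_mv": _fmt(p.holding_mV), "tail_mv": _fmt(p.tail_mV),
        "sample_interval_ms": _fmt(p.sample_interval_ms),
        "seed": str(n.seed), "generator_version": GENERATOR_VERSION,
        # extras needed for lossless reconstruction
        "step_start_mv": _fmt(p.step_start_mV),
        "step_stop_mv": _fmt(p.step_stop_mV),
        "step_increment_mv": _fmt(p.step_increment_mV),
        "step_duration_ms": _fmt(p.step_duration_ms),
        "tail_duration_ms": _fmt(p.tail_duration_ms),
        "tail_scan": "1" if p.tail_voltages_mV is not None else "0",
        "gating_json": json.dumps(dataclasses.asdict(g), sort_keys=True),
        "noise_json": json.dumps(dataclasses.asdict(n), sort_keys=True),
    }
    lines = [f"# {k}\t{v}" for k, v in header.items()]
    lines.append("\t".join(_COLUMNS))
    for idx, sw in enumerate(family.sweeps):
        step = sw.step_mask
        for t, i, seg in zip(sw.time_ms, sw.current_pA, step):
            v = sw.step_mV if seg else sw.tail_mV
            lines.append(
                f"{idx}\t{_fmt(v)}\t{_fmt(t)}\t{_fmt(i)}\t"
                f"{'step' if seg else 'tail'}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace_family(path) -> TraceFamily:
    """Parse a trace TSV file back into a typed ``TraceFamily``.

    Missing required header keys, malformed rows, and non-monotone time
    within a (sweep, segment) block raise ``TraceParseError`` with the
    offending line number."""
    text = Path(path).read_text()
    header = {}
    data_start = None
    lines = text.splitlines()
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            body = line[1:].strip()
            if "\t" not in body:
                raise TraceParseError("header line lacks a tab separator",
                                      lineno)
            k, v = body.split("\t", 1)
            header[k.strip()] = v.strip()
        else:
            data_start = lineno
            break
    if data_start is None:
        raise TraceParseError("file contains no data block")
    for key in REQUIRED_HEADER_KEYS:
        if key not in header:
            raise TraceParseError(f"missing required header key {key!r}")

    if lines[data_start - 1].split("\t") != list(_COLUMNS):
        raise TraceParseError("unexpected column header", data_start)

    try:
        conditions = SolutionConditions(
            pH_o=float(header["ph_o"]), pH_i=float(header["ph_i"]),
            temperature_C=float(header["temperature_c"]),
            main_cation=Cation(header["cation"]),
            zn_uM=float(header["zn_um"]),
            junction_potential_mV=float(header["junction_mv"]))
    except ValueError as exc:
        raise TraceParseError(f"invalid header value: {exc}")

    gating = GatingParams(**json.loads(header.get("gating_json", "{}")))
    noise = NoiseModel(**json.loads(header.get("noise_json", "{}")))

    # rows: sweep_index -> list of (v, t, i, segment)
    rows_by_sweep = {}
    prev = {}
    for lineno in range(data_start + 1, len(lines) + 1):
        line = lines[lineno - 1]
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise TraceParseError(
                f"expected 5 columns, got {len(parts)}", lineno)
        try:
            idx = int(parts[0])
            v = float(parts[1])
            t = float(parts[2])
            i = float(parts[3])
        except ValueError as exc:
            raise TraceParseError(str(exc), lineno)
        seg = parts[4]
        if seg not in ("step", "tail"):
            raise TraceParseError(f"bad segment label {seg!r}", lineno)
        key = (idx, seg)
        if key in prev and t <= prev[key]:
            raise TraceParseError(
                f"time not strictly increasing within sweep {idx} "
                f"segment {seg}", lineno)
        prev[key] = t
        rows_by_sweep.setdefault(idx, []).append((v, t, i, seg))
    if not rows_by_sweep:
        raise TraceParseError("empty data block")

    tail_scan = header.get("tail_scan", "0") == "1"
    tail_voltages = None
    sweeps = []
    step_duration = float(header["step_duration_ms"])
    for idx in sorted(rows_by_sweep):
        rows = rows_by_sweep[idx]
        t_arr = np.array([r[1] for r in rows])
        i_arr = np.array([r[2] for r in rows])
        step_rows = [r for r in rows if r[3] == "step"]
        tail_rows = [r for r in rows if r[3] == "tail"]
        if not step_rows or not tail_rows:
            raise TraceParseError(f"sweep {idx} lacks a step or tail segment")
        sweeps.append(Sweep(step_mV=step_rows[0][0], tail_mV=tail_rows[0][0],
                            time_ms=t_arr, current_pA=i_arr,
                            step_duration_ms=step_duration))
    if tail_scan:
        tail_voltages = tuple(sw.tail_mV for sw in sweeps)

    protocol = VoltageProtocol(
        holding_mV=float(header["holding_mv"]),
        step_start_mV=float(header["step_start_mv"]),
        step_stop_mV=float(header["step_stop_mv"]),
        step_increment_mV=float(header["step_increment_mv"]),
        step_duration_ms=step_duration,
        tail_mV=float(header["tail_mv"]),
        tail_duration_ms=float(header["tail_duration_ms"]),
        sample_interval_ms=float(header["sample_interval_ms"]),
        tail_voltages_mV=tail_voltages)

    return TraceFamily(conditions=conditions, protocol=protocol,
                       sweeps=sweeps, gating=gating, noise=noise)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AnalysisOptions:
    """Knobs of the analysis stage (all exposed; defaults mirror the
    documented analysis decisions)."""

    window_start_ms: float = 2.0
    settle_ms: float = 2.0
    guard_mV: float = 5.0
    saturation_pH: float = 8.0


def _build(cls, data):
    """Construct a (possibly nested) dataclass from a mapping, rejecting
    unknown keys."""
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}")
    names = {f.name: f for f in dc_fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        ftype = names[k].type
        sub = _NESTED.get((cls.__name__, k))
        if sub is not None and isinstance(v, dict):
            kwargs[k] = _build(sub, v)
        elif k == "tail_voltages_mV" and v is not None:
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Top-level JSON-serializable run configuration (strict schema)."""

    conditions: SolutionConditions = dataclasses.field(
        default_factory=SolutionConditions)
    gating: GatingParams = dataclasses.field(default_factory=GatingParams)
    noise: NoiseModel = dataclasses.field(default_factory=NoiseModel)
    protocol: VoltageProtocol = dataclasses.field(
        default_factory=VoltageProtocol)
    analysis: AnalysisOptions = dataclasses.field(
        default_factory=AnalysisOptions)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True, default=str) + "\n")


_NESTED = {
    ("RunConfig", "conditions"): SolutionConditions,
    ("RunConfig", "gating"): GatingParams,
    ("RunConfig", "noise"): NoiseModel,
    ("RunConfig", "protocol"): VoltageProtocol,
    ("RunConfig", "analysis"): AnalysisOptions,
}


def config_hash(obj) -> str:
    """Stable sha256 of a dataclass or mapping, for provenance logs."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
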