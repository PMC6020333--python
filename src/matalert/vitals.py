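"""Typed ingestion, validation and serialization of observation streams.

This module is the engine's only I/O boundary.  Vital-sign observations and
laboratory results arrive as line-delimited records (JSONL or CSV); patient
context — time-varying clinical flags such as magnesium infusion, labor
stage, delivery time and per-patient paging overrides — arrives as a single
JSON document.  Timestamps are ISO-8601 UTC strings externally and integer
minutes internally: the surveillance engine polls its data streams on a
one-minute tick, so the minute is the native time resolution.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

SCHEMA_VERSION = 1

#: Closed enumeration of monitor/vital parameters (units in parentheses).
PARAMETERS = (
    "SBP",               # systolic blood pressure (mmHg)
    "DBP",               # diastolic blood pressure (mmHg)
    "HR",                # heart rate (beats/min)
    "SpO2",              # pulse oximetry (percent)
    "temperature",       # degrees Celsius
    "urine_output_rate",  # mL/h
    "glucose",           # mg/dL
)

#: Closed enumeration of laboratory analytes.
ANALYTES = ("hematocrit", "platelet_count", "glucose")

SOURCES = ("monitor", "lab", "manual")

LABOR_STAGES = ("antepartum", "stage1", "stage2", "delivered", "postpartum-discharged")

MINUTES_PER_DAY = 1440


class StreamFormatError(ValueError):
    """A malformed record in an observation stream (carries the line number)."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


class ContextError(ValueError):
    """An invalid patient-context document."""


# ---------------------------------------------------------------------------
# time handling
# ---------------------------------------------------------------------------

def parse_minute(ts: str) -> int:
    """Parse an ISO-8601 UTC timestamp to integer minutes since the Unix epoch.

    Sub-minute components are truncated (the engine tick is one minute).
    """
    if ts.endswith("Z"):
        ts = ts[:-1] + "+00:00"
    dt = datetime.fromisoformat(ts)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return int(dt.timestamp() // 60)


def format_minute(minute: int) -> str:
    """Render integer epoch-minutes as an ISO-8601 UTC timestamp."""
    dt = datetime.fromtimestamp(minute * 60, tz=timezone.utc)
    return dt.strftime("%Y-%m-%dT%H:%M:%SZ")


# ---------------------------------------------------------------------------
# observation types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class VitalObservation:
    """One timestamped reading from a bedside monitor (or manual entry)."""

    patient_id: str
    room_id: str
    time_min: int
    parameter: str
    value: float
    source: str = "monitor"

    def __post_init__(self):
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"{self.parameter} value must be finite and >= 0, got {self.value}")
        if self.parameter == "SpO2" and self.value > 100:
            raise ValueError(f"SpO2 cannot exceed 100%, got {self.value}")

    def to_record(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "room_id": self.room_id,
            "timestamp": format_minute(self.time_min),
            "parameter": self.parameter,
            "value": self.value,
            "source": self.source,
        }

    @classmethod
    def from_record(cls, rec: Mapping) -> "VitalObservation":
        return cls(
            patient_id=str(rec["patient_id"]),
            room_id=str(rec["room_id"]),
            time_min=parse_minute(rec["timestamp"]),
            parameter=rec["parameter"],
            value=float(rec["value"]),
            source=rec.get("source", "monitor") or "monitor",
        )


@dataclass(frozen=True, slots=True)
class LabObservation:
    """One timestamped laboratory result."""

    patient_id: str
    time_min: int
    analyte: str
    value: float

    def __post_init__(self):
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"{self.analyte} value must be finite and >= 0, got {self.value}")
        if self.analyte == "hematocrit" and self.value > 100:
            raise ValueError(f"hematocrit is a percentage, got {self.value}")


# ---------------------------------------------------------------------------
# patient context
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class Interval:
    """Half-open validity interval [start_min, end_min) in epoch minutes."""

    start_min: int
    end_min: int

    def __post_init__(self):
        if self.end_min < self.start_min:
            raise ValueError(f"interval end {self.end_min} before start {self.start_min}")

    def contains(self, t: int) -> bool:
        return self.start_min <= t < self.end_min


def _covers(intervals: Sequence[Interval], t: int) -> bool:
    return any(iv.contains(t) for iv in intervals)


@dataclass(frozen=True)
class PatientContext:
    """Time-varying clinical flags for one patient.

    ``overrides`` maps a pageable criterion key (e.g. ``"hr_high"``,
    ``"sbp_low"``) to a clinician-adjusted page-trigger bound.
    ``history`` holds the discrete structured-chart flags consumed by the
    census view (airway risk factors, blood loss, pain score, ...).
    """

    patient_id: str
    room_id: str = ""
    magnesium: tuple[Interval, ...] = ()
    insulin: tuple[Interval, ...] = ()
    operating_room: tuple[Interval, ...] = ()
    labor_stages: tuple[tuple[str, Interval], ...] = ()
    delivery_time_min: int | None = None
    last_glucose_time_min: int | None = None
    overrides: Mapping[str, float] = field(default_factory=dict)
    history: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        prev_end = None
        prev_order = -1
        for stage, iv in self.labor_stages:
            if stage not in LABOR_STAGES:
                raise ContextError(f"patient {self.patient_id}: unknown labor stage {stage!r}")
            order = LABOR_STAGES.index(stage)
            if order < prev_order:
                raise ContextError(
                    f"patient {self.patient_id}: labor stages out of order ({stage})")
            if prev_end is not None and iv.start_min < prev_end:
                raise ContextError(
                    f"patient {self.patient_id}: overlapping labor-stage intervals at {stage}")
            prev_end = iv.end_min
            prev_order = order
        has_delivered = any(
            LABOR_STAGES.index(stage) >= LABOR_STAGES.index("delivered")
            for stage, _ in self.labor_stages)
        if has_delivered and self.delivery_time_min is None:
            raise ContextError(
                f"patient {self.patient_id}: delivered stage without delivery_time")
        if self.delivery_time_min is not None and self.labor_stages and not has_delivered:
            raise ContextError(
                f"patient {self.patient_id}: delivery_time set but no delivered stage")

    @classmethod
    def empty(cls, patient_id: str, room_id: str = "") -> "PatientContext":
        """Default context for a patient streaming before admission charting."""
        return cls(patient_id=patient_id, room_id=room_id)

    # -- time-varying predicates ------------------------------------------
    def on_magnesium(self, t: int) -> bool:
        return _covers(self.magnesium, t)

    def on_insulin(self, t: int) -> bool:
        return _covers(self.insulin, t)

    def in_operating_room(self, t: int) -> bool:
        return _covers(self.operating_room, t)

    def labor_stage(self, t: int) -> str | None:
        for stage, iv in self.labor_stages:
            if iv.contains(t):
                return stage
        return None

    def in_stage2(self, t: int) -> bool:
        return self.labor_stage(t) == "stage2"

    def minutes_since_delivery(self, t: int) -> int | None:
        if self.delivery_time_min is None:
            return None
        return t - self.delivery_time_min

    def with_override(self, key: str, bound: float) -> "PatientContext":
        new = dict(self.overrides)
        new[key] = bound
        return replace(self, overrides=new)


# ---------------------------------------------------------------------------
# stream I/O
# ---------------------------------------------------------------------------

_CSV_FIELDS = ("patient_id", "room_id", "timestamp", "parameter", "value", "source")


def read_observations(
    path: str | Path,
    dialect: str = "jsonl",
    on_error: Callable[[int, str, Exception], None] | None = None,
    max_clock_skew_min: int = MINUTES_PER_DAY,
) -> list[VitalObservation]:
    """Read an observation stream, sorted by timestamp (stable on ties).

    Malformed lines raise :class:`StreamFormatError` carrying the line
    number; pass ``on_error`` to report and skip them instead.  A record
    whose clock runs backwards by more than ``max_clock_skew_min`` relative
    to the latest timestamp seen so far is treated as malformed.
    """
    if dialect not in ("jsonl", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    out: list[VitalObservation] = []
    max_seen: int | None = None

    def handle(lineno: int, raw: str, parse: Callable[[], VitalObservation]):
        nonlocal max_seen
        try:
            obs = parse()
            if max_seen is not None and obs.time_min < max_seen - max_clock_skew_min:
                raise ValueError(
                    f"timestamp runs {max_seen - obs.time_min} min backwards "
                    f"(tolerance {max_clock_skew_min})")
        except Exception as exc:  # noqa: BLE001 - converted to a typed error
            if on_error is not None:
                on_error(lineno, raw, exc)
                return
            raise StreamFormatError(str(exc), lineno) from exc
        max_seen = obs.time_min if max_seen is None else max(max_seen, obs.time_min)
        out.append(obs)

    with path.open(newline="") as fh:
        if dialect == "jsonl":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                handle(lineno, line, lambda line=line: VitalObservation.from_record(json.loads(line)))
        else:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):  # header is line 1
                handle(lineno, str(row), lambda row=row: VitalObservation.from_record(row))

    # stable sort preserves input order at the same minute tick
    out.sort(key=lambda o: o.time_min)
    return out


def write_observations(path: str | Path, stream: Iterable[VitalObservation],
                       dialect: str = "jsonl") -> None:
    """Write a stream in the given dialect; inverse of :func:`read_observations`."""
    path = Path(path)
    if dialect == "jsonl":
        with path.open("w") as fh:
            for obs in stream:
                fh.write(json.dumps(obs.to_record()) + "\n")
    elif dialect == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
            writer.writeheader()
            for obs in stream:
                writer.writerow(obs.to_record())
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# context I/O
# ---------------------------------------------------------------------------

def _intervals_from(doc: object, what: str, pid: str) -> tuple[Interval, ...]:
    out = []
    for pair in doc or []:
        try:
            start, end = pair
            out.append(Interval(parse_minute(start), parse_minute(end)))
        except (ValueError, TypeError) as exc:
            raise ContextError(f"patient {pid}: bad {what} interval {pair!r}: {exc}") from exc
    return tuple(out)


def context_from_record(rec: Mapping) -> PatientContext:
    pid = str(rec["patient_id"])
    stages = []
    for s in rec.get("labor_stages", []):
        stages.append((s["stage"], Interval(parse_minute(s["start"]), parse_minute(s["end"]))))
    return PatientContext(
        patient_id=pid,
        room_id=str(rec.get("room_id", "")),
        magnesium=_intervals_from(rec.get("magnesium"), "magnesium", pid),
        insulin=_intervals_from(rec.get("insulin"), "insulin", pid),
        operating_room=_intervals_from(rec.get("operating_room"), "operating_room", pid),
        labor_stages=tuple(stages),
        delivery_time_min=(parse_minute(rec["delivery_time"])
                           if rec.get("delivery_time") else None),
        last_glucose_time_min=(parse_minute(rec["last_glucose_time"])
                               if rec.get("last_glucose_time") else None),
        overrides={str(k): float(v) for k, v in (rec.get("overrides") or {}).items()},
        history=dict(rec.get("history") or {}),
    )


def context_to_record(ctx: PatientContext) -> dict:
    def ivs(intervals):
        return [[format_minute(iv.start_min), format_minute(iv.end_min)] for iv in intervals]

    rec: dict = {"patient_id": ctx.patient_id, "room_id": ctx.room_id}
    if ctx.magnesium:
        rec["magnesium"] = ivs(ctx.magnesium)
    if ctx.insulin:
        rec["insulin"] = ivs(ctx.insulin)
    if ctx.operating_room:
        rec["operating_room"] = ivs(ctx.operating_room)
    if ctx.labor_stages:
        rec["labor_stages"] = [
            {"stage": stage, "start": format_minute(iv.start_min), "end": format_minute(iv.end_min)}
            for stage, iv in ctx.labor_stages]
    if ctx.delivery_time_min is not None:
        rec["delivery_time"] = format_minute(ctx.delivery_time_min)
    if ctx.last_glucose_time_min is not None:
        rec["last_glucose_time"] = format_minute(ctx.last_glucose_time_min)
    if ctx.overrides:
        rec["overrides"] = dict(ctx.overrides)
    if ctx.history:
        rec["history"] = dict(ctx.history)
    return rec


def read_context(path: str | Path) -> dict[str, PatientContext]:
    """Read the patient-context document into a patient_id -> context map."""
    with Path(path).open() as fh:
        doc = json.load(fh)
    if not isinstance(doc, Mapping) or "patients" not in doc:
        raise ContextError("context document must be an object with a 'patients' list")
    out: dict[str, PatientContext] = {}
    for rec in doc["patients"]:
        ctx = context_from_record(rec)
        if ctx.patient_id in out:
            raise ContextError(f"duplicate patient_id {ctx.patient_id}")
        out[ctx.patient_id] = ctx
    return out


def write_context(path: str | Path, ctx_map: Mapping[str, PatientContext]) -> None:
    doc = {"schema_version": SCHEMA_VERSION,
           "patients": [context_to_record(ctx) for ctx in ctx_map.values()]}
    with Path(path).open("w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def dumps_observations(stream: Iterable[VitalObservation], dialect: str = "jsonl") -> str:
    """Serialize a stream to a string (convenience for digests/tests)."""
    buf = io.StringIO()
    if dialect == "jsonl":
        for obs in stream:
            buf.write(json.dumps(obs.to_record()) + "\n")
    else:
        writer = csv.DictWriter(buf, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for obs in stream:
            writer.writerow(obs.to_record())
    return buf.getvalue()
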