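"""Synthetic labor-and-delivery monitor streams with calibrated exceedance.

No maternal vital-sign distributions are published alongside the unit's
exceedance counts, so the generator is calibrated to *rates*, not
physiology: each parameter draws from a mixture of a truncated-normal
baseline (confined to its non-alerting range) and a set of disjoint
exceedance segments, each drawn uniformly within its band with a
configured target fraction.  Empirical exceedance therefore converges to
the target within binomial sampling error, which is exactly the property
the alerting and reporting layers need from test data.

The default configuration emulates the studied unit sample: 34 monitored
rooms over 91 days, blood pressure roughly every 95 minutes, pulse
oximetry every 46, heart rate every 31 (reproducing the observed
47,016 / 97,558 / 143,799 reading volumes and their ~1:2:3 ratio), and
per-criterion exceedance fractions matching the published event counts.

Scenario injections (hemorrhage, severe hypertension, fever) replace a
target room's values over a fixed interval deterministically, so episode
traces can be asserted exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .vitals import (Interval, PatientContext, VitalObservation, parse_minute)

MINUTES_PER_DAY = 1440


class SimConfigError(ValueError):
    """An infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class ExceedanceSegment:
    """A target fraction of readings drawn uniformly from [low, high).

    Integer-resolution parameters draw integers in [low, high); fractional
    resolutions draw uniform reals rounded to the resolution.
    """

    name: str
    fraction: float
    low: float
    high: float

    def __post_init__(self):
        if not 0 <= self.fraction <= 1:
            raise SimConfigError(f"segment {self.name}: fraction must be in [0,1]")
        if self.high <= self.low:
            raise SimConfigError(f"segment {self.name}: empty band [{self.low},{self.high})")


@dataclass(frozen=True)
class ParameterModel:
    """Sampling cadence and value distribution for one monitored parameter."""

    parameter: str
    cadence_min: int
    mean: float
    sd: float
    normal_low: float
    normal_high: float           # inclusive after rounding
    resolution: int = 0          # decimal places; 0 -> integer readings
    segments: tuple[ExceedanceSegment, ...] = ()

    def __post_init__(self):
        if self.cadence_min < 1:
            raise SimConfigError(f"{self.parameter}: cadence must be >= 1 min")
        total = sum(s.fraction for s in self.segments)
        if total > 1:
            raise SimConfigError(
                f"{self.parameter}: exceedance fractions sum to {total:.3f} > 1")
        spans = sorted((s.low, s.high, s.name) for s in self.segments)
        for (l0, h0, n0), (l1, h1, n1) in zip(spans, spans[1:]):
            if l1 < h0:
                raise SimConfigError(
                    f"{self.parameter}: overlapping segments {n0} and {n1} "
                    "(nested criteria must be expressed as disjoint bands)")

    def draw(self, rng: np.random.Generator) -> float:
        u = rng.random()
        acc = 0.0
        for seg in self.segments:
            acc += seg.fraction
            if u < acc:
                if self.resolution == 0:
                    return float(rng.integers(int(seg.low), int(seg.high)))
                return round(float(rng.uniform(seg.low, seg.high)), self.resolution)
        # baseline: truncated normal on the non-alerting range
        for _ in range(200):
            v = rng.normal(self.mean, self.sd)
            if self.normal_low <= v <= self.normal_high:
                break
        else:
            v = min(max(self.mean, self.normal_low), self.normal_high)
        v = round(v, self.resolution)
        v = min(max(v, self.normal_low), self.normal_high)
        return float(v) if self.resolution else float(int(v))


@dataclass(frozen=True)
class Scenario:
    """Deterministic replacement of one room's values over an interval."""

    room_id: str
    kind: str                    # hemorrhage | severe_hypertension | fever
    start_min: int
    end_min: int
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("hemorrhage", "severe_hypertension", "fever"):
            raise SimConfigError(f"unknown scenario kind {self.kind!r}")
        if self.end_min <= self.start_min:
            raise SimConfigError("scenario interval is empty")


@dataclass(frozen=True)
class LaborCourse:
    """Parameters of the simulated labor progression (minutes)."""

    delivery_probability: float = 0.7    # chance a stay includes a delivery
    stage1_mean: float = 8 * 60
    stage1_sd: float = 2 * 60
    stage2_mean: float = 60
    stage2_sd: float = 20
    stay_mean_days: float = 2.0          # exponential mean length of stay


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration; the seed is mandatory."""

    seed: int
    n_rooms: int = 34
    days: float = 91.0
    start_time: int = parse_minute("2017-04-01T00:00:00Z")
    parameters: tuple[ParameterModel, ...] = ()
    labor: LaborCourse = LaborCourse()
    magnesium_fraction: float = 0.08     # severe-preeclampsia rate on a high-risk unit
    insulin_fraction: float = 0.02
    scenarios: tuple[Scenario, ...] = ()

    def __post_init__(self):
        if self.n_rooms < 1 or self.days <= 0:
            raise SimConfigError("need n_rooms >= 1 and days > 0")
        end = self.start_time + int(self.days * MINUTES_PER_DAY)
        for sc in self.scenarios:
            if sc.start_min < self.start_time or sc.end_min > end:
                raise SimConfigError(f"scenario on {sc.room_id} outside the study window")

    @property
    def end_time(self) -> int:
        return self.start_time + int(self.days * MINUTES_PER_DAY)


# fractions below mirror the published per-criterion event counts over the
# corresponding reading volumes (BP 47,016; SpO2 97,558; HR 143,799)
_BP_N, _SPO2_N, _HR_N = 47016, 97558, 143799


def default_parameters(exceedance_scale: float = 1.0) -> tuple[ParameterModel, ...]:
    """The calibrated parameter set; ``exceedance_scale`` of 0 gives an
    all-normal stream (every segment fraction scaled)."""
    s = exceedance_scale

    def seg(name, frac, low, high):
        return ExceedanceSegment(name, frac * s, low, high)

    return (
        ParameterModel("SBP", 95, 118, 12, 90, 139, segments=(
            seg("sbp_lt_85", 581 / _BP_N, 55, 85),
            seg("sbp_85_90", (1170 - 581) / _BP_N, 85, 90),
            seg("sbp_eq_160", (1021 - 910) / _BP_N, 160, 161),
            seg("sbp_gt_160", 910 / _BP_N, 161, 186),
        )),
        ParameterModel("DBP", 95, 72, 10, 50, 100, segments=(
            seg("dbp_101_110", (1317 - 483) / _BP_N, 101, 110),
            seg("dbp_ge_110", 483 / _BP_N, 110, 131),
        )),
        ParameterModel("HR", 31, 85, 14, 55, 119, segments=(
            seg("hr_lt_50", 602 / _HR_N, 35, 50),
            seg("hr_121_130", (4676 - 2168) / _HR_N, 121, 130),
            seg("hr_ge_130", 2168 / _HR_N, 130, 166),
        )),
        ParameterModel("SpO2", 46, 97.5, 1.5, 95, 100, segments=(
            seg("spo2_lt_95", 4996 / _SPO2_N, 85, 95),
        )),
        ParameterModel("temperature", 240, 36.8, 0.35, 36.0, 37.9, resolution=1, segments=(
            seg("fever", 0.01, 38.0, 39.4),
        )),
        ParameterModel("urine_output_rate", 240, 60, 20, 31, 120, segments=(
            seg("oliguria", 0.01, 10, 30),
        )),
        ParameterModel("glucose", 480, 95, 18, 70, 149, segments=(
            seg("hypoglycemia", 0.002, 40, 70),
            seg("hyperglycemia", 0.005, 150, 310),
        )),
    )


def default_config(seed: int, n_rooms: int = 34, days: float = 91.0,
                   exceedance_scale: float = 1.0, **kwargs) -> SimConfig:
    return SimConfig(seed=seed, n_rooms=n_rooms, days=days,
                     parameters=default_parameters(exceedance_scale), **kwargs)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _labor_stages(rng: np.random.Generator, labor: LaborCourse,
                  admit: int, discharge: int) -> tuple[tuple, int | None]:
    """Build an ordered, disjoint stage sequence within [admit, discharge)."""
    if rng.random() >= labor.delivery_probability:
        return (("antepartum", Interval(admit, discharge)),), None
    stage1_len = max(30, int(rng.normal(labor.stage1_mean, labor.stage1_sd)))
    stage2_len = max(10, int(rng.normal(labor.stage2_mean, labor.stage2_sd)))
    span = discharge - admit
    if stage1_len + stage2_len + 60 >= span:  # stay too short to deliver
        return (("antepartum", Interval(admit, discharge)),), None
    latest_start = discharge - (stage1_len + stage2_len + 30)
    s1 = admit + int(rng.integers(0, max(1, latest_start - admit)))
    s2 = s1 + stage1_len
    delivery = s2 + stage2_len
    stages = (
        ("antepartum", Interval(admit, s1)),
        ("stage1", Interval(s1, s2)),
        ("stage2", Interval(s2, delivery)),
        ("delivered", Interval(delivery, discharge)),
    )
    return stages, delivery


def _history(rng: np.random.Generator, delivered: bool) -> dict:
    h: dict = {}
    for flag, p in (("bmi_over_30", 0.35), ("snoring", 0.15), ("thick_neck", 0.08),
                    ("mallampati_3", 0.12), ("obstructive_sleep_apnea", 0.05),
                    ("prior_cesarean", 0.15), ("multiple_gestation", 0.03),
                    ("heart_disease", 0.04), ("documentation_deficiency", 0.05)):
        if rng.random() < p:
            h[flag] = True
    if rng.random() < 0.4:
        h["epidural_in_place"] = True
        h["pain_score"] = int(rng.integers(0, 11))
    if delivered:
        h["delivery_mode"] = "cesarean" if rng.random() < 0.3 else "vaginal"
        mean_ebl = 800 if h["delivery_mode"] == "cesarean" else 400
        h["estimated_blood_loss_ml"] = int(max(50, rng.normal(mean_ebl, mean_ebl / 3)))
    else:
        h["cervical_dilation_cm"] = int(rng.integers(0, 11))
    return h


def generate(config: SimConfig) -> tuple[list[VitalObservation], dict[str, PatientContext]]:
    """Generate a sorted observation stream and context map; reproducible by seed."""
    if not config.parameters:
        raise SimConfigError("configuration defines no parameters to sample")
    rng = np.random.default_rng(config.seed)
    stream: list[VitalObservation] = []
    ctx_map: dict[str, PatientContext] = {}
    pid_counter = 0
    stay_mean_min = config.labor.stay_mean_days * MINUTES_PER_DAY

    for room_idx in range(config.n_rooms):
        room_id = f"R{room_idx + 1:02d}"
        t = config.start_time
        while t < config.end_time:
            admit = t
            stay = max(240, int(rng.exponential(stay_mean_min)))
            discharge = min(admit + stay, config.end_time)
            if discharge - admit < 60:
                break
            pid_counter += 1
            pid = f"P{pid_counter:04d}"
            stages, delivery = _labor_stages(rng, config.labor, admit, discharge)
            delivered = delivery is not None
            on_mag = rng.random() < config.magnesium_fraction
            on_insulin = rng.random() < config.insulin_fraction
            ctx_map[pid] = PatientContext(
                patient_id=pid, room_id=room_id,
                magnesium=(Interval(admit, discharge),) if on_mag else (),
                insulin=(Interval(admit, discharge),) if on_insulin else (),
                labor_stages=stages,
                delivery_time_min=delivery,
                last_glucose_time_min=admit if on_insulin else None,
                history=_history(rng, delivered),
            )
            for model in config.parameters:
                phase = int(rng.integers(0, model.cadence_min))
                for tm in range(admit + phase, discharge, model.cadence_min):
                    stream.append(VitalObservation(
                        patient_id=pid, room_id=room_id, time_min=tm,
                        parameter=model.parameter, value=model.draw(rng)))
            t = discharge
    if config.scenarios:
        stream = inject_scenarios(stream, config.scenarios)
    stream.sort(key=lambda o: o.time_min)
    return stream, ctx_map


# ---------------------------------------------------------------------------
# scenario injection
# ---------------------------------------------------------------------------

def _scenario_value(sc: Scenario, obs: VitalObservation) -> float | None:
    """The replacement value for one observation, or None to keep it."""
    frac = (obs.time_min - sc.start_min) / max(1, sc.end_min - 1 - sc.start_min)
    frac = min(1.0, max(0.0, frac))
    p = sc.params
    if sc.kind == "severe_hypertension":
        if obs.parameter == "SBP":
            return float(p.get("sbp", 165))
        if obs.parameter == "DBP":
            return float(p.get("dbp", 112))
    elif sc.kind == "hemorrhage":
        if obs.parameter == "HR":
            return float(int(p.get("hr_start", 90) + frac * (p.get("hr_end", 145) - p.get("hr_start", 90))))
        if obs.parameter == "SBP":
            return float(int(p.get("sbp_start", 120) + frac * (p.get("sbp_end", 80) - p.get("sbp_start", 120))))
    elif sc.kind == "fever":
        if obs.parameter == "temperature":
            return float(p.get("temperature", 38.7))
    return None


def inject_scenario(stream: Sequence[VitalObservation], scenario: Scenario,
                    ) -> list[VitalObservation]:
    """Deterministically replace the target room's values over the interval."""
    out = []
    for obs in stream:
        if (obs.room_id == scenario.room_id
                and scenario.start_min <= obs.time_min < scenario.end_min):
            v = _scenario_value(scenario, obs)
            if v is not None:
                obs = replace(obs, value=v)
        out.append(obs)
    return out


def inject_scenarios(stream: Sequence[VitalObservation],
                     scenarios: Iterable[Scenario]) -> list[VitalObservation]:
    """Apply several scenarios; overlapping injections on one room are an error."""
    by_room: dict[str, list[Scenario]] = {}
    for sc in scenarios:
        by_room.setdefault(sc.room_id, []).append(sc)
    for room, scs in by_room.items():
        scs.sort(key=lambda s: s.start_min)
        for a, b in zip(scs, scs[1:]):
            if b.start_min < a.end_min:
                raise SimConfigError(f"overlapping scenario injections on room {room}")
    out = list(stream)
    for sc in scenarios:
        out = inject_scenario(out, sc)
    return out


def expected_exceedance(model: ParameterModel, name: str) -> float:
    """Configured target fraction for one named exceedance segment."""
    for seg in model.segments:
        if seg.name == name:
            return seg.fraction
    raise KeyError(name)


def binomial_sd(fraction: float, n: int) -> float:
    """Sampling standard deviation of an empirical exceedance fraction."""
    return math.sqrt(fraction * (1 - fraction) / n)
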