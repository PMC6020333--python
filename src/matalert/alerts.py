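"""Tiered classification of maternal vital signs and labs.

Every observation is assigned exactly one visual tier — normal, black, red
or flashing red — from a declarative threshold-band table, with the small
number of context-gated rules (shock index after delivery, oliguria on
magnesium, conditional hypoglycemia, glucose staleness on insulin) evaluated
against the patient's time-varying context.  Flashing-red is the only
pageable tier; the paging engine consumes these assessments.

Independently, observations can be tested against the Maternal Early
Warning Criteria (MEWC) — the published strict-comparator list (SBP < 90,
SBP > 160, DBP > 100, SpO2 < 95, HR < 50, HR > 120) — which this system
deliberately liberalizes (e.g. pages at HR >= 130 rather than HR > 120)
to reduce alarm burden.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .vitals import LabObservation, PatientContext, VitalObservation


class InvalidObservationError(ValueError):
    """An observation that cannot be classified (e.g. SBP of zero in a ratio)."""


class Level(enum.IntEnum):
    """Visual alert tiers, ordered by severity."""

    NORMAL = 0
    BLACK = 1
    RED = 2
    FLASHING_RED = 3


@dataclass(frozen=True)
class AlertAssessment:
    """The tier assigned to one observation, with its triggering rule.

    ``criterion`` is a machine-readable rule id (``sbp_low_red``,
    ``shock_index_red``, ...) naming the band or conditional rule that
    fired; ``pageable`` is true only for flashing-red assessments whose
    (possibly patient-overridden) page-trigger bound was met.
    """

    patient_id: str
    time_min: int
    parameter: str
    value: float
    level: Level
    direction: str          # "low" | "high" | "n/a"
    criterion: str
    pageable: bool = False
    observation: object | None = None
    context_snapshot: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.pageable and self.level is not Level.FLASHING_RED:
            raise ValueError("only flashing-red assessments can be pageable")


# ---------------------------------------------------------------------------
# threshold configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdBand:
    """Cutpoints partitioning one parameter's value axis into five tiers.

    ``(-inf, low_red) | [low_red, low_black) | [low_black, high_black) |
    [high_black, high_red) | [high_red, inf)``; a ``None`` cutpoint collapses
    the adjacent tier.  ``flashing`` lists which red tiers ("low"/"high")
    trigger pages at their default bound.
    """

    parameter: str
    low_red: float | None
    low_black: float | None
    high_black: float | None
    high_red: float | None
    flashing: frozenset[str] = frozenset()

    def __post_init__(self):
        cuts = [c for c in (self.low_red, self.low_black, self.high_black, self.high_red)
                if c is not None]
        if any(b > a for a, b in zip(cuts[1:], cuts)):
            raise ValueError(f"{self.parameter}: band cutpoints must be non-decreasing")
        if "low" in self.flashing and self.low_red is None:
            raise ValueError(f"{self.parameter}: flashing low requires a low_red cutpoint")
        if "high" in self.flashing and self.high_red is None:
            raise ValueError(f"{self.parameter}: flashing high requires a high_red cutpoint")

    def tier(self, value: float) -> tuple[Level, str]:
        """Base (level, tier-name) for a value, before flashing/override logic."""
        if self.low_red is not None and value < self.low_red:
            return Level.RED, "low_red"
        if self.low_black is not None and value < self.low_black:
            return Level.BLACK, "low_black"
        if self.high_red is not None and value >= self.high_red:
            return Level.RED, "high_red"
        if self.high_black is not None and value >= self.high_black:
            return Level.BLACK, "high_black"
        return Level.NORMAL, "normal"


@dataclass(frozen=True)
class ThresholdConfig:
    """The full declarative rule table (bands plus conditional rules)."""

    bands: Mapping[str, ThresholdBand]
    shock_index: Mapping[str, float]
    oliguria: Mapping[str, float]
    glucose: Mapping[str, float]
    glucose_staleness: Mapping[str, float]
    labs: Mapping[str, Mapping[str, float]]


def load_thresholds(path: str | Path | None = None) -> ThresholdConfig:
    """Load a threshold config; with no path, the packaged default table."""
    if path is None:
        text = resources.files("matalert.data").joinpath("thresholds.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    bands = {}
    for name, spec in doc["parameters"].items():
        bands[name] = ThresholdBand(
            parameter=name,
            low_red=spec.get("low_red"),
            low_black=spec.get("low_black"),
            high_black=spec.get("high_black"),
            high_red=spec.get("high_red"),
            flashing=frozenset(spec.get("flashing") or ()),
        )
    return ThresholdConfig(
        bands=bands,
        shock_index=doc["shock_index"],
        oliguria=doc["oliguria"],
        glucose=doc["glucose"],
        glucose_staleness=doc["glucose_staleness"],
        labs=doc["labs"],
    )


_DEFAULT: ThresholdConfig | None = None


def default_thresholds() -> ThresholdConfig:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_thresholds()
    return _DEFAULT


#: Criterion keys that may carry a per-patient page-trigger override.
PAGEABLE_OVERRIDE_KEYS = frozenset(
    {"sbp_low", "sbp_high", "dbp_high", "hr_high", "shock_index", "oliguria", "hematocrit"})


# ---------------------------------------------------------------------------
# band classification
# ---------------------------------------------------------------------------

def _band_assessment(obs: VitalObservation, ctx: PatientContext,
                     band: ThresholdBand) -> AlertAssessment:
    level, tier = band.tier(obs.value)
    pkey = band.parameter.lower()
    direction = "n/a"
    criterion = f"{pkey}_normal"
    pageable = False
    snapshot: dict[str, object] = {}

    if tier != "normal":
        direction, _, colour = tier.partition("_")
        criterion = f"{pkey}_{tier}"

    # page-trigger bound, possibly overridden per patient; an override can
    # re-band a value in or out of the flashing tier without touching the
    # visual red band
    for side, cmp_default in (("low", band.low_red), ("high", band.high_red)):
        if side not in band.flashing or cmp_default is None:
            continue
        bound = ctx.overrides.get(f"{pkey}_{side}", cmp_default)
        hit = obs.value < bound if side == "low" else obs.value >= bound
        if hit:
            level = Level.FLASHING_RED
            direction = side
            criterion = f"{pkey}_{side}_red"
            pageable = True
            if bound != cmp_default:
                snapshot["override_bound"] = bound
            break

    return AlertAssessment(
        patient_id=obs.patient_id, time_min=obs.time_min, parameter=obs.parameter,
        value=obs.value, level=level, direction=direction, criterion=criterion,
        pageable=pageable, observation=obs, context_snapshot=snapshot)


def classify_vital(obs: VitalObservation, ctx: PatientContext,
                   config: ThresholdConfig | None = None) -> AlertAssessment:
    """Classify one vital-sign observation into its alert tier.

    Dispatches the conditional parameters (glucose, urine output) to their
    context-gated evaluators; everything else is a pure band lookup with
    any per-patient page-bound override applied.
    """
    config = config or default_thresholds()
    if obs.parameter == "glucose":
        return evaluate_glucose(obs, ctx, config)
    if obs.parameter == "urine_output_rate":
        return evaluate_oliguria(obs, ctx, config)
    band = config.bands.get(obs.parameter)
    if band is None:
        raise KeyError(f"no threshold band defined for parameter {obs.parameter!r}")
    return _band_assessment(obs, ctx, band)


# ---------------------------------------------------------------------------
# conditional rules
# ---------------------------------------------------------------------------

def evaluate_shock_index(hr_obs: VitalObservation, sbp_obs: VitalObservation,
                         ctx: PatientContext, config: ThresholdConfig | None = None,
                         pairing_window_min: int = 5) -> AlertAssessment:
    """Shock index (HR / SBP) alert, gated on hypotension and recent delivery.

    Fires only when SBP is also below the gate (105 mmHg) and the patient is
    within 4 h after delivery; pre-delivery patients never satisfy the gate.
    """
    config = config or default_thresholds()
    si = config.shock_index
    if hr_obs.patient_id != sbp_obs.patient_id:
        raise ValueError("shock index requires readings from the same patient")
    if abs(hr_obs.time_min - sbp_obs.time_min) > pairing_window_min:
        raise ValueError(
            f"HR/SBP pair {abs(hr_obs.time_min - sbp_obs.time_min)} min apart "
            f"exceeds the {pairing_window_min}-min pairing window")
    if sbp_obs.value == 0:
        raise InvalidObservationError("SBP of 0 cannot form a shock index")
    t = max(hr_obs.time_min, sbp_obs.time_min)
    ratio = hr_obs.value / sbp_obs.value
    since = ctx.minutes_since_delivery(t)
    gated = (sbp_obs.value < si["sbp_gate"]
             and since is not None and 0 <= since <= si["postpartum_window_min"])
    snapshot = {"ratio": ratio, "sbp": sbp_obs.value, "minutes_since_delivery": since}

    level, criterion, pageable = Level.NORMAL, "shock_index_normal", False
    if gated:
        red_bound = ctx.overrides.get("shock_index", si["red"])
        if ratio >= red_bound:
            level, criterion, pageable = Level.FLASHING_RED, "shock_index_red", True
        elif ratio >= si["black"]:
            level, criterion = Level.BLACK, "shock_index_black"
    return AlertAssessment(
        patient_id=hr_obs.patient_id, time_min=t, parameter="shock_index",
        value=ratio, level=level, direction="high" if level else "n/a",
        criterion=criterion, pageable=pageable, observation=hr_obs,
        context_snapshot=snapshot)


def evaluate_oliguria(rate_obs: VitalObservation, ctx: PatientContext,
                      config: ThresholdConfig | None = None) -> AlertAssessment:
    """Oliguria (< 30 mL/h) alert, active only during a magnesium infusion."""
    config = config or default_thresholds()
    if rate_obs.value < 0:
        raise InvalidObservationError("urine output rate cannot be negative")
    on_mag = ctx.on_magnesium(rate_obs.time_min)
    bound = ctx.overrides.get("oliguria", config.oliguria["red"])
    fires = on_mag and rate_obs.value < bound
    return AlertAssessment(
        patient_id=rate_obs.patient_id, time_min=rate_obs.time_min,
        parameter="urine_output_rate", value=rate_obs.value,
        level=Level.FLASHING_RED if fires else Level.NORMAL,
        direction="low" if fires else "n/a",
        criterion="oliguria_red" if fires else "oliguria_normal",
        pageable=fires, observation=rate_obs,
        context_snapshot={"on_magnesium": on_mag})


def evaluate_glucose(obs: VitalObservation, ctx: PatientContext,
                     config: ThresholdConfig | None = None) -> AlertAssessment:
    """Glucose tiers; the [50, 70) low tiers require insulin infusion or OR.

    Glucose below 50 mg/dL is a red alert for every patient.  No glucose
    tier pages.
    """
    config = config or default_thresholds()
    g = config.glucose
    t = obs.time_min
    conditional = ctx.on_insulin(t) or ctx.in_operating_room(t)
    v = obs.value

    if v < g["low_red_all"]:
        level, direction, criterion = Level.RED, "low", "glucose_low_red"
    elif v < g["low_red_conditional"] and conditional:
        level, direction, criterion = Level.RED, "low", "glucose_low_red_conditional"
    elif v < g["low_black_conditional"] and conditional:
        level, direction, criterion = Level.BLACK, "low", "glucose_low_black_conditional"
    elif v >= g["high_red"]:
        level, direction, criterion = Level.RED, "high", "glucose_high_red"
    elif v >= g["high_black"]:
        level, direction, criterion = Level.BLACK, "high", "glucose_high_black"
    else:
        level, direction, criterion = Level.NORMAL, "n/a", "glucose_normal"
    return AlertAssessment(
        patient_id=obs.patient_id, time_min=t, parameter="glucose", value=v,
        level=level, direction=direction, criterion=criterion, pageable=False,
        observation=obs, context_snapshot={"insulin_or_or": conditional})


def evaluate_glucose_staleness(ctx: PatientContext, now: int,
                               config: ThresholdConfig | None = None) -> AlertAssessment:
    """Unmeasured-glucose-on-insulin alert: black at 2 h, red at 3 h of staleness.

    A patient on an insulin infusion with no glucose ever measured is treated
    as maximally stale (red, criterion ``glucose_never_measured``).
    """
    config = config or default_thresholds()
    s = config.glucose_staleness
    if not ctx.on_insulin(now):
        level, criterion, age = Level.NORMAL, "glucose_staleness_normal", None
    elif ctx.last_glucose_time_min is None:
        level, criterion, age = Level.RED, "glucose_never_measured", None
    else:
        age = now - ctx.last_glucose_time_min
        if age >= s["red_h"] * 60:
            level, criterion = Level.RED, "glucose_stale_red"
        elif age >= s["black_h"] * 60:
            level, criterion = Level.BLACK, "glucose_stale_black"
        else:
            level, criterion = Level.NORMAL, "glucose_staleness_normal"
    return AlertAssessment(
        patient_id=ctx.patient_id, time_min=now, parameter="glucose_staleness",
        value=float(age) if age is not None else float("nan"),
        level=level, direction="n/a", criterion=criterion, pageable=False,
        context_snapshot={"age_min": age})


def evaluate_lab(lab: LabObservation, ctx: PatientContext | None = None,
                 config: ThresholdConfig | None = None) -> AlertAssessment:
    """Classify a laboratory result.

    Hematocrit below 18% (severe anemia) is flashing red and pages
    immediately; platelets below 80 k/µL is a visual red only.  Glucose
    analytes route through the glucose evaluator.
    """
    config = config or default_thresholds()
    if lab.analyte == "glucose":
        obs = VitalObservation(patient_id=lab.patient_id, room_id="",
                               time_min=lab.time_min, parameter="glucose",
                               value=lab.value, source="lab")
        return evaluate_glucose(obs, ctx or PatientContext.empty(lab.patient_id), config)
    if lab.analyte == "hematocrit":
        rule = config.labs["hematocrit"]
        if lab.value < rule["flashing_red"]:
            level, criterion, pageable = Level.FLASHING_RED, "hematocrit_low_red", True
        elif lab.value < rule["black"]:
            level, criterion, pageable = Level.BLACK, "hematocrit_low_black", False
        else:
            level, criterion, pageable = Level.NORMAL, "hematocrit_normal", False
    else:  # platelet_count
        rule = config.labs["platelet_count"]
        if lab.value < rule["red"]:
            level, criterion, pageable = Level.RED, "platelet_low_red", False
        else:
            level, criterion, pageable = Level.NORMAL, "platelet_normal", False
    return AlertAssessment(
        patient_id=lab.patient_id, time_min=lab.time_min, parameter=lab.analyte,
        value=lab.value, level=level,
        direction="low" if level else "n/a", criterion=criterion,
        pageable=pageable, observation=lab)


# ---------------------------------------------------------------------------
# MEWC comparison
# ---------------------------------------------------------------------------

#: The six Maternal Early Warning Criteria used for burden comparison,
#: with their strict printed comparators.
MEWC_CRITERIA: tuple[tuple[str, str, str, float], ...] = (
    ("mewc_sbp_low", "SBP", "<", 90),
    ("mewc_sbp_high", "SBP", ">", 160),
    ("mewc_dbp_high", "DBP", ">", 100),
    ("mewc_spo2_low", "SpO2", "<", 95),
    ("mewc_hr_low", "HR", "<", 50),
    ("mewc_hr_high", "HR", ">", 120),
)


def meets_mewc(obs: VitalObservation) -> tuple[bool, str | None]:
    """Test an observation against the MEWC; returns (met, criterion id).

    Comparators are strict exactly as published: SBP = 160 does NOT meet
    MEWC (> 160) although it is flashing red in the engine (>= 160).
    Parameters outside the MEWC list return (False, None).
    """
    for cid, param, op, bound in MEWC_CRITERIA:
        if obs.parameter != param:
            continue
        if (op == "<" and obs.value < bound) or (op == ">" and obs.value > bound):
            return True, cid
    return False, None


# ---------------------------------------------------------------------------
# stream assessment driver
# ---------------------------------------------------------------------------

def assess_stream(stream, ctx_map: Mapping[str, PatientContext],
                  config: ThresholdConfig | None = None,
                  pairing_window_min: int = 5) -> list[AlertAssessment]:
    """Classify every observation in a time-sorted stream.

    Shock index is evaluated on each new HR reading against the patient's
    most recent SBP within the pairing window (HR is the more frequently
    sampled member of the pair); a zero SBP never forms a ratio.
    """
    config = config or default_thresholds()
    out: list[AlertAssessment] = []
    last_sbp: dict[str, VitalObservation] = {}
    for obs in stream:
        ctx = ctx_map.get(obs.patient_id) or PatientContext.empty(obs.patient_id, obs.room_id)
        out.append(classify_vital(obs, ctx, config))
        if obs.parameter == "SBP":
            last_sbp[obs.patient_id] = obs
        elif obs.parameter == "HR":
            sbp = last_sbp.get(obs.patient_id)
            if (sbp is not None and sbp.value > 0
                    and obs.time_min - sbp.time_min <= pairing_window_min):
                out.append(evaluate_shock_index(obs, sbp, ctx, config, pairing_window_min))
    return out
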