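"""Discrete-time automated paging engine (1-minute tick).

Implements the tiered nurse-first paging sequence: a flashing-red
assessment opens an episode; 10 minutes later the bedside nurse is paged
with a request to verify the finding; if a subsequent reading meets the
same flashing-red criterion the managing service is paged at once
(verified escalation); if nothing verifies within 30 minutes of the nurse
page the managing service is paged anyway (timeout escalation).  Severe
anemia on a lab result bypasses the sequence entirely: the bedside nurse,
managing service and anesthesiology are paged without delay.

Suppression rules: pages are suspended during the second stage of labor
(maternal pushing physiologically raises HR and BP), and criteria on the
suppressed list (hypoxemia, bradycardia) never open episodes.  Clinicians
may adjust the page-trigger bound per patient; those overrides are applied
at classification time and surfaced here via episode bookkeeping.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alerts import (AlertAssessment, Level, PAGEABLE_OVERRIDE_KEYS, ThresholdConfig,
                     assess_stream, default_thresholds, evaluate_lab)
from .vitals import LabObservation, PatientContext, VitalObservation, format_minute

LAB_IMMEDIATE_CRITERIA = frozenset({"hematocrit_low_red"})

#: Criteria whose page alerts were eliminated (visual bands remain).
DEFAULT_SUPPRESSED_CRITERIA = frozenset({"spo2_low_red", "hr_low_red"})


class EpisodeState(enum.Enum):
    TRIGGERED = "TRIGGERED"
    NURSE_PAGED = "NURSE_PAGED"
    ESCALATED_VERIFIED = "ESCALATED_VERIFIED"
    ESCALATED_TIMEOUT = "ESCALATED_TIMEOUT"
    CLOSED = "CLOSED"


_STATE_ORDER = {s: i for i, s in enumerate(EpisodeState)}


@dataclass(frozen=True)
class PagingConfig:
    """Timing and suppression parameters of the paging sequence."""

    nurse_delay_min: int = 10        # trigger -> nurse verify-request page
    verify_timeout_min: int = 30     # nurse page -> timeout escalation
    refractory_min: int = 60         # quiet period before a criterion re-arms
    suppressed_page_criteria: frozenset[str] = DEFAULT_SUPPRESSED_CRITERIA
    stage2_suppression: bool = True
    timeout_from_trigger: bool = False   # measure the 30 min from the trigger instead
    verify_before_nurse_page: bool = False  # count pre-nurse-page readings as verification

    def timeout_due(self, trigger_time: int, nurse_page_time: int) -> int:
        base = trigger_time if self.timeout_from_trigger else nurse_page_time
        return base + self.verify_timeout_min


@dataclass(frozen=True)
class PageEvent:
    """One page delivered to one recipient."""

    time_min: int
    recipient: str      # bedside_nurse | managing_service | anesthesiology
    patient_id: str
    criterion: str
    reason: str         # verify_request | verified_escalation | timeout_escalation | lab_immediate

    def to_record(self) -> dict:
        return {"timestamp": format_minute(self.time_min), "recipient": self.recipient,
                "patient_id": self.patient_id, "criterion": self.criterion,
                "reason": self.reason}


@dataclass
class PagingEpisode:
    """The lifecycle of one flashing-red finding for one (patient, criterion)."""

    patient_id: str
    criterion: str
    trigger_time: int
    state: EpisodeState = EpisodeState.TRIGGERED
    nurse_page_time: int | None = None
    escalation_time: int | None = None
    verifying_time: int | None = None
    outcome: str | None = None      # "verified" | "timeout"
    suppressed_pages: list[PageEvent] = field(default_factory=list)

    def advance(self, state: EpisodeState) -> None:
        if _STATE_ORDER[state] <= _STATE_ORDER[self.state] and state is not EpisodeState.CLOSED:
            raise ValueError(f"illegal transition {self.state.value} -> {state.value}")
        self.state = state

    def to_record(self) -> dict:
        return {
            "patient_id": self.patient_id, "criterion": self.criterion,
            "trigger_time": format_minute(self.trigger_time),
            "state": self.state.value, "outcome": self.outcome,
            "nurse_page_time": (format_minute(self.nurse_page_time)
                                if self.nurse_page_time is not None else None),
            "escalation_time": (format_minute(self.escalation_time)
                                if self.escalation_time is not None else None),
            "suppressed_pages": len(self.suppressed_pages),
        }


@dataclass
class PageLog:
    """Deterministic audit log of a replay: pages plus episode lifecycles."""

    events: list[PageEvent] = field(default_factory=list)
    episodes: list[PagingEpisode] = field(default_factory=list)
    suppressed: list[PageEvent] = field(default_factory=list)

    def pages_by_recipient(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ev in self.events:
            out[ev.recipient] = out.get(ev.recipient, 0) + 1
        return out

    def to_jsonl(self) -> str:
        lines = [json.dumps({"type": "page", **ev.to_record()}) for ev in self.events]
        lines += [json.dumps({"type": "episode", **ep.to_record()}) for ep in self.episodes]
        return "\n".join(lines) + ("\n" if lines else "")


class PagingEngine:
    """Stateful minute-tick driver of the paging sequence.

    Feed :meth:`process_tick` the flashing-red assessments for each minute
    in order; it returns the pages emitted at that minute and keeps all
    episode state internally.
    """

    def __init__(self, ctx_map: Mapping[str, PatientContext],
                 config: PagingConfig | None = None):
        self.config = config or PagingConfig()
        self.ctx_map = dict(ctx_map)
        self.open: dict[tuple[str, str], PagingEpisode] = {}
        self.all_episodes: list[PagingEpisode] = []
        self.suppressed_events: list[PageEvent] = []
        self._last_flashing: dict[tuple[str, str], int] = {}
        self._last_closed: set[tuple[str, str]] = set()

    def _ctx(self, patient_id: str) -> PatientContext:
        return self.ctx_map.get(patient_id) or PatientContext.empty(patient_id)

    def _emit(self, out: list[PageEvent], ev: PageEvent,
              episode: PagingEpisode | None = None) -> None:
        """Emit a page unless the patient is in second-stage labor."""
        if self.config.stage2_suppression and self._ctx(ev.patient_id).in_stage2(ev.time_min):
            self.suppressed_events.append(ev)
            if episode is not None:
                episode.suppressed_pages.append(ev)
            return
        out.append(ev)

    def _close(self, key: tuple[str, str], episode: PagingEpisode) -> None:
        episode.advance(EpisodeState.CLOSED)
        del self.open[key]
        self._last_closed.add(key)

    def process_tick(self, t: int, assessments: Sequence[AlertAssessment]) -> list[PageEvent]:
        """Advance timers to minute ``t`` and apply this minute's assessments."""
        for a in assessments:
            if a.time_min != t:
                raise ValueError(f"assessment at {a.time_min} fed to tick {t}")
        out: list[PageEvent] = []

        # timer phase: nurse pages due at trigger+10, timeouts at nurse_page+30
        for key, ep in list(self.open.items()):
            if ep.state is EpisodeState.TRIGGERED and t >= ep.trigger_time + self.config.nurse_delay_min:
                ep.nurse_page_time = ep.trigger_time + self.config.nurse_delay_min
                ep.advance(EpisodeState.NURSE_PAGED)
                self._emit(out, PageEvent(t, "bedside_nurse", ep.patient_id,
                                          ep.criterion, "verify_request"), ep)
            if (ep.state is EpisodeState.NURSE_PAGED
                    and t >= self.config.timeout_due(ep.trigger_time, ep.nurse_page_time)):
                ep.escalation_time = t
                ep.outcome = "timeout"
                ep.advance(EpisodeState.ESCALATED_TIMEOUT)
                self._emit(out, PageEvent(t, "managing_service", ep.patient_id,
                                          ep.criterion, "timeout_escalation"), ep)
                self._close(key, ep)

        # assessment phase
        for a in assessments:
            if not a.pageable or a.level is not Level.FLASHING_RED:
                continue
            if a.criterion in self.config.suppressed_page_criteria:
                continue
            if a.criterion in LAB_IMMEDIATE_CRITERIA:
                out.extend(page_for_lab(a))
                continue
            key = (a.patient_id, a.criterion)
            ep = self.open.get(key)
            if ep is not None:
                verifiable = (ep.state is EpisodeState.NURSE_PAGED
                              or (self.config.verify_before_nurse_page
                                  and ep.state is EpisodeState.TRIGGERED
                                  and t > ep.trigger_time))
                if verifiable:
                    if ep.state is EpisodeState.TRIGGERED:
                        ep.nurse_page_time = ep.nurse_page_time or t
                        ep.advance(EpisodeState.NURSE_PAGED)
                    ep.verifying_time = t
                    ep.escalation_time = t
                    ep.outcome = "verified"
                    ep.advance(EpisodeState.ESCALATED_VERIFIED)
                    self._emit(out, PageEvent(t, "managing_service", a.patient_id,
                                              a.criterion, "verified_escalation"), ep)
                    self._close(key, ep)
                # readings while TRIGGERED re-confirm the trigger; no action
            else:
                last = self._last_flashing.get(key)
                rearmed = (key not in self._last_closed or last is None
                           or t - last >= self.config.refractory_min)
                if rearmed:
                    ep = PagingEpisode(patient_id=a.patient_id, criterion=a.criterion,
                                       trigger_time=t)
                    self.open[key] = ep
                    self.all_episodes.append(ep)
                    self._last_closed.discard(key)
            self._last_flashing[key] = t
        return out


def page_for_lab(assessment: AlertAssessment) -> list[PageEvent]:
    """Immediate pages for a critical lab (severe anemia): nurse, managing
    service and anesthesiology, all at the lab timestamp, no delay machinery.

    Non-pageable lab assessments yield an empty list.
    """
    if not assessment.pageable or assessment.criterion not in LAB_IMMEDIATE_CRITERIA:
        return []
    return [PageEvent(assessment.time_min, recipient, assessment.patient_id,
                      assessment.criterion, "lab_immediate")
            for recipient in ("bedside_nurse", "managing_service", "anesthesiology")]


def apply_override(ctx: PatientContext, key: str, new_bound: float,
                   thresholds: ThresholdConfig | None = None) -> PatientContext:
    """Set a per-patient page-trigger bound (clinician adjustment).

    Only pageable criteria may be overridden, and the new bound may not
    reach into the normal band (the page region can never cover values the
    band table calls normal).
    """
    thresholds = thresholds or default_thresholds()
    if key not in PAGEABLE_OVERRIDE_KEYS:
        raise ValueError(f"{key!r} is not a pageable criterion; cannot override")
    floors: dict[str, tuple[str, float | None]] = {
        "sbp_low": ("max", thresholds.bands["SBP"].low_black),
        "sbp_high": ("min", thresholds.bands["SBP"].high_black),
        "dbp_high": ("min", thresholds.bands["DBP"].high_black),
        "hr_high": ("min", thresholds.bands["HR"].high_black),
        "shock_index": ("min", thresholds.shock_index["black"]),
        "oliguria": ("max", thresholds.oliguria["red"]),
        "hematocrit": ("max", thresholds.labs["hematocrit"]["black"]),
    }
    kind, floor = floors[key]
    if floor is not None:
        if kind == "min" and new_bound < floor:
            raise ValueError(f"override {key}={new_bound} reaches into the normal band "
                             f"(safety floor {floor})")
        if kind == "max" and new_bound > floor:
            raise ValueError(f"override {key}={new_bound} reaches into the normal band "
                             f"(safety ceiling {floor})")
    return ctx.with_override(key, new_bound)


def replay(stream: Iterable[VitalObservation], ctx_map: Mapping[str, PatientContext],
           thresholds: ThresholdConfig | None = None,
           config: PagingConfig | None = None,
           labs: Iterable[LabObservation] = (),
           assessments: Sequence[AlertAssessment] | None = None) -> PageLog:
    """Batch-drive the paging engine over a sorted stream; fully deterministic.

    Precomputed ``assessments`` may be supplied to avoid re-classifying;
    otherwise the stream (plus any labs) is assessed with ``thresholds``.
    The tick loop runs past the last observation long enough to flush every
    pending nurse page and timeout escalation.
    """
    config = config or PagingConfig()
    if assessments is None:
        assessments = list(assess_stream(stream, ctx_map, thresholds))
        assessments += [evaluate_lab(lab, ctx_map.get(lab.patient_id), thresholds)
                        for lab in labs]

    by_minute: dict[int, list[AlertAssessment]] = {}
    for a in assessments:
        if a.pageable:
            by_minute.setdefault(a.time_min, []).append(a)

    log = PageLog()
    if not by_minute:
        return log
    engine = PagingEngine(ctx_map, config)
    t0 = min(by_minute)
    t1 = max(by_minute) + config.nurse_delay_min + config.verify_timeout_min + 1
    for t in range(t0, t1 + 1):
        log.events.extend(engine.process_tick(t, by_minute.get(t, ())))
    log.episodes = engine.all_episodes
    log.suppressed = engine.suppressed_events
    return log
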