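"""Frequency-report arithmetic: event counts, rates, intervals, burden.

Per-criterion event counts over a study window are turned into
events/24 h, percent-of-recorded-values and mean inter-event intervals
(1440 min / rate).  Two criteria sets are supported: the published
Maternal Early Warning Criteria (strict comparators) and this engine's
liberalized flashing-red criteria.  The conservative hypertension
adjustment assumes every hypertensive reading carried both systolic and
diastolic hypertension, so the combined count is the larger of the two and
the total drops by the smaller.

Raw unrounded values are authoritative throughout; display rounding is
round-half-even and purely cosmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .paging import PageLog
from .vitals import MINUTES_PER_DAY, VitalObservation

#: (criterion id, parameter, comparator, bound) for the MEWC set.
MEWC_COUNT_CRITERIA: tuple[tuple[str, str, str, float], ...] = (
    ("mewc_sbp_low", "SBP", "<", 90),
    ("mewc_sbp_high", "SBP", ">", 160),
    ("mewc_dbp_high", "DBP", ">", 100),
    ("mewc_spo2_low", "SpO2", "<", 95),
    ("mewc_hr_low", "HR", "<", 50),
    ("mewc_hr_high", "HR", ">", 120),
)

#: The liberalized flashing-red vital-sign criteria (page triggers).
FLASHING_COUNT_CRITERIA: tuple[tuple[str, str, str, float], ...] = (
    ("flash_sbp_low", "SBP", "<", 85),
    ("flash_sbp_high", "SBP", ">=", 160),
    ("flash_dbp_high", "DBP", ">=", 110),
    ("flash_hr_high", "HR", ">=", 130),
)

CRITERIA_SETS = {"mewc": MEWC_COUNT_CRITERIA, "flashing": FLASHING_COUNT_CRITERIA}

#: Denominator group (recorded-value family) per parameter.
PARAMETER_GROUP = {"SBP": "BP", "DBP": "BP", "SpO2": "SpO2", "HR": "HR"}

#: Denominator group per criterion id.
CRITERION_GROUP = {cid: PARAMETER_GROUP[param]
                   for cset in CRITERIA_SETS.values() for cid, param, _, _ in cset}

_OPS = {"<": lambda v, b: v < b, ">": lambda v, b: v > b,
        "<=": lambda v, b: v <= b, ">=": lambda v, b: v >= b}


def count_events(stream: Iterable[VitalObservation],
                 criteria_set: str | Sequence[tuple[str, str, str, float]],
                 ctx_map: Mapping | None = None,
                 ) -> tuple[dict[str, int], dict[str, int]]:
    """Count, per criterion, the readings satisfying it; plus denominators.

    Every observation is tested against every criterion independently (it
    can match at most one per parameter since bands are disjoint).  The
    returned denominators count recorded values per family: BP (paired
    systolic/diastolic measurements), SpO2 and HR.
    """
    if isinstance(criteria_set, str):
        criteria = CRITERIA_SETS[criteria_set]
    else:
        criteria = tuple(criteria_set)
    counts = {cid: 0 for cid, *_ in criteria}
    recorded: dict[str, int] = {}
    for obs in stream:
        recorded[obs.parameter] = recorded.get(obs.parameter, 0) + 1
        for cid, param, op, bound in criteria:
            if obs.parameter == param and _OPS[op](obs.value, bound):
                counts[cid] += 1
    denominators = {
        "BP": max(recorded.get("SBP", 0), recorded.get("DBP", 0)),
        "SpO2": recorded.get("SpO2", 0),
        "HR": recorded.get("HR", 0),
    }
    return counts, denominators


@dataclass(frozen=True)
class CriterionRow:
    """One report row: a criterion with its count, percent and daily rate."""

    criterion: str
    count: int
    denominator: int | None
    percent: float | None
    events_per_24h: float


@dataclass
class FrequencyReport:
    """Rates and intervals derived from per-criterion counts over a window."""

    window_days: float
    criteria_set: str
    rows: list[CriterionRow]
    total_count: int
    events_per_24h: float
    mean_interval_min: float | None
    conservative_total: int | None = None
    conservative_per_24h: float | None = None
    conservative_interval_min: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "criterion": r.criterion, "events": r.count,
            "recorded_values": r.denominator,
            "percent_of_recorded": r.percent,
            "events_per_24h": r.events_per_24h,
        } for r in self.rows])

    def to_json_dict(self, display_round: bool = False) -> dict:
        def f(x, nd=2):
            if x is None:
                return None
            return round(x, nd) if display_round else x
        return {
            "window_days": self.window_days,
            "criteria_set": self.criteria_set,
            "rows": [{"criterion": r.criterion, "events": r.count,
                      "recorded_values": r.denominator,
                      "percent_of_recorded": f(r.percent),
                      "events_per_24h": f(r.events_per_24h)} for r in self.rows],
            "total_events": self.total_count,
            "events_per_24h": f(self.events_per_24h, 1),
            "mean_interval_min": f(self.mean_interval_min, 1),
            "conservative_total_events": self.conservative_total,
            "conservative_events_per_24h": f(self.conservative_per_24h, 1),
            "conservative_mean_interval_min": f(self.conservative_interval_min, 1),
            "notes": self.notes,
        }


def _interval_min(count: float, window_days: float) -> float | None:
    """Mean minutes between events; None (undefined) when the count is zero."""
    if count <= 0:
        return None
    return window_days * MINUTES_PER_DAY / count


def conservative_adjustment(counts: Mapping[str, int], systolic_key: str,
                            diastolic_key: str) -> int:
    """Total under the both-pressures-hypertensive assumption.

    Combined hypertension is counted once as max(systolic, diastolic), so
    the raw total drops by min(systolic, diastolic); if either count is
    zero the total is unchanged.
    """
    total = sum(counts.values())
    return total - min(counts.get(systolic_key, 0), counts.get(diastolic_key, 0))


_HYPERTENSION_KEYS = {
    "mewc": ("mewc_sbp_high", "mewc_dbp_high"),
    "flashing": ("flash_sbp_high", "flash_dbp_high"),
}


def derive_rates(counts: Mapping[str, int], window_days: float,
                 denominators: Mapping[str, int] | None = None,
                 criteria_set: str = "custom") -> FrequencyReport:
    """Turn per-criterion counts over a window into a full frequency report.

    events/24 h = count / window_days; mean interval = 1440 / rate;
    percent = 100 x count / recorded-value denominator (when known).
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    rows = []
    for cid, count in counts.items():
        denom = None
        if denominators is not None:
            group = CRITERION_GROUP.get(cid)
            denom = denominators.get(group) if group else denominators.get(cid)
        rows.append(CriterionRow(
            criterion=cid, count=count, denominator=denom,
            percent=(100.0 * count / denom) if denom else None,
            events_per_24h=count / window_days))
    total = sum(counts.values())
    report = FrequencyReport(
        window_days=window_days, criteria_set=criteria_set, rows=rows,
        total_count=total, events_per_24h=total / window_days,
        mean_interval_min=_interval_min(total, window_days))
    hyp = _HYPERTENSION_KEYS.get(criteria_set)
    if hyp and all(k in counts for k in hyp):
        adj = conservative_adjustment(counts, *hyp)
        report.conservative_total = adj
        report.conservative_per_24h = adj / window_days
        report.conservative_interval_min = _interval_min(adj, window_days)
    return report


def burden_comparison(page_log: PageLog | Mapping[str, int],
                      mewc_report: FrequencyReport,
                      flashing_report: FrequencyReport,
                      window_days: float,
                      ob_recipient: str = "managing_service") -> dict:
    """Side-by-side alarm-burden table: pages vs MEWC vs flashing-red rates.

    The reduction factor is the MEWC event rate over the managing-service
    page rate — how many times fewer pages the tiered sequence sends than
    paging for every MEWC-positive reading would.
    """
    if isinstance(page_log, PageLog):
        by_recipient = page_log.pages_by_recipient()
    else:
        by_recipient = dict(page_log)
    out: dict = {"window_days": window_days, "pages_by_recipient": {}}
    for recipient, n in sorted(by_recipient.items()):
        interval = _interval_min(n, window_days)
        out["pages_by_recipient"][recipient] = {
            "pages": n, "pages_per_24h": n / window_days,
            "mean_interval_min": interval,
            "mean_interval_h": interval / 60 if interval is not None else None,
        }
    ob = by_recipient.get(ob_recipient, 0)
    out["mewc_events_per_24h"] = mewc_report.events_per_24h
    out["flashing_events_per_24h"] = flashing_report.events_per_24h
    if ob > 0:
        out["reduction_factor_vs_mewc"] = (
            mewc_report.events_per_24h / (ob / window_days))
    else:
        out["reduction_factor_vs_mewc"] = None
        out["note"] = "no pages"
    return out


def nurse_page_interval_h(nurse_pages: int, window_days: float,
                          rooms_per_nurse: int = 2, n_rooms: int = 64) -> float | None:
    """Mean hours between automated pages for one nurse covering her share
    of the unit: window hours / (pages x rooms_per_nurse / n_rooms)."""
    if nurse_pages <= 0:
        return None
    share = nurse_pages * rooms_per_nurse / n_rooms
    return window_days * 24 / share


def load_table3_counts() -> dict:
    """The packaged published 91-day count fixture (report inputs)."""
    text = resources.files("matalert.data").joinpath("table3_counts.json").read_text()
    return json.loads(text)
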