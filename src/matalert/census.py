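"""Census snapshots and icon derivation from structured chart fields.

Each occupied room is summarized as one record: labor status, cervical
dilation if laboring, a set of condition icons derived from discrete chart
flags, and the current visual alert level (the supremum of the patient's
open assessment levels under the lattice none < black < red < flashing
red).  Icons whose source would require free-text parsing are derived only
from the structured boolean flags carried in the patient context.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .alerts import AlertAssessment, Level
from .vitals import PatientContext, format_minute

#: Risk factors for difficult intubation; three or more earn the at-risk icon.
AIRWAY_RISK_FLAGS = (
    "mallampati_3", "bmi_over_30", "limited_jaw_protrusion",
    "obstructive_sleep_apnea", "snoring", "thick_neck", "radiation_changes")

#: Any one of these marks a known difficult airway.
KNOWN_DIFFICULT_FLAGS = (
    "mallampati_4", "difficult_airway_letter", "fiberoptic_intubation",
    "video_laryngoscope_intubation", "difficult_mask_ventilation",
    "cormack_lehane_3_4")

LEVEL_NAMES = {Level.NORMAL: "none", Level.BLACK: "black",
               Level.RED: "red", Level.FLASHING_RED: "flashing_red"}


def derive_icons(ctx: PatientContext, assessments: Iterable[AlertAssessment] = (),
                 at_time: int | None = None) -> set[str]:
    """Derive the icon set for one patient from structured fields.

    Missing fields simply mean the icon is absent.  ``at_time`` scopes the
    magnesium-infusion check; without it any charted magnesium interval
    counts (the infusion is documented).
    """
    h = ctx.history
    icons: set[str] = set()

    if h.get("airway_exam_missing"):
        icons.add("airway_exam_missing")
    if sum(bool(h.get(f)) for f in AIRWAY_RISK_FLAGS) >= 3:
        icons.add("at_risk_difficult_intubation")
    if any(h.get(f) for f in KNOWN_DIFFICULT_FLAGS):
        icons.add("known_difficult_intubation")
    if h.get("documentation_deficiency"):
        icons.add("documentation_deficiency")
    if h.get("heart_disease"):
        icons.add("heart_disease")
    if h.get("refuses_blood"):
        icons.add("refuses_blood")
    if h.get("multiple_gestation"):
        icons.add("multiple_gestation")
    if h.get("prior_cesarean"):
        icons.add("prior_cesarean")
    if h.get("abnormal_placentation"):
        icons.add("abnormal_placentation")
    if h.get("pph_risk"):
        icons.add("pph_risk")

    # postpartum hemorrhage: blood-loss rule depends on delivery mode
    ebl = h.get("estimated_blood_loss_ml")
    mode = h.get("delivery_mode")
    if ebl is not None and ((mode == "vaginal" and ebl > 500)
                            or (mode == "cesarean" and ebl > 1000)):
        icons.add("postpartum_hemorrhage")

    if h.get("epidural_in_place"):
        pain = h.get("pain_score")
        icons.add("epidural_red" if (pain is not None and pain >= 5) else "epidural")

    on_mag = ctx.on_magnesium(at_time) if at_time is not None else bool(ctx.magnesium)
    pre = h.get("preeclampsia")
    if pre == "severe" or on_mag:
        icons.add("severe_preeclampsia")
    elif pre == "mild":
        icons.add("preeclampsia")

    if ctx.overrides:
        icons.add("paging_limit_change")
    return icons


def alert_level(assessments: Iterable[AlertAssessment]) -> Level:
    """Supremum of assessment levels (none < black < red < flashing red)."""
    level = Level.NORMAL
    for a in assessments:
        if a.level > level:
            level = a.level
    return level


def snapshot(t: int, ctx_map: Mapping[str, PatientContext],
             open_assessments: Mapping[str, Iterable[AlertAssessment]] | None = None,
             ) -> dict:
    """Deterministic machine-readable census at minute ``t``.

    One record per occupied room, ordered by room then patient id;
    ``open_assessments`` maps patient_id to the assessments currently on
    display for that patient.
    """
    open_assessments = open_assessments or {}
    records = []
    for ctx in sorted(ctx_map.values(), key=lambda c: (c.room_id, c.patient_id)):
        stage = ctx.labor_stage(t)
        laboring = stage in ("stage1", "stage2")
        current = list(open_assessments.get(ctx.patient_id, ()))
        records.append({
            "room_id": ctx.room_id,
            "patient_id": ctx.patient_id,
            "labor_status": stage or "unknown",
            "cervical_dilation_cm": (ctx.history.get("cervical_dilation_cm")
                                     if laboring else None),
            "icons": sorted(derive_icons(ctx, current, at_time=t)),
            "alert_level": LEVEL_NAMES[alert_level(current)],
        })
    return {"timestamp": format_minute(t), "patients": records}


def render_census(snap: dict) -> str:
    """Plain-text rendering of a snapshot (one line per room)."""
    lines = [f"census @ {snap['timestamp']}"]
    for rec in snap["patients"]:
        icons = ",".join(rec["icons"]) or "-"
        dil = (f" dil={rec['cervical_dilation_cm']}cm"
               if rec.get("cervical_dilation_cm") is not None else "")
        lines.append(f"  {rec['room_id'] or '??':>4} {rec['patient_id']:<8} "
                     f"{rec['labor_status']:<22}{dil} alert={rec['alert_level']:<12} {icons}")
    return "\n".join(lines)
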