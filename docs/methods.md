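# Methods

## The alerting model

The engine classifies every monitor reading into one of four visual tiers —
normal, black, red, flashing red — by a declarative band table
(`src/matalert/data/thresholds.yaml`). Each parameter's admissible axis is
partitioned by up to four cutpoints into
`(-inf, low_red) | [low_red, low_black) | [low_black, high_black) |
[high_black, high_red) | [high_red, inf)`; a null cutpoint collapses the
adjacent tier, so the partition is exhaustive and exclusive by construction.
Interval-endpoint conventions follow the convention that printed integer
bands such as "85–89" and "140–159" are closed integer ranges; e.g. systolic
pressure uses low-red (−∞, 85), low-black [85, 90), normal [90, 140),
high-black [140, 160), high-red [160, ∞), consistent with the ≥ 160 page
bound. Defaults, with units:

| parameter | low red | low black | normal | high black | high red | pages |
|---|---|---|---|---|---|---|
| SBP (mmHg) | < 85 | 85–89 | 90–139 | 140–159 | ≥ 160 | < 85, ≥ 160 |
| DBP (mmHg) | — | < 50 | 50–99 | 100–109 | ≥ 110 | ≥ 110 |
| HR (/min) | < 50 | — | 50–119 | 120–129 | ≥ 130 | ≥ 130 |
| SpO2 (%) | < 93 | 93–94 | ≥ 95 | — | — | never |
| temperature (°C) | < 36 | — | 36–37.9 | 38–38.4 | ≥ 38.5 | never |

Design choices where the banding was genuinely open:

- **DBP < 50** is assigned to the low-black tier (configurable): low
  diastolic pressure is common under epidural analgesia and never pages.
- **Temperature** has no low-black tier and never pages.
- **Bradycardia (HR < 50) and hypoxemia (SpO2 bands)** are visual-only:
  their page alerts were eliminated as predominantly artefactual. This is
  implemented twice deliberately — the default band table marks them
  non-flashing, *and* the paging engine carries a
  `suppressed_page_criteria` list — so a user-supplied band table that
  re-enables them still cannot page unless the paging config also allows it.
  Suppression is configuration, not deletion of the band.

Conditional rules, evaluated against the patient's time-varying context:

- **Shock index** = HR / SBP, black at ≥ 1.2 and flashing red at ≥ 1.3,
  gated on SBP < 105 mmHg *and* 0–4 h after the recorded delivery time
  (pre-delivery patients never qualify). HR and SBP rarely share an exact
  timestamp, so each new HR reading is paired with the patient's most recent
  SBP within a 5-minute window (configurable). Pairing on HR arrivals only
  avoids double-assessing the same pair; HR is the more frequently sampled
  member. A zero SBP is an invalid observation, not an alert.
- **Oliguria**: urine output < 30 mL/h flashes only during a documented
  magnesium infusion (seizure prophylaxis for severe preeclampsia, the
  setting where renal monitoring matters).
- **Glucose** (mg/dL): < 50 is red for every patient; [50, 60) red and
  [60, 70) black only on an insulin infusion or in the operating room;
  [150, 280) high black; ≥ 280 high red. No glucose tier pages. With
  unknown infusion status the conditional tiers stay normal.
- **Glucose staleness** on insulin: black at 2 h, red at 3 h since the last
  measurement; a patient on insulin with no glucose ever measured is
  reported red under the distinct criterion `glucose_never_measured`
  (treating the absence of data as maximally stale is the conservative
  choice for an infusion-safety rule).
- **Labs**: hematocrit < 18 % (severe anemia) is flashing red and pages
  immediately; 18–20 % is black; platelets < 80 k/µL is visual red.

**MEWC comparison.** `meets_mewc` applies the published strict comparators
exactly (SBP < 90, SBP > 160, DBP > 100, SpO2 < 95, HR < 50, HR > 120).
The engine's page criteria are deliberately a strict subset of the MEWC with
one boundary exception: SBP exactly 160 flashes (≥ 160) but does not meet
the MEWC (> 160). The test suite asserts both the subset property and the
boundary divergence.

## The paging state machine

Time is discrete at one-minute resolution — the engine polls its data
streams every minute, so the minute is the native tick; external timestamps
are ISO-8601 UTC, truncated to the minute. Episodes are keyed per
(patient, criterion), so concurrent hypertension and tachycardia page
independently. The sequence and its parameters (all in `PagingConfig`):

- `nurse_delay_min = 10`: trigger → bedside-nurse verify-request page.
- `verify_timeout_min = 30`: measured from the **nurse page** (escalation at
  trigger + 40), since the verification step follows the nurse page; a
  config flag switches to trigger-relative timing.
- Verification = a subsequent reading meeting the *same* criterion's
  flashing-red condition **after** the nurse page. Readings between trigger
  and nurse page re-confirm the trigger but do not verify (configurable).
  Within a tick, timers fire before assessments, so a reading landing on the
  nurse-page minute counts as verification, and a reading landing exactly on
  the timeout minute arrives after the timeout escalation.
- `refractory_min = 60`: after an episode escalates and closes, a new
  episode for the same key opens only once no flashing reading for that
  criterion has occurred for 60 min. Without re-arm suppression a persistent
  condition would page continuously, contradicting the observed burden of
  roughly one obstetric page per 2–4 h.
- Second-stage-labor suppression withholds page *emission* (recorded as
  suppressed audit entries) while episode state still advances — the
  suspension applies to pages, not to the visual alerts. Severe-anemia lab
  pages are not stage-2 suppressed: they bypass the episode machinery
  entirely and the suspension concerns the vital-sign sequence.
- Per-patient overrides move the page-trigger bound for one pageable
  criterion (`hr_high`, `sbp_low`, …). An override may tighten freely or
  loosen within the abnormal range, but is rejected if it would reach into
  the normal band (a page region must never cover band-normal values).
  Patients with any override carry the paging-limit-change census icon.

`replay` batch-drives the engine over a sorted stream and returns a
deterministic page log (pages + episode lifecycles); identical inputs give
byte-identical logs. Correctness is checked against an independent
brute-force oracle that sorts each (patient, criterion)'s qualifying event
times and applies the trigger/verify/timeout rules directly; the two agree
on the full page log over 1,000 randomized small streams.

## The census layer

A snapshot is a pure function of (context map, open assessments): one record
per room with labor status, cervical dilation while laboring, the icon set,
and the alert level defined as the supremum of open assessment levels under
none < black < red < flashing red. Icon rules use only structured chart
flags (at-risk airway = ≥ 3 of 7 risk factors; known difficult airway = any
of 6 findings; postpartum hemorrhage = blood loss > 500 mL after vaginal or
> 1000 mL after cesarean delivery; epidural icon red at pain score ≥ 5;
severe preeclampsia = charted severe features or an active magnesium
infusion). Icons whose real data source would be free-text parsing (heart
disease, refusal of blood products, prior cesarean, abnormal placentation)
are driven by pre-extracted boolean flags; text parsing is out of scope.
Any black-band assessment is displayed as a black alert — the black tier has
no trigger conditions beyond the band table.

## The synthetic generator

No maternal vital-sign distributions accompany the published exceedance
counts, so the generator is calibrated to *rates*, not physiology. Each
parameter draws from a mixture: disjoint exceedance segments, each sampled
uniformly within its band at a configured target fraction, and a
truncated-normal baseline confined to the non-alerting range. Integer
parameters draw integer readings (which is what makes a boundary value such
as SBP = 160 occur with its own configurable mass). Defaults reproduce the
studied 34-room / 91-day sample: per-room cadences of 95 min (BP pairs),
46 min (SpO2) and 31 min (HR) give the observed 47,016 / 97,558 / 143,799
reading volumes and their ~1:2:3 ratio, and segment fractions equal the
published per-criterion counts over those volumes (e.g. SBP ≥ 160 at
1021/47,016 ≈ 2.17 %, split into an exactly-160 mass and a > 160 mass so the
MEWC/flashing boundary divergence is represented). Labor courses are
simplified: exponential lengths of stay (mean 2 days), a 0.7 per-stay
delivery probability, normal stage-1 (8 ± 2 h) and stage-2 (60 ± 20 min)
durations; magnesium (8 %) and insulin (2 %) infusions span the stay.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: temporal autocorrelation (real abnormalities persist
across consecutive readings, so real streams verify more and time out less
than independent draws do), artefactual readings, charting delays, missing
data, and any dependence between parameters outside the injected scenarios.
Scenario injections (hemorrhage with a linear HR ramp 90→145 against SBP
120→80, severe hypertension, fever) are deterministic value replacements so
episode traces can be asserted exactly. Feasibility is validated up front:
segment fractions sum to ≤ 1 and segments must be disjoint, which is also
how nested criteria (a < 85 band inside a < 90 band) must be expressed.

## Reporting arithmetic

For counts *c* over a window of *d* days: events/24 h = *c*/*d*; mean
inter-event interval = 1440·*d*/*c* minutes (undefined — reported as null,
never an infinity string — when *c* = 0); percent of recorded values =
100·*c*/denominator, with BP criteria over the BP measurement count, SpO2
over SpO2 and HR over HR. The conservative hypertension adjustment assumes
every hypertensive reading carried both systolic and diastolic hypertension:
the combined count is max(systolic-high, diastolic-high), i.e. the total
drops by the min. Raw unrounded values are authoritative; display rounding
is round-half-even and cosmetic. The packaged 91-day count fixture is an
*input* (published event counts), and the report layer recomputes all rates
from it at run time; two of the published display cells differ from the
recomputed values at printed precision (260/91 = 2.857 prints as 2.85;
574/91 = 6.308 prints as 6.30), and one percent cell (HR ≥ 130 printed
against the BP denominator) is recomputed against the HR denominator as
1.51 % — in each case the report keeps the computed value and the
discrepancy is documented rather than matched.

## Problem sizes and numerical notes

The test suite and acceptance script use scaled-down simulations (2–10
rooms, 0.5–3 days) chosen so the whole suite runs in well under a minute;
calibration is verified at the full published BP volume (47,016 draws,
3-binomial-SD tolerance), and the paging oracle comparison uses 1,000
randomized small streams. All randomness flows through explicitly seeded
generators (`numpy.random.default_rng` / `random.Random`); replays and
reports contain no randomness at all. Stream reading tolerates ties at the
same minute by preserving input order (no sub-minute ordering exists), and
rejects clocks running backwards by more than a configurable tolerance
(default one day). The observation JSONL schema carries no per-line schema
version; the context document is versioned (`schema_version: 1`).

## Known limitations

- The engine evaluates shock index only on HR arrivals; an SBP-only burst
  with a stale HR is not re-evaluated until the next HR reading.
- No nurse-dismissal action exists: an artefactual trigger always ends in a
  timeout escalation after 40 minutes. No such cancellation pathway is
  modeled because none is specified for the underlying sequence.
- Nurse/physician page totals from the live unit (which mix staffing and
  acknowledgement behaviour into the counts) are not reproducible from the
  event counts alone and are not modeled.
- The free-text comorbidity parser, HL7/EHR integration, rendered web UI
  and real pager delivery are out of scope; the census layer emits
  structured snapshots only.
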