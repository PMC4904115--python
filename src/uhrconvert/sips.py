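"""SIPS 5.0 diagnostic rule engine.

Implements the positive-symptom diagnostic algorithm: POPS (presence of
psychotic syndrome, including the urgency rule), BIPS (brief intermittent
psychotic symptoms), APS and GRD (genetic risk and deterioration), with
onset, duration and exclusion criteria.

Criterion bands (severity and frequency are paired on the same subscale):

========================  ==========================================
psychotic intensity       severity 6 on any of P1-P5
attenuated intensity      severity 3-5 on any of P1-P5
POPS frequency            3 (at least 1 h/day, at least 4 days/week)
BIPS frequency            >= 1 (frequency 3 escalates to POPS)
APS frequency             >= 2
BIPS onset window         psychotic onset within 3 months
BIPS maximum duration     3 months
APS recency               onset within the past year OR one scale point
                          higher than 12 months before; symptoms present
                          in the past month
========================  ==========================================

Urgency: any positive psychotic symptom (severity 6) that is seriously
disorganizing or dangerous is over the psychosis threshold no matter
what its duration or frequency.

APS and BIPS carry no social/occupational dysfunction requirement; only
GRD requires the 30% GAF drop. The substance-intertwined exclusion is
per-subscale; the comorbidity exclusion ("better accounted for by another
DSM diagnosis") applies to APS and BIPS only.
"""

from __future__ import annotations

from typing import Set

from .instruments import (
    SIPS_SUBSCALES,
    ClinicalCourse,
    DiagnosticResult,
    MissingDataError,
    Outcome,
    SIPSRatings,
    SubjectRecord,
    Subgroup,
    functioning_criterion_sips_grd,
)

__all__ = [
    "SIPS_ATTENUATED_BAND",
    "SIPS_PSYCHOTIC_SEVERITY",
    "BIPS_MAX_DURATION_DAYS",
    "pops_psychosis",
    "classify_sips",
]

SIPS_ATTENUATED_BAND = (3, 5)
SIPS_PSYCHOTIC_SEVERITY = 6
POPS_FREQUENCY = 3
BIPS_MIN_FREQUENCY = 1
APS_MIN_FREQUENCY = 2
BIPS_ONSET_WINDOW_MONTHS = 3.0
BIPS_MAX_DURATION_DAYS = 91.0  # three months
APS_ONSET_WINDOW_MONTHS = 12.0


def pops_psychosis(r: SIPSRatings, course: ClinicalCourse) -> bool:
    """Presence of psychotic syndrome.

    True iff some subscale is at severity 6 with paired frequency 3, or
    at severity 6 with the urgency criterion (seriously disorganizing and
    dangerous symptoms) regardless of frequency or duration.
    """
    psychotic = [s for s in SIPS_SUBSCALES if r.severity[s] >= SIPS_PSYCHOTIC_SEVERITY]
    if not psychotic:
        return False
    if course.danger_or_disorganization:
        return True
    return any(r.frequency[s] >= POPS_FREQUENCY for s in psychotic)


def classify_sips(subject: SubjectRecord) -> DiagnosticResult:
    """Apply the SIPS 5.0 algorithm to one subject.

    Returns exactly one primary outcome with the set of UHR subgroups
    met; precedence POPS > BIPS > APS > GRD, primary subgroup label
    BLIPS(BIPS) > APS > GRD.

    Raises
    ------
    MissingDataError
        If the subject carries no SIPS ratings.
    """
    if subject.sips is None:
        raise MissingDataError("instrument not rated: SIPS")
    r = subject.sips
    course = subject.course
    trace: list = []

    def note(cid: str, passed: bool) -> bool:
        trace.append((cid, bool(passed)))
        return bool(passed)

    duration = course.psychotic_intensity_duration_days
    if duration is None:
        duration = 0.0
        trace.append(("assume:psychotic_duration=unknown->0d", True))
    danger = note("urgency:danger_or_disorganization", bool(course.danger_or_disorganization))
    comorbid = note(
        "exclusion:comorbid_disorder_better_explains",
        bool(course.comorbid_disorder_better_explains),
    )
    prior_episode = note("prior_psychotic_episode", bool(course.prior_psychotic_episode))

    psychotic: Set[str] = {
        s for s in SIPS_SUBSCALES if r.severity[s] >= SIPS_PSYCHOTIC_SEVERITY
    }
    note("psychotic_intensity", bool(psychotic))

    # --- (1) POPS ---------------------------------------------------------
    if prior_episode or pops_psychosis(r, course):
        note("POPS", True)
        return DiagnosticResult("SIPS", Outcome.PSYCHOSIS, frozenset(), trace)
    note("POPS", False)

    subgroups: set = set()
    clean = {s for s in SIPS_SUBSCALES if not r.substance_intertwined[s]}

    # --- (2) BIPS ---------------------------------------------------------
    bips_subscales = {
        s for s in psychotic & clean if r.frequency[s] >= BIPS_MIN_FREQUENCY
    }
    for s in psychotic:
        if r.frequency[s] < BIPS_MIN_FREQUENCY:
            # severity 6 below the lowest frequency anchor: printed criteria
            # leave this unclassifiable on that subscale
            trace.append((f"gap:severity6_frequency0:{s}", False))
    onset_ok = (
        course.psychotic_onset_months_ago is not None
        and course.psychotic_onset_months_ago <= BIPS_ONSET_WINDOW_MONTHS
    ) or (course.psychotic_onset_months_ago is None and duration <= BIPS_MAX_DURATION_DAYS)
    note("BIPS_psychotic_onset_within_3m", onset_ok)
    duration_ok = note("BIPS_duration_up_to_3m", duration <= BIPS_MAX_DURATION_DAYS)
    if bips_subscales and onset_ok and duration_ok and not danger and not comorbid:
        subgroups.add(Subgroup.BLIPS)
    note("BIPS", Subgroup.BLIPS in subgroups)

    # --- (3) APS ----------------------------------------------------------
    lo, hi = SIPS_ATTENUATED_BAND
    aps_subscales = {
        s for s in clean if lo <= r.severity[s] <= hi and r.frequency[s] >= APS_MIN_FREQUENCY
    }
    recency = (
        course.onset_months_ago is not None
        and course.onset_months_ago <= APS_ONSET_WINDOW_MONTHS
    ) or bool(course.severity_increased_past_year)
    note("APS_begun_past_year_or_escalated", recency)
    present = note("APS_present_past_month", bool(course.symptoms_present_past_month))
    if aps_subscales and recency and present and not comorbid:
        subgroups.add(Subgroup.APS)
    note("APS", Subgroup.APS in subgroups)

    # --- (4) GRD ----------------------------------------------------------
    grd = False
    if subject.trait.present:
        try:
            grd = functioning_criterion_sips_grd(subject.functioning)
        except MissingDataError:
            trace.append(("GRD_functioning(missing_data->false)", False))
    note("GRD", grd)
    if grd:
        subgroups.add(Subgroup.GRD)

    if subgroups:
        return DiagnosticResult("SIPS", Outcome.UHR_POS, frozenset(subgroups), trace)
    return DiagnosticResult("SIPS", Outcome.UHR_NEG, frozenset(), trace)
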