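"""CAARMS 12/2006 diagnostic rule engine.

Implements the positive-symptom diagnostic algorithm: the psychosis
threshold, BLIPS (brief limited intermittent psychotic symptoms), APS
(attenuated psychotic symptoms, via both the subthreshold-intensity and
the subthreshold-frequency path) and the vulnerability (GRD) group,
together with the onset, duration, functioning and exclusion criteria.

Criterion bands (severity and frequency are paired on the same subscale):

========================  ==========================================
psychotic intensity       severity 6 on P1, P2 or P4; 5-6 on P3
attenuated intensity      3-5 on P1, 3-5 on P2, 3-4 on P3, 4-5 on P4
psychosis / BLIPS freq.   4-6
APS frequency             3-6 (subthreshold-intensity path)
                          exactly 3 (subthreshold-frequency path)
BLIPS maximum duration    7 days
onset window              12 months; symptoms for no longer than 5 years
========================  ==========================================

Every UHR subgroup additionally requires the CAARMS functional-decline
criterion (30% SOFAS drop sustained a month within 12 months, or SOFAS
< 50 for 12+ months).
"""

from __future__ import annotations

from typing import Set

from .instruments import (
    CAARMS_SUBSCALES,
    CAARMSRatings,
    DiagnosticResult,
    MissingDataError,
    Outcome,
    SubjectRecord,
    Subgroup,
    functioning_criterion_caarms,
)

__all__ = [
    "ATTENUATED_SEVERITY_BANDS",
    "PSYCHOTIC_SEVERITY_BANDS",
    "BLIPS_MAX_DURATION_DAYS",
    "psychotic_intensity_caarms",
    "attenuated_intensity_caarms",
    "caarms_vulnerability",
    "classify_caarms",
]

# severity bands per subscale, inclusive
ATTENUATED_SEVERITY_BANDS = {"P1": (3, 5), "P2": (3, 5), "P3": (3, 4), "P4": (4, 5)}
PSYCHOTIC_SEVERITY_BANDS = {"P1": (6, 6), "P2": (6, 6), "P3": (5, 6), "P4": (6, 6)}

APS_FREQUENCY_BAND = (3, 6)          # subthreshold-intensity path
APS_SUBTHRESHOLD_FREQUENCY = 3       # subthreshold-frequency path (exact)
BLIPS_FREQUENCY_BAND = (4, 6)        # also the psychosis-threshold frequency
BLIPS_MAX_DURATION_DAYS = 7.0
ONSET_WINDOW_MONTHS = 12.0


def _in_band(value: int, band) -> bool:
    lo, hi = band
    return lo <= value <= hi


def psychotic_intensity_caarms(r: CAARMSRatings) -> Set[str]:
    """Subscales whose severity reaches the CAARMS psychotic band."""
    return {s for s in CAARMS_SUBSCALES if _in_band(r.severity[s], PSYCHOTIC_SEVERITY_BANDS[s])}


def attenuated_intensity_caarms(r: CAARMSRatings) -> Set[str]:
    """Subscales whose severity falls in the attenuated (subthreshold) band."""
    return {s for s in CAARMS_SUBSCALES if _in_band(r.severity[s], ATTENUATED_SEVERITY_BANDS[s])}


def caarms_vulnerability(subject: SubjectRecord) -> bool:
    """Vulnerability group: trait risk plus the functional-decline criterion."""
    if not subject.trait.present:
        return False
    try:
        return functioning_criterion_caarms(subject.functioning)
    except MissingDataError:
        return False


def classify_caarms(subject: SubjectRecord) -> DiagnosticResult:
    """Apply the CAARMS 12/2006 algorithm to one subject.

    Returns exactly one primary outcome. Precedence: Psychosis threshold,
    then BLIPS, APS, Vulnerability; ``subgroups_met`` collects every UHR
    subgroup whose criteria pass (a subject may meet, e.g., APS and GRD
    conjointly), and the primary subgroup label follows
    BLIPS > APS > GRD.

    Raises
    ------
    MissingDataError
        If the subject carries no CAARMS ratings.
    """
    if subject.caarms is None:
        raise MissingDataError("instrument not rated: CAARMS")
    r = subject.caarms
    course = subject.course
    trace: list = []

    def note(cid: str, passed: bool) -> bool:
        trace.append((cid, bool(passed)))
        return bool(passed)

    # --- unknown-flag handling (rule in only on positive evidence) -------
    if course.resolved_without_antipsychotics is None:
        resolved = True
        trace.append(("assume:resolved_without_antipsychotics=unknown->true", True))
    else:
        resolved = course.resolved_without_antipsychotics
    duration = course.psychotic_intensity_duration_days
    if duration is None:
        duration = 0.0
        trace.append(("assume:psychotic_duration=unknown->0d", True))
    prior_episode = note("prior_psychotic_episode", bool(course.prior_psychotic_episode))
    substance_peak = note(
        "exclusion:substance_only_at_peak_intoxication",
        bool(course.substance_only_at_peak_intoxication),
    )

    psychotic = psychotic_intensity_caarms(r)
    psych_freq = {s for s in psychotic if _in_band(r.frequency[s], BLIPS_FREQUENCY_BAND)}
    note("psychotic_intensity", bool(psychotic))
    note("psychotic_intensity_with_frequency_4_6", bool(psych_freq))

    # --- (1) psychosis threshold -----------------------------------------
    if prior_episode:
        return DiagnosticResult("CAARMS", Outcome.PSYCHOSIS, frozenset(), trace)
    if psych_freq:
        over_duration = note("psychotic_duration_over_7d", duration > BLIPS_MAX_DURATION_DAYS)
        not_resolved = note("did_not_resolve_spontaneously", not resolved)
        if over_duration or not_resolved:
            return DiagnosticResult("CAARMS", Outcome.PSYCHOSIS, frozenset(), trace)

    # --- shared UHR gates -------------------------------------------------
    try:
        functioning = note("functioning_criterion", functioning_criterion_caarms(subject.functioning))
    except MissingDataError:
        functioning = note("functioning_criterion(missing_data->false)", False)
    onset_recent = (
        course.onset_months_ago is not None and course.onset_months_ago <= ONSET_WINDOW_MONTHS
    ) or bool(course.symptoms_present_past_month)
    note("onset_within_12m", onset_recent)
    age_ok = note("symptoms_not_longer_than_5y", not course.symptoms_present_longer_than_5y)
    gates = functioning and onset_recent and age_ok and not substance_peak

    subgroups: set = set()

    # --- (2) BLIPS --------------------------------------------------------
    if psych_freq and duration <= BLIPS_MAX_DURATION_DAYS and resolved and gates:
        subgroups.add(Subgroup.BLIPS)
    note("BLIPS", Subgroup.BLIPS in subgroups)

    # --- (3) APS ----------------------------------------------------------
    attenuated_path = any(
        _in_band(r.frequency[s], APS_FREQUENCY_BAND) for s in attenuated_intensity_caarms(r)
    )
    subfreq_path = any(r.frequency[s] == APS_SUBTHRESHOLD_FREQUENCY for s in psychotic)
    note("APS_subthreshold_intensity_path", attenuated_path)
    note("APS_subthreshold_frequency_path", subfreq_path)
    if (attenuated_path or subfreq_path) and gates:
        subgroups.add(Subgroup.APS)
    note("APS", Subgroup.APS in subgroups)

    # --- (4) vulnerability ------------------------------------------------
    if caarms_vulnerability(subject):
        subgroups.add(Subgroup.GRD)
    note("GRD_vulnerability", Subgroup.GRD in subgroups)

    if subgroups:
        return DiagnosticResult("CAARMS", Outcome.UHR_POS, frozenset(subgroups), trace)
    return DiagnosticResult("CAARMS", Outcome.UHR_NEG, frozenset(), trace)
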