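"""Naive truth-table oracles for the two rule engines.

Deliberately coded as flat literal transcriptions of the printed
inclusion/onset/duration/functioning/exclusion rows, independent of the
package's implementation structure, for equivalence testing.
"""

from uhrconvert.instruments import Outcome, SubjectRecord


def _caarms_functioning(f) -> bool:
    if f.sofas_below_50_past_12m:
        return True
    if f.sofas_current is None or f.sofas_premorbid is None or f.sofas_premorbid <= 0:
        return False
    return (
        f.sofas_current <= 0.70 * f.sofas_premorbid
        and bool(f.sofas_drop_sustained_one_month_within_12m)
    )


def caarms_oracle(subject: SubjectRecord) -> str:
    """Literal transcription of the CAARMS 12/2006 criteria rows."""
    sev = subject.caarms.severity
    freq = subject.caarms.frequency
    c = subject.course

    duration = c.psychotic_intensity_duration_days or 0.0
    resolved = True if c.resolved_without_antipsychotics is None else c.resolved_without_antipsychotics

    # psychotic band: 6 on P1/P2/P4, 5-6 on P3
    psychotic = set()
    for s in ("P1", "P2", "P4"):
        if sev[s] == 6:
            psychotic.add(s)
    if sev["P3"] in (5, 6):
        psychotic.add("P3")

    if c.prior_psychotic_episode:
        return Outcome.PSYCHOSIS.value
    if any(4 <= freq[s] <= 6 for s in psychotic):
        if duration > 7 or not resolved:
            return Outcome.PSYCHOSIS.value

    func = _caarms_functioning(subject.functioning)
    onset = (
        c.onset_months_ago is not None and c.onset_months_ago <= 12
    ) or bool(c.symptoms_present_past_month)
    gates = (
        func
        and onset
        and not c.symptoms_present_longer_than_5y
        and not c.substance_only_at_peak_intoxication
    )

    blips = gates and resolved and duration <= 7 and any(
        4 <= freq[s] <= 6 for s in psychotic
    )

    attenuated = set()
    if 3 <= sev["P1"] <= 5:
        attenuated.add("P1")
    if 3 <= sev["P2"] <= 5:
        attenuated.add("P2")
    if 3 <= sev["P3"] <= 4:
        attenuated.add("P3")
    if 4 <= sev["P4"] <= 5:
        attenuated.add("P4")
    aps = gates and (
        any(3 <= freq[s] <= 6 for s in attenuated)
        or any(freq[s] == 3 for s in psychotic)
    )

    grd = (
        bool(subject.trait.schizotypal_personality_disorder)
        or bool(subject.trait.first_degree_relative_psychosis)
    ) and func

    if blips or aps or grd:
        return Outcome.UHR_POS.value
    return Outcome.UHR_NEG.value


def sips_oracle(subject: SubjectRecord) -> str:
    """Literal transcription of the SIPS 5.0 criteria rows."""
    sev = subject.sips.severity
    freq = subject.sips.frequency
    tw = subject.sips.substance_intertwined
    c = subject.course
    subs = ("P1", "P2", "P3", "P4", "P5")

    duration = c.psychotic_intensity_duration_days or 0.0
    danger = bool(c.danger_or_disorganization)
    comorbid = bool(c.comorbid_disorder_better_explains)

    psychotic = {s for s in subs if sev[s] == 6}
    if c.prior_psychotic_episode:
        return Outcome.PSYCHOSIS.value
    if psychotic and (danger or any(freq[s] == 3 for s in psychotic)):
        return Outcome.PSYCHOSIS.value

    onset3 = (
        c.psychotic_onset_months_ago is not None and c.psychotic_onset_months_ago <= 3
    ) or (c.psychotic_onset_months_ago is None and duration <= 91)
    bips = (
        any(freq[s] >= 1 and not tw[s] for s in psychotic)
        and onset3
        and duration <= 91
        and not danger
        and not comorbid
    )

    recency = (
        c.onset_months_ago is not None and c.onset_months_ago <= 12
    ) or bool(c.severity_increased_past_year)
    aps = (
        any(3 <= sev[s] <= 5 and freq[s] >= 2 and not tw[s] for s in subs)
        and recency
        and bool(c.symptoms_present_past_month)
        and not comorbid
    )

    f = subject.functioning
    grd = (
        bool(subject.trait.schizotypal_personality_disorder)
        or bool(subject.trait.first_degree_relative_psychosis)
    ) and (
        f.gaf_current_month is not None
        and f.gaf_12_months_ago is not None
        and f.gaf_12_months_ago > 0
        and f.gaf_current_month <= 0.70 * f.gaf_12_months_ago
    )

    if bips or aps or grd:
        return Outcome.UHR_POS.value
    return Outcome.UHR_NEG.value
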