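"""Cross-instrument conversion of individual UHR cases (the CONVERT engine).

A subject assessed on one instrument is mapped to the predicted outcome
under the other by (1) crosswalking subscale severities and frequencies
onto the target instrument's scales, (2) carrying the shared clinical
facts (course, trait risk, functioning) across, and (3) applying the
target instrument's own diagnostic rule engine.

Subscale crosswalk
------------------
===============  ===============
CAARMS -> SIPS   SIPS -> CAARMS
===============  ===============
P1 -> P1         P1 -> P1
P2 -> P2         max(P2, P3) -> P2
P3 -> P4         P4 -> P3
P4 -> P5         P5 -> P4
===============  ===============

SIPS P3 (Grandiose Ideas) has no CAARMS counterpart: going CAARMS->SIPS
it is left unrated (0), and going SIPS->CAARMS the CAARMS P2 receives
the highest score across SIPS P2/P3. Severities cross unchanged (the
diagnostic thresholds are defined on the raw anchors); frequencies are
mapped between the CAARMS 0-6 and SIPS 0-3 anchor sets, resolving
ambiguous anchors conservatively downward.

The engineered differences between the two rule sets then produce the
documented discordances: SIPS urgency turns a CAARMS BLIPS into SIPS
psychosis; a psychotic episode lasting between 7 days and 3 months is
psychosis under the CAARMS but BIPS under the SIPS; perceptual
abnormalities at severity 5 are psychotic under the CAARMS (P3) but
attenuated under the SIPS (P4); the CAARMS functioning gate and the SIPS
comorbidity gate each veto only their own instrument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .caarms import classify_caarms
from .instruments import (
    CAARMSRatings,
    DiagnosticResult,
    MissingDataError,
    SIPSRatings,
    SubjectRecord,
)
from .sips import classify_sips

__all__ = [
    "CAARMS_TO_SIPS_SUBSCALE",
    "SIPS_TO_CAARMS_SUBSCALE",
    "CAARMS_TO_SIPS_FREQUENCY",
    "SIPS_TO_CAARMS_FREQUENCY",
    "ConversionResult",
    "caarms_to_sips",
    "sips_to_caarms",
    "convert_cohort",
]

CAARMS_TO_SIPS_SUBSCALE = {"P1": "P1", "P2": "P2", "P3": "P4", "P4": "P5"}
SIPS_TO_CAARMS_SUBSCALE = {"P1": "P1", "P2": "P2", "P3": "P2", "P4": "P3", "P5": "P4"}

# CAARMS frequency anchors (0-6) onto SIPS anchors (0-3); ambiguous cells
# resolved downward (prefer under-calling frequency to over-calling
# diagnosis).
CAARMS_TO_SIPS_FREQUENCY = {0: 0, 1: 0, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3}
# SIPS anchors back onto the CAARMS scale.
SIPS_TO_CAARMS_FREQUENCY = {0: 1, 1: 2, 2: 3, 3: 5}
# For a subscale at SIPS psychotic intensity (severity 6), the SIPS
# anchors describe daily phenomena ("at least several min per d"), which
# sit in the CAARMS 4-5 daily band; mapping them conservatively downward
# would strand an established psychotic episode below the CAARMS 4-6
# psychotic-frequency band.
SIPS_TO_CAARMS_FREQUENCY_PSYCHOTIC = {0: 1, 1: 4, 2: 4, 3: 5}


@dataclass(frozen=True)
class ConversionResult:
    """Outcome of converting one subject to the other instrument."""

    source_instrument: str
    predicted: DiagnosticResult
    crosswalked: SubjectRecord
    notes: tuple

    @property
    def target_instrument(self) -> str:
        return self.predicted.instrument


def caarms_to_sips(subject: SubjectRecord) -> ConversionResult:
    """Predict the SIPS 5.0 outcome of a CAARMS-rated subject."""
    if subject.caarms is None:
        raise MissingDataError("instrument not rated: CAARMS")
    notes: list = []
    c = subject.caarms
    severity = {s: 0 for s in ("P1", "P2", "P3", "P4", "P5")}
    frequency = dict(severity)
    intertwined = {s: False for s in severity}
    for src, dst in CAARMS_TO_SIPS_SUBSCALE.items():
        severity[dst] = c.severity[src]
        frequency[dst] = CAARMS_TO_SIPS_FREQUENCY[c.frequency[src]]
        # CAARMS code 2 = noted only in relation to substance use
        intertwined[dst] = c.substance[src] == 2
    notes.append("SIPS P3 (Grandiose Ideas) has no CAARMS counterpart; left unrated")
    if any(intertwined.values()):
        notes.append("substance-intertwined flags derived from CAARMS code 2")

    functioning = subject.functioning
    if functioning.gaf_current_month is None or functioning.gaf_12_months_ago is None:
        if functioning.sofas_current is not None and functioning.sofas_premorbid is not None:
            functioning = subject.functioning.__class__(
                sofas_current=functioning.sofas_current,
                sofas_premorbid=functioning.sofas_premorbid,
                sofas_drop_sustained_one_month_within_12m=functioning.sofas_drop_sustained_one_month_within_12m,
                sofas_below_50_past_12m=functioning.sofas_below_50_past_12m,
                gaf_current_month=functioning.sofas_current,
                gaf_12_months_ago=functioning.sofas_premorbid,
            )
            notes.append("GAF drop proxied by SOFAS drop")

    crosswalked = subject.with_(
        sips=SIPSRatings(severity, frequency, intertwined), functioning=functioning
    )
    predicted = classify_sips(crosswalked)
    return ConversionResult("CAARMS", predicted, crosswalked, tuple(notes))


def sips_to_caarms(subject: SubjectRecord) -> ConversionResult:
    """Predict the CAARMS 12/2006 outcome of a SIPS-rated subject."""
    if subject.sips is None:
        raise MissingDataError("instrument not rated: SIPS")
    notes: list = []
    s = subject.sips
    severity = {}
    frequency = {}
    substance = {}

    def freq(sub: str) -> int:
        if s.severity[sub] >= 6:
            return SIPS_TO_CAARMS_FREQUENCY_PSYCHOTIC[s.frequency[sub]]
        return SIPS_TO_CAARMS_FREQUENCY[s.frequency[sub]]

    # CAARMS P2 takes the highest score across SIPS P2/P3 (ties keep the
    # larger frequency)
    if s.severity["P3"] > s.severity["P2"]:
        donor = "P3"
    elif s.severity["P3"] == s.severity["P2"]:
        donor = "P3" if s.frequency["P3"] > s.frequency["P2"] else "P2"
    else:
        donor = "P2"
    if donor == "P3":
        notes.append("CAARMS P2 taken from SIPS P3 (higher of P2/P3)")
    for dst, src in (("P1", "P1"), ("P2", donor), ("P3", "P4"), ("P4", "P5")):
        severity[dst] = s.severity[src]
        frequency[dst] = freq(src)
        substance[dst] = 2 if s.substance_intertwined[src] else 0

    functioning = subject.functioning
    if functioning.sofas_current is None or functioning.sofas_premorbid is None:
        if functioning.gaf_current_month is not None and functioning.gaf_12_months_ago is not None:
            # the GAF criterion's one-month window stands in for the
            # sustained-drop flag
            functioning = subject.functioning.__class__(
                sofas_current=functioning.gaf_current_month,
                sofas_premorbid=functioning.gaf_12_months_ago,
                sofas_drop_sustained_one_month_within_12m=True,
                sofas_below_50_past_12m=functioning.sofas_below_50_past_12m,
                gaf_current_month=functioning.gaf_current_month,
                gaf_12_months_ago=functioning.gaf_12_months_ago,
            )
            notes.append("SOFAS drop proxied by GAF drop")

    crosswalked = subject.with_(
        caarms=CAARMSRatings(severity, frequency, substance), functioning=functioning
    )
    predicted = classify_caarms(crosswalked)
    return ConversionResult("SIPS", predicted, crosswalked, tuple(notes))


def convert_cohort(
    records: Sequence[SubjectRecord], direction: str
) -> pd.DataFrame:
    """Convert every record in a cohort; one row per subject.

    ``direction`` is ``"caarms2sips"`` or ``"sips2caarms"``. Records also
    rated on the target instrument contribute an ``observed`` column (the
    target engine run on the actual target ratings) for validation;
    otherwise ``observed`` is missing. Per-record failures are collected
    in the ``error`` column, not raised.
    """
    if direction == "caarms2sips":
        fn, target_rated = caarms_to_sips, lambda r: r.sips is not None
        observe = classify_sips
    elif direction == "sips2caarms":
        fn, target_rated = sips_to_caarms, lambda r: r.caarms is not None
        observe = classify_caarms
    else:
        raise ValueError("direction must be 'caarms2sips' or 'sips2caarms'")

    rows = []
    for rec in records:
        row = {
            "subject_id": rec.subject_id,
            "observed": pd.NA,
            "observed_subgroup": pd.NA,
            "predicted": pd.NA,
            "predicted_subgroup": pd.NA,
            "notes": "",
            "error": "",
        }
        try:
            conv = fn(rec)
            row["predicted"] = conv.predicted.primary_outcome.value
            sg = conv.predicted.primary_subgroup
            row["predicted_subgroup"] = sg.value if sg else pd.NA
            row["notes"] = "; ".join(conv.notes)
        except (MissingDataError, ValueError) as exc:
            row["error"] = str(exc)
        if target_rated(rec):
            try:
                obs = observe(rec)
                row["observed"] = obs.primary_outcome.value
                osg = obs.primary_subgroup
                row["observed_subgroup"] = osg.value if osg else pd.NA
            except (MissingDataError, ValueError) as exc:
                row["error"] = (row["error"] + "; " if row["error"] else "") + str(exc)
        rows.append(row)
    columns = [
        "subject_id",
        "observed",
        "observed_subgroup",
        "predicted",
        "predicted_subgroup",
        "notes",
        "error",
    ]
    return pd.DataFrame(rows, columns=columns)
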