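import numpy as np
import pytest

from uhrconvert import (
    CAARMSRatings,
    ClinicalCourse,
    ContingencyTable,
    FunctioningHistory,
    SIPSRatings,
    SubjectRecord,
    TraitRisk,
)

# the published 3x3 diagnostic crosstab (rows CAARMS, columns SIPS)
TABLE3_COUNTS = [[51, 0, 0], [5, 92, 14], [1, 9, 40]]
THREE_LABELS = ("UHR_NEG", "UHR_POS", "PSYCHOSIS")


@pytest.fixture
def table3() -> ContingencyTable:
    return ContingencyTable(THREE_LABELS, TABLE3_COUNTS)


def functioning_met() -> FunctioningHistory:
    return FunctioningHistory(
        sofas_current=45,
        sofas_premorbid=80,
        sofas_drop_sustained_one_month_within_12m=True,
        sofas_below_50_past_12m=False,
        gaf_current_month=45,
        gaf_12_months_ago=80,
    )


def functioning_unmet() -> FunctioningHistory:
    return FunctioningHistory(
        sofas_current=75,
        sofas_premorbid=80,
        sofas_drop_sustained_one_month_within_12m=False,
        sofas_below_50_past_12m=False,
        gaf_current_month=75,
        gaf_12_months_ago=80,
    )


def benign_course(**overrides) -> ClinicalCourse:
    base = dict(
        onset_months_ago=6.0,
        symptoms_present_longer_than_5y=False,
        severity_increased_past_year=True,
        symptoms_present_past_month=True,
        psychotic_intensity_duration_days=0.0,
        psychotic_onset_months_ago=0.0,
        resolved_without_antipsychotics=True,
        danger_or_disorganization=False,
        prior_psychotic_episode=False,
        comorbid_disorder_better_explains=False,
        substance_only_at_peak_intoxication=False,
    )
    base.update(overrides)
    return ClinicalCourse(**base)


def make_caarms_subject(
    severity=None,
    frequency=None,
    substance=None,
    course=None,
    functioning=None,
    trait=None,
    subject_id="T",
) -> SubjectRecord:
    return SubjectRecord(
        subject_id=subject_id,
        caarms=CAARMSRatings(severity or {}, frequency or {}, substance or {}),
        course=course or benign_course(),
        functioning=functioning or functioning_met(),
        trait=trait or TraitRisk(False, False),
    )


def make_sips_subject(
    severity=None,
    frequency=None,
    intertwined=None,
    course=None,
    functioning=None,
    trait=None,
    subject_id="T",
) -> SubjectRecord:
    return SubjectRecord(
        subject_id=subject_id,
        sips=SIPSRatings(severity or {}, frequency or {}, intertwined or {}),
        course=course or benign_course(),
        functioning=functioning or functioning_met(),
        trait=trait or TraitRisk(False, False),
    )


def make_dual_subject(caarms_kwargs=None, sips_kwargs=None, **shared) -> SubjectRecord:
    c = make_caarms_subject(**(caarms_kwargs or {}), **shared)
    s = make_sips_subject(**(sips_kwargs or {}), **shared)
    return c.with_(sips=s.sips)
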