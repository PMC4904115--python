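"""Domain types shared by both ultra-high-risk (UHR) diagnostic instruments.

The package models two semi-structured interviews used to assess the
at-risk mental state for psychosis:

* **CAARMS 12/2006** — four positive-symptom subscales (P1 Unusual Thought
  Content, P2 Non-Bizarre Ideas, P3 Perceptual Abnormalities, P4
  Disorganized Speech), each rated for severity 0–6 and frequency 0–6,
  with a 0–2 substance-relation code and an informational 0–100 distress
  rating.
* **SIPS 5.0** — five positive-symptom subscales (P1 Unusual Thought
  Content/Delusional Ideas, P2 Suspiciousness, P3 Grandiose Ideas, P4
  Perceptual Abnormalities/Hallucinations, P5 Disorganized Communication),
  severity 0–6 and frequency rated on a coarser 0–3 scale (0 denotes a
  frequency below the lowest printed anchor), with a per-subscale
  substance-intertwined exclusion flag.

Both rule engines additionally consume shared clinical facts: course of
illness (onset, duration at psychotic intensity, spontaneous resolution,
danger/disorganization), trait risk (schizotypal personality disorder or a
first-degree relative with psychosis) and functioning history (SOFAS for
the CAARMS, GAF for the SIPS).

Distress ratings and the CAARMS substance-relation codes are carried for
completeness but never determine a diagnostic outcome.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

__all__ = [
    "CAARMS_SUBSCALES",
    "SIPS_SUBSCALES",
    "Outcome",
    "Subgroup",
    "CAARMSRatings",
    "SIPSRatings",
    "ClinicalCourse",
    "FunctioningHistory",
    "TraitRisk",
    "SubjectRecord",
    "DiagnosticResult",
    "MissingDataError",
    "validate_record",
    "functioning_criterion_caarms",
    "functioning_criterion_sips_grd",
]

CAARMS_SUBSCALES = ("P1", "P2", "P3", "P4")
SIPS_SUBSCALES = ("P1", "P2", "P3", "P4", "P5")


class MissingDataError(ValueError):
    """Raised when a criterion is evaluated without its required inputs."""


class Outcome(str, enum.Enum):
    """Primary diagnostic outcome of a UHR assessment."""

    UHR_NEG = "UHR_NEG"
    UHR_POS = "UHR_POS"
    PSYCHOSIS = "PSYCHOSIS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Subgroup(str, enum.Enum):
    """UHR+ inclusion subgroup.

    ``BLIPS`` covers both the CAARMS BLIPS and the SIPS BIPS syndromes;
    ``GRD`` covers SIPS genetic risk and deterioration and the CAARMS
    vulnerability group.
    """

    GRD = "GRD"
    APS = "APS"
    BLIPS = "BLIPS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_score_map(values: Mapping[str, int], subscales: Sequence[str]) -> dict:
    return {s: int(values.get(s, 0)) for s in subscales}


@dataclass(frozen=True)
class CAARMSRatings:
    """Positive-symptom ratings on the CAARMS 12/2006.

    Parameters
    ----------
    severity, frequency
        Mapping from subscale ("P1".."P4") to an integer 0-6. Missing
        subscales default to 0.
    substance
        Substance-relation code per subscale: 0 no relation, 1 occurs in
        relation to substance use and at other times, 2 only in relation
        to substance use. Informational; the subject-level peak
        intoxication flag on :class:`ClinicalCourse` drives the exclusion.
    distress
        Optional 0-100 distress rating per subscale; never used to
        determine UHR status.
    """

    severity: Mapping[str, int]
    frequency: Mapping[str, int]
    substance: Mapping[str, int] = field(default_factory=dict)
    distress: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "severity", _as_score_map(self.severity, CAARMS_SUBSCALES))
        object.__setattr__(self, "frequency", _as_score_map(self.frequency, CAARMS_SUBSCALES))
        object.__setattr__(self, "substance", _as_score_map(self.substance, CAARMS_SUBSCALES))
        if self.distress is not None:
            object.__setattr__(self, "distress", dict(self.distress))


@dataclass(frozen=True)
class SIPSRatings:
    """Positive-symptom ratings on the SIPS 5.0.

    Frequency uses the SIPS 0-3 scale where 0 means "below the lowest
    anchor" (less than several minutes per day at least once a month).
    ``substance_intertwined`` marks subscales whose symptoms are strongly
    intertwined temporally with substance use; such a subscale cannot
    qualify for APS or BIPS.
    """

    severity: Mapping[str, int]
    frequency: Mapping[str, int]
    substance_intertwined: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "severity", _as_score_map(self.severity, SIPS_SUBSCALES))
        object.__setattr__(self, "frequency", _as_score_map(self.frequency, SIPS_SUBSCALES))
        object.__setattr__(
            self,
            "substance_intertwined",
            {s: bool(self.substance_intertwined.get(s, False)) for s in SIPS_SUBSCALES},
        )


@dataclass(frozen=True)
class ClinicalCourse:
    """Shared clinical-course facts consumed by both rule engines.

    All booleans are tri-state: ``None`` means unknown. Classifiers treat
    an unknown exclusion flag as "not triggered" and record the
    assumption in the rule trace, mirroring the clinical convention of
    ruling in only on positive evidence.
    """

    onset_months_ago: Optional[float] = None
    symptoms_present_longer_than_5y: Optional[bool] = None
    severity_increased_past_year: Optional[bool] = None
    symptoms_present_past_month: Optional[bool] = None
    psychotic_intensity_duration_days: Optional[float] = None
    psychotic_onset_months_ago: Optional[float] = None
    resolved_without_antipsychotics: Optional[bool] = None
    danger_or_disorganization: Optional[bool] = None
    prior_psychotic_episode: Optional[bool] = None
    comorbid_disorder_better_explains: Optional[bool] = None
    substance_only_at_peak_intoxication: Optional[bool] = None


@dataclass(frozen=True)
class FunctioningHistory:
    """SOFAS (CAARMS) and GAF (SIPS) functioning scores, all 0-100.

    The 30% drop ratio is always derived from the stored scores, never
    stored itself.
    """

    sofas_current: Optional[int] = None
    sofas_premorbid: Optional[int] = None
    sofas_drop_sustained_one_month_within_12m: Optional[bool] = None
    sofas_below_50_past_12m: Optional[bool] = None
    gaf_current_month: Optional[int] = None
    gaf_12_months_ago: Optional[int] = None


@dataclass(frozen=True)
class TraitRisk:
    schizotypal_personality_disorder: Optional[bool] = None
    first_degree_relative_psychosis: Optional[bool] = None

    @property
    def present(self) -> bool:
        return bool(self.schizotypal_personality_disorder) or bool(
            self.first_degree_relative_psychosis
        )


@dataclass(frozen=True)
class SubjectRecord:
    """One assessed person: instrument ratings plus shared clinical facts."""

    subject_id: str
    caarms: Optional[CAARMSRatings] = None
    sips: Optional[SIPSRatings] = None
    course: ClinicalCourse = field(default_factory=ClinicalCourse)
    functioning: FunctioningHistory = field(default_factory=FunctioningHistory)
    trait: TraitRisk = field(default_factory=TraitRisk)

    def with_(self, **kwargs) -> "SubjectRecord":
        return replace(self, **kwargs)


_SUBGROUP_PRECEDENCE = (Subgroup.BLIPS, Subgroup.APS, Subgroup.GRD)


@dataclass(frozen=True)
class DiagnosticResult:
    """Outcome of one rule engine on one subject.

    ``rule_trace`` is an ordered list of ``(criterion_id, passed)`` pairs
    recording every criterion the engine evaluated, making each decision
    auditable and reproducible.
    """

    instrument: str
    primary_outcome: Outcome
    subgroups_met: frozenset
    rule_trace: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "subgroups_met", frozenset(self.subgroups_met))
        object.__setattr__(self, "rule_trace", tuple(self.rule_trace))
        if self.primary_outcome is Outcome.UHR_POS and not self.subgroups_met:
            raise ValueError("UHR_POS requires a nonempty subgroup set")
        if self.primary_outcome is not Outcome.UHR_POS and self.subgroups_met:
            raise ValueError("subgroups_met must be empty unless UHR_POS")

    @property
    def primary_subgroup(self) -> Optional[Subgroup]:
        """Highest-precedence subgroup met (BLIPS > APS > GRD), or None."""
        for sg in _SUBGROUP_PRECEDENCE:
            if sg in self.subgroups_met:
                return sg
        return None

    @property
    def fine_label(self) -> str:
        """Five-category label: UHR_NEG / GRD / APS / BLIPS / PSYCHOSIS."""
        if self.primary_outcome is Outcome.UHR_POS:
            return self.primary_subgroup.value
        return self.primary_outcome.value


# ---------------------------------------------------------------------------
# validation


def _check_range(violations, owner, name, value, lo, hi) -> None:
    if value is None:
        return
    if not (lo <= value <= hi):
        violations.append(f"{owner}.{name}: {value} out of [{lo},{hi}]")


def validate_record(record: SubjectRecord) -> list:
    """Return a list of human-readable invariant violations (empty if valid).

    Validation reports; it never raises.
    """
    v: list = []
    if record.caarms is None and record.sips is None:
        v.append("record: at least one instrument's ratings must be present")
    if record.caarms is not None:
        for s in CAARMS_SUBSCALES:
            _check_range(v, f"caarms.{s}", "severity", record.caarms.severity[s], 0, 6)
            _check_range(v, f"caarms.{s}", "frequency", record.caarms.frequency[s], 0, 6)
            _check_range(v, f"caarms.{s}", "substance", record.caarms.substance[s], 0, 2)
            if record.caarms.distress is not None and s in record.caarms.distress:
                _check_range(v, f"caarms.{s}", "distress", record.caarms.distress[s], 0, 100)
    if record.sips is not None:
        for s in SIPS_SUBSCALES:
            _check_range(v, f"sips.{s}", "severity", record.sips.severity[s], 0, 6)
            _check_range(v, f"sips.{s}", "frequency", record.sips.frequency[s], 0, 3)
    f = record.functioning
    for name in (
        "sofas_current",
        "sofas_premorbid",
        "gaf_current_month",
        "gaf_12_months_ago",
    ):
        _check_range(v, "functioning", name, getattr(f, name), 0, 100)
    c = record.course
    for name in (
        "onset_months_ago",
        "psychotic_intensity_duration_days",
        "psychotic_onset_months_ago",
    ):
        value = getattr(c, name)
        if value is not None and value < 0:
            v.append(f"course.{name}: {value} must be >= 0")
    if (
        c.psychotic_intensity_duration_days is not None
        and c.psychotic_onset_months_ago is not None
        and c.psychotic_intensity_duration_days > c.psychotic_onset_months_ago * 30.44 + 1e-9
    ):
        v.append(
            "course.psychotic_intensity_duration_days: duration exceeds time "
            "elapsed since psychotic onset"
        )
    return v


# ---------------------------------------------------------------------------
# functioning criteria

# "30% drop" is operationalized as current <= 0.70 * reference, inclusive,
# on the raw 0-100 scale.
_DROP_FACTOR = 0.70


def functioning_criterion_caarms(f: FunctioningHistory) -> bool:
    """CAARMS functional-decline criterion (required for every UHR subgroup).

    True iff a 30% SOFAS drop from the premorbid level, sustained for a
    month within the past 12 months, *or* a SOFAS score below 50 for the
    past 12 months or more.

    Raises
    ------
    MissingDataError
        If the SOFAS scores needed for the drop ratio are absent and the
        below-50 flag is not positively set.
    """
    if f.sofas_below_50_past_12m:
        return True
    if f.sofas_current is None or f.sofas_premorbid is None:
        raise MissingDataError("functioning data required: SOFAS current/premorbid")
    if f.sofas_premorbid <= 0:
        # a 30% drop from 0 is undefined and clinically meaningless
        return False
    dropped = f.sofas_current <= _DROP_FACTOR * f.sofas_premorbid
    return dropped and bool(f.sofas_drop_sustained_one_month_within_12m)


def functioning_criterion_sips_grd(f: FunctioningHistory) -> bool:
    """SIPS GRD functioning criterion: 30% GAF drop over the last month
    compared to 12 months before."""
    if f.gaf_current_month is None or f.gaf_12_months_ago is None:
        raise MissingDataError("functioning data required: GAF current/12-months-ago")
    if f.gaf_12_months_ago <= 0:
        return False
    return f.gaf_current_month <= _DROP_FACTOR * f.gaf_12_months_ago
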