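"""Synthetic dual-instrument UHR cohorts with controllable discordance.

Each subject is drawn from a latent clinical state and rated on both
instruments so that, with every discordance mechanism switched off, both
rule engines recover the state's canonical outcome:

=================  =========================================
latent state       canonical outcome
=================  =========================================
none               UHR_NEG
trait_risk         UHR_POS (GRD: trait + functional decline)
attenuated         UHR_POS (APS)
brief_psychotic    UHR_POS (BLIPS / BIPS)
frank_psychotic    PSYCHOSIS
=================  =========================================

Five documented cross-instrument discordance mechanisms can be injected
at configurable prevalences:

* ``danger_prevalence`` — brief psychotic episodes that are seriously
  disorganizing/dangerous: BLIPS under the CAARMS but over the psychosis
  threshold under the SIPS urgency rule;
* ``long_duration_prevalence`` — brief episodes lasting between 7 days
  and 3 months: psychosis under the CAARMS, BIPS under the SIPS;
* ``band_shift_prevalence`` — perceptual abnormalities at severity 5:
  psychotic under the CAARMS (P3) but attenuated under the SIPS (P4);
* ``comorbidity_prevalence`` — attenuated symptoms better explained by a
  comorbid disorder: APS under the CAARMS, UHR_NEG under the SIPS;
* ``functioning_prevalence`` (per state) — a failed SOFAS/GAF
  functional-decline criterion vetoes every CAARMS subgroup and the GRD
  route of both instruments, but not SIPS APS/BIPS.

Severities are drawn uniformly within the qualifying band; one seed
drives per-subject substreams so cohorts are reproducible and stable
under changes of ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .instruments import (
    CAARMSRatings,
    ClinicalCourse,
    FunctioningHistory,
    Outcome,
    SIPSRatings,
    SubjectRecord,
    TraitRisk,
)

__all__ = ["LATENT_STATES", "CohortSpec", "generate_cohort", "latent_truth"]

LATENT_STATES = ("none", "trait_risk", "attenuated", "brief_psychotic", "frank_psychotic")

_CANONICAL_OUTCOME = {
    "none": Outcome.UHR_NEG,
    "trait_risk": Outcome.UHR_POS,
    "attenuated": Outcome.UHR_POS,
    "brief_psychotic": Outcome.UHR_POS,
    "frank_psychotic": Outcome.PSYCHOSIS,
}

# shared positive-symptom domains: (CAARMS subscale, SIPS subscale)
_SHARED_DOMAINS = (("P1", "P1"), ("P2", "P2"), ("P3", "P4"), ("P4", "P5"))

# concordant attenuated severity range per shared domain (intersection of
# the two instruments' attenuated bands after the subscale crosswalk)
_ATTENUATED_RANGE = {"P1": (3, 5), "P2": (3, 5), "P3": (3, 4), "P4": (4, 5)}


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration: sample size, seed, latent mixture and
    discordance-mechanism prevalences."""

    n: int = 200
    seed: int = 0
    mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "none": 0.24,
            "trait_risk": 0.06,
            "attenuated": 0.34,
            "brief_psychotic": 0.12,
            "frank_psychotic": 0.24,
        }
    )
    danger_prevalence: float = 0.0
    long_duration_prevalence: float = 0.0
    band_shift_prevalence: float = 0.0
    comorbidity_prevalence: float = 0.0
    functioning_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "none": 0.2,
            "trait_risk": 1.0,
            "attenuated": 1.0,
            "brief_psychotic": 1.0,
            "frank_psychotic": 0.5,
        }
    )

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        mix = {s: float(self.mixture.get(s, 0.0)) for s in LATENT_STATES}
        if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("mixture must be a probability distribution over latent states")
        for name in (
            "danger_prevalence",
            "long_duration_prevalence",
            "band_shift_prevalence",
            "comorbidity_prevalence",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        fp = {s: float(self.functioning_prevalence.get(s, 1.0)) for s in LATENT_STATES}
        if any(not (0.0 <= v <= 1.0) for v in fp.values()):
            raise ValueError("functioning prevalences must be in [0,1]")
        object.__setattr__(self, "mixture", mix)
        object.__setattr__(self, "functioning_prevalence", fp)

    @classmethod
    def table3_like(cls, n: int = 212, seed: int = 0) -> "CohortSpec":
        """Study-condition preset: latent mixture anchored to the observed
        24%/52%/24% outcome marginals and mechanism prevalences set from
        the documented discordance counts (14/25 dangerous brief
        episodes, 4/25 long-duration brief episodes, ~6 perceptual
        band-shift cases, ~5 comorbidity exclusions)."""
        return cls(
            n=n,
            seed=seed,
            danger_prevalence=0.56,
            long_duration_prevalence=0.16,
            band_shift_prevalence=0.12,
            comorbidity_prevalence=0.045,
        )

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


def _functioning(rng, met: bool) -> FunctioningHistory:
    """SOFAS/GAF histories that do (or do not) meet the decline criteria
    of both instruments."""
    premorbid = int(rng.integers(70, 91))
    if met:
        current = int(rng.integers(25, int(0.70 * premorbid) + 1))
        return FunctioningHistory(
            sofas_current=current,
            sofas_premorbid=premorbid,
            sofas_drop_sustained_one_month_within_12m=True,
            sofas_below_50_past_12m=bool(current < 50 and rng.random() < 0.5),
            gaf_current_month=current,
            gaf_12_months_ago=premorbid,
        )
    current = int(rng.integers(int(0.75 * premorbid), premorbid + 1))
    return FunctioningHistory(
        sofas_current=current,
        sofas_premorbid=premorbid,
        sofas_drop_sustained_one_month_within_12m=False,
        sofas_below_50_past_12m=False,
        gaf_current_month=current,
        gaf_12_months_ago=premorbid,
    )


def _quiet_ratings(rng):
    """Sub-attenuated ratings on both instruments (severity <= 2)."""
    csev = {s: int(rng.integers(0, 3)) for s in ("P1", "P2", "P3", "P4")}
    cfreq = {s: int(rng.integers(0, 7)) if csev[s] else 0 for s in csev}
    ssev = {"P1": csev["P1"], "P2": csev["P2"], "P3": 0, "P4": csev["P3"], "P5": csev["P4"]}
    sfreq = {s: int(rng.integers(0, 4)) if ssev[s] else 0 for s in ssev}
    return CAARMSRatings(csev, cfreq), SIPSRatings(ssev, sfreq)


def _generate_subject(i: int, state: str, spec: CohortSpec, rng) -> SubjectRecord:
    functioning_met = rng.random() < spec.functioning_prevalence[state]
    functioning = _functioning(rng, functioning_met)
    trait = TraitRisk(schizotypal_personality_disorder=False, first_degree_relative_psychosis=False)
    course = ClinicalCourse(
        onset_months_ago=float(rng.integers(1, 12)),
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
    caarms, sips = _quiet_ratings(rng)

    if state == "none":
        pass

    elif state == "trait_risk":
        if rng.random() < 0.5:
            trait = replace(trait, schizotypal_personality_disorder=True)
        else:
            trait = replace(trait, first_degree_relative_psychosis=True)

    elif state == "attenuated":
        cs, ss = _SHARED_DOMAINS[int(rng.integers(0, len(_SHARED_DOMAINS)))]
        lo, hi = _ATTENUATED_RANGE[cs]
        sev = int(rng.integers(lo, hi + 1))
        cfreq = int(rng.integers(3, 7))  # maps to SIPS >= 2
        csev = dict(caarms.severity)
        cfr = dict(caarms.frequency)
        csev[cs], cfr[cs] = sev, cfreq
        ssev = dict(sips.severity)
        sfr = dict(sips.frequency)
        ssev[ss], sfr[ss] = sev, {3: 2, 4: 2, 5: 3, 6: 3}[cfreq]
        caarms, sips = CAARMSRatings(csev, cfr), SIPSRatings(ssev, sfr)
        if rng.random() < spec.comorbidity_prevalence:
            # SIPS excludes, CAARMS has no comorbidity criterion
            course = replace(course, comorbid_disorder_better_explains=True)

    elif state in ("brief_psychotic", "frank_psychotic"):
        brief = state == "brief_psychotic"
        u = rng.random()
        danger = brief and u < spec.danger_prevalence
        long_dur = brief and not danger and u < spec.danger_prevalence + spec.long_duration_prevalence
        band_shift = (not brief) and rng.random() < spec.band_shift_prevalence

        if band_shift:
            cs, ss, sev = "P3", "P4", 5  # psychotic on CAARMS P3, attenuated on SIPS P4
        else:
            cs, ss = _SHARED_DOMAINS[int(rng.integers(0, len(_SHARED_DOMAINS)))]
            sev = 6
        if brief:
            cfreq = 4  # SIPS frequency 2: below the POPS band
            duration = float(rng.integers(8, 91)) if long_dur else float(rng.integers(1, 8))
            course = replace(
                course,
                psychotic_intensity_duration_days=duration,
                psychotic_onset_months_ago=float(np.ceil(duration / 30.44)),
                resolved_without_antipsychotics=True,
                danger_or_disorganization=danger,
            )
        else:
            cfreq = int(rng.integers(5, 7))  # SIPS frequency 3: sustained
            duration = float(rng.integers(100, 200))
            course = replace(
                course,
                psychotic_intensity_duration_days=duration,
                psychotic_onset_months_ago=float(np.ceil(duration / 30.44)) + 1.0,
                resolved_without_antipsychotics=False,
                danger_or_disorganization=False,
            )
        csev = dict(caarms.severity)
        cfr = dict(caarms.frequency)
        csev[cs], cfr[cs] = sev, cfreq
        ssev = dict(sips.severity)
        sfr = dict(sips.frequency)
        ssev[ss], sfr[ss] = sev, {3: 2, 4: 2, 5: 3, 6: 3}[cfreq]
        caarms, sips = CAARMSRatings(csev, cfr), SIPSRatings(ssev, sfr)

    else:  # pragma: no cover - guarded by CohortSpec
        raise ValueError(f"unknown latent state {state!r}")

    return SubjectRecord(
        subject_id=f"S{i:05d}",
        caarms=caarms,
        sips=sips,
        course=course,
        functioning=functioning,
        trait=trait,
    )


def generate_cohort(spec: CohortSpec) -> List[SubjectRecord]:
    """Draw a reproducible synthetic cohort from ``spec``.

    A single seed drives one substream per subject (seeded by
    ``(spec.seed, i)``), so the first ``m`` subjects of a size-``n``
    cohort coincide with the size-``m`` cohort for the same seed.
    """
    states = _draw_states(spec)
    return [
        _generate_subject(i, state, spec, np.random.default_rng([spec.seed, i]))
        for i, state in enumerate(states)
    ]


def _draw_states(spec: CohortSpec) -> List[str]:
    rng = np.random.default_rng([spec.seed, 2**31 - 1])
    probs = np.array([spec.mixture[s] for s in LATENT_STATES])
    idx = rng.choice(len(LATENT_STATES), size=spec.n, p=probs)
    return [LATENT_STATES[j] for j in idx]


def latent_truth(spec: CohortSpec) -> List[str]:
    """Canonical (generating) outcome labels for ``spec``'s cohort, in
    subject order."""
    return [_CANONICAL_OUTCOME[s].value for s in _draw_states(spec)]
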