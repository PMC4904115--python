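"""Observed-score equipercentile linking between instrument scales.

Links an integer score on one instrument's scale to the (decimal) score
on the other instrument's scale that has the same percentile rank,
using the standard observed-score continuization in which each integer
score ``x`` is spread uniformly over ``[x - 0.5, x + 0.5)``. No
presmoothing is applied: the linking is the canonical unsmoothed
equipercentile method,

    e(x) = Q_target( P_source(x) ),

with ``P`` the continuized percentile-rank function and ``Q`` its
piecewise-linear inverse, clamped to ``[min - 0.5, max + 0.5]`` at the
extremes of the bounded scales.

For the frequency linkings the SIPS frequency is first re-coded onto the
analytic bands used in the published linking table (1: at least 1 h/day
at least 4 days/week; 2: at least several minutes/day at least once a
month; 3: at least once a week; 0: none of the above). This recode is
used for linking only, never for diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np

from .instruments import SubjectRecord

__all__ = [
    "ScoreDistribution",
    "LinkingTable",
    "percentile_rank",
    "inverse_percentile_rank",
    "link_scores",
    "recode_sips_frequency_for_linking",
    "build_linking_report",
]


@dataclass(frozen=True)
class ScoreDistribution:
    """Discrete frequency distribution over an integer score range."""

    minimum: int
    maximum: int
    counts: tuple

    def __post_init__(self) -> None:
        counts = tuple(float(c) for c in self.counts)
        if self.maximum < self.minimum:
            raise ValueError("empty score range")
        if len(counts) != self.maximum - self.minimum + 1:
            raise ValueError("need one count per score in range")
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if sum(counts) <= 0:
            raise ValueError("empty distribution")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_scores(cls, scores: Sequence[int], minimum: int, maximum: int) -> "ScoreDistribution":
        counts = [0] * (maximum - minimum + 1)
        for s in scores:
            s = int(s)
            if not (minimum <= s <= maximum):
                raise ValueError(f"score {s} outside [{minimum},{maximum}]")
            counts[s - minimum] += 1
        return cls(minimum, maximum, tuple(counts))

    @property
    def size(self) -> float:
        return float(sum(self.counts))

    @property
    def proportions(self) -> np.ndarray:
        return np.asarray(self.counts) / self.size

    @property
    def scores(self) -> range:
        return range(self.minimum, self.maximum + 1)


def percentile_rank(d: ScoreDistribution, x: float) -> float:
    """Continuized percentile rank of ``x``, in [0, 1].

    Each integer score is treated as uniform over its +/-0.5 interval,
    so for integer ``x``, ``P(x) = F(x - 1) + 0.5 f(x)``.
    """
    lo = d.minimum - 0.5
    hi = d.maximum + 0.5
    if x <= lo:
        return 0.0
    if x >= hi:
        return 1.0
    p = d.proportions
    i = int(np.floor(x + 0.5)) - d.minimum  # index of the interval holding x
    i = min(max(i, 0), len(p) - 1)
    below = float(p[:i].sum())
    frac = x - (d.minimum + i - 0.5)
    return below + frac * float(p[i])


def inverse_percentile_rank(d: ScoreDistribution, q: float) -> float:
    """Inverse of :func:`percentile_rank` (leftmost solution on flat runs).

    Values outside (0, 1) clamp to the scale boundaries
    ``min - 0.5`` / ``max + 0.5``.
    """
    if q <= 0.0:
        return d.minimum - 0.5
    if q >= 1.0:
        return d.maximum + 0.5
    p = d.proportions
    cum = np.concatenate([[0.0], np.cumsum(p)])
    # leftmost interval whose upper cumulative reaches q with positive mass
    for i in range(len(p)):
        if cum[i + 1] >= q and p[i] > 0:
            return (d.minimum + i - 0.5) + (q - cum[i]) / p[i]
    return d.maximum + 0.5  # pragma: no cover - q<1 always lands above


@dataclass(frozen=True)
class LinkingTable:
    """Source integer score -> linked decimal score on the target scale."""

    label: str
    pairs: tuple  # ((source_score, linked_score), ...)

    def as_dict(self) -> Dict[int, float]:
        return dict(self.pairs)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple((int(s), float(e)) for s, e in self.pairs))
        linked = [e for _, e in self.pairs]
        if any(b < a - 1e-12 for a, b in zip(linked, linked[1:])):
            raise ValueError("linked scores must be monotone nondecreasing")


def link_scores(
    source: ScoreDistribution,
    target: ScoreDistribution,
    scores: Sequence[int] = None,
    label: str = "",
) -> LinkingTable:
    """Equipercentile link of ``scores`` (default: the full source range)."""
    if scores is None:
        scores = list(source.scores)
    pairs = []
    for x in scores:
        q = percentile_rank(source, float(x))
        e = inverse_percentile_rank(target, q)
        e = min(max(e, target.minimum - 0.5), target.maximum + 0.5)
        pairs.append((int(x), e))
    return LinkingTable(label=label, pairs=tuple(pairs))


# standard SIPS frequency (0-3) -> analytic band used by the published
# linking table; for linking only, never for diagnosis
_SIPS_FREQ_LINKING_RECODE = {0: 0, 1: 2, 2: 3, 3: 1}


def recode_sips_frequency_for_linking(freq: int) -> int:
    """Recode a standard SIPS frequency rating onto the analytic bands.

    Band 1 is "at least 1 h/day, at least 4 days/week" (the highest
    standard anchor, 3); band 2 "at least several minutes/day at least
    once a month" (standard anchor 1); band 3 "at least once a week"
    (standard anchor 2); 0 none of the above. The recode is not an
    involution and exists only for the linking pathway.
    """
    freq = int(freq)
    if freq not in _SIPS_FREQ_LINKING_RECODE:
        raise ValueError(f"SIPS frequency {freq} out of [0,3]")
    return _SIPS_FREQ_LINKING_RECODE[freq]


def _dist(values: Sequence[int], minimum: int, maximum: int) -> ScoreDistribution:
    return ScoreDistribution.from_scores(values, minimum, maximum)


def build_linking_report(cohort: Sequence[SubjectRecord]) -> Dict[str, LinkingTable]:
    """Build the eight severity/frequency domain linkings for a cohort
    rated on both instruments.

    Domains: P1 CAARMS <-> P1 SIPS (both directions), P2 CAARMS -> P2
    SIPS, P2 CAARMS -> P3 SIPS, max(P2,P3) SIPS -> P2 CAARMS, P3 CAARMS
    <-> P4 SIPS, P4 CAARMS <-> P5 SIPS; each linked for severity and for
    frequency (SIPS frequencies recoded onto the analytic bands).
    """
    both = [r for r in cohort if r.caarms is not None and r.sips is not None]
    if not both:
        raise ValueError("cohort must contain records rated on both instruments")

    def csev(sub):
        return _dist([r.caarms.severity[sub] for r in both], 0, 6)

    def cfreq(sub):
        return _dist([r.caarms.frequency[sub] for r in both], 0, 6)

    def ssev(sub):
        return _dist([r.sips.severity[sub] for r in both], 0, 6)

    def sfreq(sub):
        return _dist(
            [recode_sips_frequency_for_linking(r.sips.frequency[sub]) for r in both], 0, 3
        )

    smax_sev = _dist([max(r.sips.severity["P2"], r.sips.severity["P3"]) for r in both], 0, 6)
    smax_freq = _dist(
        [
            max(
                recode_sips_frequency_for_linking(r.sips.frequency["P2"]),
                recode_sips_frequency_for_linking(r.sips.frequency["P3"]),
            )
            for r in both
        ],
        0,
        3,
    )

    domains = {
        "P1 CAARMS to P1 SIPS": (csev("P1"), ssev("P1"), cfreq("P1"), sfreq("P1")),
        "P1 SIPS to P1 CAARMS": (ssev("P1"), csev("P1"), sfreq("P1"), cfreq("P1")),
        "P2 CAARMS to P2 SIPS": (csev("P2"), ssev("P2"), cfreq("P2"), sfreq("P2")),
        "P2 CAARMS to P3 SIPS": (csev("P2"), ssev("P3"), cfreq("P2"), sfreq("P3")),
        "P2/P3 SIPS to P2 CAARMS": (smax_sev, csev("P2"), smax_freq, cfreq("P2")),
        "P3 CAARMS to P4 SIPS": (csev("P3"), ssev("P4"), cfreq("P3"), sfreq("P4")),
        "P4 SIPS to P3 CAARMS": (ssev("P4"), csev("P3"), sfreq("P4"), cfreq("P3")),
        "P4 CAARMS to P5 SIPS": (csev("P4"), ssev("P5"), cfreq("P4"), sfreq("P5")),
        "P5 SIPS to P4 CAARMS": (ssev("P5"), csev("P4"), sfreq("P5"), cfreq("P4")),
    }
    report: Dict[str, LinkingTable] = {}
    for name, (sev_src, sev_tgt, frq_src, frq_tgt) in domains.items():
        report[f"{name} [severity]"] = link_scores(sev_src, sev_tgt, label=f"{name} [severity]")
        report[f"{name} [frequency]"] = link_scores(frq_src, frq_tgt, label=f"{name} [frequency]")
    return report
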