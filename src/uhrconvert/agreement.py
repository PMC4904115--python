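"""Paired-outcome agreement statistics for two diagnostic instruments.

Implements the statistics used to compare two raters/instruments on the
same subjects: percent overall agreement, Cohen's kappa (with the
null-hypothesis standard error, Z statistic and 95% CI), weighted kappa,
the prevalence- and bias-adjusted kappa (PABAK), the McNemar-Bowker test
of marginal symmetry, and cell-wise expected counts with adjusted
standardized residuals.

Conventions
-----------
* The kappa confidence interval uses the null-hypothesis standard error
  SE0 (kappa +/- 1.96 * SE0); the large-sample non-null SE of Fleiss,
  Cohen & Everitt (1969) is also reported.
* Bowker's statistic drops discordant pairs with ``n_ij + n_ji = 0``
  from both the statistic and the degrees of freedom.
* Adjusted residuals beyond +/-3.29 correspond to p < 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "AgreementResult",
    "WeightedKappaSpec",
    "ResidualAnalysis",
    "AccuracyResult",
    "cohen_kappa",
    "weighted_kappa",
    "pabak",
    "bowker_test",
    "exact_mcnemar",
    "adjusted_residuals",
    "outcome_crosstab",
    "accuracy_metrics",
]

RESIDUAL_THRESHOLD = 3.29  # |r| beyond this ~ p < 0.001


@dataclass(frozen=True)
class ContingencyTable:
    """k x k paired-outcome counts (rows: instrument A, columns: B)."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("contingency table must be square")
        if counts.shape[0] != len(self.labels):
            raise ValueError("label count must match table dimension")
        if len(self.labels) < 2:
            raise ValueError("need at least 2 categories")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "counts", counts)

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class AgreementResult:
    """Kappa-family summary of one contingency table."""

    po: float                 # observed (possibly weighted) agreement
    pe: float                 # chance-expected agreement
    kappa: float
    se0: float                # null-hypothesis SE
    z: float
    p: float
    ci_low: float
    ci_high: float
    pabak: Optional[float] = None
    se: Optional[float] = None  # large-sample non-null SE

    def summary(self) -> str:
        lines = [
            f"observed agreement   {self.po * 100:.2f}%",
            f"chance agreement     {self.pe * 100:.2f}%",
            f"kappa                {self.kappa:.3f}",
            f"SE0 (null)           {self.se0:.4f}",
            f"Z                    {self.z:.2f}",
            f"p                    {self.p:.3g}",
            f"95% CI               {self.ci_low:.3f} to {self.ci_high:.3f}",
        ]
        if self.pabak is not None:
            lines.append(f"PABAK                {self.pabak:.3f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class WeightedKappaSpec:
    """Agreement weights built from per-category scores.

    The default weight matrix uses absolute-difference linear weights,
    ``w_ij = 1 - |s_i - s_j| / range(s)``, so identical categories get
    weight 1 and the most distant pair weight 0. A full weight matrix may
    be supplied instead of scores.
    """

    scores: Optional[Sequence[float]] = None
    weights: Optional[np.ndarray] = None

    def weight_matrix(self, k: int) -> np.ndarray:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (k, k):
                raise ValueError(f"weight matrix must be {k}x{k}")
            if not np.allclose(w, w.T):
                raise ValueError("weight matrix must be symmetric")
            if (w < 0).any() or (w > 1).any():
                raise ValueError("weights must lie in [0,1]")
            return w
        if self.scores is None:
            raise ValueError("provide scores or a weight matrix")
        s = np.asarray(self.scores, dtype=float)
        if s.size != k:
            raise ValueError("need one score per category")
        rng = s.max() - s.min()
        if rng == 0:
            raise ValueError("degenerate scores: zero range")
        return 1.0 - np.abs(s[:, None] - s[None, :]) / rng


def pabak(t: ContingencyTable) -> float:
    """Prevalence- and bias-adjusted kappa, (k*Po - 1) / (k - 1)."""
    po = float(np.trace(t.counts)) / t.n
    return (t.k * po - 1.0) / (t.k - 1.0)


def _kappa_core(t: ContingencyTable, w: Optional[np.ndarray]) -> AgreementResult:
    n = t.n
    if n <= 0:
        raise ValueError("empty table")
    p = t.counts / n
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    if w is None:
        po = float(np.trace(p))
        pe = float(pr @ pc)
    else:
        po = float((w * p).sum())
        pe = float(pr @ w @ pc)
    if 1.0 - pe <= 0:
        raise ValueError("kappa undefined: chance agreement is 1")
    kappa = (po - pe) / (1.0 - pe)

    if w is None:
        # Fleiss-Cohen-Everitt null SE for unweighted kappa
        inner = pe + pe**2 - float((pr * pc * (pr + pc)).sum())
        se0 = math.sqrt(max(inner, 0.0)) / ((1.0 - pe) * math.sqrt(n))
        # large-sample non-null SE
        diag = np.diag(p)
        a = float((diag * (1.0 - (pr + pc) * (1.0 - kappa)) ** 2).sum())
        off = p * ((pc[None, :] + pr[:, None]) ** 2)
        np.fill_diagonal(off, 0.0)
        b = float(((1.0 - kappa) ** 2) * off.sum())
        c = (kappa - pe * (1.0 - kappa)) ** 2
        se = math.sqrt(max(a + b - c, 0.0)) / ((1.0 - pe) * math.sqrt(n))
        pab = pabak(t)
    else:
        # weighted null SE (Fleiss, Cohen & Everitt 1969)
        wbar_i = w @ pc          # E[w | row i] under independence
        wbar_j = pr @ w          # E[w | col j]
        var = float(
            (
                (pr[:, None] * pc[None, :])
                * (w - (wbar_i[:, None] + wbar_j[None, :])) ** 2
            ).sum()
        ) - pe**2
        se0 = math.sqrt(max(var, 0.0)) / ((1.0 - pe) * math.sqrt(n))
        se = None
        pab = None
    z = kappa / se0 if se0 > 0 else math.inf
    pval = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    half = 1.959963984540054 * se0
    return AgreementResult(
        po=po, pe=pe, kappa=kappa, se0=se0, z=z, p=pval,
        ci_low=kappa - half, ci_high=kappa + half, pabak=pab, se=se,
    )


def cohen_kappa(t: ContingencyTable) -> AgreementResult:
    """Cohen's kappa with null-SE Z, 95% CI and PABAK.

    ``Po`` is the diagonal proportion, ``Pe`` the chance agreement from
    the marginals; ``kappa = (Po - Pe) / (1 - Pe)``.
    """
    return _kappa_core(t, None)


def weighted_kappa(t: ContingencyTable, spec: WeightedKappaSpec) -> AgreementResult:
    """Weighted kappa with agreement weights from ``spec``."""
    return _kappa_core(t, spec.weight_matrix(t.k))


def bowker_test(t: ContingencyTable):
    """McNemar-Bowker test of marginal symmetry.

    Returns ``(chi2, df, p)``. Discordant pairs with zero total are
    dropped from both the statistic and the degrees of freedom; a table
    with no usable pairs returns ``(0.0, 0, 1.0)``.
    """
    c = t.counts
    chi2 = 0.0
    df = 0
    for i in range(t.k):
        for j in range(i + 1, t.k):
            tot = c[i, j] + c[j, i]
            if tot > 0:
                chi2 += (c[i, j] - c[j, i]) ** 2 / tot
                df += 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), df, p


def exact_mcnemar(t: ContingencyTable):
    """Exact (binomial) McNemar test for a 2x2 table.

    Returns ``(statistic, p)`` where the statistic is the smaller
    discordant count and p is the two-sided exact binomial probability.
    """
    if t.k != 2:
        raise ValueError("exact McNemar is defined for 2x2 tables")
    b, c = t.counts[0, 1], t.counts[1, 0]
    n = int(b + c)
    if n == 0:
        return 0.0, 1.0
    res = stats.binomtest(int(min(b, c)), n, 0.5, alternative="two-sided")
    return float(min(b, c)), float(res.pvalue)


@dataclass(frozen=True)
class ResidualAnalysis:
    """Independence-model expected counts and adjusted residuals."""

    labels: tuple
    expected: np.ndarray
    residuals: np.ndarray
    threshold: float = RESIDUAL_THRESHOLD

    @property
    def min_expected(self) -> float:
        return float(self.expected.min())

    @property
    def significant(self) -> np.ndarray:
        """Boolean mask of cells with |residual| beyond the threshold."""
        return np.abs(self.residuals) > self.threshold


def adjusted_residuals(t: ContingencyTable) -> ResidualAnalysis:
    """Expected counts and Haberman adjusted standardized residuals.

    ``e_ij = n_i+ n_+j / N``;
    ``r_ij = (n_ij - e_ij) / sqrt(e_ij (1 - p_i+)(1 - p_+j))``.
    """
    n = t.n
    nr, nc = t.row_marginals, t.col_marginals
    if (nr == 0).any():
        raise ValueError(f"zero row marginal for label {t.labels[int(np.argmin(nr))]}")
    if (nc == 0).any():
        raise ValueError(f"zero column marginal for label {t.labels[int(np.argmin(nc))]}")
    e = np.outer(nr, nc) / n
    denom = np.sqrt(e * (1.0 - nr[:, None] / n) * (1.0 - nc[None, :] / n))
    r = (t.counts - e) / denom
    return ResidualAnalysis(labels=t.labels, expected=e, residuals=r)


def outcome_crosstab(results_a, results_b, labels: Sequence[str]) -> ContingencyTable:
    """Cross-tabulate paired outcome labels.

    Accepts plain label strings or :class:`~uhrconvert.instruments.DiagnosticResult`
    objects; for the latter, pass the 3-category labels
    ``("UHR_NEG","UHR_POS","PSYCHOSIS")`` to cross-tabulate primary
    outcomes, or the 5-category layout
    ``("UHR_NEG","GRD","APS","BLIPS","PSYCHOSIS")`` to split UHR+ by
    primary subgroup.
    """
    if len(results_a) != len(results_b):
        raise ValueError("paired result lists must have equal length")
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))

    def to_label(r) -> str:
        if isinstance(r, str):
            return r
        return r.fine_label if r.fine_label in index else r.primary_outcome.value

    for ra, rb in zip(results_a, results_b):
        la, lb = to_label(ra), to_label(rb)
        if la not in index or lb not in index:
            raise ValueError(f"label pair ({la},{lb}) not covered by {labels}")
        counts[index[la], index[lb]] += 1
    return ContingencyTable(labels, counts)


@dataclass(frozen=True)
class AccuracyResult:
    """Diagnostic-accuracy summary of predicted vs observed labels."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    roc_area: Optional[float]
    kappa: float
    pabak: float
    percent_agreement: float
    positive_class: str = field(default="")

    def summary(self) -> str:
        def pct(x):
            return "NA" if x is None else f"{x * 100:.2f}%"

        return "\n".join(
            [
                f"sensitivity          {pct(self.sensitivity)}",
                f"specificity          {pct(self.specificity)}",
                "roc_area             "
                + ("NA" if self.roc_area is None else f"{self.roc_area:.3f}"),
                f"kappa                {self.kappa:.3f}",
                f"PABAK                {self.pabak:.3f}",
                f"percent agreement    {self.percent_agreement:.2f}%",
            ]
        )


def accuracy_metrics(predicted, observed, positive_class: str) -> AccuracyResult:
    """Sensitivity/specificity/ROC area plus multi-class agreement.

    Sensitivity and specificity come from binarizing labels against
    ``positive_class``; the ROC area is the single-threshold trapezoid
    ``(sensitivity + specificity) / 2`` (equal to the rank concordance
    probability of a binary predictor). Kappa, PABAK and percent
    agreement are computed on the full multi-class cross-tabulation.
    A rate with an empty denominator is reported as ``None``.
    """
    predicted = [str(x) for x in predicted]
    observed = [str(x) for x in observed]
    if len(predicted) != len(observed):
        raise ValueError("predicted and observed must have equal length")
    if not predicted:
        raise ValueError("empty input")
    labels = tuple(sorted(set(predicted) | set(observed)))
    if positive_class not in labels:
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    tp = fn = fp = tn = 0
    for p, o in zip(predicted, observed):
        if o == positive_class:
            tp += p == positive_class
            fn += p != positive_class
        else:
            fp += p == positive_class
            tn += p != positive_class
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    roc = (sens + spec) / 2.0 if (sens is not None and spec is not None) else None

    if len(labels) == 1:
        kap, pab, agree = 1.0, 1.0, 100.0
    else:
        table = outcome_crosstab(predicted, observed, labels)
        agree = float(np.trace(table.counts)) / table.n * 100.0
        try:
            kap = cohen_kappa(table).kappa
        except ValueError:
            kap = float("nan")
        pab = pabak(table)
    return AccuracyResult(
        sensitivity=sens,
        specificity=spec,
        roc_area=roc,
        kappa=kap,
        pabak=pab,
        percent_agreement=agree,
        positive_class=positive_class,
    )
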