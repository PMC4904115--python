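"""Agreement statistics: kappa family, Bowker symmetry, adjusted
residuals, crosstabs and diagnostic-accuracy metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from uhrconvert import (
    ContingencyTable,
    WeightedKappaSpec,
    accuracy_metrics,
    adjusted_residuals,
    bowker_test,
    cohen_kappa,
    exact_mcnemar,
    outcome_crosstab,
    pabak,
    weighted_kappa,
)

from .conftest import TABLE3_COUNTS, THREE_LABELS


def random_table(rng, k=3, scale=30):
    counts = rng.integers(0, scale, size=(k, k))
    counts[np.diag_indices(k)] += rng.integers(1, scale, size=k)  # keep marginals positive
    return ContingencyTable(tuple("ABCDE"[:k]), counts)


class TestContingencyTable:
    def test_rejects_nonsquare(self):
        with pytest.raises(ValueError):
            ContingencyTable(("a", "b"), [[1, 2, 3], [4, 5, 6]])

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            ContingencyTable(("a", "b"), [[1, -2], [0, 3]])

    def test_marginals(self, table3):
        assert table3.n == 212
        assert list(table3.row_marginals) == [51, 111, 50]
        assert list(table3.col_marginals) == [57, 101, 54]


class TestCohenKappa:
    def test_published_three_by_three(self, table3):
        res = cohen_kappa(table3)
        assert res.po == pytest.approx(0.8632, abs=5e-5)
        assert res.pe == pytest.approx(0.3742, abs=5e-5)
        assert res.kappa == pytest.approx(0.781, abs=5e-4)
        assert res.z == pytest.approx(15.83, abs=5e-3)
        assert res.ci_low == pytest.approx(0.685, abs=1.5e-3)
        assert res.ci_high == pytest.approx(0.878, abs=1e-3)
        assert res.pabak == pytest.approx(0.795, abs=5e-4)
        assert res.p < 0.001

    def test_perfect_agreement(self):
        res = cohen_kappa(ContingencyTable(("a", "b"), [[10, 0], [0, 10]]))
        assert res.kappa == pytest.approx(1.0)

    def test_chance_only_agreement(self):
        res = cohen_kappa(ContingencyTable(("a", "b"), [[25, 25], [25, 25]]))
        assert res.kappa == pytest.approx(0.0)
        assert res.po == pytest.approx(res.pe) == pytest.approx(0.5)

    def test_degenerate_marginals_error(self):
        with pytest.raises(ValueError, match="undefined"):
            cohen_kappa(ContingencyTable(("a", "b"), [[10, 0], [0, 0]]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_kappa_bounds_and_po_dominance(self, seed):
        t = random_table(np.random.default_rng(seed))
        res = cohen_kappa(t)
        assert -1.0 - 1e-12 <= res.kappa <= 1.0 + 1e-12
        assert res.kappa <= res.po + 1e-12

    def test_kappa_one_iff_diagonal(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = random_table(rng)
            res = cohen_kappa(t)
            diagonal = np.allclose(t.counts, np.diag(np.diag(t.counts)))
            assert (abs(res.kappa - 1.0) < 1e-12) == diagonal

    def test_pabak_increases_with_po(self):
        tables = [
            ContingencyTable(("a", "b"), [[5 + d, 10 - d], [10 - d, 5 + d]]) for d in range(6)
        ]
        values = [pabak(t) for t in tables]
        assert values == sorted(values)
        assert all(np.isclose(pabak(t), 2 * np.trace(t.counts) / t.n - 1) for t in tables)

    def test_pe_matches_permutation_resample(self, table3):
        """Chance agreement equals the brute-force expectation under
        random pairing of the two margins."""
        rng = np.random.default_rng(42)
        a = np.repeat(np.arange(3), table3.row_marginals.astype(int))
        b = np.repeat(np.arange(3), table3.col_marginals.astype(int))
        draws = 20000
        agree = np.empty(draws)
        for i in range(draws):
            agree[i] = np.mean(a == rng.permutation(b))
        mc = agree.mean()
        se = agree.std() / np.sqrt(draws)
        assert abs(mc - cohen_kappa(table3).pe) < 5 * max(se, 1e-4)


class TestWeightedKappa:
    def test_identity_weights_reduce_to_unweighted(self, table3):
        spec = WeightedKappaSpec(weights=np.eye(3))
        a, b = weighted_kappa(table3, spec), cohen_kappa(table3)
        assert a.kappa == pytest.approx(b.kappa)
        assert a.po == pytest.approx(b.po)

    def test_all_ones_weights_degenerate(self, table3):
        with pytest.raises(ValueError, match="undefined"):
            weighted_kappa(table3, WeightedKappaSpec(weights=np.ones((3, 3))))

    def test_perfect_table_kappa_one_under_any_weights(self):
        t = ContingencyTable(("a", "b"), [[10, 0], [0, 10]])
        res = weighted_kappa(t, WeightedKappaSpec(scores=(0, 1)))
        assert res.kappa == pytest.approx(1.0)

    def test_functional_level_scores_weight_matrix(self, table3):
        w = WeightedKappaSpec(scores=(1.0, 0.84, 0.0)).weight_matrix(3)
        assert np.allclose(np.diag(w), 1.0)
        assert w[0, 1] == pytest.approx(0.84)
        assert w[0, 2] == pytest.approx(0.0)
        assert np.allclose(w, w.T)
        res = weighted_kappa(table3, WeightedKappaSpec(scores=(1.0, 0.84, 0.0)))
        assert res.po > cohen_kappa(table3).po  # partial credit raises agreement


class TestBowker:
    def test_published_value(self, table3):
        chi2, df, p = bowker_test(table3)
        assert chi2 == pytest.approx(7.087, abs=5e-4)
        assert df == 3
        assert p == pytest.approx(0.069, abs=5e-4)

    def test_symmetric_table_is_zero(self):
        t = ContingencyTable(("a", "b", "c"), [[5, 2, 3], [2, 8, 1], [3, 1, 9]])
        chi2, df, p = bowker_test(t)
        assert chi2 == 0.0 and p == 1.0

    def test_direct_formula_two_by_two(self):
        chi2, df, _ = bowker_test(ContingencyTable(("a", "b"), [[0, 5], [1, 0]]))
        assert chi2 == pytest.approx((5 - 1) ** 2 / 6)
        assert df == 1

    def test_zero_pair_dropped_from_df(self):
        t = ContingencyTable(("a", "b", "c"), [[1, 0, 4], [0, 1, 0], [2, 0, 1]])
        chi2, df, _ = bowker_test(t)
        assert df == 1
        assert chi2 == pytest.approx((4 - 2) ** 2 / 6)

    def test_all_concordant_table(self):
        chi2, df, p = bowker_test(ContingencyTable(("a", "b"), [[5, 0], [0, 5]]))
        assert (chi2, df, p) == (0.0, 0, 1.0)

    def test_invariant_under_transposition(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = random_table(rng)
            tt = ContingencyTable(t.labels, t.counts.T)
            assert bowker_test(t)[0] == pytest.approx(bowker_test(tt)[0])

    def test_additive_over_discordant_pairs(self):
        t = ContingencyTable(("a", "b", "c"), [[0, 6, 1], [2, 0, 7], [3, 3, 0]])
        chi2, df, _ = bowker_test(t)
        parts = [(6 - 2) ** 2 / 8, (1 - 3) ** 2 / 4, (7 - 3) ** 2 / 10]
        assert chi2 == pytest.approx(sum(parts))
        assert df == 3

    def test_exact_mcnemar_two_by_two(self):
        t = ContingencyTable(("a", "b"), [[10, 7], [2, 10]])
        stat, p = exact_mcnemar(t)
        assert stat == 2
        assert p == pytest.approx(stats.binomtest(2, 9, 0.5).pvalue)

    def test_exact_mcnemar_requires_two_by_two(self, table3):
        with pytest.raises(ValueError):
            exact_mcnemar(table3)


class TestAdjustedResiduals:
    def test_published_cells(self, table3):
        res = adjusted_residuals(table3)
        assert res.residuals[0, 0] == pytest.approx(13.5, abs=0.05)
        assert res.min_expected == pytest.approx(12.74, abs=5e-3)
        assert res.expected.sum() == pytest.approx(table3.n)
        assert res.significant[0, 0]

    def test_published_residual_matrix(self, table3):
        printed = np.array(
            [[13.5, -7.8, -4.8], [-7.7, 10.8, -4.5], [-4.5, -4.8, 10.1]]
        )
        assert np.allclose(adjusted_residuals(table3).residuals, printed, atol=0.05)

    def test_independence_gives_zero_residuals(self):
        outer = np.outer([10, 20], [15, 15]) / 30.0
        t = ContingencyTable(("a", "b"), outer)
        assert np.allclose(adjusted_residuals(t).residuals, 0.0, atol=1e-10)

    def test_residual_sign_matches_deviation(self, table3):
        res = adjusted_residuals(table3)
        dev = table3.counts - res.expected
        assert np.all(np.sign(res.residuals) == np.sign(dev))

    def test_two_by_two_residual_squares_to_pearson_chi2(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            t = random_table(rng, k=2)
            r = adjusted_residuals(t).residuals
            chi2 = stats.chi2_contingency(t.counts, correction=False)[0]
            assert r[0, 0] ** 2 == pytest.approx(chi2, rel=1e-9)
            assert np.allclose(np.abs(r), np.abs(r[0, 0]))

    def test_zero_marginal_names_label(self):
        t = ContingencyTable(("a", "b", "c"), [[1, 0, 1], [0, 0, 0], [1, 0, 1]])
        with pytest.raises(ValueError, match="b"):
            adjusted_residuals(t)


class TestCrosstabAndAccuracy:
    def test_identical_pairs_diagonal(self):
        t = outcome_crosstab(["UHR_POS"] * 3, ["UHR_POS"] * 3, THREE_LABELS)
        assert t.counts[1, 1] == 3 and t.n == 3

    def test_empty_input_all_zero(self):
        t = outcome_crosstab([], [], THREE_LABELS)
        assert t.n == 0

    def test_off_diagonal_cell(self):
        t = outcome_crosstab(["UHR_POS"] * 2, ["PSYCHOSIS"] * 2, THREE_LABELS)
        assert t.counts[1, 2] == 2 and np.trace(t.counts) == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            outcome_crosstab(["UHR_POS"], [], THREE_LABELS)

    def test_published_validation_metrics_from_two_by_two(self):
        predicted = ["P"] * 26 + ["N"] * 5 + ["P"] * 2 + ["N"] * 60
        observed = ["P"] * 31 + ["N"] * 62
        res = accuracy_metrics(predicted, observed, "P")
        assert res.sensitivity * 100 == pytest.approx(83.87, abs=5e-3)
        assert res.specificity * 100 == pytest.approx(96.77, abs=5e-3)
        assert res.roc_area == pytest.approx(0.903, abs=5e-4)

    def test_roc_area_equals_rank_concordance(self):
        """Single-threshold trapezoid equals the brute-force concordance
        probability of the binarized predictor."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            obs = rng.integers(0, 2, 40)
            pred = np.where(rng.random(40) < 0.8, obs, 1 - obs)
            if len(set(obs)) < 2:
                continue
            res = accuracy_metrics(
                ["P" if x else "N" for x in pred], ["P" if x else "N" for x in obs], "P"
            )
            pos = pred[obs == 1]
            neg = pred[obs == 0]
            pairs = [(p > n) + 0.5 * (p == n) for p, n in itertools.product(pos, neg)]
            assert res.roc_area == pytest.approx(np.mean(pairs))

    def test_perfect_prediction(self):
        res = accuracy_metrics(["P", "N"], ["P", "N"], "P")
        assert res.sensitivity == res.specificity == res.roc_area == 1.0

    def test_constant_negative_prediction(self):
        res = accuracy_metrics(["N", "N", "N"], ["P", "N", "N"], "P")
        assert res.sensitivity == 0.0 and res.specificity == 1.0
        assert res.roc_area == pytest.approx(0.5)

    def test_missing_rate_reported_as_none(self):
        res = accuracy_metrics(["P", "P"], ["P", "P"], "P")
        assert res.specificity is None and res.roc_area is None
        assert res.sensitivity == 1.0
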