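"""ROC statistics against brute-force and textbook oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

import ramanratio as rr


def auc_brute_force(pos, neg):
    """O(n*m) pair enumeration."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def youden_brute_force(pos, neg):
    """Exhaustive sweep over all midpoint thresholds."""
    pooled = np.unique(np.concatenate([pos, neg]))
    mids = (pooled[:-1] + pooled[1:]) / 2
    candidates = np.concatenate([[pooled[0] - 1], mids, [pooled[-1] + 1]])
    best = None
    for t in candidates:
        sens = np.mean(np.asarray(pos) > t)
        spec = np.mean(np.asarray(neg) <= t)
        j = sens + spec - 1
        if best is None or j > best[1] + 1e-12:
            best = (t, j, sens, spec)
    return best


def hanley_mcneil_oracle(auc, n_pos, n_neg, level=0.95):
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    se = np.sqrt(
        (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2))
        / (n_pos * n_neg)
    )
    z = norm.ppf(0.5 + level / 2)
    return max(auc - z * se, 0.0), min(auc + z * se, 1.0)


score_lists = st.lists(
    st.floats(0.0, 10.0, allow_nan=False, allow_infinity=False), min_size=1, max_size=12
)


class TestEmpiricalAUC:
    def test_fully_separated_groups(self):
        assert rr.empirical_auc([5, 6, 7], [1, 2, 3]) == 1.0

    def test_two_discordant_pairs_out_of_88(self):
        """8 low-group and 11 high-group values with exactly two discordant
        cross-group pairs give 86/88."""
        neg = [3.00, 3.04, 3.08, 3.12, 3.16, 3.20, 3.24, 3.25]
        pos = [3.22] + [3.35 + 0.02 * i for i in range(10)]
        assert rr.empirical_auc(pos, neg) == pytest.approx(86 / 88)
        assert round(rr.empirical_auc(pos, neg), 3) == 0.977

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pos=score_lists, neg=score_lists)
    def test_matches_pair_enumeration(self, pos, neg):
        assert rr.empirical_auc(pos, neg) == pytest.approx(auc_brute_force(pos, neg))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(pos=score_lists, neg=score_lists)
    def test_label_swap_antisymmetry(self, pos, neg):
        # half-weighted ties make the complement exact even with ties
        assert rr.empirical_auc(pos, neg) + rr.empirical_auc(neg, pos) == pytest.approx(1.0)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(1.0, 1.0, 20)
        neg = rng.normal(0.0, 1.0, 15)
        y = np.concatenate([np.ones(20), np.zeros(15)])
        scores = np.concatenate([pos, neg])
        assert rr.empirical_auc(pos, neg) == pytest.approx(roc_auc_score(y, scores))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            rr.empirical_auc([], [1.0])


class TestYoudenCutoff:
    def test_printed_operating_point(self):
        """One overlapping high-group value below all low-group values puts
        the cut-off at the midpoint of the separating gap."""
        neg = [3.08, 3.10, 3.13, 3.16, 3.19, 3.21, 3.23, 3.25]
        pos = [3.05] + [3.35, 3.38, 3.41, 3.44, 3.47, 3.50, 3.53, 3.56, 3.59, 3.62]
        cutoff, j, sens, spec = rr.youden_optimal_cutoff(pos, neg)
        assert cutoff == pytest.approx((3.25 + 3.35) / 2)
        assert sens == pytest.approx(10 / 11)
        assert spec == 1.0
        assert j == pytest.approx(10 / 11 + 1 - 1)

    def test_fully_separated_groups_reach_unit_youden(self):
        cutoff, j, sens, spec = rr.youden_optimal_cutoff([5, 6], [1, 2])
        assert j == 1.0 and sens == 1.0 and spec == 1.0
        assert 2 < cutoff < 5

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pos=score_lists, neg=score_lists)
    def test_matches_exhaustive_sweep(self, pos, neg):
        got = rr.youden_optimal_cutoff(pos, neg)
        want = youden_brute_force(pos, neg)
        assert got[1] == pytest.approx(want[1])
        assert got[0] == pytest.approx(want[0])

    def test_roc_sweep_monotonicity(self):
        rng = np.random.default_rng(1)
        thresholds, sens, spec = rr.roc_points(rng.normal(1, 1, 9), rng.normal(0, 1, 7))
        assert np.all(np.diff(sens) <= 0)
        assert np.all(np.diff(spec) >= 0)
        assert sens[0] == 1.0 and spec[0] == 0.0
        assert sens[-1] == 0.0 and spec[-1] == 1.0


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,lo3,hi_exact",
        [(10, 11, 0.587, None), (8, 8, 0.631, 1.0), (0, 5, 0.0, None)],
    )
    def test_reference_bounds(self, k, n, lo3, hi_exact):
        lo, hi = rr.clopper_pearson(k, n)
        assert round(lo, 3) == lo3
        if hi_exact is not None:
            assert hi == hi_exact

    def test_closed_form_all_successes(self):
        lo, hi = rr.clopper_pearson(8, 8)
        assert lo == pytest.approx(0.025 ** (1 / 8), rel=1e-12)
        assert hi == 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(n=st.integers(1, 30), frac=st.floats(0, 1))
    def test_agrees_with_statsmodels_beta_interval(self, n, frac):
        k = int(round(frac * n))
        lo, hi = rr.clopper_pearson(k, n)
        sm_lo, sm_hi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(float(sm_lo), abs=1e-12)
        assert hi == pytest.approx(float(sm_hi), abs=1e-12)

    def test_monte_carlo_coverage(self):
        """Exact intervals cover the true proportion at >= nominal rate."""
        rng = np.random.default_rng(2024)
        p, n, reps = 0.8, 11, 2000
        covered = 0
        for k in rng.binomial(n, p, size=reps):
            lo, hi = rr.clopper_pearson(int(k), n)
            covered += lo <= p <= hi
        assert covered / reps >= 0.93

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            rr.clopper_pearson(5, 4)


class TestAucConfidenceInterval:
    def test_degenerate_auc_clips_to_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = rr.auc_confidence_interval([5, 6], [1, 2], auc=1.0)
        assert hi == 1.0 and lo <= 1.0

    def test_symmetric_about_half_for_balanced_null(self):
        lo, hi = rr.auc_confidence_interval(
            np.arange(100), np.arange(100) + 0.5, auc=0.5
        )
        assert (lo + hi) / 2 == pytest.approx(0.5, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        pos=st.lists(st.floats(0, 1), min_size=3, max_size=10),
        neg=st.lists(st.floats(0, 1), min_size=3, max_size=10),
    )
    def test_matches_direct_formula(self, pos, neg):
        auc = rr.empirical_auc(pos, neg)
        got = rr.auc_confidence_interval(pos, neg, auc)
        want = hanley_mcneil_oracle(auc, len(pos), len(neg))
        assert got == pytest.approx(want, abs=1e-12)


class TestGroupSummary:
    def test_five_number_summary_no_outliers(self):
        s = rr.group_summary([1, 2, 3, 4, 5])
        assert s.median == 3 and s.q1 == 2 and s.q3 == 4
        assert s.outliers == []
        assert s.whisker_low == 1 and s.whisker_high == 5

    def test_extreme_value_flagged(self):
        s = rr.group_summary([1, 2, 3, 4, 100])
        assert s.outliers == [100.0]
        assert s.whisker_high == 4

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(vals=st.lists(st.floats(-50, 50), min_size=1, max_size=40))
    def test_quartiles_match_linear_interpolation_oracle(self, vals):
        s = rr.group_summary(vals)
        q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
        assert s.q1 == pytest.approx(q1, abs=1e-12)
        assert s.median == pytest.approx(med, abs=1e-12)
        assert s.q3 == pytest.approx(q3, abs=1e-12)


class TestAnalyzeScores:
    def test_full_report_consistency(self):
        rng = np.random.default_rng(7)
        pos = rng.normal(3.42, 0.09, 11)
        neg = rng.normal(3.17, 0.09, 8)
        roc = rr.analyze_scores(pos, neg)
        assert 0 <= roc.auc <= 1
        assert 0 <= roc.youden <= 1
        assert roc.sens_ci[0] <= roc.sens_at_cutoff <= roc.sens_ci[1]
        assert roc.spec_ci[0] <= roc.spec_at_cutoff <= roc.spec_ci[1]
        assert roc.auc_ci[0] <= roc.auc <= roc.auc_ci[1]
        assert roc.n_pos == 11 and roc.n_neg == 8
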