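"""Statistical layer against enumeration, grid-search and scipy/sklearn oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_curve

from havdvh import (
    Cohort,
    PatientRecord,
    compare_cohort_thresholds,
    fisher_exact,
    fit_univariate_logistic,
    rank_parameters_by_auc,
    roc_auc,
    wilcoxon_rank_sum,
    youden_threshold,
)


def make_cohort(x, y, name="param", label="c"):
    return Cohort(label=label, table=pd.DataFrame(
        {name: x, "rp_grade": np.where(np.asarray(y) == 1, 2, 0)}))


# ---------------------------------------------------------------------------
# logistic regression


def grid_search_mle(x, y, b0_range, b1_range, n=201):
    """Dense grid search of the Bernoulli log-likelihood (oracle)."""
    b0s = np.linspace(*b0_range, n)
    b1s = np.linspace(*b1_range, n)
    best, best_ll = None, -np.inf
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    for b0 in b0s:
        eta = b0 + np.outer(b1s, x)
        p = 1.0 / (1.0 + np.exp(-eta))
        ll = (y * np.log(p) + (1 - y) * np.log1p(-p)).sum(axis=1)
        i = int(np.argmax(ll))
        if ll[i] > best_ll:
            best_ll, best = ll[i], (b0, b1s[i])
    return best


class TestLogistic:
    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 10, size=20)
        p = 1.0 / (1.0 + np.exp(-(-2.0 + 0.5 * x)))
        y = (rng.uniform(size=20) < p).astype(int)
        fit = fit_univariate_logistic(make_cohort(x, y), "param")
        # refine the oracle grid around the fit in two passes
        b0, b1 = fit.beta0, fit.beta1
        for width in (2.0, 0.05):
            b0, b1 = grid_search_mle(x, y, (b0 - width, b0 + width),
                                     (b1 - width / 4, b1 + width / 4))
        assert fit.beta0 == pytest.approx(b0, abs=1e-3)
        assert fit.beta1 == pytest.approx(b1, abs=1e-3)
        assert fit.converged and not fit.separation

    def test_null_model_coverage(self):
        """With beta1 = 0 the Wald interval covers 0 in ~95% of replicates."""
        rng = np.random.default_rng(7)
        covered = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=120)
            y = (rng.uniform(size=120) < 0.4).astype(int)
            if y.sum() in (0, len(y)):
                covered += 1
                continue
            fit = fit_univariate_logistic(make_cohort(x, y), "param")
            if abs(fit.beta1) < 3 * fit.se_beta1:
                covered += 1
        assert covered >= 0.95 * reps

    def test_perfect_separation_flagged(self):
        x = np.array([1, 2, 3, 4, 10, 11, 12, 13], float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fit = fit_univariate_logistic(make_cohort(x, y), "param")
        assert fit.separation

    def test_constant_parameter_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_univariate_logistic(make_cohort([1.0] * 10, [0, 1] * 5), "param")

    def test_odds_ratio_identity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = (rng.uniform(size=60) < 0.5).astype(int)
        fit = fit_univariate_logistic(make_cohort(x, y), "param")
        assert fit.odds_ratio_per_unit == pytest.approx(math.exp(fit.beta1))


# ---------------------------------------------------------------------------
# ROC / AUC / Youden


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_tied_pair_counts_half(self):
        """{1,2,2,3} with outcomes {0,1,0,1}: pairs (2>1), (2=2 -> 1/2),
        (3>1), (3>2) give (1 + .5 + 1 + 1)/4 = 0.875."""
        assert roc_auc([1, 2, 2, 3], [0, 1, 0, 1]) == pytest.approx(0.875)

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = (rng.uniform(size=50) < 0.5).astype(int)
        assert roc_auc(x, y) == pytest.approx(1.0 - roc_auc(x, 1 - y))

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_trapezoidal_roc_area(self, seed):
        """Mann-Whitney value equals the trapezoid under the ROC curve."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        x = np.round(rng.normal(size=n), 1)  # rounding forces ties
        y = (rng.uniform(size=n) < 0.4).astype(int)
        if len(np.unique(y)) < 2:
            return
        fpr, tpr, _ = roc_curve(y, x)
        assert roc_auc(x, y) == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


def exhaustive_youden(values, outcomes):
    """Enumerate every distinct observed value as a >= threshold (oracle)."""
    values = np.asarray(values, float)
    outcomes = np.asarray(outcomes, int)
    best = None
    for t in sorted(set(values.tolist())):
        pred = values >= t
        sens = (pred & (outcomes == 1)).sum() / (outcomes == 1).sum()
        spec = (~pred & (outcomes == 0)).sum() / (outcomes == 0).sum()
        if best is None or sens + spec > best[1] + best[2] + 1e-12:
            best = (t, sens, spec)
    return best


class TestYouden:
    def test_perfect_separation_forced(self):
        t, sens, spec = youden_threshold([1, 2, 3, 4], [0, 0, 1, 1])
        assert (t, sens, spec) == (3.0, 1.0, 1.0)

    def test_six_point_example_matches_enumeration(self):
        values = [1, 2, 3, 4, 5, 6]
        outcomes = [0, 0, 1, 0, 1, 1]
        assert youden_threshold(values, outcomes) == exhaustive_youden(values, outcomes)

    def test_degenerate_constant_values_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([2, 2, 2, 2], [0, 1, 0, 1])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 200))
    def test_always_matches_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        values = np.round(rng.normal(size=n) * 10, 1)
        outcomes = (rng.uniform(size=n) < 0.5).astype(int)
        if len(np.unique(outcomes)) < 2 or np.unique(values).size < 2:
            return
        assert youden_threshold(values, outcomes) == \
            pytest.approx(exhaustive_youden(values, outcomes))
        t, *_ = youden_threshold(values, outcomes)
        assert t in values


class TestRanking:
    def test_informative_parameter_ranks_first(self):
        rng = np.random.default_rng(0)
        firsts = 0
        for _ in range(20):
            n = 150
            signal = rng.normal(size=n)
            noise = rng.normal(size=n)
            p = 1 / (1 + np.exp(-2.0 * signal))
            y = (rng.uniform(size=n) < p).astype(int)
            cohort = Cohort(label="c", table=pd.DataFrame(
                {"signal": signal, "noise": noise,
                 "rp_grade": np.where(y == 1, 2, 0)}))
            ranked = rank_parameters_by_auc(cohort, ["noise", "signal"])
            firsts += ranked[0].parameter == "signal"
        assert firsts >= 18

    def test_identical_columns_tie_broken_alphabetically(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = (rng.uniform(size=40) < 0.5).astype(int)
        cohort = Cohort(label="c", table=pd.DataFrame(
            {"b_param": x, "a_param": x, "rp_grade": np.where(y == 1, 2, 0)}))
        ranked = rank_parameters_by_auc(cohort, ["b_param", "a_param"])
        assert ranked[0].auc == ranked[1].auc
        assert [r.parameter for r in ranked] == ["a_param", "b_param"]

    def test_sign_flip_maps_auc(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = (x + rng.normal(size=60) > 0).astype(int)
        cohort = Cohort(label="c", table=pd.DataFrame(
            {"x": x, "neg_x": -x, "rp_grade": np.where(y == 1, 2, 0)}))
        ranked = {r.parameter: r.auc for r in
                  rank_parameters_by_auc(cohort, ["x", "neg_x"])}
        assert ranked["neg_x"] == pytest.approx(1.0 - ranked["x"])


class TestThresholdComparison:
    def test_identical_cohorts_zero_differences(self):
        rng = np.random.default_rng(4)
        x = rng.normal(10, 3, size=50)
        y = (rng.uniform(size=50) < 0.4).astype(int)
        a = make_cohort(x, y, name="MLD_Gy", label="a")
        b = make_cohort(x, y, name="MLD_Gy", label="b")
        comps = compare_cohort_thresholds(a, b, ["MLD_Gy"])
        assert comps[0].abs_difference == 0.0
        assert comps[0].counterpart is None and not comps[0].is_hav_family

    def test_hav_family_flag_and_pairing(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame({
            "HAV20_pct": rng.normal(20, 5, 60), "V20": rng.normal(30, 5, 60),
            "rp_grade": np.where(rng.uniform(size=60) < 0.4, 2, 0)})
        a = Cohort(label="a", table=table)
        b = Cohort(label="b", table=table.copy())
        comps = {c.parameter: c for c in
                 compare_cohort_thresholds(a, b, ["HAV20_pct", "V20"])}
        assert comps["HAV20_pct"].is_hav_family
        assert comps["HAV20_pct"].counterpart == "V20"
        assert not comps["V20"].is_hav_family

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(6)
        xa = rng.normal(10, 3, 40)
        ya = (rng.uniform(size=40) < 0.5).astype(int)
        xb = rng.normal(12, 3, 40)
        yb = (rng.uniform(size=40) < 0.5).astype(int)
        a, b = make_cohort(xa, ya), make_cohort(xb, yb)
        d1 = compare_cohort_thresholds(a, b, ["param"])[0].abs_difference
        d2 = compare_cohort_thresholds(b, a, ["param"])[0].abs_difference
        assert d1 == d2


# ---------------------------------------------------------------------------
# classical tests


class TestFisher:
    def test_chemotherapy_contingency_2x2(self):
        """Chemotherapy-by-outcome table: p = 0.002 at 3 decimals."""
        assert round(fisher_exact([[23, 20], [6, 28]]), 3) == 0.002

    def test_ild_contingency_2x2(self):
        assert round(fisher_exact([[1, 9], [7, 55]]), 3) == 1.000

    def test_no_association_gives_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_row_and_column_swap_invariance(self):
        table = np.array([[8, 3], [2, 9]])
        p = fisher_exact(table)
        assert fisher_exact(table[::-1]) == pytest.approx(p, rel=1e-12)
        assert fisher_exact(table[:, ::-1]) == pytest.approx(p, rel=1e-12)

    def test_rx2_reduces_to_2x2(self):
        """Freeman-Halton on a 2x2 equals the hypergeometric tail sum."""
        from havdvh.cohort_stats import _freeman_halton_rx2

        table = np.array([[23, 20], [6, 28]])
        assert _freeman_halton_rx2(table) == pytest.approx(
            fisher_exact(table), rel=1e-9)

    def test_rx2_matches_full_enumeration_oracle(self):
        """3x2 table vs direct enumeration of all tables with the margins."""
        table = np.array([[5, 2], [1, 6], [3, 3]])
        row_sums = table.sum(axis=1)
        c1 = table[:, 0].sum()

        def prob(a):
            num = math.prod(math.comb(int(r), int(v)) for r, v in zip(row_sums, a))
            return num / math.comb(int(row_sums.sum()), int(c1))

        p_obs = prob(table[:, 0])
        total = sum(
            prob(a)
            for a in itertools.product(*(range(r + 1) for r in row_sums))
            if sum(a) == c1 and prob(a) <= p_obs * (1 + 1e-9)
        )
        assert fisher_exact(table) == pytest.approx(total, rel=1e-9)

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])


class TestWilcoxon:
    def test_identical_samples_maximal_p(self):
        p = wilcoxon_rank_sum([1.0, 2.0, 3.0, 4.0] * 5, [1.0, 2.0, 3.0, 4.0] * 5)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_fully_shifted_small_sample_exact(self):
        """{1,2,3} vs {4,5,6}: 2 of C(6,3)=20 assignments as extreme."""
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_path_matches_rank_enumeration(self):
        a = [1.0, 4.0, 6.0, 9.0]
        b = [2.0, 3.0, 11.0]
        pooled = sorted(a + b)
        na = len(a)
        u_obs = sum(1 for x in a for y in b if x > y)
        us = []
        for comb in itertools.combinations(range(len(pooled)), na):
            sa = [pooled[i] for i in comb]
            sb = [pooled[i] for i in range(len(pooled)) if i not in comb]
            us.append(sum(1 for x in sa for y in sb if x > y))
        n_ab = len(a) * len(b)
        extreme = sum(1 for u in us
                      if min(u, n_ab - u) <= min(u_obs, n_ab - u_obs))
        assert wilcoxon_rank_sum(a, b) == pytest.approx(extreme / len(us))

    def test_shift_alternative_power_matches_scipy_reference(self):
        """Rejection rate at alpha=.05 tracks scipy's own test (oracle)."""
        rng = np.random.default_rng(8)
        mine, ref = 0, 0
        for _ in range(100):
            a = rng.normal(0, 1, 30)
            b = rng.normal(0.8, 1, 30)
            mine += wilcoxon_rank_sum(a, b) < 0.05
            ref += scipy.stats.mannwhitneyu(a, b, alternative="two-sided").pvalue < 0.05
        assert abs(mine - ref) <= 10

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def test_patient_record_outcome_dichotomy():
    rec = PatientRecord(dvh_row={"MLD_Gy": 10.0}, rp_grade=2)
    assert rec.outcome() == 1
    assert rec.outcome(grade_threshold=3) == 0
    with pytest.raises(ValueError):
        PatientRecord(dvh_row={}, rp_grade=7)
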