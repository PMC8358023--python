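"""Survival, correlation, association, frequency tables and power."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_call
from ctdna.cohort_stats import (
    assoc_2x2,
    binomial_power,
    correlate,
    evaluable_n,
    km_estimate,
    logrank_test,
    mann_whitney,
    summarize_frequencies,
)
from ctdna.somatic_filter import SomaticSet
from ctdna.variant_io import Material


class TestKaplanMeier:
    def test_three_uncensored_events_product_limit(self):
        km = km_estimate([1, 2, 3], [True, True, True])
        assert km.timeline == (1.0, 2.0, 3.0)
        assert km.survival == pytest.approx((2 / 3, 1 / 3, 0.0))
        assert km.median == pytest.approx(2.0)

    def test_no_events_flat_curve_median_undefined(self):
        km = km_estimate([5, 6, 7], [False, False, False])
        assert km.median is None and km.n_events == 0
        assert km.survival_at(10.0) == 1.0

    def test_censoring_shrinks_risk_set(self):
        # events at 1 and 3; censored at 2 -> S(3) = (2/3) * (1 - 1/1) = 0
        km = km_estimate([1, 2, 3], [True, False, True])
        assert km.survival == pytest.approx((2 / 3, 0.0))

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, size=60)
        km = km_estimate(times, [True] * 60)
        for t, s in zip(km.timeline, km.survival):
            assert s == pytest.approx(np.mean(times > t))

    def test_exponential_median_closed_form(self):
        lam = 0.2
        rng = np.random.default_rng(11)
        times = rng.exponential(1 / lam, size=500)
        km = km_estimate(times, [True] * 500)
        assert km.median == pytest.approx(math.log(2) / lam, rel=0.10)


def hand_logrank(times_a, times_b):
    """Independent log-rank oracle: hypergeometric sums over event times."""
    events = sorted(set(times_a) | set(times_b))
    obs_minus_exp = 0.0
    var = 0.0
    for t in events:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = times_a.count(t)
        d_b = times_b.count(t)
        n, d = n_a + n_b, d_a + d_b
        obs_minus_exp += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return obs_minus_exp**2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        stat, p = logrank_test([2, 4, 6], [1, 1, 1], [2, 4, 6], [1, 1, 1])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_data_matches_hand_computed_sum(self):
        a, b = [2, 4, 6], [8, 10, 12]
        stat, p = logrank_test(a, [1] * 3, b, [1] * 3)
        expected = hand_logrank(a, b)
        assert stat == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(sps.chi2.sf(expected, 1), rel=1e-9)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        a = list(rng.exponential(5, 20))
        b = list(rng.exponential(9, 20))
        s1, p1 = logrank_test(a, [1] * 20, b, [1] * 20)
        s2, p2 = logrank_test(b, [1] * 20, a, [1] * 20)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1], [True])

    def test_power_at_hazard_ratio_three(self):
        """HR 3, n = 40 per group: rejection rate above 80% at alpha 0.05."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.exponential(1.0, 40)
            b = rng.exponential(3.0, 40)
            _, p = logrank_test(a, [1] * 40, b, [1] * 40)
            rejections += p < 0.05
        assert rejections / n_rep > 0.80


class TestCorrelation:
    def test_perfect_pearson(self):
        r, p = correlate([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            correlate([1, 1, 1], [1, 2, 3])

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        x[:5] = x[5:10]  # introduce ties
        rs, _ = correlate(x, y, "spearman")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rp, _ = correlate(rx, ry, "pearson")
        assert rs == pytest.approx(rp, rel=1e-9)


def enumerate_mw_p(x, y):
    """Full-permutation two-sided Mann–Whitney oracle."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    center = n * (len(pooled) - n) / 2
    u_obs = sum((a > b) + 0.5 * (a == b) for a in x for b in y)
    total = extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        total += 1
        if abs(u_of(idx) - center) >= abs(u_obs - center) - 1e-12:
            extreme += 1
    return extreme / total


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)  # 2 of C(6,3) assignments as extreme

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = list(rng.integers(0, 6, size=4))
        y = list(rng.integers(0, 6, size=4))
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(enumerate_mw_p(x, y), abs=1e-12)

    def test_large_sample_uses_asymptotic(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 30)
        u, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert (u, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))


class TestAssoc2x2:
    def test_detection_by_liver_metastasis_table(self):
        # 68/71 detected with liver mets vs 16/22 without
        res = assoc_2x2([[68, 3], [16, 6]])
        assert res.test_used == "fisher_exact"  # min expected cell 22*9/93 < 5
        assert res.p < 0.05
        assert res.p_fisher == pytest.approx(
            sps.fisher_exact([[68, 3], [16, 6]])[1]
        )

    def test_large_balanced_table_uses_chi_square(self):
        res = assoc_2x2([[40, 30], [25, 45]])
        assert res.test_used == "chi_square"
        ref = sps.chi2_contingency([[40, 30], [25, 45]], correction=True)
        assert res.p == pytest.approx(ref.pvalue)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            assoc_2x2([[1, -1], [2, 3]])


class TestFrequencies:
    def _set(self, pid, genes):
        calls = [make_call(pos=1000 + i, gene=g) for i, g in enumerate(genes)]
        return SomaticSet(
            sample_id=f"{pid}_cf", calls=calls, cascade_log=[],
            patient_id=pid, material=Material.CFDNA, timepoint="baseline",
        )

    def test_two_mutations_one_patient(self):
        ft = summarize_frequencies([self._set("P1", ["APC", "APC"])])
        row = ft.table.iloc[0]
        assert row["gene"] == "APC"
        assert (row["n_mutations"], row["n_patients_with_mutation"]) == (2, 1)

    def test_totals_and_positivity(self):
        sets = [
            self._set("P1", ["APC", "TP53"]),
            self._set("P2", ["APC"]),
            self._set("P3", []),
        ]
        ft = summarize_frequencies(sets)
        assert ft.total_mutations == 3
        assert ft.n_patients_positive == 2
        assert ft.fraction_positive == pytest.approx(2 / 3)
        assert ft.mean_mutations_per_positive == pytest.approx(1.5)

    def test_v3_only_genes_footnoted(self):
        ft = summarize_frequencies([self._set("P1", ["PTEN", "KRAS"])])
        assert ft.restricted_genes == ("PTEN",)

    def test_duplicate_patient_rejected(self):
        with pytest.raises(ValueError):
            summarize_frequencies([self._set("P1", ["APC"]), self._set("P1", ["TP53"])])


class TestBinomialPower:
    def test_null_alternative_bounded_by_alpha(self):
        # p1 == p0 degenerates to the test's size, which is <= alpha
        assert binomial_power(0.7, 0.7 + 1e-12, 31, 0.05) <= 0.05

    def test_single_trial_enumeration(self):
        # n=1: p-values are >= min(p0, 1-p0) ... a single trial can only
        # reject when one outcome is itself rarer than alpha under H0
        power = binomial_power(0.02, 0.5, 1, 0.05)
        # outcome k=1 has two-sided p = P(X=1) = 0.02 <= 0.05 -> rejects;
        # power = P(X=1 | p=0.5) = 0.5
        assert power == pytest.approx(0.5)
        assert binomial_power(0.3, 0.6, 1, 0.05) == 0.0  # nothing rejects

    def test_design_anchor_eighty_percent(self):
        """Sensitivity improvement 0.7 -> 0.9 at 40% prevalence of a
        78-subject cohort: ~80% power (exact two-sided binomial test)."""
        n = evaluable_n(78, 0.4)
        assert n == 31
        assert binomial_power(0.7, 0.9, n, 0.05) == pytest.approx(0.807, abs=0.005)

    def test_power_rises_with_n_despite_sawtooth(self):
        """Exact-test power is locally non-monotone (discreteness), but
        rises over coarse n and never dips materially."""
        powers = [binomial_power(0.7, 0.9, n, 0.05) for n in range(10, 101)]
        assert powers[10] < powers[40] < powers[90]  # n = 20 < 50 < 100
        drops = [max(0.0, a - b) for a, b in zip(powers, powers[1:])]
        assert max(drops) < 0.05

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            binomial_power(0.0, 0.5, 10)
        with pytest.raises(ValueError):
            binomial_power(0.5, 1.0, 10)
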