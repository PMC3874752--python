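import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from laphase.diagnostics import (
    GREATER,
    LESS,
    dichotomize_lvedp,
    empirical_auc,
    evaluate_index,
    fisher_exact,
    group_compare,
    optimal_cutoff,
    pearson_r,
)
from laphase.errors import DomainError


def auc_oracle(pos, neg):
    """Brute-force pairwise count: wins + half-ties over all pairs."""
    wins = sum(1.0 for x in pos for y in neg if x > y)
    ties = sum(1.0 for x in pos for y in neg if x == y)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def fisher_oracle(a, b, c, d):
    """Two-sided exact p by hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = hypergeom(n, r1, c1)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    p_obs = rv.pmf(a)
    return sum(
        rv.pmf(k) for k in range(lo, hi + 1) if rv.pmf(k) <= p_obs * (1 + 1e-9)
    )


class TestDichotomize:
    def test_boundary_is_normal(self):
        assert dichotomize_lvedp(12.0) == "normal"

    def test_above_boundary(self):
        assert dichotomize_lvedp(12.1) == "elevated"

    def test_group_means(self):
        assert dichotomize_lvedp(22.0) == "elevated"
        assert dichotomize_lvedp(9.0) == "normal"

    def test_invalid(self):
        with pytest.raises(DomainError):
            dichotomize_lvedp(0.0)
        with pytest.raises(DomainError):
            dichotomize_lvedp(float("nan"))


class TestEmpiricalAuc:
    def test_perfect_separation(self):
        auc, p = empirical_auc([1, 2, 3, 4], [False, False, True, True])
        assert auc == 1.0

    def test_interleaved(self):
        # neg = (1, 3), pos = (2, 4): 3 of 4 pairs won
        auc, _ = empirical_auc(
            [1, 2, 3, 4], [False, True, False, True]
        )
        assert auc == 0.75
        assert auc == auc_oracle([2, 4], [1, 3])

    def test_all_ties(self):
        auc, p = empirical_auc([5, 5, 5, 5], [True, True, False, False])
        assert auc == 0.5
        assert p == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            empirical_auc([1, 2], [True, True])

    def test_direction_flips(self):
        scores = [1, 2, 3, 4]
        labels = [True, True, False, False]  # positives score LOW
        auc_g, _ = empirical_auc(scores, labels, GREATER)
        auc_l, _ = empirical_auc(scores, labels, LESS)
        assert auc_g == 0.0
        assert auc_l == 1.0

    def test_oracle_equivalence_exhaustive_small(self):
        """Rank implementation equals pairwise-count oracle, ties included."""
        rng = np.random.default_rng(0)
        for n_pos in range(1, 9):
            for n_neg in range(1, 9):
                for _ in range(10):
                    pos = rng.integers(0, 4, n_pos).astype(float)
                    neg = rng.integers(0, 4, n_neg).astype(float)
                    scores = np.concatenate([pos, neg])
                    labels = np.array([True] * n_pos + [False] * n_neg)
                    auc, _ = empirical_auc(scores, labels)
                    assert auc == pytest.approx(
                        auc_oracle(pos, neg), abs=1e-12
                    )

    @given(
        pos=st.lists(st.integers(0, 5), min_size=1, max_size=8),
        neg=st.lists(st.integers(0, 5), min_size=1, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_oracle_property(self, pos, neg):
        scores = np.array(pos + neg, dtype=float)
        labels = np.array([True] * len(pos) + [False] * len(neg))
        auc, _ = empirical_auc(scores, labels)
        assert auc == pytest.approx(auc_oracle(pos, neg), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        labels[0], labels[1] = True, False
        auc1, _ = empirical_auc(scores, labels)
        auc2, _ = empirical_auc(np.exp(3 * scores) + 7, labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_delong_p_reasonable(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(1.5, 1, 60), rng.normal(0, 1, 60)])
        labels = np.array([True] * 60 + [False] * 60)
        _, p_strong = empirical_auc(x, labels)
        y = rng.normal(size=120)
        _, p_null = empirical_auc(y, labels)
        assert p_strong < 1e-6
        assert p_null > 0.01


class TestOptimalCutoff:
    def test_perfect_separation_midpoint(self):
        cutoff, sens, spec = optimal_cutoff(
            [1, 2, 10, 11], [False, False, True, True]
        )
        assert sens == 1.0 and spec == 1.0
        assert cutoff == 6.0  # midpoint between the two groups

    def test_interleaved_max_j(self):
        # neg = (1, 3), pos = (2, 4); best J = 0.5, specificity tie-break
        cutoff, sens, spec = optimal_cutoff(
            [1, 2, 3, 4], [False, True, False, True]
        )
        assert sens + spec - 1 == pytest.approx(0.5)
        assert spec == 1.0  # tie between thresholds resolved to higher spec

    def test_degenerate_undefined(self):
        cutoff, sens, spec = optimal_cutoff(
            [5, 5, 5, 5], [True, False, True, False]
        )
        assert cutoff is None and sens is None and spec is None

    def test_less_direction_semantics(self):
        # positives score low; rule is "value <= cutoff"
        scores = np.array([10.0, 20.0, 30.0, 40.0])
        labels = np.array([True, True, False, False])
        cutoff, sens, spec = optimal_cutoff(scores, labels, LESS)
        assert sens == 1.0 and spec == 1.0
        assert cutoff == 25.0
        assert all(s <= cutoff for s, l in zip(scores, labels) if l)

    def test_youden_point_on_roc(self):
        """J at the reported cutoff dominates every observed threshold."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(6, 30)
            scores = rng.integers(0, 10, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            cutoff, sens, spec = optimal_cutoff(scores, labels)
            if cutoff is None:
                continue
            j_best = sens + spec - 1
            pos, neg = scores[labels], scores[~labels]
            for thr in np.unique(scores):
                j = np.mean(pos >= thr) + np.mean(neg < thr) - 1
                assert j_best >= j - 1e-12

    def test_direction_bookkeeping_on_cohort(self, small_cohort):
        lav_min = np.array([p.true_lav_min for p in small_cohort])
        laef_tot = np.array(
            [
                (p.true_lav_max - p.true_lav_min) / p.true_lav_max
                for p in small_cohort
            ]
        )
        labels = np.array([p.group == "elevated" for p in small_cohort])
        rep_v = evaluate_index("LAV_min", lav_min, labels, GREATER)
        rep_f = evaluate_index("LAEF_Total", laef_tot, labels, LESS)
        assert rep_v.direction == GREATER
        assert rep_f.direction == LESS
        assert rep_v.auc > 0.5 and rep_f.auc > 0.5


class TestGroupCompare:
    def test_identical_groups(self):
        gc = group_compare([1.0, 2, 3, 1, 2, 3], [True] * 3 + [False] * 3)
        assert gc.p_value == pytest.approx(1.0)
        assert gc.mean_elevated == gc.mean_normal

    def test_separated_groups(self):
        a = [0.0, 0.001, -0.001, 0.0005]
        b = [1.0, 1.001, 0.999, 1.0005]
        gc = group_compare(a + b, [True] * 4 + [False] * 4)
        assert gc.p_value < 1e-3

    def test_hand_computed_t(self):
        """Pooled-variance t from summary statistics, computed by hand."""
        x = np.array([2.0, 4.0, 6.0, 8.0])
        y = np.array([1.0, 2.0, 3.0])
        sp2 = (
            (len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)
        ) / (len(x) + len(y) - 2)
        t_manual = (x.mean() - y.mean()) / np.sqrt(
            sp2 * (1 / len(x) + 1 / len(y))
        )
        from scipy.stats import t as tdist

        p_manual = 2 * tdist.sf(abs(t_manual), len(x) + len(y) - 2)
        gc = group_compare(
            np.concatenate([x, y]), [True] * 4 + [False] * 3
        )
        assert gc.p_value == pytest.approx(p_manual, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(DomainError):
            group_compare([1.0, 2.0, 3.0], [True, False, False])


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_five_point_fixture_vs_brute_force(self):
        x = np.array([1.0, 3.0, 4.0, 7.0, 9.0])
        y = np.array([2.0, 2.5, 5.0, 6.0, 10.0])
        r_oracle = np.mean((x - x.mean()) * (y - y.mean())) / (
            x.std() * y.std()
        )
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(r_oracle, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFisherExact:
    def test_diagonal_table(self):
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_no_association(self):
        assert fisher_exact([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_zero_row(self):
        assert fisher_exact([[0, 0], [3, 4]]) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            fisher_exact([[1, -1], [2, 3]])

    def test_non_integer_rejected(self):
        with pytest.raises(DomainError):
            fisher_exact([[1.5, 1], [2, 3]])

    def test_enumeration_oracle_small_margins(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)
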