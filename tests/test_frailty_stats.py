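"""Group comparisons, Cohen's d, Fisher exact, and the selection stages."""

import math

import numpy as np
import pandas as pd
import pytest

from frailsense import frailty_stats as fst


def fisher_enumeration_oracle(table):
    """Two-sided Fisher exact by exhaustive enumeration of tables with the
    observed margins, summing hypergeometric probabilities <= the observed."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(aa):
        return (math.comb(r1, aa) * math.comb(r2, c1 - aa)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(aa)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def cohens_d_literal(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return abs(ma - mb) / pooled ** 0.5


class TestCohensD:
    def test_identical_groups_have_zero_effect(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert fst.cohens_d(x, x) == 0.0

    def test_unit_case(self):
        assert fst.cohens_d([0.0, 1.0, 2.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_matches_literal_formula(self, rng):
        for _ in range(30):
            a = rng.normal(0, 2, rng.integers(3, 30))
            b = rng.normal(1, 3, rng.integers(3, 30))
            assert fst.cohens_d(a, b) == pytest.approx(
                cohens_d_literal(list(a), list(b)), rel=1e-12)

    def test_symmetry_shift_and_scale(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(2, 1, 25)
        d = fst.cohens_d(a, b)
        assert fst.cohens_d(b, a) == pytest.approx(d)
        assert fst.cohens_d(a + 7, b + 7) == pytest.approx(d)
        assert fst.cohens_d(3 * a, 3 * b) == pytest.approx(d)

    def test_zero_pooled_sd_is_undefined(self):
        assert np.isnan(fst.cohens_d([1.0, 1.0], [2.0, 2.0]))


class TestFisherExact:
    def test_perfectly_separated_table(self):
        # both extreme tables are equally likely -> p = 2 / C(20, 10)
        assert fst.fisher_exact([[10, 0], [0, 10]]) == pytest.approx(
            2 / math.comb(20, 10))
        assert fst.fisher_exact([[10, 0], [0, 10]]) == pytest.approx(1 / 92378)

    def test_matches_enumeration_on_all_small_tables(self):
        for a in range(0, 8):
            for b in range(0, 8):
                for c in range(0, 8):
                    for d in range(0, 8):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        table = [[a, b], [c, d]]
                        assert fst.fisher_exact(table) == pytest.approx(
                            fisher_enumeration_oracle(table), rel=1e-9), table

    def test_rejects_non_2x2(self):
        with pytest.raises(ValueError):
            fst.fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestCompareGroups:
    @staticmethod
    def _labels(n_n, n_p, n_f):
        return np.array(["non_frail"] * n_n + ["pre_frail"] * n_p
                        + ["frail"] * n_f, dtype=object)

    def test_identical_groups_give_p_near_one(self, rng):
        base = rng.normal(0, 1, 30)
        y = np.concatenate([base, base, base[:10]])
        ps = fst.compare_groups(y, self._labels(30, 30, 10))
        assert ps[fst.CONTRAST_NP] > 0.99

    def test_separated_groups_give_tiny_p(self):
        g = np.random.default_rng(5)
        y = np.concatenate([g.normal(0, 1, 40), g.normal(5, 1, 40),
                            g.normal(5, 1, 10)])
        ps = fst.compare_groups(y, self._labels(40, 40, 10))
        assert ps[fst.CONTRAST_NP] < 1e-6

    def test_lsd_matches_pooled_t_construction(self, rng):
        """Unadjusted contrasts use the 3-group residual variance, so they
        equal a hand-built t-test with the pooled MSE."""
        y = np.concatenate([rng.normal(0, 1, 12), rng.normal(1, 1, 15),
                            rng.normal(2, 1, 9)])
        labels = self._labels(12, 15, 9)
        ps = fst.compare_groups(y, labels)
        groups = [y[labels == s] for s in ("non_frail", "pre_frail", "frail")]
        mse = sum((g.shape[0] - 1) * g.var(ddof=1) for g in groups) / (y.shape[0] - 3)
        import scipy.stats
        se = np.sqrt(mse * (1 / 12 + 1 / 15))
        t = (groups[0].mean() - groups[1].mean()) / se
        p = 2 * scipy.stats.t.sf(abs(t), y.shape[0] - 3)
        assert ps[fst.CONTRAST_NP] == pytest.approx(p, rel=1e-9)

    def test_tukey_adjustment_is_more_conservative(self, rng):
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.7, 1, 20),
                            rng.normal(1.2, 1, 20)])
        labels = self._labels(20, 20, 20)
        lsd = fst.compare_groups(y, labels, posthoc="lsd")
        hsd = fst.compare_groups(y, labels, posthoc="tukey_hsd")
        assert hsd[fst.CONTRAST_NP] >= lsd[fst.CONTRAST_NP]

    def test_degenerate_variance_gives_nan(self):
        y = np.full(60, 3.0)
        ps = fst.compare_groups(y, self._labels(20, 20, 20))
        assert np.isnan(ps[fst.CONTRAST_NP])


class TestSelection:
    @staticmethod
    def _comparisons(p_np, d_np, p_pf, d_pf):
        return pd.DataFrame([{"feature": "f", "p_np": p_np, "d_np": d_np,
                              "p_pf": p_pf, "d_pf": d_pf}])

    def test_filter_boundary_cases(self):
        assert fst.filter_select(self._comparisons(0.04, 0.41, 0.04, 0.41)) == ["f"]
        assert fst.filter_select(self._comparisons(0.04, 0.39, 0.04, 0.41)) == []
        assert fst.filter_select(self._comparisons(0.05, 0.41, 0.04, 0.41)) == []
        assert fst.filter_select(self._comparisons(0.04, 0.40, 0.04, 0.40)) == ["f"]

    def test_filter_requires_both_contrasts(self):
        assert fst.filter_select(self._comparisons(0.01, 0.9, 0.2, 0.9)) == []

    def test_filter_monotone_in_thresholds(self, rng):
        comp = pd.DataFrame({
            "feature": [f"f{i}" for i in range(30)],
            "p_np": rng.uniform(0, 0.1, 30), "d_np": rng.uniform(0.2, 0.6, 30),
            "p_pf": rng.uniform(0, 0.1, 30), "d_pf": rng.uniform(0.2, 0.6, 30)})
        strict = set(fst.filter_select(comp, p_max=0.05, d_min=0.4))
        loose = set(fst.filter_select(comp, p_max=0.08, d_min=0.3))
        assert strict <= loose


class TestUnivariateAuc:
    def test_perfectly_separating_feature(self):
        x = np.concatenate([np.zeros(40), np.ones(40)])
        y = np.concatenate([np.zeros(40, int), np.ones(40, int)])
        mean, sd = fst.univariate_auc(x, y)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_label_independent_feature_near_half(self, rng):
        x = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        mean, _ = fst.univariate_auc(x, y, seed=3)
        assert mean == pytest.approx(0.5, abs=0.12)

    def test_constant_feature_is_uninformative(self):
        y = np.array([0, 1] * 30)
        assert fst.univariate_auc(np.ones(60), y) == (0.5, 0.0)

    def test_tree_beats_monotone_threshold_when_positives_lie_between(self):
        """A pre-frail group between the two pooled groups defeats any single
        monotone threshold but not an interval-splitting tree."""
        g = np.random.default_rng(9)
        x = np.concatenate([g.normal(12, 1.5, 40),   # non-frail, high
                            g.normal(7, 1.0, 80),    # pre-frail, middle
                            g.normal(2, 1.5, 30)])   # frail, low
        y = np.concatenate([np.zeros(40, int), np.ones(80, int), np.zeros(30, int)])
        tree_auc, _ = fst.univariate_auc(x, y, seed=0)
        from frailsense.models import roc_auc
        threshold_auc = max(roc_auc(x, y), roc_auc(-x, y))
        assert tree_auc > threshold_auc
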