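"""Within-subject ANOVA, t-tests, BH correction, normality checks.

Independent oracles: brute-force sums-of-squares from the definitions,
pingouin for one-way RM-ANOVA and epsilon, statsmodels for BH-adjusted p.
"""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from encodelearn.stats import (
    bh_adjust,
    one_sample_t,
    paired_t,
    rm_anova,
    shapiro_wilk,
)


def long_format(Y, factors=1):
    """n x k (or n x a x b) array -> long DataFrame."""
    rows = []
    if factors == 1:
        for s in range(Y.shape[0]):
            for c in range(Y.shape[1]):
                rows.append({"subject": f"s{s}", "cond": c, "y": Y[s, c]})
    else:
        for s in range(Y.shape[0]):
            for a in range(Y.shape[1]):
                for b in range(Y.shape[2]):
                    rows.append({"subject": f"s{s}", "A": a, "B": b,
                                 "y": Y[s, a, b]})
    return pd.DataFrame(rows)


class TestOneWayAnova:
    def test_ss_decomposition_matches_brute_force(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(5, 4)) + rng.normal(size=(5, 1))
        res = rm_anova(long_format(Y), "y", ["cond"], "subject")[("cond")]
        # brute-force from definitions
        grand = Y.mean()
        ss_cond = 5 * sum((Y[:, c].mean() - grand) ** 2 for c in range(4))
        ss_err = sum(
            (Y[s, c] - Y[:, c].mean() - Y[s, :].mean() + grand) ** 2
            for s in range(5) for c in range(4))
        assert res.ss_effect == pytest.approx(ss_cond)
        assert res.ss_error == pytest.approx(ss_err)
        assert res.partial_eta_sq == pytest.approx(
            ss_cond / (ss_cond + ss_err))

    def test_matches_pingouin(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(12, 4)) + np.array([0.0, 0.3, 0.5, 0.4])
        data = long_format(Y)
        mine = rm_anova(data, "y", ["cond"], "subject")["cond"]
        ref = pg.rm_anova(data=data, dv="y", within="cond",
                          subject="subject", correction=True,
                          effsize="np2").iloc[0]
        assert mine.F == pytest.approx(ref["F"], rel=1e-9)
        assert mine.p_uncorrected == pytest.approx(ref["p_unc"], rel=1e-9)
        assert mine.partial_eta_sq == pytest.approx(ref["np2"], rel=1e-9)
        assert mine.gg_epsilon == pytest.approx(ref["eps"], rel=1e-6)
        assert mine.p_gg == pytest.approx(ref["p_GG_corr"], rel=1e-6)
        sph = pg.sphericity(data, dv="y", within="cond", subject="subject")
        assert mine.mauchly_W == pytest.approx(sph.W, rel=1e-6)
        # pingouin's second-order correction term differs microscopically
        assert mine.mauchly_p == pytest.approx(sph.pval, abs=1e-3)

    def test_two_levels_equals_squared_paired_t(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            Y = rng.normal(size=(9, 2))
            res = rm_anova(long_format(Y), "y", ["cond"], "subject")["cond"]
            tt = paired_t(Y[:, 0], Y[:, 1])
            assert res.F == pytest.approx(tt.t ** 2, rel=1e-10)
            assert res.p_uncorrected == pytest.approx(tt.p_two_tailed,
                                                      rel=1e-10)
            assert res.gg_epsilon == 1.0  # k = 2: epsilon is exactly 1

    def test_identical_scores_give_zero_F(self):
        Y = np.tile(np.arange(5.0)[:, None], (1, 3))  # no condition effect
        res = rm_anova(long_format(Y), "y", ["cond"], "subject")["cond"]
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_epsilon_bounds_property(self):
        rng = np.random.default_rng(6)
        for k in (3, 4, 6):
            Y = rng.normal(size=(10, k)) * rng.uniform(0.5, 2.0, size=k)
            res = rm_anova(long_format(Y), "y", ["cond"], "subject")["cond"]
            assert 1.0 / (k - 1) - 1e-12 <= res.gg_epsilon <= 1.0 + 1e-12

    def test_missing_cell_raises(self):
        data = long_format(np.zeros((4, 3))).iloc[:-1]
        with pytest.raises(ValueError, match="balanced|cell"):
            rm_anova(data, "y", ["cond"], "subject")

    def test_single_level_raises(self):
        data = long_format(np.zeros((4, 1)))
        with pytest.raises(ValueError, match="2 levels"):
            rm_anova(data, "y", ["cond"], "subject")


class TestTwoWayAnova:
    @pytest.fixture
    def data(self):
        rng = np.random.default_rng(7)
        Y = (rng.normal(size=(10, 3, 4))
             + np.linspace(0, 1, 3)[None, :, None]
             + np.linspace(0, 2, 4)[None, None, :])
        return Y, long_format(Y, factors=2)

    def test_matches_pingouin_two_way(self, data):
        Y, frame = data
        mine = rm_anova(frame, "y", ["A", "B"], "subject")
        ref = pg.rm_anova(data=frame, dv="y", within=["A", "B"],
                          subject="subject", effsize="np2")
        for name, key in [("A", "A"), ("B", "B"), ("A*B", "A * B")]:
            row = ref[ref["Source"] == key].iloc[0]
            assert mine[name].F == pytest.approx(row["F"], rel=1e-9)
            assert mine[name].p_uncorrected == pytest.approx(row["p_unc"],
                                                             rel=1e-9)

    def test_ss_match_brute_force(self, data):
        Y, frame = data
        n, a, b = Y.shape
        mine = rm_anova(frame, "y", ["A", "B"], "subject")
        grand = Y.mean()
        ss_a = n * b * sum((Y[:, i, :].mean() - grand) ** 2 for i in range(a))
        ss_ab = n * sum(
            (Y[:, i, j].mean() - Y[:, i, :].mean() - Y[:, :, j].mean()
             + grand) ** 2
            for i in range(a) for j in range(b))
        assert mine["A"].ss_effect == pytest.approx(ss_a)
        assert mine["A*B"].ss_effect == pytest.approx(ss_ab)

    def test_interaction_epsilon_in_bounds(self, data):
        _, frame = data
        res = rm_anova(frame, "y", ["A", "B"], "subject")["A*B"]
        q = (3 - 1) * (4 - 1)
        assert 1.0 / q - 1e-12 <= res.gg_epsilon <= 1.0 + 1e-12
        assert res.df_num_gg == pytest.approx(res.gg_epsilon * q)


class TestTTests:
    def test_identical_vectors(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.t, r.p_two_tailed, r.cohens_d) == (0.0, 1.0, 0.0)

    def test_three_point_hand_example(self):
        # diffs = [1, 2, 2]: mean 5/3, sd 1/sqrt(3), t = 5.0 exactly
        r = paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 1.0])
        assert r.t == pytest.approx(5.0, abs=1e-12)
        assert r.p_two_tailed == pytest.approx(0.037749551350623724, abs=1e-12)
        assert r.cohens_d == pytest.approx((5 / 3) * np.sqrt(3), rel=1e-12)

    def test_against_scipy_on_random_data(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 20))
        mine = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-12)
        lo, hi = ref.confidence_interval(0.95)
        assert (mine.ci_low, mine.ci_high) == pytest.approx((lo, hi),
                                                            rel=1e-9)

    def test_one_sample_summary_input(self):
        # published summary: mean 0.169, SD 0.303, n 27 against 0
        r = one_sample_t(mean=0.169, sd=0.303, n=27, mu0=0.0)
        assert r.t == pytest.approx(2.8981840245459436, abs=1e-12)
        assert r.df == 26
        assert (r.ci_low, r.ci_high) == pytest.approx(
            (0.04913719205250601, 0.288862807947494), abs=1e-12)
        assert r.cohens_d == pytest.approx(0.169 / 0.303, rel=1e-12)

    def test_one_sample_vector_matches_summary(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0.4, 1.0, 15)
        a = one_sample_t(x, mu0=0.1)
        b = one_sample_t(mean=float(x.mean()), sd=float(x.std(ddof=1)),
                         n=15, mu0=0.1)
        assert a.t == pytest.approx(b.t, rel=1e-12)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            one_sample_t(mean=1.0, sd=0.0, n=5)


class TestBH:
    def test_hand_example(self):
        # thresholds at q=.05, m=4: .0125 .025 .0375 .05
        res = bh_adjust([0.001, 0.013, 0.04, 0.22], q=0.05)
        assert list(res.rejected) == [True, True, False, False]

    def test_all_ones_none_rejected(self):
        assert not bh_adjust([1.0, 1.0, 1.0]).rejected.any()

    def test_single_p(self):
        assert bh_adjust([0.04], q=0.05).rejected[0]

    def test_empty(self):
        assert bh_adjust([]).rejected.size == 0

    def test_adjusted_matches_statsmodels(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            mine = bh_adjust(p, q=0.05)
            rej, adj = multipletests(p, alpha=0.05, method="fdr_bh")[:2]
            assert np.allclose(mine.p_adjusted, adj)
            assert np.array_equal(mine.rejected, rej)

    def test_contains_bonferroni_and_monotone_in_q(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.uniform(size=15) ** 2
            bh = bh_adjust(p, q=0.05)
            bonf = p <= 0.05 / p.size
            assert np.all(bh.rejected[bonf])  # BH rejects whatever Bonf does
            assert bh_adjust(p, q=0.10).rejected.sum() >= bh.rejected.sum()

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestShapiro:
    def test_skewed_sample_detected(self):
        rng = np.random.default_rng(12)
        detected = sum(shapiro_wilk(rng.exponential(size=50))[1] < 0.01
                       for _ in range(10))
        assert detected >= 8

    def test_normal_sample_usually_passes(self):
        rng = np.random.default_rng(13)
        _, p = shapiro_wilk(rng.normal(size=200))
        assert p > 0.01

    def test_range_and_degenerate_errors(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError, match="identical"):
            shapiro_wilk([1.0, 1.0, 1.0, 1.0])
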