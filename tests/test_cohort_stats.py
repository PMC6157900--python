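import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, friedmanchisquare

from pulsewave.cohort_stats import (
    MatchResult,
    RepeatedMeasuresTable,
    correlation_cluster,
    propensity_score_match,
    scheffe_pairwise,
    two_group_tests,
    wittkowski_test,
)
from pulsewave.synthetic_data import (
    CONTROL_POPULATION,
    HD_POPULATION,
    sample_virtual_patient,
)


class TestWittkowski:
    def test_equals_friedman_on_complete_balanced_tables(self, rng):
        # independent oracle: scipy's Friedman chi-square
        worst = 0.0
        for _ in range(100):
            n_sub = rng.integers(6, 15)
            n_cond = rng.integers(3, 6)
            v = rng.normal(size=(n_sub, n_cond))
            stat, p = wittkowski_test(RepeatedMeasuresTable(v))
            f_stat, f_p = friedmanchisquare(*[v[:, j] for j in range(n_cond)])
            worst = max(worst, abs(stat - f_stat), abs(p - f_p))
        assert worst < 1e-10

    def test_identical_values_give_null_result(self):
        v = np.full((5, 4), 3.0)
        stat, p = wittkowski_test(RepeatedMeasuresTable(v))
        assert stat == 0.0 and p == 1.0

    def test_type_one_error_under_mcar_missingness(self, rng):
        rejections, total = 0, 0
        for _ in range(2000):
            v = rng.normal(size=(20, 4))
            v[rng.random((20, 4)) < 0.10] = np.nan
            if ((~np.isnan(v)).sum(axis=1) >= 2).sum() < 3:
                continue
            _, p = wittkowski_test(RepeatedMeasuresTable(v))
            total += 1
            rejections += p < 0.05
        assert 0.03 <= rejections / total <= 0.07

    def test_power_under_strong_shift_with_missingness(self, rng):
        v = rng.normal(size=(20, 4))
        v[:, 2] += 2.0  # two pooled SDs
        v[rng.random((20, 4)) < 0.10] = np.nan
        _, p = wittkowski_test(RepeatedMeasuresTable(v))
        assert p < 0.01

    def test_table_validation(self):
        with pytest.raises(ValueError):
            RepeatedMeasuresTable(np.ones((5, 1)))
        v = np.full((4, 3), np.nan)
        v[0, :2] = 1.0
        with pytest.raises(ValueError):
            RepeatedMeasuresTable(v)


class TestScheffe:
    def test_adjusted_never_below_unadjusted(self, rng):
        for _ in range(20):
            v = rng.normal(size=(10, 4))
            v[rng.random((10, 4)) < 0.1] = np.nan
            try:
                df = scheffe_pairwise(RepeatedMeasuresTable(v))
            except ValueError:
                continue
            assert (df.p_adjusted >= df.p_unadjusted - 1e-12).all()

    def test_single_shifted_condition_flagged(self, rng):
        v = rng.normal(size=(25, 4))
        v[:, 1] += 2.5
        df = scheffe_pairwise(RepeatedMeasuresTable(v))
        involves = df.condition_a.eq("C1") | df.condition_b.eq("C1")
        assert (df.loc[involves, "p_adjusted"] < 0.05).all()
        assert (df.loc[~involves, "p_adjusted"] > 0.05).all()

    def test_identical_conditions_all_null(self):
        v = np.tile(np.arange(6.0)[:, None], (1, 4))
        df = scheffe_pairwise(RepeatedMeasuresTable(v))
        assert (df.p_adjusted > 0.99).all()


class TestCorrelationCluster:
    def test_three_latent_blocks_recovered(self, rng):
        n = 200
        latents = rng.normal(size=(n, 3))
        cols = {}
        for b in range(3):
            for k in range(4):
                cols[f"b{b}v{k}"] = latents[:, b] + 0.4 * rng.normal(size=n)
        df = pd.DataFrame(cols)
        R, mask, order = correlation_cluster(df)
        blocks = [name[1] for name in order]
        # contiguous blocks in the dendrogram leaf order
        seen = []
        for b in blocks:
            if not seen or seen[-1] != b:
                seen.append(b)
        assert len(seen) == 3

    def test_null_data_mostly_masked(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 6)),
                          columns=list("abcdef"))
        R, mask, order = correlation_cluster(df)
        off = ~np.eye(6, dtype=bool)
        assert np.abs(R.values[off]).max() < 0.3
        assert mask.values[off].mean() > 0.7

    def test_duplicated_variable_merges_first(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"x1": x, "x2": x, "y": rng.normal(size=100),
                           "z": rng.normal(size=100)})
        R, mask, order = correlation_cluster(df)
        assert R.loc["x1", "x2"] == pytest.approx(1.0)
        i1, i2 = order.index("x1"), order.index("x2")
        assert abs(i1 - i2) == 1

    def test_monotone_transform_invariance(self, rng):
        base = pd.DataFrame(rng.normal(size=(80, 4)),
                            columns=list("abcd"))
        R1, _, _ = correlation_cluster(base)
        trans = base.copy()
        trans["a"] = np.exp(trans["a"])
        trans["c"] = trans["c"] ** 3
        R2, _, _ = correlation_cluster(trans)
        assert np.allclose(R1.values, R2.values, atol=1e-12)


class TestTwoGroupTests:
    def test_identical_groups_null(self):
        x = np.arange(20.0)
        stat, p = two_group_tests(x, x)
        assert p > 0.9

    def test_reported_gender_split_not_significant(self):
        # 43% of 35 HD vs 47% of 32 controls male -> 15/20 vs 15/17
        hd = np.array([1] * 15 + [0] * 20)
        ctrl = np.array([1] * 15 + [0] * 17)
        stat, p = two_group_tests(hd, ctrl, kind="categorical")
        tab = np.array([[15, 20], [15, 17]])
        stat_ref, p_ref, _, _ = chi2_contingency(tab, correction=True)
        assert stat == pytest.approx(stat_ref)
        assert p > 0.05

    def test_large_shift_detected(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30) + 3.0
        _, p = two_group_tests(a, b)
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            two_group_tests(np.array([]), np.array([1.0]))


def _table1_cohort(seed=11):
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(35):
        s = sample_virtual_patient(HD_POPULATION, "HD", rng)
        rows.append({"group": "HD", "age": s.age, "male": int(s.male)})
    for _ in range(32):
        s = sample_virtual_patient(CONTROL_POPULATION, "control", rng)
        rows.append({"group": "control", "age": s.age, "male": int(s.male)})
    return pd.DataFrame(rows)


class TestPropensityMatching:
    def test_identical_covariates_retain_everyone(self):
        df = pd.DataFrame({
            "group": ["HD"] * 10 + ["control"] * 10,
            "age": list(range(10)) * 2,
            "male": [0, 1] * 10,
        })
        m = propensity_score_match(df, covariates=("age",), categorical=())
        assert m.n_matched == 10

    def test_disjoint_ages_with_tight_caliper_give_empty_result(self):
        df = pd.DataFrame({
            "group": ["HD"] * 8 + ["control"] * 8,
            "age": [80 + i for i in range(8)] + [20 + i for i in range(8)],
            "male": [0] * 16,
        })
        m = propensity_score_match(df, covariates=("age",), categorical=(),
                                   caliper_sd=0.01)
        assert isinstance(m, MatchResult)
        assert m.n_matched == 0

    def test_age_balance_restored_on_reported_age_gap(self):
        df = _table1_cohort()
        hd_age = df.loc[df.group == "HD", "age"]
        c_age = df.loc[df.group == "control", "age"]
        _, p_pre = two_group_tests(hd_age, c_age)
        assert p_pre < 0.001
        m = propensity_score_match(df)
        assert 0 < m.n_matched < 35
        _, p_post = two_group_tests(df.loc[m.treated_retained, "age"],
                                    df.loc[m.control_retained, "age"])
        assert p_post > 0.05

    def test_matching_never_worsens_age_smd(self):
        df = _table1_cohort(seed=21)
        m = propensity_score_match(df)
        bal = m.balance[m.balance.covariate == "age"].set_index("stage")
        assert abs(bal.loc["after", "smd"]) <= abs(bal.loc["before", "smd"])
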