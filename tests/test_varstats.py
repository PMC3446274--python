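"""Per-CpG statistics: covariate adjustment, variance/mean tests, q-values."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evora.matrix import MethylationMatrix, SampleAnnotation
from evora.simulate import simulate_cohort
from evora.varstats import (
    adjust_covariate,
    age_association,
    bartlett_two_group,
    estimate_qvalues,
    rank_dvcs,
    rank_vcpgs,
    ttest_two_group,
)

from conftest import small_config


def bartlett_oracle(x, y):
    """Textbook two-group Bartlett statistic, coded independently in plain Python."""
    groups = [list(x), list(y)]
    k = 2
    ns = [len(g) for g in groups]
    N = sum(ns)
    means = [sum(g) / len(g) for g in groups]
    variances = [sum((v - mu) ** 2 for v in g) / (len(g) - 1) for g, mu in zip(groups, means)]
    sp2 = sum((n - 1) * s for n, s in zip(ns, variances)) / (N - k)
    num = (N - k) * math.log(sp2) - sum((n - 1) * math.log(s) for n, s in zip(ns, variances))
    corr = 1.0 + (sum(1.0 / (n - 1) for n in ns) - 1.0 / (N - k)) / (3.0 * (k - 1))
    stat = num / corr
    return stat, float(stats.chi2.sf(stat, k - 1))


class TestAdjustCovariate:
    def test_orthogonal_covariate_leaves_values(self, tiny_matrix):
        cov = np.zeros(tiny_matrix.n_samples)
        cov[: tiny_matrix.n_samples // 2] = 1.0
        cov -= cov.mean()
        # orthogonalize one CpG's values against cov, then check invariance
        y = tiny_matrix.beta[0]
        y = y - (y @ cov) / (cov @ cov) * cov
        beta = tiny_matrix.beta.copy()
        beta[0] = np.clip(y, 0.01, 0.99)
        m = MethylationMatrix(beta, tiny_matrix.cpg_ids, tiny_matrix.sample_ids)
        adjusted = adjust_covariate(m, cov)
        np.testing.assert_allclose(adjusted.beta[0], beta[0], atol=1e-9)

    def test_perfect_linear_fit_removes_variance(self):
        age = np.linspace(20, 50, 10)
        beta = np.clip(0.2 + 0.01 * (age - 20), 0.01, 0.99)[None, :]
        m = MethylationMatrix(beta, ["cgA"], [f"s{i}" for i in range(10)])
        adjusted = adjust_covariate(m, age)
        assert np.var(adjusted.beta[0]) < 1e-20

    def test_residual_variance_never_exceeds_raw(self):
        rng = np.random.default_rng(11)
        beta = rng.uniform(0.1, 0.9, size=(500, 40))
        cov = rng.uniform(20, 60, 40)
        m = MethylationMatrix(beta, [f"cg{i}" for i in range(500)], [f"s{i}" for i in range(40)])
        adjusted = adjust_covariate(m, cov)
        raw_var = beta.var(axis=1)
        adj_var = adjusted.beta.var(axis=1)
        assert (adj_var <= raw_var + 1e-12).all()

    def test_small_group_rejected(self, tiny_matrix):
        groups = ["g1"] * 2 + ["g2"] * (tiny_matrix.n_samples - 2)
        with pytest.raises(ValueError, match="g1"):
            adjust_covariate(tiny_matrix, np.arange(tiny_matrix.n_samples), within=groups)


class TestBartlett:
    def test_equal_variances_null_point(self):
        res = bartlett_two_group([1, 2, 3], [4, 5, 6])
        assert res["stat"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)
        assert res["var_ratio"] == pytest.approx(1.0)
        assert res["b_stat"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_oracle(self):
        x = [0.10, 0.20, 0.30, 0.40, 0.50]
        y = [0.05, 0.05, 0.06, 0.06]
        res = bartlett_two_group(x, y)
        stat, p = bartlett_oracle(x, y)
        assert res["stat"] == pytest.approx(stat, abs=1e-10)
        assert res["p"] == pytest.approx(p, abs=1e-10)

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            x = rng.normal(0, rng.uniform(0.5, 2), rng.integers(3, 30))
            y = rng.normal(0, rng.uniform(0.5, 2), rng.integers(3, 30))
            res = bartlett_two_group(x, y)
            ref = stats.bartlett(x, y)
            assert res["stat"] == pytest.approx(ref.statistic, abs=1e-10)
            assert res["p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(0, 2, size=12)
        a, b = bartlett_two_group(x, y), bartlett_two_group(y, x)
        assert a["stat"] == pytest.approx(b["stat"], abs=1e-12)
        assert a["p"] == pytest.approx(b["p"], abs=1e-12)
        assert a["var_ratio"] == pytest.approx(1 / b["var_ratio"])
        assert a["b_stat"] == pytest.approx(-b["b_stat"], abs=1e-12)

    def test_zero_variance_both_groups_untestable(self):
        res = bartlett_two_group([1.0, 1.0, 1.0], [2.0, 2.0])
        assert math.isnan(res["p"])

    def test_single_vector_rejected(self):
        with pytest.raises(ValueError, match="2 non-missing"):
            bartlett_two_group([1.0, 2.0], [3.0])


class TestTtest:
    def test_identical_groups(self):
        res = ttest_two_group([1, 2, 3, 4], [1, 2, 3, 4])
        assert res["t_stat"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_constant_shift_welch_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0.3, 0.05, 20)
        x = y + 0.5
        res = ttest_two_group(x, y)
        assert res["mean_diff"] == pytest.approx(0.5, abs=1e-12)
        # closed-form Welch t and tail
        vx, vy = x.var(ddof=1) / 20, y.var(ddof=1) / 20
        t = 0.5 / math.sqrt(vx + vy)
        dof = (vx + vy) ** 2 / (vx**2 / 19 + vy**2 / 19)
        assert res["t_stat"] == pytest.approx(t, abs=1e-10)
        assert res["p"] == pytest.approx(2 * stats.t.sf(t, dof), abs=1e-10)

    def test_label_exchange_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(1, 2, size=9)
        a, b = ttest_two_group(x, y), ttest_two_group(y, x)
        assert a["t_stat"] == pytest.approx(-b["t_stat"], abs=1e-12)
        assert a["p"] == pytest.approx(b["p"], abs=1e-12)


class TestAgeAssociation:
    def _cohort(self, seed=0, n=150):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(19, 55, n)
        beta = np.clip(0.2 + 0.005 * ages + rng.normal(0, 0.01, (5, n)), 0.01, 0.99)
        beta = np.vstack([beta, np.full((1, n), 0.4)])  # constant CpG
        m = MethylationMatrix(beta, [f"cg{i}" for i in range(6)], [f"s{i}" for i in range(n)])
        ann = SampleAnnotation(
            pd.DataFrame(
                {
                    "sample_id": m.sample_ids,
                    "status": ["case", "control"] * (n // 2),
                    "age": ages,
                }
            )
        )
        return m, ann

    def test_recovers_planted_slope(self):
        m, ann = self._cohort()
        res = age_association(m, ann)
        planted = res[res["cpg_id"] != "cg5"]
        assert planted["slope"].between(0.004, 0.006).all()
        assert (planted["p_age"] < 1e-6).all()
        assert (planted["direction"] == "hyper").all()

    def test_constant_cpg_flagged(self):
        m, ann = self._cohort()
        row = age_association(m, ann).set_index("cpg_id").loc["cg5"]
        assert row["slope"] == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(row["p_age"])

    def test_permuted_age_is_null(self):
        rng = np.random.default_rng(7)
        n, p = 150, 800
        ages = rng.uniform(19, 55, n)
        beta = rng.uniform(0.2, 0.8, (p, n))
        m = MethylationMatrix(beta, [f"cg{i}" for i in range(p)], [f"s{i}" for i in range(n)])
        ann = SampleAnnotation(
            pd.DataFrame(
                {
                    "sample_id": m.sample_ids,
                    "status": ["case", "control"] * (n // 2),
                    "age": rng.permutation(ages),
                }
            )
        )
        res = age_association(m, ann)
        frac = (res["p_age"] < 0.05).mean()
        # binomial(800, 0.05) three-sigma band
        assert 0.05 - 3 * math.sqrt(0.05 * 0.95 / p) < frac < 0.05 + 3 * math.sqrt(0.05 * 0.95 / p)

    def test_constant_age_rejected(self):
        m, ann = self._cohort()
        frame = ann.frame.copy()
        frame["age"] = 30.0
        with pytest.raises(ValueError, match="constant"):
            age_association(m, SampleAnnotation(frame))


class TestQvalues:
    def test_all_ones(self):
        np.testing.assert_array_equal(estimate_qvalues([1, 1, 1, 1]), [1, 1, 1, 1])

    def test_bh_hand_computed(self):
        q = estimate_qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=500)
        q = estimate_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=300)
        perm = rng.permutation(300)
        q = estimate_qvalues(p)
        q_perm = estimate_qvalues(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])

    def test_nan_propagates(self):
        q = estimate_qvalues([0.01, np.nan, 0.5])
        assert math.isnan(q[1]) and not math.isnan(q[0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_qvalues([])


class TestRankDvcs:
    def test_planted_cpgs_dominate_ranking(self, small_cohort):
        matrix, annotation, _, truth = small_cohort
        table = rank_dvcs(matrix, annotation)
        k = int(truth.is_risk.sum())
        top = set(table.head(k)["cpg_id"])
        assert len(top & truth.risk_set()) / k >= 0.8

    def test_direction_labels(self, small_cohort):
        matrix, annotation, _, _ = small_cohort
        table = rank_dvcs(matrix, annotation)
        hyper = table["direction"] == "hypervariable"
        assert ((table["var_ratio"] > 1) == hyper).all()

    def test_permuted_labels_yield_uniform_p(self, null_cohort):
        matrix, annotation, _, _ = null_cohort
        rng = np.random.default_rng(10)
        frame = annotation.frame.copy()
        frame["status"] = rng.permutation(frame["status"].to_numpy())
        table = rank_dvcs(matrix, SampleAnnotation(frame))
        p = table["p_bartlett"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_hpv_adjustment_is_robust_without_hpv_effect(self, small_cohort):
        matrix, annotation, _, _ = small_cohort
        top = lambda adjust: set(  # noqa: E731
            rank_dvcs(matrix, annotation, adjust_hpv=adjust).head(150)["cpg_id"]
        )
        a, b = top(False), top(True)
        assert len(a ^ b) / len(a) < 0.05

    def test_single_phenotype_rejected(self, small_cohort):
        matrix, annotation, _, _ = small_cohort
        frame = annotation.frame.copy()
        frame["status"] = "case"
        with pytest.raises(ValueError, match="both phenotypes"):
            rank_dvcs(matrix, SampleAnnotation(frame))


class TestRankVcpgs:
    def test_planted_vcpgs_top_ranked_and_disjoint_from_dvcs(self, small_cohort):
        matrix, annotation, _, truth = small_cohort
        v = rank_vcpgs(matrix, annotation.age)
        k = int(truth.is_vcpg.sum())
        top_v = set(v.head(k)["cpg_id"])
        assert len(top_v & truth.vcpg_set()) / k >= 0.9
        dvc_top = set(rank_dvcs(matrix, annotation).head(k)["cpg_id"])
        assert len(top_v & dvc_top) / k < 0.05

    def test_constant_matrix_stable_order(self):
        m = MethylationMatrix(np.full((5, 8), 0.5), [f"cg{i}" for i in "31024"], list("abcdefgh"))
        v = rank_vcpgs(m, np.arange(8, dtype=float))
        assert (v["variance"] < 1e-25).all()
        assert list(v["cpg_id"]) == sorted(m.cpg_ids)


def test_outlier_contamination_contrast():
    """Variance tests reach tiny q-values where mean tests stay insignificant
    under outlier contamination (the regime the method is built for)."""
    matrix, annotation, _, truth = simulate_cohort(small_config(seed=21))
    table = rank_dvcs(matrix, annotation).set_index("cpg_id")
    planted = table.loc[sorted(truth.risk_set())]
    assert planted["q_bartlett"].median() < 1e-3
    assert planted["q_t"].median() > 0.1
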