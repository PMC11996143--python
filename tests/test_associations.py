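"""Residualization, standardized regressions, Welch test, and BH q values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
import statsmodels.api as sm

from wristrhythm import (
    association_scan,
    bh_adjust,
    residualize_outcome,
    standardized_association,
    simulate_cohort_table,
    welch_unequal_var,
)


def brute_force_bh(p):
    """Definition-based step-up BH with cumulative-minimum monotonicity."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


class TestResidualize:
    def test_exact_linear_outcome_gives_zero_residuals(self, rng):
        X = rng.normal(size=(30, 3))
        y = 2.0 + X @ np.array([1.0, -0.5, 3.0])
        np.testing.assert_allclose(residualize_outcome(y, X), 0.0, atol=1e-10)

    def test_orthogonal_confounders_return_centered_outcome(self, rng):
        n = 64
        y = rng.normal(size=n)
        y = y - y.mean()
        X = np.column_stack([np.cos(2 * np.pi * np.arange(n) / n),
                             np.sin(2 * np.pi * np.arange(n) / n)])
        # make columns exactly orthogonal to y and the intercept
        for j in range(X.shape[1]):
            X[:, j] -= X[:, j].mean()
            X[:, j] -= (X[:, j] @ y) / (y @ y) * y
        np.testing.assert_allclose(residualize_outcome(y, X), y, atol=1e-10)

    def test_random_instance_matches_normal_equations_and_statsmodels(self, rng):
        X = rng.normal(size=(40, 4))
        y = rng.normal(size=40)
        got = residualize_outcome(y, X)
        Xi = np.column_stack([np.ones(40), X])
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
        np.testing.assert_allclose(got, y - Xi @ beta, atol=1e-10)
        np.testing.assert_allclose(got, sm.OLS(y, Xi).fit().resid, atol=1e-10)
        # orthogonality + zero mean
        assert abs(got.mean()) < 1e-12
        np.testing.assert_allclose(X.T @ got, 0.0, atol=1e-9)

    def test_collinear_design_names_columns(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 2] = 2 * X[:, 0] - X[:, 1]
        with pytest.raises(ValueError, match="collinear"):
            residualize_outcome(rng.normal(size=30), X)


class TestStandardizedAssociation:
    def test_identical_vectors_give_beta_one(self, rng):
        v = rng.normal(size=30)
        res = standardized_association(v, v.copy())
        assert res.beta_std == pytest.approx(1.0)
        assert res.p_value < 1e-12
        assert res.dof == 28

    def test_fixed_small_dataset_matches_closed_form(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 6.0, 7.2, 8.0, 9.1, 10.0, 12.0])
        y = np.array([2.1, 1.0, 3.4, 2.2, 5.0, 4.1, 6.3, 5.5, 7.9, 6.8])
        res = standardized_association(x, y)
        n = 10
        r = np.corrcoef(x, y)[0, 1]
        t = r * np.sqrt((n - 2) / (1 - r**2))
        se = np.sqrt((1 - r**2) / (n - 2))
        tcrit = stats.t.ppf(0.975, n - 2)
        assert res.beta_std == pytest.approx(r, abs=1e-10)
        assert res.t_stat == pytest.approx(t, abs=1e-10)
        assert res.ci_low == pytest.approx(r - tcrit * se, abs=1e-10)
        assert res.ci_high == pytest.approx(r + tcrit * se, abs=1e-10)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), n - 2), abs=1e-10)

    def test_beta_equals_pearson_of_zscored_residualized_pipeline(self, rng):
        n = 40
        X = rng.normal(size=(n, 4))
        y = X @ np.array([0.5, -1.0, 0.2, 0.8]) + rng.normal(size=n)
        pred = rng.normal(size=n)
        resid = residualize_outcome(y, X)
        res = standardized_association(pred, resid)
        zx = (pred - pred.mean()) / pred.std(ddof=1)
        zy = (resid - resid.mean()) / resid.std(ddof=1)
        r = float(np.mean(zx * zy) * n / (n - 1))
        assert res.beta_std == pytest.approx(r, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardized_association(np.ones(10), np.arange(10.0))


class TestWelch:
    def test_equal_means_give_t_zero_p_one(self):
        t, dof, p = welch_unequal_var(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_printed_group_summaries(self):
        """Recording-length group comparison from published summary stats
        (NCD 7.2 +/- 0.6 d, n=21 vs MCI 6.6 +/- 1.2 d, n=19)."""
        t, dof, p = welch_unequal_var(6.6, 1.2, 19, 7.2, 0.6, 21)
        v1, v2 = 1.2**2 / 19, 0.6**2 / 21
        t_exp = -0.6 / np.sqrt(v1 + v2)
        dof_exp = (v1 + v2) ** 2 / (v1**2 / 18 + v2**2 / 20)
        assert t == pytest.approx(t_exp, abs=1e-10)
        assert dof == pytest.approx(dof_exp, abs=1e-10)
        res = stats.ttest_ind_from_stats(6.6, 1.2, 19, 7.2, 0.6, 21, equal_var=False)
        assert t == pytest.approx(res.statistic, abs=1e-10)
        assert p == pytest.approx(res.pvalue, abs=1e-10)
        assert t < 0 and p < 0.1  # shorter recordings in the risk group

    def test_pooled_limit_dof(self):
        _, dof, _ = welch_unequal_var(1.0, 2.0, 15, 3.0, 2.0, 15)
        assert dof == pytest.approx(28.0, abs=1e-10)

    def test_randomized_inputs_match_scipy(self, rng):
        for _ in range(50):
            m1, m2 = rng.normal(size=2)
            s1, s2 = rng.uniform(0.5, 3.0, size=2)
            n1, n2 = rng.integers(3, 50, size=2)
            t, dof, p = welch_unequal_var(m1, s1, int(n1), m2, s2, int(n2))
            ref = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            welch_unequal_var(1, 1.0, 1, 2, 1.0, 10)
        with pytest.raises(ValueError):
            welch_unequal_var(1, 0.0, 10, 2, 1.0, 10)


class TestBH:
    def test_flat_family_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.full(12, 0.03)), 0.03)

    def test_single_p_is_its_own_q(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.2])), [0.2])

    def test_twelve_test_family_matches_brute_force(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074,
                      0.205, 0.212, 0.216, 0.44, 0.9])
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_q_values_monotone_and_at_least_p(self, p_list):
        p = np.array(p_list)
        q = bh_adjust(p)
        np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-10)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestAssociationScan:
    CONFOUNDERS = ["age", "sex", "education", "recording_length"]
    OUTCOMES = ["immediate_memory", "delayed_memory", "processing_speed", "set_shifting"]

    def test_planted_effects_recovered_with_q_only_in_iv_family(self):
        table = simulate_cohort_table(n=40, seed=123)
        iv_cols = [f"iv_{tau}" for tau in range(5, 65, 5)]
        predictors = ["pseudo_f", "interdaily_stability", "relative_amplitude",
                      "up_mesor", "down_mesor"] + iv_cols
        res = association_scan(table, self.CONFOUNDERS, self.OUTCOMES, predictors,
                               bh_families={"iv": iv_cols})
        assert len(res) == len(predictors) * len(self.OUTCOMES)
        row = res[(res.predictor == "iv_40") & (res.outcome == "processing_speed")].iloc[0]
        assert row.beta_std > 0
        assert row.dof == 38
        mem = res[(res.predictor == "up_mesor") & (res.outcome == "delayed_memory")].iloc[0]
        assert mem.beta_std < 0
        assert res[res.family == "iv"].q_value.notna().all()
        assert res[res.family.isna()].q_value.isna().all()
        fam = res[(res.family == "iv") & (res.outcome == "processing_speed")]
        assert np.all(fam.q_value.to_numpy() >= fam.p_value.to_numpy() - 1e-12)

    def test_listwise_deletion_logged(self, caplog):
        table = simulate_cohort_table(n=40, seed=5)
        table.loc[3, "age"] = np.nan
        table.loc[7, "processing_speed"] = np.nan
        import logging

        with caplog.at_level(logging.INFO, logger="wristrhythm.associations"):
            association_scan(table, self.CONFOUNDERS, self.OUTCOMES, ["iv_40"])
        assert "2 rows" in caplog.text
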