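import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tmjmorph as tm
from tmjmorph.phantom import CohortSimSpec, fixture_moments, simulate_cohort
from tmjmorph.stats import (
    JFLSResponse,
    PowerSpec,
    exact_power_two_groups,
    hotelling_two_sample,
    jfls_total,
    outcome_differences,
    sample_size,
    spearman,
    strength_label,
)


class TestJFLS:
    def test_bounds(self):
        assert jfls_total(JFLSResponse((0,) * 10)) == 0
        assert jfls_total(JFLSResponse((5,) * 10)) == 50
        assert jfls_total((1, 2, 3, 0, 5, 0, 1, 2, 0, 4)) == 18

    def test_invalid_items_rejected(self):
        with pytest.raises(ValueError):
            JFLSResponse((5, 8, 0, 3, 7, 0, 0, 0, 0, 0))  # items capped at 5
        with pytest.raises(ValueError):
            JFLSResponse((1, 2, 3))  # ten items required
        with pytest.raises(ValueError):
            JFLSResponse((0.5,) * 10)  # integers only


class TestOutcomeDifferences:
    def test_fixture_change_scores(self, fixture_cohort):
        diffs = outcome_differences(fixture_cohort)
        pf = diffs["patients"]
        mand = pf[pf["group"] == "mandibulotomy"]
        assert mand["mouth_opening_decrease"].mean() == pytest.approx(10.9, abs=0.05)
        assert mand["jfls_increase"].mean() == pytest.approx(13.1, abs=0.05)
        tran = pf[pf["group"] == "transoral"]
        assert tran["mouth_opening_decrease"].mean() == pytest.approx(5.4, abs=0.05)

    def test_zero_change_cohort(self):
        moments = fixture_moments()
        for g in moments:
            m = moments[g]["means"]
            m["mxd_t2"] = m["mxd_t1"]
            m["mouth_opening_t2"] = m["mouth_opening_t1"]
            m["jfls_t2"] = m["jfls_t1"]
            moments[g]["sds"] = {k: 0.0 for k in moments[g]["sds"]}
        table = simulate_cohort(CohortSimSpec(moments=moments, seed=0))
        diffs = outcome_differences(table)
        assert np.allclose(diffs["joints"]["mxd_change"], 0.0, atol=1e-9)
        assert np.allclose(diffs["patients"]["mouth_opening_decrease"], 0.0, atol=1e-9)

    def test_missing_cells_propagate(self, fixture_cohort):
        import copy
        table = copy.deepcopy(fixture_cohort)
        table.joints[0].mxd_t1 = None
        jf = outcome_differences(table)["joints"]
        row = jf[jf["joint_id"] == table.joints[0].joint_id]
        assert row["mxd_change"].isna().all()


class TestHotelling:
    def test_univariate_equals_pooled_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, (12, 1)), rng.normal(0.7, 1, (9, 1))
        res = hotelling_two_sample(a, b)
        t = sps.ttest_ind(a.ravel(), b.ravel()).statistic
        assert res.t2 == pytest.approx(t**2, abs=1e-9)
        assert res.outcome_differences[0].p_value == pytest.approx(res.p_value, abs=1e-12)

    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10, 3))
        res = hotelling_two_sample(a, a.copy())
        assert res.t2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_implementation(self):
        """Cross-check against pingouin's Hotelling T² on a random dataset."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        A, B = rng.normal(0, 1, (15, 3)), rng.normal(0.4, 1.2, (11, 3))
        ours = hotelling_two_sample(A, B)
        ref = pg.multivariate_ttest(A, B)
        assert ours.t2 == pytest.approx(float(ref["T2"].iloc[0]), rel=1e-9)
        assert ours.p_value == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-9)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        A, B = rng.normal(0, 1, (14, 3)), rng.normal(0.5, 1, (10, 3))
        scale, shift = np.array([2.0, 0.5, 10.0]), np.array([1.0, -3.0, 100.0])
        res1 = hotelling_two_sample(A, B)
        res2 = hotelling_two_sample(A * scale + shift, B * scale + shift)
        assert res1.t2 == pytest.approx(res2.t2, rel=1e-9)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(6)
        res = hotelling_two_sample(rng.normal(0, 1, (8, 2)), rng.normal(1, 1, (9, 2)))
        for d in res.outcome_differences:
            assert d.ci_low <= d.mean_difference <= d.ci_high

    def test_singular_covariance_rejected(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(10, 1))
        A = np.hstack([a, 2 * a])  # perfectly collinear outcomes
        B = np.hstack([a + 1, 2 * (a + 1)])
        with pytest.raises(ValueError, match="singular|reduce"):
            hotelling_two_sample(A, B)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            hotelling_two_sample(np.zeros((1, 2)), np.ones((5, 2)))


class TestSpearman:
    def test_strictly_increasing_is_very_high(self):
        x = np.arange(10.0)
        res = spearman(x, np.exp(x))
        assert res.r == pytest.approx(1.0)
        assert res.strength == "very high"

    def test_fixture_condyle_correlation(self, fixture_cohort):
        jf = fixture_cohort.joints_frame()
        res = spearman(jf["condyle_dsi"], jf["condyle_rmsd"])
        assert res.r == pytest.approx(-0.77, abs=0.05)
        assert res.strength == "high"
        assert res.n == 32

    def test_strength_bands(self):
        assert strength_label(0.6) == "moderate"
        assert strength_label(-0.6) == "moderate"
        assert strength_label(0.25) == "negligible"
        assert strength_label(0.305) == "low"  # the published guide's gap, closed upward
        assert strength_label(0.45) == "low"
        assert strength_label(0.85) == "high"
        assert strength_label(0.95) == "very high"

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=40), rng.normal(size=40)
        base = spearman(x, y).r
        assert spearman(np.exp(x), y).r == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3).r == pytest.approx(base, abs=1e-12)

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2, 3, np.nan, 5, 6])
        y = np.array([2.0, 4, 6, 8, np.nan, 12])
        res = spearman(x, y)
        assert res.n == 4
        assert res.r == pytest.approx(1.0)


class TestCorrelationMatrix:
    def test_fixture_matrix(self, fixture_cohort):
        mat = tm.correlation_matrix(fixture_cohort)
        res = mat.loc["disc_dsi", "disc_rmsd"]
        assert res.r == pytest.approx(-0.59, abs=0.05)
        assert res.strength == "moderate"
        # symmetric with empty diagonal
        assert mat.loc["disc_rmsd", "disc_dsi"].r == res.r
        assert mat.loc["disc_dsi", "disc_dsi"] is None or pd.isna(mat.loc["disc_dsi", "disc_dsi"])


class TestSampleSize:
    def test_published_design(self):
        res = sample_size(PowerSpec(effect_size_f=0.8, alpha=0.05, power=0.8))
        assert res.n_per_arm == 7

    def test_dropout_inflation(self):
        res = sample_size(PowerSpec(effect_size_f=0.8, dropout=0.5))
        assert res.n_recruited_per_arm == 14  # roughly doubles

    def test_tiny_power_gives_minimum_n(self):
        res = sample_size(PowerSpec(effect_size_f=0.8, power=0.01))
        assert res.n_per_arm == 2

    def test_exact_power_monotone_in_n(self):
        powers = [exact_power_two_groups(n, 0.8) for n in (4, 6, 8, 12)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            PowerSpec(alpha=0.0)
        with pytest.raises(ValueError):
            PowerSpec(dropout=1.0)
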