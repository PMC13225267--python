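"""Point-wise GLMs, pooled BH-FDR, significance maps, volume tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtasym.asymmetry import AsymmetryTable
from mtasym.stats import (ComparisonSpec, build_design, default_comparisons,
                          family_size, fdr_bh, fit_point_glm,
                          hc_baseline_comparison, run_comparison, run_family,
                          significance_map, volume_group_test)
from mtasym.types import PipelineError


def make_covariates(n_per_group, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in n_per_group.items():
        for i in range(n):
            rows.append({
                "group": g,
                "age_at_scan": rng.normal(71, 10),
                "sex": rng.choice(["female", "male"]),
                "tiv": rng.normal(1.4e6, 1e5),
                "cdr_global": 0.0 if g == "HC" else rng.choice([0.5, 1.0]),
                "field_strength": rng.choice([1.5, 3.0]),
                "voxel_volume": 1.0,
            })
    cov = pd.DataFrame(rows)
    cov.index = [f"{r['group']}_{i}" for i, r in
                 enumerate(cov.to_dict("records"))]
    return cov


def make_table(cov, M=16, seed=1, shift_group=None, shift=0.0):
    rng = np.random.default_rng(seed)
    Y = rng.normal(0, 0.5, size=(len(cov), M))
    if shift_group is not None:
        Y[cov["group"].to_numpy() == shift_group] += shift
    pa = pd.DataFrame(Y, index=cov.index,
                      columns=[f"p{k:04d}" for k in range(M)])
    va = pd.Series(rng.normal(0, 0.05, len(cov)), index=cov.index)
    vols = pd.DataFrame({"left": 3000.0, "right": 3100.0}, index=cov.index)
    return AsymmetryTable("hippocampus", pa, va, vols)


class TestPointGLM:
    def test_matches_closed_form_on_printed_fixture(self):
        # six participants: response, group indicator, one covariate
        y = np.array([1.2, 0.8, 1.9, 2.4, 3.1, 2.6])
        grp = np.array([0.0, 0, 0, 1, 1, 1])
        age = np.array([61.0, 72, 55, 68, 75, 63])
        X = np.column_stack([np.ones(6), grp, age])
        beta, se, t, p = fit_point_glm(y, X, test_idx=1)
        # independent closed-form least squares by matrix algebra
        XtX_inv = np.linalg.inv(X.T @ X)
        b = XtX_inv @ X.T @ y
        resid = y - X @ b
        sigma2 = resid @ resid / (6 - 3)
        se_o = np.sqrt(sigma2 * XtX_inv[1, 1])
        from scipy import stats as sps
        t_o = b[1] / se_o
        p_o = 2 * sps.t.sf(abs(t_o), 3)
        assert beta == pytest.approx(b[1], abs=1e-8)
        assert se == pytest.approx(se_o, abs=1e-8)
        assert p == pytest.approx(p_o, abs=1e-8)

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(40), rng.integers(0, 2, 40),
                             rng.normal(size=40)])
        y = rng.normal(size=40)
        beta, se, t, p = fit_point_glm(y, X, test_idx=1)
        res = sm.OLS(y, X).fit()
        assert beta == pytest.approx(res.params[1], abs=1e-10)
        assert se == pytest.approx(res.bse[1], abs=1e-10)
        assert p == pytest.approx(res.pvalues[1], abs=1e-10)

    def test_null_type_one_error_near_alpha(self):
        # many independent null points in one design: rejection rate ~ 5%
        rng = np.random.default_rng(7)
        n, M = 200, 2000
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n),
                             rng.normal(size=n)])
        from mtasym.stats import _ols_multi
        _, _, _, p, _ = _ols_multi(X, rng.normal(size=(n, M)), 1)
        rate = (p < 0.05).mean()
        assert abs(rate - 0.05) < 0.02

    def test_zero_residual_variance_flagged(self):
        grp = np.array([0.0, 0, 0, 1, 1, 1])
        X = np.column_stack([np.ones(6), grp])
        from mtasym.stats import _ols_multi
        _, _, _, p, flag = _ols_multi(X, grp.reshape(-1, 1), 1)
        assert flag[0]
        assert p[0] == 1.0


class TestFamilyAndFDR:
    def test_family_size_products(self):
        assert family_size(512, 6) == 3072
        assert family_size(256, 6) == 1536
        assert family_size(1, 1) == 1
        with pytest.raises(ValueError):
            family_size(0, 6)

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(fdr_bh(np.ones(4)), np.ones(4))

    def test_hand_computed_step_up(self):
        q = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels_multipletests(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, 257)
        np.testing.assert_allclose(
            fdr_bh(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=60))
    def test_q_dominates_p_and_is_monotone(self, ps):
        p = np.array(ps)
        q = fdr_bh(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.5]))


class TestComparisons:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            ComparisonSpec("bad", ("HC",), ("HC",))

    def test_pooled_family_has_m_times_comparisons_entries(self):
        cov = make_covariates({g: 8 for g in ("AD_Epi", "nonAD_Epi",
                                              "AD_NoEpi", "nonAD_NoEpi",
                                              "HC")})
        table = make_table(cov, M=32)
        pw = run_family(table, cov, default_comparisons())
        assert len(pw) == family_size(32, 6)
        assert (pw["family_size"] == 192).all()

    def test_pooling_contract_changes_q(self):
        cov = make_covariates({"AD_Epi": 10, "AD_NoEpi": 10, "HC": 10})
        table = make_table(cov, M=16, shift_group="AD_Epi", shift=0.6)
        specs = [s for s in default_comparisons()
                 if set(s.group_a) | set(s.group_b)
                 <= {"AD_Epi", "AD_NoEpi", "HC"}]
        pooled = run_family(table, cov, specs, pooled=True)
        single = run_family(table, cov, specs[:1], pooled=True)
        sub = pooled[pooled["comparison"] == specs[0].name]
        assert not np.allclose(sub["q"].to_numpy(), single["q"].to_numpy())
        np.testing.assert_allclose(sub["p"].to_numpy(),
                                   single["p"].to_numpy())

    def test_group_too_small_rejected(self):
        cov = make_covariates({"AD_Epi": 3, "AD_NoEpi": 2})
        table = make_table(cov, M=4)
        with pytest.raises(PipelineError, match="too few"):
            run_comparison(table, cov, default_comparisons()[0])

    def test_missing_covariates_excluded_rowwise(self):
        cov = make_covariates({"AD_Epi": 12, "AD_NoEpi": 12})
        cov.loc[cov.index[0], "tiv"] = np.nan
        rows, X, _ = build_design(cov, default_comparisons()[0])
        assert cov.index[0] not in rows
        assert X.shape[0] == 23

    def test_one_group_mode_recovers_adjusted_mean(self):
        cov = make_covariates({"HC": 60}, seed=9)
        table = make_table(cov, M=8, seed=10, shift_group="HC", shift=-0.3)
        pw = run_family(table, cov, [hc_baseline_comparison()])
        assert (pw["beta"] < 0).all()
        np.testing.assert_allclose(pw["beta"],
                                   table.point_asym.mean(axis=0), atol=0.05)
        assert pw["significant"].sum() > 0

    def test_sensitivity_mode_appends_scanner_covariates(self):
        specs = default_comparisons(sensitivity=True)
        for s in specs:
            assert s.covariates[-2:] == ("field_strength", "voxel_volume")


class TestSignificanceMap:
    def test_no_rejections_gives_empty_map(self):
        cov = make_covariates({"AD_Epi": 10, "AD_NoEpi": 10})
        table = make_table(cov, M=16)
        pw = run_family(table, cov, default_comparisons()[:1])
        sm_ = significance_map(pw)
        assert (sm_["label"] == "nonsig").all()

    def test_negating_asymmetry_flips_signs(self):
        cov = make_covariates({"AD_Epi": 15, "AD_NoEpi": 15})
        table = make_table(cov, M=16, shift_group="AD_Epi", shift=1.0)
        pw = run_family(table, cov, default_comparisons()[:1])
        table_neg = AsymmetryTable("hippocampus", -table.point_asym,
                                   -table.volume_asym, table.volumes)
        pw_neg = run_family(table_neg, cov, default_comparisons()[:1])
        assert pw["significant"].sum() > 0
        sig = pw["significant"].to_numpy()
        assert (pw.loc[sig, "sign"].to_numpy()
                != pw_neg.loc[sig, "sign"].to_numpy()).all()


class TestVolumeTests:
    def test_shifted_group_detected_with_high_power(self):
        cov = make_covariates({"AD_Epi": 50, "AD_NoEpi": 50}, seed=3)
        table = make_table(cov, M=4, seed=4)
        table.volume_asym.loc[cov["group"] == "AD_Epi"] += 0.05  # 1 SD shift
        res = volume_group_test(table, cov, default_comparisons()[0])
        assert res["t_test_p_unadjusted"] < 0.001
        assert res["glm_p_adjusted"] < 0.001

    def test_null_groups_not_systematically_significant(self):
        ps = []
        for seed in range(10):
            cov = make_covariates({"AD_Epi": 30, "AD_NoEpi": 30}, seed=seed)
            table = make_table(cov, M=4, seed=seed + 100)
            res = volume_group_test(table, cov, default_comparisons()[0])
            ps.append(res["t_test_p_unadjusted"])
        assert np.mean(np.array(ps) < 0.05) <= 0.2
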