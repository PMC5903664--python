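"""DWLS engine: df accounting, fit statistics, robust SEs, multilevel."""

import numpy as np
import pytest

from wheezesev.items import ItemResponseTable, OrdinalItemSpec
from wheezesev.polychoric import assemble_summary
from wheezesev.simulate import ClusterSpec, SimConfig, generate_cohort
from wheezesev.wlsmv import (
    ModelSpec,
    cfi,
    count_df,
    fit_dwls,
    fit_multilevel_within,
    rmsea,
    robust_se,
    robust_test,
)


class TestCountDf:
    @pytest.mark.parametrize(
        "spec,expected",
        [
            (ModelSpec(), 2),  # one factor, four items
            (ModelSpec(outcome_cats=2, q_factor=8), 29),
            (ModelSpec(outcome_cats=3, q_factor=8), 29),  # ordinal outcome: same df
            (ModelSpec(q_factor=1, q_direct=2), 5),  # within-school + sex
            (ModelSpec(q_direct=2), 2),  # within-school, no predictors
            (ModelSpec(outcome_cats=2, q_factor=2), 11),
            (ModelSpec(q_factor=2), 8),
        ],
    )
    def test_published_df_accounting(self, spec, expected):
        assert count_df(spec) == expected

    def test_brute_force_count_random_specs(self, rng):
        # independent enumeration: statistics minus free parameters
        for _ in range(100):
            cats = tuple(rng.integers(2, 5, size=rng.integers(3, 6)))
            out = int(rng.integers(2, 4)) if rng.random() < 0.5 else None
            qf = int(rng.integers(0, 4))
            qd = int(rng.integers(0, 3))
            spec = ModelSpec(item_cats=cats, outcome_cats=out, q_factor=qf,
                             q_direct=qd)
            p = len(cats) + (1 if out else 0)
            n_thr = sum(c - 1 for c in cats) + ((out - 1) if out else 0)
            n_stats = n_thr + p * (qf + qd) + p * (p - 1) // 2
            n_par = (
                n_thr + len(cats) + (1 if out else 0) + qf
                + (qf if out else 0) + p * qd
            )
            if n_stats - n_par < 0:
                with pytest.raises(ValueError):
                    count_df(spec, check_identification=False)
            else:
                assert count_df(spec, check_identification=False) == n_stats - n_par

    def test_underidentified_spec_rejected(self):
        with pytest.raises(ValueError, match="identified"):
            count_df(ModelSpec(item_cats=(2, 2)))


class TestRmseaCfi:
    @pytest.mark.parametrize(
        "chi2,df,n,printed",
        [(2.35, 2, 657, 0.02), (3.76, 2, 657, 0.04), (0.83, 2, 102, 0.00)],
    )
    def test_published_rounding(self, chi2, df, n, printed):
        assert round(rmsea(chi2, df, n)[0], 2) == printed

    def test_chi2_equal_df_is_zero_with_ci(self):
        point, lo, hi = rmsea(2.0, 2, 500)
        assert point == 0.0
        assert lo == 0.0
        assert hi > 0.0

    def test_degenerate_inputs_return_zero(self):
        assert rmsea(5.0, 0, 100) == (0.0, 0.0, 0.0)

    def test_cfi_limits(self):
        assert cfi(1.5, 2, 300.0, 6) == 1.0  # chi2 <= df
        assert cfi(50.0, 2, 50.0, 2) == 0.0  # model no better than baseline
        with pytest.warns(UserWarning):
            assert cfi(50.0, 2, 10.0, 6) < 1.0


class TestRobustAlgebra:
    def _parts(self, rng, dim=9, k=3):
        J = rng.standard_normal((dim, k))
        w = rng.uniform(0.5, 2.0, dim)
        return J, w

    def test_se_reduces_to_fisher_form_when_gamma_is_weight(self, rng):
        J, w = self._parts(rng)
        se, V = robust_se(J, np.diag(w), w)
        Vref = np.linalg.inv(J.T @ (J / w[:, None]))
        np.testing.assert_allclose(V, Vref, rtol=1e-10)

    def test_se_invariant_to_statistic_reordering(self, rng):
        J, w = self._parts(rng)
        G = rng.standard_normal((9, 9))
        gamma = G @ G.T
        se1, _ = robust_se(J, gamma, w)
        perm = rng.permutation(9)
        se2, _ = robust_se(J[perm], gamma[np.ix_(perm, perm)], w[perm])
        np.testing.assert_allclose(se1, se2, rtol=1e-10)

    def test_rank_deficient_jacobian_rejected(self, rng):
        J, w = self._parts(rng)
        J[:, 2] = J[:, 0]
        with pytest.raises(ValueError, match="rank"):
            robust_se(J, np.diag(w), w)

    def test_zero_df_statistic_is_zero_p_one(self, rng):
        J = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        w = np.ones(4)
        out = robust_test(np.zeros(4), J, np.eye(4), w, 0)
        assert out["chi2"] == 0.0
        assert out["p"] == 1.0


class TestFitDwls:
    def test_saturated_model_zero_chi2(self, rng):
        # three binary items, three loadings: df = 0, residual vanishes
        lam = np.array([0.8, 0.7, 0.6])
        n = 4000
        eta = rng.standard_normal(n)
        codes = {
            f"i{j}": (lam[j] * eta + np.sqrt(1 - lam[j] ** 2)
                      * rng.standard_normal(n) > 0.3).astype(np.int64)
            for j in range(3)
        }
        t = ItemResponseTable(
            ids=np.array([f"c{i}" for i in range(n)]),
            specs={f"i{j}": OrdinalItemSpec(f"i{j}", ("a", "b")) for j in range(3)},
            codes=codes,
        )
        f = fit_dwls(assemble_summary(t), ModelSpec(item_cats=(2, 2, 2)))
        assert f.df == 0
        assert f.chi2 == pytest.approx(0.0, abs=1e-10)
        assert abs(f.T_raw) < 1e-10

    def test_loading_recovery_close_to_truth(self, default_cohort):
        f = fit_dwls(assemble_summary(default_cohort.table), ModelSpec())
        np.testing.assert_allclose(
            f.loadings, default_cohort.config.loadings, atol=0.05
        )
        assert f.converged

    def test_objective_at_estimate_beats_truth(self, default_cohort):
        summ = assemble_summary(default_cohort.table)
        f = fit_dwls(summ, ModelSpec())
        lam = np.array(default_cohort.config.loadings)
        sl = summ.stat_slices()["rho"]
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        r_true = summ.s.copy() - summ.s
        r_true[sl] = summ.s[sl] - np.array([lam[i] * lam[j] for i, j in pairs])
        T_true = float(r_true @ (r_true / summ.w_diag))
        assert f.T_raw <= T_true + 1e-10

    def test_bit_reproducible(self, default_cohort):
        summ = assemble_summary(default_cohort.table)
        f1 = fit_dwls(summ, ModelSpec())
        f2 = fit_dwls(summ, ModelSpec())
        np.testing.assert_array_equal(f1.theta, f2.theta)
        assert f1.chi2 == f2.chi2

    def test_item_relabeling_permutes_estimates(self, default_cohort):
        t = default_cohort.table
        order = ["sleep", "episodes", "exercise", "speech"]
        s1 = assemble_summary(t)
        s2 = assemble_summary(t, variables=order)
        f1 = fit_dwls(s1, ModelSpec())
        f2 = fit_dwls(s2, ModelSpec(item_cats=tuple(s2.n_cats)))
        lam1 = dict(zip(s1.var_names, f1.loadings))
        lam2 = dict(zip(order, f2.loadings))
        for v in order:
            assert lam1[v] == pytest.approx(lam2[v], abs=1e-8)

    def test_refit_from_serialized_summary_identical(self, default_cohort, tmp_path):
        summ = assemble_summary(default_cohort.table, keep_influence=False)
        f_mem = fit_dwls(summ, ModelSpec())
        summ.to_dir(tmp_path / "dep")
        f_dep = fit_dwls(type(summ).from_dir(tmp_path / "dep"), ModelSpec())
        assert f_dep.chi2 == pytest.approx(f_mem.chi2, abs=1e-8)
        np.testing.assert_allclose(f_dep.theta, f_mem.theta, atol=1e-8)


class TestMultilevelWithin:
    def _study(self, icc, seed=31, n=3000):
        return generate_cohort(
            SimConfig(n=n, seed=seed, covariates={"female": 0.4},
                      gamma={"female": -0.2},
                      clustering=ClusterSpec(n_schools=100, icc=icc,
                                             n_sites=3,
                                             site_shifts=(0.0, 0.2, -0.2)))
        )

    def _site_dummies(self, table):
        site = table.cluster_ids["site"].to_numpy().astype(int)
        return np.column_stack([(site == 1).astype(float), (site == 2).astype(float)])

    def test_df_matches_published_accounting(self):
        st = self._study(icc=0.1)
        t = st.table
        sex = t.covariates["female"].to_numpy()
        f = fit_multilevel_within(t, self._site_dummies(t),
                                  t.cluster_ids["school"].to_numpy(),
                                  modeled_X=sex)
        assert f.df == 5
        f0 = fit_multilevel_within(t, self._site_dummies(t),
                                   t.cluster_ids["school"].to_numpy())
        assert f0.df == 2

    def test_no_clustering_matches_single_level(self):
        st = self._study(icc=0.0)
        t = st.table
        f_ml = fit_multilevel_within(t, self._site_dummies(t),
                                     t.cluster_ids["school"].to_numpy())
        np.testing.assert_allclose(
            f_ml.loadings, st.config.loadings, atol=0.06
        )

    def test_too_few_schools_rejected(self):
        st = self._study(icc=0.1)
        t = st.table
        with pytest.raises(ValueError, match="20 schools"):
            fit_multilevel_within(t, self._site_dummies(t),
                                  np.repeat(np.arange(10), 300))
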