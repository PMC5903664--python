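"""Stage-1 estimation: thresholds, polychoric correlations, sandwich Gamma."""

import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import norm

from wheezesev.items import ItemResponseTable, OrdinalItemSpec, MISSING
from wheezesev.polychoric import (
    assemble_summary,
    bvn_cdf,
    cluster_robust_gamma,
    polychoric_pair,
    univariate_probit,
)
from wheezesev.simulate import SimConfig, generate_cohort


def oracle_polychoric(table_counts, tau_i, tau_j, n_gl=40):
    """Brute-force tetrachoric/polychoric: 2-D tensor Gauss-Legendre
    integration of the bivariate density over each rectangle, maximized on
    a correlation grid with local refinement.  Independent of the
    correlation-integral route used by the implementation."""
    x, w = np.polynomial.legendre.leggauss(n_gl)
    bi = np.concatenate([[-8.0], tau_i, [8.0]])
    bj = np.concatenate([[-8.0], tau_j, [8.0]])

    def cellprob(rho, a0, a1, b0, b1):
        xi = 0.5 * (a1 - a0) * x + 0.5 * (a1 + a0)
        wi = 0.5 * (a1 - a0) * w
        xj = 0.5 * (b1 - b0) * x + 0.5 * (b1 + b0)
        wj = 0.5 * (b1 - b0) * w
        H, K = np.meshgrid(xi, xj, indexing="ij")
        om = 1 - rho**2
        dens = np.exp(-(H**2 - 2 * rho * H * K + K**2) / (2 * om)) / (
            2 * np.pi * np.sqrt(om)
        )
        return float(wi @ dens @ wj)

    def ll(rho):
        tot = 0.0
        for a in range(len(bi) - 1):
            for b in range(len(bj) - 1):
                n_ab = table_counts[a, b]
                if n_ab:
                    tot += n_ab * np.log(
                        max(cellprob(rho, bi[a], bi[a + 1], bj[b], bj[b + 1]), 1e-300)
                    )
        return tot

    grid = np.arange(-0.95, 0.951, 0.01)
    vals = [ll(r) for r in grid]
    best = grid[int(np.argmax(vals))]
    fine = np.arange(best - 0.01, best + 0.0101, 1e-4)
    vals = [ll(r) for r in fine]
    return float(fine[int(np.argmax(vals))])


def _simple_table(codes: dict, cats: dict):
    n = len(next(iter(codes.values())))
    specs = {
        k: OrdinalItemSpec(k, tuple(f"L{j}" for j in range(c)))
        for k, c in cats.items()
    }
    return ItemResponseTable(
        ids=np.array([f"c{i}" for i in range(n)]),
        specs=specs,
        codes={k: np.asarray(v, dtype=np.int64) for k, v in codes.items()},
    )


class TestUnivariateProbit:
    def test_balanced_binary_threshold_is_zero(self):
        y = np.array([0, 1] * 100)
        tau, slopes = univariate_probit(y, n_cats=2)
        assert tau[0] == pytest.approx(0.0, abs=1e-12)
        assert slopes.size == 0

    def test_thresholds_match_inverse_normal_of_marginals(self):
        # counts from the infant-cohort descriptive table, year 1
        y = np.repeat([0, 1, 2, 3], [205, 328, 73, 28])
        tau, _ = univariate_probit(y, n_cats=4)
        expect = ndtri(np.cumsum([205, 328, 73]) / 634)
        np.testing.assert_allclose(tau, expect, atol=1e-10)
        np.testing.assert_allclose(tau, [-0.459, 0.997, 1.703], atol=2e-3)

    def test_rare_binary_item_threshold(self):
        y = np.repeat([0, 1], [576, 67])
        tau, _ = univariate_probit(y, n_cats=2)
        assert tau[0] == pytest.approx(1.258, abs=2e-3)

    def test_covariate_fit_matches_statsmodels_ordered_probit(self, rng):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        n = 3000
        x = rng.binomial(1, 0.4, n).astype(float)
        ystar = 0.5 * x + rng.standard_normal(n)
        y = np.digitize(ystar, [-0.3, 0.8])
        tau, b = univariate_probit(y, x[:, None], n_cats=3)
        sm = OrderedModel(y, x[:, None], distr="probit").fit(
            method="bfgs", disp=False
        )
        # statsmodels parameterizes thresholds as (cut1, log-diff)
        cut1 = sm.params[1]
        cut2 = cut1 + np.exp(sm.params[2])
        assert b[0] == pytest.approx(sm.params[0], abs=1e-4)
        np.testing.assert_allclose(tau, [cut1, cut2], atol=1e-4)

    def test_thresholds_invariant_to_zero_covariate_column(self, rng):
        y = rng.integers(0, 3, 500)
        tau0, _ = univariate_probit(y, n_cats=3)
        tau1, b1 = univariate_probit(y, np.zeros((500, 0)), n_cats=3)
        np.testing.assert_allclose(tau0, tau1, atol=1e-10)

    def test_empty_boundary_category_collapsed(self):
        # declared 4 categories, top never observed
        y = np.repeat([0, 1, 2], [50, 30, 20])
        tau, _ = univariate_probit(y, n_cats=4)
        assert len(tau) == 2
        assert np.isfinite(tau).all()


class TestPolychoricPair:
    def test_symmetry_exact(self, rng):
        y1 = rng.integers(0, 3, 500)
        y2 = rng.integers(0, 2, 500)
        assert polychoric_pair(y1, y2) == polychoric_pair(y2, y1)

    def test_independent_items_near_zero(self, big_cohort):
        rng = np.random.default_rng(5)
        n = 100_000
        y1 = rng.integers(0, 4, n)
        y2 = rng.integers(0, 2, n)
        assert abs(polychoric_pair(y1, y2)) < 0.02

    def test_recovers_generating_correlation(self, rng):
        n = 100_000
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
        y1 = np.digitize(z[:, 0], [-0.46, 1.0, 1.7])
        y2 = np.digitize(z[:, 1], [0.5])
        assert 0.48 <= polychoric_pair(y1, y2) <= 0.52

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_numeric_integration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c1, c2 = rng.choice([2, 2, 3], 2)
        rho = rng.uniform(-0.85, 0.85)
        n = 2000
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        t1 = np.sort(rng.uniform(-1.2, 1.2, c1 - 1))
        t2 = np.sort(rng.uniform(-1.2, 1.2, c2 - 1))
        y1 = np.digitize(z[:, 0], t1)
        y2 = np.digitize(z[:, 1], t2)
        tau1, _ = univariate_probit(y1, n_cats=c1)
        tau2, _ = univariate_probit(y2, n_cats=c2)
        counts = np.zeros((c1, c2))
        for a in range(c1):
            for b in range(c2):
                counts[a, b] = ((y1 == a) & (y2 == b)).sum()
        want = oracle_polychoric(counts, tau1, tau2)
        got = polychoric_pair(y1, y2, tau_i=tau1, tau_j=tau2)
        assert got == pytest.approx(want, abs=1e-4)

    def test_bvn_cdf_against_scipy(self, rng):
        from scipy.stats import multivariate_normal

        for rho in (-0.9, -0.3, 0.4, 0.95):
            h = rng.normal(size=4)
            k = rng.normal(size=4)
            ref = [
                multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([a, b])
                for a, b in zip(h, k)
            ]
            np.testing.assert_allclose(bvn_cdf(h, k, rho), ref, atol=1e-10)


class TestAssembleSummary:
    def test_statistic_dimension_binary_items(self, rng):
        codes = {f"i{j}": rng.integers(0, 2, 300) for j in range(4)}
        t = _simple_table(codes, {f"i{j}": 2 for j in range(4)})
        s = assemble_summary(t)
        assert len(s.s) == 4 + 6  # 4 thresholds + 6 correlations
        assert s.gamma.shape == (10, 10)
        assert (np.diag(s.R) == 1).all()

    def test_population_correlation_structure(self, big_cohort):
        lam = np.array(big_cohort.config.loadings)
        summ = assemble_summary(big_cohort.table, keep_influence=False)
        np.testing.assert_allclose(
            summ.R - np.diag(np.diag(summ.R)),
            np.outer(lam, lam) - np.diag(lam**2),
            atol=0.01,
        )

    def test_gamma_matches_bootstrap_covariance(self):
        # sandwich Gamma vs nonparametric bootstrap of the statistic vector
        study = generate_cohort(SimConfig(n=5000, seed=77))
        table = study.table
        summ = assemble_summary(table)
        names = table.item_names
        Y = table.item_matrix(names)
        taus = [summ.thresholds[v] for v in names]
        rng = np.random.default_rng(1)
        reps = []
        for _ in range(500):
            idx = rng.integers(0, len(Y), len(Y))
            Yb = Y[idx]
            stats = []
            for j, v in enumerate(names):
                cnt = np.bincount(Yb[:, j], minlength=len(taus[j]) + 1)
                stats.extend(ndtri(np.cumsum(cnt)[:-1] / cnt.sum()))
            for i in range(4):
                for j in range(i + 1, 4):
                    stats.append(polychoric_pair(Yb[:, i], Yb[:, j]))
            reps.append(stats)
        boot = np.cov(np.array(reps).T)
        rel = np.linalg.norm(summ.gamma - boot) / np.linalg.norm(boot)
        assert rel < 0.15

    def test_pairwise_vs_listwise_option(self, default_cohort):
        t = default_cohort.table
        s_pw = assemble_summary(t, keep_influence=False)
        s_lw = assemble_summary(t, keep_influence=False, listwise=True)
        assert s_pw.n == s_lw.n  # complete data here
        np.testing.assert_allclose(s_pw.s, s_lw.s, atol=1e-12)

    def test_serialization_round_trip(self, default_cohort, tmp_path):
        s = assemble_summary(default_cohort.table, keep_influence=False)
        s.to_dir(tmp_path / "bundle")
        back = type(s).from_dir(tmp_path / "bundle")
        np.testing.assert_allclose(back.s, s.s, rtol=1e-12)
        np.testing.assert_allclose(back.gamma, s.gamma, rtol=1e-10, atol=1e-18)
        assert back.stat_names == s.stat_names
        assert back.n == s.n


class TestClusterRobustGamma:
    def test_distinct_clusters_equal_plain_gamma(self, default_cohort):
        s = assemble_summary(default_cohort.table)
        ids = np.arange(default_cohort.config.n)
        np.testing.assert_allclose(cluster_robust_gamma(s, ids), s.gamma, rtol=1e-10)

    def test_permuted_labels_preserve_gamma(self, rng):
        study = generate_cohort(
            SimConfig(n=3000, seed=9,
                      clustering=__import__("wheezesev").ClusterSpec(
                          n_schools=100, icc=0.1))
        )
        s = assemble_summary(study.table)
        school = study.table.cluster_ids["school"].to_numpy()
        perm = rng.permutation(school)
        g_perm = cluster_robust_gamma(s, perm)
        # permuted labels break the clustering: close to the iid Gamma
        sl = s.stat_slices()["rho"]
        ratio = np.diag(g_perm)[sl] / np.diag(s.gamma)[sl]
        assert np.median(ratio) == pytest.approx(1.0, abs=0.15)

    def test_real_clustering_inflates_correlation_variances(self):
        study = generate_cohort(
            SimConfig(n=3000, seed=9,
                      clustering=__import__("wheezesev").ClusterSpec(
                          n_schools=100, icc=0.1))
        )
        s = assemble_summary(study.table)
        school = study.table.cluster_ids["school"].to_numpy()
        g_cr = cluster_robust_gamma(s, school)
        sl = s.stat_slices()["rho"]
        ratio = np.diag(g_cr)[sl] / np.diag(s.gamma)[sl]
        assert np.median(ratio) > 1.0

    def test_single_cluster_rejected(self, default_cohort):
        s = assemble_summary(default_cohort.table)
        with pytest.raises(ValueError):
            cluster_robust_gamma(s, np.zeros(default_cohort.config.n))
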