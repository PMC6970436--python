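"""Unit tests for the OLS machinery and trio construction."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import triomed as tm
from triomed.core import CovariateMatrix, Trio, fit_ols

from conftest import SEED


class TestFitOLS:
    def test_identity_fit(self):
        x = np.arange(10.0)
        fit = fit_ols(x, [("x", x)])
        assert fit["x"]["coef"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_orthogonal_response_zero_slope(self, rng):
        x = np.concatenate([np.ones(10), -np.ones(10)])
        y = np.tile([1.0, -1.0], 10)  # orthogonal to x and to the intercept
        fit = fit_ols(y, [("x", x)])
        assert fit["x"]["coef"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        n = 50
        X = rng.normal(size=(n, 4))
        y = rng.normal(size=n)
        cov = CovariateMatrix(X[:, 2:], ["c1", "c2"])
        fit = fit_ols(y, [("a", X[:, 0]), ("b", X[:, 1])], cov)
        D = np.column_stack([np.ones(n), X])
        beta_oracle = np.linalg.solve(D.T @ D, D.T @ y)
        assert np.allclose(fit.coefficients, beta_oracle, atol=1e-8)
        # standard errors against the statsmodels implementation
        import statsmodels.api as sm

        res = sm.OLS(y, D).fit()
        assert np.allclose(fit.standard_errors, res.bse, atol=1e-8)
        assert np.allclose(fit.t_statistics, res.tvalues, atol=1e-8)

    def test_collinear_column_dropped_first_kept(self, rng):
        n = 30
        x = rng.normal(size=n)
        with pytest.warns(UserWarning, match="collinear"):
            fit = fit_ols(rng.normal(size=n), [("x", x), ("x2", 2.0 * x)])
        assert "x" in fit.term_names
        assert "x2" in fit.dropped_terms

    def test_unestimable_raises(self, rng):
        with pytest.raises(ValueError, match="unestimable"):
            fit_ols(np.array([1.0, 2.0]), [("a", np.array([0.0, 1.0])),
                                           ("b", np.array([1.0, 3.0]))])


class TestAssociations:
    def test_cis_limit_case(self, rng):
        g = rng.binomial(2, 0.4, 100).astype(float)
        c = 2.0 * g + rng.normal(0, 1e-8, 100)
        fit = tm.cis_association(g, c)
        assert fit["G"]["coef"] == pytest.approx(2.0, abs=1e-6)
        assert fit["G"]["p"] < 1e-50

    def test_hand_computed_six_sample_slope(self):
        # slope = sum((G-mean(G))*(C-mean(C))) / sum((G-mean(G))^2) = 5.5/4
        g = np.array([0.0, 0, 1, 1, 2, 2])
        c = np.array([0.5, 1.0, 1.5, 2.5, 3.0, 4.0])
        fit = tm.cis_association(g, c)
        assert fit["G"]["coef"] == pytest.approx(1.375, abs=1e-12)

    def test_monomorphic_genotype_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            tm.cis_association(np.ones(20), np.random.default_rng(0).normal(size=20))

    @pytest.mark.parametrize("assoc", [tm.cis_association, tm.trans_association])
    def test_null_type_one_error(self, assoc, rng):
        n, reps, alpha = 200, 1000, 0.05
        hits = 0
        for _ in range(reps):
            g = rng.binomial(2, 0.3, n).astype(float)
            y = rng.normal(size=n)
            hits += assoc(g, y)["G"]["p"] <= alpha
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(hits / reps - alpha) < 3 * se


class TestMediationStatistic:
    def test_degenerate_strong_mediation_flagged_not_crashed(self, rng):
        n = 60
        g = rng.binomial(2, 0.5, n).astype(float)
        c = rng.normal(size=n)
        t = c.copy()  # T == C exactly: se -> 0
        z = tm.mediation_statistic(g, c, t)
        assert abs(z) >= 1e6
        assert np.isfinite(z)
        assert tm.mediation_fit(g, c, t).degenerate

    def test_frisch_waugh_oracle_eight_samples(self):
        g = np.array([0.0, 0, 1, 1, 1, 2, 2, 2])
        c = np.array([0.3, -0.1, 0.8, 1.2, 0.9, 2.1, 1.7, 2.4])
        t = np.array([0.5, 0.2, 0.4, 1.0, 0.7, 1.5, 1.1, 1.9])
        z = tm.mediation_statistic(g, c, t)
        # two-step partialled-out regression oracle
        D = np.column_stack([np.ones(8), g])
        H = D @ np.linalg.solve(D.T @ D, D.T)
        ec, et = c - H @ c, t - H @ t
        beta = (ec @ et) / (ec @ ec)
        rss = et @ et - beta**2 * (ec @ ec)
        se = np.sqrt(rss / (8 - 3) / (ec @ ec))
        assert z == pytest.approx(beta / se, abs=1e-8)

    def test_invariant_under_common_reordering(self, rng):
        n = 80
        g = rng.binomial(2, 0.3, n).astype(float)
        c = g + rng.normal(size=n)
        t = 0.5 * c + rng.normal(size=n)
        cov = CovariateMatrix(rng.normal(size=(n, 2)), ["a", "b"])
        z0 = tm.mediation_statistic(g, c, t, cov)
        perm = rng.permutation(n)
        cov_p = CovariateMatrix(cov.values[perm], ["a", "b"])
        z1 = tm.mediation_statistic(g[perm], c[perm], t[perm], cov_p)
        assert z1 == pytest.approx(z0, abs=1e-10)

    def test_orthogonal_covariate_barely_moves_z(self, rng):
        n = 200
        g = rng.binomial(2, 0.4, n).astype(float)
        c = g + rng.normal(size=n)
        t = 0.5 * c + rng.normal(size=n)
        z0 = tm.mediation_statistic(g, c, t)
        # construct a covariate orthogonal to 1, G, C, T
        B = np.column_stack([np.ones(n), g, c, t])
        Q, _ = np.linalg.qr(B)
        w = np.random.default_rng(SEED).normal(size=n)
        w -= Q @ (Q.T @ w)
        z1 = tm.mediation_statistic(g, c, t, CovariateMatrix(w[:, None], ["w"]))
        assert abs(z1 - z0) / abs(z0) < 1e-2  # same estimate, dof shifts se slightly
        # and the coefficient itself is unchanged to high precision
        b0 = tm.mediation_fit(g, c, t)["C"]["coef"]
        b1 = tm.mediation_fit(g, c, t, CovariateMatrix(w[:, None], ["w"]))["C"]["coef"]
        assert b1 == pytest.approx(b0, abs=1e-6)

    def test_null_pvalues_uniform(self, rng):
        n, reps = 60, 2000
        pvals = np.empty(reps)
        for i in range(reps):
            g = rng.binomial(2, 0.3, n).astype(float)
            c = g + rng.normal(size=n)
            t = 0.4 * g + rng.normal(size=n)  # no C -> T effect
            pvals[i] = tm.mediation_fit(g, c, t)["C"]["p"]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestTrioConstruction:
    def _tables(self):
        cis = pd.DataFrame({
            "variant_id": ["v1", "v2"], "gene_id": ["g1", "g2"],
            "beta": [1, 1], "se": [0.1, 0.1], "p": [1e-4, 0.15],
            "fdr": [0.01, 0.2],
        })
        trans = pd.DataFrame({
            "variant_id": ["v1", "v2"], "gene_id": ["g3", "g4"],
            "beta": [1, 1], "se": [0.1, 0.1], "p": [1e-9, 1e-9],
        })
        return cis, trans

    def test_threshold_filter(self):
        cis, trans = self._tables()
        trios = tm.build_candidate_trios(cis, trans)
        assert len(trios) == 1
        assert (trios[0].variant_id, trios[0].cis_gene_id,
                trios[0].trans_gene_id) == ("v1", "g1", "g3")

    def test_permissive_thresholds_full_cross(self):
        cis, trans = self._tables()
        trios = tm.build_candidate_trios(cis, trans, 1.0, 1.0)
        assert len(trios) == 2

    def test_brute_force_join_oracle(self, rng):
        m = 100
        cis = pd.DataFrame({
            "variant_id": rng.choice([f"v{i}" for i in range(20)], m),
            "gene_id": rng.choice([f"cg{i}" for i in range(10)], m),
            "beta": rng.normal(size=m), "se": np.ones(m),
            "p": rng.random(m), "fdr": rng.random(m),
        })
        trans = pd.DataFrame({
            "variant_id": rng.choice([f"v{i}" for i in range(20)], m),
            "gene_id": rng.choice([f"tg{i}" for i in range(10)], m),
            "beta": rng.normal(size=m), "se": np.ones(m),
            "p": rng.random(m) * 1e-7,
        })
        got = tm.build_candidate_trios(cis, trans, 0.5, 5e-8)
        expected = set()
        for rc in cis.itertuples():
            for rt in trans.itertuples():
                if (rc.variant_id == rt.variant_id and rc.fdr <= 0.5
                        and rt.p < 5e-8 and rc.gene_id != rt.gene_id):
                    expected.add((rc.variant_id, rc.gene_id, rt.gene_id))
        assert {(t.variant_id, t.cis_gene_id, t.trans_gene_id)
                for t in got} == expected

    def test_empty_join_warns(self):
        cis, trans = self._tables()
        with pytest.warns(UserWarning, match="no candidate trios"):
            assert tm.build_candidate_trios(cis, trans, 1e-6, 1e-12) == []

    def test_trio_same_gene_rejected(self):
        with pytest.raises(ValueError):
            Trio("v1", "g1", "g1")


class TestBestTrioPerGenePair:
    def test_minimum_kept_and_tie_rule(self):
        df = pd.DataFrame({
            "variant_id": ["v2", "v1", "v3", "v2"],
            "cis_gene_id": ["g1", "g1", "g2", "g2"],
            "trans_gene_id": ["g9", "g9", "g8", "g8"],
            "p": [0.01, 0.001, 0.05, 0.05],
        })
        best = tm.best_trio_per_gene_pair(df, p_column="p")
        assert len(best) == 2
        assert best.loc[best.cis_gene_id == "g1", "variant_id"].item() == "v1"
        # exact tie -> lexicographically smaller variant id
        assert best.loc[best.cis_gene_id == "g2", "variant_id"].item() == "v2"

    def test_groupby_minimum_oracle(self, rng):
        n = 500
        df = pd.DataFrame({
            "variant_id": [f"v{i}" for i in rng.integers(0, 300, n)],
            "cis_gene_id": [f"c{i}" for i in rng.integers(0, 10, n)],
            "trans_gene_id": [f"t{i}" for i in rng.integers(0, 5, n)],
            "p": rng.random(n),
        })
        best = tm.best_trio_per_gene_pair(df, p_column="p")
        oracle = df.groupby(["cis_gene_id", "trans_gene_id"])["p"].min()
        assert len(best) == len(oracle)
        for row in best.itertuples():
            assert row.p == oracle[(row.cis_gene_id, row.trans_gene_id)]
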