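"""Association scan: PCs, OLS oracle equivalence, preselection, thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import biclink as b
from biclink.errors import DomainError, UndefinedStatisticError
from biclink.containers import LipidomeMatrix

from test_qc import make_gm


def ols_normal_equations_oracle(y, X):
    """Closed-form (X'X)^-1 X'y with classical standard errors."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    tvals = beta / se
    p = 2 * stats.t.sf(np.abs(tvals), df)
    return beta, se, p


class TestComputePcs:
    def test_orthogonality_and_ordering(self, rng):
        X = rng.integers(0, 3, size=(80, 300)).astype(float)
        gm = make_gm(X)
        scores = b.compute_pcs(gm, 5, ld_thin_r2=None)
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8
        variances = np.var(scores, axis=0)
        assert (np.diff(variances) <= 1e-9).all()

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.integers(0, 3, size=(100, 500)).astype(float)
        gm = make_gm(X)
        scores = b.compute_pcs(gm, 4, ld_thin_r2=None)
        Z = (X - X.mean(0)) / X.std(0)
        evals, evecs = np.linalg.eigh(Z.T @ Z)
        order = np.argsort(evals)[::-1]
        oracle = Z @ evecs[:, order[:4]]
        for k in range(4):
            sign = np.sign(oracle[0, k] * scores[0, k]) or 1.0
            np.testing.assert_allclose(scores[:, k], sign * oracle[:, k], atol=1e-6)

    def test_k_exceeding_rank_errors(self, rng):
        X = rng.integers(0, 3, size=(10, 4)).astype(float)
        with pytest.raises(DomainError):
            b.compute_pcs(make_gm(X), 5, ld_thin_r2=None)


class TestFitSnpLipid:
    def test_perfect_fit(self, rng):
        x = rng.integers(0, 3, 50).astype(float)
        x[0], x[1] = 0, 1
        y = 3 + 2 * x
        rec = b.fit_snp_lipid(x, y)
        assert rec.beta == pytest.approx(2.0, abs=1e-10)
        assert rec.p < 1e-12

    def test_normal_equations_oracle(self, rng):
        n = 200
        x = rng.integers(0, 3, n).astype(float)
        C = rng.normal(size=(n, 3))
        y = 0.5 + 0.3 * x + C @ [0.2, -0.4, 0.1] + rng.normal(size=n)
        rec = b.fit_snp_lipid(x, y, pd.DataFrame(C))
        X = np.column_stack([np.ones(n), x, C])
        beta, se, p = ols_normal_equations_oracle(y, X)
        assert rec.beta == pytest.approx(beta[1], abs=1e-10)
        assert rec.se == pytest.approx(se[1], abs=1e-10)
        assert rec.p == pytest.approx(p[1], abs=1e-10)

    def test_t_squared_equals_partial_f(self, rng):
        """The dosage t-statistic squared equals the partial F for adding
        the dosage to the covariate-only model."""
        n = 120
        x = rng.integers(0, 3, n).astype(float)
        C = rng.normal(size=(n, 2))
        y = 0.2 * x + C @ [0.5, -0.3] + rng.normal(size=n)
        rec = b.fit_snp_lipid(x, y, pd.DataFrame(C))
        X_full = np.column_stack([np.ones(n), x, C])
        X_red = np.column_stack([np.ones(n), C])
        rss = lambda X: y @ y - y @ X @ np.linalg.solve(X.T @ X, X.T @ y)
        f = (rss(X_red) - rss(X_full)) / (rss(X_full) / (n - X_full.shape[1]))
        assert (rec.beta / rec.se) ** 2 == pytest.approx(f, rel=1e-8)

    def test_monomorphic_errors(self):
        with pytest.raises(UndefinedStatisticError):
            b.fit_snp_lipid(np.ones(30), np.random.default_rng(0).normal(size=30))


class TestRunGwas:
    def make_inputs(self, rng, n=60, m=15, L=6, missing=False):
        X = rng.integers(0, 3, size=(n, m)).astype(float)
        if missing:
            X[rng.random((n, m)) < 0.05] = np.nan
        gm = make_gm(X)
        Y = pd.DataFrame(
            np.exp(rng.normal(size=(n, L))),
            index=pd.Index(gm.participant_ids, name="participant_id"),
            columns=[f"L{j}" for j in range(L)],
        )
        lm = LipidomeMatrix(Y)
        cov = pd.DataFrame(
            {"age": rng.normal(40, 5, n), "sex": rng.integers(0, 2, n)},
            index=Y.index,
        )
        return gm, lm, cov

    def test_cardinality_and_validity(self, rng):
        gm, lm, cov = self.make_inputs(rng, m=100, L=10)
        table = b.run_gwas(gm, lm, cov)
        assert len(table.records) <= 1000
        assert ((table.records["p"] > 0) & (table.records["p"] <= 1)).all()
        assert (table.records["se"] > 0).all()

    def test_vectorized_equals_per_pair_fit(self, rng):
        gm, lm, cov = self.make_inputs(rng)
        table = b.run_gwas(gm, lm, cov)
        sub = table.records.sample(20, random_state=1)
        for _, row in sub.iterrows():
            j = gm.snp_index(row["snp"])
            rec = b.fit_snp_lipid(gm.dosages[:, j], lm.concentrations[row["lipid"]], cov)
            assert row["beta"] == pytest.approx(rec.beta, abs=1e-10)
            assert row["se"] == pytest.approx(rec.se, abs=1e-10)
            assert row["p"] == pytest.approx(rec.p, abs=1e-10, rel=1e-8)

    def test_missing_dosages_complete_case(self, rng):
        gm, lm, cov = self.make_inputs(rng, missing=True)
        table = b.run_gwas(gm, lm, cov)
        with_nan = [s for j, s in enumerate(gm.snp_ids) if np.isnan(gm.dosages[:, j]).any()]
        assert with_nan  # fixture actually exercises the fallback
        row = table.records[table.records["snp"] == with_nan[0]].iloc[0]
        j = gm.snp_index(with_nan[0])
        rec = b.fit_snp_lipid(gm.dosages[:, j], lm.concentrations[row["lipid"]], cov)
        assert row["beta"] == pytest.approx(rec.beta, abs=1e-10)
        assert row["n"] == rec.n < gm.n_participants

    def test_scale_equivariance(self, rng):
        gm, lm, cov = self.make_inputs(rng)
        t1 = b.run_gwas(gm, lm, cov).records
        lm2 = LipidomeMatrix(lm.concentrations * 2.0, lm.classes)
        t2 = b.run_gwas(gm, lm2, cov).records
        np.testing.assert_allclose(t2["beta"], 2 * t1["beta"], rtol=1e-10)
        np.testing.assert_allclose(t2["se"], 2 * t1["se"], rtol=1e-10)
        np.testing.assert_allclose(t2["p"], t1["p"], rtol=1e-8)

    def test_determinism(self, rng):
        gm, lm, cov = self.make_inputs(rng)
        t1 = b.run_gwas(gm, lm, cov).records
        t2 = b.run_gwas(gm, lm, cov).records
        pd.testing.assert_frame_equal(t1, t2)


class TestPreselect:
    def make_table(self, snp_ps):
        rows = [
            {"snp": s, "lipid": "L1", "beta": 0.1, "se": 0.05, "p": p, "n": 100}
            for s, p in snp_ps.items()
        ]
        return b.GwasTable(pd.DataFrame(rows))

    def test_threshold_and_cap(self):
        tab = self.make_table({"a": 1e-6, "b": 1e-5, "c": 1e-4, "d": 6e-4, "e": 0.1})
        assert b.preselect_snps(tab, 5e-4, cap=2) == ["a", "b"]
        assert b.preselect_snps(tab, 5e-4, cap=10) == ["a", "b", "c"]

    def test_empty_selection(self):
        tab = self.make_table({"a": 0.9, "b": 0.5})
        assert b.preselect_snps(tab, 5e-4) == []

    def test_cap_exact(self, rng):
        ps = {f"s{i:05d}": 10.0 ** (-5 - rng.random()) for i in range(2500)}
        tab = self.make_table(ps)
        out = b.preselect_snps(tab, 5e-4, cap=2000)
        assert len(out) == 2000
        # brute-force oracle: smallest per-SNP min p
        want = sorted(sorted(ps, key=lambda s: (ps[s], s))[:2000])
        assert out == want

    def test_monotone_in_threshold(self):
        tab = self.make_table({"a": 1e-6, "b": 1e-4, "c": 4e-4, "d": 0.01})
        s1 = set(b.preselect_snps(tab, 1e-5))
        s2 = set(b.preselect_snps(tab, 5e-4))
        assert s1 <= s2


@pytest.mark.parametrize(
    "alpha,n_ph,expected",
    [(5e-8, 437, 1.1e-10), (0.05, 1, 0.05), (5e-8, 100, 5e-10)],
)
def test_study_wide_threshold(alpha, n_ph, expected):
    assert b.study_wide_threshold(alpha, n_ph) == expected


def test_study_wide_threshold_domain():
    with pytest.raises(DomainError):
        b.study_wide_threshold(0.0, 10)


def test_null_pvalues_uniform_small():
    """Permutation-null GWAS p-values are Uniform(0,1) (KS p > 0.01)."""
    rng = np.random.default_rng(314)
    n, m, L = 150, 100, 5
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    gm = make_gm(X)
    Y = pd.DataFrame(
        rng.normal(size=(n, L)) + 10,
        index=pd.Index(gm.participant_ids, name="participant_id"),
        columns=[f"L{j}" for j in range(L)],
    )
    table = b.run_gwas(gm, LipidomeMatrix(Y), None)
    assert stats.kstest(table.records["p"], "uniform").pvalue > 0.01
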