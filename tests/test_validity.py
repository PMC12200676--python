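import numpy as np
import pandas as pd
import pytest

from kidbank.data import CovariateTable, DataError, PHQ_GAD_COLS
from kidbank.scoring import ScoreSet
from kidbank.validity import (criterion_regression, impute,
                              part_correlation, rubin_pool)


def _cov_table(n, rng, miss_income=0.0, miss_phq=0.0):
    t = pd.DataFrame({
        "child_id": [f"c{i}" for i in range(n)],
        "age_months": rng.integers(0, 72, n),
        "income": rng.lognormal(11, 0.7, n),
        "education": rng.choice(["no_hs", "hs", "some_college_aa", "ba",
                                 "ma_plus"], n),
        "race_ethnicity": rng.choice(["white_nh", "black_nh", "other_nh",
                                      "hispanic"], n),
    })
    for c in PHQ_GAD_COLS:
        t[c] = rng.integers(0, 4, n).astype(float)
    if miss_income:
        t.loc[rng.random(n) < miss_income, "income"] = np.nan
    if miss_phq:
        t.loc[rng.random(n) < miss_phq, list(PHQ_GAD_COLS)] = np.nan
    return CovariateTable(t)


def _score_set(eap, ages):
    n = len(eap)
    return ScoreSet(pd.DataFrame({
        "child_id": [f"c{i}" for i in range(n)],
        "eap": eap, "csem": np.full(n, 0.3), "age_months": ages,
        "n_items_answered": np.full(n, 20)}))


class TestPartCorrelation:
    def test_identity_gives_one(self):
        rng = np.random.default_rng(0)
        ages = rng.integers(0, 72, 200).astype(float)
        x = rng.normal(0, 1, 200)
        r = part_correlation(x, x, ages)
        assert r.r == pytest.approx(1.0, abs=1e-12)

    def test_age_induced_correlation_removed(self):
        rng = np.random.default_rng(1)
        n = 5000
        ages = rng.integers(0, 72, n).astype(float)
        x = 0.05 * ages + rng.normal(0, 1, n)
        y = 0.07 * ages + rng.normal(0, 1, n)
        raw = np.corrcoef(x, y)[0, 1]
        res = part_correlation(x, y, ages)
        assert raw > 0.4          # strongly correlated through age
        assert abs(res.r) < 0.05  # gone after residualization

    def test_known_partial_correlation_recovered(self):
        rng = np.random.default_rng(2)
        n = 5000
        ages = rng.integers(0, 72, n).astype(float)
        z = rng.normal(0, 1, n)
        rho = 0.70
        x = 0.04 * ages + z
        y = 0.02 * ages + rho * z + np.sqrt(1 - rho ** 2) * rng.normal(
            0, 1, n)
        res = part_correlation(x, y, ages)
        assert res.r == pytest.approx(rho, abs=0.03)

    def test_symmetry_both_residualized(self):
        rng = np.random.default_rng(3)
        n = 300
        ages = rng.integers(0, 72, n).astype(float)
        x = rng.normal(0, 1, n) + 0.02 * ages
        y = rng.normal(0, 1, n) - 0.01 * ages
        rxy = part_correlation(x, y, ages)
        ryx = part_correlation(y, x, ages)
        assert rxy.r == pytest.approx(ryx.r, abs=1e-12)

    def test_missing_pairs_dropped_and_min_n(self):
        with pytest.raises(DataError):
            part_correlation([1, 2, np.nan], [1, 2, 3], [10, 20, 30])

    def test_threshold_verdicts(self):
        rng = np.random.default_rng(4)
        ages = rng.integers(0, 72, 400).astype(float)
        x = rng.normal(0, 1, 400)
        res = part_correlation(x, x, ages)
        assert res.verdict() == "ideal"


class TestRubin:
    def test_worked_example(self):
        # m=3, estimates {1.0, 1.2, 0.8}, within-variances {.04,.05,.03}
        qbar, W, B, T, df = rubin_pool([1.0, 1.2, 0.8], [0.04, 0.05, 0.03])
        assert qbar == pytest.approx(1.0)
        assert W == pytest.approx(0.04)
        assert B == pytest.approx(0.04)
        assert T == pytest.approx(0.04 + (4 / 3) * 0.04)

    def test_total_variance_at_least_within(self):
        rng = np.random.default_rng(5)
        q = rng.normal(0, 1, 10)
        u = rng.uniform(0.1, 0.5, 10)
        _, W, B, T, _ = rubin_pool(q, u)
        assert T >= W
        # equality iff between-variance is zero
        _, W0, B0, T0, _ = rubin_pool([2.0] * 5, [0.3] * 5)
        assert B0 == 0 and T0 == pytest.approx(W0)


class TestImpute:
    def test_no_missingness_identity(self):
        rng = np.random.default_rng(6)
        cov = _cov_table(200, rng)
        s = impute(cov, m=3, seed=1)
        for ds in s.datasets:
            pd.testing.assert_frame_equal(ds, cov.table)

    def test_observed_cells_preserved_and_range(self):
        rng = np.random.default_rng(7)
        cov = _cov_table(400, rng, miss_income=0.1, miss_phq=0.1)
        s = impute(cov, m=4, seed=2)
        obs_inc = cov.table["income"].notna()
        for ds in s.datasets:
            assert not ds[["income", *PHQ_GAD_COLS]].isna().any().any()
            np.testing.assert_allclose(ds.loc[obs_inc, "income"],
                                       cov.table.loc[obs_inc, "income"])
            for c in PHQ_GAD_COLS:
                assert ds[c].isin([0.0, 1.0, 2.0, 3.0]).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        cov = _cov_table(300, rng, miss_income=0.1)
        a = impute(cov, m=2, seed=9)
        b = impute(cov, m=2, seed=9)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)

    def test_excessive_missingness_guard(self):
        rng = np.random.default_rng(9)
        cov = _cov_table(200, rng, miss_income=0.7)
        with pytest.raises(DataError, match="missing"):
            impute(cov, m=2, seed=0)


class TestCriterionRegression:
    def _fixture(self, rng, n=1500, miss=True):
        cov = _cov_table(n, rng,
                         miss_income=0.1 if miss else 0.0,
                         miss_phq=0.1 if miss else 0.0)
        ages = cov.table["age_months"].to_numpy(float)
        eap = 0.03 * ages + rng.normal(0, 1, n)
        return cov, _score_set(eap, ages)

    def test_no_missingness_equals_single_fit(self):
        rng = np.random.default_rng(10)
        cov, ss = self._fixture(rng, miss=False)
        pooled = criterion_regression(ss, impute(cov, m=3, seed=0))
        assert (pooled.coefficients["between_var"] < 1e-20).all()

    def test_zero_effect_covariate_null_distribution(self):
        rng = np.random.default_rng(11)
        hits = 0
        reps = 20
        for rep in range(reps):
            cov, ss = self._fixture(np.random.default_rng(100 + rep), n=800,
                                    miss=False)
            pooled = criterion_regression(ss, impute(cov, m=2, seed=rep),
                                          blocks=["phq_gad"])
            if abs(pooled.get("phq_gad_total")["t"]) > 1.96:
                hits += 1
        assert hits <= 5  # ~5% nominal, wide Monte-Carlo tolerance

    def test_reference_reparameterization_invariance(self):
        """Changing the education reference changes contrasts but not the
        fitted values of the regression."""
        import statsmodels.api as sm
        from kidbank.splines import AgeBasis
        rng = np.random.default_rng(12)
        cov, ss = self._fixture(rng, n=800, miss=False)
        df = cov.table.merge(ss.table[["child_id", "eap"]], on="child_id")
        ages = df["age_months"].to_numpy(float)
        X_age = AgeBasis().fit_transform(ages)
        y = df["eap"].to_numpy(float)

        def fitted(ref):
            levels = ["no_hs", "hs", "some_college_aa", "ba", "ma_plus"]
            cols = [np.ones(len(df))] + [X_age[:, i]
                                         for i in range(X_age.shape[1])]
            for lev in levels:
                if lev != ref:
                    cols.append((df["education"] == lev).to_numpy(float))
            return sm.OLS(y, np.column_stack(cols)).fit().fittedvalues

        np.testing.assert_allclose(fitted("ba"), fitted("hs"), atol=1e-8)

    def test_missing_reference_category_errors(self):
        rng = np.random.default_rng(13)
        cov, ss = self._fixture(rng, n=300, miss=False)
        t = cov.table.copy()
        t.loc[t["education"] == "ba", "education"] = "ma_plus"
        cov2 = CovariateTable(t)
        with pytest.raises(DataError, match="reference"):
            criterion_regression(ss, impute(cov2, m=2, seed=0),
                                 blocks=["education"])

    def test_effect_recovery_with_imputation(self):
        """MCAR missingness: pooled estimate close to the generating
        per-unit effect of the PHQ/GAD total."""
        rng = np.random.default_rng(14)
        n = 4000
        cov = _cov_table(n, rng, miss_phq=0.108)
        t = cov.table
        tot = t[list(PHQ_GAD_COLS)].sum(axis=1, skipna=False)
        tot_f = tot.fillna(tot.mean()).to_numpy()
        ages = t["age_months"].to_numpy(float)
        beta = -0.128
        eap = 0.03 * ages + beta * (tot_f - tot_f.mean()) \
            + rng.normal(0, 1, n)
        ss = _score_set(eap, ages)
        pooled = criterion_regression(ss, impute(cov, m=5, seed=3),
                                      blocks=["phq_gad"])
        row = pooled.get("phq_gad_total")
        assert row["estimate"] == pytest.approx(beta,
                                                abs=2.5 * row["total_se"])
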