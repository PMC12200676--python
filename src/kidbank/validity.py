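"""Age-adjusted validity correlations and criterion regressions with
multiple imputation.

Part correlations
-----------------
Concurrent/predictive validity is summarized by the correlation between
the ability score and an external instrument's score after adjusting for
the child's age: both variables are residualized on the natural-cubic age
spline (the one-sided semipartial is available by flag) and the Pearson
correlation of the residuals is reported, with a Fisher-z standard error
whose degrees of freedom are reduced by the basis dimension.  Reports
label correlations against the conventional r >= .70 (ideal) and
r >= .50 (minimum) convergent-validity thresholds.

Criterion regressions
---------------------
Associations of scores with family income (log scale), caregiver
education (bachelor's reference), child race/ethnicity (white
non-Hispanic reference), and the PHQ-2/GAD-2 total are estimated by OLS
of the EAP score on the age spline plus one criterion block at a time.
Missing income and PHQ/GAD items are handled by chained-equations
multiple imputation with predictive mean matching (m = 10 datasets),
and results are pooled by Rubin's rules with Barnard-Rubin degrees of
freedom.  Standardized effect sizes divide each coefficient by the
age-conditional SD of the scores (the SD of score residuals after the
age spline).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import (CovariateTable, DataError, EDUCATION_LEVELS, PHQ_GAD_COLS,
                   RACE_ETHNICITY)
from .splines import AgeBasis, DEFAULT_KNOTS

IDEAL_R = 0.70
MINIMUM_R = 0.50


# ---------------------------------------------------------------------------
# Part correlations
# ---------------------------------------------------------------------------

@dataclass
class PartCorrelationResult:
    x_name: str
    y_name: str
    r: float
    se: float
    n: int
    method: str  # "both_residualized" or "one_residualized"
    p: float

    def verdict(self, ideal=IDEAL_R, minimum=MINIMUM_R):
        a = abs(self.r)
        if a >= ideal:
            return "ideal"
        if a >= minimum:
            return "acceptable"
        return "below_minimum"

    def to_dict(self):
        return {"x": self.x_name, "y": self.y_name, "r": self.r,
                "se": self.se, "n": self.n, "method": self.method,
                "p": self.p, "verdict": self.verdict()}


def _residualize(v, X):
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def part_correlation(x, y, ages, method="both_residualized",
                     knots=DEFAULT_KNOTS, x_name="x", y_name="y"):
    """Age-adjusted correlation between two score columns.

    ``method="both_residualized"`` removes the age spline from both
    variables (the default reading of a correlation "after adjusting for
    age"); ``"one_residualized"`` removes it from ``x`` only (the
    semipartial with respect to x).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ages = np.asarray(ages, float)
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(ages))
    x, y, ages = x[keep], y[keep], ages[keep]
    n = len(x)
    if n < 4:
        raise DataError("need at least 4 complete (x, y, age) triples")
    basis = AgeBasis(knots=tuple(knots))
    Xs = basis.fit_transform(ages)
    X = np.column_stack([np.ones(n), Xs])
    p = X.shape[1] - 1  # age-adjustment dimension beyond the intercept
    rx = _residualize(x, X)
    ry = _residualize(y, X) if method == "both_residualized" else y - y.mean()
    if rx.std() == 0 or ry.std() == 0:
        raise DataError("constant residuals; correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 3 - p
    if dof < 1:
        raise DataError("not enough residual degrees of freedom")
    se_z = 1.0 / np.sqrt(dof)
    se_r = (1 - r ** 2) * se_z
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    pval = float(2 * sps.norm.sf(abs(z) / se_z))
    return PartCorrelationResult(x_name=x_name, y_name=y_name, r=r,
                                 se=float(se_r), n=n, method=method, p=pval)


# ---------------------------------------------------------------------------
# Multiple imputation (chained equations, predictive mean matching)
# ---------------------------------------------------------------------------

@dataclass
class ImputationSet:
    """m completed covariate tables; observed cells identical across them."""

    datasets: list          # list of DataFrames
    m: int
    seed: int
    imputed_columns: list

    def __iter__(self):
        return iter(self.datasets)


def _pmm_impute(target, X, miss, rng, k=5, integer_clip=None):
    """One predictive-mean-matching draw for a single variable.

    Bayesian linear regression draw on the observed rows, nearest-k donor
    matching on predicted values.
    """
    obs = ~miss
    Xo, yo = X[obs], target[obs]
    n_o, p = Xo.shape
    XtX = Xo.T @ Xo + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(n_o - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(XtX)
    beta_star = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    pred_obs = Xo @ beta_hat
    pred_mis = X[miss] @ beta_star
    out = target.copy()
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    for i, pm in zip(np.flatnonzero(miss), pred_mis):
        pos = np.searchsorted(sorted_pred, pm)
        lo = max(pos - k, 0)
        hi = min(pos + k, n_o)
        cand = order[lo:hi]
        # k nearest by predicted value
        nearest = cand[np.argsort(np.abs(sorted_pred[lo:hi] - pm))[:k]]
        donor = nearest[rng.integers(len(nearest))]
        val = yo[donor]
        if integer_clip is not None:
            val = float(np.clip(np.rint(val), *integer_clip))
        out[i] = val
    return out


def impute(covariates: CovariateTable, m=10, seed=0, cycles=10, k=5,
           scores=None, max_missing=0.5):
    """Chained-equations imputation of income (log scale) and the PHQ/GAD
    items, with predictive mean matching (k donors).

    Predictors: age spline, education and race/ethnicity dummies, the
    other incomplete variables at their current imputed values, and the
    EAP score when ``scores`` (a ScoreSet) is supplied.
    """
    t = covariates.table.copy()
    target_cols = [c for c in ["income", *PHQ_GAD_COLS] if c in t.columns]
    incomplete = [c for c in target_cols if t[c].isna().any()]
    other = [c for c in t.columns
             if c not in ("child_id", "income", *PHQ_GAD_COLS)]
    for c in other:
        if t[c].isna().any():
            raise DataError(
                f"unexpected missingness in {c!r}; only income and PHQ/GAD "
                "items may be incomplete")
    for c in incomplete:
        frac = t[c].isna().mean()
        if frac > max_missing:
            raise DataError(f"{c!r} has {frac:.0%} missing (> {max_missing:.0%})")

    basis = AgeBasis()
    Xage = basis.fit_transform(t["age_months"].to_numpy(float))
    fixed = [np.ones(len(t)), Xage]
    if "education" in t.columns:
        for lev in EDUCATION_LEVELS[1:]:
            fixed.append((t["education"] == lev).to_numpy(float))
    if "race_ethnicity" in t.columns:
        for lev in RACE_ETHNICITY[1:]:
            fixed.append((t["race_ethnicity"] == lev).to_numpy(float))
    if scores is not None:
        s = scores.table.set_index("child_id").loc[t["child_id"], "eap"]
        fixed.append(s.to_numpy(float))
    Xfixed = np.column_stack(fixed)

    # working values on the modelling scale (income -> log income)
    work = {}
    missmask = {}
    for c in target_cols:
        v = t[c].to_numpy(float)
        if c == "income":
            v = np.log(np.clip(v, 1.0, None))
        missmask[c] = np.isnan(v)
        work[c] = v

    rng_master = np.random.default_rng(seed)
    datasets = []
    for _ in range(m):
        rng = np.random.default_rng(rng_master.integers(2 ** 31))
        cur = {c: v.copy() for c, v in work.items()}
        # initial fill: random observed donors
        for c in incomplete:
            obs_vals = cur[c][~missmask[c]]
            cur[c][missmask[c]] = rng.choice(obs_vals, missmask[c].sum())
        for _cyc in range(cycles):
            for c in incomplete:
                others = [cur[o] for o in target_cols if o != c]
                X = np.column_stack([Xfixed] + others) if others else Xfixed
                clip = (0, 3) if c in PHQ_GAD_COLS else None
                cur[c] = _pmm_impute(cur[c], X, missmask[c], rng, k=k,
                                     integer_clip=clip)
        done = t.copy()
        for c in target_cols:
            done[c] = np.exp(cur[c]) if c == "income" else cur[c]
            if c == "income":
                done.loc[~missmask[c], c] = t.loc[~missmask[c], c]
        datasets.append(done)
    return ImputationSet(datasets=datasets, m=m, seed=seed,
                         imputed_columns=incomplete)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass
class PooledCoefficient:
    term: str
    estimate: float
    within_var: float
    between_var: float
    total_se: float
    df: float
    t: float
    p: float
    es: float = np.nan


def rubin_pool(estimates, variances, n_obs=None, n_params=None):
    """Pool point estimates and variances across imputations.

    Returns (qbar, W, B, T, df) with the Barnard-Rubin small-sample df when
    ``n_obs``/``n_params`` are given (df = complete-data residual df),
    otherwise the classic large-sample df.
    """
    q = np.asarray(estimates, float)
    u = np.asarray(variances, float)
    m = len(q)
    qbar = q.mean()
    W = u.mean()
    B = q.var(ddof=1) if m > 1 else 0.0
    T = W + (1 + 1 / m) * B
    if B == 0 or m == 1:
        df = np.inf if n_obs is None else max(n_obs - n_params, 1)
        return qbar, W, B, T, df
    lam = (1 + 1 / m) * B / T
    df_old = (m - 1) / lam ** 2
    if n_obs is None:
        return qbar, W, B, T, df_old
    dfcom = n_obs - n_params
    df_obs = (dfcom + 1) / (dfcom + 3) * dfcom * (1 - lam)
    df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    return qbar, W, B, T, df


# ---------------------------------------------------------------------------
# Criterion regressions
# ---------------------------------------------------------------------------

CRITERION_BLOCKS = {
    "income": ["log_income"],
    "education": [f"education[{lev}]" for lev in EDUCATION_LEVELS
                  if lev != "ba"],
    "race_ethnicity": [f"race_ethnicity[{lev}]" for lev in RACE_ETHNICITY
                       if lev != "white_nh"],
    "phq_gad": ["phq_gad_total"],
}


@dataclass
class PooledModelResult:
    """Rubin-pooled criterion-regression coefficients, one block at a time."""

    coefficients: pd.DataFrame   # term, estimate, W, B, total_se, df, t, p, es
    m: int
    n: int
    age_conditional_sd: float

    def summary(self):
        return self.coefficients

    def get(self, term):
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]

    def to_csv(self, path):
        self.coefficients.to_csv(path, index=False)


def _block_design(df, block, basis_X):
    n = len(df)
    cols, names = [np.ones(n)], ["intercept"]
    for i in range(basis_X.shape[1]):
        cols.append(basis_X[:, i])
        names.append(f"age_s{i+1}")
    if block == "income":
        cols.append(np.log(np.clip(df["income"].to_numpy(float), 1.0, None)))
        names.append("log_income")
    elif block == "education":
        if not (df["education"] == "ba").any():
            raise DataError("reference education category 'ba' absent")
        for lev in EDUCATION_LEVELS:
            if lev == "ba":
                continue
            cols.append((df["education"] == lev).to_numpy(float))
            names.append(f"education[{lev}]")
    elif block == "race_ethnicity":
        if not (df["race_ethnicity"] == "white_nh").any():
            raise DataError("reference race/ethnicity 'white_nh' absent")
        for lev in RACE_ETHNICITY:
            if lev == "white_nh":
                continue
            cols.append((df["race_ethnicity"] == lev).to_numpy(float))
            names.append(f"race_ethnicity[{lev}]")
    elif block == "phq_gad":
        tot = df[list(PHQ_GAD_COLS)].sum(axis=1, skipna=False).to_numpy(float)
        cols.append(tot)
        names.append("phq_gad_total")
    else:
        raise DataError(f"unknown criterion block {block!r}")
    return np.column_stack(cols), names


def criterion_regression(scores, imputations: ImputationSet,
                         blocks=None, knots=DEFAULT_KNOTS,
                         age_adjust="spline"):
    """OLS of the EAP score on the age spline plus one criterion block at a
    time, pooled over imputed datasets by Rubin's rules."""
    import statsmodels.api as sm

    if blocks is None:
        blocks = list(CRITERION_BLOCKS)
    rows = []
    m = imputations.m
    first = imputations.datasets[0]
    merged0 = first.merge(scores.table[["child_id", "eap"]], on="child_id")
    if merged0["eap"].isna().any() or len(merged0) < len(first):
        raise DataError("scores and covariates do not align on child_id")
    ages = merged0["age_months"].to_numpy(float)
    y = merged0["eap"].to_numpy(float)
    basis = AgeBasis(knots=tuple(knots))
    if age_adjust == "spline":
        basis_X = basis.fit_transform(ages)
    elif age_adjust == "linear":
        basis_X = (ages - ages.mean())[:, None]
    else:
        raise DataError("age_adjust must be 'spline' or 'linear'")
    # age-conditional SD of scores: residual SD after the age adjustment
    Xage = np.column_stack([np.ones(len(y)), basis_X])
    resid = _residualize(y, Xage)
    cond_sd = float(resid.std(ddof=Xage.shape[1]))

    for block in blocks:
        ests, cvars, names = [], [], None
        for ds in imputations.datasets:
            df = ds.merge(scores.table[["child_id", "eap"]], on="child_id")
            X, names = _block_design(df, block, basis_X)
            fit = sm.OLS(df["eap"].to_numpy(float), X).fit()
            ests.append(fit.params)
            cvars.append(np.diag(fit.cov_params()))
        ests = np.asarray(ests)
        cvars = np.asarray(cvars)
        n, kp = len(y), len(names)
        for c, term in enumerate(names):
            if term == "intercept" or term.startswith("age_s"):
                continue
            qbar, W, B, T, df_br = rubin_pool(ests[:, c], cvars[:, c],
                                              n_obs=n, n_params=kp)
            tval = qbar / np.sqrt(T)
            pval = float(2 * sps.t.sf(abs(tval), df_br)) \
                if np.isfinite(df_br) else float(2 * sps.norm.sf(abs(tval)))
            rows.append({"block": block, "term": term, "estimate": qbar,
                         "within_var": W, "between_var": B,
                         "total_se": float(np.sqrt(T)), "df": float(df_br),
                         "t": float(tval), "p": pval,
                         "es": qbar / cond_sd})
    coef = pd.DataFrame(rows)
    return PooledModelResult(coefficients=coef, m=m, n=len(y),
                             age_conditional_sd=cond_sd)


def pairwise_education_contrasts(scores, imputations, knots=DEFAULT_KNOTS):
    """Pairwise differences between education levels, pooled across
    imputations with Barnard-Rubin df (t-tests on pooled contrasts)."""
    import statsmodels.api as sm

    stab = scores.table[["child_id", "eap"]]
    first = imputations.datasets[0].merge(stab, on="child_id")
    ages = first["age_months"].to_numpy(float)
    basis = AgeBasis(knots=tuple(knots))
    basis_X = basis.fit_transform(ages)
    levels = [lev for lev in EDUCATION_LEVELS]
    rows = []
    ests, covs = [], []
    for ds in imputations.datasets:
        df = ds.merge(stab, on="child_id")
        X, names = _block_design(df, "education", basis_X)
        fit = sm.OLS(df["eap"].to_numpy(float), X).fit()
        ests.append(fit.params)
        covs.append(fit.cov_params())
    names_arr = names
    idx = {lev: names_arr.index(f"education[{lev}]")
           for lev in levels if lev != "ba"}
    n, kp = len(first), len(names_arr)
    for a_i in range(len(levels)):
        for b_i in range(a_i + 1, len(levels)):
            la, lb = levels[a_i], levels[b_i]
            qs, vs = [], []
            for e, V in zip(ests, covs):
                ca = np.zeros(len(names_arr))
                if la != "ba":
                    ca[idx[la]] = 1.0
                if lb != "ba":
                    ca[idx[lb]] -= 1.0
                qs.append(float(ca @ e))
                vs.append(float(ca @ V @ ca))
            qbar, W, B, T, df_br = rubin_pool(qs, vs, n_obs=n, n_params=kp)
            tval = qbar / np.sqrt(T)
            pval = float(2 * sps.t.sf(abs(tval), df_br)) \
                if np.isfinite(df_br) else float(2 * sps.norm.sf(abs(tval)))
            rows.append({"level_a": la, "level_b": lb, "difference": qbar,
                         "se": float(np.sqrt(T)), "df": float(df_br),
                         "t": float(tval), "p": pval})
    return pd.DataFrame(rows)


def validity_report(correlations, pooled: PooledModelResult, path=None):
    """Bundle part correlations and pooled criterion models into one JSON."""
    d = {
        "thresholds": {"ideal_r": IDEAL_R, "minimum_r": MINIMUM_R},
        "part_correlations": [c.to_dict() for c in correlations],
        "criterion_models": pooled.coefficients.to_dict(orient="records"),
        "age_conditional_sd": pooled.age_conditional_sd,
        "m_imputations": pooled.m,
        "n": pooled.n,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
    return d
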