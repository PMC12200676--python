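"""Marginal and age-conditional reliability of EAP scores.

Marginal reliability is the Thissen-Wainer empirical statistic

    r = Var(eap) / (Var(eap) + mean(csem^2)),

the proportion of observed score variance not attributable to measurement
error.  Because ability rises steeply with age, marginal reliability
overstates precision when children are compared with same-age peers; the
age-conditional reliability for child i is

    r_i = 1 - csem_i^2 / Var(eap | age_i),

where the age-conditional variance comes from a normal location-scale
model: eap ~ N(m(age), s(age)^2) with m and log s linear in the shared
natural-cubic age-spline basis, fitted by maximum likelihood (iterated
weighted least squares for the mean, Newton/Fisher scoring for the
log-scale).  The per-month expected reliability curve replaces csem_i^2
with a spline-smoothed E[csem^2 | age] and flags months falling below a
cutoff (default .80, the minimum tolerated for population-level use).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .splines import AgeBasis, DEFAULT_KNOTS


def marginal_reliability(scores):
    """Thissen-Wainer marginal reliability from EAP scores and CSEMs."""
    eap, csem = scores.eap, scores.csem
    if len(eap) < 2:
        raise ValueError("need at least 2 children")
    v = float(np.var(eap, ddof=1))
    if v == 0:
        raise ValueError("zero variance in EAP scores")
    e = float(np.mean(csem ** 2))
    return v / (v + e)


DEFAULT_SCALE_KNOTS = (36.0,)


@dataclass
class LocationScaleResults:
    """ML fit of y ~ N(m(age), s(age)^2) with spline mean and log-SD.

    The mean uses the full age basis; the log-SD uses a leaner spline
    (single interior knot by default) because variance functions estimated
    at the same flexibility as the mean are dominated by boundary noise.
    """

    mean_coef: np.ndarray
    logsd_coef: np.ndarray
    basis: AgeBasis
    scale_basis: AgeBasis
    loglik: float
    n_iter: int
    converged: bool

    def _design(self, basis, ages):
        X = basis.transform(np.asarray(ages, float))
        return np.column_stack([np.ones(len(X)), X])

    def predict_mean(self, ages):
        return self._design(self.basis, ages) @ self.mean_coef

    def predict_sd(self, ages):
        return np.exp(self._design(self.scale_basis, ages) @ self.logsd_coef)


class LocationScaleModel:
    """Normal location-scale spline model for heteroscedastic scores."""

    def __init__(self, y, ages, knots=DEFAULT_KNOTS,
                 scale_knots=DEFAULT_SCALE_KNOTS):
        self.y = np.asarray(y, float)
        self.ages = np.asarray(ages, float)
        self.basis = AgeBasis(knots=tuple(knots))
        Xm = self.basis.fit_transform(self.ages)
        self.X = np.column_stack([np.ones(len(Xm)), Xm])
        self.scale_basis = AgeBasis(knots=tuple(scale_knots))
        Xs = self.scale_basis.fit_transform(self.ages)
        self.Xs = np.column_stack([np.ones(len(Xs)), Xs])
        if len(self.y) < 5 * self.X.shape[1]:
            raise ValueError("too few observations for the basis dimension")

    def _loglik(self, beta, eta):
        mu = self.X @ beta
        logsd = self.Xs @ eta
        z = (self.y - mu) / np.exp(logsd)
        return float(np.sum(-logsd - 0.5 * z ** 2
                            - 0.5 * np.log(2 * np.pi)))

    def fit(self, max_iter=200, tol=1e-8):
        X, Xs, y = self.X, self.Xs, self.y
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        eta = np.zeros(Xs.shape[1])
        resid = y - X @ beta
        eta[0] = np.log(max(resid.std(), 1e-8))
        ll = self._loglik(beta, eta)
        converged = False
        # floor on the log-SD linear predictor: keeps the fit finite for
        # (near-)deterministic inputs such as a constant smoothed column
        lo = np.log(1e-8)
        for it in range(max_iter):
            # mean given scale: WLS with weights 1/s^2
            s2 = np.exp(2 * np.clip(Xs @ eta, lo, 50.0))
            W = 1.0 / s2
            XtW = X.T * W
            beta = np.linalg.solve(XtW @ X, XtW @ y)
            # scale given mean: Fisher scoring on eta
            e2 = (y - X @ beta) ** 2
            for _ in range(50):
                s2 = np.exp(2 * np.clip(Xs @ eta, lo, 50.0))
                u = e2 / s2 - 1.0           # per-obs score factor
                g = Xs.T @ u                # gradient
                FI = 2.0 * (Xs.T @ Xs)      # expected information
                step = np.linalg.solve(FI, g)
                eta_new = eta + step
                # dampen if overshooting
                while self._loglik(beta, eta_new) < self._loglik(beta, eta) - 1e-10:
                    step *= 0.5
                    eta_new = eta + step
                    if np.max(np.abs(step)) < 1e-12:
                        break
                eta = eta_new
                if eta[0] < lo:  # degenerate: essentially error-free fit
                    eta[0] = lo
                    break
                if np.max(np.abs(step)) < 1e-10:
                    break
            ll_new = self._loglik(beta, eta)
            if abs(ll_new - ll) < tol:
                ll = ll_new
                converged = True
                break
            ll = ll_new
        return LocationScaleResults(mean_coef=beta, logsd_coef=eta,
                                    basis=self.basis,
                                    scale_basis=self.scale_basis,
                                    loglik=ll, n_iter=it + 1,
                                    converged=converged)


def fit_location_scale(scores, knots=DEFAULT_KNOTS):
    """Fit the age-conditional location-scale model to EAP scores."""
    return LocationScaleModel(scores.eap, scores.ages, knots=knots).fit()


@dataclass
class ReliabilityReport:
    """Marginal and age-conditional reliability summary."""

    marginal_r: float
    mean_conditional_r_children: float     # averaged over children
    mean_conditional_r_ages: float         # averaged over months 0-71
    conditional_r_by_age: np.ndarray       # per-month curve
    ages_months: np.ndarray
    min_conditional_r: float
    age_at_min: int
    cutoff: float
    ages_below_cutoff: list = field(default_factory=list)
    per_child_r: np.ndarray = None

    def to_json(self, path=None):
        d = {
            "marginal_r": self.marginal_r,
            "mean_conditional_r_children": self.mean_conditional_r_children,
            "mean_conditional_r_ages": self.mean_conditional_r_ages,
            "min_conditional_r": self.min_conditional_r,
            "age_at_min": int(self.age_at_min),
            "cutoff": self.cutoff,
            "ages_below_cutoff": [int(a) for a in self.ages_below_cutoff],
            "conditional_r_by_age": [float(v) for v in
                                     self.conditional_r_by_age],
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=2)
        return d

    def curve_frame(self):
        import pandas as pd
        return pd.DataFrame({"age_month": self.ages_months,
                             "r": self.conditional_r_by_age})

    def plot(self, ax=None):
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ages_months, self.conditional_r_by_age, lw=2)
        ax.axhline(self.cutoff, ls="--", color="grey")
        ax.axhline(self.marginal_r, ls=":", color="black")
        ax.set_xlabel("age (months)")
        ax.set_ylabel("conditional reliability")
        ax.set_ylim(0, 1)
        return ax


def conditional_reliability(scores, ls: LocationScaleResults, cutoff=0.80,
                            knots=DEFAULT_KNOTS):
    """Age-conditional reliability per child and per month.

    Per child: r_i = 1 - csem_i^2 / s(age_i)^2 with s from the EAP
    location-scale fit.  The per-month expected curve smooths csem^2 on age
    with the same location-scale machinery and evaluates
    1 - E[csem^2|age] / s(age)^2 at each month.
    """
    ages = scores.ages
    s2 = ls.predict_sd(ages) ** 2
    if np.any(s2 <= 0):
        raise ValueError("fitted age-conditional SD must be positive")
    r_child = 1.0 - scores.csem ** 2 / s2

    months = np.arange(0, 72)
    # smooth csem^2 on age (same spline ML machinery)
    sm = LocationScaleModel(scores.csem ** 2, ages, knots=knots).fit()
    e_csem2 = np.clip(sm.predict_mean(months), 1e-10, None)
    s2_m = ls.predict_sd(months) ** 2
    curve = 1.0 - e_csem2 / s2_m

    below = months[curve < cutoff].tolist()
    imin = int(np.argmin(curve))
    return ReliabilityReport(
        marginal_r=marginal_reliability(scores),
        mean_conditional_r_children=float(np.mean(r_child)),
        mean_conditional_r_ages=float(np.mean(curve)),
        conditional_r_by_age=curve,
        ages_months=months,
        min_conditional_r=float(curve[imin]),
        age_at_min=int(months[imin]),
        cutoff=float(cutoff),
        ages_below_cutoff=below,
        per_child_r=r_child,
    )
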