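"""Graded-response IRT model with a latent regression of ability on age.

Model
-----
For child i with latent ability theta_i and item j with K_j ordered
response categories, the cumulative category probabilities are logistic,

    Pr(Y_j >= k | theta) = expit(alpha_j * (theta - delta_jk)),  0 < k <= K_j - 1,

with Pr(Y >= 0) = 1 and Pr(Y >= K_j) = 0, so category probabilities are the
telescoping differences of adjacent cumulative curves.  Ability has a
normal prior whose mean is a natural-cubic-spline function of age,

    theta_i ~ N(x_i' gamma, 1),

with the spline design centered so fitted prior means average zero and the
residual SD fixed at 1 (identification: location and scale of the latent
metric live in the item thresholds/discriminations).

Estimation is marginal maximum likelihood via EM.  The latent ability is
integrated on a fixed rectangular grid of equally spaced nodes spanning
every child's prior mean +/- 6; each child carries normalized prior weights
on the common grid.  Missing responses simply contribute nothing to the
likelihood.  The M-step maximizes the expected complete-data log-likelihood
per item by quasi-Newton on a monotonicity-preserving reparameterization
(log alpha; first threshold free; log increments), and updates gamma by
least squares of posterior ability means on the age basis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .data import ItemBank, ResponseMatrix, DataError
from .splines import AgeBasis, DEFAULT_KNOTS

_PCLIP = 1e-12


# ---------------------------------------------------------------------------
# Category probabilities
# ---------------------------------------------------------------------------

def grm_category_probs(alpha, delta, theta):
    """Category probabilities of the graded-response model.

    Parameters
    ----------
    alpha : positive discrimination
    delta : strictly increasing thresholds, length K-1
    theta : scalar or array of abilities

    Returns
    -------
    array of shape theta.shape + (K,), rows summing to 1.
    """
    alpha = float(alpha)
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    if alpha <= 0:
        raise ValueError("discrimination alpha must be > 0")
    if np.any(np.diff(delta) <= 0):
        raise ValueError("thresholds delta must be strictly increasing")
    theta = np.asarray(theta, dtype=float)
    # cumulative curves: C[..., k] = P(Y >= k+1)
    c = expit(alpha * (theta[..., None] - delta))
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    cum = np.concatenate([ones, c, zeros], axis=-1)
    return -np.diff(cum, axis=-1)


# ---------------------------------------------------------------------------
# Item-parameter reparameterization and objectives
# ---------------------------------------------------------------------------

def pack_item(alpha, delta):
    """(alpha, delta) -> unconstrained vector (log alpha, d1, log increments)."""
    delta = np.atleast_1d(np.asarray(delta, float))
    t = np.empty(1 + len(delta))
    t[0] = np.log(alpha)
    t[1] = delta[0]
    if len(delta) > 1:
        t[2:] = np.log(np.diff(delta))
    return t


def unpack_item(t):
    alpha = np.exp(t[0])
    delta = np.empty(len(t) - 1)
    delta[0] = t[1]
    if len(delta) > 1:
        delta[1:] = delta[0] + np.cumsum(np.exp(t[2:]))
    return alpha, delta


def _prob_table(alpha, delta, nodes):
    """(K, Q) category probabilities on the grid."""
    c = expit(alpha * (nodes[None, :] - delta[:, None]))  # (K-1, Q)
    cum = np.vstack([np.ones_like(nodes), c, np.zeros_like(nodes)])
    return np.clip(cum[:-1] - cum[1:], _PCLIP, 1.0)


def _grad_to_t(dC, alpha, delta, nodes, t):
    """Chain gradient wrt cumulative curves C_k(q) into the reparameterized t.

    dC : (K-1, Q) partial derivatives of the objective wrt C_k at each node.
    """
    c = expit(alpha * (nodes[None, :] - delta[:, None]))
    b = c * (1 - c)
    g_alpha = np.sum(dC * b * (nodes[None, :] - delta[:, None]))
    g_delta = -alpha * np.sum(dC * b, axis=1)
    g = np.empty_like(t)
    g[0] = g_alpha * alpha  # d alpha / d log-alpha
    g[1] = g_delta.sum()    # all deltas shift with d1
    if len(t) > 2:
        inc = np.exp(t[2:])
        # delta_k depends on increment m for m <= k (0-based: delta[m..])
        g[2:] = np.array([g_delta[m:].sum() for m in range(1, len(delta))]) * inc
    return g


def _nll_counts(t, R, nodes):
    """Expected-count M-step objective: -sum R_kq log P_kq, with gradient."""
    alpha, delta = unpack_item(t)
    P = _prob_table(alpha, delta, nodes)
    val = -np.sum(R * np.log(P))
    U = R / P  # (K, Q)
    dC = U[:-1] - U[1:]  # derivative wrt C_k, k=1..K-1
    return val, _grad_to_t(dC, alpha, delta, nodes, t)


def optimize_item(R, nodes, t0, maxiter=100):
    """Maximize the expected complete-data log-likelihood for one item."""
    res = minimize(_nll_counts, t0, args=(R, nodes), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8})
    return res.x


def _nll_marginal_item(t, y, A, rowsum_rest, nodes):
    """Marginal NLL profile in one item's parameters, others fixed.

    A : (n_obs, Q) exp of rest-loglik + log prior weights (row-shifted);
    y : (n_obs,) responses to the item; rowsum_rest unused rows excluded.
    """
    alpha, delta = unpack_item(t)
    P = _prob_table(alpha, delta, nodes)  # (K, Q)
    Py = P[y]  # (n_obs, Q)
    s = np.einsum("iq,iq->i", A, Py)
    val = -np.sum(np.log(np.clip(s, 1e-300, None)))
    W = A / s[:, None]  # (n_obs, Q)
    K = P.shape[0]
    T = np.zeros_like(P)
    for k in range(K):
        m = y == k
        if m.any():
            T[k] = W[m].sum(axis=0)
    dC = T[:-1] - T[1:]
    return val, _grad_to_t(dC, alpha, delta, nodes, t)


def optimize_item_marginal(y, A, nodes, t0, ftol=1e-11, gtol=1e-7):
    res = minimize(_nll_marginal_item, t0, args=(y, A, None, nodes), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": ftol, "gtol": gtol})
    return res.x, -res.fun


# ---------------------------------------------------------------------------
# Parameters container
# ---------------------------------------------------------------------------

@dataclass
class GRMParameters:
    """Calibrated item and latent-regression parameters."""

    item_ids: list
    alpha: np.ndarray                 # (J,)
    delta: list                       # list of (K_j - 1,) arrays
    gamma: np.ndarray                 # (p,) latent-regression coefficients
    basis: AgeBasis                   # centered age-spline basis
    residual_sd: float = 1.0          # fixed at 1 for identification

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, float)
        self.delta = [np.atleast_1d(np.asarray(d, float)) for d in self.delta]
        self.gamma = np.asarray(self.gamma, float)
        if np.any(self.alpha <= 0):
            raise ValueError("all discriminations must be > 0")
        for d in self.delta:
            if len(d) > 1 and np.any(np.diff(d) <= 0):
                raise ValueError("thresholds must be strictly increasing")

    @property
    def n_items(self):
        return len(self.item_ids)

    def n_categories(self):
        return np.array([len(d) + 1 for d in self.delta])

    def prior_means(self, ages):
        return self.basis.transform(ages) @ self.gamma

    def save(self, path):
        d = {
            "items": [
                {"item_id": i, "alpha": float(a),
                 "delta": [float(v) for v in dl]}
                for i, a, dl in zip(self.item_ids, self.alpha, self.delta)],
            "gamma": [float(v) for v in self.gamma],
            "basis": self.basis.to_dict(),
            "residual_sd": self.residual_sd,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            item_ids=[it["item_id"] for it in d["items"]],
            alpha=np.array([it["alpha"] for it in d["items"]]),
            delta=[np.array(it["delta"]) for it in d["items"]],
            gamma=np.array(d["gamma"]),
            basis=AgeBasis.from_dict(d["basis"]),
            residual_sd=d.get("residual_sd", 1.0),
        )


@dataclass
class QuadratureGrid:
    """Common ability grid with per-child normalized log prior weights."""

    nodes: np.ndarray
    log_weights: np.ndarray  # (n, Q), rows normalized

    @classmethod
    def build(cls, prior_means, n_nodes=101, pad=6.0):
        mu = np.asarray(prior_means, float)
        lo, hi = mu.min() - pad, mu.max() + pad
        nodes = np.linspace(lo, hi, n_nodes)
        lw = -0.5 * (nodes[None, :] - mu[:, None]) ** 2
        lw -= logsumexp(lw, axis=1, keepdims=True)
        return cls(nodes=nodes, log_weights=lw)


# ---------------------------------------------------------------------------
# Likelihood pieces shared by fitting, scoring, and invariance testing
# ---------------------------------------------------------------------------

def response_logprob_grid(Y, alpha, delta, nodes):
    """(n, Q) log-likelihood of each child's observed responses on the grid.

    Y : dense (n, J) responses with -1 for missing.
    """
    n, J = Y.shape
    LL = np.zeros((n, len(nodes)))
    for j in range(J):
        yj = Y[:, j]
        m = yj >= 0
        if not m.any():
            continue
        logP = np.log(_prob_table(alpha[j], delta[j], nodes))
        LL[m] += logP[yj[m]]
    return LL


def marginal_loglik(params: GRMParameters, responses, bank, ages,
                    n_nodes=101, per_child=False):
    """Marginal log-likelihood sum_i log int prod_j P(Y_ij|theta) phi dtheta
    on the common rectangular grid."""
    Y, _ = _dense(responses, bank, ages)
    mu = params.prior_means(ages)
    grid = QuadratureGrid.build(mu, n_nodes=n_nodes)
    LL = response_logprob_grid(Y, params.alpha, params.delta, grid.nodes)
    li = logsumexp(LL + grid.log_weights, axis=1)
    return li if per_child else float(li.sum())


def _dense(responses, bank, ages):
    if isinstance(responses, ResponseMatrix):
        Y, child_ids = responses.to_dense(bank)
        if len(child_ids) != len(np.asarray(ages)):
            raise DataError("ages must align with the children in responses")
        return Y, child_ids
    Y = np.asarray(responses)
    return Y.astype(np.int16), list(range(Y.shape[0]))


# ---------------------------------------------------------------------------
# Model / results
# ---------------------------------------------------------------------------

class GradedResponseModel:
    """GRM with latent age regression, fitted by EM marginal ML.

    Parameters
    ----------
    responses : ResponseMatrix or dense (n, J) int array with -1 = missing
    bank : ItemBank
    ages : per-child age in months, aligned with the response rows
    knots : interior knots of the age spline (months)
    n_quadrature : number of equally spaced ability nodes
    """

    def __init__(self, responses, bank, ages, knots=DEFAULT_KNOTS,
                 n_quadrature=101, min_n=10):
        self.bank = bank
        self.ages = np.asarray(ages, float)
        self.Y, self.child_ids = _dense(responses, bank, self.ages)
        if self.Y.shape[0] < min_n:
            raise DataError(f"need at least {min_n} children to calibrate")
        self.n_quadrature = int(n_quadrature)
        self.knots = tuple(knots)
        self.Y, self.K, self.category_maps = _collapse_categories(
            self.Y, bank.n_categories, bank.item_ids)
        self.basis = AgeBasis(knots=self.knots)
        self.X = self.basis.fit_transform(self.ages)

    @classmethod
    def from_dataset(cls, bank, responses, covariates, **kw):
        Y, child_ids = responses.to_dense(bank)
        cov = covariates.table.set_index("child_id")
        ages = cov.loc[child_ids, "age_months"].to_numpy(float)
        m = cls(Y, bank, ages, **kw)
        m.child_ids = child_ids
        return m

    # -- EM ---------------------------------------------------------------

    def _start_values(self):
        J = self.Y.shape[1]
        alpha = np.ones(J)
        delta = []
        for j in range(J):
            yj = self.Y[:, j]
            obs = yj[yj >= 0]
            K = self.K[j]
            d = np.empty(K - 1)
            for k in range(1, K):
                p = np.clip((obs >= k).mean(), 0.02, 0.98)
                d[k - 1] = np.log((1 - p) / p)
            # enforce strict increase
            for k in range(1, K - 1):
                d[k] = max(d[k], d[k - 1] + 1e-3)
            delta.append(d)
        gamma = np.zeros(self.X.shape[1])
        return alpha, delta, gamma

    def fit(self, max_cycles=500, tol_param=1e-4, tol_loglik=1e-6,
            start=None, verbose=False):
        Y, X, K = self.Y, self.X, self.K
        n, J = Y.shape
        Q = self.n_quadrature
        if start is None:
            alpha, delta, gamma = self._start_values()
        else:
            alpha = start.alpha.copy()
            delta = [d.copy() for d in start.delta]
            gamma = start.gamma.copy()
        t = [pack_item(alpha[j], delta[j]) for j in range(J)]

        XtX_inv_Xt = np.linalg.pinv(X)
        onehot = [None] * J
        for j in range(J):
            m = Y[:, j] >= 0
            oh = np.zeros((n, K[j]))
            oh[np.flatnonzero(m), Y[m, j]] = 1.0
            onehot[j] = (m, oh[m])

        trace = []
        converged = False
        prev_vec = None
        for cycle in range(max_cycles):
            mu = X @ gamma
            grid = QuadratureGrid.build(mu, n_nodes=Q)
            LL = response_logprob_grid(Y, alpha, delta, grid.nodes)
            lw = LL + grid.log_weights
            li = logsumexp(lw, axis=1)
            trace.append(float(li.sum()))
            post = np.exp(lw - li[:, None])  # (n, Q)

            # M-step: items
            for j in range(J):
                m, oh = onehot[j]
                R = oh.T @ post[m]  # (K_j, Q)
                t[j] = optimize_item(R, grid.nodes, t[j])
                alpha[j], delta[j] = unpack_item(t[j])
            # M-step: latent regression (residual variance fixed at 1)
            theta_bar = post @ grid.nodes
            gamma = XtX_inv_Xt @ theta_bar

            vec = np.concatenate([np.concatenate(
                [np.atleast_1d(alpha[j]), delta[j]]) for j in range(J)]
                + [gamma])
            if prev_vec is not None:
                dparam = np.max(np.abs(vec - prev_vec))
                dll = trace[-1] - trace[-2] if len(trace) > 1 else np.inf
                if verbose:
                    print(f"cycle {cycle}: ll={trace[-1]:.6f} "
                          f"dparam={dparam:.2e}")
                if dparam < tol_param or abs(dll) < tol_loglik:
                    converged = True
                    break
            prev_vec = vec

        params = GRMParameters(item_ids=self.bank.item_ids, alpha=alpha,
                               delta=delta, gamma=gamma, basis=self.basis)
        # final log-likelihood at the returned parameters
        mu = X @ gamma
        grid = QuadratureGrid.build(mu, n_nodes=Q)
        LL = response_logprob_grid(Y, alpha, delta, grid.nodes)
        trace.append(float(logsumexp(LL + grid.log_weights, axis=1).sum()))
        if not converged:
            warnings.warn("EM did not converge within max_cycles",
                          RuntimeWarning)
        return GRMResults(model=self, params=params,
                          loglik_trace=np.array(trace),
                          n_cycles=len(trace) - 1, converged=converged)


@dataclass
class GRMResults:
    """Calibration results: parameters, likelihood trace, diagnostics."""

    model: GradedResponseModel
    params: GRMParameters
    loglik_trace: np.ndarray
    n_cycles: int
    converged: bool
    item_se: dict = field(default=None)

    @property
    def loglik(self):
        return float(self.loglik_trace[-1])

    def score(self, responses=None, bank=None, ages=None):
        """EAP scores for the calibration sample (or new data)."""
        from .scoring import score_eap
        if responses is None:
            ss = score_eap(self.params, self.model.Y, self.model.bank,
                           self.model.ages,
                           n_nodes=self.model.n_quadrature)
            ss.table["child_id"] = self.model.child_ids
            return ss
        return score_eap(self.params, responses, bank, ages)

    def item_standard_errors(self):
        """Approximate per-item SEs from the observed information of the
        marginal likelihood, holding other items and gamma fixed."""
        mdl = self.model
        p = self.params
        mu = p.prior_means(mdl.ages)
        grid = QuadratureGrid.build(mu, n_nodes=mdl.n_quadrature)
        LLall = response_logprob_grid(mdl.Y, p.alpha, p.delta, grid.nodes)
        out = {}
        for j, item in enumerate(p.item_ids):
            yj = mdl.Y[:, j]
            m = yj >= 0
            if not m.any():
                continue
            logP = np.log(_prob_table(p.alpha[j], p.delta[j], grid.nodes))
            rest = (LLall[m] - logP[yj[m]]) + grid.log_weights[m]
            shift = rest.max(axis=1, keepdims=True)
            A = np.exp(rest - shift)
            th0 = np.concatenate([[p.alpha[j]], p.delta[j]])

            def nll(v):
                a = max(v[0], 1e-6)
                d = np.sort(v[1:]) if len(v) > 2 else v[1:]
                P = _prob_table(a, d, grid.nodes)
                s = np.einsum("iq,iq->i", A, P[yj[m]])
                return -np.sum(np.log(np.clip(s, 1e-300, None)))

            H = _numerical_hessian(nll, th0)
            try:
                cov = np.linalg.inv(H)
                se = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:
                se = np.full(len(th0), np.nan)
            out[item] = {"alpha_se": se[0], "delta_se": se[1:]}
        self.item_se = out
        return out

    def summary(self):
        """Item-parameter table plus fit diagnostics."""
        import pandas as pd
        rows = []
        for i, a, d in zip(self.params.item_ids, self.params.alpha,
                           self.params.delta):
            rows.append({"item_id": i, "alpha": a,
                         **{f"delta_{k+1}": v for k, v in enumerate(d)}})
        tbl = pd.DataFrame(rows)
        tbl.attrs["loglik"] = self.loglik
        tbl.attrs["n_cycles"] = self.n_cycles
        tbl.attrs["converged"] = self.converged
        tbl.attrs["gamma"] = self.params.gamma.tolist()
        return tbl


def _numerical_hessian(f, x0, eps=1e-4):
    d = len(x0)
    H = np.empty((d, d))
    f0 = f(x0)
    for a in range(d):
        for b in range(a, d):
            ea = np.zeros(d); ea[a] = eps
            eb = np.zeros(d); eb[b] = eps
            H[a, b] = H[b, a] = (
                f(x0 + ea + eb) - f(x0 + ea) - f(x0 + eb) + f0) / eps ** 2
    return H


def _collapse_categories(Y, n_categories, item_ids):
    """Collapse unobserved categories so every remaining category has data."""
    Y = Y.copy()
    K = np.asarray(n_categories, int).copy()
    maps = {}
    for j in range(Y.shape[1]):
        yj = Y[:, j]
        obs = np.unique(yj[yj >= 0])
        if len(obs) == K[j]:
            continue
        if len(obs) < 2:
            raise DataError(
                f"item {item_ids[j]!r} has fewer than 2 observed categories")
        remap = {int(v): r for r, v in enumerate(np.sort(obs))}
        warnings.warn(
            f"item {item_ids[j]!r}: collapsing {K[j]} categories to "
            f"{len(obs)} observed", RuntimeWarning)
        m = yj >= 0
        Y[m, j] = np.array([remap[int(v)] for v in yj[m]], dtype=Y.dtype)
        K[j] = len(obs)
        maps[item_ids[j]] = remap
    return Y, K, maps


def fit_grm(responses, bank, ages, knots=DEFAULT_KNOTS, n_quadrature=101,
            **em_config):
    """Functional wrapper: calibrate the GRM and return GRMResults."""
    model = GradedResponseModel(responses, bank, ages, knots=knots,
                                n_quadrature=n_quadrature)
    return model.fit(**em_config)
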