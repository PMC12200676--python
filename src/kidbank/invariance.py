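"""Differential item functioning (DIF) screening and the partial-invariance
sensitivity analysis.

DIF detection is a likelihood-ratio procedure with anchor purification:

1. Fit a multi-group graded-response model with all item parameters
   constrained equal across groups and group ability distributions free
   (reference group fixed to mean 0, SD 1 for identification).
2. For each testable item, compare the constrained fit against a model in
   which that item's discrimination and thresholds are group-specific.
   The per-item likelihood ratio holds all other ("anchor") item
   parameters and the group ability distributions fixed at the current
   fit and maximizes the marginal likelihood over the tested item's
   parameters directly; df = K_j x (G - 1).
3. Flag items at Benjamini-Hochberg FDR, re-anchor on unflagged items
   (re-fitting with flagged items' parameters group-specific), and repeat
   until the flag set stabilizes (at most ``max_rounds`` rounds).

The sensitivity analysis asks whether ignoring DIF changes conclusions
about group differences: group ability means are estimated under full
invariance and under partial invariance (DIF items freed), and a Wald
chi-square tests the stacked difference of group contrasts, with the
covariance of the difference estimated by a paired nonparametric bootstrap
over children (anchor item parameters held at the full-data fits).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests

from .data import DataError
from .grm import (_dense, _prob_table, pack_item, unpack_item,
                  optimize_item, optimize_item_marginal)

DEFAULT_QUAD = 71


# ---------------------------------------------------------------------------
# Multi-group GRM
# ---------------------------------------------------------------------------

@dataclass
class MultigroupResults:
    """Multi-group calibration: per-group item parameters (identical rows for
    constrained items), group ability means/SDs, likelihood."""

    item_ids: list
    alpha: np.ndarray            # (G, J)
    delta: list                  # J arrays of shape (G, K_j - 1)
    group_labels: list
    group_means: np.ndarray      # (G,)
    group_sds: np.ndarray        # (G,)
    free_items: frozenset        # item indices with group-specific params
    loglik: float
    n_cycles: int
    converged: bool
    ref_group: object = None


class MultigroupGRM:
    """Graded-response model with group-specific ability distributions and
    optionally group-specific parameters for a set of freed items."""

    def __init__(self, responses, bank, groups, free_items=(),
                 n_quadrature=DEFAULT_QUAD, ref_group=None):
        self.bank = bank
        self.Y, self.child_ids = _dense(responses, bank, np.zeros(
            np.asarray(groups).shape[0]))
        groups = np.asarray(groups)
        if len(groups) != self.Y.shape[0]:
            raise DataError("groups must align with response rows")
        self.group_labels = sorted(pd.unique(groups).tolist())
        if len(self.group_labels) < 2:
            raise DataError("need at least 2 groups for invariance analysis")
        self.ref_group = self.group_labels[0] if ref_group is None else ref_group
        if self.ref_group not in self.group_labels:
            raise DataError(f"unknown reference group {self.ref_group!r}")
        # reference first
        self.group_labels = [self.ref_group] + [
            g for g in self.group_labels if g != self.ref_group]
        self.gidx = np.array([self.group_labels.index(g) for g in groups])
        self.G = len(self.group_labels)
        self.K = np.asarray(bank.n_categories, int)
        ids = bank.item_ids
        self.free = frozenset(
            i if isinstance(i, (int, np.integer)) else ids.index(i)
            for i in free_items)
        self.n_quadrature = int(n_quadrature)
        self._onehot = None

    # -- internals --------------------------------------------------------

    def _grid(self, mu, sd):
        lo = float(np.min(mu - 6 * sd))
        hi = float(np.max(mu + 6 * sd))
        return np.linspace(lo, hi, self.n_quadrature)

    def _log_prior(self, nodes, mu, sd):
        """(n, Q) normalized log prior weights."""
        z = (nodes[None, :] - mu[self.gidx, None]) / sd[self.gidx, None]
        lw = -0.5 * z ** 2 - np.log(sd[self.gidx, None])
        return lw - logsumexp(lw, axis=1, keepdims=True)

    def loglik_matrix(self, alpha, delta, nodes, skip_item=None):
        """(n, Q) summed item log-likelihoods (optionally excluding one item)."""
        n, J = self.Y.shape
        LL = np.zeros((n, len(nodes)))
        for j in range(J):
            if j == skip_item:
                continue
            yj = self.Y[:, j]
            m = yj >= 0
            if not m.any():
                continue
            if j in self.free:
                for g in range(self.G):
                    mg = m & (self.gidx == g)
                    if not mg.any():
                        continue
                    logP = np.log(_prob_table(alpha[g, j], delta[j][g], nodes))
                    LL[mg] += logP[yj[mg]]
            else:
                logP = np.log(_prob_table(alpha[0, j], delta[j][0], nodes))
                LL[m] += logP[yj[m]]
        return LL

    def _start(self, start):
        J = self.Y.shape[1]
        if start is not None:
            alpha = start.alpha.copy()
            delta = [d.copy() for d in start.delta]
            mu = start.group_means.copy()
            sd = start.group_sds.copy()
            return alpha, delta, mu, sd
        alpha = np.ones((self.G, J))
        delta = []
        for j in range(J):
            yj = self.Y[:, j]
            obs = yj[yj >= 0]
            K = self.K[j]
            d = np.empty(K - 1)
            for k in range(1, K):
                p = np.clip((obs >= k).mean(), 0.02, 0.98)
                d[k - 1] = np.log((1 - p) / p)
            for k in range(1, K - 1):
                d[k] = max(d[k], d[k - 1] + 1e-3)
            delta.append(np.tile(d, (self.G, 1)))
        mu = np.zeros(self.G)
        sd = np.ones(self.G)
        return alpha, delta, mu, sd

    def _precompute(self):
        """Per-item observation indices and one-hot response matrices."""
        if self._onehot is not None:
            return self._onehot
        Y, gidx = self.Y, self.gidx
        pre = []
        for j in range(Y.shape[1]):
            yj = Y[:, j]
            m = yj >= 0
            rows = np.flatnonzero(m)
            oh = np.zeros((len(rows), self.K[j]))
            oh[np.arange(len(rows)), yj[rows]] = 1.0
            per_group = []
            for g in range(self.G):
                rg = rows[gidx[rows] == g]
                ohg = np.zeros((len(rg), self.K[j]))
                if len(rg):
                    ohg[np.arange(len(rg)), yj[rg]] = 1.0
                per_group.append((rg, ohg))
            pre.append((rows, oh, per_group))
        self._onehot = pre
        return pre

    # one EM cycle as a parameter-vector map (enables SQUAREM acceleration)

    def _pack(self, t, mu, sd):
        parts = [t[k] for k in sorted(t)]
        return np.concatenate(parts + [mu[1:], np.log(sd[1:])])

    def _unpack(self, vec, keys, sizes):
        t = {}
        pos = 0
        for k, s in zip(keys, sizes):
            t[k] = vec[pos:pos + s]
            pos += s
        G = self.G
        mu = np.zeros(G)
        sd = np.ones(G)
        mu[1:] = vec[pos:pos + G - 1]
        sd[1:] = np.exp(vec[pos + G - 1:pos + 2 * (G - 1)])
        return t, mu, sd

    def _expand(self, t):
        J = self.Y.shape[1]
        alpha = np.empty((self.G, J))
        delta = [np.empty((self.G, self.K[j] - 1)) for j in range(J)]
        for (j, g), tv in t.items():
            a, d = unpack_item(tv)
            if g == -1:
                alpha[:, j] = a
                delta[j][:] = d
            else:
                alpha[g, j] = a
                delta[j][g] = d
        return alpha, delta

    def _loglik_vec(self, t, mu, sd):
        alpha, delta = self._expand(t)
        nodes = self._grid(mu, sd)
        LL = self.loglik_matrix(alpha, delta, nodes)
        return float(logsumexp(
            LL + self._log_prior(nodes, mu, sd), axis=1).sum())

    def _em_step(self, t, mu, sd, maxiter=8):
        """One EM cycle; returns (new t, mu, sd, loglik at input params)."""
        gidx, G = self.gidx, self.G
        pre = self._precompute()
        alpha, delta = self._expand(t)
        nodes = self._grid(mu, sd)
        LL = self.loglik_matrix(alpha, delta, nodes)
        lw = LL + self._log_prior(nodes, mu, sd)
        li = logsumexp(lw, axis=1)
        post = np.exp(lw - li[:, None])
        t_new = {}
        for (j, g), tv in t.items():
            rows, oh, per_group = pre[j]
            if g == -1:
                R = oh.T @ post[rows]
            else:
                rg, ohg = per_group[g]
                if not len(rg):
                    t_new[(j, g)] = tv
                    continue
                R = ohg.T @ post[rg]
            t_new[(j, g)] = optimize_item(R, nodes, tv, maxiter=maxiter)
        pm = post @ nodes
        pv = post @ nodes ** 2 - pm ** 2
        mu_new, sd_new = mu.copy(), sd.copy()
        for g in range(1, G):  # reference group stays N(0, 1)
            sel = gidx == g
            mu_new[g] = pm[sel].mean()
            sd_new[g] = np.sqrt(np.clip(
                (pv[sel] + (pm[sel] - mu_new[g]) ** 2).mean(), 1e-6, None))
        return t_new, mu_new, sd_new, float(li.sum())

    def fit(self, start=None, max_cycles=300, tol_loglik=1e-5,
            tol_param=1e-4, accelerate=True):
        """EM (SQUAREM-accelerated by default, with a monotone safeguard)."""
        Y = self.Y
        J = Y.shape[1]
        alpha, delta, mu, sd = self._start(start)
        t = {}
        for j in range(J):
            if j in self.free:
                for g in range(self.G):
                    t[(j, g)] = pack_item(alpha[g, j], delta[j][g])
            else:
                t[(j, -1)] = pack_item(alpha[0, j], delta[j][0])
        keys = sorted(t)
        sizes = [len(t[k]) for k in keys]

        trace = []
        converged = False
        n_steps = 0
        ll_prev = -np.inf
        while n_steps < max_cycles:
            t1, mu1, sd1, ll0 = self._em_step(t, mu, sd)
            trace.append(ll0)
            n_steps += 1
            if abs(ll0 - ll_prev) < tol_loglik:
                t, mu, sd = t1, mu1, sd1
                converged = True
                break
            if not accelerate or n_steps + 2 > max_cycles:
                t, mu, sd = t1, mu1, sd1
                ll_prev = ll0
                continue
            t2, mu2, sd2, ll1 = self._em_step(t1, mu1, sd1)
            trace.append(ll1)
            n_steps += 1
            v0 = self._pack(t, mu, sd)
            v1 = self._pack(t1, mu1, sd1)
            v2 = self._pack(t2, mu2, sd2)
            r = v1 - v0
            q = v2 - 2 * v1 + v0
            nq = np.linalg.norm(q)
            if nq < 1e-12:
                t, mu, sd = t2, mu2, sd2
                ll_prev = ll1
                continue
            a = -max(np.linalg.norm(r) / nq, 1.0)
            v_acc = v0 - 2 * a * r + a * a * q
            t_acc, mu_acc, sd_acc = self._unpack(v_acc, keys, sizes)
            # safeguard: accept the extrapolation only if it does not hurt
            if self._loglik_vec(t_acc, mu_acc, sd_acc) >= ll1:
                t, mu, sd = t_acc, mu_acc, sd_acc
            else:
                t, mu, sd = t2, mu2, sd2
            ll_prev = ll1
        alpha, delta = self._expand(t)
        nodes = self._grid(mu, sd)
        LL = self.loglik_matrix(alpha, delta, nodes)
        final_ll = float(logsumexp(
            LL + self._log_prior(nodes, mu, sd), axis=1).sum())
        if not converged:
            warnings.warn("multi-group EM did not converge", RuntimeWarning)
        return MultigroupResults(
            item_ids=self.bank.item_ids, alpha=alpha, delta=delta,
            group_labels=self.group_labels, group_means=mu, group_sds=sd,
            free_items=self.free, loglik=final_ll,
            n_cycles=n_steps, converged=converged,
            ref_group=self.ref_group)

    # -- fast re-estimation with anchors fixed ---------------------------

    def estimate_group_dists(self, fit: MultigroupResults, rows=None,
                             free_override=None, max_cycles=60, tol=1e-7):
        """Re-estimate group means/SDs (and freed-item parameters) with
        anchor item parameters fixed at ``fit``; used by the bootstrap.

        ``rows``: optional bootstrap index vector over children.
        """
        idx = np.arange(self.Y.shape[0]) if rows is None else np.asarray(rows)
        gidx = self.gidx[idx]
        free = self.free if free_override is None else frozenset(free_override)
        alpha = fit.alpha.copy()
        delta = [d.copy() for d in fit.delta]
        mu = fit.group_means.copy()
        sd = fit.group_sds.copy()
        nodes = self._grid(mu, np.maximum(sd, 1.0))
        Ysub = self.Y[idx]

        # anchor log-likelihood (free items handled separately)
        LL_anchor = np.zeros((len(idx), len(nodes)))
        for j in range(self.Y.shape[1]):
            if j in free:
                continue
            yj = Ysub[:, j]
            m = yj >= 0
            if not m.any():
                continue
            logP = np.log(_prob_table(alpha[0, j], delta[j][0], nodes))
            LL_anchor[m] += logP[yj[m]]

        def free_ll():
            LLf = np.zeros_like(LL_anchor)
            for j in free:
                yj = Ysub[:, j]
                m = yj >= 0
                for g in range(self.G):
                    mg = m & (gidx == g)
                    if not mg.any():
                        continue
                    logP = np.log(_prob_table(alpha[g, j], delta[j][g], nodes))
                    LLf[mg] += logP[yj[mg]]
            return LLf

        prev_ll = -np.inf
        for _ in range(max_cycles):
            LL = LL_anchor + free_ll()
            z = (nodes[None, :] - mu[gidx, None]) / sd[gidx, None]
            lw = -0.5 * z ** 2 - np.log(sd[gidx, None])
            lw -= logsumexp(lw, axis=1, keepdims=True)
            li = logsumexp(LL + lw, axis=1)
            ll = float(li.sum())
            post = np.exp(LL + lw - li[:, None])
            pm = post @ nodes
            pv = post @ nodes ** 2 - pm ** 2
            for g in range(1, self.G):
                sel = gidx == g
                if not sel.any():
                    continue
                mu[g] = pm[sel].mean()
                sd[g] = np.sqrt(np.clip(
                    (pv[sel] + (pm[sel] - mu[g]) ** 2).mean(), 1e-6, None))
            # freed items: per-group direct marginal ML on the resample,
            # rest-likelihood includes anchors and the other freed items
            LLf = free_ll()
            for j in free:
                yj = Ysub[:, j]
                m = yj >= 0
                for g in range(self.G):
                    mg = m & (gidx == g)
                    if not mg.any():
                        continue
                    logPj = np.log(_prob_table(alpha[g, j], delta[j][g],
                                               nodes))
                    zg = (nodes[None, :] - mu[g]) / sd[g]
                    rest = (LL_anchor[mg] + LLf[mg] - logPj[yj[mg]]
                            - 0.5 * zg ** 2)
                    A = np.exp(rest - rest.max(axis=1, keepdims=True))
                    t0 = pack_item(alpha[g, j], delta[j][g])
                    tj, _ = optimize_item_marginal(yj[mg], A, nodes, t0)
                    alpha[g, j], delta[j][g] = unpack_item(tj)
            if abs(ll - prev_ll) < tol:
                break
            prev_ll = ll
        return mu, sd, alpha, delta


def _counts(y, post, K):
    R = np.zeros((K, post.shape[1]))
    np.add.at(R, y, post)
    return R


# ---------------------------------------------------------------------------
# DIF detection
# ---------------------------------------------------------------------------

@dataclass
class DIFReport:
    """Per-item DIF test results for one grouping variable."""

    grouping: str
    items: pd.DataFrame          # item_id, statistic, df, p, p_adj, flagged
    n_tested: int
    n_flagged: int
    fdr: float
    group_labels: list
    group_means: np.ndarray
    group_sds: np.ndarray
    n_rounds: int

    @property
    def fraction_flagged(self):
        return self.n_flagged / self.n_tested if self.n_tested else 0.0

    @property
    def flagged_items(self):
        return self.items.loc[self.items["flagged"], "item_id"].tolist()

    def to_json(self, path=None):
        d = {
            "grouping": self.grouping,
            "fdr": self.fdr,
            "n_tested": self.n_tested,
            "n_flagged": self.n_flagged,
            "fraction_flagged": self.fraction_flagged,
            "n_rounds": self.n_rounds,
            "group_labels": list(self.group_labels),
            "group_means": [float(v) for v in self.group_means],
            "group_sds": [float(v) for v in self.group_sds],
            "items": self.items.to_dict(orient="records"),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=2)
        return d


def _item_lrt(model: MultigroupGRM, fit: MultigroupResults, j, nodes,
              LL_full, log_prior):
    """Anchored LRT for item j: group-specific vs shared parameters."""
    Y, gidx, G = model.Y, model.gidx, model.G
    yj = Y[:, j]
    m = yj >= 0
    # rest likelihood (item j removed) + prior weights
    if j in fit.free_items:
        restm = LL_full[m].copy()
        for g in range(G):
            mg = m & (gidx == g)
            sel = mg[m]
            if not sel.any():
                continue
            logP = np.log(_prob_table(fit.alpha[g, j], fit.delta[j][g], nodes))
            restm[sel] -= logP[yj[mg]]
    else:
        logP = np.log(_prob_table(fit.alpha[0, j], fit.delta[j][0], nodes))
        restm = LL_full[m] - logP[yj[m]]
    restm = restm + log_prior[m]
    shift = restm.max(axis=1, keepdims=True)
    A = np.exp(restm - shift)
    gm = gidx[m]
    ym = yj[m]
    t0 = pack_item(fit.alpha[0, j], fit.delta[j][0])
    # shared parameters
    _, ll_shared = optimize_item_marginal(ym, A, nodes, t0)
    # group-specific parameters (separable across groups)
    ll_free = 0.0
    for g in range(G):
        sel = gm == g
        tg = pack_item(fit.alpha[g, j], fit.delta[j][g])
        _, llg = optimize_item_marginal(ym[sel], A[sel], nodes, tg)
        ll_free += llg
    stat = max(2.0 * (ll_free - ll_shared), 0.0)
    df = int(model.K[j]) * (G - 1)
    return stat, df


def detect_dif(responses, bank, ages, groups, fdr=0.05, min_group_n=1,
               max_rounds=3, n_quadrature=DEFAULT_QUAD, grouping_name="group",
               ref_group=None):
    """LRT-with-purification DIF screen across groups.

    ``ages`` is accepted for interface symmetry with calibration (and to
    document that responses already carry the age-window structural
    missingness); the multi-group model conditions ability on group only.
    """
    groups = np.asarray(groups)
    base = MultigroupGRM(responses, bank, groups,
                         n_quadrature=n_quadrature, ref_group=ref_group)
    G, Y = base.G, base.Y

    testable = []
    for j in range(Y.shape[1]):
        yj = Y[:, j]
        ok = all(((yj >= 0) & (base.gidx == g)).sum() >= min_group_n
                 for g in range(G))
        if ok:
            testable.append(j)
        else:
            warnings.warn(
                f"item {bank.item_ids[j]!r} skipped: some group has fewer "
                f"than {min_group_n} responses", RuntimeWarning)
    if not testable:
        raise DataError("no testable items")

    flagged = frozenset()
    fit = None
    for rnd in range(1, max_rounds + 1):
        model = MultigroupGRM(Y, bank, groups, free_items=flagged,
                              n_quadrature=n_quadrature, ref_group=ref_group)
        fit = model.fit(start=fit)
        nodes = model._grid(fit.group_means, fit.group_sds)
        LL_full = model.loglik_matrix(fit.alpha, fit.delta, nodes)
        log_prior = model._log_prior(nodes, fit.group_means, fit.group_sds)
        stats, dfs, ps = [], [], []
        for j in testable:
            s, df = _item_lrt(model, fit, j, nodes, LL_full, log_prior)
            stats.append(s)
            dfs.append(df)
            ps.append(float(chi2_dist.sf(s, df)))
        rej, p_adj, _, _ = multipletests(ps, alpha=fdr, method="fdr_bh")
        new_flagged = frozenset(j for j, r in zip(testable, rej) if r)
        stable = new_flagged == flagged
        flagged = new_flagged
        if stable or not flagged:
            break

    # final model with the stable flag set freed
    if flagged == fit.free_items:
        final = fit
    else:
        model = MultigroupGRM(Y, bank, groups, free_items=flagged,
                              n_quadrature=n_quadrature, ref_group=ref_group)
        final = model.fit(start=fit)

    items = pd.DataFrame({
        "item_id": [bank.item_ids[j] for j in testable],
        "statistic": stats,
        "df": dfs,
        "p": ps,
        "p_adj": p_adj,
        "flagged": [j in flagged for j in testable],
    })
    return DIFReport(
        grouping=grouping_name, items=items, n_tested=len(testable),
        n_flagged=len(flagged), fdr=fdr, group_labels=final.group_labels,
        group_means=final.group_means, group_sds=final.group_sds,
        n_rounds=rnd)


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """Free-vs-constrained comparison of group ability-mean contrasts."""

    group_labels: list
    contrasts_full: np.ndarray      # (G-1,) mean differences vs reference
    contrasts_partial: np.ndarray
    difference: np.ndarray
    chi2: float
    df: int
    p: float
    n_boot: int
    n_boot_failed: int = 0
    flagged: bool = False

    def to_json(self, path=None):
        d = {
            "group_labels": list(self.group_labels),
            "contrasts_full_invariance": [float(v) for v in
                                          self.contrasts_full],
            "contrasts_partial_invariance": [float(v) for v in
                                             self.contrasts_partial],
            "difference": [float(v) for v in self.difference],
            "chi2": self.chi2, "df": self.df, "p": self.p,
            "n_boot": self.n_boot, "n_boot_failed": self.n_boot_failed,
            "flagged": self.flagged,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=2)
        return d


def sensitivity_analysis(responses, bank, ages, groups, dif_items,
                         n_boot=200, seed=0, n_quadrature=DEFAULT_QUAD,
                         ref_group=None, max_fail=0.2):
    """Wald test of whether freeing DIF items changes group-mean contrasts.

    Group ability-mean contrasts (vs the reference group) are estimated
    under (a) full invariance and (b) partial invariance with ``dif_items``
    group-specific.  The chi-square statistic uses a paired nonparametric
    bootstrap over children (stratified by group) for the covariance of the
    contrast differences; anchor item parameters stay at the full-data
    estimates within the bootstrap.
    """
    groups = np.asarray(groups)
    ids = bank.item_ids
    dif_idx = frozenset(
        i if isinstance(i, (int, np.integer)) else ids.index(i)
        for i in dif_items)
    unknown = [i for i in dif_idx if i >= len(ids)]
    if unknown:
        raise DataError("dif_items outside the bank")

    m_full = MultigroupGRM(responses, bank, groups,
                           n_quadrature=n_quadrature, ref_group=ref_group)
    fit_full = m_full.fit()
    ca = fit_full.group_means[1:].copy()
    G = m_full.G

    if not dif_idx:
        return SensitivityResult(
            group_labels=fit_full.group_labels, contrasts_full=ca,
            contrasts_partial=ca.copy(), difference=np.zeros(G - 1),
            chi2=0.0, df=G - 1, p=1.0, n_boot=0)

    m_part = MultigroupGRM(m_full.Y, bank, groups, free_items=dif_idx,
                           n_quadrature=n_quadrature, ref_group=ref_group)
    fit_part = m_part.fit(start=fit_full)
    cb = fit_part.group_means[1:].copy()
    d = cb - ca

    rng = np.random.default_rng(seed)
    n = m_full.Y.shape[0]
    by_group = [np.flatnonzero(m_full.gidx == g) for g in range(G)]
    diffs = []
    n_failed = 0
    for _ in range(int(n_boot)):
        rows = np.concatenate([rng.choice(ix, size=len(ix), replace=True)
                               for ix in by_group])
        try:
            mu_a, _, _, _ = m_full.estimate_group_dists(fit_full, rows=rows)
            mu_b, _, _, _ = m_part.estimate_group_dists(fit_part, rows=rows)
            diffs.append(mu_b[1:] - mu_a[1:])
        except Exception:
            n_failed += 1
    diffs = np.asarray(diffs)
    flagged = n_failed > max_fail * n_boot or len(diffs) < max(10, G)
    if len(diffs) >= 2:
        cov = np.cov(diffs.T).reshape(G - 1, G - 1)
        stat = float(d @ np.linalg.pinv(cov) @ d)
    else:
        stat = np.nan
        flagged = True
    df = G - 1
    p = float(chi2_dist.sf(stat, df)) if np.isfinite(stat) else np.nan
    return SensitivityResult(
        group_labels=fit_full.group_labels, contrasts_full=ca,
        contrasts_partial=cb, difference=d, chi2=stat, df=df, p=p,
        n_boot=int(n_boot), n_boot_failed=n_failed, flagged=flagged)
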