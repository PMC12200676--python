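"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's quadrature machinery: dense
trapezoid integration for marginal likelihoods and posterior moments,
direct logistic evaluation for category probabilities.
"""

import numpy as np
from scipy.special import expit
from scipy.stats import norm


def category_probs_direct(alpha, delta, theta):
    """Differences of logistic CDFs, computed independently."""
    delta = np.atleast_1d(delta)
    cum = [1.0]
    for d in delta:
        cum.append(expit(alpha * (theta - d)))
    cum.append(0.0)
    return np.array([cum[k] - cum[k + 1] for k in range(len(delta) + 1)])


def trapezoid_posterior(alphas, deltas, ys, mu, npts=10001, span=8.0):
    """Posterior mean/SD and marginal log-likelihood for one child by dense
    trapezoid integration against the true N(mu, 1) prior."""
    theta = np.linspace(mu - span, mu + span, npts)
    ll = np.zeros_like(theta)
    for a, d, y in zip(alphas, deltas, ys):
        d = np.atleast_1d(d)
        # P(Y=y) = C_y - C_{y+1} with C_0 = 1, C_K = 0
        C = np.vstack([np.ones_like(theta)]
                      + [expit(a * (theta - dk)) for dk in d]
                      + [np.zeros_like(theta)])
        ll += np.log(np.clip(C[y] - C[y + 1], 1e-300, None))
    prior = norm.pdf(theta, loc=mu, scale=1.0)
    integrand = np.exp(ll) * prior
    Z = np.trapezoid(integrand, theta)
    mean = np.trapezoid(integrand * theta, theta) / Z
    second = np.trapezoid(integrand * theta ** 2, theta) / Z
    sd = np.sqrt(max(second - mean ** 2, 0.0))
    return mean, sd, float(np.log(Z))


def random_bounded_gamma(rng, basis, amp_range=(-2.0, 2.0)):
    """Latent-regression coefficients whose implied prior means stay within
    a realistic ability range: project a random logistic growth curve onto
    the centered age basis."""
    months = np.arange(72, dtype=float)
    amp = rng.uniform(*amp_range)
    mid = rng.uniform(10, 60)
    curve = amp * expit((months - mid) / 10.0)
    X = basis.transform(months)
    return np.linalg.lstsq(X, curve - curve.mean(), rcond=None)[0]


def binary_item_logistic_mle(y, theta_fixed=0.0):
    """MLE of (alpha, delta) for a single binary item when every child has
    the same known ability is degenerate; with ability fixed at a constant
    the likelihood depends only on p = expit(alpha*(theta-delta)), whose MLE
    is the observed frequency.  Returns that frequency."""
    return np.mean(y)
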