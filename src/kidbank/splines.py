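"""Natural cubic spline bases for age, shared across the latent regression,
location-scale reliability model, and age-adjusted validity analyses.

The basis is the standard truncated-power construction of a natural cubic
spline (linear beyond the boundary knots): with knots k_1 < ... < k_M the
non-intercept functions are

    N_1(x) = x,
    N_{j+1}(x) = d_j(x) - d_{M-1}(x),   j = 1, ..., M-2,

with d_j(x) = [(x - k_j)_+^3 - (x - k_M)_+^3] / (k_M - k_j), giving M - 1
columns.  Ages are in integer months on [0, 71]; default interior knots sit
at the yearly boundaries 12, 24, 36, 48, 60 months with boundary knots at
0 and 71.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_KNOTS = (12.0, 24.0, 36.0, 48.0, 60.0)
DEFAULT_BOUNDARY = (0.0, 71.0)


def natural_spline_matrix(x, knots=DEFAULT_KNOTS, boundary=DEFAULT_BOUNDARY):
    """Uncentered natural cubic spline basis (no intercept column).

    Parameters
    ----------
    x : array-like of ages (months)
    knots : interior knots
    boundary : (low, high) boundary knots

    Returns
    -------
    ndarray of shape (n, len(knots) + 1)
    """
    x = np.asarray(x, dtype=float)
    allk = np.sort(np.r_[boundary[0], np.asarray(knots, float), boundary[1]])
    if np.any(np.diff(allk) <= 0):
        raise ValueError("knots (with boundaries) must be strictly increasing")
    M = len(allk)
    kM = allk[-1]
    kM1 = allk[-2]

    def d(j):
        return (np.clip(x - allk[j], 0, None) ** 3
                - np.clip(x - kM, 0, None) ** 3) / (kM - allk[j])

    cols = [x]
    dlast = d(M - 2)
    for j in range(M - 2):
        cols.append(d(j) - dlast)
    return np.column_stack(cols)


@dataclass
class AgeBasis:
    """Centered age basis with persisted centering constants.

    Column means are subtracted so that a regression through this basis with
    no intercept has fitted values averaging zero over the construction
    sample — the location-identification constraint for the latent
    regression.
    """

    knots: tuple = DEFAULT_KNOTS
    boundary: tuple = DEFAULT_BOUNDARY
    col_means: np.ndarray = field(default=None)

    def fit(self, ages):
        ages = np.asarray(ages, dtype=float)
        if np.any(ages < self.boundary[0]) or np.any(ages > self.boundary[1]):
            raise ValueError("ages outside the supported range "
                             f"[{self.boundary[0]}, {self.boundary[1]}]")
        raw = natural_spline_matrix(ages, self.knots, self.boundary)
        if len(np.unique(ages)) < raw.shape[1]:
            raise ValueError(
                "fewer distinct ages than basis dimension; the latent "
                "regression design is rank deficient")
        self.col_means = raw.mean(axis=0)
        return self

    def transform(self, ages):
        if self.col_means is None:
            raise RuntimeError("AgeBasis.fit must be called first")
        raw = natural_spline_matrix(np.asarray(ages, float),
                                    self.knots, self.boundary)
        return raw - self.col_means

    def fit_transform(self, ages):
        return self.fit(ages).transform(ages)

    @property
    def dim(self):
        return len(self.knots) + 1

    def to_dict(self):
        return {
            "knots": list(self.knots),
            "boundary": list(self.boundary),
            "col_means": None if self.col_means is None
            else [float(v) for v in self.col_means],
        }

    @classmethod
    def from_dict(cls, d):
        b = cls(knots=tuple(d["knots"]), boundary=tuple(d["boundary"]))
        if d.get("col_means") is not None:
            b.col_means = np.asarray(d["col_means"], float)
        return b


def latent_regression_basis(ages, knots=DEFAULT_KNOTS, boundary=DEFAULT_BOUNDARY):
    """Centered design matrix for the latent regression of ability on age.

    Raises if there are fewer distinct ages than basis columns.  Column
    means of the returned matrix are zero by construction.
    """
    basis = AgeBasis(knots=tuple(knots), boundary=tuple(boundary))
    return basis.fit_transform(ages), basis
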