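"""Expected-a-posteriori (EAP) ability estimates and conditional standard
errors of measurement (CSEM).

Each child's posterior over ability combines the age-dependent normal prior
N(x_i' gamma, 1) with the likelihood of their observed item responses,
evaluated on the common rectangular quadrature grid.  The EAP score is the
posterior mean; the CSEM is the posterior SD.  A child with no answered
items receives the prior mean and SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .grm import GRMParameters, QuadratureGrid, response_logprob_grid, _dense


@dataclass
class ScoreSet:
    """Per-child scores: child_id, eap, csem, age_months, n_items_answered."""

    table: pd.DataFrame

    def __post_init__(self):
        required = ["child_id", "eap", "csem", "age_months",
                    "n_items_answered"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"score table missing columns: {missing}")
        if (self.table["csem"] <= 0).any():
            raise ValueError("csem must be positive")

    @property
    def eap(self):
        return self.table["eap"].to_numpy(float)

    @property
    def csem(self):
        return self.table["csem"].to_numpy(float)

    @property
    def ages(self):
        return self.table["age_months"].to_numpy(float)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path, dtype={"child_id": str}))


def score_eap(params: GRMParameters, responses, bank, ages, n_nodes=101):
    """EAP ability estimate and CSEM for every child.

    Parameters
    ----------
    params : calibrated GRMParameters
    responses : ResponseMatrix or dense (n, J) array (-1 = missing)
    bank : ItemBank (used to align dense columns; may be None for dense input)
    ages : per-child ages in months
    """
    ages = np.asarray(ages, float)
    Y, child_ids = _dense(responses, bank, ages)
    mu = params.prior_means(ages)
    grid = QuadratureGrid.build(mu, n_nodes=n_nodes)
    LL = response_logprob_grid(Y, params.alpha, params.delta, grid.nodes)
    lw = LL + grid.log_weights
    li = logsumexp(lw, axis=1)
    post = np.exp(lw - li[:, None])
    eap = post @ grid.nodes
    second = post @ grid.nodes ** 2
    csem = np.sqrt(np.clip(second - eap ** 2, 1e-12, None))
    n_ans = (Y >= 0).sum(axis=1)
    tbl = pd.DataFrame({
        "child_id": child_ids,
        "eap": eap,
        "csem": csem,
        "age_months": ages,
        "n_items_answered": n_ans,
    })
    return ScoreSet(tbl)
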