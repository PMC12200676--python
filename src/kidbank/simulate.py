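"""Synthetic data generator for item-bank calibration studies.

Emulates the structure the analysis assumes: a birth-to-five caregiver
item bank (default 197 items) whose age-administration windows yield about
39 administered items per child; latent ability rising steeply with age
(a scaled logistic curve spanning 4 SD over 0-71 months) with standardized
criterion shifts (income, caregiver education, race/ethnicity, caregiver
PHQ-2/GAD-2 distress); graded-response sampling of polytomous responses
restricted to age-eligible items; covariates with MCAR missingness at the
study rates (7.2% income, 10.8% PHQ/GAD); optional item-level DIF
injection; and concurrent-instrument stand-in score columns with chosen
age-adjusted correlations.

All randomness flows from one root seed through named substreams (ages,
bank, covariates, theta, responses, scores), so stages are independently
reproducible and identical configs give byte-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import (CovariateTable, DataError, EDUCATION_LEVELS, ItemBank,
                   PHQ_GAD_COLS, RACE_ETHNICITY, ResponseMatrix,
                   SOURCE_INSTRUMENTS, DOMAINS, write_dataset)
from .grm import GRMParameters, grm_category_probs
from .splines import AgeBasis

_STREAMS = {"ages": 0, "bank": 1, "covariates": 2, "theta": 3,
            "responses": 4, "scores": 5}

# Standardized criterion shifts used as generating truth (per-unit for the
# continuous criteria, group offsets for the categorical ones).
DEFAULT_CRITERION_EFFECTS = {
    "log_income": 0.09,
    "no_hs": -0.34, "hs": -0.27, "some_college_aa": -0.08, "ma_plus": 0.05,
    "black_nh": -0.137, "other_nh": -0.113, "hispanic": -0.237,
    "phq_gad_total": -0.128,
}

# Age-adjusted correlations for concurrent-instrument stand-in columns.
DEFAULT_CONCURRENT_TARGETS = {
    "d_score": 0.93, "credi_overall": 0.89, "ecdi2030": 0.75,
    "hrtl_early_learning": 0.77, "hrtl_physical": 0.62,
    "hrtl_socemot": 0.39, "hrtl_self_regulation": 0.38, "gsed_pf": -0.20,
}

_EDU_PROBS = (0.033, 0.133, 0.321, 0.313, 0.200)
_RACE_PROBS = (0.597, 0.091, 0.134, 0.178)
# single-item response probabilities for categories 0..3 (means ~0.6-0.9)
_PHQ_CUTS = (0.55, 1.45, 2.35)  # thresholds on the latent distress scale


def ability_curve(ages, amplitude=4.0, midpoint=20.0, scale=10.0):
    """Monotone mean-ability curve m(age): rapid early growth, flattening.

    Scaled logistic with ``amplitude`` SD of total growth over 0-71 months,
    centered to mean zero over the month grid.
    """
    ages = np.asarray(ages, float)
    raw = amplitude * expit((ages - midpoint) / scale)
    grid = amplitude * expit((np.arange(72) - midpoint) / scale)
    return raw - grid.mean()


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic-data generator."""

    n_children: int = 5001
    n_items: int = 197
    seed: int = 0
    age_range_months: tuple = (0, 71)
    mean_admin_items: int = 39
    criterion_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_CRITERION_EFFECTS))
    dif_spec: list = field(default_factory=list)
    # entries: (item_id, grouping_column, group_level, delta_shift, alpha_ratio)
    missing_income_rate: float = 0.072
    missing_phqgad_rate: float = 0.108
    incidental_missing_rate: float = 0.0
    concurrent_targets: dict = None     # None -> defaults; {} -> none
    true_params: object = "random"

    def __post_init__(self):
        if self.n_children < 1:
            raise DataError("n_children must be >= 1")
        lo, hi = self.age_range_months
        if lo < 0 or hi > 71 or lo > hi:
            raise DataError("age_range_months must lie within [0, 71]")
        for r in (self.missing_income_rate, self.missing_phqgad_rate,
                  self.incidental_missing_rate):
            if not 0 <= r <= 1:
                raise DataError("rates must be in [0, 1]")

    def rng(self, stream):
        return np.random.default_rng([_STREAMS[stream], self.seed])


@dataclass
class SyntheticDataset:
    """Generated bank, responses, covariates, and ground truth."""

    item_bank: ItemBank
    responses: ResponseMatrix
    covariates: CovariateTable
    true_theta: np.ndarray
    true_params: GRMParameters
    complete_covariates: pd.DataFrame = None

    def save(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_dataset(self.item_bank, self.responses, self.covariates,
                      outdir / "item_bank.csv", outdir / "responses.csv",
                      outdir / "children.csv")
        self.true_params.save(outdir / "true_params.json")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"true_theta": [float(v) for v in self.true_theta],
                       "child_id": self.covariates.child_ids}, fh)


# ---------------------------------------------------------------------------
# Ages
# ---------------------------------------------------------------------------

def generate_ages(config: GeneratorConfig):
    """Uniform integer ages over the configured month range."""
    rng = config.rng("ages")
    lo, hi = config.age_range_months
    return rng.integers(lo, hi + 1, size=config.n_children)


# ---------------------------------------------------------------------------
# Item bank
# ---------------------------------------------------------------------------

def _calibrate_widths(mids, base_widths, target_mean, lo=0, hi=71):
    """Scale window widths so the enumerated mean administered count over a
    uniform month distribution matches ``target_mean``."""
    months = np.arange(lo, hi + 1)

    def mean_for(s):
        wlo = np.clip(np.rint(mids - s * base_widths / 2), lo, hi)
        whi = np.clip(np.rint(mids + s * base_widths / 2), lo, hi)
        whi = np.maximum(whi, wlo)
        counts = ((months[:, None] >= wlo[None, :])
                  & (months[:, None] <= whi[None, :])).sum(axis=1)
        return counts.mean(), wlo.astype(int), whi.astype(int)

    s_lo, s_hi = 1e-3, 1.0
    while mean_for(s_hi)[0] < target_mean and s_hi < 1e3:
        s_hi *= 2
    for _ in range(60):
        s = 0.5 * (s_lo + s_hi)
        m, _, _ = mean_for(s)
        if m < target_mean:
            s_lo = s
        else:
            s_hi = s
    m, wlo, whi = mean_for(s_hi)
    return wlo, whi, m


def generate_item_bank(config: GeneratorConfig):
    """Item bank with age windows, domains, category counts, and true GRM
    parameters implied by each item's window midpoint."""
    if config.n_items < 2:
        raise DataError("n_items must be >= 2")
    if config.mean_admin_items > config.n_items:
        raise DataError("mean_admin_items cannot exceed n_items")
    rng = config.rng("bank")
    J = config.n_items
    lo, hi = config.age_range_months

    mids = (np.arange(J) + 0.5) / J * (hi - lo) + lo
    mids = np.clip(mids + rng.normal(0, 2.0, J), lo, hi)
    mids.sort()
    if config.mean_admin_items == config.n_items:
        wlo = np.full(J, lo, int)
        whi = np.full(J, hi, int)
    else:
        base = np.full(J, (hi - lo + 1) * config.mean_admin_items / J)
        base = base * rng.lognormal(0, 0.15, J)
        wlo, whi, _ = _calibrate_widths(mids, base, config.mean_admin_items,
                                        lo, hi)

    years = np.clip(mids / 12.0, 0, 5) / 5.0  # 0 at birth-year, 1 at year 5
    p_motor = 0.53 + (0.20 - 0.53) * years
    p_cog = 0.23 + (0.50 - 0.23) * years
    u = rng.random(J)
    domain = np.where(u < p_motor, "motor_phys",
                      np.where(u < p_motor + p_cog, "cog_lang", "socemot"))
    source = rng.choice(SOURCE_INSTRUMENTS[:4], size=J,
                        p=[0.45, 0.25, 0.08, 0.22])
    K = rng.choice([2, 3, 4], size=J, p=[0.6, 0.3, 0.1])

    alpha = rng.lognormal(np.log(2.0), 0.3, J)
    locs = ability_curve(mids)
    delta = []
    for j in range(J):
        spread = rng.uniform(0.5, 0.9)
        offs = (np.arange(K[j] - 1) - (K[j] - 2) / 2) * spread
        delta.append(locs[j] + offs)

    table = pd.DataFrame({
        "item_id": [f"item{j+1:03d}" for j in range(J)],
        "source_instrument": source,
        "domain": domain,
        "n_categories": K.astype(int),
        "age_min_months": wlo,
        "age_max_months": whi,
    })
    bank = ItemBank(table)
    basis = AgeBasis()
    months = np.arange(72, dtype=float)
    X = basis.fit_transform(months)
    gamma = np.linalg.lstsq(X, ability_curve(months), rcond=None)[0]
    params = GRMParameters(item_ids=bank.item_ids, alpha=alpha, delta=delta,
                           gamma=gamma, basis=basis)
    return bank, params


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def _draw_complete_covariates(config: GeneratorConfig, ages):
    rng = config.rng("covariates")
    n = len(ages)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=_EDU_PROBS)
    race = rng.choice(RACE_ETHNICITY, size=n, p=_RACE_PROBS)
    income = rng.lognormal(np.log(60000.0), 0.8, n)
    distress = rng.normal(0, 1, n)
    phq = {}
    for c in PHQ_GAD_COLS:
        z = distress * 0.8 + rng.normal(0, 0.6, n)
        phq[c] = np.digitize(z, _PHQ_CUTS).astype(float)
    tbl = pd.DataFrame({
        "child_id": [f"c{i+1:05d}" for i in range(n)],
        "age_months": np.asarray(ages, int),
        "income": income,
        "education": education,
        "race_ethnicity": race,
        **phq,
    })
    return tbl


def apply_missingness(complete, config: GeneratorConfig):
    """MCAR missingness: income at the income rate; all four PHQ/GAD items
    jointly at the PHQ/GAD rate (planned-missingness style blocks)."""
    rng = config.rng("covariates").spawn(1)[0]
    t = complete.copy()
    n = len(t)
    miss_inc = rng.random(n) < config.missing_income_rate
    t.loc[miss_inc, "income"] = np.nan
    miss_phq = rng.random(n) < config.missing_phqgad_rate
    t.loc[miss_phq, list(PHQ_GAD_COLS)] = np.nan
    return t


def generate_covariates(config: GeneratorConfig, ages=None, theta=None):
    """Covariate table with MCAR missingness at the configured rates.

    ``theta`` is accepted for interface compatibility (stand-in score
    columns conditioned on ability are added by generate_dataset)."""
    if ages is None:
        ages = generate_ages(config)
    complete = _draw_complete_covariates(config, ages)
    return CovariateTable(apply_missingness(complete, config)), complete


# ---------------------------------------------------------------------------
# Abilities
# ---------------------------------------------------------------------------

def criterion_shifts(effects, complete):
    """Standardized ability shifts implied by the criterion covariates."""
    n = len(complete)
    shift = np.zeros(n)
    for key, eff in effects.items():
        if key == "log_income":
            li = np.log(np.clip(complete["income"].to_numpy(float), 1, None))
            shift += eff * (li - li.mean())
        elif key == "phq_gad_total":
            tot = complete[list(PHQ_GAD_COLS)].sum(axis=1).to_numpy(float)
            shift += eff * (tot - tot.mean())
        elif key in EDUCATION_LEVELS:
            shift += eff * (complete["education"] == key).to_numpy(float)
        elif key in RACE_ETHNICITY:
            shift += eff * (complete["race_ethnicity"] == key).to_numpy(float)
        else:
            raise DataError(f"unknown covariate in criterion_effects: {key!r}")
    return shift


def generate_abilities(config: GeneratorConfig, ages, covariates=None):
    """theta_i = m(age_i) + criterion shifts + N(0, 1) residual."""
    ages = np.asarray(ages)
    lo, hi = config.age_range_months
    if np.any(ages < lo) or np.any(ages > hi):
        raise DataError("ages outside the configured range")
    if covariates is None:
        covariates = _draw_complete_covariates(config, ages)
    rng = config.rng("theta")
    shift = criterion_shifts(config.criterion_effects, covariates)
    return ability_curve(ages) + shift + rng.normal(0, 1, len(ages))


# ---------------------------------------------------------------------------
# Responses
# ---------------------------------------------------------------------------

def generate_responses(bank: ItemBank, theta, params: GRMParameters, ages,
                       seed=0, groups=None, dif_spec=(),
                       incidental_missing_rate=0.0, as_long=True):
    """Graded-response sampling restricted to age-eligible items.

    ``dif_spec`` entries (item_id, grouping_column_ignored, group_level,
    delta_shift, alpha_ratio) modify the generating parameters for children
    whose ``groups`` value equals ``group_level``.
    """
    rng = np.random.default_rng([_STREAMS["responses"], seed])
    theta = np.asarray(theta, float)
    n, J = len(theta), bank.n_items
    if params.n_items != J:
        raise DataError("params not conformable with bank")
    elig = bank.eligibility_matrix(np.asarray(ages))
    Y = np.full((n, J), -1, dtype=np.int16)
    dif_by_item = {}
    for entry in dif_spec:
        item_id, _col, level, dshift, aratio = entry
        dif_by_item.setdefault(item_id, []).append((level, dshift, aratio))
    groups = None if groups is None else np.asarray(groups)
    for j, item_id in enumerate(bank.item_ids):
        rows = np.flatnonzero(elig[:, j])
        if len(rows) == 0:
            continue
        a0, d0 = params.alpha[j], params.delta[j]
        specs = dif_by_item.get(item_id, [])
        handled = np.zeros(len(rows), bool)
        for level, dshift, aratio in specs:
            if groups is None:
                raise DataError("dif_spec given but no groups supplied")
            sel = groups[rows] == level
            handled |= sel
            sub = rows[sel]
            if len(sub):
                Y[sub, j] = _sample_item(a0 * aratio, d0 + dshift,
                                         theta[sub], rng)
        rest = rows[~handled]
        if len(rest):
            Y[rest, j] = _sample_item(a0, d0, theta[rest], rng)
    if incidental_missing_rate > 0:
        drop = (rng.random(Y.shape) < incidental_missing_rate) & (Y >= 0)
        Y[drop] = -1
    if not as_long:
        return Y
    return dense_to_long(Y, bank, [f"c{i+1:05d}" for i in range(n)])


def _sample_item(alpha, delta, theta, rng):
    P = grm_category_probs(alpha, delta, theta)
    c = np.cumsum(P, axis=-1)
    u = rng.random(len(theta))[:, None]
    return (u > c[:, :-1]).sum(axis=1).astype(np.int16)


def dense_to_long(Y, bank: ItemBank, child_ids):
    rows, cols = np.nonzero(Y >= 0)
    tbl = pd.DataFrame({
        "child_id": np.asarray(child_ids)[rows],
        "item_id": np.asarray(bank.item_ids)[cols],
        "response": Y[rows, cols].astype(int),
    })
    return ResponseMatrix(tbl)


# ---------------------------------------------------------------------------
# Concurrent-instrument stand-ins
# ---------------------------------------------------------------------------

def generate_concurrent_scores(config: GeneratorConfig, theta, ages,
                               targets=None):
    """Stand-in score columns with chosen age-adjusted correlations.

    Each column is r * z + sqrt(1-r^2) * noise + an age trend, where z is
    the standardized age-adjusted ability residual, so the construction's
    true part correlation with ability is r.
    """
    if targets is None:
        targets = dict(DEFAULT_CONCURRENT_TARGETS)
    rng = config.rng("scores")
    z = np.asarray(theta, float) - ability_curve(ages)
    z = (z - z.mean()) / z.std()
    out = {}
    for name, r in targets.items():
        noise = rng.normal(0, 1, len(z))
        out[name] = (r * z + np.sqrt(max(1 - r ** 2, 0)) * noise
                     + 0.5 * ability_curve(ages))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def generate_dataset(config: GeneratorConfig):
    """Full synthetic dataset: bank -> covariates -> abilities -> responses
    (plus concurrent stand-in scores), with known ground truth."""
    ages = generate_ages(config)
    bank, params = generate_item_bank(config)
    if config.true_params != "random" and config.true_params is not None:
        params = config.true_params
    covariates, complete = generate_covariates(config, ages)
    theta = generate_abilities(config, ages, covariates=complete)

    groups = None
    dif_col = None
    if config.dif_spec:
        dif_col = config.dif_spec[0][1]
        groups = complete[dif_col].to_numpy()
    responses = generate_responses(
        bank, theta, params, ages, seed=config.seed, groups=groups,
        dif_spec=config.dif_spec,
        incidental_missing_rate=config.incidental_missing_rate)

    targets = config.concurrent_targets
    if targets is None:
        targets = dict(DEFAULT_CONCURRENT_TARGETS)
    cov_tbl = covariates.table
    if targets:
        scores = generate_concurrent_scores(config, theta, ages,
                                            targets=targets)
        cov_tbl = pd.concat([cov_tbl, scores], axis=1)
    return SyntheticDataset(
        item_bank=bank,
        responses=responses,
        covariates=CovariateTable(cov_tbl),
        true_theta=theta,
        true_params=params,
        complete_covariates=complete,
    )


def simulate_two_group(n_per_group=1000, n_items=40, n_categories=3,
                       dif_items=(), delta_shift=0.5, alpha_ratio=1.0,
                       group_mean_diff=0.0, seed=0):
    """Compact two-group design for invariance simulations.

    All items share the full age window (no structural missingness); the
    focal group's ability distribution may be shifted; listed items get
    focal-group DIF.  Returns (Y dense, bank, groups, params, theta).
    """
    rng = np.random.default_rng([9, seed])
    J = n_items
    alpha = rng.lognormal(np.log(1.6), 0.25, J)
    locs = rng.uniform(-1.5, 1.5, J)
    delta = []
    for j in range(J):
        offs = (np.arange(n_categories - 1) - (n_categories - 2) / 2) * 0.8
        delta.append(locs[j] + offs)
    table = pd.DataFrame({
        "item_id": [f"item{j+1:03d}" for j in range(J)],
        "source_instrument": "other",
        "domain": "cog_lang",
        "n_categories": n_categories,
        "age_min_months": 0,
        "age_max_months": 71,
    })
    bank = ItemBank(table)
    n = 2 * n_per_group
    groups = np.array(["ref"] * n_per_group + ["focal"] * n_per_group)
    theta = rng.normal(0, 1, n)
    theta[n_per_group:] += group_mean_diff
    basis = AgeBasis()
    basis.fit(np.arange(72, dtype=float))
    params = GRMParameters(item_ids=bank.item_ids, alpha=alpha, delta=delta,
                           gamma=np.zeros(basis.dim), basis=basis)
    ages = rng.integers(0, 72, n)
    dif_spec = [(bank.item_ids[j] if isinstance(j, (int, np.integer)) else j,
                 "group", "focal", delta_shift, alpha_ratio)
                for j in dif_items]
    Y = generate_responses(bank, theta, params, ages, seed=seed,
                           groups=groups, dif_spec=dif_spec, as_long=False)
    return Y, bank, groups, params, theta
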