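"""Core data containers and CSV I/O for item-bank psychometrics.

An analysis works with three tables:

* an item bank (one row per item: source instrument, developmental domain,
  number of ordered response categories, and the age window in months over
  which the item is administered),
* a long response table (child x item x ordinal response, 0-based), and
* a child covariate table (age in months plus family/caregiver criterion
  variables).

All files are UTF-8 comma-separated with a header row; missing values are
empty cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SOURCE_INSTRUMENTS = ("GSED-SF", "CREDI-LF", "ECDI2030", "HRTL", "other")
DOMAINS = ("motor_phys", "cog_lang", "socemot")
EDUCATION_LEVELS = ("no_hs", "hs", "some_college_aa", "ba", "ma_plus")
RACE_ETHNICITY = ("white_nh", "black_nh", "other_nh", "hispanic")
PHQ_GAD_COLS = ("phq1", "phq2", "gad1", "gad2")
AGE_MIN, AGE_MAX = 0, 71


class DataError(ValueError):
    """Schema or validation failure in one of the input tables."""


# ---------------------------------------------------------------------------
# Item bank
# ---------------------------------------------------------------------------

@dataclass
class ItemBank:
    """Per-item metadata.

    ``table`` columns: item_id, source_instrument, domain, n_categories,
    age_min_months, age_max_months.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = ["item_id", "source_instrument", "domain", "n_categories",
                    "age_min_months", "age_max_months"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise DataError(f"item bank missing columns: {missing}")
        if t["item_id"].duplicated().any():
            dup = t.loc[t["item_id"].duplicated(), "item_id"].iloc[0]
            raise DataError(f"duplicate item_id in bank: {dup!r}")
        bad = ~t["domain"].isin(DOMAINS)
        if bad.any():
            raise DataError(
                f"unknown domain {t.loc[bad, 'domain'].iloc[0]!r}")
        bad = ~t["source_instrument"].isin(SOURCE_INSTRUMENTS)
        if bad.any():
            raise DataError("unknown source_instrument "
                            f"{t.loc[bad, 'source_instrument'].iloc[0]!r}")
        if (t["n_categories"] < 2).any():
            raise DataError("n_categories must be >= 2 for every item")
        if (t["age_min_months"] > t["age_max_months"]).any():
            raise DataError("age_min_months > age_max_months for some item")
        if (t["age_min_months"] < AGE_MIN).any() or \
                (t["age_max_months"] > AGE_MAX).any():
            raise DataError(f"age windows must lie within [{AGE_MIN},{AGE_MAX}]")
        self.table = t.reset_index(drop=True)

    @property
    def n_items(self):
        return len(self.table)

    @property
    def item_ids(self):
        return self.table["item_id"].tolist()

    @property
    def n_categories(self):
        return self.table["n_categories"].to_numpy(int)

    def eligible_items(self, age_months):
        """Item ids administered at ``age_months`` (closed interval), in bank order."""
        if not (AGE_MIN <= age_months <= AGE_MAX):
            raise DataError(f"age {age_months} outside [{AGE_MIN},{AGE_MAX}]")
        t = self.table
        m = (t["age_min_months"] <= age_months) & (age_months <= t["age_max_months"])
        return t.loc[m, "item_id"].tolist()

    def eligibility_matrix(self, ages):
        """Boolean (n_children, n_items) eligibility array for integer ages."""
        ages = np.asarray(ages)
        lo = self.table["age_min_months"].to_numpy()
        hi = self.table["age_max_months"].to_numpy()
        return (ages[:, None] >= lo[None, :]) & (ages[:, None] <= hi[None, :])

    def mean_administered(self, age_distribution=None):
        """Expected administered-item count under an age distribution.

        ``age_distribution``: probabilities over integer months 0..71;
        defaults to uniform.  Computed by exact enumeration over months.
        """
        months = np.arange(AGE_MIN, AGE_MAX + 1)
        if age_distribution is None:
            w = np.full(len(months), 1.0 / len(months))
        else:
            w = np.asarray(age_distribution, float)
            w = w / w.sum()
        counts = self.eligibility_matrix(months).sum(axis=1)
        return float(np.dot(w, counts))

    def domain_composition_by_age(self):
        """Domain proportions of eligible items within yearly age bands.

        Returns a DataFrame indexed by band label with one column per
        domain; rows sum to 1.  A band with zero eligible items gets NaN
        proportions and ``defined=False``.
        """
        if self.n_items == 0:
            raise DataError("empty item bank")
        rows = []
        months = np.arange(AGE_MIN, AGE_MAX + 1)
        elig = self.eligibility_matrix(months)
        dom = self.table["domain"].to_numpy()
        for year in range(6):
            band = (months >= 12 * year) & (months <= 12 * year + 11)
            # average domain composition of administered items over the band
            props = np.zeros(len(DOMAINS))
            n_months_def = 0
            for m in np.where(band)[0]:
                sel = elig[m]
                if sel.sum() == 0:
                    continue
                n_months_def += 1
                for d_i, d in enumerate(DOMAINS):
                    props[d_i] += (dom[sel] == d).mean()
            label = f"{12 * year}-{12 * year + 11}"
            if n_months_def == 0:
                rows.append([label, *([np.nan] * len(DOMAINS)), False])
            else:
                rows.append([label, *(props / n_months_def), True])
        out = pd.DataFrame(rows, columns=["age_band", *DOMAINS, "defined"])
        return out.set_index("age_band")

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path, dtype={"item_id": str}))


# ---------------------------------------------------------------------------
# Responses
# ---------------------------------------------------------------------------

@dataclass
class ResponseMatrix:
    """Long polytomous response table: child_id, item_id, response.

    Responses are 0-based integers; a (child, item) pair appears at most
    once.  Structural missingness (age-ineligible items) is simply the
    absence of a row.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = ["child_id", "item_id", "response"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise DataError(f"response table missing columns: {missing}")
        if t.duplicated(["child_id", "item_id"]).any():
            r = t[t.duplicated(["child_id", "item_id"])].iloc[0]
            raise DataError("duplicate (child,item) pair: "
                            f"({r['child_id']!r}, {r['item_id']!r})")
        self.table = t.reset_index(drop=True)

    def validate_against(self, bank: ItemBank):
        """Check every response names a bank item and lies in its category range."""
        kmap = dict(zip(bank.table["item_id"], bank.table["n_categories"]))
        t = self.table
        unknown = ~t["item_id"].isin(kmap)
        if unknown.any():
            raise DataError(
                f"response references unknown item {t.loc[unknown, 'item_id'].iloc[0]!r}")
        kj = t["item_id"].map(kmap).to_numpy(int)
        resp = t["response"].to_numpy()
        bad = (resp < 0) | (resp > kj - 1)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise DataError(
                f"response {resp[i]} out of range 0..{kj[i]-1} for item "
                f"{t['item_id'].iloc[i]!r} (child {t['child_id'].iloc[i]!r})")

    @property
    def child_ids(self):
        return pd.unique(self.table["child_id"]).tolist()

    def to_dense(self, bank: ItemBank, child_ids=None):
        """Dense (n_children, n_items) int array, -1 for missing cells.

        Rows follow ``child_ids`` (default: order of first appearance),
        columns follow bank order.
        """
        if child_ids is None:
            child_ids = self.child_ids
        self.validate_against(bank)
        c_index = {c: i for i, c in enumerate(child_ids)}
        j_index = {j: i for i, j in enumerate(bank.item_ids)}
        Y = np.full((len(child_ids), bank.n_items), -1, dtype=np.int16)
        t = self.table
        rows = t["child_id"].map(c_index).to_numpy()
        cols = t["item_id"].map(j_index).to_numpy()
        keep = ~pd.isna(rows)
        Y[rows[keep].astype(int), cols[keep].astype(int)] = \
            t["response"].to_numpy()[keep]
        return Y, list(child_ids)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path, dtype={"child_id": str, "item_id": str}))


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

@dataclass
class CovariateTable:
    """Per-child covariates: age, income, education, race/ethnicity,
    PHQ-2/GAD-2 items, plus optional concurrent-instrument score columns."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = ["child_id", "age_months"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise DataError(f"covariate table missing columns: {missing}")
        if t["child_id"].duplicated().any():
            dup = t.loc[t['child_id'].duplicated(), 'child_id'].iloc[0]
            raise DataError(f"duplicate child_id: {dup!r}")
        ages = t["age_months"]
        if ages.isna().any() or (ages < AGE_MIN).any() or (ages > AGE_MAX).any():
            raise DataError(f"age_months must be within [{AGE_MIN},{AGE_MAX}]")
        if "education" in t.columns:
            bad = ~(t["education"].isna() | t["education"].isin(EDUCATION_LEVELS))
            if bad.any():
                raise DataError(
                    f"unknown education level {t.loc[bad, 'education'].iloc[0]!r}")
        if "race_ethnicity" in t.columns:
            bad = ~(t["race_ethnicity"].isna()
                    | t["race_ethnicity"].isin(RACE_ETHNICITY))
            if bad.any():
                raise DataError("unknown race_ethnicity "
                                f"{t.loc[bad, 'race_ethnicity'].iloc[0]!r}")
        for c in PHQ_GAD_COLS:
            if c in t.columns:
                v = t[c].dropna()
                if ((v < 0) | (v > 3)).any():
                    raise DataError(f"{c} values must be integers 0-3")
        self.table = t.reset_index(drop=True)

    @property
    def child_ids(self):
        return self.table["child_id"].tolist()

    def phq_gad_total(self):
        """Sum of the four PHQ-2/GAD-2 items; NaN if any item is missing."""
        cols = [c for c in PHQ_GAD_COLS if c in self.table.columns]
        if len(cols) < 4:
            raise DataError("PHQ/GAD item columns missing")
        return self.table[cols].sum(axis=1, skipna=False)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path, dtype={"child_id": str}))


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningReport:
    """Outcome of the extreme-score screen (|z| beyond a threshold)."""

    n_in: int
    n_excluded: int
    threshold_sd: float
    excluded_ids: list = field(default_factory=list)
    rule: str = "abs_z"

    def to_json(self, path=None):
        d = {"n_in": self.n_in, "n_excluded": self.n_excluded,
             "n_retained": self.n_in - self.n_excluded,
             "threshold_sd": self.threshold_sd,
             "excluded_ids": list(self.excluded_ids), "rule": self.rule}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=2)
        return d


def screen_scores(scores, threshold_sd=5.0, ids=None, mean=None, sd=None):
    """Flag children whose score sits more than ``threshold_sd`` SDs from the
    column mean (the extreme-score exclusion applied to concurrent
    instrument scores before analysis).

    ``mean``/``sd`` allow an external reference; by default the column's own
    mean and SD are used.  Missing scores are never flagged.
    """
    s = np.asarray(scores, dtype=float)
    if ids is None:
        ids = list(range(len(s)))
    obs = ~np.isnan(s)
    if obs.sum() < 2:
        raise DataError("need at least 2 non-missing scores to screen")
    mu = float(np.mean(s[obs])) if mean is None else float(mean)
    sigma = float(np.std(s[obs], ddof=1)) if sd is None else float(sd)
    if sigma == 0:
        raise DataError("zero variance in score column; cannot screen")
    z = (s - mu) / sigma
    flagged = obs & (np.abs(z) > threshold_sd)
    excluded = [ids[i] for i in np.flatnonzero(flagged)]
    return ScreeningReport(n_in=len(s), n_excluded=len(excluded),
                           threshold_sd=float(threshold_sd),
                           excluded_ids=excluded)


# ---------------------------------------------------------------------------
# Dataset-level I/O
# ---------------------------------------------------------------------------

def read_dataset(bank_path, responses_path, children_path):
    """Read and cross-validate the three tables.

    Returns (ItemBank, ResponseMatrix, CovariateTable); raises DataError
    with row/column context on the first violation.
    """
    bank = ItemBank.from_csv(bank_path)
    responses = ResponseMatrix.from_csv(responses_path)
    covariates = CovariateTable.from_csv(children_path)
    responses.validate_against(bank)
    known = set(covariates.child_ids)
    orphan = set(responses.child_ids) - known
    if orphan:
        raise DataError(
            f"responses for child absent from covariates: {sorted(orphan)[0]!r}")
    return bank, responses, covariates


def write_dataset(bank, responses, covariates, bank_path, responses_path,
                  children_path):
    bank.to_csv(bank_path)
    responses.to_csv(responses_path)
    covariates.to_csv(children_path)


def drop_items(bank: ItemBank, responses: ResponseMatrix, item_ids):
    """Remove listed items from bank and responses (generic screening hook
    for externally determined item exclusions)."""
    drop = set(item_ids)
    unknown = drop - set(bank.item_ids)
    if unknown:
        raise DataError(f"cannot drop unknown item {sorted(unknown)[0]!r}")
    bank2 = ItemBank(bank.table[~bank.table["item_id"].isin(drop)].copy())
    resp2 = ResponseMatrix(
        responses.table[~responses.table["item_id"].isin(drop)].copy())
    return bank2, resp2
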