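import numpy as np
import pandas as pd
import pytest

from kidbank.data import ItemBank, ResponseMatrix, CovariateTable


@pytest.fixture
def tiny_bank():
    return ItemBank(pd.DataFrame({
        "item_id": ["a", "b", "c"],
        "source_instrument": ["GSED-SF", "CREDI-LF", "HRTL"],
        "domain": ["motor_phys", "cog_lang", "socemot"],
        "n_categories": [2, 3, 4],
        "age_min_months": [0, 12, 0],
        "age_max_months": [71, 24, 71],
    }))


@pytest.fixture
def tiny_responses():
    return ResponseMatrix(pd.DataFrame({
        "child_id": ["c1", "c1", "c1", "c2", "c2"],
        "item_id": ["a", "b", "c", "a", "c"],
        "response": [1, 2, 3, 0, 1],
    }))


@pytest.fixture
def tiny_covariates():
    return CovariateTable(pd.DataFrame({
        "child_id": ["c1", "c2"],
        "age_months": [18, 40],
        "income": [50000.0, np.nan],
        "education": ["ba", "hs"],
        "race_ethnicity": ["white_nh", "hispanic"],
        "phq1": [0, 1], "phq2": [0, 2], "gad1": [1, 3], "gad2": [0, 0],
    }))


@pytest.fixture(scope="session")
def calibration_fit():
    """Moderate-size calibration shared by several test modules:
    n=1000, J=40, K=3, known generating parameters, no latent age trend."""
    from kidbank.simulate import simulate_two_group
    from kidbank.grm import GradedResponseModel

    Y, bank, groups, params, theta = simulate_two_group(
        n_per_group=500, n_items=40, n_categories=3, seed=42)
    ages = np.random.default_rng(42).integers(0, 72, 1000)
    model = GradedResponseModel(Y, bank, ages)
    res = model.fit(max_cycles=500)
    return {"Y": Y, "bank": bank, "params": params, "theta": theta,
            "ages": ages, "model": model, "res": res}
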