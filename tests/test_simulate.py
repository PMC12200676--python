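import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from kidbank.data import DataError, PHQ_GAD_COLS
from kidbank.grm import grm_category_probs
from kidbank.simulate import (GeneratorConfig, ability_curve,
                              generate_abilities, generate_covariates,
                              generate_dataset, generate_item_bank,
                              generate_responses, generate_ages,
                              _draw_complete_covariates)


@pytest.fixture(scope="module")
def default_dataset():
    return generate_dataset(GeneratorConfig(seed=11, n_children=3000))


class TestItemBankGeneration:
    def test_default_bank_hits_administered_target(self):
        bank, _ = generate_item_bank(GeneratorConfig(seed=0))
        mean = bank.mean_administered()
        assert 39 * 0.8 <= mean <= 39 * 1.2

    def test_full_windows_all_administered(self):
        cfg = GeneratorConfig(seed=1, n_items=2, mean_admin_items=2,
                              n_children=50)
        bank, _ = generate_item_bank(cfg)
        assert (bank.table["age_min_months"] == 0).all()
        assert (bank.table["age_max_months"] == 71).all()
        assert bank.mean_administered() == pytest.approx(2.0)

    def test_reported_mean_matches_bruteforce_enumeration(self):
        bank, _ = generate_item_bank(GeneratorConfig(seed=2, n_items=40,
                                                     mean_admin_items=13))
        months = np.arange(72)
        counts = []
        for m in months:
            counts.append(sum(
                1 for _, row in bank.table.iterrows()
                if row["age_min_months"] <= m <= row["age_max_months"]))
        assert bank.mean_administered() == pytest.approx(np.mean(counts))

    def test_infeasible_window_request(self):
        with pytest.raises(DataError):
            generate_item_bank(GeneratorConfig(n_items=10,
                                               mean_admin_items=20))

    def test_thresholds_ordered_and_age_graded(self):
        bank, params = generate_item_bank(GeneratorConfig(seed=3))
        for d in params.delta:
            assert np.all(np.diff(d) > 0)
        # median threshold rises with window midpoint
        mids = (bank.table["age_min_months"]
                + bank.table["age_max_months"]).to_numpy() / 2
        med = np.array([np.median(d) for d in params.delta])
        order = np.argsort(mids)
        rho = np.corrcoef(mids[order], med[order])[0, 1]
        assert rho > 0.95


class TestAbilities:
    def test_standard_normal_when_no_structure(self):
        cfg = GeneratorConfig(seed=4, n_children=20000,
                              criterion_effects={})
        ages = generate_ages(cfg)
        th = generate_abilities(cfg, ages) - ability_curve(ages)
        assert th.mean() == pytest.approx(0, abs=0.03)
        assert th.std() == pytest.approx(1, abs=0.03)

    def test_group_shift_recovered(self):
        cfg = GeneratorConfig(seed=5, n_children=10000,
                              criterion_effects={"hispanic": -0.237})
        ages = generate_ages(cfg)
        comp = _draw_complete_covariates(cfg, ages)
        th = generate_abilities(cfg, ages, covariates=comp)
        resid = th - ability_curve(ages)
        hisp = comp["race_ethnicity"] == "hispanic"
        ref = comp["race_ethnicity"] == "white_nh"
        diff = resid[hisp.to_numpy()].mean() - resid[ref.to_numpy()].mean()
        assert diff == pytest.approx(-0.237, abs=0.06)

    def test_linear_age_slope_recovered(self):
        cfg = GeneratorConfig(seed=6, n_children=20000, criterion_effects={})
        ages = generate_ages(cfg)
        th_flat = generate_abilities(cfg, ages) - ability_curve(ages)
        th = th_flat + 0.05 * ages
        slope = np.polyfit(ages, th, 1)[0]
        assert slope == pytest.approx(0.05, abs=0.005)

    def test_unknown_covariate_errors(self):
        cfg = GeneratorConfig(seed=7, n_children=100,
                              criterion_effects={"martian": 1.0})
        with pytest.raises(DataError, match="martian"):
            generate_abilities(cfg, generate_ages(cfg))

    def test_ability_curve_monotone(self):
        m = ability_curve(np.arange(72))
        assert np.all(np.diff(m) >= 0)
        assert m.max() - m.min() < 4.0


class TestResponses:
    def test_binary_item_half_probability(self):
        from kidbank.data import ItemBank
        from kidbank.grm import GRMParameters
        from kidbank.splines import AgeBasis
        bank = ItemBank(pd.DataFrame({
            "item_id": ["x"], "source_instrument": ["other"],
            "domain": ["cog_lang"], "n_categories": [2],
            "age_min_months": [0], "age_max_months": [71]}))
        basis = AgeBasis().fit(np.arange(72, dtype=float))
        params = GRMParameters(item_ids=["x"], alpha=[1.0],
                               delta=[np.array([0.0])],
                               gamma=np.zeros(6), basis=basis)
        n = 50_000
        Y = generate_responses(bank, np.zeros(n), params, np.full(n, 30),
                               seed=8, as_long=False)
        assert Y.mean() == pytest.approx(0.5, abs=0.01)

    def test_category_frequencies_match_model_gof(self):
        """Chi-square goodness of fit of sampled categories against the
        closed-form category probabilities (alpha=2, delta={-1,1})."""
        from kidbank.data import ItemBank
        from kidbank.grm import GRMParameters
        from kidbank.splines import AgeBasis
        bank = ItemBank(pd.DataFrame({
            "item_id": ["x"], "source_instrument": ["other"],
            "domain": ["cog_lang"], "n_categories": [3],
            "age_min_months": [0], "age_max_months": [71]}))
        basis = AgeBasis().fit(np.arange(72, dtype=float))
        params = GRMParameters(item_ids=["x"], alpha=[2.0],
                               delta=[np.array([-1.0, 1.0])],
                               gamma=np.zeros(6), basis=basis)
        n = 50_000
        Y = generate_responses(bank, np.zeros(n), params, np.full(n, 30),
                               seed=9, as_long=False).ravel()
        expected = grm_category_probs(2.0, [-1.0, 1.0], 0.0) * n
        observed = np.bincount(Y, minlength=3)
        stat, p = chisquare(observed, expected)
        assert p > 0.01

    def test_structural_missingness_exact(self, default_dataset):
        ds = default_dataset
        Y, ids = ds.responses.to_dense(ds.item_bank)
        ages = ds.covariates.table.set_index("child_id").loc[
            ids, "age_months"].to_numpy()
        elig = ds.item_bank.eligibility_matrix(ages)
        assert np.all((Y >= 0) == elig)

    def test_dif_injection_shifts_focal_frequencies(self):
        from kidbank.simulate import simulate_two_group
        Y, bank, groups, params, theta = simulate_two_group(
            n_per_group=20000, n_items=1, n_categories=2,
            dif_items=[0], delta_shift=1.0, seed=10)
        # harder item for focal group at matched (identical) theta draw
        p_ref = Y[np.asarray(groups) == "ref", 0].mean()
        p_focal = Y[np.asarray(groups) == "focal", 0].mean()
        assert p_focal < p_ref - 0.05


class TestCovariates:
    def test_missing_fractions_near_targets(self):
        cfg = GeneratorConfig(seed=12, n_children=10_000)
        cov, _ = generate_covariates(cfg)
        assert cov.table["income"].isna().mean() == pytest.approx(
            0.072, abs=0.01)
        assert cov.phq_gad_total().isna().mean() == pytest.approx(
            0.108, abs=0.01)

    def test_zero_rates_no_missing(self):
        cfg = GeneratorConfig(seed=13, n_children=2000,
                              missing_income_rate=0.0,
                              missing_phqgad_rate=0.0)
        cov, _ = generate_covariates(cfg)
        assert not cov.table[["income", *PHQ_GAD_COLS]].isna().any().any()

    def test_phq_total_range_by_enumeration(self):
        """Every combination of four items in {0..3} sums into [0, 12]."""
        from itertools import product
        sums = {sum(c) for c in product(range(4), repeat=4)}
        assert min(sums) == 0 and max(sums) == 12
        cfg = GeneratorConfig(seed=14, n_children=3000,
                              missing_phqgad_rate=0.0)
        cov, _ = generate_covariates(cfg)
        tot = cov.phq_gad_total()
        assert tot.between(0, 12).all()


class TestDeterminismAndTruth:
    def test_identical_seed_identical_dataset(self):
        a = generate_dataset(GeneratorConfig(seed=15, n_children=400))
        b = generate_dataset(GeneratorConfig(seed=15, n_children=400))
        pd.testing.assert_frame_equal(a.responses.table, b.responses.table)
        pd.testing.assert_frame_equal(a.covariates.table, b.covariates.table)
        np.testing.assert_array_equal(a.true_theta, b.true_theta)

    def test_different_seed_different_dataset(self):
        a = generate_dataset(GeneratorConfig(seed=16, n_children=400))
        b = generate_dataset(GeneratorConfig(seed=17, n_children=400))
        assert not a.responses.table.equals(b.responses.table)

    def test_truth_saved_and_responses_valid(self, tmp_path,
                                             default_dataset):
        ds = default_dataset
        assert len(ds.true_theta) == len(ds.covariates.child_ids)
        ds.responses.validate_against(ds.item_bank)
        ds.save(tmp_path)
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "item_bank.csv").exists()
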