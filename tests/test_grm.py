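import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from kidbank.data import DataError
from kidbank.grm import (GRMParameters, GradedResponseModel, fit_grm,
                         grm_category_probs, marginal_loglik, pack_item,
                         unpack_item, _nll_counts)
from kidbank.splines import AgeBasis

from _oracles import (category_probs_direct, random_bounded_gamma,
    trapezoid_posterior)


class TestCategoryProbs:
    def test_binary_item_at_threshold(self):
        np.testing.assert_allclose(grm_category_probs(1.0, [0.0], 0.0),
                                   [0.5, 0.5], atol=1e-12)

    def test_matches_direct_logistic_differences(self):
        p = grm_category_probs(1.5, [-1.0, 0.5], 0.5)
        np.testing.assert_allclose(
            p, category_probs_direct(1.5, [-1.0, 0.5], 0.5), atol=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0.1, 5), st.floats(-3, 3), st.integers(2, 5),
           st.floats(-4, 4))
    def test_probabilities_valid_for_random_items(self, alpha, d0, K, theta):
        delta = d0 + np.arange(K - 1) * 0.7
        p = grm_category_probs(alpha, delta, theta)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unordered_delta_rejected(self):
        with pytest.raises(ValueError):
            grm_category_probs(1.0, [1.0, -1.0], 0.0)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            grm_category_probs(0.0, [0.0], 0.0)


class TestReparameterization:
    def test_pack_unpack_round_trip(self):
        a, d = 1.7, np.array([-1.2, 0.3, 2.0])
        a2, d2 = unpack_item(pack_item(a, d))
        assert a2 == pytest.approx(a)
        np.testing.assert_allclose(d2, d)

    def test_mstep_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        nodes = np.linspace(-4, 4, 31)
        R = rng.random((3, 31))
        t = pack_item(1.3, [-0.5, 0.8])
        val, grad = _nll_counts(t, R, nodes)
        eps = 1e-6
        for i in range(len(t)):
            tp = t.copy(); tp[i] += eps
            tm = t.copy(); tm[i] -= eps
            num = (_nll_counts(tp, R, nodes)[0]
                   - _nll_counts(tm, R, nodes)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestMarginalLoglik:
    def _params_for(self, bank_like, alphas, deltas, gamma_dim=6):
        basis = AgeBasis().fit(np.arange(72, dtype=float))
        return GRMParameters(item_ids=[f"i{k}" for k in range(len(alphas))],
                             alpha=alphas, delta=deltas,
                             gamma=np.zeros(gamma_dim), basis=basis)

    def test_single_binary_item_symmetry(self):
        # int expit(theta) phi(theta) dtheta = 1/2 by symmetry
        p = self._params_for(None, [1.0], [np.array([0.0])])
        Y = np.array([[1]], dtype=np.int16)
        ll = marginal_loglik(p, Y, None, [35.0])
        assert ll == pytest.approx(np.log(0.5), abs=1e-7)

    def test_additivity_over_children(self):
        p = self._params_for(None, [1.2, 0.8],
                             [np.array([0.3]), np.array([-0.5, 0.7])])
        Y = np.array([[1, 2], [0, 0]], dtype=np.int16)
        both = marginal_loglik(p, Y, None, [20.0, 50.0])
        one = marginal_loglik(p, Y[:1], None, [20.0])
        two = marginal_loglik(p, Y[1:], None, [50.0])
        assert both == pytest.approx(one + two, abs=1e-10)

    def test_against_dense_trapezoid_oracle(self):
        rng = np.random.default_rng(3)
        basis = AgeBasis().fit(np.arange(72, dtype=float))
        for _ in range(25):
            J = rng.integers(1, 6)
            alphas = rng.uniform(0.5, 2.5, J)
            deltas = [np.sort(rng.uniform(-2, 2, rng.integers(1, 4)))
                      for _ in range(J)]
            for d in deltas:
                d += np.arange(len(d)) * 1e-3  # guarantee strict order
            gamma = random_bounded_gamma(rng, basis)
            p = GRMParameters(item_ids=[f"i{k}" for k in range(J)],
                              alpha=alphas, delta=deltas, gamma=gamma,
                              basis=basis)
            age = float(rng.integers(0, 72))
            mu = p.prior_means([age])[0]
            ys = [int(rng.integers(0, len(d) + 1)) for d in deltas]
            Y = np.array([ys], dtype=np.int16)
            ll = marginal_loglik(p, Y, None, [age])
            _, _, ll_oracle = trapezoid_posterior(alphas, deltas, ys, mu)
            assert ll == pytest.approx(ll_oracle, abs=1e-6)


class TestFit:
    def test_parameter_recovery(self, calibration_fit):
        cf = calibration_fit
        est, true = cf["res"].params, cf["params"]
        assert np.corrcoef(est.alpha, true.alpha)[0, 1] >= 0.90
        assert np.corrcoef(np.concatenate(est.delta),
                           np.concatenate(true.delta))[0, 1] >= 0.97

    def test_em_loglik_monotone(self, calibration_fit):
        tr = calibration_fit["res"].loglik_trace
        assert np.all(np.diff(tr) > -1e-8)

    def test_mle_dominates_truth(self, calibration_fit):
        cf = calibration_fit
        true = GRMParameters(item_ids=cf["bank"].item_ids,
                             alpha=cf["params"].alpha,
                             delta=cf["params"].delta,
                             gamma=cf["res"].params.gamma,
                             basis=cf["res"].params.basis)
        ll_true = marginal_loglik(true, cf["Y"], None, cf["ages"])
        assert cf["res"].loglik >= ll_true

    def test_binary_reduces_to_2pl_logistic_curve(self, calibration_fit):
        """K=2 category probabilities are exactly the 2PL item response
        function and its complement."""
        theta = np.linspace(-3, 3, 11)
        p = grm_category_probs(1.4, [0.6], theta)
        irf = expit(1.4 * (theta - 0.6))
        np.testing.assert_allclose(p[:, 1], irf, atol=1e-12)
        np.testing.assert_allclose(p[:, 0], 1 - irf, atol=1e-12)

    def test_identified_solution_stable_under_shifted_start(self,
                                                            calibration_fit):
        """Shifting all starting thresholds by a constant must return the
        same identified solution (centered latent regression pins location)."""
        cf = calibration_fit
        res = cf["res"]
        shifted = GRMParameters(
            item_ids=res.params.item_ids, alpha=res.params.alpha,
            delta=[d + 0.5 for d in res.params.delta],
            gamma=res.params.gamma, basis=res.params.basis)
        res2 = cf["model"].fit(start=shifted, max_cycles=500)
        np.testing.assert_allclose(res2.params.alpha, res.params.alpha,
                                   atol=0.02)
        np.testing.assert_allclose(np.concatenate(res2.params.delta),
                                   np.concatenate(res.params.delta),
                                   atol=0.03)

    def test_consistency_rmse_decreases_with_n(self):
        from kidbank.simulate import simulate_two_group
        rmses = []
        for n in (250, 1000, 4000):
            Y, bank, _, params, _ = simulate_two_group(
                n_per_group=n // 2, n_items=10, n_categories=3, seed=5)
            ages = np.random.default_rng(5).integers(0, 72, n)
            res = fit_grm(Y, bank, ages)
            err = np.concatenate([
                res.params.alpha - params.alpha,
                np.concatenate(res.params.delta)
                - np.concatenate(params.delta)])
            rmses.append(np.sqrt(np.mean(err ** 2)))
        assert rmses[2] < rmses[0]
        assert rmses[1] < rmses[0] * 1.2  # allow mild non-monotonic noise

    def test_category_collapse_warning_and_error(self, calibration_fit):
        import pandas as pd
        from kidbank.data import ItemBank
        bank = ItemBank(pd.DataFrame({
            "item_id": ["x"], "source_instrument": ["other"],
            "domain": ["cog_lang"], "n_categories": [3],
            "age_min_months": [0], "age_max_months": [71]}))
        rng = np.random.default_rng(0)
        Y = rng.integers(0, 2, size=(200, 1)).astype(np.int16)  # cat 2 absent
        with pytest.warns(RuntimeWarning, match="collapsing"):
            model = GradedResponseModel(Y, bank, rng.integers(0, 72, 200))
        assert model.K[0] == 2

    def test_params_json_round_trip(self, tmp_path, calibration_fit):
        p = calibration_fit["res"].params
        path = tmp_path / "params.json"
        p.save(path)
        p2 = GRMParameters.load(path)
        np.testing.assert_array_equal(p.alpha, p2.alpha)
        for d1, d2 in zip(p.delta, p2.delta):
            np.testing.assert_array_equal(d1, d2)
        np.testing.assert_array_equal(p.gamma, p2.gamma)
        ages = [0.0, 35.0, 71.0]
        np.testing.assert_allclose(p.prior_means(ages), p2.prior_means(ages))


def test_too_few_children_rejected(tiny_bank):
    Y = np.zeros((3, 3), dtype=np.int16)
    with pytest.raises(DataError):
        GradedResponseModel(Y, tiny_bank, [10, 20, 30])
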