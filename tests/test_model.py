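"""Two-channel Poisson mixture: likelihood oracle, EM behaviour, calling."""

import math

import numpy as np
import pytest

from stopem import (
    MixtureParams,
    SimulationScenario,
    TwoChannelPoissonEM,
    simulate_pair,
)

from conftest import make_pair


def brute_force_class_terms(pair, params):
    """Per-position, per-class joint probability computed term by term with
    exact Poisson pmfs (math.factorial), independent of the model code."""
    lo, hi = params.lambda_low, params.lambda_high
    lam = {"U": (lo, lo), "H": (hi, hi), "M": (hi, lo)}

    def pois(d, mu):
        return math.exp(-mu) * mu**d / math.factorial(d)

    rows = []
    for x in range(pair.length):
        n_t, n_c = pair.treated.coverage[x], pair.control.coverage[x]
        d_t, d_c = pair.treated.stops[x], pair.control.stops[x]
        if n_t == 0 or n_c == 0:
            rows.append(None)
            continue
        terms = [
            params.weights[k] * pois(d_t, lam[c][0] * n_t) * pois(d_c, lam[c][1] * n_c)
            for k, c in enumerate("UHM")
        ]
        rows.append(terms)
    return rows


def brute_force_loglik(pair, params):
    return sum(math.log(sum(t)) for t in brute_force_class_terms(pair, params) if t)


class TestLikelihoodOracle:
    params = MixtureParams(0.002, 0.02, np.array([0.9, 0.05, 0.05]))

    def test_loglik_matches_brute_force_on_toy_pair(self, toy_pair):
        model = TwoChannelPoissonEM.from_pair(toy_pair)
        assert model.loglik(self.params) == pytest.approx(
            brute_force_loglik(toy_pair, self.params), rel=1e-10
        )

    def test_e_step_matches_brute_force_enumeration(self, toy_pair):
        model = TwoChannelPoissonEM.from_pair(toy_pair)
        gamma = model.e_step(self.params)
        for x, terms in enumerate(brute_force_class_terms(toy_pair, self.params)):
            if terms is None:
                assert np.isnan(gamma[x]).all()
            else:
                total = sum(terms)
                np.testing.assert_allclose(
                    gamma[x], [t / total for t in terms], rtol=1e-10
                )

    def test_zero_count_position_closed_form(self):
        # single position, d=0 both channels: mixture of pure Poisson-zero masses
        pair = make_pair([0], [100], [0], [120])
        model = TwoChannelPoissonEM.from_pair(pair)
        p = self.params
        expected = math.log(
            p.weights[0] * math.exp(-p.lambda_low * 220)
            + p.weights[1] * math.exp(-p.lambda_high * 220)
            + p.weights[2] * math.exp(-(p.lambda_high * 100 + p.lambda_low * 120))
        )
        assert model.loglik(p) == pytest.approx(expected, rel=1e-12)

    def test_equal_rates_collapse_classes(self, toy_pair):
        """With lambda_low == lambda_high the likelihood ignores the weights
        and the posteriors equal the weights."""
        model = TwoChannelPoissonEM.from_pair(toy_pair)
        p1 = MixtureParams(0.01, 0.01, np.array([0.9, 0.05, 0.05]))
        p2 = MixtureParams(0.01, 0.01, np.array([0.2, 0.5, 0.3]))
        assert model.loglik(p1) == pytest.approx(model.loglik(p2), rel=1e-12)
        gamma = model.e_step(p2)
        for x in np.flatnonzero(model.usable):
            np.testing.assert_allclose(gamma[x], p2.weights, rtol=1e-9)

    def test_dominating_treated_spike_is_called_modified(self):
        pair = make_pair([200, 1], [1000, 1000], [0, 1], [1000, 1000])
        model = TwoChannelPoissonEM.from_pair(pair)
        gamma = model.e_step(MixtureParams(0.002, 0.2))
        assert gamma[0, 2] > 1 - 1e-6

    def test_random_small_pairs_match_oracle(self):
        """Oracle equivalence on random pairs of <= 20 positions."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            L = int(rng.integers(3, 21))
            cov = rng.integers(0, 400, size=(2, L))
            d = rng.poisson(0.01 * cov)
            pair = make_pair(d[0], cov[0], d[1], cov[1])
            w = rng.dirichlet([5, 1, 1])
            params = MixtureParams(
                float(rng.uniform(1e-4, 5e-3)), float(rng.uniform(1e-2, 0.1)), w
            )
            model = TwoChannelPoissonEM.from_pair(pair)
            expected = brute_force_loglik(pair, params)
            assert model.loglik(params) == pytest.approx(expected, rel=1e-10)


class TestMStep:
    def test_all_mass_on_unmodified_pools_both_channels(self, toy_pair):
        model = TwoChannelPoissonEM.from_pair(toy_pair)
        gamma = np.zeros((toy_pair.length, 3))
        gamma[:, 0] = 1.0
        params = model.m_step(gamma, prev=MixtureParams(0.001, 0.5))
        u = model.usable
        pooled = (model.d_t[u].sum() + model.d_c[u].sum()) / (
            model.n_t[u].sum() + model.n_c[u].sum()
        )
        assert params.lambda_low == pytest.approx(pooled)

    def test_hand_built_posteriors_match_weighted_ratio(self):
        pair = make_pair([2, 10, 4], [100, 100, 100], [1, 9, 0], [100, 100, 100])
        model = TwoChannelPoissonEM.from_pair(pair)
        g = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.2, 0.0, 0.8]])
        params = model.m_step(g, prev=MixtureParams(0.001, 0.01))
        # spreadsheet-style recompute of the weighted ratios
        num_low = 1.0 * (2 + 1) + 0.2 * (4 + 0) + 0.8 * 0
        den_low = 1.0 * 200 + 0.2 * 200 + 0.8 * 100
        num_high = 1.0 * (10 + 9) + 0.8 * 4
        den_high = 1.0 * 200 + 0.8 * 100
        assert params.lambda_low == pytest.approx(num_low / den_low)
        assert params.lambda_high == pytest.approx(num_high / den_high)
        np.testing.assert_allclose(params.weights, g.mean(axis=0))

    def test_channel_symmetry_without_modified_class(self):
        d = np.array([3, 20, 5])
        n = np.array([200, 210, 190])
        fwd = make_pair(d, n, d[::-1], n[::-1])
        swapped = make_pair(d[::-1], n[::-1], d, n)
        g = np.array([[1, 0, 0], [0, 1, 0], [1, 0, 0]], dtype=float)
        p1 = TwoChannelPoissonEM.from_pair(fwd).m_step(g, prev=MixtureParams(0.001, 0.01))
        p2 = TwoChannelPoissonEM.from_pair(swapped).m_step(g, prev=MixtureParams(0.001, 0.01))
        assert p1.lambda_low == pytest.approx(p2.lambda_low)
        assert p1.lambda_high == pytest.approx(p2.lambda_high)

    def test_vanished_class_keeps_previous_rate(self, toy_pair):
        model = TwoChannelPoissonEM.from_pair(toy_pair)
        gamma = np.zeros((toy_pair.length, 3))
        gamma[:, 0] = 1.0  # H and M vanish
        prev = MixtureParams(0.001, 0.37)
        params = model.m_step(gamma, prev=prev)
        assert params.lambda_high == pytest.approx(prev.lambda_high)
        assert params.weights[1] > 0  # floored, not zero


class TestFit:
    def test_parameter_recovery_on_default_scenario(self):
        scn = SimulationScenario(
            length=5000, mod_density=0.04, frac_high_both=0.02, seed=17
        )
        truth = simulate_pair(scn)
        res = TwoChannelPoissonEM.from_pair(truth.pair).fit()
        assert res.converged
        assert abs(res.params.lambda_low - scn.lambda_low) / scn.lambda_low < 0.2
        assert abs(res.params.lambda_high - scn.lambda_high) / scn.lambda_high < 0.2
        assert abs(res.params.weights[2] - 0.04) < 0.02

    def test_loglik_trace_non_decreasing(self):
        for seed in range(3):
            truth = simulate_pair(SimulationScenario(length=1500, seed=seed))
            res = TwoChannelPoissonEM.from_pair(truth.pair).fit()
            diffs = np.diff(res.log_likelihood_trace)
            slack = 1e-8 * np.abs(res.log_likelihood_trace[:-1])
            assert np.all(diffs >= -slack)

    def test_posteriors_normalized(self):
        truth = simulate_pair(SimulationScenario(length=1000, seed=5))
        res = TwoChannelPoissonEM.from_pair(truth.pair).fit()
        sums = res.posteriors[res.defined_mask].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_null_pair_yields_no_calls(self):
        truth = simulate_pair(SimulationScenario(length=2000, mod_density=0.0, seed=8))
        # treated channel literally identical to control
        pair = make_pair(
            truth.pair.control.stops,
            truth.pair.control.coverage,
            truth.pair.control.stops,
            truth.pair.control.coverage,
        )
        res = TwoChannelPoissonEM.from_pair(pair).fit()
        calls = res.call_modified(0.90)
        assert calls.n_called == 0

    def test_label_swap_invariance(self):
        truth = simulate_pair(SimulationScenario(length=1500, mod_density=0.04, seed=23))
        model = TwoChannelPoissonEM.from_pair(truth.pair)
        base = model.auto_init()
        swapped = MixtureParams(
            base.lambda_high, base.lambda_low, base.weights[[1, 0, 2]]
        )
        r1 = model.fit(init=base)
        r2 = model.fit(init=swapped)
        assert r1.params.lambda_low == pytest.approx(r2.params.lambda_low, rel=1e-6)
        assert r1.params.lambda_high == pytest.approx(r2.params.lambda_high, rel=1e-6)

    def test_too_few_positions_rejected(self):
        pair = make_pair([1] * 5, [10] * 5, [1] * 5, [10] * 5)
        with pytest.raises(ValueError, match=">= 10"):
            TwoChannelPoissonEM.from_pair(pair).fit()

    def test_fix_weights_keeps_initial_weights(self):
        truth = simulate_pair(SimulationScenario(length=1200, seed=31))
        model = TwoChannelPoissonEM.from_pair(truth.pair)
        init = model.auto_init()
        res = model.fit(init=init, fix_weights=True)
        np.testing.assert_allclose(res.params.weights, init.weights)

    def test_summary_mentions_fitted_rates(self):
        truth = simulate_pair(SimulationScenario(length=1200, seed=31))
        res = TwoChannelPoissonEM.from_pair(truth.pair).fit()
        text = res.summary()
        assert "lambda_low" in text and "converged" in text


@pytest.fixture(scope="module")
def fitted():
    truth = simulate_pair(SimulationScenario(length=2000, mod_density=0.04, seed=13))
    # knock out coverage at one position to exercise the undefined path
    truth.pair.treated.coverage[4] = 0
    model = TwoChannelPoissonEM.from_pair(truth.pair)
    return model.fit()


class TestCalling:
    def test_exact_threshold_not_called(self, fitted):
        import copy

        res = copy.deepcopy(fitted)
        res.posteriors[0] = [0.05, 0.05, 0.90]  # exactly at threshold
        calls = res.call_modified(0.90)
        assert not calls.called[0]  # strictly greater than required

    def test_zero_posterior_zero_calls(self, fitted):
        import copy

        res = copy.deepcopy(fitted)
        res.posteriors[:, 2] = 0.0
        assert res.call_modified(0.90).n_called == 0

    def test_call_count_monotone_in_threshold(self, fitted):
        counts = [fitted.call_modified(t).n_called for t in (0.5, 0.7, 0.9, 0.95, 0.99)]
        assert counts == sorted(counts, reverse=True)

    def test_undefined_positions_never_called(self, fitted):
        calls = fitted.call_modified(0.5)
        assert not calls.called[4]  # zero treated coverage
        assert np.isnan(calls.p_modified[4])

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_threshold_rejected(self, fitted, threshold):
        with pytest.raises(ValueError):
            fitted.call_modified(threshold)
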