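"""Analytic uncertainty/sensitivity analysis against Monte Carlo oracles."""

import numpy as np
import pytest

from cardioemu.design import InputSpace
from cardioemu.emulator import GaussianProcessEmulator
from cardioemu.errors import DegenerateOutputError
from cardioemu.lr1991 import StimulusProtocol
from cardioemu.sensitivity import (
    InputDistribution,
    main_effect_indices,
    mc_oracle,
    mean_effect,
    propagate_distribution,
    uncertainty_analysis,
)


@pytest.fixture(scope="module")
def dist():
    return InputDistribution()


def _fit(f, n=50, seed=0, **kw):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 6))
    kw.setdefault("n_restarts", 4)
    return GaussianProcessEmulator(**kw).fit(X, f(X)), X


class TestUncertaintyAnalysis:
    def test_constant_output(self, dist):
        em, _ = _fit(lambda X: np.full(X.shape[0], 4.2), n=20)
        ua = uncertainty_analysis(em, dist)
        assert ua.e_mean == pytest.approx(4.2, abs=1e-6)
        assert ua.e_var == pytest.approx(0.0, abs=1e-8)
        assert ua.cov == pytest.approx(0.0, abs=1e-4)

    def test_linear_output_closed_form(self, dist):
        em, _ = _fit(lambda X: X[:, 0], n=40, seed=1)
        ua = uncertainty_analysis(em, dist)
        assert ua.e_mean == pytest.approx(0.5, abs=1e-3)
        assert ua.e_var == pytest.approx(0.04, rel=0.02)

    def test_matches_emulator_monte_carlo(self, toy_surface, dist):
        _, _, em = toy_surface
        ua = uncertainty_analysis(em, dist)
        rng = np.random.default_rng(2)
        z = dist.sample(10000, rng)
        vals = em.predict(z)
        se_mean = vals.std(ddof=1) / 100.0
        assert abs(ua.e_mean - vals.mean()) < 3 * se_mean
        var_se = vals.var(ddof=1) * np.sqrt(2.0 / (vals.size - 1))
        assert abs(ua.e_var - vals.var(ddof=1)) < 3 * var_se + 1e-4


class TestMeanEffect:
    def test_additive_separation(self, dist):
        em, _ = _fit(lambda X: X[:, 0], n=40, seed=3)
        grid = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        curve0 = mean_effect(em, 0, grid, dist)
        curve1 = mean_effect(em, 1, grid, dist)
        assert np.allclose(curve0, grid, atol=5e-3)
        assert np.allclose(curve1, 0.5, atol=5e-3)

    def test_matches_double_loop_monte_carlo(self, toy_surface, dist):
        _, _, em = toy_surface
        rng = np.random.default_rng(4)
        inner = dist.sample(40000, rng)
        for s in (0.2, 0.7):
            z = inner.copy()
            z[:, 1] = s
            mc = em.predict(z)
            analytic = mean_effect(em, 1, np.array([s]), dist)[0]
            se = mc.std(ddof=1) / np.sqrt(mc.size)
            assert abs(analytic - mc.mean()) < 3 * se


class TestMainEffectIndices:
    def test_additive_function_shares(self, dist):
        em, _ = _fit(lambda X: X[:, 0] + X[:, 1], n=50, seed=5)
        sa = main_effect_indices(em, dist)
        assert sa.indices[0] == pytest.approx(0.5, abs=0.02)
        assert sa.indices[1] == pytest.approx(0.5, abs=0.02)
        assert np.all(sa.indices[2:] < 0.01)
        assert sa.sum_of_indices == pytest.approx(1.0, abs=0.02)

    def test_pure_interaction_has_no_main_effects(self, dist):
        em, _ = _fit(lambda X: (X[:, 0] - 0.5) * (X[:, 1] - 0.5), n=60, seed=6)
        sa = main_effect_indices(em, dist)
        assert np.all(sa.indices < 0.05)

    def test_recovers_analytic_variance_shares(self, dist):
        # y = x1 + 2*x2: shares v/(5v) and 4v/(5v)
        em, _ = _fit(lambda X: X[:, 0] + 2.0 * X[:, 1], n=50, seed=7)
        sa = main_effect_indices(em, dist)
        assert sa.indices[0] == pytest.approx(0.2, abs=0.05)
        assert sa.indices[1] == pytest.approx(0.8, abs=0.05)

    def test_affine_invariance_of_indices(self, toy_surface, dist):
        import json

        _, _, em = toy_surface
        payload = json.loads(em.to_json())
        payload["y"] = (10.0 - 5.0 * np.array(payload["y"])).tolist()
        em2 = GaussianProcessEmulator.from_json(json.dumps(payload))
        s1 = main_effect_indices(em, dist)
        s2 = main_effect_indices(em2, dist)
        assert np.allclose(s1.indices, s2.indices, atol=1e-6)

    def test_degenerate_output_rejected(self, dist):
        em, _ = _fit(lambda X: np.full(X.shape[0], 1.0), n=20, seed=8)
        with pytest.raises(DegenerateOutputError):
            main_effect_indices(em, dist)

    def test_matches_monte_carlo_on_toy_surface(self, toy_surface, dist):
        _, _, em = toy_surface
        sa = main_effect_indices(em, dist)
        rng = np.random.default_rng(9)
        z = dist.sample(60000, rng)
        vals = em.predict(z)
        var_tot = vals.var(ddof=1)
        # conditional-mean variance of input 0 by binning
        order = np.argsort(z[:, 0])
        nb = 60
        chunks = np.array_split(vals[order], nb)
        v0 = np.var([c.mean() for c in chunks], ddof=1)
        assert sa.indices[0] == pytest.approx(v0 / var_tot, abs=0.05)


class TestPropagation:
    def test_degenerate_distribution_is_spike(self, toy_surface):
        _, _, em = toy_surface
        tiny = InputDistribution(var=np.full(6, 1e-12))
        res = propagate_distribution(em, tiny, n_samples=200, seed=0)
        nominal = em.predict(np.full((1, 6), 0.5))[0]
        assert res.samples.std() < 1e-5
        assert res.samples.mean() == pytest.approx(nominal, abs=1e-5)

    def test_output_sd_monotone_in_input_sd(self, toy_surface):
        _, _, em = toy_surface
        sds = []
        for s in (0.01, 0.02, 0.05, 0.1):
            d = InputDistribution.varying_one(0, s**2)
            sds.append(np.sqrt(uncertainty_analysis(em, d).e_var))
        assert np.all(np.diff(sds) > 0)

    def test_propagation_consistent_with_analytic_ua(self, toy_surface, dist):
        _, _, em = toy_surface
        res = propagate_distribution(em, dist, n_samples=20000, seed=1)
        ua = uncertainty_analysis(em, dist)
        assert res.samples.mean() == pytest.approx(ua.e_mean, abs=0.02)
        assert res.samples.std(ddof=1) == pytest.approx(np.sqrt(ua.e_var), rel=0.05)

    def test_sample_floor(self, toy_surface, dist):
        _, _, em = toy_surface
        with pytest.raises(ValueError):
            propagate_distribution(em, dist, n_samples=10)


class TestMcOracle:
    def test_emulator_propagation_matches_simulator_monte_carlo(self, apd90_emulator):
        """Mirror of the published emulator-vs-simulator density check:
        with only the repolarising conductance uncertain, the APD90
        distribution propagated through the emulator matches a direct
        simulator Monte Carlo (reduced n) in location and spread."""
        d = InputDistribution.varying_one(2, 0.1**2)
        prop = propagate_distribution(apd90_emulator, d, n_samples=20000, seed=0)
        sim = mc_oracle(InputSpace(), StimulusProtocol(), d, 200, seed=1)
        apd = sim[:, 3]
        assert prop.samples.mean() == pytest.approx(apd.mean(), rel=0.01)
        rel_se = 1.0 / np.sqrt(2.0 * (apd.size - 1))   # SE of a sample SD
        assert prop.samples.std(ddof=1) == pytest.approx(
            apd.std(ddof=1), rel=3 * rel_se
        )

    def test_deterministic_per_seed(self):
        space = InputSpace()
        p = StimulusProtocol()
        d = InputDistribution.varying_one(2, 0.01**2)
        a = mc_oracle(space, p, d, 2, seed=5)
        b = mc_oracle(space, p, d, 2, seed=5)
        assert np.array_equal(a, b)

    def test_single_draw_equals_direct_run(self):
        from cardioemu.biomarkers import extract_ap_biomarkers
        from cardioemu.lr1991 import Conductances, run_s1_protocol

        space = InputSpace()
        p = StimulusProtocol()
        d = InputDistribution.varying_one(2, 0.01**2)
        rng = np.random.default_rng(6)
        x = d.sample(1, rng)[0]
        sample = mc_oracle(space, p, d, 1, seed=6)
        bm = extract_ap_biomarkers(
            run_s1_protocol(Conductances.from_array(space.denormalize(x)), p)
        )
        assert np.allclose(sample[0], bm.as_array()[:6])
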