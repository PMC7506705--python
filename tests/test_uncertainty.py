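import numpy as np
import pytest

from fireflysim.exceptions import DomainError
from fireflysim.instrument import NoiseModel
from fireflysim.retrieval import indirect_retrieve
from fireflysim.uncertainty import (Influence, aggregate_and_fit,
                                    apply_influence, cv_residual,
                                    indirect_error_closed_form,
                                    indirect_error_sd, monte_carlo_ci,
                                    paired_aggregation_experiment,
                                    trimmed_windows)

WL = np.linspace(670.0, 780.0, 500)


class TestApplyInfluence:
    def test_zero_magnitude_identity_bit_exact(self):
        spec = np.random.default_rng(0).uniform(10, 200, WL.size)
        for infl in (Influence("uniform", u=0.0),
                     Influence("slope", m=0.0),
                     Influence("random", sigma=0.0, seed=1)):
            out = apply_influence(spec, WL, infl)
            assert np.array_equal(out, spec)

    def test_slope_arithmetic(self):
        spec = np.zeros(WL.size)
        out = apply_influence(spec, WL, Influence("slope", m=1.0,
                                                  pivot_nm=670.0))
        i = np.argmin(np.abs(WL - 680.0))
        assert out[i] == pytest.approx(WL[i] - 670.0)

    def test_random_sd_matches_noise_model(self):
        nm = NoiseModel()
        spec = np.array([16.88, 60.0, 164.94])
        rng = np.random.default_rng(5)
        draws = np.stack([apply_influence(spec, spec, Influence(
            "random", noise_model=nm), rng=rng) for _ in range(10000)])
        sd = draws.std(axis=0, ddof=1)
        assert np.all(np.abs(sd - nm.sigma(spec)) / nm.sigma(spec) < 0.03)

    def test_exactly_one_kind(self):
        with pytest.raises(DomainError):
            Influence("banana")
        with pytest.raises(DomainError):
            Influence("random")   # no sigma, no model


class TestClosedForms:
    def test_zero_gradient(self):
        assert indirect_error_closed_form(0.0, 0.15, 0.9) == 0.0

    def test_sign_rule(self):
        # peak raised relative to the valley (positive m, redward peak)
        # biases the retrieval negative, and vice versa
        assert indirect_error_closed_form(1.0, 0.15, 0.5) < 0
        assert indirect_error_closed_form(-1.0, 0.15, 0.5) > 0
        assert indirect_error_closed_form(1.0, -0.15, 0.5) > 0

    def test_magnitude_monotonic_in_all_drivers(self):
        base = abs(indirect_error_closed_form(1.0, 0.1, 0.5))
        assert abs(indirect_error_closed_form(2.0, 0.1, 0.5)) > base
        assert abs(indirect_error_closed_form(1.0, 0.2, 0.5)) > base
        assert abs(indirect_error_closed_form(1.0, 0.1, 0.7)) > base

    def test_matches_direct_simulation(self):
        # perturb an ideal pair with a slope pivoted at the valley and
        # compare with the closed form
        k, p0, delta, m = 0.3, 120.0, 0.153, 2.5
        v = k * p0
        err = indirect_retrieve(v, p0 + m * delta, k) - 0.0
        assert err == pytest.approx(
            indirect_error_closed_form(m, delta, k), rel=1e-12)

    def test_valley_only_influence_amplified(self):
        for k in (0.2, 0.5, 0.8):
            u_v = 1.0
            err = indirect_retrieve(k * 100.0 + u_v, 100.0, k)
            assert err == pytest.approx(u_v / (1.0 - k))
            assert err > u_v
        # amplification grows with k
        errs = [indirect_retrieve(k * 100.0 + 1.0, 100.0, k)
                for k in (0.2, 0.5, 0.8)]
        assert errs[0] < errs[1] < errs[2]

    def test_gaussian_propagation_sd(self):
        nm = NoiseModel()
        v0, p0, k = 16.88, 153.45, 0.11
        rng = np.random.default_rng(21)
        n = 100000
        v = v0 + rng.normal(0, nm.sigma(v0), n)
        p = p0 + rng.normal(0, nm.sigma(p0), n)
        err = indirect_retrieve(v, p, k) - indirect_retrieve(v0, p0, k)
        expected = indirect_error_sd(nm.sigma(v0), nm.sigma(p0), k)
        assert err.std(ddof=1) == pytest.approx(expected, rel=0.03)


class TestMonteCarloCI:
    def test_inverse_sqrt_n_law(self):
        df = monte_carlo_ci(16.88, 153.45, 0.11, NoiseModel(), 8000,
                            reps=4, seed=2)
        for col in ("ci_direct", "ci_indirect"):
            ratio = df[col][1999] / df[col][7999]
            assert ratio == pytest.approx(2.0, rel=0.05)

    def test_indirect_to_direct_ratio(self):
        nm = NoiseModel()
        v0, p0, k = 16.88, 153.45, 0.11
        df = monte_carlo_ci(v0, p0, k, nm, 20000, seed=3)
        expected = np.sqrt(1.0 + k ** 2 * (nm.sigma(p0) / nm.sigma(v0)) ** 2) \
            / (1.0 - k)
        n = 19999
        assert df.ci_indirect[n] / df.ci_direct[n] == pytest.approx(
            expected, rel=0.05)

    def test_zero_noise_zero_ci(self):
        df = monte_carlo_ci(16.88, 153.45, 0.11, None, 500, seed=4)
        assert (df.ci_direct == 0).all() and (df.ci_indirect == 0).all()


class TestAggregation:
    def test_factor_one_noise_free_exact(self, veg36_scene):
        silent = NoiseModel(amplitude=0.0)
        res = aggregate_and_fit(veg36_scene, 1, method="direct", seed=0,
                                noise_model=silent)
        assert res.params.apex_740 == pytest.approx(2.5, rel=1e-5)
        res_i = aggregate_and_fit(veg36_scene, 1, method="indirect", seed=0,
                                  noise_model=silent)
        # the FLD pair spans ~0.15 nm, over which the emission curve varies
        # slightly, so indirect recovery is near-exact rather than exact
        assert res_i.params.apex_740 == pytest.approx(2.5, rel=5e-3)

    def test_not_enough_pixels(self, veg36_scene):
        with pytest.raises(DomainError, match="vegetation"):
            aggregate_and_fit(veg36_scene, 7)

    def test_direct_beats_indirect_smoke(self, veg36_scene):
        df = paired_aggregation_experiment(veg36_scene, 6, reps=8, seed=5)
        assert df.ssr_direct.median() < df.ssr_indirect.median()

    def test_ssr_improves_with_aggregation(self, veg36_scene):
        ssr = {}
        for factor in (2, 6):
            reps = []
            for r in range(15):
                res = aggregate_and_fit(veg36_scene, factor,
                                        method="indirect", seed=100 + r)
                reps.append(res.ssr)
            ssr[factor] = np.median(reps)
        assert ssr[6] <= ssr[2]


class TestCvResidual:
    def _series(self, rng, n, bands=np.linspace(20.0, 200.0, 40)):
        nm = NoiseModel()
        return bands + rng.normal(0, nm.sigma(bands), (n, bands.size)), nm

    def test_self_consistent_residual_near_zero(self):
        rng = np.random.default_rng(8)
        series, nm = self._series(rng, 10000)
        resid = cv_residual(series, nm)
        assert np.abs(np.nanmean(resid)) < 0.002

    def test_trending_window_trimmed(self):
        rng = np.random.default_rng(9)
        series, nm = self._series(rng, 600)
        series[100:200] += np.linspace(0, 30, 100)[:, None]   # drift
        mask = trimmed_windows(series)
        assert mask[1] and not mask[0]
        resid = cv_residual(series, nm)   # survives with drift removed
        assert np.abs(np.nanmean(resid)) < 0.01

    def test_extra_variance_detected(self):
        rng = np.random.default_rng(10)
        series, nm = self._series(rng, 600)
        series += rng.normal(0, 2.0, series.shape)   # un-modelled variance
        resid = cv_residual(series, nm)
        assert np.nanmean(resid) > 0.0

    def test_all_windows_trimmed_is_an_error(self):
        rng = np.random.default_rng(11)
        series, nm = self._series(rng, 200)
        series += np.linspace(0, 50, 200)[:, None]
        with pytest.raises(DomainError, match="trimmed"):
            cv_residual(series, nm)

    def test_needs_enough_repeats(self):
        with pytest.raises(DomainError):
            cv_residual(np.ones((50, 5)), NoiseModel())
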