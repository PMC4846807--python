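import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import gammaln
from scipy.stats import norm

from forestdiv import sad_fit as sf
from forestdiv.synthetic_data import gen_community, model_proportions


class TestExpectedCurves:
    def test_broken_stick_hand_values(self):
        np.testing.assert_allclose(
            sf.expected_broken_stick(30, 3), [18.333333, 8.333333, 3.333333], atol=1e-5
        )
        assert sf.expected_broken_stick(17, 1)[0] == pytest.approx(17.0)

    @given(st.integers(1, 40), st.integers(1, 500))
    def test_broken_stick_conserves_total(self, S, extra):
        N = S + extra
        assert sf.expected_broken_stick(N, S).sum() == pytest.approx(N, rel=1e-12)

    def test_preemption_hand_values_and_decay(self):
        np.testing.assert_allclose(sf.expected_preemption(100, 3, 0.5), [50, 25, 12.5])
        a = sf.expected_preemption(1000, 20, 0.17)
        assert (np.diff(a) < 0).all()

    @given(st.floats(0.01, 0.99), st.integers(2, 30))
    def test_preemption_partial_sum_closed_form(self, alpha, S):
        N = 1000.0
        total = sf.expected_preemption(N, S, alpha).sum()
        assert total == pytest.approx(N * (1 - (1 - alpha) ** S), rel=1e-9)

    def test_preemption_domain(self):
        with pytest.raises(ValueError):
            sf.expected_preemption(10, 3, 1.5)

    def test_lognormal_degenerate_and_median(self):
        a = sf.expected_lognormal(7, 10.0, 1.0 + 1e-9)
        np.testing.assert_allclose(a, 10.0, rtol=1e-6)
        # odd S: middle rank sits exactly at plotting position 0.5
        a = sf.expected_lognormal(5, 10.0, np.e)
        assert a[2] == pytest.approx(10.0, rel=1e-12)

    def test_lognormal_matches_quantile_oracle(self):
        # independent recomputation: ranks 1..5, positions (5-r+0.5)/5
        a = sf.expected_lognormal(5, 10.0, np.e)
        for r in range(1, 6):
            phi = norm.ppf((5 - r + 0.5) / 5)
            assert a[r - 1] == pytest.approx(np.exp(np.log(10) + phi), rel=1e-12)

    def test_zipf_hand_values(self):
        np.testing.assert_allclose(
            sf.expected_zipf(100, 3, 0.5, -1.0), [50, 25, 50 / 3], rtol=1e-12
        )

    @given(st.floats(0.05, 0.9), st.floats(-2.5, -0.2), st.integers(3, 25))
    def test_zm_reduces_to_zipf_at_beta_zero(self, p1, gamma, S):
        z = sf.expected_zipf(500, S, p1, gamma)
        zm = sf.expected_zm(500, S, p1, 0.0, gamma)
        np.testing.assert_allclose(z, zm, rtol=1e-12)

    def test_zipf_parameter_recovery(self, rng):
        # data generated from Zipf(gamma=-1.2): fitted exponent within 0.1
        p = model_proportions("zipf", 50, {"gamma": -1.2})
        gammas = []
        for seed in range(5):
            x = np.random.default_rng(seed).multinomial(20000, p)
            fit = sf.fit_sad(x, "zipf")
            gammas.append(fit.params["gamma"])
        assert np.mean(gammas) == pytest.approx(-1.2, abs=0.1)


class TestNeutralPhi:
    def test_nonnegative_on_parameter_grid(self):
        phi = sf.neutral_phi(np.array([1, 5, 50, 500, 1000]), 50.0, 0.1, 1000)
        assert (np.asarray(phi) >= 0).all()

    def test_abundance_weighted_sum_is_community_size(self):
        J = 200
        phi = sf.neutral_phi(np.arange(1, J + 1), 50.0, 0.1, J)
        assert np.sum(np.arange(1, J + 1) * phi) == pytest.approx(J, rel=0.01)

    def test_high_migration_limit_approaches_ewens_expectation(self):
        # m -> 1: the local community becomes a metacommunity (Ewens) sample.
        # The mean-field sampling formula tracks the Ewens expectation
        # E[species with n individuals] = (theta/n) prod (J-i)/(theta+J-1-i)
        # closely but not exactly (see the J=2 closed form below), so the
        # comparison is at the approximation's accuracy, not machine precision.
        J, theta = 100, 8.0
        phi = np.asarray(sf.neutral_phi(np.arange(1, J + 1), theta, 0.999, J))
        i = np.arange(J)
        for n in (1, 2, 5, 10, 25):
            ew = theta / n * np.prod((J - i[:n]) / (theta + J - 1 - i[:n]))
            assert phi[n - 1] == pytest.approx(ew, rel=0.08)

    def test_high_migration_limit_closed_form_at_j_two(self):
        # J=2, m -> 1: the integral evaluates analytically to
        # phi_1 = 2 (theta - 1 + e^-theta) / theta
        theta = 8.0
        limit = 2 * (theta - 1 + np.exp(-theta)) / theta
        assert sf.neutral_phi(1, theta, 0.99999, 2) == pytest.approx(limit, rel=1e-4)

    def test_quadrature_agrees_with_dense_trapezoid(self):
        # brute-force log-domain trapezoid on a fine grid, 4 significant digits
        theta, m, J = 20.0, 0.3, 60
        g = m * (J - 1) / (1 - m)
        y = np.linspace(0, g, 2_000_001)[:-1]
        for n in (1, 3, 10, 30, 60):
            li = (
                gammaln(n + y) - gammaln(1 + y)
                + gammaln(J - n + g - y) - gammaln(g - y)
                - y * theta / g
            )
            integral = np.trapezoid(np.exp(li - li.max()), y) * np.exp(li.max())
            oracle = (
                theta
                * np.exp(gammaln(J + 1) - gammaln(n + 1) - gammaln(J - n + 1))
                * np.exp(gammaln(g) - gammaln(J + g))
                * integral
            )
            assert sf.neutral_phi(n, theta, m, J) == pytest.approx(oracle, rel=1e-4)

    def test_parameter_domain(self):
        with pytest.raises(ValueError):
            sf.neutral_phi(1, -1.0, 0.5, 100)
        with pytest.raises(ValueError):
            sf.neutral_phi(1, 10.0, 1.5, 100)


class TestFitting:
    def test_aic_identity(self):
        assert sf.aic(-10.0, 2) == 24.0

    def test_aic_identity_on_every_fit(self, belt_counts):
        for fit in sf.compare_models(belt_counts["pine-oak"]):
            if fit.converged and np.isfinite(fit.logL):
                assert fit.AIC == -2 * fit.logL + 2 * fit.k

    def test_ks_zero_iff_identical(self):
        a = np.array([50.0, 20, 10, 5, 1])
        stat, _ = sf.ks_discrepancy(a, a.copy())
        assert stat == 0.0
        stat2, _ = sf.ks_discrepancy(a, a * 3)
        assert 0 < stat2 <= 1

    def test_ks_stat_within_unit_interval(self, belt_counts):
        for fit in sf.compare_models(belt_counts["birch"]):
            if fit.converged:
                assert 0 <= fit.ks_stat <= 1

    def test_comparison_always_reports_six_models(self, belt_counts):
        fits = sf.compare_models(belt_counts["birch"])
        assert len(fits) == 6
        assert {f.model for f in fits} == set(sf.MODELS)
        for f in fits:
            assert np.isfinite(f.AIC) or not f.converged

    def test_failures_sort_last(self):
        fits = [
            sf.SADFitResult(model="a", AIC=10.0, converged=True),
            sf.SADFitResult(model="b", AIC=5.0, converged=False),
            sf.SADFitResult(model="c", AIC=7.0, converged=True),
        ]
        ordered = sorted(fits, key=lambda f: (not f.converged, f.AIC))
        assert [f.model for f in ordered] == ["c", "a", "b"]

    def test_dominant_plus_singletons_prefers_geometric_family(self):
        x = np.array([400] + [1] * 15)
        fits = {f.model: f for f in sf.compare_models(x)}
        geometric_best = min(
            fits[m].AIC for m in ("niche-preemption", "zipf", "zipf-mandelbrot")
            if fits[m].converged
        )
        assert geometric_best < fits["broken-stick"].AIC

    def test_preemption_recovers_alpha(self):
        x = gen_community(25, 5000, "niche-preemption", {"alpha": 0.25}, seed=11)
        fit = sf.fit_sad(x, "niche-preemption")
        assert fit.params["alpha"] == pytest.approx(0.25, abs=0.03)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            sf.fit_sad([5, 3], "zipf")
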