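import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from forestdiv import hill_diversity as hd
from forestdiv.plot_data import IncidenceTable


def _incidence(y):
    return IncidenceTable(pd.Series(dict(enumerate(y[0]))), y[1])


counts_strategy = st.lists(st.integers(min_value=1, max_value=60), min_size=2, max_size=12)


class TestHillNumber:
    def test_uniform_community_gives_richness_for_every_q(self):
        for q in (0, 1, 2):
            assert hd.hill_number([10, 10, 10, 10], q) == pytest.approx(4.0)

    def test_hand_computed_simpson(self):
        # p = (0.9, 0.1): 1/(0.81 + 0.01)
        assert hd.hill_number([9, 1], 2) == pytest.approx(1 / 0.82, rel=1e-12)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            hd.hill_number([0, 0], 1)

    @given(counts_strategy)
    def test_monotone_nonincreasing_in_q(self, x):
        d = [hd.hill_number(x, q) for q in (0, 1, 2)]
        assert d[0] >= d[1] - 1e-9 >= d[2] - 2e-9


class TestCoverage:
    def test_no_singletons_means_complete_coverage(self):
        assert hd.coverage_estimate([5, 5, 3]) == 1.0

    def test_all_singletons_means_zero_coverage(self):
        assert hd.coverage_estimate([1] * 10) == 0.0

    def test_interpolated_coverage_matches_exact_combinatorics(self):
        # independent oracle: same estimator assembled from exact rational
        # binomial coefficients instead of log-gamma floats
        x = [5, 3, 2, 1, 1]
        n = sum(x)
        for m in (2, 4, 6, 9, 11):
            est = hd.coverage_estimate(x, m)
            oracle = 1 - sum(
                Fraction(xi, n) * Fraction(math.comb(n - xi, m), math.comb(n - 1, m))
                for xi in x
            )
            assert est == pytest.approx(float(oracle), rel=1e-10)

    def test_nondecreasing_in_m_through_reference_and_beyond(self, belt_counts):
        x = belt_counts["birch"]
        n = int(x.sum())
        grid = [1, n // 4, n // 2, n - 1, n, n + n // 2, 2 * n]
        cov = [hd.coverage_estimate(x, m) for m in grid]
        assert all(b >= a - 1e-12 for a, b in zip(cov, cov[1:]))
        assert 0 <= cov[0] and cov[-1] <= 1

    def test_beyond_doubling_rejected(self):
        with pytest.raises(ValueError, match="extrapolation range"):
            hd.coverage_estimate([3, 2, 1], 13)


class TestRarefaction:
    def test_reference_endpoint_identity(self, belt_counts):
        x = belt_counts["pine-oak"]
        n = int(x.sum())
        for q in (0, 1, 2):
            assert hd.rarefy(x, q, n).estimate == pytest.approx(hd.hill_number(x, q), rel=1e-12)

    def test_single_individual_is_one_species(self):
        for q in (0, 1, 2):
            assert hd.rarefy([4, 2, 1], q, 1).estimate == pytest.approx(1.0, abs=1e-9)

    def test_richness_matches_exhaustive_enumeration(self):
        # all C(7,3) subsamples of the 7 individuals of community [4,2,1]
        x = [4, 2, 1]
        ind = [0] * 4 + [1] * 2 + [2]
        m = 3
        vals = [len(set(c)) for c in itertools.combinations(ind, m)]
        assert hd.rarefy(x, 0, m).estimate == pytest.approx(np.mean(vals), rel=1e-12)

    def test_shannon_matches_exhaustive_enumeration(self):
        # expected plug-in entropy over all subsamples of a 12-individual toy
        x = [6, 3, 2, 1]
        ind = sum(([i] * c for i, c in enumerate(x)), [])
        m = 5
        ents = []
        for c in itertools.combinations(ind, m):
            p = np.bincount(c, minlength=4) / m
            p = p[p > 0]
            ents.append(-np.sum(p * np.log(p)))
        assert hd.rarefy(x, 1, m).estimate == pytest.approx(np.exp(np.mean(ents)), rel=1e-10)

    def test_curves_nondecreasing_in_m(self, belt_counts):
        x = belt_counts["birch"]
        n = int(x.sum())
        grid = hd.knot_grid(n, knots=15)
        for q in (0, 1, 2):
            est = [hd.estimate_at(x, q, m).estimate for m in grid]
            assert all(b >= a - 1e-8 for a, b in zip(est, est[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hd.rarefy([4, 2, 1], 0, 8)
        with pytest.raises(ValueError):
            hd.rarefy([4, 2, 1], 0, 0)


class TestExtrapolation:
    def test_complete_sample_stays_flat(self):
        x = [5, 4, 3]  # f1 = 0: no unseen-species signal
        n = sum(x)
        for m in (n + 1, n + 5, 2 * n):
            assert hd.extrapolate(x, 0, m).estimate == pytest.approx(3.0)

    def test_doubling_rule(self):
        assert hd.doubling_rule([2934, 2752]) == 5504

    def test_continuity_at_reference(self, belt_counts):
        for x in belt_counts.values():
            n = int(x.sum())
            for q in (0, 1, 2):
                obs = hd.estimate_at(x, q, n).estimate
                below = hd.estimate_at(x, q, n - 1).estimate
                above = hd.estimate_at(x, q, n + 1).estimate
                assert below == pytest.approx(obs, rel=5e-3)
                assert above == pytest.approx(obs, rel=5e-3)
                # the two segments meet the observed value to 6 significant
                # digits in the limit: evaluate the analytic segments at n
                assert hd.rarefy(x, q, n).estimate == pytest.approx(obs, rel=1e-9)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            hd.extrapolate([4, 2, 1], 0, 7)  # not beyond reference
        with pytest.raises(ValueError):
            hd.extrapolate([4, 2, 1], 0, 15)  # beyond doubling


class TestIncidence:
    def test_reference_identities(self):
        t = _incidence(([5, 3, 1], 5))
        y = np.array([5.0, 3, 1])
        p = y / y.sum()
        assert hd.hill_number_incidence(t, 0) == 3
        assert hd.hill_number_incidence(t, 1) == pytest.approx(np.exp(-np.sum(p * np.log(p))))
        assert hd.hill_number_incidence(t, 2) == pytest.approx(1 / np.sum(p**2))

    def test_richness_matches_unit_enumeration(self):
        # 4 units; species occupy fixed unit subsets; enumerate C(4,2) unit picks
        occup = {"a": {0, 1, 2, 3}, "b": {0, 1}, "c": {2}}
        T = 4
        t = IncidenceTable(pd.Series({k: len(v) for k, v in occup.items()}), T)
        vals = [
            sum(1 for sp in occup.values() if sp & set(pick))
            for pick in itertools.combinations(range(T), 2)
        ]
        assert hd.rarefy(t, 0, 2).estimate == pytest.approx(np.mean(vals), rel=1e-12)

    def test_monotone_and_continuous(self, survey):
        from forestdiv.plot_data import incidence_table

        stems, plots, _ = survey
        t = incidence_table([s for s in stems if s.belt == "birch"],
                            [p for p in plots if p.stand_code.endswith("BA")])
        T = t.T
        for q in (0, 1, 2):
            grid = list(range(1, 2 * T + 1))
            est = [hd.estimate_at(t, q, m).estimate for m in grid]
            assert all(b >= a - 1e-8 for a, b in zip(est, est[1:]))
            assert est[T - 1] == pytest.approx(hd.hill_number_incidence(t, q), rel=1e-9)


class TestBootstrap:
    def test_deterministic_under_fixed_seed(self, belt_counts):
        x = belt_counts["pine-oak"]
        a = hd.bootstrap_ci(x, q=1, m_grid=[100, 500], replications=2, seed=7)
        b = hd.bootstrap_ci(x, q=1, m_grid=[100, 500], replications=2, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = hd.bootstrap_ci(x, q=1, m_grid=[100, 500], replications=2, seed=8)
        assert not a.equals(c)

    def test_single_species_zero_width_richness_ci(self):
        df = hd.bootstrap_ci([50], q=0, m_grid=[25, 50], replications=20, seed=0)
        assert np.allclose(df.ci_high - df.ci_low, 0.0)

    def test_band_contains_point_estimate(self, belt_counts):
        x = belt_counts["birch"]
        df = hd.bootstrap_ci(x, q=(0, 1, 2), m_grid=[200, int(x.sum())], replications=30, seed=3)
        assert ((df.ci_low <= df.estimate) & (df.estimate <= df.ci_high)).all()
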