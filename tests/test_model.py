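"""Analytic model: pass kernel, survival probabilities, theory surfaces."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrdyn.params import (
    PositionGrid,
    StrataConfig,
    TcrParams,
    initiation_mixture,
)
from tcrdyn.model import (
    bypass_fraction,
    expected_obs_exp,
    m_bounds_from_census,
    pass_transition,
    survival_probability,
    theory_surface,
)


class TestInitiationMixture:
    @pytest.mark.parametrize(
        "m,e,n_floor,c",
        [
            (1.5, 2.0, 3, 1.0),       # integral product: all genes at the floor
            (1.0, 0.0, 0, 1.0),       # no expression, no initiations
            (1.59, 11.15, 17, 0.2715),  # stratum-6 median at the fitted m
        ],
    )
    def test_examples(self, m, e, n_floor, c):
        mx = initiation_mixture(m, e)
        assert mx.n_floor == n_floor
        assert mx.c == pytest.approx(c, abs=1e-9)

    @given(
        m=st.floats(0, 20, allow_nan=False),
        e=st.floats(0, 50, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_mean_preserved(self, m, e):
        mx = initiation_mixture(m, e)
        assert mx.mean == pytest.approx(m * e, abs=1e-9)
        assert 0.0 < mx.c <= 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            initiation_mixture(-1.0, 2.0)
        with pytest.raises(ValueError):
            initiation_mixture(1.0, -2.0)


class TestPassTransition:
    def test_no_upstream_lesions(self):
        d = pass_transition(0, True, 0.3, 0.5)
        assert d == pytest.approx({(0, True): 0.7, (0, False): 0.3})

    def test_one_upstream_lesion_enumeration(self):
        # 5-leaf outcome tree: focal dies iff the RNAP reaches it (bypass or
        # repair+restart of the upstream lesion) and then detects it.
        d = pass_transition(1, True, 0.5, 0.5)
        p_dead = sum(p for (k, alive), p in d.items() if not alive)
        assert p_dead == pytest.approx(0.375)

    def test_no_detection_is_identity(self):
        assert pass_transition(3, True, 0.0, 0.7) == {(3, True): 1.0}

    @pytest.mark.parametrize("pd", [0.0, 0.3, 1.0])
    @pytest.mark.parametrize("pr", [0.0, 0.5, 1.0])
    @pytest.mark.parametrize("k", [0, 1, 4])
    def test_distribution_is_proper(self, pd, pr, k):
        for alive in (True, False):
            d = pass_transition(k, alive, pd, pr)
            assert sum(d.values()) == pytest.approx(1.0)
            for (k2, alive2), p in d.items():
                assert 0 <= k2 <= k          # upstream lesions never revive
                assert 0.0 <= p <= 1.0
                if not alive:
                    assert not alive2        # a dead focal never revives


class TestSurvivalProbability:
    @pytest.mark.parametrize("pd", [0.05, 0.25, 0.5, 0.95])
    @pytest.mark.parametrize("n", [0, 1, 3, 10])
    def test_closed_form_no_shielding(self, pd, n):
        assert survival_probability(n, 0, pd, 0.3) == pytest.approx(
            (1 - pd) ** n, abs=1e-12
        )

    @pytest.mark.parametrize("pd", [0.05, 0.5, 0.95])
    @pytest.mark.parametrize("k", [1, 5])
    def test_closed_form_full_restart(self, pd, k):
        # pr = 1: restarting RNAPs always reach the focal site, removing the
        # shielding effect of upstream lesions entirely.
        for n in (1, 4, 12):
            assert survival_probability(n, k, pd, 1.0) == pytest.approx(
                (1 - pd) ** n, abs=1e-12
            )

    def test_enumeration_example(self):
        assert survival_probability(1, 1, 0.5, 0.5) == pytest.approx(0.625)

    @pytest.mark.parametrize("pd,pr", [(0.3, 0.2), (0.7, 0.9), (0.9, 0.0)])
    def test_monotone_in_passes_and_shielding(self, pd, pr):
        surv_n = [survival_probability(n, 3, pd, pr) for n in range(12)]
        assert all(b <= a + 1e-14 for a, b in zip(surv_n, surv_n[1:]))
        surv_k = [survival_probability(5, k, pd, pr) for k in range(10)]
        assert all(b >= a - 1e-14 for a, b in zip(surv_k, surv_k[1:]))
        assert all(0.0 <= s <= 1.0 for s in surv_n + surv_k)


def _mc_survival(pd, pr, pv, lam, n, n_rep, seed):
    """Brute-force Monte Carlo of the focal-lesion fate, independent of the
    package's transition-matrix machinery."""
    rng = np.random.default_rng(seed)
    alive_count = 0
    for _ in range(n_rep):
        if rng.random() >= pv:
            alive_count += 1          # invisible: never touched
            continue
        k = rng.poisson(pv * lam)
        alive = True
        for _ in range(n):
            if not alive:
                break
            terminated = False
            removed = 0
            for _ in range(k):
                if rng.random() < pd:
                    removed += 1
                    if rng.random() >= pr:
                        terminated = True
                        break
            k -= removed
            if terminated:
                continue
            if rng.random() < pd:
                alive = False
        if alive:
            alive_count += 1
    return alive_count / n_rep


class TestExpectedObsExp:
    @pytest.mark.parametrize(
        "params",
        [
            TcrParams(pd=0.0, pr=0.5, pv=0.8, m=1.0),   # nothing repaired
            TcrParams(pd=0.5, pr=0.5, pv=0.0, m=1.0),   # nothing visible
        ],
    )
    def test_degenerate_cases_give_unity(self, params):
        assert expected_obs_exp(params, 2.0, 5) == 1.0
        assert expected_obs_exp(params, 0.0, 0) == 1.0

    def test_bounds_and_monotonicity_in_position(self):
        p = TcrParams(pd=0.4, pr=0.3, pv=0.7, m=1.0)
        vals = [expected_obs_exp(p, lam, 6) for lam in np.linspace(0, 4, 20)]
        assert all(1 - p.pv <= v <= 1.0 for v in vals)
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_against_monte_carlo_oracle(self):
        p = TcrParams(pd=0.25, pr=0.25, pv=1.0, m=1.0)
        n_rep = 60_000
        mc = _mc_survival(0.25, 0.25, 1.0, 2.0, 5, n_rep, seed=7)
        analytic = expected_obs_exp(p, 2.0, 5)
        se = math.sqrt(mc * (1 - mc) / n_rep)
        assert abs(mc - analytic) < 3 * se

    def test_truncation_tolerance_insensitive(self):
        p = TcrParams(pd=0.6, pr=0.1, pv=0.9, m=1.0)
        for lam in (0.5, 2.0, 3.95):
            a = expected_obs_exp(p, lam, 8, tail_tol=1e-9)
            b = expected_obs_exp(p, lam, 8, tail_tol=1e-8)
            assert abs(a - b) < 1e-6


class TestTheorySurface:
    def test_full_restart_rows_are_flat(self):
        s = theory_surface(TcrParams(pd=0.3, pr=1.0, pv=0.9, m=2.0))
        spread = s.values.max(axis=1) - s.values.min(axis=1)
        assert np.all(spread < 1e-9)

    def test_unexpressed_stratum_is_ones(self):
        s = theory_surface(TcrParams(pd=0.8, pr=0.2, pv=1.0, m=5.0))
        assert np.array_equal(s.values[0], np.ones(40))  # stratum 1: e = 0

    @pytest.mark.parametrize(
        "params",
        [
            TcrParams(pd=0.0, pr=0.5, pv=0.8, m=1.5),
            TcrParams(pd=0.5, pr=0.5, pv=0.0, m=1.5),
            TcrParams(pd=0.5, pr=0.5, pv=0.8, m=0.0),
        ],
    )
    def test_no_repair_regimes_are_all_ones(self, params):
        s = theory_surface(params)
        assert np.array_equal(s.values, np.ones((6, 40)))

    def test_values_bounded_and_rows_monotone(self):
        s = theory_surface(TcrParams(pd=0.42, pr=0.66, pv=0.8, m=1.59))
        assert np.all((s.values >= 0) & (s.values <= 1))
        assert np.all(np.diff(s.values, axis=1) >= -1e-12)

    def test_bin_average_close_to_midpoint(self):
        p = TcrParams(pd=0.25, pr=0.25, pv=1.0, m=1.5)
        mid = theory_surface(p).values
        avg = theory_surface(p, bin_eval="average5").values
        assert np.abs(mid - avg).max() < 1e-4

    def test_bad_bin_eval_rejected(self):
        with pytest.raises(ValueError):
            theory_surface(TcrParams(0.3, 0.3), bin_eval="edges")


class TestClosedFormHelpers:
    def test_m_bound_from_polymerase_census(self):
        assert m_bounds_from_census(180_000, 2, 60, 2280) == pytest.approx(13.68)
        assert m_bounds_from_census(110_000, 2, 60, 2280) == pytest.approx(8.36)
        assert m_bounds_from_census(0, 2, 60, 2280) == 0.0
        with pytest.raises(ValueError):
            m_bounds_from_census(1000, 2, 0, 2280)

    def test_bypass_fraction(self):
        assert bypass_fraction(TcrParams(pd=0.42, pr=0.5, pv=0.8)) == pytest.approx(0.664)
        assert bypass_fraction(TcrParams(pd=1.0, pr=0.5, pv=1.0)) == 0.0
        assert bypass_fraction(TcrParams(pd=0.0, pr=0.5, pv=0.9)) == 1.0


class TestParamValidation:
    @pytest.mark.parametrize("bad", [{"pd": 1.2}, {"pr": -0.1}, {"pv": 2.0}, {"m": -1.0}])
    def test_out_of_range_rejected(self, bad):
        kwargs = {"pd": 0.5, "pr": 0.5, "pv": 0.5, "m": 1.0}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            TcrParams(**kwargs)

    def test_strata_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            StrataConfig(proportions=(0.5, 0.1, 0.1, 0.1, 0.1, 0.2))

    def test_grid_requires_positive_bins(self):
        with pytest.raises(ValueError):
            PositionGrid(n_bins=0)
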