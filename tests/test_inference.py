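"""Inference: grid search, refinement, bootstrap, AIC, orthogonal m."""

import numpy as np
import pandas as pd
import pytest

from tcrdyn.params import TcrParams
from tcrdyn.model import theory_surface
from tcrdyn.simulate import SimulationConfig, simulate_cohort_data
from tcrdyn.inference import (
    GridSpec,
    aic_compare,
    bootstrap_ci,
    estimate_m_orthogonal,
    fit_surface,
    grid_search,
    manhattan_distance,
    plausibility_map,
    refine_fit,
)

ONES = (np.ones((6, 40)), np.ones((6, 40), dtype=bool))


class TestManhattanDistance:
    def test_identical_surfaces(self):
        a = np.random.default_rng(0).random((6, 40))
        assert manhattan_distance(a, a) == 0.0

    def test_full_mask_unit_difference(self):
        assert manhattan_distance(np.ones((6, 40)), np.zeros((6, 40))) == 240.0

    def test_masking_removes_exactly_the_masked_deltas(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((6, 40)), rng.random((6, 40))
        mask = np.ones((6, 40), dtype=bool)
        mask[2] = False
        full = manhattan_distance(a, b)
        masked = manhattan_distance(a, b, mask)
        assert full - masked == pytest.approx(np.abs(a[2] - b[2]).sum())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            manhattan_distance(np.ones((6, 40)), np.ones((6, 39)))


class TestGridSearch:
    def test_recovers_grid_point_exactly(self):
        theta = TcrParams(pd=0.25, pr=0.4, pv=0.8, m=1.25)
        best, dist = grid_search(theory_surface(theta), GridSpec.coarse())
        assert best == theta
        assert dist < 1e-6

    def test_all_ones_hits_first_zero_repair_point(self):
        # deterministic lexicographic tie-break over a genuinely flat region
        best, dist = grid_search(ONES, GridSpec.coarse())
        assert dist == 0.0
        assert best == TcrParams(pd=0.0, pr=0.0, pv=0.0, m=0.25)

    def test_pinning_restricts_the_search(self):
        best, _ = grid_search(ONES, GridSpec.coarse(), fixed={"pv": 0.77})
        assert best.pv == 0.77

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            grid_search((np.ones((6, 40)), np.zeros((6, 40), bool)), GridSpec.coarse())

    def test_grid_spec_validation(self):
        with pytest.raises(ValueError):
            GridSpec(prob_step=0.0)
        with pytest.raises(ValueError):
            GridSpec(m_range=(0.0, 10.0))


class TestRefineFit:
    def test_no_movement_from_exact_optimum(self):
        theta = TcrParams(pd=0.25, pr=0.4, pv=0.8, m=1.25)
        data = theory_surface(theta)
        fit = refine_fit(data, theta, fixed={"pv": 0.8})
        assert fit.distance <= 1e-6
        assert fit.params.pd == pytest.approx(theta.pd, abs=1e-3)
        assert fit.params.m == pytest.approx(theta.m, abs=1e-2)

    def test_optimizer_dominance_over_truth(self):
        # the refined objective never exceeds the objective at the true
        # generating parameters
        true = TcrParams(0.25, 0.25, 0.8, 1.5)
        for seed in range(5):
            data = simulate_cohort_data(
                true, SimulationConfig(n_genes=60_000), rng=seed
            ).surface()
            fit = fit_surface(data, GridSpec.coarse(), fixed={"pv": 0.8})
            d_true = manhattan_distance(
                theory_surface(true).values, data.obs_exp, data.mask
            )
            assert fit.distance <= d_true + 1e-9

    def test_distance_never_worse_than_start(self):
        data = simulate_cohort_data(
            TcrParams(0.3, 0.5, 0.8, 2.0), SimulationConfig(n_genes=30_000), rng=3
        ).surface()
        start, d0 = grid_search(data, GridSpec.coarse(), fixed={"pv": 0.8})
        fit = refine_fit(data, start, fixed={"pv": 0.8})
        assert fit.distance <= d0


class TestBootstrap:
    def test_identical_genes_give_degenerate_cis(self):
        # a cohort of identical gene records: every resample rebuilds the
        # same surface, so the CIs collapse onto the point estimate
        from tcrdyn.simulate import SimCohortData
        from tcrdyn.params import PositionGrid

        n = 50
        data = SimCohortData(
            strata_idx=np.zeros(n, dtype=int),
            covered_bins=np.full(n, 10),
            frac_cov=np.full(n, 10.0),
            lesion_gene=np.arange(n),
            lesion_cell=np.full(n, 3),
            grid=PositionGrid(),
            n_strata=6,
        )
        res = bootstrap_ci(data, n_reps=5, fixed={"pv": 0.8}, rng=0, refine=False)
        for lo, hi in res.ci95.values():
            assert lo == hi

    def test_same_seed_reproduces_cis(self):
        data = simulate_cohort_data(
            TcrParams(0.3, 0.3, 0.8, 1.5), SimulationConfig(n_genes=20_000), rng=1
        )
        a = bootstrap_ci(data, n_reps=8, fixed={"pv": 0.8}, rng=42)
        b = bootstrap_ci(data, n_reps=8, fixed={"pv": 0.8}, rng=42)
        assert a.ci95 == b.ci95

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            bootstrap_ci(None, n_reps=1)


class TestAicCompare:
    def test_pure_parameter_penalty_when_pr_unidentifiable(self):
        # all-ones data: both models fit perfectly, AIC difference is the
        # +2 penalty for the extra restart parameter
        with pytest.warns(UserWarning):
            mc = aic_compare(ONES, GridSpec.bootstrap())
        assert mc.aic_full - mc.aic_norestart == pytest.approx(2.0)
        assert mc.loglik_full == pytest.approx(mc.loglik_norestart)

    def test_variance_is_mean_squared_residual(self):
        rng = np.random.default_rng(5)
        theta = TcrParams(0.3, 0.0, 0.8, 2.0)
        values = theory_surface(theta).values + rng.normal(0, 0.02, (6, 40))
        mask = np.ones((6, 40), bool)
        mc = aic_compare((values, mask), GridSpec.bootstrap())
        resid = theory_surface(mc.mle_full).values - values
        assert mc.v_full == pytest.approx((resid ** 2).mean(), rel=1e-6)
        # nested models: the full model fits at least as well; AIC uses
        # k = 5 (full) vs k = 4 (no restart)
        assert mc.loglik_full >= mc.loglik_norestart - 1e-6
        assert mc.aic_full == pytest.approx(10.0 - 2.0 * mc.loglik_full)
        assert mc.aic_norestart == pytest.approx(8.0 - 2.0 * mc.loglik_norestart)

    def test_norestart_truth_prefers_reduced_model(self):
        wins = 0
        for seed in range(6):
            data = simulate_cohort_data(
                TcrParams(0.4, 0.0, 0.8, 2.0), SimulationConfig(n_genes=150_000),
                rng=seed,
            ).surface()
            mc = aic_compare((data.obs_exp, data.mask), GridSpec.bootstrap(),
                             fixed={"pv": 0.8})
            wins += mc.aic_norestart <= mc.aic_full
        assert wins >= 4


class TestPlausibilityMap:
    def test_quantile_ranking(self):
        theta = TcrParams(pd=0.3, pr=0.4, pv=0.8, m=1.5)
        data = theory_surface(theta)
        boot = np.array([0.5, 1.0, 2.0, 4.0])
        pm = plausibility_map(data, boot, GridSpec.bootstrap(), fixed={"pv": 0.8})
        i, j = np.unravel_index(np.argmin(pm.distance), pm.distance.shape)
        assert pm.quantile[i, j] == pm.quantile.max()
        far = pm.distance > boot.max()
        assert np.all(pm.quantile[far] == 0.0)

    def test_empty_bootstrap_rejected(self):
        with pytest.raises(ValueError):
            plausibility_map(ONES, np.array([]))


class TestOrthogonalM:
    def test_single_gene_fit(self):
        df = pd.DataFrame({"rate": [27.7 / 2280.0], "active_fraction": [1.0],
                           "ntpm": [10.0]})
        assert estimate_m_orthogonal(df) == pytest.approx(2.77)

    def test_exact_table_returns_m(self):
        rng = np.random.default_rng(0)
        e = rng.uniform(0.5, 20, size=7)
        m_true = 2.77
        df = pd.DataFrame({"rate": m_true * e / 2280.0,
                           "active_fraction": np.ones(7), "ntpm": e})
        assert estimate_m_orthogonal(df) == pytest.approx(m_true)

    def test_noisy_tables_recover_m_in_median(self):
        m_true = 2.77
        ests = []
        rng = np.random.default_rng(9)
        for _ in range(200):
            e = rng.uniform(0.5, 20, size=7)
            noise = rng.lognormal(0.0, 0.3, size=7)
            df = pd.DataFrame({"rate": m_true * e * noise / 2280.0,
                               "active_fraction": np.ones(7), "ntpm": e})
            ests.append(estimate_m_orthogonal(df))
        assert abs(np.median(ests) - m_true) / m_true < 0.10

    def test_nonpositive_rows_excluded_with_warning(self):
        df = pd.DataFrame({"rate": [1.0, 0.0], "active_fraction": [1.0, 1.0],
                           "ntpm": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            m = estimate_m_orthogonal(df)
        assert m == pytest.approx(2280.0)

    def test_empty_table_rejected(self):
        df = pd.DataFrame({"rate": [0.0], "active_fraction": [1.0], "ntpm": [1.0]})
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                estimate_m_orthogonal(df)
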