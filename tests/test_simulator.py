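"""Stochastic simulator: per-gene pass semantics, aggregation, oracle checks."""

import numpy as np
import pytest

from tcrdyn.params import PositionGrid, StrataConfig, TcrParams
from tcrdyn.model import theory_surface
from tcrdyn.simulate import (
    GeneSim,
    SimulationConfig,
    aggregate_surface,
    sample_genes,
    simulate_cohort_data,
    simulate_surface,
    transcribe_and_repair,
    _cohort_survivors,
)


def _gene(positions, visible=None, n_rnaps=1, length=100_000.0, stratum=1):
    positions = np.asarray(positions, dtype=float)
    if visible is None:
        visible = np.ones(len(positions), dtype=bool)
    return GeneSim(length=length, stratum=stratum, n_rnaps=n_rnaps,
                   lesions=positions, visible=visible)


class TestTranscribeAndRepair:
    def test_first_lesion_repaired_then_dissociation(self, rng):
        # pd=1, pr=0: one RNAP deterministically repairs the first visible
        # lesion and dissociates, leaving downstream lesions untouched.
        g = _gene([10, 20, 30])
        out = transcribe_and_repair(g, TcrParams(pd=1.0, pr=0.0), rng)
        assert list(out) == [20, 30]

    def test_full_detection_with_restart_clears_gene(self, rng):
        g = _gene([10, 20, 30])
        out = transcribe_and_repair(g, TcrParams(pd=1.0, pr=1.0), rng)
        assert len(out) == 0

    def test_no_detection_keeps_all(self, rng):
        g = _gene([10, 20, 30], n_rnaps=7)
        out = transcribe_and_repair(g, TcrParams(pd=0.0, pr=0.5), rng)
        assert list(out) == [10, 20, 30]

    def test_invisible_lesions_always_survive(self, rng):
        g = _gene([10, 20, 30], visible=np.array([False, True, False]))
        out = transcribe_and_repair(g, TcrParams(pd=1.0, pr=1.0), rng)
        assert list(out) == [10, 30]

    def test_survivors_subset_of_input(self, rng):
        g = _gene(np.sort(rng.random(12)) * 1e5, n_rnaps=3)
        out = transcribe_and_repair(g, TcrParams(pd=0.5, pr=0.5), rng)
        assert set(out).issubset(set(g.lesions))


class TestSampleGenes:
    def test_zero_rate_gives_no_lesions(self, rng):
        cfg = SimulationConfig(n_genes=500, lesion_rate=1e-300)
        cohort = sample_genes(cfg, TcrParams(0.5, 0.5, 0.8, 1.5), rng)
        assert cohort.offsets[-1] == 0

    def test_zero_multiplier_gives_no_rnaps(self, rng):
        cfg = SimulationConfig(n_genes=500)
        cohort = sample_genes(cfg, TcrParams(0.5, 0.5, 0.8, 0.0), rng)
        assert np.all(cohort.n_rnaps == 0)

    def test_poisson_lesion_mean(self, tmp_path, rng):
        # fixed 100 kb genes at 13e-6 per bp: mean lesion count 1.3
        lengths = tmp_path / "lengths.txt"
        lengths.write_text("100000\n")
        cfg = SimulationConfig(n_genes=50_000, gene_lengths_file=str(lengths))
        cohort = sample_genes(cfg, TcrParams(0.5, 0.5, 1.0, 1.5), rng)
        mean = cohort.offsets[-1] / cfg.n_genes
        se = np.sqrt(1.3 / cfg.n_genes)
        assert abs(mean - 1.3) < 3 * se

    def test_positions_sorted_within_genes(self, rng):
        cfg = SimulationConfig(n_genes=2000)
        cohort = sample_genes(cfg, TcrParams(0.5, 0.5, 0.8, 1.5), rng)
        for g in range(0, len(cohort), 97):
            gene = cohort[g]
            assert np.all(np.diff(gene.lesions) >= 0)
            assert np.all((gene.lesions >= 0) & (gene.lesions < gene.length))


class TestKernelMatchesReference:
    def test_deterministic_first_hit_semantics(self, rng):
        # pd=1, pr=0: each pass removes exactly the first remaining visible
        # lesion, so survivors per gene = max(0, n_visible - n_rnaps).
        cfg = SimulationConfig(n_genes=3000)
        params = TcrParams(pd=1.0, pr=0.0, pv=0.7, m=1.5)
        cohort = sample_genes(cfg, params, rng)
        survived = _cohort_survivors(cohort, params, rng)
        for g in range(0, len(cohort), 53):
            lo, hi = cohort.offsets[g], cohort.offsets[g + 1]
            n_vis = int(cohort.visible[lo:hi].sum())
            expect = (hi - lo) - min(n_vis, cohort.n_rnaps[g])
            assert int(survived[lo:hi].sum()) == expect

    def test_no_detection_keeps_everything(self, rng):
        cfg = SimulationConfig(n_genes=1000)
        params = TcrParams(pd=0.0, pr=0.5, pv=0.8, m=1.5)
        cohort = sample_genes(cfg, params, rng)
        assert np.all(_cohort_survivors(cohort, params, rng))


class TestAggregation:
    def test_lesion_bin_arithmetic(self):
        # lesion at 25 kb with rho = 13e-6 -> lambda 0.325 -> bin 3
        cfg = SimulationConfig(n_genes=1)
        params = TcrParams(0.0, 0.5, 1.0, 0.0)
        cohort = sample_genes(cfg, params, np.random.default_rng(0))
        cohort.lengths[:] = 400_000.0
        cohort.offsets[:] = [0, 1]
        cohort.positions = np.array([25_000.0])
        cohort.visible = np.ones(1, bool)
        data = aggregate_surface(cohort, np.ones(1, bool), cfg)
        assert data.lesion_cell[0] % 40 == 3

    def test_partial_gene_expected_mass(self):
        # a gene with rho*L = 0.35 fully covers bins 0-2 only
        cfg = SimulationConfig(n_genes=1)
        params = TcrParams(0.0, 0.5, 1.0, 0.0)
        cohort = sample_genes(cfg, params, np.random.default_rng(0))
        cohort.lengths[:] = 0.35 / cfg.lesion_rate
        cohort.offsets[:] = [0, 0]
        cohort.positions = np.zeros(0)
        cohort.visible = np.zeros(0, bool)
        data = aggregate_surface(cohort, np.zeros(0, bool), cfg)
        surf = data.surface()
        s = int(cohort.strata_idx[0])
        occupied = np.flatnonzero(surf.expected[s] > 0)
        assert list(occupied) == [0, 1, 2]
        assert surf.expected[s, :3] == pytest.approx([0.1, 0.1, 0.1])

    def test_prorated_rule_credits_partial_bins(self):
        cfg = SimulationConfig(n_genes=1, expected_rule="prorated")
        params = TcrParams(0.0, 0.5, 1.0, 0.0)
        cohort = sample_genes(cfg, params, np.random.default_rng(0))
        cohort.lengths[:] = 0.35 / cfg.lesion_rate
        cohort.offsets[:] = [0, 0]
        cohort.positions = np.zeros(0)
        cohort.visible = np.zeros(0, bool)
        surf = aggregate_surface(cohort, np.zeros(0, bool), cfg).surface()
        s = int(cohort.strata_idx[0])
        assert surf.expected[s, 3] == pytest.approx(0.05)
        assert surf.expected[s, 4] == 0.0


class TestSimulateSurface:
    def test_same_seed_is_bit_identical(self):
        cfg = SimulationConfig(n_genes=20_000)
        p = TcrParams(0.25, 0.25, 0.8, 1.5)
        a = simulate_surface(p, cfg, rng=5)
        b = simulate_surface(p, cfg, rng=5)
        assert np.array_equal(a.observed, b.observed)
        assert np.array_equal(a.expected, b.expected)

    def test_no_repair_means_unit_ratio(self):
        surf = simulate_surface(
            TcrParams(pd=0.0, pr=0.5, pv=0.8, m=1.5),
            SimulationConfig(n_genes=100_000), rng=3,
        )
        z = np.abs(surf.obs_exp[surf.mask] - 1.0) * np.sqrt(surf.expected[surf.mask])
        assert z.max() < 4.0
        assert abs(surf.obs_exp[surf.mask].mean() - 1.0) < 0.02

    def test_zero_multiplier_means_unit_ratio(self):
        surf = simulate_surface(
            TcrParams(pd=0.5, pr=0.5, pv=0.8, m=0.0),
            SimulationConfig(n_genes=50_000), rng=4,
        )
        assert abs(surf.obs_exp[surf.mask].mean() - 1.0) < 0.03

    def test_matches_theory_at_moderate_scale(self):
        p = TcrParams(0.25, 0.25, 1.0, 1.5)
        cfg = SimulationConfig(n_genes=150_000)
        sim = simulate_surface(p, cfg, rng=11)
        th = theory_surface(p, cfg.strata, cfg.grid)
        se = np.sqrt(np.maximum(sim.observed, 1.0)) / np.maximum(sim.expected, 1e-12)
        z = np.where(sim.mask, np.abs(sim.obs_exp - th.values) / se, 0.0)
        assert (z > 3).mean() < 0.02
        assert z.max() < 5.0

    def test_full_restart_rows_flat(self):
        p = TcrParams(pd=0.5, pr=1.0, pv=1.0, m=2.0)
        sim = simulate_surface(p, SimulationConfig(n_genes=150_000), rng=9)
        th = theory_surface(p)
        # no positional trend: slope of obs:exp against bin index ~ 0
        for s in range(1, 6):
            row = sim.obs_exp[s][sim.mask[s]]
            bins = np.arange(40)[sim.mask[s]]
            slope = np.polyfit(bins, row, 1)[0]
            assert abs(slope) < 0.003
            assert abs(row.mean() - th.values[s].mean()) < 0.05

    def test_survivors_never_exceed_lesions(self, rng):
        cfg = SimulationConfig(n_genes=5000)
        p = TcrParams(0.6, 0.3, 0.8, 2.0)
        data = simulate_cohort_data(p, cfg, rng)
        surf = data.surface()
        assert np.all(surf.observed >= 0)
        assert np.all(surf.observed[~surf.mask] == 0)

    def test_convergence_with_cohort_size(self):
        p = TcrParams(0.25, 0.25, 1.0, 1.5)
        th = theory_surface(p)
        errs = []
        for n in (10_000, 300_000):
            sim = simulate_surface(p, SimulationConfig(n_genes=n), rng=21)
            err = np.abs(sim.obs_exp - th.values)[sim.mask].mean()
            errs.append(err)
        assert errs[1] < errs[0]

    def test_bootstrap_resample_shapes_and_determinism(self):
        p = TcrParams(0.3, 0.3, 0.8, 1.5)
        data = simulate_cohort_data(p, SimulationConfig(n_genes=5000), rng=2)
        a = data.resample(np.random.default_rng(7))
        b = data.resample(np.random.default_rng(7))
        assert np.array_equal(a.observed, b.observed)
        assert a.observed.shape == (6, 40)
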