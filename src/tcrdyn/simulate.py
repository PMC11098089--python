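"""Forward simulation of DNA damage and transcription-coupled repair on
abstract gene cohorts, and aggregation into observed:expected surfaces.

Genes carry no nucleotide sequence here: a gene is a length, an expression
stratum, a number of sequentially initiating RNAPs and a set of lesions at
uniform positions.  Lesion counts are Poisson with mean ``rho * length``
(``rho`` defaults to 13e-6 per bp, the median per-base mutation rate of the
DEN-induced mouse liver tumors the model targets).  Sequence-level cohorts
with mutation spectra live in :mod:`tcrdyn.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numba import njit

from .params import PositionGrid, StrataConfig, TcrParams, initiation_mixture
from .surface import ObsExpSurface

__all__ = [
    "SimulationConfig",
    "GeneSim",
    "SimulatedSurface",
    "SimCohortData",
    "sample_genes",
    "transcribe_and_repair",
    "aggregate_surface",
    "simulate_cohort_data",
    "simulate_surface",
]

#: Cumulative number of phaseable genes across the murine liver tumor cohort.
DEFAULT_N_GENES = 1_940_237
#: Median per-base mutagenic lesion rate (per bp).
DEFAULT_LESION_RATE = 13e-6


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = DEFAULT_N_GENES
    lesion_rate: float = DEFAULT_LESION_RATE
    gene_length_median: float = 60_000.0   # bp; mouse-liver median gene length
    gene_length_log_sd: float = 1.0        # sd of ln(length) in the log-normal stand-in
    gene_lengths_file: str | None = None   # overrides the parametric lengths
    strata: StrataConfig = field(default_factory=StrataConfig)
    grid: PositionGrid = field(default_factory=PositionGrid)
    expected_rule: str = "covered"         # or "prorated"

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0 < self.lesion_rate < 1:
            raise ValueError("lesion_rate must lie in (0, 1)")
        if self.expected_rule not in ("covered", "prorated"):
            raise ValueError("expected_rule must be 'covered' or 'prorated'")


@dataclass
class GeneSim:
    """A single simulated gene (positions in bp from the TSS, sorted)."""

    length: float
    stratum: int
    n_rnaps: int
    lesions: np.ndarray
    visible: np.ndarray

    def __post_init__(self) -> None:
        self.lesions = np.asarray(self.lesions, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.lesions.size and (
            np.any(self.lesions < 0) or np.any(self.lesions >= self.length)
        ):
            raise ValueError("lesion positions must lie in [0, length)")
        if np.any(np.diff(self.lesions) < 0):
            raise ValueError("lesion positions must be sorted")


def _draw_lengths(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.gene_lengths_file is not None:
        try:
            pool = np.loadtxt(config.gene_lengths_file, dtype=float, ndmin=1)
        except OSError as exc:
            raise OSError(f"cannot read gene lengths file: {exc}") from exc
        return rng.choice(pool, size=n, replace=True)
    mu = np.log(config.gene_length_median)
    return np.maximum(np.exp(rng.normal(mu, config.gene_length_log_sd, size=n)), 1.0)


class _Cohort:
    """Array-of-struct gene cohort; indexable as a sequence of GeneSim."""

    def __init__(self, lengths, strata_idx, n_rnaps, offsets, positions, visible):
        self.lengths = lengths          # (n,) bp
        self.strata_idx = strata_idx    # (n,) 0-based stratum
        self.n_rnaps = n_rnaps          # (n,)
        self.offsets = offsets          # (n+1,) lesion slices
        self.positions = positions      # (L,) bp, sorted within gene
        self.visible = visible          # (L,) bool

    def __len__(self) -> int:
        return len(self.lengths)

    def __getitem__(self, g: int) -> GeneSim:
        lo, hi = self.offsets[g], self.offsets[g + 1]
        return GeneSim(
            length=float(self.lengths[g]),
            stratum=int(self.strata_idx[g]) + 1,
            n_rnaps=int(self.n_rnaps[g]),
            lesions=self.positions[lo:hi],
            visible=self.visible[lo:hi],
        )


def sample_genes(
    config: SimulationConfig, params: TcrParams, rng: np.random.Generator
) -> _Cohort:
    """Draw a gene cohort: lengths, strata, RNAP counts, lesions, visibility.

    RNAP counts follow the floor/floor+1 initiation mixture of the gene's
    stratum-median expression, assigned Bernoulli per gene (mean-preserving).
    """
    n = config.n_genes
    strata = config.strata
    lengths = _draw_lengths(config, n, rng)
    strata_idx = rng.choice(strata.n_strata, size=n, p=np.asarray(strata.proportions))

    n_rnaps = np.zeros(n, dtype=np.int64)
    for s, e in enumerate(strata.medians):
        mx = initiation_mixture(params.m, e)
        sel = strata_idx == s
        extra = rng.random(int(sel.sum())) < (1.0 - mx.c)
        n_rnaps[sel] = mx.n_floor + extra

    counts = rng.poisson(config.lesion_rate * lengths)
    offsets = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    total = int(offsets[-1])
    positions = rng.random(total) * np.repeat(lengths, counts)
    # sort within genes: positions are iid uniform per gene, so sorting the
    # (gene, position) pairs gene-major orders each gene's lesions 5'->3'
    order = np.lexsort((positions, np.repeat(np.arange(n), counts)))
    positions = positions[order]
    visible = rng.random(total) < params.pv
    return _Cohort(lengths, strata_idx, n_rnaps, offsets, positions, visible)


def transcribe_and_repair(
    gene: GeneSim, params: TcrParams, rng: np.random.Generator
) -> np.ndarray:
    """Apply the gene's RNAP passes; return surviving lesion positions.

    Pure-Python reference implementation of the per-pass semantics: each pass
    scans live visible lesions 5'->3'; detection (prob ``pd``) removes the
    lesion and the pass continues only on restart (prob ``pr``).  Invisible
    lesions never interact with RNAP and always survive transcription.
    """
    alive = np.ones(len(gene.lesions), dtype=bool)
    vis_idx = np.flatnonzero(gene.visible)
    vis_alive = np.ones(len(vis_idx), dtype=bool)
    for _ in range(gene.n_rnaps):
        if not vis_alive.any():
            break
        for i in np.flatnonzero(vis_alive):
            if rng.random() < params.pd:
                vis_alive[i] = False
                if rng.random() >= params.pr:
                    break
    alive[vis_idx] = vis_alive
    return gene.lesions[alive]


@njit(cache=True)
def _repair_kernel(offsets, n_rnaps, pd, pr, seed, alive):  # pragma: no cover
    np.random.seed(seed)
    n_genes = offsets.shape[0] - 1
    for g in range(n_genes):
        lo = offsets[g]
        hi = offsets[g + 1]
        if hi == lo:
            continue
        n_alive = hi - lo
        for _ in range(n_rnaps[g]):
            if n_alive == 0:
                break
            for i in range(lo, hi):
                if not alive[i]:
                    continue
                if np.random.random() < pd:
                    alive[i] = False
                    n_alive -= 1
                    if np.random.random() >= pr:
                        break


def _cohort_survivors(
    cohort: _Cohort, params: TcrParams, rng: np.random.Generator
) -> np.ndarray:
    """Survivor flags for every lesion in the cohort (vectorized kernel)."""
    survived = np.ones(len(cohort.positions), dtype=bool)
    vis = np.flatnonzero(cohort.visible)
    if vis.size == 0 or params.pd == 0.0:
        return survived
    n = len(cohort)
    vis_counts = np.diff(np.searchsorted(vis, cohort.offsets))
    vis_offsets = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(vis_counts, out=vis_offsets[1:])
    alive = np.ones(vis.size, dtype=np.bool_)
    seed = int(rng.integers(0, 2**31 - 1))
    _repair_kernel(vis_offsets, cohort.n_rnaps, float(params.pd), float(params.pr),
                   seed, alive)
    survived[vis] = alive
    return survived


@dataclass
class SimulatedSurface:
    observed: np.ndarray   # (n_strata, n_bins) survivor counts
    expected: np.ndarray   # (n_strata, n_bins) repair-free expectation
    obs_exp: np.ndarray    # ratio where expected > 0
    mask: np.ndarray       # expected > 0

    @property
    def surface(self) -> ObsExpSurface:
        n_bins = self.observed.shape[1]
        return ObsExpSurface(
            values=self.obs_exp, mask=self.mask,
            grid=PositionGrid(n_bins=n_bins, bin_width=self._bin_width),
            meta={"kind": "simulated"},
        )

    _bin_width: float = 0.1


class SimCohortData:
    """Gene-level simulation records supporting surface rebuilds under gene
    resampling (the unit of the bootstrap is the gene, not the surface cell).
    """

    def __init__(self, strata_idx, covered_bins, frac_cov, lesion_gene, lesion_cell,
                 grid: PositionGrid, n_strata: int, expected_rule: str = "covered"):
        self.strata_idx = strata_idx        # (n,) 0-based
        self.covered_bins = covered_bins    # (n,) fully covered bin count
        self.frac_cov = frac_cov            # (n,) rho*L/width, capped at n_bins
        self.lesion_gene = lesion_gene      # (L,) gene index of counted survivors
        self.lesion_cell = lesion_cell      # (L,) flat (stratum, bin) cell index
        self.grid = grid
        self.n_strata = n_strata
        self.expected_rule = expected_rule

    @property
    def n_genes(self) -> int:
        return len(self.strata_idx)

    def surface(self, multiplicities: np.ndarray | None = None) -> SimulatedSurface:
        grid, n_s = self.grid, self.n_strata
        n_b = grid.n_bins
        w = grid.bin_width
        if multiplicities is None:
            mult = np.ones(self.n_genes)
        else:
            mult = np.asarray(multiplicities, dtype=float)
        observed = np.bincount(
            self.lesion_cell, weights=mult[self.lesion_gene], minlength=n_s * n_b
        ).reshape(n_s, n_b)
        if self.expected_rule == "covered":
            flat = self.strata_idx * (n_b + 1) + self.covered_bins
            hist = np.bincount(flat, weights=mult, minlength=n_s * (n_b + 1))
            hist = hist.reshape(n_s, n_b + 1)
            # expected[s, t] = width * (# genes in s fully covering bin t)
            expected = w * (hist[:, ::-1].cumsum(axis=1)[:, ::-1][:, 1:])
        else:
            expected = np.zeros((n_s, n_b))
            for t in range(n_b):
                contrib = np.clip(self.frac_cov - t, 0.0, 1.0) * w
                expected[:, t] = np.bincount(
                    self.strata_idx, weights=mult * contrib, minlength=n_s
                )
        mask = expected > 0
        obs_exp = np.zeros_like(expected)
        np.divide(observed, expected, out=obs_exp, where=mask)
        out = SimulatedSurface(observed=observed, expected=expected,
                               obs_exp=obs_exp, mask=mask)
        out._bin_width = w
        return out

    def resample(self, rng: np.random.Generator) -> SimulatedSurface:
        n = self.n_genes
        mult = np.bincount(rng.integers(0, n, size=n), minlength=n)
        return self.surface(mult)


def aggregate_surface(
    cohort: _Cohort, survived: np.ndarray, config: SimulationConfig
) -> SimCohortData:
    """Bin surviving lesions into (stratum, lambda) cells.

    A surviving lesion at position ``x`` bp maps to ``lambda = rho * x`` and
    bin ``floor(lambda / width)``; lesions beyond the grid are discarded.
    Under the default ``covered`` rule a gene contributes repair-free
    expectation (and counted survivors) only for bins its expected-lesion
    length fully covers, keeping observed and expected commensurate; the
    ``prorated`` rule instead credits partial bin coverage on both sides.
    """
    grid = config.grid
    rho = config.lesion_rate
    w = grid.bin_width
    frac_cov = np.minimum(rho * cohort.lengths / w, float(grid.n_bins))
    covered = np.floor(frac_cov).astype(np.int64)

    lam = rho * cohort.positions
    bins = np.floor(lam / w).astype(np.int64)
    lesion_gene = np.repeat(np.arange(len(cohort)), np.diff(cohort.offsets))
    keep = survived & (bins < grid.n_bins)
    if config.expected_rule == "covered":
        keep &= bins < covered[lesion_gene]
    lg = lesion_gene[keep]
    cell = cohort.strata_idx[lg] * grid.n_bins + bins[keep]
    return SimCohortData(
        strata_idx=cohort.strata_idx,
        covered_bins=covered,
        frac_cov=frac_cov,
        lesion_gene=lg,
        lesion_cell=cell,
        grid=grid,
        n_strata=config.strata.n_strata,
        expected_rule=config.expected_rule,
    )


def simulate_cohort_data(
    params: TcrParams,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimCohortData:
    """Sample a cohort, run TCR, and return gene-level binned records."""
    config = config or SimulationConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cohort = sample_genes(config, params, rng)
    survived = _cohort_survivors(cohort, params, rng)
    return aggregate_surface(cohort, survived, config)


def simulate_surface(
    params: TcrParams,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimulatedSurface:
    """Simulate a fresh cohort and aggregate it; deterministic given a seed."""
    return simulate_cohort_data(params, config, rng).surface()
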