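"""Parameter inference for the TCR model.

The observed:expected surface (6 strata x 40 position bins) is fitted by
minimizing the Manhattan (L1) distance between the data and the analytic
surface: an exhaustive grid search provides the starting point for a bounded
derivative-free simplex refinement.  Confidence intervals come from refitting
surfaces rebuilt under bootstrap resampling of genes; restart vs no-restart
models are compared by AIC under a Gaussian error model with common variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import poisson_kmax, survival_stack, theory_surface
from .params import PositionGrid, StrataConfig, TcrParams, initiation_mixture
from .surface import ObsExpSurface

__all__ = [
    "GridSpec",
    "FitResult",
    "BootstrapResult",
    "ModelComparison",
    "PlausibilityMap",
    "manhattan_distance",
    "grid_search",
    "refine_fit",
    "fit_surface",
    "bootstrap_ci",
    "aic_compare",
    "plausibility_map",
    "estimate_m_orthogonal",
    "parameter_recovery",
]


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(n + 1), 10)


@dataclass(frozen=True)
class GridSpec:
    """Search-grid axes for (pd, pr, pv, m).

    The reference grid steps probabilities by 0.01 and m by 0.25 over
    [0.25, 10]; :meth:`coarse` (0.05 / 0.5) is desk-scale and
    :meth:`bootstrap` (0.1 / 1.0) keeps per-replicate refits cheap.
    """

    prob_step: float = 0.01
    m_range: tuple[float, float] = (0.25, 10.0)
    m_step: float = 0.25

    def __post_init__(self) -> None:
        if self.prob_step <= 0 or self.m_step <= 0:
            raise ValueError("grid steps must be positive")
        if not 0 < self.m_range[0] <= self.m_range[1]:
            raise ValueError("m range must be positive and ordered")

    @classmethod
    def fine(cls) -> "GridSpec":
        return cls()

    @classmethod
    def coarse(cls) -> "GridSpec":
        return cls(prob_step=0.05, m_step=0.5)

    @classmethod
    def bootstrap(cls) -> "GridSpec":
        return cls(prob_step=0.1, m_step=1.0)

    def prob_values(self) -> np.ndarray:
        return _axis(0.0, 1.0, self.prob_step)

    def m_values(self) -> np.ndarray:
        return _axis(self.m_range[0], self.m_range[1], self.m_step)

    def bounds(self, name: str) -> tuple[float, float]:
        return self.m_range if name == "m" else (0.0, 1.0)


@dataclass
class FitResult:
    params: TcrParams
    distance: float
    grid_start: TcrParams | None = None
    converged: bool = True
    n_evals: int = 0


@dataclass
class BootstrapResult:
    estimates: np.ndarray               # (n_reps, 4) columns pd, pr, pv, m
    ci95: dict[str, tuple[float, float]]
    n_reps: int
    distances: np.ndarray | None = None  # refit distance per replicate

    PARAM_NAMES = ("pd", "pr", "pv", "m")


@dataclass
class ModelComparison:
    mle_full: TcrParams
    mle_norestart: TcrParams
    v_full: float
    v_norestart: float
    loglik_full: float
    loglik_norestart: float
    aic_full: float
    aic_norestart: float


@dataclass
class PlausibilityMap:
    pd_values: np.ndarray
    pr_values: np.ndarray
    distance: np.ndarray   # (n_pd, n_pr), profiled over (pv, m)
    quantile: np.ndarray   # fraction of bootstrap distances >= distance

    def to_tsv(self, path) -> None:
        lines = ["pd\tpr\tdistance\tquantile"]
        for i, pd_ in enumerate(self.pd_values):
            for j, pr_ in enumerate(self.pr_values):
                lines.append(f"{float(pd_)!r}\t{float(pr_)!r}\t"
                             f"{float(self.distance[i, j])!r}\t"
                             f"{float(self.quantile[i, j])!r}")
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


def _as_values_mask(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, ObsExpSurface):
        return data.values, data.mask
    if hasattr(data, "obs_exp"):
        return data.obs_exp, data.mask
    values, mask = data
    return np.asarray(values, float), np.asarray(mask, bool)


def manhattan_distance(a, b, mask=None) -> float:
    """Sum of |a - b| over unmasked cells (the L1 fit objective)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError("mask shape mismatch")
    return float(np.abs(a - b)[mask].sum())


def _grid_blocks(
    grid: GridSpec,
    strata: StrataConfig,
    posgrid: PositionGrid,
    fixed: dict | None,
    tail_tol: float = 1e-9,
):
    """Iterate (pd, pr, values) blocks over the grid in lexicographic scan
    order; ``values`` has shape (n_pv, n_m, n_strata, n_bins)."""
    fixed = fixed or {}
    pd_vals = np.array([fixed["pd"]]) if "pd" in fixed else grid.prob_values()
    pr_vals = np.array([fixed["pr"]]) if "pr" in fixed else grid.prob_values()
    pv_vals = np.array([fixed["pv"]]) if "pv" in fixed else grid.prob_values()
    m_vals = np.array([fixed["m"]]) if "m" in fixed else grid.m_values()

    medians = np.asarray(strata.medians)
    n_s, n_b = strata.n_strata, posgrid.n_bins
    lams = posgrid.midpoints
    nf = np.floor(m_vals[:, None] * medians[None, :]).astype(int)   # (nm, ns)
    cc = 1.0 - (m_vals[:, None] * medians[None, :] - nf)
    zero_e = (m_vals[:, None] * medians[None, :]) == 0.0
    n_max = int(nf.max()) + 1
    pv_max = float(pv_vals.max())
    kmax = poisson_kmax(pv_max * float(lams.max()), tail_tol) if pv_max > 0 else 0
    karr = np.arange(kmax + 1)
    # Poisson weights per (pv, bin, k)
    pw = stats.poisson.pmf(karr[None, None, :], pv_vals[:, None, None] * lams[None, :, None])
    pw_flat = pw.reshape(-1, kmax + 1)

    ones_block = np.ones((len(pv_vals), len(m_vals), n_s, n_b))
    for pd in pd_vals:
        for pr in pr_vals:
            if pd == 0.0:
                yield float(pd), float(pr), ones_block
                continue
            V = survival_stack(float(pd), float(pr), n_max, kmax)
            M = (V @ pw_flat.T).reshape(n_max + 1, len(pv_vals), n_b)
            rows = (
                cc[:, :, None, None] * M[nf].transpose(0, 1, 2, 3)
                + (1.0 - cc)[:, :, None, None] * M[nf + 1]
            )  # (nm, ns, npv, nbins)
            rows[zero_e] = 1.0  # no transcription, no repair
            vals = (1.0 - pv_vals)[None, None, :, None] + pv_vals[None, None, :, None] * rows
            vals[zero_e] = 1.0
            yield float(pd), float(pr), vals.transpose(2, 0, 1, 3)
    return


def grid_search(
    data,
    grid: GridSpec | None = None,
    fixed: dict | None = None,
    strata: StrataConfig | None = None,
    posgrid: PositionGrid | None = None,
    metric: str = "l1",
) -> tuple[TcrParams, float]:
    """Exhaustive scan of the parameter grid; returns the minimizer.

    Ties are broken by lexicographic scan order over (pd, pr, pv, m), which
    makes results deterministic on flat objective regions (these are real,
    e.g. when only unexpressed genes carry signal).  ``fixed`` pins any
    subset of parameters to off-grid values.
    """
    grid = grid or GridSpec()
    strata = strata or StrataConfig()
    posgrid = posgrid or PositionGrid()
    values, mask = _as_values_mask(data)
    if not mask.any():
        raise ValueError("data mask is empty: nothing to fit")
    fixed = fixed or {}
    pv_vals = np.array([fixed["pv"]]) if "pv" in fixed else grid.prob_values()
    m_vals = np.array([fixed["m"]]) if "m" in fixed else grid.m_values()

    target = np.where(mask, values, 0.0)
    best = (np.inf, None)
    for pd, pr, block in _grid_blocks(grid, strata, posgrid, fixed):
        diff = np.where(mask[None, None], block - target[None, None], 0.0)
        if metric == "l1":
            dist = np.abs(diff).sum(axis=(2, 3))
        else:
            dist = (diff ** 2).sum(axis=(2, 3))
        flat = int(np.argmin(dist))
        d = float(dist.flat[flat])
        if d < best[0]:
            i_pv, i_m = np.unravel_index(flat, dist.shape)
            best = (d, TcrParams(pd=pd, pr=pr, pv=float(pv_vals[i_pv]),
                                 m=float(m_vals[i_m])))
    return best[1], best[0]


def _objective(values, mask, fixed, free_names, strata, posgrid, metric="l1"):
    target = np.where(mask, values, 0.0)

    def f(x):
        kw = dict(fixed)
        kw.update({n: float(np.clip(v, 0.0, None)) for n, v in zip(free_names, x)})
        try:
            p = TcrParams(**kw)
        except ValueError:
            return np.inf
        th = theory_surface(p, strata, posgrid).values
        diff = np.where(mask, th - target, 0.0)
        if metric == "l1":
            return float(np.abs(diff).sum())
        return float((diff ** 2).sum())

    return f


def refine_fit(
    data,
    start: TcrParams,
    fixed: dict | None = None,
    grid: GridSpec | None = None,
    strata: StrataConfig | None = None,
    posgrid: PositionGrid | None = None,
    metric: str = "l1",
    maxfev: int = 2000,
    tol: float = 1e-6,
) -> FitResult:
    """Bounded Nelder-Mead descent of the surface-distance objective from a
    grid-search starting point; the final distance never exceeds the start's."""
    grid = grid or GridSpec()
    strata = strata or StrataConfig()
    posgrid = posgrid or PositionGrid()
    fixed = dict(fixed or {})
    values, mask = _as_values_mask(data)
    free_names = [n for n in ("pd", "pr", "pv", "m") if n not in fixed]
    f = _objective(values, mask, fixed, free_names, strata, posgrid, metric)
    x0 = np.array([getattr(start, n) for n in free_names])
    f0 = f(x0)
    if not free_names:
        return FitResult(params=start, distance=f0, grid_start=start, n_evals=1)
    bounds = [grid.bounds(n) for n in free_names]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            f, x0, method="Nelder-Mead", bounds=bounds,
            options={"maxfev": maxfev, "fatol": tol, "xatol": tol},
        )
    if res.fun <= f0:
        x, fun = res.x, float(res.fun)
    else:  # pathological simplex collapse: keep the grid point
        x, fun = x0, f0
    kw = dict(fixed)
    kw.update({n: float(v) for n, v in zip(free_names, x)})
    return FitResult(
        params=TcrParams(**kw), distance=fun, grid_start=start,
        converged=bool(res.success), n_evals=int(res.nfev),
    )


def fit_surface(
    data,
    grid: GridSpec | None = None,
    fixed: dict | None = None,
    strata: StrataConfig | None = None,
    posgrid: PositionGrid | None = None,
    metric: str = "l1",
    refine: bool = True,
    maxfev: int = 2000,
) -> FitResult:
    """Grid search followed by simplex refinement (the standard workflow)."""
    start, d0 = grid_search(data, grid, fixed, strata, posgrid, metric)
    if not refine:
        return FitResult(params=start, distance=d0, grid_start=start)
    return refine_fit(data, start, fixed, grid, strata, posgrid, metric,
                      maxfev=maxfev)


class MaterializedGrid:
    """Pre-computed theory surfaces for every grid point, in scan order.

    Makes repeated (bootstrap) grid searches a single vectorized distance
    reduction.  Only sensible for desk-scale grids; refuses to materialize
    more than ``max_points`` combinations.
    """

    def __init__(self, grid, strata=None, posgrid=None, fixed=None,
                 max_points: int = 500_000):
        grid = grid or GridSpec()
        self.strata = strata or StrataConfig()
        self.posgrid = posgrid or PositionGrid()
        fixed = fixed or {}
        pv_vals = np.array([fixed["pv"]]) if "pv" in fixed else grid.prob_values()
        m_vals = np.array([fixed["m"]]) if "m" in fixed else grid.m_values()
        pd_vals = np.array([fixed["pd"]]) if "pd" in fixed else grid.prob_values()
        pr_vals = np.array([fixed["pr"]]) if "pr" in fixed else grid.prob_values()
        n_pts = len(pd_vals) * len(pr_vals) * len(pv_vals) * len(m_vals)
        if n_pts > max_points:
            raise ValueError(
                f"grid has {n_pts} points; materializing would exceed "
                f"max_points={max_points}"
            )
        params = []
        blocks = []
        for pd, pr, block in _grid_blocks(grid, self.strata, self.posgrid, fixed):
            for i_pv, pv in enumerate(pv_vals):
                for i_m, m in enumerate(m_vals):
                    params.append((pd, pr, float(pv), float(m)))
            blocks.append(block.reshape(-1, block.shape[2], block.shape[3]))
        self.params = np.array(params)
        self.surfaces = np.concatenate(blocks, axis=0).astype(np.float32)

    def search(self, values, mask) -> tuple[TcrParams, float]:
        target = np.where(mask, values, 0.0).astype(np.float32)
        diff = np.where(mask[None], self.surfaces - target[None], 0.0)
        dist = np.abs(diff).sum(axis=(1, 2))
        i = int(np.argmin(dist))  # first occurrence == lexicographic tie-break
        p = self.params[i]
        return TcrParams(pd=p[0], pr=p[1], pv=p[2], m=p[3]), float(dist[i])


def bootstrap_ci(
    gene_data,
    n_reps: int = 100,
    grid: GridSpec | None = None,
    fixed: dict | None = None,
    rng: np.random.Generator | int | None = None,
    strata: StrataConfig | None = None,
    posgrid: PositionGrid | None = None,
    refine: bool = True,
    refine_maxfev: int = 400,
) -> BootstrapResult:
    """Bootstrap confidence intervals by resampling genes with replacement.

    ``gene_data`` must expose ``resample(rng)`` returning a surface rebuilt
    from a gene-level resample (see :class:`tcrdyn.simulate.SimCohortData`
    and :class:`tcrdyn.pipeline.PipelineGeneData`).  Each replicate is refit
    from scratch (coarse grid + simplex); the CI95 is the (0.025, 0.975)
    quantile band of the replicate estimates.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    grid = grid or GridSpec.bootstrap()
    strata = strata or StrataConfig()
    posgrid = posgrid or PositionGrid()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lib = MaterializedGrid(grid, strata, posgrid, fixed)
    ests = np.empty((n_reps, 4))
    dists = np.empty(n_reps)
    for r in range(n_reps):
        surf = gene_data.resample(rng)
        values, mask = _as_values_mask(surf)
        start, d0 = lib.search(values, mask)
        if refine:
            fit = refine_fit((values, mask), start, fixed, grid, strata, posgrid,
                             maxfev=refine_maxfev)
            ests[r] = fit.params.astuple()
            dists[r] = fit.distance
        else:
            ests[r] = start.astuple()
            dists[r] = d0
    ci = {
        name: (float(np.quantile(ests[:, i], 0.025)),
               float(np.quantile(ests[:, i], 0.975)))
        for i, name in enumerate(BootstrapResult.PARAM_NAMES)
    }
    return BootstrapResult(estimates=ests, ci95=ci, n_reps=n_reps, distances=dists)


def aic_compare(
    data,
    grid: GridSpec | None = None,
    strata: StrataConfig | None = None,
    posgrid: PositionGrid | None = None,
    fixed: dict | None = None,
) -> ModelComparison:
    """AIC comparison of the full model vs the no-restart (pr = 0) model.

    Cells are modeled as Gaussian around the theory surface with a common
    variance ``v`` whose MLE is the mean squared residual; maximizing the
    likelihood over the surface parameters therefore reduces to least
    squares.  Parameter counts are k = 5 (pd, pr, pv, m, v) and k = 4.
    """
    grid = grid or GridSpec.coarse()
    strata = strata or StrataConfig()
    posgrid = posgrid or PositionGrid()
    values, mask = _as_values_mask(data)
    n = int(mask.sum())
    if n < 6:
        raise ValueError("need at least 6 unmasked cells for model comparison")

    def loglik_from(dist):
        v = dist / n
        if v < 1e-12:
            warnings.warn("perfect fit: variance floored at 1e-12")
            v = 1e-12
        return v, -0.5 * n * (np.log(2.0 * np.pi * v) + 1.0)

    fixed = dict(fixed or {})
    full_fix = dict(fixed)
    nr_fix = dict(fixed)
    nr_fix["pr"] = 0.0
    fit_full = fit_surface((values, mask), grid, full_fix, strata, posgrid,
                           metric="l2")
    fit_nr = fit_surface((values, mask), grid, nr_fix, strata, posgrid,
                         metric="l2")
    if fit_nr.distance < fit_full.distance:
        # nested models: the restricted optimum is a feasible full-model
        # point, so restart the full refinement from there
        alt = refine_fit((values, mask), fit_nr.params, full_fix, grid, strata,
                         posgrid, metric="l2")
        if alt.distance < fit_full.distance:
            fit_full = alt
    p_full, (v_full, ll_full) = fit_full.params, loglik_from(fit_full.distance)
    p_nr, (v_nr, ll_nr) = fit_nr.params, loglik_from(fit_nr.distance)
    return ModelComparison(
        mle_full=p_full, mle_norestart=p_nr,
        v_full=v_full, v_norestart=v_nr,
        loglik_full=ll_full, loglik_norestart=ll_nr,
        aic_full=2 * 5 - 2 * ll_full, aic_norestart=2 * 4 - 2 * ll_nr,
    )


def plausibility_map(
    data,
    bootstrap_distances: np.ndarray,
    grid: GridSpec | None = None,
    strata: StrataConfig | None = None,
    posgrid: PositionGrid | None = None,
    fixed: dict | None = None,
) -> PlausibilityMap:
    """(pd, pr) landscape of best achievable distance, profiled over (pv, m),
    shaded by its quantile within the bootstrap-distance distribution.

    A cell is plausible at level q if the theory-to-data distance there is
    smaller than a fraction q of the distances between bootstrap resamples
    and the original data.
    """
    boot = np.asarray(bootstrap_distances, dtype=float)
    if boot.size == 0:
        raise ValueError("bootstrap distances must be nonempty")
    grid = grid or GridSpec.coarse()
    strata = strata or StrataConfig()
    posgrid = posgrid or PositionGrid()
    values, mask = _as_values_mask(data)
    target = np.where(mask, values, 0.0)
    fixed = dict(fixed or {})
    pd_vals = grid.prob_values() if "pd" not in fixed else np.array([fixed["pd"]])
    pr_vals = grid.prob_values() if "pr" not in fixed else np.array([fixed["pr"]])
    dist = np.empty((len(pd_vals), len(pr_vals)))
    for pd, pr, block in _grid_blocks(grid, strata, posgrid, fixed):
        diff = np.where(mask[None, None], block - target[None, None], 0.0)
        d = np.abs(diff).sum(axis=(2, 3)).min()
        i = int(np.searchsorted(pd_vals, pd))
        j = int(np.searchsorted(pr_vals, pr))
        dist[i, j] = d
    quant = (boot[None, None, :] >= dist[:, :, None]).mean(axis=2)
    return PlausibilityMap(pd_values=pd_vals, pr_values=pr_vals,
                           distance=dist, quantile=quant)


def estimate_m_orthogonal(gene_table, minutes: float = 2280.0) -> float:
    """Least-squares estimate of the expression multiplier from single-gene
    transcription kinetics.

    Each gene provides ``n = rate * active_fraction * minutes`` transcripts
    between damage and replication; fitting ``log10(n) = log10(e) + log10(m)``
    gives ``m = 10**mean(log10 n - log10 e)``.  Genes with nonpositive ``n``
    or ``e`` are excluded with a warning.
    """
    import pandas as pd

    df = pd.DataFrame(gene_table)
    required = {"rate", "active_fraction", "ntpm"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    n = df["rate"].to_numpy(float) * df["active_fraction"].to_numpy(float) * minutes
    e = df["ntpm"].to_numpy(float)
    ok = (n > 0) & (e > 0)
    if (~ok).any():
        warnings.warn(f"excluding {int((~ok).sum())} genes with nonpositive n or e")
    if not ok.any():
        raise ValueError("no usable genes in table")
    return float(10.0 ** np.mean(np.log10(n[ok]) - np.log10(e[ok])))


def parameter_recovery(
    n_sets: int = 30,
    n_genes: int = 100_000,
    grid: GridSpec | None = None,
    fixed: dict | None = None,
    rng: np.random.Generator | int | None = None,
    pd_range: tuple[float, float] = (0.1, 0.9),
    pr_range: tuple[float, float] = (0.1, 1.0),
    m_range: tuple[float, float] = (0.5, 8.5),
    pv_true: float = 0.8,
):
    """Simulate datasets at random true parameters and refit each one.

    Returns a DataFrame with the true and estimated parameters and percent
    errors per set; median percent errors quantify recovery accuracy.  The
    visible fraction is fixed at ``pv_true`` for both simulation and fitting,
    mirroring the simulation-study design.
    """
    import pandas as pd

    from .simulate import SimulationConfig, simulate_cohort_data

    grid = grid or GridSpec.coarse()
    if fixed is None:
        fixed = {"pv": pv_true}
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cfg = SimulationConfig(n_genes=n_genes)
    rows = []
    for i in range(n_sets):
        true = TcrParams(
            pd=float(rng.uniform(*pd_range)),
            pr=float(rng.uniform(*pr_range)),
            pv=pv_true,
            m=float(rng.uniform(*m_range)),
        )
        data = simulate_cohort_data(true, cfg, rng)
        fit = fit_surface(data.surface(), grid, fixed)
        row = {"set": i}
        for name in ("pd", "pr", "m"):
            t, est = getattr(true, name), getattr(fit.params, name)
            row[f"true_{name}"] = t
            row[f"est_{name}"] = est
            row[f"pct_err_{name}"] = 100.0 * abs(est - t) / t
        row["distance"] = fit.distance
        rows.append(row)
    return pd.DataFrame(rows)
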