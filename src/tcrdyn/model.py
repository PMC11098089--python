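"""Analytic expectation of template-strand lesion survival under TCR.

A focal template-strand lesion sits at genic position ``lam`` (measured in
expected upstream lesions).  RNAPs initiate sequentially at the promoter and
travel 5'->3'.  On encountering a visible, still-unrepaired lesion an RNAP

* bypasses it with probability ``1 - pd`` (lesion untouched, RNAP continues),
* repairs it and restarts with probability ``pd * pr`` (lesion removed,
  RNAP continues), or
* repairs it and dissociates with probability ``pd * (1 - pr)`` (lesion
  removed, the pass ends; downstream lesions are untouched).

Upstream lesions therefore shield the focal lesion: every pass that
terminates upstream leaves the focal site untouched, but also erodes the
shield by one lesion.  The number of visible upstream lesions is Poisson with
mean ``pv * lam``.  The focal lesion survives all ``n`` passes with a
probability computed exactly by iterating the per-pass transition kernel of
the Markov chain on states ``(upstream lesions remaining, focal alive)``.

Dividing the surviving template-lesion burden by the transcription-free
(coding-strand) burden yields the theoretical observed:expected surface that
is fitted to strand-phased tumor mutation data.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import special, stats

from .params import InitiationMixture, PositionGrid, StrataConfig, TcrParams, initiation_mixture
from .surface import ObsExpSurface

__all__ = [
    "initiation_mixture",
    "pass_transition",
    "survival_probability",
    "survival_stack",
    "expected_obs_exp",
    "theory_surface",
    "m_bounds_from_census",
    "bypass_fraction",
]


def _removal_probs(pd: float, pr: float, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pass removal-count distributions over upstream lesions.

    Returns ``(reach, stop)`` where, starting a pass with ``j`` live upstream
    lesions, ``reach[j, i]`` is the probability the RNAP reaches the focal
    site having repaired ``i`` upstream lesions, and ``stop[j, d]`` the
    probability it dissociates upstream having removed ``d`` lesions in total
    (the lesion that triggered dissociation is itself repaired).
    """
    b = 1.0 - pd          # bypass
    rc = pd * pr          # repair + continue
    rs = pd * (1.0 - pr)  # repair + dissociate
    idx = np.arange(kmax + 1)
    j = idx[:, None]
    i = idx[None, :]
    tri = i <= j
    exp_ji = np.where(tri, j - i, 0)
    # reach[j, i] = C(j, i) * rc^i * b^(j-i); 0^0 == 1 handles pd in {0, 1}.
    reach = special.comb(j, i) * np.power(rc, i) * np.power(b, exp_ji)
    reach[~tri] = 0.0

    # stop[j, d] = rs * rc^(d-1) * sum_{l=d-1}^{j-1} C(l, d-1) b^(l-d+1)
    l = idx[None, :]
    a_i = idx[:, None]
    low = l >= a_i
    A = special.comb(l, a_i) * np.power(b, np.where(low, l - a_i, 0))
    A[~low] = 0.0
    G = np.cumsum(A, axis=1)  # G[i, t] = sum_{l<=t} C(l, i) b^(l-i)
    stop = np.zeros((kmax + 1, kmax + 1))
    if kmax >= 1:
        d = idx[1:]
        # rows j >= 1, removals d = 1..j
        stop[1:, 1:] = rs * np.power(rc, d - 1)[None, :] * G[:-1, :-1].T
        # zero entries with d > j
        jj = idx[:, None]
        dd = idx[None, :]
        stop[dd > jj] = 0.0
    return reach, stop


def _scatter_by_removal(T: np.ndarray) -> np.ndarray:
    """Map ``T[j, d]`` (probability of removing d from j) to ``M[j, j-d]``."""
    k = T.shape[0] - 1
    idx = np.arange(k + 1)
    jj = idx[:, None]
    dd = idx[None, :]
    valid = dd <= jj
    M = np.zeros_like(T)
    rows, rem = np.nonzero(valid)
    M[rows, rows - rem] = T[rows, rem]
    return M


def _pass_matrices(pd: float, pr: float, kmax: int):
    """One-pass transition matrices over upstream-lesion counts 0..kmax.

    Returns ``(q_alive, to_dead, p_dead)``: focal-alive -> focal-alive,
    focal-alive -> focal-dead, and focal-dead -> focal-dead kernels.
    """
    reach, stop = _removal_probs(pd, pr, kmax)
    q_alive = _scatter_by_removal(reach * (1.0 - pd) + stop)
    to_dead = _scatter_by_removal(reach * pd)
    p_dead = _scatter_by_removal(reach + stop)
    return q_alive, to_dead, p_dead


def pass_transition(k_upstream: int, focal_alive: bool, pd: float, pr: float) -> dict:
    """Distribution over ``(k_upstream', focal_alive')`` after one RNAP pass.

    Encodes a single RNAP traversal over ``k_upstream`` live visible upstream
    lesions followed by the focal lesion.  A dead (already repaired) focal
    lesion never revives; upstream lesions continue to be eroded by later
    passes regardless of the focal state.
    """
    if k_upstream < 0:
        raise ValueError("k_upstream must be non-negative")
    TcrParams(pd=pd, pr=pr)  # validate probabilities
    q_alive, to_dead, p_dead = _pass_matrices(pd, pr, k_upstream)
    out: dict[tuple[int, bool], float] = {}
    if focal_alive:
        for k2 in range(k_upstream + 1):
            if q_alive[k_upstream, k2] > 0:
                out[(k2, True)] = float(q_alive[k_upstream, k2])
            if to_dead[k_upstream, k2] > 0:
                out[(k2, False)] = float(to_dead[k_upstream, k2])
    else:
        for k2 in range(k_upstream + 1):
            if p_dead[k_upstream, k2] > 0:
                out[(k2, False)] = float(p_dead[k_upstream, k2])
    return out


def survival_stack(pd: float, pr: float, n_max: int, kmax: int) -> np.ndarray:
    """Matrix ``V[n, k]``: focal survival probability after ``n`` passes
    starting with ``k`` visible upstream lesions, for all ``n <= n_max`` and
    ``k <= kmax``."""
    q_alive, _, _ = _pass_matrices(pd, pr, kmax)
    V = np.empty((n_max + 1, kmax + 1))
    v = np.ones(kmax + 1)
    V[0] = v
    for n in range(1, n_max + 1):
        v = q_alive @ v
        V[n] = v
    return V


@lru_cache(maxsize=200_000)
def _survival_cached(n: int, k: int, pd: float, pr: float) -> float:
    return float(survival_stack(pd, pr, n, k)[n, k])


def survival_probability(n: int, k: int, pd: float, pr: float) -> float:
    """Probability a focal visible lesion survives ``n`` sequential RNAP
    passes given ``k`` visible upstream lesions initially.

    Closed forms: equals ``(1 - pd)**n`` when ``k == 0`` (no shielding) or
    when ``pr == 1`` (restarting RNAPs always reach the focal site).  Results
    are cached; grid-search inference re-evaluates them massively.
    """
    if n < 0 or k < 0:
        raise ValueError("n and k must be non-negative")
    return _survival_cached(int(n), int(k), float(pd), float(pr))


def poisson_kmax(mu: float, tail_tol: float = 1e-9) -> int:
    """Smallest K with Poisson(mu) tail mass beyond K below ``tail_tol``."""
    if mu <= 0:
        return 0
    k = int(stats.poisson.isf(tail_tol, mu)) + 1
    return max(k, 2)


def expected_obs_exp(
    params: TcrParams, lam: float, n: int, tail_tol: float = 1e-9
) -> float:
    """Expected observed:expected ratio at position ``lam`` after ``n`` passes.

    Averages the focal survival probability over the Poisson(pv * lam) number
    of visible upstream lesions and adds the invisible fraction ``1 - pv``
    (invisible lesions never interact with RNAP).  The Poisson sum is
    truncated once its residual tail mass falls below ``tail_tol``.
    """
    if lam < 0 or n < 0:
        raise ValueError("lam and n must be non-negative")
    pd, pr, pv = params.pd, params.pr, params.pv
    if pd == 0.0 or pv == 0.0 or n == 0:
        return 1.0
    mu = pv * lam
    if mu == 0.0:
        return (1.0 - pv) + pv * (1.0 - pd) ** n
    kmax = poisson_kmax(mu, tail_tol)
    weights = stats.poisson.pmf(np.arange(kmax + 1), mu)
    v = survival_stack(pd, pr, n, kmax)[n]
    return float((1.0 - pv) + pv * np.dot(weights, v))


def _strata_mixtures(m: float, strata: StrataConfig) -> list[InitiationMixture]:
    return [initiation_mixture(m, e) for e in strata.medians]


def theory_surface(
    params: TcrParams,
    strata: StrataConfig | None = None,
    grid: PositionGrid | None = None,
    tail_tol: float = 1e-9,
    bin_eval: str = "midpoint",
) -> ObsExpSurface:
    """Analytic observed:expected surface over strata x position bins.

    Each stratum's RNAP count is the mean-preserving floor/floor+1 mixture of
    ``m * e`` (see :func:`initiation_mixture`); each bin is evaluated at its
    lambda midpoint by default, or averaged over five equispaced points per
    bin with ``bin_eval="average5"`` (a sensitivity check -- the within-bin
    evaluation point is a modeling choice, not data).
    """
    strata = strata or StrataConfig()
    grid = grid or PositionGrid()
    if bin_eval not in ("midpoint", "average5"):
        raise ValueError("bin_eval must be 'midpoint' or 'average5'")
    pd, pr, pv, m = params.pd, params.pr, params.pv, params.m
    n_s, n_b = strata.n_strata, grid.n_bins
    values = np.ones((n_s, n_b))
    mask = np.ones((n_s, n_b), dtype=bool)
    meta = {"params": params.astuple(), "kind": "theory"}
    if pd == 0.0 or pv == 0.0 or m == 0.0:
        return ObsExpSurface(values=values, mask=mask, grid=grid, meta=meta)

    if bin_eval == "midpoint":
        lams = grid.midpoints
    else:
        offsets = (np.arange(5) + 0.5) / 5.0
        lams = (np.arange(n_b)[:, None] + offsets[None, :]).ravel() * grid.bin_width

    mixtures = _strata_mixtures(m, strata)
    n_max = max(mx.n_floor + 1 for mx in mixtures)
    kmax = poisson_kmax(pv * float(lams.max()), tail_tol)
    V = survival_stack(pd, pr, n_max, kmax)  # (n_max+1, kmax+1)
    pw = stats.poisson.pmf(np.arange(kmax + 1)[None, :], pv * lams[:, None])
    M1 = V @ pw.T  # (n_max+1, n_lams): E_k[survival] per pass count

    for s, (e, mx) in enumerate(zip(strata.medians, mixtures)):
        if e == 0.0 or m * e == 0.0:
            continue  # no transcription, no repair: exact row of ones
        row = mx.c * M1[mx.n_floor] + (1.0 - mx.c) * M1[mx.n_floor + 1]
        row = (1.0 - pv) + pv * row
        if bin_eval == "average5":
            row = row.reshape(n_b, 5).mean(axis=1)
        values[s] = row
    return ObsExpSurface(values=values, mask=mask, grid=grid, meta=meta)


def m_bounds_from_census(
    polymerases: float, rate: float, gene_len: float, minutes: float
) -> float:
    """Plausibility bound for the expression multiplier from an RNAP census.

    ``polymerases`` actively transcribing RNAP II complexes per cell, each
    elongating at ``rate`` kb/min over genes of median length ``gene_len`` kb
    for ``minutes`` minutes between damage and replication, produce
    ``polymerases * rate * minutes / gene_len`` transcripts; dividing by 1e6
    expresses the result in the units of ``m`` (millions of initiations).
    """
    if polymerases < 0 or rate < 0 or minutes < 0:
        raise ValueError("census inputs must be non-negative")
    if gene_len <= 0:
        raise ValueError("gene_len must be positive")
    return polymerases * rate * minutes / gene_len / 1e6


def bypass_fraction(params: TcrParams) -> float:
    """Probability a lesion encounter does not trigger TCR: ``1 - pv * pd``.

    Counts both invisible lesions (never detected) and visible lesions that
    the RNAP transcribes over without stalling.
    """
    return 1.0 - params.pv * params.pd
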