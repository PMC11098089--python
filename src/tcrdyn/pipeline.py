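"""From strand-resolved mutations to observed:expected surfaces.

The pipeline mirrors the tumor-genome analysis the model is fitted to:

1. genes are stratified into six nascent-expression strata;
2. each tumor's genomic segments are phased to a lesion strand, labeling
   every gene's lesions as template (TCR-exposed) or nontemplate;
3. genic positions are normalized to "expected upstream lesions" (lambda):
   the per-tumor expected lesion count between the TSS and the analysis
   window, from upstream sequence composition and the tumor's per-context
   mutation rates;
4. template and nontemplate mutation rates are accumulated per (stratum,
   lambda-bin) cell, and their ratio forms the observed:expected surface
   fitted by :mod:`tcrdyn.inference`.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import PositionGrid, StrataConfig
from .phasing import FORWARD, REVERSE, template_status
from .rates import (
    GenomeCodes,
    TrinucRateTable,
    context_counts,
    genome_composition,
    mutation_context_codes,
    rc_context_perm,
)
from .surface import ObsExpSurface

__all__ = [
    "stratify_genes",
    "drop_overlapping_genes",
    "prepare_genes",
    "expected_upstream_lesions",
    "genic_window_rates",
    "obs_exp_surface",
    "expression_curve",
    "StratifiedObsExp",
    "PipelineGeneData",
]

WINDOW_BP = 5000


def stratify_genes(
    ntpm, boundaries: tuple[float, float] = StrataConfig().boundaries
) -> np.ndarray:
    """Assign expression strata 1-6 from nascent expression (nTPM).

    Genes below the lower boundary are stratum 1 (no detectable TCR signal),
    genes above the upper boundary stratum 6 (saturated repair); the genes in
    between are quantile-split into four equal-count strata 2-5.  The split
    is idempotent and order-independent (ranking ties broken by value only).
    """
    e = np.asarray(ntpm, dtype=float)
    if np.any(e < 0) or np.any(~np.isfinite(e)):
        raise ValueError("nTPM values must be finite and non-negative")
    lo, hi = boundaries
    out = np.full(e.shape, 0, dtype=np.int64)
    out[e < lo] = 1
    out[e > hi] = 6
    mid = np.flatnonzero(out == 0)
    if mid.size:
        order = np.argsort(e[mid], kind="stable")
        ranks = np.empty(mid.size, dtype=np.int64)
        ranks[order] = np.arange(mid.size)
        out[mid] = 2 + (ranks * 4) // mid.size
    return out


def drop_overlapping_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Hierarchical overlap exclusion: keep the most expressed gene and drop
    any less-expressed gene whose span overlaps it."""
    keep = []
    taken: dict[str, list[tuple[int, int]]] = {}
    for _, g in genes.sort_values("ntpm", ascending=False).iterrows():
        spans = taken.setdefault(g["chrom"], [])
        if any(g["start"] < e and g["end"] > s for s, e in spans):
            continue
        spans.append((int(g["start"]), int(g["end"])))
        keep.append(g.name)
    return genes.loc[sorted(keep)].reset_index(drop=True)


def prepare_genes(
    genes: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    boundaries: tuple[float, float] = StrataConfig().boundaries,
) -> pd.DataFrame:
    """Join expression onto the annotation, drop overlaps, assign strata."""
    df = genes.copy()
    if expression is not None:
        df = df.merge(expression[["gene_id", "ntpm"]], on="gene_id", how="inner")
    if "ntpm" not in df.columns:
        raise ValueError("genes need an 'ntpm' column or an expression table")
    df = drop_overlapping_genes(df)
    df["stratum"] = stratify_genes(df["ntpm"].to_numpy(), boundaries)
    return df


def _tx_window_bounds(start: int, end: int, strand: str, w: int, widx: int):
    """Genomic [lo, hi) of window ``widx`` counted from the TSS in
    transcription direction."""
    if strand == "+":
        lo = start + widx * w
        return lo, min(lo + w, end)
    hi = end - widx * w
    return max(hi - w, start), hi


def expected_upstream_lesions(
    gene,
    window_start: int,
    tumor_rates: TrinucRateTable | np.ndarray,
    genome,
    lesion_strand: str,
) -> float:
    """Expected lesion count between the TSS and ``window_start``.

    ``window_start`` is an offset in bp from the TSS in transcription
    direction.  The upstream sequence is read on the lesion strand and each
    trinucleotide context contributes its per-context rate from
    ``tumor_rates`` (a :class:`TrinucRateTable` or a raw 64-vector of rates
    expressed on the lesion strand).
    """
    rates64 = (
        tumor_rates.rates64 if isinstance(tumor_rates, TrinucRateTable) else np.asarray(tumor_rates)
    )
    gc = genome if isinstance(genome, GenomeCodes) else GenomeCodes(genome)
    start, end, strand = int(gene["start"]), int(gene["end"]), gene["strand"]
    if not 0 <= window_start <= end - start:
        raise ValueError("window_start must lie within the gene span")
    if strand == "+":
        lo, hi = start, start + window_start
    else:
        lo, hi = end - window_start, end
    c64 = context_counts(gc.codes(gene["chrom"]), lo, hi)
    if lesion_strand == REVERSE:
        c64 = c64[rc_context_perm]
    return float(np.dot(c64, rates64))


def _gene_window_contexts(gc: GenomeCodes, genes: pd.DataFrame, w: int):
    """Per-gene stacked plus-strand context counts per 5 kb window, ordered
    in transcription direction, with exclusive upstream cumulative sums."""
    per_gene = []
    for _, g in genes.iterrows():
        n_w = max(1, -(-(int(g["end"]) - int(g["start"])) // w))
        c = np.zeros((n_w, 64), dtype=np.int64)
        codes = gc.codes(g["chrom"])
        for widx in range(n_w):
            lo, hi = _tx_window_bounds(int(g["start"]), int(g["end"]), g["strand"], w, widx)
            c[widx] = context_counts(codes, lo, hi)
        u = np.zeros_like(c)
        np.cumsum(c[:-1], axis=0, out=u[1:])
        per_gene.append((c, u))
    return per_gene


def _assign_windows(
    muts: pd.DataFrame, genes: pd.DataFrame, w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Gene index and transcription-direction window per mutation (-1 = none).

    Genes must be non-overlapping (see :func:`drop_overlapping_genes`).
    """
    gene_idx = np.full(len(muts), -1, dtype=np.int64)
    widx = np.full(len(muts), -1, dtype=np.int64)
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        sel = np.flatnonzero((muts["chrom"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        pos = muts["pos"].to_numpy()[sel]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        rows = sub.index.to_numpy()[j[ok]]
        gene_idx[sel[ok]] = rows
        strands = sub["strand"].to_numpy()[j[ok]]
        offset = np.where(
            strands == "+",
            pos[ok] - starts[j[ok]],
            ends[j[ok]] - 1 - pos[ok],
        )
        widx[sel[ok]] = offset // w
    return gene_idx, widx


def _tumor_context_rates(
    mutations: pd.DataFrame,
    phases: pd.DataFrame,
    genes: pd.DataFrame,
    gc: GenomeCodes,
    per_tumor_contexts: bool,
    region_mode: str,
):
    """Per-tumor 64-vectors of lesion-strand per-context rates.

    The context spectrum is estimated from phaseable sequence outside genes
    (``region_mode="intergenic"``, default) or from nontemplate gene bodies;
    by default the spectrum is pooled across tumors and rescaled to each
    tumor's own burden (stable when per-tumor mutation counts are modest),
    with ``per_tumor_contexts=True`` switching to fully per-tumor rates.
    """
    chrom_genes = {c: sub.sort_values("start") for c, sub in genes.groupby("chrom")}
    pooled_counts = np.zeros(64)
    pooled_opp = np.zeros(64)
    tumor_counts: dict[str, np.ndarray] = {}
    tumor_opp: dict[str, np.ndarray] = {}

    def region_spans(chrom, lesion_strand):
        """(start, end) spans used for rate estimation on this chromosome."""
        sub = chrom_genes.get(chrom)
        length = gc.length(chrom)
        if sub is None:
            return [(0, length)] if region_mode == "intergenic" else []
        if region_mode == "intergenic":
            spans, prev = [], 0
            for s, e in zip(sub["start"], sub["end"]):
                if s > prev:
                    spans.append((prev, int(s)))
                prev = int(e)
            if prev < length:
                spans.append((prev, length))
            return spans
        spans = []
        for s, e, gs in zip(sub["start"], sub["end"], sub["strand"]):
            if template_status(gs, lesion_strand) == "nontemplate":
                spans.append((int(s), int(e)))
        return spans

    opp_cache: dict[tuple[str, str], np.ndarray] = {}
    for (tumor_id, chrom), seg in phases.groupby(["tumor_id", "chrom"]):
        strand = seg["lesion_strand"].iloc[0]
        if strand not in (FORWARD, REVERSE):
            continue
        key = (chrom, strand)
        if key not in opp_cache:
            opp = np.zeros(64)
            for s, e in region_spans(chrom, strand):
                opp += context_counts(gc.codes(chrom), s, e)
            if strand == REVERSE:
                opp = opp[rc_context_perm]
            opp_cache[key] = opp
        opp = opp_cache[key]
        sel = (mutations["tumor_id"] == tumor_id) & (mutations["chrom"] == chrom)
        pos_all = mutations.loc[sel, "pos"].to_numpy()
        in_region = np.zeros(pos_all.size, dtype=bool)
        for s, e in region_spans(chrom, strand):
            in_region |= (pos_all >= s) & (pos_all < e)
        ctx = np.zeros(64)
        if in_region.any():
            c, _ = mutation_context_codes(gc, chrom, pos_all[in_region])
            if strand == REVERSE:
                c = rc_context_perm[c]
            ctx = np.bincount(c, minlength=64).astype(float)
        tumor_counts[tumor_id] = tumor_counts.get(tumor_id, np.zeros(64)) + ctx
        tumor_opp[tumor_id] = tumor_opp.get(tumor_id, np.zeros(64)) + opp
        pooled_counts += ctx
        pooled_opp += opp

    rates = {}
    ok = pooled_opp > 0
    pooled_rates = np.zeros(64)
    pooled_rates[ok] = pooled_counts[ok] / pooled_opp[ok]
    pooled_mean = pooled_counts.sum() / max(pooled_opp.sum(), 1.0)
    for tumor_id, cnt in tumor_counts.items():
        if per_tumor_contexts:
            r = np.zeros(64)
            tok = tumor_opp[tumor_id] > 0
            r[tok] = cnt[tok] / tumor_opp[tumor_id][tok]
        else:
            burden = cnt.sum() / max(tumor_opp[tumor_id].sum(), 1.0)
            scale = burden / pooled_mean if pooled_mean > 0 else 0.0
            r = pooled_rates * scale
        rates[tumor_id] = r
    return rates


@dataclass
class StratifiedObsExp:
    """Observed:expected surface plus the per-cell rate components."""

    surface: ObsExpSurface
    template_rate: np.ndarray
    nontemplate_rate: np.ndarray
    template_count: np.ndarray
    nontemplate_count: np.ndarray
    exclusions: dict = field(default_factory=dict)
    gene_data: "PipelineGeneData | None" = None


class PipelineGeneData:
    """Sparse per-gene cell contributions enabling gene-level bootstrap.

    Rows are (gene, cell) contributions of composition-weighted mutation
    counts and opportunities, split by template/nontemplate orientation.
    """

    def __init__(self, n_genes, gene_idx, cell_idx, is_template, wcount, wopp,
                 grid: PositionGrid, n_strata: int = 6):
        self.n_genes = n_genes
        self.gene_idx = gene_idx
        self.cell_idx = cell_idx
        self.is_template = is_template
        self.wcount = wcount
        self.wopp = wopp
        self.grid = grid
        self.n_strata = n_strata

    def _cells(self, mult: np.ndarray):
        n_cells = self.n_strata * self.grid.n_bins
        w = mult[self.gene_idx]
        out = []
        for tmpl in (True, False):
            sel = self.is_template == tmpl
            cnt = np.bincount(self.cell_idx[sel], weights=w[sel] * self.wcount[sel],
                              minlength=n_cells)
            opp = np.bincount(self.cell_idx[sel], weights=w[sel] * self.wopp[sel],
                              minlength=n_cells)
            out.append((cnt.reshape(self.n_strata, -1), opp.reshape(self.n_strata, -1)))
        return out

    def surface(self, multiplicities: np.ndarray | None = None) -> ObsExpSurface:
        mult = (np.ones(self.n_genes) if multiplicities is None
                else np.asarray(multiplicities, float))
        (t_cnt, t_opp), (n_cnt, n_opp) = self._cells(mult)
        t_rate = np.divide(t_cnt, t_opp, out=np.zeros_like(t_cnt), where=t_opp > 0)
        n_rate = np.divide(n_cnt, n_opp, out=np.zeros_like(n_cnt), where=n_opp > 0)
        mask = (t_opp > 0) & (n_opp > 0) & (n_cnt > 0)
        values = np.divide(t_rate, n_rate, out=np.zeros_like(t_rate), where=mask)
        return ObsExpSurface(values=values, mask=mask, grid=self.grid,
                             meta={"kind": "pipeline"})

    def resample(self, rng: np.random.Generator) -> ObsExpSurface:
        mult = np.bincount(rng.integers(0, self.n_genes, size=self.n_genes),
                           minlength=self.n_genes)
        return self.surface(mult)


def obs_exp_surface(
    mutations: pd.DataFrame,
    genes: pd.DataFrame,
    phases: pd.DataFrame,
    genome,
    grid: PositionGrid | None = None,
    window: int = WINDOW_BP,
    rate_table: np.ndarray | None = None,
    per_tumor_contexts: bool = False,
    rate_regions: str = "intergenic",
    lambda_at: str = "window_start",
) -> StratifiedObsExp:
    """Build the stratified observed:expected surface from phased mutations.

    For every (tumor, gene, 5 kb window) the genic position is normalized to
    expected upstream lesions using the tumor's per-context rates (or a
    fixed ``rate_table`` 64-vector in lesion-strand frame, useful for
    controlled synthetic comparisons), then template and nontemplate
    composition-weighted mutation rates are accumulated per (stratum,
    lambda-bin) cell.  Cells without nontemplate signal are masked, never
    zero-filled.  ``lambda_at`` evaluates lambda at the window start
    (default) or midpoint.
    """
    grid = grid or PositionGrid()
    if lambda_at not in ("window_start", "window_mid"):
        raise ValueError("lambda_at must be 'window_start' or 'window_mid'")
    gc = genome if isinstance(genome, GenomeCodes) else GenomeCodes(genome)
    mutations = mutations.reset_index(drop=True)
    genes = genes.reset_index(drop=True)
    if "stratum" not in genes.columns:
        raise ValueError("genes must carry a 'stratum' column (see prepare_genes)")
    weights = genome_composition(gc)
    per_gene_ctx = _gene_window_contexts(gc, genes, window)
    gene_idx_mut, widx_mut = _assign_windows(mutations, genes, window)

    if rate_table is not None:
        tumor_rates = None
    else:
        tumor_rates = _tumor_context_rates(
            mutations, phases, genes, gc, per_tumor_contexts, rate_regions
        )

    phase_lookup = {
        (r.tumor_id, r.chrom): r.lesion_strand
        for r in phases.itertuples()
    }
    mut_ctx_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    rows_gene, rows_cell, rows_tmpl, rows_wc, rows_wo = [], [], [], [], []
    excl = {"input": len(mutations), "unphased_segment": 0, "outside_genes": 0,
            "beyond_grid": 0}

    tumor_ids = sorted(mutations["tumor_id"].unique())
    chrom_of_gene = genes["chrom"].to_numpy()
    strand_of_gene = genes["strand"].to_numpy()
    stratum_of_gene = genes["stratum"].to_numpy()

    mut_by_tumor = {t: np.flatnonzero((mutations["tumor_id"] == t).to_numpy())
                    for t in tumor_ids}
    for tumor_id in tumor_ids:
        r64 = rate_table if rate_table is not None else tumor_rates.get(tumor_id)
        if r64 is None:
            excl["unphased_segment"] += len(mut_by_tumor[tumor_id])
            continue
        mrows = mut_by_tumor[tumor_id]
        for g in range(len(genes)):
            chrom = chrom_of_gene[g]
            strand_lesion = phase_lookup.get((tumor_id, chrom))
            if strand_lesion not in (FORWARD, REVERSE):
                continue
            orient = template_status(strand_of_gene[g], strand_lesion)
            c64, u64 = per_gene_ctx[g]
            rvec = r64 if strand_lesion == FORWARD else r64[rc_context_perm]
            lam = u64 @ rvec
            if lambda_at == "window_mid":
                lam = lam + 0.5 * (c64 @ rvec)
            bins = np.floor(lam / grid.bin_width).astype(np.int64)
            ok_w = bins < grid.n_bins
            if not ok_w.any():
                continue
            ctx_counts = c64 if strand_lesion == FORWARD else c64[:, rc_context_perm]
            pl = 1 if str(chrom).lstrip("chr") == "X" else 2
            wopp = pl * (ctx_counts @ weights)
            stratum = stratum_of_gene[g] - 1
            cells = stratum * grid.n_bins + bins[ok_w]
            n_w = int(ok_w.sum())
            rows_gene.append(np.full(n_w, g))
            rows_cell.append(cells)
            rows_tmpl.append(np.full(n_w, orient == "template"))
            rows_wc.append(np.zeros(n_w))
            rows_wo.append(wopp[ok_w])
        # mutation contributions
        gsel = mrows[gene_idx_mut[mrows] >= 0]
        excl["outside_genes"] += int((gene_idx_mut[mrows] < 0).sum())
        if gsel.size == 0:
            continue
        gidx = gene_idx_mut[gsel]
        wdx = widx_mut[gsel]
        chroms = chrom_of_gene[gidx]
        for chrom in np.unique(chroms):
            strand_lesion = phase_lookup.get((tumor_id, chrom))
            csel = chroms == chrom
            if strand_lesion not in (FORWARD, REVERSE):
                excl["unphased_segment"] += int(csel.sum())
                continue
            rvec = r64 if strand_lesion == FORWARD else r64[rc_context_perm]
            sub = gsel[csel]
            gi = gidx[csel]
            wi = wdx[csel]
            if chrom not in mut_ctx_cache:
                pos_all = mutations["pos"].to_numpy()
                # contexts computed lazily per chromosome for all mutations
                rows_c = np.flatnonzero((mutations["chrom"] == chrom).to_numpy())
                ctx_all, _ = mutation_context_codes(gc, chrom, pos_all[rows_c])
                full = np.full(len(mutations), -1, dtype=np.int64)
                full[rows_c] = ctx_all
                mut_ctx_cache[chrom] = full
            ctx_plus = mut_ctx_cache[chrom][sub]
            ctx_lesion = ctx_plus if strand_lesion == FORWARD else rc_context_perm[ctx_plus]
            wcount = weights[ctx_lesion]
            # lambda of the mutation's window
            lam_vals = np.empty(sub.size)
            bins = np.empty(sub.size, dtype=np.int64)
            for g in np.unique(gi):
                c64, u64 = per_gene_ctx[g]
                lam_g = u64 @ rvec
                if lambda_at == "window_mid":
                    lam_g = lam_g + 0.5 * (c64 @ rvec)
                sel_g = gi == g
                lam_vals[sel_g] = lam_g[np.clip(wi[sel_g], 0, len(lam_g) - 1)]
            bins = np.floor(lam_vals / grid.bin_width).astype(np.int64)
            keep = bins < grid.n_bins
            excl["beyond_grid"] += int((~keep).sum())
            if not keep.any():
                continue
            gi, wi, bins, wcount = gi[keep], wi[keep], bins[keep], wcount[keep]
            orient = np.array(
                [template_status(strand_of_gene[g], strand_lesion) == "template"
                 for g in gi]
            )
            cells = (stratum_of_gene[gi] - 1) * grid.n_bins + bins
            rows_gene.append(gi)
            rows_cell.append(cells)
            rows_tmpl.append(orient)
            rows_wc.append(wcount)
            rows_wo.append(np.zeros(keep.sum()))

    gene_data = PipelineGeneData(
        n_genes=len(genes),
        gene_idx=np.concatenate(rows_gene) if rows_gene else np.zeros(0, dtype=int),
        cell_idx=np.concatenate(rows_cell).astype(int) if rows_cell else np.zeros(0, dtype=int),
        is_template=np.concatenate(rows_tmpl) if rows_tmpl else np.zeros(0, dtype=bool),
        wcount=np.concatenate(rows_wc) if rows_wc else np.zeros(0),
        wopp=np.concatenate(rows_wo) if rows_wo else np.zeros(0),
        grid=grid,
    )
    surf = gene_data.surface()
    (t_cnt, t_opp), (n_cnt, n_opp) = gene_data._cells(np.ones(len(genes)))
    t_rate = np.divide(t_cnt, t_opp, out=np.zeros_like(t_cnt), where=t_opp > 0)
    n_rate = np.divide(n_cnt, n_opp, out=np.zeros_like(n_cnt), where=n_opp > 0)
    return StratifiedObsExp(
        surface=surf,
        template_rate=t_rate,
        nontemplate_rate=n_rate,
        template_count=t_cnt,
        nontemplate_count=n_cnt,
        exclusions=excl,
        gene_data=gene_data,
    )


def genic_window_rates(
    mutations: pd.DataFrame,
    genes: pd.DataFrame,
    phases: pd.DataFrame,
    genome,
    window: int = WINDOW_BP,
    max_windows: int = 40,
) -> pd.DataFrame:
    """Aggregate mutation rates in consecutive 5 kb windows from the TSS.

    Windows advance in transcription direction (a reverse-strand gene's
    window 0 abuts its TSS at the highest genomic coordinate).  Rates are
    composition-weighted, reported separately for genes with template- and
    nontemplate-strand lesions, per expression stratum.
    """
    gc = genome if isinstance(genome, GenomeCodes) else GenomeCodes(genome)
    weights = genome_composition(gc)
    mutations = mutations.reset_index(drop=True)
    genes = genes.reset_index(drop=True)
    gene_idx_mut, widx_mut = _assign_windows(mutations, genes, window)
    phase_lookup = {(r.tumor_id, r.chrom): r.lesion_strand for r in phases.itertuples()}
    tumor_ids = sorted(mutations["tumor_id"].unique())
    n_s = int(genes["stratum"].max())
    shape = (n_s, max_windows, 2)
    counts = np.zeros(shape)
    opps = np.zeros(shape)
    per_gene_ctx = _gene_window_contexts(gc, genes, window)
    for tumor_id in tumor_ids:
        for g in range(len(genes)):
            chrom = genes.loc[g, "chrom"]
            lesion = phase_lookup.get((tumor_id, chrom))
            if lesion not in (FORWARD, REVERSE):
                continue
            orient = 0 if template_status(genes.loc[g, "strand"], lesion) == "template" else 1
            c64, _ = per_gene_ctx[g]
            ctx = c64 if lesion == FORWARD else c64[:, rc_context_perm]
            n_w = min(len(c64), max_windows)
            s = int(genes.loc[g, "stratum"]) - 1
            opps[s, :n_w, orient] += 2 * (ctx[:n_w] @ weights)
    msel = gene_idx_mut >= 0
    for row in np.flatnonzero(msel):
        tumor_id = mutations["tumor_id"].iloc[row]
        g = gene_idx_mut[row]
        chrom = genes.loc[g, "chrom"]
        lesion = phase_lookup.get((tumor_id, chrom))
        if lesion not in (FORWARD, REVERSE):
            continue
        w = widx_mut[row]
        if w >= max_windows:
            continue
        orient = 0 if template_status(genes.loc[g, "strand"], lesion) == "template" else 1
        ctx, _ = mutation_context_codes(gc, chrom, np.array([mutations["pos"].iloc[row]]))
        ctx_l = ctx[0] if lesion == FORWARD else rc_context_perm[ctx[0]]
        counts[int(genes.loc[g, "stratum"]) - 1, w, orient] += weights[ctx_l]
    rows = []
    for s in range(n_s):
        for w in range(max_windows):
            for o, name in ((0, "template"), (1, "nontemplate")):
                if opps[s, w, o] > 0:
                    rows.append({
                        "stratum": s + 1, "window": w, "orientation": name,
                        "rate": counts[s, w, o] / opps[s, w, o],
                        "weighted_count": counts[s, w, o],
                    })
    return pd.DataFrame(rows)


def expression_curve(
    mutations: pd.DataFrame,
    genes: pd.DataFrame,
    phases: pd.DataFrame,
    genome,
    low_cut: float = 0.01,
    high_cut: float = 100.0,
    n_mid_bins: int = 15,
) -> pd.DataFrame:
    """Observed:expected mutation ratio versus expression, per tumor.

    Genes below ``low_cut`` nTPM form one bin and genes above ``high_cut``
    another; the rest are split into ``n_mid_bins`` equal-count bins (17
    total by default).  Within each bin, template and nontemplate
    composition-weighted rates are computed per tumor and their ratio
    reported (NaN where the nontemplate rate is zero).
    """
    gc = genome if isinstance(genome, GenomeCodes) else GenomeCodes(genome)
    weights = genome_composition(gc)
    mutations = mutations.reset_index(drop=True)
    genes = genes.reset_index(drop=True)
    e = genes["ntpm"].to_numpy(float)
    bin_of = np.zeros(len(genes), dtype=np.int64)
    mid = (e >= low_cut) & (e <= high_cut)
    bin_of[e > high_cut] = n_mid_bins + 1
    if mid.any():
        order = np.argsort(e[mid], kind="stable")
        ranks = np.empty(mid.sum(), dtype=np.int64)
        ranks[order] = np.arange(mid.sum())
        bin_of[np.flatnonzero(mid)] = 1 + (ranks * n_mid_bins) // mid.sum()

    gene_idx_mut, _ = _assign_windows(mutations, genes, WINDOW_BP)
    phase_lookup = {(r.tumor_id, r.chrom): r.lesion_strand for r in phases.itertuples()}
    n_bins = n_mid_bins + 2

    # per-gene lesion-strand weighted opportunity for each orientation choice
    gene_ctx = []
    for _, g in genes.iterrows():
        gene_ctx.append(context_counts(gc.codes(g["chrom"]), int(g["start"]), int(g["end"])))
    gene_ctx = np.array(gene_ctx)

    rows = []
    for tumor_id, tdf in mutations.groupby("tumor_id", sort=True):
        cnt = np.zeros((n_bins, 2))
        opp = np.zeros((n_bins, 2))
        for g in range(len(genes)):
            chrom = genes.loc[g, "chrom"]
            lesion = phase_lookup.get((tumor_id, chrom))
            if lesion not in (FORWARD, REVERSE):
                continue
            orient = 0 if template_status(genes.loc[g, "strand"], lesion) == "template" else 1
            ctx = gene_ctx[g] if lesion == FORWARD else gene_ctx[g][rc_context_perm]
            opp[bin_of[g], orient] += 2 * float(ctx @ weights)
        midx = tdf.index.to_numpy()
        pos_rows = np.flatnonzero(np.isin(mutations.index.to_numpy(), midx))
        for row in pos_rows:
            g = gene_idx_mut[row]
            if g < 0:
                continue
            chrom = genes.loc[g, "chrom"]
            lesion = phase_lookup.get((tumor_id, chrom))
            if lesion not in (FORWARD, REVERSE):
                continue
            orient = 0 if template_status(genes.loc[g, "strand"], lesion) == "template" else 1
            ctx, _ = mutation_context_codes(gc, chrom, np.array([mutations["pos"].iloc[row]]))
            ctx_l = ctx[0] if lesion == FORWARD else rc_context_perm[ctx[0]]
            cnt[bin_of[g], orient] += weights[ctx_l]
        for b in range(n_bins):
            t_rate = cnt[b, 0] / opp[b, 0] if opp[b, 0] > 0 else np.nan
            n_rate = cnt[b, 1] / opp[b, 1] if opp[b, 1] > 0 else np.nan
            ratio = t_rate / n_rate if n_rate and np.isfinite(n_rate) and n_rate > 0 else np.nan
            rows.append({
                "tumor_id": tumor_id, "bin": b, "n_genes": int((bin_of == b).sum()),
                "template_rate": t_rate, "nontemplate_rate": n_rate, "obs_exp": ratio,
                "template_wcount": cnt[b, 0], "template_wopp": opp[b, 0],
                "nontemplate_wcount": cnt[b, 1], "nontemplate_wopp": opp[b, 1],
            })
    return pd.DataFrame(rows)
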