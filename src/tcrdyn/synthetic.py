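"""Fully synthetic tumor cohorts with known ground-truth TCR parameters.

The generator emulates the genomic features the analysis pipeline depends
on, with everything else deliberately simple:

* random chromosome sequences and non-overlapping genes on both strands,
  with nascent expression drawn so the expression strata match the
  configured proportions and (approximately) the configured medians;
* whole-chromosome lesion segregation: each tumor inherits lesions on one
  randomly chosen strand per chromosome;
* lesions placed at T nucleotides of the lesion strand (the principal
  mutagenic adduct of the targeted alkylation chemistry is an ethyl-T), at
  a per-T rate calibrated so the genome-wide per-base rate is ~13e-6;
* template-strand lesions of transcribed genes passed through the TCR pass
  semantics of :mod:`tcrdyn.simulate`; nontemplate and intergenic lesions
  skip repair;
* surviving lesions miscode into mutations with probability ``mu`` and a
  fixed T->C/T->A/T->G spectrum.

Each tumor is a perfect clone: no subclonality, replication timing or
selection is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import StrataConfig, TcrParams, initiation_mixture
from .phasing import FORWARD, REVERSE, template_status
from .pipeline import stratify_genes
from .rates import BASES, seq_to_codes

__all__ = [
    "SyntheticGenomeConfig",
    "SyntheticTumorConfig",
    "SyntheticGenome",
    "TumorTruth",
    "generate_genome",
    "generate_tumor",
    "generate_cohort",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    n_chroms: int = 4
    chrom_length: int = 5_000_000
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_genes: int = 130
    gene_length_median: float = 60_000.0
    gene_length_log_sd: float = 1.0
    min_gene_length: int = 2_000
    max_gene_length: int = 320_000   # ~4 expected lesions at 13e-6/bp
    strata: StrataConfig = field(default_factory=StrataConfig)
    max_gene_fill: float = 0.85   # genes may occupy at most this genome fraction

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        if self.n_chroms <= 0 or self.chrom_length <= 0 or self.n_genes <= 0:
            raise ValueError("n_chroms, chrom_length and n_genes must be positive")


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    genes: pd.DataFrame          # chrom, start, end, strand, gene_id, ntpm, stratum
    codes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.codes:
            self.codes = {c: seq_to_codes(s) for c, s in self.sequences.items()}
        self._t_cache: dict[tuple[str, str], np.ndarray] = {}

    def t_positions(self, chrom: str, lesion_strand: str) -> np.ndarray:
        """Positions whose lesion-strand base is T (cached per chromosome)."""
        key = (chrom, lesion_strand)
        if key not in self._t_cache:
            target = 3 if lesion_strand == FORWARD else 0  # T fwd, A plus = T rev
            self._t_cache[key] = np.flatnonzero(self.codes[chrom] == target)
        return self._t_cache[key]


# Sub-interval edges for intermediate expression whose uniform midpoints sit
# close to the observed stratum medians (0.49, 1.16, 2.07, 3.14 nTPM).
_MID_EDGES = (0.287, 0.693, 1.627, 2.513, 3.73)


def _draw_ntpm(strata: StrataConfig, labels: np.ndarray, rng: np.random.Generator):
    lo, hi = strata.boundaries
    e = np.zeros(labels.shape)
    s1 = labels == 1
    zero = rng.random(int(s1.sum())) < 0.55  # keeps the stratum-1 median at 0
    vals = np.where(zero, 0.0, rng.uniform(0.0, lo, int(s1.sum())))
    e[s1] = vals
    for s in (2, 3, 4, 5):
        sel = labels == s
        e[sel] = rng.uniform(_MID_EDGES[s - 2], _MID_EDGES[s - 1], int(sel.sum()))
    s6 = labels == 6
    med6 = strata.medians[5]
    e[s6] = hi + np.exp(rng.normal(np.log(med6 - hi), 0.9, int(s6.sum())))
    return e


def generate_genome(
    config: SyntheticGenomeConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> SyntheticGenome:
    """Random genome + gene annotation + expression with matched strata.

    Genes are placed without overlap, on random strands, with log-normal
    lengths; expression is drawn per assigned stratum and the final stratum
    labels are recomputed with :func:`tcrdyn.pipeline.stratify_genes` so the
    annotation round-trips exactly through the pipeline's stratification.
    """
    config = config or SyntheticGenomeConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    codes = {}
    sequences = {}
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    for i in range(config.n_chroms):
        c = rng.choice(4, size=config.chrom_length, p=np.asarray(config.base_probs))
        codes[f"chr{i + 1}"] = c.astype(np.uint8)
        sequences[f"chr{i + 1}"] = base_arr[c].tobytes().decode("ascii")

    lengths = np.exp(
        rng.normal(np.log(config.gene_length_median), config.gene_length_log_sd,
                   config.n_genes)
    ).astype(np.int64)
    lengths = np.clip(
        lengths, config.min_gene_length,
        min(config.max_gene_length, config.chrom_length // 4),
    )
    if lengths.sum() > config.max_gene_fill * config.n_chroms * config.chrom_length:
        raise ValueError(
            "configured genes do not fit in the genome: reduce n_genes or "
            "gene lengths, or enlarge chromosomes"
        )
    order = rng.permutation(config.n_genes)
    chrom_of = np.arange(config.n_genes) % config.n_chroms
    rows = []
    gid = 0
    for ci in range(config.n_chroms):
        sel = order[chrom_of == ci]
        lens = lengths[sel]
        free = config.chrom_length - int(lens.sum())
        if free < len(lens) + 1:
            raise ValueError("genes do not fit on a chromosome; adjust the config")
        gaps = rng.multinomial(free - len(lens) - 1, np.ones(len(lens) + 1) / (len(lens) + 1))
        pos = 0
        for k, L in enumerate(lens):
            pos += gaps[k] + 1
            rows.append({
                "chrom": f"chr{ci + 1}", "start": int(pos), "end": int(pos + L),
                "strand": "+" if rng.random() < 0.5 else "-",
                "gene_id": f"g{gid:05d}",
            })
            pos += int(L)
            gid += 1
    genes = pd.DataFrame(rows)
    labels0 = rng.choice(
        np.arange(1, config.strata.n_strata + 1),
        size=len(genes),
        p=np.asarray(config.strata.proportions),
    )
    genes["ntpm"] = _draw_ntpm(config.strata, labels0, rng)
    genes["stratum"] = stratify_genes(genes["ntpm"].to_numpy(),
                                      config.strata.boundaries)
    return SyntheticGenome(sequences=sequences, genes=genes, codes=codes)


#: Per-T lesion probability giving ~13e-6 lesions per bp at uniform base
#: composition (one in four bases is a T on any given strand).
DEFAULT_LESION_RATE_PER_T = 52e-6


@dataclass(frozen=True)
class SyntheticTumorConfig:
    params: TcrParams = field(default_factory=lambda: TcrParams(0.42, 0.66, 0.8, 1.59))
    lesion_rate_per_t: float = DEFAULT_LESION_RATE_PER_T
    miscoding_prob: float = 1.0
    spectrum: tuple[float, float, float] = (0.8, 0.1, 0.1)  # T->C, T->A, T->G
    n_tumors: int = 1
    segmentation: str = "chromosome"   # or "segmental"
    segment_length: int = 2_000_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.miscoding_prob <= 1.0:
            raise ValueError("miscoding_prob must lie in [0, 1]")
        if abs(sum(self.spectrum) - 1.0) > 1e-9:
            raise ValueError("spectrum must sum to 1")
        if self.segmentation not in ("chromosome", "segmental"):
            raise ValueError("segmentation must be 'chromosome' or 'segmental'")


@dataclass
class TumorTruth:
    params: TcrParams
    lesion_strand: dict          # (chrom, seg_start) -> strand
    n_lesions: int
    n_template_lesions: int
    n_surviving: int
    gene_lesions: pd.DataFrame   # gene_id, n_initial, n_surviving (template genes)


def _repair_gene_lesions(
    visible: np.ndarray, n_rnaps: int, pd_: float, pr_: float,
    rng: np.random.Generator
) -> np.ndarray:
    """Pass semantics on one gene's template lesions (transcription order).

    Invisible lesions never interact with RNAP and always survive.
    """
    alive_vis = visible.copy()
    for _ in range(n_rnaps):
        idx = np.flatnonzero(alive_vis)
        if idx.size == 0:
            break
        for i in idx:
            if rng.random() < pd_:
                alive_vis[i] = False
                if rng.random() >= pr_:
                    break
    out = np.ones(len(visible), dtype=bool)
    out[visible & ~alive_vis] = False
    return out


def generate_tumor(
    genome: SyntheticGenome,
    config: SyntheticTumorConfig | None = None,
    rng: np.random.Generator | int | None = None,
    tumor_id: str = "T0001",
):
    """One clonal tumor: mutation table, true segment phases, ground truth."""
    config = config or SyntheticTumorConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # separate stream for miscoding so the realized lesion/repair history is
    # invariant to the miscoding probability at a fixed seed
    rng_mis = rng.spawn(1)[0]
    params = config.params
    genes = genome.genes
    mut_rows = []
    phase_rows = []
    lesion_strand: dict = {}
    n_lesions = n_template = n_surv = 0
    gene_rows: dict[str, list[int]] = {}

    alt_bases_fwd = np.array(list("CAG"))  # T->C, T->A, T->G on the lesion strand
    alt_bases_rev = np.array([_COMP[b] for b in alt_bases_fwd])

    for chrom, codes in genome.codes.items():
        length = len(codes)
        if config.segmentation == "chromosome":
            segs = [(0, length)]
        else:
            edges = list(range(0, length, config.segment_length)) + [length]
            segs = list(zip(edges[:-1], edges[1:]))
        cgenes = genes[genes["chrom"] == chrom]
        for seg_start, seg_end in segs:
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            lesion_strand[(chrom, seg_start)] = strand
            phase_rows.append({"chrom": chrom, "start": seg_start, "end": seg_end,
                               "lesion_strand": strand})
            t_all = genome.t_positions(chrom, strand)
            t_pos = t_all[(t_all >= seg_start) & (t_all < seg_end)]
            n_hit = rng.binomial(t_pos.size, config.lesion_rate_per_t)
            sites = np.sort(t_pos[rng.choice(t_pos.size, size=n_hit, replace=False)])
            visible = rng.random(n_hit) < params.pv
            survived = np.ones(n_hit, dtype=bool)
            n_lesions += n_hit

            # TCR on template-orientation genes within this segment
            for _, g in cgenes.iterrows():
                if template_status(g["strand"], strand) != "template":
                    continue
                lo = max(int(g["start"]), seg_start)
                hi = min(int(g["end"]), seg_end)
                idx = np.flatnonzero((sites >= lo) & (sites < hi))
                n_template += idx.size
                if idx.size == 0:
                    continue
                if g["strand"] == "-":
                    idx = idx[::-1]  # transcription runs toward lower coordinates
                mx = initiation_mixture(params.m, float(g["ntpm"]))
                n_rnaps = mx.n_floor + int(rng.random() < (1.0 - mx.c))
                alive = _repair_gene_lesions(
                    visible[idx], n_rnaps, params.pd, params.pr, rng
                )
                survived[idx] = alive
                gene_rows.setdefault(g["gene_id"], [0, 0])
                gene_rows[g["gene_id"]][0] += idx.size
                gene_rows[g["gene_id"]][1] += int(alive.sum())

            surv_sites = sites[survived]
            n_surv += surv_sites.size
            miscode = rng_mis.random(surv_sites.size) < config.miscoding_prob
            ms = surv_sites[miscode]
            alt_idx = rng_mis.choice(3, size=ms.size, p=np.asarray(config.spectrum))
            if strand == FORWARD:
                refs = np.full(ms.size, "T")
                alts = alt_bases_fwd[alt_idx]
            else:
                refs = np.full(ms.size, "A")
                alts = alt_bases_rev[alt_idx]
            for p, rb, ab in zip(ms, refs, alts):
                mut_rows.append({"chrom": chrom, "pos": int(p), "ref": rb,
                                 "alt": ab, "tumor_id": tumor_id})

    mutations = pd.DataFrame(
        mut_rows, columns=["chrom", "pos", "ref", "alt", "tumor_id"]
    )
    phases = pd.DataFrame(phase_rows)
    phases["tumor_id"] = tumor_id
    gl = pd.DataFrame(
        [{"gene_id": k, "n_initial": v[0], "n_surviving": v[1]}
         for k, v in sorted(gene_rows.items())]
    )
    truth = TumorTruth(
        params=params, lesion_strand=lesion_strand, n_lesions=n_lesions,
        n_template_lesions=n_template, n_surviving=n_surv, gene_lesions=gl,
    )
    return mutations, phases, truth


def generate_cohort(
    genome: SyntheticGenome,
    config: SyntheticTumorConfig | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Independent tumors over a shared genome, with a reproducibility
    manifest recording all derived seeds and ground-truth summaries."""
    config = config or SyntheticTumorConfig()
    if isinstance(rng, np.random.Generator):
        root = rng.bit_generator.seed_seq
    else:
        root = np.random.SeedSequence(rng)
    children = root.spawn(config.n_tumors)
    all_muts, all_phases, truths = [], [], []
    manifest = {"n_tumors": config.n_tumors,
                "params": config.params.astuple(),
                "lesion_rate_per_t": config.lesion_rate_per_t,
                "miscoding_prob": config.miscoding_prob,
                "seed_entropy": str(root.entropy),
                "tumors": []}
    for i, child in enumerate(children):
        tid = f"T{i + 1:04d}"
        muts, phases, truth = generate_tumor(
            genome, config, np.random.default_rng(child), tumor_id=tid
        )
        all_muts.append(muts)
        all_phases.append(phases)
        truths.append(truth)
        manifest["tumors"].append({
            "tumor_id": tid,
            "n_lesions": truth.n_lesions,
            "n_template_lesions": truth.n_template_lesions,
            "n_surviving": truth.n_surviving,
            "n_mutations": len(muts),
            "lesion_strand": {f"{c}:{s}": st for (c, s), st in truth.lesion_strand.items()},
        })
    mutations = pd.concat(all_muts, ignore_index=True)
    phases = pd.concat(all_phases, ignore_index=True)
    return mutations, phases, truths, manifest
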