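"""Trinucleotide-context mutation rates on the lesion strand.

Rates are organized in the field's standard 192-category layout: 64
trinucleotide contexts (5' neighbor, mutated base, 3' neighbor) times 3
alternative bases, each rate being a mutation count divided by the count of
that context in the analyzed sequence (the "opportunity").  All counting is
performed with respect to the lesion-containing strand: for reverse-strand
lesions both the mutation calls and the sequence composition are
reverse-complemented.  Autosomes are treated as diploid and X as haploid
when tallying opportunities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "GenomeCodes",
    "TrinucRateTable",
    "context_index",
    "context_label",
    "rc_context_perm",
    "context_counts",
    "genome_composition",
    "trinuc_rates",
    "aggregate_rate",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G

_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _i in _CODE.items():
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def seq_to_codes(seq: str) -> np.ndarray:
    """Map a sequence string to codes A=0 C=1 G=2 T=3 (other = 4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class GenomeCodes:
    """Lazy per-chromosome code arrays over a genome.

    Accepts a dict of sequence strings, a dict of code arrays, or any mapping
    with string values (e.g. ``pyfaidx.Fasta`` records via ``str``).
    """

    def __init__(self, genome):
        self._genome = genome
        self._cache: dict[str, np.ndarray] = {}

    @property
    def chroms(self) -> list[str]:
        return list(self._genome.keys())

    def codes(self, chrom: str) -> np.ndarray:
        if chrom not in self._cache:
            seq = self._genome[chrom]
            if isinstance(seq, np.ndarray):
                self._cache[chrom] = seq.astype(np.uint8)
            else:
                self._cache[chrom] = seq_to_codes(str(seq))
        return self._cache[chrom]

    def length(self, chrom: str) -> int:
        return len(self.codes(chrom))


def context_index(up: int, mid: int, down: int) -> int:
    return 16 * up + 4 * mid + down


def context_label(idx: int) -> str:
    return BASES[idx // 16] + BASES[(idx // 4) % 4] + BASES[idx % 4]


def _build_rc_perm() -> np.ndarray:
    perm = np.empty(64, dtype=np.int64)
    for up in range(4):
        for mid in range(4):
            for down in range(4):
                perm[context_index(up, mid, down)] = context_index(
                    _COMPLEMENT[down], _COMPLEMENT[mid], _COMPLEMENT[up]
                )
    return perm


#: Permutation mapping each plus-strand context to its reverse complement.
rc_context_perm = _build_rc_perm()


def context_counts(codes: np.ndarray, start: int = 0, end: int | None = None) -> np.ndarray:
    """64-vector of trinucleotide counts for positions in ``[start, end)``.

    Each counted position uses its immediate neighbors as flanks, so
    positions at the very ends of the array (or next to non-ACGT bases) are
    skipped.
    """
    if end is None:
        end = len(codes)
    start = max(start, 1)
    end = min(end, len(codes) - 1)
    if end <= start:
        return np.zeros(64, dtype=np.int64)
    up = codes[start - 1:end - 1].astype(np.int64)
    mid = codes[start:end].astype(np.int64)
    down = codes[start + 1:end + 1].astype(np.int64)
    ok = (up < 4) & (mid < 4) & (down < 4)
    idx = 16 * up[ok] + 4 * mid[ok] + down[ok]
    return np.bincount(idx, minlength=64)


def genome_composition(genome) -> np.ndarray:
    """Genome-wide trinucleotide fractions (forward strand), the default
    weight vector for aggregate mutation rates."""
    gc = genome if isinstance(genome, GenomeCodes) else GenomeCodes(genome)
    total = np.zeros(64, dtype=np.int64)
    for chrom in gc.chroms:
        total += context_counts(gc.codes(chrom))
    if total.sum() == 0:
        raise ValueError("genome contains no countable trinucleotides")
    return total / total.sum()


@dataclass
class TrinucRateTable:
    counts192: np.ndarray                      # mutation counts, (64, 3)
    opportunities: np.ndarray                  # context counts x ploidy, (64,)
    rates192: np.ndarray = field(init=False)   # (64, 3)
    rates64: np.ndarray = field(init=False)    # per-context sums, (64,)

    def __post_init__(self) -> None:
        self.counts192 = np.asarray(self.counts192, dtype=float)
        self.opportunities = np.asarray(self.opportunities, dtype=float)
        bad = (self.counts192.sum(axis=1) > 0) & (self.opportunities == 0)
        if bad.any():
            labels = [context_label(i) for i in np.flatnonzero(bad)]
            raise ValueError(
                f"mutations observed in contexts with zero opportunity "
                f"(data/sequence mismatch): {labels}"
            )
        self.rates192 = np.zeros_like(self.counts192)
        ok = self.opportunities > 0
        self.rates192[ok] = self.counts192[ok] / self.opportunities[ok, None]
        self.rates64 = self.rates192.sum(axis=1)

    def aggregate(self, weights: np.ndarray) -> float:
        return aggregate_rate(self.rates64, weights)


def mutation_context_codes(
    gc: GenomeCodes, chrom: str, pos: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Plus-strand (context, center) codes at 0-based positions."""
    codes = gc.codes(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    if np.any(pos < 1) or np.any(pos >= len(codes) - 1):
        raise ValueError("mutation positions must have both flanks on the chromosome")
    up = codes[pos - 1].astype(np.int64)
    mid = codes[pos].astype(np.int64)
    down = codes[pos + 1].astype(np.int64)
    if np.any(up >= 4) or np.any(mid >= 4) or np.any(down >= 4):
        raise ValueError("ambiguous base in a mutation context")
    return 16 * up + 4 * mid + down, mid


def trinuc_rates(
    mutations: pd.DataFrame,
    regions,
    genome,
    ploidy: dict[str, int] | None = None,
) -> TrinucRateTable:
    """Lesion-strand 192-category mutation rates over a set of regions.

    ``regions`` is an iterable (or DataFrame) of
    ``(chrom, start, end, lesion_strand)`` with ``lesion_strand`` in
    ``{"forward", "reverse"}``; mutations outside the regions are ignored.
    For reverse-strand regions both mutation calls and sequence composition
    are reverse-complemented before tallying.  ``ploidy`` maps chromosome
    names to copy number (default: 2, or 1 for X/chrX).
    """
    from .phasing import FORWARD, REVERSE

    gc = genome if isinstance(genome, GenomeCodes) else GenomeCodes(genome)
    if isinstance(regions, pd.DataFrame):
        regions = list(
            regions[["chrom", "start", "end", "lesion_strand"]].itertuples(index=False)
        )
    ploidy = ploidy or {}

    def chrom_ploidy(chrom: str) -> int:
        if chrom in ploidy:
            return ploidy[chrom]
        return 1 if chrom.lstrip("chr") == "X" else 2

    counts = np.zeros((64, 3), dtype=float)
    opps = np.zeros(64, dtype=float)
    alt_codes = mutations["alt"].map(_CODE).to_numpy()
    for chrom, start, end, strand in regions:
        if strand not in (FORWARD, REVERSE):
            raise ValueError(f"lesion_strand must be forward/reverse, got {strand!r}")
        pl = chrom_ploidy(chrom)
        c64 = context_counts(gc.codes(chrom), int(start), int(end))
        if strand == REVERSE:
            c64 = c64[rc_context_perm]
        opps += pl * c64
        sel = (
            (mutations["chrom"] == chrom)
            & (mutations["pos"] >= start)
            & (mutations["pos"] < end)
        ).to_numpy()
        if not sel.any():
            continue
        pos = mutations.loc[sel, "pos"].to_numpy()
        ctx, mid = mutation_context_codes(gc, chrom, pos)
        alts = alt_codes[sel]
        if strand == REVERSE:
            ctx = rc_context_perm[ctx]
            alts = _COMPLEMENT[alts]
            mid = _COMPLEMENT[mid]
        ranks = alts - (alts > mid)
        np.add.at(counts, (ctx, ranks), 1.0)
    return TrinucRateTable(counts192=counts, opportunities=opps)


def aggregate_rate(rates64: np.ndarray, weights: np.ndarray) -> float:
    """Weighted mean of per-context rates; weights are the fraction of each
    trinucleotide in a reference sequence and must sum to 1."""
    rates64 = np.asarray(rates64, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if rates64.shape != weights.shape:
        raise ValueError("rates and weights lengths differ")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return float(np.dot(rates64, weights))
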