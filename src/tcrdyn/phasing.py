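"""Lesion-strand phasing from mutational strand asymmetry.

After a single mutagenic burst, semiconservative replication segregates the
two damaged parental strands into separate daughter lineages ("lesion
segregation"), so each tumor shows chromosome-scale runs of strand-asymmetric
mutations.  For alkylation damage the mutagenic adduct sits on T, so the
asymmetry score ``S = (F - R) / (F + R)`` — built from the rates of
mutations-from-T on the forward (``F``) and reverse (``R``) reference
strands — resolves which strand carries the lesions.  ``|S| > 0.33`` phases
a segment; combining the lesion strand with gene orientation then labels each
gene's lesions as template (subject to TCR) or nontemplate.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "FORWARD",
    "REVERSE",
    "UNPHASED",
    "asymmetry_score",
    "classify_segment",
    "template_status",
    "phase_segments",
]

FORWARD = "forward"
REVERSE = "reverse"
UNPHASED = "unphased"

#: Asymmetry threshold used to call a lesion strand.
S_THRESHOLD = 0.33


def asymmetry_score(f: float, r: float) -> float:
    """Relative-difference asymmetry ``S = (F - R) / (F + R)`` in [-1, 1].

    ``F`` and ``R`` are the rates (or counts, if opportunities are equal) of
    mutations from T on the forward and reverse strands.  Returns NaN (the
    unphased marker) when ``F + R == 0``.
    """
    if f < 0 or r < 0:
        raise ValueError("F and R must be non-negative")
    if f + r == 0:
        return math.nan
    return (f - r) / (f + r)


def classify_segment(s: float, threshold: float = S_THRESHOLD) -> str:
    """Call the lesion strand from an asymmetry score.

    ``S > threshold`` -> forward-strand lesions, ``S < -threshold`` ->
    reverse-strand lesions, otherwise (including NaN) unphased.
    """
    if math.isnan(s):
        return UNPHASED
    if not -1.0 <= s <= 1.0:
        raise ValueError(f"S must lie in [-1, 1], got {s}")
    if s > threshold:
        return FORWARD
    if s < -threshold:
        return REVERSE
    return UNPHASED


def template_status(gene_strand: str, lesion_strand: str) -> str:
    """Whether a gene's lesions sit on its transcription template strand.

    A plus-strand gene is transcribed using the reverse strand as template,
    so reverse-strand lesions in a plus-strand gene (RP orientation) are
    subject to TCR, as are forward-strand lesions in a minus-strand gene
    (FM).  FP and RM orientations place lesions on the nontemplate strand.
    Unphased lesion strands yield the exclusion marker ``"excluded"``.
    """
    if gene_strand not in ("+", "-"):
        raise ValueError(f"gene_strand must be '+' or '-', got {gene_strand!r}")
    if lesion_strand == UNPHASED:
        return "excluded"
    if lesion_strand not in (FORWARD, REVERSE):
        raise ValueError(f"bad lesion_strand {lesion_strand!r}")
    if (gene_strand == "+") == (lesion_strand == REVERSE):
        return "template"
    return "nontemplate"


def phase_segments(
    mutations: pd.DataFrame,
    segments: pd.DataFrame | None = None,
    genome=None,
    threshold: float = S_THRESHOLD,
) -> pd.DataFrame:
    """Score and classify the lesion strand per tumor per genomic segment.

    ``mutations`` needs columns (chrom, pos, ref, alt, tumor_id).  Segments
    default to whole chromosomes (the scale of lesion segregation); pass a
    (chrom, start, end) frame for finer segmentation.  When ``genome`` is
    given, F and R are per-base rates (counts divided by the segment's T/A
    base counts); otherwise raw counts are used, which is adequate for
    near-symmetric base composition.
    """
    from .rates import GenomeCodes

    muts = mutations
    if segments is None:
        if genome is not None:
            gc = GenomeCodes(genome)
            segments = pd.DataFrame(
                [(c, 0, gc.length(c)) for c in gc.chroms],
                columns=["chrom", "start", "end"],
            )
        else:
            segments = (
                muts.groupby("chrom")["pos"]
                .max()
                .reset_index()
                .rename(columns={"pos": "end"})
            )
            segments["end"] += 1
            segments["start"] = 0
            segments = segments[["chrom", "start", "end"]]
    rows = []
    gc = GenomeCodes(genome) if genome is not None else None
    for tumor_id, tdf in muts.groupby("tumor_id", sort=True):
        for _, seg in segments.iterrows():
            sel = tdf[
                (tdf["chrom"] == seg["chrom"])
                & (tdf["pos"] >= seg["start"])
                & (tdf["pos"] < seg["end"])
            ]
            n_f = int((sel["ref"] == "T").sum())
            n_r = int((sel["ref"] == "A").sum())
            if gc is not None:
                codes = gc.codes(seg["chrom"])[int(seg["start"]):int(seg["end"])]
                t_fwd = int((codes == 3).sum())
                t_rev = int((codes == 0).sum())
                f = n_f / t_fwd if t_fwd else 0.0
                r = n_r / t_rev if t_rev else 0.0
            else:
                f, r = float(n_f), float(n_r)
            s = asymmetry_score(f, r)
            rows.append(
                {
                    "tumor_id": tumor_id,
                    "chrom": seg["chrom"],
                    "start": int(seg["start"]),
                    "end": int(seg["end"]),
                    "n_forward": n_f,
                    "n_reverse": n_r,
                    "S": s,
                    "lesion_strand": classify_segment(s, threshold),
                }
            )
    return pd.DataFrame(rows)
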