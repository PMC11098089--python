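"""Core parameter containers for the transcription-coupled repair (TCR) model.

The model describes the fate of template-strand DNA lesions in the window
between a mutagenic burst and DNA replication.  Four free parameters govern
the dynamics:

``pd``
    Probability that an RNA polymerase II (RNAP) encountering a TCR-visible
    lesion detects it and triggers repair.
``pr``
    Probability that the RNAP resumes transcription from the repaired site
    rather than dissociating from the template.
``pv``
    Fraction of lesions that are visible to TCR at all.
``m``
    Expression multiplier: millions of genome-wide transcription initiations
    between damage and replication.  It links nascent expression ``e`` (nTPM)
    to the expected per-gene RNAP initiation count via ``n = m * e``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class TcrParams:
    """The four free parameters of the TCR model."""

    pd: float
    pr: float
    pv: float = 1.0
    m: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pd", "pr", "pv"):
            val = getattr(self, name)
            if not (isinstance(val, (int, float)) and math.isfinite(val)):
                raise ValueError(f"{name} must be a finite number, got {val!r}")
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if not (isinstance(self.m, (int, float)) and math.isfinite(self.m)):
            raise ValueError(f"m must be a finite number, got {self.m!r}")
        if self.m < 0:
            raise ValueError(f"m must be non-negative, got {self.m}")

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.pd, self.pr, self.pv, self.m)

    def replace(self, **kwargs) -> "TcrParams":
        d = {"pd": self.pd, "pr": self.pr, "pv": self.pv, "m": self.m}
        d.update(kwargs)
        return TcrParams(**d)


# Expression strata measured in the mouse-liver nascent RNA-seq data.
# Stratum 1: < 0.287 nTPM (no detectable repair signal); stratum 6: > 3.73
# nTPM (repair saturated); intermediate genes quantile-split into strata 2-5.
DEFAULT_STRATA_MEDIANS = (0.0, 0.49, 1.16, 2.07, 3.14, 11.15)
DEFAULT_STRATA_COUNTS = (4649, 1001, 1001, 1001, 1002, 7176)
DEFAULT_STRATA_BOUNDARIES = (0.287, 3.73)


@dataclass(frozen=True)
class StrataConfig:
    """Six expression strata: per-stratum median nTPM and gene proportions."""

    medians: tuple[float, ...] = DEFAULT_STRATA_MEDIANS
    proportions: tuple[float, ...] = field(
        default_factory=lambda: tuple(
            c / sum(DEFAULT_STRATA_COUNTS) for c in DEFAULT_STRATA_COUNTS
        )
    )
    boundaries: tuple[float, float] = DEFAULT_STRATA_BOUNDARIES

    def __post_init__(self) -> None:
        if len(self.medians) != len(self.proportions):
            raise ValueError("medians and proportions must have equal length")
        if any(b < a for a, b in zip(self.medians, self.medians[1:])):
            raise ValueError("strata medians must be non-decreasing")
        if any(p < 0 for p in self.proportions):
            raise ValueError("strata proportions must be non-negative")
        if abs(sum(self.proportions) - 1.0) > 1e-12:
            raise ValueError("strata proportions must sum to 1")
        if not self.boundaries[0] <= self.boundaries[1]:
            raise ValueError("strata boundaries must be ordered")

    @property
    def n_strata(self) -> int:
        return len(self.medians)


@dataclass(frozen=True)
class PositionGrid:
    """Genic position grid in units of expected upstream lesions (lambda).

    Bin ``t`` covers ``[t * bin_width, (t + 1) * bin_width)``.  The default 40
    bins of width 0.1 span lambda in [0, 4); few genes are long enough to
    accumulate more than 4 expected upstream lesions.
    """

    n_bins: int = 40
    bin_width: float = 0.1

    def __post_init__(self) -> None:
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def midpoints(self):
        import numpy as np

        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def right_edges(self):
        import numpy as np

        return (np.arange(self.n_bins) + 1.0) * self.bin_width

    @property
    def lam_max(self) -> float:
        return self.n_bins * self.bin_width


@dataclass(frozen=True)
class InitiationMixture:
    """Mean-preserving two-point mixture of RNAP initiation counts.

    A gene with expression ``e`` under multiplier ``m`` initiates on average
    ``m * e`` transcripts; a fraction ``c`` of genes get ``n_floor`` RNAPs and
    the rest ``n_floor + 1``, with ``c = 1 - (m*e - floor(m*e))``.
    """

    n_floor: int
    c: float

    def __post_init__(self) -> None:
        if self.n_floor < 0:
            raise ValueError("n_floor must be non-negative")
        if not 0.0 < self.c <= 1.0:
            raise ValueError("c must lie in (0, 1]")

    @property
    def mean(self) -> float:
        return self.c * self.n_floor + (1.0 - self.c) * (self.n_floor + 1)


def initiation_mixture(m: float, e: float) -> InitiationMixture:
    """Split the mean initiation count ``m * e`` into a floor/floor+1 mixture.

    Parameters
    ----------
    m : expression multiplier (millions of initiations), >= 0.
    e : nascent expression of the gene or stratum (nTPM), >= 0.
    """
    if m < 0 or e < 0:
        raise ValueError("m and e must be non-negative")
    me = m * e
    n_floor = int(math.floor(me))
    c = 1.0 - (me - n_floor)
    # me exactly integral: c == 1, all genes get n_floor RNAPs.
    return InitiationMixture(n_floor=n_floor, c=c)
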