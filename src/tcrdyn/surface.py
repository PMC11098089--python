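"""Observed:expected surfaces — the common currency between data, simulation
and theory — plus their TSV/JSON serializations.

A surface is a strata x position-bin matrix of template/nontemplate ratios
with a validity mask (cells without nontemplate opportunity are masked, never
zero-filled).  The TSV dialect has columns ``stratum`` (1-based),
``bin_index`` (0-based), ``lambda_mid`` and ``obs_exp`` (``NA`` when masked);
the JSON dialect stores the full matrices plus metadata.  Both round-trip
bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import PositionGrid


class SurfaceFormatError(ValueError):
    """Raised on a malformed surface file; carries the offending line."""


@dataclass
class ObsExpSurface:
    values: np.ndarray                 # (n_strata, n_bins) float
    mask: np.ndarray                   # (n_strata, n_bins) bool, True = valid
    grid: PositionGrid = field(default_factory=PositionGrid)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape[1] != self.grid.n_bins:
            raise ValueError(
                f"surface has {self.values.shape[1]} bins but grid expects "
                f"{self.grid.n_bins}"
            )

    @property
    def n_strata(self) -> int:
        return self.values.shape[0]

    def masked_values(self) -> np.ndarray:
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out

    def __eq__(self, other) -> bool:  # bit-exact on unmasked cells
        if not isinstance(other, ObsExpSurface):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and bool(np.array_equal(self.mask, other.mask))
            and bool(np.array_equal(self.values[self.mask], other.values[other.mask]))
        )


def _fmt(x: float) -> str:
    return repr(float(x))  # shortest round-trip decimal representation


def write_surface_tsv(surface: ObsExpSurface, path: str | Path) -> None:
    grid = surface.grid
    mids = grid.midpoints
    lines = ["stratum\tbin_index\tlambda_mid\tobs_exp"]
    for s in range(surface.n_strata):
        for t in range(grid.n_bins):
            val = _fmt(surface.values[s, t]) if surface.mask[s, t] else "NA"
            lines.append(f"{s + 1}\t{t}\t{_fmt(mids[t])}\t{val}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_surface_tsv(path: str | Path) -> ObsExpSurface:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["stratum", "bin_index", "lambda_mid", "obs_exp"]:
        raise SurfaceFormatError(f"{path}: line 1: bad or missing surface header")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise SurfaceFormatError(f"{path}: line {lineno}: expected 4 columns")
        try:
            s = int(parts[0])
            t = int(parts[1])
            v = np.nan if parts[3] == "NA" else float(parts[3])
        except ValueError as exc:
            raise SurfaceFormatError(f"{path}: line {lineno}: {exc}") from exc
        rows.append((s, t, float(parts[2]), v))
    if not rows:
        raise SurfaceFormatError(f"{path}: no data rows")
    n_strata = max(r[0] for r in rows)
    n_bins = max(r[1] for r in rows) + 1
    widths = sorted({r[2] for r in rows if r[1] == 0})
    bin_width = 2.0 * widths[0] if widths else 0.1
    values = np.full((n_strata, n_bins), np.nan)
    for s, t, _, v in rows:
        values[s - 1, t] = v
    mask = ~np.isnan(values)
    values[~mask] = 0.0
    return ObsExpSurface(
        values=values, mask=mask, grid=PositionGrid(n_bins=n_bins, bin_width=bin_width)
    )


def write_surface_json(surface: ObsExpSurface, path: str | Path) -> None:
    payload = {
        "grid": {"n_bins": surface.grid.n_bins, "bin_width": surface.grid.bin_width},
        "meta": surface.meta,
        "values": [
            [surface.values[s, t] if surface.mask[s, t] else None
             for t in range(surface.grid.n_bins)]
            for s in range(surface.n_strata)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_surface_json(path: str | Path) -> ObsExpSurface:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SurfaceFormatError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    vals = payload["values"]
    values = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in vals]
    )
    mask = ~np.isnan(values)
    values[~mask] = 0.0
    grid = PositionGrid(**payload.get("grid", {}))
    return ObsExpSurface(values=values, mask=mask, grid=grid, meta=payload.get("meta", {}))
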