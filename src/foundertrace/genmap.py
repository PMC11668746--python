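"""Genetic maps: physical->genetic interpolation and the Kosambi map function.

A :class:`GeneticMap` holds, per chromosome, an ordered knot table of
(physical bp, sex-averaged genetic position in Kosambi cM), the layout of a
Rutgers-style map table.  Physical positions are interpolated piecewise
linearly between knots; beyond the terminal knots the genetic position is
held constant (no recombination is fabricated outside map support) and a
warning is logged.

Coordinates are 1-based inclusive throughout this module; BED export
converts to 0-based half-open at the I/O boundary.  The genome build of the
map is the caller's responsibility — the declared build string is carried
through to outputs but never checked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticMap",
    "PhysicalInterval",
    "read_map",
    "write_map",
    "interpolate_cm",
    "genetic_length",
    "kosambi_rf",
    "kosambi_d",
]


@dataclass(frozen=True)
class PhysicalInterval:
    """A physical interval, 1-based inclusive on both ends."""

    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must not exceed end_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass
class GeneticMap:
    """Per-chromosome knot tables (bp strictly increasing, cM non-decreasing)."""

    knots: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    build: str = "unspecified"

    def add_chromosome(self, chromosome: str, bp, cm) -> None:
        bp = np.asarray(bp, dtype=np.int64)
        cm = np.asarray(cm, dtype=np.float64)
        if bp.shape != cm.shape or bp.ndim != 1 or bp.size == 0:
            raise ValueError("bp and cm must be equal-length non-empty 1-D arrays")
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"{chromosome}: physical positions not strictly increasing")
        bad = np.flatnonzero(np.diff(cm) < 0)
        if bad.size:
            rows = ", ".join(
                f"row {i + 1}->{i + 2} ({cm[i]:.6f} -> {cm[i + 1]:.6f} cM)"
                for i in bad[:5]
            )
            raise ValueError(f"{chromosome}: genetic positions decrease at {rows}")
        self.knots[chromosome] = (bp, cm)

    def chromosomes(self) -> list[str]:
        return list(self.knots)

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self.knots


#: column orders accepted by :func:`read_map`; all are whitespace/comma tables
_DIALECTS = {
    "chr_bp_cm": ("chromosome", "bp", "cm"),
    "bp_cm": ("bp", "cm"),
}


def read_map(path, dialect: str = "chr_bp_cm", *, sep: str | None = None,
             header: bool = True, build: str = "unspecified",
             chromosome: str = "chr1") -> GeneticMap:
    """Read a genetic-map knot table.

    ``dialect`` names the column order: ``chr_bp_cm`` (three columns) or
    ``bp_cm`` (two columns, single chromosome given by ``chromosome``).
    Duplicate physical positions are collapsed keeping the first row, with a
    logged warning; a decrease in cM is a hard error naming the rows.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    cols = _DIALECTS[dialect]
    df = pd.read_csv(path, sep=sep, engine="python",
                     header=0 if header else None, comment="#")
    if df.shape[1] < len(cols):
        raise ValueError(f"expected >= {len(cols)} columns for dialect {dialect!r}")
    df = df.iloc[:, : len(cols)]
    df.columns = list(cols)
    if "chromosome" not in df.columns:
        df["chromosome"] = chromosome

    gmap = GeneticMap(build=build)
    for chrom, sub in df.groupby("chromosome", sort=False):
        sub = sub.sort_values("bp", kind="stable")
        dup = sub["bp"].duplicated()
        if dup.any():
            logger.warning(
                "%s: %d duplicate physical positions collapsed (keeping first)",
                chrom, int(dup.sum()),
            )
            sub = sub[~dup]
        gmap.add_chromosome(str(chrom),
                            sub["bp"].to_numpy(np.int64),
                            sub["cm"].to_numpy(np.float64))
    return gmap


def write_map(gmap: GeneticMap, path) -> None:
    """Write a map as a three-column tab-separated table (chromosome, bp, cm)."""
    frames = [
        pd.DataFrame({"chromosome": chrom, "bp": bp, "cm": cm})
        for chrom, (bp, cm) in gmap.knots.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def interpolate_cm(gmap: GeneticMap, chromosome: str, bp) -> float | np.ndarray:
    """Genetic position (cM) of physical position(s) by linear interpolation.

    At a knot the knot's cM is returned exactly; outside the knot range the
    terminal cM value is used (constant extrapolation) with a warning.
    """
    if chromosome not in gmap.knots:
        raise KeyError(f"chromosome {chromosome!r} not in map "
                       f"(has {gmap.chromosomes()})")
    kbp, kcm = gmap.knots[chromosome]
    arr = np.asarray(bp, dtype=np.float64)
    if np.any(arr < kbp[0]) or np.any(arr > kbp[-1]):
        logger.warning(
            "%s: position(s) outside map support [%d, %d]; "
            "constant extrapolation at terminal cM", chromosome, kbp[0], kbp[-1],
        )
    out = np.interp(arr, kbp, kcm)
    return float(out) if np.isscalar(bp) or arr.ndim == 0 else out


def genetic_length(gmap: GeneticMap, interval: PhysicalInterval) -> float:
    """Genetic length (cM) of a physical interval: cm(end) - cm(start)."""
    return float(
        interpolate_cm(gmap, interval.chromosome, interval.end_bp)
        - interpolate_cm(gmap, interval.chromosome, interval.start_bp)
    )


def kosambi_rf(d_morgans) -> float | np.ndarray:
    """Kosambi map function: recombination fraction r = tanh(2d) / 2 for d >= 0."""
    d = np.asarray(d_morgans, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * d)
    return float(r) if np.isscalar(d_morgans) else r


def kosambi_d(r) -> float | np.ndarray:
    """Inverse Kosambi function: d = ln((1 + 2r) / (1 - 2r)) / 4 for 0 <= r < 0.5."""
    rr = np.asarray(r, dtype=np.float64)
    if np.any(rr < 0) or np.any(rr >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 0.25 * np.log((1.0 + 2.0 * rr) / (1.0 - 2.0 * rr))
    return float(d) if np.isscalar(r) else d


def interval_to_bed_line(interval: PhysicalInterval, name: str = ".") -> str:
    """One BED line for an interval (converts to 0-based half-open)."""
    return f"{interval.chromosome}\t{interval.start_bp - 1}\t{interval.end_bp}\t{name}"
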