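"""Run-of-homozygosity (ROH) detection from per-marker genotype calls.

A fully parameterised sliding-window caller in the style of exome/genome
autozygosity mappers: windows of a fixed number of markers tolerate a small
number of heterozygous and missing calls; passing windows seed candidate
regions, overlapping seeds merge, region ends are trimmed to homozygous
non-missing markers, and short or marker-poor regions are dropped.  Windows
are counted in markers, not base pairs, so the caller is robust to the
uneven marker density of exome data.  Missing calls never terminate a run
by themselves; only an excess of heterozygous calls does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .genmap import PhysicalInterval

logger = logging.getLogger(__name__)

__all__ = [
    "Call",
    "MarkerGenotypes",
    "AutozygousSegment",
    "RohParams",
    "detect_roh",
    "intersect_segments",
    "segment_length_mb",
]


class Call(IntEnum):
    """Genotype call codes for a biallelic marker."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = 3


@dataclass
class MarkerGenotypes:
    """Genotype calls of one sample along one chromosome."""

    chromosome: str
    positions: np.ndarray  # 1-based bp, strictly increasing
    calls: np.ndarray      # Call codes
    sample_id: str

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.positions.shape != self.calls.shape or self.positions.ndim != 1:
            raise ValueError("positions and calls must be equal-length 1-D arrays")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class AutozygousSegment:
    """One called ROH interval, 1-based inclusive, with marker support counts."""

    chromosome: str
    start_bp: int
    end_bp: int
    n_markers: int
    n_het_inside: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must not exceed end_bp")

    def as_interval(self) -> PhysicalInterval:
        return PhysicalInterval(self.chromosome, self.start_bp, self.end_bp)


@dataclass(frozen=True)
class RohParams:
    """Sliding-window ROH calling thresholds.

    Defaults give AutoMap-like behaviour at exome marker density; all are
    exposed because published pipelines rarely restate them.
    """

    window_markers: int = 25
    max_het_per_window: int = 1
    max_missing_per_window: int = 2
    min_length_bp: int = 1_000_000
    min_markers: int = 50

    def __post_init__(self) -> None:
        for name in ("window_markers", "min_length_bp", "min_markers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_het_per_window < 0 or self.max_missing_per_window < 0:
            raise ValueError("per-window tolerances must be non-negative")
        if self.max_het_per_window >= self.window_markers:
            raise ValueError("max_het_per_window must be below window_markers")


def _passing_window_mask(calls: np.ndarray, params: RohParams) -> np.ndarray:
    """Boolean mask over markers covered by at least one passing window."""
    n = calls.size
    w = params.window_markers
    het = (calls == Call.HET).astype(np.int32)
    mis = (calls == Call.MISSING).astype(np.int32)
    # rolling sums over each window [i, i+w)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    het_w = chet[w:] - chet[:-w]
    mis_w = cmis[w:] - cmis[:-w]
    passing = (het_w <= params.max_het_per_window) & (
        mis_w <= params.max_missing_per_window
    )
    covered = np.zeros(n + 1, dtype=np.int32)
    starts = np.flatnonzero(passing)
    np.add.at(covered, starts, 1)
    np.add.at(covered, starts + w, -1)
    return np.cumsum(covered[:-1]) > 0


def detect_roh(g: MarkerGenotypes, params: RohParams = RohParams()
               ) -> list[AutozygousSegment]:
    """Call runs of homozygosity in one sample.

    Returns segments sorted by start, non-overlapping, each trimmed so its
    first and last supporting markers are homozygous and non-missing.  With
    fewer markers than one window the result is empty (with a warning), not
    an error.
    """
    n = g.n_markers
    if n < params.window_markers:
        logger.warning(
            "%s/%s: %d markers < window of %d; no ROH called",
            g.sample_id, g.chromosome, n, params.window_markers,
        )
        return []
    covered = _passing_window_mask(g.calls, params)
    hom = (g.calls == Call.HOM_REF) | (g.calls == Call.HOM_ALT)

    segments: list[AutozygousSegment] = []
    i = 0
    while i < n:
        if not covered[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and covered[j + 1]:
            j += 1
        # trim ends to homozygous non-missing markers
        lo, hi = i, j
        while lo <= hi and not hom[lo]:
            lo += 1
        while hi >= lo and not hom[hi]:
            hi -= 1
        if lo <= hi:
            start = int(g.positions[lo])
            end = int(g.positions[hi])
            n_markers = hi - lo + 1
            if end - start + 1 >= params.min_length_bp and n_markers >= params.min_markers:
                segments.append(
                    AutozygousSegment(
                        chromosome=g.chromosome,
                        start_bp=start,
                        end_bp=end,
                        n_markers=n_markers,
                        n_het_inside=int(np.sum(g.calls[lo : hi + 1] == Call.HET)),
                        sample_id=g.sample_id,
                    )
                )
        i = j + 1
    return segments


def _contains(seg: AutozygousSegment, anchor: PhysicalInterval) -> bool:
    return (
        seg.chromosome == anchor.chromosome
        and seg.start_bp <= anchor.start_bp
        and seg.end_bp >= anchor.end_bp
    )


def intersect_segments(
    segments: list[AutozygousSegment],
    anchor: PhysicalInterval | int,
) -> PhysicalInterval:
    """Shared core interval of per-sample segments around an anchor locus.

    ``anchor`` may be a position (bp on the segments' chromosome) or an
    interval; every segment must contain it.  Returns
    [max of starts, min of ends].
    """
    if not segments:
        raise ValueError("need at least one segment")
    chrom = segments[0].chromosome
    if isinstance(anchor, int):
        anchor = PhysicalInterval(chrom, anchor, anchor)
    for seg in segments:
        if not _contains(seg, anchor):
            raise ValueError(
                f"segment of sample {seg.sample_id!r} "
                f"({seg.chromosome}:{seg.start_bp}-{seg.end_bp}) does not "
                f"contain the anchor {anchor.chromosome}:{anchor.start_bp}"
                f"-{anchor.end_bp}"
            )
    return PhysicalInterval(
        chromosome=chrom,
        start_bp=max(s.start_bp for s in segments),
        end_bp=min(s.end_bp for s in segments),
    )


def segment_length_mb(segment: AutozygousSegment | PhysicalInterval) -> float:
    """Unrounded segment length in Mb: (end - start + 1) / 1e6."""
    return (segment.end_bp - segment.start_bp + 1) / 1e6


def display_mb(length_mb: float) -> float:
    """Display rounding for Mb lengths: 1 decimal, half away from zero."""
    import decimal

    return float(
        decimal.Decimal(repr(length_mb)).quantize(
            decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
        )
    )
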