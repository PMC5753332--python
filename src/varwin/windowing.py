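"""Mask-aware window placement and recombination-rate attachment.

Two schemes are supported:

* ``fully_accessible_10kb`` — non-overlapping windows of a nominal size
  tiled inside each accessible mask interval, anchored at the interval
  start; a window never overlaps a non-accessible base and remainders
  shorter than the window size are discarded.
* ``fixed_100kb`` — windows tiled along the whole chromosome regardless of
  accessibility; per-window accessible base counts are recorded and serve
  as the per-site denominator downstream (inaccessible positions are
  discarded from the statistics, not from the window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .io import AccessibilityMask, GeneticMap

__all__ = [
    "GenomicWindow",
    "place_accessible_windows",
    "place_fixed_windows",
    "window_recomb_rate",
]


@dataclass(frozen=True)
class GenomicWindow:
    chromosome: str
    start: int
    end: int
    accessible_bases: int
    scheme: str  # "fully_accessible_10kb" | "fixed_100kb"

    @property
    def length(self) -> int:
        return self.end - self.start


def place_accessible_windows(mask: AccessibilityMask, size: int = 10_000) -> list[GenomicWindow]:
    """Tile non-overlapping windows inside accessible intervals.

    Within each interval [a, b): windows [a, a+size), [a+size, a+2*size), ...
    while the window end is <= b; the remainder is discarded.  Windows never
    span two intervals, so none overlaps a non-accessible base.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    windows: list[GenomicWindow] = []
    for chrom in mask.intervals:
        for a, b in mask.chrom(chrom):
            start = int(a)
            while start + size <= b:
                windows.append(GenomicWindow(chrom, start, start + size, size,
                                             "fully_accessible_10kb"))
                start += size
    return windows


def place_fixed_windows(
    chromosome_sizes: Mapping[str, int],
    size: int = 100_000,
    mask: AccessibilityMask | None = None,
) -> list[GenomicWindow]:
    """Tile fixed windows along each chromosome from 0.

    The last partial window is retained with its true extent.  Accessible
    base counts come from mask intersection; a chromosome absent from the
    mask yields windows with zero accessible bases (statistics undefined).
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    windows: list[GenomicWindow] = []
    for chrom, length in chromosome_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive size")
        start = 0
        while start < length:
            end = min(start + size, length)
            acc = mask.accessible_bases(chrom, start, end) if mask is not None else end - start
            windows.append(GenomicWindow(chrom, start, end, acc, "fixed_100kb"))
            start = end
    return windows


def window_recomb_rate(gmap: GeneticMap, window: GenomicWindow) -> float:
    """Mean recombination rate over a window in cM/Mb.

    Cumulative cM at the window bounds is obtained by linear interpolation
    between flanking map points; positions outside the map range clamp to
    the terminal cM values (rate 0 beyond the map).
    """
    cm_span = float(gmap.cm_at(window.end)) - float(gmap.cm_at(window.start))
    mb = window.length / 1e6
    return cm_span / mb
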