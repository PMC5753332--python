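"""Linkage-disequilibrium summaries: r2, Kelly's ZnS, Rozas' ZA/ZZ, Wall's B/Q.

All statistics are computed on phased haplotypes of one population; sites
fixed within that population are excluded before pairing.  "Adjacent" means
consecutive in genomic position among the window's segregating sites and
never crosses a window boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io import HaplotypePanel
from .windowing import GenomicWindow

__all__ = [
    "LDStats",
    "pairwise_r2",
    "kelly_zns",
    "rozas_za_zz",
    "wall_b_q",
    "ld_stats",
]


@dataclass
class LDStats:
    zns: float | None
    za: float | None
    zz: float | None
    wall_b: float | None
    wall_q: float | None
    n_pairs_used: int


def _segregating_columns(panel: HaplotypePanel, window: GenomicWindow) -> np.ndarray:
    sl = panel.site_range(window.start, window.end)
    cols = panel.haplotypes[:, sl]
    counts = cols.sum(axis=0)
    keep = (counts > 0) & (counts < panel.n_haplotypes)
    if panel.three_state is not None:
        keep &= ~panel.three_state[sl]
    return cols[:, keep]


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    p1 = x.mean()
    p2 = y.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("monomorphic site passed to r2; pre-filter segregating sites")
    f11 = float((x & y).sum()) / n
    d = f11 - p1 * p2
    return d * d / (p1 * (1 - p1) * p2 * (1 - p2))


def pairwise_r2(panel: HaplotypePanel, site_i: int, site_j: int) -> float:
    """r^2 between two site columns (indices into panel.positions)."""
    return _r2(panel.haplotypes[:, site_i].astype(bool),
               panel.haplotypes[:, site_j].astype(bool))


def kelly_zns(panel: HaplotypePanel, window: GenomicWindow) -> float | None:
    """Mean r^2 over all C(S,2) pairs of segregating sites; None if S < 2."""
    cols = _segregating_columns(panel, window).astype(bool)
    S = cols.shape[1]
    if S < 2:
        return None
    vals = [_r2(cols[:, i], cols[:, j]) for i, j in combinations(range(S), 2)]
    return float(np.mean(vals))


def rozas_za_zz(panel: HaplotypePanel, window: GenomicWindow):
    """ZA = mean r^2 over the S-1 adjacent pairs; ZZ = ZA - ZnS."""
    cols = _segregating_columns(panel, window).astype(bool)
    S = cols.shape[1]
    if S < 2:
        return None, None
    za = float(np.mean([_r2(cols[:, i], cols[:, i + 1]) for i in range(S - 1)]))
    zns = kelly_zns(panel, window)
    return za, za - zns


def _partition_key(col: np.ndarray) -> tuple:
    """Canonical bipartition induced by a binary column (label-flip invariant)."""
    bits = tuple(col.astype(int))
    if bits and bits[0] == 1:
        bits = tuple(1 - b for b in bits)
    return bits


def wall_b_q(panel: HaplotypePanel, window: GenomicWindow):
    """Wall's B and Q from congruent adjacent segregating-site pairs.

    A pair is congruent when its two columns jointly show only two distinct
    two-site haplotypes (same or complementary bipartition of the sample).
    B = B'/(S-1); Q = (B' + A)/S with A the number of distinct bipartitions
    among congruent pairs.
    """
    cols = _segregating_columns(panel, window)
    S = cols.shape[1]
    if S < 2:
        return None, (None if S < 1 else 0.0)
    b_prime = 0
    partitions: set[tuple] = set()
    for i in range(S - 1):
        pair = cols[:, i] * 2 + cols[:, i + 1]
        if len(np.unique(pair)) <= 2:
            b_prime += 1
            partitions.add(_partition_key(cols[:, i]))
    b = b_prime / (S - 1)
    q = (b_prime + len(partitions)) / S
    return b, q


def ld_stats(panel: HaplotypePanel, window: GenomicWindow) -> LDStats:
    """All LD summaries for one window of one population's panel."""
    cols = _segregating_columns(panel, window)
    S = cols.shape[1]
    zns = kelly_zns(panel, window)
    za, zz = rozas_za_zz(panel, window)
    b, q = wall_b_q(panel, window)
    n_pairs = S * (S - 1) // 2 if S >= 2 else 0
    return LDStats(zns=zns, za=za, zz=zz, wall_b=b, wall_q=q, n_pairs_used=n_pairs)
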