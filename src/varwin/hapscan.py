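"""Haplotype-based selection scans: EHH, iHS and XP-EHH.

EHH at distance x from a core allele is the probability that two randomly
drawn haplotypes carrying that allele are identical over the interval
between the core and x.  iHS is the log-ratio of the EHH integrals (iHH)
for the ancestral vs derived allele, standardized within derived-allele-
frequency bins; XP-EHH compares total-sample iHH between two populations
at the same core, standardized in a single bin.

Filters follow the scan conventions used here throughout: biallelic SNPs
with minor allele frequency above 0.05, an EHH cutoff of 0.05, and a
maximum gap of 20 kb between consecutive informative SNPs — a larger gap
truncates the integration and flags the site, excluding it from
standardization.  Integration is over physical distance (bp) by default;
pass a genetic map to integrate over cM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import GeneticMap, HaplotypePanel
from .windowing import GenomicWindow

__all__ = [
    "SiteScore",
    "HapScanScores",
    "WindowScoreSummary",
    "ehh_curve",
    "integrated_ehh",
    "ihs_scan",
    "ihs_at_site",
    "xpehh_scan",
    "summarize_window_scores",
]

EHH_CUTOFF = 0.05
MAX_GAP = 20_000
MAF_MIN = 0.05


@dataclass
class SiteScore:
    position: int
    freq: float                      # derived (iHS) or pooled-derived (XP-EHH) frequency
    unstandardized: float | None
    standardized: float | None
    qc_flag: str                     # "passed" | "truncated" | "skipped"


@dataclass
class HapScanScores:
    statistic: str                   # "iHS" | "XP_EHH"
    records: list[SiteScore] = field(default_factory=list)

    def passed(self) -> list[SiteScore]:
        return [r for r in self.records if r.qc_flag == "passed" and r.standardized is not None]

    def write_tsv(self, path) -> None:
        lines = ["position\tfreq\tunstandardized\tstandardized\tqc_flag"]
        for r in self.records:
            u = "." if r.unstandardized is None else f"{r.unstandardized:.6g}"
            s = "." if r.standardized is None else f"{r.standardized:.6g}"
            lines.append(f"{r.position}\t{r.freq:.6g}\t{u}\t{s}\t{r.qc_flag}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class WindowScoreSummary:
    window: GenomicWindow
    mean_abs_score: float | None
    n_snps: int


# ---------------------------------------------------------------------------
# EHH machinery
# ---------------------------------------------------------------------------

def _derived_matrix(panel: HaplotypePanel) -> np.ndarray:
    """0/1 matrix recoded so 1 = derived allele (unpolarized sites unchanged)."""
    m = panel.haplotypes.copy()
    flip = panel.ancestral_state == "alt"
    m[:, flip] = 1 - m[:, flip]
    return m


def ehh_curve(
    panel: HaplotypePanel,
    core_site: int,
    allele: str | None,
    direction: str,
) -> list[tuple[int, float]]:
    """EHH values at successive informative sites outward from the core.

    *allele* selects the carrier set: "derived", "ancestral", or None for
    the whole sample (the total EHH used by XP-EHH).  *direction* is
    "left" or "right".  The first point is (core position, 1.0); the curve
    is non-increasing.  Fewer than two carriers -> ValueError.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    m = _derived_matrix(panel)
    core_col = m[:, core_site]
    if allele is None:
        rows = np.arange(panel.n_haplotypes)
    elif allele == "derived":
        rows = np.flatnonzero(core_col == 1)
    elif allele == "ancestral":
        rows = np.flatnonzero(core_col == 0)
    else:
        raise ValueError("allele must be 'derived', 'ancestral' or None")
    k = len(rows)
    if k < 2:
        raise ValueError("fewer than 2 carriers at the core")

    step = 1 if direction == "right" else -1
    idx = core_site + step
    ids = np.zeros(k, dtype=np.int64)
    curve = [(int(panel.positions[core_site]), 1.0)]
    denom = k * (k - 1) / 2.0
    n_sites = panel.n_sites
    while 0 <= idx < n_sites:
        ids = ids * 2 + m[rows, idx]
        _, counts = np.unique(ids, return_counts=True)
        ids = np.unique(ids, return_inverse=True)[1]  # keep ids small
        ehh = float((counts * (counts - 1) / 2.0).sum() / denom)
        curve.append((int(panel.positions[idx]), ehh))
        if ehh == 0.0:
            break
        idx += step
    return curve


def integrated_ehh(
    curve: list[tuple[int, float]],
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP,
    gmap: GeneticMap | None = None,
) -> tuple[float, str]:
    """Trapezoidal integral of an EHH curve until it drops below *cutoff*.

    Returns (iHH, flag).  The trapezoid ending at the first sub-cutoff
    point is included.  A gap larger than *max_gap* between consecutive
    informative SNPs, or a curve that never reaches the cutoff before the
    data edge, flags the result "truncated".  With a genetic map the
    x-axis is cM (iHH in cM units); otherwise physical bp.
    """
    if not curve:
        return 0.0, "truncated"
    if curve[0][1] < cutoff:
        return 0.0, "passed"
    total = 0.0
    for (p0, e0), (p1, e1) in zip(curve, curve[1:]):
        if abs(p1 - p0) > max_gap:
            return total, "truncated"
        if gmap is not None:
            dx = abs(float(gmap.cm_at(p1)) - float(gmap.cm_at(p0)))
        else:
            dx = abs(p1 - p0)
        total += 0.5 * (e0 + e1) * dx
        if e1 < cutoff:
            return total, "passed"
    return total, "truncated"


def _ihh_both_sides(panel, core, allele, cutoff, max_gap, gmap):
    total, flag = 0.0, "passed"
    for direction in ("left", "right"):
        curve = ehh_curve(panel, core, allele, direction)
        ihh, f = integrated_ehh(curve, cutoff=cutoff, max_gap=max_gap, gmap=gmap)
        total += ihh
        if f == "truncated":
            flag = "truncated"
    return total, flag


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def _standardize(records, bin_of):
    """Z-score unstandardized scores within bins; returns nothing (in-place)."""
    groups: dict[int, list[SiteScore]] = {}
    for r in records:
        if r.qc_flag == "passed" and r.unstandardized is not None:
            groups.setdefault(bin_of(r), []).append(r)
    for rs in groups.values():
        vals = np.array([r.unstandardized for r in rs])
        sd = vals.std()
        if sd == 0 or len(vals) < 2:
            for r in rs:
                r.qc_flag = "skipped"
            continue
        mean = vals.mean()
        for r in rs:
            r.standardized = float((r.unstandardized - mean) / sd)


def _merged_bins(freqs: np.ndarray, width: float, min_count: int) -> np.ndarray:
    """Assign frequency bins of the given width, merging bins with fewer
    than *min_count* members into their neighbors."""
    edges = np.arange(0.0, 1.0 + width / 2, width)
    idx = np.clip(np.digitize(freqs, edges) - 1, 0, len(edges) - 2)
    labels = sorted(set(idx.tolist()))
    counts = {b: int((idx == b).sum()) for b in labels}
    merge_into = {b: b for b in labels}
    while len(labels) > 1:
        small = [b for b in labels if counts[b] < min_count]
        if not small:
            break
        b = small[0]
        pos = labels.index(b)
        nbr = labels[pos - 1] if pos > 0 else labels[pos + 1]
        counts[nbr] += counts.pop(b)
        labels.remove(b)
        for k, v in merge_into.items():
            if v == b:
                merge_into[k] = nbr
    return np.array([merge_into[b] for b in idx])


def ihs_at_site(
    panel: HaplotypePanel,
    position: int,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP,
    gmap: GeneticMap | None = None,
) -> SiteScore:
    """Unstandardized iHS at one core position (no genome-wide scan).

    Useful for targeted checks at a known core, e.g. a simulated sweep.
    """
    j = int(np.searchsorted(panel.positions, position))
    if j >= panel.n_sites or panel.positions[j] != position:
        raise ValueError(f"no site at position {position}")
    n = panel.n_haplotypes
    derived = panel.derived_counts()[j]
    daf = derived / n if derived >= 0 else float("nan")
    if derived < 2 or n - derived < 2:
        return SiteScore(position, daf, None, None, "skipped")
    ihh_d, f_d = _ihh_both_sides(panel, j, "derived", cutoff, max_gap, gmap)
    ihh_a, f_a = _ihh_both_sides(panel, j, "ancestral", cutoff, max_gap, gmap)
    if ihh_d == 0.0 or ihh_a == 0.0:
        return SiteScore(position, daf, None, None, "skipped")
    flag = "truncated" if "truncated" in (f_d, f_a) else "passed"
    return SiteScore(position, daf, math.log(ihh_a / ihh_d), None, flag)


def ihs_scan(
    panel: HaplotypePanel,
    region: tuple[int, int] | None = None,
    maf_min: float = MAF_MIN,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP,
    bin_width: float = 0.02,
    min_bin: int = 20,
    gmap: GeneticMap | None = None,
) -> HapScanScores:
    """iHS scan: per-site ln(iHH_ancestral / iHH_derived), standardized
    within derived-allele-frequency bins.

    Sites failing the MAF filter, lacking polarization, or with fewer than
    two carriers of either allele are skipped; gap/edge truncation flags a
    site out of standardization.
    """
    if region is not None:
        panel = panel.subset_region(*region)
    n = panel.n_haplotypes
    derived = panel.derived_counts()
    alt = panel.alt_counts()
    maf = np.minimum(alt, n - alt) / n

    scores = HapScanScores(statistic="iHS")
    for j in range(panel.n_sites):
        pos = int(panel.positions[j])
        if derived[j] < 0:
            continue  # unpolarized: not a candidate site
        daf = derived[j] / n
        if panel.three_state is not None and panel.three_state[j]:
            scores.records.append(SiteScore(pos, daf, None, None, "skipped"))
            continue
        if not maf[j] > maf_min:
            scores.records.append(SiteScore(pos, daf, None, None, "skipped"))
            continue
        if derived[j] < 2 or n - derived[j] < 2:
            scores.records.append(SiteScore(pos, daf, None, None, "skipped"))
            continue
        ihh_d, f_d = _ihh_both_sides(panel, j, "derived", cutoff, max_gap, gmap)
        ihh_a, f_a = _ihh_both_sides(panel, j, "ancestral", cutoff, max_gap, gmap)
        if ihh_d == 0.0 or ihh_a == 0.0:
            scores.records.append(SiteScore(pos, daf, None, None, "skipped"))
            continue
        unstd = math.log(ihh_a / ihh_d)
        flag = "truncated" if "truncated" in (f_d, f_a) else "passed"
        scores.records.append(SiteScore(pos, daf, unstd, None, flag))

    passed = [r for r in scores.records if r.qc_flag == "passed"]
    if passed:
        freqs = np.array([r.freq for r in passed])
        bins = _merged_bins(freqs, bin_width, min_bin)
        bin_map = {id(r): int(b) for r, b in zip(passed, bins)}
        _standardize(scores.records, lambda r: bin_map[id(r)])
    return scores


def xpehh_scan(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    region: tuple[int, int] | None = None,
    maf_min: float = MAF_MIN,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP,
    gmap: GeneticMap | None = None,
) -> HapScanScores:
    """XP-EHH scan between two populations sharing the same site set.

    Per site, ln(iHH_A / iHH_B) where each iHH integrates the population's
    total-sample EHH; the integration extent per direction is set where the
    pooled (A+B) EHH drops below the cutoff, so both populations are
    integrated over the same interval.  Standardized in a single bin.
    """
    if region is not None:
        panel_a = panel_a.subset_region(*region)
        panel_b = panel_b.subset_region(*region)
    if not np.array_equal(panel_a.positions, panel_b.positions):
        raise ValueError("panels must share the same site set")
    import dataclasses as _dc

    pooled = _dc.replace(
        panel_a,
        haplotypes=np.vstack([panel_a.haplotypes, panel_b.haplotypes]),
        sample_ids=panel_a.sample_ids + panel_b.sample_ids,
        population_of={**panel_a.population_of, **panel_b.population_of},
    )
    n_pool = pooled.n_haplotypes
    alt_pool = pooled.alt_counts()
    maf = np.minimum(alt_pool, n_pool - alt_pool) / n_pool
    derived = pooled.derived_counts()

    scores = HapScanScores(statistic="XP_EHH")
    for j in range(pooled.n_sites):
        pos = int(pooled.positions[j])
        freq = derived[j] / n_pool if derived[j] >= 0 else alt_pool[j] / n_pool
        if not maf[j] > maf_min:
            scores.records.append(SiteScore(pos, freq, None, None, "skipped"))
            continue
        ihh_a = ihh_b = 0.0
        flag = "passed"
        for direction in ("left", "right"):
            pooled_curve = ehh_curve(pooled, j, None, direction)
            stop_pos, f = _extent(pooled_curve, cutoff, max_gap)
            if f == "truncated":
                flag = "truncated"
            ca = _truncate_curve(ehh_curve(panel_a, j, None, direction), stop_pos)
            cb = _truncate_curve(ehh_curve(panel_b, j, None, direction), stop_pos)
            ihh_a += _integrate_full(ca, gmap)
            ihh_b += _integrate_full(cb, gmap)
        if ihh_a == 0.0 or ihh_b == 0.0:
            scores.records.append(SiteScore(pos, freq, None, None, "skipped"))
            continue
        scores.records.append(SiteScore(pos, freq, math.log(ihh_a / ihh_b), None, flag))

    _standardize(scores.records, lambda r: 0)
    return scores


def _extent(curve, cutoff, max_gap):
    """Outermost position of the pooled curve's integration extent."""
    if not curve:
        return None, "truncated"
    last = curve[0][0]
    for (p0, e0), (p1, e1) in zip(curve, curve[1:]):
        if abs(p1 - p0) > max_gap:
            return last, "truncated"
        last = p1
        if e1 < cutoff:
            return last, "passed"
    return last, "truncated"


def _truncate_curve(curve, stop_pos):
    if stop_pos is None:
        return curve[:1]
    core = curve[0][0]
    span = abs(stop_pos - core)
    return [(p, e) for p, e in curve if abs(p - core) <= span]


def _integrate_full(curve, gmap):
    total = 0.0
    for (p0, e0), (p1, e1) in zip(curve, curve[1:]):
        dx = (abs(float(gmap.cm_at(p1)) - float(gmap.cm_at(p0)))
              if gmap is not None else abs(p1 - p0))
        total += 0.5 * (e0 + e1) * dx
    return total


def summarize_window_scores(
    scores: HapScanScores, windows: list[GenomicWindow]
) -> list[WindowScoreSummary]:
    """Per-window mean of |standardized score| over passed SNPs."""
    passed = scores.passed()
    positions = np.array([r.position for r in passed], dtype=np.int64)
    values = np.array([abs(r.standardized) for r in passed])
    out = []
    for w in windows:
        inside = (positions >= w.start) & (positions < w.end)
        k = int(inside.sum())
        mean = float(values[inside].mean()) if k else None
        out.append(WindowScoreSummary(window=w, mean_abs_score=mean, n_snps=k))
    return out
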