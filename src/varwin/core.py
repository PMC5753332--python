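"""Frequency-based diversity, divergence and SFS neutrality tests.

Statistics are computed per window on a population-specific
:class:`~varwin.io.HaplotypePanel` (subset the panel first; an allele fixed
in one population is not segregating there).  Polarized statistics (Fu &
Li's D/F, Fay & Wu's H, Zeng's E) use the unfolded site frequency spectrum
xi_i = number of sites whose derived allele appears i times among the n
haplotypes; folded quantities (S, pi, theta_W, Tajima's D) use all
segregating sites regardless of polarization.

The per-site denominator L is the window's count of mask-accessible bases,
not its full length — inaccessible positions carry no information.
Undefined statistics are returned as ``None``, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io import AccessibilityMask, HaplotypePanel, OutgroupTrack
from .windowing import GenomicWindow

__all__ = [
    "SiteSpectrum",
    "SampleConstants",
    "DiversityStats",
    "sample_constants",
    "site_spectrum",
    "diversity_stats",
    "tajimas_d",
    "fu_li_tests",
    "fay_wu_h",
    "zeng_e",
    "jukes_cantor",
]


# ---------------------------------------------------------------------------
# spectra and constants
# ---------------------------------------------------------------------------

@dataclass
class SiteSpectrum:
    """Site frequency spectrum of one window.

    ``xi[i]`` counts polarized segregating sites with derived-allele count i
    (index 0 and n unused); ``all_counts`` holds the alternate-allele counts
    of every segregating site (polarized or not) for folded statistics.
    """

    n: int
    xi: np.ndarray           # length n+1; xi[1..n-1] meaningful
    all_counts: np.ndarray   # alt counts of all segregating sites
    L: int                   # accessible bases (denominator)

    @property
    def S(self) -> int:
        """All segregating sites (folded)."""
        return len(self.all_counts)

    @property
    def S_polarized(self) -> int:
        return int(self.xi.sum())

    @property
    def singletons(self) -> int:
        """Derived singletons xi_1."""
        return int(self.xi[1])

    def pi_total(self) -> float:
        """Mean pairwise differences, all segregating sites."""
        n = self.n
        c = self.all_counts
        return float((2.0 * c * (n - c) / (n * (n - 1))).sum())

    def pi_polarized(self) -> float:
        n = self.n
        i = np.arange(n + 1)
        return float((2.0 * i * (n - i) * self.xi / (n * (n - 1))).sum())

    def theta_l(self) -> float:
        """Zeng's theta_L = (1/(n-1)) * sum(i * xi_i)."""
        i = np.arange(self.n + 1)
        return float((i * self.xi).sum() / (self.n - 1))

    def theta_h(self) -> float:
        """Fay & Wu's theta_H = sum(2 i^2 xi_i) / (n(n-1))."""
        i = np.arange(self.n + 1)
        return float((2.0 * i * i * self.xi).sum() / (self.n * (self.n - 1)))


@dataclass(frozen=True)
class SampleConstants:
    """Sample-size-only constants of the SFS tests (n = haplotypes)."""

    n: int
    a1: float   # sum 1/i, i=1..n-1
    a2: float   # sum 1/i^2
    # Tajima (1989)
    e1: float
    e2: float
    # Fu & Li (1993), outgroup versions
    u_d: float
    v_d: float
    u_f: float
    v_f: float


@lru_cache(maxsize=None)
def sample_constants(n: int) -> SampleConstants:
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())

    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)

    cn = 1.0 if n == 2 else 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v_d = 1.0 + (a1**2 / (a2 + a1**2)) * (cn - (n + 1) / (n - 1))
    u_d = a1 - 1.0 - v_d
    v_f = (cn + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (a1**2 + a2)
    a1n1 = a1 + 1.0 / n  # sum 1/i up to n
    u_f = (1.0 + (n + 1) / (3.0 * (n - 1))
           - 4.0 * (n + 1) / (n - 1) ** 2 * (a1n1 - 2.0 * n / (n + 1))) / a1 - v_f

    return SampleConstants(n=n, a1=a1, a2=a2, e1=e1, e2=e2,
                           u_d=u_d, v_d=v_d, u_f=u_f, v_f=v_f)


def site_spectrum(panel: HaplotypePanel, window: GenomicWindow) -> SiteSpectrum:
    """Build the window's SFS from a population-specific panel.

    Three-state sites (outgroup matching neither allele) are excluded
    entirely.  Sites fixed within this panel (count 0 or n) are not
    segregating and do not enter the spectrum.
    """
    n = panel.n_haplotypes
    xi = np.zeros(n + 1, dtype=np.int64)
    if window.accessible_bases == 0:
        return SiteSpectrum(n=n, xi=xi, all_counts=np.empty(0, dtype=np.int64), L=0)
    sl = panel.site_range(window.start, window.end)
    alt = panel.haplotypes[:, sl].sum(axis=0).astype(np.int64)
    anc = panel.ancestral_state[sl]
    ok = np.ones(len(alt), dtype=bool)
    if panel.three_state is not None:
        ok &= ~panel.three_state[sl]
    seg = ok & (alt > 0) & (alt < n)

    derived = np.where(anc == "ref", alt, n - alt)
    pol = seg & np.isin(anc, ("ref", "alt"))
    np.add.at(xi, derived[pol], 1)
    return SiteSpectrum(n=n, xi=xi, all_counts=alt[seg], L=window.accessible_bases)


# ---------------------------------------------------------------------------
# diversity and divergence
# ---------------------------------------------------------------------------

@dataclass
class DiversityStats:
    S_per_site: float | None
    pi_per_site: float | None
    theta_w_per_site: float | None
    hap_diversity: float | None
    theta_l: float | None
    theta_h: float | None
    divsites: int | None
    K_jc: float | None


def jukes_cantor(p: float) -> float | None:
    """Substitutions per site from an observed difference fraction p."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def diversity_stats(
    panel: HaplotypePanel,
    window: GenomicWindow,
    outgroup: OutgroupTrack | None = None,
    mask: AccessibilityMask | None = None,
) -> DiversityStats:
    """Table-style diversity/divergence battery for one window.

    Divergent sites are positions where all sample alleles agree and differ
    from the aligned outgroup: divergence-only records plus fixed
    differences at segregating-record positions.  K applies the
    Jukes-Cantor correction with the accessible-and-aligned base count as
    denominator.  For the fixed-window scheme pass the mask so inaccessible
    positions are discarded from both counts and denominators.
    """
    L = window.accessible_bases
    if L == 0:
        return DiversityStats(*([None] * 8))
    spec = site_spectrum(panel, window)
    n = panel.n_haplotypes
    S = spec.S

    pi = spec.pi_total()
    const = sample_constants(n)

    # haplotype diversity over distinct haplotype strings in the window
    sl = panel.site_range(window.start, window.end)
    cols = panel.haplotypes[:, sl]
    if cols.shape[1]:
        _, counts = np.unique(cols, axis=0, return_counts=True)
    else:
        counts = np.array([n])
    freqs = counts / n
    hap_div = (n / (n - 1)) * (1.0 - float((freqs**2).sum()))

    divsites: int | None = None
    k_jc: float | None = None
    if outgroup is not None:
        divsites, l_aligned = _divergence_in_window(panel, window, outgroup, mask)
        if l_aligned > 0:
            k_jc = jukes_cantor(divsites / l_aligned)

    return DiversityStats(
        S_per_site=S / L,
        pi_per_site=pi / L,
        theta_w_per_site=S / (const.a1 * L),
        hap_diversity=hap_div,
        theta_l=spec.theta_l(),
        theta_h=spec.theta_h(),
        divsites=divsites,
        K_jc=k_jc,
    )


def _divergence_in_window(panel, window, outgroup, mask):
    start, end = window.start, window.end
    # accessible & aligned denominator
    lo = max(start, outgroup.offset)
    hi = min(end, outgroup.end)
    if lo >= hi:
        return 0, 0
    aligned = np.zeros(end - start, dtype=bool)
    aligned[lo - start : hi - start] = outgroup.aligned[lo - outgroup.offset : hi - outgroup.offset]
    if mask is not None:
        aligned &= mask.boolean_mask(window.chromosome, start, end)
    l_aligned = int(aligned.sum())

    count = 0
    # divergence-only records (monomorphic reference positions)
    if panel.divergence_only is not None:
        d = panel.divergence_only
        d = d[(d >= start) & (d < end)]
        if mask is not None and len(d):
            d = d[mask.is_accessible(window.chromosome, d)]
        count += len(d)
    # fixed differences at panel record positions
    sl = panel.site_range(start, end)
    if sl.stop > sl.start and panel.outgroup_allele is not None:
        alt = panel.haplotypes[:, sl].sum(axis=0)
        n = panel.n_haplotypes
        og = panel.outgroup_allele[sl]
        ref, altn = panel.ref[sl], panel.alt[sl]
        ok = og != ""
        if panel.three_state is not None:
            ok &= ~panel.three_state[sl]
        if mask is not None:
            ok &= mask.is_accessible(window.chromosome, panel.positions[sl])
        fixed_ref = ok & (alt == 0) & (og != ref)
        fixed_alt = ok & (alt == n) & (og != altn)
        count += int(fixed_ref.sum() + fixed_alt.sum())
    return count, l_aligned


# ---------------------------------------------------------------------------
# neutrality tests
# ---------------------------------------------------------------------------

def tajimas_d(spectrum: SiteSpectrum, constants: SampleConstants | None = None) -> float | None:
    """Tajima's D: (pi - S/a1) / sqrt(e1*S + e2*S*(S-1))."""
    c = constants or sample_constants(spectrum.n)
    S = spectrum.S
    if S == 0:
        return None
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var <= 0:
        return None
    return (spectrum.pi_total() - S / c.a1) / math.sqrt(var)


def fu_li_tests(spectrum: SiteSpectrum, constants: SampleConstants | None = None):
    """Fu & Li's D and F (outgroup versions, derived singletons xi_1)."""
    c = constants or sample_constants(spectrum.n)
    eta = spectrum.S_polarized
    if eta == 0:
        return None, None
    xi1 = spectrum.singletons
    var_d = c.u_d * eta + c.v_d * eta * eta
    var_f = c.u_f * eta + c.v_f * eta * eta
    d = (eta - c.a1 * xi1) / math.sqrt(var_d) if var_d > 0 else None
    f = (spectrum.pi_polarized() - xi1) / math.sqrt(var_f) if var_f > 0 else None
    return d, f


def fay_wu_h(spectrum: SiteSpectrum, normalized: bool = False) -> float | None:
    """Fay & Wu's H = pi - theta_H (unnormalized by default).

    The normalized variant divides by the variance of Zeng et al.'s
    formulation for H/sqrt(Var(pi - theta_L) * 2)-style scaling; here the
    normalized form standardizes pi - theta_L as in the cited framework.
    """
    if spectrum.S_polarized == 0:
        return None
    h = spectrum.pi_polarized() - spectrum.theta_h()
    if not normalized:
        return h
    # normalized H of Zeng et al.: (pi - theta_L) / sqrt(var)
    n = spectrum.n
    c = sample_constants(n)
    S = spectrum.S_polarized
    theta_w = S / c.a1
    theta_sq = S * (S - 1) / (c.a1**2 + c.a2)
    var = (theta_w * (n - 2) / (6.0 * (n - 1))
           + theta_sq * (18 * n * n * (3 * n + 2) * _bsub(n + 1)
                         - (88 * n**3 + 9 * n * n - 13 * n + 6))
           / (9.0 * n * (n - 1) ** 2))
    if var <= 0:
        return None
    return (spectrum.pi_polarized() - spectrum.theta_l()) / math.sqrt(var)


def _bsub(n: int) -> float:
    return float((1.0 / np.arange(1, n) ** 2).sum())


def zeng_e(spectrum: SiteSpectrum, constants: SampleConstants | None = None) -> float | None:
    """Zeng et al.'s E = (theta_L - theta_W) / sqrt(Var)."""
    c = constants or sample_constants(spectrum.n)
    S = spectrum.S_polarized
    if S == 0:
        return None
    n = spectrum.n
    theta_w = S / c.a1
    theta_sq = S * (S - 1) / (c.a1**2 + c.a2)
    var = (theta_w * (n / (2.0 * (n - 1)) - 1.0 / c.a1)
           + theta_sq * (c.a2 / c.a1**2
                         + 2.0 * (n / (n - 1.0)) ** 2 * c.a2
                         - 2.0 * (n * c.a2 - n + 1) / ((n - 1.0) * c.a1)
                         - (3.0 * n + 1) / (n - 1.0)))
    if var <= 0:
        return None
    return (spectrum.theta_l() - theta_w) / math.sqrt(var)
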