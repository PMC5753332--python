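"""Gene-based polymorphism/divergence machinery: site-class annotation,
DAF spectra, the standard McDonald-Kreitman test (alpha, NI, DoS) and the
integrative MKT with the MAF < 5% slightly-deleterious correction.

The MKT contrasts a putatively selected site class (0-fold coding, UTRs,
introns, intergenic flanks) against a neutral reference class (4-fold
synonymous sites).  The integrative extension partitions test-class
polymorphism at a minor-allele-frequency cutoff: the excess of low-MAF
test sites relative to the neutral class estimates the weakly deleterious
fraction b, the low-MAF-corrected neutral polymorphism yields a corrected
alpha, and the remainder d = 1 - b - f is the strongly deleterious
fraction.  gamma splits the neutral fraction f into recently neutral
(gamma) versus neutral since before the species split (f - gamma), using a
divergence-based neutral fraction anchored on the pi/K form of alpha —
a reconstruction of the cited framework, documented in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import jukes_cantor, sample_constants
from .io import AccessibilityMask, GeneModel, HaplotypePanel, OutgroupTrack

__all__ = [
    "SITE_CLASSES",
    "SiteClassMap",
    "ClassCounts",
    "MKTCounts",
    "MKTResult",
    "classify_coding_degeneracy",
    "build_site_class_map",
    "daf_spectrum",
    "mkt_counts",
    "standard_mkt",
    "integrative_mkt",
]

SITE_CLASSES = (
    "fourfold", "zerofold", "utr5", "utr3", "intron",
    "intergenic_flank", "other", "excluded",
)

# Standard genetic code (DNA codons). "*" = stop.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_coding_degeneracy(codon: str, position: int) -> str:
    """Degeneracy class of one codon position.

    "fourfold" if every substitution at the position is synonymous,
    "zerofold" if every substitution changes the encoded residue (a stop
    counts as a change), "other" for two/three-fold sites, "excluded" for
    codons with ambiguous bases.
    """
    codon = codon.upper()
    if position not in (0, 1, 2):
        raise ValueError("codon position must be 0, 1 or 2")
    if any(b not in _BASES for b in codon) or len(codon) != 3:
        return "excluded"
    aa = CODON_TABLE[codon]
    syn = 0
    for b in _BASES:
        if b == codon[position]:
            continue
        mutant = codon[:position] + b + codon[position + 1:]
        if CODON_TABLE[mutant] == aa:
            syn += 1
    if syn == 3:
        return "fourfold"
    if syn == 0:
        return "zerofold"
    return "other"


# ---------------------------------------------------------------------------
# site-class map
# ---------------------------------------------------------------------------

@dataclass
class SiteClassMap:
    """Per-position site classes over a gene's extent plus flanks."""

    gene_id: str
    chromosome: str
    start: int                 # 0-based start of the mapped region
    classes: np.ndarray        # (end-start,) small strings from SITE_CLASSES
    coding_withheld: bool = False   # internal stop: coding classes excluded

    @property
    def end(self) -> int:
        return self.start + len(self.classes)

    def positions_of(self, site_class: str) -> np.ndarray:
        rel = np.flatnonzero(self.classes == site_class)
        return rel + self.start

    def class_at(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(len(positions), "excluded", dtype="<U16")
        ok = (positions >= self.start) & (positions < self.end)
        out[ok] = self.classes[positions[ok] - self.start]
        return out


def build_site_class_map(
    gene: GeneModel,
    reference_sequence: str,
    other_genes: list[GeneModel] | None = None,
    ref_offset: int = 0,
) -> SiteClassMap:
    """Classify every position in the gene's span plus flanks.

    CDS positions are classified by codon degeneracy on the coding strand;
    exonic non-CDS positions become 5'/3' UTR by strand; intra-transcript
    non-exonic positions are introns; the +/- flank_size outside the
    transcript is intergenic flank except where it falls inside another
    gene's transcript (excluded).  An internal stop codon flags the gene
    and withholds the coding classes.
    """
    span_start, span_end = gene.span_with_flank
    if span_start < ref_offset or span_end > ref_offset + len(reference_sequence):
        raise ValueError("reference sequence does not cover the gene span plus flanks")
    classes = np.full(span_end - span_start, "excluded", dtype="<U16")

    def put(s, e, label):
        s, e = max(s, span_start), min(e, span_end)
        if s < e:
            classes[s - span_start : e - span_start] = label

    # flanks, then introns, then exonic layers (later layers overwrite)
    put(span_start, gene.tx_start, "intergenic_flank")
    put(gene.tx_end, span_end, "intergenic_flank")
    put(gene.tx_start, gene.tx_end, "intron")
    for s, e in gene.exons:
        put(s, e, "other")
    for s, e in gene.utr5:
        put(s, e, "utr5")
    for s, e in gene.utr3:
        put(s, e, "utr3")

    coding_withheld = False
    if gene.codable and gene.cds:
        cds_positions: list[int] = []
        for s, e in sorted(gene.cds):
            cds_positions.extend(range(s, e))
        seq = "".join(reference_sequence[p - ref_offset] for p in cds_positions).upper()
        if gene.strand == "-":
            seq = revcomp(seq)
            cds_positions = cds_positions[::-1]
        # internal stop check (final codon may legitimately be a stop)
        protein = [CODON_TABLE.get(seq[i:i + 3], "X") for i in range(0, len(seq) - 3, 3)]
        if "*" in protein:
            coding_withheld = True
        for i, pos in enumerate(cds_positions):
            if coding_withheld:
                label = "excluded"
            else:
                codon = seq[(i // 3) * 3 : (i // 3) * 3 + 3]
                label = classify_coding_degeneracy(codon, i % 3)
            put(pos, pos + 1, label)
    elif gene.cds:
        # non-codable model: CDS positions unusable for coding classes
        for s, e in gene.cds:
            put(s, e, "excluded")

    # neighbors' transcripts mask the flank
    for other in other_genes or []:
        if other.gene_id == gene.gene_id or other.chromosome != gene.chromosome:
            continue
        o_s, o_e = other.tx_start, other.tx_end
        for fs, fe in ((span_start, gene.tx_start), (gene.tx_end, span_end)):
            s, e = max(fs, o_s), min(fe, o_e)
            if s < e:
                put(s, e, "excluded")

    return SiteClassMap(
        gene_id=gene.gene_id,
        chromosome=gene.chromosome,
        start=span_start,
        classes=classes,
        coding_withheld=coding_withheld,
    )


# ---------------------------------------------------------------------------
# spectra and counts
# ---------------------------------------------------------------------------

def daf_spectrum(panel: HaplotypePanel, sites: np.ndarray, bins: int = 10) -> np.ndarray:
    """Normalized derived-allele-frequency histogram over the given positions.

    Only polarized segregating sites contribute; returns an all-zero array
    when none exist.
    """
    sites = np.asarray(sites, dtype=np.int64)
    idx = np.flatnonzero(np.isin(panel.positions, sites))
    n = panel.n_haplotypes
    derived = panel.derived_counts()[idx]
    seg = (derived > 0) & (derived < n)
    if panel.three_state is not None:
        seg &= ~panel.three_state[idx]
    freqs = derived[seg] / n
    hist, _ = np.histogram(freqs, bins=bins, range=(0.0, 1.0))
    total = hist.sum()
    return hist / total if total else hist.astype(float)


@dataclass
class ClassCounts:
    site_class: str
    m: int = 0           # analyzable (accessible, outgroup-aligned) sites
    P: int = 0           # segregating sites
    P_low: int = 0       # MAF < cutoff
    P_high: int = 0      # MAF >= cutoff
    D: int = 0           # fixed differences vs outgroup
    pi: float | None = None
    K: float | None = None


@dataclass
class MKTCounts:
    test: ClassCounts
    neutral: ClassCounts
    maf_cutoff: float = 0.05


def _class_counts(panel, outgroup, positions, site_class, maf_cutoff, mask, chromosome):
    positions = np.asarray(positions, dtype=np.int64)
    aligned = outgroup.aligned_at(positions)
    usable = positions[aligned]
    if mask is not None and len(usable):
        usable = usable[mask.is_accessible(chromosome, usable)]
    cc = ClassCounts(site_class=site_class, m=len(usable))
    if cc.m == 0:
        return cc

    usable_set = usable
    idx = np.flatnonzero(np.isin(panel.positions, usable_set))
    n = panel.n_haplotypes
    div = 0
    if len(idx):
        alt = panel.haplotypes[:, idx].sum(axis=0).astype(np.int64)
        ok = np.ones(len(idx), dtype=bool)
        if panel.three_state is not None:
            ok &= ~panel.three_state[idx]
        seg = ok & (alt > 0) & (alt < n)
        maf = np.minimum(alt, n - alt) / n
        cc.P = int(seg.sum())
        cc.P_low = int((seg & (maf < maf_cutoff)).sum())
        cc.P_high = cc.P - cc.P_low
        cc.pi = float((2.0 * alt[seg] * (n - alt[seg]) / (n * (n - 1))).sum()) / cc.m
        # fixed differences at panel record positions
        if panel.outgroup_allele is not None:
            og = panel.outgroup_allele[idx]
            fixed_ref = ok & (alt == 0) & (og != "") & (og != panel.ref[idx])
            fixed_alt = ok & (alt == n) & (og != "") & (og != panel.alt[idx])
            div += int(fixed_ref.sum() + fixed_alt.sum())
    else:
        cc.pi = 0.0
    if panel.divergence_only is not None:
        div += int(np.isin(panel.divergence_only, usable_set).sum())
    cc.D = div
    cc.K = jukes_cantor(div / cc.m)
    return cc


def mkt_counts(
    panel: HaplotypePanel,
    outgroup: OutgroupTrack,
    class_map: SiteClassMap,
    test_class: str,
    neutral_class: str = "fourfold",
    maf_cutoff: float = 0.05,
    mask: AccessibilityMask | None = None,
) -> MKTCounts:
    """Site counts (m, P partitioned at the MAF cutoff, D, pi, K) for a
    test class against a neutral class.

    A site is analyzable when accessible and outgroup-aligned.  P and D are
    mutually exclusive: polymorphic sites never count as divergent.
    Three-state sites are excluded from both.
    """
    if test_class not in SITE_CLASSES or neutral_class not in SITE_CLASSES:
        raise ValueError("unknown site class")
    return MKTCounts(
        test=_class_counts(panel, outgroup, class_map.positions_of(test_class),
                           test_class, maf_cutoff, mask, class_map.chromosome),
        neutral=_class_counts(panel, outgroup, class_map.positions_of(neutral_class),
                              neutral_class, maf_cutoff, mask, class_map.chromosome),
        maf_cutoff=maf_cutoff,
    )


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def standard_mkt(counts: MKTCounts):
    """Standard MKT summaries from the 2x2 table.

    Returns (alpha_std, alpha_pik, NI, DoS); any statistic whose
    denominator cell is zero is None, never +/-inf.
    """
    t, s = counts.test, counts.neutral
    ni = alpha_std = alpha_pik = dos = None
    if s.P > 0 and t.D > 0 and s.D > 0:
        ni = (t.P / s.P) / (t.D / s.D)
        alpha_std = 1.0 - ni
    if (t.pi is not None and s.pi not in (None, 0.0) and s.pi and
            t.K not in (None, 0.0) and s.K is not None and t.K):
        alpha_pik = 1.0 - (t.pi / s.pi) * (s.K / t.K)
    if (t.D + s.D) > 0 and (t.P + s.P) > 0:
        dos = t.D / (t.D + s.D) - t.P / (t.P + s.P)
    return alpha_std, alpha_pik, ni, dos


@dataclass
class MKTResult:
    alpha_std: float | None = None
    alpha_pik: float | None = None
    NI: float | None = None
    DoS: float | None = None
    d: float | None = None
    b: float | None = None
    f: float | None = None
    f_old: float | None = None    # reported as "f - gamma"
    gamma: float | None = None
    alpha_cor: float | None = None
    clamped: bool = False


def integrative_mkt(counts: MKTCounts, maf_cutoff: float | None = None) -> MKTResult:
    """Integrative MKT with the low-MAF slightly-deleterious correction.

    Neutral-class polymorphism predicts the test class's neutral share:
    P_t_neutral = P_t_high * P_s / P_s_high; the low-MAF excess
    P_t_wd = P_t_low - P_t_high * (P_s_low / P_s_high) (floored at 0) is
    attributed to weakly deleterious mutations.  Fractions of new
    mutations: f (neutral), b (weakly deleterious), d = 1 - f - b
    (strongly deleterious); alpha_cor removes the deleterious excess from
    the MKT.  gamma = max(0, f - f_divergence) splits f into recently vs
    anciently neutral, with the divergence-based neutral fraction built on
    the pi/K form of alpha.  Fractions are clamped to [0, 1] (flagged).
    """
    res = MKTResult()
    res.alpha_std, res.alpha_pik, res.NI, res.DoS = standard_mkt(counts)
    t, s = counts.test, counts.neutral
    if s.P_high <= 0 or t.D <= 0 or s.D <= 0 or t.m <= 0 or s.m <= 0 or s.P <= 0:
        return res

    ratio_m = s.m / t.m
    p_t_neutral = t.P_high * s.P / s.P_high
    p_t_wd = t.P_low - t.P_high * (s.P_low / s.P_high)
    if p_t_wd < 0:
        p_t_wd = 0.0
        res.clamped = True

    f = ratio_m * p_t_neutral / s.P
    b = ratio_m * p_t_wd / s.P
    f, b, clamped = _clamp01(f), _clamp01(b), False
    if f != ratio_m * p_t_neutral / s.P or b != ratio_m * p_t_wd / s.P:
        res.clamped = True
    d = 1.0 - f - b
    if not 0.0 <= d <= 1.0:
        d = min(1.0, max(0.0, d))
        res.clamped = True

    res.f, res.b, res.d = f, b, d
    res.alpha_cor = 1.0 - (p_t_neutral / s.P) * (s.D / t.D)

    if res.alpha_pik is not None:
        f_div = ratio_m * (1.0 - res.alpha_pik) * t.D / s.D
        res.gamma = max(0.0, f - f_div)
        res.f_old = f - res.gamma   # = min(f, f_div); keeps f = f_old + gamma
    return res


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def descriptive_stats(
    panel: HaplotypePanel,
    outgroup: OutgroupTrack,
    class_map: SiteClassMap,
    mask: AccessibilityMask | None = None,
    daf_bins: int = 10,
):
    """Whole-region (gene +/- flank) pi, K and DAF spectrum."""
    region = np.arange(class_map.start, class_map.end, dtype=np.int64)
    usable = region[class_map.classes != "excluded"]
    cc = _class_counts(panel, outgroup, usable, "whole_region", 0.05, mask,
                       class_map.chromosome)
    daf = daf_spectrum(panel, usable, bins=daf_bins)
    return cc.pi, cc.K, daf
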