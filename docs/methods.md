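# Methods

This note documents the models, conventions and design choices behind
varwin, in the spirit of a statistical-software methods appendix. It
states nothing the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and conventions

All internal coordinates are 0-based half-open; VCF and GFF3 (1-based) are
converted at the I/O boundary. This matches BED/bedGraph, the dominant
exchange formats here.

The panel is a phased, biallelic 0/1 haplotype matrix (rows = 2N
haplotypes). Multi-allelic records, indels and structural variants are
dropped on read; unphased genotypes are a hard error because every
haplotype statistic requires phase. Sample exclusion (e.g. removing
reportedly inbred individuals) is a generic `exclude_samples` list rather
than a baked-in roster: the filter, not the roster, is the reusable part.

Ancestral states come from the VCF `AA` annotation when it matches one of
the two alleles, with the aligned outgroup call as fallback; sites with
neither are usable only by folded statistics. Sites where the outgroup
matches neither sample allele ("three-state" sites) are excluded from
both polymorphism and divergence counting: they violate the biallelic,
infinite-sites treatment under which both P and D are defined.

Lowercase (soft-masked) alignment bases are valid calls — masking is the
accessibility mask's job, not the alignment's.

## Windowing

Two schemes:

1. *Fully accessible 10 kb*: windows are tiled inside each accessible
   mask interval, anchored at the interval start; the remainder shorter
   than the window size is discarded and windows never span two
   intervals, so no window contains an inaccessible base. Anchoring per
   interval (rather than at global coordinates) maximizes the number of
   windows placeable without touching inaccessible sequence, and makes
   the window count invariant to splitting an interval at a window
   boundary (a tested property).
2. *Fixed 100 kb*: windows tile the chromosome from 0; the last partial
   window is retained with its true extent (discarding it would silently
   drop chromosome ends). Accessible-base counts from mask intersection
   are the per-site denominator; a fully masked window reports every
   statistic as missing.

Per-site denominators are always accessible bases L, never the nominal
window length: inaccessible positions carry no information and inflating
L would bias every per-site estimate downward.

Recombination rates are (cM(end) − cM(start)) / Mb with cumulative cM
linearly interpolated between map points and clamped to the terminal
values outside the map (rate 0 beyond the mapped range).

## SFS statistics

The unfolded spectrum ξᵢ counts polarized segregating sites with derived
count i; folded quantities (S, π, θ_W, Tajima's D) use all segregating
sites. Sample-size constants: Tajima's e₁/e₂ from the 1989 formulation;
Fu & Li's u_D/v_D and u_F/v_F in the outgroup (derived-singleton ξ₁)
versions, using the corrected u_F/v_F expressions adopted by the standard
implementations; Zeng's E variance with θ estimated by S/a₁ and θ² by
S(S−1)/(a₁²+a₂). None of these constants is printed in applied work, so
each is verified in tests against sign oracles, hand arithmetic at n=4,
the algebraic identity π + θ_H = 2θ_L on polarized data, and
neutral-calibration means over replicates.

Fay & Wu's H defaults to the unnormalized π − θ_H; a flag enables a
variance-normalized variant. Undefined statistics (S = 0, no polarizable
sites, saturated divergence p ≥ 3/4 in the Jukes–Cantor correction)
propagate as missing values, never as 0 — a 0 is a data statement, a
missing value is not.

Divergent sites are positions where all sample alleles agree and differ
from the aligned outgroup: divergence-only records at monomorphic
reference positions plus fixed differences at variant-record positions. A
polymorphic site is never counted as divergent.

## Linkage disequilibrium

r² = D²/(p₁q₁p₂q₂) on phased haplotypes (no genotype-based composite LD:
the input is phased). Sites fixed within the analyzed population are
excluded before pairing; "adjacent" means consecutive segregating sites
in genomic order within one window, never across a boundary. Wall's
congruence: an adjacent pair is congruent when its two columns jointly
show at most two two-site haplotypes; B = B′/(S−1) and Q = (B′+A)/S with
A the number of distinct sample bipartitions among congruent pairs — the
original definition, adopted as-is.

## Haplotype scans

EHH at distance x from a core allele is the probability that two randomly
drawn carrier haplotypes are identical over [core, x]; iHH integrates the
curve trapezoidally until EHH < 0.05 (the trapezoid ending at the first
sub-cutoff point is included). Integration is over physical distance by
default; supplying a genetic map switches the axis to cM. A gap > 20 kb
between consecutive informative SNPs truncates the integration and flags
the site, which removes it from standardization but keeps it in the
per-site report — truncating rather than discarding the whole region
matches the "maximum gap" semantics with minimal data loss.

iHS = ln(iHH_ancestral/iHH_derived), computed only at polarized sites
with MAF > 0.05 and at least two carriers of each allele, standardized to
zero mean and unit variance within derived-allele-frequency bins of width
0.02; bins with fewer than 20 scores are merged into neighbors.
Standardization is pooled across the scanned input (documented in output
headers by construction of one score set per run). XP-EHH integrates each
population's total-sample EHH over a shared extent set where the pooled
two-population EHH drops below the cutoff, and standardizes in a single
bin. Sex chromosomes are skipped by scan commands unless overridden.

## MKT family

Degeneracy is classified per codon position with the standard genetic
code: 4-fold if all three substitutions are synonymous, 0-fold if none is
(a change to or from a stop counts as non-synonymous); 2-/3-fold sites
fall in class `other` and never enter the MKT. Site-class maps cover a
gene's transcript ± 500 bp: CDS by degeneracy on the coding strand, exon
minus CDS as 5′/3′ UTR by strand, intra-transcript non-exonic positions
as intron, and flanks as intergenic except where they overlap another
gene's transcript. A CDS with an internal stop withholds the coding
classes for that gene (flagged). One transcript per gene — the longest
codable one, deterministic tie-break — keeps gene counts unambiguous.

Standard MKT: NI = (P_t/P_s)/(D_t/D_s), α = 1 − NI, DoS =
D_t/(D_t+D_s) − P_t/(P_t+P_s), plus the π/K form of α. Integrative MKT
with the MAF < 5% partition (minor, not derived, allele frequency, and a
strict inequality): the neutral class's high/low split predicts the test
class's neutral polymorphism P_t,neutral = P_t,high·P_s/P_s,high; the
low-frequency excess P_t,wd = P_t,low − P_t,high·(P_s,low/P_s,high)
(floored at 0) is attributed to weakly deleterious mutations. Then
f = (m_s/m_t)·P_t,neutral/P_s, b = (m_s/m_t)·P_t,wd/P_s, d = 1 − f − b,
and α_cor = 1 − (P_t,neutral/P_s)(D_s/D_t). Fractions are clamped to
[0, 1] with a truthful flag; negative intermediates from sampling noise
are floored, never propagated.

γ splits f into recently vs anciently neutral by comparing f with a
divergence-based neutral fraction f_div = (m_s/m_t)(1−α_div)D_t/D_s.
Using α_cor as α_div would make γ ≡ 0 algebraically, so α_div is the
π/K-based α. This operationalization is a reconstruction of the cited
integrative framework, not a transcription of a published closed form,
and is the module's most consequential interpretation; results for γ and
f−γ should be read with that caveat. The reported f−γ is min(f, f_div)
so that f = (f−γ) + γ holds identically.

## Synthetic data generator

The generator draws accessible/inaccessible mask runs with exponential
lengths (mean run 5 kb, accessible fraction 0.9), places segregating
sites uniformly on accessible positions with S ~ Poisson(θ·a₁·L) and
derived counts ∝ 1/i (the neutral SFS expectation), assigns carriers
independently per site, and writes an outgroup sequence that carries the
ancestral allele at every SNP and diverges elsewhere at 1.2% per site
(the human–chimpanzee autosomal scale). Default sample size is 10
diploids (20 haplotypes) in two populations; per-site θ defaults to
0.001, the human autosomal scale. Gene models are stop-free random CDS
with UTRs, an intron and a terminal stop; one gene is placed on the minus
strand to exercise strand handling.

Because sites are independent, the generator calibrates SFS statistics
but carries no linkage: LD and EHH behaviour is validated with explicitly
constructed haplotype patterns and with `inject_sweep`, which forces a
carrier fraction to share one haplotype over a chosen length around a
derived core. `inject_deleterious_class` adds low-MAF sites in a chosen
site class, solving b = (m_s/m_t)·P_wd/P_s for the count needed to hit a
target b; sample sizes for such fixtures use 25 diploids so singletons
and doubletons fall strictly below the 5% MAF cutoff. Passing tests on
these fixtures therefore demonstrate estimator correctness and
calibration under the stated generative model — not robustness to
demography, linked selection or recombination-rate variation, which real
panels exhibit and the generator deliberately omits.

## Problem sizes and numerical choices

Calibration tests use 500 neutral replicates of 10 kb at n = 20
haplotypes; parameter-recovery tests use 100 replicates each; the
standardization-tail check uses a single 500 kb panel (~2400 scored
SNPs). These sizes give standard errors comfortably below the asserted
tolerances while keeping the default suite fast. Oracle-equivalence
checks assert agreement to 1e-12 on ≥ 200 random panels. Floats in
track files are written with repr-stable `%.10g` formatting so repeated
runs are byte-identical; window statistics never depend on RNG state.

## Known limitations

- The genome-scale windowing validation against the published GRCh37
  pilot-mask totals requires downloading that mask; it cannot run
  air-gapped.
- No D′, no LD-decay fitting, no nSL/XP-nSL, no asymptotic-MKT
  extrapolation, no polarized MKT variants, no Wiggle/BigWig output
  (bedGraph is the textual equivalent).
- Missing genotypes are not modelled: sites with missing calls are
  rejected at read time (fully genotyped panels are assumed).
- The γ/f−γ split depends on the divergence-based neutral fraction as
  described above.
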