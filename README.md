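# varwin

**varwin** is a population-genomics statistics engine: from phased variant
panels (VCF), a genome accessibility mask (BED), gene annotations (GFF3)
and a reference-vs-outgroup alignment (two-sequence multi-FASTA), it
computes a battery of diversity, divergence, linkage-disequilibrium and
neutrality statistics per population — in mask-aware non-overlapping
windows and in annotated protein-coding genes — and exports them as
browser-ready bedGraph/GFF3/TSV tracks.

It is written for population geneticists who want reproducible windowed
scans and gene-level McDonald–Kreitman analyses over large phased panels
(e.g. human 1000-Genomes-style data with a chimpanzee outgroup) without
assembling a pipeline by hand.

## What it computes

**Windowed statistics** (per population, per window):

- Frequency-based diversity: segregating sites per site *S/L*, nucleotide
  diversity π = Σ 2p(1−p)·n/(n−1)/L, Watterson's θ_W = S/(a₁L) with
  a₁ = Σ_{i<n} 1/i, haplotype diversity.
- Divergence: divergent-site counts against an aligned outgroup and
  Jukes–Cantor-corrected divergence K = −¾ ln(1 − 4p/3).
- SFS neutrality tests on the unfolded spectrum ξᵢ: Tajima's D,
  Fu & Li's D and F (outgroup versions using derived singletons ξ₁),
  Fay & Wu's H = π − θ_H with θ_H = Σ 2i²ξᵢ/(n(n−1)), and Zeng's
  E = (θ_L − θ_W)/√Var with θ_L = Σ iξᵢ/(n−1).
- Linkage disequilibrium: pairwise r², Kelly's ZnS (mean r² over all site
  pairs), Rozas' ZA (adjacent pairs) and ZZ = ZA − ZnS, Wall's B and Q
  (congruent adjacent-pair statistics).
- Haplotype scans: EHH, iHS = ln(iHH_ancestral/iHH_derived) standardized
  in derived-allele-frequency bins, and XP-EHH between two populations,
  with MAF > 0.05 site filtering, an EHH cutoff of 0.05 and a 20 kb
  maximum SNP gap; windows are summarized by the mean |score|.
- Recombination rates (cM/Mb) interpolated from cumulative genetic maps.

**Gene-based statistics** (per gene ± 500 bp flanks, per population):
site-class annotation (4-fold, 0-fold, UTRs, introns, intergenic flanks),
DAF spectra, the standard MKT (α = 1 − NI, NI = (P_t/P_s)/(D_t/D_s), DoS)
and the integrative MKT, which partitions polymorphism at MAF < 5% to
estimate the fractions of new mutations that are strongly deleterious
(*d*), weakly deleterious (*b*) and neutral (*f*, split into anciently and
recently neutral, f−γ and γ), plus a corrected α.

**Windowing** follows two schemes: 10 kb windows tiled inside accessible
mask intervals so that no window overlaps an inaccessible base, and fixed
100 kb windows tiled along the chromosome with inaccessible positions
discarded from every denominator.

A seeded synthetic-input generator (`varwin.sim`) emulates the whole input
ensemble at toy scale and powers the test-bed, including sweep and
weakly-deleterious-site injections with known ground truth.

## Worked example

```python
from varwin.hapscan import ihs_at_site
from varwin.sim import FixtureSpec, inject_sweep, simulate_panel

spec = FixtureSpec(seed=31, genome_length=60_000, accessible_fraction=1.0,
                   n_genes=0, theta=0.002, sweep_core=30_000,
                   sweep_length=20_000, sweep_carrier_fraction=0.6)
sim = simulate_panel(spec)
panel = inject_sweep(sim.panel, spec)
s = ihs_at_site(panel, 30_000)
print(f"{s.unstandardized:+.3f}")
```

prints `-3.103`: the derived allele at the swept core sits on long shared
haplotypes, so its EHH integral dwarfs the ancestral one and the
log-ratio is strongly negative — the classic incomplete-sweep signature.
Running the full scan (`examples/03_selection_scan.py`) shows window mean
|iHS| rising from ~0.3–0.5 in neutral background windows to ~1.5–1.6 in
the two windows covering the sweep.

The `examples/` directory holds one short narrative script per
capability: windowed statistics, gene MKT, selection scans, and neutral
calibration. The `varwin` CLI exposes the same stages as `windows`,
`genes`, `scan` and `simulate` subcommands.

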