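"""Synthetic toy-scale inputs with known statistical structure.

The generator emulates the pipeline's whole input ensemble — a few-kb
"genome", an accessibility mask with accessible/inaccessible runs, phased
haplotypes whose segregating sites are drawn from the neutral site
frequency spectrum (xi_i proportional to 1/i, independent sites), an
outgroup sequence with Poisson-like divergence, a handful of protein-coding
gene models, a genetic map and a sample/population panel — and can write
all of it in the external formats the readers consume (VCF, BED, GFF3,
two-sequence MFA, TSVs).

It is a test harness, not a population-genetics simulator: there is no
demography and no recombination graph.  Sites are independent, which is
sufficient to calibrate SFS statistics; haplotype-structure statistics
(LD, EHH) are exercised with explicitly constructed patterns and
:func:`inject_sweep`.  Every stochastic draw flows from the spec's seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import sample_constants
from .io import (
    AccessibilityMask,
    GeneModel,
    GeneticMap,
    HaplotypePanel,
    OutgroupTrack,
    merge_outgroup_panel,
)
from .mkt import SiteClassMap, revcomp

__all__ = [
    "FixtureSpec",
    "SimulatedData",
    "simulate_panel",
    "inject_sweep",
    "inject_deleterious_class",
    "write_fixture_dir",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in _STOPS]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic data set.

    Defaults: a 100 kb genome, 90% accessible in ~5 kb runs, 10 diploid
    samples (20 haplotypes) split over two populations, per-site diversity
    theta = 0.001, outgroup divergence 1.2% (the human-chimp autosomal
    scale), a 1.2 cM/Mb linear genetic map, and three genes (one on the
    minus strand).  The seed is mandatory and governs every draw.
    """

    seed: int
    chromosome: str = "chr1"
    genome_length: int = 100_000
    accessible_fraction: float = 0.9
    run_length: int = 5_000
    n_samples: int = 10                 # diploid individuals; 2N haplotypes
    n_populations: int = 2
    theta: float = 0.001                # per-site Watterson target
    divergence: float = 0.012           # per-site outgroup substitution rate
    aligned_fraction: float = 1.0
    deleterious_fraction: float = 0.0
    sweep_core: int | None = None
    sweep_length: int = 0
    sweep_carrier_fraction: float = 0.0
    n_genes: int = 3
    utr_length: int = 60
    cds_exon_length: int = 150          # two CDS exons -> CDS of 300 bp
    intron_length: int = 120
    recomb_cm_per_mb: float = 1.2
    flank_size: int = 500

    def __post_init__(self) -> None:
        for name in ("accessible_fraction", "divergence", "aligned_fraction",
                     "deleterious_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimulatedData:
    spec: FixtureSpec
    panel: HaplotypePanel            # outgroup-merged
    outgroup: OutgroupTrack
    mask: AccessibilityMask
    genes: list[GeneModel]
    reference: str
    gmap: GeneticMap


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_mask(spec: FixtureSpec, rng) -> AccessibilityMask:
    L, f = spec.genome_length, spec.accessible_fraction
    if f >= 1.0:
        return AccessibilityMask({spec.chromosome: np.array([[0, L]])})
    if f <= 0.0:
        return AccessibilityMask({spec.chromosome: np.empty((0, 2), dtype=np.int64)})
    mean_acc = spec.run_length
    mean_gap = spec.run_length * (1.0 / f - 1.0)
    iv, pos = [], 0
    while pos < L:
        a = pos
        b = min(L, a + max(1, int(rng.exponential(mean_acc))))
        iv.append((a, b))
        pos = b + max(1, int(rng.exponential(mean_gap)))
    return AccessibilityMask({spec.chromosome: np.array(iv, dtype=np.int64)})


def _lay_genes(spec: FixtureSpec, rng) -> list[GeneModel]:
    genes: list[GeneModel] = []
    if spec.n_genes <= 0:
        return genes
    unit = (2 * spec.utr_length + 2 * spec.cds_exon_length + spec.intron_length)
    spacing = max(unit + 2 * spec.flank_size + 200,
                  spec.genome_length // (spec.n_genes + 1))
    for k in range(spec.n_genes):
        g = spec.flank_size + 100 + k * spacing
        if g + unit + spec.flank_size >= spec.genome_length:
            break
        strand = "-" if k == 1 else "+"
        e1 = (g, g + spec.utr_length + spec.cds_exon_length)
        intron_start = e1[1]
        e2s = intron_start + spec.intron_length
        e2 = (e2s, e2s + spec.cds_exon_length + spec.utr_length)
        cds = [(g + spec.utr_length, e1[1]), (e2s, e2s + spec.cds_exon_length)]
        if strand == "+":
            utr5, utr3 = [(g, g + spec.utr_length)], [(e2s + spec.cds_exon_length, e2[1])]
        else:
            utr3, utr5 = [(g, g + spec.utr_length)], [(e2s + spec.cds_exon_length, e2[1])]
            # minus strand: 5'UTR is the rightmost segment
        genes.append(GeneModel(
            gene_id=f"gene{k + 1}",
            transcript_id=f"gene{k + 1}.t1",
            chromosome=spec.chromosome,
            strand=strand,
            exons=[e1, e2],
            cds=cds,
            utr5=utr5,
            utr3=utr3,
            flank_size=spec.flank_size,
        ))
    return genes


def _reference_with_genes(spec: FixtureSpec, genes, rng) -> str:
    ref = rng.choice(_BASES, size=spec.genome_length)
    for gene in genes:
        cds_positions = [p for s, e in sorted(gene.cds) for p in range(s, e)]
        n_codons = len(cds_positions) // 3
        codons = [_NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS),
                                                           size=n_codons)]
        codons[-1] = "TAA"
        seq = "".join(codons)
        if gene.strand == "-":
            seq = revcomp(seq)
        for p, b in zip(cds_positions, seq):
            ref[p] = b
    return "".join(ref)


def simulate_panel(spec: FixtureSpec) -> SimulatedData:
    """Generate the full toy input ensemble, deterministic under the seed.

    Segregating sites are placed uniformly on accessible positions; derived
    counts are drawn from the neutral expectation xi_i proportional to 1/i;
    carrier haplotypes per site are independent across sites.  The outgroup
    equals the ancestral (reference) allele at every segregating site and
    diverges elsewhere at the specified rate.
    """
    rng = np.random.default_rng(spec.seed)
    n_hap = 2 * spec.n_samples
    mask = _draw_mask(spec, rng)
    genes = _lay_genes(spec, rng)
    reference = _reference_with_genes(spec, genes, rng)

    acc_positions = np.concatenate([
        np.arange(a, b) for a, b in mask.chrom(spec.chromosome)
    ]) if mask.total_accessible(spec.chromosome) else np.empty(0, dtype=np.int64)
    n_acc = len(acc_positions)

    a1 = sample_constants(n_hap).a1
    expected_s = spec.theta * a1 * n_acc
    S = int(rng.poisson(expected_s)) if expected_s > 0 else 0
    if S > n_acc:
        raise ValueError("theta too high for the accessible genome length")
    positions = np.sort(rng.choice(acc_positions, size=S, replace=False))

    i_vals = np.arange(1, n_hap)
    probs = (1.0 / i_vals) / (1.0 / i_vals).sum()
    derived_counts = rng.choice(i_vals, size=S, p=probs)

    hap = np.zeros((n_hap, S), dtype=np.uint8)
    for j, c in enumerate(derived_counts):
        rows = rng.choice(n_hap, size=c, replace=False)
        hap[rows, j] = 1

    ref_alleles = np.array([reference[p] for p in positions], dtype="<U1")
    alt_alleles = np.array([
        rng.choice([b for b in "ACGT" if b != r]) for r in ref_alleles
    ], dtype="<U1") if S else np.empty(0, dtype="<U1")

    samples = [f"s{i:03d}" for i in range(spec.n_samples)]
    pops = {}
    per_pop = max(1, spec.n_samples // max(1, spec.n_populations))
    for i, s in enumerate(samples):
        pops[s] = f"POP{min(i // per_pop, spec.n_populations - 1) + 1}"

    panel = HaplotypePanel(
        chromosome=spec.chromosome,
        positions=positions.astype(np.int64),
        haplotypes=hap,
        ref=ref_alleles,
        alt=alt_alleles,
        ancestral_state=np.full(S, "ref", dtype="<U7"),
        sample_ids=samples,
        population_of=pops,
    )

    out_seq = np.array(list(reference))
    divergent = rng.random(spec.genome_length) < spec.divergence
    divergent[positions] = False  # outgroup carries the ancestral allele at SNPs
    for p in np.flatnonzero(divergent):
        out_seq[p] = rng.choice([b for b in "ACGT" if b != reference[p]])
    aligned = np.ones(spec.genome_length, dtype=bool)
    if spec.aligned_fraction < 1.0:
        aligned = rng.random(spec.genome_length) < spec.aligned_fraction
    outgroup = OutgroupTrack(
        chromosome=spec.chromosome,
        offset=0,
        aligned=aligned,
        calls=np.where(aligned, out_seq, ""),
        ref_seq=np.array(list(reference), dtype="<U1"),
    )

    gmap = GeneticMap(
        positions=np.array([0.0, float(spec.genome_length)]),
        cm=np.array([0.0, spec.recomb_cm_per_mb * spec.genome_length / 1e6]),
    )

    merged = merge_outgroup_panel(panel, outgroup)
    return SimulatedData(spec=spec, panel=merged, outgroup=outgroup, mask=mask,
                         genes=genes, reference=reference, gmap=gmap)


# ---------------------------------------------------------------------------
# injections
# ---------------------------------------------------------------------------

class _ConstRef:
    """Reference lookup returning a constant base for any position."""

    def __init__(self, base: str):
        self.base = base

    def __getitem__(self, pos) -> str:
        return self.base


def _insert_sites(panel: HaplotypePanel, new_positions, new_cols, reference, rng):
    """Insert new segregating columns (ancestral = ref) keeping order."""
    order = np.argsort(new_positions)
    new_positions = np.asarray(new_positions)[order]
    new_cols = np.asarray(new_cols)[:, order]
    ref = np.array([reference[p] for p in new_positions], dtype="<U1")
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref], dtype="<U1")

    positions = np.concatenate([panel.positions, new_positions])
    order = np.argsort(positions)
    hap = np.concatenate([panel.haplotypes, new_cols.astype(np.uint8)], axis=1)

    def cat(a, b):
        return np.concatenate([a, b])[order]

    extra_anc = np.full(len(new_positions), "ref", dtype="<U7")
    kwargs = dict(
        positions=positions[order],
        haplotypes=hap[:, order],
        ref=cat(panel.ref, ref),
        alt=cat(panel.alt, alt),
        ancestral_state=cat(panel.ancestral_state, extra_anc),
    )
    if panel.outgroup_allele is not None:
        kwargs["outgroup_allele"] = cat(panel.outgroup_allele, ref.copy())
    if panel.three_state is not None:
        kwargs["three_state"] = cat(panel.three_state,
                                    np.zeros(len(new_positions), dtype=bool))
    if panel.divergence_only is not None:
        kwargs["divergence_only"] = np.setdiff1d(panel.divergence_only, new_positions)
    return dataclasses.replace(panel, **kwargs)


def inject_sweep(panel: HaplotypePanel, spec: FixtureSpec) -> HaplotypePanel:
    """Force a long shared derived haplotype around a core site.

    A carrier subset of haplotypes receives the derived allele at the core
    and is made identical over the sweep length; non-carriers are
    untouched.  Zero sweep length returns the panel unchanged.
    """
    if spec.sweep_length == 0:
        return panel
    if not 0.0 < spec.sweep_carrier_fraction < 1.0:
        raise ValueError("sweep carrier fraction must lie in (0, 1)")
    core = spec.sweep_core if spec.sweep_core is not None else spec.genome_length // 2
    rng = np.random.default_rng(spec.seed + 7_777)
    n = panel.n_haplotypes

    if core not in panel.positions:
        # create the core site as an all-ancestral column first
        col = np.zeros((n, 1), dtype=np.uint8)
        panel = _insert_sites(panel, np.array([core]), col, _ConstRef("A"), rng)
    hap = panel.haplotypes.copy()
    positions = panel.positions

    core_idx = int(np.searchsorted(positions, core))
    k = max(2, int(round(spec.sweep_carrier_fraction * n)))
    carriers = rng.choice(n, size=k, replace=False)

    # derived orientation at the core: ancestral is ref -> derived = alt = 1
    anc = panel.ancestral_state.copy()
    anc[core_idx] = "ref"
    hap[:, core_idx] = 0
    hap[carriers, core_idx] = 1

    half = spec.sweep_length // 2
    lo, hi = np.searchsorted(positions, [core - half, core + half + 1])
    template = hap[carriers[0], lo:hi].copy()
    for c in carriers:
        hap[c, lo:hi] = template
    hap[carriers, core_idx] = 1
    return dataclasses.replace(panel, haplotypes=hap, ancestral_state=anc)


def inject_deleterious_class(
    panel: HaplotypePanel,
    class_map: SiteClassMap,
    fraction: float,
    spec: FixtureSpec,
    reference: str,
    test_class: str = "zerofold",
    neutral_class: str = "fourfold",
    maf_cutoff: float = 0.05,
) -> HaplotypePanel:
    """Add low-MAF segregating sites in the test class so that the
    integrative MKT's weakly-deleterious fraction b is ~ *fraction*.

    The number of injected sites solves b = (m_s/m_t) * P_wd / P_s for
    P_wd given the panel's current neutral-class polymorphism.  Derived
    counts are forced strictly below the MAF cutoff; the neutral class is
    untouched.
    """
    if fraction == 0.0:
        return panel
    rng = np.random.default_rng(spec.seed + 13_131)
    n = panel.n_haplotypes
    c_max = int(np.ceil(maf_cutoff * n)) - 1
    if c_max < 1:
        raise ValueError("sample too small: no count is strictly below the MAF cutoff")

    t_pos = class_map.positions_of(test_class)
    s_pos = class_map.positions_of(neutral_class)
    m_t, m_s = len(t_pos), len(s_pos)
    if m_t == 0 or m_s == 0:
        raise ValueError("class map lacks test or neutral sites")
    seg_mask = (panel.alt_counts() > 0) & (panel.alt_counts() < n)
    p_s = int(np.isin(panel.positions[seg_mask], s_pos).sum())
    if p_s == 0:
        raise ValueError("no neutral-class polymorphism to scale against")

    n_add = int(round(fraction * p_s * m_t / m_s))
    free = np.setdiff1d(t_pos, panel.positions)
    if n_add > len(free):
        raise ValueError("requested deleterious fraction exceeds achievable density")
    if n_add == 0:
        return panel
    new_pos = np.sort(rng.choice(free, size=n_add, replace=False))
    cols = np.zeros((n, n_add), dtype=np.uint8)
    for j in range(n_add):
        c = int(rng.integers(1, c_max + 1))
        rows = rng.choice(n, size=c, replace=False)
        cols[rows, j] = 1
    return _insert_sites(panel, new_pos, cols, reference, rng)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_fixture_dir(sim: SimulatedData, outdir) -> dict[str, Path]:
    """Write the simulated ensemble as VCF/BED/GFF3/MFA/TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = sim.spec
    paths = {
        "vcf": outdir / "panel.vcf",
        "mask": outdir / "mask.bed",
        "gff": outdir / "genes.gff3",
        "mfa": outdir / "outgroup.mfa",
        "panel": outdir / "samples.panel.tsv",
        "map": outdir / "map.sexavg.tsv",
        "sizes": outdir / "chrom.sizes",
    }
    _write_vcf(sim.panel, paths["vcf"], spec.genome_length)
    _write_bed(sim.mask, paths["mask"])
    _write_gff3(sim.genes, paths["gff"])
    _write_mfa(sim, paths["mfa"])
    paths["panel"].write_text("".join(
        f"{s}\t{sim.panel.population_of[s]}\n" for s in sim.panel.sample_ids))
    paths["map"].write_text(
        "position\tcM\n" + "".join(
            f"{int(p)}\t{c:.8f}\n" for p, c in zip(sim.gmap.positions, sim.gmap.cm)))
    paths["sizes"].write_text(f"{spec.chromosome}\t{spec.genome_length}\n")
    return paths


def _write_vcf(panel: HaplotypePanel, path, contig_length: int) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={panel.chromosome},length={contig_length}>",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(panel.sample_ids),
    ]
    for j in range(panel.n_sites):
        anc = panel.ancestral_state[j]
        aa = panel.ref[j] if anc == "ref" else panel.alt[j] if anc == "alt" else "."
        gts = "\t".join(
            f"{panel.haplotypes[2 * i, j]}|{panel.haplotypes[2 * i + 1, j]}"
            for i in range(len(panel.sample_ids))
        )
        lines.append(
            f"{panel.chromosome}\t{panel.positions[j] + 1}\t.\t{panel.ref[j]}\t"
            f"{panel.alt[j]}\t.\tPASS\tAA={aa}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _write_bed(mask: AccessibilityMask, path) -> None:
    lines = [f"{c}\t{a}\t{b}" for c in mask.intervals for a, b in mask.chrom(c)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _write_gff3(genes: list[GeneModel], path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(f"{g.chromosome}\tvarwin\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}")
        lines.append(f"{g.chromosome}\tvarwin\tmRNA\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                     f"{g.strand}\t.\tID={g.transcript_id};Parent={g.gene_id}")
        for s, e in g.exons:
            lines.append(f"{g.chromosome}\tvarwin\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"Parent={g.transcript_id}")
        phase_positions = 0
        cds = sorted(g.cds) if g.strand == "+" else sorted(g.cds, reverse=True)
        for s, e in cds:
            phase = (3 - phase_positions % 3) % 3
            lines.append(f"{g.chromosome}\tvarwin\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                         f"{phase}\tParent={g.transcript_id}")
            phase_positions += e - s
    Path(path).write_text("\n".join(lines) + "\n")


def _write_mfa(sim: SimulatedData, path) -> None:
    out = np.where(sim.outgroup.aligned, sim.outgroup.calls, "N")
    lines = [f">{sim.spec.chromosome} reference", _wrap(sim.reference),
             f">outgroup aligned to {sim.spec.chromosome}", _wrap("".join(out))]
    Path(path).write_text("\n".join(lines) + "\n")


def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))
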