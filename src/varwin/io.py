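"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open.  VCF and GFF3 use 1-based
conventions and are converted at the boundary; BED, bedGraph and the
internal window/interval types share the same 0-based half-open convention.

The central in-memory container is :class:`HaplotypePanel`: a phased,
biallelic 0/1 haplotype matrix (rows = 2N haplotypes, columns = sites)
with per-site ancestral-state polarization and a sample→population map.
Divergence data live in :class:`OutgroupTrack`, a dense per-position record
of the outgroup allele and alignment coverage derived from a two-sequence
multi-FASTA (reference first, outgroup second).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "HaplotypePanel",
    "AccessibilityMask",
    "OutgroupTrack",
    "GeneModel",
    "GeneticMap",
    "WindowStatsRow",
    "read_vcf_panel",
    "read_panel_table",
    "read_mask_bed",
    "pairwise_mfa_to_outgroup",
    "merge_outgroup_panel",
    "read_gene_models",
    "collapse_longest_transcript",
    "read_genetic_map",
    "read_chrom_sizes",
    "write_track",
    "read_bedgraph",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes with polarization and population labels."""

    chromosome: str
    positions: np.ndarray          # (S,) int64, 0-based, strictly increasing
    haplotypes: np.ndarray         # (2N, S) uint8 in {0, 1}; 0=ref, 1=alt
    ref: np.ndarray                # (S,) single-character reference alleles
    alt: np.ndarray                # (S,) single-character alternate alleles
    ancestral_state: np.ndarray    # (S,) one of {"ref", "alt", "unknown"}
    sample_ids: list[str]
    population_of: dict[str, str]
    # filled by merge_outgroup_panel
    outgroup_allele: np.ndarray | None = None   # (S,) char, "" = unaligned
    three_state: np.ndarray | None = None       # (S,) bool
    divergence_only: np.ndarray | None = None   # positions, monomorphic diverged

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("haplotype matrix shape does not match positions")
        if self.haplotypes.size and self.haplotypes.max(initial=0) > 1:
            raise ValueError("haplotype matrix entries must be 0/1")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("row count must be 2 x sample count")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def alt_counts(self) -> np.ndarray:
        """Per-site count of the alternate allele among haplotypes."""
        return self.haplotypes.sum(axis=0).astype(np.int64)

    def derived_counts(self) -> np.ndarray:
        """Per-site derived-allele counts; -1 where the site is unpolarized."""
        alt = self.alt_counts()
        out = np.full(self.n_sites, -1, dtype=np.int64)
        is_ref = self.ancestral_state == "ref"
        is_alt = self.ancestral_state == "alt"
        out[is_ref] = alt[is_ref]
        out[is_alt] = self.n_haplotypes - alt[is_alt]
        return out

    def site_range(self, start: int, end: int) -> slice:
        """Column slice of sites with start <= position < end."""
        lo, hi = np.searchsorted(self.positions, [start, end])
        return slice(int(lo), int(hi))

    # -- subsetting ---------------------------------------------------------

    def for_population(self, population: str) -> "HaplotypePanel":
        """Panel restricted to samples of one population (sites kept as-is)."""
        keep = [s for s in self.sample_ids if self.population_of[s] == population]
        if not keep:
            raise ValueError(f"population {population!r} has no samples in panel")
        idx = []
        for s in keep:
            i = self.sample_ids.index(s)
            idx.extend((2 * i, 2 * i + 1))
        return dataclasses.replace(
            self,
            haplotypes=self.haplotypes[idx, :],
            sample_ids=keep,
            population_of={s: self.population_of[s] for s in keep},
        )

    def subset_region(self, start: int, end: int) -> "HaplotypePanel":
        sl = self.site_range(start, end)
        div = self.divergence_only
        if div is not None:
            div = div[(div >= start) & (div < end)]
        return dataclasses.replace(
            self,
            positions=self.positions[sl],
            haplotypes=self.haplotypes[:, sl],
            ref=self.ref[sl],
            alt=self.alt[sl],
            ancestral_state=self.ancestral_state[sl],
            outgroup_allele=None if self.outgroup_allele is None else self.outgroup_allele[sl],
            three_state=None if self.three_state is None else self.three_state[sl],
            divergence_only=div,
        )

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.population_of[s], None)
        return list(seen)


@dataclass
class AccessibilityMask:
    """Per-chromosome accessible intervals, 0-based half-open, normalized."""

    intervals: dict[str, np.ndarray]  # chrom -> (k, 2) int64, sorted, merged

    def __post_init__(self) -> None:
        self.intervals = {
            c: _normalize_intervals(iv) for c, iv in self.intervals.items()
        }

    def chrom(self, chromosome: str) -> np.ndarray:
        return self.intervals.get(chromosome, np.empty((0, 2), dtype=np.int64))

    def accessible_bases(self, chromosome: str, start: int, end: int) -> int:
        """Count of accessible positions intersecting [start, end)."""
        iv = self.chrom(chromosome)
        if not len(iv):
            return 0
        s = np.minimum(np.maximum(iv[:, 0], start), end)
        e = np.minimum(np.maximum(iv[:, 1], start), end)
        return int(np.maximum(e - s, 0).sum())

    def boolean_mask(self, chromosome: str, start: int, end: int) -> np.ndarray:
        """Boolean accessibility over [start, end)."""
        out = np.zeros(end - start, dtype=bool)
        for a, b in self.chrom(chromosome):
            a, b = max(a, start), min(b, end)
            if a < b:
                out[a - start : b - start] = True
        return out

    def is_accessible(self, chromosome: str, positions: np.ndarray) -> np.ndarray:
        iv = self.chrom(chromosome)
        positions = np.asarray(positions, dtype=np.int64)
        if not len(iv):
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(iv[:, 0], positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(len(positions), dtype=bool)
        res[ok] = positions[ok] < iv[idx[ok], 1]
        return res

    def total_accessible(self, chromosome: str | None = None) -> int:
        chroms = [chromosome] if chromosome else list(self.intervals)
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for c in chroms
                       for iv in [self.chrom(c)]))


def _normalize_intervals(iv) -> np.ndarray:
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if not len(iv):
        return iv
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    merged = [list(iv[0])]
    for a, b in iv[1:]:
        if a <= merged[-1][1]:  # overlap or adjacency -> merge
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return np.asarray(merged, dtype=np.int64)


@dataclass
class OutgroupTrack:
    """Dense per-position outgroup calls over [offset, offset + len)."""

    chromosome: str
    offset: int
    aligned: np.ndarray      # (L,) bool, True where the outgroup covers the ref
    calls: np.ndarray        # (L,) single chars; defined only where aligned
    ref_seq: np.ndarray      # (L,) reference bases from the alignment

    @property
    def end(self) -> int:
        return self.offset + len(self.aligned)

    def in_range(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        return (positions >= self.offset) & (positions < self.end)

    def aligned_at(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        out = np.zeros(len(positions), dtype=bool)
        ok = self.in_range(positions)
        out[ok] = self.aligned[positions[ok] - self.offset]
        return out

    def call_at(self, positions: np.ndarray) -> np.ndarray:
        """Outgroup calls; '' where unaligned or out of range."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(len(positions), "", dtype="<U1")
        ok = self.in_range(positions)
        rel = positions[ok] - self.offset
        vals = np.where(self.aligned[rel], self.calls[rel], "")
        out[ok] = vals
        return out

    def reference_string(self) -> str:
        return "".join(self.ref_seq)


@dataclass
class GeneModel:
    """One transcript of a protein-coding gene, 0-based half-open intervals."""

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str                      # "+" or "-"
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    flank_size: int = 500
    codable: bool = True             # CDS length divisible by 3 and non-empty

    @property
    def tx_start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def tx_end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span_with_flank(self) -> tuple[int, int]:
        return max(0, self.tx_start - self.flank_size), self.tx_end + self.flank_size


@dataclass
class GeneticMap:
    """Cumulative genetic map: (bp position, cM) points, one sex variant."""

    positions: np.ndarray
    cm: np.ndarray
    sex: str = "sexavg"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if len(self.positions) != len(self.cm) or len(self.positions) == 0:
            raise ValueError("map requires matched, non-empty position/cM columns")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            row = int(np.argmax(np.diff(self.cm) < 0)) + 2
            raise ValueError(f"cumulative cM decreases at row {row}")

    def cm_at(self, position) -> np.ndarray | float:
        """Linear interpolation; clamped to terminal cM outside the range."""
        return np.interp(position, self.positions, self.cm)


@dataclass
class WindowStatsRow:
    """One window x one population x one statistic — the track unit."""

    chromosome: str
    start: int
    end: int
    population: str
    statistic: str
    value: float | None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_panel_table(path) -> dict[str, str]:
    """Read a two-column sample<TAB>population table."""
    mapping: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"panel table line {ln}: expected sample<TAB>population")
        mapping[parts[0]] = parts[1]
    return mapping


def read_vcf_panel(
    path,
    panel: Mapping[str, str],
    region: tuple[int, int] | None = None,
    exclude_samples: Iterable[str] = (),
) -> HaplotypePanel:
    """Load phased biallelic SNPs from a VCF into a HaplotypePanel.

    Multi-allelic records, indels and structural variants are dropped.  The
    ancestral state is taken from the AA INFO annotation when it matches one
    of the two alleles, else left unknown.  VCF 1-based positions become
    0-based internal coordinates.  Any retained sample missing from *panel*,
    or any unphased genotype, raises ``ValueError``.
    """
    from cyvcf2 import VCF

    excluded = set(exclude_samples)
    vcf = VCF(str(path))
    samples = [s for s in vcf.samples if s not in excluded]
    missing = [s for s in samples if s not in panel]
    if missing:
        raise ValueError(f"samples absent from panel table: {', '.join(missing)}")
    vcf = VCF(str(path), samples=samples)
    samples = list(vcf.samples)  # cyvcf2 keeps file order

    chrom = None
    positions, cols, refs, alts, anc = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            continue
        pos0 = v.POS - 1
        if region is not None and not (region[0] <= pos0 < region[1]):
            continue
        chrom = chrom or v.CHROM
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, g in enumerate(v.genotypes):
            a, b, phased = g[0], g[1], g[-1]
            if a < 0 or b < 0:
                raise ValueError(f"missing genotype at {v.CHROM}:{v.POS}")
            if not phased:
                raise ValueError(
                    f"unphased genotype at {v.CHROM}:{v.POS} sample {samples[i]}: "
                    "phased haplotypes are required"
                )
            col[2 * i], col[2 * i + 1] = a, b
        positions.append(pos0)
        cols.append(col)
        refs.append(v.REF.upper())
        alts.append(v.ALT[0].upper())
        aa = v.INFO.get("AA")
        if aa:
            aa = str(aa).split("|")[0].strip().upper()
        if aa == v.REF.upper():
            anc.append("ref")
        elif aa == v.ALT[0].upper():
            anc.append("alt")
        else:
            anc.append("unknown")

    hap = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((2 * len(samples), 0), dtype=np.uint8)
    )
    return HaplotypePanel(
        chromosome=chrom or "",
        positions=np.asarray(positions, dtype=np.int64),
        haplotypes=hap,
        ref=np.asarray(refs, dtype="<U1"),
        alt=np.asarray(alts, dtype="<U1"),
        ancestral_state=np.asarray(anc, dtype="<U7"),
        sample_ids=samples,
        population_of={s: panel[s] for s in samples},
    )


def read_mask_bed(path) -> AccessibilityMask:
    """Read a BED3 accessibility mask; intervals are sorted and merged."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed BED line {ln}: fewer than 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"malformed BED line {ln}: {exc}") from None
        if start >= end:
            raise ValueError(f"BED line {ln}: start >= end ({start} >= {end})")
        per_chrom.setdefault(parts[0], []).append((start, end))
    return AccessibilityMask(
        {c: np.asarray(iv, dtype=np.int64) for c, iv in per_chrom.items()}
    )


_VALID = set("ACGT")


def pairwise_mfa_to_outgroup(path, offset: int = 0, chromosome: str = "") -> OutgroupTrack:
    """Convert a two-sequence reference/outgroup alignment to an OutgroupTrack.

    Columns with a reference gap consume no reference coordinate; columns
    where the outgroup shows a gap or N are recorded as unaligned.  Soft-
    masked (lowercase) bases are valid calls — masking is the accessibility
    mask's job, not the alignment's.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 aligned sequences, got {len(records)}")
    ref_aln = str(records[0].seq).upper()
    out_aln = str(records[1].seq).upper()
    if len(ref_aln) != len(out_aln):
        raise ValueError("aligned sequences differ in length")

    aligned, calls, ref_seq = [], [], []
    for r, o in zip(ref_aln, out_aln):
        if r == "-":
            continue  # insertion in outgroup: no reference coordinate
        ref_seq.append(r)
        if o == "-" or o not in _VALID:
            aligned.append(False)
            calls.append("")
        else:
            aligned.append(True)
            calls.append(o)
    return OutgroupTrack(
        chromosome=chromosome or records[0].id,
        offset=offset,
        aligned=np.asarray(aligned, dtype=bool),
        calls=np.asarray(calls, dtype="<U1"),
        ref_seq=np.asarray(ref_seq, dtype="<U1"),
    )


def merge_outgroup_panel(panel: HaplotypePanel, outgroup: OutgroupTrack) -> HaplotypePanel:
    """Annotate a panel with outgroup calls and divergence-only records.

    Sites where the aligned outgroup matches neither sample allele are
    flagged three-state and excluded downstream from both polymorphism and
    divergence counting.  Monomorphic reference positions with a differing
    outgroup call become divergence-only records.  Where the panel lacks an
    ancestral annotation the outgroup call supplies it.
    """
    calls = outgroup.call_at(panel.positions)
    three_state = (calls != "") & (calls != panel.ref) & (calls != panel.alt)

    anc = panel.ancestral_state.copy()
    unknown = anc == "unknown"
    anc[unknown & (calls == panel.ref)] = "ref"
    anc[unknown & (calls == panel.alt)] = "alt"

    rel = np.arange(len(outgroup.aligned))
    differs = outgroup.aligned & (outgroup.calls != outgroup.ref_seq)
    div_pos = rel[differs] + outgroup.offset
    div_pos = np.setdiff1d(div_pos, panel.positions, assume_unique=False)

    return dataclasses.replace(
        panel,
        ancestral_state=anc,
        outgroup_allele=calls,
        three_state=three_state,
        divergence_only=div_pos.astype(np.int64),
    )


def read_gene_models(path, flank_size: int = 500) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into GeneModel objects.

    One model per transcript; UTRs are derived as exon minus CDS, split into
    5'/3' by strand.  GFF3 1-based inclusive coordinates become 0-based
    half-open.  A transcript whose CDS length is not divisible by 3 is kept
    with ``codable=False`` (usable for non-coding site classes only).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        for tx in db.children(gene, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = [(f.start - 1, f.end) for f in db.children(tx, featuretype="exon", order_by="start")]
            cds = [(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS", order_by="start")]
            if not exons:
                exons = list(cds)
            if not exons:
                continue
            utr5, utr3 = _derive_utrs(exons, cds, tx.strand)
            cds_len = sum(e - s for s, e in cds)
            models.append(GeneModel(
                gene_id=gene.id,
                transcript_id=tx.id,
                chromosome=gene.seqid,
                strand=tx.strand,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
                flank_size=flank_size,
                codable=bool(cds) and cds_len % 3 == 0,
            ))
    return models


def _derive_utrs(exons, cds, strand):
    if not cds:
        return [], []
    cds_start = min(s for s, _ in cds)
    cds_end = max(e for _, e in cds)
    left, right = [], []
    for s, e in exons:
        if s < cds_start:
            left.append((s, min(e, cds_start)))
        if e > cds_end:
            right.append((max(s, cds_end), e))
    return (left, right) if strand == "+" else (right, left)


def collapse_longest_transcript(models: Sequence[GeneModel]) -> list[GeneModel]:
    """One transcript per gene: the longest codable one (longest overall if
    no transcript is codable). Deterministic tie-break by transcript id."""
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    out = []
    for gid, group in by_gene.items():
        codable = [m for m in group if m.codable]
        pool = codable or group
        pool.sort(key=lambda m: (-m.cds_length, -(m.tx_end - m.tx_start), m.transcript_id))
        out.append(pool[0])
    return out


def read_genetic_map(path, sex: str = "sexavg") -> GeneticMap:
    """Read a two-column (position bp, cumulative cM) TSV genetic map."""
    pos, cm = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            p, c = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            if ln == 1:
                continue  # header row
            raise ValueError(f"malformed map line {ln}") from None
        pos.append(p)
        cm.append(c)
    return GeneticMap(np.asarray(pos), np.asarray(cm), sex=sex)


def read_chrom_sizes(path) -> dict[str, int]:
    """UCSC chrom.sizes dialect: chrom<TAB>size."""
    sizes = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, size = line.split("\t")[:2]
        sizes[name] = int(size)
    return sizes


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def write_track(rows: Sequence[WindowStatsRow], format: str, path) -> None:
    """Write one statistic's windows as bedGraph, GFF3 or TSV.

    bedGraph lines are 0-based half-open and omit missing values; GFF3 uses
    1-based inclusive coordinates; TSV writes '.' for missing.  Mixing
    statistics (or populations) in one track is an error.
    """
    rows = list(rows)
    stats = {r.statistic for r in rows}
    pops = {r.population for r in rows}
    if len(stats) > 1:
        raise ValueError(f"mixed statistics in one track: {sorted(stats)}")
    if len(pops) > 1:
        raise ValueError(f"mixed populations in one track: {sorted(pops)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []
    if format == "bedGraph":
        for r in rows:
            if _is_missing(r.value):
                continue
            lines.append(f"{r.chromosome}\t{r.start}\t{r.end}\t{_fmt(r.value)}")
    elif format == "GFF3":
        lines.append("##gff-version 3")
        stat = next(iter(stats)) if stats else "stat"
        pop = next(iter(pops)) if pops else "."
        for r in rows:
            if _is_missing(r.value):
                continue
            lines.append(
                f"{r.chromosome}\tvarwin\tregion\t{r.start + 1}\t{r.end}\t{_fmt(r.value)}"
                f"\t.\t.\tstatistic={stat};population={pop}"
            )
    elif format == "TSV":
        lines.append("chromosome\tstart\tend\tpopulation\tstatistic\tvalue")
        for r in rows:
            val = "." if _is_missing(r.value) else _fmt(r.value)
            lines.append(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.population}\t{r.statistic}\t{val}")
    else:
        raise ValueError(f"unknown track format: {format}")
    path.write_text("\n".join(lines) + "\n")


def _fmt(v: float) -> str:
    return format(float(v), ".10g")


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        c, s, e, v = line.split("\t")
        out.append((c, int(s), int(e), float(v)))
    return out
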