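"""End-to-end orchestration: inputs -> per-window / per-gene statistics -> tracks.

Populations are processed independently: allele counts are recomputed after
sample subsetting, so an allele fixed within one population is not
segregating there.  Outputs are deterministic for a given configuration —
track files carry no timestamps, and per-window failures surface as missing
values (logged), never aborts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, hapscan, ld
from .io import (
    HaplotypePanel,
    WindowStatsRow,
    collapse_longest_transcript,
    merge_outgroup_panel,
    pairwise_mfa_to_outgroup,
    read_chrom_sizes,
    read_gene_models,
    read_genetic_map,
    read_mask_bed,
    read_panel_table,
    read_vcf_panel,
    write_track,
)
from .mkt import (
    build_site_class_map,
    daf_spectrum,
    descriptive_stats,
    integrative_mkt,
    mkt_counts,
)
from .windowing import place_accessible_windows, place_fixed_windows, window_recomb_rate

log = logging.getLogger("varwin")

WINDOW_STATISTICS = (
    "S", "Pi", "theta", "hap_diversity_within", "Divsites", "K",
    "Tajima_D", "FuLi_D", "FuLi_F", "FayWu_H", "Zeng_E",
    "Kelly_ZnS", "Rozas_ZA", "Rozas_ZZ", "Wall_B", "Wall_Q",
)

MKT_TEST_CLASSES = ("zerofold", "utr5", "utr3", "intron", "intergenic_flank")

SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y"}


@dataclass
class RunConfig:
    """Run-level inputs and constants for one analysis."""

    vcf: str
    mask: str
    panel: str
    outgroup_mfa: str | None = None
    gff: str | None = None
    genetic_map: str | None = None
    chrom_sizes: str | None = None
    populations: list[str] = field(default_factory=list)
    population_pairs: list[tuple[str, str]] = field(default_factory=list)
    exclude_samples: list[str] = field(default_factory=list)
    window_size: int = 10_000
    fixed_window_size: int = 100_000
    maf_scan: float = 0.05
    maf_mkt: float = 0.05
    flank_size: int = 500
    statistics: list[str] | None = None   # None = all window statistics
    out_dir: str = "varwin_out"
    seed: int = 0
    include_sex_chromosomes: bool = False

    def validate(self) -> None:
        for name in ("vcf", "mask", "panel"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input {name!r} missing: {p}")
        for name in ("outgroup_mfa", "gff", "genetic_map", "chrom_sizes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input {name!r} does not exist: {p}")
        if self.window_size <= 0 or self.fixed_window_size <= 0:
            raise ValueError("window sizes must be positive")


def _load_panel(config: RunConfig) -> HaplotypePanel:
    table = read_panel_table(config.panel)
    panel = read_vcf_panel(config.vcf, table, exclude_samples=config.exclude_samples)
    available = set(panel.populations)
    pops = config.populations or sorted(available)
    missing = [p for p in pops if p not in available]
    if missing:
        raise ValueError(f"populations absent from panel: {', '.join(missing)}")
    config.populations = pops
    log.info("panel: %d samples, %d sites, populations %s",
             len(panel.sample_ids), panel.n_sites, ", ".join(pops))
    if config.outgroup_mfa:
        track = pairwise_mfa_to_outgroup(config.outgroup_mfa,
                                         chromosome=panel.chromosome)
        panel = merge_outgroup_panel(panel, track)
        panel._outgroup_track = track  # transient, used by gene analysis
    return panel


def _window_rows(pop_panel, window, outgroup, mask, stats_enabled):
    """All enabled window statistics for one population x window."""
    rows = {}
    use_mask = mask if window.scheme == "fixed_100kb" else None
    spec = core.site_spectrum(pop_panel, window)
    div = core.diversity_stats(pop_panel, window, outgroup=outgroup, mask=use_mask)
    consts = core.sample_constants(pop_panel.n_haplotypes)
    d, f = core.fu_li_tests(spec, consts)
    rows.update({
        "S": div.S_per_site,
        "Pi": div.pi_per_site,
        "theta": div.theta_w_per_site,
        "hap_diversity_within": div.hap_diversity,
        "Divsites": div.divsites,
        "K": div.K_jc,
        "Tajima_D": core.tajimas_d(spec, consts),
        "FuLi_D": d,
        "FuLi_F": f,
        "FayWu_H": core.fay_wu_h(spec),
        "Zeng_E": core.zeng_e(spec, consts),
    })
    lds = ld.ld_stats(pop_panel, window)
    rows.update({
        "Kelly_ZnS": lds.zns, "Rozas_ZA": lds.za, "Rozas_ZZ": lds.zz,
        "Wall_B": lds.wall_b, "Wall_Q": lds.wall_q,
    })
    return {k: v for k, v in rows.items() if k in stats_enabled}


def run_windows_analysis(config: RunConfig) -> list[WindowStatsRow]:
    """Per-population windowed statistics; writes one bedGraph per
    statistic x population under out_dir and returns every row."""
    config.validate()
    mask = read_mask_bed(config.mask)
    panel = _load_panel(config)
    outgroup = getattr(panel, "_outgroup_track", None)

    windows = place_accessible_windows(mask, size=config.window_size)
    if config.chrom_sizes:
        windows = windows + place_fixed_windows(
            read_chrom_sizes(config.chrom_sizes), size=config.fixed_window_size,
            mask=mask)
    log.info("placed %d windows", len(windows))

    stats_enabled = set(config.statistics or WINDOW_STATISTICS)
    rows: list[WindowStatsRow] = []
    for pop in config.populations:
        pop_panel = panel.for_population(pop)
        for w in windows:
            try:
                values = _window_rows(pop_panel, w, outgroup, mask, stats_enabled)
            except Exception as exc:  # per-window failure -> missing, never abort
                log.warning("window %s:%d-%d failed for %s: %s",
                            w.chromosome, w.start, w.end, pop, exc)
                values = {s: None for s in stats_enabled}
            for stat in sorted(stats_enabled):
                v = values.get(stat)
                rows.append(WindowStatsRow(w.chromosome, w.start, w.end, pop,
                                           stat, None if v is None else float(v)))

    if config.genetic_map:
        gmap = read_genetic_map(config.genetic_map)
        for w in windows:
            rows.append(WindowStatsRow(w.chromosome, w.start, w.end, "ALL",
                                       f"recomb_{gmap.sex}",
                                       window_recomb_rate(gmap, w)))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_track: dict[tuple[str, str], list[WindowStatsRow]] = {}
    for r in rows:
        by_track.setdefault((r.statistic, r.population), []).append(r)
    for (stat, pop), track_rows in sorted(by_track.items()):
        write_track(track_rows, "bedGraph", out / f"{stat}.{pop}.bedGraph")
    return rows


def run_genes_analysis(config: RunConfig) -> pd.DataFrame:
    """Per-gene descriptive statistics plus standard and integrative MKT.

    One row per gene x population x test class (4-fold sites are the
    neutral reference).  Genes without a codable transcript report only
    non-coding classes; flags record internal-stop or clamping events.
    """
    config.validate()
    if not config.gff or not config.outgroup_mfa:
        raise FileNotFoundError("gene analysis requires both --gff and --outgroup")
    mask = read_mask_bed(config.mask)
    panel = _load_panel(config)
    outgroup = panel._outgroup_track
    reference = outgroup.reference_string()
    genes = collapse_longest_transcript(
        read_gene_models(config.gff, flank_size=config.flank_size))
    log.info("analyzing %d genes", len(genes))

    records = []
    for pop in config.populations:
        pop_panel = panel.for_population(pop)
        for gene in genes:
            cmap = build_site_class_map(gene, reference,
                                        other_genes=genes,
                                        ref_offset=outgroup.offset)
            pi, k, daf = descriptive_stats(pop_panel, outgroup, cmap, mask=mask)
            for test_class in MKT_TEST_CLASSES:
                counts = mkt_counts(pop_panel, outgroup, cmap, test_class,
                                    maf_cutoff=config.maf_mkt, mask=mask)
                res = integrative_mkt(counts)
                flags = []
                if cmap.coding_withheld:
                    flags.append("internal_stop")
                if res.clamped:
                    flags.append("clamped")
                records.append({
                    "gene_id": gene.gene_id,
                    "population": pop,
                    "class": test_class,
                    "m": counts.test.m,
                    "m_neutral": counts.neutral.m,
                    "P_low": counts.test.P_low,
                    "P_high": counts.test.P_high,
                    "D": counts.test.D,
                    "pi": counts.test.pi,
                    "K": counts.test.K,
                    "pi_gene": pi,
                    "K_gene": k,
                    "daf_peak_bin": int(np.argmax(daf)) if daf.sum() else None,
                    "alpha_std": res.alpha_std,
                    "alpha_pik": res.alpha_pik,
                    "NI": res.NI,
                    "DoS": res.DoS,
                    "d": res.d,
                    "b": res.b,
                    "f_old": res.f_old,
                    "gamma": res.gamma,
                    "alpha_cor": res.alpha_cor,
                    "flags": ";".join(flags),
                })
    df = pd.DataFrame.from_records(records)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "genes_mkt.tsv", sep="\t", index=False, na_rep=".",
              float_format="%.6g")
    return df


def run_hap_scan(config: RunConfig) -> dict[str, hapscan.HapScanScores]:
    """iHS per population and XP-EHH per configured population pair.

    Sex chromosomes are skipped with a log notice unless overridden.
    Per-site scores land in TSVs; window mean-|score| summaries in
    bedGraphs, under the track names iHS and XP_EHH.
    """
    config.validate()
    mask = read_mask_bed(config.mask)
    panel = _load_panel(config)
    if panel.chromosome in SEX_CHROMOSOMES and not config.include_sex_chromosomes:
        log.info("skipping sex chromosome %s for haplotype scans", panel.chromosome)
        return {}
    windows = place_accessible_windows(mask, size=config.window_size)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, hapscan.HapScanScores] = {}

    for pop in config.populations:
        scores = hapscan.ihs_scan(panel.for_population(pop), maf_min=config.maf_scan)
        results[f"iHS.{pop}"] = scores
        scores.write_tsv(out / f"iHS.{pop}.scores.tsv")
        rows = [WindowStatsRow(w.window.chromosome, w.window.start, w.window.end,
                               pop, "iHS", w.mean_abs_score)
                for w in hapscan.summarize_window_scores(scores, windows)]
        write_track(rows, "bedGraph", out / f"iHS.{pop}.bedGraph")

    for pop_a, pop_b in config.population_pairs:
        scores = hapscan.xpehh_scan(panel.for_population(pop_a),
                                    panel.for_population(pop_b),
                                    maf_min=config.maf_scan)
        key = f"XP_EHH.{pop_a}_{pop_b}"
        results[key] = scores
        scores.write_tsv(out / f"{key}.scores.tsv")
        rows = [WindowStatsRow(w.window.chromosome, w.window.start, w.window.end,
                               f"{pop_a}_{pop_b}", "XP_EHH", w.mean_abs_score)
                for w in hapscan.summarize_window_scores(scores, windows)]
        write_track(rows, "bedGraph", out / f"{key}.bedGraph")
    return results
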