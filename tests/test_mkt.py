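"""Degeneracy classification, site-class maps, DAF and the MKT family."""

import numpy as np
import pytest
from Bio.Seq import Seq

from varwin.io import GeneModel
from varwin.mkt import (
    ClassCounts,
    MKTCounts,
    build_site_class_map,
    classify_coding_degeneracy,
    daf_spectrum,
    integrative_mkt,
    mkt_counts,
    standard_mkt,
)

from conftest import make_panel


class TestDegeneracy:
    def test_fourfold_example(self):
        assert classify_coding_degeneracy("GGG", 2) == "fourfold"

    def test_zerofold_examples(self):
        assert classify_coding_degeneracy("ATG", 0) == "zerofold"
        # TGA is a stop: a change to stop counts as non-synonymous
        assert classify_coding_degeneracy("TGG", 2) == "zerofold"

    def test_ambiguous_base_excluded(self):
        assert classify_coding_degeneracy("ANG", 1) == "excluded"

    def test_full_enumeration_against_genetic_code_oracle(self):
        """All 64 codons x 3 positions versus a Biopython-translation oracle."""
        bases = "ACGT"
        for c1 in bases:
            for c2 in bases:
                for c3 in bases:
                    codon = c1 + c2 + c3
                    aa = str(Seq(codon).translate())
                    for pos in range(3):
                        syn = sum(
                            str(Seq(codon[:pos] + b + codon[pos + 1:]).translate()) == aa
                            for b in bases if b != codon[pos]
                        )
                        expect = {3: "fourfold", 0: "zerofold"}.get(syn, "other")
                        assert classify_coding_degeneracy(codon, pos) == expect, codon


def simple_gene(strand="+", flank=50):
    # exon [100,160) = 5'UTR [100,110) + CDS [110,140); exon2 [200,260)
    # = CDS [200,230) + 3'UTR [230,260); intron [160,200)
    utr_a, utr_b = ([(100, 110)], [(230, 260)])
    if strand == "-":
        utr_a, utr_b = ([(230, 260)], [(100, 110)])
    return GeneModel(
        gene_id="g1", transcript_id="g1.t1", chromosome="chr1", strand=strand,
        exons=[(100, 160), (200, 260)], cds=[(110, 140), (200, 230)],
        utr5=utr_a, utr3=utr_b, flank_size=flank,
    )


def reference_for(gene, length=400, seed=0):
    rng = np.random.default_rng(seed)
    ref = rng.choice(list("ACGT"), size=length)
    # stop-free CDS: repeat CTG (Leu) and end with TAA on the coding strand
    cds_pos = [p for s, e in sorted(gene.cds) for p in range(s, e)]
    codons = "CTG" * (len(cds_pos) // 3 - 1) + "TAA"
    seq = codons
    if gene.strand == "-":
        from varwin.mkt import revcomp
        seq = revcomp(seq)
    for p, b in zip(cds_pos, seq):
        ref[p] = b
    return "".join(ref)


class TestSiteClassMap:
    def test_layout_classes(self):
        gene = simple_gene()
        cmap = build_site_class_map(gene, reference_for(gene))
        assert cmap.start == 50 and cmap.end == 310
        assert set(cmap.class_at(np.arange(50, 100))) == {"intergenic_flank"}
        assert set(cmap.class_at(np.arange(100, 110))) == {"utr5"}
        assert set(cmap.class_at(np.arange(160, 200))) == {"intron"}
        assert set(cmap.class_at(np.arange(230, 260))) == {"utr3"}
        # CTG codons: position 0 is two-fold (TTG=Leu), 1 zero-fold, 2 four-fold
        assert cmap.class_at(np.array([110]))[0] == "other"
        assert cmap.class_at(np.array([111]))[0] == "zerofold"
        assert cmap.class_at(np.array([112]))[0] == "fourfold"

    def test_minus_strand_degeneracy_on_reverse_complement(self):
        gene = simple_gene(strand="-")
        cmap = build_site_class_map(gene, reference_for(gene))
        # coding order runs right-to-left: genomic 229 is codon position 0
        assert cmap.class_at(np.array([229]))[0] == "other"
        assert cmap.class_at(np.array([228]))[0] == "zerofold"
        assert cmap.class_at(np.array([227]))[0] == "fourfold"

    def test_flank_overlapping_neighbor_transcript_excluded(self):
        gene = simple_gene()
        other = GeneModel("g2", "g2.t1", "chr1", "+", exons=[(0, 80)], cds=[])
        cmap = build_site_class_map(gene, reference_for(gene), other_genes=[other])
        assert set(cmap.class_at(np.arange(50, 80))) == {"excluded"}
        assert set(cmap.class_at(np.arange(80, 100))) == {"intergenic_flank"}

    def test_internal_stop_withholds_coding_classes(self):
        gene = simple_gene()
        ref = list(reference_for(gene))
        ref[110:113] = list("TAA")  # first codon becomes a stop
        cmap = build_site_class_map(gene, "".join(ref))
        assert cmap.coding_withheld
        assert set(cmap.class_at(np.arange(110, 140))) == {"excluded"}


class TestDafSpectrum:
    def test_single_site_bin_placement(self):
        # 7/20 derived -> frequency 0.35 -> bin index 3 of 10
        cols = [[1] * 7 + [0] * 13]
        p = make_panel(cols, positions=[5])
        spec = daf_spectrum(p, np.array([5]), bins=10)
        assert spec[3] == 1.0 and spec.sum() == pytest.approx(1.0)

    def test_normalization(self):
        p = make_panel([[1, 0, 0, 0], [1, 1, 1, 0]], positions=[5, 15])
        spec = daf_spectrum(p, np.array([5, 15]))
        assert spec.sum() == pytest.approx(1.0)

    def test_neutral_fixture_is_rare_skewed(self):
        from varwin.sim import FixtureSpec, simulate_panel

        sim = simulate_panel(FixtureSpec(seed=9, genome_length=50_000,
                                         accessible_fraction=1.0, n_genes=0,
                                         theta=0.005))
        spec = daf_spectrum(sim.panel, sim.panel.positions, bins=10)
        assert spec[0] > spec[4] > 0  # 1/i shape: rare alleles dominate


class TestStandardMkt:
    def test_hand_arithmetic_table(self):
        c = MKTCounts(
            test=ClassCounts("zerofold", m=100, P=2, P_low=0, P_high=2, D=7),
            neutral=ClassCounts("fourfold", m=100, P=42, P_low=0, P_high=42, D=17),
        )
        alpha, _, ni, dos = standard_mkt(c)
        assert ni == pytest.approx(0.11565, abs=5e-6)
        assert alpha == pytest.approx(0.88435, abs=5e-6)
        assert dos == pytest.approx(0.24621, abs=5e-6)

    def test_neutral_table_gives_zero(self):
        c = MKTCounts(
            test=ClassCounts("zerofold", m=100, P=10, P_low=0, P_high=10, D=5),
            neutral=ClassCounts("fourfold", m=100, P=20, P_low=0, P_high=20, D=10),
        )
        alpha, _, ni, dos = standard_mkt(c)
        assert alpha == pytest.approx(0.0) and dos == pytest.approx(0.0)

    def test_zero_denominator_gives_missing(self):
        c = MKTCounts(
            test=ClassCounts("zerofold", m=100, P=2, D=7),
            neutral=ClassCounts("fourfold", m=100, P=0, D=17),
        )
        alpha, _, ni, _ = standard_mkt(c)
        assert ni is None and alpha is None


class TestIntegrativeMkt:
    WORKED = MKTCounts(
        test=ClassCounts("zerofold", m=1000, P=80, P_low=50, P_high=30, D=40,
                         pi=0.08, K=0.04),
        neutral=ClassCounts("fourfold", m=1000, P=100, P_low=30, P_high=70, D=60,
                            pi=0.10, K=0.06),
    )

    def test_worked_example(self):
        r = integrative_mkt(self.WORKED)
        assert r.f == pytest.approx(0.4286, abs=5e-5)
        assert r.b == pytest.approx(0.3714, abs=5e-5)
        assert r.d == pytest.approx(0.2000, abs=5e-5)
        assert r.alpha_cor == pytest.approx(0.3571, abs=5e-5)
        assert r.alpha_std == pytest.approx(-0.2, abs=1e-9)

    def test_fraction_identity_and_gamma_split(self):
        r = integrative_mkt(self.WORKED)
        assert r.d + r.b + r.f == pytest.approx(1.0)
        assert r.f_old + r.gamma == pytest.approx(r.f)

    def test_no_low_frequency_excess_collapses_to_standard(self):
        c = MKTCounts(
            test=ClassCounts("zerofold", m=500, P=40, P_low=10, P_high=30, D=30),
            neutral=ClassCounts("fourfold", m=500, P=80, P_low=20, P_high=60, D=40),
        )
        r = integrative_mkt(c)   # P_t_low/P_t = P_s_low/P_s = 0.25
        assert r.b == pytest.approx(0.0)
        assert r.alpha_cor == pytest.approx(r.alpha_std)

    def test_alpha_cor_exceeds_alpha_std_with_deleterious_excess(self):
        r = integrative_mkt(self.WORKED)
        assert r.alpha_cor > r.alpha_std

    def test_preconditions_missing(self):
        c = MKTCounts(
            test=ClassCounts("zerofold", m=500, P=40, P_low=10, P_high=30, D=0),
            neutral=ClassCounts("fourfold", m=500, P=80, P_low=20, P_high=60, D=40),
        )
        r = integrative_mkt(c)
        assert r.f is None and r.alpha_cor is None

    def test_dos_and_alpha_share_sign(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            c = MKTCounts(
                test=ClassCounts("z", m=100, P=int(rng.integers(1, 40)),
                                 D=int(rng.integers(1, 40))),
                neutral=ClassCounts("f", m=100, P=int(rng.integers(1, 40)),
                                    D=int(rng.integers(1, 40))),
            )
            alpha, _, ni, dos = standard_mkt(c)
            if ni is not None and ni != 1.0:
                assert np.sign(alpha) == np.sign(dos)


class TestMktCounts:
    def _setup(self):
        from varwin.sim import FixtureSpec, simulate_panel

        spec = FixtureSpec(seed=4, genome_length=30_000, accessible_fraction=1.0,
                           n_samples=25, theta=0.01, n_genes=1,
                           cds_exon_length=600)
        sim = simulate_panel(spec)
        cmap = build_site_class_map(sim.genes[0], sim.reference,
                                    other_genes=sim.genes)
        return sim, cmap

    def test_maf_partition_and_exclusive_p_d(self):
        sim, cmap = self._setup()
        counts = mkt_counts(sim.panel, sim.outgroup, cmap, "zerofold",
                            mask=sim.mask)
        for cc in (counts.test, counts.neutral):
            assert cc.P == cc.P_low + cc.P_high
            assert cc.m >= cc.P
            assert cc.D >= 0
        # no site may be both polymorphic and divergent
        seg = sim.panel.positions[
            (sim.panel.alt_counts() > 0)
            & (sim.panel.alt_counts() < sim.panel.n_haplotypes)]
        assert not np.isin(sim.panel.divergence_only, seg).any()

    def test_low_maf_site_lands_in_p_low(self):
        p = make_panel([[1] + [0] * 49], positions=[5])  # MAF 0.02 at 2N=50
        from varwin.io import OutgroupTrack
        track = OutgroupTrack("chr1", 0, np.ones(10, bool),
                              np.array(list("A" * 10)),
                              np.array(list("A" * 10)))
        from varwin.mkt import SiteClassMap
        cmap = SiteClassMap("g", "chr1", 0,
                            np.array(["fourfold"] * 10, dtype="<U16"))
        from varwin.io import merge_outgroup_panel
        counts = mkt_counts(merge_outgroup_panel(p, track), track, cmap,
                            "fourfold")
        assert counts.test.P_low == 1 and counts.test.P_high == 0
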