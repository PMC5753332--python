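"""EHH curves, iHH integration, iHS/XP-EHH scans and window summaries."""

import math

import numpy as np
import pytest

from varwin import hapscan
from varwin.sim import FixtureSpec, inject_sweep, simulate_panel
from varwin.windowing import GenomicWindow

from conftest import make_panel


class TestEhhCurve:
    def test_identical_carriers_stay_at_one(self):
        p = make_panel([[1, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]],
                       positions=[10, 20, 30])
        curve = hapscan.ehh_curve(p, 0, "derived", "right")
        assert [e for _, e in curve] == [1.0, 1.0, 1.0]

    def test_two_carriers_split_drops_to_zero(self):
        p = make_panel([[1, 1, 0, 0], [1, 0, 0, 0]], positions=[10, 20])
        curve = hapscan.ehh_curve(p, 0, "derived", "right")
        assert curve == [(10, 1.0), (20, 0.0)]

    def test_four_carriers_two_two_split(self):
        p = make_panel([[1, 1, 1, 1, 0, 0], [1, 1, 0, 0, 0, 0]],
                       positions=[10, 20])
        curve = hapscan.ehh_curve(p, 0, "derived", "right")
        assert curve[1] == (20, pytest.approx(2 / 6))

    def test_monotone_nonincreasing_and_bounded(self):
        sim = simulate_panel(FixtureSpec(seed=5, genome_length=20_000,
                                         accessible_fraction=1.0, n_genes=0,
                                         theta=0.002))
        p = sim.panel
        alt = p.alt_counts()
        core = int(np.argmax((alt >= 4) & (alt <= p.n_haplotypes - 4)))
        for direction in ("left", "right"):
            curve = hapscan.ehh_curve(p, core, "derived", direction)
            vals = [e for _, e in curve]
            assert all(0.0 <= v <= 1.0 for v in vals)
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_single_carrier_rejected(self):
        p = make_panel([[1, 0, 0, 0]])
        with pytest.raises(ValueError, match="carriers"):
            hapscan.ehh_curve(p, 0, "derived", "right")


class TestIntegratedEhh:
    def test_rectangle_plus_triangle(self):
        ihh, flag = hapscan.integrated_ehh([(0, 1.0), (10_000, 1.0), (12_000, 0.0)])
        assert ihh == pytest.approx(10_000 + 0.5 * 2_000)
        assert flag == "passed"

    def test_large_gap_truncates(self):
        ihh, flag = hapscan.integrated_ehh([(0, 1.0), (25_000, 0.5)])
        assert flag == "truncated" and ihh == 0.0

    def test_cutoff_one_gives_zero(self):
        ihh, _ = hapscan.integrated_ehh([(0, 1.0), (100, 0.9)], cutoff=1.01)
        assert ihh == 0.0

    def test_never_reaching_cutoff_flags_truncated(self):
        _, flag = hapscan.integrated_ehh([(0, 1.0), (1_000, 0.9)])
        assert flag == "truncated"


class TestIhsScan:
    def test_symmetric_alleles_give_zero_score(self):
        # derived and ancestral carriers decay identically by symmetry
        p = make_panel([
            [1, 1, 0, 0],   # core, 2/2
            [1, 0, 1, 0],   # both groups split
            [1, 0, 1, 0],
        ], positions=[100, 200, 300])
        s = hapscan.ihs_at_site(p, 100)
        assert s.unstandardized == pytest.approx(0.0)

    def test_sweep_core_negative_unstandardized(self):
        spec = FixtureSpec(seed=2, genome_length=60_000, accessible_fraction=1.0,
                           n_genes=0, theta=0.002, sweep_core=30_000,
                           sweep_length=20_000, sweep_carrier_fraction=0.5)
        p = inject_sweep(simulate_panel(spec).panel, spec)
        s = hapscan.ihs_at_site(p, 30_000)
        assert s.unstandardized is not None and s.unstandardized < 0

    def test_standardized_bins_have_zero_mean_unit_sd(self):
        sim = simulate_panel(FixtureSpec(seed=11, genome_length=200_000,
                                         accessible_fraction=1.0, n_genes=0,
                                         theta=0.002))
        scores = hapscan.ihs_scan(sim.panel)
        z = np.array([r.standardized for r in scores.passed()])
        assert len(z) > 50
        assert abs(z.mean()) < 1e-9
        assert z.std() == pytest.approx(1.0, abs=1e-6)

    def test_low_maf_sites_skipped(self):
        sim = simulate_panel(FixtureSpec(seed=12, genome_length=30_000,
                                         accessible_fraction=1.0, n_genes=0))
        scores = hapscan.ihs_scan(sim.panel, maf_min=0.05)
        n = sim.panel.n_haplotypes
        for r in scores.records:
            daf_count = round(r.freq * n)
            maf = min(daf_count, n - daf_count) / n
            if maf <= 0.05:
                assert r.qc_flag == "skipped"

    def test_antisymmetric_under_polarity_swap(self):
        spec = FixtureSpec(seed=3, genome_length=40_000, accessible_fraction=1.0,
                           n_genes=0, theta=0.002)
        p = simulate_panel(spec).panel
        alt = p.alt_counts()
        n = p.n_haplotypes
        core = int(np.argmax((alt >= 4) & (alt <= n - 4)))
        pos = int(p.positions[core])
        s1 = hapscan.ihs_at_site(p, pos)
        q = p.subset_region(0, 40_000)
        q.ancestral_state = q.ancestral_state.copy()
        q.ancestral_state[core] = "alt"  # flip ancestral/derived at the core
        s2 = hapscan.ihs_at_site(q, pos)
        assert s1.unstandardized == pytest.approx(-s2.unstandardized, abs=1e-12)


class TestXpEhh:
    def test_identical_panels_score_zero(self):
        sim = simulate_panel(FixtureSpec(seed=21, genome_length=40_000,
                                         accessible_fraction=1.0, n_genes=0,
                                         theta=0.002))
        p = sim.panel
        scores = hapscan.xpehh_scan(p, p)
        unstd = [r.unstandardized for r in scores.records
                 if r.unstandardized is not None]
        assert unstd and all(u == pytest.approx(0.0) for u in unstd)

    def test_sweep_in_one_population_positive_at_core(self):
        spec = FixtureSpec(seed=22, genome_length=60_000, accessible_fraction=1.0,
                           n_genes=0, theta=0.002, sweep_core=30_000,
                           sweep_length=20_000, sweep_carrier_fraction=0.8)
        sim = simulate_panel(spec)
        a = inject_sweep(sim.panel.for_population("POP1"), spec)
        b = sim.panel.for_population("POP2")
        b = b.subset_region(0, 60_000)
        # align site sets: the sweep may insert the core site into A only
        if a.n_sites != b.n_sites:
            import dataclasses
            extra = np.setdiff1d(a.positions, b.positions)
            from varwin.sim import _insert_sites, _ConstRef
            b = _insert_sites(b, extra,
                              np.zeros((b.n_haplotypes, len(extra)), np.uint8),
                              _ConstRef("A"), np.random.default_rng(0))
        scores = hapscan.xpehh_scan(a, b)
        rec = {r.position: r for r in scores.records}
        assert rec[30_000].unstandardized is not None
        assert rec[30_000].unstandardized > 0


class TestWindowSummaries:
    def _scores(self, triples):
        s = hapscan.HapScanScores(statistic="iHS")
        for pos, std in triples:
            s.records.append(hapscan.SiteScore(pos, 0.5, std, std, "passed"))
        return s

    def test_mean_absolute_value(self):
        w = GenomicWindow("chr1", 0, 10_000, 10_000, "fully_accessible_10kb")
        s = self._scores([(10, -2.0), (20, 1.5), (30, 0.5)])
        (out,) = hapscan.summarize_window_scores(s, [w])
        assert out.mean_abs_score == pytest.approx(4 / 3)
        assert out.n_snps == 3

    def test_empty_window_missing(self):
        w = GenomicWindow("chr1", 50_000, 60_000, 10_000, "fully_accessible_10kb")
        (out,) = hapscan.summarize_window_scores(self._scores([(10, 1.0)]), [w])
        assert out.mean_abs_score is None and out.n_snps == 0

    def test_single_negative_score(self):
        w = GenomicWindow("chr1", 0, 10_000, 10_000, "fully_accessible_10kb")
        (out,) = hapscan.summarize_window_scores(self._scores([(10, -1.7)]), [w])
        assert out.mean_abs_score == pytest.approx(1.7)

    def test_sign_flip_invariance(self):
        w = GenomicWindow("chr1", 0, 10_000, 10_000, "fully_accessible_10kb")
        a = self._scores([(10, -2.0), (20, 1.5)])
        b = self._scores([(10, 2.0), (20, -1.5)])
        (ra,) = hapscan.summarize_window_scores(a, [w])
        (rb,) = hapscan.summarize_window_scores(b, [w])
        assert ra.mean_abs_score == rb.mean_abs_score
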