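"""Diversity statistics and SFS neutrality tests against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from varwin import core
from varwin.io import OutgroupTrack

from conftest import make_panel, random_panel, window


def brute_pi_total(hap):
    """Mean pairwise Hamming distance over all C(2N,2) haplotype pairs."""
    n = hap.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    return sum(np.sum(hap[i] != hap[j]) for i, j in pairs) / len(pairs)


class TestSiteSpectrum:
    def test_derived_count_class(self):
        p = make_panel([[1, 1, 1, 0]])
        s = core.site_spectrum(p, window())
        assert s.xi[3] == 1 and s.S == 1

    def test_monomorphic_window_empty(self):
        p = make_panel([[0, 0, 0, 0], [1, 1, 1, 1]])
        s = core.site_spectrum(p, window())
        assert s.S == 0 and s.xi.sum() == 0

    def test_ancestral_alt_flips_polarization(self):
        p = make_panel([[1, 1, 1, 0]], anc=["alt"])
        s = core.site_spectrum(p, window())
        assert s.xi[1] == 1  # 3 alt copies, alt ancestral -> 1 derived

    def test_zero_accessible_window_is_empty(self):
        p = make_panel([[1, 0, 0, 0]])
        s = core.site_spectrum(p, window(accessible=0))
        assert s.S == 0 and s.L == 0


class TestDiversity:
    def test_pi_two_haplotypes_one_difference(self):
        p = make_panel([[0, 1]])
        d = core.diversity_stats(p, window(end=10, accessible=10))
        assert d.pi_per_site == pytest.approx(0.1)

    def test_pi_enumerated_over_pairs(self):
        p = make_panel([[1, 1, 0, 0]], positions=[0])
        d = core.diversity_stats(p, window(end=1, accessible=1))
        assert d.pi_per_site == pytest.approx(4 / 6)

    def test_jukes_cantor_closed_form(self):
        assert core.jukes_cantor(0.05) == pytest.approx(
            -0.75 * math.log(1 - 0.2 / 3))
        assert core.jukes_cantor(0.05) == pytest.approx(0.051744, abs=1e-6)
        assert core.jukes_cantor(0.8) is None  # saturation

    def test_hap_diversity_all_distinct(self):
        p = make_panel([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]])
        d = core.diversity_stats(p, window())
        assert d.hap_diversity == pytest.approx(1.0)

    def test_hap_diversity_zero_iff_identical(self):
        p = make_panel([[0, 0, 0, 0], [1, 1, 1, 1]])
        d = core.diversity_stats(p, window())
        assert d.hap_diversity == 0.0

    def test_per_site_values_translation_invariant(self):
        cols = [[1, 1, 0, 0], [1, 0, 0, 0]]
        a = core.diversity_stats(make_panel(cols, positions=[5, 15]),
                                 window(0, 1000, accessible=1000))
        b = core.diversity_stats(make_panel(cols, positions=[505, 515]),
                                 window(500, 1500, accessible=1000))
        assert a.pi_per_site == b.pi_per_site
        assert a.theta_w_per_site == b.theta_w_per_site
        assert a.S_per_site == b.S_per_site

    def test_divergence_counts_and_k(self):
        # panel: one segregating site at 2 (not divergent), outgroup differs
        # at invariant positions 0 and 5 -> divsites = 2 over L_aligned = 10
        from varwin.io import merge_outgroup_panel

        ref = "ACGTACGTAC"
        out = "TCGTAGGTAC"  # diffs at 0 and 5
        track = OutgroupTrack("chr1", 0, np.ones(10, bool),
                              np.array(list(out)), np.array(list(ref)))
        p = make_panel([[0, 1, 0, 1]], positions=[2])
        p = merge_outgroup_panel(p, track)
        d = core.diversity_stats(p, window(0, 10, accessible=10), outgroup=track)
        assert d.divsites == 2
        assert d.K_jc == pytest.approx(core.jukes_cantor(0.2))


class TestOracleEquivalence:
    def test_pi_equals_mean_pairwise_hamming(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            p = random_panel(rng)
            w = window(0, 1000, accessible=1000)
            spec = core.site_spectrum(p, w)
            assert spec.pi_total() == pytest.approx(
                brute_pi_total(p.haplotypes), abs=1e-12)

    def test_watterson_uses_harmonic_number(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = random_panel(rng)
            n = p.n_haplotypes
            a1 = sum(1 / i for i in range(1, n))
            d = core.diversity_stats(p, window(0, 1000, accessible=1000))
            assert d.theta_w_per_site == pytest.approx(p.n_sites / a1 / 1000, abs=1e-12)


class TestTajimasD:
    def test_no_segregating_sites_is_missing(self):
        p = make_panel([[0, 0, 0, 0]])
        assert core.tajimas_d(core.site_spectrum(p, window())) is None

    def test_matches_published_formula_recomputed_from_scratch(self):
        # n=4, derived counts {1,1,2}
        p = make_panel([[1, 0, 0, 0], [0, 1, 0, 0], [1, 1, 0, 0]])
        spec = core.site_spectrum(p, window())
        n, S = 4, 3
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        pi = brute_pi_total(p.haplotypes)
        expect = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert core.tajimas_d(spec) == pytest.approx(expect, abs=1e-12)

    def test_singleton_excess_more_negative_than_intermediates(self):
        singles = make_panel([[1, 0, 0, 0, 0, 0]] * 4)
        inter = make_panel([[1, 1, 1, 0, 0, 0]] * 4)
        d_s = core.tajimas_d(core.site_spectrum(singles, window()))
        d_i = core.tajimas_d(core.site_spectrum(inter, window()))
        assert d_s < d_i


class TestFuLi:
    def test_all_singletons_negative(self):
        p = make_panel([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1]])
        d, f = core.fu_li_tests(core.site_spectrum(p, window()))
        assert d < 0 and f is not None

    def test_no_singletons_positive(self):
        p = make_panel([[1, 1, 0, 0], [0, 1, 1, 0]])
        d, _ = core.fu_li_tests(core.site_spectrum(p, window()))
        assert d > 0

    def test_empty_spectrum_missing(self):
        p = make_panel([[0, 0, 0, 0]])
        assert core.fu_li_tests(core.site_spectrum(p, window())) == (None, None)


class TestFayWuZeng:
    def test_high_frequency_derived_site(self):
        p = make_panel([[1, 1, 1, 0]])
        spec = core.site_spectrum(p, window())
        assert core.fay_wu_h(spec) == pytest.approx(-1.0)
        assert spec.theta_l() == pytest.approx(1.0)

    def test_singleton_site(self):
        p = make_panel([[1, 0, 0, 0]])
        spec = core.site_spectrum(p, window())
        assert core.fay_wu_h(spec) == pytest.approx(0.5 - 1 / 6)

    def test_zeng_numerator_sign(self):
        a1 = 1 + 1 / 2 + 1 / 3
        p_high = make_panel([[1, 1, 1, 0]])
        s = core.site_spectrum(p_high, window())
        assert s.theta_l() - s.S_polarized / a1 == pytest.approx(1 - 1 / a1)
        assert core.zeng_e(s) > 0
        p_low = make_panel([[1, 0, 0, 0]])
        s = core.site_spectrum(p_low, window())
        assert core.zeng_e(s) < 0

    def test_identity_pi_plus_theta_h_equals_two_theta_l(self):
        rng = np.random.default_rng(9)
        for _ in range(40):
            p = random_panel(rng)
            p.ancestral_state[:] = "ref"  # fully polarized
            s = core.site_spectrum(p, window(0, 1000, accessible=1000))
            assert s.pi_polarized() + s.theta_h() == pytest.approx(
                2 * s.theta_l(), abs=1e-12)


def test_neutral_fixture_test_means_near_zero():
    """On neutral independent-site fixtures the SFS tests are centred on 0."""
    from varwin.sim import FixtureSpec, simulate_panel

    sums = {k: [] for k in ("D", "FLD", "FLF", "H", "E")}
    for seed in range(150):
        sim = simulate_panel(FixtureSpec(
            seed=seed, genome_length=10_000, accessible_fraction=1.0, n_genes=0))
        spec = core.site_spectrum(sim.panel, window())
        if spec.S == 0:
            continue
        c = core.sample_constants(spec.n)
        d, (fd, ff), h, e = (core.tajimas_d(spec, c), core.fu_li_tests(spec, c),
                             core.fay_wu_h(spec), core.zeng_e(spec, c))
        for key, val in zip(sums, (d, fd, ff, h, e)):
            if val is not None:
                sums[key].append(val)
    for key, vals in sums.items():
        vals = np.array(vals)
        se = vals.std() / math.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 1e-9, key
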