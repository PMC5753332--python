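import numpy as np
import pytest

from varwin.io import HaplotypePanel
from varwin.windowing import GenomicWindow


def make_panel(columns, anc=None, positions=None, chromosome="chr1"):
    """Build a tiny panel from per-site haplotype columns.

    ``columns`` is a list of site columns (each a 0/1 sequence over the 2N
    haplotypes); sites default to positions 5, 15, 25, ...
    """
    h = np.array(columns, dtype=np.uint8).T
    n_hap, n_sites = h.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = np.arange(n_sites) * 10 + 5
    samples = [f"s{i}" for i in range(n_hap // 2)]
    return HaplotypePanel(
        chromosome=chromosome,
        positions=np.asarray(positions, dtype=np.int64),
        haplotypes=h,
        ref=np.full(n_sites, "A", dtype="<U1"),
        alt=np.full(n_sites, "G", dtype="<U1"),
        ancestral_state=np.array(anc if anc is not None else ["ref"] * n_sites,
                                 dtype="<U7"),
        sample_ids=samples,
        population_of={s: "POP1" for s in samples},
    )


def window(start=0, end=10_000, scheme="fully_accessible_10kb", accessible=None):
    return GenomicWindow("chr1", start, end,
                         accessible if accessible is not None else end - start,
                         scheme)


def random_panel(rng, n_hap=None, n_sites=None):
    """Random segregating panel for oracle-equivalence checks."""
    n_hap = n_hap or int(rng.integers(2, 5)) * 2
    n_sites = n_sites if n_sites is not None else int(rng.integers(2, 21))
    cols = []
    for _ in range(n_sites):
        while True:
            c = rng.integers(0, 2, size=n_hap)
            if 0 < c.sum() < n_hap:
                break
        cols.append(c)
    anc = rng.choice(["ref", "alt"], size=n_sites)
    return make_panel(cols, anc=list(anc))


@pytest.fixture
def small_sim():
    from varwin.sim import FixtureSpec, simulate_panel

    return simulate_panel(FixtureSpec(seed=42))
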