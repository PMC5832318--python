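import numpy as np
import pandas as pd
import pytest

from scnv import normalization, simulation
from scnv.genome_model import BIN_COLUMNS
from scnv.read_counting import CountVector


def make_bin_table(n_bins: int, bin_size: int = 500, chrom: str = "chr1",
                   gc=None, mappability=1.0) -> pd.DataFrame:
    starts = np.arange(n_bins, dtype=np.int64) * bin_size
    return pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + bin_size,
        "gc": 0.5 if gc is None else gc,
        "mappability": mappability,
        "weighted_fragments": 1.0, "n_fraction": 0.0, "masked": False,
    })[BIN_COLUMNS]


def make_profile(ratio, chrom="chr1", bin_size=500_000, usable=None,
                 ) -> normalization.NormalizedProfile:
    """Wrap a ratio vector into a NormalizedProfile without re-normalizing."""
    ratio = np.asarray(ratio, dtype=float)
    bins = make_bin_table(len(ratio), bin_size=bin_size, chrom=chrom)
    if usable is None:
        usable = np.ones(len(ratio), dtype=bool)
    return normalization.NormalizedProfile(
        bins=bins, raw=np.zeros(len(ratio), dtype=int),
        ratio=ratio, usable=np.asarray(usable, dtype=bool))


def simulate_aberrant_profile(seed, main_ploidy, cn_levels,
                              reads=1_000_000, n_bins=5700, n_chroms=6,
                              bin_size=500_000):
    """Genome-scale aberrant cell: random CNA blocks of the given copy
    levels over a main-ploidy background, normalized ratio profile."""
    L = (n_bins // n_chroms) * bin_size
    cnp = []
    rng_profile = np.random.default_rng(seed + 1000)
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        pos = 0
        while pos < L * 0.7:
            size = int(rng_profile.uniform(20e6, 60e6))
            level = int(rng_profile.choice(cn_levels))
            cnp.append((chrom, pos, pos + size, level))
            pos += size + int(rng_profile.uniform(10e6, 40e6))
    sim = simulation.SimulationConfig(
        n_chroms=n_chroms, chrom_length=L, bin_size=bin_size,
        main_ploidy=main_ploidy, total_reads=reads,
        cn_profile=tuple(cnp), seed=seed)
    rng = np.random.default_rng(seed)
    bins = simulation.simulate_bin_table(sim, rng)
    counts = simulation.simulate_cell_counts(sim, bins, rng=rng)
    return normalization.normalize_counts(counts, bins), sim, bins


@pytest.fixture
def rng():
    return np.random.default_rng(0)
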