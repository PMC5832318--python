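"""Synthetic data with the representation biases the workflow assumes.

Two levels of realism:

* sequence level — :func:`simulate_reference` writes actual sequences with
  a smooth GC landscape and TTAA restriction sites planted at a rate that
  decreases with GC (the natural expectation for an A/T motif), so
  digestion, binning, annotation and read counting can be exercised
  end to end on small genomes;
* bin level — :func:`simulate_bin_table` fabricates an annotated bin table
  directly (GC landscape, mappability, weighted fragment counts) so that
  genome-scale experiments run in seconds without generating gigabases.

Per-bin expected read weight is
``copy_number x weighted_fragments x gc_bias(gc) x mappability``;
counts are multinomial over bins given a total read budget, optionally
over-dispersed by a per-bin Gamma multiplier.  Everything is driven by a
single :class:`numpy.random.Generator`, so a fixed seed reproduces output
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import BIN_COLUMNS, find_motif_occurrences
from .read_counting import CountVector, READ_COLUMNS

DEFAULT_DISPERSION = 0.1


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic low-pass single-cell experiment.

    Defaults mirror the control-cell setting of the workflow: 500-kb bins,
    ~500k reads per cell, mild over-dispersion beyond multinomial noise,
    and a unimodal GC bias peaking near GC 0.45.
    """

    n_chroms: int = 4
    chrom_length: int = 125_000_000
    bin_size: int = 500_000
    gc_low: float = 0.3
    gc_high: float = 0.7
    cn_profile: tuple = ()              # (chrom, start, end, copy_number)
    main_ploidy: int = 2
    total_reads: int = 500_000
    dispersion: float = DEFAULT_DISPERSION
    gc_bias_strength: float = 1.0       # 0 disables the amplification bias
    low_mapp_fraction: float = 0.02
    seed: int = 0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


# ---------------------------------------------------------------------------
# bias models
# ---------------------------------------------------------------------------

def site_density(gc: np.ndarray) -> np.ndarray:
    """Expected TTAA sites per bp in iid sequence of the given GC content:
    ((1-gc)/2)^4 — monotonically decreasing in GC."""
    gc = np.asarray(gc, dtype=float)
    return ((1.0 - gc) / 2.0) ** 4


_GC_BIAS_SUPPORT = (0.15, 0.85)
_GC_BIAS_AB = (3.5, 4.6)  # Beta shape; mode near GC 0.45


def gc_bias(gc: np.ndarray, strength: float = 1.0) -> np.ndarray:
    """Unimodal amplification efficiency, Beta-shaped with mode ~0.45.

    ``strength`` interpolates between no bias (0) and the full curve (1).
    """
    gc = np.asarray(gc, dtype=float)
    lo, hi = _GC_BIAS_SUPPORT
    z = np.clip((gc - lo) / (hi - lo), 1e-6, 1 - 1e-6)
    a, b = _GC_BIAS_AB
    curve = stats.beta.pdf(z, a, b)
    curve = curve / stats.beta.pdf((a - 1) / (a + b - 2), a, b)
    curve = np.maximum(curve, 0.05)
    return 1.0 + strength * (curve - 1.0)


def _gc_landscape(n_bins: int, rng: np.random.Generator,
                  lo: float, hi: float) -> np.ndarray:
    """Smooth per-bin GC track: sum of two random-phase sinusoids plus a
    little white noise, clipped to [lo, hi]."""
    i = np.arange(n_bins)
    mid, amp = (lo + hi) / 2, (hi - lo) / 2
    p1, p2 = rng.uniform(0, 2 * np.pi, 2)
    f1 = rng.uniform(0.5, 1.5) / max(n_bins, 1) * 6
    f2 = rng.uniform(0.5, 1.5) / max(n_bins, 1) * 23
    track = (mid + 0.55 * amp * np.sin(2 * np.pi * f1 * i + p1)
             + 0.3 * amp * np.sin(2 * np.pi * f2 * i + p2)
             + rng.normal(0, 0.01, n_bins))
    return np.clip(track, lo, hi)


# ---------------------------------------------------------------------------
# bin-level genome
# ---------------------------------------------------------------------------

def simulate_bin_table(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fabricate an annotated bin table without generating sequence."""
    rng = rng or np.random.default_rng(config.seed)
    rows = []
    for chrom in config.chrom_names():
        n_bins = config.chrom_length // config.bin_size
        starts = np.arange(n_bins, dtype=np.int64) * config.bin_size
        gc = _gc_landscape(n_bins, rng, config.gc_low, config.gc_high)
        n_frags = rng.poisson(site_density(gc) * config.bin_size)
        mapp = np.clip(1.0 - np.abs(rng.normal(0, 0.008, n_bins)), 0.0, 1.0)
        low = rng.random(n_bins) < config.low_mapp_fraction
        mapp[low] = rng.uniform(0.2, 0.8, int(low.sum()))
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": starts + config.bin_size, "gc": gc,
            "mappability": mapp,
            "weighted_fragments": n_frags * 0.5,
            "n_fraction": 0.0, "masked": False,
        }))
    return pd.concat(rows, ignore_index=True)[BIN_COLUMNS]


def copy_number_per_bin(config: SimulationConfig,
                        bins: pd.DataFrame) -> np.ndarray:
    """Ground-truth copy number of each bin: the main ploidy, overridden
    where the bin midpoint falls inside a cn_profile interval."""
    cn = np.full(len(bins), config.main_ploidy, dtype=float)
    mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
    chroms = bins["chrom"].to_numpy()
    for chrom, start, end, value in config.cn_profile:
        sel = (chroms == chrom) & (mid >= start) & (mid < end)
        cn[sel] = value
    return cn


# ---------------------------------------------------------------------------
# cell counts
# ---------------------------------------------------------------------------

def expected_bin_weights(config: SimulationConfig, bins: pd.DataFrame,
                         cn: np.ndarray | None = None) -> np.ndarray:
    if cn is None:
        cn = copy_number_per_bin(config, bins)
    lam = (np.asarray(cn, dtype=float)
           * bins["weighted_fragments"].to_numpy(dtype=float)
           * gc_bias(bins["gc"].to_numpy(), config.gc_bias_strength)
           * bins["mappability"].to_numpy(dtype=float))
    return lam


def simulate_cell_counts(config: SimulationConfig, bins: pd.DataFrame,
                         rng: np.random.Generator | None = None,
                         cn: np.ndarray | None = None,
                         total_reads: int | None = None,
                         dispersion: float | None = None) -> CountVector:
    """Multinomial per-bin counts with optional Gamma over-dispersion."""
    rng = rng or np.random.default_rng(config.seed)
    total = config.total_reads if total_reads is None else int(total_reads)
    disp = config.dispersion if dispersion is None else float(dispersion)
    lam = expected_bin_weights(config, bins, cn)
    if lam.sum() <= 0:
        raise ValueError("all expected bin weights are zero")
    if disp > 0:
        lam = lam * rng.gamma(shape=1.0 / disp**2, scale=disp**2,
                              size=len(lam))
    counts = rng.multinomial(total, lam / lam.sum())
    return CountVector(counts=counts.astype(np.int64),
                       total_assigned=total, total_discarded=0)


def thin_counts(counts: CountVector, rate: float,
                rng: np.random.Generator) -> CountVector:
    """Binomial thinning: keep each read independently with probability
    ``rate`` (commutes with counting a smaller simulation)."""
    thinned = rng.binomial(counts.counts, rate)
    return CountVector(counts=thinned.astype(np.int64),
                       total_assigned=int(thinned.sum()),
                       total_discarded=0)


def emit_reads(bins: pd.DataFrame, counts: CountVector,
               rng: np.random.Generator, read_length: int = 100,
               mapq: int = 60) -> pd.DataFrame:
    """Fixed-length reads placed uniformly inside each bin, one per count."""
    chroms, starts = [], []
    bstart = bins["start"].to_numpy()
    bend = bins["end"].to_numpy()
    bchrom = bins["chrom"].to_numpy()
    for i, c in enumerate(counts.counts):
        if c == 0:
            continue
        hi = max(bend[i] - read_length, bstart[i] + 1)
        pos = rng.integers(bstart[i], hi, size=int(c))
        chroms.extend([bchrom[i]] * int(c))
        starts.extend(pos.tolist())
    starts = np.asarray(starts, dtype=np.int64)
    return pd.DataFrame({
        "chrom": chroms, "start": starts, "end": starts + read_length,
        "mapq": mapq})[READ_COLUMNS]


def simulate_normal_panel(config: SimulationConfig, n_cells: int,
                          bad_bins: np.ndarray = (),
                          bad_factor: float = 1.6,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[pd.DataFrame, list[CountVector]]:
    """Flat-diploid panel sharing a systematic factor on ``bad_bins``.

    Returns the common bin table and one count vector per cell.  The bad
    bins emulate genome regions that misbehave identically in every
    normal cell (the signature the blacklist is built to catch).
    """
    if n_cells < 2:
        raise ValueError("a panel needs at least 2 cells")
    rng = rng or np.random.default_rng(config.seed)
    flat = replace(config, cn_profile=(), main_ploidy=2)
    bins = simulate_bin_table(flat, rng)
    lam0 = expected_bin_weights(flat, bins)
    factor = np.ones(len(bins))
    factor[np.asarray(bad_bins, dtype=int)] = bad_factor
    cells = []
    for _ in range(n_cells):
        lam = lam0 * factor
        if flat.dispersion > 0:
            lam = lam * rng.gamma(1.0 / flat.dispersion**2,
                                  flat.dispersion**2, len(lam))
        counts = rng.multinomial(flat.total_reads, lam / lam.sum())
        cells.append(CountVector(counts=counts.astype(np.int64),
                                 total_assigned=flat.total_reads,
                                 total_discarded=0))
    return bins, cells


# ---------------------------------------------------------------------------
# aggregation across resolutions
# ---------------------------------------------------------------------------

def aggregate_bins(bins: pd.DataFrame, counts: CountVector, factor: int,
                   ) -> tuple[pd.DataFrame, CountVector]:
    """Merge blocks of ``factor`` consecutive bins into coarser bins.

    GC and mappability average, fragment weights and counts add, trailing
    incomplete blocks drop; a coarse bin is masked when more than half of
    its atoms are.  Lets one simulation serve several resolutions.
    """
    if factor == 1:
        return bins, counts
    rows = []
    agg_counts = []
    c = counts.counts
    for chrom, grp in bins.groupby("chrom", sort=False):
        n_blocks = len(grp) // factor
        if n_blocks == 0:
            continue
        idx = grp.index.to_numpy()[:n_blocks * factor]
        block = lambda col: grp[col].to_numpy()[:n_blocks * factor].reshape(
            n_blocks, factor)
        starts = block("start")[:, 0]
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": block("end")[:, -1],
            "gc": block("gc").mean(axis=1),
            "mappability": block("mappability").mean(axis=1),
            "weighted_fragments": block("weighted_fragments").sum(axis=1),
            "n_fraction": block("n_fraction").mean(axis=1),
            "masked": block("masked").sum(axis=1) > factor / 2,
        }))
        agg_counts.append(c[idx].reshape(n_blocks, factor).sum(axis=1))
    out_bins = pd.concat(rows, ignore_index=True)[BIN_COLUMNS]
    out_counts = np.concatenate(agg_counts)
    return out_bins, CountVector(counts=out_counts.astype(np.int64),
                                 total_assigned=int(out_counts.sum()),
                                 total_discarded=0)


# ---------------------------------------------------------------------------
# sequence-level genome
# ---------------------------------------------------------------------------

def _random_sequence(length: int, gc: float,
                     rng: np.random.Generator) -> np.ndarray:
    gc = float(np.clip(gc, 0.02, 0.95))
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                      size=length, p=p)


def _repair_accidental_sites(seq: np.ndarray, planted: set,
                             site: str = "TTAA", max_passes: int = 20) -> None:
    """Mutate away motif occurrences not in ``planted`` (in place)."""
    motif = site.encode("ascii")
    for _ in range(max_passes):
        text = seq.tobytes().decode("ascii")
        hits = [h for h in find_motif_occurrences(text, site)
                if h not in planted]
        if not hits:
            return
        for h in hits:
            # swap the final A for T: keeps A+T content, kills the site
            seq[h + len(motif) - 1] = ord("T")
    raise RuntimeError("could not eliminate accidental restriction sites")


def simulate_reference(config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[dict, pd.DataFrame, dict]:
    """Sequence-level genome with a GC landscape and planted TTAA sites.

    Returns ``(sequences, true_bins, planted_sites)`` where ``true_bins``
    carries the target GC per bin and ``planted_sites`` maps chromosome to
    the sorted planted site positions.  Site rate decreases with GC
    (:func:`site_density`), reproducing the anticorrelation between
    restriction-fragment density and GC content.  Intended for small
    genomes; use :func:`simulate_bin_table` at scale.
    """
    rng = rng or np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    planted_all: dict[str, np.ndarray] = {}
    rows = []
    site = "TTAA"
    slen = len(site)
    for chrom in config.chrom_names():
        n_bins = config.chrom_length // config.bin_size
        length = n_bins * config.bin_size
        seq = np.empty(length, dtype=np.uint8)
        planted: list[int] = []
        gc_track = _gc_landscape(n_bins, rng, config.gc_low, config.gc_high)
        for b in range(n_bins):
            lo = b * config.bin_size
            gc = float(gc_track[b])
            n_sites = rng.poisson(site_density(gc) * config.bin_size)
            # non-overlapping site positions within the bin
            slots = np.arange(0, config.bin_size - slen, slen)
            n_sites = min(n_sites, len(slots))
            pos = lo + np.sort(rng.choice(slots, size=n_sites, replace=False))
            # spacer GC compensates for the A/T bases of planted sites
            frac_planted = n_sites * slen / config.bin_size
            gc_spacer = min(gc / max(1 - frac_planted, 1e-6), 0.95)
            seq[lo:lo + config.bin_size] = _random_sequence(
                config.bin_size, gc_spacer, rng)
            for p in pos:
                seq[p:p + slen] = np.frombuffer(site.encode(), dtype=np.uint8)
            planted.extend(pos.tolist())
            rows.append({"chrom": chrom, "start": lo,
                         "end": lo + config.bin_size, "gc_target": gc,
                         "n_planted_sites": n_sites})
        _repair_accidental_sites(seq, set(planted), site=site)
        sequences[chrom] = seq.tobytes().decode("ascii")
        planted_all[chrom] = np.asarray(sorted(planted), dtype=np.int64)
    return sequences, pd.DataFrame(rows), planted_all
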