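"""Static genome representation for restriction-site based low-pass WGS.

Ligation-mediated WGA amplifies the fragments produced by a restriction
digest (MseI, cutting at TTAA), so the representable genome is the set of
in-silico restriction fragments, weighted by the probability that a fragment
of that length survives size selection.  This module builds that static
picture: fixed-size genomic bins, their GC / N / mappability annotation, the
fragment set, and the size-selection-weighted fragment count per bin.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("scnv")

BIN_COLUMNS = [
    "chrom", "start", "end", "gc", "mappability",
    "weighted_fragments", "n_fraction", "masked",
]
FRAGMENT_COLUMNS = ["chrom", "start", "end", "length", "weight"]

#: default N-content above which a bin is masked from all statistics
DEFAULT_MAX_N_FRACTION = 0.5

_ACGT = frozenset("ACGT")


# ---------------------------------------------------------------------------
# fragment-length weighting (size selection)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthWeightFunction:
    """Weight of a restriction fragment as a function of its length.

    Models the size-selection step of the library prep: fragments outside
    ``support`` receive weight 0, fragments inside are weighted by a
    non-negative density.  The default is a log-normal density over
    [50, 3000] bp — a unimodal, right-skewed shape typical of
    size-selected restriction libraries.
    """

    func: Callable[[np.ndarray], np.ndarray]
    support: tuple[int, int] = (50, 3000)
    name: str = "custom"

    def __call__(self, lengths) -> np.ndarray:
        lengths = np.asarray(lengths, dtype=float)
        w = np.asarray(self.func(lengths), dtype=float)
        lo, hi = self.support
        w = np.where((lengths >= lo) & (lengths <= hi), w, 0.0)
        if np.any(w < 0):
            raise ValueError("length weights must be non-negative")
        return w

    @classmethod
    def lognormal(cls, meanlog: float = math.log(350.0), sdlog: float = 0.5,
                  support: tuple[int, int] = (50, 3000)) -> "LengthWeightFunction":
        def dens(x: np.ndarray) -> np.ndarray:
            x = np.maximum(x, 1e-9)
            return np.exp(-((np.log(x) - meanlog) ** 2) / (2 * sdlog**2)) / (
                x * sdlog * math.sqrt(2 * math.pi))
        return cls(func=dens, support=support, name="lognormal")

    @classmethod
    def uniform(cls, support: tuple[int, int] = (0, 10**9)) -> "LengthWeightFunction":
        return cls(func=lambda x: np.ones_like(np.asarray(x, dtype=float)),
                   support=support, name="uniform")

    @classmethod
    def from_table(cls, lengths: np.ndarray, weights: np.ndarray) -> "LengthWeightFunction":
        """Tabulated length→weight map with nearest-neighbour lookup."""
        lengths = np.asarray(lengths, dtype=float)
        weights = np.asarray(weights, dtype=float)
        order = np.argsort(lengths)
        lengths, weights = lengths[order], weights[order]

        def lookup(x: np.ndarray) -> np.ndarray:
            idx = np.clip(np.searchsorted(lengths, x), 0, len(lengths) - 1)
            left = np.clip(idx - 1, 0, len(lengths) - 1)
            use_left = np.abs(lengths[left] - x) < np.abs(lengths[idx] - x)
            return weights[np.where(use_left, left, idx)]

        return cls(func=lookup, support=(int(lengths[0]), int(lengths[-1])),
                   name="table")


# ---------------------------------------------------------------------------
# in-silico digestion
# ---------------------------------------------------------------------------

def find_motif_occurrences(sequence: str, motif: str) -> np.ndarray:
    """Start positions of every (possibly overlapping) forward-strand
    occurrence of ``motif`` in the uppercased ``sequence``."""
    if not motif:
        raise ValueError("motif must be non-empty")
    if set(motif.upper()) - _ACGT:
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    seq = sequence.upper()
    motif = motif.upper()
    hits = []
    pos = seq.find(motif)
    while pos != -1:
        hits.append(pos)
        pos = seq.find(motif, pos + 1)  # +1, not +len: overlap-aware
    return np.asarray(hits, dtype=np.int64)


def digest_genome(sequences: Mapping[str, str], site: str = "TTAA",
                  cut_offset: int = 1,
                  length_weight: LengthWeightFunction | None = None,
                  ) -> pd.DataFrame:
    """In-silico restriction digestion of a set of named sequences.

    Cut positions are ``occurrence_start + cut_offset`` for every motif
    occurrence; fragments are the intervals between consecutive cuts plus
    the two terminal intervals, so fragments tile each sequence exactly.
    MseI cuts T^TAA, hence the defaults ``site="TTAA", cut_offset=1``.

    Returns a fragment table (chrom, start, end, length, weight).
    """
    if not (0 <= cut_offset <= len(site)):
        raise ValueError("cut_offset must lie within the motif")
    if length_weight is None:
        length_weight = LengthWeightFunction.lognormal()
    records: list[pd.DataFrame] = []
    for chrom, seq in sequences.items():
        n = len(seq)
        if n == 0:
            continue
        cuts = find_motif_occurrences(seq, site) + cut_offset
        cuts = cuts[(cuts > 0) & (cuts < n)]
        bounds = np.concatenate([[0], cuts, [n]])
        starts = bounds[:-1]
        ends = bounds[1:]
        records.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "length": ends - starts,
        }))
    if not records:
        frags = pd.DataFrame(columns=FRAGMENT_COLUMNS)
        return frags.astype({"start": np.int64, "end": np.int64,
                             "length": np.int64, "weight": float},
                            errors="ignore")
    frags = pd.concat(records, ignore_index=True)
    frags["weight"] = length_weight(frags["length"].to_numpy())
    return frags


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def make_bins(chrom_lengths: Mapping[str, int], bin_size: int) -> pd.DataFrame:
    """Fixed-size non-overlapping bins; trailing partial bins are dropped.

    Keeping only complete bins means every retained bin has identical
    length, so no per-bin length correction is needed downstream.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        n_bins = int(length) // int(bin_size)
        if n_bins == 0:
            logger.warning("chromosome %s shorter than one bin (%d < %d)",
                           chrom, length, bin_size)
            continue
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + bin_size,
        }))
    if not rows:
        bins = pd.DataFrame(columns=BIN_COLUMNS)
    else:
        bins = pd.concat(rows, ignore_index=True)
        bins["gc"] = np.nan
        bins["mappability"] = np.nan
        bins["weighted_fragments"] = 0.0
        bins["n_fraction"] = 0.0
        bins["masked"] = False
    return bins


def validate_bins(bins: pd.DataFrame) -> int:
    """Check sortedness / contiguity / constant size; return the bin size."""
    sizes = (bins["end"] - bins["start"]).unique()
    if len(sizes) != 1:
        raise ValueError("bins must all have the same size")
    for _, grp in bins.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        if np.any(np.diff(starts) != sizes[0]) or (len(starts) and starts[0] != 0):
            raise ValueError("bins must be sorted, contiguous and start at 0 "
                             "within each chromosome")
    return int(sizes[0])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _base_counts(seq: str) -> tuple[int, int, int]:
    """(gc, acgt, n) counts for an uppercase-insensitive sequence slice."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    g = int(np.count_nonzero(arr == ord("G")))
    c = int(np.count_nonzero(arr == ord("C")))
    a = int(np.count_nonzero(arr == ord("A")))
    t = int(np.count_nonzero(arr == ord("T")))
    n = len(arr) - (a + c + g + t)
    return g + c, a + c + g + t, n


def annotate_bins(bins: pd.DataFrame, sequences: Mapping[str, str],
                  mappability: pd.DataFrame | None = None,
                  max_n_fraction: float = DEFAULT_MAX_N_FRACTION) -> pd.DataFrame:
    """Annotate bins with GC fraction, N fraction and mean mappability.

    gc is (G+C)/(A+C+G+T) over the bin (NaN if no determined base);
    n_fraction counts every non-ACGT base; mappability is the
    length-weighted mean of the track value over the bin, positions absent
    from the track counting as 0.  When no track is supplied mappability
    defaults to 1.0 (every position assumed uniquely alignable).  Bins with
    n_fraction above ``max_n_fraction`` are masked.
    """
    bins = bins.reset_index(drop=True).copy()
    gc = np.full(len(bins), np.nan)
    nf = np.zeros(len(bins))
    for chrom, grp in bins.groupby("chrom", sort=False):
        if chrom not in sequences:
            raise ValueError(f"no sequence for chromosome {chrom}")
        seq = sequences[chrom]
        if grp["end"].max() > len(seq):
            raise ValueError(
                f"bin beyond end of sequence {chrom} "
                f"({grp['end'].max()} > {len(seq)})")
        for idx, start, end in zip(grp.index, grp["start"], grp["end"]):
            gc_n, acgt, n = _base_counts(seq[start:end])
            gc[idx] = gc_n / acgt if acgt > 0 else np.nan
            nf[idx] = n / (end - start)
    bins["gc"] = gc
    bins["n_fraction"] = nf
    bins["mappability"] = (np.ones(len(bins)) if mappability is None
                           else _mean_track_over_bins(bins, mappability))
    bins["masked"] = bins["n_fraction"] > max_n_fraction
    return bins


def _mean_track_over_bins(bins: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Length-weighted mean of an interval-value track over each bin.

    ``track`` columns: chrom, start, end, value (bedGraph dialect,
    0-based half-open).  Missing positions contribute value 0.
    """
    out = np.zeros(len(bins))
    for chrom, grp in bins.groupby("chrom", sort=False):
        t = track[track["chrom"] == chrom]
        if t.empty:
            continue
        bin_start = grp["start"].to_numpy()
        bin_end = grp["end"].to_numpy()
        acc = np.zeros(len(grp))
        for ts, te, val in zip(t["start"], t["end"], t["value"]):
            # overlap of one track interval with every bin of this chrom
            ov = np.minimum(bin_end, te) - np.maximum(bin_start, ts)
            np.maximum(ov, 0, out=ov)
            acc += ov * val
        out[grp.index] = acc / (bin_end - bin_start)
    return out


# ---------------------------------------------------------------------------
# weighted fragment counts per bin
# ---------------------------------------------------------------------------

def weighted_fragment_count(fragments: pd.DataFrame, bins: pd.DataFrame,
                            length_weight: LengthWeightFunction | None = None,
                            ) -> pd.DataFrame:
    """Sum of size-selection weights of the fragments assigned to each bin.

    A fragment belongs to the single bin containing its midpoint;
    fragments whose midpoint falls beyond the last complete bin of a
    chromosome (dropped partial-bin territory) are ignored.  When a
    ``length_weight`` is given it overrides the weights stored on the
    fragment table.
    """
    bins = bins.reset_index(drop=True).copy()
    bin_size = validate_bins(bins)
    weights_col = pd.Series(
        length_weight(fragments["length"].to_numpy())
        if length_weight is not None
        else fragments["weight"].to_numpy(dtype=float),
        index=fragments.index)
    n_bins_per_chrom = bins.groupby("chrom", sort=False).size()
    offsets = {}
    off = 0
    for chrom, n in n_bins_per_chrom.items():
        offsets[chrom] = off
        off += int(n)
    total = np.zeros(len(bins))
    for chrom, grp in fragments.groupby("chrom", sort=False):
        if chrom not in offsets:
            continue
        nb = int(n_bins_per_chrom[chrom])
        mid = ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2)
        idx = mid // bin_size
        keep = idx < nb
        np.add.at(total, offsets[chrom] + idx[keep],
                  weights_col.loc[grp.index].to_numpy()[keep])
    bins["weighted_fragments"] = total
    return bins
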