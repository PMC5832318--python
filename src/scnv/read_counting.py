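"""Assignment of aligned reads to genomic bins and restriction fragments.

Rules:

* bin counting — a read spanning more than one bin is assigned to the bin
  with the longest overlap (ties broken by the leftmost bin, which makes
  the result deterministic and independent of read order);
* fragment counting — a read matching more than one restriction fragment
  is discarded, since a sequenced molecule originates from exactly one
  amplified fragment.

Reads are plain reference intervals (chrom, start, end, mapq).  They can
come from a BAM file or from a minimal BED3+1 text dialect so the whole
pipeline runs without binary alignment files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import validate_bins

READ_COLUMNS = ["chrom", "start", "end", "mapq"]


@dataclass
class CountVector:
    """Per-unit (bin or fragment) integer counts with exact accounting."""

    counts: np.ndarray
    total_assigned: int
    total_discarded: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        assert int(self.counts.sum()) == self.total_assigned


def load_reads_bed(path) -> pd.DataFrame:
    """Read the BED3+1 dialect: chrom, start, end, mapq (tab-separated)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=READ_COLUMNS,
                     dtype={"chrom": str, "start": np.int64,
                            "end": np.int64, "mapq": np.int64})
    return df


def load_reads_bam(path) -> pd.DataFrame:
    """Extract aligned reference spans from a BAM/SAM file.

    Unmapped, secondary and supplementary alignments are excluded.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path)) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            rows.append((rec.reference_name, rec.reference_start,
                         rec.reference_end, rec.mapping_quality))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def load_reads(path) -> pd.DataFrame:
    p = str(path)
    if p.endswith(".bam") or p.endswith(".sam"):
        return load_reads_bam(p)
    return load_reads_bed(p)


def count_reads_in_bins(reads: pd.DataFrame, bins: pd.DataFrame,
                        min_mapq: int = 0) -> CountVector:
    """Count reads per bin with longest-overlap assignment.

    Discards (and tallies) reads below ``min_mapq``, on chromosomes absent
    from the bin table, or lying entirely in the dropped partial-bin
    territory past the last complete bin.
    """
    bin_size = validate_bins(bins)
    sizes = bins.groupby("chrom", sort=False).size()
    offsets: dict[str, int] = {}
    off = 0
    for chrom, n in sizes.items():
        offsets[chrom] = off
        off += int(n)
    counts = np.zeros(len(bins), dtype=np.int64)
    n_in = len(reads)
    assigned = 0
    for chrom, grp in reads.groupby("chrom", sort=False):
        if chrom not in offsets:
            continue
        nb = int(sizes[chrom])
        limit = nb * bin_size
        s = grp["start"].to_numpy(dtype=np.int64)
        e = grp["end"].to_numpy(dtype=np.int64)
        q = grp["mapq"].to_numpy(dtype=np.int64)
        keep = (q >= min_mapq) & (s < limit) & (e > s) & (s >= 0)
        s, e = s[keep], e[keep]
        if len(s) == 0:
            continue
        e_cl = np.minimum(e, limit)  # overlap past the last bin is not a bin
        first = s // bin_size
        last = (e_cl - 1) // bin_size
        boundary = (first + 1) * bin_size
        left_ov = boundary - s
        right_ov = e_cl - boundary
        idx = np.where(
            last == first, first,
            np.where(last > first + 1,
                     first + 1,            # a full middle bin always wins
                     np.where(left_ov >= right_ov, first, first + 1)))
        np.add.at(counts, offsets[chrom] + idx, 1)
        assigned += len(s)
    return CountVector(counts=counts, total_assigned=assigned,
                       total_discarded=n_in - assigned)


def count_reads_on_fragments(reads: pd.DataFrame,
                             fragments: pd.DataFrame) -> CountVector:
    """Count reads per restriction fragment, discarding multi-fragment reads.

    Fragments must tile each chromosome; a read is kept only when both its
    first and last covered base fall in the same fragment.
    """
    counts = np.zeros(len(fragments), dtype=np.int64)
    frag_index = pd.Series(np.arange(len(fragments)), index=fragments.index)
    n_in = len(reads)
    assigned = 0
    by_chrom = {
        chrom: (grp["start"].to_numpy(dtype=np.int64),
                int(grp["end"].iloc[-1]),
                frag_index.loc[grp.index].to_numpy())
        for chrom, grp in fragments.groupby("chrom", sort=False)
    }
    for chrom, grp in reads.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        starts, span_end, rows = by_chrom[chrom]
        s = grp["start"].to_numpy(dtype=np.int64)
        e = grp["end"].to_numpy(dtype=np.int64)
        keep = (s >= 0) & (e > s) & (e <= span_end)
        s, e = s[keep], e[keep]
        if len(s) == 0:
            continue
        f_first = np.searchsorted(starts, s, side="right") - 1
        f_last = np.searchsorted(starts, e - 1, side="right") - 1
        single = f_first == f_last
        np.add.at(counts, rows[f_first[single]], 1)
        assigned += int(single.sum())
    return CountVector(counts=counts, total_assigned=assigned,
                       total_discarded=n_in - assigned)
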