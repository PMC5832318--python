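"""Segmentation-based copy-number alteration calling.

Normalized ratio profiles are segmented per chromosome by recursive binary
splitting: a split is accepted only when the residual-sum-of-squares gain
exceeds ``penalty * sigma^2 * log(n)``, with sigma estimated robustly from
the median absolute consecutive difference of the ratios.  Segment means
times the cell's main ploidy give integer copy numbers (round half away
from zero); segments whose copy number differs from the main ploidy are
candidate gains/losses.  A candidate is significant when BOTH a Wilcoxon
rank-sum test and a two-sample Kolmogorov-Smirnov test of its per-bin
ratios against all neutral bins genome-wide give p < alpha (default 0.01).
Significant calls overlapping a panel-of-normals blacklist by more than
``max_overlap`` of their length are removed as artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import Blacklist, NormalizedProfile

logger = logging.getLogger("scnv")

DEFAULT_PENALTY = 2.0
DEFAULT_MIN_SEGMENT_BINS = 3
DEFAULT_ALPHA = 0.01
DEFAULT_MAX_BLACKLIST_OVERLAP = 0.5

# sd of consecutive differences of iid normals is sigma*sqrt(2); their MAD
# is 0.6745 * sigma * sqrt(2)
_MAD_DIFF_FACTOR = 0.6744897501960817 * np.sqrt(2)


@dataclass
class Segment:
    """One piecewise-constant stretch of a copy-number profile."""

    chrom: str
    start_bin: int          # half-open indices into the usable bins of chrom
    end_bin: int
    start: int              # genomic span (bp)
    end: int
    n_bins: int             # usable bins in the segment
    mean_ratio: float
    copy_number: int = -1
    cn_class: str = "neutral"          # gain | loss | neutral
    p_wilcoxon: float = float("nan")
    p_ks: float = float("nan")
    significant: bool = False
    testable: bool = True
    blacklisted_fraction: float = 0.0
    bin_indices: np.ndarray = field(default=None, repr=False)

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class CNACallSet:
    """Significant non-neutral calls for one cell."""

    cell_id: str
    main_ploidy: int
    calls: list
    bin_size: int

    @property
    def mbp_gained(self) -> float:
        return sum(s.n_bins * self.bin_size for s in self.calls
                   if s.cn_class == "gain") / 1e6

    @property
    def mbp_lost(self) -> float:
        return sum(s.n_bins * self.bin_size for s in self.calls
                   if s.cn_class == "loss") / 1e6


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def robust_noise_sd(profile: NormalizedProfile) -> float:
    """Noise sd estimated from the median absolute consecutive difference
    of the ratio within chromosomes (insensitive to true copy steps)."""
    diffs = []
    chroms = profile.bins["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        r = profile.ratio[(chroms == chrom) & profile.usable]
        if len(r) >= 2:
            diffs.append(np.abs(np.diff(r)))
    if not diffs:
        return 0.0
    return float(np.median(np.concatenate(diffs)) / _MAD_DIFF_FACTOR)


def _best_split(x: np.ndarray) -> tuple[int | None, float]:
    """Best single split point of ``x`` and its RSS gain."""
    n = len(x)
    if n < 2:
        return None, 0.0
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    total_rss = c2[-1] - c1[-1] ** 2 / n
    k = np.arange(1, n)
    left_rss = c2[k - 1] - c1[k - 1] ** 2 / k
    right_sum = c1[-1] - c1[k - 1]
    right_sq = c2[-1] - c2[k - 1]
    right_rss = right_sq - right_sum**2 / (n - k)
    gains = total_rss - (left_rss + right_rss)
    best = int(np.argmax(gains))
    return int(k[best]), float(gains[best])


def _segment_1d(x: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Recursive binary splitting; returns sorted half-open boundaries."""
    out: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        i, j = stack.pop()
        k, gain = _best_split(x[i:j])
        if k is not None and gain > threshold:
            stack.append((i, i + k))
            stack.append((i + k, j))
        else:
            out.append((i, j))
    return sorted(out)


def _merge_short(bounds: list[tuple[int, int]], x: np.ndarray,
                 min_bins: int) -> list[tuple[int, int]]:
    """Merge segments shorter than ``min_bins`` into the neighbour whose
    mean is closest."""
    bounds = list(bounds)
    while len(bounds) > 1:
        lengths = [j - i for i, j in bounds]
        short = [idx for idx, ln in enumerate(lengths) if ln < min_bins]
        if not short:
            break
        idx = min(short, key=lambda t: lengths[t])
        i, j = bounds[idx]
        mean = x[i:j].mean()
        cands = []
        if idx > 0:
            li, lj = bounds[idx - 1]
            cands.append((abs(x[li:lj].mean() - mean), idx - 1))
        if idx < len(bounds) - 1:
            ri, rj = bounds[idx + 1]
            cands.append((abs(x[ri:rj].mean() - mean), idx + 1))
        _, nb = min(cands)
        lo = min(bounds[idx][0], bounds[nb][0])
        hi = max(bounds[idx][1], bounds[nb][1])
        bounds[min(idx, nb)] = (lo, hi)
        del bounds[max(idx, nb)]
    return bounds


def segment_profile(profile: NormalizedProfile,
                    penalty: float = DEFAULT_PENALTY,
                    min_bins: int = DEFAULT_MIN_SEGMENT_BINS,
                    ) -> list[Segment]:
    """Piecewise-constant segmentation of the ratio, per chromosome.

    Deterministic: the same profile and parameters always give the same
    boundaries.  Chromosomes with fewer than ``min_bins`` usable bins
    yield a single segment (with a warning).
    """
    sigma = robust_noise_sd(profile)
    segments: list[Segment] = []
    chroms = profile.bins["chrom"].to_numpy()
    starts = profile.bins["start"].to_numpy()
    ends = profile.bins["end"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero((chroms == chrom) & profile.usable)
        if len(sel) == 0:
            continue
        x = profile.ratio[sel]
        n = len(x)
        if n < min_bins:
            logger.warning("chromosome %s has %d < %d usable bins; "
                           "single segment", chrom, n, min_bins)
            bounds = [(0, n)]
        else:
            threshold = penalty * sigma**2 * np.log(max(n, 2))
            bounds = _segment_1d(x, threshold)
            bounds = _merge_short(bounds, x, min_bins)
        for i, j in bounds:
            idx = sel[i:j]
            segments.append(Segment(
                chrom=str(chrom), start_bin=i, end_bin=j,
                start=int(starts[idx[0]]), end=int(ends[idx[-1]]),
                n_bins=j - i, mean_ratio=float(x[i:j].mean()),
                bin_indices=idx))
    return segments


# ---------------------------------------------------------------------------
# copy-number assignment and significance
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def assign_copy_numbers(segments: list[Segment],
                        main_ploidy: int) -> list[Segment]:
    """Integer copy number = round(mean_ratio * ploidy), floored at 0."""
    if main_ploidy < 1:
        raise ValueError("main_ploidy must be >= 1")
    out = []
    for seg in segments:
        cn = max(0, _round_half_away(seg.mean_ratio * main_ploidy))
        cls = "gain" if cn > main_ploidy else (
            "loss" if cn < main_ploidy else "neutral")
        out.append(replace(seg, copy_number=cn, cn_class=cls))
    return out


def test_segment_significance(segments: list[Segment],
                              profile: NormalizedProfile,
                              alpha: float = DEFAULT_ALPHA) -> list[Segment]:
    """Wilcoxon rank-sum + KS tests of each segment against the neutral
    background (all bins of neutral segments, genome-wide).

    Significant requires a non-neutral class AND both p-values < alpha.
    Segments with < 2 usable bins, or profiles with no neutral background,
    are marked untestable and not significant.
    """
    neutral_idx = np.concatenate(
        [s.bin_indices for s in segments if s.cn_class == "neutral"]
    ) if any(s.cn_class == "neutral" for s in segments) else np.array([], dtype=int)
    background = profile.ratio[neutral_idx]
    out = []
    for seg in segments:
        vals = profile.ratio[seg.bin_indices]
        if len(vals) < 2 or len(background) == 0:
            out.append(replace(seg, testable=False, significant=False))
            continue
        p_w = float(stats.mannwhitneyu(vals, background,
                                       alternative="two-sided").pvalue)
        p_ks = float(stats.ks_2samp(vals, background).pvalue)
        sig = seg.cn_class != "neutral" and p_w < alpha and p_ks < alpha
        out.append(replace(seg, p_wilcoxon=p_w, p_ks=p_ks,
                           significant=sig, testable=True))
    return out


def call_cnas(profile: NormalizedProfile, main_ploidy: int,
              cell_id: str = "cell",
              penalty: float = DEFAULT_PENALTY,
              min_bins: int = DEFAULT_MIN_SEGMENT_BINS,
              alpha: float = DEFAULT_ALPHA,
              ) -> tuple[list[Segment], CNACallSet]:
    """Segment, assign copy numbers, test; return (all segments, calls)."""
    segments = segment_profile(profile, penalty=penalty, min_bins=min_bins)
    segments = assign_copy_numbers(segments, main_ploidy)
    segments = test_segment_significance(segments, profile, alpha=alpha)
    bin_size = int((profile.bins["end"] - profile.bins["start"]).iloc[0])
    calls = [s for s in segments if s.significant]
    return segments, CNACallSet(cell_id=cell_id, main_ploidy=main_ploidy,
                                calls=calls, bin_size=bin_size)


# ---------------------------------------------------------------------------
# blacklist filtering
# ---------------------------------------------------------------------------

def _overlap_bp(chrom: str, start: int, end: int,
                regions: pd.DataFrame) -> int:
    r = regions[regions["chrom"] == chrom]
    if r.empty:
        return 0
    ov = (np.minimum(r["end"].to_numpy(), end)
          - np.maximum(r["start"].to_numpy(), start))
    return int(np.maximum(ov, 0).sum())


def filter_calls(callset: CNACallSet, blacklist: Blacklist,
                 max_overlap: float = DEFAULT_MAX_BLACKLIST_OVERLAP,
                 ) -> CNACallSet:
    """Drop calls whose blacklist overlap fraction exceeds ``max_overlap``
    (strictly); surviving calls carry their overlap fraction.  Idempotent."""
    kept = []
    for seg in callset.calls:
        frac = (_overlap_bp(seg.chrom, seg.start, seg.end, blacklist.regions)
                / max(seg.length_bp, 1))
        if frac > max_overlap:
            continue
        kept.append(replace(seg, blacklisted_fraction=float(frac)))
    return CNACallSet(cell_id=callset.cell_id, main_ploidy=callset.main_ploidy,
                      calls=kept, bin_size=callset.bin_size)


# ---------------------------------------------------------------------------
# multi-cell summary
# ---------------------------------------------------------------------------

def _merge_intervals(iv: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(iv):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
        else:
            out.append((chrom, start, end))
    return [tuple(t) for t in out]


def _intersect_intervals(a, b):
    out = []
    for chrom, s1, e1 in a:
        for c2, s2, e2 in b:
            if c2 != chrom:
                continue
            s, e = max(s1, s2), min(e1, e2)
            if s < e:
                out.append((chrom, s, e))
    return _merge_intervals(out)


def _interval_length(iv) -> int:
    return sum(e - s for _, s, e in iv)


def summarize_and_intersect(callsets: list[CNACallSet]) -> dict:
    """Cross-cell call summary: per-cell Mbp tallies, core (shared by every
    cell, per class) alterations, per-cell shared fraction and private
    (single-cell) call length."""
    if not callsets:
        raise ValueError("need at least one call set")
    per_class_cells = {}
    for cls in ("gain", "loss"):
        per_class_cells[cls] = [
            _merge_intervals([(s.chrom, s.start, s.end)
                              for s in cs.calls if s.cn_class == cls])
            for cs in callsets]
    core = {}
    for cls in ("gain", "loss"):
        cells = per_class_cells[cls]
        cur = cells[0]
        for other in cells[1:]:
            cur = _intersect_intervals(cur, other)
        core[cls] = cur
    core_len = sum(_interval_length(core[c]) for c in core)

    per_cell = []
    for k, cs in enumerate(callsets):
        shared = 0
        private = 0
        for cls in ("gain", "loss"):
            mine = per_class_cells[cls][k]
            shared += _interval_length(_intersect_intervals(mine, core[cls]))
            others = []
            for j, iv in enumerate(per_class_cells[cls]):
                if j != k:
                    others.extend(iv)
            others = _merge_intervals(others)
            overlap_others = _interval_length(_intersect_intervals(mine, others))
            private += _interval_length(mine) - overlap_others
        per_cell.append({
            "cell_id": cs.cell_id,
            "mbp_gained": cs.mbp_gained,
            "mbp_lost": cs.mbp_lost,
            "shared_fraction": shared / core_len if core_len else float("nan"),
            "private_mbp": private / 1e6,
        })
    return {
        "core": {cls: core[cls] for cls in core},
        "core_mbp": core_len / 1e6,
        "n_core_gains": len(core["gain"]),
        "n_core_losses": len(core["loss"]),
        "per_cell": per_cell,
    }
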