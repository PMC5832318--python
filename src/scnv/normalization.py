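"""Bias correction and QC of binned read counts.

Correction order follows the workflow: GC first (LOWESS of count on GC),
then mappability division, then median centering so the resulting ratio has
median 1 over usable bins.  A panel of karyotypically normal cells yields a
blacklist of systematically mis-behaving bins (per-bin panel median ratio
strictly above ``hi`` or strictly below ``lo``).

Quality metrics:

* uniformity — fraction of usable bins with ratio >= 0.2 x mean ratio;
* coverage fraction — fraction with ratio > 0.6 x mean ratio;
* DLRS — sd of consecutive log2-ratio differences / sqrt(2), pairs crossing
  chromosome boundaries excluded (the standard derivative-log-ratio-spread
  noise measure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

#: LOWESS neighbourhood fraction.  Small enough to track a strong,
#: curved amplification bias without systematic residual trend at the GC
#: extremes; larger spans leave a monotone few-percent residual that
#: shows up as spurious ratio-GC correlation.
DEFAULT_LOWESS_SPAN = 0.15
DEFAULT_LOWESS_ITERATIONS = 3
DEFAULT_MIN_MAPPABILITY = 0.85
#: bins whose fitted GC expectation falls below this fraction of the
#: median expectation are too poorly represented to quantify at low pass
DEFAULT_MIN_FIT_FRACTION = 0.1
DEFAULT_BLACKLIST_HI = 1.4
DEFAULT_BLACKLIST_LO = 0.6
_EPS = 1e-8


@dataclass
class NormalizedProfile:
    """Per-bin normalized ratios for one cell.

    ``ratio`` has median 1 over usable bins; it is NaN exactly where
    ``usable`` is False.
    """

    bins: pd.DataFrame
    raw: np.ndarray
    ratio: np.ndarray
    usable: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)
        self.ratio = np.where(self.usable, self.ratio, np.nan)


@dataclass
class Blacklist:
    """Problematic genome regions derived from a panel of normals."""

    regions: pd.DataFrame  # chrom, start, end, median_fc, direction

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def total_bp(self) -> int:
        if self.regions.empty:
            return 0
        return int((self.regions["end"] - self.regions["start"]).sum())

    @classmethod
    def empty(cls) -> "Blacklist":
        return cls(regions=pd.DataFrame(
            columns=["chrom", "start", "end", "median_fc", "direction"]))


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------

def gc_normalize(counts: np.ndarray, bins: pd.DataFrame,
                 span: float = DEFAULT_LOWESS_SPAN,
                 iterations: int = DEFAULT_LOWESS_ITERATIONS,
                 min_fit_fraction: float = DEFAULT_MIN_FIT_FRACTION,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Divide counts by a robust LOWESS fit of count versus GC content.

    Returns ``(corrected, usable)``.  Bins that are masked, lack a GC
    value, or whose fitted expectation falls below ``min_fit_fraction``
    times the median fitted expectation become unusable: at low pass a
    bin expecting only a handful of reads carries no usable copy-number
    signal, and dividing by a near-zero expectation manufactures wild
    ratios (the same reason GC-extreme bins are excluded by read-depth
    callers).  Raises on an all-zero sample.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("empty sample: all bin counts are zero")
    gc = bins["gc"].to_numpy(dtype=float)
    usable = (~bins["masked"].to_numpy(dtype=bool)) & np.isfinite(gc)
    if usable.sum() < 50:
        raise ValueError("need at least 50 usable bins with defined GC")
    fit = np.full(len(counts), np.nan)
    fit[usable] = lowess(counts[usable], gc[usable], frac=span, it=iterations,
                         return_sorted=False)
    floor = max(_EPS,
                min_fit_fraction * float(np.nanmedian(fit[usable])))
    corrected = np.full(len(counts), np.nan)
    ok = usable & np.isfinite(fit) & (fit > floor)
    corrected[ok] = counts[ok] / fit[ok]
    return corrected, ok


def mappability_normalize(values: np.ndarray, bins: pd.DataFrame,
                          usable: np.ndarray,
                          min_mappability: float = DEFAULT_MIN_MAPPABILITY,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Divide by per-bin mappability; bins below the floor become unusable.

    The hard floor mirrors unique-match filtering: a bin where fewer than
    ``min_mappability`` of positions align uniquely cannot be rescued by
    rescaling.
    """
    values = np.asarray(values, dtype=float)
    mapp = bins["mappability"].to_numpy(dtype=float)
    ok = np.asarray(usable, dtype=bool) & np.isfinite(mapp) & (
        mapp >= min_mappability)
    out = np.full(len(values), np.nan)
    out[ok] = values[ok] / mapp[ok]
    return out, ok


def median_center(values: np.ndarray, bins: pd.DataFrame,
                  raw: np.ndarray, usable: np.ndarray) -> NormalizedProfile:
    """Scale so the median over usable bins equals 1."""
    values = np.asarray(values, dtype=float)
    usable = np.asarray(usable, dtype=bool)
    if not usable.any():
        raise ValueError("no usable bins to center on")
    med = float(np.median(values[usable]))
    if med <= 0:
        raise ValueError("median of usable values is not positive")
    ratio = values / med
    return NormalizedProfile(bins=bins, raw=np.asarray(raw),
                             ratio=ratio, usable=usable)


def normalize_counts(counts, bins,
                     span: float = DEFAULT_LOWESS_SPAN,
                     iterations: int = DEFAULT_LOWESS_ITERATIONS,
                     min_mappability: float = DEFAULT_MIN_MAPPABILITY,
                     ) -> NormalizedProfile:
    """GC correction, then mappability correction, then median centering."""
    raw = np.asarray(getattr(counts, "counts", counts))
    corrected, usable = gc_normalize(raw, bins, span=span,
                                     iterations=iterations)
    corrected, usable = mappability_normalize(corrected, bins, usable,
                                              min_mappability=min_mappability)
    return median_center(corrected, bins, raw, usable)


# ---------------------------------------------------------------------------
# quality metrics
# ---------------------------------------------------------------------------

def quality_metrics(profile: NormalizedProfile,
                    uniformity_threshold: float = 0.2,
                    coverage_threshold: float = 0.6) -> dict:
    """Uniformity, 60%-of-mean coverage fraction, and DLRS for one profile."""
    r = profile.ratio[profile.usable]
    if len(r) < 3:
        raise ValueError("need at least 3 usable bins")
    mean = float(r.mean())
    uniformity = float((r >= uniformity_threshold * mean).mean())
    coverage_fraction = float((r > coverage_threshold * mean).mean())
    return {
        "uniformity": uniformity,
        "coverage_fraction": coverage_fraction,
        "dlrs": dlrs(profile),
        "n_usable": int(len(r)),
        "mean_ratio": mean,
    }


def dlrs(profile: NormalizedProfile) -> float:
    """Derivative log-ratio spread: sd of consecutive log2-ratio
    differences within chromosomes, divided by sqrt(2)."""
    diffs: list[np.ndarray] = []
    chroms = profile.bins["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = (chroms == chrom) & profile.usable & (profile.ratio > 0)
        r = profile.ratio[sel]
        if len(r) >= 2:
            diffs.append(np.diff(np.log2(r)))
    if not diffs:
        return float("nan")
    d = np.concatenate(diffs)
    if len(d) < 2:
        return 0.0
    return float(np.std(d, ddof=1) / np.sqrt(2))


def flag_outlier_bins(profile: NormalizedProfile, n_sd: float = 3.0) -> np.ndarray:
    """Diagnostic flag for bins deviating more than ``n_sd`` standard
    deviations from the median ratio (reported, never used as a filter)."""
    r = profile.ratio[profile.usable]
    med, sd = float(np.median(r)), float(np.std(r, ddof=1))
    out = np.zeros(len(profile.ratio), dtype=bool)
    out[profile.usable] = np.abs(profile.ratio[profile.usable] - med) > n_sd * sd
    return out


# ---------------------------------------------------------------------------
# panel-of-normals blacklist
# ---------------------------------------------------------------------------

def detect_problematic_regions(panel: list[NormalizedProfile],
                               hi: float = DEFAULT_BLACKLIST_HI,
                               lo: float = DEFAULT_BLACKLIST_LO) -> Blacklist:
    """Blacklist bins whose median ratio across the panel is > hi or < lo.

    Inequalities are strict.  A bin is evaluable only when usable in more
    than half the panel members.  Maximal runs of adjacent flagged bins of
    the same direction merge into regions.
    """
    if len(panel) < 2:
        raise ValueError("panel must contain at least 2 profiles")
    bins = panel[0].bins
    for p in panel[1:]:
        if len(p.bins) != len(bins) or not (
                p.bins[["chrom", "start", "end"]].reset_index(drop=True)
                .equals(bins[["chrom", "start", "end"]].reset_index(drop=True))):
            raise ValueError("panel profiles must share one bin table")
    ratios = np.vstack([p.ratio for p in panel])
    usable = np.vstack([p.usable for p in panel])
    n_usable = usable.sum(axis=0)
    evaluable = n_usable > len(panel) / 2
    med = np.full(len(bins), np.nan)
    masked_ratios = np.where(usable, ratios, np.nan)
    if evaluable.any():
        med[evaluable] = np.nanmedian(masked_ratios[:, evaluable], axis=0)
    gain = evaluable & (med > hi)
    loss = evaluable & (med < lo)

    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    rows = []
    i = 0
    n = len(bins)
    while i < n:
        if gain[i] or loss[i]:
            direction = "gain" if gain[i] else "loss"
            j = i
            flag = gain if direction == "gain" else loss
            while (j + 1 < n and flag[j + 1] and chroms[j + 1] == chroms[i]
                   and starts[j + 1] == ends[j]):
                j += 1
            rows.append((chroms[i], int(starts[i]), int(ends[j]),
                         float(np.median(med[i:j + 1])), direction))
            i = j + 1
        else:
            i += 1
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                          "median_fc", "direction"])
    return Blacklist(regions=regions)
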