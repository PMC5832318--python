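"""Windowed benchmarking of CNA calls: ROC/AUC, specificity, profile R².

Comparisons run in fixed-size genomic windows.  A window counts as truly
altered when any reference call overlaps it (type and magnitude of the
alteration are ignored); the classifier score of a window is
``-log10(p_wilcoxon)`` of the non-neutral segment covering it, zero on
neutral territory, so sweeping the score reproduces a p-value-threshold
sweep.  Windows with less than half their bins usable are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .cna_calling import Segment
from .normalization import NormalizedProfile

DEFAULT_WINDOW_SIZE = 500_000
MIN_USABLE_WINDOW_FRACTION = 0.5
_P_FLOOR = 1e-300


@dataclass
class WindowComparison:
    window_size: int
    windows: pd.DataFrame      # chrom, start, end, truth, score
    auc: float
    degenerate: bool = False


def _window_table(profile: NormalizedProfile, window_size: int,
                  ) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Windows tiling the binned genome plus, per window, the indices of
    its usable bins; windows below the usable floor are dropped."""
    bins = profile.bins
    rows = []
    members: list[np.ndarray] = []
    for chrom, grp in bins.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        starts = grp["start"].to_numpy()
        span = int(grp["end"].max())
        for wstart in range(0, span, window_size):
            wend = min(wstart + window_size, span)
            in_w = idx[(starts >= wstart) & (starts < wend)]
            if len(in_w) == 0:
                continue
            usable = in_w[profile.usable[in_w]]
            if len(usable) < MIN_USABLE_WINDOW_FRACTION * len(in_w):
                continue
            rows.append((chrom, wstart, wend))
            members.append(usable)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]), members


def _per_bin_scores(profile: NormalizedProfile,
                    segments: list[Segment]) -> np.ndarray:
    scores = np.zeros(len(profile.ratio))
    for seg in segments:
        if seg.cn_class == "neutral" or not seg.testable:
            continue
        scores[seg.bin_indices] = -np.log10(max(seg.p_wilcoxon, _P_FLOOR))
    return scores


def _truth_any_overlap(windows: pd.DataFrame,
                       reference_calls: list) -> np.ndarray:
    truth = np.zeros(len(windows), dtype=bool)
    wc = windows["chrom"].to_numpy()
    ws = windows["start"].to_numpy()
    we = windows["end"].to_numpy()
    for call in reference_calls:
        chrom, start, end = call.chrom, call.start, call.end
        truth |= (wc == chrom) & (ws < end) & (we > start)
    return truth


def roc_auc_windows(profile: NormalizedProfile, segments: list[Segment],
                    reference_calls: list,
                    window_size: int = DEFAULT_WINDOW_SIZE,
                    ) -> WindowComparison:
    """Windowed ROC of a test profile's segment evidence against a
    reference call set.  AUC is the rank statistic over all thresholds."""
    windows, members = _window_table(profile, window_size)
    scores_bin = _per_bin_scores(profile, segments)
    score = np.array([scores_bin[m].max() if len(m) else 0.0
                      for m in members])
    truth = _truth_any_overlap(windows, reference_calls)
    windows = windows.assign(truth=truth, score=score)
    if truth.all() or not truth.any():
        return WindowComparison(window_size=window_size, windows=windows,
                                auc=float("nan"), degenerate=True)
    auc = float(roc_auc_score(truth.astype(int), score))
    return WindowComparison(window_size=window_size, windows=windows, auc=auc)


def specificity_flat(calls: list, profile: NormalizedProfile,
                     window_size: int = DEFAULT_WINDOW_SIZE) -> float:
    """On an expected-flat sample every call is a false positive;
    specificity is the fraction of windows not touched by any call."""
    windows, _ = _window_table(profile, window_size)
    if len(windows) == 0:
        raise ValueError("no evaluable windows")
    fp = _truth_any_overlap(windows, calls)
    return float(1.0 - fp.sum() / len(windows))


def profile_r2(profile_a: NormalizedProfile, profile_b: NormalizedProfile,
               window_size: int = DEFAULT_WINDOW_SIZE) -> float:
    """Squared Pearson correlation of per-window mean ratios over windows
    usable in both profiles.  Symmetric in its arguments."""
    wa, ma = _window_table(profile_a, window_size)
    wb, mb = _window_table(profile_b, window_size)
    key_a = {t: i for i, t in enumerate(
        zip(wa["chrom"], wa["start"], wa["end"]))}
    pairs = [(key_a[t], j) for j, t in enumerate(
        zip(wb["chrom"], wb["start"], wb["end"])) if t in key_a]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 shared windows")
    va = np.array([profile_a.ratio[ma[i]].mean() for i, _ in pairs])
    vb = np.array([profile_b.ratio[mb[j]].mean() for _, j in pairs])
    r = np.corrcoef(va, vb)[0, 1]
    return float(r * r)
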