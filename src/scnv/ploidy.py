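"""Absolute main-ploidy estimation from a median-centered ratio profile.

Binned read depth determines copy number only up to the cell's main ploidy:
a ratio of 1.5 is copy number 3 in a diploid but 9 in a hexaploid.  The
estimator exploits the linearity between read depth and DNA content:

1. multiply the centered ratio by a candidate ploidy P and smooth it along
   the genome (running median then running mean, width 5 bins) to suppress
   shot noise of shallow sequencing;
2. estimate the density of the smoothed values by a Gaussian KDE with
   Silverman's rule-of-thumb bandwidth (manual override supported);
3. locate density modes by continuous-wavelet-transform ridge detection
   (Ricker kernel); modes carrying less than 2% of the probability mass
   (integrated over the basin between flanking minima) are dropped;
4. round each mode to the nearest integer — the putative copy number —
   and regress mode position on putative copy number by OLS *with an
   intercept*; record R^2 and the sum of squared residuals (SSR);
5. repeat for P = 2..8; keep candidates with R^2 > 0.98 and select the
   lowest ploidy whose SSR is within a tolerance (default 25%) of the
   minimum, which automates the rule that exact multiples of the true
   ploidy fit equally well and the lowest plausible one should win.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import median_filter, uniform_filter1d

from .normalization import NormalizedProfile

DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_MIN_PEAK_MASS = 0.02
DEFAULT_R2_MIN = 0.98
DEFAULT_SSR_TOLERANCE = 0.25
#: plausible per-copy spacing of density modes.  At the true ploidy the
#: modes sit ~one copy apart (slope ~1, slightly below under WGA
#: compression); a candidate whose regression slope falls outside this
#: window has mis-scaled the profile (e.g. slope 2/3 when testing P-1 on
#: a run of consecutive copy levels, a case R^2 alone cannot reject).
DEFAULT_SLOPE_RANGE = (0.8, 1.2)
DEFAULT_PLOIDY_RANGE = (2, 8)
DEFAULT_GRID_SIZE = 1024


@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    degenerate: bool = False


@dataclass
class PloidyFit:
    """Peak set and regression diagnostics for one candidate ploidy."""

    ploidy_tested: int
    peaks: np.ndarray
    peak_masses: np.ndarray
    putative_cn: np.ndarray
    slope: float = float("nan")
    intercept: float = float("nan")
    r2: float = float("nan")
    ssr: float = float("nan")
    passes_r2: bool = False

    def to_dict(self) -> dict:
        return {
            "ploidy_tested": self.ploidy_tested,
            "peaks": [float(p) for p in self.peaks],
            "peak_masses": [float(m) for m in self.peak_masses],
            "putative_cn": [int(c) for c in self.putative_cn],
            "slope": self.slope, "intercept": self.intercept,
            "r2": self.r2, "ssr": self.ssr, "passes_r2": self.passes_r2,
        }


@dataclass
class PloidyScan:
    fits: list
    selected: int | None
    selection_rationale: str

    def to_dict(self) -> dict:
        return {"fits": [f.to_dict() for f in self.fits],
                "selected": self.selected,
                "selection_rationale": self.selection_rationale}


# ---------------------------------------------------------------------------
# step 1: scale and smooth
# ---------------------------------------------------------------------------

def prepare_signal(profile: NormalizedProfile, ploidy: int,
                   smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """ratio * ploidy, smoothed per chromosome by a running median then a
    running mean of width ``smooth_window``.

    The median pass kills isolated spikes, the mean pass softens the
    remaining staircase noise; true copy steps survive within one window.
    Chromosomes shorter than the window pass through unsmoothed.  Returns
    the smoothed values of usable bins in genome order.
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    chroms = profile.bins["chrom"].to_numpy()
    out = []
    for chrom in pd.unique(chroms):
        v = profile.ratio[(chroms == chrom) & profile.usable] * ploidy
        if len(v) == 0:
            continue
        if len(v) >= smooth_window:
            v = median_filter(v, size=smooth_window, mode="nearest")
            v = uniform_filter1d(v, size=smooth_window, mode="nearest")
        out.append(v)
    if not out:
        raise ValueError("profile has no usable bins")
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# step 2: kernel density estimation
# ---------------------------------------------------------------------------

def silverman_bandwidth(values: np.ndarray) -> float:
    """h = 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (
        sd > 0 or iqr > 0) else 0.0
    return 0.9 * spread * n ** (-1 / 5)


def estimate_density(values: np.ndarray, bandwidth: float | None = None,
                     grid_size: int = DEFAULT_GRID_SIZE) -> DensityEstimate:
    """Gaussian-kernel density on a uniform grid.

    ``bandwidth=None`` applies Silverman's rule of thumb; passing a number
    overrides it (the manual-tweak escape hatch).  Zero-variance input is
    flagged degenerate and returns a single point mass.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 values for density estimation")
    h = silverman_bandwidth(values) if bandwidth is None else float(bandwidth)
    if h <= 0:
        v = float(values[0])
        grid = np.linspace(v - 1, v + 1, grid_size)
        dens = np.zeros(grid_size)
        dens[grid_size // 2] = 1.0 / (grid[1] - grid[0])
        return DensityEstimate(grid=grid, density=dens, bandwidth=0.0,
                               degenerate=True)
    lo = values.min() - 3 * h
    hi = values.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    # direct Gaussian mixture evaluation; chunked to bound memory
    dens = np.zeros(grid_size)
    for chunk in np.array_split(values, max(1, len(values) // 4096)):
        z = (grid[None, :] - chunk[:, None]) / h
        dens += np.exp(-0.5 * z * z).sum(axis=0)
    dens /= len(values) * h * np.sqrt(2 * np.pi)
    return DensityEstimate(grid=grid, density=dens, bandwidth=h)


# ---------------------------------------------------------------------------
# step 3: peak detection
# ---------------------------------------------------------------------------

def _local_maxima(density: np.ndarray) -> np.ndarray:
    idx, _ = signal.find_peaks(density)
    return idx


def _basin_masses(grid: np.ndarray, density: np.ndarray,
                  peak_idx: np.ndarray) -> np.ndarray:
    """Probability mass of each peak's basin, delimited by the density
    minima between consecutive peaks (grid ends for the outermost)."""
    total = np.trapezoid(density, grid)
    bounds = [0]
    for a, b in zip(peak_idx[:-1], peak_idx[1:]):
        bounds.append(a + int(np.argmin(density[a:b + 1])))
    bounds.append(len(grid) - 1)
    masses = np.array([
        np.trapezoid(density[bounds[i]:bounds[i + 1] + 1],
                     grid[bounds[i]:bounds[i + 1] + 1])
        for i in range(len(peak_idx))])
    return masses / total


def find_density_peaks(dens: DensityEstimate,
                       min_mass: float = DEFAULT_MIN_PEAK_MASS,
                       method: str = "cwt",
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Density modes and their basin probability masses.

    ``method="cwt"`` (default) keeps modes persistent across a Ricker-
    wavelet scale ladder spanning ~1-10% of the grid; ``method="local"``
    is a plain local-maxima finder kept as a cross-check.  Modes with
    basin mass below ``min_mass`` are excluded.
    """
    grid, density = dens.grid, dens.density
    if dens.degenerate:
        return np.array([grid[int(np.argmax(density))]]), np.array([1.0])
    maxima = _local_maxima(density)
    if len(maxima) == 0:
        maxima = np.array([int(np.argmax(density))])
    if method == "cwt":
        g = len(grid)
        widths = np.unique(np.linspace(max(2, 0.01 * g), 0.1 * g, 10)
                           .astype(int))
        cwt_idx = signal.find_peaks_cwt(density, widths)
        if len(cwt_idx) == 0:
            peak_idx = maxima
        else:
            # snap each ridge to the nearest true local maximum
            snapped = sorted({int(maxima[np.argmin(np.abs(maxima - i))])
                              for i in cwt_idx})
            peak_idx = np.array(snapped, dtype=int)
    elif method == "local":
        peak_idx = maxima
    else:
        raise ValueError(f"unknown peak method {method!r}")
    peak_idx = np.sort(peak_idx)
    masses = _basin_masses(grid, density, peak_idx)
    keep = masses >= min_mass
    # a dropped minor mode's mass is not re-attributed; reported masses
    # therefore sum to <= 1
    peak_idx, masses = peak_idx[keep], masses[keep]
    if len(peak_idx) == 0:
        raise ValueError("uninterpretable density: no peak above the "
                         f"{min_mass:.0%} mass threshold")
    return grid[peak_idx], masses


# ---------------------------------------------------------------------------
# step 4: regression of peaks on putative copy numbers
# ---------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, np.floor(x + 0.5), -np.floor(-x + 0.5)).astype(int)


def fit_ploidy_regression(peaks: np.ndarray, peak_masses: np.ndarray,
                          ploidy_tested: int) -> PloidyFit:
    """OLS (with intercept) of peak positions on their rounded values.

    The intercept absorbs the small systematic shift that smoothing and
    KDE bandwidth introduce; with it the regression reproduces published
    diagnostics that a through-the-origin fit does not.  Duplicate
    putative copy numbers are allowed; a peak set collapsing onto a single
    integer leaves the fit undefined.
    """
    peaks = np.asarray(peaks, dtype=float)
    fit = PloidyFit(ploidy_tested=ploidy_tested, peaks=peaks,
                    peak_masses=np.asarray(peak_masses, dtype=float),
                    putative_cn=_round_half_away(peaks))
    if len(peaks) < 2 or len(np.unique(fit.putative_cn)) < 2:
        return fit
    x = fit.putative_cn.astype(float)
    A = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), *_ = np.linalg.lstsq(A, peaks, rcond=None)
    pred = slope * x + intercept
    ssr = float(((peaks - pred) ** 2).sum())
    tss = float(((peaks - peaks.mean()) ** 2).sum())
    fit.slope, fit.intercept, fit.ssr = float(slope), float(intercept), ssr
    fit.r2 = 1.0 - ssr / tss if tss > 0 else float("nan")
    return fit


# ---------------------------------------------------------------------------
# step 5: candidate scan and selection
# ---------------------------------------------------------------------------

def select_ploidy(fits: list[PloidyFit],
                  r2_min: float = DEFAULT_R2_MIN,
                  ssr_tolerance: float = DEFAULT_SSR_TOLERANCE,
                  slope_range: tuple[float, float] = DEFAULT_SLOPE_RANGE,
                  ) -> PloidyScan:
    """Keep fits with R^2 > r2_min and a plausible per-copy slope; among
    them select the lowest ploidy whose SSR is within
    ``(1 + ssr_tolerance) * min(SSR)``."""
    survivors = [f for f in fits
                 if np.isfinite(f.r2) and f.r2 > r2_min
                 and np.isfinite(f.slope)
                 and slope_range[0] <= f.slope <= slope_range[1]]
    if not survivors:
        return PloidyScan(fits=fits, selected=None,
                          selection_rationale=(
                              f"no candidate ploidy reached R^2 > {r2_min} "
                              f"with slope in {slope_range}"))
    min_ssr = min(f.ssr for f in survivors)
    cutoff = (1 + ssr_tolerance) * min_ssr
    plausible = [f for f in survivors if f.ssr <= cutoff]
    chosen = min(plausible, key=lambda f: f.ploidy_tested)
    ranking = ", ".join(
        f"P={f.ploidy_tested}: R2={f.r2:.4f} SSR={f.ssr:.4f}"
        for f in sorted(survivors, key=lambda f: f.ssr))
    rationale = (f"selected lowest ploidy with SSR <= {cutoff:.4g} "
                 f"(min SSR {min_ssr:.4g}); ranking: {ranking}")
    return PloidyScan(fits=fits, selected=chosen.ploidy_tested,
                      selection_rationale=rationale)


def scan_ploidies(profile: NormalizedProfile,
                  ploidy_range: tuple[int, int] = DEFAULT_PLOIDY_RANGE,
                  smooth_window: int = DEFAULT_SMOOTH_WINDOW,
                  bandwidth: float | None = None,
                  min_peak_mass: float = DEFAULT_MIN_PEAK_MASS,
                  r2_min: float = DEFAULT_R2_MIN,
                  ssr_tolerance: float = DEFAULT_SSR_TOLERANCE,
                  slope_range: tuple[float, float] = DEFAULT_SLOPE_RANGE,
                  peak_method: str = "cwt") -> PloidyScan:
    """Run the full five-step scan over candidate main ploidies."""
    fits = []
    for ploidy in range(ploidy_range[0], ploidy_range[1] + 1):
        values = prepare_signal(profile, ploidy, smooth_window=smooth_window)
        dens = estimate_density(values, bandwidth=bandwidth)
        try:
            peaks, masses = find_density_peaks(dens, min_mass=min_peak_mass,
                                               method=peak_method)
        except ValueError:
            fits.append(PloidyFit(ploidy_tested=ploidy,
                                  peaks=np.array([]),
                                  peak_masses=np.array([]),
                                  putative_cn=np.array([], dtype=int)))
            continue
        fit = fit_ploidy_regression(peaks, masses, ploidy)
        fit.passes_r2 = bool(np.isfinite(fit.r2) and fit.r2 > r2_min)
        fits.append(fit)
    return select_ploidy(fits, r2_min=r2_min, ssr_tolerance=ssr_tolerance,
                         slope_range=slope_range)


def absolute_copy_numbers(profile: NormalizedProfile,
                          main_ploidy: int) -> np.ndarray:
    """Per-bin integer copy numbers at the given main ploidy (NaN-safe:
    unusable bins return -1)."""
    cn = np.full(len(profile.ratio), -1, dtype=int)
    vals = profile.ratio[profile.usable] * main_ploidy
    cn[profile.usable] = np.maximum(0, _round_half_away(vals))
    return cn
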