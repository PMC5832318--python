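"""Pipeline orchestration: per-cell run, panel building, file formats,
and the synthetic benchmark experiments.

The per-cell pipeline is counting → normalization → QC → ploidy scan →
CNA calling at the selected main ploidy → blacklist filtering.  Every
stage logs one structured line with its in/out tallies, and reports carry
a hash of the configuration plus the seed so reruns are attributable.

The experiment functions at the bottom reproduce, on synthetic data, the
benchmark computations of the workflow's validation: specificity on
expected-flat samples, post-normalization uniformity, subsampling ROC/AUC
against a deep reference, and profile stability under read thinning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import cna_calling, evaluation, normalization, ploidy, simulation
from .normalization import Blacklist, NormalizedProfile
from .read_counting import CountVector

logger = logging.getLogger("scnv")


@dataclass
class PipelineConfig:
    """Every tunable threshold of the workflow, at its standard default."""

    bin_size: int = 500_000
    min_mapq: int = 0
    lowess_span: float = 0.15
    lowess_iterations: int = 3
    min_mappability: float = 0.85
    blacklist_hi: float = 1.4
    blacklist_lo: float = 0.6
    alpha: float = 0.01
    uniformity_threshold: float = 0.2
    coverage_threshold: float = 0.6
    uniformity_floor: float = 0.9       # QC warning below this
    segment_penalty: float = 2.0
    min_segment_bins: int = 3
    max_blacklist_overlap: float = 0.5
    min_peak_mass: float = 0.02
    r2_min: float = 0.98
    ssr_tolerance: float = 0.25
    ploidy_range: tuple = (2, 8)
    smooth_window: int = 5
    kde_bandwidth: float | None = None
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class CellResult:
    cell_id: str
    profile: NormalizedProfile
    qc: dict
    ploidy_scan: ploidy.PloidyScan
    main_ploidy: int
    segments: list
    calls: cna_calling.CNACallSet
    status: str  # ok | warn

    def summary(self, config: PipelineConfig) -> dict:
        return {
            "cell_id": self.cell_id,
            "config_hash": config.hash(),
            "seed": config.seed,
            "status": self.status,
            "qc": self.qc,
            "main_ploidy": self.main_ploidy,
            "ploidy": self.ploidy_scan.to_dict(),
            "n_segments": len(self.segments),
            "n_calls": len(self.calls.calls),
            "mbp_gained": self.calls.mbp_gained,
            "mbp_lost": self.calls.mbp_lost,
        }


def run_cell(config: PipelineConfig, bins: pd.DataFrame, counts: CountVector,
             blacklist: Blacklist | None = None,
             cell_id: str = "cell",
             main_ploidy: int | None = None) -> CellResult:
    """Full per-cell analysis from binned counts.

    ``main_ploidy=None`` triggers the KDE-peak ploidy scan; a profile that
    is unimodal at every candidate (nothing to regress on — e.g. a flat
    normal cell) falls back to the lowest plausible ploidy, 2.
    """
    blacklist = blacklist or Blacklist.empty()
    profile = normalization.normalize_counts(
        counts, bins, span=config.lowess_span,
        iterations=config.lowess_iterations,
        min_mappability=config.min_mappability)
    logger.info("cell=%s bins_usable=%d/%d", cell_id,
                int(profile.usable.sum()), len(bins))
    qc = normalization.quality_metrics(
        profile, uniformity_threshold=config.uniformity_threshold,
        coverage_threshold=config.coverage_threshold)
    status = "ok" if qc["uniformity"] >= config.uniformity_floor else "warn"

    scan = ploidy.scan_ploidies(
        profile, ploidy_range=tuple(config.ploidy_range),
        smooth_window=config.smooth_window,
        bandwidth=config.kde_bandwidth,
        min_peak_mass=config.min_peak_mass,
        r2_min=config.r2_min, ssr_tolerance=config.ssr_tolerance)
    if main_ploidy is None:
        main_ploidy = scan.selected if scan.selected is not None else 2
    logger.info("cell=%s main_ploidy=%d selected=%s", cell_id, main_ploidy,
                scan.selected)

    segments, callset = cna_calling.call_cnas(
        profile, main_ploidy, cell_id=cell_id,
        penalty=config.segment_penalty, min_bins=config.min_segment_bins,
        alpha=config.alpha)
    n_before = len(callset.calls)
    callset = cna_calling.filter_calls(
        callset, blacklist, max_overlap=config.max_blacklist_overlap)
    logger.info("cell=%s segments=%d calls_pre=%d calls_post=%d", cell_id,
                len(segments), n_before, len(callset.calls))
    return CellResult(cell_id=cell_id, profile=profile, qc=qc,
                      ploidy_scan=scan, main_ploidy=main_ploidy,
                      segments=segments, calls=callset, status=status)


def build_panel(config: PipelineConfig, bins: pd.DataFrame,
                cells: list[CountVector]) -> tuple[Blacklist, pd.DataFrame]:
    """Normalize a panel of normal cells and derive the blacklist plus a
    per-cell QC table."""
    if len(cells) < 2:
        raise ValueError("panel requires at least 2 cells")
    profiles = []
    qc_rows = []
    for i, counts in enumerate(cells):
        p = normalization.normalize_counts(
            counts, bins, span=config.lowess_span,
            iterations=config.lowess_iterations,
            min_mappability=config.min_mappability)
        profiles.append(p)
        qc = normalization.quality_metrics(
            p, uniformity_threshold=config.uniformity_threshold,
            coverage_threshold=config.coverage_threshold)
        qc_rows.append({"cell": f"normal_{i}", **qc})
    blacklist = normalization.detect_problematic_regions(
        profiles, hi=config.blacklist_hi, lo=config.blacklist_lo)
    logger.info("panel n_cells=%d blacklist_regions=%d total_bp=%d",
                len(cells), blacklist.n_regions, blacklist.total_bp)
    return blacklist, pd.DataFrame(qc_rows)


# ---------------------------------------------------------------------------
# file formats (TSV/BED/JSON round-trips)
# ---------------------------------------------------------------------------

def write_profile(profile: NormalizedProfile, path) -> None:
    df = profile.bins[["chrom", "start", "end"]].copy()
    df["raw"] = profile.raw
    df["ratio"] = profile.ratio
    df["usable"] = profile.usable.astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_profile(path, bins: pd.DataFrame | None = None) -> NormalizedProfile:
    df = pd.read_csv(path, sep="\t")
    if bins is None:
        bins = df[["chrom", "start", "end"]].copy()
        bins["gc"] = np.nan
        bins["mappability"] = np.nan
        bins["weighted_fragments"] = 0.0
        bins["n_fraction"] = 0.0
        bins["masked"] = False
    return NormalizedProfile(bins=bins, raw=df["raw"].to_numpy(),
                             ratio=df["ratio"].to_numpy(),
                             usable=df["usable"].to_numpy(dtype=bool))


def write_blacklist(blacklist: Blacklist, path) -> None:
    blacklist.regions.to_csv(path, sep="\t", index=False, header=False,
                             columns=["chrom", "start", "end",
                                      "median_fc", "direction"],
                             float_format="%.6g")


def read_blacklist(path) -> Blacklist:
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "median_fc",
                                "direction"])
    except pd.errors.EmptyDataError:
        return Blacklist.empty()
    return Blacklist(regions=df)


def calls_table(segments: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": s.chrom, "start": s.start, "end": s.end,
        "class": s.cn_class, "copy_number": s.copy_number,
        "mean_ratio": s.mean_ratio, "p_wilcoxon": s.p_wilcoxon,
        "p_ks": s.p_ks, "significant": int(s.significant),
        "blacklisted_fraction": s.blacklisted_fraction,
    } for s in segments])


def write_bins(bins: pd.DataFrame, path) -> None:
    bins.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_bins(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["masked"] = df["masked"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# synthetic benchmark experiments
# ---------------------------------------------------------------------------

def flat_specificity_experiment(seed: int, n_bins: int = 2000,
                                bin_size: int = 200_000,
                                total_reads: int = 400_000,
                                n_panel: int = 10,
                                config: PipelineConfig | None = None) -> dict:
    """Specificity of calling on a simulated expected-flat diploid cell.

    Builds a blacklist from a panel of flat normals, runs the full
    pipeline on an independent flat cell, and counts every called window
    as a false positive.
    """
    config = config or PipelineConfig(bin_size=bin_size, seed=seed)
    rng = np.random.default_rng(seed)
    n_chroms = 4
    sim = simulation.SimulationConfig(
        n_chroms=n_chroms,
        chrom_length=(n_bins // n_chroms) * bin_size,
        bin_size=bin_size, total_reads=total_reads, seed=seed)
    bins, panel_cells = simulation.simulate_normal_panel(sim, n_panel,
                                                         rng=rng)
    blacklist, _ = build_panel(config, bins, panel_cells)
    counts = simulation.simulate_cell_counts(sim, bins, rng=rng)
    result = run_cell(config, bins, counts, blacklist=blacklist,
                      cell_id="flat")
    spec = evaluation.specificity_flat(result.calls.calls, result.profile,
                                       window_size=bin_size)
    return {"specificity": spec, "n_windows": len(bins),
            "n_false_calls": len(result.calls.calls),
            "main_ploidy": result.main_ploidy}


def uniformity_experiment(seed: int, n_bins: int = 1000,
                          bin_size: int = 500_000,
                          total_reads: int = 500_000) -> dict:
    """Post-normalization uniformity and 60%-of-mean coverage fraction on
    a GC-biased flat control cell."""
    rng = np.random.default_rng(seed)
    n_chroms = 4
    sim = simulation.SimulationConfig(
        n_chroms=n_chroms, chrom_length=(n_bins // n_chroms) * bin_size,
        bin_size=bin_size, total_reads=total_reads, seed=seed)
    bins = simulation.simulate_bin_table(sim, rng)
    counts = simulation.simulate_cell_counts(sim, bins, rng=rng)
    profile = normalization.normalize_counts(counts, bins)
    qc = normalization.quality_metrics(profile)
    return {"uniformity": qc["uniformity"],
            "coverage_fraction": qc["coverage_fraction"],
            "dlrs": qc["dlrs"], "n_usable": qc["n_usable"]}


#: planted alterations for the aberrant-cell experiments: 12 CNAs of
#: 8-16 Mb on a 8 x 40 Mb genome (~36% of it altered), copy numbers 1-4
#: around a diploid main ploidy
ABERRANT_CN_PROFILE = (
    ("chr1", 2_000_000, 14_000_000, 3),
    ("chr1", 24_000_000, 36_000_000, 1),
    ("chr2", 6_000_000, 16_000_000, 4),
    ("chr2", 28_000_000, 38_000_000, 1),
    ("chr3", 10_000_000, 20_000_000, 3),
    ("chr4", 0, 10_000_000, 1),
    ("chr4", 22_000_000, 32_000_000, 3),
    ("chr5", 14_000_000, 24_000_000, 4),
    ("chr6", 4_000_000, 12_000_000, 1),
    ("chr6", 26_000_000, 40_000_000, 3),
    ("chr7", 8_000_000, 18_000_000, 1),
    ("chr8", 16_000_000, 28_000_000, 3),
)


def _aberrant_sim(seed: int, atom_size: int = 100_000) -> tuple:
    sim = simulation.SimulationConfig(
        n_chroms=8, chrom_length=40_000_000, bin_size=atom_size,
        cn_profile=ABERRANT_CN_PROFILE, main_ploidy=2, seed=seed)
    rng = np.random.default_rng(seed)
    bins = simulation.simulate_bin_table(sim, rng)
    return sim, rng, bins


def subsampling_auc_experiment(seed: int,
                               deep_reads: int = 3_500_000,
                               shallow_reads: int = 200_000,
                               resolutions: tuple = (100_000, 200_000,
                                                     500_000, 2_000_000),
                               config: PipelineConfig | None = None) -> dict:
    """Windowed ROC AUC of shallow-data calls against deep-data calls from
    the same simulated aberrant cell, across bin-size resolutions.

    The shallow dataset is a binomial thinning of the deep one, mirroring
    subsampling of one sequencing run.  The deep calls define truth; the
    shallow segment evidence provides the score.
    """
    config = config or PipelineConfig(seed=seed)
    atom = min(resolutions)
    sim, rng, atom_bins = _aberrant_sim(seed, atom_size=atom)
    deep = simulation.simulate_cell_counts(sim, atom_bins, rng=rng,
                                           total_reads=deep_reads)
    shallow = simulation.thin_counts(deep, shallow_reads / deep_reads, rng)
    aucs = {}
    for res in resolutions:
        factor = res // atom
        bins_r, deep_r = simulation.aggregate_bins(atom_bins, deep, factor)
        _, shallow_r = simulation.aggregate_bins(atom_bins, shallow, factor)
        ref = run_cell(config, bins_r, deep_r, cell_id="deep",
                       main_ploidy=2)
        test = run_cell(config, bins_r, shallow_r, cell_id="shallow",
                        main_ploidy=2)
        cmp = evaluation.roc_auc_windows(test.profile, test.segments,
                                         ref.calls.calls, window_size=res)
        aucs[int(res)] = cmp.auc
    return {"auc_by_resolution": aucs, "min_auc": min(aucs.values())}


def profile_stability_experiment(seed: int,
                                 deep_reads: int = 3_500_000,
                                 shallow_reads: int = 1_000_000,
                                 bin_size: int = 500_000,
                                 window_size: int = 500_000) -> dict:
    """R² between copy-number profiles of the same aberrant cell at full
    and thinned read depth, in fixed windows."""
    sim, rng, bins = _aberrant_sim(seed, atom_size=bin_size)
    deep = simulation.simulate_cell_counts(sim, bins, rng=rng,
                                           total_reads=deep_reads)
    shallow = simulation.thin_counts(deep, shallow_reads / deep_reads, rng)
    p_deep = normalization.normalize_counts(deep, bins)
    p_shallow = normalization.normalize_counts(shallow, bins)
    r2 = evaluation.profile_r2(p_deep, p_shallow, window_size=window_size)
    return {"r2": r2, "n_bins": len(bins)}
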