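"""GC/mappability correction, QC metrics and the panel blacklist."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from scnv import normalization as nm
from scnv import simulation
from tests.conftest import make_bin_table, make_profile


def gc_bins(n, rng=None, bin_size=500):
    gc = (np.linspace(0.3, 0.7, n) if rng is None
          else rng.uniform(0.3, 0.7, n))
    return make_bin_table(n, bin_size=bin_size, gc=gc)


class TestGCNormalize:
    def test_flat_counts_give_flat_ratio(self):
        bins = gc_bins(500)
        counts = np.full(500, 200)
        corrected, usable = nm.gc_normalize(counts, bins)
        profile = nm.median_center(corrected, bins, counts, usable)
        assert np.nanmax(np.abs(profile.ratio - 1)) < 0.02

    def test_noiseless_smooth_bias_removed(self):
        bins = gc_bins(500)
        gc = bins["gc"].to_numpy()
        bias = np.exp(-((gc - 0.45) ** 2) / 0.02)      # smooth unimodal
        counts = np.round(100 * bias)
        corrected, usable = nm.gc_normalize(counts, bins)
        vals = corrected[usable]
        assert np.std(vals) / np.mean(vals) < 0.05

    def test_poisson_gc_bias_decorrelated(self, rng):
        bins = gc_bins(500, rng)
        gc = bins["gc"].to_numpy()
        lam = 300 * np.exp(-((gc - 0.45) ** 2) / 0.02)
        counts = rng.poisson(lam)
        corrected, usable = nm.gc_normalize(counts, bins)
        rho = spearmanr(corrected[usable], gc[usable]).statistic
        assert abs(rho) < 0.1

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="empty sample"):
            nm.gc_normalize(np.zeros(100), gc_bins(100))

    def test_low_representation_bins_excluded(self, rng):
        """Bins whose expected count collapses (e.g. extreme GC under a
        strong amplification bias) are unusable, not wildly ratioed."""
        bins = gc_bins(400)
        gc = bins["gc"].to_numpy()
        lam = np.where(gc > 0.65, 1.0, 500.0)    # representation collapse
        counts = rng.poisson(lam)
        corrected, usable = nm.gc_normalize(counts, bins)
        # the LOWESS fit smooths the cliff, so allow a transition zone
        assert not usable[gc > 0.685].any()
        assert usable[gc < 0.6].all()

    def test_scale_equivariance(self, rng):
        bins = gc_bins(300, rng)
        counts = rng.poisson(200, 300)
        c1, u1 = nm.gc_normalize(counts, bins)
        c2, u2 = nm.gc_normalize(counts * 7, bins)
        assert (u1 == u2).all()
        assert np.allclose(c1[u1], c2[u2], atol=1e-9)


class TestMappability:
    def test_full_mappability_is_identity(self):
        bins = make_bin_table(100, mappability=1.0)
        vals = np.linspace(1, 2, 100)
        out, usable = nm.mappability_normalize(vals, bins,
                                               np.ones(100, bool))
        assert np.allclose(out, vals)
        assert usable.all()

    def test_division_arithmetic(self):
        bins = make_bin_table(3)
        bins.loc[1, "mappability"] = 0.5
        out, usable = nm.mappability_normalize(
            np.array([50.0, 50.0, 50.0]), bins, np.ones(3, bool),
            min_mappability=0.3)
        assert out[1] == pytest.approx(100.0)

    def test_default_floor_excludes_low_mappability(self):
        bins = make_bin_table(3)
        bins.loc[1, "mappability"] = 0.5
        bins.loc[2, "mappability"] = 0.2
        out, usable = nm.mappability_normalize(
            np.array([50.0, 50.0, 50.0]), bins, np.ones(3, bool))
        assert list(usable) == [True, False, False]   # 0.85 floor
        assert np.isnan(out[2])


class TestMedianCenter:
    def test_simple_values(self):
        bins = make_bin_table(3)
        prof = nm.median_center(np.array([2.0, 4.0, 6.0]), bins,
                                np.zeros(3), np.ones(3, bool))
        assert np.allclose(prof.ratio, [0.5, 1.0, 1.5])

    def test_median_is_one_by_construction(self, rng):
        bins = make_bin_table(101)
        vals = rng.uniform(10, 100, 101)
        prof = nm.median_center(vals, bins, np.zeros(101), np.ones(101, bool))
        assert np.median(prof.ratio) == pytest.approx(1.0, abs=1e-9)

    def test_unusable_bins_excluded_from_median(self):
        bins = make_bin_table(4)
        usable = np.array([True, True, True, False])
        prof = nm.median_center(np.array([2.0, 4.0, 6.0, 1000.0]), bins,
                                np.zeros(4), usable)
        assert prof.ratio[1] == pytest.approx(1.0)
        assert np.isnan(prof.ratio[3])

    def test_zero_median_rejected(self):
        bins = make_bin_table(3)
        with pytest.raises(ValueError):
            nm.median_center(np.zeros(3), bins, np.zeros(3),
                             np.ones(3, bool))


class TestQualityMetrics:
    def test_constant_profile(self):
        prof = make_profile(np.ones(10))
        qc = nm.quality_metrics(prof)
        assert qc["uniformity"] == 1.0
        assert qc["coverage_fraction"] == 1.0
        assert qc["dlrs"] == 0.0

    def test_uniformity_hand_enumeration(self):
        # ratios (10,10,10,1): mean 7.75, 20% threshold 1.55 -> 3/4 pass
        prof = make_profile([10.0, 10.0, 10.0, 1.0])
        qc = nm.quality_metrics(prof)
        assert qc["uniformity"] == pytest.approx(0.75)

    def test_dlrs_closed_form(self):
        # log2 ratios (0, .2, 0, .2): diffs (.2,-.2,.2), sd .23094
        prof = make_profile(2.0 ** np.array([0.0, 0.2, 0.0, 0.2]))
        qc = nm.quality_metrics(prof)
        assert qc["dlrs"] == pytest.approx(0.16330, abs=1e-4)

    def test_dlrs_excludes_chromosome_boundary_pairs(self):
        a = make_profile([1.0, 1.0], chrom="chr1")
        ratio = np.array([1.0, 1.0, 4.0, 4.0])
        bins = pd.concat([a.bins, a.bins.assign(chrom="chr2")],
                         ignore_index=True)
        prof = nm.NormalizedProfile(bins=bins, raw=np.zeros(4),
                                    ratio=ratio, usable=np.ones(4, bool))
        # within each chromosome the signal is flat: no cross-chrom jump
        assert nm.dlrs(prof) == 0.0

    def test_alternating_log_signal_limit(self):
        """Closed form: an alternating +-d/2 log2 signal has consecutive
        differences of -+d, whose sd tends to |d| for large n, so DLRS
        tends to |d|/sqrt(2)."""
        d = 0.3
        n = 2000
        log2r = np.where(np.arange(n) % 2 == 0, d / 2, -d / 2)
        prof = make_profile(2.0 ** log2r)
        assert nm.dlrs(prof) == pytest.approx(d / np.sqrt(2), rel=0.01)


class TestBlacklist:
    def _panel(self, ratio_rows):
        profiles = []
        for row in ratio_rows:
            profiles.append(make_profile(row, bin_size=500))
        return profiles

    def test_flat_panel_empty_blacklist(self):
        panel = self._panel([np.ones(4)] * 3)
        bl = nm.detect_problematic_regions(panel)
        assert bl.n_regions == 0 and bl.total_bp == 0

    def test_flagged_bins_merge_into_region(self):
        rows = [[1.0, 1.5, 0.5, 1.0]] * 3
        bl = nm.detect_problematic_regions(self._panel(rows))
        # bins 2 and 3 flagged but in opposite directions: two regions
        assert bl.n_regions == 2
        assert bl.total_bp == 1000
        assert set(bl.regions["direction"]) == {"gain", "loss"}

    def test_same_direction_run_merges(self):
        rows = [[1.0, 1.6, 1.7, 1.0]] * 3
        bl = nm.detect_problematic_regions(self._panel(rows))
        assert bl.n_regions == 1
        assert (bl.regions["end"] - bl.regions["start"]).iloc[0] == 1000

    def test_boundary_value_not_flagged(self):
        """Median exactly at the threshold stays clean (strict > and <)."""
        rows = [[1.0, 1.4, 0.6, 1.0]] * 3
        bl = nm.detect_problematic_regions(self._panel(rows))
        assert bl.n_regions == 0

    def test_panel_of_one_rejected(self):
        with pytest.raises(ValueError):
            nm.detect_problematic_regions(self._panel([np.ones(4)]))

    def test_mismatched_bin_tables_rejected(self):
        a = make_profile(np.ones(4))
        b = make_profile(np.ones(5))
        with pytest.raises(ValueError):
            nm.detect_problematic_regions([a, b])

    def test_recovers_planted_bad_bins(self):
        """>= 95% of systematically biased bins are blacklisted from a
        20-cell panel."""
        sim = simulation.SimulationConfig(
            n_chroms=2, chrom_length=125_000_000, bin_size=500_000,
            total_reads=400_000, seed=11)
        rng = np.random.default_rng(11)
        bad = np.arange(40, 60)
        bins, cells = simulation.simulate_normal_panel(
            sim, 20, bad_bins=bad, bad_factor=1.6, rng=rng)
        profiles = [nm.normalize_counts(c, bins) for c in cells]
        bl = nm.detect_problematic_regions(profiles)
        flagged = np.zeros(len(bins), dtype=bool)
        starts = bins["start"].to_numpy()
        chroms = bins["chrom"].to_numpy()
        for _, r in bl.regions.iterrows():
            flagged |= ((chroms == r["chrom"]) & (starts >= r["start"])
                        & (starts < r["end"]))
        assert flagged[bad].mean() >= 0.95


def test_end_to_end_normalization_quality(rng):
    """Simulated GC-biased flat diploid: uniformity > 0.99 and GC
    decorrelation after the full correction stack."""
    sim = simulation.SimulationConfig(n_chroms=2, chrom_length=125_000_000,
                                      bin_size=500_000, seed=2)
    bins = simulation.simulate_bin_table(sim, rng)
    counts = simulation.simulate_cell_counts(sim, bins, rng=rng)
    prof = nm.normalize_counts(counts, bins)
    qc = nm.quality_metrics(prof)
    assert qc["uniformity"] > 0.99
    gc = prof.bins["gc"].to_numpy()[prof.usable]
    rho = spearmanr(prof.ratio[prof.usable], gc).statistic
    assert abs(rho) < 0.1
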