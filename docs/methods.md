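# Methods

## Model

Low-pass sequencing of LM-PCR–amplified single-cell DNA yields read counts
per fixed-size genomic bin that are, in expectation, proportional to

    E[count_b] ∝ copy_number_b × representation_b × bias(gc_b) × mappability_b

where `representation_b` is the size-selection-weighted number of MseI
restriction fragments in the bin (only fragments of amplifiable length are
observable) and `bias(gc)` is a unimodal amplification/sequencing
efficiency curve.  All inference reduces to estimating `copy_number_b` up
to a global scale — the cell's main ploidy — and then fixing that scale.

### Genome representation

MseI cuts `T^TAA`; the cut offset within the motif is fixed at 1.  The
exact convention is immaterial at bin scale (fragment lengths shift by
≤ 3 bp under alternatives) but is pinned for reproducibility.
Overlap-aware motif scanning is used even though TTAA cannot self-overlap,
so the digester is correct for arbitrary motifs.  Fragments tile each
chromosome; each is assigned to the bin containing its midpoint, which is
unambiguous and conserves totals.  Trailing partial bins are dropped so
every retained bin has identical length and no per-bin length correction
is needed downstream.  The size-selection weight defaults to a log-normal
density (median 350 bp, log-sd 0.5) supported on [50, 3000] bp — a
unimodal right-skewed shape; any tabulated length→weight map can be
substituted.

### Counting rules

A read spanning bins goes to the longest-overlap bin, ties to the
leftmost (deterministic, order-free).  A read overlapping two or more
restriction fragments is discarded in fragment-level counting, since a
sequenced molecule derives from exactly one amplified fragment.  The read
interval is the aligned reference span; duplicates are not removed
(a documented limitation — at these depths duplicate rates are low, and
the upstream chemistry makes true duplicates indistinguishable from
independent amplicon reads).

### Normalization

Order: GC first, then mappability, then median centering.  GC correction
divides by a robustified LOWESS fit of count on GC (neighbourhood fraction
0.15, 3 re-weighting iterations).  The span was chosen so that a strongly
curved bias (20-fold across the GC range) leaves no systematic residual
trend — wider spans leave a monotone few-percent residual at the GC
extremes that shows up as spurious ratio–GC correlation.  Bins whose
fitted expectation falls below 10% of the median fitted expectation are
marked unusable: at a few hundred thousand reads such bins expect only a
handful of reads, carry no usable copy-number signal, and dividing by a
near-zero fit manufactures extreme ratios that would otherwise contaminate
segmentation and the ploidy density.  Mappability divides the corrected
value, with a hard usability floor at 0.85 (the unique-match rationale: a
bin where many positions are ambiguous cannot be rescued by rescaling).
The 3-sd outlier rule seen in representation diagnostics is reported as a
flag only, never used as a filter.

DLRS uses the sample sd of consecutive log2-ratio differences within
chromosomes divided by √2 (the standard array-QC definition); pairs
spanning chromosome boundaries are excluded.

### Panel blacklist

Per bin, the median ratio across ≥ 2 normal profiles; strict thresholds
(> 1.4, < 0.6).  A bin is evaluable when usable in more than half of the
panel.  Runs of adjacent flagged bins merge into regions; a run is split
where the flag direction changes, so each region carries one direction.

### Segmentation and calling

Per chromosome, recursive binary splitting of the usable-bin ratio vector
minimising residual sum of squares; a split is accepted when the RSS gain
exceeds `penalty · σ̂² · log n` (penalty 2.0), with σ̂ from the median
absolute consecutive difference (MAD of first differences / 0.9539, robust
to true copy steps).  Segments shorter than 3 bins merge into the
neighbour with the closer mean.  This is a deliberately simple,
deterministic changepoint scheme: the workflow's contract is a
piecewise-constant fit with controlled false splitting, not a specific
third-party algorithm.

Copy number is `round(mean_ratio × P)` (half away from zero, floored at
0); class is gain/loss/neutral relative to the main ploidy P.  Candidate
(non-neutral) segments are tested against the pooled bins of all neutral
segments genome-wide with both the Wilcoxon rank-sum and the two-sample
KS test; a call requires both p < 0.01.  The comparison population is a
design choice (segment vs flanks and segment vs whole genome are
alternatives); neutral-background pooling gives the tests maximal power at
shallow depth while anchoring them to the cell's own noise.  Calls whose
genomic span overlaps the blacklist by more than 50% are removed.

Mbp tallies (`mbp_gained`, `mbp_lost`) count usable bins × bin size, so
gained + lost + neutral always equals the usable genome exactly; reported
call coordinates span from the first to the last bin of the segment.

### Absolute ploidy

For each candidate P in 2..8:

1. multiply the centered ratio by P and smooth within chromosomes —
   running median then running mean, both of width 5 bins.  The median
   pass removes isolated spikes, the mean pass softens residual noise;
   steps survive within one window.  This simple robust smoother stands in
   for a published adaptive smoother whose algorithm is not described; the
   contract is "attenuate isolated spikes, preserve steps".
2. Gaussian KDE with Silverman's rule of thumb
   `h = 0.9·min(sd, IQR/1.34)·n^(−1/5)`; a manual bandwidth override is
   supported.  Silverman's rule needs the genome-scale sample (~5,000+
   bins at 500 kb) to resolve unit-spaced modes; at toy genome sizes the
   bandwidth is too wide and adjacent copy levels merge.
3. modes by continuous-wavelet-transform ridge detection (Ricker kernel,
   scales spanning ~1–10% of the grid), snapped to density maxima; a plain
   local-maxima finder is retained as a cross-checked fallback.  A mode's
   probability contribution is the density mass integrated over its basin
   (between flanking minima); modes under 2% are dropped.  Masses of
   dropped modes are not re-attributed, so reported masses sum to ≤ 1.
4. OLS of mode position on rounded mode position **with an intercept**.
   The intercept absorbs the small systematic shift introduced by
   smoothing and finite bandwidth; with it the regression reproduces the
   published diagnostic values for the reference peak set
   (1.0, 1.97, 2.94, 3.82, 4.67 → SSR 0.008, R² 1.0) which a
   through-the-origin fit does not (SSR ≈ 0.022).
5. selection: candidates need R² > 0.98 **and** a per-copy slope in
   [0.8, 1.2]; among those, the lowest ploidy whose SSR is within 25% of
   the minimum wins.  The slope window encodes the physical constraint
   that at the true ploidy modes sit one copy apart: when only consecutive
   copy levels are detected, every candidate is perfectly linear and SSR
   scales as P², so R²/SSR alone degenerately prefer the smallest P.  The
   SSR tolerance automates the observation that exact multiples of the
   true ploidy fit equally well and the lowest plausible one should be
   chosen.  Both rules together replace what is otherwise a manual review.

A profile that is unimodal at every candidate (e.g. a flat normal cell)
offers nothing to regress on; the pipeline then reports main ploidy 2,
the lowest plausible value for a profile consistent with any ploidy.

### Evaluation

Comparisons run in fixed windows tiling the binned genome; windows with
fewer than half their bins usable are excluded.  A window is truly altered
if any reference call overlaps it (type and magnitude ignored).  The ROC
score of a window is −log10 of the Wilcoxon p of the non-neutral segment
covering it (0 on neutral territory), so the AUC sweep is a p-threshold
sweep; AUC is the Mann–Whitney rank statistic.  Specificity on an
expected-flat profile is the fraction of windows untouched by any call.
Profile agreement is the squared Pearson correlation of per-window mean
ratios over mutually usable windows.

## Simulation: what it emulates and what it does not

The bin-level generator fabricates an annotated bin table directly: a
smooth GC landscape (two random-phase sinusoids plus white noise, clipped
to [0.3, 0.7]), restriction-site density `((1−gc)/2)^4` per bp (the iid
expectation for an A/T-only motif — monotone decreasing in GC, which
reproduces the observed anticorrelation between fragment density and GC),
mappability near 1 with a 2% admixture of low-mappability bins, and a
Beta-shaped amplification bias peaking near GC 0.45.  Counts are
multinomial over bins given a total read budget with per-bin Gamma
multipliers (dispersion 0.1 by default) for over-dispersion beyond
Poisson.  Thinning a deep dataset binomially models subsampling of one
sequencing run, sharing the amplification noise between depths exactly as
resampling of real alignments does.

The sequence-level generator writes actual sequence with planted TTAA
sites at the same GC-dependent rate and repairs accidental occurrences, so
digestion/annotation/counting can be verified base-accurately; it is used
at small scale.

Not emulated: sequencing errors and alignment artifacts; WGA chimeras;
locus-specific (non-GC) amplification bias beyond the shared bad-bin
factors of the normal panel; allelic structure.  Passing tests therefore
demonstrate the statistical machinery under the stated noise model, not
robustness to every artifact of real libraries.

## Problem sizes and defaults

Benchmark analogs run at desk scale: flat-sample specificity on 2,000 ×
200-kb bins at 400k reads with a 10-cell panel blacklist; uniformity on
~1,000 × 500-kb bins at 500k reads; subsampling AUC on a 320-Mb-equivalent
genome simulated at 100-kb atoms (12 planted CNAs of 8–16 Mb, ~36% of the
genome, copy numbers 1–4) at 3.5M reads thinned to 200k, aggregated to
100 kb–2 Mb; ploidy recovery on ~5,700 × 500-kb bins at 1M reads — the
bin count at which Silverman bandwidth resolves unit-spaced modes, which
is also the genome-scale operating point of the workflow.

Every threshold is surfaced in `PipelineConfig` with its standard default:
bin size 500 kb; blacklist 1.4/0.6; alpha 0.01; uniformity threshold 0.2;
coverage threshold 0.6; peak mass 0.02; R² 0.98; ploidy range 2–8;
LOWESS span 0.15 × 3 iterations; mappability floor 0.85; representation
floor 0.1; segmentation penalty 2.0; minimum segment 3 bins; smoothing
window 5; SSR tolerance 0.25; slope window 0.8–1.2.

## Numerical notes and edge cases

* Rounding of ratios and peak positions is half-away-from-zero; ties at
  .5 therefore round up for positive values.
* Zero-variance KDE input returns a flagged single point mass; a density
  with no mode above the mass threshold is a hard error
  ("uninterpretable density").
* GC of a bin with no determined base is undefined (NaN) and the bin is
  unusable; bins with > 50% N are masked outright.
* All randomness flows through one `numpy.random.Generator`; identical
  seeds give byte-identical outputs, including the simulators.
* Segmentation is exactly deterministic; appending an all-masked
  chromosome does not change existing segments.

## Known limitations

* No duplicate-read handling and no allele-aware analysis (no usable
  allelic signal at these depths).
* Calls are bin-resolution; breakpoints are not refined to reads.
* The ploidy scan needs ≥ 2 resolvable copy-number modes; cells with
  almost no CNAs are reported at the fallback ploidy 2.
* Sub-clonal fractions are not modelled; segments are assumed clonal.
* The blacklist models direction-consistent systematic bins; variance
  outliers without a median shift are not flagged (they are instead
  suppressed by the representation and mappability floors).
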