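# Methods

## The detection model

A centroided spectrum is reduced to a peak-density profile: the count of
peaks in a half-open sliding window `[c - w/2, c + w/2)` of width
`window_width` (default 1 m/z), evaluated on a grid anchored at
`mz_range.lo + w/2` and stepped by `step` (default 0.1 m/z). Counting uses
two binary searches per window on the sorted m/z array, vectorized over
the whole grid. Raw density is not thresholdable directly — density falls
with m/z (signal-to-noise and digitization both decline), and the decline
differs by instrument — so each test window is instead scored against its
own neighborhood.

`n_pairs` (default 2) pairs of reference windows, each `ref_width`
(default 3 m/z) wide, tile outward from the test window with no gaps: pair
*k* occupies `[c - w/2 - k*ref, c - w/2 - (k-1)*ref)` and its mirror
image. For pair *k*, the mean `mu_k` and population standard deviation
`sigma_k` are pooled over the density-profile values whose full windows
lie inside the pair's two reference windows (21 values per side at the
defaults). The score is one-sided and chi-squared-inspired:

    S_k = ((d - mu_k) / max(sigma_k, sigma_floor))^2   if d > mu_k, else 0
    S    = max_k S_k

Maximizing over pairs preserves sensitivity when the nearer reference pair
itself overlaps an artifact: the contaminated pair's inflated mean and
sigma suppress its own score, and the cleaner, farther pair wins the max.
At the spectrum ends only reference windows that fit inside the
acquisition range are used; a center with no usable window scores 0.

Runs of consecutive grid centers with `S > threshold` (default 100,
strictly greater, i.e. ten reference standard deviations) whose center
span reaches `min_region_width` (default 0.3 m/z, smaller than any
credible fuzzy site) are reported as regions `[first - step/2,
last + step/2)` with the run's maximum S and the enclosed peak count.

### Numerical choices

- **`sigma_floor` = 1 count.** Reference windows over sparse stretches can
  have `sigma_k = 0` (and a flat synthetic comb has exactly 0); flooring at
  one count means densities are never compared on a sub-single-peak scale
  and the statistic stays finite. It also makes the threshold boundary
  exact on constructed inputs: a window with exactly 10 extra counts over
  a zero-variance background scores S = 100 and is *not* called.
- **Population (not sample) sigma** over the pooled per-pair values; the
  values are heavily overlapping windows, so no independence correction is
  meaningful either way.
- **Half-open `[lo, hi)` intervals everywhere** (windows, regions, feature
  tainting), so boundary peaks and features are counted exactly once.
- **Span tolerance of 1e-9 m/z** when testing a run against
  `min_region_width`, so a 4-center run at 0.1 m/z spacing (span 0.4) is
  never lost to float accumulation while a 3-center run (span 0.2) is
  never promoted.
- Degenerate geometry (acquisition range narrower than the window, no
  fitting reference windows) yields an empty profile or S = 0 with a log
  message, never an exception.

## Consistent regions and filtering

Per-sample regions are merged on an occupancy grid of `grid` = 0.1 m/z
(the detector step, anchored at m/z 0): a bin's occupancy is the fraction
of cohort spectra with any HPD region overlapping it, bins at or above
`min_fraction` (default 0.10) merge into maximal contiguous consistent
regions. The grid formulation is order-independent and
resolution-matched; interval clustering would move borders slightly but
not membership at this granularity. Spectra with no called regions count
in the denominator. With `min_fraction = 0` the result is the bin-level
union of all per-sample regions; above 1 it is empty.

Feature filtering treats "present" as a non-missing, non-zero value.
`sample_specific` blanking stores missing (not zero) so downstream
presence logic stays unambiguous; features absent from every sample after
blanking are dropped. `consistent` removal drops tainted features
globally, which is what makes it non-encoding: the retained m/z set is
identical across samples, so a classifier cannot read class membership
out of the missingness pattern. The prevalence filter requires exactly
two classes and drops a feature when its presence fraction falls strictly
below `min_fraction` (default 0.25) in *either* class.

## The simulator: what it emulates, and what it does not

The generator reproduces the detectable phenomenology of DI-FT-MS
artifacts, not instrument physics:

- **Baseline**: an inhomogeneous Poisson process whose rate decays
  exponentially from `baseline_rate` (default 6 peaks per m/z at the low
  edge) with decay length `baseline_decay` (default 2000 m/z, i.e. about a
  two-fold decline over a 150–1600 m/z acquisition, ~6-7k noise peaks per
  spectrum — typical of an intensity-thresholded peaklist). Noise
  intensities are log-normal around `noise_median` (1e3).
- **Signal peaks**: fixed m/z with 5e-4 m/z per-draw jitter — far below
  the 0.1 m/z grid, so genuine compounds never trigger the detector and
  correspond nearly perfectly between scans; intensity 1e6 by default.
- **Fuzzy sites**: uniform extra peaks at `multiplier` (default 10) times
  the *local* baseline density over a 0.5–3 m/z interval; intensities from
  a truncated normal between the noise median and half the signal
  intensity (the "intermediate intensity, Gaussian-like" signature). At
  scan level only a uniformly placed sub-interval of fractional width
  `scan_coverage` is populated, re-drawn each scan: pairwise sub-interval
  overlap has the closed-form probability `1 - ((1-2f)/(1-f))^2` (f < ½),
  scan-to-scan correspondence inside a site is accordingly poor, and
  aggregate in-site counts grow linearly with scan count while the
  envelope fills in.
- **Ringing**: `count` symmetric side peaks at `± k*spacing` around an
  existing intense peak with geometrically decaying intensity, injected at
  scan level (aggregate-level injection is labelled partial ringing).
- **Cohorts**: two classes share one site list; each class's site centers
  are shifted by per-class offsets (default: class B shifted 2 m/z, 12 m/z
  for the highest-m/z site, matching the observed magnitude of
  class-dependent location shifts). True biology is modelled as shared
  signal peaks of which a subset differs two-fold between classes with
  log-normal between-sample noise (sigma 0.3); signal positions are kept
  5 m/z clear of all site intervals so biology and artifact are separable
  by construction. The feature table emulates peak assignment: candidate
  m/z values (signal positions plus positions sampled inside every
  class's sites) are matched within ±0.05 m/z against each sample's
  aggregate spectrum, taking the maximum matched intensity, missing on no
  match. Artifact-feature positions therefore match dense site peaks in
  their own class and occasional baseline noise in the other — which is
  why many of them survive a 25% prevalence filter and can hijack a
  classifier, exactly the failure mode the filtering exists to remove.

Default site placement for the bundled cohort: centers 300, 550, 800,
1100, 1400 m/z with widths 0.8, 1.2, 1.6, 2.2, 3.0 m/z (width grows with
m/z, as observed for real fuzzy sites).

What passing tests on this generator do **not** show: performance on real
spectra with chemical fine structure (isotopologues, charge states,
adducts), intensity-dependent centroiding errors, correlated noise, or
fuzzy sites whose internal spacing is structured in the frequency domain
rather than uniform in m/z. The published sensitivity/specificity of the
approach on manually inspected real spectra depends on human labels and
is deliberately not a claim of this package.

## Classifier harness

`rf_importance_ensemble` trains `n_forests` (default 20) scikit-learn
`RandomForestClassifier`s with default hyperparameters apart from
`n_estimators` (default 1000), forest *i* seeded `seed + i`. Importances
are mean decrease in impurity, averaged across forests (invariant to
forest order); ranking ties break by m/z ascending. Per-class error is
out-of-bag — whether the original report's errors were out-of-bag or
held-out is not documented, and OOB needs no extra split at these cohort
sizes; samples without OOB votes in a forest (rare, small tree counts
only) are excluded from that forest's error. Missing feature values enter
as zero intensity.

## Boundary accuracy: definition and expectation

A 1 m/z test window smears site edges: on the density ramp into a site of
extra density `m*lambda`, S stays above threshold while the window-site
overlap exceeds roughly `sqrt(lambda)/ (m*lambda)`, so a called edge sits
a few tenths of an m/z outside the true edge, with Poisson jitter on top.
Recovery is therefore scored in two parts: a truth site counts as
*recovered* when any called region overlaps it, and boundary accuracy is
the *mean* absolute offset between matched region edges and truth edges
(per-instance offsets are noisy; their mean is the stable cohort-level
accuracy). Under the default conditions the suite measures 100% recovery
over 250 site instances with mean per-edge error ≈ 0.16 m/z, and all five
distinct sites covered by consistent regions; the one-sided statistic
additionally yields ~1 spurious region per 100 artifact-free spectra.

## Scaling of the bundled experiments

The suite and the acceptance script run the cohort experiments at 50
spectra (recovery), 2 x 10 samples (classification) and 20 forests x 200
trees, sizes at which every measured property is already stable while a
full run stays in the tens of seconds. With only ten samples per class a
single reassigned sample moves a per-class OOB error by 10 points, so the
error-change quantity is intrinsically granular at this cohort size;
the library defaults (1000 trees) remain the published operating point.

## Known limitations

- No per-peak artifact probability: whole regions are flagged, so genuine
  peaks consistently co-located with a fuzzy site are discarded with it.
- Consistent-region removal discards more spectrum as cohorts and classes
  grow.
- The uniform-in-m/z placement of fuzzy-site peaks is a stand-in; no
  quantitative model of their internal spacing is available.
- The prevalence filter and cohort generator support exactly two classes;
  multi-class extension is mechanical but unimplemented.
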