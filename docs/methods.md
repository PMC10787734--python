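# Methods

This note documents the models and procedures implemented in
`masstaxa`, the assumptions behind them, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Spectrum conditioning

A raw fingerprint is a profile-mode spectrum: intensities on a
near-uniform mass grid (Da), non-negative, with a smooth chemical
background and detector noise. The conditioning chain is applied in a
fixed order; each stage is a pure function:

1. **Trim** to a common window, default 2000–20000 Da (closed interval
   on both ends). All library spectra must cover the same axis before
   peaks can be compared.
2. **Square root** of the intensities. Ion counts are Poisson-like;
   the square root approximately stabilizes their variance.
3. **Savitzky–Golay smoothing** on the *sample index* (not the Da
   axis): each point is replaced by the centre value of a least-squares
   polynomial of degree `sg_polyorder` (default 3) fitted to the
   `2·sg_half_window+1` surrounding points (default half-window 10).
   At the spectrum edges the window is truncated and the fit repeated
   on what remains, so the local-polynomial contract holds at every
   index; the interior is delegated to `scipy.signal.savgol_filter`
   and the whole output is checked in the tests against a brute-force
   per-index least-squares oracle. Negative overshoot — possible only
   where the signal sits at the noise floor — is clamped to zero to
   preserve the non-negativity invariant of the container.
4. **SNIP baseline subtraction.** The baseline estimate is the
   clipping recursion `y_i ← min(y_i, (y_{i−k}+y_{i+k})/2)` with the
   window `k` growing from 1 to `baseline_iterations` (default 22; a
   decreasing schedule is available because published implementations
   differ in direction). Points closer than `k` to an edge are left
   unchanged at that `k`. The estimate is pointwise ≤ the input;
   linear and constant signals are fixed points; on smooth convex
   backgrounds with sparse narrow peaks the relative error away from
   the edges stays below 5 % (an acceptance test asserts this on
   `a·exp(−b·m)` baselines). More iterations remove wider structures
   and progressively erode low-intensity peaks — which is exactly why
   the iteration count is a tuning parameter of the workflow. The
   sqrt/log-log-sqrt transform some SNIP variants apply internally is
   *not* used here: the chain's global square root precedes baseline
   estimation. Negative residuals after subtraction are clamped to 0.
5. **TIC normalization**: intensities are divided by their sum, making
   spectra comparable across specimens with different absolute signal.

## Peak picking and binning

**Noise** is `1.4826 × median(|I − median(I)|)` over the whole
conditioned spectrum — the MAD made consistent with a Gaussian σ. A
degenerate constant spectrum falls back to a machine-epsilon-scale
value with a warning. Local-noise windows are not implemented; the
global estimate matches common practice for this spectrum class.

**Peak picking**: point *i* is a peak iff its intensity exceeds
`snr × noise` *and* is strictly greater than every other intensity in
`[i−hws, i+hws]` (sample points). Exact ties keep the leftmost point,
making detection deterministic and order-independent. Raising `snr`
or `hws` can only remove peaks (tested as a monotonicity property).
Defaults `snr = 3`, `hws = 7` are the workflow's standard settings.

**Strict binning** makes peaks comparable across spectra. All peaks
are pooled and sorted; a candidate group becomes one bin iff (a) every
member is within `bin_tolerance × mean` of the group mean (default
relative tolerance 0.002) and (b) no spectrum contributes two peaks.
A violating group is split at its largest internal mass gap (leftmost
on ties) and the rule re-applied. The bin's feature mass is the mean
of its members; members are re-labelled to it. Because re-labelled
peaks can merge further, binning is repeated until the feature count
is unchanged between two successive passes; the count is
non-increasing and bounded below, so termination is guaranteed.

**Feature matrix**: one row per specimen (technical replicates
averaged per feature by default; a `separate` policy keeps one row per
replicate for sensitivity analyses), one column per converged feature
mass, zero where a specimen lacks the peak. All-zero columns are
dropped with a warning. Replicates are averaged on the TIC intensity
scale *before* the Hellinger transform — the transform is applied to
the row a classifier will actually see.

**Hellinger transform**: `x′ = sqrt(x / Σx)` per row, so squared row
values sum to 1. It removes residual per-specimen scale and tempers
dominant peaks, which benefits tree ensembles on composition-like data.

## Quality screening

The atypicality score of a TIC-normalized spectrum is its intensity
arc length divided by its maximum, `A = Σ|I_{i+1} − I_i| / max(I)`.
Smooth fingerprints score low; noisy or distorted measurements zig-zag
and score high. Scores are compared against Tukey fences over the
collection: above `Q3 + 1.5·IQR` → `review` (check by eye, as in
practice), above `Q3 + 3·IQR` → `discard`. If discards leave a species
with a single specimen, that specimen is discarded too — one specimen
cannot anchor a species in a supervised library. The score is an
explicit re-specification of the screening idea, not a
re-implementation of any particular package's statistic, and is
documented as such.

## Identification and the post-hoc test

`FingerprintClassifier` wraps a random forest (default `ntree = 2000`,
`mtry = 35`; `mtry` is clamped to `floor(sqrt(n_features))` with a
warning when the matrix is narrower). Alongside the OOB error the
fitted model stores, per class, the OOB assignment probabilities — the
fraction of out-of-bag trees voting the true class — of every training
row of that class. These empirical distributions power the post-hoc
test: a query's vote fraction is compared with the predicted class's
stored distribution, `posthoc_p = mean(stored ≤ prob)`, and the
identification is **accepted** iff `posthoc_p > α` (default 0.05).
Specimens of species absent from the library receive scattered votes,
fall below the stored distribution and are rejected — the false-
positive guard of the workflow. Vote-fraction ties between classes
resolve lexicographically (deterministic). Rows that were never out
of bag (essentially impossible at practical `ntree`) are excluded from
the stored distributions with a warning.

With `n` stored probabilities per class, an exchangeable in-library
query is accepted with probability at most `1 − 1/(n+1)` (it must not
fall below the stored minimum), so acceptance rates are read against
the library depth: 8 specimens per species cap acceptance near 89 %,
16 near 94 %. The post-hoc calibration analyses therefore use a
library with 16 specimens per species.

**External queries** are aligned to a model's feature masses by
re-binning: the feature masses enter the strict binning recursion as
anchor peaks and each query peak is assigned to the feature anchoring
its bin. This resolves assignments between adjacent features the same
way training-time binning would; raw nearest-distance matching
mis-assigns jittered peaks near bin boundaries. Unmatched query peaks
are dropped with a warning; zero overlap is an error.

**Evaluation protocols.** Leave-one-specimen-out identification
removes *all* technical replicates of the held-out specimen before
retraining (preventing replicate leakage), identifies it, and reports
the fraction correct and correct-and-accepted, overall and per
class/phylum; species enter only with at least `min_specimens`
(default 6) specimens. Higher-taxon fallback removes a species
entirely, trains at class or phylum level on the rest and classifies
the removed specimens; species that are sole members of their category
are skipped with a warning. Congeneric affinity removes each species
with a congener present and records how often its specimens are
assigned to a congener, specimen-weighted overall. Gini importance
ranks features by mean decrease in impurity, with per-class mean
Hellinger intensities for heat-map display. Bootstrap clustering
builds an average-linkage (or Ward) tree on Euclidean distances of
Hellinger rows and reports, per internal node, the percentage of
feature-bootstrap replicates in which the node's exact leaf set
reappears; the tree is exported as newick with supports as node names.

## Processing-parameter optimization

`grid_search` evaluates the full Cartesian product of baseline
iterations × HWS × SNR by running the entire pipeline per grid point
and recording feature count and OOB error; preprocessing is shared
across grid points with equal baseline iterations, and each point's
forest seed derives from the master seed plus the grid coordinates, so
any row is reproducible in isolation. A grid point yielding no
features is recorded with OOB error 1.0 and flagged. The recommended
setting is the OOB-error argmin; ties break by fewer features, then
lower SNR, lower HWS, lower baseline iterations. The standard ranges
5–30 × 5–30 × 3–20 span 26·26·18 = 12 168 combinations.

`fit_gam` fits a binomial (logit) GAM of the OOB error — as a
proportion with a specimens-per-analysis denominator (`weights`,
scalar or per-row; the weighting is exposed because it is a modelling
choice, not a given) — on the three parameters. Nonconstant predictors
with enough distinct values get penalized B-spline smooths (basis
dimension ≤ 5; effects of these parameters are nearly monotone, so
small bases suffice), others enter linearly; constant predictors are
dropped with a warning. Per-term effective degrees of freedom come
from the penalized hat-matrix trace; significance is a likelihood-
ratio chi-square against the refitted model without the term, on the
term's edf. The Wald route through the backend's penalized covariance
was rejected after it proved badly miscalibrated (orders of magnitude
weaker than the deviance drop on the same strong effect). The penalty
weight is fixed (default 1.0) and deterministic; data-driven penalty
selection was far too slow for grid-scale use and is unnecessary for
driver detection.

`specimen_saturation` samples `n` specimens per species (without
replacement, per-(n, replicate) derived seeds) from species with at
least `min_pool = 11` specimens, trains a forest and records the OOB
error, for `n` over an inclusive range or an explicit list, summarized
as mean/SD/min/max per `n`. Mean OOB error decreases as specimens per
species grow — the library-sizing curve.

## Synthetic fingerprint libraries

The generator produces the structure the workflow assumes: species
nested in genera, classes and phyla; each species defined by peak
masses partly inherited from its higher taxa (phylum/class/genus-
shared) and partly species-specific; several specimens per species
with 2–3 technical replicates. A measurement places Gaussian peaks
(σ 15 Da) at the species' masses — jittered by ~200 ppm per replicate,
scaled by per-specimen lognormal multipliers (CV 0.5), with per-peak
Bernoulli dropout (p 0.15 per specimen, shared by replicates) — on an
exponentially decaying baseline `2·exp(−2.5·10⁻⁴ m)` with additive
Gaussian noise (sd 0.02), sampled on a uniform 2 Da grid over
2–16 kDa. Everything derives from `(seed, species, specimen,
replicate)`, so any single spectrum is reproducible.

Defaults describe a desk-scale reference library: 20 species (2 phyla
× 2 classes × 5 genera), 8 specimens × 2 replicates, 78 peaks per
species (12 phylum- + 20 class- + 6 genus-shared + 40 specific),
within-species peak separation ≥ 50 Da. Two realism constraints shaped
these numbers. First, spectra must be *peak-rich*: when most of the
mass axis is signal-free, the MAD noise floor sits on the quiet-region
fluctuations left by baseline subtraction (SNIP tracks the lower noise
envelope, leaving a positive offset) and SNR-thresholding then fires
on noise regardless of the noise amplitude — an effect that is
scale-free and disappears only when the whole-spectrum MAD reflects
signal-scale variation, as it does in real fingerprints. Second, the
sampling grid must be fine relative to the binning tolerance (0.002
relative ≈ 8 Da at 4 kDa); a coarse grid quantizes peak positions
enough to corrupt query-to-model feature alignment. Uniqueness of
masses is enforced within a species only; unrelated lineages may
collide, as in real libraries.

Named presets construct the study scenarios: `hierarchy` (16 species,
2 × 2 × 2 × 2, strong class-shared peaks) for fallback and congeneric
analyses; `cryptic` (two species with identical masses, intensities
differing ≥ 2× on half the peaks) — separable by intensity pattern
alone; `sex` (sex-exclusive masses plus shared peaks, with an outgroup
species); `low_intensity` (diagnostic peaks deliberately faint, with
post-pipeline SNR between 3 and 15, so low SNR thresholds win the grid
search; genus-level peaks are faint too because with one species per
genus they would otherwise identify species outright); `hard` (few
specific peaks, CV 0.9, dropout 0.25 — for saturation curves, where
two specimens per species must genuinely not suffice).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: isotopic envelopes and adducts, detector
saturation, mass-dependent resolution and calibration drift, chemical
noise with structured (non-Gaussian) statistics, correlated peak
intensities within protein families, and real biological overlap
between closely related species. Identification rates on the synthetic
libraries are accordingly optimistic; they validate the machinery and
its contracts, not field performance.

## Problem sizes and runtime choices

The test and acceptance runs use the 20-species default library
(320 spectra), forests of 200–500 trees for evaluation loops
(leave-one-out retrains one forest per specimen; OOB error is
insensitive to forest size beyond a few hundred trees at these matrix
dimensions), saturation at 25 replicates per `n`, and the full
12 168-row grid only as a cardinality check — grid *evaluations* in
tests use small targeted grids. The complete acceptance script runs in
a few minutes on one CPU.

## Known limitations

- mzML support is read-only and minimal (first spectrum, standard
  base64/zlib encodings); vendor raw formats are out of scope.
- The quality score is a re-specification, not bit-compatible with any
  published screening tool; review-flagged spectra still need eyes.
- The GAM backend's fixed penalty weight makes per-term edf mildly
  penalty-dependent; p-values are calibrated by simulation (null terms
  non-significant, planted drivers detected) rather than by asymptotic
  theory.
- The post-hoc test is an empirical left-tail proportion; with few
  specimens per species its acceptance rate is capped combinatorially
  (see above), so thin classes reject a larger share of valid queries.
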