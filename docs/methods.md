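# Methods

This note documents the models, algorithms and numerical choices behind the
package, in the spirit of a methods appendix: what is computed, under what
assumptions, and where the genuinely open design decisions were settled.

## Microstate model and pipeline

The EEG is treated as a sequence of instantaneous scalp topographies. At
each sample the global field power (GFP) — the spatial standard deviation
of the average-referenced potentials — indexes topographic signal strength;
topographies at *strict* local GFP maxima ("original maps") are taken as
the high-SNR representatives of their neighbourhood and are the only
samples used for clustering and back-fitting. Strictness means plateaus
emit no peak; at floating-point resolution exact plateaus occur only in
degenerate inputs. Peaks are never taken across epoch boundaries, because
epochs are discontinuous after artifact rejection.

Resting-state topographies are treated as polarity-free: a map and its
negation are the same microstate. This has two non-obvious consequences
implemented throughout:

- All correlations used for clustering and back-fitting are absolute
  spatial (Pearson) correlations across electrodes.
- Cluster means are computed after **sign-aligning** members to the current
  mean; without this, the polarity inversions of the oscillatory carrier
  cancel the mean to zero.

### Preprocessing

2-s epoching → (downsample to an intermediate rate if above it) → 55–65 Hz
notch → 1–50 Hz band-pass, both as 2nd-order zero-phase (forward–backward)
Butterworth filters applied per epoch → amplitude-threshold epoch rejection
(default ±100 µV; a deterministic, reproducible surrogate for manual
artifact review) → average reference → 1–30 Hz analysis band → 200 Hz.
Montage subsetting (19 or 8 electrodes from the 30-channel set) happens
*after* preprocessing, followed by re-referencing over the remaining
channels. Spectral band powers (δ 1–3.5, θ 4–7, α 8–12, β 12–30 Hz;
mean periodogram over epochs and channels) are computed on the broadband
(1–50 Hz) stage; relative power is each band's share of total 1–30 Hz
power — the analysis band, chosen because the band set itself stops at
30 Hz.

### Clustering

**TAAHC** starts from singleton clusters and repeatedly atomizes the worst
cluster — lowest summed member-to-mean |correlation| — reassigning its
members sequentially in input order to the remaining cluster of highest
|correlation|, recomputing the receiving cluster's sign-aligned mean after
each insertion, until K clusters remain. All ties break toward the lowest
cluster index, making the algorithm fully deterministic given the input
order.

**Modified k-means** seeds each restart with K distinct maps drawn at
random, alternates |correlation| assignment with sign-aligned re-averaging,
and stops when GEV improves by less than 1e-7 (cap 1000 iterations); a
cluster that empties keeps its template. The best of 300 restarts (50 in
the desk-scale profile) by GEV is returned. The RNG is an explicit seeded
generator, so results are reproducible.

Three derivation strategies share a first level that clusters each
recording's original maps into K = 4 maps: *global* pools all first-level
maps (4 × n_recordings) into a second round of clustering; *by session*
pools within sessions; *by recording* stops at the first level. First-level
maps are GFP-normalized before pooling. Map sets are label-matched (A–D) to
the global TAAHC solution by exhaustive assignment maximizing total
|correlation|; K is fixed at 4 a priori. The cross-validation criterion
`CV = σ̂²·((n−1)/(n−1−K))²`, with σ̂² the mean residual variance of maps
about their assigned templates, is exposed as an optional model-order
diagnostic only — it is sensitive to electrode count and is not used to
pick K.

A caution from validation: best-of-restarts k-means provably attains the
exhaustive-search GEV optimum only on *clusterable* inputs (prototypes plus
noise, every prototype represented). When K exceeds the number of real
clusters, the GEV-optimal partition need not be a fixed point of the
assignment rule, and k-means can sit measurably below it.

### Back-fitting, smoothing and features

Original maps are labeled with the template of highest |correlation|
(ties toward label order, logged). The label sequence then receives a
light **statistical smoothing**: each peak's class score is its squared
correlation plus 0.2 per same-labeled neighbour within ±1 peak of the same
epoch, iterated simultaneously until stable (cap 20 iterations). This is
the classic correlation-plus-neighbourhood (Besag-style) relabeling adapted
to the GFP-peak sequence. The weight was selected as the argmax of
peak-label *accuracy* against synthetic ground truth across SNR ∈ {∞, 4, 2}
(a flat optimum over 0.15–0.3); smoothing improves accuracy at every noise
level, including the noiseless limit, because isolated low-confidence flips
at dwell transitions are absorbed while confident labels are untouched.
`smoothing_weight=0` disables it, recovering raw winner-take-all labels.

Segments are maximal runs of identically labeled peaks; boundaries between
unlike runs lie at the temporal midpoint between the flanking peaks, and
each epoch's first/last segments are truncated at the epoch edges and
flagged. Features per class and recording: mean lifespan (ms), frequency
(segments per second), coverage (fraction of time). Total time is the
summed lifespan of all segments, so truncated segments **are** included:
this makes coverage ≡ frequency × mean lifespan hold identically and
per-recording coverages sum to exactly 1. Excluding truncated segments is
available for sensitivity analysis but breaks those identities.

## Reliability statistics

The unit of analysis is a subjects × K matrix of one feature under K
repeated measurements (sessions, algorithms, or montages).

- **Cronbach's α** = K/(K−1)·(1 − Σᵢσ²ᵢ/σ²_Y), sample variances over
  subjects, Y the per-subject sum. Numerically identical to ICC(3,k) from
  the two-way subject × measurement ANOVA (verified to 1e-9 against an
  independent decomposition). Undefined (returned as NaN, logged) when the
  between-subject variance of totals is zero — e.g. a generator configured
  with zero between-subject spread.
- **SEM** = √MS_error of the same ANOVA, in feature units. The paper trail
  for SEM formulas is notoriously loose; √MS_error is the choice consistent
  with α-as-ICC(3,k): a pure session shift (every subject changes by the
  same amount) contributes nothing to SEM, exactly as it costs α nothing.
- **SDC₉₅** = 1.96·√2·SEM — the smallest within-subject change
  distinguishable from measurement error at 95% confidence. With an
  overall-lifespan SEM of 6.41 ms this gives 17.77 ms.
- Missing cells (a class absent from a recording) are handled by listwise
  deletion per feature with a logged count. No multiple-testing correction
  is applied anywhere; all p-values are reported raw.

**TANOVA.** Two paired sets of per-subject maps are GFP-normalized and
sign-aligned to the first principal component of the pooled maps — the
polarity-invariant grand topography (a plain grand mean is near zero for
polarity-free maps, so it cannot serve as the alignment anchor). The test
statistic is the GMD between the normalized group means; the null
distribution swaps each subject's pair with probability ½ (default 5000
permutations). Permuted statistics at least as large as the observed one
count toward p: with a strictly-greater rule, identical groups — all
permuted statistics exactly equal to the observed zero — would absurdly
yield p = 0 instead of 1, and for continuous data the two rules differ
only on measure-zero ties. Calibration: the null rejection rate at
p < 0.05 over 200 synthetic null studies sits inside the binomial 95%
interval.

**Regressions.** Overall lifespan and frequency are regressed (OLS) on the
four relative band powers simultaneously. Zero-variance regressors are
dropped with a warning; near-perfect collinearity is flagged via the
design-matrix condition number rather than silently pseudo-inverted.

## Synthetic data generator

The generator emulates a 10-subject × 3-session eyes-closed resting-state
study (30 channels, 120 s per recording at 200 Hz by default) with known
ground truth. What it models:

- **Templates**: four smooth dipolar-gradient maps on frozen 2-D projected
  10-20 coordinates, matching the canonical class geometries
  (right-anterior/left-posterior, left-anterior/right-posterior, symmetric
  anterior–posterior, fronto-central), zero-mean and unit-GFP, pairwise
  |correlation| < 0.7 on all three montages (max ≈ 0.61), individuated by a
  small seed-dependent smooth perturbation.
- **Dwell times**: truncated Gamma, shape 4, floor 30 ms. The scale is
  solved numerically so the truncated distribution's mean equals the
  configured mean (100 ms default; naive parameterization would bias it
  ≈ +2%). Between-subject variability is a per-subject multiplicative
  factor on the mean (SD 10 ms default), shared across that subject's
  sessions — the source of genuine between-subject variance that makes
  test–retest α well-defined.
- **Class sequence**: first-order Markov chain; the transition matrix
  defaults to uniform off-diagonal (no published syntax statistics to
  calibrate against) and is configuration-exposed.
- **Carrier**: each dwell multiplies its template by a 10 Hz sinusoid with
  a fresh random phase, so scalp polarity inverts every half cycle while
  the topography stays fixed — GFP peaks therefore arrive at ≈ 2 × the
  carrier frequency.
- **Noise**: channel-wise Gaussian noise smoothed spatially over electrode
  distance (raw white noise is spatially implausible), band-limited in time
  to 1–15 Hz — eyes-closed background EEG is low-frequency dominated, and a
  background fluctuating slower than the carrier half-period keeps spurious
  GFP peaks rare, preserving the ≈ 2 × carrier peak rate — then
  average-referenced and scaled to the configured signal/noise power ratio
  (SNR 2 default). `snr=inf` yields noiseless recordings.

What it does **not** model, and hence what passing tests do not show about
real data: biophysical volume conduction (templates are geometric, not
lead-field projections), eye-blink/EMG artifacts, non-stationary alpha
power, drift between sessions, electrode placement error. Reliability on
synthetic data is an upper bound: real between-session variance includes
physiological and technical sources absent here.

## Problem sizes and profiles

The default synthetic study is analyzed end-to-end (both algorithms,
global strategy, 30 channels) in roughly two minutes on one CPU. The
desk-scale ("CI") profile reduces k-means restarts 300 → 50 and TANOVA
permutations 5000 → 1000; at both settings the global k-means maps recover
the generator templates with |correlation| well above the 0.95 validation
bar on the default study. The acceptance script uses the full-profile
values. One study seed fans out to
per-stage seeds through independent seed-sequence children, so any stage
can be re-run in isolation with identical results.

## Known limitations

- TAAHC is O(m²) in the number of original maps per recording; very long
  recordings (≫ 10 min at 200 Hz) would benefit from peak subsampling.
- The smoothing weight was calibrated on the generator's signal model; for
  real data with different transition sharpness the weight (or disabling
  smoothing) should be revisited.
- The α/SEM machinery assumes complete subjects × measurements matrices
  after listwise deletion and no subject-by-measurement interaction
  replication; with K = 3 sessions the error term is accordingly coarse.
- EDF files are read (via MNE) but not written; delimited text is the
  native interchange format.
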