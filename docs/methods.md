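# Methods

`pulsecraft` analyses pulsed actomyosin contractions in epithelia from
per-cell time series: apical myosin intensity, apical area and centroid per
cell per frame, plus the cell adjacency graph. This note records the models,
conventions and numerical choices the package implements, and what its
synthetic-data generator does and does not emulate.

## Temporal alignment

Movies are aligned to a common developmental clock. Two conventions are
supported: the time at which the smoothed mean apical area first crosses
below 40 μm² (the typical apical area at the end of cellularization; linear
interpolation between frames), or the onset of net tissue contraction,
detected automatically as the first run of `run_length` frames (default 3)
in which the smoothed mean-area derivative stays below −`slope_tol`
(default 0.05 μm²/s). Smoothing is a centred moving average over
`smoothing_window` frames (default 5). A manual offset in the run
configuration always overrides both. All internal times are seconds;
reported times are relative to the aligned t = 0.

## Pulse detection

The myosin trace of one cell is modelled as

    y(t) = offset + scale·exp(rate·t) + Σᵢ aᵢ·exp(−(t − μᵢ)² / 2σᵢ²)

with the exponential background capturing the developmental ramp of apical
myosin (scale, rate ≥ 0 so the background is non-decreasing) and each
Gaussian one contractile pulse. Pulse duration is enforced by bounding
σ ∈ [10, 30] s; amplitudes are non-negative and means confined to the
observed span. Fitting is bounded trust-region nonlinear least squares;
missing samples are excluded from the objective, never imputed.

Models with n = 1, 2, … Gaussians are fitted iteratively. The (n+1)-model is
warm-started from the n-model with the new component seeded at the largest
positive residual (amplitude = that residual, σ = 15 s), which makes the fit
deterministic and keeps the residual sum of squares non-increasing in n. The
stopping rule is an F test on the reduced residuals,
F = (RSSₙ/dfₙ)/(RSSₙ₊₁/dfₙ₊₁) with dfₙ = N − (3n + 3), one-sided at
α = 0.01 against F(dfₙ, dfₙ₊₁): if adding a component does not significantly
reduce the residual variance, the n-model is retained. The retained model
must finally beat the background-only model by the same test, otherwise the
trace is reported pulse-free. This stopping rule is deliberately
conservative: on long movies where pulses crowd the trace, the first
accepted components absorb only part of the structure and iteration may
stop early, so the detected set is a high-confidence subset. The curation
workflow (below) exists precisely to reconcile such a subset with manual
annotations; on short or sparse traces recovery is essentially exact (see
the detection tests: noise-free recovery to optimizer tolerance, and ≥95%
correct pulse counts with centres within 5 s at signal-to-noise 10).

Detection is equivariant to intensity rescaling (F statistics are
scale-free), so arbitrary intensity units across movies are harmless.

### Curation against manual tracks

Detected pulses are assigned a frame support (centre ± 2σ, rounded to
frames) and matched to manually tracked pulses whenever supports overlap by
more than two frames (configurable). Connected components of the resulting
bipartite graph are categorized: one-to-one, missed by fitting (manual
only), added by fitting (detected only), split by fitting (one manual, k
detected), merged by fitting (k manual, one detected); components with
several tracks on both sides are flagged ambiguous for review. Counts
partition the union of tracks.

## Per-pulse measurements

* **Amplitude bins.** Raw intensities are not comparable across movies, so
  each pulse's Gaussian amplitude is percentile-ranked within its embryo
  (percentile = (ordinal rank − 0.5)/n, ties broken by centre time then
  pulse id) and binned into deciles; bin 10 is the 91st–100th percentile.
* **Area response.** The apical-area series is linearly resampled to a
  standard frame interval (default: the mean frame interval of the loaded
  movies), truncated to 30 s before and 45 s after the pulse centre, and
  mean-centred over that window. Interior gaps are linearly imputed and
  counted; windows reaching past the movie are flagged incomplete and
  excluded from clustering (no extrapolation).
* **Myosin persistence.** (min myosin after the centre − min before) / mean
  over the window, on the same resampled window. The sign convention makes
  residual post-pulse myosin positive, so stabilized (ratcheted)
  constrictions score high. Persistence is invariant to intensity rescaling.
* **Maximum constriction rate.** The resampled area is smoothed with a
  3-frame centred moving average and differentiated by central differences;
  the maximum of −dA/dt over the window is reported (negative when the apex
  only expands — reported, not clipped).

## Behaviour classification

Complete response windows are normalized by their own sample s.d. (shape,
not magnitude; rows with s.d. below 1e−9 or with missing values are
excluded and remain uncategorized) and clustered by fuzzy c-means with
Euclidean distance, fuzzifier m = 2.0, tolerance 1e−6 on the membership
matrix, at most 1000 iterations, random initial memberships. These are the
defaults of the classical implementation of the algorithm. A datum
coinciding with a centroid takes membership 1 there. The FCM objective is
non-increasing across iterations and memberships sum to 1 per datum. The
pipeline entry point restarts FCM from 8 independent initializations and
keeps the lowest-objective solution, because area-response data form a
behavioural continuum on which single starts occasionally settle in
secondary optima.

With k = 3 the centroids are mapped to semantic names by a rule on the
normalized centroid shape: depth d = −min(centroid) and recovery
r = centroid[end] − min(centroid). d < 0.8 → *unconstricting*; else
r ≥ 0.25·d → *unratcheted*; else *ratcheted*. The thresholds reflect two
facts about unit-s.d.-normalized rows: a real class signal pushes a
centroid well below −1 while the centroid of a weak/noise cluster hovers
near 0 (so the flat cutoff sits between those regimes), and the ongoing
tissue contraction in the tail of every window eats into the measured
recovery of genuinely re-expanding pulses (so demanding half-depth recovery
mislabels them; a quarter of the depth separates observed recovery ratios
— ≲0.15 for stabilized vs ≳0.35 for re-expanding centroids — with margin).
If two centroids map to the same name the rule raises an error asking for
threshold adjustment rather than guessing; on ambiguous small samples this
is a legitimate outcome of the continuum. Cluster-count diagnostics
(distortion, mean silhouette, PCA variance fractions, pairwise Rand index
across seeded replicates) are reported but never gate k.

## Temporal statistics

Pulse-timing distributions per amplitude bin or behaviour class are
histograms on shared edges spanning the pooled range (default bin width
30 s), normalized to probability vectors; the per-group s.d. of timing is
reported alongside. Dissimilarity between timing distributions is the
Jensen–Shannon divergence in natural log units,
JSD(R,Q) = ½KL(R‖M) + ½KL(Q‖M) with M = (R+Q)/2 and the 0·log 0 = 0
convention, bounded by ln 2. The pulse-period trend pairs each consecutive
within-cell interval with the midpoint of its two pulse centres and fits
ordinary least squares; the slope is reported in s/min. Class-transition
matrices count consecutive categorized pulse pairs within each cell
(uncategorized pulses are skipped so a transition links the flanking
categorized pulses) and are row-normalized; all-zero rows are flagged, not
normalized.

## Spatial statistics

**Neighbour pulses.** A neighbouring pulse is any pulse in an adjacent cell
whose centre lies within the closed ±15 s window of the central pulse's
centre; same-cell pulses are never counted. Adjacency is taken at the frame
nearest the pulse centre (per-frame lists when available, else static).

**Spatiotemporal pair correlation function.** Pulses are treated as events
(sᵢ, tᵢ) at the pulsing cell's centroid and Gaussian centre, inside a
window W × [0, T] (W is the convex hull of the centroids, or a given
rectangle). The estimator smooths pair offsets with a box kernel in space
(half-width h) and a Gaussian kernel in time (s.d. s) and normalizes by the
expectation of the same kernel product under complete spatiotemporal
randomness in the same window: a Monte-Carlo estimate of the pair-distance
density of W (200k uniform pairs, seeded) times the closed-form triangular
density of |Δt| on [0, T]. This pins ĝ = 1 under CSR on the finite window
without per-pair edge correction; the CSR contract is verified on 3000-event
Poisson patterns (ĝ within [0.85, 1.15] across an interior grid). Default
bandwidths: h = half the median nearest-neighbour distance among distinct
centroids, s = 10 s; both configurable. λ̂ = N/(|W|·T) is reported.

**Connectivity-preserving randomization.** The null for neighbour-pulse
enrichment randomizes which cell each pulse occupies while preserving, per
pulse, its time, class label and local connectivity (the number of
neighbours of the pulsing cell at the pulse's centre frame), and,
statistically, the within-cell inter-pulse interval law. Pulses are
processed in centre-time order; candidates are all cells with identical
connectivity (original included); a uniformly drawn candidate with a prior
placed pulse Δt ago is accepted with probability f(1/Δt)/f(mode), where f
is a gamma density fitted by the method of moments to the empirical pulse
frequencies (reciprocal intervals), and unconditionally when the candidate
has no prior pulse; after 100 failed draws the pulse keeps its original
cell. Normalizing the acceptance by the density mode caps it at 1. The
frequency-domain acceptance is what actually reproduces the empirical
interval distribution under competitive sequential placement (two-sample
KS p > 0.05 in ≈90% of seeded runs at ~500 intervals); an interval-domain
density ratio systematically favours sub-mode intervals and fails that
contract.

**Enrichment Z-scores.** For each behaviour class, the empirical mean
neighbour-pulse count over central pulses (boundary cells are excluded as
centres but still count as neighbours) is compared with the distribution of
the same statistic over 1000 randomization iterations:
Z = (empirical − null mean)/null s.d. Classes' Z-scores are compared by
recomputing both on 200 subsamples of 500 iterations drawn without
replacement and applying a paired t test across subsamples.

**Correlation machinery.** Partial correlation removes a confounder z from
the correlation of x and y; the closed form
(r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) and the residual-regression
definition agree to 1e−12 and both are implemented (the second as a
cross-check route); p-values use the Fisher transform with √(n−3). The
polyserial correlation between a continuous x and an ordinal y is the
two-step maximum-likelihood estimate: thresholds fixed at standard-normal
quantiles of the cumulative level frequencies, x standardized by sample
moments, ρ maximized over (−0.999, 0.999) by bounded scalar minimization
(tolerance 1e−8), with the s.d. from the observed information (numerical
second derivative) at the optimum; boundary solutions are flagged. The
competition analysis pairs each pulse's maximum constriction rate with its
neighbour-pulse count, reports per-amplitude-bin means by neighbour count
and a per-bin polyserial ρ (strata under 5 pulses skipped), and a pooled
partial correlation of rate vs neighbour count controlling for amplitude
bin.

## The synthetic-data generator

The generator emulates a pulsing epithelium during furrow formation well
enough to exercise and calibrate every analysis stage against known ground
truth. Cells sit on a hexagonal lattice (default 10 × 10, 7 μm spacing;
interior connectivity 6; optional periodic wrap making connectivity
uniform), imaged every 6 s.

* **Pulse timing**: per-cell gamma renewal process (shape 3, i.e. CV ≈ 0.58,
  matching the broad scatter of experimental inter-pulse intervals) whose
  mean follows the studied programme — 85 s before t = 0, shortening by
  8 s per minute after (wild-type preset), or 95 s shortening by 2 s per
  minute with no floor reached (Twist-depleted preset); floor 40 s.
* **Pulse classes**: drawn per pulse from a time-dependent mixture — wild
  type: 15% ratcheted before t = 0, 65% after; Twist-depleted preset:
  time-invariant (30/45/25). Unconstricting pulses draw systematically
  weaker amplitudes (factor 0.6), reproducing their enrichment in the low
  amplitude bins.
* **Myosin**: exponential background ramp plus one Gaussian per pulse
  (amplitude mean 40 a.u. at t = 0 growing 4 a.u./min, lognormal scatter
  0.25; σ uniform on [11, 25] s), Gaussian measurement noise s.d. 1.
  Ratcheted pulses additionally deposit a slowly decaying post-pulse
  plateau (30% of amplitude, 200 s decay) so persistence analyses have
  signal with the correct sign ordering.
* **Area**: cells start near the end-of-cellularization area (44 μm²,
  cell-to-cell s.d. 1.5). Net tissue contraction arises mostly from the
  accumulation of ratcheted step-downs (sigmoidal, depth 0.12 μm² per a.u.
  of amplitude, 10 s timescale); unratcheted pulses dip and fully recover;
  unconstricting pulses leave area untouched. A shallow base ramp is solved
  at generation time so the expected mean apical area crosses 40 μm²
  exactly at t = 0 — both alignment modes can therefore be exercised and
  verified. Segmentation-like area noise s.d. 0.8 μm².
* **Neighbour coupling**: optionally, a pulse of a given class triggers a
  pulse in one uniformly chosen neighbour within ±15 s with a configured
  probability; triggered pulses do not cascade. Coupling restricted to
  ratcheted pulses constructs the neighbour-enrichment signature used by
  the end-to-end enrichment test.

Everything is reproducible from a single seed, and ground truth (per-pulse
cell, centre, amplitude, σ, class; graph; coupling events; the raw-clock
time of t = 0) is returned alongside the dataset. A separate fixture
generator renders the three canonical response templates directly (600
windows on the standard −30…+45 s grid, unit-s.d. templates, additive noise
s.d. 0.2) for clustering calibration, and a homogeneous Poisson pattern
generator serves the CSR contract.

What the generator does **not** emulate: mechanical force balance (area
responses are additive templates, not a vertex model), cell rearrangement
or T1 transitions, segmentation dropouts and tracking errors beyond i.i.d.
noise, spatial gradients across the tissue, and image-level artefacts.
Passing tests therefore demonstrate that the statistical machinery is
correct and calibrated under known generative conditions — not that the
biological conclusions would survive every property of real imaging data.

## Problem sizes and determinism

The test suite and acceptance checks run at deliberately modest scales
chosen to match the information content of curated experimental datasets
(hundreds of cells, a few pulses per cell): 10 × 10 cells × 600 s for
pipeline checks; 14 × 14 × 500 s with coupling 0.5 (≈1500 pulses, ≥200
ratcheted) and 1000 randomization iterations for the enrichment analysis;
14 × 14 periodic × 300 s (≈480 intervals) for the randomization interval
contract; 3000-event patterns for the CSR contract; n = 2000 × 200
replicates for polyserial calibration. At several-fold higher per-cell
pulse density the sequential randomization develops occupancy concentration
that inflates the null variance — another reason the experimental per-cell density is
the right operating regime. Every stochastic component takes an explicit
seed (NumPy `default_rng`); identical seeds give bit-identical outputs.

## Known limitations

* Whole-movie detection at high pulse density is conservative (see above);
  sensitivity analyses should use the curation workflow or per-epoch
  traces.
* The F test compares nested models through a variance ratio, as specified,
  which is weaker than the extra-sum-of-squares F test; both stop rules
  share the α = 0.01 convention but the variance ratio needs longer traces
  for the same per-component power.
* The randomization null reproduces the interval *law* statistically, not
  per-cell trains; long-range temporal structure within single cells is not
  preserved beyond what the gamma acceptance imposes.
* Semantic labelling assumes k = 3; other k get generic cluster names.
* stPCF bandwidth selection is rule-of-thumb (no MSE minimization).
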