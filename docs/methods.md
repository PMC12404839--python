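# Methods

## Signal model and segmentation

A recording is a `q × (p·Z)` matrix of `q` channels sampled at `Z` Hz for
`p` seconds; the reference acquisition setting is 173 Hz with a 0.5–85 Hz
spectral spread. Each channel is cut into consecutive non-overlapping
windows of `N = ⌊window_s · Z⌋` samples (default 50 s → N = 8650); the
trailing partial window is discarded rather than padded, because the codec
header and the zerotree geometry assume one fixed `N` per dataset. Indices
are 1-based in user-facing output.

## Preprocessing

Three operations, each preserving segment length:

* **Band-pass + notch** — zero-phase (forward–backward) Butterworth band-pass,
  1–70 Hz by default, followed by an IIR notch at 50 Hz (Q = 30). The
  hardware description of "low-pass 1.0 Hz, high-pass 70 Hz" is read as a
  1–70 Hz pass band; the literal reading would pass nothing.
* **Adaptive median filter** (1-D) — at each sample the window grows from
  `window_init` (3) to `window_max` (9) until the window median lies strictly
  between the window extremes; the sample is replaced by that median only if
  it equals the window min or max. Edges use reflection; note that under
  this rule the first/last samples of a monotone ramp are themselves window
  extremes and are smoothed — the interior is untouched. An adaptive *mean*
  variant is available behind the same interface.
* **Histogram equalization** — amplitudes quantized to `n_bins` (256) uniform
  bins over `[min, max]`, mapped through the cumulative histogram, rescaled
  to the original range. Monotone, idempotent up to one bin width. It is
  applied per segment. **It is not part of the default feature path**: HE is
  a rank-flattening transform, and flattening the amplitude distribution
  before computing distribution-shape features (entropy, kurtosis, skewness)
  would erase precisely the information the classifier uses. It remains
  available (`PipelineConfig.equalize`) for contrast-enhanced display and
  export.

## Wavelet pyramid

Multilevel 1-D DWT via PyWavelets, mother wavelet Daubechies-4, 3 levels,
**periodization** boundary mode — the only standard mode whose coefficient
count equals the sample count, which the zerotree parent/child indexing
requires. For `N` not divisible by `2^L` the periodized transform carries a
few extra boundary coefficients (band lengths are ceil-halved; e.g. 8652
coefficients for N = 8650 at L = 3); rate accounting always divides by the
sample count `N`. Orthogonality gives energy conservation, and
analysis/synthesis round-trips are exact to ~1e−10.

Coefficients are uniformly quantized (`round(c/step)`, default step 1/64 of
the unit-variance amplitude scale) before coding; the codec is defined on
integers so that losslessness is a meaningful, testable contract.

## The zerotree codec

Tree: `approx[i] → d_L[i]`; `d_j[k] → d_{j−1}[2k], d_{j−1}[2k+1]` (children
beyond a shorter finer band simply do not exist); the finest band has no
children, so its subthreshold coefficients are zerotree roots vacuously.
Scan order is band-major, coarse to fine.

Per round at threshold `T` (starting at `T₀ = 2^⌊log₂ max|c|⌋`, halving each
round, an all-zero pyramid coded as a header-only stream):

1. **Dominant pass** over not-yet-significant, not-skipped coefficients:
   `POS`/`NEG` when `|c| ≥ T` (reconstruction `±1.5T`, interval `[T, 2T)`);
   `ZTR` when the coefficient and all its not-yet-significant descendants are
   below `T` (already-significant descendants count as zero, as in the
   classic formulation), with the subtree skipped for the rest of the pass;
   `IZ` otherwise. Internally the pass is vectorized per band: a bottom-up
   descendant-maximum array makes the zerotree test O(1) per node; a
   brute-force descendant-enumeration oracle in the test suite checks the
   equivalence exhaustively on small pyramids.
2. **Refinement pass** over coefficients significant *before this round*, in
   order of becoming significant: one bit halving the magnitude interval
   (`bit = |c| ≥ midpoint`, ties upward). A coefficient found at `T = 2^k`
   is refined in each later round, so after the final `T = 1` round its
   interval has unit width and the decoder emits the exact integer; truncated
   streams decode to interval midpoints (the minimax estimate).

Symbols cost 2 bits (fixed alphabet, no entropy coder — keeps the stream
byte-exact and testable), refinement bits 1 bit, the optional cluster
preamble 8 bits. The encoder emits greedily and stops before exceeding the
bit budget, which yields the embedded-prefix property: the stream at budget
`N_b` is a prefix of the stream at any larger budget, and RMSE is
nonincreasing in the budget. The rate of a stream with `b` payload bits is
`(b + 8)/N`, the 8 bits being the logical header (4-bit threshold exponent,
4-bit depth). The serialized `.ezw1d` container additionally stores `N`,
the wavelet name and the quantizer step outside the accounted budget — the
decoder needs them, but the rate formula's header is the 8 logical bits.

## Cluster / differential encoding

Segments are grouped by K-means (custom Lloyd loop: seeded k-means++
initialization via scikit-learn, best of 4 restarts, ≤ 100 iterations,
lowest-index tie-breaks). The within-cluster objective is recorded per
iteration and is nonincreasing — an asserted invariant. Distance is
Euclidean by default; an angle metric (`arccos` of the normalized inner
product) is available, as is the Pearson correlation for analysis. Each
cluster's prototype is the member closest to the centroid. A segment whose
distance to every centroid exceeds `raw_threshold` (disabled by default)
stays unclustered.

Differential coding writes the cluster id in an 8-bit preamble and codes the
DWT of `segment − prototype`; unclustered segments carry the reserved raw
marker (preamble 0) and are coded as-is. The decoder needs the prototypes:
the fitted model is serialized to a delimited-text sidecar. Because both
paths use the same quantizer, distortion is matched, and tight clusters
(small residuals → shallow significance pyramids) cut total bits — about 5×
on prototype-plus-noise fixtures.

## Features

Per reconstructed segment (or per subband, giving `(L+1) × 5` features):
histogram entropy over 256 uniform bins of the normalized histogram
(`−Σ p log₂ p`, in bits; an unnormalized raw-count variant `Σ z log₂ z` is
kept behind a flag for comparison), population mean and variance, skewness
`m₃/m₂^{3/2}`, and kurtosis `m₄/m₂²` (Gaussian reference 3; leptokurtic
above). Moment ratios are undefined for constant input and raise.

## Synthetic data generator

The generator emulates the study conditions so the pipeline is testable
without clinical data: 173 Hz sampling, 50-s segments, and two classes whose
feature statistics separate in the clinically reported directions (epileptic
higher in entropy, kurtosis, skewness and mean).

*Background (normal class):* spectral synthesis — an amplitude spectrum with
a 1/f floor plus Gaussian bumps at the delta/theta/alpha/beta rhythms
(centers 2/6/10/20 Hz, relative amplitudes 1.0/0.6/0.8/0.3), zeroed above
80 Hz, with complex-Gaussian coefficients; inverse FFT, centred and scaled
to unit SD. A stationary Gaussian process: skewness ≈ 0, kurtosis ≈ 3 by
construction, fully deterministic per seed (PCG64).

*Discharge (epileptic class):* a run of 3 Hz spike–wave complexes over a
random 40–50 % sub-interval. Each complex is a 70 ms half-sine spike at
6× background SD (jittered ±15 %) followed by a 250 ms slow wave whose
amplitude varies per complex as `6 · U^{1.2}` — the waxing-and-waning of
discharge amplitude seen on scalp EEG, where the slow wave can match or
exceed the spike. Within the discharge the background is attenuated to 20 %
(ictal activity replaces the background). These three choices are what make
all four class directions hold simultaneously: the spikes supply heavy tails
(kurtosis) and positive asymmetry (skewness, mean), the amplitude-varying
waves spread the amplitude histogram across its whole range (entropy), and
the background suppression keeps the ictal variance from diluting the
kurtosis. What the generator does **not** model: patient-specific morphology
and montage effects, non-impulsive artifact classes (EMG, electrode drift),
inter-channel correlation structure beyond what clustering tests construct
explicitly, and any amplitude normalization of real hardware — so passing
tests demonstrate the pipeline's mechanics and statistical directions, not
clinical performance.

## Classification and evaluation

Soft-margin SVM (scikit-learn `SVC`), linear kernel with C = 1 by default —
five-dimensional feature vectors rarely benefit from kernelization and the
linear model keeps leave-one-out deterministic; RBF is available. Features
are z-scored inside the pipeline object, so each leave-one-out fold
standardizes on its own training data (no leakage). Exact-zero decision
values map to +1, favouring sensitivity in a screening context. A
single-class training fold (only possible when a class has one member)
yields an abstention counted as a misclassification by default, so the
confusion counts always sum to `n`; a strict mode raises instead.
Metrics are percentages: precision, recall, F score (harmonic mean),
accuracy, false-positive rate. A published 15-row benchmark confusion table
(`ezweeg.benchmarks`) exercises the metric formulas on realistic epoch
counts; the percentages are always recomputed from the counts.

## Numerical choices and problem sizes

Test and acceptance runs use sizes chosen to exercise every code path at
desk scale: codec guarantees on pyramids of 8–1024 coefficients, the
exhaustive zerotree-oracle comparison on all 5⁸ eight-coefficient pyramids
over {−2…2} plus sampled 16-coefficient pyramids, rate–distortion sweeps on
512-sample segments, and the end-to-end run on the full default dataset of
120 × 50 s segments at 4 bits/sample. Thresholds in tests come from the
contracts above (exactness for integer round-trips, monotonicity to 1e−12
slack for accumulated float error, ±0.1 on the n = 10⁵ Gaussian kurtosis).
The permutation-null check compares the mean leave-one-out accuracy over 20
label shuffles against the 50 % chance level; individual shuffles scatter
widely at n = 120, the mean does not.

## Known limitations

* No arithmetic/entropy coding stage, so lossless rates (~9–12 bits/sample
  on unit-variance synthetic EEG at step 1/64) are above what a
  context-coded EZW would achieve; rate comparisons inside the package are
  self-consistent.
* The adaptive median filter's reflected edges smooth boundary extremes of
  monotone signals (see above).
* Clustering operates on raw sample vectors; no time-alignment, so it
  benefits phase-locked segments (as in the differential-coding fixtures)
  more than free-running rhythms.
* The synthetic generator's class separation is strong; leave-one-out
  accuracy on the default dataset is at or near 100 %, so the end-to-end
  check validates the pipeline's wiring and feature directions rather than
  discriminative difficulty.
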