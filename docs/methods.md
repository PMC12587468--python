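# Methods

This note documents the models, estimators and numerical choices behind
`electosleep`, and what the synthetic-data tests do and do not establish
about real recordings.

## Signal model and feature extraction

Recordings are multi-channel LFP matrices sampled at 1 kHz (band-limited
0.5–250 Hz at acquisition), with a channel→region map over eight regions
(CxCg, CxPrL, CxIL, NAc, Amy, ThalMD, HippV, VTA) and an optional EMG
channel.

**Artifact masking.** Each channel is 30 Hz high-passed (4th-order
Butterworth, zero-phase `sosfiltfilt`) and samples with |value| > 20 × MAD
of the high-passed trace are flagged. A flagged sample in any region-mapped
channel invalidates its whole 2 s window; no interpolation is attempted —
exclusion is the conservative choice, and at realistic artifact rates it
costs a few percent of windows. A constant channel (MAD = 0) produces no
flags (strict inequality against a zero threshold) but is reported as
suspect. A separate saturation screen flags channels with > 1% of samples
pinned at their min/max rails; suspects require explicit exclusion rather
than being dropped silently.

**Windowing and Welch cross-spectra.** Region traces (sample-wise means of
their channels) are cut into non-overlapping, half-open 2 s windows
[2k, 2k+2) s; a trailing partial window is dropped. Within each window,
cross-power spectral densities between every ordered region pair are
estimated by Welch's method: 512-sample Hann-tapered segments, 50% overlap,
constant detrend, one-sided density scaling (`scipy.signal.csd`). The stored
feature is the **magnitude** of the averaged cross-spectrum — non-negative,
symmetric in the pair, and reducing to the ordinary PSD on the diagonal.
Magnitude (rather than coherence or the real part) keeps the features
compatible with the non-negative factor decoder.

The frequency grid is the Welch grid fs/512 · k = 1.953 Hz × k for
k = 0…28 — exactly **29 bins in [0, 54.7] Hz**, including the DC bin
(negligible after the acquisition high-pass). The 512-sample segment length
is the one geometry that reproduces this 29-bin grid; it is a package
constant but overridable. Flattening the full 8×8×29 tensor (both symmetric
copies retained, row-major, fixed region order) gives the
d = 1,856-dimensional per-window feature vector.

**Estimator floor for synchrony.** With a 2 s window, 512/50% segments give
K ≈ 6 averaged cross-spectra. For truly independent signals the magnitude of
the averaged cross-spectrum does not vanish; it has a Rayleigh-type floor
E|P̂xy| ≈ √(π/4K) ≈ 0.36 relative to the geometric mean of the diagonal
powers. Off-diagonal features must therefore be read as *relative* synchrony
against this floor; the tests verify that synchrony is strictly monotone in
the generator's shared-component gain and equals the independent-noise floor
at gain zero, rather than asserting an absolute near-zero value.

**Normalization.** All entries of a recording's tensor are divided by one
scalar — the median over all valid windows, region pairs and frequencies —
which removes per-subject gain (electrode impedance, amplifier settings):
scaling the raw signals by g scales all raw features by g² and leaves the
normalized tensor unchanged. A per-feature variant is deliberately not the
default; the single scalar preserves the relative scale between bands and
regions that the factors are meant to interpret.

## EMG-informed state-map labeling

Training labels come from two per-window scatter maps computed with a
full-window (2,000-sample) periodogram, whose 0.5 Hz resolution represents
the band edges exactly (the 1.953 Hz classifier grid cannot):

- **map1**: x = RMS of a selected reference region's trace; y = EMG power,
  the sum of per-bin power (spectrum scaling, so a pure sine of amplitude a
  contributes a²/2) over 30–60 Hz plus 60–250 Hz.
- **map2**: x = (0.5–4.5 Hz)/(0.5–9 Hz) and y = (0.5–20 Hz)/(0.5–55 Hz)
  band-power ratios of the reference trace, band edges inclusive.

Wake separates by high EMG power; NREM by low EMG with high LFP RMS; REM by
low EMG and low LFP RMS. A window is labeled only if its map1 point falls in
a state polygon; an NREM candidate must additionally fall inside the map2
NREM (high-ratio-y) polygon. Map2 is *not* used to separate wake from REM
(they mix in its lower cluster). Points in overlapping polygons resolve by a
configured priority (NREM > wake > REM by default) and everything else stays
UNKNOWN. Point-in-polygon uses shapely with boundary points counted inside;
polygons must be simple.

`auto_polygons` replaces interactive drawing: per 60 min segment, 3-means on
standardized (log RMS, log EMG power) with deterministic quantile-based
initial centroids (duplication-invariant, seed-independent given the data),
heuristic centroid→state assignment, and convex hulls of each cluster's
central 90%. Segments with under 100 points, a cluster smaller than 3, or a
silhouette below 0.45 are marked unlabelable rather than guessed at.

Rater agreement is quantified by Cohen's κ (scikit-learn's estimator) after
dropping UNKNOWN windows pairwise.

## Supervised autoencoder

Per labeled window, with x ∈ ℝᵈ and one-hot y over (wake, NREM, REM):

    loss = CE(softmax(C(Ax + b)), y) + μ · ‖Hᵀ softplus(Ax + b) − x‖₂

- `A` (32×d), `b` (32): linear encoder to 32 electome scores.
- `C`: diagonal, three trainable entries (initialized at 1, unconstrained in
  sign) scaling the first three scores into state logits.
- `H` (32×d, entrywise ≥ 0): non-negative decoder; each row un-flattens to a
  rank-1-style regions×regions×frequency factor. Rows 0–2 are the supervised
  (state) factors, the remaining 29 unsupervised.
- μ > 0 weighs reconstruction; the Euclidean norm is used exactly as written
  (not squared; a `squared_reconstruction` flag offers the NMF convention).

Batches aggregate by the mean of per-window losses. Gradients are derived
analytically (see `sae._loss_and_grads`) and verified against central finite
differences to < 10⁻⁴ relative error in the test suite. Optimization is Adam
(lr 10⁻³, batch 256, ≤ 300 epochs by default) with `H` clamped at 0 after
every step (projected gradient); `A`, `H` initialize from N(0, 0.01²) (H
clamped), b = 0, all from a seeded generator, so training is bit-reproducible
given (data, config). These optimizer settings are package defaults chosen
for desk-scale robustness, not claims about any reference implementation.

UNKNOWN windows are excluded from training entirely (both loss terms) by
default; the cross-entropy is unweighted (imbalance is reported via balanced
accuracy instead of being corrected in the loss). With a validation set,
early stopping monitors validation balanced accuracy (patience 20);
validation balanced accuracy was preferred over validation loss because it
is the reported metric.

**Model selection** is leave-one-mouse-out nested cross-validation: for each
outer test mouse, 3 shuffled splits of the remaining mice (6 train / 2
validation when 8 remain; 1 validation mouse for smaller cohorts, ≥ 4 mice
required) score each μ ∈ {10⁻¹, 10⁻², 10⁻³} by mean validation balanced
accuracy; the winner is refit on all outer-training mice and scored on the
test mouse; finally the overall winning μ is refit on all mice.

Single-region variants use the same architecture and machinery with d = 29
(one region's power only).

**Prediction** is softmax(C(Ax+b)) per window; the label is the argmax with
ties broken in state order (wake < NREM < REM); invalid windows become
UNKNOWN with NaN probabilities. **Balanced accuracy** is the unweighted mean
of per-state recalls (states absent from the truth are dropped with a
warning), reported in percent; chance is 33%.

## Hypnogram smoothing and sleep architecture

The 3×3 transition matrix is estimated from labeled sequences by counting
consecutive pairs (UNKNOWN breaks adjacency), add-one smoothing (so rare
transitions such as REM→wake stay representable) and row normalization.

Smoothing maximizes Σₜ log p(sₜ|window t) + Σₜ log T(sₜ, sₜ₊₁) with a k-best
list-Viterbi dynamic program (k = 10 by default): each state keeps its k
best-scoring predecessor paths per step. The SAE softmax outputs are used
directly as emission likelihoods (no prior division), the initial
distribution is the transition matrix's stationary distribution (the neutral
choice for long recordings), and UNKNOWN gaps are bridged with uniform
emissions. The smoothed label track is the **top-1** path — the minimal
reading of "smoothed sequences" — while the k-path ensemble is preserved as a
per-window confidence (fraction of the top-k paths agreeing with the top-1
state, ∈ [1/k, 1]). The k-best implementation is verified against exhaustive
enumeration of all 3^T sequences on short instances.

Architecture statistics decompose the labeled track into maximal runs
(bouts): per state, percent of labeled time, bout count, and mean/median
bout duration (length × 2 s), optionally within a time interval. Statistics
are invariant to UNKNOWN padding.

## Group comparisons

Subjects are the statistical unit: features are first averaged per subject
and state over valid windows. Each of the d features is compared between
conditions with an independent two-sided **Welch** (unequal-variance) t-test
— the robust default where only "independent two-sided t tests" is specified
— giving d p-values per state (1,856 for 8 regions). These are combined into
a headline p-value by the harmonic mean p:

    HMP = (Σ wᵢ) / (Σ wᵢ/pᵢ),  uniform weights by default,

with the asymptotically exact correction: the headline p is the upper tail
of 1/HMP under a Landau distribution with location log L + 0.874367 and
scale π/2 (L = number of tests). This controls the familywise error rate at
≈ α even under dependence between tests; Monte Carlo calibration in the test
suite confirms ≤ 7% rejection at α = 0.05 over 500 null replicates.
Individual features are displayed at unadjusted α = 0.01, independent of the
HMP, with the sign of the mean difference. Degenerate features (zero
variance in both groups) record t = 0, p = 1 and a flag.

## Synthetic-data generator

The generator emulates the *statistical* structure the classifier assumes,
not biophysics. Per 2 s window, a 3-state Markov chain (default: strong
self-transitions, stationary ≈ 51% wake / 41% NREM / 8% REM, REM entered
only from NREM) chooses the state; state changes occur exactly at window
boundaries. Each region's trace sums:

- state-specific band-limited Gaussian noise components (frequency-domain
  Gaussian shaping, unit RMS, scaled by the component amplitude) — NREM:
  1–4 Hz delta (amplitude 3.0); REM: 6–12 Hz theta (1.6) plus 18–26 (0.8)
  and 42–50 Hz (0.7); wake: low-amplitude mixed-frequency (0.6/0.5 around
  6 and 20 Hz with broadband SD 0.8);
- a cohort-shared copy of each component mixed as √(1−g²)·private + g·shared
  with g = `shared_component_gain` (default 0.6), so cross-region synchrony
  is zero-excess at g = 0 and strictly increasing in g;
- white broadband noise, all scaled by a log-normal mouse×region gain
  (σ = 0.2) that the median normalization must remove.

The EMG channel is flat band-limited 30–250 Hz noise whose RMS follows the
state (wake 2.0, NREM 0.4, REM 0.05 — atonia). Isolated artifact samples
(60 × channel MAD, default 0.5/min) exercise the outlier mask. Band
amplitudes and tones are fixture parameters chosen once to reproduce the
qualitative state signatures; they are not claims about mouse biology.

**What passing tests show — and don't.** On these cohorts the states are
close to linearly separable, so held-out balanced accuracy near 100% (the
test threshold is ≥ 85%) demonstrates correct *plumbing and recovery of
planted structure* — the supervised NREM factor localizes to the planted
delta band, the multi-region model is at least as accurate as every
single-region model — not real-world accuracy. Real recordings carry
non-stationarity, volume conduction, correlated artifacts, state-transition
ambiguity and inter-mouse montage variation that the generator deliberately
omits; only the relative orderings (multi-region ≥ single-region, synchrony
monotone in shared gain, REM features closer to wake than to NREM) should be
expected to transfer.

## Default problem sizes

Test and acceptance runs use 6 mice × 1,200 s (600 windows each); these
sizes were fixed as the package's desk-scale study conditions. The
acceptance script (`scripts/acceptance.py`) re-simulates everything from its
`--seed` and completes in about a minute; the full test suite runs in about
two minutes on one CPU.

## Known limitations

- No EDF export (HDF5 + JSON channel map is the container); EDF input can be
  converted externally.
- The statemap labeler's automatic initializer assumes three separable
  clusters per 60 min segment; heavily fragmented or single-state segments
  are marked unlabelable by design.
- The HMP correction assumes the uniform-weight harmonic mean for its Landau
  tail; user-supplied weights affect the raw HMP but the headline tail is
  computed for the uniform case.
- Top-k path aggregation beyond top-1 (e.g., posterior voting) is not
  implemented; the ensemble appears only as confidence.
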