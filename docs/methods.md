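# Methods

This note documents the models and procedures implemented in `vnseeg`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Scientific setting

Vagus nerve stimulation (VNS) — delivered either through an implanted
cervical cuff (iVNS) or transcutaneously at the outer ear (taVNS) — evokes
small, spatially distributed changes in low-frequency (1–20 Hz) amplitude
in intracranial EEG. The effects of interest are on the order of a few
tenths of a z-unit relative to a pre-stimulation baseline, superimposed on
a 1/f background and contaminated by large electrical pulse artifacts.
The pipeline quantifies these evoked changes per electrode and trial,
tests them with cluster-based permutation statistics, and groups
electrodes into spatial networks by the shape of their condition-averaged
response timecourses.

## Stimulation model

Two train geometries are modeled:

* **Rapid duty cycle** (iVNS and taVNS-matched): a 2 s linear amplitude
  ramp up, 7 s plateau, 2 s ramp down (11 s active), followed by a rest
  interval (default 8 s). Pulses are biphasic square waves (positive lobe
  then an equal negative lobe, 250 µs per lobe by default) delivered
  continuously at the programmed rate; each pulse is scaled by the
  trapezoid envelope evaluated at its center.
* **Short burst** (taVNS-short): 15 pulses at the programmed rate with no
  ramp (rectangular envelope).

The 2 × 2 experimental design crosses pulse frequency (a low level of
10 Hz against a high level of 30 Hz, or 25 Hz for short bursts, treated as
equivalent to 30 Hz) with amplitude (high = just below the perceptual
threshold; low = half of that).

## Synthetic recordings

`generate_recording` produces multichannel voltage with the statistical
structure the analysis assumes:

* **Background**: spectrally shaped Gaussian noise with power ∝ 1/f^α,
  α = 1.5 by default (typical intracranial spectra), broadband SD 20 µV.
  Each channel's noise is synthesized in the frequency domain; the same
  FFT supplies the in-band (effect-band) component of the realization.
* **Planted effects**: electrodes are split into contiguous spatial
  clusters (default 2). Inside the effect window (default 2–6 s after
  train onset) the in-band noise component is multiplied by a
  condition-dependent gain, with 100 ms cosine tapers at the window
  edges. Default per-condition targets mirror the effect scale reported for
  sub-perceptual VNS in the intracranial literature:
  cluster 1 gains +0.28 z at high-frequency/high-amplitude, −0.25 z at
  low-frequency/high-amplitude (half those at low amplitude); cluster 2
  responds with the opposite sign at half magnitude, giving the opposed
  frequency-specific pattern seen across electrodes.
* **Artifacts**: the clean pulse train is placed on an auxiliary sync
  channel (500 µV scale, plus weak Gaussian noise at 1/20 of that) and
  bleeds onto every neural channel with a per-channel uniform random gain
  in [0.05, 0.5].
* **Bad channels** are replaced by high-variance white noise and recorded
  in the bad-channel set; **ictal intervals** are config-specified (not
  randomized) and stored as mask intervals which the preprocessing sets
  to NaN.

### Effect-size calibration

Planted shifts are specified on the z-scale of the downstream single-trial
normalization. For Gaussian band-limited noise the analytic envelope is
Rayleigh-distributed, so multiplying the in-band component by a gain g
shifts the mean envelope by (g − 1)·√(π/2) in units of the in-band
envelope scale. The calibration additionally accounts for two properties
of the measurement chain:

1. the analysis band filter (3rd-order Butterworth, applied
   forward–backward) passes unmodulated out-of-band 1/f leakage, whose
   relative power λ is computed by integrating the filter's power
   response against the f^−α spectrum; and
2. the full-epoch SD used by the normalization itself grows (or shrinks)
   with the planted gain; the realized shift is modeled as a
   Rayleigh-mixture mean difference divided by the mixture SD over the
   epoch.

The gain for a requested z-shift is obtained by root-finding on this
model. A residual bias of up to roughly ±25 % of the target remains at the
largest planted magnitudes: the per-trial window fluctuation is positively
correlated with that same trial's full-epoch SD estimate, which deflates
positive and inflates negative measured shifts. This is a property of
single-trial full-epoch normalization itself (it equally affects real
data analyzed this way), so it is documented rather than corrected.

The fast path `generate_trial_tensor` skips signal synthesis and draws
unit-SD white Gaussian z-values with additive planted mean shifts; there
the planted sizes are exact by construction. Note the fast path has no
temporal autocorrelation, whereas real band-limited envelopes decorrelate
over ≈ 1/bandwidth seconds; statistical power measured on the fast path
therefore corresponds to the least favorable (white-noise) regime for
cluster-based statistics.

## Preprocessing

Fixed order: detect pulses (aux channel) → interpolate artifacts →
broadband band-pass 0.1–250 Hz (2nd-order Butterworth) → notch 60/120/180
Hz (Q = 35) → downsample to 512 Hz (polyphase, Kaiser window) →
band-pass (3rd-order Butterworth) → Hilbert analytic amplitude →
downsample to 100 Hz. For acquisition rates below 20 kHz the notch
filters run before the interpolation. All filters are applied
forward–backward (zero phase): evoked latencies are not distorted, and
the stated orders refer to the designed filter before doubling.

**Pulse detection.** The aux trace is band-passed 100–1000 Hz, rectified,
and thresholded at median + 6·MAD with a refractory period of
0.8/pulse-rate; detections far below the group's typical pulse height
(isolated noise crossings) and filter edge transients are discarded.
Because the device keeps pulsing through the amplitude ramps, ramp-edge
pulses fall below any amplitude threshold. When the programmed train
duration is supplied, each detected train is therefore completed to the
full regular grid: the pulse period and phase are fitted to the strong
detections (index snapping against the circular-mean phase, one
outlier-rejection pass) and the grid placement maximizes the rectified
aux energy at the predicted positions, weighted by the trapezoid envelope
when the ramp duration is known. Pulses in the outermost part of the
ramp carry < 2 % of the plateau amplitude, so at realistic noise levels a
placement error of one grid slot at the train edges is possible
(observed ≈ 1 % of runs at SNR 10 without envelope weighting, < 1 % with
it); such an error misplaces only near-zero-amplitude pulses.

**Artifact interpolation** replaces a merged 8 ms window around each
pulse center with the straight line joining the samples immediately
outside the window; windows reaching the signal edge hold the available
anchor value.

**NaN propagation.** Ictal intervals are masked at 512 Hz; any amplitude
sample whose band-filter support (±3/(π·bandwidth) seconds) touches a
masked sample is NaN in the 100 Hz output. NaN runs are bridged by linear
interpolation before filtering so that the filters remain well-defined;
full-segment NaN-ing was rejected because realistic ictal masks would
erase entire channels.

**Spectrograms** use 40 bands with centers linearly spaced on [1, 20] Hz
(spacing 19/39 ≈ 0.487 Hz) and 0.5 Hz bandwidth (center ± 0.25 Hz);
"linearly spaced bands" is read as spaced centers, chosen for symmetry of
coverage at both ends.

## Epoching and normalization

Epochs are [−4, 11) s around train onset for the duty-cycle modalities
(1500 samples at 100 Hz) and [−2, 2.5) s for short bursts (450 samples),
with half-open windows throughout and sample index = round((t − t₀)·rate).
Each electrode × trial is normalized as
z(t) = (x(t) − mean over baseline) / SD over the full epoch,
with baseline [−4, −0.5) s (or [−2, −0.5) s) and the sample (n − 1) SD
convention. The full-epoch SD makes single trials robust when the
baseline alone is noisy. Constant epochs normalize to NaN with a warning.

Condition averages are concatenated in the fixed order low-frequency/low,
low/high, high/low, high/high; absent conditions are omitted and the
layout recorded. Sliding-window summaries use 2 s windows stepped by 1 s
anchored at the epoch start (14 windows on the 15 s epoch), comparing
per-trial window means against the same trials' baseline means with an
independent two-sample rank-sum test per electrode at α = 0.01,
uncorrected, reported as proportions of electrodes split by direction.
The independent-sample variant (rather than a paired test) follows the
test named by the procedure; this choice is documented, not inferred.

## Cluster-based permutation tests

Pointwise statistics: deviation-coded (sum-to-zero) Type III two-way
ANOVA F traces for frequency, amplitude, and their interaction (each
effect has one degree of freedom, so the Type III F equals the squared
Wald t of the coefficient; on balanced designs this coincides with the
sequential decomposition); pooled two-sample t; tie-corrected rank-sum z;
and one-sample t against zero for tests versus baseline. The
cluster-forming threshold is the upper-α quantile of the matching
reference distribution (α = 0.05 by default). Suprathreshold samples are
grouped by 1-D contiguity or 2-D 4-connectivity (no diagonals —
conservative); signed statistics form positive and negative clusters
separately on ±threshold.

The permutation null is the maximum cluster sum per permutation (zero
when none forms): unrestricted shuffling of the joint condition labels
for between-condition statistics, per-trial sign flips for baseline
tests. p = (b + 1)/(n + 1) with b the count of null values at or above
the observed sum — this add-one estimator cannot return zero (minimum
1/1001 at 1000 permutations) and keeps the test exact-level. NaN trials
are dropped per time sample for observed ANOVA traces (degrees of freedom
recomputed per sample); for permutation runs, trials containing NaN are
removed so the statistic remains exchangeable.

All permutation statistics are computed in vectorized batches (the
deviation-coded design has a permutation-invariant Gram matrix, so only
the cross-product with the data is recomputed per permutation), which
keeps a 1000-permutation test on a 1500-sample trace at ~0.2 s.

The group-level model (`group_factorial`) is a fixed-effects,
deviation-coded Type III factorial ANOVA of window-averaged power on
frequency × amplitude × modality × band (main effects and two-way
interactions), with the Bonferroni-adjusted significance level 0.003
reported alongside raw p-values. It deliberately does not reproduce a
nested mixed model with per-group variance structures; with handfuls of
participants such random effects are not estimable from synthetic data
and are out of scope.

## Convex NMF network clustering

With X arranged as (time·condition features) × electrodes, convex NMF
factorizes X ≈ F Gᵀ with F = X W: centroid timecourses are convex-like
combinations of electrode columns, which keeps them interpretable even
though z-valued data are mixed-sign. W and G are non-negative; the hard
electrode assignment is argmax over G's rows. Fitting uses the
multiplicative updates for the convex variant of semi-NMF driven entirely
by the electrode Gram matrix XᵀX (cheap even for long feature axes),
initialized from a k-means partition of the electrodes (G = indicator +
0.2, W = indicator normalized by cluster size), 10 restarts by default,
best final squared error kept. An update step that would increase the
error numerically is rejected, so each restart's error trace is
non-increasing; iteration stops at relative improvement < 1e−6 or 500
iterations.

Rank selection fits each candidate rank (2–6 by default) and evaluates
four internal validity indices on the electrode partition (centroids are
G-weighted means of the electrode feature vectors): Wemmert–Gançarski and
PBM (maximize) and the WB-index (minimize) on hard assignments, and the
fuzzy Xie–Beni index (minimize) on row-normalized G with fuzzifier 2.
Index formulas follow their original publications; small-denominator
cases are guarded with ε = 1e−12. The chosen rank is the majority vote of
the per-index optima with ties broken toward the smallest rank (the
aggregation rule is the implementer's; no canonical rule exists). Each
rank k > min(candidates) receives one extra restart warm-started from the
rank-(k−1) solution with a small appended component, which guarantees the
best-restart error is non-increasing in rank. With very few electrodes
(≈ 10) and large candidate ranks, singleton clusters make all internal
indices degenerate toward the largest rank; rank selection is therefore
only meaningful with comfortably more electrodes than the largest
candidate rank (the bundled analyses use ≥ 24).

Projection onto trials uses W with each column normalized to sum to one
(a weighted electrode average per cluster), after NaN imputation by
linear interpolation along the unfolded (trial-concatenated) time axis
with nearest-value edge fill.

Partition similarity between modalities is quantified by the adjusted
Rand index computed from the contingency table (permutation-model chance
correction) together with raw percent agreement under the optimal
one-to-one label matching (Hungarian assignment).

## Validation strategy and problem sizes

Patient-level quantities of this kind (cluster extents, group-model F
values, cross-modality ARIs) depend on recordings that are not publicly
deposited, so validation is property-based on synthetic data:

* **Family-wise error**: 500 null simulations (white-noise z traces,
  1500 samples, 2 × 2 design with 30 trials per condition, 1000
  permutations each) — the rate of any cluster p < 0.05 stays at or
  below the nominal 0.05 within binomial error.
* **Power**: a planted 0.3 z two-condition shift over 2–6 s (the
  magnitude scale the generator targets) is detected by an overlapping
  significant cluster in ≥ 80 % of 100 seeds.
* **Oracle equivalence**: on short traces the vectorized CBPT matches an
  explicit-loop brute-force implementation exactly (shared seed).
* **End-to-end recovery**: 50 synthetic recordings (8 channels, 2 kHz,
  500 µs pulse lobes, 30 trials per condition — the channel count and
  acquisition rate are scaled down for desk-scale runtimes; per-trial
  SNR and trial counts are not) are pushed through the full chain;
  rank-2 cNMF recovers the planted partition with ARI ≥ 0.9 in ≥ 80 % of
  seeds. Rank selection is validated on condition matrices at the default
  24 electrodes (chosen rank 2 in ≥ 80 % of 50 seeds).
* **Preprocessing invariants**: normalized baseline means < 1e−9 and
  full-epoch SDs within 1e−9 of 1; ≥ 20 dB attenuation of the
  stimulation-frequency spectral line by artifact interpolation; unit
  6 Hz sinusoid recovered in theta within 5 %.

What passing these does *not* show about real data: the generator plants
stationary, cluster-homogeneous effects with known timing, contains no
physiological artifacts other than the modeled pulse bleed (no movement,
no electrode drift, no true ictal waveforms — ictal periods are masks,
not waveforms), and its cross-channel noise is independent, unlike
volume-conducted real recordings.

## Known limitations

* The iVNS pulse-detection algorithm is this package's own design (the
  stand-in described above); it was validated only on the synthetic
  artifact model.
* Realized planted effect magnitudes carry the normalization bias
  described under calibration (up to ≈ ±25 % at the largest magnitudes).
* `group_factorial` is a fixed-effects surrogate for a mixed model; its
  p-values ignore within-participant correlation.
* The ANOVA permutation scheme permutes joint condition labels
  unrestrictedly; exact restricted schemes for testing individual main
  effects in the presence of the other are not implemented.
* EDF export is not provided; interchange uses HDF5 and TSV.
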