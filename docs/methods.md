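# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate. Units are seconds, micrometers and
ΔF/F throughout.

## Event detection

Raw fluorescence is normalized to ΔF/F with one of three baselines:

- **running_min** — F₀(t) is the minimum over all samples up to t. A
  monotone bleaching baseline is tracked intrinsically, so no explicit
  detrending is applied before event detection.
- **global_mean** — F₀ is the trace mean (the convention used for
  single-neuron network traces).
- **detrended_mean** (network analyses only) — a rolling 10th-percentile
  baseline (60 s window) is subtracted before dividing by the trace mean.
  Photobleaching is a *shared* slow component across simultaneously imaged
  ROIs; under a plain global-mean convention it appears as network-wide
  correlation which the permutation null correctly reports as significant,
  swamping the neural structure. Removing the slow component first leaves
  the event-scale signal that the correlation analysis is about.

Spikes are local maxima (scipy `find_peaks`) with prominence at least

```
max( 0.2 × P95(ΔF/F),  6 × σ_noise )
```

and pairwise separation ≥ 1 s (the calcium-kernel width scale; the larger
peak wins, ties resolve to the earlier). σ_noise is a robust scale,
1.4826·MAD of the first-differenced trace ÷ √2; for the detection floor we
take the 95th percentile of rolling 60 s estimates rather than the global
value, because normalization against a decaying baseline amplifies noise
late in a recording and the floor must clear the *worst* local noise. The
relative term mirrors the 20%-of-largest-amplitude convention; the noise
floor is needed because on sparse recordings (events occupy ~5–10% of the
trace) P95 sits inside the baseline and a purely relative threshold would
admit noise peaks en masse.

Spikes separated by ≤ 5 s merge into one contraction event. The grouping
gap is not dictated by the biology alone — intra-burst spacing is of order
seconds and inter-event intervals of order tens of seconds — so 5 s sits
in the gap of that bimodal distribution and is exposed as a parameter. An
event's extent runs from the last upward crossing of
(rolling 10th-percentile baseline + 3·σ_noise) before its first spike to
the first downward crossing after its last spike, searched within 30 s
(bounds are clamped and flagged if no crossing exists). Events with one
spike are *pulses*, others *bursts*; the inter-contraction interval is
measured end-of-event to start-of-next.

## Response statistics

Trials are the valve onsets. The **response probability** is the fraction
of trials with at least one spike peak in the half-open window
[onset, onset+1 s); the spike peak time is the membership criterion since
it is the only defined spike timestamp. The **spontaneous null** cuts an
unstimulated segment into consecutive 30 s pseudo-trials (matching the
stimulation cycle) and slides a 1 s window in 0.3 s steps across the
pseudo-trial; each offset yields a hit fraction, and the mean over offsets
is the spontaneous contraction probability. Estimates are aggregated
per-animal first, then averaged with SEM across animals.

Paired condition comparisons report the paired t-test, **Cohen's d** in
the two-sample pooled-SD form (n−1 denominators) — consistent with the
group-wise, rank-based Cliff's δ reported beside it; the paired
standardized difference d_z is also returned — and **Cliff's δ** over all
cross pairs. Degenerate inputs (zero variance) are flagged, not raised:
identical samples give t = 0, d = 0, δ = 0; separated constants give
infinite d with δ = ±1.

**Response latency** is estimated as the median stimulus-relative spike
time within a window, pooled across trials. A triggered-average peak is
deliberately not used for this number: per-trial latency jitter convolved
with the right-skewed calcium kernel shifts the mode of the average by
up to a second, while the median of per-trial spike times is unbiased at
the sub-frame level.

## Correlation networks

Pairwise Pearson correlation over the full record (detrended-mean ΔF/F;
zero-variance ROIs are zeroed and flagged). Significance comes from a
**block-permutation null**: each series is cut into 30 contiguous blocks
(remainder appended to the final block), each iteration permutes the block
order independently per ROI (permutation without replacement — the
independent per-ROI shuffle is the stronger null for pairwise
correlation), the correlation matrix is recomputed, and z = (x−μ)/σ over
1000 iterations (μ, σ per pair; σ = 0 pairs flagged undefined). Block
shuffling preserves each trace's marginal distribution and short-range
autocorrelation while destroying cross-trace alignment.

Clustering is agglomerative on the Euclidean distance between
correlation-matrix rows, with the dendrogram leaf order used to sort
heat-map axes. Average linkage is the default: single linkage (the
referenced routine's historical default) chains badly on correlated
neural data; reproductions of orderings built with single linkage can set
`method="single"`.

Classification rules, per ROI:

- **CB** — permutation z-score against the peduncle readout ≥ 3
  (≈ p < 0.003 two-sided under the null) *and* the contraction-triggered
  average peaks within ±2 s of contraction onset. Anchors are the first
  spike peak of each detected peduncle event; the ±2 s tolerance admits
  burst events whose averaged maximum falls on the second pulse
  (intra-burst spacing ~1.5 s).
- **MR** — not CB; the stimulus-triggered average peaks within the 5–15 s
  latency window (bracketing the ~10 s slow response) *and* the response
  is stimulus-locked across trials: the count of trials with a spike in
  the latency window is tested against the ROI's own spontaneous window
  probability (estimated by the sliding-window null on the pre-stimulation
  segment) with a one-sided binomial test at α = 0.01. Trial consistency
  separates genuine slow responses from spontaneous coincidences far more
  reliably than average amplitude, which for ~20 trials is of the same
  order (0.05–0.15 ΔF/F) for both. When per-trial evidence is unavailable
  the fallback requires the average's peak height above the pre-stimulus
  baseline to reach max(0.05, 5 × baseline SD).
- **unspecified** — everything else.

The pixel cross-correlation map block-averages each movie frame to a
64×64 grid and reports, per pixel, the maximum Pearson correlation with a
reference signal over integer-frame lags |τ| ≤ 50 ms (boundary included);
constant pixels map to 0.

## Kinematics

Displacement is the Euclidean step between consecutive tracked positions;
missing frames leave gaps (no interpolation) and single-frame neurons are
dropped with a log entry. Baseline displacement averages all valve-off
frames excluding transitions; evoked displacement averages the frames
immediately after pressurization and after depressurization — both
reported separately and pooled, since either transition stretches the
tissue — compared by a two-sided rank-sum test. The radial profile bins
neurons by distance to the valve center at the pre-stimulus reference
frame (half-open 50 µm bands [r, r+50)), then averages the top-3 largest
stimulus-frame displacements per band (all values when fewer than three;
empty bands are missing). Body length is the major-axis length of the
moment-matched ellipse on the largest connected component after Otsu
binarization and a 2 px closing; it is provided for artifact
characterization, not response statistics, because stimulation artifacts
make length an unreliable contraction readout.

## Synthetic generator

The generator is the package's test substrate: it produces recordings
with the statistical structure the analysis assumes, and returns the
ground truth.

- **Spontaneous events**: a renewal process with gamma(shape 2)
  inter-event intervals, mean 72.98 s. Shape 2 avoids the unrealistic
  memorylessness of exponential waiting times while staying
  single-parameter; it is configurable. 83% of spontaneous events are
  bursts; burst pulse counts are 1+Poisson(3) at 1.5 s spacing (burst-size
  statistics are not constrained by data and are exposed in the spec).
- **Stimulated events**: per valve onset an independent Bernoulli draw
  from the pressure→probability map (defaults 5:0.09, 10:0.23, 15:0.24,
  20:0.60, 25:0.77); the first pulse falls uniformly 0.1–0.6 s after
  onset, matching signals that rise within ~0.1–0.2 s and peak at
  ~0.5–0.6 s; 60% of stimulated events are single pulses. A 5 s
  refractory suppresses spontaneous events after a stimulated one.
- **MR channel**: per onset an independent Bernoulli; the response time is
  onset + Normal(10, 2) s, clipped ≥ 1 s, *shared* across MR ROIs with
  the draw made once per trial — MR neurons are defined as a correlated
  group, and independent per-ROI latencies would erase exactly the
  correlation structure the network analysis must recover.
- **Rendering**: pulses convolve with a difference-of-exponentials kernel
  (rise 0.1 s, decay 1 s; peak-normalized — the analytic pulse-to-peak
  lag is exposed as `expected_peak_lag`), scaled by lognormal(σ=0.25)
  per-pulse amplitudes; the baseline bleaches exponentially with a 7200 s
  half-life (mild, realistic wide-field bleaching — strong enough to
  exercise the running-min and detrending paths, not enough to dominate
  them); Gaussian noise (SD 0.05 ΔF/F) is additive in baseline units, so
  its absolute scale is stationary over the recording.
- **Tracks**: neurons uniform over a 1.5×1.5 mm field; Brownian jitter
  with mean step 0.4 µm/frame (the baseline cellular displacement of the
  recordings); on the valve-on frame each neuron is displaced radially by
  profile(r) and on the valve-off frame it relaxes back.
- **Movies**: elliptical body-shaped background plus Gaussian blobs at
  neuron positions scaled by instantaneous ΔF/F.

All randomness flows from a single seed through named sub-streams, so
ground truth is bit-reproducible and each stage can be regenerated
independently.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: body deformation and motion artifacts (ROIs are
perfectly registered); entrainment or suppression of spontaneous activity
during repeated stimulation beyond the 5 s refractory (real recordings
show near-complete interval locking to the 31 s cycle under strong
stimulation, so measured interval medians and single-pulse percentages on
fully mixed synthetic recordings sit below the locked values);
animal-to-animal heterogeneity in response probability (per-animal
variance is purely binomial); indicator saturation and nonlinearity; and
z-motion or focus drift.

## Verification conditions and problem sizes

Parameter-recovery checks run at the study's scale where that is cheap
and at reduced replication where it is not: psychometric recovery uses
3 animals × 119 trials per pressure; spike-detection fidelity pools 50
ten-minute recordings; the permutation-null calibration uses 100
white-noise pairs at 200 shuffle iterations (the estimator is unbiased in
n_iter; 200 iterations only widen the z-score's own sampling noise);
network recovery uses 20 thirty-minute recordings with 12 neurons + the
peduncle readout at 200 iterations. Psychometric recovery simulates the
stimulus-locked channel in isolation (spontaneous rate 0): with
background activity present the measured window probability is the
planted probability plus a ~0.05–0.08 coincidence floor — the same floor
the unstimulated control measures at ~0.11 — so recovery of the Bernoulli
parameter itself is only defined without the background. The radial-profile
check compares each band's top-3 statistic to its Monte-Carlo expectation
under the known neuron radii, planted profile and jitter, restricted to
bands where the planted displacement exceeds the 5 µm negligibility
threshold; below that level tracking jitter dominates by construction.

## Known limitations

- Event bounds depend on the baseline-crossing rule; heavily overlapping
  bursts can merge, and durations inherit the rolling-baseline window.
- The sliding-null offsets are correlated (windows overlap in source
  data), so the null *distribution* understates independent-trial
  variance; only its mean is used as the spontaneous probability.
- MAT v7.3 reading covers the deposited layouts (struct-of-cell-arrays
  and plain matrices), not arbitrary MATLAB files.
- The MR/CB rules are threshold classifiers, not probabilistic models; on
  recordings much shorter than 30 min the binomial gate loses power and
  classification degrades toward "unspecified".
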