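# Methods

This note documents the models, parameter choices and numerical conventions
behind `duetsync`, the reasoning where the design was genuinely open, and
what the simulation-based validation does and does not establish.

## Movement extraction

A performer's movement is summarized per video frame by the barycentre
(grey-intensity-weighted centroid) of a fixed region of interest, in 0-based
full-frame pixel coordinates with a top-left origin; ROIs are half-open
rectangles. An optional dense-optical-flow backend (iterative Lucas–Kanade,
via scikit-image) weights pixels by flow magnitude instead of intensity; the
default is plain intensity weighting, and the backend used is recorded on the
trace. Frames whose ROI is entirely black re-use the previous centroid and
are flagged rather than emitting a jump. Validation of the tracking path is
against synthetic blob videos with known motion, not against any particular
historical tracker implementation.

Quantity of motion (QoM) is frame differencing against an adaptive
background: a running exponential mean of past frames (rate 0.05 per frame by
default; rate 1 degenerates to pure frame-to-frame differencing), thresholded
at 15 grey levels. QoM is normalized by ROI area so differently sized ROIs
are comparable; raw pixel counts are available via `normalize=False`.

**Radial reduction.** The (x, y) trace is smoothed with a Savitzky–Golay
filter (order 3, window 5 frames), converted to the radial coordinate
ρ = √(x² + y²), linearly detrended, and min–max normalized to [0, 1]. The
pole of the polar conversion is the pixel-frame origin by default. This was a
deliberate choice over the trace's time-mean position: with the pole at the
mean, any oscillation symmetric about it folds onto ρ = |A sin ωt| and the
apparent frequency doubles (and circular motion about the pole collapses to a
constant), which would corrupt every downstream frequency estimate. With the
frame-origin pole the barycentre sits hundreds of pixels from the pole while
oscillating over a few pixels, so ρ is first-order linear in the movement and
preserves its frequency; the constant offset and slow staging drift are
removed by the detrend. `origin="mean"` remains available, and its
frequency-doubling behaviour is exercised in the tests. A consequence worth
knowing: with the frame pole, ρ measures the projection of the movement onto
the radial direction from the image corner, so the relative weighting of x
and y motion depends on where the performer stands; after per-recording
min–max normalization this affects only the mixture, not the periodicity.
Translation invariance of the pipeline is exact for the mean pole and
first-order (tested with tolerance) for the frame pole.

Constant traces normalize to all zeros, never NaN.

## Wavelet analysis

The Morlet mother wavelet ψ(u) = π^(−1/4) e^{iω₀u} e^{−u²/2} is used with
ω₀ = 6, the standard admissible choice for which the pseudo-frequency
f = ω₀/(2πs) is within 2% of the true modulus-peak frequency and, for
practical purposes, the inverse period. The analysis grid is log-spaced with
20 voices per octave, spanning 0.3–2.0 Hz for movement (body-sway to head-nod
periods) and 0.25–10 Hz for the audio envelope (musical events recur faster
than ancillary movements).

**Normalization.** The transform kernel is scaled as
(dt/s) π^(−1/4) e^{iω₀u/s} e^{−u²/(2s²)} — amplitude (L1-type) normalization,
under which a unit sinusoid produces the same response magnitude (≈ 0.94) at
every scale. This puts the modulus ridge of a pure tone exactly at the
nearest grid frequency; the more common energy (1/√s) normalization biases
ridges low by about half a grid step, which matters when frequencies are read
off the ridge. Total energy still scales as amplitude squared.

**Implementation.** The transform is computed in the frequency domain (the
kernel's Fourier transform is a Gaussian at sω = ω₀) with zero padding of at
least 8 scales on each side, making the circular convolution equal to the
literal time-domain convolution to the kernel's truncation error (< 1e-12).
The test suite and the acceptance script verify this against an
independently written direct-convolution oracle to < 1e-6 relative error.

**Cone of influence.** A coefficient is flagged edge-affected when its time
is within √2·s (the e-folding time of the wavelet envelope) of either series
end. Band summaries accept a `coi_policy`: `keep` (default — the predictor
pipeline instead trims 5 s from each recording end, which at 0.3 Hz covers
the √2·s ≈ 4.5 s e-folding width) or `mask` (masked cells excluded; fully
masked columns yield NaN missing markers, never silent zeros).

**Cross spectrum.** The cross coefficient W_a · conj(W_b) is smoothed along
time with a Bartlett (triangular) window of 1 s (configurable); energy is the
squared modulus of the smoothed coefficients. Smoothing matters: it
attenuates cross terms whose phase difference drifts (unrelated frequencies)
while preserving phase-locked ones, sharpening the contrast the classifier
relies on. Phase is taken from the smoothed coefficients by default
(`phase_from_smoothed=False` gives the raw pointwise phase). The sign
convention — positive phase = second signal lags the first; a quarter-period
delay gives +π/2 — is asserted in tests. Band phase is the energy-weighted
circular mean over band rows. "Energy" always means squared modulus;
amplitude profiles use the plain modulus.

**Bands.** Narrow predictor bands are centred at 0.3, 0.4, 0.6, 0.9 and
2.0 Hz. Only the centres are canonical; edges are geometric midpoints
√(cᵢcᵢ₊₁) of adjacent centres (log-frequency symmetry), with the outer edges
pinned at 0.26 and 2.3 Hz so the bank tiles the 0.3–2.0 Hz analysis range
with a small margin. The seven co-occurrence bands (0.29 … 2.0 Hz) use the
same midpoint rule with log-symmetric outer extensions. Band membership is
half-open [low, high); the per-band summary is the mean over member grid
rows, so the broad band is exactly the row-count-weighted combination of the
narrow bands (asserted to 1e-10). Co-occurrence ties (argmax over equal
energies) resolve to the lowest frequency.

## Audio

The joint performance audio is reduced to a 100 Hz envelope: full-wave
rectification, zero-phase 20 Hz Butterworth low-pass, resampling to 100 Hz,
then (1 − λ)·half-wave-rectified-derivative + λ·envelope with λ = 0.1,
Gaussian-smoothed with σ = 3 samples. The derivative term emphasises onsets;
the small plain-envelope admixture keeps sustained-level information. The
mixing convention is fixed here and covered by tests.

`pulse_clarity_simple` is deliberately a reduced model: per 5 s window, the
height of the maximum normalized autocorrelation peak of the mean-removed
onset signal over beat-plausible lags (0.25–2 s), in [0, 1], 0 for silence.
Mean removal is essential — the non-negative onset signal otherwise
contributes a constant autocorrelation floor (~0.3 for noise) at every lag.
The full multi-component pulse-clarity literature model (resonance curves,
periodicity entropy, …) is not reproduced and no numerical equivalence with
it is claimed; in the classification stage this predictor is screened out
anyway. `event_density` (envelope peaks above threshold per second) and
`tempo_estimate` (60/lag of the onset autocorrelation peak within a
60–180 bpm prior, preferring the shortest lag within 85% of the strongest
peak so the beat rather than a multiple is reported) are simplified
descriptors of the same spirit.

## Annotations, alignment and agreement

Intervals are half-open [onset, offset) in seconds; tiers are sorted and
non-overlapping (overlaps merge with a warning on load). Binarization puts a
1 at every frame whose timestamp lies inside an interval.

Pairwise agreement is computed after dynamic time warping one binarized tier
onto the other with an asymmetric step pattern (1,0), (1,1), (1,2) — the
reference index always advances; the other tier may repeat or skip a frame —
inside a Sakoe–Chiba band of ±2 s by default (configurable; band 0 is the
identity). Ties in the dynamic program resolve to the diagonal, so identical
inputs return the identity path exactly. Cohen's κ then comes from the 2×2
frame-coincidence table, with the large-sample null variance for the z
statistic; unaligned κ is reported alongside for transparency. The annotation
consistency measure `frame_overlap_fraction` is defined frame-wise: of all
(tier, frame) marks, the share whose frame is marked by at least two tiers.

Consensus bouts are frames marked by ≥ 2 raters, converted back to
intervals; aggregated bouts shorter than 2 video frames are discarded as
degenerate. Aggregation is monotone in the rater threshold (tested).

Bout-onset structural position uses 5%-wide bins of relative position within
the enclosing structure section; onsets outside any section are dropped and
counted. Two-sample histogram comparisons use the chi-square homogeneity
test without continuity correction, with both-zero bins merged out.

## Predictor table

Per recording, the twelve predictors are computed on the video frame grid,
audio features linearly interpolated onto it from their native rates. The
first and last 5 s are trimmed (annotation and wavelet edge artefacts), then
every 5th frame is kept — plain subsampling without an anti-alias filter,
which is adequate because band energies are already smoothed over ~1 s by the
wavelet support and the Bartlett window. Feature columns are z-scored over
the assembled analysis set as a whole (matching the pooled-observations
convention; per-recording standardization is an option), with means and s.d.s
stored in the table metadata for inversion. Missing audio drops the three
audio columns (recorded in metadata) rather than imputing. Assembly from
identical inputs is bit-identical; column order is fixed and asserted against
the CSV header. The phase predictor is exported as the signed angle to keep
twelve named columns; note that as a circular quantity its linear z-score is
a crude encoding, which is consistent with its failure to survive screening.

## Classification

Screening fits one univariate logistic regression per predictor under
repeated stratified k-fold CV (10×10 default) and flags predictors whose
CV-AUC lower bound (mean − 1.64 s.d.) does not clear 0.5 — the AUC of the
baseline that always predicts the majority class. The two model families are
additive logistic regression (optionally with all pairwise product terms)
and a random forest with 500 trees and √p features per split. The reported
AUC is always computed on held-out data with a DeLong CI95; CV inside the
training split is a stability check only (the models have no tuned
hyperparameters), so heavyweight validation runs skip it (`cv=None`).
Model comparison uses DeLong's paired test for correlated ROC curves
(implemented here with the standard midrank algorithm; identical prediction
vectors return p = 1). Class imbalance (~30% positives) is handled without
reweighting; the Youden-index cutoff (midpoint candidate thresholds, ties to
the lowest) provides the operating point at which the FN/FP asymmetry is
reported.

**Splitting and leakage.** `split_train_eval` splits at the frame level by
default, mirroring the pooled-frames convention; but temporally adjacent
frames are strongly autocorrelated, so a flexible model can score far above
chance on a frame-level split by interpolating its own training
neighbourhood even when movement and labels are causally unrelated (we
measure null AUCs above 0.9 for the forest this way). This is documented
rather than silently "fixed": the ground-truth recovery benchmark in
`duetsync.validation` therefore evaluates with grouped 5-fold CV over
*recordings*, which is what makes the zero-coupling null land at chance
(0.5 ± 0.05) while full coupling is recovered at AUC ≥ 0.95. A recording
grouped split is recommended for any generalization claim.

Variable importance is permutation importance — the drop in held-out
accuracy when one predictor column is shuffled — normalized to a maximum of
1. This is the same construct as out-of-bag permutation importance in
classic random-forest implementations, evaluated on an explicit held-out set
instead of the out-of-bag samples (which scikit-learn does not expose);
negative mean drops floor at zero. With all-noise predictors the normalized
ranking is unstable across seeds, and a test asserts exactly that.

Excerpt selection slides 7.5 s windows (0.5 s hop); a window joins a
prediction cell (TP/TN/FP/FN) only if frames satisfying both the annotation
and the thresholded prediction for that cell total ≥ 4 s. Window QoM is
median-split into high/low over the candidate pool, and up to 12
non-overlapping windows per cell are returned balanced on QoM class,
preferring QoM-extreme candidates. Cells with too few candidates return
fewer with a warning — criteria are never relaxed silently.

## The dyad simulator

Each performer is an oscillator x(t) = A·m(t)·cos φ(t) + noise + slow
positional random walk, rendered around a fixed centre; A = 20 px, white
noise σ = 2 px, drift 1 px/√s, and m(t) a ±20% slow amplitude modulation.
Momentary frequency performs a reflected random walk (σ = 0.03 Hz/√s)
mean-reverting to per-performer solo frequencies (defaults 0.45 and 1.0 Hz,
i.e. distinct sway/nod tempi) with a ~2 s time constant, confined to
0.25–2.2 Hz. During a scheduled bout with coupling c ∈ [0, 1], each
frequency relaxes (1.5 /s) toward (1 − c)·solo + c·f_shared and performer B's
phase obeys dφ_B += 3·c·sin(φ_A − φ_B − lag)·dt — a Kuramoto-style pull. Two
properties are built in deliberately: coupling gates *everything*, so at
c = 0 the bout schedule has no effect on the dynamics whatsoever (the
classifier's null case is exactly null); and both the residual frequency gap
and the lock tightness scale with c, so the mean within-bout cross energy
rises monotonically over the whole coupling range instead of saturating
(asserted with Spearman ρ > 0.9).

Bout schedules alternate exponential gaps and bouts (bouts floored at 4 s so
they are resolvable at the slowest analysis periods); shared bout frequencies
are log-uniform in 0.35–1.8 Hz. The two presets mirror the two performance
styles the method targets: `nonpulsed` (longer bouts, mean 11 s; sparse
Poisson audio events at 0.45 /s) and `pulsed` (shorter bouts, mean 5 s;
isochronous click train at 132 bpm with an accent every 4 beats). Both give
roughly one-third label prevalence. Annotators observe the true bouts with
Gaussian onset/offset jitter (0.25 s), per-bout miss probability (0.1) and
Poisson false alarms (0.2/min, ~4 s long). Blob videos rasterize traces as
soft-edged discs so sub-pixel positions survive and the tracking round trip
correlates ≥ 0.99 with the generator. Same (config, seed) is bit-identical.

**What the simulator does not emulate:** human kinematics (multi-limb,
non-sinusoidal waveforms), visual appearance (clothing, lighting, two
performers overlapping one ROI), instrument sound, annotator biases that
correlate across raters, and any dependence of movement on musical structure.
Passing the validation suite therefore shows that the pipeline recovers the
coordination construct it defines under controlled conditions — not that it
attains any particular accuracy on real performance corpora, whose published
headline figures depend on the original videos and raters.

## Validation problem sizes

The ground-truth recovery benchmark uses 20 simulated duos of 120 s each
(≈ 11 000 analysis frames), grouped 5-fold CV, forests of 500 trees; the
video loop uses 40 runs of 30 s at 80×64 px; audio contrasts use 30 paired
seeds of 30 s. These sizes were chosen so the full validation runs in a few
minutes on a single CPU while keeping the binomial/fold-mean noise of each
reported rate well inside its acceptance margin.

## Known limitations

- Radial reduction is blind to movement direction; two performers moving at
  the same frequency along orthogonal axes are "coordinated" to the CWT.
  Circular motion about the mean pole is invisible (tested).
- Phase as a linear z-scored column wastes its circular structure.
- The frame-level split reproduces a convention that leaks autocorrelated
  frames; use recording-level splits for honest generalization estimates.
- Wavelet coherence (normalized cross spectrum) and significance testing
  against autoregressive nulls are out of scope.
- `pulse_clarity_simple`, `event_density` and `tempo_estimate` are
  simplified descriptors, not re-implementations of any published toolbox.
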