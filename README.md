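# duetsync

Quantifying and predicting visually apparent bouts of interpersonal
coordination between two performers, from video-derived movement time series.

When two musicians improvise together, their ancillary movements — body sway,
head nods — periodically fall into visible correspondence. Human raters can
mark these *bouts of interaction* from silent video; `duetsync` asks whether
they can be predicted from the movement signals themselves. The package is
aimed at researchers studying joint action, musical ensemble interaction and
non-verbal communication who work with ordinary video recordings rather than
motion-capture rigs.

## The method

Each performer's upper body is tracked as the intensity barycentre of a
user-drawn region of interest, giving an (x, y) pixel trace at the video rate
(25 Hz). The trace is Savitzky–Golay smoothed, reduced to a radial coordinate
ρ, detrended and normalized to [0, 1]. Coordination is measured with the
**cross-wavelet transform (CWT)**: each ρ is transformed with a complex Morlet
wavelet (ω₀ = 6, log-spaced frequencies, 20 voices per octave)

    W(s, t) = Σ_u x(u) ψ*((u − t)/s),   ψ(u) = π^(−1/4) e^{iω₀u} e^{−u²/2},

with the pseudo-frequency f = ω₀ / (2πs), and the cross spectrum is

    W_ab(s, t) = W_a(s, t) · conj(W_b(s, t)).

|W_ab|² after Bartlett smoothing is the joint *energy* — large exactly when
both performers move periodically at the same frequency at the same time —
and arg W_ab is their momentary lead/lag phase. Twelve frame-wise predictors
(broad 0.3–2 Hz cross energy, its phase, five narrow-band cross energies,
summed individual wavelet energy, summed quantity of motion, and three audio
envelope descriptors) feed a logistic regression and a 500-tree random
forest that classify each frame as inside/outside a consensus bout, with
held-out AUC, DeLong confidence intervals and Youden-cutoff error analysis.

Consensus bouts come from ≥ 2-of-n rater aggregation of interval annotations
(ELAN-style tiers), with inter-rater agreement measured by Cohen's κ after a
band-constrained asymmetric dynamic time warp absorbs small timing
discrepancies.

Because the corpus the method was developed on is not bundled, the package
includes a first-class **dyad simulator**: two Kuramoto-style coupled
oscillators with frequency drift, scheduled coordination bouts, noisy
annotators, pulsed / non-pulsed audio synthesis and blob-video rendering, so
every stage is testable against ground truth.

## Worked example

```bash
python examples/02_simulated_duo_classification.py
```

simulates six coupled duos, builds the predictor table and prints:

```
3300 analysis frames, 27.8% inside coordination bouts

univariate screening (CV AUC):
           predictor  auc_mean  auc_sd  eliminate
mov_cwt_energy_broad     0.985   0.006      False
  mov_cwt_energy_0.9     0.720   0.018      False
  ...
   movement_quantity     0.508   0.012       True

1-predictor logistic (broad CWT energy): held-out AUC 0.990 (CI95 0.985-0.995), FN 4.1% / FP 5.2% at the Youden cutoff
8-predictor random forest: held-out AUC 0.999 (CI95 0.998-1.000), FN 0.5% / FP 2.6% at the Youden cutoff
```

Reading this: about 28% of analysis frames lie inside scheduled coordination
bouts. In univariate screening the broad-band cross-wavelet energy is by far
the strongest single cue (CV AUC 0.985) while phase and overall movement
quantity cannot beat the majority-class baseline and are flagged. On held-out
frames the single-predictor logistic model already recovers bouts almost
perfectly for these strongly coupled synthetic dyads, and the 8-predictor
random forest closes the remaining gap. The FN/FP rates show the error
asymmetry at the Youden-optimal decision threshold.

The other examples demonstrate one capability each: cross-wavelet phase of
lagged oscillations (`01`), annotator agreement and consensus aggregation
(`03`), the full video → tracking → spectrum path (`04`), and pulsed vs
non-pulsed audio descriptors (`05`). A thin CLI covers the same workflow on
files: `duetsync simulate | extract | features | agree | aggregate | screen |
fit | excerpts | report`.

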