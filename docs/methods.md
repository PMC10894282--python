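# Methods

`myorsa` analyses multi-channel surface-EMG (sEMG) sessions in which a
participant repeatedly attempts a set of hand movements with both limbs,
and asks three questions: are the per-channel excitation patterns of a
movement *reproducible* across repetitions, are different movements
*distinguishable* from one another, and is the movement structure *shared*
across the two limbs.  Because clinical recordings of this kind are
restricted, the package ships a seeded synthetic generator that emulates
the acquisition protocol; all statistical machinery operates identically
on real recordings supplied in the same containers.

## Recording protocol and segmentation

The default protocol models a 7-electrode-per-limb acquisition at
6000 Hz with a 20–450 Hz analog band-pass and a ±11 mV ADC range.  Ten
movements are each performed as 2 trials of 5 cycles of 4 s relaxation
followed by 3 s contraction, giving 10 repetitions of each phase per
movement.  To guard against reaction-time transients around the auditory
cue, 15% of every phase interval is discarded from both the onset and the
recession, keeping the central 70% (e.g. 6000 Hz × 3 s × 0.7 = 12,600
contraction samples).  Odd trimmed lengths are floored, with the surplus
sample removed at the segment end.  Repetitions are grouped, never
concatenated: every feature is computed per repetition, which is what the
consistency analysis requires (10 values per movement and channel).

## Features

Two features are computed per trimmed repetition and channel:

* **RMS** = sqrt(mean(x_i²)) over the N samples of the repetition — the
  amplitude-domain excitation measure, in mV.
* **MNF** = Σ f_j p_j / Σ p_j — the power-weighted mean frequency over
  M = f_max / 0.4 bins of 0.4 Hz covering 0–1000 Hz (M = 2500 at the full
  sampling rate), in Hz.

The spectrum is a single windowed periodogram with enough zero padding
that the raw resolution is at most half the bin width; raw power is summed
into the bins, so the binned total exactly equals the periodogram total
below f_max.  A Hann taper is the default: a rectangular window leaks
roughly 7% of a pure tone's power into distant bins through sinc²
sidelobes, which distorts MNF for narrowband content, whereas the Hann
mainlobe keeps > 99.9% of the power within ±1 Hz.  The window is a
parameter (`window="boxcar"` restores the plain periodogram).  Bin
frequencies are taken at bin centres.  For slow-sampled (scaled-down)
data the spectrum cap is lowered to 40% of the sampling rate to respect
the Nyquist precondition.

Per limb and channel, each feature is divided by its maximum over all
movements, repetitions and both phases and expressed in percent, so all
downstream statistics compare patterns rather than per-electrode gains;
the relaxed state shares the percentage scale.  Quartiles use linear
interpolation between order statistics (the numpy default); this matters
because the interquartile range feeds the dissimilarity matrices.
Box-plot exports use the 1.5 × IQR whisker convention.

## Within-movement consistency

For each limb, movement and measure, the repetitions × channels matrix of
normalised values is scored with Kendall's coefficient of concordance W:
each repetition ranks the channels, and W ∈ [0, 1] measures agreement of
those rankings, with mid-ranks for ties and the standard per-judge
correction Σ(t³ − t).  This orientation (judges = repetitions) captures
reproducibility of the *spatial pattern*; the transposed reading is
available via `orientation="channels"`.  W values are banded as poor
(< 0.20), minimal (< 0.40), weak (< 0.60), moderate (< 0.80) and strong
(≥ 0.80), with half-open intervals.

Across limbs, the paired per-movement W values are compared with an exact
two-sided Wilcoxon signed-rank test.  Zero differences are dropped before
ranking (classical convention); the null distribution of the signed-rank
sum is computed exactly by a subset-sum count over doubled mid-ranks,
which remains exact under tied absolute differences and is feasible for
all n ≤ 25.  The reported direction (which limb has the larger median) is
stated separately from the two-sided p.  Shapiro–Wilk screening is
provided to justify the nonparametric path in reports; the rank-based
tests are applied regardless.

## Distinguishability (representational dissimilarity)

Repetitions are split into even and odd halves by repetition-index parity
(a trial-parity split is available via `split_by="trial"`; with two trials
the two readings differ only in which cycles land in each half).  Each
movement is summarised per split by the per-channel median and IQR of each
normalised measure, giving four summary measures: RMS-median, RMS-IQR,
MNF-median, MNF-IQR.  The distance between two movements' channel vectors
is 1 − τb (Kendall's tau-b, tie-adjusted denominator), in [0, 2].

The split-data RDM (sdRDM) has entry (i, j) = distance(even vector of
movement i, odd vector of movement j); its diagonal measures
within-movement reliability.  The exemplar discriminability index,

    EDI = mean(off-diagonal) − mean(diagonal),

is positive when movements are more dissimilar between than within.  Its
null distribution is obtained by permuting the rows of the sdRDM:
exhaustively for n ≤ 10 conditions (all n! permutations, enumerated in
chunks using the identity that only the diagonal sum varies), or by
Monte-Carlo draws including the identity permutation so that p is never
zero.

### p-value conventions for a discrete null

Two p-values are reported.  `p` counts null EDIs greater than *or equal
to* the observed value — the conservative counting that guarantees a
valid test and yields p = 1 for degenerate (constant) matrices.  `p_mid`
is the tie-split mid-p (ties counted half).  The distinction matters
because τb between few-channel vectors is lattice-valued (7 possible
values for 4 channels), so the permutation null is heavily tied: at the
scaled-down study size the ≥-counting p rejects a true null at rate
≈ 0.02 instead of 0.05 and loses power correspondingly, while counting
only strictly-greater values over-rejects (≈ 0.11).  The mid-p — the
standard recommendation for discrete permutation nulls, and exactly the
average of the two counting rules — restores calibration (≈ 0.04 at
α = 0.05).  The simulation studies and the acceptance script therefore
use `p_mid` for accept/reject decisions; with 7 channels and 10 movements
the two conventions nearly coincide because ties become rare.

## Across-limb relatedness

The unsplit RDMs of the two limbs are vectorised over the upper triangle
(45 entries for 10 movements) and correlated with Kendall's τa
(untied-pair denominator n(n−1)/2; ties count in neither direction).  The
null applies one random condition permutation simultaneously to the rows
and columns of the affected RDM per draw (default 50,000 draws) and
recomputes τa; p = (#{null ≥ observed} + 1) / (n_draws + 1).  Differing
channel counts across limbs are legal: distances are within-limb, and the
test compares equally-sized RDMs.

## Nonmetric MDS

RDMs are embedded in 3-D by nonmetric MDS under the squared-stress
(sstress) criterion: sstress² = Σ(d²_ij − δ̂²_ij)² / Σ d⁴_ij, where the
disparities δ̂² are the isotonic (monotone) regression of the squared
configuration distances onto the rank order of the dissimilarities.  The
fit alternates isotonic regression with L-BFGS updates of the
configuration (analytic gradient), initialised from classical (metric)
scaling plus 4 random restarts; the best solution is kept, iterations
stop when the relative stress change falls below 10⁻⁶ (or when a step
fails to improve, in which case the previous configuration is retained,
making the recorded stress sequence non-increasing).  A distance matrix
that is exactly Euclidean in 3-D is recovered at machine-precision
stress because the classical-scaling start is already optimal.

## Synthetic session generator

Every phase segment is Gaussian noise synthesised in the frequency
domain, confined to the configured band.  Relaxation carries baseline
noise (default sd 0.05 mV, a realistic resting noise floor within the
±11 mV range).  Contraction adds an excitation component whose spectrum
is a Gaussian bump (width 8% of the band) centred at the movement- and
channel-specific `spectral_center`, so both amplitude and mean frequency
carry movement information; the per-channel contraction sd equals
`baseline_sd · (1 + gain · weight · jitter)` with gain defaulting to 4
(contractions up to ~5× the noise floor) and `jitter = exp(N(0, 0.2))`
redrawn per repetition — multiplicative log-normal variability that keeps
amplitudes positive and lets consistency degrade smoothly.  Samples are
clipped to the ADC range and the clipped fraction is logged.  All
randomness descends from one integer seed through a `SeedSequence` tree
split per (movement, trial, cycle); a cohort's two limbs share the noise
stream so that a perfect-fidelity affected limb reproduces the unaffected
signal exactly.

Movement structure is controlled by `distinctness` ∈ [0, 1]: activation
weights are `(1 − d) · 0.5 + d · U(0, 1)` per movement and channel.  The
distinctness-0 limit is deliberately *flat* (all channels at mid-scale):
it represents the null of no movement structure with uniform mean
excitation, so that the channel ordering of any repetition is driven
entirely by repetition variability.  (A shared but *ordered* base pattern
would also be movement-exchangeable, but it degenerates the rank-based
null — nearly all distances collapse to zero and the EDI permutation
distribution becomes a point mass; the flat base makes the null
maximum-entropy and, usefully, independent of the jitter, gain and
baseline settings.)  The affected limb's profile keeps a fraction
`fidelity` of the unaffected structure, mixes in a fresh draw otherwise,
and is scaled by `attenuation` — free knobs, not estimates: no
quantitative description of affected-limb degradation exists to calibrate
them against.

What the generator does *not* emulate: motor-unit physiology, electrode
crosstalk or shift, fatigue drift of MNF, reaction-time variability
(trimming is still applied for pipeline fidelity), or inter-participant
anatomy.  Passing simulation studies therefore demonstrate the
correctness and calibration of the statistical machinery under the
protocol's structure, not clinical performance on real sEMG.

## Scaled-down study conditions

The simulation studies (and the acceptance script) use a reduced
protocol chosen once: 5 movements, 4 channels per limb, 6 repetitions
(2 trials × 3 cycles) at 500 Hz, with the band lowered to 20–200 Hz and
the spectrum cap to 200 Hz because the full-protocol values would violate
Nyquist at 500 Hz.  Calibration runs 500 distinctness-0 cohorts; power
runs 50 cohorts at distinctness 0.8 and gain 2; relatedness runs 50
cohorts at fidelity 0.9 (and 50 at fidelity 0 for the null), with 3000
permutations per relatedness test, ample for decisions at α = 0.05.
Consistency recovery uses 10-movement sessions at repetition jitter 0.05
("low jitter": the regime where a motivated participant reproduces a
movement cleanly).

## Known limitations

* The EDI exhaustive mode at 10 conditions enumerates 3,628,800
  permutations (~seconds); beyond 10 conditions only Monte-Carlo mode is
  offered.
* Mid-p decisions trade the strict validity guarantee of the ≥-counting
  p for calibration; both are always reported.
* The Wilcoxon exact null is computed for n ≤ 25 pairs; larger designs
  would need the normal approximation, which is not implemented because
  the protocol has 10 movements.
* τb is undefined for a fully tied channel vector; such segments raise a
  diagnostic error rather than being silently imputed.
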