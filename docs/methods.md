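# Methods

This note documents the models, estimators and numerical choices behind
`mfvepcad`, the assumptions they make, and what the synthetic cohorts can
and cannot establish.

## Signal model and analysis windows

A recording is a 60 × 6 × 600 block of microvolt samples at 1200 Hz
(500 ms epochs). Sample *i* covers time *i/fs* from stimulus onset; window
bounds are converted to sample indices inclusive-start/exclusive-end with
floor rounding, so the 45–150 ms signal window is samples 54–180
(126 samples) and the 325–430 ms noise window samples 390–516. The two
windows are disjoint by construction and validated in the configuration.

Band-pass filtering (1–35 Hz) is an ideal mask on the discrete Fourier
spectrum: bins strictly outside the band are zeroed, bins at the edge
frequencies retained. This makes the filter exactly linear, idempotent and
zero-phase, at the cost of potential ringing for broadband inputs — an
acceptable trade for evoked responses that are already band-limited. The
channel derivation order and polarity of the 6 channels are treated as
opaque; nothing downstream depends on them.

## Features

**SNR.** The RMS of the signal window divided by the per-channel mean over
all 60 sectors of the noise-window RMS. Normalising by the *mean* noise of
the channel rather than the sector's own noise makes a channel of pure
stationary noise average to SNR 1 (a property test), and a sector is
non-analysable (NAS) when the best of the six channels stays below 1.7.
Ties for best channel break to the lowest channel index.

**Latencies.** Both latency estimators maximise the Pearson correlation
over the overlap of two signal-window segments across integer-sample lags
within ±50 ms. There is no sub-sample interpolation: the clinical
quantities are reported at millisecond scale and one sample is 0.833 ms.
Interocular latency takes the absolute lag between the two eyes'
best-channel responses and assigns it to both eyes; monocular latency is
the signed lag against a control template (subject later than template ⇒
positive). Correlation ties resolve to the smallest |lag| (then the
smaller lag); flat traces raise a degenerate-input error. The template is
the pointwise mean waveform of the control eyes per (sector, channel, eye
side). With a finite control sample the template's own mean latency
carries a sampling error of a few tenths of a millisecond per √n, which
shifts *all* monocular latencies of a cohort coherently — visible as a
small common offset in the synthetic patient groups and an inherent
property of template-based latency estimation.

**Singular spectrum analysis.** The signal-window segment of the best
channel (126 samples) is embedded into the L × (N−L+1) Hankel trajectory
matrix with L = 7, giving exactly seven singular values σ₁ ≥ … ≥ σ₇.
Energy is conserved (Σσₖ² equals the squared Frobenius norm of the
trajectory matrix — a test oracle), and σ scales linearly with trace
amplitude, so the σ features implicitly encode evoked amplitude and
waveform complexity. Only the singular values are used; no component
reconstruction or grouping is performed. L and the analysis segment are
configurable; whether to apply the embedding to the full epoch instead of
the signal window is a genuine design freedom — the signal window was
chosen because the noise window carries no evoked information and a
window-length embedding keeps the σ count at the conventional seven.

**Ring aggregation.** Sectors are averaged within six concentric
eccentricity rings with a default layout of 4, 8, 12, 12, 12, 12 sectors
from centre to periphery (configurable; the ring count and eccentricities
are standard, the per-ring sector counts are a layout choice). Per ring:
mean best-channel SNR over analysable sectors, NAS count, mean
|interocular latency| over sectors analysable in both eyes, mean monocular
latency, and the mean of each σₖ over analysable sectors. A ring whose
sectors are all NAS imputes the SNR mean with the 1.7 threshold and the
latency/σ means with 0 — the NAS count itself carries the information and
the vector length stays fixed at 6 · (4 + i) for i σ values.

## Classification

k-NN is implemented from scratch: Euclidean distance on per-feature
z-scores computed from the training fold (features constant in the fold
are dropped). Standardisation is a deliberate addition — raw Euclidean
distance would be dominated by σ₁ magnitudes (tens of µV) over latencies
(ms) and counts. Vote ties break to the class of the nearest neighbour
among the tied classes, distance ties by training-row order, so
predictions are deterministic. `k = all` uses every training row.

The flat multiclass classifier is a single 6-class k-NN on the base 24
ring features plus σ₁–σ₄ with k = 1. The hierarchical classifier chains
five binary stages — Controls vs patients (no σ), RIS vs CIS+MS (σ₄–σ₇),
CIS vs MS (no σ), CIS-ON vs CIS-non-ON (σ₁–σ₃), MS-ON vs MS-non-ON
(σ₁–σ₃, k = 10) — all other stages k = 1. Stages train on their
ground-truth super-classes (standard practice for hierarchical
classifiers) and include the 24 base ring features alongside their σ
subset. Test eyes follow the stage predictions down the tree, so only the
first stage can emit "Controls". Stages degrade gracefully on degenerate
folds: a missing side predicts the present class with a warning, k is
clamped to the stage's training size, and a σ subset is intersected with
the σ values the vectors carry.

Cross-validation is stratified 5-fold. By default both eyes of a subject
stay in the same fold (stratified on the subject class) to prevent
fellow-eye leakage — fellow eyes share physiology and would otherwise act
as near-duplicates across the train/validation split; a flag switches to
independent per-eye assignment since the original protocol is unknown.
Classes smaller than the fold count trigger a fall back to unstratified
assignment with a warning.

## Subject fusion

Eye predictions are mapped to the four subject classes (ON status is an
eye property), and agreement is judged after that mapping by default — a
CIS-ON and a CIS-non-ON eye agree on CIS; a flag requires raw 6-class
agreement instead, since the clinical description is ambiguous on this
point. On disagreement the eye with the larger mean best-channel SNR
(default: over all 60 sectors; configurable to analysable-only) decides;
at exactly equal SNR the right eye wins (deterministic, documented).

## Metrics

Per-class sensitivity, specificity and precision come from one-vs-rest
collapsing of the confusion matrix; 0/0 cells report 0 with a warning.
The multiclass Matthews correlation coefficient is the Gorodkin RK
statistic, which reduces exactly to the binary MCC on 2 × 2 matrices and
is invariant under simultaneous row/column permutation; degenerate margins
return 0. Recomputing the published benchmark matrices through this
implementation reproduces every printed overall and per-class figure to
the printed two decimals, which pins down the formulation. Group summaries
report mean (sd) per group and a one-way ANOVA p-value per parameter
(no multiple-testing correction, matching the original analysis).

## Synthetic cohorts

The generator exists because the clinical recordings are not deposited.
Per eye it synthesises a damped-oscillation evoked response (Gaussian
envelope centred at 97.5 ms, 12 Hz carrier with a weak 24 Hz second
harmonic, unit RMS over the signal window) scaled by
`1.225 µV × amplitude_scale × eye and sector log-normal factors`, delayed
by `group shift + subject offset (sd 4.2 ms, shared by both eyes) +
eye offset + per-sector jitter`, abolished with the group's dropout
probability, with one dominant channel per sector (off-channel gain 0.4)
plus band-limited (1–35 Hz) Gaussian noise of 0.25 µV RMS. The
oscillatory waveform was chosen over a plain biphasic pulse because a
single smooth pulse is nearly rank-1 in the L = 7 Hankel embedding; the
two spectral components reproduce the paired decay of the clinical σ
spectrum qualitatively while keeping a biphasic morphology inside the
45–150 ms window.

Group profiles (amplitude scale, latency shift, eye-level latency sd,
sector jitter sd, dropout) are calibrated so that *extracted* cohort means
of SNR, NAS, interocular and monocular latency track the published
clinical group statistics within one published standard deviation for
Controls, CIS-ON and MS-ON (the acceptance calibration suite; e.g.
Controls SNR ≈ 5.0, CIS-ON NAS ≈ 25, interocular latency ≈ 4 ms in
controls vs ≈ 14 ms in CIS-ON). Optic-neuritis eyes get large per-sector
jitter, which is what drives their interocular latency up. Eyes are paired
into subjects within each subject class; CIS and MS subjects may mix ON
and non-ON eyes, as in clinical cohorts, and the eye-count layout of the
clinical study (44/30/13/49/37/19) is available as a preset.

What the synthetic cohorts do **not** emulate: within-group correlations
between parameters beyond those induced by the shared amplitude/latency
injection (the true covariance structure is unknowable from published
marginals); realistic cortical topography or inter-subject anatomy; the
full richness of the clinical σ spectrum (the synthetic σ₅–σ₇ are much
smaller than clinical values because the synthetic residual noise is
smoother than real EEG within a 7-sample embedding window); and real
artefact structure. Passing tests therefore demonstrate that the pipeline
recovers the designed group structure and that its estimators satisfy
their identities — not that clinical classification accuracy would be
reproduced on real patients. Consistent with that, the 6-class eye
accuracy on calibrated synthetic cohorts (≈ 0.45–0.55) sits above chance
but below the published clinical figures, whose feature covariances the
generator does not attempt to match.

`scaled_profiles(m)` spreads the six group profiles apart around their
grand mean (log space for amplitude, logit for dropout, linear for
latencies) while shrinking within-group variability by 1/m; it is a
sanity oracle for the classification stack (m = 5 must classify almost
perfectly; m = 1 is the identity), not a realistic condition.
`null_profiles()` removes all group effects and must drive both
classifiers back to chance.

## Problem sizes and determinism

Default test and acceptance runs use 30 eyes per group (180 eyes, 90
subjects) for calibrated cohorts, 50 per group for the calibration spot
checks, and 15 per group for null cohorts, balancing statistical
resolution against run time; the full end-to-end run completes in well
under a minute on one core. All randomness flows from a single
`numpy` Generator seeded per cohort, so identical specifications produce
byte-identical cohorts, fold assignments and reports.

## Known limitations

- The agreement semantics of subject fusion (4- vs 6-class) and the
  fold-assignment policy of the original study are unknown; both are
  configurable and documented defaults were chosen.
- Monocular latencies inherit a small coherent offset from the finite
  control template (see above).
- NAS counts depend on the best-of-six selection: with band-limited noise
  the effective degrees of freedom in a 126-sample window are low, so a
  pure-noise sector occasionally exceeds the 1.7 threshold (~3–5% of
  sectors), which is faithful to the threshold's clinical purpose.
- The EMCC denominator is 0 for single-row/column matrices; 0 is returned
  by convention.
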