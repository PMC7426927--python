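# Methods

## The analysis

`slowmod` quantifies how the anesthesia slow wave modulates activity at
higher frequencies, across space and depth of anesthesia.

**Signal model.** Under propofol the EEG develops a large 0.1–4 Hz slow
oscillation, understood as a scalp-level surrogate for cortical up/down
states: during the down state, cortical firing — rhythmic or not — is
silenced, so power at *all* higher frequencies should wax and wane with the
slow wave. The analysis therefore avoids narrow-band phase estimators and
uses a signed correlation:

    r = Vᵀ A / ( √(VᵀV) · √(AᵀA) )

where `V` is the band-passed slow voltage and `A` the instantaneous
amplitude (analytic-signal magnitude) of one high band. `A` is centered by
subtracting its mean within each 30 s epoch; `V` is deliberately **not**
centered — its expectation is zero, and centering it empirically would
change the pooled estimator below. `r > 0` means the high-band amplitude is
largest at the slow-wave **peak** ("peakmax"), `r < 0` at the **trough**
("troughmax"). Because no slow-wave phase is estimated, the sign of `r` is
robust to non-sinusoidal slow waveforms.

**Averaging by stacking.** To average over epochs, channels, or locations,
the segments are concatenated ("stacked") into single `V` and `A` vectors
and one correlation is computed: covariance and the two norms are pooled
*before* normalization. This is not the mean of per-segment correlations;
the two estimators differ whenever segments have unequal variances, and the
test suite asserts both the equivalence with direct concatenation and the
divergence from the naive mean on a heteroscedastic example.

**Filter bank.** The slow band is 0.1–4 Hz; the high bands tile 4–50 Hz in
2 Hz steps (23 bands) with a 1 Hz transition band; a 8–16 Hz summary band
is filtered directly (never assembled from the 2 Hz tiles). Filters are
Hamming windowed-sinc FIR kernels of order `ceil(3.3·fs/Δf)` (rounded to
even), applied forward and backward for exactly zero phase. The
forward–backward pass is realized as a single linear convolution with the
kernel's autocorrelation, evaluated by FFT with cached kernel spectra; the
analytic signal is obtained in the same pass by folding the one-sided
spectrum selection into the cached multiplier. At the 0.1 Hz low edge a
1 Hz transition is geometrically impossible (the stopband would be
negative), so the low-edge transition is clamped to `min(transition,
low_hz)` — 0.1 Hz for the slow band, giving a 33 s kernel. Half a (single
pass) kernel span at each end of the session is flagged as edge-distorted
and excluded from epoch selection.

**Reference.** Sensor-level analyses use a surface Laplacian: each channel
minus the mean of its first nearest neighbors. "First nearest neighbors" is
made precise by a mutual-closeness rule — `j` neighbors `i` when
`‖i−j‖ ≤ 1.25 ×` the distance from `i` to its single nearest channel —
symmetrized by union; the rule is deterministic and montage-agnostic. The
Laplacian is linear, so it commutes with filtering (asserted in a test);
the implementation exploits this by filtering once and mixing channels
afterwards.

**Two analysis tracks.** Region/location-resolved analyses (the stand-in
for source-space coupling) use the *unreferenced* channel signals: a scalp
re-reference is a sensor-level construct, and applying it to the location
track would bleed opposite-signed coupling into uncoupled neighboring
regions when regions have hard boundaries. Mean vectors (below) are
computed on the same unreferenced track, because mixing neighboring slow
waves with independent phases shifts the apparent preferred phase.

**Levels and epochs.** The stepped protocol is divided into constant-dose
"levels". Four levels of interest are derived from the annotations:
Baseline (before drug onset), Sedation (the level prior to the one
containing loss of consciousness, absent when LOC falls in the first drug
level), Unconscious Low Dose (the first full level after LOC) and
Unconscious High Dose (the highest-dose level, or the level before burst
suppression). Within each level, disjoint artifact-free 30 s epochs are
selected earliest-first (deterministic); level-based coupling stacks all
selected epochs.

**Principal frequency modes.** Level-based coupling spectra for all
(subject, level, channel) observations form an aggregate matrix `A(f, i)`
(23 bands × observations), decomposed by a plain SVD `A = U S Wᵀ` with
**no mean subtraction**: non-centered PCA partitions total energy about the
origin — the physically meaningful "no coupling anywhere" state — rather
than variance about the grand-mean coupling pattern. Each mode (column of
`U`) is sign-fixed so its element of maximal absolute value is positive
(ties broken toward the lowest frequency), preserving the peakmax/troughmax
reading; mode `j` explains `S(j,j)²/Σₖ S(k,k)²` of the energy. Region
patterns are projected onto the sensor-derived modes, `P = Uᵀ A_region`;
the first row of `P` is the broadband-peakmax score.

**Mean-vector validation.** `mean(A·e^{iφ_S})`, with `φ_S` the analytic
phase of the slow band, is computed per epoch for the summary band. Its
preferred phase concentrates at 0 (peak) or π (trough) on coupled epochs,
which is the empirical justification for collapsing phase-amplitude
coupling to a single signed correlation.

**Bootstrap.** Cross-subject uncertainty of first-mode projections is
summarized per (level, region) by resampling subjects with replacement
(2000 resamples, seeded). The default interval is Hesterberg's *expanded
percentile*: the 2.5/97.5 percentile interval widened about the observed
mean by `t_{0.975,n−1}/z_{0.975}·√(n/(n−1))`. With cohorts of 6–10
subjects the plain percentile interval is materially anti-conservative
(Monte-Carlo true coverage ≈ 90% at n=10, ≈ 84% at n=6, against a nominal
95%); the expansion restores ≈ 96% / 94% under the same simulation. The
plain percentile interval remains available (`method="percentile"`); its
bounds never leave the observed data range, which the expanded interval
does not guarantee.

## The synthetic session generator

Real recordings of this design are not redistributable, so every stage is
validated against generated sessions with exactly known coupling.

Each channel carries, per level:

* **Slow wave** — `a·cos(φ(t) + skew·sin φ(t))`, nominal 1 Hz with
  fractional frequency jitter (a smoothed random trace below 0.2 Hz scaled
  by the jitter fraction), mean-removed per level. The monotone phase
  distortion produces asymmetric, non-sinusoidal cycles while keeping
  > 99.99% of the energy below 4 Hz for any skew < 1 (verified by FFT
  enumeration); `skew = 0` is a pure sinusoid. Amplitude defaults to
  50 µV. Every channel has an *independent* slow realization, so the
  Laplacian attenuates but cannot cancel the slow component.
* **Modulated components** — per planned (band, depth): band-limited
  Gaussian noise synthesized in the frequency domain (exact band support),
  or a sinusoid for rhythmic (alpha) entries, with instantaneous envelope
  `base·(1 + depth·ŝ(t))`, `ŝ` the channel's slow wave rescaled to
  [−1, 1]. `depth ∈ [−1, 1]` is the ground-truth coupling: its sign is the
  peakmax/troughmax target every end-to-end test recovers. Base scale
  2 µV per 2 Hz band. Independent noise per band makes per-band depth
  directly controllable.
* **Background** — 1/f-amplitude broadband noise (1 µV total SD, flattened
  below 0.5 Hz) and white sensor noise (0.5 µV SD), both uncoupled.
* **Artifacts** — optional 1000 µV steps over configured windows, recorded
  in the artifact mask; they exercise epoch exclusion, not artifact
  physics.

All randomness derives from named `SeedSequence` substreams of one seed;
identical configuration and seed reproduce the session bit for bit.

**Presets.** `paper-like` encodes the emulated study's spatial story:
frontal alpha (8–12 Hz sinusoid) troughmax at depth −0.6 during Sedation;
posterior-only broadband peakmax (+0.6, all 23 bands) at the Unconscious
Low Dose; global broadband peakmax (+0.8) at the High Dose. `null` has no
coupling; `broadband-only` couples every region at both unconscious doses
(+0.7), the condition under which the first principal mode must come out
flat, positive and dominant. The schedule is lead-in (30 s), Baseline, L1,
a short transition level containing LOC, L3, L4, tail (30 s); the lead/tail
keep filter-edge exclusion out of the analysis levels.

**What the generator does not emulate.** Spatially coherent slow waves,
realistic artifact morphology, volume conduction, electrode bridging
physics, burst suppression waveforms, or any biophysical (neural-mass)
dynamics. Passing tests therefore demonstrate that the estimators recover
planted modulation structure through the full preprocessing chain — not
that the pipeline is robust to everything real EEG can do.

## Problem sizes and numerical choices

* Cohort presets default to 2 min per level (4 × 30 s epochs per level,
  ≈ 10 s of sessions per subject at 200 Hz × 32 channels), the package's
  standard quick-cohort size; the full protocol scale (14 min levels, 10
  epochs, 300 s of data per level-based correlation) is one configuration
  switch (`level_duration_s=840`), and the epoch count auto-resolves as
  `min(10, duration // 30 s)`.
* The end-to-end recovery check uses 6 subjects × 32 channels × 23 bands ×
  4 levels over 10 independent cohort seeds. A planned-zero cell counts as
  recovered when |r| < 0.1, about five times the Monte-Carlo null standard
  deviation of the stacked estimator at these data sizes; "frontal near
  zero" means < 0.3 × the posterior projection at the same level.
* Heavy array work runs in float32/complex64; all correlations accumulate
  in float64. Analytic identities hold to 1e-9 and scale invariance to
  1e-12 in the float64 reference paths.
* Zero-variance inputs to the correlation yield an explicit undefined
  record (`defined=False`, NaN), never a silent 0 — a 0 would read as "no
  coupling", which is a claim, not an absence.
* SVD is `numpy.linalg.svd`; its singular values are cross-checked in
  tests against an independent Gram-matrix eigendecomposition
  (`scipy.linalg.eigh`), and reconstruction is asserted to 1e-8 relative
  Frobenius error.
* Channels whose whole-session correlation exceeds 0.999 are treated as
  bridged and dropped (later channel of the pair); samples over 500 µV or
  flat for 1 s are masked as artifacts. Both are simple testable stand-ins
  for manual/visual procedures.

## Known limitations

* Region analysis treats channel groups (frontal/central/posterior by the
  anterior-posterior coordinate) as opaque "locations"; no inverse
  modelling is performed or emulated.
* The epoch placement rule (earliest-first) is one deterministic choice
  among many defensible ones; results at these effect sizes do not depend
  on it.
* The modulogram stacks channels within each 30 s window; per-channel
  session modulograms are available by passing singleton location sets.
* With very small montages (< ~6 channels) some anterior-posterior groups
  are empty and preset plans silently restrict to the groups that exist.
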