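# slowmod

Broadband slow-wave modulation analysis for anesthesia EEG.

Under propofol, the EEG develops a large 0.1–4 Hz slow oscillation — a
scalp-level surrogate for cortical up/down states in which neural firing is
periodically silenced. `slowmod` quantifies how strongly, and with what
sign, activity in every higher frequency band is modulated by that slow
wave, and how the spatial pattern of this modulation changes with
anesthetic depth. It is written for researchers analyzing stepped-dose
anesthesia (or sleep) EEG who want a phase-free, broadband alternative to
conventional phase-amplitude coupling metrics.

## The method

Coupling between the slow wave and a high band is a signed correlation:

```
r = VᵀA / ( √(VᵀV) · √(AᵀA) )
```

with `V` the band-passed slow voltage (0.1–4 Hz, left uncentered — its
expected value is zero) and `A` the instantaneous amplitude of the high
band (analytic-signal magnitude, mean-centered within each 30 s epoch).
`r > 0`: amplitude is largest at the slow-wave **peak** (*peakmax*);
`r < 0`: at the **trough** (*troughmax*). Averages across epochs, channels
or regions stack the segments into single `V`, `A` vectors before the one
correlation — pooling covariance and norms separately, which is not the
mean of per-segment correlations.

Computing `r` for 23 bands tiling 4–50 Hz yields a coupling spectrum per
(subject, level, location). These are collected into a matrix `A(f, i)`
and decomposed by **non-centered PCA** (a plain SVD, `A = U S Wᵀ`, with no
mean subtraction, so energy is decomposed about the physically meaningful
"no coupling" origin). The first principal frequency mode is a flat,
all-positive pattern — broadband coupling — and region-resolved coupling
spectra are projected onto it (`P = Uᵀ A_region`) to score broadband
peakmax per region and dose, with bootstrap-over-subjects confidence
intervals. A mean-vector estimator (`mean(A·e^{iφ_S})`) validates that
coupling concentrates at the slow-wave peak or trough.

Because real recordings of this design are not redistributable, the
package ships a synthetic session generator with exactly known coupling
(`depth ∈ [−1, 1]` per channel, band and dose level), emulating the study
structure: frontal alpha troughmax during sedation, posterior-only
broadband peakmax at a low unconscious dose, global broadband peakmax at a
high dose. Every end-to-end test recovers that ground truth through the
full preprocessing chain (zero-phase FIR filter bank, nearest-neighbor
Laplacian reference, artifact-free epoch selection). See
`docs/methods.md` for the model, parameters and limitations.

## Worked example

```python
from slowmod import RunConfig, run_synthetic_cohort

config = RunConfig(preset="paper-like", n_subjects=6, n_channels=32, seed=7)
result = run_synthetic_cohort(config)

d = result.decomposition
print(f"first principal mode: {d.percent_energy[0]:.1f}% of total energy "
      f"(mode 2: {d.percent_energy[1]:.1f}%)")
print(f"mode-1 weights all positive: {bool((d.modes[:, 0] > 0).all())}")

proj = result.projection.first_mode()
table = proj.groupby(["level", "location"])["projection"].mean().unstack()
print(table.round(3).to_string())
```

prints

```
first principal mode: 85.0% of total energy (mode 2: 9.3%)
mode-1 weights all positive: True
location  central  frontal  posterior
level
Baseline   -0.004    0.008      0.018
Sedation    0.001   -0.395      0.001
UncHigh     1.842    1.846      1.845
UncLow      0.004    0.018      1.564
```

Read the table row by row: at Baseline nothing couples to the slow wave
(scores ≈ 0). During Sedation only the frontal region shows a *negative*
score — the planted alpha troughmax. At the Unconscious Low Dose the
posterior region alone swings strongly positive (broadband peakmax) while
frontal stays near zero; at the High Dose all three regions are positive
and of similar magnitude — global broadband peakmax. The dominant,
all-positive first mode is what makes a single number per region capture
"broadband coupling to the slow-wave peak".

The same pipeline runs from the shell and writes CSV tables, HDF5
modulograms and a reproducibility manifest:

```bash
slowmod run --preset paper-like --seed 7 --out results/
slowmod simulate --preset paper-like --seed 1 --out session/   # one synthetic subject
slowmod couple session/session.h5 --out coupling/              # coupling tables
slowmod modes coupling/coupling_levels.csv --out modes/        # principal modes
```

Real recordings enter either through the HDF5 interchange container
(`slowmod.save_session` / `load_session`) or standard EEG formats via
`slowmod.read_eeg`, with level annotations as a CSV table.

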