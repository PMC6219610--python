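# Methods

This note documents the models, parameter choices and numerical
decisions behind `ufd_hemo`, and what the synthetic data do — and do
not — establish about real ultrafast-Doppler recordings.

## Signal model of the synthetic IQ data

IQ blocks are synthesized directly in image space (post-beamforming).
This decouples the Doppler-processing chain from beamformer
correctness; raw channel data exist separately
(`simulate_rf_plane_wave`) solely to exercise the delay-and-sum module.

Per pixel p and frame time t the complex signal is

```
s(p, t) = A(p) e^{iψ(p)} e^{ik [d₁(t) + w(p) d₂(t)]}        (tissue)
        + Σ_j a e^{i[φ_j + k γ_j ∫ v(τ)dτ]}                  (blood)
        + n(p, t),                                           (noise)
```

with k = 4π f₀/c the two-way Doppler wavenumber (a scatterer at axial
speed v advances the phase by 4π f₀ v Δt / c per frame, i.e. Doppler
frequency 2 f₀ v/c — the standard pulsed-Doppler convention; the
acquisition literature states none explicitly).

**Tissue.** A(p) is a smoothed texture around amplitude 90 (power
~8100), ψ(p) uniform.  Motion has two parts: a spatially uniform
sinusoid d₁ (5.7 µm at 1.7 Hz, peak tissue velocity ≈ 60 µm/s) and a
spatially weighted steady drift d₂ (57 µm/s, weight map w(p) ∈ [0, 1]).
A shared displacement of any size is *exactly* one singular component
of the Casorati matrix (one temporal function times one spatial
pattern); the weighted drift contributes a second component whose
energy is set well above the blood level.  A drift is used rather than
a second sinusoid because over a 0.1–0.5 s block a slow sinusoid can
sit on a crest and contribute nothing, letting the second removed
component capture blood instead — a failure mode we observed directly
(blood energy projected onto the removed subspace reached 15 % for
crest-aligned realizations, versus < 0.1 % with the drift).

**Blood.** Vessel pixels (35 % of the slice, drawn per subject) carry a
Poisson number of scatterers, expectation 8 per pixel at baseline
scaled by the local density multiplier 1 + CBV(t)/100 (floor 0.05),
each with unit amplitude, a random phase, and a per-scatterer
multiplicative velocity jitter (SD 5 %).  The jitter decorrelates pixel
time series so blood spans many singular components, and reproduces
physiological spectral broadening.  Speckle statistics follow: pixel
power is exponential with mean ∝ scatterer count, hence power Doppler ∝
CBV.  Tissue-to-blood power is ≈ 30 dB (configurable; the scanner's
actual echo budget is not published).  Complex white noise has power
0.15 (≈ 2 % of baseline blood power).

**Velocity waveform.** `pulsatile_velocity` is a raised-cosine systolic
pulse (systole = 40 % of the cycle) on a diastolic baseline: max =
v_sys, min = v_dia, period 1/heart rate (4.2 Hz ≈ 250 bpm rabbit), so
the prescribed resistivity index is exactly 1 − v_dia/v_sys.  Velocity
states per protocol phase keep the 4σ-jittered systolic speed below the
one-sided aliasing limit c·fs/(4f₀) ≈ 12 cm/s.

**Motion artifacts.** Within 23–26 min post-CPR (chest-compression
window), noise amplitude ×5 and tissue drift ×10; the elevated drift
deliberately leaks clutter past the filter, producing the artefactual
relative-UfD excursions that the artifact mask excludes from AUC
integration and peak detection.

## Group templates

Relative-CBV curves are piecewise linear in minutes relative to CPR,
anchored at 0 % through baseline, dipping to −80 % during arrest,
peaking at t = 10 min, and settling slightly below baseline by 67 min.
Regional peaks (Control): cortex +150 %, hippocampus +210 %, thalamus
+126.6 %; the background-vessel peak is solved so the vessel-area-
weighted whole-slice curve peaks at exactly +150 % (density multiplier
2.5).  TLV peaks are scaled down (whole-slice +43 %, chosen so the
7–37 min normalized AUC ≈ +26 % against the Control ≈ +84 %) and stay
pointwise below Control throughout the window.

**Subject-level variation** multiplies each region's hyperemic lobe by
shared × region-specific Gaussian factors (mean 1, truncated at 0.1).
Dispersions: hippocampus rel SD 0.35 (peak ±74 on 210) and whole-slice
≈ 32 (±34 reported) match the reported values; cortex and thalamus
dispersions (total rel SD ≈ 0.62 / 0.67) are deliberately larger than a
literal reading of their printed peak ±SDs.  With the literal values
the thalamus — smallest dispersion — would mechanically carry the
largest Cohen's d, inverting the reported effect-size ordering
(hippocampus 1.76 > thalamus 1.081 ≈ cortex 1.08).  Since per-subject
AUC dispersions are not derivable from the published summary numbers,
we prioritised the reported *ordering* (hippocampus largest effect,
population d ≈ 2.5 vs ≈ 1.65) over the per-region peak ±SDs.

**MAP.** Arrest groups: baseline ≈ 70 mmHg, a transient compensatory
rise then collapse during asphyxia, recovery after CPR clipped to the
physiological 60–90 mmHg band (Control base 77 mmHg, SD 4; TLV base
60 mmHg plus a pressure-passive coupling of 0.4 mmHg per % CBV, SD 1.5
— this coupling is what produces the steep-but-linear CBV–MAP cloud).
Sham: a 4 min baseline at 72 mmHg then a sweep 42→138 mmHg; its CBV
follows a classical autoregulation curve (slope 0.1 %/mmHg on the
60–105 plateau, 0.8 below, 0.3 above, zero at 72 mmHg).

## Processing choices

- **SVD filter**: economy decomposition via the nt×nt temporal Gram
  matrix (frames ≪ pixels; identical result, orders of magnitude
  cheaper), eigensolve in double precision whatever the input dtype, so
  Parseval (Σσᵢ² = ‖X‖²) and the kept+removed complement identity hold
  to < 1e−8 relative error.  Default cutoff: remove the 2 leading
  components (the synthetic clutter occupies two modes); an
  energy-fraction mode and a high-rank noise cutoff are available but
  off by default.
- **Power** is the per-pixel *mean* of |s|² over frames (mean vs sum
  differ by a constant that cancels in relative maps).
- **Baseline** is the per-pixel mean power over all blocks in
  [−23, −13] min; pixels below the noise floor (default: 3× the median
  baseline power, separating vessel from noise-only pixels while
  vessels are a minority) are NaN in every relative map and excluded
  from regional averages.
- **Spectrogram**: Hann window of 64 frames (32 ms at 2 kHz), 75 %
  overlap, implemented as a windowed DFT with the exact Parseval
  scaling Σ_f P = n_fft·Σ_t |x·w|².  The window resolves the ~4 Hz
  cardiac modulation with ≥ 31 Hz spectral resolution; the first moment
  uses |f| (speed magnitude — RI is direction-free) after subtracting
  the per-slice median spectral power as a robust white-noise floor.
  Windowed smoothing attenuates the systolic peak by ≈ 4 % of the
  pulse amplitude; the residual RI bias stays below the 0.05 recovery
  tolerance.
- **RI extremes** are taken over the whole block (≥ 1 cycle required,
  ≥ 2 at the full 0.5 s), avoiding beat segmentation.
- **Peak relative UfD** per subject is the maximum of the artifact-free
  regional series after a 3-block moving average.  The average
  suppresses the upward bias of a max over noisy samples at the cost of
  ≈ 3 % flattening of the triangular peak; the two biases largely
  cancel (single-subject estimates track realized ground truth to a few
  percent).
- **Exact Mann-Whitney U**: U counts pairs with a_i > b_j plus ½ per
  tie; p-values enumerate all C(n₁+n₂, n₁) labelings of the observed
  multiset (midranks), falling back with a warning to the tie-corrected
  normal approximation above n = 10 per group.  The test is discrete
  and conservative: at n = 5 + 5 the attainable two-sided p-values jump
  from 8/252 ≈ 0.032 to 0.056, so the true level at nominal 0.05 is
  ≈ 0.032 — the calibration test verifies the empirical rate ≤ 0.05.
- **AUC** is the trapezoidal integral over the window divided by its
  length (a constant c % series yields c), with artifact points removed
  before integration and window edges obtained by linear interpolation.
- **Autoregulation standardization** (default `pooled`): per-variable
  mean removal, then division of both centred variables by the single
  SD of their concatenation, preserving the native anisotropy between
  CBV (%) and MAP (mmHg) spreads; `per_variable` z-scoring is provided
  as an option.  With realistic post-arrest spreads (CBV SD ~40 % vs
  MAP SD ~6 mmHg) the pooled control cloud is strongly anisotropic
  along the CBV axis, so the classifier treats a near-vertical first
  axis — CBV varying with no MAP counterpart — as impaired, alongside
  the low-ratio criterion; the control cloud's decorrelation (λ₁/λ₂ <
  3) appears in the z-score plane.  Classification thresholds
  (flat ≤ 15°, steep > 75°, ratio high ≥ 5 / low < 3) are configurable.
- **PCA** uses the n−1 covariance; eigenvector signs are fixed by the
  first-nonnegative-coordinate rule (matching the reported vector
  conventions); λ₁/λ₂ is the anisotropy diagnostic.

## Problem sizes

Desk-scale runs use 64×64-pixel grids, 200-frame blocks and a 30 s
block cadence (the full-scale values — 1000 frames, 10 s cadence — are
plain configuration switches).  The cadence subsamples piecewise-linear
template curves whose knots it hits exactly, so no peak information is
lost.  Resistivity analyses need at least one cardiac period per block
and therefore use 600-frame (0.3 s) blocks.  The acceptance run (five
subjects × 181 blocks through the full chain) takes ~2 minutes on one
CPU; the statistical-calibration check runs 500 template-level
repetitions.

## What the synthetic data do not show

The generator emulates the clutter/blood energy ordering, speckle
statistics, pulsatile Doppler spectra and group-level CBV/MAP dynamics,
but not: acoustic propagation (element directivity, attenuation,
reverberation), scatterer translation across pixels (speckle is static
within a block and redrawn between blocks, so within-block speckle
averaging is absent), vessel geometry and flow angles (axial velocities
only), aliased or out-of-plane flow, respiratory motion, or
inter-animal anatomical variability (masks are shared rectangles).
Passing tests therefore establish the correctness and calibration of
the *processing chain* under a faithful signal model, not scanner-level
performance on in-vivo data; the in-vivo group statistics themselves
(e.g. p = 0.032, d = 1.76, MAP medians) are not reproducible without
the animal recordings and are not targets.

## Known limitations

- The clutter rank is exactly two by construction; real tissue motion
  spreads over more components and the fixed-count cutoff would need
  adjustment (the spectrum is returned for diagnostics, and an
  energy-fraction mode exists).
- The blood-to-tissue ratio, noise floor and vessel density are
  configurable assumptions, not calibrated to a scanner.
- The probe's element count/pitch are placeholders (128 × 0.3 mm); the
  beamformer is verified on point-spread localization and linearity,
  not against a hardware reference.
- `BaselineReference`'s automatic noise floor assumes vessels occupy a
  minority of pixels; dense vascular fields need an explicit floor.
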