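# ufd-hemo

Multi-parametric **ultrafast Doppler (UfD)** analysis of cerebral
hemodynamics around cardiac arrest and resuscitation, as a tested,
reproducible Python pipeline on synthetic ultrasound data.

The package is aimed at researchers in functional ultrasound and
neurocritical-care imaging who want a working, end-to-end reference for
the processing chain behind UfD hemodynamic studies — from plane-wave
acquisition timing through clutter filtering to regional statistics —
with every stage testable against known ground truth.  No animal data
are required or used: a first-class synthetic-data module generates
complex IQ blocks with prescribed tissue clutter, pulsatile blood flow
and group-level cerebral-blood-volume (CBV) dynamics.

## The processing chain

1. **Acquisition model.** A 6.4 MHz linear array fires 4 tilted plane
   waves (−3°, −1°, 1°, 3°) at an 8 kHz pulse repetition frequency;
   delay-and-sum beamforming plus coherent compounding yields complex
   frames at fs = PRF/4 = 2 kHz.  Each Doppler block holds 1000 frames
   (0.5 s, ≈2 rabbit cardiac cycles); blocks repeat every 10 s over a
   90-minute protocol (10 min baseline, 13 min asphyxia, CPR at t = 0,
   follow-up to 67 min).  Axial flows up to c·fs/(2f₀) ≈ 24 cm/s are
   sampled without aliasing.
2. **SVD clutter filtering.** Each block is rearranged into its
   Casorati matrix X (rows = pixels, columns = frames) and decomposed,
   X = Σᵢ σᵢ uᵢ vᵢᴴ.  Tissue clutter — strong, spatially coherent,
   slowly varying — concentrates in the leading singular components;
   removing them (default: the first 2) leaves the blood signal.
3. **Power Doppler and relative CBV.** Per pixel, the time-averaged
   energy P = ⟨|s(t)|²⟩ of the filtered signal is proportional to CBV;
   relative CBV = 100·(P − P₀)/P₀ against the per-pixel mean power P₀
   of the −23′..−13′ baseline window (so +150 % means 2.5× baseline).
4. **Resistivity index.** A per-pixel spectrogram gives the mean blood
   speed v(t) = (Σ P(f)·|f| / Σ P(f))·c/(2f₀) at each instant; the
   resistivity index over the cardiac cycle is
   RI = (v_max − v_min)/v_max ∈ [0, 1].
5. **Regional statistics.** Relative-CBV maps are averaged over
   anatomical masks (cortex, hippocampus, thalamus, whole slice),
   summarised as time-normalized AUC over a protocol window (7–37 min,
   chest-compression artifacts at 23–26 min excluded), and compared
   between groups with an **exact Mann-Whitney U test** (full
   enumeration of all C(n₁+n₂, n₁) labelings) and **Cohen's d**.
6. **Autoregulation PCA.** Paired (CBV, MAP) samples per group are
   standardized and decomposed into principal axes v₁, v₂ with weights
   λ₁ ≥ λ₂; a flat v₁ with large λ₁/λ₂ is an autoregulation plateau, a
   steep anisotropic cloud a pressure-passive circulation, and a cloud
   with no dominant CBV–MAP axis impaired regulation.

Three shipped hemodynamic templates define the study conditions: a
**Sham** MAP sweep under intact autoregulation, a **Control** group with
severe transient hyperemia (whole-slice peak +150 %, hippocampus
+210 %, ~10 min after CPR), and a **TLV** group (total liquid
ventilation, rapid hypothermia) with mitigated hyperemia.

## Worked example

Regional hyperemia and autoregulation on five-subject synthetic
cohorts (`python analysis/04_regional_hyperemia.py`,
`python analysis/05_autoregulation.py`):

```
auc_7_37 whole_slice : control median   85.4 % vs tlv   23.6 %  U=25 p=0.0079 d=2.94
auc_7_22 hippocampus : control median  163.8 % vs tlv   25.7 %  U=25 p=0.0040 d=3.51
...
sham    : v1=(+0.98, +0.21) lambda1/lambda2=31.5 angle=+12.2 deg -> plateau
control : v1=(+0.00, +1.00) lambda1/lambda2=83.5 angle=+89.8 deg -> impaired
tlv     : v1=(+0.32, +0.95) lambda1/lambda2=30.0 angle=+71.4 deg -> linear_steep
```

Reading: over 7–37 min post-resuscitation the Control group's
whole-brain blood volume averaged +85 % above baseline against +24 %
under rapid cooling (exact two-sided p = 0.0079, the smallest value
attainable at n = 5 per group apart from the perfect split); the
hippocampus carries the largest effect size.  The PCA line shows the
sham cloud as a near-horizontal dominant axis (CBV held constant across
a wide MAP range — a plateau), the TLV cloud as a steep but still
linear CBV–MAP relationship, and the control cloud as CBV varying with
no MAP counterpart — impaired autoregulation.

Resistivity recovery (`python analysis/03_resistivity_recovery.py`):

```
prescribed      RI_true=0.200 recovered median=0.218
prescribed      RI_true=0.500 recovered median=0.510
prescribed      RI_true=0.800 recovered median=0.801
baseline        RI_true=0.600 recovered median=0.607
hyperemic_peak  RI_true=0.350 recovered median=0.364
```

The numbered scripts under `analysis/` run the full narrative in order
(01 simulate → 02 Doppler processing → 03 resistivity → 04 regional →
05 autoregulation), writing their tables under `results/`.  The same
chain is available as a CLI (`ufd-hemo simulate|filter|maps|…|run`)
driven by a YAML configuration with per-stage content hashing, so
re-runs skip unchanged stages.

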