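# Methods

## Problem and model

During tumour resection near a motor nerve, a surgeon localises the nerve by
probing with constant-current pulses and watching for compound muscle action
potentials (CMAPs) in the target muscle's EMG. A single CMAP amplitude does
not encode how far the probe is from the nerve, because the intervening
medium's impedance modulates how much current reaches it. `nervelocate`
implements a localisation pipeline that combines three measurement channels
into a quantitative probe-to-nerve distance estimate:

1. **Tissue equivalent circuit.** The load seen by the probe is modelled as a
   series access resistance `Rs` in line with a parallel pair `Rp || Cp`.
   Driving a constant current `i` produces the voltage response

       V(t) = i·Rs + i·Rp·(1 − e^{−(t−t0)/τ}),   τ = Rp·Cp,

   so `Rs = V0/i` from the instantaneous step, `Rp = Vx/i − Rs` from the
   saturated plateau, and `Cp = τ/Rp` with τ from a one-parameter nonlinear
   least-squares fit of the charging segment. The impedance magnitude at a
   probing frequency f is `|Z| = |Rs + Rp/(1 + j·2πf·Rp·Cp)|` (default
   f = 500 kHz). Note the charging curve is written with `(Vx − V0)`; this is
   the only form consistent with the boundary conditions `V(t0) = V0` and
   `V(∞) = Vx` for this topology.

2. **CMAP features.** Four stimulus levels at 100/110/120/130% of the motor
   threshold (MT), four pulses per level (~500 ms apart), are delivered while
   EMG (2 kHz) and a trigger channel are recorded. Per level the four
   trigger-aligned sweeps are grand-averaged; the peak-to-peak voltage of the
   grand average is the CMAP amplitude and the time of its largest-magnitude
   peak the latency. Amplitudes are normalised to `NCMAP_k = (CMAP_k −
   CMAP_1)/(CMAP_4 − CMAP_1)·100`, removing subject-dependent gain, and the
   line `NCMAP = θ1·i + θ2` is fitted by OLS. The trial latency `tL` is the
   mean over the four grand averages.

3. **Distance regression.** The base model

       d = λ1·iMT/(CMAP·Z) + λ2·tL/Z + η

   inverts the generative assumptions that amplitude scales as `iMT/(d·Z)`
   and latency as `Z·d`. The extended model replaces the constant η with two
   structured error functions:

       η1 = Σ_j b1(j)·X1(j),  X1 = [1, θ1, θ2, R²_lin, iMT/Rp]
       η2 = Σ_j b2(j)·X2(j) + Σ_k α(k)·e^{β(k)·R̃(k)},
            X2 = [Cp, R²_τ, Rs/Cp, tL],  R = [Rs, Rp]

   for 15 parameters, fitted by minimising the sum of squared distance
   residuals.

## Numerical choices

- **Edge detection.** The rising edge is the largest forward difference,
  accepted only above 10× the pre-pulse noise SD, then walked back across the
  contiguous run of significant positive differences: for fast time constants
  the first *charging* increment can exceed the onset step itself, and without
  the walk-back `V0` lands one sample late and `Rs` is badly biased. `v0`
  defaults to the single sample at the edge (exact on synthetic and
  grid-aligned captures); a `v0_samples` median mode exists for noisy traces,
  at the cost of a known upward Rs bias of order `(Vx−V0)(1−e^{−Δt/τ})/i` per
  extra sample. The plateau begins where the boxcar-smoothed slope drops below
  1% of the initial slope *or* below the slope noise floor (3 SD of smoothed
  pre-pulse slope) — near saturation the true slope is far below per-sample
  noise, so a raw 1% rule never fires on real traces. `vx` is the mean of the
  final 10% of the plateau.
- **τ fit.** Bounded one-parameter least squares (`scipy.optimize.
  least_squares`, trust-region-reflective) with `V0`, `Vx` pinned to the
  landmarks, initialised at the 63.2%-rise time, bounded by one sample period
  and the observed span. A warning is issued when the record is shorter than
  5τ. Degenerate charging (`vx ≈ v0` within 1e-3 relative) returns a purely
  resistive circuit: `Rp = 0`, `Cp`/τ undefined (NaN), and impedance is only
  defined at f = 0.
- **Ambiguous fraction renderings.** Three regression features are written by
  juxtaposition in the source formulas; the ratio readings (`tL/Z`, `iMT/Rp`,
  `Rs/Cp`) are the defaults because the latency generative law (`tL ∝ Z·d`)
  inverts to `d ∝ tL/Z` and the same rendering is used elsewhere for `Cp =
  τ/Rp`. The product readings are available through `FeatureReading`.
- **Feature standardisation.** Every predictor column is centred and scaled
  internally (constant columns pass through), and the exponentials act on the
  *scaled* resistances — `exp(β·Rp)` with Rp ~ 10⁴ Ω overflows for any
  |β| > ~10⁻³. Coefficients are stored in scaled space together with the
  scaling, so predictions are invariant to the raw units;
  `raw_base_coefficients()` undoes the scaling for the base variant.
- **Extended fit.** Multi-start bounded least squares (|β| ≤ 10, 8 starts):
  the base solution embedded in the extended parameterisation, the
  11-parameter linear subproblem's OLS solution with β = ±0.1, and seeded
  perturbations of it. Because one start *is* the base optimum and the
  optimiser is monotone, the extended training SSE can never exceed the base
  SSE. The α/β parameters are not always identifiable (exponentials can be
  locally linear over the data range); predictions are the reproducible
  quantity, not individual coefficients. Fits are bit-reproducible for a
  fixed seed.
- **Cross-validation.** Seeded shuffled k-fold (default k = 10) with fold
  sizes differing by at most one. Accuracy is the per-fold Pearson
  correlation × 100, averaged across folds with the sample SD (ddof = 1,
  n = k); note this metric is invariant to affine transforms of the
  predictions with positive slope, so it measures linear association, not
  calibration. Error is the per-fold mean absolute deviation in mm (RMSE
  behind a flag). A `group_by_subject` mode keeps each subject's trials in
  one fold; the default ungrouped split matches the reference protocol but
  leaks subject effects across folds.

## The phantom

The phantom reproduces the bench protocol — 12 subjects × 4 mock materials ×
5 distances (0–4 mm), i.e. 240 trials — entirely in software, and extracts
every feature by running the *real* pipeline on synthetic raw signals.

- **Materials.** Four equivalent circuits spanning the measured range of
  gelatin mock materials from ~1161 Ω down to ~332 Ω at 500 kHz, with 5%
  lognormal per-subject jitter (heterogeneity, not noise).
- **Generative laws.** Amplitude `CMAP = λ1*·iMT/(d_eff·Z)` with
  λ1* = 2·10⁴ V·Ω·mm/A; latency `tL = 7 ms + λ2*·Z·d_eff` with
  λ2* = 5·10⁻⁷ s/(Ω·mm); threshold `i_th = a0(1 + a1·d_eff)(1 + a2/Z)` with
  a0 = 20 µA, a1 = 1/mm, a2 = 200 Ω (MT rises with distance and with
  shunting, spanning ~30–180 µA). `d_eff = d + 0.5 mm` models the electrode
  standoff and keeps the inverse-distance law finite at contact. Recruitment
  across the 100–130% levels is mildly saturating (`1 + 2x − 0.8x²`,
  x = fractional overdrive); exact linearity would make θ2 a constant for
  the fixed level ladder and degenerate the extended design. These
  coefficients are synthetic choices spanning realistic ranges, not
  measured tissue properties.
- **CMAP template.** Biphasic, ~2.6 ms, with flat-topped lobes of 0.6 ms —
  longer than one EMG sample at 2 kHz — so the sampled peak-to-peak equals
  the generative amplitude for any sub-sample latency alignment, and the
  noiseless pipeline is exact up to latency quantisation (≤ one sample).
- **MT search oracle.** Single simulated sweep per tested current; detection
  threshold 10× the EMG noise SD. The max–min of a 96-sample noise window
  averages ≈4.9 SD, so the generic 5× default used for grand-averaged
  responses would false-trigger on single sweeps (measured 5.9·10⁻⁵
  false-positive rate per sweep at 8×, negligible at 10×).
- **Noise model.** Gaussian waveform noise (2 mV), EMG noise (20 µV), 5%
  lognormal amplitude jitter, 0.2 ms latency jitter, 5% threshold jitter;
  all scaled by a single `noise_scale` (0 = noiseless limit). The phantom
  models *measurement* noise only — no biological trial-to-trial
  variability, electrode drift, spontaneous EMG activity, or model
  misspecification (its records follow the generative laws by
  construction). Consequently its cross-validated metrics (~99% accuracy,
  ~0.14 mm error at default noise) are substantially better than what the
  same pipeline achieves on real animal data, and passing tests demonstrate
  correctness of the computation, not field performance.

## Problem sizes and determinism

The test suite and the acceptance script use the full 240-trial factorial
for noiseless recovery checks, and a reduced 3-subject factorial (60 trials)
across 3 noise scales × 20 seeds for the noise-degradation rank test. All
randomness flows through `numpy.random.Generator` instances derived from a
single `SeedSequence`; regeneration with the same configuration is
bit-identical.

## Known limitations

- Landmark-based `Rs` estimation assumes the onset step is resolved within
  one sample; heavily band-limited captures need the median `v0` mode and
  inherit its bias.
- The accuracy metric (correlation) cannot detect affine miscalibration;
  always read it together with the absolute error.
- Extended-model coefficients are reported in scaled space and are not
  individually interpretable when the exponential terms are near-linear.
- The ungrouped CV default mirrors the reference protocol; for honest
  subject-level generalisation use `group_by_subject=True`, which is
  systematically harder.
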