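# Methods

## Vocal-fold model

The larynx is a symmetric three-mass body-cover model: lower and upper
cover masses (m1, m2) and a body mass (mb) per fold, coupled by linear
springs with cubic hardening, a cover–cover shear spring (kc), viscous
dampers, and one-sided collision springs (h_i = 3·k_i) with added
contact damping. Aerodynamic drive is quasi-steady Bernoulli flow from
the subglottal pressure P_s with separation at the minimum glottal
area: the lower cover sees P_s·[1 − (a_min/a1)²] while the channel is
open and the full stagnation pressure when it is blocked; the upper
mass sits at the (atmospheric) supraglottal pressure. A constant
posterior glottal gap (A_PGO = 2 mm²) adds a DC leak to the flow
U_g = (a_min + A_PGO)·sqrt(2·P_s/ρ). The equations of motion are
integrated with fixed-step RK4 at 44.1 kHz (numba-compiled); the
integration is fully deterministic.

### Muscle activation rules

Geometry and stiffness follow activation rules in the canonical style
of low-dimensional fold models:

- strain eps = G(R·a_CT − a_TA) − H·a_LC with G = 0.2, R = 3, H = 0.2;
  fold length L = L0(1+eps), thickness T = T0/(1+0.8·eps), L0 = 16 mm,
  T0 = 3 mm;
- nodal point z_n = (1+a_TA)·T/3 splits the cover masses; cover and
  body depths D_c = (D_muc + D_lig/2)/(1+0.2 eps) and
  D_b = (a_TA·D_mus + D_lig/2)/(1+0.2 eps);
- per-tissue fiber stresses (mucosa, ligament, muscle) combine a linear
  ramp from eps = −0.5 with an exponential branch; the thyroarytenoid
  adds an active stress σ_max·a_TA·[1 − 1.07(eps − 0.4)²]⁺ with
  σ_max = 105 kPa. Depth-weighted stresses give the fiber (string)
  contribution π²σ·T_i·D/L of each spring and shear moduli
  (cover 500 Pa, body 4 kPa) the shear contribution 2μ·L·T_i/D;
- adduction: rest half-widths ξ02 = 0.25·L0(1 − 2·a_LC) and
  ξ01 = ξ02 + 0.1·T (slightly convergent pre-phonatory glottis);
- lumped masses are modal masses of the distributed layers
  (ρ = 1040 kg/m³ with a modal factor of 0.5).

The exact constant set behind the published configuration is not
printed anywhere accessible, so the free scale factors are calibrated
**once** to the stated male modal operating point — the four
iso-frequency activation cases (a_CT/a_TA = 0.300/0.050, 0.169/0.175,
0.202/0.400, 0.256/0.600 at a_LC = 0.5, P_s = 800 Pa) producing
~134 Hz at ~74–76 dB — via a single global stiffness scale
(`STIFFNESS_SCALE = 1.0526`, minimax over the four case frequencies)
and one flow-depth constant for the absolute SPL level (below). They
are never adjusted per experiment. With this configuration the four
cases produce 135.5 / 133.9 / 132.2 / 134.3 Hz: each within ±2 Hz of
its published value, with a mutual spread of 3.2 Hz. The published
mutual agreement (0.5 Hz) is not reached — the reconstruction's
iso-frequency contour has slightly different curvature — and this is a
known, accepted deviation.

### Acoustic measures

f_o is estimated by FFT autocorrelation of the glottal-area segment
(50–500 Hz search band), with parabolic peak interpolation refined by
the highest clean lag multiple; accuracy on known-period signals is
well under one cent. A segment is voiced when its steady peak-to-peak
area exceeds 10⁻⁷ m² and the normalized autocorrelation peak exceeds
0.5.

SPL uses the printed formula 20·log10(rms(Z_v·dU_g/dt)/2·10⁻⁵),
Z_v = 45000 kg·m⁻⁴, with two conventions fixed by the published levels
(71–76 dB):

1. the derivative is referenced to the 44.1-kHz sampling interval (a
   per-sample difference); an absolute per-second derivative would put
   every level ~93 dB higher without changing any controller behavior;
2. the flow signal entering the level computation is the synthesis-chain
   flow U_syn = K_FLOW·(d a_g/dt), where K_FLOW = 1.89 mm is an
   effective depth converting area rate to volume velocity, calibrated
   once so the modal baseline (case 0.169/0.175) sits at 74 dB. This
   convention reproduces the published cross-case SPL *ordering*
   (the low-a_TA case ~2 dB louder than baseline); the thick-fold
   cases remain ~3 dB louder than their published 71 dB — the
   reconstruction under-reproduces the amplitude drop at high
   thyroarytenoid activation. The physical Bernoulli U_g remains the
   waveform output and the synthesis source.

Audio synthesis differentiates U_g (radiation) and filters it through
a fixed all-pole /ɑ/ cascade (700/1220/2600 Hz); 16-bit WAV export.

## Forward map and inverse

The forward map tabulates steady-state (f_o, SPL) per activation node
from 0.5-s simulations (0.2-s onset discarded). The published grid
(step 0.02 in activations, 100 Pa in P_s, smoothed by linear
interpolation to 0.001/5 Pa) is supported; the default working map is
the P_s = 800 Pa slice over the operating region (step 0.05,
a_CT ≤ 0.6, a_TA ≤ 0.7), since all experiments hold P_s at 800 Pa.
Unvoiced nodes carry NaN f_o and a voicing mask; lookups are
(tri)linear with NaN propagation and clamping at the grid edge.

Both tables receive a voiced-aware 3-node box average at build time
("table conditioning"): the raw surfaces carry node-scale roughness —
waveform-regime ridges in SPL (~1 dB) and mode-locking wiggle in f_o
(~1 Hz) — that corrupts finite-difference directions. Conditioning
keeps off-grid fidelity within 0.5 Hz / 0.9 dB of direct simulation
while making the Jacobian usable; it can be disabled
(`condition_tables=False`), in which case each node reproduces its
direct simulation value exactly.

The inverse map perturbs each controlled dimension by ξ = 0.01,
assembles the sensitivity matrix, and returns the damped least-squares
inverse ξ·Sᵀ[SSᵀ + γξ²I]⁺. The solve runs in JND-normalized task space
(1 JND = 5 cents ≈ 0.39 Hz for f_o, 6 dB for SPL) with γ = 2: without
the normalization the weakly and noisily sensed SPL dimension demands
enormous activation excursions and one-step descent failed at almost
half of the tested states; with it, one corrective step reduces the
auditory error norm at ≈98–99% of random (state, error ≤ 10 Hz / 2 dB)
pairs, the residual failures sitting at oscillation-regime boundaries.
P_s is excluded from corrective commands (it is a respiratory input,
held at 800 Pa throughout).

## Control loop

The loop runs at 5-ms steps for a 3050-ms sustained vowel. The
feedforward program (per-step multiplicative weights on the motor
reference trajectory) is read out on the production timeline — premotor
preparation leads the acoustics — while corrective commands reach the
folds one actuation delay (50 ms) after being issued. The sensing leg
(acoustics → auditory cortex → motor cortex, 50 + 5 ms) is padded so
the full perturbation-to-production latency equals the configured
120 ms.

Errors are gated by the target region and referenced to its midpoint
once outside: deviations inside ±5 cents (f_o) or 68–80 dB (SPL) are
undetectable and elicit exactly no command. The detected error is
inverse-mapped, scaled by g_fb_aud, capped at ±0.5 activation units,
and realized by the motor integrator at a first-order rate of 0.15 per
step. The accumulated correction therefore settles at the proportional
fixed point: production shifts by −g/(1+g) of a sustained perturbation,
giving exactly half compensation at g = 1 (≈50.6 cents for +100 cents
in Hz-space algebra) and graded plateaus at lower gains. A persistent
integrator reading of the loop would instead null the error entirely
(full compensation), contradicting the feedforward/feedback-competition
bound the architecture is built around; the proportional realization is
the reading consistent with that bound.

Feedforward learning applies once per trial at trial end:
Δw = λ_ff·e_motor(x) with the error trajectory re-aligned to the
program steps that caused it and the weighted command projected back
into the physical activation range (anti-windup; commands saturate, so
weights must not wind up against a saturated bound). Somatosensory
machinery exists in the same form with g_fb_somat = 0 (no laryngeal
somatosensory map in this version).

Target tuning inverts the map along a_CT to seed the motor trajectory,
then iterates open-loop productions with trust-region-limited
(±0.08/step) Jacobian updates until the produced contour sits inside
the target region (or within tolerance of a point target). Learning
iterations run without online feedback: the online correction lags
sloped targets by the loop latency and its transient would be imprinted
into the weights; once converged, the engaged loop has nothing left to
correct.

## Paradigms

- **Reflexive**: +100 cents applied to the fed-back f_o from 500 ms
  after vocal onset, sustained to trial end; λ_ff forced to 0. The
  response trace is the produced f_o in cents, normalized to the 100 ms
  before onset. Only perturbed trials are simulated — the 25%-perturbed
  trial structure of behavioral sessions matters for humans, not for a
  deterministic model.
- **Adaptive**: 108 trials — 24 baseline, 30 ramp (+3.33 cents/trial),
  30 hold (+100 cents), 24 aftereffect — with the shift applied before
  vocal onset. Per-trial adaptation is the mean f_o over the 40–120 ms
  post-onset window (cents re the baseline-phase mean); the window
  precedes the 120-ms auditory latency and therefore isolates the
  feedforward command. With λ_ff = 0.1 and g = 0.5 the response tracks
  the ramp with a lag, plateaus near −50 cents in the hold phase
  (limited by the model's downward f_o authority at P_s = 800 Pa), and
  decays through the aftereffect.
- **Motor equivalence**: the reflexive paradigm run from each of the
  four iso-f_o cases. SPL errors are identically zero (the trajectory
  never leaves 68–80 dB); the within-run SPL excursion is 0.3–1.4 dB,
  slightly above the published <1 dB, reflecting the reconstructed SPL
  surface's gradient along the compensation path.
- **Prosody**: point f_o target contours (optionally +30-Hz-shifted and
  5-point moving-average smoothed) tracked with λ_ff = 0.5,
  g_fb_aud = 1; convergence to <5 cents typically takes 1–10
  iterations. The model's usable f_o range at 800 Pa is roughly
  125–176 Hz, so bundled demonstration contours stay within ±1.5
  semitones of the 134-Hz baseline.
- **Fit machinery**: RMSE, R² (against reference variance) and the
  absolute trapezoidal-AUC difference compare model and reference
  traces; grid fits select minimum RMSE with |ΔAUC| tiebreak.

## Synthetic reference traces

The behavioral-like fixtures stand in for group-mean human responses:
the model trace for known true parameters plus independent zero-mean
Gaussian trial noise (default σ = 5 cents) for each of 20 simulated
subjects, averaged, with a 1.96·σ/√n CI. Deterministic per seed. They
emulate the magnitude of trial-to-trial scatter only — no vocal drift,
fatigue, onset jitter, attention effects, or subject-level parameter
heterogeneity — so parameter-recovery results show that the fit
machinery distinguishes the model's own gain/learning-rate family under
realistic noise, not that it would identify human parameters.

## Problem sizes and runtime

Default runs use the 800-Pa operating-region slice (13×15 nodes,
~2 s to build), 1-s fold simulations at 44.1 kHz for steady-state
measures, 610-step utterances, and the full 108-trial adaptive
sequence; the complete test suite runs in ~2 minutes and the
acceptance script in a few seconds on one CPU. The full published grid
(51×51×21) builds in a few minutes via `laryngosim build-map --coarse`.

## Known limitations

- The muscle-rule constants are a reconstruction; the iso-frequency
  contour through the four published cases agrees to ±2 Hz but not to
  their 0.5-Hz mutual spread, and the SPL contrast across cases is
  under-reproduced (~3 dB high for the thick-fold cases).
- f_o sensitivity to a_CT is shallower than the original's (roughly
  20–30 Hz per unit activation near the modal point), which narrows the
  usable prosodic range and places the −50-cent compensation target
  near the a_CT = 0 boundary.
- No tissue–aero-acoustic coupling with a vocal-tract load, no
  asymmetric-fold variants, no dynamic adductory control, no fatigue.
- The somatosensory channel is structural only (gain 0); production
  noise is available as a seeded hook (σ = 0 by default).
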