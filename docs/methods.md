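# Methods

## Scope and model

`canatrial` simulates a canine atrial myocyte and a homogeneous 1D strand of
such myocytes to study how heart-failure (HF) electrical remodelling and
fibrotic loss of cell-to-cell coupling promote action-potential (AP) and
Ca2+-transient (CaT) alternans.

The cell is a Hodgkin–Huxley-type ionic model of the
Courtemanche–Ramirez–Nattel atrial family (21 state variables: V, 15 gates,
[Na+]i, [K+]i, [Ca2+]i and the network/junctional SR Ca2+ pools) with the
original Na+/Ca2+ exchanger replaced by the Weber formulation, whose
allosteric cytosolic-Ca2+ site makes I_NCX respond steeply to the Ca2+
transient.  `docs/provenance.md` maps every equation block to its published
source and lists the five constants this package calibrates to the canine
atrium (g_to, g_kr, ncx_v_max, j_up_max, ca_up_max).  The calibration was
performed once, by bisection on g_kr, so that the control model paced for
100 beats at 1 Hz yields a basal APD90 of 185.8 ms with CaT amplitude and SR
content at a canine operating point; it is frozen in the defaults of
`CellParameters`.

HF remodelling is the seven-parameter phenotype of the short-term
(ventricular-tachypacing) dog model with prolonged APD: G_Ca x0.70,
G_to x0.50, G_Ks x0.55, J_up(max) x0.70, K_up x0.22 (standing in for
increased phospholamban phosphorylation), J_rel(max) x0.40 and
[Csqn]_max x0.85.  Each factor is an independent, composable multiplicative
transform (`remodelling.py`), so knockout ("HF without X") and graded
variants are first-class.

## Numerics

All simulations advance with an explicit scheme at dt = 0.02 ms: forward
Euler for the membrane potential and all concentrations, and exponential
(closed-form) relaxation toward x_inf(V) for the Hodgkin–Huxley gates.  The
gate update is required for stability rather than taste: the Na+ activation
gate has tau_m ≈ 8 µs at the resting potential, so a pure forward-Euler gate
update is unstable at any practical dt (amplification |1 − dt/tau| > 1); the
exponential update integrates the locally linear gate equation exactly and
is unconditionally stable while leaving the overall scheme first-order in
the nonlinear coupling.  A paced beat at dt = 0.02 ms agrees with
dt = 0.002 ms within 1 ms of APD90 (tested).

A state variable leaving its physical range (gate outside [0,1],
concentration negative, V outside [-150, 90] mV) raises a
`NumericalInstabilityError` naming the variable, the dt and the simulation
time — instabilities surface, they are never clipped.

Removable singularities of the rate expressions (V = -47.13, -14.1, 3.3328,
19.9, -10, 7.9 mV) are evaluated by their analytic limits.

The 1D cable (`tissue1d.py`) solves dV/dt = -I_ion/C_m + D d2V/dx2 on 300
cells at dx = 0.167 mm (50.1 mm strand) with second-order central
differences, ghost-cell no-flux boundaries, and reaction and diffusion
advanced in the same explicit step.  The explicit stability bound
D dt/dx^2 < 0.5 is enforced at configuration time (0.12 at the strongest
coupling used).  Activation times (max dV/dt per cell per beat) are tracked
at full resolution inside the compiled kernel; V/Ca maps are stored
decimated (1 ms) for the final beats only, from which per-beat, per-cell
APD90 and peak-CaT matrices are measured.

## Protocols

* **Stimulus** — rectangular, 2 ms, at twice the diastolic threshold found
  once per parameter set by bisection (threshold-relative amplitude keeps
  control and HF comparable).  Depolarizing current is positive.
* **Fixed-rate trains** — n beats at one PCL from the frozen resting state;
  quasi-steady state is reached well within 100 beats at 1 Hz (APD90 of
  beats 100 and 101 differ by < 0.5 ms, tested).
* **Dynamic pacing** — a strictly descending PCL ladder, 50 beats per rung,
  each rung continuing from the previous rung's final state; the biomarkers
  of the two final consecutive beats form the even/odd branches of the
  rate-dependence curve.  The bifurcation scan uses 200 -> 140 ms at 1 ms
  resolution.
* **S1–S2 restitution** — 20 S1 beats at PCL 1000 ms (integrated once and
  checkpointed), one premature S2 per coupling interval; DI is measured from
  the 90%-repolarization time of the last S1 to the S2 onset, and pairs with
  failed capture or negative DI are excluded.  The maximum slope is taken
  from centered finite differences on the DI-sorted curve.
* **Cable pacing** — all cells initialized from the single-cell quasi-steady
  state at PCL 750 ms; 20 preparatory beats at 750 ms, then 50 beats at the
  test PCL, stimulating the first four cells.  CV is measured between the
  cells at 25% and 75% of cable length (central window, away from the
  stimulus and the sealed end) from max-dV/dt activation times.

## Biomarkers and alternans definitions

APD90 runs from the max-dV/dt time (not stimulus onset, so it is insensitive
to stimulus latency) to the linearly interpolated crossing of
V_rest + 0.1 x amplitude; V_rest and diastolic Ca2+ are sampled 1 ms before
the stimulus.  Beats with amplitude < 30 mV are capture failures (NaN
biomarkers, never exceptions).  CaT amplitude is peak minus diastolic
[Ca2+]i (reported in nM); the CaT decay time is the time from the peak to
recovery of 90% of the amplitude — a recovery time, mirroring the APD90
convention, rather than an exponential time constant (the level is a
parameter).  SR content is end-diastolic [Ca2+]_NSR / [Ca2+]_JSR.

A biomarker sequence alternates when its successive differences strictly
alternate in sign and their mean magnitude exceeds 1 ms (APD90) or 5 nM
(CaT amplitude) — thresholds far below observed alternans magnitudes
(tens of ms / hundreds of nM) and far above numerical jitter.  On a
rate-dependence curve, the eye-type window is the maximal contiguous PCL run
with separated branches; its long-PCL edge is the onset (bifurcation) PCL.
During deep alternans the long beat may not repolarize to 90% before the
next stimulus; such one-finite/one-NaN branch pairs (with both beats
captured) count as alternating.  Deep in the alternating regime the
period-1 and period-2 rhythms can coexist as attractors, so the measured
onset PCL depends on the pacing history; the package fixes the protocol
(descending 1 ms ladder, 50 beats per rung) and reports the onset under
that protocol.

The conduction pattern of a cable run is classified from the final ten
beats: `block_2to1` when conduction to the cell at 90% of cable length
alternates beat-to-beat; `discordant_alternans` when an APD node exists
(zero crossing of the beat-pair APD difference, sub-cell position by linear
interpolation) with above-threshold alternation of opposite sign on its two
sides; `normal` when neither; `other` for irregular conduction sequences.

## Sensitivity analysis

300 model variants multiply each of the seven remodelled parameters by
independent log-normal factors, sigma = 0.1 on the log scale — the spread
conventional in population-of-models electrophysiology, small enough to stay
in the locally log-linear regime and large enough to separate parameter
effects from solver noise.  Outputs (APD90, CaT amplitude, NSR content on
the final of 100 beats at 1 Hz) are log-transformed, column-standardized and
regressed by ordinary least squares on the standardized log factors — at
n = 300 for 7 well-conditioned predictors OLS is adequate and transparent;
partial-least-squares would only matter near collinearity, which the
sampling excludes by construction.  Coefficient magnitudes are therefore
comparable only within this convention.  R^2 per output is reported;
rank-deficient designs raise with the collinear columns named.

## Synthetic waveform generators

`synthetic.py` emulates the *geometry* of paced recordings — square-rise
APs with linear or exponential repolarization, exponential-decay Ca2+
transients, planted even/odd alternans fractions, optional Gaussian noise —
and returns closed-form ground truth with every trace.  It deliberately does
not emulate ionic dynamics: restitution, memory, SR loading and
conduction are absent.  Tests passing on these fixtures therefore validate
the *measurement* layers (biomarkers, alternans detection, node detection)
exactly, and say nothing about the ionic model itself, which is tested
separately against its own invariants and the printed study values.  The
waveform starts one sample after the nominal stimulus onset so the maximum
upstroke slope is well-defined inside the measurement window; the analytic
APD therefore carries a one-sample (0.1 ms) offset, included in the returned
ground truth.

## Problem sizes

The default test suite and the acceptance script use the study's native
single-cell protocols unreduced (100-beat trains, 1 ms bifurcation ladders,
full S1-S2 curves).  Cable runs use the full 300-cell strand; conduction
velocity is measured on 5-beat runs at PCL 750 ms and the discordant-
alternans analyses keep the final 12-16 beats of the standard 20 + 50-beat
protocol.  Property checks that only exercise analysis code (regression
recovery, node geometry, pattern classification) run on synthetic inputs.
Population checks in the test suite use reduced populations (tens of
variants, 50-60 beats); the CLI default remains the full 300 x 100.

## Known limitations

* The canine-specific current reformulations of the original canine atrial
  model (canine I_to/I_Kur kinetics, Ca2+-activated chloride current) are
  not reproduced; the package reconstructs the canine phenotype from the
  published family backbone by the five-constant calibration above.  The
  basal control phenotype matches the canine reference exactly and the HF
  model reproduces the qualitative alternans programme (eye-type window,
  HF-only bifurcation in the scanned range, in-phase V/Ca alternation,
  knockout directionality), but quantities dominated by the human-atrial
  backbone carry that imprint: the bifurcation onset sits a few ms below
  the canine reference, the control restitution curve is shallower, the HF
  increase in APD90 and SR content deviates from the canine deltas, and the
  relative ranking of K_up versus J_up(max)/G_Ca in the sensitivity
  regression is shifted toward K_up.
* The alternating rhythms are long-lived transients of this model rather
  than stable attractors: paced far beyond the protocol horizon (hundreds
  of beats) they relax to 1:1.  All alternans statements therefore refer to
  the declared 50-beat quasi-steady horizon; in the control model,
  decaying 2:2 transients outlive that horizon below a PCL of about 135 ms.
* In tissue, the weakly coupled HF strand blocks 2:1 over part of the PCL
  range where the reference study reports discordant alternans; discordant
  conduction with a stable node appears at slightly longer PCLs instead.
* CaMKII signalling is not modelled; lowered K_up is the stand-in for
  enhanced phospholamban phosphorylation.
* Tissue is homogeneous 1D; no fibroblast coupling, no 2D/3D re-entry.
* Forward-Euler/exponential-gate integration is first-order; all printed
  values are reported at dt = 0.02 ms, the study's operating point.
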