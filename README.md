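# canatrial

Simulation and analysis of heart-failure-induced **atrial alternans** in the
dog: a canine atrial myocyte ionic model with HF electrical remodelling, the
pacing protocols that expose period-doubling (alternans) bifurcations, and a
monodomain 1D tissue strand for spatially discordant alternans — for
cardiac-electrophysiology modellers studying how HF remodelling predisposes
the atria to fibrillation.

## The model

The myocyte is a Courtemanche–Ramirez–Nattel-family atrial model (21 state
variables) with the Na+/Ca2+ exchanger replaced by the Weber formulation,
whose allosteric Ca2+ regulation couples the exchanger current to the Ca2+
transient:

    dV/dt = -(I_Na + I_K1 + I_to + I_Kur + I_Kr + I_Ks + I_Ca,L
              + I_p,Ca + I_NaK + I_NCX + I_b,Na + I_b,Ca)/C_m + I_stim

with Hodgkin–Huxley gates dx/dt = (x_inf(V) - x)/tau_x(V) and a
two-compartment SR (uptake J_up = J_up,max / (1 + K_up/[Ca2+]i), release
J_rel through a flux-gated channel, calsequestrin buffering).  Repolarization
conductances and the exchanger maximum are calibrated to the canine atrium
(`docs/provenance.md`): the control model paced 100 beats at 1 Hz yields the
canine basal APD90 of 185.8 ms.

HF remodelling (short-term tachypacing phenotype, prolonged APD) multiplies
seven parameters: G_Ca x0.70, G_to x0.50, G_Ks x0.55, J_up(max) x0.70,
K_up x0.22 (increased phospholamban phosphorylation), J_rel(max) x0.40,
[Csqn]_max x0.85 — each independently toggleable for knockout and graded
scans.

Tissue is a 50.1 mm monodomain strand, dV/dt = -I_ion/C_m + D d2V/dx2, of
300 cells (dx = 0.167 mm, no-flux ends); reduced D (0.167 -> 0.084 -> 0.028
mm^2/ms) mimics fibrotic uncoupling.

## Worked example

Pace the control and HF cells to quasi-steady state and locate the HF
alternans window:

    $ canatrial cell --condition control --pcl 1000 --beats 100 --out ctl
    last-beat APD90 = 185.8 ms

    $ canatrial cell --condition hf --pcl 1000 --beats 100 --out hf
    last-beat APD90 = 226.5 ms

    $ canatrial scan --condition hf --pcl-max 200 --pcl-min 140 \
          --pcl-step 1 --out hfscan
    alternans window: 146 -> 140 ms

The control cell repolarizes in 185.8 ms; HF remodelling prolongs the AP by
~41 ms (increased SR Ca2+ load drives a larger Ca2+ transient and more
inward exchanger current, compounded by the loss of I_to and I_Ks).  Under
dynamic pacing the HF cell bifurcates to long–short APD/CaT alternans below
a PCL of 146 ms and recovers 1:1 rhythm below 140 ms (an "eye-type" window);
the same scan on the control cell finds no window there.  The same machinery
is available from Python:

    from canatrial.cell_model import CellParameters
    from canatrial.remodelling import hf_default_config, apply_remodelling
    from canatrial.pacing import pace_fixed_pcl

    hf = apply_remodelling(CellParameters(), hf_default_config())
    trace, _ = pace_fixed_pcl(hf, pcl=1000.0, n_beats=100)
    print(trace.biomarkers().iloc[-1].apd90_ms)

Cable runs and D–PCL pattern grids (`canatrial cable`, `canatrial
dpcl-scan`) classify conduction as normal, discordant alternans or 2:1
block, and track APD-node positions along the strand.

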