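# Equation provenance

The ionic model is assembled from published formulations; this file maps each
block of `cell_model.py` to its source and lists every constant that this
package calibrates itself.

## Membrane and Ca2+-handling formulation

All gating kinetics, membrane currents (except I_NCX) and the two-compartment
SR Ca2+-handling scheme follow the atrial myocyte model of Courtemanche,
Ramirez & Nattel (Am J Physiol 275:H301-H321, 1998) — the published backbone
of the canine atrial model family:

| Block | Source |
| --- | --- |
| I_Na (m, h, j; Luo-Rudy kinetics) | CRN 1998, Table/App. eqns |
| I_K1, I_to (oa, oi), I_Kur (ua, ui, V-dependent g_Kur) | CRN 1998 |
| I_Kr (xr), I_Ks (xs) | CRN 1998 |
| I_Ca,L (d, f, fCa) | CRN 1998 |
| I_NaK (Luo-Rudy sigma/f_NaK form), I_p,Ca, I_b,Na, I_b,Ca | CRN 1998 |
| SR uptake/leak/transfer/release (J_up, J_up,leak, J_tr, J_rel; u, v, w gates driven by the flux signal Fn) | CRN 1998 |
| Rapid buffering (troponin, calmodulin, calsequestrin) | CRN 1998 |
| Cell geometry, volumes, milieu, F, RT/F | CRN 1998 |

## Na+/Ca2+ exchanger

I_NCX uses the formulation of Weber et al. (J Gen Physiol 117:119-131, 2001),
fitted to canine NCX1: driving term with energy-partition eta = 0.35,
saturation factor k_sat = 0.27, Michaelis constants K_m,Cai = 3.59 uM,
K_m,Cao = 1.3 mM, K_m,Nai = 12.29 mM, K_m,Nao = 87.5 mM, and allosteric
activation by intracellular Ca2+, Allo = 1 / (1 + (K_d,act/[Ca2+]i)^2) with
K_d,act = 0.256 uM.

## Constants calibrated by this package

The backbone above is a human atrial parameterization; the following
constants were set once so that the control model reproduces the canine
atrial phenotype (basal APD90 of 185.8 ms after 100 beats at 1 Hz, CaT
amplitude and SR content in the canine experimental range) and are frozen as
the package defaults:

| Parameter | Backbone value | This package | Role |
| --- | --- | --- | --- |
| g_to | 0.1652 nS/pF | 0.36344 | larger canine transient outward current |
| g_kr | 0.029411765 nS/pF | 0.070254059 | canine repolarization reserve; tuned by bisection to basal APD90 = 185.8 ms |
| ncx_v_max | — (new current) | 8.0 | exchanger maximum, set with the backbone swap so Ca2+ dynamics stay in the canine range |
| j_up_max | 0.005 mM/ms | 0.004 | SERCA maximum at the canine SR-load operating point |
| ca_up_max | 15 mM | 5 | NSR leak saturation; caps SR loading |

Everything else is bit-identical to the cited sources.  The quiescent
initial condition in `default_state` was frozen from a 60 s stimulus-free
equilibration of the calibrated control model (forward integration at
dt = 0.02 ms).
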