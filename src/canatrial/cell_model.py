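"""Canine atrial myocyte ionic model with an allosterically regulated Na+/Ca2+ exchanger.

The membrane model is the Courtemanche–Ramirez–Nattel atrial formulation
(Hodgkin–Huxley gating for I_Na, I_to, I_Kur, I_Kr, I_Ks, I_Ca,L; two-compartment
sarcoplasmic reticulum with a phenomenological Ca2+-induced-Ca2+-release gate set;
rapid-buffering approximation for troponin, calmodulin and calsequestrin), with the
original exchanger replaced by the Weber formulation whose allosteric intracellular
Ca2+ site regulates I_NCX.  Repolarization conductances and the exchanger maximum
are calibrated for the canine atrium; see ``docs/provenance.md`` for the
equation-by-equation source map and the two calibrated constants.

Units: mV, ms, mM, pA/pF throughout; capacitance in pF, volumes in um^3.
All state is carried in a flat float64 vector (see the ``S_*`` index constants)
so the right-hand side can be compiled with numba and shared verbatim between
the single-cell and cable integrators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "CellParameters",
    "CellState",
    "Stimulus",
    "NumericalInstabilityError",
    "compute_derivatives",
    "ncx_current",
    "step_euler",
    "default_state",
    "equilibrate",
    "find_stimulus_threshold",
    "default_stimulus",
    "STATE_NAMES",
    "CURRENT_NAMES",
]

# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "v", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v_rel", "w", "na_i", "k_i", "ca_i",
    "ca_up", "ca_rel",
)
# indices
(S_V, S_M, S_H, S_J, S_OA, S_OI, S_UA, S_UI, S_XR, S_XS,
 S_D, S_F, S_FCA, S_U, S_VREL, S_W, S_NAI, S_KI, S_CAI,
 S_CAUP, S_CAREL) = range(21)
N_STATE = 21
GATE_SLICE = slice(S_M, S_W + 1)  # the 15 dimensionless gates

CURRENT_NAMES = (
    "i_na", "i_k1", "i_to", "i_kur", "i_kr", "i_ks", "i_ca_l", "i_p_ca",
    "i_na_k", "i_ncx", "i_b_na", "i_b_ca", "j_rel", "j_tr", "j_up",
    "j_up_leak", "fn",
)
(C_INA, C_IK1, C_ITO, C_IKUR, C_IKR, C_IKS, C_ICAL, C_IPCA,
 C_INAK, C_INCX, C_IBNA, C_IBCA, C_JREL, C_JTR, C_JUP,
 C_JUPLEAK, C_FN) = range(17)
N_CURRENT = 17

# parameter vector layout
PARAM_NAMES = (
    "g_na", "g_ca", "g_to", "g_kur_scale", "g_kr", "g_ks", "g_k1",
    "i_nak_max", "km_na_i", "km_k_o", "i_p_ca_max", "g_b_ca", "g_b_na",
    "ncx_v_max", "ncx_km_na_i", "ncx_km_na_o", "ncx_km_ca_i", "ncx_km_ca_o",
    "ncx_k_sat", "ncx_eta", "ncx_kd_act",
    "j_up_max", "k_up", "j_rel_max", "ca_up_max", "tau_tr",
    "csqn_max", "km_csqn", "trpn_max", "km_trpn", "cmdn_max", "km_cmdn",
    "c_m", "v_i", "v_up", "v_rel",
    "na_o", "k_o", "ca_o", "rt_over_f", "faraday",
)
(P_GNA, P_GCA, P_GTO, P_GKURS, P_GKR, P_GKS, P_GK1,
 P_INAKMAX, P_KMNAI, P_KMKO, P_IPCAMAX, P_GBCA, P_GBNA,
 P_NCXVMAX, P_NCXKMNAI, P_NCXKMNAO, P_NCXKMCAI, P_NCXKMCAO,
 P_NCXKSAT, P_NCXETA, P_NCXKDACT,
 P_JUPMAX, P_KUP, P_JRELMAX, P_CAUPMAX, P_TAUTR,
 P_CSQNMAX, P_KMCSQN, P_TRPNMAX, P_KMTRPN, P_CMDNMAX, P_KMCMDN,
 P_CM, P_VI, P_VUP, P_VREL,
 P_NAO, P_KO, P_CAO, P_RTOF, P_FARADAY) = range(41)
N_PARAM = 41

_KQ10 = 3.0  # temperature adjustment on oa/oi/ua/ui kinetics


class NumericalInstabilityError(RuntimeError):
    """Raised when the explicit integrator drives a state variable out of range.

    Attributes carry the offending variable name, the time step and the
    simulation time so instabilities surface instead of being clipped away.
    """

    def __init__(self, variable: str, dt: float, t_ms: float):
        self.variable = variable
        self.dt = dt
        self.t_ms = t_ms
        super().__init__(
            f"state variable '{variable}' left its valid range at "
            f"t = {t_ms:.3f} ms (dt = {dt} ms)"
        )


@dataclass
class CellParameters:
    """Maximal conductances, pump/exchanger maxima and Ca2+-handling constants.

    Conductances in nS/pF, fluxes in mM/ms (``j_up_max``) or 1/ms
    (``j_rel_max``), concentrations in mM, capacitance in pF, volumes in um^3.
    ``g_kr`` and ``g_ks`` carry a canine repolarization calibration; ``ncx_v_max``
    is calibrated so the control model reproduces the basal canine APD90
    (see docs/provenance.md).
    """

    g_na: float = 7.8
    g_ca: float = 0.12375
    g_to: float = 0.36344
    g_kur_scale: float = 1.0
    g_kr: float = 0.075567074
    g_ks: float = 0.12941176
    g_k1: float = 0.09
    i_nak_max: float = 0.59933874
    km_na_i: float = 10.0
    km_k_o: float = 1.5
    i_p_ca_max: float = 0.275
    g_b_ca: float = 0.001131
    g_b_na: float = 0.0006744375
    # Weber NCX
    ncx_v_max: float = 8.0
    ncx_km_na_i: float = 12.29
    ncx_km_na_o: float = 87.5
    ncx_km_ca_i: float = 0.00359
    ncx_km_ca_o: float = 1.3
    ncx_k_sat: float = 0.27
    ncx_eta: float = 0.35
    ncx_kd_act: float = 0.000256
    # SR Ca handling
    j_up_max: float = 0.004
    k_up: float = 0.00092
    j_rel_max: float = 30.0
    ca_up_max: float = 5.0
    tau_tr: float = 180.0
    csqn_max: float = 10.0
    km_csqn: float = 0.8
    trpn_max: float = 0.07
    km_trpn: float = 0.0005
    cmdn_max: float = 0.05
    km_cmdn: float = 0.00238
    # geometry / milieu
    c_m: float = 100.0
    v_i: float = 13668.0
    v_up: float = 1109.52
    v_rel: float = 96.48
    na_o: float = 140.0
    k_o: float = 5.4
    ca_o: float = 1.8
    rt_over_f: float = 26.712832
    faraday: float = 96.4867

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "g_na", "g_ca", "g_to", "g_kur_scale", "g_kr", "g_ks", "g_k1",
            "i_nak_max", "km_na_i", "km_k_o", "i_p_ca_max",
            "ncx_v_max", "ncx_km_na_i", "ncx_km_na_o", "ncx_km_ca_i",
            "ncx_km_ca_o", "ncx_kd_act", "j_up_max", "k_up", "j_rel_max",
            "ca_up_max", "tau_tr", "km_csqn", "km_trpn", "km_cmdn",
            "c_m", "v_i", "v_up", "v_rel", "na_o", "k_o", "ca_o",
            "rt_over_f", "faraday",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if self.csqn_max < 0 or self.trpn_max < 0 or self.cmdn_max < 0:
            raise ValueError("buffer totals must be non-negative")
        if not 0.0 < self.ncx_eta < 1.0:
            raise ValueError("ncx_eta must lie in (0, 1)")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CellParameters":
        return cls(**{n: float(arr[i]) for i, n in enumerate(PARAM_NAMES)})

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "CellParameters":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "CellParameters":
        return replace(self, **kw)


@dataclass
class CellState:
    """Membrane potential, gating variables, ion concentrations and SR load."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.y.shape != (N_STATE,):
            raise ValueError(f"state vector must have shape ({N_STATE},)")

    # convenience accessors used throughout the analysis layers
    @property
    def v(self) -> float:
        return float(self.y[S_V])

    @property
    def ca_i(self) -> float:
        return float(self.y[S_CAI])

    @property
    def na_i(self) -> float:
        return float(self.y[S_NAI])

    @property
    def k_i(self) -> float:
        return float(self.y[S_KI])

    @property
    def ca_up(self) -> float:
        return float(self.y[S_CAUP])

    @property
    def ca_rel(self) -> float:
        return float(self.y[S_CAREL])

    @property
    def gates(self) -> np.ndarray:
        return self.y[GATE_SLICE].copy()

    def buffer_occupancies(self, params: "CellParameters") -> dict:
        """Fractional Ca2+ occupancy of the rapid buffers at the current state."""
        cai, carel = self.ca_i, self.ca_rel
        return {
            "troponin": cai / (cai + params.km_trpn),
            "calmodulin": cai / (cai + params.km_cmdn),
            "calsequestrin": carel / (carel + params.km_csqn),
        }

    def copy(self) -> "CellState":
        return CellState(self.y.copy())

    def as_dict(self) -> dict:
        return {n: float(self.y[i]) for i, n in enumerate(STATE_NAMES)}


@dataclass(frozen=True)
class Stimulus:
    """Rectangular stimulus train; amplitude is depolarizing-positive in pA/pF."""

    amplitude: float
    duration: float = 2.0
    onsets: tuple = ()

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("stimulus duration must be positive")
        onsets = tuple(float(t) for t in self.onsets)
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")
        object.__setattr__(self, "onsets", onsets)


# ---------------------------------------------------------------------------
# compiled kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ncx(v, na_i, ca_i, p):
    """Weber Na/Ca exchanger current (pA/pF), inward-positive when extruding Ca."""
    rtof = p[P_RTOF]
    na_o = p[P_NAO]
    ca_o = p[P_CAO]
    eta = p[P_NCXETA]
    ef = math.exp(eta * v / rtof)
    efm = math.exp((eta - 1.0) * v / rtof)
    num = ef * na_i ** 3 * ca_o - efm * na_o ** 3 * ca_i
    km_cai = p[P_NCXKMCAI]
    km_cao = p[P_NCXKMCAO]
    km_nai = p[P_NCXKMNAI]
    km_nao = p[P_NCXKMNAO]
    denom = (
        km_cai * na_o ** 3 * (1.0 + (na_i / km_nai) ** 3)
        + km_nao ** 3 * ca_i * (1.0 + ca_i / km_cai)
        + km_cao * na_i ** 3
        + na_i ** 3 * ca_o
        + na_o ** 3 * ca_i
    )
    allo = 1.0 / (1.0 + (p[P_NCXKDACT] / ca_i) ** 2)
    return p[P_NCXVMAX] * allo * num / (denom * (1.0 + p[P_NCXKSAT] * efm))


@njit(cache=True)
def _currents(y, p, cur):
    """Fill ``cur`` with all membrane currents (pA/pF) and SR fluxes (mM/ms)."""
    v = y[S_V]
    na_i = y[S_NAI]
    k_i = y[S_KI]
    ca_i = y[S_CAI]
    rtof = p[P_RTOF]

    e_na = rtof * math.log(p[P_NAO] / na_i)
    e_k = rtof * math.log(p[P_KO] / k_i)
    e_ca = 0.5 * rtof * math.log(p[P_CAO] / ca_i)

    cur[C_INA] = p[P_GNA] * y[S_M] ** 3 * y[S_H] * y[S_J] * (v - e_na)
    cur[C_IK1] = p[P_GK1] * (v - e_k) / (1.0 + math.exp(0.07 * (v + 80.0)))
    cur[C_ITO] = p[P_GTO] * y[S_OA] ** 3 * y[S_OI] * (v - e_k)
    g_kur = p[P_GKURS] * (0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0)))
    cur[C_IKUR] = g_kur * y[S_UA] ** 3 * y[S_UI] * (v - e_k)
    cur[C_IKR] = (
        p[P_GKR] * y[S_XR] * (v - e_k) / (1.0 + math.exp((v + 15.0) / 22.4))
    )
    cur[C_IKS] = p[P_GKS] * y[S_XS] ** 2 * (v - e_k)
    cur[C_ICAL] = p[P_GCA] * y[S_D] * y[S_F] * y[S_FCA] * (v - 65.0)
    cur[C_IPCA] = p[P_IPCAMAX] * ca_i / (0.0005 + ca_i)

    sigma = (math.exp(p[P_NAO] / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (
        1.0
        + 0.1245 * math.exp(-0.1 * v / rtof)
        + 0.0365 * sigma * math.exp(-v / rtof)
    )
    cur[C_INAK] = (
        p[P_INAKMAX]
        * f_nak
        / (1.0 + (p[P_KMNAI] / na_i) ** 1.5)
        * p[P_KO]
        / (p[P_KO] + p[P_KMKO])
    )
    cur[C_INCX] = _ncx(v, na_i, ca_i, p)
    cur[C_IBNA] = p[P_GBNA] * (v - e_na)
    cur[C_IBCA] = p[P_GBCA] * (v - e_ca)

    cur[C_JREL] = (
        p[P_JRELMAX] * y[S_U] ** 2 * y[S_VREL] * y[S_W] * (y[S_CAREL] - ca_i)
    )
    cur[C_JTR] = (y[S_CAUP] - y[S_CAREL]) / p[P_TAUTR]
    cur[C_JUP] = p[P_JUPMAX] / (1.0 + p[P_KUP] / ca_i)
    cur[C_JUPLEAK] = p[P_JUPMAX] * y[S_CAUP] / p[P_CAUPMAX]

    cur[C_FN] = 1e-12 * p[P_VREL] * cur[C_JREL] - (5e-13 / p[P_FARADAY]) * (
        0.5 * cur[C_ICAL] - 0.2 * cur[C_INCX]
    ) * p[P_CM]


@njit(cache=True)
def _gate_inf_tau(v, ca_i, fn, inf, tau):
    """Steady states and time constants of the 15 gates (order of STATE_NAMES)."""
    # I_Na activation / inactivation (Luo-Rudy kinetics)
    dvm = v + 47.13
    if abs(dvm) < 1e-10:
        a_m = 3.2
    else:
        a_m = 0.32 * dvm / (1.0 - math.exp(-0.1 * dvm))
    b_m = 0.08 * math.exp(-v / 11.0)
    inf[0] = a_m / (a_m + b_m)
    tau[0] = 1.0 / (a_m + b_m)

    if v >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        a_j = 0.0
        b_j = (
            0.3
            * math.exp(-2.535e-7 * v)
            / (1.0 + math.exp(-0.1 * (v + 32.0)))
        )
    else:
        a_h = 0.135 * math.exp(-(v + 80.0) / 6.8)
        b_h = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        a_j = (
            (-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        b_j = (
            0.1212
            * math.exp(-0.01052 * v)
            / (1.0 + math.exp(-0.1378 * (v + 40.14)))
        )
    inf[1] = a_h / (a_h + b_h)
    tau[1] = 1.0 / (a_h + b_h)
    inf[2] = a_j / (a_j + b_j)
    tau[2] = 1.0 / (a_j + b_j)

    # transient outward
    a_oa = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    tau[3] = 1.0 / ((a_oa + b_oa) * _KQ10)
    inf[3] = 1.0 / (1.0 + math.exp(-(v + 20.47) / 17.54))
    a_oi = 1.0 / (18.53 + math.exp((v + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + math.exp(-(v + 1.26) / 7.44))
    tau[4] = 1.0 / ((a_oi + b_oi) * _KQ10)
    inf[4] = 1.0 / (1.0 + math.exp((v + 43.1) / 5.3))

    # ultrarapid delayed rectifier
    a_ua = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    tau[5] = 1.0 / ((a_ua + b_ua) * _KQ10)
    inf[5] = 1.0 / (1.0 + math.exp(-(v + 30.3) / 9.6))
    a_ui = 1.0 / (21.0 + math.exp(-(v - 185.0) / 28.0))
    b_ui = math.exp((v - 158.0) / 16.0)
    tau[6] = 1.0 / ((a_ui + b_ui) * _KQ10)
    inf[6] = 1.0 / (1.0 + math.exp((v - 99.45) / 27.48))

    # rapid delayed rectifier
    dvr = v + 14.1
    if abs(dvr) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * dvr / (1.0 - math.exp(-dvr / 5.0))
    dvr2 = v - 3.3328
    if abs(dvr2) < 1e-10:
        b_xr = 3.7862e-4
    else:
        b_xr = 7.3898e-5 * dvr2 / (math.exp(dvr2 / 5.1237) - 1.0)
    tau[7] = 1.0 / (a_xr + b_xr)
    inf[7] = 1.0 / (1.0 + math.exp(-dvr / 6.5))

    # slow delayed rectifier
    dvs = v - 19.9
    if abs(dvs) < 1e-10:
        a_xs = 0.00068
        b_xs = 0.000315
    else:
        a_xs = 4e-5 * dvs / (1.0 - math.exp(-dvs / 17.0))
        b_xs = 3.5e-5 * dvs / (math.exp(dvs / 9.0) - 1.0)
    tau[8] = 0.5 / (a_xs + b_xs)
    inf[8] = 1.0 / math.sqrt(1.0 + math.exp(-dvs / 12.7))

    # L-type Ca
    dvd = v + 10.0
    if abs(dvd) < 1e-10:
        tau[9] = 1.0 / (0.035 * 2.0 * 6.24)  # 0/0 limit
    else:
        e10 = math.exp(-dvd / 6.24)
        tau[9] = (1.0 - e10) / (0.035 * dvd * (1.0 + e10))
    inf[9] = 1.0 / (1.0 + math.exp(-dvd / 8.0))
    inf[10] = 1.0 / (1.0 + math.exp((v + 28.0) / 6.9))
    tau[10] = 9.0 / (
        0.0197 * math.exp(-(0.0337 ** 2) * dvd ** 2) + 0.02
    )
    inf[11] = 1.0 / (1.0 + ca_i / 0.00035)
    tau[11] = 2.0

    # SR release gates (driven by the Ca-flux signal fn)
    inf[12] = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    tau[12] = 8.0
    inf[13] = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau[13] = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    inf[14] = 1.0 - 1.0 / (1.0 + math.exp(-(v - 40.0) / 17.0))
    dvw = v - 7.9
    if abs(dvw) < 1e-10:
        tau[14] = 6.0 / 6.5
    else:
        e5 = math.exp(-dvw / 5.0)
        tau[14] = 6.0 * (1.0 - e5) / ((1.0 + 0.3 * e5) * dvw)


@njit(cache=True)
def _rhs(y, p, i_stim, dy, cur, inf, tau):
    """Time derivative of the full state; fills dy (and cur/inf/tau scratch)."""
    _currents(y, p, cur)
    _gate_inf_tau(y[S_V], y[S_CAI], cur[C_FN], inf, tau)

    i_ion = (
        cur[C_INA] + cur[C_IK1] + cur[C_ITO] + cur[C_IKUR] + cur[C_IKR]
        + cur[C_IKS] + cur[C_ICAL] + cur[C_IPCA] + cur[C_INAK] + cur[C_INCX]
        + cur[C_IBNA] + cur[C_IBCA]
    )
    dy[S_V] = -i_ion + i_stim

    for g in range(15):
        dy[S_M + g] = (inf[g] - y[S_M + g]) / tau[g]

    cm = p[P_CM]
    f = p[P_FARADAY]
    v_i = p[P_VI]
    dy[S_NAI] = (
        (-3.0 * cur[C_INAK] - 3.0 * cur[C_INCX] - cur[C_IBNA] - cur[C_INA])
        * cm
        / (f * v_i)
    )
    dy[S_KI] = (
        (
            2.0 * cur[C_INAK]
            - cur[C_IK1]
            - cur[C_ITO]
            - cur[C_IKUR]
            - cur[C_IKR]
            - cur[C_IKS]
        )
        * cm
        / (f * v_i)
    )

    ca_i = y[S_CAI]
    b1 = (
        (2.0 * cur[C_INCX] - cur[C_IPCA] - cur[C_ICAL] - cur[C_IBCA])
        * cm
        / (2.0 * f * v_i)
        + (
            p[P_VUP] * (cur[C_JUPLEAK] - cur[C_JUP])
            + cur[C_JREL] * p[P_VREL]
        )
        / v_i
    )
    b2 = (
        1.0
        + p[P_TRPNMAX] * p[P_KMTRPN] / (ca_i + p[P_KMTRPN]) ** 2
        + p[P_CMDNMAX] * p[P_KMCMDN] / (ca_i + p[P_KMCMDN]) ** 2
    )
    dy[S_CAI] = b1 / b2
    dy[S_CAUP] = (
        cur[C_JUP] - cur[C_JUPLEAK] - cur[C_JTR] * p[P_VREL] / p[P_VUP]
    )
    dy[S_CAREL] = (cur[C_JTR] - cur[C_JREL]) / (
        1.0
        + p[P_CSQNMAX] * p[P_KMCSQN] / (y[S_CAREL] + p[P_KMCSQN]) ** 2
    )


@njit(cache=True)
def _check_state(y):
    """Return the index of the first out-of-range state variable, or -1."""
    v = y[S_V]
    if not (-150.0 <= v <= 90.0):
        return S_V
    for g in range(S_M, S_W + 1):
        x = y[g]
        if not (-1e-9 <= x <= 1.0 + 1e-9):
            return g
    for idx in (S_NAI, S_KI, S_CAI, S_CAUP, S_CAREL):
        c = y[idx]
        if not (c >= 0.0 and c < 1e4):
            return idx
    return -1


@njit(cache=True)
def _step_hybrid(y, p, dt, i_stim, dy, cur, inf, tau):
    """One time step: explicit Euler on V and concentrations, exponential
    relaxation (unconditionally stable) on the Hodgkin-Huxley gates, whose
    fastest time constant (~8 us for the Na+ activation gate at rest) is far
    below any practical explicit step."""
    _rhs(y, p, i_stim, dy, cur, inf, tau)
    y[S_V] += dt * dy[S_V]
    for g in range(15):
        i = S_M + g
        y[i] = inf[g] + (y[i] - inf[g]) * math.exp(-dt / tau[g])
    for i in range(S_NAI, N_STATE):
        y[i] += dt * dy[i]


@njit(cache=True)
def _integrate(y, p, dt, n_steps, t0, stim_start_steps, stim_dur_steps,
               stim_amp, rec_every, rec):
    """Explicit integration of one cell (Euler + exponential gate update).

    ``rec`` has shape (n_rec, N_STATE) and receives the state every
    ``rec_every`` steps (pass rec_every <= 0 to disable recording).
    Returns (status_index, step): status_index is -1 on success, otherwise
    the index of the offending state variable.
    """
    dy = np.empty(N_STATE)
    cur = np.empty(N_CURRENT)
    inf = np.empty(15)
    tau = np.empty(15)
    n_stim = stim_start_steps.shape[0]
    k = 0
    n_rec = rec.shape[0]
    r = 0
    for step in range(n_steps):
        if rec_every > 0 and step % rec_every == 0 and r < n_rec:
            for i in range(N_STATE):
                rec[r, i] = y[i]
            r += 1
        i_stim = 0.0
        while k < n_stim and step >= stim_start_steps[k] + stim_dur_steps:
            k += 1
        if k < n_stim and stim_start_steps[k] <= step:
            i_stim = stim_amp
        _step_hybrid(y, p, dt, i_stim, dy, cur, inf, tau)
        bad = _check_state(y)
        if bad >= 0:
            return bad, step
    return -1, n_steps


@njit(cache=True)
def _currents_batch(states, p):
    n = states.shape[0]
    out = np.empty((n, N_CURRENT))
    cur = np.empty(N_CURRENT)
    for i in range(n):
        _currents(states[i], p, cur)
        for c in range(N_CURRENT):
            out[i, c] = cur[c]
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def compute_derivatives(state: CellState, params: CellParameters,
                        i_stim: float = 0.0) -> np.ndarray:
    """Time derivative of every state variable at the given state (per ms).

    Raises :class:`NumericalInstabilityError` if any derivative is non-finite,
    naming the offending variable.
    """
    dy = np.empty(N_STATE)
    cur = np.empty(N_CURRENT)
    inf = np.empty(15)
    tau = np.empty(15)
    _rhs(state.y, params.to_array(), i_stim, dy, cur, inf, tau)
    if not np.all(np.isfinite(dy)):
        bad = STATE_NAMES[int(np.flatnonzero(~np.isfinite(dy))[0])]
        raise NumericalInstabilityError(bad, float("nan"), float("nan"))
    return dy


def currents(state: CellState, params: CellParameters) -> dict:
    """All membrane currents (pA/pF) and SR fluxes (mM/ms) at the state."""
    cur = np.empty(N_CURRENT)
    _currents(state.y, params.to_array(), cur)
    return {n: float(cur[i]) for i, n in enumerate(CURRENT_NAMES)}


def gate_steady_states(v: float, ca_i: float = 1e-4, fn: float = 0.0):
    """(x_inf, tau_x) arrays for the 15 gates at membrane potential ``v``."""
    inf = np.empty(15)
    tau = np.empty(15)
    _gate_inf_tau(float(v), float(ca_i), float(fn), inf, tau)
    return inf, tau


def ncx_current(v: float, na_i: float, ca_i: float,
                params: CellParameters) -> float:
    """Weber Na/Ca exchanger current (pA/pF) with allosteric Ca_i regulation.

    Positive (inward, depolarizing) in forward mode, i.e. while extruding Ca2+.
    """
    if na_i <= 0 or ca_i <= 0:
        raise ValueError("concentrations must be strictly positive")
    out = _ncx(float(v), float(na_i), float(ca_i), params.to_array())
    if not math.isfinite(out):
        raise NumericalInstabilityError("i_ncx", float("nan"), float("nan"))
    return float(out)


def step_euler(state: CellState, params: CellParameters, dt: float = 0.02,
               i_stim: float = 0.0) -> CellState:
    """One explicit forward-Euler step: state + dt * derivative.

    A gate or concentration leaving its valid range raises
    :class:`NumericalInstabilityError` (never silently clipped).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    dy = compute_derivatives(state, params, i_stim)
    new = CellState(state.y + dt * dy)
    bad = _check_state(new.y)
    if bad >= 0:
        raise NumericalInstabilityError(STATE_NAMES[int(bad)], dt, 0.0)
    return new


# Resting state of the calibrated control model, frozen from a 60 s
# stimulus-free forward-Euler equilibration at dt = 0.02 ms.
_DEFAULT_Y = np.array([
    -82.1842007380, 2.4651687193e-3, 9.7184575050e-1, 9.8224185991e-1,
    2.8790868497e-2, 9.9937327668e-1, 4.4757108999e-3, 9.9865464592e-1,
    2.8246783865e-5, 1.7966852041e-2, 1.2058620011e-4, 9.9961149276e-1,
    6.8323479882e-1, 0.0, 1.0, 9.9924444786e-1, 1.1176778688e1,
    1.3913376021e2, 1.6226892282e-4, 7.4989736091e-1, 7.5000073900e-1,
])


def default_state(params: CellParameters | None = None) -> CellState:
    """Quiescent initial condition of the control model (deterministic)."""
    return CellState(_DEFAULT_Y.copy())


def integrate(state: CellState, params: CellParameters, duration: float,
              dt: float = 0.02, stimulus: Stimulus | None = None,
              record_stride: float = 0.0, t0: float = 0.0):
    """Integrate for ``duration`` ms; returns (final CellState, times, states).

    ``record_stride`` (ms) <= 0 disables recording (times/states are empty).
    Stimulus onsets are interpreted on the same clock as ``t0``.
    """
    n_steps = int(round(duration / dt))
    if stimulus is None:
        starts = np.empty(0, dtype=np.int64)
        dur_steps = 0
        amp = 0.0
    else:
        starts = np.array(
            [int(round((t - t0) / dt)) for t in stimulus.onsets], dtype=np.int64
        )
        starts = starts[(starts >= 0) & (starts < n_steps)]
        dur_steps = max(1, int(round(stimulus.duration / dt)))
        amp = stimulus.amplitude
    if record_stride > 0:
        rec_every = max(1, int(round(record_stride / dt)))
        n_rec = (n_steps + rec_every - 1) // rec_every
    else:
        rec_every = 0
        n_rec = 0
    rec = np.empty((n_rec, N_STATE))
    y = state.y.copy()
    bad, step = _integrate(y, params.to_array(), dt, n_steps, t0,
                           starts, dur_steps, amp, rec_every, rec)
    if bad >= 0:
        raise NumericalInstabilityError(STATE_NAMES[int(bad)], dt,
                                        t0 + step * dt)
    if rec_every > 0:
        times = t0 + dt * rec_every * np.arange(rec.shape[0])
    else:
        times = np.empty(0)
    return CellState(y), times, rec


def equilibrate(params: CellParameters, duration: float = 10_000.0,
                dt: float = 0.02, state: CellState | None = None) -> CellState:
    """Stimulus-free integration to (quasi-)rest from the default state."""
    s = state if state is not None else default_state(params)
    final, _, _ = integrate(s, params, duration, dt=dt)
    return final


def _elicits_ap(params: CellParameters, state: CellState, amplitude: float,
                duration: float, dt: float) -> bool:
    stim = Stimulus(amplitude=amplitude, duration=duration, onsets=(5.0,))
    _, _, rec = integrate(state.copy(), params, 60.0, dt=dt, stimulus=stim,
                          record_stride=0.5)
    return float(rec[:, S_V].max()) > -10.0


def find_stimulus_threshold(params: CellParameters,
                            state: CellState | None = None,
                            duration: float = 2.0, dt: float = 0.02,
                            tol: float = 0.25) -> float:
    """Diastolic stimulus threshold (pA/pF) by bisection on a single beat."""
    s = state if state is not None else default_state(params)
    lo, hi = 0.0, 8.0
    while not _elicits_ap(params, s, hi, duration, dt):
        hi *= 2.0
        if hi > 512.0:
            raise RuntimeError("no stimulus threshold found below 512 pA/pF")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _elicits_ap(params, s, mid, duration, dt):
            hi = mid
        else:
            lo = mid
    return hi


def default_stimulus(params: CellParameters,
                     state: CellState | None = None) -> Stimulus:
    """Rectangular 2 ms stimulus at twice the diastolic threshold."""
    thr = find_stimulus_threshold(params, state=state)
    return Stimulus(amplitude=2.0 * thr, duration=2.0)
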