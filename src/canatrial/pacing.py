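"""Pacing protocols: fixed-rate trains, dynamic-pacing ladders, S1-S2 restitution.

All protocols drive the cell with a rectangular stimulus at twice the
diastolic threshold (found once per parameter set by bisection) unless an
explicit :class:`~canatrial.cell_model.Stimulus` is supplied.  Protocols are
fully deterministic: identical inputs produce bit-identical traces, and every
protocol returns the final cell state so runs can be chained or checkpointed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from canatrial import biomarkers as bm
from canatrial.cell_model import (
    CellParameters, CellState, Stimulus, N_STATE,
    S_V, S_CAI, S_CAUP, S_CAREL,
    default_state, default_stimulus, integrate,
)

__all__ = ["Trace", "pace_fixed_pcl", "dynamic_pacing_scan",
           "s1s2_restitution", "default_s2_list"]

_PRE_STIM_PAD_MS = 5.0


@dataclass
class Trace:
    """Uniformly sampled recording of a pacing run (times in ms)."""

    t: np.ndarray
    v: np.ndarray
    ca_i: np.ndarray
    ca_up: np.ndarray
    ca_rel: np.ndarray
    stim_onsets: tuple
    pcl: float
    states: np.ndarray | None = None  # full (n, N_STATE) state history

    def __post_init__(self) -> None:
        dt = np.diff(self.t)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("trace times must be strictly increasing and uniform")
        for onset in self.stim_onsets:
            if not (self.t[0] <= onset <= self.t[-1]):
                raise ValueError("stimulus onsets must lie within the time span")

    @classmethod
    def from_states(cls, t, states, stim_onsets, pcl, keep_states=False):
        return cls(
            t=t, v=states[:, S_V].copy(), ca_i=states[:, S_CAI].copy(),
            ca_up=states[:, S_CAUP].copy(), ca_rel=states[:, S_CAREL].copy(),
            stim_onsets=tuple(stim_onsets), pcl=pcl,
            states=states if keep_states else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.t, "V_mV": self.v, "Cai_mM": self.ca_i,
            "CaNSR_mM": self.ca_up, "CaJSR_mM": self.ca_rel,
        })

    def biomarkers(self) -> pd.DataFrame:
        return bm.beat_biomarkers(self)


def _resolve_stimulus(params: CellParameters, stimulus, state) -> Stimulus:
    if stimulus is not None:
        return stimulus
    return default_stimulus(params, state=state)


def pace_fixed_pcl(params: CellParameters, pcl: float, n_beats: int,
                   record_last: int = 2, state: CellState | None = None,
                   stimulus: Stimulus | None = None, dt: float = 0.02,
                   record_stride: float = 0.1, keep_states: bool = False):
    """Pace ``n_beats`` at a fixed cycle length; record the last ``record_last``.

    Returns ``(trace, final_state)``.  The trace clock starts shortly before
    the first recorded beat (5 ms pre-stimulus padding when unrecorded beats
    precede it) so diastolic baselines are available to the biomarker layer.
    """
    if not (n_beats >= record_last >= 1):
        raise ValueError("need n_beats >= record_last >= 1")
    if pcl <= 0:
        raise ValueError("pcl must be positive")
    s = (state if state is not None else default_state(params)).copy()
    stim = _resolve_stimulus(params, stimulus, s)
    n_head = n_beats - record_last
    pad = _PRE_STIM_PAD_MS if n_head > 0 else 0.0
    if n_head > 0:
        head = Stimulus(stim.amplitude, stim.duration,
                        onsets=tuple(k * pcl for k in range(n_head)))
        s, _, _ = integrate(s, params, n_head * pcl - pad, dt=dt, stimulus=head)
    tail = Stimulus(stim.amplitude, stim.duration,
                    onsets=tuple(pad + k * pcl for k in range(record_last)))
    s, t, rec = integrate(s, params, record_last * pcl + pad, dt=dt,
                          stimulus=tail, record_stride=record_stride)
    trace = Trace.from_states(t, rec, tail.onsets, pcl, keep_states=keep_states)
    return trace, s


def _alternation_magnitude(table: pd.DataFrame) -> float:
    """|CaT-amplitude difference| of the last two beats (nM).

    CaT amplitude is finite even when a truncated APD is undefined (0 on
    capture failure), so it tracks the 2:2 rhythm through every regime.
    """
    cat = table["cat_amp_nM"].to_numpy()
    return abs(cat[-1] - cat[-2])


def dynamic_pacing_scan(params: CellParameters, pcl_ladder, beats_per_pcl: int = 50,
                        state: CellState | None = None,
                        stimulus: Stimulus | None = None, dt: float = 0.02,
                        record_stride: float = 0.1,
                        max_beats_per_pcl: int | None = None,
                        convergence_cat_tol: float = 1.0):
    """Dynamic pacing down a PCL ladder, carrying the state between rungs.

    At each PCL the cell is paced ``beats_per_pcl`` beats continuing from the
    previous PCL's final state and the biomarkers of the two final
    consecutive beats are recorded as branches 0 and 1 (the even/odd branches
    of a rate-dependence curve).  Capture failures appear as NaN biomarkers,
    never as exceptions.  Returns ``(DataFrame, final_state)``.

    Passing ``max_beats_per_pcl`` enables convergence-extended rungs: pacing
    continues in 25-beat increments until the beat-to-beat CaT alternation
    magnitude stops changing between increments (tolerance
    ``convergence_cat_tol``).  The default leaves this off: the alternating
    rhythms under study are assessed at the protocol's fixed quasi-steady
    horizon, and several are long-lived transients that an
    integrate-to-attractor protocol would suppress entirely.
    """
    pcls = [float(p) for p in pcl_ladder]
    if any(b >= a for a, b in zip(pcls, pcls[1:])):
        raise ValueError("pcl_ladder must be strictly descending")
    if beats_per_pcl < 2:
        raise ValueError("beats_per_pcl must be at least 2")
    s = (state if state is not None else default_state(params)).copy()
    stim = _resolve_stimulus(params, stimulus, s)
    rows = []
    for pcl in pcls:
        extend = (max_beats_per_pcl is not None and beats_per_pcl >= 4
                  and max_beats_per_pcl > beats_per_pcl)
        chunk = beats_per_pcl
        delivered = 0
        prev_mag = None
        while True:
            trace, s = pace_fixed_pcl(params, pcl, chunk,
                                      record_last=min(4, chunk),
                                      state=s, stimulus=stim, dt=dt,
                                      record_stride=record_stride)
            table = trace.biomarkers()
            delivered += chunk
            mag = _alternation_magnitude(table)
            converged = (prev_mag is not None
                         and abs(mag - prev_mag) <= convergence_cat_tol)
            prev_mag = mag
            if (not extend or converged
                    or delivered + 25 > max_beats_per_pcl):
                break
            chunk = 25
        for parity, row in ((0, table.iloc[-2]), (1, table.iloc[-1])):
            rows.append({
                "pcl_ms": pcl, "beat_parity": parity,
                "apd90_ms": row["apd90_ms"], "cat_amp_nM": row["cat_amp_nM"],
                "cat_decay_ms": row["cat_decay_ms"], "nsr_mM": row["nsr_mM"],
                "jsr_mM": row["jsr_mM"],
                "ap_amplitude_mV": row["ap_amplitude_mV"],
                "beats_delivered": delivered,
            })
    return pd.DataFrame(rows), s


def default_s2_list(s1_pcl: float = 1000.0) -> np.ndarray:
    """Descending S2 coupling intervals, refined where restitution is steep."""
    return np.concatenate([
        np.arange(s1_pcl, 400.0, -50.0),
        np.arange(400.0, 250.0, -25.0),
        np.arange(250.0, 150.0, -5.0),
        np.arange(150.0, 60.0, -2.0),
    ])


def s1s2_restitution(params: CellParameters, s1_pcl: float = 1000.0,
                     n_s1: int = 20, s2_list=None,
                     state: CellState | None = None,
                     stimulus: Stimulus | None = None, dt: float = 0.02,
                     record_stride: float = 0.1) -> pd.DataFrame:
    """Standard S1-S2 restitution: (DI, APD90) pairs of the premature beat.

    ``n_s1`` S1 beats at ``s1_pcl`` bring the cell to quasi-steady state (the
    S1 train is integrated once and checkpointed); each S2 then runs from that
    checkpoint.  DI is the interval from the 90%-repolarization time of the
    last S1 beat to the S2 onset; pairs where the S2 fails to capture or the
    S2 falls before full repolarization (negative DI) are excluded.
    """
    if s2_list is None:
        s2_list = default_s2_list(s1_pcl)
    s = (state if state is not None else default_state(params)).copy()
    stim = _resolve_stimulus(params, stimulus, s)
    if n_s1 > 1:
        head = Stimulus(stim.amplitude, stim.duration,
                        onsets=tuple(k * s1_pcl for k in range(n_s1 - 1)))
        s, _, _ = integrate(s, params, (n_s1 - 1) * s1_pcl, dt=dt, stimulus=head)
    rows = []
    for s2 in np.asarray(s2_list, dtype=float):
        pair = Stimulus(stim.amplitude, stim.duration, onsets=(0.0, s2))
        _, t, rec = integrate(s.copy(), params, s2 + 600.0, dt=dt,
                              stimulus=pair, record_stride=record_stride)
        v = rec[:, S_V]
        apd_s1, t_act1, _, _ = bm.apd(t, v, 0.0, s2)
        apd_s2, t_act2, amp2, _ = bm.apd(t, v, s2, None)
        if not np.isfinite(apd_s1) or not np.isfinite(apd_s2):
            continue
        t_repol = t_act1 + apd_s1
        di = s2 - t_repol
        if di <= 0:
            continue
        rows.append({"s2_ms": s2, "di_ms": di, "apd90_ms": apd_s2})
    return pd.DataFrame(rows)
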