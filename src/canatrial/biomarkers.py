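"""Per-beat scalar biomarkers from voltage / Ca2+ traces.

APD is measured from the maximum-upstroke-velocity time (not stimulus onset)
to the linearly interpolated crossing of ``V_rest + (1 - level) * amplitude``;
the Ca2+-transient decay time is the interval from the transient peak to
recovery of 90% of its amplitude.  Resting potential and diastolic Ca2+ are
sampled 1 ms before the stimulus onset.  Beats with an AP amplitude below
30 mV count as capture failures and yield NaN biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BeatBiomarkers", "apd", "cat_metrics", "sr_content",
           "beat_biomarkers", "CAPTURE_AMPLITUDE_MV"]

CAPTURE_AMPLITUDE_MV = 30.0
_UPSTROKE_WINDOW_MS = 20.0  # max-dV/dt search window after stimulus onset
_BASELINE_LEAD_MS = 1.0


@dataclass(frozen=True)
class BeatBiomarkers:
    """Scalar biomarkers of one stimulated beat (NaN where undefined)."""

    apd90: float
    ap_amplitude: float
    v_rest: float
    cat_amplitude: float     # nM
    cat_decay_time: float    # ms
    diastolic_ca: float      # nM
    nsr_content: float       # mM
    jsr_content: float       # mM
    activation_time: float   # ms, absolute on the trace clock


def _interp_crossing(t0, t1, y0, y1, level):
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def _sample_before(t, y, t_point):
    """Value just before ``t_point`` (1 ms lead, clamped to the trace start)."""
    idx = np.searchsorted(t, t_point - _BASELINE_LEAD_MS, side="right") - 1
    return y[max(idx, 0)]


def apd(t, v, stim_onset, next_onset=None, level: float = 0.9):
    """Action-potential duration at the given repolarization level (ms).

    ``t``/``v`` are full trace arrays; the beat is the window from
    ``stim_onset`` to ``next_onset`` (trace end if None).  Returns
    (duration, activation_time, amplitude, v_rest); duration is NaN when the
    beat fails to capture or never repolarizes to the level within the window.
    """
    t = np.asarray(t)
    v = np.asarray(v)
    if next_onset is None:
        next_onset = t[-1]
    i0 = np.searchsorted(t, stim_onset)
    i1 = np.searchsorted(t, next_onset)
    if i1 - i0 < 4:
        return np.nan, np.nan, np.nan, np.nan
    v_rest = _sample_before(t, v, stim_onset)
    iw = min(i0 + max(2, np.searchsorted(t[i0:i1], t[i0] + _UPSTROKE_WINDOW_MS)),
             i1 - 1)
    dvdt = np.diff(v[i0:iw]) / np.diff(t[i0:iw])
    if dvdt.size == 0:
        return np.nan, np.nan, np.nan, np.nan
    i_act = i0 + int(np.argmax(dvdt))
    t_act = t[i_act]
    seg_v = v[i0:i1]
    i_peak = i0 + int(np.argmax(seg_v))
    amplitude = v[i_peak] - v_rest
    if amplitude < CAPTURE_AMPLITUDE_MV:
        return np.nan, t_act, amplitude, v_rest
    v90 = v_rest + (1.0 - level) * amplitude
    below = np.flatnonzero(v[i_peak:i1] < v90)
    if below.size == 0:
        return np.nan, t_act, amplitude, v_rest
    ic = i_peak + below[0]
    t_cross = _interp_crossing(t[ic - 1], t[ic], v[ic - 1], v[ic], v90)
    return t_cross - t_act, t_act, amplitude, v_rest


def cat_metrics(t, ca, stim_onset, next_onset=None,
                recovery_level: float = 0.9):
    """Ca2+-transient amplitude (nM), decay time (ms) and diastolic level (nM).

    Amplitude is peak minus pre-stimulus diastolic [Ca2+]i; decay time runs
    from the peak to recovery of ``recovery_level`` of the amplitude.  A
    monotone (peak-free) segment yields amplitude 0 and NaN decay time.
    """
    t = np.asarray(t)
    ca = np.asarray(ca)
    if next_onset is None:
        next_onset = t[-1]
    i0 = np.searchsorted(t, stim_onset)
    i1 = np.searchsorted(t, next_onset)
    if i1 - i0 < 4:
        return np.nan, np.nan, np.nan
    dia = _sample_before(t, ca, stim_onset)
    i_peak = i0 + int(np.argmax(ca[i0:i1]))
    amp = ca[i_peak] - dia
    if amp <= 0 or i_peak in (i0, i1 - 1):
        return 0.0, np.nan, dia * 1e6
    target = ca[i_peak] - recovery_level * amp
    below = np.flatnonzero(ca[i_peak:i1] < target)
    if below.size == 0:
        decay = np.nan
    else:
        ic = i_peak + below[0]
        t_cross = _interp_crossing(t[ic - 1], t[ic], ca[ic - 1], ca[ic], target)
        decay = t_cross - t[i_peak]
    return amp * 1e6, decay, dia * 1e6


def sr_content(t, ca_up, ca_rel, stim_onset, reference=None):
    """End-diastolic NSR / JSR Ca2+ content (mM) just before stimulus onset.

    With ``reference=(nsr_ref, jsr_ref)`` also returns the percent change of
    the NSR content against the reference run.
    """
    nsr = float(_sample_before(np.asarray(t), np.asarray(ca_up), stim_onset))
    jsr = float(_sample_before(np.asarray(t), np.asarray(ca_rel), stim_onset))
    if reference is None:
        return nsr, jsr, np.nan
    nsr_ref = reference[0]
    return nsr, jsr, 100.0 * (nsr - nsr_ref) / nsr_ref


def beat_biomarkers(trace) -> pd.DataFrame:
    """One biomarker row per stimulated beat of a :class:`~canatrial.pacing.Trace`."""
    rows = []
    onsets = list(trace.stim_onsets)
    for k, onset in enumerate(onsets):
        nxt = onsets[k + 1] if k + 1 < len(onsets) else None
        dur, t_act, amp, v_rest = apd(trace.t, trace.v, onset, nxt)
        cat_amp, cat_decay, dia = cat_metrics(trace.t, trace.ca_i, onset, nxt)
        nsr, jsr, _ = sr_content(trace.t, trace.ca_up, trace.ca_rel, onset)
        rows.append({
            "beat": k, "stim_onset_ms": onset, "apd90_ms": dur,
            "ap_amplitude_mV": amp, "v_rest_mV": v_rest,
            "cat_amp_nM": cat_amp, "cat_decay_ms": cat_decay,
            "diastolic_ca_nM": dia, "nsr_mM": nsr, "jsr_mM": jsr,
            "activation_ms": t_act,
        })
    return pd.DataFrame(rows)
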