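"""Synthetic AP / Ca2+-transient waveforms with closed-form ground truth.

Stand-ins for simulated traces: parameterized triangular or exponential
action potentials and bi-level exponential Ca2+ transients, with optional
planted beat-to-beat alternans and additive Gaussian noise.  Every generator
returns its ground truth alongside the data so the biomarker, alternans and
node-detection layers can be tested without running the ionic model.  All
randomness is seeded and recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from canatrial.pacing import Trace

__all__ = ["SyntheticBeatSpec", "make_trace", "make_apd_map"]


@dataclass(frozen=True)
class SyntheticBeatSpec:
    """Shape parameters of a synthetic beat (voltages mV, Ca nM, times ms)."""

    v_rest: float = -80.0
    v_peak: float = 20.0
    repol_shape: str = "linear"      # "linear" | "exponential"
    repol_time: float = 200.0        # linear: fall duration; exp: time constant
    cat_diastolic: float = 100.0
    cat_amplitude: float = 500.0
    cat_tau: float = 100.0
    apd_alternans: float = 0.0       # fractional beat-to-beat APD alternation
    cat_alternans: float = 0.0       # fractional CaT-amplitude alternation
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cat_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise SD must be non-negative")
        if self.repol_shape not in ("linear", "exponential"):
            raise ValueError("repol_shape must be 'linear' or 'exponential'")
        if self.v_peak <= self.v_rest:
            raise ValueError("v_peak must exceed v_rest")


def _true_apd90(spec: SyntheticBeatSpec, repol_time: float, dt: float) -> float:
    """Closed-form APD90 of the synthetic beat.

    The rise is a one-sample jump placed ``dt`` after the stimulus onset (so
    the maximum upstroke slope falls inside the measurement window), hence
    the analytic duration carries a ``+ dt`` offset from the activation time.
    """
    if spec.repol_shape == "linear":
        return 0.9 * repol_time + dt
    # exponential fall to rest: V(t) = rest + amp*exp(-t/tau); 90% at tau*ln(10)
    return repol_time * math.log(10.0) + dt


def make_trace(spec: SyntheticBeatSpec, n_beats: int, pcl: float,
               dt: float = 0.1):
    """Generate a paced synthetic trace and its per-beat ground truth.

    Returns ``(trace, truth)`` where ``truth`` has one row per beat with the
    analytic APD90, CaT amplitude, CaT 90%-decay time and diastolic level
    (noise-free values).  Even/odd beats carry the planted alternans
    fractions: successive-beat differences equal fraction x mean value.
    """
    if n_beats < 1 or pcl <= 0:
        raise ValueError("need n_beats >= 1 and pcl > 0")
    rng = np.random.default_rng(spec.seed)
    onset_in_beat = 5.0
    n_per = int(round(pcl / dt))
    t = dt * np.arange(n_per * n_beats)
    v = np.full(t.size, spec.v_rest, dtype=float)
    ca = np.full(t.size, spec.cat_diastolic, dtype=float)
    amp_v = spec.v_peak - spec.v_rest
    truth_rows = []
    onsets = []
    for b in range(n_beats):
        sign = 1.0 if b % 2 == 0 else -1.0
        repol = spec.repol_time * (1.0 + sign * spec.apd_alternans / 2.0)
        cat_amp = spec.cat_amplitude * (1.0 + sign * spec.cat_alternans / 2.0)
        t0 = b * pcl + onset_in_beat
        onsets.append(t0)
        # waveform starts one sample after the onset: v[i0] is still resting,
        # the jump to peak occurs between i0 and i0+1
        i0 = int(round(t0 / dt)) + 1
        i_end = min((b + 1) * n_per, t.size)
        tb = dt * np.arange(i_end - i0)  # beat-local clock, exact across beats
        if spec.repol_shape == "linear":
            seg = spec.v_peak - amp_v * tb / repol
            v[i0:i_end] = np.maximum(seg, spec.v_rest)
        else:
            v[i0:i_end] = spec.v_rest + amp_v * np.exp(-tb / repol)
        ca[i0:i_end] = spec.cat_diastolic + cat_amp * np.exp(-tb / spec.cat_tau)
        truth_rows.append({
            "beat": b,
            "apd90_ms": _true_apd90(spec, repol, dt),
            "cat_amp_nM": cat_amp,
            "cat_decay_ms": spec.cat_tau * math.log(10.0),
            "diastolic_ca_nM": spec.cat_diastolic,
        })
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd, v.size)
        ca = ca + rng.normal(0.0, spec.noise_sd, ca.size)
    trace = Trace(t=t, v=v, ca_i=ca * 1e-6, ca_up=np.zeros_like(t),
                  ca_rel=np.zeros_like(t), stim_onsets=tuple(onsets), pcl=pcl)
    return trace, pd.DataFrame(truth_rows)


def make_apd_map(n_cells: int, n_beats: int, node_positions,
                 magnitude: float = 20.0, base_apd: float = 150.0,
                 dx: float = 0.167, gradient: float = 0.0):
    """Beat x cell APD matrix whose dAPD sign structure plants exact nodes.

    ``node_positions`` is either one sequence of node positions (mm), reused
    for every beat pair, or one sequence per beat pair (length
    ``n_beats - 1``) to emulate drifting nodes.  Between nodes, consecutive
    beats differ by ±2 x amplitude, with the sign flipping linearly through
    each node, so ``detect_nodes`` recovers the planted positions exactly.
    ``gradient`` adds a linear APD trend along the cable (ms/mm).

    Returns ``(matrix, x_mm)``.
    """
    x = (np.arange(n_cells) + 0.5) * dx
    length = n_cells * dx
    per_pair = (len(node_positions) == n_beats - 1
                and n_beats > 1
                and all(np.iterable(p) for p in node_positions))
    pairs = (list(node_positions) if per_pair
             else [node_positions] * max(n_beats - 1, 0))
    for nodes in pairs:
        for nd in nodes:
            if not 0.0 <= nd <= length:
                raise ValueError("node positions must lie on the cable")

    def profile(nodes):
        """Piecewise-linear alternation amplitude crossing zero at nodes."""
        if len(nodes) == 0:
            return np.full(n_cells, magnitude)
        # sign wave: start +, flip linearly through each node
        pts_x, pts_y = [0.0], [1.0]
        w = dx / 2.0
        for i, nd in enumerate(sorted(nodes)):
            s = 1.0 if i % 2 == 0 else -1.0
            pts_x += [nd - w, nd + w]
            pts_y += [s, -s]
        pts_x.append(length)
        pts_y.append(pts_y[-1])
        return magnitude * np.interp(x, pts_x, pts_y)

    mat = np.empty((n_beats, n_cells))
    mat[0] = base_apd + gradient * x
    for b in range(n_beats - 1):
        amp = profile(pairs[b])
        sign = 1.0 if b % 2 == 0 else -1.0
        mat[b + 1] = mat[b] + sign * 2.0 * amp
    return mat, x
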