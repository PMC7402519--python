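"""Beat-to-beat alternans detection, eye-type window location, restitution slope.

A biomarker sequence at fixed PCL alternates when its successive differences
are large (mean absolute difference above threshold) *and* strictly alternate
in sign.  On a rate-dependence curve (two quasi-steady branches per PCL) the
eye-type window is the maximal contiguous PCL run with separated branches:
the onset PCL is its long-PCL edge (the period-doubling bifurcation point),
the offset its short-PCL edge.  Default thresholds: 1 ms on APD90, 5 nM on
CaT amplitude — far below reported alternans magnitudes, far above numerical
jitter; both configurable.

During deep alternans the long beat may fail to repolarize to 90% before the
next stimulus, leaving its APD90 undefined (NaN) while the short beat's is
finite.  One-finite/one-NaN branch pairs with both beats captured are counted
as alternating (the separation is maximal, not absent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AlternansWindow", "detect_alternans", "alternans_window",
           "max_restitution_slope", "APD_THRESHOLD_MS", "CAT_THRESHOLD_NM"]

APD_THRESHOLD_MS = 1.0
CAT_THRESHOLD_NM = 5.0


@dataclass(frozen=True)
class AlternansWindow:
    """Contiguous PCL range with beat-to-beat alternans (eye-type)."""

    onset_pcl: float   # largest PCL with alternans
    offset_pcl: float  # smallest PCL with alternans
    magnitudes: pd.Series  # per-PCL branch separation (NaN when undefined)

    def __post_init__(self) -> None:
        if self.offset_pcl > self.onset_pcl:
            raise ValueError("offset PCL must not exceed onset PCL")

    @property
    def max_magnitude(self) -> float:
        m = self.magnitudes.dropna()
        return float(m.max()) if len(m) else float("nan")

    def to_dict(self) -> dict:
        return {"onset_pcl_ms": self.onset_pcl,
                "offset_pcl_ms": self.offset_pcl,
                "max_magnitude": self.max_magnitude}


def detect_alternans(values, threshold: float):
    """Flag beat-to-beat alternans in ``values`` (>= 4 consecutive beats).

    Returns ``(flag, magnitude)`` where magnitude is the mean absolute
    successive difference; the flag requires the mean difference to exceed
    ``threshold`` with strictly sign-alternating successive differences.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("alternans detection needs at least 4 beats")
    if not np.all(np.isfinite(v)):
        return False, float("nan")
    d = np.diff(v)
    magnitude = float(np.mean(np.abs(d)))
    if magnitude <= threshold:
        return False, magnitude
    signs = np.sign(d)
    alternating = bool(np.all(signs[1:] * signs[:-1] < 0))
    return alternating, magnitude


def _branch_alternating(row, apd_threshold, cat_threshold):
    a0, a1 = row["apd90_0"], row["apd90_1"]
    c0, c1 = row["cat_0"], row["cat_1"]
    m0, m1 = row["amp_0"], row["amp_1"]
    if np.isfinite(a0) and np.isfinite(a1) and abs(a0 - a1) > apd_threshold:
        return True
    if np.isfinite(c0) and np.isfinite(c1) and abs(c0 - c1) > cat_threshold:
        return True
    # truncated repolarization on exactly one branch of a captured pair
    if np.isnan(a0) != np.isnan(a1) and np.isfinite(m0) and np.isfinite(m1):
        return True
    return False


def alternans_window(curve: pd.DataFrame,
                     apd_threshold: float = APD_THRESHOLD_MS,
                     cat_threshold: float = CAT_THRESHOLD_NM):
    """Locate the eye-type alternans window on a rate-dependence curve.

    ``curve`` is the tidy frame produced by
    :func:`canatrial.pacing.dynamic_pacing_scan` (columns ``pcl_ms``,
    ``beat_parity``, ``apd90_ms``, ``cat_amp_nM``, ``ap_amplitude_mV``).
    Returns an :class:`AlternansWindow` for the maximal contiguous run of
    alternating PCLs, or ``None`` when no PCL alternates.
    """
    wide = curve.pivot(index="pcl_ms", columns="beat_parity")
    table = pd.DataFrame({
        "apd90_0": wide[("apd90_ms", 0)], "apd90_1": wide[("apd90_ms", 1)],
        "cat_0": wide[("cat_amp_nM", 0)], "cat_1": wide[("cat_amp_nM", 1)],
        "amp_0": wide[("ap_amplitude_mV", 0)],
        "amp_1": wide[("ap_amplitude_mV", 1)],
    }).sort_index(ascending=False)  # long -> short PCL

    flags = table.apply(
        _branch_alternating, axis=1,
        apd_threshold=apd_threshold, cat_threshold=cat_threshold,
    )
    if not flags.any():
        return None
    # maximal contiguous run of flagged PCLs (grid order, long to short)
    runs = []
    start = None
    idx = list(table.index)
    for i, pcl in enumerate(idx):
        if flags.loc[pcl] and start is None:
            start = i
        if (not flags.loc[pcl] or i == len(idx) - 1) and start is not None:
            end = i if flags.loc[pcl] else i - 1
            runs.append((start, end))
            start = None
    best = max(runs, key=lambda r: r[1] - r[0])
    sub = table.iloc[best[0]:best[1] + 1]
    mags = (sub["apd90_0"] - sub["apd90_1"]).abs()
    return AlternansWindow(onset_pcl=float(sub.index.max()),
                           offset_pcl=float(sub.index.min()),
                           magnitudes=mags)


def max_restitution_slope(pairs) -> float:
    """Maximum slope of an APD90 restitution curve by centered differences.

    ``pairs`` is an iterable of (DI, APD90) or a DataFrame with columns
    ``di_ms``/``apd90_ms``.  Pairs are sorted by DI; duplicate DIs raise.
    """
    if isinstance(pairs, pd.DataFrame):
        di = pairs["di_ms"].to_numpy(dtype=float)
        ap = pairs["apd90_ms"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be (DI, APD90) tuples")
        di, ap = arr[:, 0], arr[:, 1]
    if di.size < 3:
        raise ValueError("need at least 3 restitution pairs")
    order = np.argsort(di)
    di, ap = di[order], ap[order]
    if np.any(np.diff(di) == 0):
        raise ValueError("duplicate DI values in restitution pairs")
    slopes = np.gradient(ap, di)
    return float(np.max(slopes))
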