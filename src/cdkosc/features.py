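"""Extrema-based oscillation feature extraction.

Given any trajectory, the leading transient is discarded and local maxima
and minima of the Cdk1 series are located by three-point comparison, then
refined to sub-sample accuracy by fitting a parabola through each extremum
and its two neighbours.  The period is the mean peak-to-peak interval, the
amplitude the mean peak minus the mean trough, and the S- and M-phase
proxies are the mean rising (trough -> peak) and falling (peak -> trough)
segment durations.  A trajectory counts as oscillating when at least three
full cycles are present, the peak intervals are regular (coefficient of
variation below 5%) and the amplitude exceeds a floor that separates
genuine limit cycles from numerical ripple near a Hopf boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import InsufficientDataError
from .trajectory import Trajectory

__all__ = ["OscillationFeatures", "extract_features"]

#: Default amplitude floor: 1e-3 of the canonical 32 nM activation threshold.
DEFAULT_AMPLITUDE_FLOOR = 0.032


@dataclass(frozen=True)
class OscillationFeatures:
    """Period, amplitude, phase durations and oscillation flag of a trajectory."""

    oscillating: bool
    period: float
    amplitude: float
    s_duration: float  # mean rising (accumulation) segment, min
    m_duration: float  # mean falling (degradation) segment, min
    n_cycles: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _refine(t: np.ndarray, x: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample extremum location via a parabola through points i-1, i, i+1."""
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = (y0 - 2.0 * y1 + y2)
    if denom == 0.0:
        return t1, y1
    # uniform-spacing vertex formula; guard against drifting outside the bracket
    h = 0.5 * (t2 - t0)
    shift = 0.5 * (y0 - y2) / denom * h
    shift = float(np.clip(shift, t0 - t1, t2 - t1))
    tv = t1 + shift
    yv = y1 - 0.125 * (y0 - y2) ** 2 / denom
    return tv, yv


def extract_features(
    traj: Trajectory,
    transient_fraction: float = 0.5,
    amplitude_floor: float = DEFAULT_AMPLITUDE_FLOOR,
    min_cycles: int = 3,
    cv_tol: float = 0.05,
) -> OscillationFeatures:
    """Extract oscillation features from a trajectory.

    Raises :class:`~cdkosc.errors.InsufficientDataError` when the retained
    window is too short to analyze at all — distinct from returning a
    non-oscillating result.
    """
    if not 0.0 <= transient_fraction < 1.0:
        raise ValueError("transient_fraction must lie in [0, 1)")
    t, x = traj.t, traj.cdk1
    t_cut = t[0] + transient_fraction * (t[-1] - t[0])
    keep = t >= t_cut
    t, x = t[keep], x[keep]
    if len(t) < 16:
        raise InsufficientDataError(
            f"only {len(t)} samples after transient removal; cannot analyze"
        )

    ds = np.sign(np.diff(x))
    # carry the sign through flat runs so plateaus do not split extrema
    for i in range(1, len(ds)):
        if ds[i] == 0:
            ds[i] = ds[i - 1]
    sign_flip = np.nonzero((ds[:-1] != ds[1:]) & (ds[:-1] != 0))[0] + 1
    peaks_i = [i for i in sign_flip if ds[i - 1] > 0]
    troughs_i = [i for i in sign_flip if ds[i - 1] < 0]

    not_osc = OscillationFeatures(False, math.nan, math.nan, math.nan, math.nan, 0)
    if len(peaks_i) < 2 or len(troughs_i) < 1:
        return not_osc

    peaks = np.array([_refine(t, x, i) for i in peaks_i])
    troughs = np.array([_refine(t, x, i) for i in troughs_i])
    intervals = np.diff(peaks[:, 0])
    n_cycles = len(intervals)
    if n_cycles < 1:
        return not_osc

    period = float(np.mean(intervals))
    amplitude = float(np.mean(peaks[:, 1]) - np.mean(troughs[:, 1]))
    cv = float(np.std(intervals) / period) if period > 0 else math.inf

    # rising (S) and falling (M) segment durations between alternating extrema
    s_durs, m_durs = [], []
    tp, tt = peaks[:, 0], troughs[:, 0]
    for t_tr in tt:
        nxt = tp[tp > t_tr]
        if len(nxt):
            s_durs.append(nxt[0] - t_tr)
    for t_pk in tp:
        nxt = tt[tt > t_pk]
        if len(nxt):
            m_durs.append(nxt[0] - t_pk)
    s_duration = float(np.mean(s_durs)) if s_durs else math.nan
    m_duration = float(np.mean(m_durs)) if m_durs else math.nan

    oscillating = (amplitude > amplitude_floor and n_cycles >= min_cycles
                   and cv < cv_tol)
    return OscillationFeatures(bool(oscillating), period, amplitude,
                               s_duration, m_duration, int(n_cycles))
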