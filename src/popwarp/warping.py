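"""Piecewise-linear landmark time warping.

A warp maps template time to trial time through fixed landmarks: the
identity outside the two peak intervals, and within each interval a linear
interpolation that moves the peak landmark by the trial's shift.  Warps are
strictly increasing bijections of [0, T] as long as each shift stays inside
the open interval around its peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class WarpSpec:
    """Landmarks of the two-peak warp: 0 < t1l < tpeak1 < t1r <= t2l < tpeak2 < t2r < T."""

    t1l: float
    tpeak1: float
    t1r: float
    t2l: float
    tpeak2: float
    t2r: float
    T: float

    def __post_init__(self):
        seq = (0.0, self.t1l, self.tpeak1, self.t1r, self.t2l, self.tpeak2,
               self.t2r, self.T)
        strict = [(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (6, 7)]
        for i, j in strict:
            if not seq[i] < seq[j]:
                raise ValueError(f"landmarks must increase: {seq}")
        if not self.t1r <= self.t2l:  # shared boundary allowed
            raise ValueError("peak-1 interval must end before peak-2 interval begins")

    def peak1_domain(self, margin: float = 0.0) -> tuple:
        """Open admissible interval for the peak-1 shift (optionally shrunk)."""
        return (self.t1l - self.tpeak1 + margin, self.t1r - self.tpeak1 - margin)

    def peak2_domain(self, margin: float = 0.0) -> tuple:
        return (self.t2l - self.tpeak2 + margin, self.t2r - self.tpeak2 - margin)


class PiecewiseLinearWarp:
    """Monotone piecewise-linear map through the warp join-points.

    ``__call__`` maps template time to trial time; :meth:`inverse` maps
    back.  Both are exact piecewise-linear interpolations through the
    (swapped) join-points.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.x = x
        self.y = y

    def __call__(self, t):
        return np.interp(t, self.x, self.y)

    def inverse(self, s):
        return np.interp(s, self.y, self.x)

    def inverted(self) -> "PiecewiseLinearWarp":
        return PiecewiseLinearWarp(self.y.copy(), self.x.copy())


def build_warp(spec: WarpSpec, peak1: float, peak2: float) -> PiecewiseLinearWarp:
    """Warp with join-points (0,0), (t1l,t1l), (tpeak1, tpeak1+peak1),
    (t1r,t1r), (t2l,t2l), (tpeak2, tpeak2+peak2), (t2r,t2r), (T,T).

    Shifts outside the open admissible intervals are rejected (the warp
    would not be strictly increasing).
    """
    d1lo, d1hi = spec.peak1_domain()
    d2lo, d2hi = spec.peak2_domain()
    if not (d1lo < peak1 < d1hi):
        raise ValueError(f"peak-1 shift {peak1} outside open domain ({d1lo}, {d1hi})")
    if not (d2lo < peak2 < d2hi):
        raise ValueError(f"peak-2 shift {peak2} outside open domain ({d2lo}, {d2hi})")
    x = np.array([0.0, spec.t1l, spec.tpeak1, spec.t1r, spec.t2l, spec.tpeak2,
                  spec.t2r, spec.T])
    y = np.array([0.0, spec.t1l, spec.tpeak1 + peak1, spec.t1r, spec.t2l,
                  spec.tpeak2 + peak2, spec.t2r, spec.T])
    if spec.t1r == spec.t2l:  # shared boundary: drop the duplicate joint
        keep = np.ones(len(x), bool)
        keep[4] = False
        x, y = x[keep], y[keep]
    return PiecewiseLinearWarp(x, y)


def invert_warp(warp: PiecewiseLinearWarp) -> PiecewiseLinearWarp:
    """Inverse warp: the piecewise-linear map through the swapped join-points."""
    return warp.inverted()


def warp_spike_times(times, inverse_warp) -> np.ndarray:
    """Map spike times to template coordinates through the inverse warp.

    Order is preserved and the window endpoints are fixed.  ``inverse_warp``
    may be a :class:`PiecewiseLinearWarp` (its inverse is NOT taken again;
    pass ``invert_warp(w)`` or ``w.inverse``) or any callable.
    """
    t = np.asarray(times, dtype=float)
    return inverse_warp(t) if callable(inverse_warp) else inverse_warp.inverse(t)
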