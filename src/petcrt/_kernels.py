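"""Compiled per-event pulse evaluation and discriminator kernels.

The photodetector pulse is a sum of bi-exponential SER shapes.  Between two
consecutive (sorted) photoelectron times the pulse has the exact closed form

    P(T_j + d) = C * (u_j * exp(-d/Sd) - v_j * exp(-d/Sr)),   0 < d <= dt_j

where u_j = sum_{i<=j} exp(-(T_j - T_i)/Sd) (v_j likewise with Sr) obey the
stable recurrences u_{j} = u_{j-1} * exp(-dt/Sd) + 1.  C normalizes to
SER-peak units (one photoelectron peaks at amplitude 1).  Walking segments
gives the global maximum analytically (each segment is unimodal) and each
threshold's first crossing by bisection on the segment's rising branch.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _ser_scale(sr, sd):
    """1 / (peak of the unit-area SER * (Sd - Sr)) -> SER-peak units."""
    tstar = sr * sd / (sd - sr) * np.log(sd / sr)
    peak = (np.exp(-tstar / sd) - np.exp(-tstar / sr)) / (sd - sr)
    return 1.0 / (peak * (sd - sr))


@njit(cache=True)
def _segment_value(u, v, d, sr, sd, scale):
    return scale * (u * np.exp(-d / sd) - v * np.exp(-d / sr))


@njit(cache=True)
def pulse_max_sorted(t, sr, sd):
    """Exact maximum amplitude (SER-peak units) of the summed pulse."""
    scale = _ser_scale(sr, sd)
    kfac = sr * sd / (sd - sr)
    m = len(t)
    u = 0.0
    v = 0.0
    best = 0.0
    for j in range(m):
        if j > 0:
            dt = t[j] - t[j - 1]
            u *= np.exp(-dt / sd)
            v *= np.exp(-dt / sr)
        u += 1.0
        v += 1.0
        dend = t[j + 1] - t[j] if j < m - 1 else np.inf
        dstar = kfac * np.log(v * sd / (u * sr))
        if dstar > 0.0:
            dm = dstar if dstar < dend else dend
            p = _segment_value(u, v, dm, sr, sd, scale)
            if p > best:
                best = p
    return best


@njit(cache=True)
def _bisect_segment(u, v, lo, hi, target, sr, sd, scale):
    """First crossing of target on the rising branch [lo, hi] of a segment."""
    flo = _segment_value(u, v, lo, sr, sd, scale) if lo > 0.0 else scale * (u - v)
    # target is between f(lo) and f(hi) by construction
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        fmid = _segment_value(u, v, mid, sr, sd, scale)
        if fmid < target:
            lo = mid
            flo = fmid
        else:
            hi = mid
        if hi - lo < 1e-9 * (1.0 + hi):
            break
    return 0.5 * (lo + hi)


@njit(cache=True)
def first_crossings_sorted(t, targets, sr, sd, out):
    """First times the summed pulse reaches each ascending target level.

    Writes trigger times into ``out`` (NaN where the pulse never reaches the
    level).  ``targets`` must be ascending and positive.
    """
    scale = _ser_scale(sr, sd)
    kfac = sr * sd / (sd - sr)
    m = len(t)
    nlev = len(targets)
    for n in range(nlev):
        out[n] = np.nan
    u = 0.0
    v = 0.0
    idx = 0
    for j in range(m):
        if idx >= nlev:
            break
        if j > 0:
            dt = t[j] - t[j - 1]
            u *= np.exp(-dt / sd)
            v *= np.exp(-dt / sr)
        u += 1.0
        v += 1.0
        dend = t[j + 1] - t[j] if j < m - 1 else np.inf
        dstar = kfac * np.log(v * sd / (u * sr))
        if dstar <= 0.0:
            continue  # pulse only falls in this segment
        dm = dstar if dstar < dend else dend
        rise_max = _segment_value(u, v, dm, sr, sd, scale)
        while idx < nlev and targets[idx] <= rise_max:
            out[idx] = t[j] + _bisect_segment(
                u, v, 0.0, dm, targets[idx], sr, sd, scale
            )
            idx += 1


@njit(cache=True)
def batch_triggers(times_flat, starts, counts, sr, sd, levels, is_cf, pmax_out, trig_out):
    """Per-event pulse maximum and trigger times for a batch.

    ``levels`` is the ascending trigger table: fractions of the pulse maximum
    if ``is_cf`` else absolute amplitudes in SER-peak units.  Events with an
    empty train get pmax 0 and all-NaN triggers.
    """
    n_events = len(starts)
    nlev = len(levels)
    targets = np.empty(nlev)
    for e in range(n_events):
        c = counts[e]
        if c == 0:
            pmax_out[e] = 0.0
            for n in range(nlev):
                trig_out[e, n] = np.nan
            continue
        seg = np.sort(times_flat[starts[e] : starts[e] + c])
        pmax = pulse_max_sorted(seg, sr, sd)
        pmax_out[e] = pmax
        if is_cf:
            for n in range(nlev):
                targets[n] = levels[n] * pmax
        else:
            for n in range(nlev):
                targets[n] = levels[n]
        first_crossings_sorted(seg, targets, sr, sd, trig_out[e])
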