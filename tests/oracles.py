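"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain Python loops and explicit sorting so
it shares no code path with the package: percentiles by direct order-statistic
interpolation, medians by sorting, candidate detection by examining every
difference triple, and de-duplication by explicit group construction.
"""

from __future__ import annotations

import math


def percentile_linear(values, p):
    s = sorted(values)
    n = len(s)
    if n == 1:
        return s[0]
    pos = p / 100.0 * (n - 1)
    lo = int(math.floor(pos))
    frac = pos - lo
    if lo + 1 >= n:
        return s[-1]
    return s[lo] + frac * (s[lo + 1] - s[lo])


def median_by_sorting(values):
    s = sorted(values)
    n = len(s)
    mid = n // 2
    if n % 2 == 1:
        return s[mid]
    return 0.5 * (s[mid - 1] + s[mid])


def mad_by_sorting(values):
    med = median_by_sorting(values)
    return median_by_sorting([abs(v - med) for v in values])


def brute_force_candidates(dff):
    """Every index t whose difference triple matches (+, <=0, -)."""
    out = []
    for t in range(len(dff)):
        if t < 1 or t > len(dff) - 3:
            continue
        d_prev = dff[t] - dff[t - 1]
        d_here = dff[t + 1] - dff[t]
        d_next = dff[t + 2] - dff[t + 1]
        if d_prev > 0 and d_here <= 0 and d_next < 0:
            out.append(t)
    return out


def brute_force_dedup(retained, dff, threshold):
    """Group construction by explicit scanning; one event per group, highest
    amplitude, earliest on ties."""
    groups = []
    for t in retained:
        start_new = True
        if groups:
            prev = groups[-1][-1]
            between = [dff[i] for i in range(prev + 1, t)]
            if not between or min(between) >= threshold:
                start_new = False
        if start_new:
            groups.append([t])
        else:
            groups[-1].append(t)
    events = []
    for group in groups:
        best = group[0]
        for t in group[1:]:
            if dff[t] > dff[best]:
                best = t
        events.append(best)
    return events


def brute_force_detect(intensities, f0_percentile=5.0, mad_multiplier=2.0, floor=0.1):
    """Full reference detector; returns (event indices, threshold)."""
    f0 = percentile_linear(list(intensities), f0_percentile)
    dff = [(f - f0) / f0 for f in intensities]
    mad = mad_by_sorting(dff)
    threshold = mad_multiplier * mad
    if threshold < floor:
        threshold = floor
    candidates = brute_force_candidates(dff)
    retained = [t for t in candidates if dff[t] > threshold]
    return brute_force_dedup(retained, dff, threshold), threshold
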