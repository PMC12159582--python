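"""1D interval algebra along a cast ray.

The ray parameter t is distance from the ray origin in mm.  A watertight
solid intersected by a ray whose origin lies outside the solid is "inside"
between alternating pairs of surface crossings, so a sorted hit list maps
directly to a union of disjoint intervals.  An odd number of retained hits
means the solid extends past the range cutoff, which closes the final
interval at ``max_range``.
"""

from __future__ import annotations

import numpy as np


def intervals_from_hits(hits, max_range: float):
    """Inside-intervals of a solid from sorted crossing distances.

    Hits must be ascending, positive and <= max_range (the caster
    guarantees this).  Returns a list of (t_in, t_out) tuples.
    """
    hits = list(hits)
    out = []
    for i in range(0, len(hits) - 1, 2):
        out.append((float(hits[i]), float(hits[i + 1])))
    if len(hits) % 2 == 1:
        out.append((float(hits[-1]), float(max_range)))
    return [(a, b) for a, b in out if b > a]


def complement(intervals, max_range: float):
    """[0, max_range] minus the given disjoint sorted intervals."""
    out = []
    cursor = 0.0
    for a, b in intervals:
        if a > cursor:
            out.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < max_range:
        out.append((cursor, max_range))
    return out


def intersect(first, second):
    """Intersection of two disjoint sorted interval lists."""
    out = []
    i = j = 0
    while i < len(first) and j < len(second):
        a0, a1 = first[i]
        b0, b1 = second[j]
        lo, hi = max(a0, b0), min(a1, b1)
        if hi > lo:
            out.append((lo, hi))
        if a1 <= b1:
            i += 1
        else:
            j += 1
    return out


def subtract(first, second, max_range: float):
    """Set difference first \\ second within [0, max_range]."""
    return intersect(first, complement(second, max_range))


def total_length(intervals) -> float:
    return float(sum(b - a for a, b in intervals))


def sample_points(intervals, step: float | None = None):
    """Representative t-values per interval: endpoints and midpoint, plus
    optional densification at ``step`` mm spacing (thin defects would be
    under-sampled by endpoints alone)."""
    ts = []
    for a, b in intervals:
        ts.extend((a, 0.5 * (a + b), b))
        if step is not None and b - a > step:
            n = int(np.floor((b - a) / step))
            ts.extend(a + np.arange(1, n + 1) * step)
    return np.unique(np.asarray(ts, dtype=float))
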