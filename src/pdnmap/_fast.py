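"""Optional numba-accelerated kernels for the edge-correction hot path.

Pure-numpy fallbacks live in :mod:`geometry`; these kernels only change
speed, not results (same even-odd rule, same angle grid).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly wherever numba exists
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(fn):
            return fn
        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _arc_fractions_nb(cx, cy, d, ex0, ey0, ex1, ey1, resolution):
    m = cx.size
    ne = ex0.size
    out = np.empty(m)
    cos_t = np.empty(resolution)
    sin_t = np.empty(resolution)
    for a in range(resolution):
        t = 2.0 * math.pi * a / resolution
        cos_t[a] = math.cos(t)
        sin_t[a] = math.sin(t)
    for i in range(m):
        inside = 0
        for a in range(resolution):
            x = cx[i] + d[i] * cos_t[a]
            y = cy[i] + d[i] * sin_t[a]
            crossings = 0
            for e in range(ne):
                y0 = ey0[e]
                y1 = ey1[e]
                if (y0 > y) != (y1 > y):
                    xint = ex0[e] + (y - y0) * (ex1[e] - ex0[e]) / (y1 - y0)
                    if x < xint:
                        crossings += 1
            if crossings & 1:
                inside += 1
        out[i] = inside / resolution
    return out


@njit(cache=True)
def _boundary_distance_nb(px, py, ex0, ey0, ex1, ey1):
    n = px.size
    ne = ex0.size
    out = np.empty(n)
    for i in range(n):
        best = 1e300
        for e in range(ne):
            dx = ex1[e] - ex0[e]
            dy = ey1[e] - ey0[e]
            seg2 = dx * dx + dy * dy
            if seg2 > 0.0:
                t = ((px[i] - ex0[e]) * dx + (py[i] - ey0[e]) * dy) / seg2
                if t < 0.0:
                    t = 0.0
                elif t > 1.0:
                    t = 1.0
            else:
                t = 0.0
            qx = ex0[e] + t * dx - px[i]
            qy = ey0[e] + t * dy - py[i]
            d2 = qx * qx + qy * qy
            if d2 < best:
                best = d2
        out[i] = math.sqrt(best)
    return out
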