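"""Independent brute-force oracles used only by the tests.

The edge-correction fraction is derived here by a different route than the
package: the set of circle angles theta whose point (x + d cos t, y + d sin t)
satisfies each of the four half-plane constraints is built as explicit angular
intervals, and the four sets are intersected.  K-functions are direct
double-loop sums per radius.
"""

from __future__ import annotations

import math

import numpy as np

TWO_PI = 2.0 * math.pi


def _cos_ge(c: float) -> list[tuple[float, float]]:
    # {t in [0, 2pi): cos t >= c}
    if c <= -1.0:
        return [(0.0, TWO_PI)]
    if c > 1.0:
        return []
    a = math.acos(c)
    return [(0.0, a), (TWO_PI - a, TWO_PI)]


def _cos_le(c: float) -> list[tuple[float, float]]:
    if c >= 1.0:
        return [(0.0, TWO_PI)]
    if c < -1.0:
        return []
    a = math.acos(c)
    return [(a, TWO_PI - a)]


def _sin_ge(c: float) -> list[tuple[float, float]]:
    if c <= -1.0:
        return [(0.0, TWO_PI)]
    if c > 1.0:
        return []
    a = math.asin(c)  # in [-pi/2, pi/2]
    if a >= 0.0:
        return [(a, math.pi - a)]
    return [(0.0, math.pi - a), (TWO_PI + a, TWO_PI)]


def _sin_le(c: float) -> list[tuple[float, float]]:
    if c >= 1.0:
        return [(0.0, TWO_PI)]
    if c < -1.0:
        return []
    a = math.asin(c)
    if a > 0.0:
        return [(0.0, a), (math.pi - a, TWO_PI)]
    return [(math.pi - a, TWO_PI + a)]  # may wrap past 2pi; normalized below


def _normalize(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for lo, hi in intervals:
        if hi <= lo:
            continue
        if hi > TWO_PI:
            out.append((lo, TWO_PI))
            out.append((0.0, hi - TWO_PI))
        else:
            out.append((lo, hi))
    return sorted(out)


def _intersect(a: list[tuple[float, float]], b: list[tuple[float, float]]):
    out = []
    for lo1, hi1 in a:
        for lo2, hi2 in b:
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            if hi > lo:
                out.append((lo, hi))
    return out


def circle_fraction_oracle(x: float, y: float, d: float, width: float, height: float) -> float:
    """Fraction of the circle of radius d at (x, y) inside [0,w]x[0,h]."""
    sets = [
        _normalize(_cos_ge(-x / d)),          # x + d cos t >= 0
        _normalize(_cos_le((width - x) / d)),  # x + d cos t <= width
        _normalize(_sin_ge(-y / d)),           # y + d sin t >= 0
        _normalize(_sin_le((height - y) / d)),  # y + d sin t <= height
    ]
    current = sets[0]
    for s in sets[1:]:
        current = _intersect(current, s)
    return sum(hi - lo for lo, hi in current) / TWO_PI


def k_univariate_oracle(
    points: np.ndarray, width: float, height: float, radii: np.ndarray, unbiased: bool = False
) -> np.ndarray:
    """Direct O(n^2 * len(radii)) sum of the edge-corrected univariate K."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    area = width * height
    denom = n * (n - 1) if unbiased else n * n
    out = np.zeros(len(radii))
    for ridx, r in enumerate(radii):
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = math.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1])
                if d <= r:
                    frac = circle_fraction_oracle(pts[i, 0], pts[i, 1], d, width, height)
                    total += 1.0 / frac
        out[ridx] = area / denom * total
    return out


def k_bivariate_oracle(
    big: np.ndarray, small: np.ndarray, width: float, height: float, radii: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Direct double-loop K_bs, K_sb and their count-weighted combination."""
    big = np.asarray(big, dtype=float)
    small = np.asarray(small, dtype=float)
    n_b, n_s = big.shape[0], small.shape[0]
    area = width * height
    k_bs = np.zeros(len(radii))
    k_sb = np.zeros(len(radii))
    for ridx, r in enumerate(radii):
        t_bs = 0.0
        t_sb = 0.0
        for i in range(n_b):
            for j in range(n_s):
                d = math.hypot(big[i, 0] - small[j, 0], big[i, 1] - small[j, 1])
                if d <= r:
                    t_bs += 1.0 / circle_fraction_oracle(big[i, 0], big[i, 1], d, width, height)
                    t_sb += 1.0 / circle_fraction_oracle(
                        small[j, 0], small[j, 1], d, width, height
                    )
        k_bs[ridx] = area / (n_b * n_s) * t_bs
        k_sb[ridx] = area / (n_b * n_s) * t_sb
    k_biv = (n_b * k_sb + n_s * k_bs) / (n_b + n_s)
    return k_bs, k_sb, k_biv
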