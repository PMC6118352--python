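"""Isotropic (Ripley) edge correction for rectangular windows.

A particle near the window boundary has part of its distance-``d`` search
circle outside the window, so its neighbour count is biased low.  The
isotropic correction weights each ordered pair (i, j) by

    w_ij = 1 / (fraction of the circumference of the circle centred at x_i
                with radius ||x_i - x_j|| that lies inside the window)

The fraction is computed analytically for a rectangle by inclusion-exclusion
over the four half-plane constraints: each side at distance ``e < d`` removes
an arc of angle ``2*arccos(e/d)``; when the circle also covers a corner the
two adjacent arcs overlap by ``pi/2 - arcsin(ex/d) - arcsin(ey/d)``, which is
added back.  Opposite sides can never be violated simultaneously by a point
inside the window, so pairwise corner terms complete the expansion exactly,
for any radius.
"""

from __future__ import annotations

import warnings

import numpy as np

from .patterns import StudyRegion, ValidationError

__all__ = ["edge_weight", "interior_fraction", "EdgeCorrectionRangeWarning"]

_TWO_PI = 2.0 * np.pi


class EdgeCorrectionRangeWarning(UserWarning):
    """Radii exceed the range where the rectangle correction is well-behaved."""


def interior_fraction(
    x: np.ndarray, y: np.ndarray, d: np.ndarray, region: StudyRegion
) -> np.ndarray:
    """Fraction of each circle's circumference lying inside the region.

    ``x``, ``y`` are circle-centre coordinates (must be inside the region) and
    ``d`` the radii; all three broadcast together.  Returns values in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    x, y, d = np.broadcast_arrays(x, y, d)
    if np.any(d <= 0):
        raise ValidationError("circle radius (pair distance) must be > 0")

    w, h = float(region.width), float(region.height)
    ex = (x, w - x)  # distances to the two vertical sides
    ey = (y, h - y)  # distances to the two horizontal sides

    exterior = np.zeros(d.shape, dtype=float)
    for e in (*ex, *ey):
        m = e < d
        if np.any(m):
            exterior[m] += 2.0 * np.arccos(e[m] / d[m])
    for cx in ex:
        for cy in ey:
            m = cx * cx + cy * cy < d * d
            if np.any(m):
                dm = d[m]
                exterior[m] -= (
                    0.5 * np.pi - np.arcsin(cx[m] / dm) - np.arcsin(cy[m] / dm)
                )
    frac = 1.0 - exterior / _TWO_PI
    # guard against rounding slightly past the ends of the valid range
    return np.clip(frac, 0.0, 1.0)


def edge_weight(point: tuple[float, float], distance: float, region: StudyRegion) -> float:
    """Isotropic edge-correction weight for one circle centre and radius.

    Returns ``w >= 1``; raises if the circle's circumference lies entirely
    outside the window (possible only when the radius exceeds the distance to
    the farthest corner), where the weight is undefined.
    """
    px, py = float(point[0]), float(point[1])
    if not region.contains(np.array([[px, py]]))[0]:
        raise ValidationError(f"circle centre {point!r} lies outside the region")
    if not np.isfinite(distance) or distance <= 0:
        raise ValidationError(f"distance must be finite and > 0, got {distance!r}")
    frac = float(interior_fraction(np.array(px), np.array(py), np.array(distance), region))
    if frac <= 0.0:
        raise ValidationError(
            f"circle of radius {distance} nm at {point!r} lies entirely outside the "
            "region; edge weight is degenerate"
        )
    return 1.0 / frac


def warn_if_radii_exceed_validity(radii: np.ndarray, region: StudyRegion) -> None:
    """Warn once when radii pass min(width, height)/4.

    Beyond a quarter of the short side the isotropic correction remains exact
    for the rectangle but becomes variance-inflating; standard practice keeps
    r below this bound (240 nm on a 1000 nm sheet satisfies it).
    """
    limit = min(region.width, region.height) / 4.0
    rmax = float(np.max(radii))
    if rmax > limit:
        warnings.warn(
            f"max radius {rmax:g} nm exceeds min(width, height)/4 = {limit:g} nm; "
            "edge-corrected estimates at large r are noisy",
            EdgeCorrectionRangeWarning,
            stacklevel=3,
        )
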