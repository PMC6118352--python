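"""Univariate nanoclustering statistics: Ripley's K, L(r)-r, envelopes, L_max.

The estimator for a pattern of n particles in a window of area A is

    K(r) = A n^-2  sum_{i != j} w_ij 1(||x_i - x_j|| <= r)

with the isotropic edge weight w_ij centred at x_i.  Note the n^-2
normalization (matching the published form) rather than the more common
unbiased 1/(n(n-1)); the latter is available via ``unbiased=True``.

L(r)-r = sqrt(K(r)/pi) - r is the variance-stabilized transform: 0 under
complete spatial randomness (CSR), positive under clustering at scale r.
Observed curves are standardized by pointwise division by the upper bound of
a Monte Carlo CSR envelope (99% by convention), so the confidence bound maps
to 1 and peak values above 1 — the L_max statistic — indicate statistically
meaningful nanoclustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .edge import interior_fraction, warn_if_radii_exceed_validity
from .patterns import (
    InsufficientPointsError,
    PointPattern,
    RadialCurve,
    StudyRegion,
    ValidationError,
    radius_grid,
    same_grid,
)

__all__ = [
    "Envelope",
    "LMax",
    "k_univariate",
    "l_transform",
    "csr_envelope",
    "standardize",
    "lmax",
]

DEFAULT_ENVELOPE_FLOOR = 1e-6


def _weighted_count_leq(d: np.ndarray, w: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """sum of w over pairs with distance <= r, for each r (ties count as within)."""
    order = np.argsort(d, kind="stable")
    ds = d[order]
    cw = np.concatenate(([0.0], np.cumsum(w[order])))
    return cw[np.searchsorted(ds, radii, side="right")]


def _k_values_univariate(
    pts: np.ndarray, region: StudyRegion, radii: np.ndarray, unbiased: bool
) -> np.ndarray:
    n = pts.shape[0]
    dmat = cdist(pts, pts)
    ii, jj = np.nonzero(~np.eye(n, dtype=bool))
    d = dmat[ii, jj]
    keep = d <= radii[-1]
    ii, d = ii[keep], d[keep]
    if d.size:
        w = 1.0 / interior_fraction(pts[ii, 0], pts[ii, 1], d, region)
        counts = _weighted_count_leq(d, w, radii)
    else:
        counts = np.zeros(radii.shape)
    denom = n * (n - 1) if unbiased else n * n
    return region.area / denom * counts


def _l_values_univariate(
    pts: np.ndarray, region: StudyRegion, radii: np.ndarray, unbiased: bool = False
) -> np.ndarray:
    k = _k_values_univariate(pts, region, radii, unbiased)
    return np.sqrt(k / np.pi) - radii


def k_univariate(
    pattern: PointPattern,
    radii: np.ndarray | None = None,
    *,
    unbiased: bool = False,
) -> RadialCurve:
    """Edge-corrected univariate K-function of one pattern.

    Parameters
    ----------
    pattern
        At least two points.
    radii
        Strictly increasing evaluation grid in nm; defaults to 1..240 nm.
    unbiased
        Use the 1/(n(n-1)) normalization instead of the published n^-2.
    """
    if pattern.n < 2:
        raise InsufficientPointsError(
            f"univariate K needs n >= 2 points, sheet {pattern.sheet_id!r} has {pattern.n}"
        )
    radii = radius_grid() if radii is None else np.asarray(radii, dtype=float)
    warn_if_radii_exceed_validity(radii, pattern.region)
    values = _k_values_univariate(pattern.points, pattern.region, radii, unbiased)
    return RadialCurve(radii, values, "K")


def l_transform(k_curve: RadialCurve) -> RadialCurve:
    """Variance-stabilized transform L(r) - r = sqrt(K(r)/pi) - r."""
    if np.any(k_curve.values < 0):
        raise ValidationError("K(r) must be non-negative for the L transform")
    values = np.sqrt(k_curve.values / np.pi) - k_curve.radii
    return RadialCurve(k_curve.radii, values, "L_minus_r")


@dataclass
class Envelope:
    """Pointwise upper Monte Carlo confidence bound for an L(r)-r statistic.

    ``bound`` holds the nearest-rank upper quantile at ``level`` across
    ``n_sim`` null simulations, clamped below by ``floor`` (radii where the
    clamp was active are marked in ``clamped``; standardized values there are
    reported but flagged).
    """

    radii: np.ndarray
    bound: np.ndarray
    level: float
    n_sim: int
    floor: float
    clamped: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValidationError(f"level must be in (0, 1), got {self.level}")
        if self.n_sim < 1:
            raise ValidationError("n_sim must be >= 1")
        if not np.all(np.isfinite(self.bound)) or np.any(self.bound <= 0):
            raise ValidationError("envelope bound must be finite and positive after clamping")

    def as_curve(self) -> RadialCurve:
        return RadialCurve(self.radii, self.bound, "envelope", flags=self.clamped.copy())


def _envelope_from_sims(
    sims: np.ndarray, radii: np.ndarray, level: float, floor: float
) -> Envelope:
    n_sim = sims.shape[0]
    rank = int(np.ceil(level * n_sim))  # nearest-rank upper quantile, 1-based
    rank = min(max(rank, 1), n_sim)
    bound = np.sort(sims, axis=0)[rank - 1]
    clamped = bound < floor
    bound = np.maximum(bound, floor)
    return Envelope(radii, bound, level, n_sim, floor, clamped)


def csr_envelope(
    n: int,
    region: StudyRegion,
    radii: np.ndarray | None = None,
    level: float = 0.99,
    n_sim: int = 1000,
    seed=None,
    floor: float = DEFAULT_ENVELOPE_FLOOR,
    unbiased: bool = False,
) -> Envelope:
    """Upper CSR envelope for the univariate L(r)-r at a fixed point count.

    Simulates ``n_sim`` binomial (conditioned-on-n) CSR patterns of exactly
    ``n`` uniform points, computes each L(r)-r, and returns the pointwise
    nearest-rank upper quantile at ``level``.  Deterministic given ``seed``.
    """
    if n < 2:
        raise InsufficientPointsError(f"CSR envelope needs n >= 2, got {n}")
    if n_sim < 1:
        raise ValidationError("n_sim must be >= 1")
    radii = radius_grid() if radii is None else np.asarray(radii, dtype=float)
    rng = np.random.default_rng(seed)
    lo = np.zeros(2)
    hi = np.array([region.width, region.height])
    sims = np.empty((n_sim, radii.size))
    for s in range(n_sim):
        pts = rng.uniform(lo, hi, size=(n, 2))
        sims[s] = _l_values_univariate(pts, region, radii, unbiased)
    return _envelope_from_sims(sims, radii, level, floor)


def standardize(l_curve: RadialCurve, envelope: Envelope) -> RadialCurve:
    """Divide an L(r)-r curve pointwise by the envelope bound.

    The confidence bound maps to exactly 1, so standardized values above 1
    are significant at the envelope's level.  Radii where the envelope floor
    clamp was active are flagged on the returned curve.
    """
    if not same_grid(l_curve.radii, envelope.radii):
        raise ValidationError("curve and envelope must share the same radius grid")
    values = l_curve.values / envelope.bound
    return RadialCurve(l_curve.radii, values, "standardized", flags=envelope.clamped.copy())


@dataclass(frozen=True)
class LMax:
    """Peak of a standardized curve and the radius where it occurs."""

    value: float
    radius: float


def lmax(std_curve: RadialCurve) -> LMax:
    """Maximum standardized value over the grid; ties go to the smallest radius."""
    i = int(np.argmax(std_curve.values))
    return LMax(float(std_curve.values[i]), float(std_curve.radii[i]))
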