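"""Core domain types for immunogold point-pattern analysis.

An electron-microscopy experiment yields, per plasma-membrane (PM) sheet, the
centroid coordinates of antibody-conjugated gold nanoparticles inside a
rectangular study region (by convention ~1000 x 1000 nm, i.e. 1 um^2 of basal
membrane).  Coordinates are continuous, in nanometres, with the origin at the
lower-left corner of the region; the region is closed, so particles digitized
exactly on the boundary are kept.

These containers perform eager validation so that every downstream statistic
can assume finite, in-region coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "InsufficientPointsError",
    "StudyRegion",
    "PointPattern",
    "BivariatePattern",
    "RadialCurve",
    "CURVE_KINDS",
    "radius_grid",
]


class ValidationError(ValueError):
    """An input violates a documented invariant (bad coordinates, grids, bounds)."""


class InsufficientPointsError(ValidationError):
    """A pattern has too few points for the requested statistic."""


@dataclass(frozen=True)
class StudyRegion:
    """Rectangular observation window on one PM sheet, in nm.

    The default 1000 x 1000 nm window corresponds to the conventional 1 um^2
    counting area used for gold-density estimates.
    """

    width: float = 1000.0
    height: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("width", "height"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"StudyRegion.{name} must be finite and > 0, got {v!r}")

    @property
    def area(self) -> float:
        """Window area in nm^2."""
        return float(self.width) * float(self.height)

    @property
    def area_um2(self) -> float:
        """Window area in um^2 (1 um^2 = 1e6 nm^2)."""
        return self.area / 1e6

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of rows of ``xy`` inside the closed region."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return (
            (xy[:, 0] >= 0.0)
            & (xy[:, 0] <= self.width)
            & (xy[:, 1] >= 0.0)
            & (xy[:, 1] <= self.height)
        )


@dataclass
class PointPattern:
    """One channel's gold-particle coordinates on one PM sheet.

    Parameters
    ----------
    points
        Array-like of shape ``(n, 2)`` with x, y in nm.
    region
        The observation window; every point must lie inside it (closed).
    sheet_id, condition
        Free-text identifiers for the replicate sheet and experimental
        condition (treatment / dose / time label).
    """

    points: np.ndarray
    region: StudyRegion = field(default_factory=StudyRegion)
    sheet_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = np.empty((0, 2), dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(f"points must have shape (n, 2), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValidationError(f"non-finite coordinate in sheet {self.sheet_id!r}")
        inside = self.region.contains(pts)
        if not np.all(inside):
            bad = int(np.nonzero(~inside)[0][0])
            raise ValidationError(
                f"point {tuple(pts[bad])} of sheet {self.sheet_id!r} lies outside the "
                f"{self.region.width} x {self.region.height} nm region"
            )
        self.points = pts

    @property
    def n(self) -> int:
        """Number of gold particles."""
        return int(self.points.shape[0])

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


@dataclass
class BivariatePattern:
    """Paired big/small gold channels sharing one region on one sheet.

    ``big`` is the 6 nm gold channel (e.g. anti-GFP), ``small`` the 2 nm gold
    channel (e.g. anti-RFP).  Both channels must reference the identical
    observation window.
    """

    big: PointPattern
    small: PointPattern

    def __post_init__(self) -> None:
        if self.big.region != self.small.region:
            raise ValidationError("big and small channels must share the same region")

    @property
    def region(self) -> StudyRegion:
        return self.big.region

    @property
    def sheet_id(self) -> str:
        return self.big.sheet_id or self.small.sheet_id

    @property
    def condition(self) -> str:
        return self.big.condition or self.small.condition

    @property
    def n_big(self) -> int:
        return self.big.n

    @property
    def n_small(self) -> int:
        return self.small.n


CURVE_KINDS = ("K", "L_minus_r", "standardized", "envelope")


def radius_grid(r_min: float = 1.0, r_max: float = 240.0, step: float = 1.0) -> np.ndarray:
    """The analysis radius grid, default 1..240 nm at 1 nm increments."""
    if not (r_min > 0 and r_max > r_min and step > 0):
        raise ValidationError(f"invalid radius grid ({r_min}, {r_max}, {step})")
    return np.arange(r_min, r_max + 0.5 * step, step, dtype=float)


@dataclass
class RadialCurve:
    """A statistic sampled on a radius grid.

    ``kind`` selects the units contract: ``"K"`` is in nm^2, ``"L_minus_r"``
    and ``"envelope"`` in nm, ``"standardized"`` dimensionless.  ``flags``
    optionally marks radii whose value involved the envelope floor clamp and
    should be interpreted with care.
    """

    radii: np.ndarray
    values: np.ndarray
    kind: str
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float).ravel()
        v = np.asarray(self.values, dtype=float).ravel()
        if self.kind not in CURVE_KINDS:
            raise ValidationError(f"kind must be one of {CURVE_KINDS}, got {self.kind!r}")
        if r.size == 0:
            raise ValidationError("empty radius grid")
        if v.shape != r.shape:
            raise ValidationError(f"values length {v.size} != radii length {r.size}")
        if not np.all(np.isfinite(r)) or not np.all(np.isfinite(v)):
            raise ValidationError("radii and values must be finite")
        if np.any(np.diff(r) <= 0):
            raise ValidationError("radii must be strictly increasing")
        self.radii = r
        self.values = v
        if self.flags is not None:
            f = np.asarray(self.flags, dtype=bool).ravel()
            if f.shape != r.shape:
                raise ValidationError("flags length must match radii")
            self.flags = f

    def __len__(self) -> int:
        return int(self.radii.size)


def same_grid(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two radius grids are identical."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return a.shape == b.shape and bool(np.array_equal(a, b))
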