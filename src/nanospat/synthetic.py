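"""Synthetic point-pattern generators emulating immunogold TEM data.

Three statistical structures cover what the analysis pipeline assumes:

* complete spatial randomness (CSR) — uniform points, the null model;
* a Neyman-Scott (Thomas-like) cluster process — uniform parent points with
  offspring displaced by an isotropic Gaussian (sigma, nm) or uniformly in a
  hard disc, emulating membrane nanodomains at the 5-40 nm dispersion scales
  the statistics probe;
* bivariate patterns whose two channels place a tunable fraction of their
  clusters around shared parents, emulating co-localized versus independent
  protein/lipid populations.

Offspring are wrapped toroidally so the realized intensity matches the
specification without edge-density artifacts.  Independent Bernoulli thinning
models incomplete immunogold labeling.  All generators are bit-reproducible
from (spec, seed); ground-truth parent assignments are retained for recovery
tests.

Defaults mirror the study's scale: 1000 x 1000 nm sheets, >= 15 sheets per
condition, and order 10^2-10^3 gold particles per sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .patterns import BivariatePattern, PointPattern, StudyRegion, ValidationError

__all__ = [
    "ClusterProcessSpec",
    "BivariateSpec",
    "ClusteredPattern",
    "BivariateTruth",
    "gen_csr",
    "gen_clustered",
    "gen_bivariate",
    "thin",
]


@dataclass(frozen=True)
class ClusterProcessSpec:
    """Parameters of the parent-offspring cluster process for one channel.

    Parameters
    ----------
    parents
        Fixed number of cluster centres per sheet (used when
        ``parent_intensity_um2`` is None).
    parent_intensity_um2
        Alternatively, Poisson parent intensity per um^2.
    offspring
        Offspring per parent: exact count when ``offspring_poisson`` is
        False, Poisson mean otherwise.
    sigma / disc_radius
        Isotropic Gaussian dispersion, or hard cluster radius (uniform in
        disc), in nm.  Exactly one must be set.
    background_fraction
        Expected fraction of final points contributed by a CSR background.
    labeling_efficiency
        Independent retention probability per point, in (0, 1].
    """

    parents: int = 25
    parent_intensity_um2: float | None = None
    offspring: float = 6.0
    offspring_poisson: bool = False
    sigma: float | None = 10.0
    disc_radius: float | None = None
    background_fraction: float = 0.0
    labeling_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.parent_intensity_um2 is None and self.parents < 0:
            raise ValidationError("parents must be >= 0")
        if self.parent_intensity_um2 is not None and self.parent_intensity_um2 < 0:
            raise ValidationError("parent_intensity_um2 must be >= 0")
        if self.offspring < 0:
            raise ValidationError("offspring must be >= 0")
        if (self.sigma is None) == (self.disc_radius is None):
            raise ValidationError("set exactly one of sigma or disc_radius")
        scale = self.sigma if self.sigma is not None else self.disc_radius
        if scale is not None and scale <= 0:
            raise ValidationError("cluster dispersion scale must be > 0")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValidationError("background_fraction must be in [0, 1)")
        if not (0.0 < self.labeling_efficiency <= 1.0):
            raise ValidationError("labeling_efficiency must be in (0, 1]")


@dataclass(frozen=True)
class BivariateSpec:
    """Two channels with a tunable fraction of shared cluster parents."""

    shared_fraction: float = 1.0
    big: ClusterProcessSpec = field(default_factory=ClusterProcessSpec)
    small: ClusterProcessSpec = field(default_factory=ClusterProcessSpec)

    def __post_init__(self) -> None:
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValidationError("shared_fraction must be in [0, 1]")


class ClusteredPattern(NamedTuple):
    """A generated pattern plus its ground truth."""

    pattern: PointPattern
    parents: np.ndarray  # (P, 2) parent coordinates
    parent_index: np.ndarray  # per retained point: parent row, or -1 for background


class BivariateTruth(NamedTuple):
    pattern: BivariatePattern
    big: ClusteredPattern
    small: ClusteredPattern
    n_shared_parents: int


def gen_csr(
    n: int,
    region: StudyRegion | None = None,
    seed=None,
    sheet_id: str = "",
    condition: str = "",
) -> PointPattern:
    """``n`` i.i.d. uniform points on the region (binomial CSR)."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    region = region or StudyRegion()
    rng = np.random.default_rng(seed)
    pts = rng.uniform([0.0, 0.0], [region.width, region.height], size=(int(n), 2))
    return PointPattern(pts, region, sheet_id=sheet_id, condition=condition)


def _offspring_counts(rng: np.random.Generator, spec: ClusterProcessSpec, n_parents: int):
    if spec.offspring_poisson:
        return rng.poisson(spec.offspring, size=n_parents)
    k = spec.offspring
    if abs(k - round(k)) > 1e-9:
        raise ValidationError("fixed offspring count must be an integer")
    return np.full(n_parents, int(round(k)), dtype=int)


def _displace(rng: np.random.Generator, m: int, spec: ClusterProcessSpec) -> np.ndarray:
    if spec.sigma is not None:
        return rng.normal(0.0, spec.sigma, size=(m, 2))
    rad = spec.disc_radius * np.sqrt(rng.uniform(size=m))
    ang = rng.uniform(0.0, 2.0 * np.pi, size=m)
    return np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])


def _realize(
    rng: np.random.Generator,
    spec: ClusterProcessSpec,
    parents: np.ndarray,
    region: StudyRegion,
    sheet_id: str,
    condition: str,
) -> ClusteredPattern:
    wh = np.array([region.width, region.height])
    counts = _offspring_counts(rng, spec, parents.shape[0])
    parent_index = np.repeat(np.arange(parents.shape[0]), counts)
    offspring = parents[parent_index] + _displace(rng, parent_index.size, spec)
    offspring %= wh  # toroidal wrap keeps realized intensity on-spec

    if spec.background_fraction > 0.0:
        f = spec.background_fraction
        n_bg = rng.poisson(offspring.shape[0] * f / (1.0 - f))
        bg = rng.uniform([0.0, 0.0], wh, size=(n_bg, 2))
        offspring = np.vstack([offspring, bg])
        parent_index = np.concatenate([parent_index, np.full(n_bg, -1, dtype=int)])

    if spec.labeling_efficiency < 1.0:
        keep = rng.uniform(size=offspring.shape[0]) < spec.labeling_efficiency
        offspring = offspring[keep]
        parent_index = parent_index[keep]

    pattern = PointPattern(offspring, region, sheet_id=sheet_id, condition=condition)
    return ClusteredPattern(pattern, parents, parent_index)


def gen_clustered(
    spec: ClusterProcessSpec,
    region: StudyRegion | None = None,
    seed=None,
    sheet_id: str = "",
    condition: str = "",
) -> ClusteredPattern:
    """One clustered sheet: uniform parents, displaced offspring, optional
    CSR background and labeling-efficiency thinning."""
    region = region or StudyRegion()
    rng = np.random.default_rng(seed)
    if spec.parent_intensity_um2 is not None:
        n_parents = rng.poisson(spec.parent_intensity_um2 * region.area_um2)
    else:
        n_parents = int(spec.parents)
    parents = rng.uniform([0.0, 0.0], [region.width, region.height], size=(n_parents, 2))
    return _realize(rng, spec, parents, region, sheet_id, condition)


def gen_bivariate(
    spec: BivariateSpec,
    region: StudyRegion | None = None,
    seed=None,
    sheet_id: str = "",
    condition: str = "",
) -> BivariateTruth:
    """One two-channel sheet with ``shared_fraction`` of cluster parents in common.

    A shared fraction of 0 gives fully independent channels; 1 centres every
    cluster of both channels on common parents (maximal co-clustering).
    """
    region = region or StudyRegion()
    rng = np.random.default_rng(seed)
    wh = np.array([region.width, region.height])

    def _parent_count(cspec: ClusterProcessSpec) -> int:
        if cspec.parent_intensity_um2 is not None:
            return int(rng.poisson(cspec.parent_intensity_um2 * region.area_um2))
        return int(cspec.parents)

    p_big = _parent_count(spec.big)
    p_small = _parent_count(spec.small)
    n_shared = int(round(spec.shared_fraction * min(p_big, p_small)))
    shared = rng.uniform([0.0, 0.0], wh, size=(n_shared, 2))
    parents_big = np.vstack([shared, rng.uniform([0.0, 0.0], wh, size=(p_big - n_shared, 2))])
    parents_small = np.vstack(
        [shared, rng.uniform([0.0, 0.0], wh, size=(p_small - n_shared, 2))]
    )
    big = _realize(rng, spec.big, parents_big, region, sheet_id, condition)
    small = _realize(rng, spec.small, parents_small, region, sheet_id, condition)
    bp = BivariatePattern(big.pattern, small.pattern)
    return BivariateTruth(bp, big, small, n_shared)


def thin(pattern: PointPattern, efficiency: float, seed=None) -> PointPattern:
    """Independent Bernoulli retention of each point (labeling efficiency)."""
    if not (0.0 < efficiency <= 1.0):
        raise ValidationError(f"efficiency must be in (0, 1], got {efficiency!r}")
    if efficiency == 1.0:
        return PointPattern(
            pattern.points.copy(), pattern.region, pattern.sheet_id, pattern.condition
        )
    rng = np.random.default_rng(seed)
    keep = rng.uniform(size=pattern.n) < efficiency
    return PointPattern(
        pattern.points[keep], pattern.region, pattern.sheet_id, pattern.condition
    )
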