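"""Group-level pooling and significance tests across replicate PM sheets.

A condition is summarized over >= 15 sheets as mean +/- SEM of a per-sheet
scalar (L_max, LBI, gold density).  Curve-level differences between two
conditions are tested with a residual bootstrap for replicated K/L curves:

  * observed statistic  T = integral of (Lbar_a(r) - Lbar_b(r))^2 dr, where
    each group mean is weighted by sheet point counts (w_i = n_i / sum n);
  * null distribution: pool each sheet's residual curve (curve minus its own
    group's weighted mean), resample residuals with replacement into two
    pseudo-groups of the original sizes, recompute T, repeat n_boot times;
  * p = (1 + #{T* >= T_obs}) / (n_boot + 1)  (add-one convention).

Gold-count (density) differences across conditions use classical one-way
ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .patterns import PointPattern, RadialCurve, ValidationError, same_grid
from .univariate import _l_values_univariate

__all__ = [
    "GroupSummary",
    "BootstrapResult",
    "AnovaResult",
    "density",
    "group_summary",
    "bootstrap_compare",
    "bootstrap_vs_csr",
    "anova_densities",
]


def density(pattern: PointPattern) -> float:
    """Gold particles per um^2 of study region (n=350 on 1000x1000 nm -> 350)."""
    area = pattern.region.area_um2
    if area <= 0:
        raise ValidationError("region area must be positive")
    return pattern.n / area


@dataclass
class GroupSummary:
    """Mean +/- SEM of one per-sheet scalar over a condition's sheets."""

    condition: str
    values: np.ndarray
    mean: float
    sem: float
    n_sheets: int


def group_summary(condition: str, values: Sequence[float]) -> GroupSummary:
    v = np.asarray(list(values), dtype=float)
    if v.size < 1:
        raise ValidationError("group summary needs at least one sheet")
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return GroupSummary(condition, v, float(np.mean(v)), sem, int(v.size))


def _curve_matrix(curves: Sequence[RadialCurve]) -> tuple[np.ndarray, np.ndarray]:
    if len(curves) == 0:
        raise ValidationError("empty curve group")
    radii = curves[0].radii
    for c in curves[1:]:
        if not same_grid(c.radii, radii):
            raise ValidationError("all curves in a comparison must share the radius grid")
    return radii, np.vstack([c.values for c in curves])


def _weights(counts: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "points":
        total = counts.sum()
        if total <= 0:
            raise ValidationError("point-count weighting needs positive counts")
        return counts / total
    if weighting == "equal":
        return np.full(counts.size, 1.0 / counts.size)
    raise ValidationError(f"weighting must be 'points' or 'equal', got {weighting!r}")


def _t_statistic(
    mean_a: np.ndarray, mean_b: np.ndarray, radii: np.ndarray, mask: np.ndarray
) -> float:
    diff = (mean_a - mean_b) ** 2
    return float(np.trapezoid(diff[mask], radii[mask]))


@dataclass
class BootstrapResult:
    """Outcome of a curve-level bootstrap comparison."""

    t_obs: float
    p_value: float
    n_boot: int
    weighting: str
    r_range: tuple[float, float]


def bootstrap_compare(
    curves_a: Sequence[RadialCurve],
    counts_a: Sequence[int],
    curves_b: Sequence[RadialCurve],
    counts_b: Sequence[int],
    n_boot: int = 1000,
    seed=None,
    r_range: tuple[float, float] | None = None,
    weighting: str = "points",
) -> BootstrapResult:
    """Residual-bootstrap test for a difference between two groups of curves.

    Each group needs >= 2 sheets on a shared radius grid; ``counts`` are the
    per-sheet particle numbers used for variance-motivated weighting.
    Deterministic given ``seed``.
    """
    if len(curves_a) < 2 or len(curves_b) < 2:
        raise ValidationError("bootstrap_compare needs >= 2 sheets per group")
    if len(curves_a) != len(counts_a) or len(curves_b) != len(counts_b):
        raise ValidationError("each curve needs a matching point count")
    radii, va = _curve_matrix(curves_a)
    radii_b, vb = _curve_matrix(curves_b)
    if not same_grid(radii, radii_b):
        raise ValidationError("groups must share the radius grid")
    ca = np.asarray(list(counts_a), dtype=float)
    cb = np.asarray(list(counts_b), dtype=float)
    if r_range is None:
        mask = np.ones(radii.size, dtype=bool)
        r_range = (float(radii[0]), float(radii[-1]))
    else:
        mask = (radii >= r_range[0]) & (radii <= r_range[1])
        if mask.sum() < 2:
            raise ValidationError(f"r_range {r_range} covers fewer than 2 grid radii")

    mean_a = _weights(ca, weighting) @ va
    mean_b = _weights(cb, weighting) @ vb
    t_obs = _t_statistic(mean_a, mean_b, radii, mask)

    residuals = np.vstack([va - mean_a, vb - mean_b])
    counts = np.concatenate([ca, cb])
    ka, kb = va.shape[0], vb.shape[0]
    k = ka + kb
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, k, size=k)
        ra, rb = residuals[idx[:ka]], residuals[idx[ka:]]
        wa = _weights(counts[idx[:ka]], weighting)
        wb = _weights(counts[idx[ka:]], weighting)
        t_star = _t_statistic(wa @ ra, wb @ rb, radii, mask)
        if t_star >= t_obs:
            exceed += 1
    p = (1 + exceed) / (n_boot + 1)
    return BootstrapResult(t_obs, p, n_boot, weighting, r_range)


def bootstrap_vs_csr(
    curves: Sequence[RadialCurve],
    counts: Sequence[int],
    region,
    n_boot: int = 200,
    seed=None,
    r_range: tuple[float, float] | None = None,
    weighting: str = "points",
) -> BootstrapResult:
    """One-group test of departure from CSR.

    T = integral of the (weighted) group-mean L(r)-r squared; the null
    distribution re-simulates groups of CSR sheets with the observed per-sheet
    point counts.  Provided as the companion mode to the two-group comparison
    for designs without a contemporaneous control group.
    """
    if len(curves) < 2:
        raise ValidationError("bootstrap_vs_csr needs >= 2 sheets")
    radii, v = _curve_matrix(curves)
    c = np.asarray(list(counts), dtype=float)
    if r_range is None:
        mask = np.ones(radii.size, dtype=bool)
        r_range = (float(radii[0]), float(radii[-1]))
    else:
        mask = (radii >= r_range[0]) & (radii <= r_range[1])
    zero = np.zeros(radii.size)
    t_obs = _t_statistic(_weights(c, weighting) @ v, zero, radii, mask)
    rng = np.random.default_rng(seed)
    lo = np.zeros(2)
    hi = np.array([region.width, region.height])
    w = _weights(c, weighting)
    exceed = 0
    for _ in range(n_boot):
        sims = np.vstack(
            [
                _l_values_univariate(rng.uniform(lo, hi, size=(int(ni), 2)), region, radii)
                for ni in c
            ]
        )
        if _t_statistic(w @ sims, zero, radii, mask) >= t_obs:
            exceed += 1
    p = (1 + exceed) / (n_boot + 1)
    return BootstrapResult(t_obs, p, n_boot, weighting, r_range)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    n_groups: int


def anova_densities(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA on per-sheet densities (or any per-sheet scalar)."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValidationError("every ANOVA group needs >= 2 sheets")
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(float(f), float(p), len(arrays))
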