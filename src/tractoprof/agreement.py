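"""Tract-to-tract agreement metrics: Dice, density correlation, bundle adjacency.

These are the macrostructural reproducibility measures used to compare two
reconstructions of the same tract (repeated computation, or test vs retest):

* Dice volume overlap of the binary masks, 2|A∩B| / (|A|+|B|).
* Density correlation: Pearson correlation of per-voxel streamline counts
  over the union of the two supports.  Restricting to the union keeps the
  statistic from being inflated by shared empty space while still counting
  voxels where the tracts disagree.
* Bundle adjacency: the average distance of disagreement, in mm.  Over the
  voxels of A not in B, take the mean world-space distance to the nearest
  voxel centre of B; symmetrically for B \\ A; average the two directional
  means.  Identical masks have adjacency 0.

A profile correlation (Pearson over the two 100-node profiles) completes the
microstructural side.  Statistics that are undefined for the given inputs
(zero variance, empty masks) raise :class:`UndefinedMetricError` rather than
silently returning NaN; the report builder records them as flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import FrameMismatchError, UndefinedMetricError, ValidationError
from .io_formats import ScalarMap, grids_equal
from .profiling import TractProfile

__all__ = [
    "AgreementReport",
    "dice_coefficient",
    "density_correlation",
    "bundle_adjacency",
    "profile_correlation",
    "compare_tracts",
]


@dataclass
class AgreementReport:
    """Agreement metrics between two reconstructions of one tract.

    ``None`` entries mark metrics undefined for the inputs (with the reason
    recorded in ``undefined``).
    """

    dice: float
    bundle_adjacency_mm: float
    density_correlation: float | None = None
    profile_correlation: float | None = None
    undefined: dict = None

    def __post_init__(self) -> None:
        if self.undefined is None:
            self.undefined = {}


def _binary(mask: ScalarMap | np.ndarray) -> np.ndarray:
    values = mask.values if isinstance(mask, ScalarMap) else np.asarray(mask)
    return values > 0


def _check_grids(a: ScalarMap, b: ScalarMap) -> None:
    if isinstance(a, ScalarMap) and isinstance(b, ScalarMap):
        if not grids_equal(a.grid, b.grid):
            raise FrameMismatchError("masks are on different grids")


def dice_coefficient(a: ScalarMap | np.ndarray, b: ScalarMap | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks."""
    _check_grids(a, b)
    ma, mb = _binary(a), _binary(b)
    if ma.shape != mb.shape:
        raise FrameMismatchError("mask shapes differ")
    na, nb = int(ma.sum()), int(mb.sum())
    if na == 0 and nb == 0:
        raise UndefinedMetricError("Dice undefined for two empty masks")
    return 2.0 * int((ma & mb).sum()) / (na + nb)


def density_correlation(a: ScalarMap | np.ndarray, b: ScalarMap | np.ndarray) -> float:
    """Pearson correlation of streamline counts over the union of supports."""
    _check_grids(a, b)
    ca = a.values if isinstance(a, ScalarMap) else np.asarray(a, dtype=float)
    cb = b.values if isinstance(b, ScalarMap) else np.asarray(b, dtype=float)
    if ca.shape != cb.shape:
        raise FrameMismatchError("mask shapes differ")
    union = (ca > 0) | (cb > 0)
    if not union.any():
        raise UndefinedMetricError("density correlation undefined: both counts empty")
    x, y = ca[union], cb[union]
    if x.std() == 0 or y.std() == 0:
        raise UndefinedMetricError("density correlation undefined: zero variance over the union support")
    return float(np.corrcoef(x, y)[0, 1])


def bundle_adjacency(a: ScalarMap, b: ScalarMap) -> float:
    """Average distance of disagreement between two binary masks, in mm."""
    _check_grids(a, b)
    ma, mb = _binary(a), _binary(b)
    if ma.shape != mb.shape:
        raise FrameMismatchError("mask shapes differ")
    if not ma.any() or not mb.any():
        raise ValidationError("bundle adjacency needs two nonempty masks")
    if np.array_equal(ma, mb):
        return 0.0
    grid = a.grid if isinstance(a, ScalarMap) else b.grid
    world_a = grid.voxel_to_world(np.argwhere(ma))
    world_b = grid.voxel_to_world(np.argwhere(mb))

    def directional(only: np.ndarray, others_world: np.ndarray) -> float:
        # mean nearest-centre distance from voxels unique to one mask
        idx = np.argwhere(only)
        if idx.size == 0:
            return 0.0
        d, _ = cKDTree(others_world).query(grid.voxel_to_world(idx))
        return float(np.mean(d))

    d_ab = directional(ma & ~mb, world_b)
    d_ba = directional(mb & ~ma, world_a)
    return 0.5 * (d_ab + d_ba)


def profile_correlation(p: TractProfile | np.ndarray, q: TractProfile | np.ndarray) -> float:
    """Pearson correlation between two along-tract profiles."""
    x = p.values if isinstance(p, TractProfile) else np.asarray(p, dtype=float)
    y = q.values if isinstance(q, TractProfile) else np.asarray(q, dtype=float)
    if isinstance(p, TractProfile) and isinstance(q, TractProfile):
        if p.metric_name != q.metric_name:
            raise ValidationError("profiles measure different metrics")
    if x.shape != y.shape:
        raise ValidationError("profiles have different lengths")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValidationError("profiles contain non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedMetricError("profile correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def compare_tracts(
    binary_a: ScalarMap,
    binary_b: ScalarMap,
    count_a: ScalarMap | None = None,
    count_b: ScalarMap | None = None,
    profile_a: TractProfile | None = None,
    profile_b: TractProfile | None = None,
) -> AgreementReport:
    """Build the full agreement report; undefined metrics become flags."""
    report = AgreementReport(
        dice=dice_coefficient(binary_a, binary_b),
        bundle_adjacency_mm=bundle_adjacency(binary_a, binary_b),
    )
    if count_a is not None and count_b is not None:
        try:
            report.density_correlation = density_correlation(count_a, count_b)
        except UndefinedMetricError as exc:
            report.undefined["density_correlation"] = str(exc)
    if profile_a is not None and profile_b is not None:
        try:
            report.profile_correlation = profile_correlation(profile_a, profile_b)
        except UndefinedMetricError as exc:
            report.undefined["profile_correlation"] = str(exc)
    return report
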